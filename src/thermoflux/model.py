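"""Core data model for stoichiometric metabolic networks.

A :class:`MetabolicModel` is the central in-memory container used by every
stage of the pipeline: it holds metabolites, reactions (stoichiometry, flux
bounds, gene-protein-reaction rules), an objective reaction and optional
extra linear constraints over fluxes (used e.g. for yield caps that must
scale with uptake).

Conventions
-----------
* Flux units are mmol gDW^-1 h^-1; biomass/growth flux is h^-1.
* Exchange reactions are written ``met[e] ->`` with positive flux =
  secretion and negative flux = uptake.
* Compartments are restricted to ``c`` (cytosol) and ``e`` (extracellular).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

COMPARTMENTS = ("c", "e")

DEFAULT_BOUND = 1000.0


class RuleSyntaxError(ValueError):
    """Raised for a malformed gene-association expression."""


class ModelStructureError(ValueError):
    """Raised when an operation references undeclared model components."""


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<op>[&|()])|(?P<and>\band\b)|(?P<or>\bor\b)"
                       r"|(?P<gene>[A-Za-z0-9_.\-]+))")


def _tokenize_rule(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"bad token at position {pos} in rule {text!r}")
        if m.group("op"):
            tokens.append(m.group("op"))
        elif m.group("and"):
            tokens.append("&")
        elif m.group("or"):
            tokens.append("|")
        else:
            tokens.append(("g", m.group("gene")))  # type: ignore[arg-type]
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class GeneRule:
    """Boolean gene-association expression over gene identifiers.

    The expression tree uses nested tuples: ``("gene", id)``,
    ``("and", (children...))`` and ``("or", (children...))``.  ``expr is
    None`` encodes the empty rule (no gene associated), which always
    evaluates to True: reactions without genes can never be disabled by a
    gene deletion.
    """

    expr: tuple | None = None

    # -- parsing ------------------------------------------------------------
    @classmethod
    def parse(cls, text: str | None) -> "GeneRule":
        """Parse ``&``/``|``/parenthesis syntax (``and``/``or`` accepted).

        ``&`` binds tighter than ``|``, as in Table-style rules such as
        ``Tsac_1550 & Tsac_1551 & Tsac_1552 & Tsac_1553``.
        """
        if text is None or not text.strip():
            return cls(None)
        tokens = _tokenize_rule(text)
        expr, rest = cls._parse_or(tokens)
        if rest:
            raise RuleSyntaxError(f"trailing tokens {rest!r} in rule {text!r}")
        return cls(expr)

    @staticmethod
    def _parse_or(tokens: list) -> tuple[tuple, list]:
        left, tokens = GeneRule._parse_and(tokens)
        parts = [left]
        while tokens and tokens[0] == "|":
            nxt, tokens = GeneRule._parse_and(tokens[1:])
            parts.append(nxt)
        if len(parts) == 1:
            return parts[0], tokens
        return ("or", tuple(parts)), tokens

    @staticmethod
    def _parse_and(tokens: list) -> tuple[tuple, list]:
        left, tokens = GeneRule._parse_atom(tokens)
        parts = [left]
        while tokens and tokens[0] == "&":
            nxt, tokens = GeneRule._parse_atom(tokens[1:])
            parts.append(nxt)
        if len(parts) == 1:
            return parts[0], tokens
        return ("and", tuple(parts)), tokens

    @staticmethod
    def _parse_atom(tokens: list) -> tuple[tuple, list]:
        if not tokens:
            raise RuleSyntaxError("unexpected end of rule")
        tok = tokens[0]
        if tok == "(":
            inner, rest = GeneRule._parse_or(tokens[1:])
            if not rest or rest[0] != ")":
                raise RuleSyntaxError("unbalanced parenthesis in gene rule")
            return inner, rest[1:]
        if isinstance(tok, tuple) and tok[0] == "g":
            return ("gene", tok[1]), tokens[1:]
        raise RuleSyntaxError(f"unexpected token {tok!r} in gene rule")

    # -- semantics ----------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.expr is None

    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing in the rule."""
        out: set[str] = set()

        def walk(node: tuple) -> None:
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        if self.expr is not None:
            walk(self.expr)
        return frozenset(out)

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction is still catalysed under the deletion set.

        A gene literal is False iff deleted; the empty rule is True.
        """
        deleted = set(deleted_genes)

        def walk(node: tuple) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in deleted
            if kind == "and":
                return all(walk(c) for c in node[1])
            return any(walk(c) for c in node[1])

        if self.expr is None:
            return True
        return walk(self.expr)

    def to_string(self) -> str:
        def walk(node: tuple, parent: str) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            sep = " & " if kind == "and" else " | "
            body = sep.join(walk(c, kind) for c in node[1])
            # parenthesise an OR inside an AND
            if kind == "or" and parent == "and":
                return f"({body})"
            return body

        if self.expr is None:
            return ""
        return walk(self.expr, "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition like ``C6H12O6`` into a dict."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    annotations: dict = field(default_factory=dict)

    def elements(self) -> dict[str, int] | None:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a gene rule.

    ``stoichiometry`` maps metabolite id -> signed coefficient
    (negative = consumed, positive = produced).  Exchange reactions are
    single-metabolite drains flagged ``is_exchange``.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = field(default_factory=GeneRule)
    is_exchange: bool = False
    annotations: dict = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class LinearConstraint:
    """Extra inequality/equality over reaction fluxes: sum(coef*v) sense rhs."""

    coefficients: dict[str, float]
    sense: str  # "<=", ">=", "=="
    rhs: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad constraint sense {self.sense!r}")


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None
    extra_constraints: list[LinearConstraint] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_rule.genes()
        return frozenset(out)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assemble_stoichiometric_matrix(model: MetabolicModel):
    """Build the S matrix (metabolites x reactions) as a dense ndarray.

    Returns ``(S, met_ids, rxn_ids)`` where entry ``S[i, j]`` is the signed
    coefficient of metabolite ``met_ids[i]`` in reaction ``rxn_ids[j]``.
    Raises :class:`ModelStructureError` on unresolved metabolite references.
    """
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            if met not in index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                )
            S[index[met], j] = coef
    return S, met_ids, rxn_ids


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    statistics: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(model: MetabolicModel) -> ValidationReport:
    """Structural validation: report, never raise.

    Checks duplicate ids, unresolved references, inverted bounds, orphan
    metabolites, a resolvable objective, and (advisory) elemental balance
    for non-exchange reactions whose metabolites all carry formulas.
    """
    report = ValidationReport()
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()

    seen: set[str] = set()
    for mid in met_ids:
        if mid in seen:
            report.errors.append(("DUPLICATE_METABOLITE", mid))
        seen.add(mid)
    seen = set()
    for rid in rxn_ids:
        if rid in seen:
            report.errors.append(("DUPLICATE_REACTION", rid))
        seen.add(rid)

    met_set = set(met_ids)
    used: set[str] = set()
    for rxn in model.reactions:
        for met in rxn.stoichiometry:
            if met not in met_set:
                report.errors.append(
                    ("UNRESOLVED_METABOLITE", f"{rxn.id}: {met}"))
            used.add(met)
        if rxn.lower_bound > rxn.upper_bound:
            report.errors.append(
                ("BOUNDS_INVERTED",
                 f"{rxn.id}: lb={rxn.lower_bound} > ub={rxn.upper_bound}"))
        if not rxn.stoichiometry and not rxn.is_exchange:
            report.errors.append(("EMPTY_STOICHIOMETRY", rxn.id))

    for met in model.metabolites:
        if met.compartment not in COMPARTMENTS:
            report.errors.append(
                ("BAD_COMPARTMENT", f"{met.id}: {met.compartment}"))
        if met.id not in used:
            report.warnings.append(("ORPHAN_METABOLITE", met.id))

    if model.objective_id is not None and model.objective_id not in set(rxn_ids):
        report.errors.append(("UNRESOLVED_OBJECTIVE", str(model.objective_id)))

    rxn_set = set(rxn_ids)
    for con in model.extra_constraints:
        for rid in con.coefficients:
            if rid not in rxn_set:
                report.errors.append(
                    ("UNRESOLVED_CONSTRAINT_REACTION", f"{con.name}: {rid}"))

    # advisory elemental balance
    formulas = {m.id: m.elements() for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.is_exchange or not rxn.stoichiometry:
            continue
        elems = [formulas.get(met) for met in rxn.stoichiometry]
        if any(e is None for e in elems):
            continue
        net: dict[str, float] = {}
        for met, coef in rxn.stoichiometry.items():
            for el, n in formulas[met].items():  # type: ignore[union-attr]
                net[el] = net.get(el, 0.0) + coef * n
        imbalance = {el: v for el, v in net.items() if abs(v) > 1e-9}
        if imbalance:
            report.warnings.append(
                ("ELEMENTAL_IMBALANCE", f"{rxn.id}: {imbalance}"))

    gene_assoc = sum(1 for r in model.reactions if not r.gene_rule.is_empty)
    report.statistics = {
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
        "genes": len(model.genes()),
        "gene_associated_reactions": gene_assoc,
        "exchange_reactions": sum(1 for r in model.reactions if r.is_exchange),
    }
    return report


def evaluate_gene_rule(rule: GeneRule, deleted_genes: Iterable[str] = ()) -> bool:
    """Standard boolean semantics; the empty rule is always True."""
    return rule.evaluate(deleted_genes)


def knock_out_reactions(model: MetabolicModel,
                        reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with the named reactions' bounds pinned to zero."""
    ids = set(reaction_ids)
    known = set(model.reaction_ids())
    missing = sorted(ids - known)
    if missing:
        raise ModelStructureError(f"unknown reaction ids: {missing}")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in ids:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def reactions_disabled_by_genes(model: MetabolicModel,
                                deleted_genes: Iterable[str]) -> set[str]:
    """Reactions whose gene rule evaluates False under the deletion set."""
    deleted = set(deleted_genes)
    return {r.id for r in model.reactions if not r.gene_rule.evaluate(deleted)}
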