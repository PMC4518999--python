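"""Model file I/O: native JSON, native TSV, and an SBML Level 3 subset.

The native TSV dialect is reaction-centric — one reaction per row with
columns ``id  name  formula  lower_bound  upper_bound  gene_rule`` — and its
formula grammar accepts published reaction strings verbatim, e.g.::

    glu-L[c] + ATP[c] + NH4[c] - > ADP[c] + Pi[c] + H[c] + gln-L[c]
    lac-L[c] + NAD[c] < = > NADH [c] + H[c] + pyr[c]

Arrows ``->``, ``- >``, ``<=>``, ``< = >``, ``<==>`` (and spaced variants)
are recognised; ``<`` in the arrow means reversible.  Coefficients precede
the species token; a missing ``[c]``/``[e]`` suffix defaults to the cytosol.
When the bound columns are empty, the arrow decides the defaults:
reversible -> (-1000, 1000), irreversible -> (0, 1000).

Metabolite metadata, the objective, and extra flux constraints travel in
``#``-prefixed directive lines so that a write/read cycle is the identity.

The SBML reader/writer covers a deliberate subset of Level 3 core plus the
fbc package (species, reactions, stoichiometry, flux bounds via parameters,
gene-product associations, one maximisation objective).  Anything outside
that subset raises :class:`UnsupportedSBMLError` rather than being dropped
silently.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from lxml import etree

from .model import (
    DEFAULT_BOUND,
    GeneRule,
    LinearConstraint,
    MetabolicModel,
    Metabolite,
    Reaction,
)


class ParseError(ValueError):
    """Malformed native model file; message carries line/element context."""


class UnsupportedSBMLError(ValueError):
    """SBML document uses a feature outside the supported subset."""


# ---------------------------------------------------------------------------
# Reaction formula grammar
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<\s*=+\s*>|<\s*-+\s*>|=+\s*>|-+\s*>")
_TERM_RE = re.compile(
    r"^(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?"
    r"(?P<tok>[^\s\[\]]+)\s*(?:\[(?P<comp>[A-Za-z0-9]+)\])?$"
)


def parse_reaction_formula(text: str) -> tuple[dict[str, float], bool]:
    """Parse a formula string into ``(stoichiometry, reversible)``.

    Metabolite ids in the result carry their compartment suffix
    (``glu-L[c]``); a bare token defaults to the cytosol.
    """
    m = _ARROW_RE.search(text)
    if m is None:
        raise ParseError(f"no reaction arrow found in formula {text!r}")
    reversible = "<" in m.group(0)
    left, right = text[: m.start()], text[m.end():]

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s*\+\s*", side):
            term = term.strip()
            if not term:
                raise ParseError(f"empty species term in formula {text!r}")
            tm = _TERM_RE.match(term)
            if tm is None:
                raise ParseError(f"cannot parse term {term!r} in {text!r}")
            coef = float(tm.group("coef") or 1.0)
            comp = tm.group("comp") or "c"
            met = f"{tm.group('tok')}[{comp}]"
            stoich[met] = stoich.get(met, 0.0) + sign * coef
        return

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return stoich, reversible


def format_reaction_formula(rxn: Reaction) -> str:
    """Inverse of :func:`parse_reaction_formula` (canonical spacing)."""

    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coef in items:
            if abs(coef - 1.0) < 1e-12:
                parts.append(met)
            else:
                parts.append(f"{_fmt_num(coef)} {met}")
        return " + ".join(parts)

    lhs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _met_token(met_id: str) -> tuple[str, str]:
    """Split ``tok[comp]`` id into (token, compartment)."""
    m = re.match(r"^(?P<tok>.+)\[(?P<comp>[A-Za-z0-9]+)\]$", met_id)
    if m is None:
        return met_id, "c"
    return m.group("tok"), m.group("comp")


def infer_exchange(rxn: Reaction) -> bool:
    """Single extracellular species on one side only -> boundary drain."""
    if len(rxn.stoichiometry) != 1:
        return False
    met = next(iter(rxn.stoichiometry))
    return _met_token(met)[1] == "e"


# ---------------------------------------------------------------------------
# Native JSON
# ---------------------------------------------------------------------------

_KNOWN_MODEL_KEYS = {"id", "metabolites", "reactions", "objective_id",
                     "extra_constraints", "annotations"}
_KNOWN_MET_KEYS = {"id", "name", "compartment", "formula", "annotations"}
_KNOWN_RXN_KEYS = {"id", "name", "stoichiometry", "lower_bound",
                   "upper_bound", "gene_rule", "is_exchange", "annotations"}


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula, "annotations": m.annotations}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": dict(r.stoichiometry),
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gene_rule": r.gene_rule.to_string(),
             "is_exchange": r.is_exchange,
             "annotations": r.annotations}
            for r in model.reactions
        ],
        "objective_id": model.objective_id,
        "extra_constraints": [
            {"coefficients": c.coefficients, "sense": c.sense,
             "rhs": c.rhs, "name": c.name}
            for c in model.extra_constraints
        ],
        "annotations": model.annotations,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = []
        for d in data.get("metabolites", []):
            extra = {k: v for k, v in d.items() if k not in _KNOWN_MET_KEYS}
            ann = dict(d.get("annotations", {}))
            ann.update(extra)
            mets.append(Metabolite(
                id=d["id"], name=d.get("name", ""),
                compartment=d.get("compartment", "c"),
                formula=d.get("formula"), annotations=ann))
        rxns = []
        for d in data.get("reactions", []):
            extra = {k: v for k, v in d.items() if k not in _KNOWN_RXN_KEYS}
            ann = dict(d.get("annotations", {}))
            ann.update(extra)
            rxns.append(Reaction(
                id=d["id"], name=d.get("name", ""),
                stoichiometry={k: float(v)
                               for k, v in d.get("stoichiometry", {}).items()},
                lower_bound=float(d.get("lower_bound", 0.0)),
                upper_bound=float(d.get("upper_bound", DEFAULT_BOUND)),
                gene_rule=GeneRule.parse(d.get("gene_rule")),
                is_exchange=bool(d.get("is_exchange", False)),
                annotations=ann))
        cons = [LinearConstraint(
            coefficients={k: float(v) for k, v in c["coefficients"].items()},
            sense=c["sense"], rhs=float(c["rhs"]), name=c.get("name", ""))
            for c in data.get("extra_constraints", [])]
        ann = dict(data.get("annotations", {}))
        ann.update({k: v for k, v in data.items() if k not in _KNOWN_MODEL_KEYS})
        return MetabolicModel(
            id=data.get("id", "model"), metabolites=mets, reactions=rxns,
            objective_id=data.get("objective_id"),
            extra_constraints=cons, annotations=ann)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed model JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# Native TSV
# ---------------------------------------------------------------------------

_TSV_HEADER = ["id", "name", "formula", "lower_bound", "upper_bound",
               "gene_rule"]


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [f"#model\t{model.id}"]
    if model.objective_id is not None:
        lines.append(f"#objective\t{model.objective_id}")
    for con in model.extra_constraints:
        lines.append("#constraint\t" + json.dumps(
            {"coefficients": con.coefficients, "sense": con.sense,
             "rhs": con.rhs, "name": con.name}))
    for met in model.metabolites:
        lines.append("#metabolite\t" + json.dumps(
            {"id": met.id, "name": met.name, "compartment": met.compartment,
             "formula": met.formula, "annotations": met.annotations}))
    if model.annotations:
        lines.append("#annotations\t" + json.dumps(model.annotations))
    lines.append("\t".join(_TSV_HEADER))
    for r in model.reactions:
        row = [r.id, r.name, format_reaction_formula(r),
               _fmt_num(r.lower_bound), _fmt_num(r.upper_bound),
               r.gene_rule.to_string()]
        if r.annotations or r.is_exchange != infer_exchange(r):
            row.append(json.dumps(
                {"annotations": r.annotations, "is_exchange": r.is_exchange}))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path) -> MetabolicModel:
    model = MetabolicModel(id=path.stem)
    declared: dict[str, Metabolite] = {}
    header_seen = False
    referenced: dict[str, None] = {}

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            tag, _, rest = line[1:].partition("\t")
            try:
                if tag == "model":
                    model.id = rest
                elif tag == "objective":
                    model.objective_id = rest
                elif tag == "constraint":
                    c = json.loads(rest)
                    model.extra_constraints.append(LinearConstraint(
                        coefficients=c["coefficients"], sense=c["sense"],
                        rhs=float(c["rhs"]), name=c.get("name", "")))
                elif tag == "metabolite":
                    d = json.loads(rest)
                    declared[d["id"]] = Metabolite(
                        id=d["id"], name=d.get("name", ""),
                        compartment=d.get("compartment", "c"),
                        formula=d.get("formula"),
                        annotations=d.get("annotations", {}))
                elif tag == "annotations":
                    model.annotations = json.loads(rest)
                # unknown directives are preserved as opaque annotations
                else:
                    model.annotations.setdefault("unknown_directives", []) \
                        .append(line)
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ParseError(f"line {lineno}: bad directive: {exc}") from exc
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields[:6]] != _TSV_HEADER:
                raise ParseError(
                    f"line {lineno}: expected header {_TSV_HEADER}, "
                    f"got {fields!r}")
            header_seen = True
            continue
        if len(fields) < 6:
            raise ParseError(
                f"line {lineno} (reaction {fields[0]!r}): expected "
                f"{len(_TSV_HEADER)} fields, got {len(fields)}")
        rid, name, formula, lb_s, ub_s, rule_s = fields[:6]
        try:
            stoich, reversible = parse_reaction_formula(formula)
        except ParseError as exc:
            raise ParseError(f"line {lineno} (reaction {rid!r}): {exc}") from exc
        if lb_s.strip():
            lb = float(lb_s)
        else:
            lb = -DEFAULT_BOUND if reversible else 0.0
        ub = float(ub_s) if ub_s.strip() else DEFAULT_BOUND
        rxn = Reaction(id=rid, name=name, stoichiometry=stoich,
                       lower_bound=lb, upper_bound=ub,
                       gene_rule=GeneRule.parse(rule_s))
        rxn.is_exchange = infer_exchange(rxn)
        if len(fields) > 6 and fields[6].strip():
            try:
                extra = json.loads(fields[6])
            except json.JSONDecodeError as exc:
                raise ParseError(
                    f"line {lineno} (reaction {rid!r}): bad extra column: "
                    f"{exc}") from exc
            rxn.annotations = extra.get("annotations", {})
            rxn.is_exchange = bool(extra.get("is_exchange", rxn.is_exchange))
        model.reactions.append(rxn)
        for met in stoich:
            referenced.setdefault(met)

    if not header_seen:
        raise ParseError("no reaction table header found")

    for met_id in referenced:
        if met_id in declared:
            continue
        tok, comp = _met_token(met_id)
        declared[met_id] = Metabolite(id=met_id, name=tok, compartment=comp)
    # declared order first (stable round-trip), then inferred extras
    model.metabolites = list(declared.values())
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 subset
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
_NSMAP = {None: _SBML_NS, "fbc": _FBC_NS}

_UNSUPPORTED_SBML = ["listOfRules", "listOfEvents", "listOfConstraints",
                     "listOfFunctionDefinitions", "listOfInitialAssignments"]

_SID_SUB = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """Mangle an id into a valid SBML SId (prefixed, alnum+underscore)."""
    s = _SID_SUB.sub("__", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return s


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    if model.extra_constraints:
        raise UnsupportedSBMLError(
            "extra flux constraints cannot be represented in the supported "
            "SBML subset; use the native JSON or TSV dialect")
    E = lambda tag: f"{{{_SBML_NS}}}{tag}"  # noqa: E731
    F = lambda tag: f"{{{_FBC_NS}}}{tag}"  # noqa: E731
    sbml = etree.Element(E("sbml"), nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(F("required"), "false")
    mdl = etree.SubElement(sbml, E("model"))
    mdl.set("id", _sid(model.id))
    mdl.set("name", model.id)
    mdl.set(F("strict"), "false")

    comps = etree.SubElement(mdl, E("listOfCompartments"))
    for cid in ("c", "e"):
        c = etree.SubElement(comps, E("compartment"))
        c.set("id", cid)
        c.set("constant", "true")

    species = etree.SubElement(mdl, E("listOfSpecies"))
    sid_of_met = {}
    for met in model.metabolites:
        s = etree.SubElement(species, E("species"))
        sid = "M_" + _sid(met.id)
        sid_of_met[met.id] = sid
        s.set("id", sid)
        # the original id (with its compartment suffix) rides in the name
        # attribute so that reading recovers it exactly; display names are
        # outside the supported subset
        s.set("name", met.id)
        s.set("compartment", met.compartment)
        s.set("hasOnlySubstanceUnits", "false")
        s.set("boundaryCondition", "false")
        s.set("constant", "false")
        if met.formula:
            s.set(F("chemicalFormula"), met.formula)

    params = etree.SubElement(mdl, E("listOfParameters"))
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = etree.SubElement(params, E("parameter"))
            p.set("id", pid)
            p.set("value", repr(float(value)))
            p.set("constant", "true")
            bound_params[value] = pid
        return bound_params[value]

    genes = sorted(model.genes())
    if genes:
        lgp = etree.SubElement(mdl, F("listOfGeneProducts"))
        for g in genes:
            gp = etree.SubElement(lgp, F("geneProduct"))
            gp.set(F("id"), "G_" + _sid(g))
            gp.set(F("label"), g)

    rxns = etree.SubElement(mdl, E("listOfReactions"))
    for r in model.reactions:
        x = etree.SubElement(rxns, E("reaction"))
        x.set("id", "R_" + _sid(r.id))
        x.set("name", r.id)
        x.set("reversible", "true" if r.reversible else "false")
        x.set("fast", "false")
        x.set(F("lowerFluxBound"), bound_param(r.lower_bound))
        x.set(F("upperFluxBound"), bound_param(r.upper_bound))
        reactants = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
        products = [(m, c) for m, c in r.stoichiometry.items() if c > 0]
        if reactants:
            lst = etree.SubElement(x, E("listOfReactants"))
            for met, coef in reactants:
                ref = etree.SubElement(lst, E("speciesReference"))
                ref.set("species", sid_of_met[met])
                ref.set("stoichiometry", repr(float(coef)))
                ref.set("constant", "true")
        if products:
            lst = etree.SubElement(x, E("listOfProducts"))
            for met, coef in products:
                ref = etree.SubElement(lst, E("speciesReference"))
                ref.set("species", sid_of_met[met])
                ref.set("stoichiometry", repr(float(coef)))
                ref.set("constant", "true")
        if not r.gene_rule.is_empty:
            gpa = etree.SubElement(x, F("geneProductAssociation"))
            _write_gpa(gpa, r.gene_rule.expr, F)

    if model.objective_id is not None:
        lo = etree.SubElement(mdl, F("listOfObjectives"))
        lo.set(F("activeObjective"), "obj")
        ob = etree.SubElement(lo, F("objective"))
        ob.set(F("id"), "obj")
        ob.set(F("type"), "maximize")
        lfo = etree.SubElement(ob, F("listOfFluxObjectives"))
        fo = etree.SubElement(lfo, F("fluxObjective"))
        fo.set(F("reaction"), "R_" + _sid(model.objective_id))
        fo.set(F("coefficient"), "1")

    etree.ElementTree(sbml).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def _write_gpa(parent, expr, F) -> None:
    kind = expr[0]
    if kind == "gene":
        el = etree.SubElement(parent, F("geneProductRef"))
        el.set(F("geneProduct"), "G_" + _sid(expr[1]))
    else:
        el = etree.SubElement(parent, F("and" if kind == "and" else "or"))
        for child in expr[1]:
            _write_gpa(el, child, F)


def _read_gpa(el, label_of_gene) -> tuple:
    tag = etree.QName(el).localname
    if tag == "geneProductRef":
        ref = el.get(f"{{{_FBC_NS}}}geneProduct") or el.get("geneProduct")
        return ("gene", label_of_gene.get(ref, ref))
    if tag in ("and", "or"):
        return (tag, tuple(_read_gpa(c, label_of_gene) for c in el))
    raise UnsupportedSBMLError(f"unsupported gene association element <{tag}>")


def _read_sbml(path: Path) -> MetabolicModel:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ParseError("root element is not <sbml>")
    ns = etree.QName(root).namespace
    if ns != _SBML_NS:
        raise UnsupportedSBMLError(
            f"only SBML Level 3 Version 1 is supported, got namespace {ns}")
    mdl = root.find(f"{{{ns}}}model")
    if mdl is None:
        raise ParseError("no <model> element")
    for bad in _UNSUPPORTED_SBML:
        if mdl.find(f"{{{ns}}}{bad}") is not None:
            raise UnsupportedSBMLError(f"<{bad}> is not supported")

    out = MetabolicModel(id=mdl.get("name") or mdl.get("id") or "model")

    for comp in mdl.findall(f"{{{ns}}}listOfCompartments/{{{ns}}}compartment"):
        if comp.get("id") not in ("c", "e"):
            raise UnsupportedSBMLError(
                f"compartment {comp.get('id')!r} outside supported set "
                "{'c', 'e'}")

    params: dict[str, float] = {}
    for p in mdl.findall(f"{{{ns}}}listOfParameters/{{{ns}}}parameter"):
        if p.get("value") is not None:
            params[p.get("id")] = float(p.get("value"))

    label_of_gene: dict[str, str] = {}
    for gp in mdl.iter(f"{{{_FBC_NS}}}geneProduct"):
        gid = gp.get(f"{{{_FBC_NS}}}id") or gp.get("id")
        label_of_gene[gid] = gp.get(f"{{{_FBC_NS}}}label") or gid

    met_of_sid: dict[str, str] = {}
    for s in mdl.findall(f"{{{ns}}}listOfSpecies/{{{ns}}}species"):
        if s.get("boundaryCondition") == "true":
            raise UnsupportedSBMLError(
                f"boundary-condition species {s.get('id')!r} not supported")
        name = s.get("name") or s.get("id")
        comp = s.get("compartment") or "c"
        mid = name if name.endswith(f"[{comp}]") else f"{name}[{comp}]"
        met_of_sid[s.get("id")] = mid
        out.metabolites.append(Metabolite(
            id=mid, name=name, compartment=comp,
            formula=s.get(f"{{{_FBC_NS}}}chemicalFormula")))

    for x in mdl.findall(f"{{{ns}}}listOfReactions/{{{ns}}}reaction"):
        if x.find(f"{{{ns}}}kineticLaw") is not None:
            raise UnsupportedSBMLError(
                f"kineticLaw on reaction {x.get('id')!r} not supported")
        rid = x.get("name") or x.get("id")
        stoich: dict[str, float] = {}
        for ref in x.findall(f"{{{ns}}}listOfReactants/{{{ns}}}speciesReference"):
            met = met_of_sid[ref.get("species")]
            stoich[met] = stoich.get(met, 0.0) - float(ref.get("stoichiometry", 1))
        for ref in x.findall(f"{{{ns}}}listOfProducts/{{{ns}}}speciesReference"):
            met = met_of_sid[ref.get("species")]
            stoich[met] = stoich.get(met, 0.0) + float(ref.get("stoichiometry", 1))
        lb_ref = x.get(f"{{{_FBC_NS}}}lowerFluxBound")
        ub_ref = x.get(f"{{{_FBC_NS}}}upperFluxBound")
        reversible = x.get("reversible", "true") == "true"
        lb = params.get(lb_ref) if lb_ref else None
        ub = params.get(ub_ref) if ub_ref else None
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        rule = GeneRule()
        gpa = x.find(f"{{{_FBC_NS}}}geneProductAssociation")
        if gpa is not None and len(gpa):
            rule = GeneRule(_read_gpa(gpa[0], label_of_gene))
        rxn = Reaction(id=rid, name=x.get("name") or rid, stoichiometry=stoich,
                       lower_bound=lb, upper_bound=ub, gene_rule=rule)
        rxn.is_exchange = infer_exchange(rxn)
        out.reactions.append(rxn)

    active = None
    lo = mdl.find(f"{{{_FBC_NS}}}listOfObjectives")
    if lo is not None:
        fo = lo.find(f".//{{{_FBC_NS}}}fluxObjective")
        if fo is not None:
            active = fo.get(f"{{{_FBC_NS}}}reaction") or fo.get("reaction")
    if active is not None:
        for x in mdl.findall(f"{{{ns}}}listOfReactions/{{{ns}}}reaction"):
            if x.get("id") == active:
                out.objective_id = x.get("name") or x.get("id")
                break
    return out


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

_FORMATS = ("native-json", "native-tsv", "sbml-subset")

_EXT_FORMAT = {".json": "native-json", ".tsv": "native-tsv",
               ".xml": "sbml-subset", ".sbml": "sbml-subset"}


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    guess = _EXT_FORMAT.get(path.suffix.lower())
    if guess is None:
        raise ValueError(
            f"cannot infer model format from suffix {path.suffix!r}; "
            f"pass format= one of {_FORMATS}")
    return guess


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in the named (or inferred) dialect."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "native-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return model_from_dict(data)
    if fmt == "native-tsv":
        return _read_tsv(path)
    return _read_sbml(path)


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write ``model`` to ``path`` in the named (or inferred) dialect."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "native-json":
        path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
    elif fmt == "native-tsv":
        _write_tsv(model, path)
    else:
        _write_sbml(model, path)
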