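# Methods

## Scope and model form

All analyses operate on a steady-state stoichiometric model: metabolites
and reactions with flux bounds (mmol gDW⁻¹ h⁻¹; growth in h⁻¹),
gene–protein–reaction boolean rules, one biomass objective, and optional
extra linear constraints over fluxes. Compartments are restricted to
cytosol (`c`) and extracellular (`e`). Exchange reactions are written
`met[e] →` with positive flux = secretion and negative = uptake; yield
computations use the positive magnitude of the glucose exchange flux.
Default bounds are ±1000 for reversible and [0, 1000] for irreversible
reactions.

Model I/O supports a native JSON dialect (full fidelity, unknown fields
preserved as opaque annotations), a native TSV dialect whose formula
grammar accepts published reaction strings verbatim (coefficients,
`[c]`/`[e]` suffixes with cytosol default, `- >` vs `< = >` arrows with
arbitrary internal spacing, hyphenated species tokens as atomic ids), and
a deliberately narrow SBML Level 3 core + fbc subset (species, reactions,
stoichiometry, bounds via parameters, gene associations, one maximisation
objective). Anything outside the SBML subset — including extra flux
constraints, which fbc v2 cannot express — raises an explicit
unsupported-feature error rather than being dropped. Elemental-balance
checking is advisory (warnings), since lumped reactions legitimately
omit water/proton bookkeeping.

## The core organism model

The core network (40 reactions, 37 metabolites) covers glucose
fermentation in *T. saccharolyticum*: lumped glycolysis
(glc → 2 pyr + 2 ATP + 2 NADH), pyruvate:ferredoxin oxidoreductase,
the lactate (LDH_L), acetate (PTAr + ACKr) and ethanol (ACALD + ALCD2x,
2 NADH per ethanol) branches, four hydrogenases (HFS, ECH, BIFH2, NADH2),
a ferredoxin:NAD oxidoreductase (RNF), a lumped α-ketoglutarate branch,
ammonium assimilation (GLNS, GLUDy, GLUSy), ATP maintenance, and a biomass
drain. The six enzymes with curated formulas and gene associations
(GLNS/Tsac_2029, GLUDy/Tsac_2172, GLUSy/Tsac_1234, LDH_L/Tsac_0179,
PTAr/Tsac_1744, HFS/Tsac_1550–1553) are entered verbatim in the TSV
grammar; prose aliases (GLUD, PTA, LDH) are accepted by the constructors.

Ferredoxin is modelled as an Fdred/Fdox pair carrying two electrons, so
HFS (Fdred + 2 H⁺ ↔ Fdox + H₂) yields one H₂ per reduced ferredoxin.
Lumped stoichiometries chosen here (none are published for this organism
at this granularity):

| reaction | stoichiometry | rationale |
|---|---|---|
| GLYC | glc + 2 ADP + 2 Pi + 2 NAD → 2 pyr + 2 ATP + 2 NADH | textbook EMP lump |
| POR  | pyr + CoA + Fdox → AcCoA + CO₂ + Fdred | 2 e⁻ to ferredoxin per pyruvate |
| ECH  | Fdred + 3 H⁺ → Fdox + H₂ + H⁺(e) | energy conservation as proton export |
| BIFH2 | Fdred + NADH + 3 H⁺ ↔ Fdox + NAD + 2 H₂ | electron-confurcating; written in the producing direction |
| NADH2 | NADH + H⁺ ↔ NAD + H₂ | simple NADH hydrogenase |
| RNF  | Fdred + NAD + H⁺ → Fdox + NADH | exergonic direction only; the bifurcating variant's exact stoichiometry is unpublished, so this conservative form is the documented default |
| AKGS | pyr + AcCoA + NADP → akg + CoA + NADPH | C3+C2→C5 anaplerosis+citrate lump; sole NADPH source, 1:1 with akg, which exactly balances either assimilation route's NADPH demand |
| BIOMASS | 0.5 pyr + 0.3 glu + 0.1 gln + 2 NADH + 40 ATP → ADP/Pi/NAD | see below |

Biomass parameters: 40 ATP per unit growth gives a wild-type optimum of
~0.56 h⁻¹ at an uptake of 10 mmol gDW⁻¹ h⁻¹ — a realistic doubling time
for a thermophilic anaerobe on glucose. Nitrogen enters biomass
exclusively through glutamate and glutamine (demand ratio 3:1), which is
what makes the GLUD deletion consequential: without it, every
glutamate-derived nitrogen costs one extra ATP through the glutamine
synthetase / glutamate synthase cycle. The 2 NADH anabolic reduction
demand is structurally necessary: biomass removes carbon (pyruvate,
glutamate) whose catabolism would have produced electrons, while the
glycolytic NADH yield is fixed per glucose; without a compensating
biomass electron demand the fully coupled Δldh-Δhfs strain — whose only
remaining electron sink is ethanol, at exactly 2 e⁻-pairs per carbon
pair — would be over-determined and infeasible at any positive growth.
ATP maintenance is 2 mmol gDW⁻¹ h⁻¹. All of these values are fixed study
conditions, set once when the model was built.

The glucose uptake bound (10 mmol gDW⁻¹ h⁻¹) is a configuration
parameter; the phase-plane axis defaults are glucose uptake [−10, 0] and
ethanol [0, 20].

### Hydrogenase constraint set

Unconstrained, the four hydrogenases let the network regenerate cofactors
so freely that very high acetate + hydrogen yields are growth-optimal.
The constraint set encodes the observed physiology top-down: ECH bounds
(0, 0); BIFH2 and NADH2 restricted to the H₂-consuming direction (upper
bound 0 given their written producing direction); and the coupling
constraint `v_EX_h2 + 0.9·v_EX_glc ≤ 0` capping hydrogen yield at 0.9 mol
per mol glucose across the entire flux space (it scales with uptake — a
fixed bound would not). Application is idempotent; the cap applies to the
glucose exchange only.

## Numerical choices

LPs and MILPs are solved with HiGHS via scipy. Primal feasibility is the
solver default (~10⁻⁹); reported values are compared at 10⁻⁶, two orders
below the smallest meaningful flux differences in these analyses (the
smallest real gap, the triple-vs-double guaranteed-ethanol improvement,
is ~6.5·10⁻³). FBA returns one arbitrary optimal vertex; every scientific
claim about "flux at the optimum" is therefore phrased through flux
variability, `product_range_at_optimum`, or `coupling_strength`
(minimum product subject to growth ≥ fraction × optimum), all of which
are degeneracy-proof. Optimal-face constraints back the floor off by
10⁻⁹·max(1, |optimum|) so the face itself stays feasible. Phase-plane
cells fix both fluxes exactly and mark infeasible cells as NA (never
zero). Envelope growth grids run from 0 to the optimum with the top
point backed off by the same whisker. Grid resolution defaults to
50 points per axis.

## Knockout design

The bilevel design problem (outer: pick ≤ K knockouts to maximise
product; inner: the mutant maximises growth) is solved as a single-level
MILP. Inner optimality is enforced exactly by strong duality: the master
program contains the inner LP's primal constraints with knockout binaries
gating the bounds (lb_j·y_j ≤ v_j ≤ ub_j·y_j), the dual constraints, and
the primal–dual objective equality, with the bilinear y·dual terms
linearised exactly for binary y (dual variables bounded at 1000, a bound
validated by oracle agreement on every tested instance).

Because the inner optimum generally admits alternate flux states, the
product flux "at the optimum" is an interval. Designs are ranked by its
lower end — the guaranteed minimum product at the inner optimum — rather
than the classical upper end. The choice is deliberate: the upper end
cannot distinguish a design that merely *permits* high product from one
that *forces* it, and under the upper-end objective any network in which
a GLUD-style deletion improves yield through slower growth makes
{GLUD, HFS} tie or beat {LDH, HFS} at K = 2 (deleting LDH changes nothing
the outer maximiser would use). The guaranteed minimum is the quantity
growth coupling is actually about, and both values are reported in every
`KnockoutDesign`. Since the master MILP's value (the at-optimum maximum)
upper-bounds the guaranteed minimum, the search is exact: solve the
master, evaluate the returned design's guaranteed minimum by two LPs on
the knocked-out network, exclude that design with a no-good cut, and stop
once the master bound falls below the incumbent. Ties break by smaller
cardinality, then lexicographically smaller id set — identically in the
MILP search and the exhaustive oracle, whose agreement is asserted in the
tests. The default minimum-growth threshold is 10 % of the wild-type
optimum; knockouts are reaction-level, with gene-level deletions
available through GPR propagation (`reactions_disabled_by_genes`).

## Gap filling

Gap filling minimises the number (or optional per-reaction cost) of
universe reactions activated inside the combined draft+universe
steady-state system subject to growth ≥ threshold (default 10⁻³ h⁻¹).
Reversible universe reactions are gated by a single binary opening both
bound directions — equivalent, for a cardinality objective, to splitting
by direction, and numerically simpler. Minimality and the reported growth
are re-verified a posteriori (subset enumeration; plain FBA re-solve).

## Synthetic data

The generators produce the networks the tests measure, with ground truth
derivable by hand from the construction, never from the solver:

* **Linear pathways** — chains whose optimum is the minimum of the uptake
  bound and an optional tightened step.
* **Coupled toy** — catabolism yields precursor, ATP and NADH; NADH can
  leave through a venting sink (no product) or through product synthesis.
  With the vent open the minimum product at optimum is 0; knocking the
  vent halves growth and pins the product at exactly the uptake rate
  (stoichiometric ratios of the build). The uptake bound is the seeded
  quantity.
* **Degraded drafts** — remove k growth-essential reactions (found by
  single-knockout essentiality testing) and return them in a universe
  among dead-end decoy reactions that can never carry steady-state flux.
* **Random small networks** — ≤ 6 reactions with integer stoichiometry
  and finite bounds, used to check the LP core against an independent
  brute-force vertex-enumeration oracle (every basic solution of the
  bounded polytope is enumerated and tested for feasibility).

What the toys emulate is the *structure* of the real analyses — electron
sinks competing with product formation, essential-reaction gaps, bounded
flux polytopes — not genome-scale network statistics, realistic biomass
composition, or kinetic/regulatory effects. Tests passing on them show
the algorithms are correct on networks with known answers; claims about
the organism itself rest on the curated core model, whose own
simplifications (lumped pathways, two compartments, no proton-motive
accounting beyond the lumped ECH, glucose only) are listed above.

## Known limitations

* The core model is a ~40-reaction skeleton, not the full genome-scale
  reconstruction; absolute flux values depend on the documented biomass
  and uptake parameters, while the qualitative contracts (coupling
  ordering, design identity, ATP accounting) are parameter-robust.
* The growth penalty of the electron-centred strain relative to the
  carbon-centred strain is smaller here than observed in vivo; the model
  reproduces the penalty relative to wild type and the coupling ordering.
* No thermodynamic (ΔG), kinetic or regulatory constraints; the
  hydrogenase constraint set is the top-down stand-in for them.
* The SBML subset cannot carry extra flux constraints (fbc v2 has no
  such construct); constrained models round-trip through the native
  dialects only.
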