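# thermoflux

Constraint-based metabolic modelling of *Thermoanaerobacterium
saccharolyticum*, a thermophilic anaerobe of industrial interest for
cellulosic ethanol production. The package is aimed at metabolic engineers
and systems biologists who want to analyse — and re-derive — the
growth-coupled ethanol knockout designs for this organism: it provides a
curated core fermentation model with the organism's hydrogenase
constraints, flux balance analysis, phenotypic phase planes and production
envelopes for the engineered strains, a bilevel knockout-design optimiser,
and a minimal-additions gap filler, plus seeded synthetic-network
generators so that every stage runs and is tested with no external data.

## The model

Flux balance analysis treats metabolism as a steady-state linear program
over the stoichiometric matrix *S* (metabolites × reactions):

```
max  c·v    subject to   S v = 0,   lb ≤ v ≤ ub,   A v ≤ b
```

where *v* are reaction fluxes (mmol gDW⁻¹ h⁻¹), *c* selects the biomass
reaction (growth, h⁻¹), and *A v ≤ b* carries extra linear constraints —
here the hydrogen yield cap `v_H2 ≤ 0.9·|v_glc|`, a coupling constraint
that scales with uptake. The organism-specific constraint set blocks the
energy-conserving hydrogenase (ECH), restricts the bifurcating (BIFH2) and
NADH (NADH2) hydrogenases to hydrogen uptake, and leaves the ferredoxin
hydrogenase (HFS, the *hfs* four-gene complex) as the only H₂ producer.

On top of the LP core sit:

* **Phase planes / production envelopes** — max growth over a grid of two
  fixed fluxes; min/max product flux at each growth value.
* **Coupling strength** — the guaranteed minimum product secretion at a
  fraction of optimal growth: the degeneracy-proof statistic for growth
  coupling (alternate optima cannot hide behind it).
* **Knockout design** — a bilevel program (outer: choose ≤ K reaction
  knockouts; inner: the mutant maximises growth) solved as a single-level
  mixed-integer program via LP strong duality, ranked by guaranteed
  product flux at the inner optimum and cross-checked by exhaustive
  subset enumeration.
* **Gap filling** — a MILP choosing the smallest set of universe reactions
  that restores biomass flux to an infeasible draft.

## Worked example

```bash
python examples/02_strain_phase_planes.py
```

prints, for glucose uptake 10 mmol gDW⁻¹ h⁻¹:

```
strain           growth  min EtOH  max EtOH  range coupling@99%
WT               0.5632     4.190    14.683   0.71        3.968
ldh_pta          0.4489    10.282    19.282   0.47       10.190
ldh_hfs          0.4506    19.347    19.347   0.00       19.173
ldh_hfs_glud     0.4461    19.353    19.353   0.00       19.180
```

Each row is a strain; `min/max EtOH` is the ethanol flux interval over all
growth-optimal flux states and `coupling@99%` the guaranteed minimum
ethanol at ≥ 99 % of that strain's optimum. The wild-type optimum admits a
wide ethanol range (ratio 0.71) because lactate and capped H₂ can carry
electrons instead; deleting LDH+PTA (carbon-centred strategy) tightens it;
deleting LDH+HFS (electron-centred strategy) pins ethanol to a single
value — every optimal state must secrete ≈19.35 mmol gDW⁻¹ h⁻¹ — at a
growth penalty versus the wild type. Adding the GLUD deletion forces
ammonium assimilation through glutamine synthetase + glutamate synthase at
one extra ATP per NH₄ (`examples/03`, and
`ammonium_assimilation_atp_cost`), which lowers growth slightly and yields
a small strict improvement in guaranteed ethanol. The knockout-design
optimiser recovers exactly these designs: `{LDH_L, HFS}` at K = 2 and
`{LDH_L, HFS, GLUDy}` at K = 3, in agreement with the exhaustive oracle
(`examples/03_optknock_designs.py`).

The other examples: `01` (plain FBA of the core model), `04` (gap-filling
a deliberately broken network). A thin CLI mirrors the library:
`thermoflux validate|fba|fva|phase-plane|envelope|optknock|gapfill|make-synthetic|reproduce-figs`
(see `thermoflux --help`); `reproduce-figs` writes the four strains' phase
planes and envelopes as TSV.

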