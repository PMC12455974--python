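# Methods

## Constraint-based core

A metabolic network is the pair (S, bounds): `S` the metabolites × reactions
stoichiometric matrix, each flux `v_i` (mmol gDW⁻¹ hr⁻¹) constrained to
`lb_i <= v_i <= ub_i`. All analyses assume steady state, `S v = 0`.

* **FBA** maximises `Z = c^T v`. The objective sense is always maximise;
  minimisation is expressed by negating `c`.
* **pFBA** minimises `Σ_i |v_i|` subject to `c^T v >= f · Z*` (default
  `f = 1`), linearised with auxiliary variables `t_i >= |v_i|` — an exact
  LP, no quadratic solver. The reported objective is `c^T v`, not the flux
  sum. Under degenerate optima the solver picks one parsimonious vertex;
  downstream metrics must not depend on which one beyond the stated
  tolerances.
* **FVA** computes `min/max v_i` over the near-optimal set
  `{v : S v = 0, bounds, c^T v >= f Z*}`. It is well defined under
  degeneracy (a min/max over the optimal face). `f` defaults to 1.0 and is
  configurable because with large degenerate models 0.999 is sometimes more
  stable.

LPs are solved with HiGHS through `scipy.optimize.linprog` at a
feasibility/optimality tolerance of 1e-9; package-level assertions
(steady-state residual, range containment) use 1e-6, standard practice in
constraint-based modelling. Infeasible and unbounded statuses are reported
as data, not exceptions, except where an operation's precondition requires
an optimal base problem.

An independent oracle (`mgeburden.exact`) enumerates all vertices of the
flux polytope for networks of ≲ 8 reactions by solving every basic system of
active constraints, and recovers FBA optima and FVA ranges as min/max over
finite vertex sets. The optimal face of a polytope is itself a face, so
filtering vertices at `c^T v = Z*` is exact. The test suite checks the LP
route against this oracle and against COBRApy (GLPK) as a second
independent implementation.

## MGE biomass pseudoreactions

Per MGE particle: nucleotide counts `N_i_tot = C_g (N_i_G + N_i_int)`, with
both strands counted for dsDNA genomes and replication intermediates counted
as given (for ssDNA phage the default intermediate is one complementary
strand — the double-stranded replicative form — toggleable; dsDNA plasmids
default to none). Amino-acid counts are `AA_j_tot = Σ_k C_k AA_j_k`.
Polymerisation energetics: 4 ATP per amino acid *incorporated* (charged on
total residue counts, not residues − 1; a `bonds` basis is available for
sensitivity analysis) and 1 PPi released per nucleotide, intermediates
included. Each ATP hydrolysis consumes one water and yields ADP + Pi + H+,
so the H2O coefficient equals the ATP coefficient by construction.

The particle's molar mass `M` is the monomer-mass-weighted sum of all counts.
Every coefficient is `count / M × 1000`, giving mmol per gram of MGE, whence
the invariant `Σ coeff × monomer mass = 1000` exactly — one gram of monomers
per gram of MGE. The monomer mass basis is the *consumed species* as
configured in the `MonomerTable` (defaults: free dNTP and free amino-acid
average masses, BiGG-style cytosolic ids `datp_c…`, `ala__L_c…`), applied
consistently in both the gram conversion and the total molar mass so the
identity holds to machine precision. Any other basis (e.g. residue masses)
can be supplied per model dialect.

Conjugative pilus costs: the major pilin copy number is
`round(length_µm × 1000 / pitch_nm × subunits_per_turn)` with defaults of
12.8 subunits per turn (5-start helix) and a 20 µm maximum filament; the
helical pitch is a required configuration value, and an explicit per-protein
copy-number table overrides the calculator entirely. The default
configuration charges a single pilus structure. Extracellular transport of
phage particles is not modelled.

## Host edits and carriage states

* *metB* knockout: bounds of the cystathionine-gamma-synthase reaction(s)
  set to [0, 0], resolved through gene rules where annotated, else by an
  explicit reaction id (model dialects differ in gene annotation).
* Methionine secretor: the biomass reaction gains `ratio` (default 0.5) mmol
  of extracellular methionine per unit biomass flux, and every reaction that
  could take extracellular methionine back up is clamped to export-only.
  The coupling therefore holds exactly in every optimal solution:
  export / growth = ratio.
* Carriage states set the objective (host biomass, plasmid, or phage
  pseudoreaction) and impose constitutive production demands as lower
  bounds: plasmid 0.9 and phage 0.06 mmol gDW⁻¹ hr⁻¹ in the double-carriage
  configuration; the phage-optimised state retains the 0.9 plasmid demand.
  Pseudoreactions attach with bounds [0, 1000].

## Conflict statistics

FVA ranges are closed intervals; two states conflict on a reaction iff
`max_A < min_B − tol` or `max_B < min_A − tol` (a shared endpoint is not
conflict; default tol 1e-6, and shrinking tol can only enlarge the conflict
set). Subsystem tallies use the model's subsystem labels; empty subsystems
are omitted.

The demand metric compares absolute parsimonious fluxes. Reactions whose
flux direction flips between states (both magnitudes above `zero_tol =
1e-9`) are dropped from every sum; fluxes below `zero_tol` in both states
contribute nothing and are not direction changes. The denominator spans all
retained reactions of the model, exchanges and pseudoreactions included
(the metric's definition places no exclusions; a flag can exclude
exchanges). A subsystem with zero flux in exactly one state has no finite
fold-change and is flagged undefined rather than raising; zero in both
states reads as no change. Any presentation filter (e.g. |log2FC| > 0.5)
is left to the caller.

## Batch dynamic FBA

One to three species share a well-mixed batch pool (mmol per metabolite).
Each cycle of length Δt: every species' exchange uptake bound is capped at
`min(Vmax, pool / (X · Δt))` with `Vmax = 10 mmol gDW⁻¹ hr⁻¹` (the standard
coarse-grained batch contract — the protocol itself pins only Δt, cycle
count, inocula and media); the species' FBA is solved with its carriage
objective; biomass advances by forward Euler `X ← X(1 + µΔt)`; the pool is
updated from exchange fluxes evaluated at start-of-cycle biomasses, so all
species see the same environment and no update order bias exists. If
several species together would overdraw a pool, their uptake bounds on that
metabolite are scaled by the common factor that empties it and the cycle is
re-solved — mass-conserving and order-independent. An infeasible species LP
reads as zero growth and zero exchange for that cycle (logged). There is no
death term; maintenance enters only through a model's own ATP-maintenance
reaction if present. "Excess" nutrients are explicit 1000 mmol pool entries
rather than infinite bounds, so depletion remains representable.

Default protocol: Δt = 1 h, 200 cycles, inocula of 1e-8 gDW per species
(≈ 3.33 × 10⁴ cells at 3e-13 g dry weight per cell), limiting carbon
2.78e-4 mmol.

## Synthetic fixtures: what they emulate, what they do not

The generators produce the smallest inputs on which every claim is exactly
checkable:

* **Toy host** (~45 reactions): sugar uptake, a capacity-limited respiration
  branch vs an overflow fermentation branch exporting an acetate-like
  byproduct, one lumped biosynthesis reaction per monomer (all 24 monomers
  of the default table, so pseudoreactions attach unchanged), PPi recycling,
  and a biomass reaction. Seeded jitter (±10%) on biosynthetic yields gives
  a family of distinct hosts for the burden-ordering sweeps. Capacities were
  chosen once so the standard carriage demands (0.9 / 0.06) are feasible.
* **Conflict fixture** (5 reactions): one substrate, two disjoint routes to
  two sinks. At 100% of either optimum the whole supply is forced down one
  branch, so the four branch/sink reactions have provably disjoint singleton
  ranges — the ground truth is re-derived by vertex enumeration at
  generation time, not stored.
* **Batch fixture**: biomass formation partitions sugar carbon 40:8:12
  (biomass : byproduct : CO2) per 60 consumed, yield 0.1 gDW/mmol, giving
  closed-form final biomass `X0 + 0.1·C0` and exact carbon bookkeeping.
* **Mutualism fixture**: a methionine auxotroph that obligately exports a
  carbon byproduct (20 mmol per gDW of growth) paired with a methionine
  secretor (0.5 mmol per gDW) growing only on that byproduct. A strictly
  obligate loop can never start from a sterile medium under FBA — some
  partner must move first — so the media seed a methionine trace (1e-11
  mmol) chosen so solo auxotroph growth stays below 1% of the inoculum
  while the co-culture loop (gain ≈ 2 per exchange round) amplifies to full
  growth. The toy MGE drain on the auxotroph converts sugar partly into
  byproduct, encoding the overflow-metabolism signature of carriage.

These fixtures reproduce the *mechanisms* — mass-normalised pseudoreaction
accounting, range-disjointness, burden ordering, cross-feeding feedback —
at hand-checkable size. They do not emulate the scale, redundancy or curated
subsystem structure of a genome-scale reconstruction: conflict fractions on
the toy host are far larger than in a real model (its optimal face is
nearly a point), and no kinetic realism is attempted. Passing desk-scale
tests therefore validates the machinery, not the published counts; those
are recomputed by the genome-scale recipe (`analysis/06_reproduce_ijo1366.py`)
when the published model and composition tables are supplied.

## Problem sizes and numerical choices

The suite and the acceptance script run entirely on the fixtures above
(≤ 45 reactions, ≤ 200 dFBA cycles, 20-host sweeps), completing in seconds.
Vertex enumeration is restricted to fixtures of ≲ 8 reactions, where it is
exhaustive and exact. Ties in pFBA are broken by the solver; all assertions
compare quantities that are invariant across optimal-face vertices.
Degenerate inputs (empty MGE, zero-length pilus, zero-biomass species,
empty media pools) are defined behaviours with tests, not errors, except
where a contract is genuinely violated (negative copy numbers, unknown
monomers, mismatched reaction sets).

## Known limitations

Loopless FBA, thermodynamic constraints, proteome-allocation models, MOMA
and expression integration are out of scope. The dFBA scheme is explicit
Euler with linear uptake caps, not Michaelis–Menten kinetics, and has no
spatial structure, lag phases or stochastic demography. Gene–reaction
association is a flat gene → reactions map sufficient for single knockouts,
not full boolean GPR evaluation. Reproduction of published genome-scale
counts depends on the exact pilus/capsid copy-number table used to build
the pseudoreactions.
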