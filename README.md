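# mgeburden

Mobile genetic elements (MGEs) — conjugative plasmids, filamentous phage —
replicate inside bacterial hosts and divert nucleotides, amino acids and ATP
from host growth. `mgeburden` quantifies that metabolic conflict inside
genome-scale metabolic models and propagates it to community scale:

1. **MGE biomass pseudoreactions.** From an MGE's genome sequence and its
   proteome (sequences + per-particle copy numbers), build a single-direction
   pseudoreaction whose stoichiometric coefficients are expressed in mmol per
   gram of MGE. Per particle, nucleotide counts are
   `N_i_tot = C_g (N_i_genome + N_i_intermediates)` (both strands for dsDNA;
   the replicative-form second strand for ssDNA phage) and amino-acid counts
   are `AA_j_tot = sum_k C_k AA_j_k`. Polymerisation is charged at 4 ATP per
   amino acid (hydrolysed with H2O to ADP + Pi + H+) and credited 1 PPi per
   nucleotide. Coefficients are `count / M_MGE x 1000`, so 1 mmol of
   pseudoreaction flux consumes exactly 1 g of monomers. Pilus costs come
   from a helical geometry calculator (propilin copies =
   `round(length / pitch x subunits_per_turn)`, default 12.8 subunits/turn on
   a 5-start helix, 20 µm maximum length) or an explicit copy-number table.
2. **Constraint-based analyses.** FBA (`maximize Z = c^T v` subject to
   `S v = 0`, `lb <= v <= ub`), parsimonious FBA (minimum total |flux| at the
   optimum) and FVA (per-reaction flux ranges over the optimal face), solved
   with HiGHS via SciPy. Carriage states follow the standard protocol:
   host-optimised (biomass objective, MGE bounds 0), plasmid-optimised, and
   phage-optimised with a constitutive plasmid demand of 0.9 mmol gDW⁻¹ hr⁻¹
   (phage demand 0.06 in the intermediate double-carriage state).
3. **Conflict statistics.** Reactions whose FVA ranges in host- vs
   MGE-optimised states share no value are *conflict reactions* (tallied per
   cellular subprocess), and pFBA gives per-subsystem demand fold-changes
   `log2[(Σ_i|F_i^P|/Σ_k|F_k^P|) / (Σ_i|F_i^H|/Σ_k|F_k^H|)]`, dropping
   reactions whose flux direction flips between states.
4. **Dynamic FBA.** Batch co-culture of up to three species sharing a
   well-mixed nutrient pool (1 h cycles, uptake capped by pool size and a
   10 mmol gDW⁻¹ hr⁻¹ Vmax, forward-Euler biomass updates), for studying how
   MGE burden reshapes cross-feeding mutualisms.

Host edits for the classic methionine cross-feeding system are built in: a
*metB* (cystathionine gamma-synthase) knockout makes the *E. coli*-like host
a methionine auxotroph, and a secretor edit couples 0.5 mmol of extracellular
methionine to each gram of partner biomass with reuptake blocked.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale on
generated fixtures (a ~45-reaction toy host whose metabolite namespace
matches the default monomer table, plus toy MGE compositions):

```bash
python analysis/01_make_fixtures.py
python analysis/02_build_pseudoreactions.py
python analysis/03_conflict_analysis.py
python analysis/04_dfba_monoculture.py
python analysis/05_dfba_mutualism.py
```

`02` prints, for the 4-nt + ("MK" × 2) hand-checked toy MGE:

```
hand_toy: M = 2,538.5 g/mol; ATP 6.303, PPi 1.576 mmol/g; mass-normalisation residual 0.00e+00 (target < 1e-6)
```

i.e. the particle weighs 2 538.5 g/mol, producing 1 g of it costs 6.3 mmol
ATP and releases 1.58 mmol PPi, and the monomer coefficients account for
exactly one gram. `03` reports the conflict statistics on the toy host
(37/45 reactions in conflict under plasmid optimisation, 38 under
phage-plus-plasmid, 1 unique to the double carrier — at toy scale the
optimal face is tiny, so conflict fractions are far higher than in a
genome-scale model). `05` shows the community consequence:

```
solo growth (fold over inoculum): auxotroph 1.002, secretor 1.000  (obligate pair)
co-culture: auxotroph 2,781x, secretor 5,561x inoculum; auxotroph share 0.333
with MGE demand 0.9 mmol/gDW/hr on the auxotroph: share 0.279 (shift toward partner: +0.055)
```

— neither partner grows alone, both grow together, and forcing the
auxotroph to produce MGE particles shifts the final species ratio toward its
partner.

`analysis/06_reproduce_ijo1366.py` is the genome-scale recipe: given
`data/external/iJO1366.json` (BiGG) and MGE composition YAMLs derived from
GenBank NZ_CP014271 + AY528506 (plasmid F128/Tn10) and JX412914 (phage M13)
with a pilus/capsid copy-number table, it rebuilds the published conflict
counts (2,585 reactions; 103 and 117 conflict reactions; 15 double-carrier
unique; 4 direction-change drops). These inputs are published datasets and
are not shipped in this repository.

A `mgeburden` CLI wraps the same library (`build-mge`, `integrate`, `fba`,
`pfba`, `fva`, `conflicts`, `demand`, `dfba`, `make-fixtures`).

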