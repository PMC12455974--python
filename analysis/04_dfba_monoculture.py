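#!/usr/bin/env python
"""Batch dynamic FBA monocultures: growth, yield and secretion under burden.

Runs the closed-form batch fixture (yield check) and the auxotroph
monoculture with and without a forced MGE production demand, showing that
carriage raises biomass-normalised byproduct secretion — the overflow
signature.  Trajectories go to results/dfba_monoculture/.
"""

from pathlib import Path

from mgeburden import io as mio
from mgeburden.dfba import biomass_normalized_secretion, cells_from_biomass, run
from mgeburden.synth import (BATCH_YIELD, make_batch_growth_fixture,
                             make_mutualism_fixture)

OUT = Path(__file__).resolve().parents[1] / "results" / "dfba_monoculture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    x0 = 1e-8
    print(f"inoculum: {x0:g} gDW = {cells_from_biomass(x0):,.0f} cells "
          f"at 3e-13 g/cell")

    c0 = 1e-3
    batch = run(make_batch_growth_fixture(carbon_mmol=c0, x0=x0))
    batch.to_frame().to_csv(OUT / "batch_trajectory.tsv", sep="\t", index=False)
    batch.media_frame().to_csv(OUT / "batch_media.tsv", sep="\t", index=False)
    expected = x0 + BATCH_YIELD * c0
    print(f"batch fixture: final biomass {batch.final_biomass('batch'):.6g} gDW "
          f"(closed form {expected:.6g}; "
          f"error {100 * abs(batch.final_biomass('batch') - expected) / expected:.3f}%)")

    for label, lb in (("wt", 0.0), ("mge_carrier", 0.9)):
        cfg = make_mutualism_fixture(include_secretor=False,
                                     auxotroph_mge_lb=lb, n_cycles=40)
        cfg.media["met__L_e"] = 1000.0  # methionine in excess for monoculture
        traj = run(cfg)
        traj.to_frame().to_csv(OUT / f"auxotroph_{label}_trajectory.tsv",
                               sep="\t", index=False)
        sec = biomass_normalized_secretion(traj, "byp_e", "auxotroph")
        print(f"auxotroph {label}: final biomass "
              f"{traj.final_biomass('auxotroph'):.4g} gDW; "
              f"normalised byproduct secretion {sec[-1]:.3f} mmol/gDW")

    mio.write_provenance(OUT, {"step": "04_dfba_monoculture"})


if __name__ == "__main__":
    main()
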