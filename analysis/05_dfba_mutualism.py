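#!/usr/bin/env python
"""Cross-feeding co-cultures: obligate mutualism and the effect of MGE burden.

Runs the two-species methionine/byproduct mutualism solo and together, then
repeats the co-culture with a constitutive MGE production demand on the
auxotroph, quantifying the shift of the final species ratio toward the
partner.  Outputs under results/dfba_mutualism/.
"""

from pathlib import Path

from mgeburden import io as mio
from mgeburden.dfba import run
from mgeburden.synth import make_mutualism_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "dfba_mutualism"
X0 = 1e-8


def aux_share(traj) -> float:
    a = traj.final_biomass("auxotroph")
    s = traj.final_biomass("secretor")
    return a / (a + s)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    solo_aux = run(make_mutualism_fixture(include_secretor=False))
    solo_sec = run(make_mutualism_fixture(include_auxotroph=False))
    print(f"solo growth (fold over inoculum): auxotroph "
          f"{solo_aux.final_biomass('auxotroph') / X0:.3f}, secretor "
          f"{solo_sec.final_biomass('secretor') / X0:.3f}  (obligate pair)")

    both = run(make_mutualism_fixture())
    both.to_frame().to_csv(OUT / "coculture_trajectory.tsv", sep="\t", index=False)
    both.media_frame().to_csv(OUT / "coculture_media.tsv", sep="\t", index=False)
    print(f"co-culture: auxotroph {both.final_biomass('auxotroph') / X0:,.0f}x, "
          f"secretor {both.final_biomass('secretor') / X0:,.0f}x inoculum; "
          f"auxotroph share {aux_share(both):.3f}")

    burdened = run(make_mutualism_fixture(auxotroph_mge_lb=0.9))
    burdened.to_frame().to_csv(OUT / "coculture_burdened_trajectory.tsv",
                               sep="\t", index=False)
    print(f"with MGE demand 0.9 mmol/gDW/hr on the auxotroph: share "
          f"{aux_share(burdened):.3f} "
          f"(shift toward partner: {aux_share(both) - aux_share(burdened):+.3f})")

    mio.write_provenance(OUT, {"step": "05_dfba_mutualism"})


if __name__ == "__main__":
    main()
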