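#!/usr/bin/env python
"""Genome-scale reproduction recipe on iJO1366 (requires external inputs).

Expected inputs under data/external/ (published datasets, not shipped):
  - iJO1366.json        the E. coli reconstruction from the BiGG collection
  - f128_mge.yaml       plasmid F128 + Tn10 composition (genome sequence from
                        GenBank NZ_CP014271 + AY528506; pilus copy numbers)
  - m13_mge.yaml        phage M13 composition (JX412914; capsid copy numbers)

The pipeline knocks out metB, attaches both pseudoreactions, runs FVA in
host- vs MGE-optimised states and the pFBA demand metric, and writes the
conflict tables under results/ijo1366/.  Expected outcomes for reference:
2,585 metabolic reactions; 103 conflict reactions for F128+; 117 for
F128+ M13+; 15 unique to the double carrier; 4 direction-change drops.
Exact agreement depends on the pilus/capsid copy-number table used.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
EXTERNAL = ROOT / "data" / "external"
OUT = ROOT / "results" / "ijo1366"


def main() -> int:
    inputs = {name: EXTERNAL / name
              for name in ("iJO1366.json", "f128_mge.yaml", "m13_mge.yaml")}
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        print("genome-scale inputs not found (they are external downloads):")
        for p in missing:
            print(f"  missing {p}")
        print(__doc__)
        return 0

    from mgeburden.conflict import conflict_table
    from mgeburden import io as mio
    from mgeburden.pipeline import reproduce_genome_scale

    res = reproduce_genome_scale(inputs["iJO1366.json"],
                                 inputs["f128_mge.yaml"],
                                 inputs["m13_mge.yaml"])
    OUT.mkdir(parents=True, exist_ok=True)
    res["report_plasmid"].to_frame().to_csv(
        OUT / "conflict_subsystems_f128.tsv", sep="\t", index=False)
    res["report_double"].to_frame().to_csv(
        OUT / "conflict_subsystems_f128_m13.tsv", sep="\t", index=False)
    res["demand_plasmid"].to_frame().to_csv(
        OUT / "demand_fold_change_f128.tsv", sep="\t", index=False)
    res["demand_double"].to_frame().to_csv(
        OUT / "demand_fold_change_f128_m13.tsv", sep="\t", index=False)
    mio.write_provenance(OUT, {"step": "06_reproduce_ijo1366"})

    print(f"reactions: {res['n_reactions']} (reference 2585)")
    print(f"F128+ conflicts: {res['n_conflicts_f128']} (reference 103)")
    print(f"F128+M13+ conflicts: {res['n_conflicts_f128_m13']} (reference 117)")
    print(f"unique to double carrier: {res['n_unique_double']} (reference 15)")
    print(f"direction-change drops: {res['n_dropped']} (reference 4)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
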