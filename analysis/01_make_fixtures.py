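#!/usr/bin/env python
"""Generate the desk-scale study inputs and export them as files.

Writes the seeded toy host model, the certified branch-point conflict
fixture, and the toy MGE composition (FASTA + copy-number TSV) under
results/fixtures/, so later steps and readers can inspect the exact inputs.
"""

from pathlib import Path

from mgeburden import io as mio
from mgeburden.core import fba
from mgeburden.synth import (DEFAULT_SEED, ToySpec, hand_toy_mge,
                             make_conflict_fixture, make_toy_host, make_toy_mge)

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    host = make_toy_host(ToySpec(seed=DEFAULT_SEED))
    mio.write_model(host, OUT / "toy_host.json")
    z = fba(host).objective_value
    print(f"toy host (seed {DEFAULT_SEED}): {len(host.reactions)} reactions, "
          f"{len(host.metabolites)} metabolites, biomass optimum {z:.3f} /hr")

    model, mge_rxn, truth = make_conflict_fixture()
    mio.write_model(model, OUT / "conflict_fixture.json")
    print(f"conflict fixture: {model.reactions and len(model.reactions)} reactions; "
          f"certified conflict set {sorted(truth.conflict_reactions)} "
          f"({100 * truth.fraction_of_total:.0f}% of reactions)")

    genome, proteome = make_toy_mge(seed=DEFAULT_SEED)
    mio.write_mge_fasta_tsv(genome, proteome,
                            OUT / "toy_mge_genome.fasta",
                            OUT / "toy_mge_proteins.fasta",
                            OUT / "toy_mge_copies.tsv")
    gh, ph = hand_toy_mge()
    mio.write_mge_fasta_tsv(gh, ph,
                            OUT / "hand_toy_genome.fasta",
                            OUT / "hand_toy_proteins.fasta",
                            OUT / "hand_toy_copies.tsv")
    print(f"toy MGE: {len(genome.sequence)} nt genome, {len(proteome)} proteins; "
          f"hand toy: 4 nt + 'MK' x2 -> {OUT}")

    mio.write_provenance(OUT, {"step": "01_make_fixtures", "seed": DEFAULT_SEED},
                         seed=DEFAULT_SEED)


if __name__ == "__main__":
    main()
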