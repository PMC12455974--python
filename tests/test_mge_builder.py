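"""MGE composition accounting: monomer counts, polymerisation energetics,
molar mass, mmol-per-gram normalisation, pilus copy numbers, integration.

The reference coefficients for the hand toy MGE (4-nt ssDNA genome "ACGT",
one protein "MK" at 2 copies) were computed independently by spreadsheet
arithmetic before the builder existed and are frozen below.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgeburden.core import fba
from mgeburden.errors import IntegrationError, ValidationError
from mgeburden.mge import (AMINO_ACIDS, MgeGenomeSpec, MonomerTable,
                           NUCLEOTIDES, ProteinSpec, attach_pseudoreaction,
                           build_pseudoreaction, count_amino_acids,
                           count_nucleotides, pilin_copy_number,
                           polymerization_costs, scale_pilus_proteome,
                           ssdna_phage_genome, total_molar_mass)
from mgeburden.synth import hand_toy_mge, make_toy_mge

# spreadsheet oracle for the hand toy (M = 491.18+467.16+507.18+482.17
# + 2*149.21 + 2*146.19 = 2538.49 g/mol)
HAND_TOY_MASS = 2538.49
HAND_TOY_NT_COEFF = 0.39393497709268105     # 1000 / 2538.49
HAND_TOY_AA_COEFF = 0.7878699541853621      # 2000 / 2538.49
HAND_TOY_ATP_COEFF = 6.302959633482897      # 16000 / 2538.49
HAND_TOY_PPI_COEFF = 1.5757399083707242     # 4000 / 2538.49


class TestCountNucleotides:
    def test_ssdna_single_copy(self):
        g = MgeGenomeSpec("ACGT", strandedness="ssDNA")
        assert count_nucleotides(g) == {"A": 1, "C": 1, "G": 1, "T": 1}

    def test_dsdna_counts_both_strands(self):
        g = MgeGenomeSpec("AACG", strandedness="dsDNA")
        # complement strand contributes T,T,G,C
        assert count_nucleotides(g) == {"A": 2, "C": 2, "G": 2, "T": 2}

    def test_linearity_in_copy_number(self):
        g1 = MgeGenomeSpec("ACGTTGCA", strandedness="dsDNA", copy_number=1)
        g2 = MgeGenomeSpec("ACGTTGCA", strandedness="dsDNA", copy_number=2)
        c1, c2 = count_nucleotides(g1), count_nucleotides(g2)
        assert all(c2[nt] == 2 * c1[nt] for nt in NUCLEOTIDES)

    def test_replicative_form_intermediate(self):
        g = ssdna_phage_genome("AAAC")
        counts = count_nucleotides(g)
        # genome AAAC plus complementary-strand intermediate GTTT
        assert counts == {"A": 3, "C": 1, "G": 1, "T": 3}

    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError):
            count_nucleotides(MgeGenomeSpec("ACGN"))


class TestCountAminoAcids:
    def test_single_protein_with_copies(self):
        counts = count_amino_acids([ProteinSpec("p", "MK", 3)])
        assert counts["M"] == 3 and counts["K"] == 3

    def test_two_proteins_sum(self):
        counts = count_amino_acids([ProteinSpec("p1", "MK", 3),
                                    ProteinSpec("p2", "MMA", 2)])
        assert counts["M"] == 7 and counts["K"] == 3 and counts["A"] == 2

    def test_empty_proteome_all_zero(self):
        assert all(v == 0 for v in count_amino_acids([]).values())

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValidationError):
            count_amino_acids([ProteinSpec("p", "MXZ", 1)])


class TestPolymerizationCosts:
    def test_atp_is_four_per_amino_acid(self):
        aa = count_amino_acids([ProteinSpec("p", "MK", 1)])
        nt = {n: 0.0 for n in NUCLEOTIDES}
        atp, ppi = polymerization_costs(nt, aa)
        assert atp == 8.0 and ppi == 0.0

    def test_ppi_is_one_per_nucleotide(self):
        nt = count_nucleotides(MgeGenomeSpec("ACGT", strandedness="ssDNA"))
        atp, ppi = polymerization_costs(nt, {a: 0.0 for a in AMINO_ACIDS})
        assert atp == 0.0 and ppi == 4.0

    def test_empty_is_zero(self):
        atp, ppi = polymerization_costs({n: 0.0 for n in NUCLEOTIDES},
                                        {a: 0.0 for a in AMINO_ACIDS})
        assert (atp, ppi) == (0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            polymerization_costs({"A": -1, "C": 0, "G": 0, "T": 0}, {})


class TestTotalMolarMass:
    def test_single_nucleotide(self):
        table = MonomerTable()
        nt = {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}
        mass = total_molar_mass(nt, {a: 0.0 for a in AMINO_ACIDS}, table)
        assert mass == pytest.approx(table.nucleotide_masses["A"])

    def test_linearity_in_genome_copies(self):
        table = MonomerTable()
        aa0 = {a: 0.0 for a in AMINO_ACIDS}
        m1 = total_molar_mass(count_nucleotides(MgeGenomeSpec("ACGT")), aa0, table)
        m2 = total_molar_mass(
            count_nucleotides(MgeGenomeSpec("ACGT", copy_number=2)), aa0, table)
        assert m2 == pytest.approx(2 * m1)

    def test_hand_toy_matches_spreadsheet(self):
        genome, proteome = hand_toy_mge()
        mass = total_molar_mass(count_nucleotides(genome),
                                count_amino_acids(proteome), MonomerTable())
        assert mass == pytest.approx(HAND_TOY_MASS, rel=1e-12)


class TestBuildPseudoreaction:
    def test_hand_toy_coefficients_match_spreadsheet(self):
        genome, proteome = hand_toy_mge()
        spec, _ = build_pseudoreaction(genome, proteome)
        for nt in NUCLEOTIDES:
            assert spec.nucleotide_coeffs[nt] == pytest.approx(HAND_TOY_NT_COEFF, rel=1e-9)
        assert spec.aa_coeffs["M"] == pytest.approx(HAND_TOY_AA_COEFF, rel=1e-9)
        assert spec.aa_coeffs["K"] == pytest.approx(HAND_TOY_AA_COEFF, rel=1e-9)
        assert spec.atp_coeff == pytest.approx(HAND_TOY_ATP_COEFF, rel=1e-9)
        assert spec.ppi_coeff == pytest.approx(HAND_TOY_PPI_COEFF, rel=1e-9)
        assert spec.total_molar_mass == pytest.approx(HAND_TOY_MASS, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_mass_normalization_identity(self, seed):
        """1 mmol of pseudoreaction flux consumes exactly 1 g of monomers."""
        genome, proteome = make_toy_mge(seed=seed, genome_length=80, n_proteins=4)
        spec, _ = build_pseudoreaction(genome, proteome)
        assert spec.mass_check(MonomerTable()) == pytest.approx(1000.0, abs=1e-6)

    def test_phosphate_bookkeeping(self):
        genome, proteome = make_toy_mge(seed=3, genome_length=60, n_proteins=3)
        spec, _ = build_pseudoreaction(genome, proteome)
        assert spec.adp_coeff == spec.atp_coeff == spec.pi_coeff
        assert spec.h_coeff == spec.h2o_coeff == spec.atp_coeff
        assert spec.ppi_coeff == pytest.approx(sum(spec.nucleotide_coeffs.values()))

    def test_linearity_in_protein_copies(self):
        genome, _ = hand_toy_mge()
        s1, _ = build_pseudoreaction(genome, [ProteinSpec("p", "MK", 1)])
        s2, _ = build_pseudoreaction(genome, [ProteinSpec("p", "MK", 2)])
        # counts double; coefficients renormalise to the heavier particle
        assert s2.total_molar_mass > s1.total_molar_mass
        assert s2.aa_coeffs["M"] * s2.total_molar_mass == pytest.approx(
            2 * s1.aa_coeffs["M"] * s1.total_molar_mass)

    def test_empty_proteome_has_no_atp_terms(self):
        genome = MgeGenomeSpec("ACGTACGT")
        spec, rxn = build_pseudoreaction(genome, [])
        assert spec.atp_coeff == spec.adp_coeff == spec.pi_coeff == 0.0
        assert spec.h_coeff == spec.h2o_coeff == 0.0
        table = MonomerTable()
        assert table.atp_id not in rxn.stoichiometry

    def test_bonds_basis_reduces_atp(self):
        genome, proteome = hand_toy_mge()
        total, _ = build_pseudoreaction(genome, proteome, atp_basis="total")
        bonds, _ = build_pseudoreaction(genome, proteome, atp_basis="bonds")
        # "MK" x2: 4 residues vs 2 bonds
        assert bonds.atp_coeff == pytest.approx(total.atp_coeff / 2)

    def test_reaction_sides(self):
        genome, proteome = hand_toy_mge()
        _, rxn = build_pseudoreaction(genome, proteome)
        table = MonomerTable()
        assert rxn.stoichiometry[table.atp_id] < 0
        assert rxn.stoichiometry[table.h2o_id] < 0
        assert rxn.stoichiometry[table.nucleotide_ids["A"]] < 0
        for pid in (table.adp_id, table.pi_id, table.h_id, table.ppi_id):
            assert rxn.stoichiometry[pid] > 0
        assert rxn.lower_bound == 0.0 and rxn.upper_bound == 1000.0
        assert rxn.is_pseudoreaction


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    genome=st.text(alphabet="ACGT", min_size=1, max_size=60),
    protein=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30),
    copies=st.integers(min_value=1, max_value=50),
    cg=st.integers(min_value=1, max_value=5),
    ds=st.booleans(),
)
def test_mass_normalization_holds_for_arbitrary_compositions(genome, protein,
                                                             copies, cg, ds):
    """Property: the mmol-per-gram coefficients always account for exactly
    one gram of monomer mass, whatever the composition."""
    spec, _ = build_pseudoreaction(
        MgeGenomeSpec(genome, strandedness="dsDNA" if ds else "ssDNA",
                      copy_number=cg),
        [ProteinSpec("p", protein, copies)])
    assert spec.mass_check(MonomerTable()) == pytest.approx(1000.0, abs=1e-6)
    assert spec.ppi_coeff == pytest.approx(sum(spec.nucleotide_coeffs.values()))


class TestPilinCopyNumber:
    def test_zero_length_zero_copies(self):
        assert pilin_copy_number(0.0, 12.8, 1.28) == 0

    def test_one_turn_rounds_up(self):
        # one full turn of pitch 1.28 nm -> 12.8 subunits -> rounds to 13
        assert pilin_copy_number(1.28e-3, 12.8, 1.28) == 13

    def test_twenty_micron_pilus_scales_with_pitch(self):
        # 20 um at 12.8 subunits per turn; pitch is a config value
        copies = pilin_copy_number(20.0, 12.8, 1.28)
        assert copies == round(20.0 * 1000 / 1.28 * 12.8)
        ratios = scale_pilus_proteome(copies, {"traB": 0.01})
        assert ratios["traB"] == round(copies * 0.01)

    def test_invalid_pitch_rejected(self):
        with pytest.raises(ValidationError):
            pilin_copy_number(20.0, 12.8, 0.0)


class TestAttachPseudoreaction:
    def test_unused_pseudoreaction_leaves_optimum(self, toy_host):
        genome, proteome = hand_toy_mge()
        _, rxn = build_pseudoreaction(genome, proteome, reaction_id="MGE_toy")
        z0 = fba(toy_host).objective_value
        attached = attach_pseudoreaction(toy_host, rxn, lower_bound=0.0)
        assert fba(attached).objective_value == pytest.approx(z0, rel=1e-9)
        assert attached.reaction("MGE_toy").is_pseudoreaction
        assert not toy_host.has_reaction("MGE_toy")

    def test_forced_production_lowers_optimum(self, toy_host):
        genome, proteome = hand_toy_mge()
        _, rxn = build_pseudoreaction(genome, proteome, reaction_id="MGE_toy")
        z0 = fba(toy_host).objective_value
        attached = attach_pseudoreaction(toy_host, rxn, lower_bound=0.9)
        z1 = fba(attached).objective_value
        assert z1 <= z0 + 1e-9

    def test_double_attach_rejected(self, toy_host):
        genome, proteome = hand_toy_mge()
        _, rxn = build_pseudoreaction(genome, proteome, reaction_id="MGE_toy")
        attached = attach_pseudoreaction(toy_host, rxn)
        with pytest.raises(IntegrationError):
            attach_pseudoreaction(attached, rxn)

    def test_missing_metabolite_rejected(self, chain_model):
        genome, proteome = hand_toy_mge()
        _, rxn = build_pseudoreaction(genome, proteome)
        with pytest.raises(IntegrationError):
            attach_pseudoreaction(chain_model, rxn)
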