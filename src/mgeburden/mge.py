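"""Build biomass pseudoreactions for mobile genetic elements.

An MGE particle (conjugative plasmid, filamentous phage) is reduced to its
genome and proteome composition.  Per-particle monomer counts are

    N_i^tot  = C_g * (N_i^genome + N_i^intermediates)      (deoxynucleotides)
    AA_j^tot = sum_k C_k * AA_j^k                          (amino acids)

with C_g the genome copy number per particle and C_k the copy number of
protein k.  Counts are converted to stoichiometric coefficients in
**mmol per gram of MGE** by dividing by the particle's total molar mass
(genome + proteome) and multiplying by 1000.  Polymerisation energetics are
charged as 4 ATP per amino acid (hydrolysed to ADP + Pi + H+, consuming one
water each) and credited as 1 PPi released per nucleotide incorporated.

The resulting single-direction pseudoreaction consumes dNTPs, amino acids,
ATP and H2O and produces ADP, H+, Pi and PPi, mapped into the host model's
metabolite namespace through a :class:`MonomerTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .core import MetabolicModel, Reaction
from .errors import IntegrationError, ValidationError

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: average molar masses (g/mol) of the free deoxynucleoside triphosphates
DNTP_MASSES = {"A": 491.18, "C": 467.16, "G": 507.18, "T": 482.17}

#: average molar masses (g/mol) of the free amino acids
AMINO_ACID_MASSES = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

ATP_PER_AMINO_ACID = 4.0
PPI_PER_NUCLEOTIDE = 1.0


@dataclass
class MgeGenomeSpec:
    """Genome of one MGE particle.

    ``sequence`` is the particle's packaged strand (5'->3').  For dsDNA the
    complementary strand is counted automatically.  ``intermediates`` are
    additional sequences replicated per particle (e.g. the second strand of a
    filamentous phage's double-stranded replicative form), counted as given.
    """

    sequence: str
    strandedness: str = "dsDNA"  # ssDNA | dsDNA
    copy_number: int = 1
    intermediates: Tuple[str, ...] = ()

    def validate(self) -> None:
        if self.strandedness not in ("ssDNA", "dsDNA"):
            raise ValidationError(f"unknown strandedness {self.strandedness!r}")
        if self.copy_number < 1:
            raise ValidationError("genome copy number must be >= 1")
        for seq in (self.sequence, *self.intermediates):
            bad = set(seq.upper()) - set(NUCLEOTIDES)
            if bad:
                raise ValidationError(f"non-ACGT characters in genome sequence: {sorted(bad)}")


def ssdna_phage_genome(sequence: str, copy_number: int = 1,
                       include_replicative_form: bool = True) -> MgeGenomeSpec:
    """ssDNA genome spec; by default the complementary strand of the
    double-stranded replicative form is included as a replication intermediate."""
    intermediates: Tuple[str, ...] = ()
    if include_replicative_form:
        intermediates = (reverse_complement(sequence),)
    return MgeGenomeSpec(sequence=sequence, strandedness="ssDNA",
                         copy_number=copy_number, intermediates=intermediates)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ProteinSpec:
    protein_id: str
    sequence: str
    copy_number: int = 1

    def validate(self) -> None:
        if self.copy_number < 0:
            raise ValidationError(f"protein {self.protein_id!r}: negative copy number")
        if self.copy_number > 0 and not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence with copies > 0")
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}")


@dataclass
class MonomerTable:
    """Monomer masses and host-model metabolite ids.

    Maps the 4 deoxynucleotides and 20 amino acids (plus the energy species
    ATP/ADP/Pi/PPi/H2O/H+) onto the host model's namespace.  Defaults use
    BiGG-style cytosolic ids and free-monomer average masses.
    """

    nucleotide_masses: Dict[str, float] = field(default_factory=lambda: dict(DNTP_MASSES))
    amino_acid_masses: Dict[str, float] = field(default_factory=lambda: dict(AMINO_ACID_MASSES))
    nucleotide_ids: Dict[str, str] = field(default_factory=lambda: {
        "A": "datp_c", "C": "dctp_c", "G": "dgtp_c", "T": "dttp_c"})
    amino_acid_ids: Dict[str, str] = field(default_factory=lambda: {
        "A": "ala__L_c", "R": "arg__L_c", "N": "asn__L_c", "D": "asp__L_c",
        "C": "cys__L_c", "E": "glu__L_c", "Q": "gln__L_c", "G": "gly_c",
        "H": "his__L_c", "I": "ile__L_c", "L": "leu__L_c", "K": "lys__L_c",
        "M": "met__L_c", "F": "phe__L_c", "P": "pro__L_c", "S": "ser__L_c",
        "T": "thr__L_c", "W": "trp__L_c", "Y": "tyr__L_c", "V": "val__L_c"})
    atp_id: str = "atp_c"
    adp_id: str = "adp_c"
    pi_id: str = "pi_c"
    ppi_id: str = "ppi_c"
    h2o_id: str = "h2o_c"
    h_id: str = "h_c"

    def validate(self) -> None:
        for nt in NUCLEOTIDES:
            if nt not in self.nucleotide_masses or nt not in self.nucleotide_ids:
                raise ValidationError(f"monomer table missing nucleotide {nt}")
            if self.nucleotide_masses[nt] <= 0:
                raise ValidationError(f"nonpositive mass for nucleotide {nt}")
        for aa in AMINO_ACIDS:
            if aa not in self.amino_acid_masses or aa not in self.amino_acid_ids:
                raise ValidationError(f"monomer table missing amino acid {aa}")
            if self.amino_acid_masses[aa] <= 0:
                raise ValidationError(f"nonpositive mass for amino acid {aa}")


@dataclass
class PseudoreactionSpec:
    """Stoichiometric coefficients of an MGE biomass pseudoreaction, mmol/g MGE."""

    nucleotide_coeffs: Dict[str, float]
    aa_coeffs: Dict[str, float]
    atp_coeff: float
    h2o_coeff: float
    adp_coeff: float
    pi_coeff: float
    h_coeff: float
    ppi_coeff: float
    total_molar_mass: float  # g per mol of MGE particle

    def mass_check(self, table: MonomerTable) -> float:
        """Sum over monomers of coeff * molar mass; 1000 by construction."""
        total = sum(self.nucleotide_coeffs[nt] * table.nucleotide_masses[nt]
                    for nt in NUCLEOTIDES)
        total += sum(self.aa_coeffs[aa] * table.amino_acid_masses[aa]
                     for aa in AMINO_ACIDS)
        return total


def count_nucleotides(genome: MgeGenomeSpec) -> Dict[str, float]:
    """Per-particle nucleotide counts N_i^tot = C_g * (genome + intermediates).

    dsDNA genomes contribute both strands of the packaged molecule;
    intermediate sequences are counted exactly as given.
    """
    genome.validate()
    counts = {nt: 0.0 for nt in NUCLEOTIDES}
    seq = genome.sequence.upper()
    for nt in NUCLEOTIDES:
        counts[nt] += seq.count(nt)
    if genome.strandedness == "dsDNA":
        comp = seq.translate(_COMPLEMENT)
        for nt in NUCLEOTIDES:
            counts[nt] += comp.count(nt)
    for inter in genome.intermediates:
        s = inter.upper()
        for nt in NUCLEOTIDES:
            counts[nt] += s.count(nt)
    return {nt: genome.copy_number * counts[nt] for nt in NUCLEOTIDES}


def count_amino_acids(proteome: List[ProteinSpec]) -> Dict[str, float]:
    """Per-particle amino-acid counts AA_j^tot = sum_k C_k * AA_j^k."""
    counts = {aa: 0.0 for aa in AMINO_ACIDS}
    for p in proteome:
        p.validate()
        seq = p.sequence.upper()
        for aa in AMINO_ACIDS:
            counts[aa] += p.copy_number * seq.count(aa)
    return counts


def polymerization_costs(nt_counts: Mapping[str, float],
                         aa_counts: Mapping[str, float]) -> Tuple[float, float]:
    """(ATP required, PPi released) per particle.

    4 ATP per amino acid incorporated (charged on total residue counts) and
    1 PPi per nucleotide incorporated, replication intermediates included.
    """
    if any(v < 0 for v in nt_counts.values()) or any(v < 0 for v in aa_counts.values()):
        raise ValidationError("negative monomer counts")
    atp = ATP_PER_AMINO_ACID * sum(aa_counts.values())
    ppi = PPI_PER_NUCLEOTIDE * sum(nt_counts.values())
    return atp, ppi


def total_molar_mass(nt_counts: Mapping[str, float], aa_counts: Mapping[str, float],
                     table: MonomerTable) -> float:
    """Particle molar mass (g/mol) from genome + proteome monomer content."""
    table.validate()
    mass = sum(nt_counts.get(nt, 0.0) * table.nucleotide_masses[nt] for nt in NUCLEOTIDES)
    mass += sum(aa_counts.get(aa, 0.0) * table.amino_acid_masses[aa] for aa in AMINO_ACIDS)
    return mass


def pilin_copy_number(total_length_um: float, subunits_per_turn: float,
                      pitch_per_turn_nm: float) -> int:
    """Copies of the major pilin needed for a pilus of the given total length.

    The conjugative pilus is a multi-start helix; with ``subunits_per_turn``
    pilin monomers per helical turn and a helical rise of
    ``pitch_per_turn_nm`` per turn, a filament of ``total_length_um`` microns
    requires length / pitch turns.
    """
    if pitch_per_turn_nm <= 0:
        raise ValidationError("helical pitch must be positive")
    if subunits_per_turn <= 0:
        raise ValidationError("subunits per turn must be positive")
    if total_length_um < 0:
        raise ValidationError("pilus length cannot be negative")
    turns = total_length_um * 1000.0 / pitch_per_turn_nm
    return int(round(turns * subunits_per_turn))


def scale_pilus_proteome(pilin_copies: int, ratio_table: Mapping[str, float]) -> Dict[str, int]:
    """Scale other pilus-protein copy numbers from the major pilin count.

    ``ratio_table`` maps protein id -> copies per pilin copy.
    """
    return {pid: int(round(pilin_copies * ratio)) for pid, ratio in ratio_table.items()}


def build_pseudoreaction(genome: Optional[MgeGenomeSpec], proteome: List[ProteinSpec],
                         table: Optional[MonomerTable] = None,
                         reaction_id: str = "MGE_biomass",
                         lower_bound: float = 0.0, upper_bound: float = 1000.0,
                         atp_basis: str = "total",
                         ) -> Tuple[PseudoreactionSpec, Reaction]:
    """Assemble the single-direction MGE biomass pseudoreaction.

    Left-hand side: dNTPs, amino acids, ATP and H2O; right-hand side: ADP,
    H+ and Pi from amino-acid polymerisation plus PPi from nucleotide
    polymerisation.  All coefficients are count / total molar mass * 1000,
    i.e. mmol consumed (produced) per gram of MGE biomass flux.

    ``atp_basis='bonds'`` charges 4 ATP per peptide *bond* (residues - 1 per
    protein) instead of per residue, for sensitivity analysis.
    """
    table = table or MonomerTable()
    table.validate()
    nt_counts = count_nucleotides(genome) if genome is not None else {nt: 0.0 for nt in NUCLEOTIDES}
    aa_counts = count_amino_acids(proteome)
    M = total_molar_mass(nt_counts, aa_counts, table)
    if M <= 0:
        raise ValidationError("MGE has zero mass: empty genome and proteome")

    if atp_basis == "total":
        atp_count, ppi_count = polymerization_costs(nt_counts, aa_counts)
    elif atp_basis == "bonds":
        atp_count = ATP_PER_AMINO_ACID * sum(
            p.copy_number * max(len(p.sequence) - 1, 0) for p in proteome)
        _, ppi_count = polymerization_costs(nt_counts, aa_counts)
    else:
        raise ValidationError(f"unknown atp_basis {atp_basis!r}")

    to_mmol = 1000.0 / M
    nt_coeffs = {nt: nt_counts[nt] * to_mmol for nt in NUCLEOTIDES}
    aa_coeffs = {aa: aa_counts[aa] * to_mmol for aa in AMINO_ACIDS}
    atp_coeff = atp_count * to_mmol
    ppi_coeff = ppi_count * to_mmol

    spec = PseudoreactionSpec(
        nucleotide_coeffs=nt_coeffs, aa_coeffs=aa_coeffs,
        atp_coeff=atp_coeff, h2o_coeff=atp_coeff,
        adp_coeff=atp_coeff, pi_coeff=atp_coeff, h_coeff=atp_coeff,
        ppi_coeff=ppi_coeff, total_molar_mass=M)

    stoich: Dict[str, float] = {}
    for nt, coeff in nt_coeffs.items():
        if coeff > 0:
            stoich[table.nucleotide_ids[nt]] = stoich.get(table.nucleotide_ids[nt], 0.0) - coeff
    for aa, coeff in aa_coeffs.items():
        if coeff > 0:
            stoich[table.amino_acid_ids[aa]] = stoich.get(table.amino_acid_ids[aa], 0.0) - coeff
    if atp_coeff > 0:
        stoich[table.atp_id] = stoich.get(table.atp_id, 0.0) - atp_coeff
        stoich[table.h2o_id] = stoich.get(table.h2o_id, 0.0) - atp_coeff
        stoich[table.adp_id] = stoich.get(table.adp_id, 0.0) + atp_coeff
        stoich[table.pi_id] = stoich.get(table.pi_id, 0.0) + atp_coeff
        stoich[table.h_id] = stoich.get(table.h_id, 0.0) + atp_coeff
    if ppi_coeff > 0:
        stoich[table.ppi_id] = stoich.get(table.ppi_id, 0.0) + ppi_coeff
    if not stoich:
        raise ValidationError("pseudoreaction has empty stoichiometry")

    rxn = Reaction(id=reaction_id, stoichiometry=stoich,
                   lower_bound=lower_bound, upper_bound=upper_bound,
                   subsystem="MGE biomass", is_pseudoreaction=True,
                   name=f"{reaction_id} production pseudoreaction")
    return spec, rxn


def attach_pseudoreaction(model: MetabolicModel, rxn: Reaction,
                          lower_bound: float = 0.0,
                          upper_bound: float = 1000.0) -> MetabolicModel:
    """Return a copy of ``model`` with the pseudoreaction added.

    Every metabolite the reaction touches must already exist in the model;
    an existing reaction with the same id is an integration error.
    """
    if model.has_reaction(rxn.id):
        raise IntegrationError(f"model already contains a reaction {rxn.id!r}")
    missing = [m for m in rxn.stoichiometry if not model.has_metabolite(m)]
    if missing:
        raise IntegrationError(
            f"model lacks metabolites required by {rxn.id!r}: {sorted(missing)}")
    out = model.copy()
    new = Reaction(id=rxn.id, stoichiometry=dict(rxn.stoichiometry),
                   lower_bound=lower_bound, upper_bound=upper_bound,
                   subsystem=rxn.subsystem or "MGE biomass",
                   is_exchange=False, is_pseudoreaction=True, name=rxn.name)
    out.reactions.append(new)
    out.validate()
    return out
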