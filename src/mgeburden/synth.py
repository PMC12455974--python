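"""Desk-scale synthetic fixtures with known ground truth.

Generates the four kinds of inputs the analyses need at hand-checkable size:

* a toy host network (carbon uptake, respiration/overflow branch, monomer
  biosynthesis subsystems, biomass) whose metabolite namespace matches the
  default monomer table, so MGE pseudoreactions attach unchanged;
* toy MGE composition specs (random genome + proteome, seeded), including a
  fixed 4-nt / one-protein "hand toy" whose coefficients were computed
  independently by spreadsheet arithmetic;
* an analytic branch-point conflict fixture whose FVA conflict set is
  certified by brute-force vertex enumeration at generation time;
* batch-growth and two-species cross-feeding mutualism configurations for
  the dynamic FBA simulator, with closed-form expectations.

All generators are deterministic under a fixed seed (default 1729).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .conflict import ConflictReport
from .core import MetabolicModel, Metabolite, Reaction, fba
from .dfba import SimulationConfig, SpeciesState
from .errors import ValidationError
from .exact import oracle_fva
from .mge import (AMINO_ACIDS, MgeGenomeSpec, MonomerTable, NUCLEOTIDES,
                  ProteinSpec)

DEFAULT_SEED = 1729


@dataclass
class ToySpec:
    """Parameters of the seeded toy host generator."""

    seed: int = DEFAULT_SEED
    carbon_uptake_bound: float = 50.0  # mmol gDW^-1 hr^-1 sugar uptake cap
    respiration_cap: float = 10.0      # flux cap forcing overflow at high demand
    yield_jitter: float = 0.2          # relative jitter on biosynthetic yields
    atp_per_biomass: float = 10.0


def make_toy_host(spec: Optional[ToySpec] = None) -> MetabolicModel:
    """Small host model: sugar uptake, fermentation/respiration branch with
    overflow byproduct export, amino-acid / nucleotide / lipid biosynthesis
    subsystems, and a biomass reaction consuming all of them.

    Metabolite ids follow the default monomer table (datp_c, ala__L_c, ...)
    so that MGE pseudoreactions built with default settings attach directly.
    Biosynthetic yields carry seeded jitter so repeated seeds give a family
    of distinct but structurally identical hosts.
    """
    spec = spec or ToySpec()
    rng = np.random.default_rng(spec.seed)
    table = MonomerTable()

    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def M(mid: str, compartment: str) -> None:
        mets.append(Metabolite(id=mid, compartment=compartment))

    for mid in ("lcts_e", "ac_e", "co2_e", "h2o_e", "h_e", "met__L_e", "pi_e"):
        M(mid, "e")
    for mid in ("lcts_c", "ac_c", "co2_c", "atp_c", "adp_c", "pi_c", "ppi_c",
                "h2o_c", "h_c", "lipid_c"):
        M(mid, "c")
    for aa in AMINO_ACIDS:
        M(table.amino_acid_ids[aa], "c")
    for nt in NUCLEOTIDES:
        M(table.nucleotide_ids[nt], "c")

    def R(rid: str, stoich: Dict[str, float], lb: float, ub: float, subsystem: str,
          exchange: bool = False, gene_rule: str = "") -> None:
        rxns.append(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                             upper_bound=ub, subsystem=subsystem,
                             is_exchange=exchange, gene_reaction_rule=gene_rule))

    # environment coupling
    R("EX_lcts_e", {"lcts_e": -1}, -spec.carbon_uptake_bound, 1000, "Exchange", True)
    R("EX_ac_e", {"ac_e": -1}, 0, 1000, "Exchange", True)
    R("EX_co2_e", {"co2_e": -1}, 0, 1000, "Exchange", True)
    R("EX_h2o_e", {"h2o_e": -1}, -1000, 1000, "Exchange", True)
    R("EX_h_e", {"h_e": -1}, -1000, 1000, "Exchange", True)
    R("EX_met__L_e", {"met__L_e": -1}, 0, 1000, "Exchange", True)
    R("EX_pi_e", {"pi_e": -1}, -1000, 1000, "Exchange", True)
    R("PIt", {"pi_e": -1, "pi_c": 1}, -1000, 1000, "Transport")
    R("LCTSt", {"lcts_e": -1, "lcts_c": 1}, 0, 1000, "Transport")
    R("ACt", {"ac_c": -1, "ac_e": 1}, 0, 1000, "Transport")
    R("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, "Transport")
    R("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, "Transport")
    R("Ht", {"h_c": -1, "h_e": 1}, -1000, 1000, "Transport")
    R("METt", {"met__L_e": -1, "met__L_c": 1}, -1000, 1000, "Transport")

    # energy metabolism: fermentation (low yield, overflow acetate) vs
    # respiration (high yield, capacity-limited)
    R("FERM", {"lcts_c": -1, "adp_c": -4, "pi_c": -4, "atp_c": 4, "ac_c": 6,
               "h2o_c": 4}, 0, 1000, "Overflow metabolism")
    R("RESP", {"lcts_c": -1, "adp_c": -20, "pi_c": -20, "atp_c": 20, "co2_c": 12,
               "h2o_c": 20}, 0, spec.respiration_cap, "Oxidative phosphorylation")

    def jitter(base: float) -> float:
        return float(base * (1.0 + spec.yield_jitter * (rng.random() - 0.5)))

    # monomer biosynthesis, one lumped reaction per monomer
    for aa in AMINO_ACIDS:
        mid = table.amino_acid_ids[aa]
        sugar = jitter(0.10)
        atp = jitter(1.0)
        sub = "Methionine metabolism" if aa == "M" else "Amino acid biosynthesis"
        rule = "metB" if aa == "M" else ""
        R(f"SYN_{mid}", {"lcts_c": -sugar, "atp_c": -atp, "h2o_c": -atp,
                         "adp_c": atp, "pi_c": atp, "h_c": atp, mid: 1},
          0, 1000, sub, gene_rule=rule)
    for nt in NUCLEOTIDES:
        mid = table.nucleotide_ids[nt]
        sugar = jitter(0.15)
        atp = jitter(2.0)
        R(f"SYN_{mid}", {"lcts_c": -sugar, "atp_c": -atp, "h2o_c": -atp,
                         "adp_c": atp, "pi_c": atp, "h_c": atp, mid: 1},
          0, 1000, "Nucleotide biosynthesis")
    R("SYN_lipid", {"lcts_c": -jitter(0.2), "atp_c": -1, "h2o_c": -1,
                    "adp_c": 1, "pi_c": 1, "h_c": 1, "lipid_c": 1},
      0, 1000, "Lipid biosynthesis")

    # pyrophosphate recycling (needed once MGE pseudoreactions release PPi)
    R("PPIH", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1}, 0, 1000,
      "Pyrophosphate recycling")

    bio: Dict[str, float] = {}
    for aa in AMINO_ACIDS:
        bio[table.amino_acid_ids[aa]] = -0.2
    for nt in NUCLEOTIDES:
        bio[table.nucleotide_ids[nt]] = -0.05
    bio["lipid_c"] = -0.1
    atp_b = spec.atp_per_biomass
    bio.update({"atp_c": -atp_b, "h2o_c": -atp_b,
                "adp_c": atp_b, "pi_c": atp_b, "h_c": atp_b})
    R("BIOMASS", bio, 0, 1000, "Biomass")

    model = MetabolicModel(
        metabolites=mets, reactions=rxns, objective={"BIOMASS": 1.0},
        gene_rules={"metB": [f"SYN_{MonomerTable().amino_acid_ids['M']}"]},
        id=f"toy_host_seed{spec.seed}")
    model.validate()
    sol = fba(model)
    if not sol.optimal or sol.objective_value <= 0:
        raise ValidationError(
            f"degenerate toy host (seed {spec.seed}): no growth on default media")
    return model


_HAND_TOY_GENOME = "ACGT"
_HAND_TOY_PROTEIN = ProteinSpec(protein_id="toy_p1", sequence="MK", copy_number=2)


def hand_toy_mge() -> Tuple[MgeGenomeSpec, List[ProteinSpec]]:
    """The fixed 4-nt ssDNA genome + "MK" x2 proteome toy used by the
    spreadsheet-verified coefficient tests."""
    genome = MgeGenomeSpec(sequence=_HAND_TOY_GENOME, strandedness="ssDNA",
                           copy_number=1, intermediates=())
    return genome, [ProteinSpec(_HAND_TOY_PROTEIN.protein_id,
                                _HAND_TOY_PROTEIN.sequence,
                                _HAND_TOY_PROTEIN.copy_number)]


def make_toy_mge(seed: int = DEFAULT_SEED, genome_length: int = 300,
                 n_proteins: int = 5, strandedness: str = "dsDNA",
                 max_protein_length: int = 60,
                 ) -> Tuple[MgeGenomeSpec, List[ProteinSpec]]:
    """Random MGE composition spec, reproducible by seed.

    ``genome_length=4, n_proteins=1`` returns the fixed hand-oracle toy
    regardless of seed so that every module exercises the same reference MGE.
    """
    if genome_length < 1:
        raise ValidationError("genome length must be >= 1")
    if genome_length == 4 and n_proteins == 1:
        return hand_toy_mge()
    rng = np.random.default_rng(seed)
    genome_seq = "".join(rng.choice(list(NUCLEOTIDES), size=genome_length))
    genome = MgeGenomeSpec(sequence=genome_seq, strandedness=strandedness,
                           copy_number=1)
    proteome = []
    for k in range(n_proteins):
        length = int(rng.integers(5, max_protein_length + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        copies = int(rng.integers(1, 101))
        proteome.append(ProteinSpec(protein_id=f"mge_p{k + 1}", sequence=seq,
                                    copy_number=copies))
    return genome, proteome


def make_conflict_fixture(identical_objectives: bool = False,
                          ) -> Tuple[MetabolicModel, Reaction, ConflictReport]:
    """Analytic branch-point network with a certified FVA conflict set.

    A single substrate feeds two disjoint routes: one is the unique path to
    the host biomass sink, the other the unique path to the MGE sink.  At
    100% of either optimum the full substrate supply is forced down one
    branch, so the flux ranges of all four branch/sink reactions are
    disjoint singletons between the two optimisation states — the certified
    conflict set.  Ground truth is recomputed here by vertex enumeration,
    not stored.

    With ``identical_objectives=True`` the "MGE" reaction *is* the biomass
    sink, so the two states coincide and the conflict set is empty.
    """
    mets = [Metabolite("A_c", compartment="c"),
            Metabolite("H_c", compartment="c"),
            Metabolite("M_c", compartment="c")]
    rxns = [
        Reaction("UPTAKE_A", {"A_c": 1}, 0, 10, subsystem="Transport",
                 is_exchange=True),
        Reaction("HOSTPATH", {"A_c": -1, "H_c": 1}, 0, 1000, subsystem="Host pathway"),
        Reaction("BIOMASS", {"H_c": -1}, 0, 1000, subsystem="Biomass"),
        Reaction("MGEPATH", {"A_c": -1, "M_c": 1}, 0, 1000, subsystem="MGE pathway"),
        Reaction("MGE_SINK", {"M_c": -1}, 0, 1000, subsystem="MGE biomass",
                 is_pseudoreaction=True),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective={"BIOMASS": 1.0}, id="conflict_fixture")
    model.validate()

    mge_rxn_id = "BIOMASS" if identical_objectives else "MGE_SINK"
    host_model = model.copy()
    host_model.objective = {"BIOMASS": 1.0}
    mge_model = model.copy()
    mge_model.objective = {mge_rxn_id: 1.0}

    # certify by brute-force vertex enumeration (independent of the LP path)
    ranges_host = oracle_fva(host_model)
    ranges_mge = oracle_fva(mge_model)
    conflicts = set()
    for rid in ranges_host:
        h, g = ranges_host[rid], ranges_mge[rid]
        if h.max_flux < g.min_flux - 1e-9 or g.max_flux < h.min_flux - 1e-9:
            conflicts.add(rid)
    subsys = {r.id: r.subsystem for r in model.reactions}
    totals: Dict[str, int] = {}
    hits: Dict[str, int] = {}
    for rid in ranges_host:
        s = subsys[rid]
        totals[s] = totals.get(s, 0) + 1
        if rid in conflicts:
            hits[s] = hits.get(s, 0) + 1
    report = ConflictReport(
        conflict_reactions=conflicts,
        per_subsystem_counts={s: (hits.get(s, 0), n, hits.get(s, 0) / n)
                              for s, n in totals.items()},
        total_reactions=len(ranges_host),
        fraction_of_total=len(conflicts) / len(ranges_host),
    )
    return model, model.reaction(mge_rxn_id), report


# ---------------------------------------------------------------------------
# dynamic-FBA fixtures


#: carbon content (mmol C per mmol) of the batch fixture's media species
BATCH_CARBON = {"sug_e": 6.0, "byp_e": 2.0, "co2_e": 1.0}
#: carbon content of fixture biomass, mmol C per gDW
BATCH_BIOMASS_CARBON = 40.0
#: gDW biomass formed per mmol sugar in the batch fixture
BATCH_YIELD = 0.1


def make_batch_growth_species(species_id: str = "batch") -> MetabolicModel:
    """Single-species batch model with exact carbon bookkeeping.

    Biomass formation consumes 10 mmol sugar (6 C each, 60 C) per gDW and
    partitions the carbon as 40 C into biomass, 4 x 2 C into an acetate-like
    byproduct and 12 C into CO2, so elemental conservation can be checked in
    closed form; the stoichiometric yield is 0.1 gDW per mmol sugar.
    """
    mets = [Metabolite("sug_e", compartment="e"), Metabolite("sug_c", compartment="c"),
            Metabolite("byp_e", compartment="e"), Metabolite("byp_c", compartment="c"),
            Metabolite("co2_e", compartment="e"), Metabolite("co2_c", compartment="c")]
    rxns = [
        Reaction("EX_sug_e", {"sug_e": -1}, -10, 1000, subsystem="Exchange",
                 is_exchange=True),
        Reaction("SUGt", {"sug_e": -1, "sug_c": 1}, 0, 1000, subsystem="Transport"),
        Reaction("BIOMASS", {"sug_c": -10, "byp_c": 4, "co2_c": 12}, 0, 1000,
                 subsystem="Biomass"),
        Reaction("BYPt", {"byp_c": -1, "byp_e": 1}, 0, 1000, subsystem="Transport"),
        Reaction("EX_byp_e", {"byp_e": -1}, 0, 1000, subsystem="Exchange",
                 is_exchange=True),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, subsystem="Transport"),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, 1000, subsystem="Exchange",
                 is_exchange=True),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective={"BIOMASS": 1.0}, id=species_id)
    model.validate()
    return model


def make_batch_growth_fixture(carbon_mmol: float = 1e-3, x0: float = 1e-8,
                              n_cycles: int = 60, dt: float = 1.0) -> SimulationConfig:
    """Monoculture batch configuration with closed-form final biomass
    X0 + 0.1 * C0 once the sugar is exhausted."""
    model = make_batch_growth_species()
    return SimulationConfig(
        species=[SpeciesState("batch", model, x0)],
        media={"sug_e": carbon_mmol, "byp_e": 0.0, "co2_e": 0.0},
        timestep=dt, n_cycles=n_cycles)


def _make_auxotroph_model(mge_lb: float = 0.0) -> MetabolicModel:
    """Methionine auxotroph: grows on sugar + exogenous methionine, obligately
    secreting a carbon byproduct; optional MGE pseudoreaction drain."""
    mets = [Metabolite("sug_e", compartment="e"), Metabolite("sug_c", compartment="c"),
            Metabolite("met__L_e", compartment="e"), Metabolite("met__L_c", compartment="c"),
            Metabolite("byp_e", compartment="e"), Metabolite("byp_c", compartment="c")]
    rxns = [
        Reaction("EX_sug_e", {"sug_e": -1}, -10, 1000, subsystem="Exchange",
                 is_exchange=True),
        Reaction("SUGt", {"sug_e": -1, "sug_c": 1}, 0, 1000, subsystem="Transport"),
        Reaction("EX_met__L_e", {"met__L_e": -1}, -10, 1000, subsystem="Exchange",
                 is_exchange=True),
        Reaction("METt", {"met__L_e": -1, "met__L_c": 1}, 0, 1000,
                 subsystem="Transport"),
        Reaction("BIOMASS", {"sug_c": -10, "met__L_c": -0.5, "byp_c": 20}, 0, 1000,
                 subsystem="Biomass"),
        Reaction("BYPt", {"byp_c": -1, "byp_e": 1}, 0, 1000, subsystem="Transport"),
        Reaction("EX_byp_e", {"byp_e": -1}, 0, 1000, subsystem="Exchange",
                 is_exchange=True),
        # MGE production drains sugar carbon, part of which overflows to the
        # byproduct pool (carriage pushes the host toward overflow metabolism)
        Reaction("MGE_TOY", {"sug_c": -2.0, "byp_c": 4.0}, mge_lb, 1000,
                 subsystem="MGE biomass", is_pseudoreaction=True),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective={"BIOMASS": 1.0}, id="auxotroph")
    model.validate()
    return model


def _make_secretor_model() -> MetabolicModel:
    """Methionine over-secretor growing on the auxotroph's byproduct; 0.5 mmol
    extracellular methionine produced per gDW of growth, reuptake blocked."""
    mets = [Metabolite("byp_e", compartment="e"), Metabolite("byp_c", compartment="c"),
            Metabolite("met__L_e", compartment="e")]
    rxns = [
        Reaction("EX_byp_e", {"byp_e": -1}, -10, 1000, subsystem="Exchange",
                 is_exchange=True),
        Reaction("BYPt", {"byp_e": -1, "byp_c": 1}, 0, 1000, subsystem="Transport"),
        Reaction("BIOMASS", {"byp_c": -10, "met__L_e": 0.5}, 0, 1000,
                 subsystem="Biomass"),
        Reaction("EX_met__L_e", {"met__L_e": -1}, 0, 1000, subsystem="Exchange",
                 is_exchange=True),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective={"BIOMASS": 1.0}, id="secretor")
    model.validate()
    return model


#: trace of methionine (mmol) seeding the cross-feeding loop; small enough
#: that solo auxotroph growth stays below 1% of the inoculum
MUTUALISM_MET_TRACE = 1e-11


def make_mutualism_fixture(auxotroph_mge_lb: float = 0.0,
                           sugar_mmol: float = 2.78e-4,
                           x0: float = 1e-8, n_cycles: int = 200,
                           dt: float = 1.0,
                           include_secretor: bool = True,
                           include_auxotroph: bool = True) -> SimulationConfig:
    """Obligate cross-feeding pair: a methionine auxotroph that secretes a
    carbon byproduct, and a methionine secretor that consumes that byproduct.

    Neither partner grows appreciably alone on the fixture media (sugar plus
    a methionine trace far below one inoculum-doubling's worth); together the
    positive feedback loop amplifies from the trace and both grow.  An MGE
    production demand on the auxotroph (``auxotroph_mge_lb`` > 0) diverts its
    precursors and shifts the final species ratio toward the partner.
    """
    species = []
    if include_auxotroph:
        species.append(SpeciesState("auxotroph", _make_auxotroph_model(auxotroph_mge_lb), x0))
    if include_secretor:
        species.append(SpeciesState("secretor", _make_secretor_model(), x0))
    if not species:
        raise ValidationError("mutualism fixture needs at least one species")
    media = {"sug_e": sugar_mmol, "met__L_e": MUTUALISM_MET_TRACE, "byp_e": 0.0}
    return SimulationConfig(species=species, media=media, timestep=dt,
                            n_cycles=n_cycles)
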