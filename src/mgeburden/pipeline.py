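"""End-to-end genome-scale analysis: host edits, MGE integration, conflict
statistics.

This is the recipe applied to a published host reconstruction (e.g. BiGG's
iJO1366 for *E. coli*): knock out methionine biosynthesis, attach plasmid and
phage biomass pseudoreactions built from GenBank-derived composition specs,
run FVA in host- vs MGE-optimised states, and compute the conflict counts
and pFBA subsystem demand report.  The host model and MGE composition tables
are user-supplied inputs (they are published datasets, not part of this
package).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

from . import io as mio
from .conflict import find_conflicts, subsystem_demand_fold_change
from .core import MetabolicModel, fva, pfba
from .hosts import (DEFAULT_PLASMID_LB, make_metB_knockout,
                    plasmid_optimized_state, phage_optimized_state,
                    set_carriage_state, wild_type_state)
from .mge import attach_pseudoreaction, build_pseudoreaction

IJO1366_BIOMASS = "BIOMASS_Ec_iJO1366_core_53p95M"


def integrate_mges(model: MetabolicModel, plasmid_spec_yaml: Union[str, Path],
                   phage_spec_yaml: Union[str, Path],
                   monomer_table=None) -> MetabolicModel:
    """Attach plasmid and phage pseudoreactions built from YAML specs."""
    gp, pp = mio.read_mge_spec(yaml_path=plasmid_spec_yaml)
    _, plasmid_rxn = build_pseudoreaction(gp, pp, monomer_table,
                                          reaction_id="MGE_plasmid")
    gf, pf = mio.read_mge_spec(yaml_path=phage_spec_yaml)
    _, phage_rxn = build_pseudoreaction(gf, pf, monomer_table,
                                        reaction_id="MGE_phage")
    model = attach_pseudoreaction(model, plasmid_rxn)
    return attach_pseudoreaction(model, phage_rxn)


def conflict_analysis(model: MetabolicModel, biomass_rxn: str,
                      plasmid_rxn: str = "MGE_plasmid",
                      phage_rxn: str = "MGE_phage",
                      plasmid_lb: float = DEFAULT_PLASMID_LB,
                      fraction_of_optimum: float = 1.0,
                      tol: float = 1e-6) -> Dict[str, object]:
    """FVA conflict counts and pFBA demand reports for both carriage states.

    Host-optimised vs plasmid-optimised gives the single-carriage conflict
    set; host-optimised vs phage-optimised (with the constitutive plasmid
    demand) gives the double-carriage set.
    """
    host = set_carriage_state(model, wild_type_state(biomass_rxn))
    plasmid_state = set_carriage_state(
        model, plasmid_optimized_state(plasmid_rxn, phage_rxn))
    phage_state = set_carriage_state(
        model, phage_optimized_state(phage_rxn, plasmid_rxn, plasmid_lb=plasmid_lb))

    fva_host = fva(host, fraction_of_optimum)
    fva_plasmid = fva(plasmid_state, fraction_of_optimum)
    fva_phage = fva(phage_state, fraction_of_optimum)

    rep_plasmid = find_conflicts(fva_host, fva_plasmid, model=model, tol=tol)
    rep_phage = find_conflicts(fva_host, fva_phage, model=model, tol=tol)

    pfba_host = pfba(host, fraction_of_optimum)
    demand_plasmid = subsystem_demand_fold_change(
        pfba(plasmid_state, fraction_of_optimum), pfba_host, model)
    demand_phage = subsystem_demand_fold_change(
        pfba(phage_state, fraction_of_optimum), pfba_host, model)

    unique_double = rep_phage.conflict_reactions - rep_plasmid.conflict_reactions
    dropped = demand_plasmid.dropped_reactions | demand_phage.dropped_reactions
    return {
        "report_plasmid": rep_plasmid,
        "report_double": rep_phage,
        "demand_plasmid": demand_plasmid,
        "demand_double": demand_phage,
        "fva": {"host": fva_host, "plasmid": fva_plasmid, "phage": fva_phage},
        "n_reactions": rep_plasmid.total_reactions,
        "n_conflicts_f128": len(rep_plasmid.conflict_reactions),
        "n_conflicts_f128_m13": len(rep_phage.conflict_reactions),
        "n_unique_double": len(unique_double),
        "n_dropped": len(dropped),
    }


def reproduce_genome_scale(model_path: Union[str, Path],
                           plasmid_spec_yaml: Union[str, Path],
                           phage_spec_yaml: Union[str, Path],
                           biomass_rxn: str = IJO1366_BIOMASS,
                           metB_reaction: Optional[str] = None) -> Dict[str, object]:
    """Full published-model recipe: load, knock out *metB*, integrate both
    MGEs, and run the conflict analysis."""
    model = mio.read_model(model_path)
    model = make_metB_knockout(model, reaction_id=metB_reaction)
    model = integrate_mges(model, plasmid_spec_yaml, phage_spec_yaml)
    return conflict_analysis(model, biomass_rxn)
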