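"""Species-specific model edits and MGE carriage states.

Covers the three host configurations used throughout the analyses:

* a methionine auxotroph (cystathionine gamma-synthase / *metB* knockout),
* a methionine over-secretor whose biomass formation is stoichiometrically
  coupled to methionine export (with reuptake blocked), and
* carriage states that place lower bounds on plasmid/phage pseudoreaction
  flux and pick the optimisation objective (host biomass, plasmid, or phage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import MetabolicModel, knock_out
from .errors import ConfigurationError, IntegrationError, TargetNotFoundError

#: constitutive plasmid production demand, mmol gDW^-1 hr^-1
DEFAULT_PLASMID_LB = 0.9
#: constitutive phage production demand in the double-carriage state
DEFAULT_PHAGE_LB = 0.06


@dataclass
class CarriageState:
    """Which MGEs a host bears and what the LP optimises.

    ``objective_target`` is the reaction whose flux is maximised (host
    biomass, plasmid pseudoreaction, or phage pseudoreaction);
    ``plasmid_lb``/``phage_lb`` are constitutive production demands imposed
    as lower bounds on the corresponding pseudoreactions.
    """

    label: str
    objective_target: str
    plasmid_lb: float = 0.0
    phage_lb: float = 0.0
    plasmid_rxn: Optional[str] = None
    phage_rxn: Optional[str] = None

    def validate(self) -> None:
        if self.plasmid_lb < 0 or self.phage_lb < 0:
            raise ConfigurationError("MGE lower bounds must be nonnegative")
        if self.label == "WT" and (self.plasmid_lb > 0 or self.phage_lb > 0):
            raise ConfigurationError("WT state cannot impose MGE production")


def wild_type_state(biomass_rxn: str) -> CarriageState:
    """Host-optimised, no MGE production demanded."""
    return CarriageState(label="WT", objective_target=biomass_rxn)


def plasmid_carrier_state(biomass_rxn: str, plasmid_rxn: str,
                          plasmid_lb: float = DEFAULT_PLASMID_LB) -> CarriageState:
    """Biomass-optimised host constitutively producing plasmid (F128+)."""
    return CarriageState(label="F128_plus", objective_target=biomass_rxn,
                         plasmid_lb=plasmid_lb, plasmid_rxn=plasmid_rxn)


def double_carrier_state(biomass_rxn: str, plasmid_rxn: str, phage_rxn: str,
                         plasmid_lb: float = DEFAULT_PLASMID_LB,
                         phage_lb: float = DEFAULT_PHAGE_LB) -> CarriageState:
    """Biomass-optimised host producing both plasmid and phage (F128+ M13+)."""
    return CarriageState(label="F128_M13_plus", objective_target=biomass_rxn,
                         plasmid_lb=plasmid_lb, phage_lb=phage_lb,
                         plasmid_rxn=plasmid_rxn, phage_rxn=phage_rxn)


def plasmid_optimized_state(plasmid_rxn: str, phage_rxn: Optional[str] = None) -> CarriageState:
    """Objective = plasmid pseudoreaction; no phage demand."""
    return CarriageState(label="plasmid_optimized", objective_target=plasmid_rxn,
                         plasmid_rxn=plasmid_rxn, phage_rxn=phage_rxn)


def phage_optimized_state(phage_rxn: str, plasmid_rxn: str,
                          plasmid_lb: float = DEFAULT_PLASMID_LB) -> CarriageState:
    """Objective = phage pseudoreaction with constitutive plasmid demand."""
    return CarriageState(label="phage_optimized", objective_target=phage_rxn,
                         plasmid_lb=plasmid_lb,
                         plasmid_rxn=plasmid_rxn, phage_rxn=phage_rxn)


def set_carriage_state(model: MetabolicModel, state: CarriageState) -> MetabolicModel:
    """Return a copy of the model configured for the carriage state."""
    state.validate()
    if not model.has_reaction(state.objective_target):
        raise ConfigurationError(
            f"objective reaction {state.objective_target!r} absent from model")
    for rxn_id, lb, what in ((state.plasmid_rxn, state.plasmid_lb, "plasmid"),
                             (state.phage_rxn, state.phage_lb, "phage")):
        if lb > 0 and rxn_id is None:
            raise ConfigurationError(f"state {state.label!r} demands {what} production "
                                     f"but names no {what} pseudoreaction")
        if rxn_id is not None and not model.has_reaction(rxn_id):
            raise ConfigurationError(f"{what} pseudoreaction {rxn_id!r} not attached")
    out = model.copy()
    out.objective = {state.objective_target: 1.0}
    if state.plasmid_rxn is not None:
        out.reaction(state.plasmid_rxn).lower_bound = state.plasmid_lb
    if state.phage_rxn is not None:
        out.reaction(state.phage_rxn).lower_bound = state.phage_lb
    return out


def make_metB_knockout(model: MetabolicModel, gene: str = "metB",
                       reaction_id: Optional[str] = None) -> MetabolicModel:
    """Block methionine biosynthesis (cystathionine gamma-synthase).

    Resolves via the model's gene rules when the gene is annotated, else via
    an explicitly named reaction id.
    """
    target = gene
    if not (model.gene_rules and gene in model.gene_rules):
        if reaction_id is None:
            if model.has_reaction(gene):
                target = gene
            else:
                raise TargetNotFoundError(gene)
        else:
            target = reaction_id
    return knock_out(model, target)


def make_methionine_secretor(model: MetabolicModel, ratio: float = 0.5,
                             biomass_rxn: Optional[str] = None,
                             met_e_id: str = "met__L_e") -> MetabolicModel:
    """Couple biomass formation to methionine over-secretion.

    The biomass reaction gains ``ratio`` mmol of extracellular methionine
    produced per unit biomass flux (per gram of growth), and every route that
    could take extracellular methionine back up is made export-only.
    """
    if not model.has_metabolite(met_e_id):
        raise IntegrationError(f"model lacks extracellular methionine {met_e_id!r}")
    out = model.copy()
    if biomass_rxn is None:
        if len(out.objective) != 1:
            raise ConfigurationError(
                "cannot infer biomass reaction: objective is not a single reaction")
        biomass_rxn = next(iter(out.objective))
    bio = out.reaction(biomass_rxn)
    bio.stoichiometry[met_e_id] = bio.stoichiometry.get(met_e_id, 0.0) + ratio

    for r in out.reactions:
        if r.id == biomass_rxn or met_e_id not in r.stoichiometry:
            continue
        coeff = r.stoichiometry[met_e_id]
        if r.is_exchange:
            # uptake is negative exchange flux
            r.lower_bound = max(r.lower_bound, 0.0)
            continue
        if coeff < 0:  # positive flux consumes met_e: cap above at 0
            r.upper_bound = min(r.upper_bound, 0.0)
        elif coeff > 0:  # negative flux would consume met_e: cap below at 0
            r.lower_bound = max(r.lower_bound, 0.0)
        if r.lower_bound > r.upper_bound:
            r.lower_bound = r.upper_bound = 0.0
    return out
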