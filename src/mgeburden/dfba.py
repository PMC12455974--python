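"""Batch dynamic FBA of one to three species sharing a well-mixed media pool.

Each cycle of length dt (hours): every species' exchange uptake bounds are
capped at ``min(vmax, pool_amount / (X * dt))``, its FBA is solved with its
carriage-state objective and bounds, biomass advances by forward Euler
``X <- X * (1 + mu * dt)``, and the shared pool is updated from the exchange
fluxes of all species evaluated at start-of-cycle biomasses (simultaneous
update, no species ordering bias).  If several species together would
overdraw a pool, their uptake bounds on that metabolite are scaled by the
common factor that empties it and the cycle is re-solved, conserving mass.
An infeasible species LP in a cycle reads as no growth and no exchange for
that cycle.

The default configuration mirrors a standard batch protocol: 1 h timesteps,
200 cycles, 1e-8 gDW inocula, non-carbon nutrients supplied at 1000 mmol
("present in excess"), limiting carbon in the 1e-4 mmol range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import MetabolicModel, fba
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: default per-exchange uptake cap, mmol gDW^-1 hr^-1
DEFAULT_VMAX = 10.0
#: estimated cell dry weight (g per cell) used for cell-count conversion
DEFAULT_CELL_DRY_WEIGHT = 3e-13


@dataclass
class Environment:
    """Well-mixed batch nutrient pool, mmol per metabolite."""

    amounts: Dict[str, float] = field(default_factory=dict)

    def copy(self) -> "Environment":
        return Environment(amounts=dict(self.amounts))

    def validate(self) -> None:
        for m, a in self.amounts.items():
            if a < 0:
                raise ValidationError(f"negative pool amount for {m!r}: {a}")


@dataclass
class SpeciesState:
    species_id: str
    model: MetabolicModel
    biomass: float  # gDW
    vmax_default: float = DEFAULT_VMAX

    def validate(self) -> None:
        if self.biomass < 0:
            raise ValidationError(f"species {self.species_id!r}: negative biomass")
        self.model.validate()


@dataclass
class SimulationConfig:
    species: List[SpeciesState]
    media: Dict[str, float]
    timestep: float = 1.0  # hr
    n_cycles: int = 200
    cell_dry_weight: float = DEFAULT_CELL_DRY_WEIGHT  # g per cell

    def validate(self) -> None:
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be positive")
        if self.n_cycles < 0:
            raise ConfigurationError("cycle count must be nonnegative")
        if not self.species:
            raise ConfigurationError("at least one species required")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate species ids")
        for s in self.species:
            s.validate()
        for m, a in self.media.items():
            if a < 0:
                raise ConfigurationError(f"negative media amount for {m!r}")


@dataclass
class Trajectory:
    """Per-cycle record of biomasses, growth rates, exchange fluxes and pools."""

    species_ids: List[str]
    times: List[float] = field(default_factory=list)
    biomass: Dict[str, List[float]] = field(default_factory=dict)
    growth_rate: Dict[str, List[float]] = field(default_factory=dict)
    exchange_fluxes: Dict[str, List[Dict[str, float]]] = field(default_factory=dict)
    environment: List[Dict[str, float]] = field(default_factory=list)

    def n_cycles(self) -> int:
        return len(self.times) - 1

    def final_biomass(self, species_id: str) -> float:
        return self.biomass[species_id][-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: cycle, time, species, biomass, growth rate."""
        rows = []
        for i, t in enumerate(self.times):
            for sid in self.species_ids:
                rows.append({"cycle": i, "time_hr": t, "species": sid,
                             "biomass_gDW": self.biomass[sid][i],
                             "growth_rate_per_hr": self.growth_rate[sid][i]})
        return pd.DataFrame(rows, columns=["cycle", "time_hr", "species",
                                           "biomass_gDW", "growth_rate_per_hr"])

    def media_frame(self) -> pd.DataFrame:
        """Tidy table: cycle, metabolite, amount (mmol)."""
        rows = []
        for i, env in enumerate(self.environment):
            for m in sorted(env):
                rows.append({"cycle": i, "metabolite": m, "amount_mmol": env[m]})
        return pd.DataFrame(rows, columns=["cycle", "metabolite", "amount_mmol"])


def _exchange_info(model: MetabolicModel) -> Dict[str, Tuple[str, float]]:
    """reaction id -> (metabolite id, original lower bound) for all exchanges."""
    out = {}
    for r in model.reactions:
        if r.is_exchange:
            met = next(iter(r.stoichiometry))
            out[r.id] = (met, r.lower_bound)
    return out


def _solve_species(model: MetabolicModel) -> Tuple[float, Dict[str, float], bool]:
    """(growth rate, exchange fluxes, ok). Infeasible/unbounded -> zeros."""
    sol = fba(model)
    if not sol.optimal:
        return 0.0, {}, False
    ex = {rid: sol.fluxes[rid] for rid in sol.fluxes
          if model.reaction(rid).is_exchange}
    return max(sol.objective_value, 0.0), ex, True


def step(env: Environment, species: List[SpeciesState], dt: float,
         _work_models: Optional[List[MetabolicModel]] = None,
         _orig_lbs: Optional[List[Dict[str, Tuple[str, float]]]] = None,
         ):
    """Advance the shared environment and all species by one cycle.

    Returns ``(env, species, growth_rates, exchange_fluxes)`` where
    ``exchange_fluxes`` is one metabolite-keyed dict per species.
    Exchange-flux sign convention: positive flux secretes the metabolite into
    the pool, negative flux takes it up.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    env.validate()
    if _work_models is None:
        _work_models = [s.model.copy() for s in species]
    if _orig_lbs is None:
        _orig_lbs = [_exchange_info(m) for m in _work_models]

    amounts = dict(env.amounts)
    n = len(species)
    # per-species extra scaling on uptake bounds, used for overdraw resolution
    scale: List[Dict[str, float]] = [dict() for _ in range(n)]
    mus = [0.0] * n
    exch: List[Dict[str, float]] = [dict() for _ in range(n)]

    for _ in range(8):  # overdraw-resolution loop; terminates immediately if none
        for i, s in enumerate(species):
            model = _work_models[i]
            if s.biomass <= 0:
                mus[i], exch[i] = 0.0, {}
                continue
            for rid, (met, orig_lb) in _orig_lbs[i].items():
                pool = amounts.get(met, 0.0)
                cap = min(s.vmax_default, pool / (s.biomass * dt))
                cap *= scale[i].get(met, 1.0)
                model.reaction(rid).lower_bound = max(orig_lb, -cap)
            mu, ex, ok = _solve_species(model)
            if not ok:
                logger.info("species %s infeasible this cycle; growth set to 0",
                            s.species_id)
            mus[i], exch[i] = mu, ex

        # net pool change with start-of-cycle biomasses
        delta: Dict[str, float] = {}
        for i, s in enumerate(species):
            for rid, v in exch[i].items():
                met = _orig_lbs[i][rid][0]
                delta[met] = delta.get(met, 0.0) + dt * v * s.biomass
        overdrawn = {m for m, d in delta.items()
                     if amounts.get(m, 0.0) + d < -1e-12}
        if not overdrawn:
            break
        for m in overdrawn:
            consumed = -sum(dt * v * species[i].biomass
                            for i in range(n) for rid, v in exch[i].items()
                            if _orig_lbs[i][rid][0] == m and v < 0)
            produced = sum(dt * v * species[i].biomass
                           for i in range(n) for rid, v in exch[i].items()
                           if _orig_lbs[i][rid][0] == m and v > 0)
            factor = (amounts.get(m, 0.0) + produced) / consumed if consumed > 0 else 0.0
            factor = min(max(factor, 0.0), 1.0)
            for i in range(n):
                scale[i][m] = scale[i].get(m, 1.0) * factor

    new_amounts = dict(amounts)
    for m, d in delta.items():
        new_amounts[m] = max(new_amounts.get(m, 0.0) + d, 0.0)

    new_species = []
    met_fluxes: List[Dict[str, float]] = []
    for i, s in enumerate(species):
        new_species.append(SpeciesState(
            species_id=s.species_id, model=s.model,
            biomass=s.biomass * (1.0 + mus[i] * dt),
            vmax_default=s.vmax_default))
        by_met: Dict[str, float] = {}
        for rid, v in exch[i].items():
            met = _orig_lbs[i][rid][0]
            by_met[met] = by_met.get(met, 0.0) + v
        met_fluxes.append(by_met)
    new_env = Environment(amounts=new_amounts)
    new_env.validate()
    return new_env, new_species, mus, met_fluxes


def run(config: SimulationConfig) -> Trajectory:
    """Iterate the batch cycle for the configured number of cycles (deterministic)."""
    config.validate()
    env = Environment(amounts=dict(config.media))
    species = [SpeciesState(s.species_id, s.model, s.biomass, s.vmax_default)
               for s in config.species]
    work_models = [s.model.copy() for s in species]
    orig_lbs = [_exchange_info(m) for m in work_models]

    traj = Trajectory(species_ids=[s.species_id for s in species])
    for s in species:
        traj.biomass[s.species_id] = [s.biomass]
        traj.growth_rate[s.species_id] = [0.0]
        traj.exchange_fluxes[s.species_id] = [{}]
    traj.times.append(0.0)
    traj.environment.append(dict(env.amounts))

    for cycle in range(config.n_cycles):
        env, species, mus, exch = step(env, species, config.timestep,
                                       _work_models=work_models, _orig_lbs=orig_lbs)
        traj.times.append((cycle + 1) * config.timestep)
        traj.environment.append(dict(env.amounts))
        for i, s in enumerate(species):
            traj.biomass[s.species_id].append(s.biomass)
            traj.growth_rate[s.species_id].append(mus[i])
            traj.exchange_fluxes[s.species_id].append(dict(exch[i]))
    return traj


def biomass_normalized_secretion(traj: Trajectory, metabolite_id: str,
                                 species_id: str) -> np.ndarray:
    """Cumulative net secretion of a metabolite by one species, per unit of
    its current biomass (mmol gDW^-1); NaN where biomass is zero."""
    if species_id not in traj.biomass:
        raise ValidationError(f"unknown species {species_id!r}")
    n = len(traj.times)
    out = np.zeros(n)
    cum = 0.0
    for i in range(n):
        if i > 0:
            dt = traj.times[i] - traj.times[i - 1]
            x_pre = traj.biomass[species_id][i - 1]
            v = traj.exchange_fluxes[species_id][i].get(metabolite_id, 0.0)
            cum += dt * x_pre * v
        x = traj.biomass[species_id][i]
        out[i] = cum / x if x > 0 else float("nan")
    return out


def cells_from_biomass(biomass_gdw: float,
                       cell_dry_weight: float = DEFAULT_CELL_DRY_WEIGHT) -> float:
    """Cell count equivalent of a dry-weight biomass (e.g. 1e-8 gDW at
    3e-13 g/cell ~ 3.33e4 cells)."""
    if cell_dry_weight <= 0:
        raise ValidationError("cell dry weight must be positive")
    if biomass_gdw < 0:
        raise ValidationError("biomass cannot be negative")
    return biomass_gdw / cell_dry_weight
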