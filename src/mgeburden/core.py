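"""Stoichiometric model container and the three steady-state LP analyses.

A metabolic network at steady state satisfies ``S v = 0`` with per-reaction
flux bounds ``lb_i <= v_i <= ub_i`` (mmol gDW^-1 hr^-1).  Flux balance
analysis (FBA) maximises a linear objective ``Z = c^T v`` over that polytope;
parsimonious FBA (pFBA) additionally minimises total absolute flux at the
optimum; flux variability analysis (FVA) reports the attainable min/max flux
of every reaction on the (near-)optimal face.

All three are solved with the HiGHS simplex/IPM backends of
:func:`scipy.optimize.linprog`.  The objective sense is always *maximise*;
minimisation is expressed by negating the objective vector.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError, TargetNotFoundError, ValidationError

#: assertion-level tolerance used in postcondition checks (solver itself runs tighter)
FEASIBILITY_TOL = 1e-6

#: tolerance passed to the LP solver
SOLVER_TOL = 1e-9


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    molar_mass: Optional[float] = None  # g/mol, used only for bookkeeping


@dataclass
class Reaction:
    """A (pseudo)reaction: signed stoichiometry, bounds and annotations.

    Negative stoichiometric coefficients denote consumption at positive flux.
    Exchange reactions touch exactly one metabolite and connect the network
    to the environment (positive flux = secretion, negative = uptake).
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    is_exchange: bool = False
    is_pseudoreaction: bool = False
    name: str = ""
    gene_reaction_rule: str = ""

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    ``objective`` maps reaction ids to weights of the linear objective
    ``Z = c^T v``.  ``gene_rules`` optionally maps gene ids to the reactions
    they enable (a flat association sufficient for single-gene knockouts).
    """

    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    gene_rules: Optional[Dict[str, List[str]]] = None
    id: str = "model"

    # -- lookups ---------------------------------------------------------
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise TargetNotFoundError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise TargetNotFoundError(met_id)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- structure -------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            raise ValidationError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValidationError("duplicate reaction ids")
        met_set = set(met_ids)
        for r in self.reactions:
            r.validate()
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        unknown_obj = set(self.objective) - set(rxn_ids)
        if unknown_obj:
            raise ValidationError(f"objective references unknown reactions {sorted(unknown_obj)}")
        for m in self.metabolites:
            if not m.compartment:
                raise ValidationError(f"metabolite {m.id!r}: empty compartment")

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, Dict[str, int], Dict[str, int]]:
        """Dense S (metabolites x reactions) with row/column index maps."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for r in self.reactions:
            j = rxn_index[r.id]
            for met, coeff in r.stoichiometry.items():
                S[met_index[met], j] = coeff
        return S, met_index, rxn_index

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_array(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        for rid, w in self.objective.items():
            c[rxn_index[rid]] = w
        return c


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _solve(c_min: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
           A_ub: Optional[np.ndarray] = None, b_ub: Optional[np.ndarray] = None):
    """Minimise ``c_min . x`` subject to ``S x = 0``, bounds and optional A_ub x <= b_ub."""
    res = linprog(
        c_min,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximise ``Z = c^T v`` subject to ``S v = 0`` and flux bounds."""
    model.validate()
    S, _, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    res = _solve(-c, S, lb, ub)
    status = _STATUS.get(res.status, "failed")
    if status in ("infeasible", "unbounded"):
        return FluxSolution(status=status, objective_value=float("nan"))
    if status != "optimal":
        raise SolverError(f"LP solver failed: {res.message}", status=status)
    v = res.x
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(status="optimal", objective_value=float(c @ v), fluxes=fluxes)


def pfba(model: MetabolicModel, fraction_of_optimum: float = 1.0) -> FluxSolution:
    """Minimise total absolute flux while holding ``c^T v`` at its FBA optimum.

    Linearised with auxiliary variables ``t_i >= |v_i|``; the returned
    ``objective_value`` is the primary objective ``c^T v``, not the flux sum.
    """
    base = fba(model)
    if not base.optimal:
        raise SolverError(
            f"pFBA requires an optimal base problem; FBA status was {base.status}",
            status=base.status,
        )
    z_star = base.objective_value
    S, _, _ = model.stoichiometric_matrix()
    n = S.shape[1]
    lb, ub = model.bounds_arrays()
    c = model.objective_array()

    # variables x = [v, t]; minimise sum(t); S v = 0; v - t <= 0; -v - t <= 0;
    # -c.v <= -fraction * Z*
    S_aug = np.hstack([S, np.zeros_like(S)])
    eye = np.eye(n)
    A_ub = np.vstack([
        np.hstack([eye, -eye]),
        np.hstack([-eye, -eye]),
        np.hstack([-c[None, :], np.zeros((1, n))]),
    ])
    b_ub = np.concatenate([np.zeros(2 * n), [-fraction_of_optimum * z_star]])
    big = max(1.0, np.max(np.abs(lb[np.isfinite(lb)]), initial=0.0),
              np.max(np.abs(ub[np.isfinite(ub)]), initial=0.0))
    lb_aug = np.concatenate([lb, np.zeros(n)])
    ub_aug = np.concatenate([ub, np.full(n, big)])
    c_min = np.concatenate([np.zeros(n), np.ones(n)])
    res = _solve(c_min, S_aug, lb_aug, ub_aug, A_ub=A_ub, b_ub=b_ub)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        raise SolverError(f"pFBA LP failed: {res.message}", status=status)
    v = res.x[:n]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(status="optimal", objective_value=float(c @ v), fluxes=fluxes)


def fva(model: MetabolicModel, fraction_of_optimum: float = 1.0,
        reactions: Optional[Iterable[str]] = None) -> Dict[str, FluxRange]:
    """Per-reaction min/max flux over the (near-)optimal face of the FBA polytope."""
    base = fba(model)
    if not base.optimal:
        raise SolverError(
            f"FVA requires an optimal base problem; FBA status was {base.status}",
            status=base.status,
        )
    z_star = base.objective_value
    S, _, rxn_index = model.stoichiometric_matrix()
    n = S.shape[1]
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    A_ub = -c[None, :]
    b_ub = np.array([-fraction_of_optimum * z_star])

    wanted = list(reactions) if reactions is not None else model.reaction_ids()
    out: Dict[str, FluxRange] = {}
    for rid in wanted:
        j = rxn_index[rid]
        e = np.zeros(n)
        e[j] = 1.0
        lo_res = _solve(e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        hi_res = _solve(-e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        lo = float(lo_res.x[j]) if lo_res.status == 0 else (
            float("-inf") if lo_res.status == 3 else float("nan"))
        hi = float(hi_res.x[j]) if hi_res.status == 0 else (
            float("inf") if hi_res.status == 3 else float("nan"))
        if np.isnan(lo) or np.isnan(hi):
            raise SolverError(f"FVA subproblem failed for reaction {rid!r}")
        if lo > hi:  # solver noise on a degenerate singleton
            lo = hi = 0.5 * (lo + hi)
        out[rid] = FluxRange(reaction_id=rid, min_flux=lo, max_flux=hi)
    return out


def knock_out(model: MetabolicModel, target: str) -> MetabolicModel:
    """Return a copy with the target gene's (or reaction's) reactions blocked.

    A gene id resolves through ``model.gene_rules``; otherwise the target must
    be a reaction id.  Affected reactions get bounds [0, 0].
    """
    affected: List[str]
    if model.gene_rules and target in model.gene_rules:
        affected = list(model.gene_rules[target])
    elif model.has_reaction(target):
        affected = [target]
    else:
        raise TargetNotFoundError(target)
    out = model.copy()
    for rid in affected:
        r = out.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    return out


def check_steady_state(model: MetabolicModel, solution: FluxSolution,
                       tol: float = FEASIBILITY_TOL) -> float:
    """Max metabolite imbalance |S v| of an optimal solution (raises if > tol)."""
    S, _, rxn_index = model.stoichiometric_matrix()
    v = np.zeros(S.shape[1])
    for rid, flux in solution.fluxes.items():
        v[rxn_index[rid]] = flux
    resid = float(np.max(np.abs(S @ v))) if S.size else 0.0
    if resid > tol:
        raise ValidationError(f"steady-state residual {resid} exceeds {tol}")
    return resid
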