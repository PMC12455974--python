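"""Host–MGE metabolic conflict statistics.

Two complementary readouts of conflict between a host-optimised and an
MGE-optimised model state:

* **FVA range overlap** — a reaction whose feasible flux ranges in the two
  states share no value admits no solution satisfying both objectives and is
  scored as a conflict reaction; conflicts are tallied per cellular
  subprocess (subsystem).
* **pFBA subsystem demand** — the log2 fold-change of each subsystem's share
  of total absolute parsimonious flux between the two states,

      log2[ (sum_i |F_i^P| / sum_k |F_k^P|) / (sum_i |F_i^H| / sum_k |F_k^H|) ]

  where i runs over the subsystem's reactions, k over all retained reactions
  of the model, P marks the MGE-optimised and H the host-optimised state.
  Reactions whose flux changes sign between states are dropped from both
  sums; positive values mean more demand for the subprocess under MGE
  production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Set, Tuple

import pandas as pd

from .core import FluxRange, FluxSolution, MetabolicModel
from .errors import ValidationError


@dataclass
class ConflictReport:
    conflict_reactions: Set[str]
    per_subsystem_counts: Dict[str, Tuple[int, int, float]]  # (n_conflict, n_total, fraction)
    total_reactions: int
    fraction_of_total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subsystem": s, "n_conflict": nc, "n_total": nt, "fraction": fr}
                for s, (nc, nt, fr) in sorted(self.per_subsystem_counts.items())]
        return pd.DataFrame(rows, columns=["subsystem", "n_conflict", "n_total", "fraction"])


@dataclass
class SubsystemDemand:
    """Per-subsystem absolute parsimonious flux sums and log2 fold-changes."""

    sum_mge: Dict[str, float]
    sum_host: Dict[str, float]
    total_mge: float
    total_host: float
    log2_fold_change: Dict[str, float]  # NaN where undefined
    undefined: Set[str] = field(default_factory=set)
    dropped_reactions: Set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in sorted(set(self.sum_mge) | set(self.sum_host)):
            rows.append({
                "subsystem": s,
                "sum_flux_mge": self.sum_mge.get(s, 0.0),
                "sum_flux_host": self.sum_host.get(s, 0.0),
                "log2_fold_change": self.log2_fold_change.get(s, float("nan")),
                "defined": s not in self.undefined,
            })
        return pd.DataFrame(rows, columns=["subsystem", "sum_flux_mge", "sum_flux_host",
                                           "log2_fold_change", "defined"])


def _subsystem_map(model_or_map) -> Mapping[str, str]:
    if model_or_map is None:
        return {}
    if isinstance(model_or_map, MetabolicModel):
        return {r.id: r.subsystem for r in model_or_map.reactions}
    return model_or_map


def find_conflicts(fva_host: Mapping[str, FluxRange], fva_mge: Mapping[str, FluxRange],
                   model: Optional[MetabolicModel] = None,
                   tol: float = 1e-6) -> ConflictReport:
    """Reactions whose host- and MGE-state flux ranges do not overlap.

    Ranges are closed intervals: a shared endpoint is *not* conflict.
    ``model`` (or a reaction-id -> subsystem mapping) provides the subsystem
    labels for the per-subprocess tallies.
    """
    if set(fva_host) != set(fva_mge):
        raise ValidationError("host and MGE FVA results cover different reaction sets")
    subsys = _subsystem_map(model)

    conflicts: Set[str] = set()
    for rid, h in fva_host.items():
        m = fva_mge[rid]
        if h.max_flux < m.min_flux - tol or m.max_flux < h.min_flux - tol:
            conflicts.add(rid)

    per_sub: Dict[str, Tuple[int, int, float]] = {}
    if subsys:
        totals: Dict[str, int] = {}
        hits: Dict[str, int] = {}
        for rid in fva_host:
            s = subsys.get(rid, "")
            totals[s] = totals.get(s, 0) + 1
            if rid in conflicts:
                hits[s] = hits.get(s, 0) + 1
        per_sub = {s: (hits.get(s, 0), n, hits.get(s, 0) / n)
                   for s, n in totals.items() if n > 0}

    total = len(fva_host)
    return ConflictReport(
        conflict_reactions=conflicts,
        per_subsystem_counts=per_sub,
        total_reactions=total,
        fraction_of_total=len(conflicts) / total if total else 0.0,
    )


def subsystem_conflict_fraction(report: ConflictReport) -> Dict[str, float]:
    """Fraction of each subsystem's reactions in conflict (empty subsystems omitted)."""
    return {s: fr for s, (nc, nt, fr) in report.per_subsystem_counts.items() if nt > 0}


def subsystem_demand_fold_change(pfba_mge: FluxSolution, pfba_host: FluxSolution,
                                 model: MetabolicModel, zero_tol: float = 1e-9,
                                 exclude_exchanges: bool = False) -> SubsystemDemand:
    """Subsystem shares of total |parsimonious flux| between two states.

    Reactions whose flux direction changed between states (sign flip with
    both magnitudes above ``zero_tol``) are dropped from every sum.  The
    denominator spans all retained reactions of the model (optionally
    excluding exchange reactions).  A subsystem with zero flux in exactly one
    state has no finite fold-change and is flagged undefined; zero in both
    states reads as no change (0.0).
    """
    if set(pfba_mge.fluxes) != set(pfba_host.fluxes):
        raise ValidationError("the two flux solutions cover different reaction sets")

    subsys = {r.id: r.subsystem for r in model.reactions}
    exchange = {r.id for r in model.reactions if r.is_exchange}

    dropped: Set[str] = set()
    for rid, vp in pfba_mge.fluxes.items():
        vh = pfba_host.fluxes[rid]
        if abs(vp) > zero_tol and abs(vh) > zero_tol and (vp > 0) != (vh > 0):
            dropped.add(rid)

    sum_mge: Dict[str, float] = {}
    sum_host: Dict[str, float] = {}
    total_mge = total_host = 0.0
    for rid, vp in pfba_mge.fluxes.items():
        if rid in dropped:
            continue
        if exclude_exchanges and rid in exchange:
            continue
        vh = pfba_host.fluxes[rid]
        s = subsys.get(rid, "")
        sum_mge[s] = sum_mge.get(s, 0.0) + abs(vp)
        sum_host[s] = sum_host.get(s, 0.0) + abs(vh)
        total_mge += abs(vp)
        total_host += abs(vh)

    log2fc: Dict[str, float] = {}
    undefined: Set[str] = set()
    for s in set(sum_mge) | set(sum_host):
        num = sum_mge.get(s, 0.0)
        den = sum_host.get(s, 0.0)
        num_zero = num <= zero_tol or total_mge <= zero_tol
        den_zero = den <= zero_tol or total_host <= zero_tol
        if num_zero and den_zero:
            log2fc[s] = 0.0
        elif num_zero or den_zero:
            log2fc[s] = float("nan")
            undefined.add(s)
        else:
            log2fc[s] = math.log2((num / total_mge) / (den / total_host))

    return SubsystemDemand(sum_mge=sum_mge, sum_host=sum_host,
                           total_mge=total_mge, total_host=total_host,
                           log2_fold_change=log2fc, undefined=undefined,
                           dropped_reactions=dropped)


def conflict_table(fva_host: Mapping[str, FluxRange], fva_mge: Mapping[str, FluxRange],
                   model: Optional[MetabolicModel] = None,
                   tol: float = 1e-6) -> pd.DataFrame:
    """Tidy per-reaction table: id, subsystem, both ranges, conflict flag."""
    report = find_conflicts(fva_host, fva_mge, model=model, tol=tol)
    subsys = _subsystem_map(model)
    rows = []
    for rid in sorted(fva_host):
        h, m = fva_host[rid], fva_mge[rid]
        rows.append({
            "reaction_id": rid,
            "subsystem": subsys.get(rid, ""),
            "host_min": h.min_flux, "host_max": h.max_flux,
            "mge_min": m.min_flux, "mge_max": m.max_flux,
            "conflict": rid in report.conflict_reactions,
        })
    return pd.DataFrame(rows, columns=["reaction_id", "subsystem", "host_min", "host_max",
                                       "mge_min", "mge_max", "conflict"])
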