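"""Brute-force vertex enumeration of the flux polytope.

Independent oracle for the LP analyses on tiny networks (<= ~8 reactions).
The polytope ``{v : S v = 0, lb <= v <= ub}`` is bounded for the fixtures we
use; its vertices are the feasible basic solutions obtained by making enough
bound constraints active to pin down the null space of S.  Optima of linear
objectives, and per-reaction ranges over the optimal face, are then min/max
over finite vertex sets — no LP solver involved.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Dict, List, Tuple

import numpy as np

from .core import FluxRange, MetabolicModel

_TOL = 1e-9


def enumerate_vertices(model: MetabolicModel, extra_eq: List[Tuple[np.ndarray, float]] = None,
                       tol: float = 1e-7) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub [, a.v = b for extras]}.

    Returns an array of shape (n_vertices, n_reactions), deduplicated.
    """
    S, _, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    rows = [S[i] for i in range(S.shape[0])]
    rhs = [0.0] * S.shape[0]
    if extra_eq:
        for a, b in extra_eq:
            rows.append(np.asarray(a, dtype=float))
            rhs.append(float(b))
    A = np.array(rows) if rows else np.zeros((0, n))
    b = np.array(rhs)
    base_rank = np.linalg.matrix_rank(A) if A.size else 0
    k = n - base_rank  # number of active bounds needed to pin a vertex

    verts: List[np.ndarray] = []
    for idx in combinations(range(n), k):
        for sides in product((0, 1), repeat=k):
            E = np.zeros((k, n))
            eb = np.zeros(k)
            ok = True
            for row, (j, side) in enumerate(zip(idx, sides)):
                val = lb[j] if side == 0 else ub[j]
                if not np.isfinite(val):
                    ok = False
                    break
                E[row, j] = 1.0
                eb[row] = val
            if not ok:
                continue
            M = np.vstack([A, E]) if A.size else E
            r = np.concatenate([b, eb])
            if np.linalg.matrix_rank(M) < n:
                continue
            x, *_ = np.linalg.lstsq(M, r, rcond=None)
            if np.max(np.abs(M @ x - r)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            verts.append(np.clip(x, lb, ub))
    if not verts:
        return np.zeros((0, n))
    arr = np.array(verts)
    # deduplicate at 1e-7 resolution
    rounded = np.round(arr, 7)
    _, keep = np.unique(rounded, axis=0, return_index=True)
    return arr[np.sort(keep)]


def oracle_fba(model: MetabolicModel) -> Tuple[float, np.ndarray]:
    """(Z*, argmax vertex) by exhaustive vertex search; raises if infeasible."""
    verts = enumerate_vertices(model)
    if verts.shape[0] == 0:
        raise ValueError("flux polytope has no vertices (infeasible or unbounded)")
    c = model.objective_array()
    scores = verts @ c
    j = int(np.argmax(scores))
    return float(scores[j]), verts[j]


def oracle_fva(model: MetabolicModel, tol: float = 1e-7) -> Dict[str, FluxRange]:
    """Flux ranges over the optimal face, from vertices with c.v = Z*.

    The optimal face of a polytope is itself a face, so its vertices are
    vertices of the full polytope; filtering suffices.
    """
    verts = enumerate_vertices(model)
    if verts.shape[0] == 0:
        raise ValueError("flux polytope has no vertices")
    c = model.objective_array()
    scores = verts @ c
    z = float(np.max(scores))
    face = verts[scores >= z - tol]
    out: Dict[str, FluxRange] = {}
    for j, r in enumerate(model.reactions):
        out[r.id] = FluxRange(r.id, float(np.min(face[:, j])), float(np.max(face[:, j])))
    return out
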