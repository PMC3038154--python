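"""Independent brute-force oracles for the optimization routines.

The L1 oracles enumerate candidate basic points directly with dense
linear algebra (no LP solver): the minimum of a weighted L1 objective
over the polytope {S·v = 0, lb ≤ v ≤ ub} is attained at a point where
the mass-balance rows plus pinned hyperplanes from {lb_i, ub_i, kink_i}
span flux space, so pinning every choice of n − rank(S) coordinates and
solving the remaining square system visits all candidate optima.

The ROOM oracle enumerates all binary on/off patterns and probes each
pattern's tightened box with an LP feasibility check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from fluxseries.fabase import effective_bounds
from fluxseries.model import Network


def _matrices(net: Network, bounds: dict[str, tuple[float, float]]):
    rids = list(net.reactions)
    mids = net.internal_metabolite_ids()
    S = np.zeros((len(mids), len(rids)))
    for j, rid in enumerate(rids):
        for mid, coeff in net.reactions[rid].stoichiometry.items():
            if mid in mids:
                S[mids.index(mid), j] += coeff
    lb = np.array([bounds[r][0] for r in rids])
    ub = np.array([bounds[r][1] for r in rids])
    return rids, S, lb, ub


def l1_minimum(
    net: Network,
    constraints=None,
    centers: dict[str, float] | None = None,
    weights: dict[str, float] | None = None,
    tol: float = 1e-7,
) -> float | None:
    """Brute-force minimum of Σ w_i |v_i − c_i| over the flux polytope.

    Returns None when the polytope is empty.  With zero centers and the
    network's weights this is the flux-minimization objective; with a
    reference as centers and unit weights it is the L1-MOMA objective.
    """
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return None
    rids, S, lb, ub = _matrices(net, bounds)
    n = len(rids)
    c = np.array([(centers or {}).get(r, 0.0) for r in rids])
    w = np.array(
        [
            (weights or {}).get(r, net.reactions[r].weight)
            for r in rids
        ]
    )
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_pin = n - rank
    best: float | None = None
    for pinned in itertools.combinations(range(n), n_pin):
        free = [j for j in range(n) if j not in pinned]
        S_free = S[:, free]
        if free and (np.linalg.matrix_rank(S_free) if S_free.size else 0) < len(
            free
        ):
            continue  # non-unique solve: not a basic point
        choice_sets = []
        for j in pinned:
            vals = {lb[j], ub[j]}
            if lb[j] - tol <= c[j] <= ub[j] + tol:
                vals.add(min(max(c[j], lb[j]), ub[j]))
            choice_sets.append(sorted(vals))
        for pin_vals in itertools.product(*choice_sets):
            v = np.empty(n)
            for j, val in zip(pinned, pin_vals):
                v[j] = val
            if free:
                rhs = -S[:, list(pinned)] @ np.array(pin_vals) if pinned else (
                    np.zeros(S.shape[0])
                )
                sol, res, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                if np.linalg.norm(S_free @ sol - rhs) > 1e-8:
                    continue
                for j, val in zip(free, sol):
                    v[j] = val
            if S.size and np.linalg.norm(S @ v) > 1e-8:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(np.sum(w * np.abs(v - c)))
            if best is None or value < best:
                best = value
    return best


def room_minimum(
    net: Network,
    reference: dict[str, float],
    constraints=None,
    delta: float = 0.0,
    epsilon: float = 0.001,
) -> int | None:
    """Brute force over all binary change patterns: minimal number of
    fluxes allowed outside the window ref ± (δ·|ref| + ε)."""
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return None
    rids, S, lb, ub = _matrices(net, bounds)
    n = len(rids)
    ref = np.array([reference.get(r, 0.0) for r in rids])
    halfw = delta * np.abs(ref) + epsilon
    best: int | None = None
    for pattern in itertools.product((0, 1), repeat=n):
        count = sum(pattern)
        if best is not None and count >= best:
            continue
        lo = lb.copy()
        hi = ub.copy()
        keep = np.array(pattern) == 0
        lo[keep] = np.maximum(lo[keep], (ref - halfw)[keep])
        hi[keep] = np.minimum(hi[keep], (ref + halfw)[keep])
        if np.any(lo > hi + 1e-12):
            continue
        res = linprog(
            np.zeros(n),
            A_eq=S if S.size else None,
            b_eq=np.zeros(S.shape[0]) if S.size else None,
            bounds=list(zip(lo, hi)),
            method="highs",
        )
        if res.status == 0:
            best = count
    return best


def sample_feasible_points(
    net: Network, constraints, n_points: int, seed: int
) -> list[dict[str, float]]:
    """Feasible flux vectors: random convex combinations of LP vertices
    obtained from random objective directions."""
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return []
    rids, S, lb, ub = _matrices(net, bounds)
    rng = np.random.default_rng(seed)
    vertices = []
    for _ in range(24):
        direction = rng.normal(size=len(rids))
        res = linprog(
            -direction,
            A_eq=S if S.size else None,
            b_eq=np.zeros(S.shape[0]) if S.size else None,
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if res.status == 0:
            vertices.append(res.x)
    if not vertices:
        return []
    V = np.array(vertices)
    points = []
    for _ in range(n_points):
        lam = rng.dirichlet(np.ones(len(vertices)))
        x = lam @ V
        points.append(dict(zip(rids, x)))
    return points
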