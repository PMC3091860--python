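"""Phase-plane and bifurcation analysis of the reduced two-variable model.

The reduced model lives in the (t, q) plane (scaled T cells and plasma cells).
Because peptide is slaved to t, the t-nullcline consists of vertical lines
(t = 0 plus up to two positive roots of the per-capita growth balance), while
the q-nullcline is a Hill-like curve q(t).  Bistability — coexistence of a
healthy state (t = 0) and an autoimmune state (elevated t, q) separated by a
saddle — exists below a critical reciprocal avidity k1*, where the autoimmune
state and the saddle annihilate in a saddle-node (fold) bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, fsolve

from .model_core import ReducedParams, reduced_rhs
from .simulate import integrate

__all__ = [
    "FixedPoint",
    "Branch",
    "nullclines",
    "fixed_points",
    "stability",
    "continue_branch",
    "saddle_node",
    "basin_map",
]

RESIDUAL_TOL = 1e-9
DEDUP_RADIUS = 1e-6


@dataclass
class FixedPoint:
    """An equilibrium of the reduced model with its linearization."""

    state: np.ndarray
    classification: str          # stable node/focus, saddle, unstable, marginal
    eigenvalues: np.ndarray
    residual: float

    @property
    def t(self) -> float:
        return float(self.state[0])

    @property
    def q(self) -> float:
        return float(self.state[1])

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")


@dataclass
class Branch:
    """A continuation branch of fixed points over one parameter."""

    parameter: str
    values: np.ndarray
    states: np.ndarray           # (n, 2)
    stability: list
    fold_indices: list           # indices where the branch terminates in a fold

    def __len__(self) -> int:
        return len(self.values)


def _growth_residual(t: float, params: ReducedParams) -> float:
    """Per-capita T growth alpha*p/(k1+p) - delta_T - eps*t at QSS peptide."""
    p = params.pep_gain * params.eta * t
    return (params.alpha * p / (params.k1 + p)
            - params.delta_T - params.eps_comp * t)


def _q_of_t(t: float, params: ReducedParams) -> float:
    p = params.pep_gain * params.eta * t
    denom = params.delta_B + params.mu_mat * p * t - params.rho_B * p
    B = params.sigma_B / max(denom, 1e-9)
    return params.mu_mat * p * t * B / params.delta_P


def _positive_growth_roots(params: ReducedParams, t_max: float = None) -> list:
    """Positive roots of the per-capita growth balance by dense sign scan."""
    if t_max is None:
        t_max = 2.0 * params.alpha / params.eps_comp
    grid = np.linspace(1e-8, t_max, 2000)
    vals = np.array([_growth_residual(t, params) for t in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_growth_residual, grid[i], grid[i + 1],
                                args=(params,), xtol=1e-14))
    # dedup (tangencies can give near-coincident roots)
    out = []
    for r in roots:
        if not out or abs(r - out[-1]) > DEDUP_RADIUS:
            out.append(r)
    return out


def nullclines(params: ReducedParams, window=None, resolution: int = 400):
    """Zero-level sets of each derivative component as polylines.

    Returns ``{"t": [curves], "q": [curve]}``.  The t-nullcline contains the
    q-axis (t = 0) and one vertical line per positive growth root; the
    q-nullcline is the graph q = q*(t).
    """
    params.validate()
    if window is None:
        window = (0.0, 2.0 * params.alpha / params.eps_comp)
    lo, hi = window
    if hi <= lo or hi <= 0:
        raise ValueError("window must be a nonempty positive range")
    q_hi = max(_q_of_t(t, params) for t in np.linspace(lo, hi, 50))
    q_hi = 1.2 * q_hi + 1e-6
    qs = np.linspace(0.0, q_hi, resolution)
    t_curves = [np.column_stack([np.zeros_like(qs), qs])]
    for r in _positive_growth_roots(params, hi):
        if lo <= r <= hi:
            t_curves.append(np.column_stack([np.full_like(qs, r), qs]))
    ts = np.linspace(max(lo, 0.0), hi, resolution)
    q_curve = np.column_stack([ts, [_q_of_t(t, params) for t in ts]])
    return {"t": t_curves, "q": [q_curve]}


def _jacobian(state, params: ReducedParams) -> np.ndarray:
    """Central-difference Jacobian with step 1e-6 * (1 + |x|)."""
    state = np.asarray(state, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = 1e-6 * (1.0 + abs(state[j]))
        up = state.copy(); up[j] += h
        dn = state.copy(); dn[j] -= h
        J[:, j] = (reduced_rhs(up, params, check=False)
                   - reduced_rhs(dn, params, check=False)) / (2 * h)
    return J


def stability(fp_state, params: ReducedParams) -> tuple[str, np.ndarray]:
    """Classify an equilibrium by the eigenvalues of the numerical Jacobian."""
    eig = np.linalg.eigvals(_jacobian(fp_state, params))
    re = np.real(eig)
    if np.any(np.abs(re) < 1e-7):
        label = "marginal"
    elif np.all(re < 0):
        label = "stable focus" if np.any(np.abs(np.imag(eig)) > 1e-12) \
            else "stable node"
    elif np.all(re > 0):
        label = "unstable"
    else:
        label = "saddle"
    return label, eig


def fixed_points(params: ReducedParams, n_starts: int = 64,
                 tol: float = RESIDUAL_TOL) -> list[FixedPoint]:
    """All equilibria, from the structural roots plus multi-start polishing.

    The healthy state (t = 0, q = 0) is always present.  Positive equilibria
    are seeded from the growth-balance roots and from a grid of random starts,
    polished with a root finder, deduplicated within 1e-6.
    """
    params.validate()
    seeds = [np.array([0.0, 0.0])]
    for r in _positive_growth_roots(params):
        seeds.append(np.array([r, _q_of_t(r, params)]))
    rng = np.random.default_rng(12345)
    t_hi = 2.0 * params.alpha / params.eps_comp
    for _ in range(n_starts):
        t0 = rng.uniform(0, t_hi)
        seeds.append(np.array([t0, _q_of_t(t0, params)]))
    found = []
    for s in seeds:
        sol, info, ier, _ = fsolve(
            lambda y: reduced_rhs(np.maximum(y, 0.0), params, check=False),
            s, full_output=True, xtol=1e-13)
        if ier != 1:
            continue
        sol = np.maximum(sol, 0.0)
        res = float(np.max(np.abs(reduced_rhs(sol, params, check=False))))
        if res > tol:
            continue
        if any(np.max(np.abs(sol - f.state)) < DEDUP_RADIUS for f in found):
            continue
        label, eig = stability(sol, params)
        found.append(FixedPoint(sol, label, eig, res))
    found.sort(key=lambda f: f.t)
    return found


def _count_nontrivial(params: ReducedParams) -> int:
    return len(_positive_growth_roots(params))


def saddle_node(params: ReducedParams, parameter: str, bracket,
                rtol: float = 1e-6) -> float:
    """Locate the fold by bisection on the count of positive equilibria.

    ``bracket`` must straddle the change from two positive fixed points
    (bistable side) to zero (healthy-only side).
    """
    params.validate()
    lo, hi = float(bracket[0]), float(bracket[1])

    def count(v):
        return _count_nontrivial(replace(params, **{parameter: v}))

    if lo > hi:
        lo, hi = hi, lo
    c_lo, c_hi = count(lo), count(hi)
    if (c_lo >= 2) == (c_hi >= 2):
        raise ValueError(
            f"bracket ({lo}, {hi}) does not straddle a change in fixed-point "
            f"count (counts {c_lo}, {c_hi})")
    while (hi - lo) > rtol * max(abs(hi), abs(lo)):
        mid = 0.5 * (lo + hi)
        if (count(mid) >= 2) == (c_lo >= 2):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def continue_branch(params: ReducedParams, parameter: str, prange,
                    step: float, min_step: float = None) -> list[Branch]:
    """Natural-parameter continuation of all equilibria with step halving.

    Branches are traced from the start of ``prange`` towards its end; when a
    positive branch disappears between consecutive parameter values the step is
    halved until below ``min_step`` and the last point is marked as a fold.
    Sufficient here because reduced-model branches fold at most once.
    """
    params.validate()
    lo, hi = float(prange[0]), float(prange[1])
    if min_step is None:
        min_step = abs(step) / 1024.0
    direction = 1.0 if hi >= lo else -1.0
    step = abs(step) * direction

    branches: dict[str, dict] = {}

    def record(key, v, fp):
        b = branches.setdefault(key, {"values": [], "states": [],
                                      "stability": [], "folds": []})
        b["values"].append(v)
        b["states"].append(fp.state)
        b["stability"].append(fp.classification)

    v = lo
    cur_step = step
    prev_count = None
    while (v - hi) * direction <= 1e-12:
        # guard against floating-point overshoot past the range end
        v = min(max(v, min(lo, hi)), max(lo, hi))
        fps = fixed_points(replace(params, **{parameter: v}), n_starts=16)
        pos = [f for f in fps if f.t > DEDUP_RADIUS]
        healthy = [f for f in fps if f.t <= DEDUP_RADIUS]
        if healthy:
            record("healthy", v, healthy[0])
        n = len(pos)
        if prev_count is not None and n < prev_count and abs(cur_step) > min_step:
            v -= cur_step
            cur_step /= 2.0
            v += cur_step
            continue
        if prev_count is not None and n < prev_count:
            for key in ("autoimmune", "saddle"):
                if key in branches and not branches[key]["folds"]:
                    branches[key]["folds"].append(len(branches[key]["values"]) - 1)
        if n >= 1:
            record("autoimmune", v, pos[-1])
        if n >= 2:
            record("saddle", v, pos[0])
        prev_count = n
        cur_step = step if abs(cur_step) < abs(step) else cur_step
        v += cur_step
    out = []
    for key, b in branches.items():
        out.append(Branch(parameter=parameter,
                          values=np.array(b["values"]),
                          states=np.array(b["states"]),
                          stability=b["stability"],
                          fold_indices=b["folds"]))
    return out


def basin_map(params: ReducedParams, t_grid: Sequence[float],
              q_grid: Sequence[float], horizon_days: float = 4000.0,
              rtol: float = 1e-8) -> np.ndarray:
    """Label each initial condition by its limiting attractor.

    Returns an array of shape (len(t_grid), len(q_grid)) of labels
    'healthy' | 'autoimmune' | 'undecided'.  Because the t dynamics are
    autonomous in t, the separatrix is the vertical line through the saddle.
    """
    params.validate()
    fps = fixed_points(params, n_starts=16)
    pos_stable = [f for f in fps if f.t > DEDUP_RADIUS and f.stable]
    target = pos_stable[0].t if pos_stable else None
    labels = np.empty((len(t_grid), len(q_grid)), dtype=object)
    for i, t0 in enumerate(t_grid):
        for j, q0 in enumerate(q_grid):
            traj = integrate("reduced", params, [t0, q0], horizon_days,
                             rtol=rtol, atol=1e-12, n_out=50, dense=False)
            tf = traj.y[-1, 0]
            if tf < 1e-5:
                labels[i, j] = "healthy"
            elif target is not None and abs(tf - target) < 0.05 * (target + 1e-12):
                labels[i, j] = "autoimmune"
            else:
                labels[i, j] = "undecided"
    return labels
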