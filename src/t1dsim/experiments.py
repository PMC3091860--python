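"""The package's computational experiments.

* the avidity x killing-efficacy landscape: a log-spaced sweep of the full
  one-clone model over (k, kappa), with steady-state beta fraction, onset time
  and antibody readouts per cell, and the four-regime classification of
  autoantibody time courses;
* named parameter presets: the "standard clone" P1 (autoantibodies elevated
  until onset, then basal) and P2 (elevated throughout despite onset), and the
  three two-clone presets that vary the EC50 of the low-avidity clone-1
  subclone (k_1l = 0.7, 0.8, 1.1);
* two-clone runs with clonal-switch detection and the population-weighted
  average reciprocal avidity (avidity-maturation statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import OneCloneParams, TwoCloneParams, healthy_state
from .simulate import (
    DAYS_PER_YEAR,
    Readouts,
    Trajectory,
    antibody_readouts,
    find_onset_time,
    integrate,
)

__all__ = [
    "DEFAULT_K_GRID",
    "DEFAULT_KAPPA_GRID",
    "SWEEP_HORIZON_DAYS",
    "SweepMaps",
    "RegimeLabel",
    "SwitchReport",
    "P1",
    "P2",
    "TWO_CLONE_PRESETS",
    "TWO_CLONE_HORIZON_DAYS",
    "sweep_avidity_killing",
    "classify_regime",
    "run_two_clone",
    "switch_detector",
    "average_inverse_avidity",
]

# Default landscape grid: reciprocal avidity spans the admissible EC50 range;
# killing efficacy spans from far below the onset boundary to two decades
# above the smallest value that produces onset at mid-range avidity.
DEFAULT_K_GRID = np.geomspace(0.01, 1.4, 40)
DEFAULT_KAPPA_GRID = np.geomspace(1e-4, 0.3, 40)
SWEEP_HORIZON_DAYS = 30 * DAYS_PER_YEAR
ELEVATED_MULTIPLIER = 2.0

#: P1, the "standard clone": autoantibodies stay elevated until clinical
#: onset (~11 years), then decay to basal (regime iii behaviour).
P1 = replace(OneCloneParams(), k_pep=0.25, kappa=6.5e-3)

#: P2: higher avidity, lower killing efficacy; slower beta-cell decline with
#: autoantibodies elevated throughout the simulated horizon (regime ii).
P2 = replace(OneCloneParams(), k_pep=0.22, kappa=2.6e-3)

#: Two-clone presets named by the EC50 of the clone-1 low-avidity subclone.
#: 0.7 is the reconstructed default; 0.8 and 1.1 are the printed variants.
TWO_CLONE_PRESETS = {
    "k1l_0.7": replace(TwoCloneParams(), k=(0.7, 0.62, 0.3, 0.045)),
    "k1l_0.8": replace(TwoCloneParams(), k=(0.8, 0.62, 0.3, 0.045)),
    "k1l_1.1": replace(TwoCloneParams(), k=(1.1, 0.62, 0.3, 0.045)),
}
TWO_CLONE_HORIZON_DAYS = 12 * DAYS_PER_YEAR


@dataclass
class RegimeLabel:
    """One of the four autoantibody regimes, or healthy-silent."""

    label: str                   # 'i' | 'ii' | 'iii' | 'iv' | 'healthy-silent'
    predicate: str               # the decisive condition, recorded

    def __str__(self) -> str:
        return self.label


def classify_regime(readouts: Readouts) -> RegimeLabel:
    """Deterministic regime classification from the elevation predicates.

    (i)   elevated at 6 months and at the end-of-horizon state, no onset;
    (ii)  onset, elevated at the end of the horizon (persistent);
    (iii) onset, elevated at 6 months and/or onset, basal afterwards;
    (iv)  onset with no elevation at any probed time;
    healthy-silent: no onset and no sustained elevation.

    The mapping is total: runs whose elevation faded before onset are grouped
    with (iii) (elevated during the prodrome only).
    """
    e6, eo, es = (readouts.elevated_6mo, readouts.elevated_onset,
                  readouts.elevated_ss)
    if readouts.onset_days is None:
        if e6 and es:
            return RegimeLabel("i", "elevated at 6mo and horizon, no onset")
        return RegimeLabel("healthy-silent", "no onset, no sustained elevation")
    if not e6 and not eo and not es:
        return RegimeLabel("iv", "onset without elevation at any probe")
    if es:
        return RegimeLabel("ii", "onset with elevation persisting at horizon")
    if eo:
        return RegimeLabel("iii", "elevated until onset, basal at horizon")
    return RegimeLabel("iii", "elevated during prodrome only, basal at horizon")


@dataclass
class SweepMaps:
    """Gridded landscape readouts over (k, kappa)."""

    k_grid: np.ndarray
    kappa_grid: np.ndarray
    beta_ss: np.ndarray              # steady-state (horizon) beta fraction
    onset_days: np.ndarray           # NaN where no onset within horizon
    ab_6mo: np.ndarray
    ab_onset: np.ndarray             # NaN where no onset
    ab_ss: np.ndarray
    regime: np.ndarray               # dtype=object of labels
    errors: list                     # [(i, j, message)] for failed cells

    def to_frame(self):
        import pandas as pd
        recs = []
        for i, k in enumerate(self.k_grid):
            for j, kp in enumerate(self.kappa_grid):
                recs.append({
                    "k": k, "kappa": kp,
                    "beta_fraction": self.beta_ss[i, j],
                    "onset_days": self.onset_days[i, j],
                    "ab_6mo": self.ab_6mo[i, j],
                    "ab_onset": self.ab_onset[i, j],
                    "ab_ss": self.ab_ss[i, j],
                    "regime": str(self.regime[i, j]),
                })
        return pd.DataFrame.from_records(recs)

    def regime_counts(self) -> dict:
        labels, counts = np.unique(
            np.vectorize(str)(self.regime), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _cell_readouts(base: OneCloneParams, k: float, kappa: float,
                   horizon: float, T0: float, rtol: float, atol: float):
    params = replace(base, k_pep=float(k), kappa=float(kappa))
    traj = integrate("one_clone", params, healthy_state(params, T0), horizon,
                     rtol=rtol, atol=atol, n_out=500)
    return antibody_readouts(traj, params,
                             elevated_multiplier=ELEVATED_MULTIPLIER)


def sweep_avidity_killing(
    base: OneCloneParams = None,
    k_grid=None,
    kappa_grid=None,
    horizon: float = SWEEP_HORIZON_DAYS,
    *,
    T0: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    progress: bool = False,
) -> SweepMaps:
    """One full simulate-and-classify pass per (k, kappa) grid cell.

    Cells are independent; a solver failure is recorded per cell and leaves
    NaNs, it does not abort the sweep.  The "steady state" readouts are taken
    at the end of the horizon (30 years by default), matching the landscape's
    observation window; the true long-run steady state of a single cell is
    available through :func:`t1dsim.simulate.steady_state`.
    """
    if base is None:
        base = OneCloneParams()
    if horizon < 30 * DAYS_PER_YEAR:
        raise ValueError("landscape sweep horizon must be at least 30 years")
    k_grid = DEFAULT_K_GRID if k_grid is None else np.asarray(k_grid, float)
    kappa_grid = (DEFAULT_KAPPA_GRID if kappa_grid is None
                  else np.asarray(kappa_grid, float))
    for g, name in ((k_grid, "k"), (kappa_grid, "kappa")):
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} grid must be positive, strictly increasing")
    shape = (k_grid.size, kappa_grid.size)
    maps = SweepMaps(
        k_grid=k_grid, kappa_grid=kappa_grid,
        beta_ss=np.full(shape, np.nan), onset_days=np.full(shape, np.nan),
        ab_6mo=np.full(shape, np.nan), ab_onset=np.full(shape, np.nan),
        ab_ss=np.full(shape, np.nan),
        regime=np.empty(shape, dtype=object), errors=[],
    )
    iterator = enumerate(k_grid)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(list(iterator), desc="avidity sweep")
    for i, k in iterator:
        for j, kappa in enumerate(kappa_grid):
            try:
                r = _cell_readouts(base, k, kappa, horizon, T0, rtol, atol)
            except Exception as exc:           # per-cell, not fatal
                maps.errors.append((i, j, str(exc)))
                maps.regime[i, j] = RegimeLabel("error", str(exc)[:60])
                continue
            maps.beta_ss[i, j] = r.beta_ss_fraction
            maps.onset_days[i, j] = (np.nan if r.onset_days is None
                                     else r.onset_days)
            maps.ab_6mo[i, j] = r.ab_6mo
            maps.ab_onset[i, j] = (np.nan if r.ab_onset is None else r.ab_onset)
            maps.ab_ss[i, j] = r.ab_ss
            maps.regime[i, j] = classify_regime(r)
    return maps


# ---------------------------------------------------------------------------
# two-clone experiments
# ---------------------------------------------------------------------------

@dataclass
class SwitchReport:
    """Within-clone dominance succession of the low/high-avidity subclones."""

    clone: int
    low_peak_time: float             # days
    low_peak_value: float
    high_peak_time: float
    high_peak_value: float
    switch_time: float | None        # first low->high dominance crossing after
                                     # the low subclone's peak; None if never
    low_dominance_days: float        # total time with low > high

    def as_record(self) -> dict:
        return {
            "clone": self.clone,
            "low_peak_days": self.low_peak_time,
            "high_peak_days": self.high_peak_time,
            "switch_days": np.nan if self.switch_time is None else self.switch_time,
            "low_dominance_days": self.low_dominance_days,
        }


def switch_detector(traj: Trajectory, clone: int) -> SwitchReport:
    """Peak and dominance-crossing times for one clone's subclone pair.

    The switch time is the first time the high-avidity subclone exceeds the
    low-avidity one after the low subclone's (global) peak, refined by linear
    interpolation between grid points.  Peaks are global maxima over t > 0,
    with plateaus resolved to the earliest time.
    """
    if clone not in (1, 2):
        raise ValueError("clone must be 1 or 2")
    lo = traj.series(f"t_{clone}l")
    hi = traj.series(f"t_{clone}h")
    if lo.shape != hi.shape:
        raise ValueError("subclone series lengths differ")
    t = traj.t
    i_lo = int(np.argmax(lo))
    i_hi = int(np.argmax(hi))
    diff = hi - lo
    switch = None
    for i in range(i_lo, len(t) - 1):
        if diff[i] <= 0 < diff[i + 1]:
            frac = -diff[i] / (diff[i + 1] - diff[i])
            switch = float(t[i] + frac * (t[i + 1] - t[i]))
            break
        if i == i_lo and diff[i] > 0:
            switch = float(t[i])
            break
    dt = np.diff(t)
    dom = float(np.sum(dt[(lo > hi)[:-1]]))
    return SwitchReport(
        clone=clone,
        low_peak_time=float(t[i_lo]), low_peak_value=float(lo[i_lo]),
        high_peak_time=float(t[i_hi]), high_peak_value=float(hi[i_hi]),
        switch_time=switch, low_dominance_days=dom,
    )


def average_inverse_avidity(traj: Trajectory, clone: int,
                            k_values=None, *, tol: float = 1e-6) -> np.ndarray:
    """Population-weighted mean EC50 of a clone's subclones over time.

    <k>_i(t) = (k_il t_il + k_ih t_ih) / (t_il + t_ih); a decline signals
    avidity maturation.  Where the clone total falls below ``tol`` the value
    is NaN (the statistic is meaningless for an extinct clone, and late
    rises there are artefacts of the slower-decaying subclone's tail).
    """
    if clone not in (1, 2):
        raise ValueError("clone must be 1 or 2")
    lo = traj.series(f"t_{clone}l")
    hi = traj.series(f"t_{clone}h")
    if lo.shape != hi.shape:
        raise ValueError("subclone series lengths differ")
    if k_values is None:
        raise ValueError("k_values (k_low, k_high) required")
    k_lo, k_hi = k_values
    total = lo + hi
    with np.errstate(invalid="ignore"):
        avg = (k_lo * lo + k_hi * hi) / np.where(total > 0, total, np.nan)
    return np.where(total > tol, avg, np.nan)


def run_two_clone(preset="k1l_0.7", horizon: float = TWO_CLONE_HORIZON_DAYS,
                  *, T0: float = 1e-3, rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate a two-clone preset and analyse the clonal succession.

    Returns ``(trajectory, {clone: SwitchReport}, summary)`` where summary
    holds onset, final beta fraction, per-clone antibody peak times and the
    final defined value of each clone's average reciprocal avidity.
    """
    if isinstance(preset, str):
        try:
            params = TWO_CLONE_PRESETS[preset]
        except KeyError:
            raise KeyError(f"unknown preset {preset!r}; "
                           f"known: {sorted(TWO_CLONE_PRESETS)}")
    else:
        params = preset
    params.validate()
    traj = integrate("two_clone", params, healthy_state(params, T0), horizon,
                     rtol=rtol, atol=atol, n_out=900, method="BDF")
    switches = {c: switch_detector(traj, c) for c in (1, 2)}
    onset = find_onset_time(traj)
    summary = {
        "onset_days": onset,
        "beta_end_fraction": float(traj.series("beta")[-1] / params.beta0),
    }
    for c in (1, 2):
        ab = traj.series(f"A_{c}")
        summary[f"ab{c}_peak_days"] = float(traj.t[int(np.argmax(ab))])
        ks = params.k[0:2] if c == 1 else params.k[2:4]
        avg = average_inverse_avidity(traj, c, ks)
        defined = np.isfinite(avg)
        summary[f"avg_k{c}_initial"] = float(avg[defined][0]) if defined.any() else np.nan
        summary[f"avg_k{c}_final"] = float(avg[defined][-1]) if defined.any() else np.nan
    return traj, switches, summary
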