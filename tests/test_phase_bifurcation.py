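"""Fixed points, stability, continuation and fold location (reduced model)."""

from dataclasses import replace

import numpy as np
import pytest

from t1dsim.model_core import ReducedParams, reduced_rhs
from t1dsim.phase_bifurcation import (
    basin_map,
    continue_branch,
    fixed_points,
    nullclines,
    saddle_node,
    stability,
)
from t1dsim.simulate import integrate


@pytest.fixture(scope="module")
def bistable():
    return ReducedParams()          # k1 = 0.25: bistable at full beta mass


@pytest.fixture(scope="module")
def fold_value(bistable):
    return saddle_node(bistable, "k1", (bistable.k1, 2.0))


class TestFixedPoints:
    def test_bistable_count_and_types(self, bistable):
        fps = fixed_points(bistable)
        assert len(fps) == 3
        labels = [f.classification for f in fps]
        assert sum(l.startswith("stable") for l in labels) == 2
        assert labels[1] == "saddle"

    def test_monostable_above_fold(self, bistable, fold_value):
        fps = fixed_points(replace(bistable, k1=1.5 * fold_value))
        assert len(fps) == 1
        assert fps[0].t == pytest.approx(0.0, abs=1e-9)
        assert fps[0].stable

    def test_residuals_and_dedup(self, bistable):
        fps = fixed_points(bistable)
        for f in fps:
            assert f.residual < 1e-9
        ts = [f.t for f in fps]
        assert np.min(np.diff(sorted(ts))) > 1e-6

    def test_grid_scan_oracle(self, bistable):
        """Brute-force sign-change scan of the t-growth balance on a dense
        grid finds the same positive equilibria."""
        t_hi = 2 * bistable.alpha / bistable.eps_comp
        grid = np.linspace(1e-7, t_hi, 400)
        vals = np.array([reduced_rhs([t, 0.0], bistable, check=False)[0] / t
                         for t in grid])
        brute = int(np.sum(np.sign(vals[:-1]) != np.sign(vals[1:])))
        fps = fixed_points(bistable)
        assert brute == sum(1 for f in fps if f.t > 1e-6)

    def test_fixed_points_lie_on_nullclines(self, bistable):
        nc = nullclines(bistable, resolution=800)
        verticals = [c[0, 0] for c in nc["t"]]
        q_curve = nc["q"][0]
        for f in fixed_points(bistable):
            assert min(abs(f.t - v) for v in verticals) < 1e-4
            q_at = np.interp(f.t, q_curve[:, 0], q_curve[:, 1])
            assert abs(q_at - f.q) < 1e-3 * (1 + abs(f.q))


class TestNullclines:
    def test_t_axis_always_a_component(self, bistable):
        nc = nullclines(bistable)
        assert any(np.allclose(c[:, 0], 0.0) for c in nc["t"])

    def test_three_vertical_lines_at_high_avidity(self, bistable):
        """In the bistable regime the t-nullcline has three vertical lines."""
        assert len(nullclines(bistable)["t"]) == 3

    def test_empty_window_rejected(self, bistable):
        with pytest.raises(ValueError):
            nullclines(bistable, window=(1.0, 1.0))


class TestStability:
    def test_healthy_state_stable(self, bistable):
        label, eig = stability([0.0, 0.0], bistable)
        assert label.startswith("stable")
        assert np.all(np.real(eig) < 0)

    def test_middle_point_is_saddle(self, bistable):
        fps = fixed_points(bistable)
        assert fps[1].classification == "saddle"
        re = np.sort(np.real(fps[1].eigenvalues))
        assert re[0] < 0 < re[1]

    def test_linearization_matches_trajectory_decay(self, bistable):
        """Near the stable autoimmune state, perturbations decay at the rate
        of the leading eigenvalue of the Jacobian."""
        fp = fixed_points(bistable)[-1]
        lam = np.max(np.real(fp.eigenvalues))
        y0 = fp.state * 1.02
        horizon = 3.0 / abs(lam)
        traj = integrate("reduced", bistable, y0, horizon, n_out=200,
                         rtol=1e-10, atol=1e-13)
        dev = np.abs(traj.y - fp.state).sum(axis=1)
        half = int(len(dev) * 0.5)
        rate = np.polyfit(traj.t[half:], np.log(dev[half:]), 1)[0]
        assert rate == pytest.approx(lam, rel=0.15)


class TestSaddleNode:
    def test_count_changes_across_fold(self, bistable, fold_value):
        def count(k1):
            return sum(1 for f in fixed_points(replace(bistable, k1=k1))
                       if f.t > 1e-6)
        assert count(fold_value * 0.995) == 2
        assert count(fold_value * 1.005) == 0

    def test_closed_form_cross_check(self, bistable, fold_value):
        """The tangency closed form for this transcription agrees with the
        numeric fold to the bisection tolerance."""
        assert fold_value == pytest.approx(
            bistable.saddle_node_k1_closed_form(), rel=1e-5)

    def test_eta_fold_shrinks_with_beta_loss(self, bistable):
        """Lowering the frozen beta fraction destroys bistability: the eta
        fold sits where k1 = k1*(eta), and below it only the healthy state
        remains."""
        eta_star = saddle_node(bistable, "eta", (1.0, 0.05))
        assert 0 < eta_star < 1
        assert len(fixed_points(replace(bistable, eta=0.8 * eta_star))) == 1
        assert len(fixed_points(replace(bistable, eta=1.2 * eta_star))) == 3

    def test_bad_bracket_rejected(self, bistable):
        with pytest.raises(ValueError):
            saddle_node(bistable, "k1", (0.05, 0.2))   # bistable at both ends


class TestContinuation:
    def test_branches_fold_once_and_healthy_continues(self, bistable):
        branches = {id(b): b for b in
                    continue_branch(bistable, "k1", (0.1, 2.0), 0.05)}.values()
        folds = [b for b in branches if b.fold_indices]
        full = [b for b in branches if not b.fold_indices]
        assert len(folds) == 2               # autoimmune + saddle branches
        assert len(full) == 1                # healthy branch spans the range
        for b in folds:
            assert len(b.fold_indices) == 1
        assert max(b.values.max() for b in full) > 1.9

    def test_fold_location_step_invariant(self, bistable, fold_value):
        for step in (0.05, 0.025):
            ends = [b.values.max() for b in
                    continue_branch(bistable, "k1", (0.1, 2.0), step)
                    if b.fold_indices]
            assert max(ends) == pytest.approx(fold_value, abs=2 * step)

    def test_autoimmune_t_grows_with_avidity_plasma_flat(self, bistable):
        """Along the autoimmune branch, T rises as avidity increases (k1
        decreases) while plasma stays comparatively flat."""
        ks = np.linspace(0.05, 0.5, 10)
        ts, qs = [], []
        for k1 in ks:
            pos = [f for f in fixed_points(replace(bistable, k1=k1))
                   if f.t > 1e-6 and f.stable]
            ts.append(pos[-1].t)
            qs.append(pos[-1].q)
        ts, qs = np.array(ts), np.array(qs)
        assert np.all(np.diff(ts) < 0)           # t falls as k1 rises
        # plasma varies only modestly over a ten-fold avidity change
        assert (qs.max() - qs.min()) / qs.mean() < 0.35

    def test_branch_residuals(self, bistable):
        for b in continue_branch(bistable, "k1", (0.2, 0.6), 0.1):
            for v, st in zip(b.values, b.states):
                r = reduced_rhs(st, replace(bistable, k1=v), check=False)
                assert np.max(np.abs(r)) < 1e-9


class TestBasins:
    def test_tiny_t_reaches_healthy(self, bistable):
        labels = basin_map(bistable, [1e-5], [0.0, 0.1])
        assert set(labels.ravel()) == {"healthy"}

    def test_separatrix_matches_saddle(self, bistable):
        """Labels flip across the saddle's t coordinate (the separatrix is the
        saddle's stable manifold, a vertical line)."""
        saddle_t = fixed_points(bistable)[1].t
        labels = basin_map(bistable, [0.5 * saddle_t, 2.0 * saddle_t], [0.0])
        assert labels[0, 0] == "healthy"
        assert labels[1, 0] == "autoimmune"

    def test_avidity_enlarges_autoimmune_basin(self, bistable):
        """Increasing avidity (smaller k1) moves the separatrix toward the
        healthy state, enlarging the autoimmune basin."""
        s_hi = fixed_points(replace(bistable, k1=0.1))[1].t
        s_lo = fixed_points(replace(bistable, k1=0.5))[1].t
        assert s_hi < s_lo
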