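"""Unit tests for parameter contracts and the ODE right-hand sides."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest

from t1dsim.model_core import (
    ONE_CLONE_STATE_VARS,
    TWO_CLONE_STATE_VARS,
    InVitroParams,
    OneCloneParams,
    ParameterError,
    ReducedParams,
    ScaleSet,
    StateError,
    TwoCloneParams,
    healthy_state,
    invitro_rhs,
    nondimensionalize,
    one_clone_rhs,
    reduced_rhs,
    two_clone_rhs,
    undo_nondimensionalize,
    validate_params,
)
from t1dsim.model_core import invitro_initial_state
from t1dsim.simulate import integrate


def one_clone_terms(state, p):
    """Independent term-by-term arithmetic oracle for the one-clone RHS."""
    T, B, P, A, beta, pep = state
    renewal = p.alpha * (pep / (p.k_pep + pep)) * T if pep > 0 else 0.0
    competition = p.eps_comp * T ** 2
    maturation = p.mu_mat * pep * T * B
    return np.array([
        renewal - p.delta_T * T - competition,
        p.sigma_B + p.rho_B * pep * B - maturation - p.delta_B * B,
        maturation - p.delta_P * P,
        p.s_Ig * (p.f_ratio * B + P) - p.delta_A * A,
        -p.kappa * T * beta,
        p.R_pep * T * beta - p.delta_p * pep,
    ])


class TestOneCloneRHS:
    def test_pure_peptide_decay(self, one_clone_params):
        """With everything zero but peptide, only peptide decays (at 0.1/day)."""
        state = [0, 0, 0, 0, 0, 1.0]
        d = one_clone_rhs(state, one_clone_params)
        assert d[5] == pytest.approx(-0.1)
        assert d[0] == 0.0 and d[4] == 0.0

    def test_t_cells_decline_without_fuel(self, one_clone_params):
        """No peptide and no beta cells: T cells strictly decline."""
        state = [0.5, 0, 0, 0, 0, 0]
        d = one_clone_rhs(state, one_clone_params)
        expected = -(one_clone_params.delta_T * 0.5
                     + one_clone_params.eps_comp * 0.25)
        assert d[0] == pytest.approx(expected)
        assert d[0] < 0

    @pytest.mark.parametrize("state", [
        [0.03, 1.2, 0.4, 2.0, 0.8, 0.5],
        [1e-3, 1.0, 0.0, 1.0, 1.0, 0.0],
        [0.06, 4.0, 0.3, 3.0, 0.25, 0.9],
    ])
    def test_term_by_term_oracle(self, one_clone_params, state):
        d = one_clone_rhs(state, one_clone_params)
        assert d == pytest.approx(one_clone_terms(state, one_clone_params),
                                  rel=1e-12)

    def test_negative_state_rejected(self, one_clone_params):
        with pytest.raises(StateError):
            one_clone_rhs([-1e-3, 1, 0, 1, 1, 0], one_clone_params)


class TestReducedRHS:
    def test_origin_is_equilibrium(self, reduced_params):
        d = reduced_rhs([0.0, 0.0], reduced_params)
        assert d[0] == 0.0

    def test_no_beta_cells_means_decay(self, reduced_params):
        """At eta -> 0 the growth term vanishes: T strictly decays."""
        p = replace(reduced_params, eta=1e-9)
        d = reduced_rhs([0.05, 0.1], p)
        assert d[0] < 0

    def test_qss_consistency_with_full_model(self, one_clone_params):
        """Along a full-model trajectory the reduced (dt, dq) agree with the
        full model's (dT, dP) to within the time-scale-separation error."""
        traj = integrate("one_clone", one_clone_params,
                         healthy_state(one_clone_params), 3000.0, n_out=400)
        # probe the quasi-static plateau (after transients, before collapse)
        for day in (600, 1200, 2000):
            state = traj.at(day)
            eta = state[4] / one_clone_params.beta0
            rp = ReducedParams.from_one_clone(one_clone_params, eta=eta)
            d_full = one_clone_rhs(state, one_clone_params)
            d_red = reduced_rhs([state[0], state[2]], rp)
            scale = one_clone_params.delta_T * max(state[0], 1e-6)
            assert abs(d_red[0] - d_full[0]) < 0.25 * scale + 1e-5


class TestTwoCloneRHS:
    def test_peptides_decay_without_t_cells(self, two_clone_params):
        state = dict(zip(TWO_CLONE_STATE_VARS, np.zeros(13)))
        state["p_1"] = state["p_2"] = 1.0
        state["beta"] = 1.0
        y = [state[v] for v in TWO_CLONE_STATE_VARS]
        d = two_clone_rhs(y, two_clone_params)
        i1 = TWO_CLONE_STATE_VARS.index("p_1")
        i2 = TWO_CLONE_STATE_VARS.index("p_2")
        assert d[i1] == pytest.approx(-0.1)
        assert d[i2] == pytest.approx(-0.1)

    def test_reduction_to_one_clone(self, two_clone_params):
        """Clone 2 and the clone-1 high-avidity subclone zeroed (with zero
        clone-2 input): clone-1 derivatives match the weighted one-clone
        equivalent model."""
        p2 = replace(two_clone_params, sigma_B=(two_clone_params.sigma_B[0], 0.0))
        one = p2.clone_params(1)
        T, B, P, A, beta, pep = 0.02, 1.3, 0.2, 1.5, 0.7, 0.8
        y = dict(zip(TWO_CLONE_STATE_VARS, np.zeros(13)))
        y.update({"t_1l": T, "B_1": B, "P_1": P, "A_1": A,
                  "beta": beta, "p_1": pep})
        d2 = two_clone_rhs([y[v] for v in TWO_CLONE_STATE_VARS], p2)
        d1 = one_clone_rhs([T, B, P, A, beta, pep], one)
        got = [d2[TWO_CLONE_STATE_VARS.index(v)]
               for v in ("t_1l", "B_1", "P_1", "A_1", "beta", "p_1")]
        assert got == pytest.approx(list(d1), rel=1e-12)

    def test_full_state_term_oracle(self, two_clone_params):
        """Arithmetic oracle for one representative nonzero state."""
        y = np.array([0.02, 0.01, 0.015, 0.004, 1.1, 0.9, 0.2, 0.1,
                      3.0, 1.5, 0.6, 0.8, 0.3])
        p = two_clone_params
        w = p.weights
        d = two_clone_rhs(y, p)
        t1l, t1h, t2l, t2h = y[0:4]
        drive1 = w[0] * t1l + w[1] * t1h
        drive2 = w[2] * t2l + w[3] * t2h
        # subclone t_1l
        expect_t1l = (p.alpha[0] * y[11] / (p.k[0] + y[11]) * t1l
                      - p.delta[0] * t1l
                      - p.eps[0] * t1l * (t1l + p.cross_comp[0] * t1h))
        assert d[0] == pytest.approx(expect_t1l, rel=1e-12)
        # beta: weighted mass-action killing from all four subclones
        assert d[10] == pytest.approx(-p.kappa * y[10] * (drive1 + drive2),
                                      rel=1e-12)
        # clone-2 plasma influx
        mat2 = p.mu_mat[1] * y[12] * drive2 * y[5]
        assert d[7] == pytest.approx(mat2 - p.delta_P[1] * y[7], rel=1e-12)


class TestInVitroRHS:
    def test_zero_cells_zero_secretion(self):
        p = InVitroParams()
        d = invitro_rhs([0, 0, 0, 0], p)
        assert d[2] == 0.0

    def test_accumulation_tracks_secretion(self):
        p = replace(InVitroParams(), delta_A=0.0)
        y = invitro_initial_state(p, B0=2.0, P0=0.5)
        d = invitro_rhs(y, p)
        assert d[3] == pytest.approx(y[2])
        assert d[3] >= 0

    def test_forward_shapes(self):
        """B declines, plasma rises then decays, accumulation saturates."""
        p = InVitroParams()
        traj = integrate("invitro", p, invitro_initial_state(p), 60.0,
                         n_out=400)
        B, P, C = traj.series("B"), traj.series("P"), traj.series("C")
        assert np.all(np.diff(B) < 0)
        ipk = int(np.argmax(P))
        assert 0 < ipk < len(P) - 1
        assert P[-1] < P[ipk]
        # accumulation saturates over the 20-day design span: still rising at
        # the start, within 20% of its maximum at day 20
        t20 = integrate("invitro", p, invitro_initial_state(p), 20.0,
                        n_out=200)
        C20 = t20.series("C")
        assert C20[10] > 0 and np.all(np.diff(C20[:100]) > 0)
        assert C20[-1] > 0.8 * C20.max()
        # with zero immunoglobulin degradation it is nondecreasing throughout
        p0 = replace(p, delta_A=0.0)
        traj0 = integrate("invitro", p0, invitro_initial_state(p0), 60.0,
                          n_out=400)
        assert np.all(np.diff(traj0.series("C")) > -1e-12)


class TestValidation:
    def test_default_tables_pass(self):
        validate_params(OneCloneParams())
        validate_params(TwoCloneParams())
        validate_params(InVitroParams())
        validate_params(ReducedParams())

    def test_turnover_ordering_violation(self, two_clone_params):
        """Swapping delta_1l and delta_1h (high-avidity subclone living
        longer) must be rejected, naming the inequality."""
        bad = replace(two_clone_params, delta=(0.15, 0.1, 0.1, 0.2))
        with pytest.raises(ParameterError, match="turnover ordering"):
            bad.validate()

    def test_avidity_ordering_violation(self, two_clone_params):
        bad = replace(two_clone_params, k=(0.3, 0.62, 0.7, 0.045))
        with pytest.raises(ParameterError, match="avidity ordering"):
            bad.validate()

    @pytest.mark.parametrize("field,value", [
        ("delta_B", -0.1), ("f_ratio", 1.5), ("k_pep", 0.0),
    ])
    def test_one_clone_invalid_fields(self, field, value):
        with pytest.raises(ParameterError):
            replace(OneCloneParams(), **{field: value}).validate()


class TestNondimensionalize:
    def test_identity_scales(self, one_clone_params):
        scaled, s = nondimensionalize(one_clone_params, ScaleSet())
        for f in dataclasses.fields(one_clone_params):
            assert getattr(scaled, f.name) == pytest.approx(
                getattr(one_clone_params, f.name))

    def test_round_trip_is_identity(self):
        p = OneCloneParams(beta0=2.5)
        s = ScaleSet(time=3.0, cell_T=0.2, cell_B=5.0, ig=2.0, beta=2.5,
                     peptide=0.5)
        back = undo_nondimensionalize(nondimensionalize(p, s)[0], s)
        for f in dataclasses.fields(p):
            assert getattr(back, f.name) == pytest.approx(
                getattr(p, f.name), rel=1e-12)

    def test_state_round_trip(self):
        s = ScaleSet(time=2.0, cell_T=0.3, cell_B=4.0, ig=1.7, beta=2.0,
                     peptide=0.6)
        y = np.array([0.1, 2.0, 0.5, 3.0, 1.0, 0.2])
        assert s.unscale_state(s.scale_state(y, "one_clone"), "one_clone") \
            == pytest.approx(y, rel=1e-15)

    @pytest.mark.parametrize("params_cls", [OneCloneParams, TwoCloneParams])
    def test_trajectory_equivalence(self, params_cls):
        """Integrating the rescaled system and mapping back reproduces the
        original trajectory to 1e-6 relative over ten simulated years."""
        p = params_cls()
        s = ScaleSet(time=2.0, cell_T=0.5, cell_B=2.0, ig=4.0, beta=1.0,
                     peptide=0.25)
        scaled, _ = nondimensionalize(p, s)
        model = "one_clone" if params_cls is OneCloneParams else "two_clone"
        y0 = healthy_state(p)
        kw = dict(rtol=1e-10, atol=1e-12, n_out=80,
                  method="BDF" if model == "two_clone" else "LSODA")
        tr = integrate(model, p, y0, 3650.0, **kw)
        trs = integrate(model, scaled, s.scale_state(y0, model),
                        3650.0 / s.time, **kw)
        back = s.unscale_state(trs.y[-1], model)
        rel = np.abs(back - tr.y[-1]) / (np.abs(tr.y[-1]) + 1e-9)
        assert np.max(rel) < 1e-6

    def test_zero_scale_rejected(self, one_clone_params):
        with pytest.raises(ParameterError):
            nondimensionalize(one_clone_params, ScaleSet(time=0.0))
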