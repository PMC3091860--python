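"""Parameter sets, state contracts and right-hand sides of the T1D ODE models.

All models are expressed in the scaled (nondimensional) convention used
throughout the package: beta cells in units of the initial count ``beta0``,
time in days, and cell/peptide/immunoglobulin variables in scaled units chosen
so that the healthy B-cell and antibody baselines equal 1.  The mapping between
dimensional and scaled systems lives in :class:`ScaleSet` /
:func:`nondimensionalize`.

Model family
------------
* full one-clone model: effector T cells (T), B cells (B), plasma cells (P),
  immunoglobulin (A), beta cells (beta) and autoantigenic peptide (p);
* reduced one-clone model: (t, q) = (T cells, plasma cells) after quasi-steady
  state on peptide and B cells with the beta-cell fraction ``eta`` frozen;
* two-clone model: two antigen specificities, each split into a low- and a
  high-avidity subclone, with per-clone B/plasma/immunoglobulin compartments;
* in-vitro co-culture model: B-cell maturation and immunoglobulin
  secretion/accumulation at a fixed T-cell count, used by the fitting stage.

T-cell avidity is encoded inversely by ``k`` (peptide level for half-maximal
activation, EC50): smaller ``k`` means higher avidity.  Killing efficacy
``kappa`` is the per-T-cell, per-day beta-cell death rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "StateError",
    "OneCloneParams",
    "ReducedParams",
    "TwoCloneParams",
    "InVitroParams",
    "ScaleSet",
    "ONE_CLONE_STATE_VARS",
    "REDUCED_STATE_VARS",
    "TWO_CLONE_STATE_VARS",
    "INVITRO_STATE_VARS",
    "one_clone_rhs",
    "reduced_rhs",
    "two_clone_rhs",
    "invitro_rhs",
    "validate_params",
    "nondimensionalize",
    "undo_nondimensionalize",
    "healthy_state",
    "state_vars",
    "rhs_for",
]

#: Solver-tolerance floor below which a state component is a contract violation.
NEG_TOL = 1e-6

ONE_CLONE_STATE_VARS = ("T", "B", "P", "A", "beta", "p")
REDUCED_STATE_VARS = ("t", "q")
TWO_CLONE_STATE_VARS = (
    "t_1l", "t_1h", "t_2l", "t_2h",
    "B_1", "B_2", "P_1", "P_2", "A_1", "A_2",
    "beta", "p_1", "p_2",
)
INVITRO_STATE_VARS = ("B", "P", "S", "C")


class ParameterError(ValueError):
    """A parameter set violates one of its declared invariants."""


class StateError(ValueError):
    """A state vector is outside the model's domain (negative beyond tolerance)."""


def _check_state(y, label: str) -> None:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise StateError(f"{label}: non-finite state component")
    if y.min(initial=0.0) < -NEG_TOL:
        i = int(np.argmin(y))
        raise StateError(
            f"{label}: state component {i} = {y[i]:.3e} below -{NEG_TOL:.0e}"
        )


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class OneCloneParams:
    """Scaled rate constants of the full one-clone model.

    Printed values (expansion/turnover/maturation/secretion-ratio rows) follow
    the standard scaled parameter table; the activation parameter ``k_pep``,
    competition ``eps_comp``, bone-marrow input ``sigma_B``, B-cell expansion
    ``rho_B``, killing efficacy ``kappa``, peptide gain ``R_pep`` and the
    secretion constant ``s_Ig`` are reconstructed so that the healthy baselines
    are 1 in scaled units and the documented qualitative regimes are
    reproduced (see docs/methods.md).
    """

    alpha: float = 4.0          # max T-cell self-renewal rate (1/day)
    delta_T: float = 0.1        # T-cell turnover (1/day)
    k_pep: float = 0.25         # peptide level for 50%-max T activation (EC50)
    eps_comp: float = 60.0      # intra-clonal competition (1/(cell*day), scaled)
    sigma_B: float = 0.02       # bone-marrow B-cell input (cells/day, scaled)
    rho_B: float = 0.095        # peptide-proportional B self-renewal (1/(peptide*day))
    mu_mat: float = 2.858       # peptide- and T-dependent B->plasma maturation
    delta_B: float = 0.02       # B-cell turnover (1/day)
    delta_P: float = 0.2        # plasma-cell turnover (1/day)
    delta_A: float = 0.034      # immunoglobulin turnover (1/day)
    delta_p: float = 0.1        # peptide turnover (1/day)
    s_Ig: float = 0.34          # Ig secretion per plasma cell (scaled conc/(cell*day))
    f_ratio: float = 0.1        # B-to-plasma secretion ratio, f << 1
    kappa: float = 6.5e-3       # killing efficacy (1/(cell*day), scaled)
    R_pep: float = 3.0          # peptide released per T-cell/beta-cell encounter
    beta0: float = 1.0          # initial beta-cell count (scaled)

    def validate(self) -> "OneCloneParams":
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{f_.name} must be finite and >= 0, got {v}")
        for name in ("delta_T", "delta_B", "delta_P", "delta_A", "delta_p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not (0 < self.f_ratio < 1):
            raise ParameterError(f"f_ratio must lie in (0, 1), got {self.f_ratio}")
        if self.k_pep <= 0:
            raise ParameterError("k_pep must be > 0")
        if self.beta0 <= 0:
            raise ParameterError("beta0 must be > 0")
        return self

    @property
    def pep_gain(self) -> float:
        """Quasi-steady-state peptide per unit T at full beta mass, R*beta0/delta_p."""
        return self.R_pep * self.beta0 / self.delta_p

    def healthy_baseline(self) -> dict[str, float]:
        """Closed-form healthy equilibrium: zero T, P and peptide."""
        B = self.sigma_B / self.delta_B
        return {
            "T": 0.0,
            "B": B,
            "P": 0.0,
            "A": self.s_Ig * self.f_ratio * B / self.delta_A,
            "beta": self.beta0,
            "p": 0.0,
        }


@dataclass
class ReducedParams:
    """Scaled coefficients of the reduced (t, q) model.

    ``k1`` is the lumped reciprocal-avidity parameter, on the same scale as the
    full model's ``k_pep``; ``eta`` is the frozen beta-cell fraction
    beta/beta0 in (0, 1].  The remaining coefficients are inherited from the
    one-clone model through the quasi-steady-state reduction: peptide
    p = pep_gain * eta * t and B cells at their fast equilibrium.
    """

    k1: float = 0.25
    eta: float = 1.0
    alpha: float = 4.0
    delta_T: float = 0.1
    eps_comp: float = 60.0
    pep_gain: float = 30.0      # R_pep * beta0 / delta_p of the parent model
    sigma_B: float = 0.02
    rho_B: float = 0.095
    mu_mat: float = 2.858
    delta_B: float = 0.02
    delta_P: float = 0.2

    @classmethod
    def from_one_clone(cls, p: OneCloneParams, eta: float = 1.0) -> "ReducedParams":
        return cls(
            k1=p.k_pep, eta=eta, alpha=p.alpha, delta_T=p.delta_T,
            eps_comp=p.eps_comp, pep_gain=p.pep_gain, sigma_B=p.sigma_B,
            rho_B=p.rho_B, mu_mat=p.mu_mat, delta_B=p.delta_B, delta_P=p.delta_P,
        )

    def validate(self) -> "ReducedParams":
        if self.k1 <= 0:
            raise ParameterError("k1 must be > 0")
        if not (0 < self.eta <= 1):
            raise ParameterError(f"eta must lie in (0, 1], got {self.eta}")
        for name in ("alpha", "delta_T", "eps_comp", "pep_gain", "sigma_B",
                     "rho_B", "mu_mat", "delta_B", "delta_P"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        return self

    def saddle_node_k1_closed_form(self) -> float:
        """Analytic fold location for this transcription (tangency condition).

        Setting the per-capita growth alpha*p/(k1+p) - delta_T - eps*t to zero
        together with its t-derivative, with p = pep_gain*eta*t, gives
        k1* = eta * pep_gain / eps * (sqrt(alpha) - sqrt(delta_T))^2.
        Used as a cross-check for the numeric fold detector.
        """
        return (
            self.eta * self.pep_gain / self.eps_comp
            * (math.sqrt(self.alpha) - math.sqrt(self.delta_T)) ** 2
        )


_SUBCLONES = ("1l", "1h", "2l", "2h")


def _tuple2(x) -> tuple[float, float]:
    a, b = x
    return float(a), float(b)


def _tuple4(x) -> tuple[float, float, float, float]:
    a, b, c, d = x
    return float(a), float(b), float(c), float(d)


@dataclass
class TwoCloneParams:
    """Scaled rate constants of the two-clone, four-subclone model.

    Subclone order is (t_1l, t_1h, t_2l, t_2h): clone 1 reacts to autoantigen 1
    (lower avidity, conventional-autoantibody-like), clone 2 to autoantigen 2
    (higher avidity).  Invariants: ``k`` strictly decreases along the subclone
    order (ascending avidity), the effective killing weights are non-decreasing
    along the same order, and within each clone the high-avidity subclone has
    the larger turnover (activation-induced cell death).
    """

    alpha: tuple = (7.0, 6.0, 4.0, 2.0)        # expansion rates (1/day)
    delta: tuple = (0.1, 0.15, 0.1, 0.2)       # subclone turnovers (1/day)
    k: tuple = (0.7, 0.62, 0.3, 0.045)         # EC50s, k_1l occasionally altered
    eps: tuple = (90.0, 120.0)                 # within-clone competition
    sigma_B: tuple = (0.02, 0.04)              # bone-marrow input per clone
    rho_B: tuple = (0.095, 0.095)              # B expansion per clone
    mu_mat: tuple = (7.36, 8.28)               # B maturation rates per clone
    delta_B: tuple = (0.02, 0.04)
    delta_P: tuple = (0.2, 0.4)
    delta_A: tuple = (0.001, 0.034)
    f_ratio: tuple = (0.1, 0.1)
    s_Ig: tuple = (0.34, 0.34)
    delta_p: tuple = (0.1, 0.1)
    R_pep: tuple = (4.0, 1.7)
    kappa: float = 6.5e-3                      # base killing efficacy
    a2: float = 0.8                            # low-vs-high within-clone effect
    b_factors: tuple = (1.25, 2.0)             # clone-2-vs-clone-1 effects
    cross_comp: tuple = (1.0, 0.66)            # sibling-vs-self competition overlap
    beta0: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = _tuple4(self.alpha)
        self.delta = _tuple4(self.delta)
        self.k = _tuple4(self.k)
        self.b_factors = _tuple2(self.b_factors)
        for name in ("eps", "sigma_B", "rho_B", "mu_mat", "delta_B", "delta_P",
                     "delta_A", "f_ratio", "s_Ig", "delta_p", "R_pep",
                     "cross_comp"):
            setattr(self, name, _tuple2(getattr(self, name)))

    @property
    def weights(self) -> tuple[float, float, float, float]:
        """Per-subclone relative-effect weights on maturation/killing/peptide."""
        b1, b2 = self.b_factors
        return (self.a2, 1.0, b1 * self.a2, b2)

    def validate(self) -> "TwoCloneParams":
        for name in ("alpha", "delta", "k", "eps", "sigma_B", "rho_B", "mu_mat",
                     "delta_B", "delta_P", "delta_A", "f_ratio", "s_Ig",
                     "delta_p", "R_pep", "b_factors", "cross_comp"):
            for v in getattr(self, name):
                if not (math.isfinite(v) and v >= 0):
                    raise ParameterError(f"{name} entries must be finite and >= 0")
        if self.kappa < 0 or not (0 < self.a2 <= 1):
            raise ParameterError("kappa must be >= 0 and a2 in (0, 1]")
        if any(not (0 <= c <= 1) for c in self.cross_comp):
            raise ParameterError("cross_comp entries must lie in [0, 1]")
        names = [f"k_{s}" for s in _SUBCLONES]
        for i in range(3):
            if not self.k[i] > self.k[i + 1]:
                raise ParameterError(
                    "avidity ordering violated: require "
                    f"{names[i]} > {names[i + 1]}, got {self.k[i]} <= {self.k[i + 1]}"
                )
        w = self.weights
        wnames = [f"w_{s}" for s in _SUBCLONES]
        for i in range(3):
            if w[i] > w[i + 1]:
                raise ParameterError(
                    "killing-efficacy ordering violated: require "
                    f"{wnames[i]} <= {wnames[i + 1]}, got {w[i]} > {w[i + 1]}"
                )
        for clone, (lo, hi) in enumerate(((0, 1), (2, 3)), start=1):
            if not self.delta[lo] < self.delta[hi]:
                raise ParameterError(
                    f"turnover ordering violated in clone {clone}: require "
                    f"delta_{_SUBCLONES[lo]} < delta_{_SUBCLONES[hi]}"
                )
        return self

    def clone_params(self, clone: int) -> OneCloneParams:
        """One-clone equivalent of a single low-avidity subclone of ``clone``.

        Used by reduction-consistency checks: with the other clone and the
        high-avidity subclone zeroed, the remaining subsystem follows a
        one-clone model whose maturation/killing/peptide rates carry that
        subclone's relative-effect weight.
        """
        i = 0 if clone == 1 else 2
        c = clone - 1
        w = self.weights[i]
        return OneCloneParams(
            alpha=self.alpha[i], delta_T=self.delta[i], k_pep=self.k[i],
            eps_comp=self.eps[c], sigma_B=self.sigma_B[c], rho_B=self.rho_B[c],
            mu_mat=self.mu_mat[c] * w, delta_B=self.delta_B[c],
            delta_P=self.delta_P[c], delta_A=self.delta_A[c],
            delta_p=self.delta_p[c], s_Ig=self.s_Ig[c], f_ratio=self.f_ratio[c],
            kappa=self.kappa * w, R_pep=self.R_pep[c] * w, beta0=self.beta0,
        )

    def healthy_baseline(self) -> dict[str, float]:
        out = {v: 0.0 for v in TWO_CLONE_STATE_VARS}
        out["beta"] = self.beta0
        for c in (0, 1):
            B = self.sigma_B[c] / self.delta_B[c]
            out[f"B_{c + 1}"] = B
            out[f"A_{c + 1}"] = self.s_Ig[c] * self.f_ratio[c] * B / self.delta_A[c]
        return out


@dataclass
class InVitroParams:
    """Rate constants of the co-culture maturation/secretion model.

    The T-cell count is an exogenous constant; there is no antigen drive in
    the dish, so B-cell self-renewal is absent and B cells only mature and
    turn over.  ``mu_mat`` here is the maturation rate per (scaled) T cell.
    """

    mu_mat: float = 0.13
    delta_B: float = 0.02
    delta_P: float = 0.2
    s_Ig: float = 0.34
    f_ratio: float = 0.1
    delta_A: float = 0.034
    T_cells: float = 1.0

    def validate(self) -> "InVitroParams":
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{f_.name} must be finite and >= 0, got {v}")
        if not (0 < self.f_ratio < 1):
            raise ParameterError("f_ratio must lie in (0, 1)")
        return self

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


def validate_params(params):
    """Validate any parameter container, raising on the first violated invariant."""
    return params.validate()


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def one_clone_rhs(state, params: OneCloneParams, *, check: bool = True):
    """Time derivative of the full one-clone model.

    Terms, in order: peptide-dependent T-cell self-renewal (Michaelis-Menten in
    peptide), T turnover, intra-clonal competition; bone-marrow B input,
    peptide-proportional B self-renewal, T- and peptide-dependent B maturation,
    B turnover; maturation influx minus plasma turnover; Ig secretion from B
    (weight f) and plasma cells minus Ig turnover; beta-cell killing by T cells
    (mass action, no replication source); peptide release from killing minus
    peptide turnover.
    """
    if check:
        _check_state(state, "one_clone_rhs")
    T, B, P, A, beta, p = (float(x) for x in state)
    act = p / (params.k_pep + p) if p > 0 else 0.0
    mat = params.mu_mat * p * T * B
    dT = params.alpha * act * T - params.delta_T * T - params.eps_comp * T * T
    dB = params.sigma_B + params.rho_B * p * B - mat - params.delta_B * B
    dP = mat - params.delta_P * P
    dA = params.s_Ig * (params.f_ratio * B + P) - params.delta_A * A
    dbeta = -params.kappa * T * beta
    dp = params.R_pep * T * beta - params.delta_p * p
    return np.array([dT, dB, dP, dA, dbeta, dp])


def reduced_qss_B(t: float, params: ReducedParams) -> tuple[float, float]:
    """Quasi-steady-state peptide and B-cell levels at T-cell level ``t``."""
    p = params.pep_gain * params.eta * t
    denom = params.delta_B + params.mu_mat * p * t - params.rho_B * p
    # The calibrated regime keeps denom > 0 for every t; the floor only guards
    # pathological parameter sets from producing a negative fast equilibrium.
    B = params.sigma_B / max(denom, 1e-9)
    return p, B


def reduced_rhs(state, params: ReducedParams, *, check: bool = True):
    """Time derivative of the reduced (t, q) model.

    Peptide and B cells are at quasi-steady state, beta frozen at
    ``eta * beta0``; immunoglobulin is dropped (no feedback).  At eta -> 0 the
    growth term vanishes and t strictly decays.
    """
    if check:
        _check_state(state, "reduced_rhs")
    t, q = (float(x) for x in state)
    p, B = reduced_qss_B(t, params)
    act = p / (params.k1 + p) if p > 0 else 0.0
    dt = params.alpha * act * t - params.delta_T * t - params.eps_comp * t * t
    dq = params.mu_mat * p * t * B - params.delta_P * q
    return np.array([dt, dq])


def two_clone_rhs(state, params: TwoCloneParams, *, check: bool = True):
    """Time derivative of the two-clone model (13 dynamic compartments).

    Each subclone is activated by its own clone's peptide; competition is
    within-clone only.  The displayed quadratic competition is transcribed
    per subclone with a partial sibling overlap: subclone j of clone i feels
    eps_i * t_ij * (t_ij + cross_comp_i * t_sibling).  Full overlap
    (cross_comp = 1, one shared pressure term) forces competitive exclusion
    and drives the temporarily disadvantaged high-avidity subclone to
    extinction before beta-cell decline can favour it again, abolishing the
    documented clonal switch; the partial overlap keeps both subclones in the
    clone's niche so dominance can be exchanged.  Maturation, killing and
    peptide release weight the subclones by the relative-effect factors (a2
    within clones, b_factors between clones).  Peptide p_i is released when
    clone-i T cells kill beta cells.
    """
    if check:
        _check_state(state, "two_clone_rhs")
    y = [float(x) for x in state]
    t = y[0:4]
    Bc = y[4:6]
    Pc = y[6:8]
    Ac = y[8:10]
    beta = y[10]
    pc = y[11:13]
    w = params.weights
    drive = (w[0] * t[0] + w[1] * t[1], w[2] * t[2] + w[3] * t[3])

    dt = []
    for j in range(4):
        c = 0 if j < 2 else 1
        sib = t[j + 1] if j in (0, 2) else t[j - 1]
        p = pc[c]
        act = p / (params.k[j] + p) if p > 0 else 0.0
        dt.append(
            params.alpha[j] * act * t[j]
            - params.delta[j] * t[j]
            - params.eps[c] * t[j] * (t[j] + params.cross_comp[c] * sib)
        )
    dB, dP, dA, dp = [], [], [], []
    for c in (0, 1):
        mat = params.mu_mat[c] * pc[c] * drive[c] * Bc[c]
        dB.append(
            params.sigma_B[c] + params.rho_B[c] * pc[c] * Bc[c]
            - mat - params.delta_B[c] * Bc[c]
        )
        dP.append(mat - params.delta_P[c] * Pc[c])
        dA.append(
            params.s_Ig[c] * (params.f_ratio[c] * Bc[c] + Pc[c])
            - params.delta_A[c] * Ac[c]
        )
        dp.append(params.R_pep[c] * drive[c] * beta - params.delta_p[c] * pc[c])
    dbeta = -params.kappa * beta * (drive[0] + drive[1])
    return np.array(dt + dB + dP + dA + [dbeta] + dp)


def invitro_rhs(state, params: InVitroParams, *, check: bool = True):
    """Time derivative of the co-culture model: (B, P, S, C).

    S is the instantaneous Ig secretion rate s*(f*B + P), carried as a state so
    that its trajectory can be fitted directly; C accumulates secretion and
    decays at the Ig turnover rate (C is nondecreasing when delta_A = 0).
    """
    if check:
        _check_state(state, "invitro_rhs")
    B, P, S, C = (float(x) for x in state)
    m = params.mu_mat * params.T_cells
    dB = -(m + params.delta_B) * B
    dP = m * B - params.delta_P * P
    dS = params.s_Ig * (params.f_ratio * dB + dP)
    dC = S - params.delta_A * C
    return np.array([dB, dP, dS, dC])


def invitro_initial_state(params: InVitroParams, B0: float = 1.0, P0: float = 0.0):
    """Consistent initial state with S(0) matching the secretion identity."""
    S0 = params.s_Ig * (params.f_ratio * B0 + P0)
    return np.array([B0, P0, S0, 0.0])


# ---------------------------------------------------------------------------
# model registry helpers
# ---------------------------------------------------------------------------

_MODEL_TABLE = {
    "one_clone": (one_clone_rhs, ONE_CLONE_STATE_VARS, OneCloneParams),
    "reduced": (reduced_rhs, REDUCED_STATE_VARS, ReducedParams),
    "two_clone": (two_clone_rhs, TWO_CLONE_STATE_VARS, TwoCloneParams),
    "invitro": (invitro_rhs, INVITRO_STATE_VARS, InVitroParams),
}


def rhs_for(model_id: str):
    """Return the RHS callable for a model id."""
    try:
        return _MODEL_TABLE[model_id][0]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; known: {sorted(_MODEL_TABLE)}")


def state_vars(model_id: str) -> tuple[str, ...]:
    return _MODEL_TABLE[model_id][1]


def healthy_state(params, T0: float = 1e-3) -> np.ndarray:
    """Default initial condition: healthy baseline plus a small effector seed.

    ``T0`` represents autoreactive T cells that escaped central tolerance; the
    outcome can depend on it (it selects the basin of attraction), so it is an
    explicit argument.
    """
    if isinstance(params, OneCloneParams):
        base = params.healthy_baseline()
        base["T"] = T0
        return np.array([base[v] for v in ONE_CLONE_STATE_VARS])
    if isinstance(params, TwoCloneParams):
        base = params.healthy_baseline()
        for s in _SUBCLONES:
            base[f"t_{s}"] = T0
        return np.array([base[v] for v in TWO_CLONE_STATE_VARS])
    if isinstance(params, ReducedParams):
        return np.array([T0, 0.0])
    raise TypeError(f"unsupported parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

@dataclass
class ScaleSet:
    """Characteristic scales mapping dimensional to scaled variables.

    ``x_scaled = x_dimensional / scale``.  B and plasma cells share one scale
    (``cell_B``) so that a single maturation coefficient serves both equations;
    time is rescaled by ``time`` (scaled rates = dimensional rates * time).
    """

    time: float = 1.0
    cell_T: float = 1.0
    cell_B: float = 1.0
    ig: float = 1.0
    beta: float = 1.0
    peptide: float = 1.0

    def validate(self) -> "ScaleSet":
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"scale {f_.name} must be > 0, got {v}")
        return self

    def state_scales(self, model_id: str) -> np.ndarray:
        if model_id == "one_clone":
            s = (self.cell_T, self.cell_B, self.cell_B, self.ig,
                 self.beta, self.peptide)
        elif model_id == "two_clone":
            s = (self.cell_T,) * 4 + (self.cell_B,) * 2 + (self.cell_B,) * 2 \
                + (self.ig,) * 2 + (self.beta,) + (self.peptide,) * 2
        else:
            raise KeyError(f"no state scales for model {model_id!r}")
        return np.array(s, dtype=float)

    def scale_state(self, state, model_id: str) -> np.ndarray:
        return np.asarray(state, dtype=float) / self.state_scales(model_id)

    def unscale_state(self, state, model_id: str) -> np.ndarray:
        return np.asarray(state, dtype=float) * self.state_scales(model_id)

    def scale_times(self, times) -> np.ndarray:
        return np.asarray(times, dtype=float) / self.time


def _scale_one_clone(p: OneCloneParams, s: ScaleSet) -> OneCloneParams:
    tau = s.time
    return OneCloneParams(
        alpha=p.alpha * tau,
        delta_T=p.delta_T * tau,
        k_pep=p.k_pep / s.peptide,
        eps_comp=p.eps_comp * s.cell_T * tau,
        sigma_B=p.sigma_B * tau / s.cell_B,
        rho_B=p.rho_B * s.peptide * tau,
        mu_mat=p.mu_mat * s.peptide * s.cell_T * tau,
        delta_B=p.delta_B * tau,
        delta_P=p.delta_P * tau,
        delta_A=p.delta_A * tau,
        delta_p=p.delta_p * tau,
        s_Ig=p.s_Ig * s.cell_B * tau / s.ig,
        f_ratio=p.f_ratio,
        kappa=p.kappa * s.cell_T * tau,
        R_pep=p.R_pep * s.cell_T * s.beta * tau / s.peptide,
        beta0=p.beta0 / s.beta,
    )


def _scale_two_clone(p: TwoCloneParams, s: ScaleSet) -> TwoCloneParams:
    tau = s.time
    return replace(
        p,
        alpha=tuple(a * tau for a in p.alpha),
        delta=tuple(d * tau for d in p.delta),
        k=tuple(k / s.peptide for k in p.k),
        eps=tuple(e * s.cell_T * tau for e in p.eps),
        sigma_B=tuple(x * tau / s.cell_B for x in p.sigma_B),
        rho_B=tuple(x * s.peptide * tau for x in p.rho_B),
        mu_mat=tuple(x * s.peptide * s.cell_T * tau for x in p.mu_mat),
        delta_B=tuple(x * tau for x in p.delta_B),
        delta_P=tuple(x * tau for x in p.delta_P),
        delta_A=tuple(x * tau for x in p.delta_A),
        delta_p=tuple(x * tau for x in p.delta_p),
        s_Ig=tuple(x * s.cell_B * tau / s.ig for x in p.s_Ig),
        R_pep=tuple(x * s.cell_T * s.beta * tau / s.peptide for x in p.R_pep),
        kappa=p.kappa * s.cell_T * tau,
        beta0=p.beta0 / s.beta,
    )


def nondimensionalize(params, scales: ScaleSet | None = None):
    """Rescale a parameter set so the two systems are dynamically equivalent.

    Returns ``(scaled_params, scales)``.  Default scales measure beta cells in
    units of ``beta0`` and leave everything else unchanged.  Integrating the
    scaled system from a scaled initial condition and mapping the trajectory
    back reproduces the original system (the correctness gate used in tests).
    """
    if scales is None:
        scales = ScaleSet(beta=float(params.beta0))
    scales.validate()
    if isinstance(params, OneCloneParams):
        return _scale_one_clone(params.validate(), scales), scales
    if isinstance(params, TwoCloneParams):
        return _scale_two_clone(params.validate(), scales), scales
    raise TypeError(f"cannot nondimensionalize {type(params)!r}")


def undo_nondimensionalize(params, scales: ScaleSet):
    """Inverse of :func:`nondimensionalize` (round-trip is the identity)."""
    inv = ScaleSet(**{f_.name: 1.0 / getattr(scales, f_.name)
                      for f_ in fields(ScaleSet)})
    if isinstance(params, OneCloneParams):
        return _scale_one_clone(params, inv)
    if isinstance(params, TwoCloneParams):
        return _scale_two_clone(params, inv)
    raise TypeError(f"cannot rescale {type(params)!r}")
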