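"""Two-state time-inhomogeneous hidden Markov movement model.

State 1 is short-distance local movement (SDLM), state 2 long-distance
movement (LDM).  Conditional on the state, daily step lengths are gamma and
turning angles wrapped Cauchy; the daily 2x2 transition matrix has
logit-linear off-diagonals with a state-pair-specific intercept plus a
penalized-spline seasonal effect of day of year.  The likelihood marginalizes
the latent states with the forward algorithm, computed in log space, with
missing steps/turns contributing nothing to the emission term (transitions
still apply across gaps).

The label constraint mu2 = mu1 + delta (delta > 0) defines state 2 as the
larger-step state and removes label switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from ._kernels import forward_stacked
from .splines import SplineBasis, seasonal_effect
from .tracks import DailyStepSeries

__all__ = [
    "EmissionParams",
    "TransitionParams",
    "InitialStateParams",
    "HMMParams",
    "StackedSeries",
    "gamma_shape_rate",
    "gamma_logpdf",
    "wrapped_cauchy_logpdf",
    "transition_probs",
    "transition_matrix",
    "emission_logdensity",
    "emission_logb",
    "forward_loglik",
    "viterbi_decode",
]

_LOG_2PI_CIRC = np.log(2.0 * np.pi)


def gamma_shape_rate(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matching (mean, sd) -> (shape, rate) for the gamma density."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return mean * mean / (sd * sd), mean / (sd * sd)


def gamma_logpdf(x, mean: float, sd: float):
    """Gamma log-density parameterized by mean and sd (NaN passes through)."""
    shape, rate = gamma_shape_rate(mean, sd)
    x = np.asarray(x, dtype=float)
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def wrapped_cauchy_logpdf(theta, mu: float, rho: float):
    """Log-density of the wrapped Cauchy on (-pi, pi].

    f(theta) = (1 - rho^2) / (2 pi (1 + rho^2 - 2 rho cos(theta - mu))),
    rho in [0, 1); rho = 0 is the circular uniform.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    theta = np.asarray(theta, dtype=float)
    return (
        np.log1p(-rho * rho)
        - _LOG_2PI_CIRC
        - np.log1p(rho * rho - 2.0 * rho * np.cos(theta - mu))
    )


@dataclass
class EmissionParams:
    """State-conditional movement distributions.

    Step lengths: gamma with mean ``mu1_step`` (state 1) and
    ``mu1_step + delta`` (state 2) and per-state sd ``sd_step``; turning
    angles: wrapped Cauchy with mean direction ``mu_turn`` and concentration
    ``rho_turn`` per state.
    """

    mu1_step: float
    delta: float
    sd_step: np.ndarray  # (2,)
    mu_turn: np.ndarray  # (2,) radians in (-pi, pi]
    rho_turn: np.ndarray  # (2,) in [0, 1)

    def __post_init__(self):
        self.sd_step = np.asarray(self.sd_step, dtype=float)
        self.mu_turn = np.asarray(self.mu_turn, dtype=float)
        self.rho_turn = np.asarray(self.rho_turn, dtype=float)
        if self.mu1_step <= 0:
            raise ValueError("mu1_step must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (state 2 has larger steps)")
        if np.any(self.sd_step <= 0):
            raise ValueError("sd_step must be > 0")
        if np.any((self.rho_turn < 0) | (self.rho_turn >= 1)):
            raise ValueError("rho_turn must be in [0, 1)")

    @property
    def mu2_step(self) -> float:
        return self.mu1_step + self.delta

    @property
    def step_means(self) -> np.ndarray:
        return np.array([self.mu1_step, self.mu2_step])


@dataclass
class TransitionParams:
    """Logit-scale intercepts and spline coefficients of the daily
    transition probabilities; row 0 parameterizes gamma_12, row 1 gamma_21."""

    beta0: np.ndarray  # (2,) [beta0_12, beta0_21]
    b: np.ndarray  # (2, K) spline coefficients [b_12, b_21]
    sigma_b: np.ndarray  # (2,) random-effect sds

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        if np.any(self.sigma_b <= 0):
            raise ValueError("sigma_b must be > 0")


@dataclass
class InitialStateParams:
    """Record-start state probabilities: phi[start_day] = (P(1), P(2))."""

    phi: dict = field(default_factory=dict)

    def __post_init__(self):
        for d, p in self.phi.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"phi[{d}] must be a probability pair")
            self.phi[d] = p

    def get(self, start_day: int) -> np.ndarray:
        return np.asarray(self.phi.get(int(start_day), (0.5, 0.5)), dtype=float)


@dataclass
class HMMParams:
    emissions: EmissionParams
    transitions: TransitionParams
    initial: InitialStateParams

    def to_dict(self) -> dict:
        e, t = self.emissions, self.transitions
        return {
            "mu1_step": float(e.mu1_step),
            "delta": float(e.delta),
            "sd_step": e.sd_step.tolist(),
            "mu_turn": e.mu_turn.tolist(),
            "rho_turn": e.rho_turn.tolist(),
            "beta0": t.beta0.tolist(),
            "b": t.b.tolist(),
            "sigma_b": t.sigma_b.tolist(),
            "phi": {int(k): v.tolist() for k, v in self.initial.phi.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            EmissionParams(
                d["mu1_step"], d["delta"], d["sd_step"], d["mu_turn"], d["rho_turn"]
            ),
            TransitionParams(d["beta0"], d["b"], d["sigma_b"]),
            InitialStateParams({int(k): v for k, v in d.get("phi", {}).items()}),
        )


def transition_probs(
    tp: TransitionParams, basis: SplineBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Daily off-diagonal transition probabilities (gamma_12, gamma_21) for
    every day of the basis domain."""
    days = np.arange(1, basis.n_days + 1)
    g12 = expit(tp.beta0[0] + seasonal_effect(days, tp.b[0], basis))
    g21 = expit(tp.beta0[1] + seasonal_effect(days, tp.b[1], basis))
    return g12, g21


def transition_matrix(day: int, tp: TransitionParams, basis: SplineBasis) -> np.ndarray:
    """2x2 stochastic matrix for the step into ``day``; rows sum to 1."""
    if not 1 <= day <= basis.n_days:
        raise ValueError(f"day out of range 1..{basis.n_days}")
    g12 = expit(tp.beta0[0] + seasonal_effect(int(day), tp.b[0], basis))
    g21 = expit(tp.beta0[1] + seasonal_effect(int(day), tp.b[1], basis))
    return np.array([[1.0 - g12, g12], [g21, 1.0 - g21]])


def emission_logdensity(step, turn, state: int, ep: EmissionParams) -> float:
    """Joint log-density of one day's (step, turn) given the state.

    A MISSING (NaN) component is marginalized out and contributes 0.
    """
    if state not in (1, 2):
        raise ValueError("state must be 1 or 2")
    i = state - 1
    out = 0.0
    if step is not None and not np.isnan(step):
        if step <= 0:
            raise ValueError("observed step must be positive")
        out += float(gamma_logpdf(step, ep.step_means[i], ep.sd_step[i]))
    if turn is not None and not np.isnan(turn):
        out += float(wrapped_cauchy_logpdf(turn, ep.mu_turn[i], ep.rho_turn[i]))
    return out


def emission_logb(steps: np.ndarray, turns: np.ndarray, ep: EmissionParams) -> np.ndarray:
    """Vectorized per-day emission log-densities, shape ``steps.shape + (2,)``.

    NaN steps/turns (missing or padding) contribute 0 to the corresponding
    state column.
    """
    steps = np.asarray(steps, dtype=float)
    turns = np.asarray(turns, dtype=float)
    out = np.zeros(steps.shape + (2,))
    sobs = ~np.isnan(steps)
    tobs = ~np.isnan(turns)
    for i in range(2):
        gs = gamma_logpdf(steps[sobs], ep.step_means[i], ep.sd_step[i])
        ws = wrapped_cauchy_logpdf(turns[tobs], ep.mu_turn[i], ep.rho_turn[i])
        out[..., i][sobs] += gs
        out[..., i][tobs] += ws
    return out


class StackedSeries:
    """Padded array view of a collection of :class:`DailyStepSeries`, the
    input format of the JIT-compiled forward pass."""

    def __init__(self, series_list: list[DailyStepSeries]):
        if len(series_list) == 0:
            raise ValueError("need at least one series")
        self.series_list = series_list
        n = len(series_list)
        self.lengths = np.array([len(s) for s in series_list], dtype=np.int64)
        self.start_days = np.array([s.start_day for s in series_list], dtype=np.int64)
        t_max = int(self.lengths.max())
        self.steps = np.full((n, t_max), np.nan)
        self.turns = np.full((n, t_max), np.nan)
        for i, s in enumerate(series_list):
            self.steps[i, : len(s)] = s.step_km
            self.turns[i, : len(s)] = s.turn_rad
        self.unique_start_days = sorted(set(int(d) for d in self.start_days))

    def __len__(self) -> int:
        return len(self.series_list)

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.steps)))


def _log_transition_table(tp: TransitionParams, basis: SplineBasis) -> np.ndarray:
    g12, g21 = transition_probs(tp, basis)
    with np.errstate(divide="ignore"):
        return np.column_stack(
            [np.log(1.0 - g12), np.log(g12), np.log(g21), np.log(1.0 - g21)]
        )


def forward_loglik_stacked(
    stacked: StackedSeries,
    params: HMMParams,
    basis: SplineBasis,
    logb: np.ndarray | None = None,
) -> float:
    """Pooled forward log-likelihood over all stacked series."""
    if logb is None:
        logb = emission_logb(stacked.steps, stacked.turns, params.emissions)
    log_tr = _log_transition_table(params.transitions, basis)
    phis = np.array([params.initial.get(d) for d in stacked.start_days])
    with np.errstate(divide="ignore"):
        lp = np.log(phis)
    return float(
        np.sum(
            forward_stacked(
                logb, log_tr, stacked.start_days - 1, stacked.lengths, lp[:, 0], lp[:, 1]
            )
        )
    )


def forward_loglik(
    series: DailyStepSeries, params: HMMParams, basis: SplineBasis
) -> float:
    """Forward-algorithm log P(observations | params) for one animal-year.

    Missing observations contribute a unit emission factor; the transition
    step across them is still applied, so a fully missing series has
    log-likelihood 0.
    """
    return forward_loglik_stacked(StackedSeries([series]), params, basis)


def viterbi_decode(
    series: DailyStepSeries, params: HMMParams, basis: SplineBasis
) -> np.ndarray:
    """Most probable state path (values 1 or 2), ties broken toward state 1."""
    logb = emission_logb(series.step_km, series.turn_rad, params.emissions)
    log_tr = _log_transition_table(params.transitions, basis)
    T = len(series)
    phi = params.initial.get(series.start_day)
    with np.errstate(divide="ignore"):
        delta = np.log(phi) + logb[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        d = series.day[t] - 1  # 0-based day-of-year row of the step into day t
        for j in range(2):
            cand = np.array(
                [delta[0] + log_tr[d, 0 + j], delta[1] + log_tr[d, 2 + j]]
            )
            # argmax with ties toward state 1 (index 0)
            back[t, j] = 0 if cand[0] >= cand[1] else 1
            logb_tj = logb[t, j]
            if j == 0:
                new0 = cand[back[t, j]] + logb_tj
            else:
                new1 = cand[back[t, j]] + logb_tj
        delta = np.array([new0, new1])
    states = np.zeros(T, dtype=int)
    states[-1] = 0 if delta[0] >= delta[1] else 1
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states + 1
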