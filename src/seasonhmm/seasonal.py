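"""Post hoc seasonal summaries: daily marginal LDM probabilities and
derivative-based timing of seasonal movement events.

The marginal probability of being in the long-distance movement state on day
t is obtained by propagating the record-start state distribution through the
daily transition matrices (Chapman-Kolmogorov); seasonal events are read off
the first derivative of that curve, scanning from day 1: fall start = first
local maximum, fall end = first subsequent local minimum, spring start =
second maximum, spring end = second minimum.  Both steps are computed per
posterior draw so that event-day intervals carry posterior uncertainty.

The propagation anchor starts at day 1 of the biological year using the
estimated initial-state distribution for the earliest record-start day
(falling back to (0.5, 0.5) if no record starts on day 1); this choice is
recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .inference import PosteriorSamples, hpdi
from .model import HMMParams, transition_probs
from .splines import SplineBasis

__all__ = [
    "SeasonalCurve",
    "EventTiming",
    "EVENT_NAMES",
    "marginal_ldm_curve",
    "curve_derivative",
    "event_days",
    "summarize_events",
    "posterior_transition_curves",
    "posterior_marginal_curve",
    "params_from_draw",
    "plot_seasonal_curves",
]

EVENT_NAMES = ("fall_start", "fall_end", "spring_start", "spring_end")

#: Defaults for derivative smoothing and extremum detection (configurable).
DEFAULT_SMOOTH_WINDOW = 7
DEFAULT_PROMINENCE = 0.005


@dataclass
class SeasonalCurve:
    """Per-day posterior summary (median + HPDI) of a probability curve."""

    day: np.ndarray
    median: np.ndarray
    hpdi_lo: np.ndarray
    hpdi_hi: np.ndarray
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "median": self.median,
                "hpdi_lo": self.hpdi_lo,
                "hpdi_hi": self.hpdi_hi,
            }
        )


@dataclass
class EventTiming:
    """Posterior summaries of the four seasonal event days."""

    events: dict  # name -> (median_day, lo, hi) or None if absent
    fraction_undefined: dict  # name -> fraction of draws without the event

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in EVENT_NAMES:
            ev = self.events.get(name)
            rows.append(
                {
                    "event": name,
                    "median_day": ev[0] if ev else np.nan,
                    "hpdi_lo": ev[1] if ev else np.nan,
                    "hpdi_hi": ev[2] if ev else np.nan,
                    "fraction_undefined": self.fraction_undefined.get(name, 1.0),
                }
            )
        return pd.DataFrame(rows)


def params_from_draw(row: pd.Series, K: int) -> HMMParams:
    """Rebuild an :class:`HMMParams` from one posterior draw row."""
    from .model import EmissionParams, InitialStateParams, TransitionParams

    b = np.vstack(
        [
            [row[f"b_12[{k + 1}]"] for k in range(K)],
            [row[f"b_21[{k + 1}]"] for k in range(K)],
        ]
    )
    phi = {}
    for name in row.index:
        if name.startswith("phi["):
            d = int(name[4:-1])
            p2 = float(row[name])
            phi[d] = np.array([1.0 - p2, p2])
    return HMMParams(
        EmissionParams(
            row["mu1_step"],
            row["delta"],
            np.array([row["sd_step[1]"], row["sd_step[2]"]]),
            np.array([row["mu_turn[1]"], row["mu_turn[2]"]]),
            np.array([row["rho_turn[1]"], row["rho_turn[2]"]]),
        ),
        TransitionParams(np.array([row["beta0_12"], row["beta0_21"]]), b,
                         np.array([row["sigma_b[1]"], row["sigma_b[2]"]])),
        InitialStateParams(phi),
    )


def marginal_ldm_curve(params: HMMParams, basis: SplineBasis) -> np.ndarray:
    """P(LDM state on day t) for t = 1..365 by forward propagation.

    The day-1 distribution is the initial-state distribution of the earliest
    record-start day if that day is 1, else (0.5, 0.5); subsequent days apply
    p_t = p_{t-1} Gamma(t).
    """
    g12, g21 = transition_probs(params.transitions, basis)
    anchor = params.initial.get(1) if 1 in params.initial.phi else np.array([0.5, 0.5])
    p = anchor.astype(float).copy()
    out = np.empty(basis.n_days)
    out[0] = p[1]
    for t in range(2, basis.n_days + 1):
        g12t, g21t = g12[t - 1], g21[t - 1]
        p = np.array(
            [p[0] * (1.0 - g12t) + p[1] * g21t, p[0] * g12t + p[1] * (1.0 - g21t)]
        )
        out[t - 1] = p[1]
    return out


def curve_derivative(
    curve: np.ndarray, smooth_window: int | None = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """First derivative per day: centered differences on interior days,
    one-sided at the ends, after optional centered moving-average smoothing."""
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 3:
        raise ValueError("need at least 3 days")
    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        half = w // 2
        padded = np.pad(curve, half, mode="edge")
        kernel = np.ones(w) / w
        curve = np.convolve(padded, kernel, mode="valid")[: len(curve)]
    deriv = np.empty_like(curve)
    deriv[1:-1] = (curve[2:] - curve[:-2]) / 2.0
    deriv[0] = curve[1] - curve[0]
    deriv[-1] = curve[-1] - curve[-2]
    return deriv


def event_days(
    derivative: np.ndarray, prominence: float = DEFAULT_PROMINENCE
) -> dict:
    """Seasonal event days from the derivative of the marginal LDM curve.

    Scanning from day 1: fall_start = first local maximum of the derivative,
    fall_end = first subsequent local minimum, spring_start = the second
    maximum, spring_end = the second subsequent minimum.  Local extrema are
    detected with a prominence floor; events whose required extremum is
    absent are returned as None (flagged, not an error).
    """
    d = np.asarray(derivative, dtype=float)
    peaks, _ = find_peaks(d, prominence=prominence)
    troughs, _ = find_peaks(-d, prominence=prominence)
    extrema = sorted(
        [(int(i), "max") for i in peaks] + [(int(i), "min") for i in troughs]
    )
    wanted = ("max", "min", "max", "min")
    found: list[int | None] = []
    pos = 0
    for kind in wanted:
        nxt = next((i for i, (idx, k) in enumerate(extrema) if i >= pos and k == kind), None)
        if nxt is None:
            found.append(None)
            continue
        found.append(extrema[nxt][0] + 1)  # index -> day of year
        pos = nxt + 1
    return dict(zip(EVENT_NAMES, found))


def summarize_events(per_draw_events: list[dict], mass: float = 0.90) -> EventTiming:
    """Median and HPDI of each event day over the draws where it is defined."""
    if len(per_draw_events) == 0:
        raise ValueError("no draws")
    events = {}
    frac_undef = {}
    for name in EVENT_NAMES:
        vals = np.array(
            [e[name] for e in per_draw_events if e.get(name) is not None], dtype=float
        )
        frac_undef[name] = 1.0 - len(vals) / len(per_draw_events)
        if len(vals) < 20:
            events[name] = None
            continue
        lo, hi = hpdi(vals, mass)
        events[name] = (float(np.median(vals)), lo, hi)
    return EventTiming(events, frac_undef)


def _per_day_summary(draw_matrix: np.ndarray, name: str, mass: float, meta: dict) -> SeasonalCurve:
    med = np.median(draw_matrix, axis=0)
    lo = np.empty(draw_matrix.shape[1])
    hi = np.empty(draw_matrix.shape[1])
    for d in range(draw_matrix.shape[1]):
        lo[d], hi[d] = hpdi(draw_matrix[:, d], mass)
    return SeasonalCurve(
        np.arange(1, draw_matrix.shape[1] + 1), med, lo, hi, name=name, metadata=meta
    )


def posterior_transition_curves(
    samples: PosteriorSamples, basis: SplineBasis, mass: float = 0.90
) -> tuple[SeasonalCurve, SeasonalCurve]:
    """Posterior per-day summaries of gamma_12 and gamma_21."""
    K = basis.n_coef
    g12_draws = np.empty((len(samples.draws), basis.n_days))
    g21_draws = np.empty_like(g12_draws)
    for i, (_, row) in enumerate(samples.draws.iterrows()):
        p = params_from_draw(row, K)
        g12_draws[i], g21_draws[i] = transition_probs(p.transitions, basis)
    meta = {"mass": mass}
    return (
        _per_day_summary(g12_draws, "gamma_12", mass, meta),
        _per_day_summary(g21_draws, "gamma_21", mass, meta),
    )


def posterior_marginal_curve(
    samples: PosteriorSamples,
    basis: SplineBasis,
    mass: float = 0.90,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
    events_on: str = "draws",
) -> tuple[SeasonalCurve, EventTiming, np.ndarray]:
    """Marginal LDM curve summary, event timing and the raw per-draw curves.

    ``events_on`` selects whether events are computed per posterior draw and
    then summarized (``"draws"``, the default, propagating uncertainty) or
    once on the posterior-median curve (``"median"``).
    """
    K = basis.n_coef
    curves = np.empty((len(samples.draws), basis.n_days))
    for i, (_, row) in enumerate(samples.draws.iterrows()):
        curves[i] = marginal_ldm_curve(params_from_draw(row, K), basis)
    meta = {
        "anchor": "day 1 of the biological year; phi[1] if a record starts "
        "on day 1, else (0.5, 0.5)",
        "smooth_window": smooth_window,
        "prominence": prominence,
        "events_on": events_on,
    }
    curve = _per_day_summary(curves, "marginal_ldm", mass, meta)
    if events_on == "draws":
        per_draw = [
            event_days(curve_derivative(c, smooth_window), prominence) for c in curves
        ]
        timing = summarize_events(per_draw, mass)
    elif events_on == "median":
        ev = event_days(curve_derivative(curve.median, smooth_window), prominence)
        timing = EventTiming(
            {k: (float(v), float(v), float(v)) if v is not None else None for k, v in ev.items()},
            {k: 0.0 if v is not None else 1.0 for k, v in ev.items()},
        )
    else:
        raise ValueError("events_on must be 'draws' or 'median'")
    return curve, timing, curves


def plot_seasonal_curves(curves: list[SeasonalCurve], path=None):
    """Median-line + HPDI-ribbon panels, one per curve (layout of the
    seasonal transition / marginal-probability figures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(curves), 1, figsize=(8, 2.8 * len(curves)), squeeze=False)
    for ax, c in zip(axes[:, 0], curves):
        ax.fill_between(c.day, c.hpdi_lo, c.hpdi_hi, alpha=0.3, label="90% HPDI")
        ax.plot(c.day, c.median, lw=1.5, label="median")
        ax.set_xlabel("day of biological year (July 1 = 1)")
        ax.set_ylabel(c.name)
        ax.set_ylim(0, None)
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
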