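"""Low-rank radial (thin-plate-style) spline basis over day of year.

The seasonal trend in the logit transition probabilities, f(day), is a
penalized spline with K knots evenly spaced over the biological year.  We use
the random-effects formulation: with raw basis ``Z_raw[d, k] = |d - kappa_k|^3``
and knot Gram matrix ``Omega[k, k'] = |kappa_k - kappa_k'|^3``, the working
basis is ``Z = Z_raw @ Omega^{-1/2}``, under which iid Normal(0, sigma)
coefficients b induce the intended smoothness penalty.  The cubic radial Gram
matrix is only conditionally positive definite, so the symmetric square root
is taken through the SVD (the convention of the penalized-spline literature).

Columns of Z are additionally rescaled to unit sample standard deviation so
that the prior scale of sigma is decoupled from the raw cubic magnitudes
(which are O(10^6) over a 365-day domain); this reparameterization leaves the
curve family unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplineBasis", "make_knots", "build_basis", "seasonal_effect"]


@dataclass(frozen=True)
class SplineBasis:
    """Knots plus the (n_days x K) evaluated basis matrix.

    Row ``d-1`` of ``Z`` is the basis evaluated at day ``d``;
    ``formulation_tag`` records how the matrix was constructed.
    """

    knots: np.ndarray
    Z: np.ndarray
    formulation_tag: str

    @property
    def n_coef(self) -> int:
        return self.Z.shape[1]

    @property
    def n_days(self) -> int:
        return self.Z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Basis as a day x K table (for CSV export / plotting)."""
        df = pd.DataFrame(self.Z, columns=[f"Z{k + 1}" for k in range(self.n_coef)])
        df.insert(0, "day", np.arange(1, self.n_days + 1))
        return df


def make_knots(K: int, lo: float = 1.0, hi: float = 365.0) -> np.ndarray:
    """K knots evenly spaced on [lo, hi], endpoints included."""
    if K < 2:
        raise ValueError(f"need at least 2 knots, got {K}")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return np.linspace(lo, hi, K)


def _radial_Z(knots: np.ndarray, days: np.ndarray) -> tuple[np.ndarray, str]:
    Z_raw = np.abs(days[:, None] - knots[None, :]) ** 3
    Omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    U, s, Vt = np.linalg.svd(Omega)
    if np.min(s) < 1e-10 * np.max(s):
        raise np.linalg.LinAlgError(
            "knot Gram matrix is numerically singular; knots must be distinct"
        )
    Omega_inv_half = (U / np.sqrt(s)) @ Vt
    return Z_raw @ Omega_inv_half, "lowrank-radial-svd"


def _bspline_Z(knots: np.ndarray, days: np.ndarray) -> tuple[np.ndarray, str]:
    # alternative formulation: cubic B-spline design matrix with one column
    # per interior basis function and iid-normal coefficients
    from scipy.interpolate import BSpline

    k = 3
    t = np.concatenate([[knots[0]] * k, knots, [knots[-1]] * k])
    n_basis = len(t) - k - 1
    Z = BSpline.design_matrix(days, t, k).toarray()[:, :n_basis]
    return Z, "cubic-bspline"


def build_basis(
    knots: np.ndarray,
    days: np.ndarray | None = None,
    *,
    kind: str = "radial",
    scale_columns: bool = True,
) -> SplineBasis:
    """Evaluate the seasonal basis at ``days`` (default: 1..365).

    ``kind`` selects the formulation: ``"radial"`` (default, the random-
    effects construction described in the module docstring) or ``"bspline"``
    (plug-in alternative).  Downstream code is basis-agnostic.
    """
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing with length >= 2")
    if days is None:
        days = np.arange(1, 366, dtype=float)
    days = np.asarray(days, dtype=float)

    if kind == "radial":
        Z, tag = _radial_Z(knots, days)
    elif kind == "bspline":
        Z, tag = _bspline_Z(knots, days)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    if scale_columns:
        sd = Z.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("basis has a constant column; cannot scale")
        Z = Z / sd
        tag += "|unit-sd"
    return SplineBasis(knots=knots, Z=Z, formulation_tag=tag)


def seasonal_effect(day, b: np.ndarray, basis: SplineBasis):
    """Seasonal logit-scale effect f(day) = sum_k b_k Z[day, k].

    ``day`` may be a scalar or array of integer days in 1..n_days.
    """
    day_arr = np.atleast_1d(np.asarray(day, dtype=int))
    if np.any(day_arr < 1) or np.any(day_arr > basis.n_days):
        raise ValueError(f"day out of range 1..{basis.n_days}")
    b = np.asarray(b, dtype=float)
    if b.shape != (basis.n_coef,):
        raise ValueError(f"b must have shape ({basis.n_coef},)")
    vals = basis.Z[day_arr - 1] @ b
    return vals if np.ndim(day) else float(vals[0])
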