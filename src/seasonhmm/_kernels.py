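"""Numba kernels for the forward recursion over stacked animal-year series.

The two-state forward pass is a tight sequential loop (365 steps per series)
that dominates MCMC cost, so it is JIT-compiled.  Emission log-densities are
precomputed outside (they vectorize trivially) and passed in as an
(n_series, T_max, 2) array with zeros at missing observations and padding.
"""

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def forward_stacked(logb, log_tr, start_idx, lengths, log_phi1, log_phi2):
    """Per-series log-likelihood vector over stacked series.

    Parameters
    ----------
    logb : (n, T_max, 2) per-day per-state emission log-density (0 = missing).
    log_tr : (n_days, 4) log transition entries per day of year
        ``[log(1-g12), log g12, log g21, log(1-g21)]``; the step into the day
        at position ``t`` of a series uses the row for that day.
    start_idx : (n,) zero-based day-of-year index of each series' first day.
    lengths : (n,) series grid lengths.
    log_phi1, log_phi2 : (n,) log initial-state probabilities per series.
    """
    n = logb.shape[0]
    out = np.empty(n)
    for s in range(n):
        a1 = log_phi1[s] + logb[s, 0, 0]
        a2 = log_phi2[s] + logb[s, 0, 1]
        for t in range(1, lengths[s]):
            d = start_idx[s] + t
            x1 = np.logaddexp(a1 + log_tr[d, 0], a2 + log_tr[d, 2]) + logb[s, t, 0]
            x2 = np.logaddexp(a1 + log_tr[d, 1], a2 + log_tr[d, 3]) + logb[s, t, 1]
            a1 = x1
            a2 = x2
        out[s] = np.logaddexp(a1, a2)
    return out
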