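"""Independent oracles used by the tests.

These re-derive expected values by brute force or closed form, independently
of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_es(metrics: np.ndarray, hit_positions, weight: int) -> float:
    """Running-sum ES by direct O(N) walk over the full ranked list."""
    n = len(metrics)
    hits = set(int(i) for i in hit_positions)
    absm = np.abs(np.asarray(metrics, dtype=float))
    w = np.array([absm[i] ** weight if i in hits else 0.0 for i in range(n)])
    denom = w.sum()
    if denom == 0:
        w = np.array([1.0 if i in hits else 0.0 for i in range(n)])
        denom = float(len(hits))
    miss = 1.0 / (n - len(hits))
    run = np.cumsum([w[i] / denom if i in hits else -miss for i in range(n)])
    mx = max(run.max(), 0.0)
    mn = min(run.min(), 0.0)
    if np.isclose(mx, -mn, rtol=1e-9, atol=1e-12) or mx > -mn:
        return float(mx)
    return float(mn)


def two_sample_t_power(
    delta: float, n_per_group: int, sd: float = 1.0, alpha: float = 0.05
) -> float:
    """Closed-form power of the two-sided pooled-variance t-test (noncentral t)."""
    df = 2 * n_per_group - 2
    ncp = (delta / sd) * np.sqrt(n_per_group * n_per_group / (2 * n_per_group))
    crit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(crit, df, ncp)
    lower = stats.nct.cdf(-crit, df, ncp)
    # scipy's noncentral t underflows to NaN far in the tail; that tail is 0
    if np.isnan(lower):
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0 if ncp > crit else 0.0
    return float(upper + lower)


def effect_for_power(
    target: float, n_per_group: int, sd: float = 1.0, alpha: float = 0.05
) -> float:
    """Mean shift giving the target two-sample t power (bisection on the oracle)."""
    from scipy.optimize import brentq

    return float(
        brentq(
            lambda d: two_sample_t_power(d, n_per_group, sd, alpha) - target,
            0.05,
            4.0,
        )
    )
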