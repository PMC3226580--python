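"""Per-condition differential statistics and the signed ranking metric.

Each gene is scored against its condition with a two-sided Student's
(pooled-variance) t-test between treated and control replicates; Welch's
unequal-variance variant is available behind a flag.  The ranking metric is
``log10(1/p)`` signed by the direction of the mean treated-minus-control
difference, so strongly up-regulated genes land at the top of the ranked
list and strongly down-regulated genes at the bottom.  P-values are floored
(default 1e-16) before the log so the metric stays finite; rank order among
floored genes then falls to the deterministic tie rule (descending metric,
then gene id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionExperiment, RankedList

__all__ = [
    "GeneTestResult",
    "gene_t_test",
    "ranking_metric",
    "build_ranked_list",
    "DEFAULT_P_FLOOR",
]

DEFAULT_P_FLOOR = 1e-16


@dataclass
class GeneTestResult:
    gene: str
    p_value: float
    direction: str  # "up" | "down"
    t_statistic: float
    degenerate: bool = False  # both groups constant and equal


def _t_test_arrays(
    treated: np.ndarray, control: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided t-test over rows (genes). Returns (t, p)."""
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = treated.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 values per group")
    if not (np.isfinite(treated).all() and np.isfinite(control).all()):
        raise ValueError("non-finite expression values")
    m1 = treated.mean(axis=1)
    m2 = control.mean(axis=1)
    v1 = treated.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    # zero pooled variance: identical constant groups -> t=0, p=1;
    # different constant groups -> infinitely significant, p floored later
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.ones_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df[finite])
    p[~finite] = 0.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p


def gene_t_test(
    treated, control, gene: str = "", welch: bool = False
) -> GeneTestResult:
    """Two-sided t-test for one gene; direction from the sign of the mean difference.

    Identical constant groups are a degenerate case: p=1, direction reported
    as "up" with ``degenerate=True``.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    t, p = _t_test_arrays(treated[None, :], control[None, :], welch=welch)
    diff = treated.mean() - control.mean()
    degenerate = bool(diff == 0 and treated.var() == 0 and control.var() == 0)
    direction = "up" if diff >= 0 else "down"
    return GeneTestResult(
        gene=gene,
        p_value=float(p[0]),
        direction=direction,
        t_statistic=float(t[0]),
        degenerate=degenerate,
    )


def ranking_metric(result: GeneTestResult, p_floor: float = DEFAULT_P_FLOOR) -> float:
    """Signed ``log10(1/p)``: positive for up-regulated, negative for down."""
    p = result.p_value
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value out of (0, 1]: {p}")
    p = max(p, p_floor)
    magnitude = np.log10(1.0 / p)
    return float(magnitude if result.direction == "up" else -magnitude)


def build_ranked_list(
    experiment: ExpressionExperiment,
    welch: bool = False,
    p_floor: float = DEFAULT_P_FLOOR,
) -> RankedList:
    """Rank all genes of one experiment by the signed metric (descending)."""
    treated = experiment.group_values("treated")
    control = experiment.group_values("control")
    t, p = _t_test_arrays(treated, control, welch=welch)
    p = np.maximum(p, p_floor)
    sign = np.where(treated.mean(axis=1) - control.mean(axis=1) >= 0, 1.0, -1.0)
    metric = sign * np.log10(1.0 / p)
    return RankedList.from_pairs(
        zip(experiment.genes, metric.tolist()), condition_id=experiment.condition_id
    )
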