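"""Pathway responsiveness: significant-response counts, NPC, HR/MR/LR classes.

A pathway's responsiveness is the number of conditions in which its
enrichment is nominally significant (p < alpha); missing cells never count.
The normalized pathway coverage NPC(theta) is the mean of n_i / C over the
pathways whose count n_i meets the threshold theta — the average fraction of
the C conditions covered by a surviving pathway.  The NPC curve against the
surviving percentage is the instrument for choosing the class thresholds;
threshold selection itself stays a config decision (defaults 10 and 5):
HR with n_i >= 10, MR with 5 <= n_i <= 9, LR below 5.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import NESMatrix

__all__ = [
    "count_significant",
    "npc",
    "npc_curve",
    "classify",
    "responsiveness_profile",
]


def count_significant(matrix: NESMatrix) -> pd.Series:
    """Per-pathway count n_i of conditions with nominal p < alpha."""
    return matrix.significant().sum(axis=1).rename("n_significant")


def npc(counts: Sequence[int] | pd.Series, C: int, theta: int) -> float:
    """Normalized pathway coverage at threshold ``theta`` over ``C`` conditions.

    NPC(theta) = mean over {i : n_i >= theta} of n_i / C.  Returns NaN when
    no pathway meets the threshold — an empty survivor set is a missing
    point on the curve, not a zero.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    counts = np.asarray(counts, dtype=float)
    surviving = counts[counts >= theta]
    if surviving.size == 0:
        return float("nan")
    return float(np.mean(surviving / C))


def npc_curve(counts: Sequence[int] | pd.Series, C: int) -> pd.DataFrame:
    """NPC(theta) and surviving-percentage for every theta in 0..C."""
    counts = np.asarray(counts, dtype=float)
    total = counts.size
    rows = []
    for theta in range(C + 1):
        n_surviving = int((counts >= theta).sum())
        rows.append(
            {
                "theta": theta,
                "npc": npc(counts, C, theta),
                "pct_pathways": 100.0 * n_surviving / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def classify(
    counts: pd.Series | Sequence[int], theta_hr: int = 10, theta_mr: int = 5
) -> pd.Series:
    """HR iff n_i >= theta_hr; MR iff theta_mr <= n_i < theta_hr; else LR."""
    if not theta_mr < theta_hr:
        raise ValueError("theta_mr must be < theta_hr")
    counts = pd.Series(counts)
    klass = pd.Series("LR", index=counts.index, name="class")
    klass[counts >= theta_mr] = "MR"
    klass[counts >= theta_hr] = "HR"
    return klass


def responsiveness_profile(
    matrix: NESMatrix, theta_hr: int = 10, theta_mr: int = 5
) -> pd.DataFrame:
    """Per-pathway table: n_significant, n_conditions, class."""
    counts = count_significant(matrix)
    return pd.DataFrame(
        {
            "n_significant": counts,
            "n_conditions": len(matrix.conditions),
            "class": classify(counts, theta_hr=theta_hr, theta_mr=theta_mr),
        }
    )
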