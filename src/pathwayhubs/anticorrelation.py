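"""Seed-condition scoring of anti-correlated pathway behavior.

Conditions in which the two hub groups show clearly inverted activity act
as "seeds".  For every pathway, each significant response within a seed
condition transfers +1 to the hub group whose consensus activity direction
it matches and -1 to the other group, so A_score = -B_score always.  With
n the number of significant seed responses, the anti-correlation score is
max(A_score, B_score) / n — the fraction-weighted agreement with the
winning group on a grid (2k - n)/n.  A pathway joins Group A when
A_score >= 3 (equivalently B_score <= -3), and is called anti-correlated
when its score strictly exceeds 0.7 (with 3 <= n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import NESMatrix

__all__ = [
    "SeedConditionSet",
    "AntiCorrelationResult",
    "consensus_direction",
    "select_seed_conditions",
    "score_pathway",
    "assign_groups",
    "score_all",
]


@dataclass
class SeedConditionSet:
    """Seed conditions and the per-condition hub-group consensus directions."""

    conditions: list[str]
    consensus: dict[str, tuple[int, int]]  # condition -> (dir A, dir B), each +-1

    def __post_init__(self) -> None:
        for cond in self.conditions:
            da, db = self.consensus[cond]
            if da != -db or da not in (-1, 1):
                raise ValueError(
                    f"seed {cond!r}: group consensus directions must be opposite"
                )


@dataclass
class AntiCorrelationResult:
    pathway: str
    a_score: int
    b_score: int
    n: int
    anti_score: float  # NaN when n == 0
    assigned_group: str = "none"
    anti_correlated: bool = False


def consensus_direction(
    nes: NESMatrix,
    group_hubs: Sequence[str],
    condition: str,
    min_hubs: int = 3,
) -> int | None:
    """Sign of the mean NES of the group's significant hubs in a condition.

    Undefined (None) when fewer than ``min_hubs`` hubs respond significantly
    or the mean is exactly zero.
    """
    if len(group_hubs) == 0:
        raise ValueError("empty hub group")
    hubs = [h for h in group_hubs if h in nes.nes.index]
    sig = nes.significant().loc[hubs, condition]
    responding = [h for h in hubs if sig[h]]
    if len(responding) < min_hubs:
        return None
    mean = nes.nes.loc[responding, condition].mean()
    if mean == 0:
        return None
    return 1 if mean > 0 else -1


def select_seed_conditions(
    nes: NESMatrix,
    groups: Mapping[str, str],
    min_hubs: int = 3,
    manual: Sequence[str] | None = None,
) -> SeedConditionSet:
    """Conditions whose two hub-group consensuses are defined and opposite.

    ``groups`` maps hub pathway -> "A" | "B".  A ``manual`` list of condition
    labels overrides the automatic rule but is validated the same way.
    """
    hubs_a = [p for p, g in groups.items() if g == "A"]
    hubs_b = [p for p, g in groups.items() if g == "B"]
    if not hubs_a or not hubs_b:
        raise ValueError("both hub groups must be non-empty")
    candidates = list(nes.conditions) if manual is None else list(manual)
    unknown = [c for c in candidates if c not in nes.conditions]
    if unknown:
        raise ValueError(f"unknown condition(s): {unknown}")
    conditions: list[str] = []
    consensus: dict[str, tuple[int, int]] = {}
    for cond in candidates:
        da = consensus_direction(nes, hubs_a, cond, min_hubs=min_hubs)
        db = consensus_direction(nes, hubs_b, cond, min_hubs=min_hubs)
        if da is None or db is None or da != -db:
            if manual is not None:
                raise ValueError(
                    f"condition {cond!r} does not show an inverted hub profile"
                )
            continue
        conditions.append(cond)
        consensus[cond] = (da, db)
    if not conditions:
        raise ValueError("no seed condition found: scoring scheme needs seeds")
    return SeedConditionSet(conditions=conditions, consensus=consensus)


def score_pathway(
    pathway: str,
    responses: Mapping[str, tuple[bool, int]],
    seeds: SeedConditionSet,
) -> AntiCorrelationResult:
    """Score one pathway over the seed conditions.

    ``responses`` maps seed condition -> (significant?, NES sign).  Each
    significant seed response matching Group A's consensus direction moves
    A_score up and B_score down by one, and symmetrically for B.  n counts
    the significant seed responses; with n < 3 no group is assigned.
    """
    a_score = 0
    n = 0
    for cond in seeds.conditions:
        significant, sign = responses.get(cond, (False, 0))
        if not significant or sign == 0:
            continue
        n += 1
        da, _db = seeds.consensus[cond]
        a_score += 1 if sign == da else -1
    b_score = -a_score
    anti = max(a_score, b_score) / n if n > 0 else float("nan")
    return AntiCorrelationResult(
        pathway=pathway, a_score=a_score, b_score=b_score, n=n, anti_score=anti
    )


def assign_groups(
    results: Sequence[AntiCorrelationResult],
    min_group_score: int = 3,
    anti_threshold: float = 0.7,
    min_n: int = 3,
) -> pd.DataFrame:
    """Final table: group membership and the strict anti-correlation call."""
    rows = []
    for r in results:
        group = "none"
        if r.n >= min_n:
            if r.a_score >= min_group_score:
                group = "A"
            elif r.b_score >= min_group_score:
                group = "B"
        anti = group != "none" and r.anti_score > anti_threshold
        r.assigned_group = group
        r.anti_correlated = bool(anti)
        rows.append(
            {
                "pathway": r.pathway,
                "a_score": r.a_score,
                "b_score": r.b_score,
                "n": r.n,
                "anti_score": r.anti_score,
                "group": group,
                "anti_correlated": bool(anti),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway", "a_score", "b_score", "n", "anti_score", "group",
            "anti_correlated",
        ],
    ).set_index("pathway")


def score_all(
    nes: NESMatrix,
    seeds: SeedConditionSet,
    min_group_score: int = 3,
    anti_threshold: float = 0.7,
) -> pd.DataFrame:
    """Score every pathway of the matrix against the seed set."""
    sig = nes.significant()
    results = []
    for pathway in nes.pathways:
        responses = {}
        for cond in seeds.conditions:
            value = nes.nes.loc[pathway, cond]
            sign = 0 if pd.isna(value) or value == 0 else (1 if value > 0 else -1)
            responses[cond] = (bool(sig.loc[pathway, cond]), sign)
        results.append(score_pathway(pathway, responses, seeds))
    return assign_groups(
        results, min_group_score=min_group_score, anti_threshold=anti_threshold
    )
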