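"""Preranked gene-set enrichment: running-sum ES, permutation null, NES.

The enrichment score (ES) walks down the ranked gene list, increasing a
running sum at gene-set members and decreasing it elsewhere; the ES is the
maximum deviation from zero, a weighted Kolmogorov-Smirnov-like statistic.
With ``weight=1`` (default) hit increments are proportional to the absolute
ranking metric; ``weight=0`` gives the classic unweighted KS walk.

Significance is calibrated with a gene-label permutation null: random gene
sets of the same size are drawn from the ranked list (preranked mode has no
phenotype labels to permute).  The nominal p-value uses an add-one empirical
tail estimator over the same-signed part of the null, and the NES divides
the ES by the mean absolute same-signed null ES — the standard
operationalization of normalizing the score to set size.

The per-condition results are assembled into a pathway × condition NES
matrix (the "meta-activity" of each pathway in each condition) with a
matching nominal-p matrix; cells where a pathway had fewer than ``min_size``
mapped genes are missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection, RankedList

__all__ = [
    "EnrichmentResult",
    "NESMatrix",
    "enrichment_score",
    "permutation_null",
    "nominal_p",
    "normalized_es",
    "enrich_collection",
    "build_nes_matrix",
]


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_from_positions(
    abs_metrics: np.ndarray, positions: np.ndarray, weight: int
) -> np.ndarray:
    """Vectorized ES for a batch of hit-position sets.

    ``positions``: (n_sets, k) int array of 0-based hit positions, each row
    sorted ascending.  Returns the signed ES per row.  Extremes of the walk
    occur only immediately after a hit (positive candidates) or immediately
    before a hit (negative candidates); between hits the walk declines
    linearly.  A tie |max| == |min| resolves to the positive deviation.
    """
    positions = np.atleast_2d(positions)
    n_sets, k = positions.shape
    n = len(abs_metrics)
    if not (1 <= k < n):
        raise ValueError("set size must satisfy 1 <= k < N")
    if weight == 0:
        w = np.ones_like(positions, dtype=float)
    else:
        w = abs_metrics[positions] ** weight
    denom = w.sum(axis=1, keepdims=True)
    # all-zero metrics in the set: fall back to equal hit weights
    flat = denom[:, 0] == 0
    if flat.any():
        w[flat] = 1.0
        denom[flat] = k
    cum = np.cumsum(w, axis=1) / denom
    miss = 1.0 / (n - k)
    j = np.arange(1, k + 1)
    after_hit = cum - (positions + 1 - j) * miss
    before_hit = cum - w / denom - (positions - (j - 1)) * miss
    pos_extreme = np.maximum(after_hit.max(axis=1), 0.0)
    neg_extreme = np.minimum(before_hit.min(axis=1), 0.0)
    # |max| == |min| ties resolve to the positive deviation; compare with a
    # tolerance so float accumulation order cannot flip a true tie
    tie = np.isclose(pos_extreme, -neg_extreme, rtol=1e-9, atol=1e-12)
    return np.where(tie | (pos_extreme > -neg_extreme), pos_extreme, neg_extreme)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: int = 1
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set against one ranked list.

    Raises if no set gene maps to the list ("set not represented") or the set
    covers every ranked gene (the miss decrement is then undefined).
    """
    pos_of = ranked.position_of()
    positions = sorted(pos_of[g] for g in set(gene_set) if g in pos_of)
    n = len(ranked)
    if not positions:
        raise ValueError("set not represented in the ranked list")
    if len(positions) == n:
        raise ValueError("set covers the whole ranked list")
    abs_metrics = np.abs(ranked.metrics)
    k = len(positions)
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    if weight == 0:
        w = np.ones(k)
    else:
        w = abs_metrics[positions] ** weight
    denom = w.sum()
    if denom == 0:
        w = np.ones(k)
        denom = float(k)
    step = np.full(n, -1.0 / (n - k))
    step[positions] = w / denom
    running = np.cumsum(step)
    es = float(_es_from_positions(abs_metrics, np.array([positions]), weight)[0])
    return es, running


# ---------------------------------------------------------------------------
# permutation null / p / NES
# ---------------------------------------------------------------------------


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    weight: int = 1,
    seed: int | np.random.SeedSequence | None = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """ES sample for random gene sets of ``set_size`` drawn from the list.

    ``exhaustive=True`` enumerates every C(N, k) subset instead of sampling
    (only sensible for tiny lists; used as its own oracle in tests).
    """
    n = len(ranked)
    if not (1 <= set_size < n):
        raise ValueError(f"set_size must be in [1, {n - 1}], got {set_size}")
    abs_metrics = np.abs(ranked.metrics)
    if exhaustive:
        subsets = np.array(
            list(itertools.combinations(range(n), set_size)), dtype=np.intp
        )
        return _es_from_positions(abs_metrics, subsets, weight)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(u, set_size - 1, axis=1)[:, :set_size], axis=1)
    return _es_from_positions(abs_metrics, positions, weight)


def nominal_p(es: float, null: Sequence[float]) -> float:
    """Add-one empirical tail probability over the same-signed null.

    p = (1 + #{null with same sign and |null| >= |es|}) / (1 + #same-sign).
    Returns NaN (flagged missing) when the null contains no same-signed
    values.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    same = null * es > 0 if es != 0 else np.ones_like(null, dtype=bool)
    n_same = int(same.sum())
    if n_same == 0:
        return float("nan")
    extreme = int((np.abs(null[same]) >= abs(es)).sum())
    return (1 + extreme) / (1 + n_same)


def normalized_es(es: float, null: Sequence[float]) -> float:
    """ES divided by the mean |ES| of the same-signed null; sign preserved."""
    null = np.asarray(null, dtype=float)
    same = null * es > 0 if es != 0 else np.ones_like(null, dtype=bool)
    if not same.any():
        return float("nan")
    return float(es / np.abs(null[same]).mean())


# ---------------------------------------------------------------------------
# collections and the NES matrix
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    nominal_p: float
    n_mapped: int
    running_sum: np.ndarray | None = None


def _null_seed(seed: int, set_size: int) -> np.random.SeedSequence:
    # null depends only on (root seed, set size): identical across GMT orders
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(set_size),))


def enrich_collection(
    ranked: RankedList,
    collection: GeneSetCollection,
    min_size: int = 10,
    n_perm: int = 1000,
    weight: int = 1,
    seed: int = 0,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Score every gene set with >= ``min_size`` mapped genes.

    Returns (results, skipped set names).  Permutation nulls are shared
    between sets with the same mapped size — the gene-label null depends only
    on the ranked list and the set size — and are seeded by (seed, size), so
    output is independent of the order of sets in the collection.
    """
    pos_of = ranked.position_of()
    abs_metrics = np.abs(ranked.metrics)
    n = len(ranked)
    mapped: dict[str, list[int]] = {}
    skipped: list[str] = []
    for name, genes in collection:
        positions = sorted(pos_of[g] for g in genes if g in pos_of)
        if len(positions) < min_size or len(positions) == n:
            skipped.append(name)
        else:
            mapped[name] = positions
    null_cache: dict[int, np.ndarray] = {}
    results: list[EnrichmentResult] = []
    for name in sorted(mapped):
        positions = mapped[name]
        k = len(positions)
        if k not in null_cache:
            null_cache[k] = permutation_null(
                ranked, k, n_perm=n_perm, weight=weight, seed=_null_seed(seed, k)
            )
        null = null_cache[k]
        es = float(_es_from_positions(abs_metrics, np.array([positions]), weight)[0])
        results.append(
            EnrichmentResult(
                pathway=name,
                es=es,
                nes=normalized_es(es, null),
                nominal_p=nominal_p(es, null),
                n_mapped=k,
            )
        )
    return results, skipped


@dataclass
class NESMatrix:
    """Pathway × condition NES values with the matching nominal-p matrix.

    Missing cells (pathway untestable in that condition) are NaN in both
    matrices simultaneously.  ``alpha`` is the nominal significance level
    used everywhere downstream (default 0.05).
    """

    nes: pd.DataFrame
    nominal_p: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.nes.shape != self.nominal_p.shape:
            raise ValueError("nes and nominal_p shapes differ")
        if not (
            self.nes.index.equals(self.nominal_p.index)
            and self.nes.columns.equals(self.nominal_p.columns)
        ):
            raise ValueError("nes and nominal_p labels differ")
        if (self.nes.isna() != self.nominal_p.isna()).any().any():
            raise ValueError("missing cells of nes and nominal_p must coincide")

    @property
    def pathways(self) -> list[str]:
        return list(self.nes.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.nes.columns)

    def significant(self) -> pd.DataFrame:
        """Boolean mask: nominal p < alpha (missing cells are False)."""
        return (self.nominal_p < self.alpha).fillna(False).astype(bool)


def build_nes_matrix(
    results: Mapping[str, Sequence[EnrichmentResult]], alpha: float = 0.05
) -> NESMatrix:
    """Assemble per-condition result lists into a NESMatrix.

    ``results`` maps condition label → enrichment results.  Pathway rows are
    the union across conditions; untested cells stay missing.
    """
    conditions = list(results)
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition label")
    if not conditions:
        raise ValueError("need at least one condition")
    pathways = sorted({r.pathway for rs in results.values() for r in rs})
    for cond, rs in results.items():
        names = [r.pathway for r in rs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate pathway in condition {cond!r}")
    nes = pd.DataFrame(np.nan, index=pathways, columns=conditions, dtype=float)
    pval = pd.DataFrame(np.nan, index=pathways, columns=conditions, dtype=float)
    for cond, rs in results.items():
        for r in rs:
            if np.isnan(r.nes) or np.isnan(r.nominal_p):
                continue  # undefined score: leave the cell missing
            nes.loc[r.pathway, cond] = r.nes
            pval.loc[r.pathway, cond] = r.nominal_p
    return NESMatrix(nes=nes, nominal_p=pval, alpha=alpha)
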