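"""Readers and writers for every external representation the pipeline touches.

Formats: GMT gene-set files, RNK preranked lists, expression tables with a
treated/control design, pathway × condition matrices (TSV, ``NA`` for missing
cells), network exports (edge-list TSV and GraphML) and YAML config files.

All readers reject malformed input rather than silently repairing it, and
every writer/reader pair is a round-trip identity on valid data.  Gene
identifiers are case-sensitive opaque strings; any homolog mapping happens
upstream of this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneSetCollection",
    "ExpressionExperiment",
    "RankedList",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_expression_table",
    "read_matrix",
    "write_matrix",
    "export_network",
    "load_config",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named pathway → ordered unique gene identifiers.

    Invariants: set names unique (dict keys), no empty set, gene identifiers
    non-empty strings, duplicates within a set collapsed (first occurrence
    wins).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not name:
                raise ValueError("empty gene-set name")
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains an empty gene id")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ExpressionExperiment:
    """One perturbation condition: a gene × sample matrix plus the design.

    ``values`` holds normalized log-ratio expression (unitless); ``design``
    maps every sample to ``"treated"`` or ``"control"``.  At least two
    replicates per group are required so a two-sample t-test is defined.
    """

    condition_id: str
    values: pd.DataFrame  # genes × samples
    design: dict[str, str]  # sample -> "treated" | "control"

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        missing = [s for s in samples if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        bad = {g for g in self.design.values() if g not in ("treated", "control")}
        if bad:
            raise ValueError(f"unknown design group(s): {sorted(bad)}")
        for group in ("treated", "control"):
            n = sum(1 for s in samples if self.design[s] == group)
            if n < 2:
                raise ValueError(
                    f"condition {self.condition_id!r}: need >=2 {group} samples, got {n}"
                )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def group_values(self, group: str) -> np.ndarray:
        cols = [s for s in self.values.columns if self.design[s] == group]
        return self.values[cols].to_numpy(dtype=float)


@dataclass
class RankedList:
    """Genes ordered by a signed ranking metric for one condition.

    Strictly sorted by descending metric, ties broken by ascending gene id —
    a stated deterministic order, not whatever the source file happened to
    contain.
    """

    genes: np.ndarray  # str array, ranked order
    metrics: np.ndarray  # float array, same order
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metrics = np.asarray(self.metrics, dtype=float)
        if self.genes.shape != self.metrics.shape:
            raise ValueError("genes and metrics length mismatch")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValueError("duplicate gene in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, float]], condition_id: str = ""
    ) -> "RankedList":
        items = sorted(pairs, key=lambda gv: (-gv[1], gv[0]))
        genes = np.array([g for g, _ in items], dtype=object)
        metrics = np.array([v for _, v in items], dtype=float)
        return cls(genes=genes, metrics=metrics, condition_id=condition_id)

    def position_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


# ---------------------------------------------------------------------------
# GMT / RNK
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name <TAB> description <TAB> gene...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_rnk(path: str | Path, condition_id: str = "") -> RankedList:
    """Parse an RNK file (gene <TAB> metric), re-sorting to the canonical order."""
    pairs: list[tuple[str, float]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            gene, metric_str = fields
            try:
                metric = float(metric_str)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric metric {metric_str!r}"
                ) from exc
            if not np.isfinite(metric):
                raise FormatError(f"{path}: line {lineno}: non-finite metric")
            if gene in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            pairs.append((gene, metric))
    return RankedList.from_pairs(pairs, condition_id=condition_id)


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, metric in zip(ranked.genes, ranked.metrics):
            fh.write(f"{gene}\t{float(metric)!r}\n")


# ---------------------------------------------------------------------------
# expression tables and generic matrices
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, design: Mapping[str, str], condition_id: str = ""
) -> ExpressionExperiment:
    """Read a TSV expression table (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression table")
    return ExpressionExperiment(
        condition_id=condition_id or Path(path).stem,
        values=df,
        design=dict(design),
    )


def write_matrix(table: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled real matrix as TSV with ``NA`` for missing cells.

    Values are written with 17 significant digits so ``read_matrix`` recovers
    every float64 bitwise.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("refusing to write an empty matrix")
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty matrix file")
    ncols = [len(line.split("\t")) for line in text.splitlines() if line]
    if len(set(ncols)) != 1:
        raise FormatError(f"{path}: ragged rows (field counts {sorted(set(ncols))})")
    df = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    return df.astype(float)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "pcc", "sign", "p"]


def export_network(network, path: str | Path, format: str = "edge-list") -> None:
    """Serialize a :class:`~pathwayhubs.network.PathwayNetwork`.

    ``edge-list``: TSV with columns source, target, pcc, sign (+/-), p.
    ``graphml``: full graph with node attributes (responsiveness count,
    class, degree, hub flag, group).
    """
    if format == "edge-list":
        rows = network.edges[["source", "target", "pcc", "sign", "p"]].copy()
        rows["sign"] = rows["sign"].map({1: "+", -1: "-"})
        rows.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(network.to_graph(), path)
    else:
        raise ValueError(f"unknown network export format {format!r}")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _EDGE_COLUMNS:
        raise FormatError(f"{path}: expected columns {_EDGE_COLUMNS}")
    df["sign"] = df["sign"].map({"+": 1, "-": -1})
    return df


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML config file as a flat dict (validated by the pipeline)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
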