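"""Pathway co-activity network: z-scored NES, Pearson edges, hubs, A/B split.

The NES matrix is z-scored per condition (column) so heterogeneous
perturbations become comparable, then every pathway pair is correlated
across conditions (Pearson, pairwise-complete over present cells).  Pairs
with |PCC| above ``r_min`` (default 0.5, strict) and correlation p below
``p_max`` are functionally connected; a pathway's degree is its number of
connections.  Hubs are pathways that are both highly responsive and highly
connected (both thresholds default 10).

The hub-induced signed subgraph is then two-colored: positive edges keep
the color, negative edges flip it.  If the graph is structurally balanced
the coloring yields the two inverted groups (labelled A and B); otherwise
the frustrated edges are reported and no labels are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import NESMatrix

__all__ = [
    "PathwayNetwork",
    "zscore_by_condition",
    "pearson_with_p",
    "build_network",
    "identify_hubs",
    "partition_signed",
]


def zscore_by_condition(matrix: NESMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardize each condition column over its present cells.

    Sample (n-1) standard deviation.  Columns with fewer than 2 present
    values or zero variance are set entirely missing (flagged by NaN).
    """
    df = matrix.nes if isinstance(matrix, NESMatrix) else matrix
    out = df.copy().astype(float)
    for col in out.columns:
        x = out[col]
        n = x.notna().sum()
        sd = x.std(ddof=1)
        if n < 2 or not np.isfinite(sd) or sd == 0:
            out[col] = np.nan
        else:
            out[col] = (x - x.mean()) / sd
    return out


def pearson_with_p(
    matrix: pd.DataFrame, min_overlap: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation between rows, with p-values.

    p is two-sided from t = r * sqrt((n-2) / (1-r^2)) with n the overlapping
    condition count of the pair.  Pairs with overlap below ``min_overlap``
    or a constant row over the overlap are missing.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    W = np.isfinite(X).astype(float)
    Xf = np.where(np.isfinite(X), X, 0.0)
    n = W @ W.T
    sx = Xf @ W.T  # sum of x_i over the (i, j) overlap
    sxx = (Xf**2) @ W.T
    sxy = Xf @ Xf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        vary = varx.T
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    bad = (n < max(min_overlap, 3)) | (varx <= 0) | (vary <= 0)
    r[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p[np.isinf(t)] = 0.0  # |r| == 1 over the overlap
    p[np.isnan(r)] = np.nan
    idx = matrix.index
    pcc = pd.DataFrame(r, index=idx, columns=idx)
    pcc_p = pd.DataFrame(p, index=idx, columns=idx)
    np.fill_diagonal(pcc.values, 1.0)
    np.fill_diagonal(pcc_p.values, 0.0)
    return pcc, pcc_p


@dataclass
class PathwayNetwork:
    """Signed pathway correlation network with node annotations."""

    pcc: pd.DataFrame
    pcc_p: pd.DataFrame
    edges: pd.DataFrame  # columns: source, target, pcc, sign, p
    degree: pd.Series
    hub_flags: pd.Series = None
    group: dict[str, str] = field(default_factory=dict)
    node_attrs: pd.DataFrame = None  # optional: n_significant, class

    @property
    def pathways(self) -> list[str]:
        return list(self.pcc.index)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.pathways:
            attrs = {"degree": int(self.degree.get(node, 0))}
            if self.hub_flags is not None:
                attrs["hub"] = bool(self.hub_flags.get(node, False))
            if self.group:
                attrs["group"] = self.group.get(node, "")
            if self.node_attrs is not None and node in self.node_attrs.index:
                row = self.node_attrs.loc[node]
                if "n_significant" in row:
                    attrs["n_significant"] = int(row["n_significant"])
                if "class" in row:
                    attrs["responsiveness_class"] = str(row["class"])
            g.add_node(node, **attrs)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source, row.target, pcc=float(row.pcc), sign=int(row.sign),
                p=float(row.p),
            )
        return g

    def subnetwork(self, nodes: list[str]) -> "PathwayNetwork":
        nodes = [p for p in self.pathways if p in set(nodes)]
        mask = self.edges["source"].isin(nodes) & self.edges["target"].isin(nodes)
        edges = self.edges[mask].reset_index(drop=True)
        degree = _degree_from_edges(edges, nodes)
        return PathwayNetwork(
            pcc=self.pcc.loc[nodes, nodes],
            pcc_p=self.pcc_p.loc[nodes, nodes],
            edges=edges,
            degree=degree,
            hub_flags=self.hub_flags[nodes] if self.hub_flags is not None else None,
            group={p: g for p, g in self.group.items() if p in set(nodes)},
            node_attrs=(
                self.node_attrs.loc[nodes] if self.node_attrs is not None else None
            ),
        )


def _degree_from_edges(edges: pd.DataFrame, pathways: list[str]) -> pd.Series:
    degree = pd.Series(0, index=pathways, name="degree")
    for col in ("source", "target"):
        counts = edges[col].value_counts()
        degree = degree.add(counts.reindex(pathways).fillna(0).astype(int), fill_value=0)
    return degree.astype(int)


def build_network(
    pcc: pd.DataFrame,
    pcc_p: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 1e-4,
) -> PathwayNetwork:
    """Edges where |PCC| > r_min (strict) and p < p_max; degrees per node."""
    if pcc.shape != pcc_p.shape or not pcc.index.equals(pcc_p.index):
        raise ValueError("pcc and pcc_p must share shape and labels")
    pathways = list(pcc.index)
    rows = []
    r = pcc.to_numpy()
    p = pcc_p.to_numpy()
    iu, ju = np.triu_indices(len(pathways), k=1)
    keep = (np.abs(r[iu, ju]) > r_min) & (p[iu, ju] < p_max)
    keep &= np.isfinite(r[iu, ju])
    for i, j in zip(iu[keep], ju[keep]):
        rows.append(
            {
                "source": pathways[i],
                "target": pathways[j],
                "pcc": r[i, j],
                "sign": 1 if r[i, j] > 0 else -1,
                "p": p[i, j],
            }
        )
    edges = pd.DataFrame(rows, columns=["source", "target", "pcc", "sign", "p"])
    degree = _degree_from_edges(edges, pathways)
    return PathwayNetwork(pcc=pcc, pcc_p=pcc_p, edges=edges, degree=degree)


def identify_hubs(
    n_significant: pd.Series,
    degree: pd.Series,
    theta_resp: int = 10,
    theta_deg: int = 10,
) -> pd.Series:
    """Hub iff responsiveness count >= theta_resp and degree >= theta_deg."""
    pathways = n_significant.index
    deg = degree.reindex(pathways).fillna(0)
    return ((n_significant >= theta_resp) & (deg >= theta_deg)).rename("hub")


def partition_signed(
    network: PathwayNetwork, anchor: str | None = None
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Two-color a signed graph into the inverted groups A and B.

    Traversal keeps the color across positive edges and flips it across
    negative edges.  If every edge is consistent (the graph is structurally
    balanced) the labels are returned with A the side containing ``anchor``
    (per component; otherwise the larger side, ties to the side with the
    lexicographically smallest member).  If not, the list of frustrated
    edges is returned and the label map is empty.
    """
    nodes = network.pathways
    if not nodes:
        raise ValueError("empty node set")
    adj: dict[str, list[tuple[str, int]]] = {v: [] for v in nodes}
    for row in network.edges.itertuples(index=False):
        adj[row.source].append((row.target, int(row.sign)))
        adj[row.target].append((row.source, int(row.sign)))
    color: dict[str, int] = {}
    frustrated: list[tuple[str, str]] = []
    for start in nodes:
        if start in color:
            continue
        color[start] = 0
        queue = [start]
        while queue:
            v = queue.pop()
            for u, sign in adj[v]:
                expected = color[v] if sign > 0 else 1 - color[v]
                if u not in color:
                    color[u] = expected
                    queue.append(u)
                elif color[u] != expected:
                    edge = tuple(sorted((v, u)))
                    if edge not in frustrated:
                        frustrated.append(edge)
    if frustrated:
        return {}, frustrated
    # orient each component: anchor's side (or the larger side) is "A"
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(nodes)
    comp_graph.add_edges_from(
        (r.source, r.target) for r in network.edges.itertuples(index=False)
    )
    labels: dict[str, str] = {}
    for comp in nx.connected_components(comp_graph):
        comp = sorted(comp)
        side0 = [v for v in comp if color[v] == 0]
        side1 = [v for v in comp if color[v] == 1]
        if anchor is not None and anchor in set(comp):
            a_side = side0 if anchor in side0 else side1
        elif len(side0) != len(side1):
            a_side = side0 if len(side0) > len(side1) else side1
        else:  # equal sizes: the side with the lexicographically first member
            a_side = side0 if not side1 or (side0 and side0[0] < side1[0]) else side1
        a_set = set(a_side)
        for v in comp:
            labels[v] = "A" if v in a_set else "B"
    return labels, []
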