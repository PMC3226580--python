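import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathwayhubs.network import (
    PathwayNetwork,
    build_network,
    identify_hubs,
    partition_signed,
    pearson_with_p,
    zscore_by_condition,
)


class TestZScore:
    def test_column_standardization_sample_sd(self):
        df = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = zscore_by_condition(df)
        np.testing.assert_allclose(z["c1"], [-1.0, 0.0, 1.0])  # sd(n-1) = 1

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"c1": rng.normal(size=30)})
        z1 = zscore_by_condition(df)
        z2 = zscore_by_condition(z1)
        pd.testing.assert_frame_equal(z1, z2)

    def test_columns_have_mean0_sd1(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(25, 6)) * 3 + 2)
        df.iloc[rng.random((25, 6)) < 0.15] = np.nan
        z = zscore_by_condition(df)
        for col in z.columns:
            x = z[col].dropna()
            assert x.mean() == pytest.approx(0.0, abs=1e-12)
            assert x.std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_column_flagged_missing(self):
        df = pd.DataFrame({"c1": [2.0, 2.0, 2.0], "c2": [1.0, 2.0, 3.0]})
        z = zscore_by_condition(df)
        assert z["c1"].isna().all()
        assert z["c2"].notna().all()

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame({"c1": [1.0, np.nan, 3.0, 4.0]})
        z = zscore_by_condition(df)
        assert z["c1"].isna().tolist() == [False, True, False, False]


class TestPearsonWithP:
    def test_identical_and_negated_rows(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        df = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        pcc, pcc_p = pearson_with_p(df, min_overlap=5)
        assert pcc.loc["a", "b"] == pytest.approx(1.0)
        assert pcc.loc["a", "c"] == pytest.approx(-1.0)
        assert pcc_p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]], index=["x", "y"]
        )
        pcc, _ = pearson_with_p(df, min_overlap=3)
        assert pcc.loc["x", "y"] == pytest.approx(3 / np.sqrt(28 / 3))  # ~0.9820

    def test_matches_scipy_pairwise_complete(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(6, 20)))
        df.iloc[rng.random((6, 20)) < 0.2] = np.nan
        pcc, pcc_p = pearson_with_p(df, min_overlap=5)
        for i, j in itertools.combinations(range(6), 2):
            both = df.iloc[i].notna() & df.iloc[j].notna()
            if both.sum() < 5:
                assert np.isnan(pcc.iloc[i, j])
                continue
            r_ref, p_ref = stats.pearsonr(df.iloc[i][both], df.iloc[j][both])
            assert pcc.iloc[i, j] == pytest.approx(r_ref)
            assert pcc_p.iloc[i, j] == pytest.approx(p_ref, rel=1e-6)

    def test_low_overlap_pair_missing(self):
        df = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0]],
            index=["a", "b", "c"],
        )
        pcc, _ = pearson_with_p(df, min_overlap=3)
        assert np.isnan(pcc.loc["a", "b"])

    def test_invariant_under_positive_row_affine_rescale(self):
        # row-wise affine maps with positive slope cannot change the network
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(8, 15)))
        scaled = df.mul(rng.uniform(0.5, 4.0, size=8), axis=0).add(
            rng.normal(size=8), axis=0
        )
        pcc1, _ = pearson_with_p(df, min_overlap=5)
        pcc2, _ = pearson_with_p(scaled, min_overlap=5)
        np.testing.assert_allclose(pcc1, pcc2, atol=1e-10)


class TestBuildNetwork:
    def _matrices(self, r_ab, p_ab=1e-6):
        idx = ["a", "b"]
        pcc = pd.DataFrame([[1.0, r_ab], [r_ab, 1.0]], index=idx, columns=idx)
        p = pd.DataFrame([[0.0, p_ab], [p_ab, 0.0]], index=idx, columns=idx)
        return pcc, p

    def test_threshold_is_strict(self):
        net = build_network(*self._matrices(0.5), r_min=0.5, p_max=1e-4)
        assert len(net.edges) == 0

    def test_strong_positive_edge(self):
        net = build_network(*self._matrices(0.9), r_min=0.5, p_max=1e-4)
        assert len(net.edges) == 1
        assert net.edges.loc[0, "sign"] == 1

    def test_insignificant_p_blocks_edge(self):
        net = build_network(*self._matrices(0.9, p_ab=0.01), r_min=0.5, p_max=1e-4)
        assert len(net.edges) == 0

    def test_path_degrees(self):
        idx = ["a", "b", "c"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.8
        r[1, 2] = r[2, 1] = -0.7
        p = np.where(np.eye(3, dtype=bool), 0.0, 1e-9)
        net = build_network(
            pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
        )
        assert net.degree.tolist() == [1, 2, 1]


class TestIdentifyHubs:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(10, 10, True), (9, 50, False), (43, 0, False), (10, 9, False), (11, 11, True)],
    )
    def test_joint_thresholds(self, n, k, expected):
        flags = identify_hubs(
            pd.Series({"p": n}), pd.Series({"p": k}), theta_resp=10, theta_deg=10
        )
        assert bool(flags["p"]) is expected


def _signed_network(nodes, signed_edges):
    idx = list(nodes)
    pcc = pd.DataFrame(np.eye(len(idx)), index=idx, columns=idx)
    pcc_p = pd.DataFrame(np.zeros((len(idx), len(idx))), index=idx, columns=idx)
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "pcc": 0.9 * s, "sign": s, "p": 1e-9}
            for u, v, s in signed_edges
        ],
        columns=["source", "target", "pcc", "sign", "p"],
    )
    degree = pd.Series(0, index=idx)
    for u, v, _ in signed_edges:
        degree[u] += 1
        degree[v] += 1
    return PathwayNetwork(pcc=pcc, pcc_p=pcc_p, edges=edges, degree=degree)


class TestPartitionSigned:
    def test_one_negative_pair_triangle_bipartition(self):
        # (+, -, -) triangle is balanced: exhaustive check over all 2^3 colorings
        net = _signed_network("xyz", [("x", "y", -1), ("y", "z", 1), ("x", "z", -1)])
        labels, frustrated = partition_signed(net)
        assert frustrated == []
        valid = []
        for colors in itertools.product("AB", repeat=3):
            cmap = dict(zip("xyz", colors))
            ok = all(
                (cmap[u] == cmap[v]) == (s > 0)
                for u, v, s in [("x", "y", -1), ("y", "z", 1), ("x", "z", -1)]
            )
            if ok:
                valid.append(cmap)
        assert labels in valid
        assert labels["y"] == labels["z"] != labels["x"]

    def test_all_negative_triangle_frustrated(self):
        net = _signed_network("xyz", [("x", "y", -1), ("y", "z", -1), ("x", "z", -1)])
        labels, frustrated = partition_signed(net)
        assert labels == {}
        # exhaustively: every 2-coloring leaves >= 1 inconsistent edge
        min_bad = min(
            sum(
                (cmap[u] == cmap[v]) != (s > 0)
                for u, v, s in [("x", "y", -1), ("y", "z", -1), ("x", "z", -1)]
            )
            for cmap in (
                dict(zip("xyz", colors))
                for colors in itertools.product("AB", repeat=3)
            )
        )
        assert min_bad == 1 and len(frustrated) >= 1

    def test_all_positive_component_single_group(self):
        net = _signed_network("xyz", [("x", "y", 1), ("y", "z", 1)])
        labels, frustrated = partition_signed(net)
        assert frustrated == []
        assert set(labels.values()) == {"A"}

    def test_anchor_names_group_a(self):
        net = _signed_network("xyz", [("x", "y", -1), ("y", "z", 1)])
        labels, _ = partition_signed(net, anchor="y")
        assert labels["y"] == labels["z"] == "A" and labels["x"] == "B"
        labels2, _ = partition_signed(net, anchor="x")
        assert labels2["x"] == "A" and labels2["y"] == labels2["z"] == "B"

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            partition_signed(_signed_network([], []))

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_balanced_partition(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        nodes = [f"n{i:02d}" for i in range(n)]
        truth = {v: rng.integers(0, 2) for v in nodes}
        edges = []
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.4:
                s = 1 if truth[nodes[i]] == truth[nodes[j]] else -1
                edges.append((nodes[i], nodes[j], s))
        labels, frustrated = partition_signed(_signed_network(nodes, edges))
        assert frustrated == []
        # agreement up to global swap, per connected component
        for u, v, s in edges:
            assert (labels[u] == labels[v]) == (truth[u] == truth[v])


def test_fig2_contract_no_crossing_positive_or_within_negative_edges():
    # whenever a bipartition exists it satisfies the inverted-groups contract
    rng = np.random.default_rng(9)
    nodes = [f"h{i}" for i in range(10)]
    truth = {v: ("A" if i < 5 else "B") for i, v in enumerate(nodes)}
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < 0.5:
            edges.append((u, v, 1 if truth[u] == truth[v] else -1))
    labels, frustrated = partition_signed(_signed_network(nodes, edges))
    assert frustrated == []
    for u, v, s in edges:
        if s > 0:
            assert labels[u] == labels[v]
        else:
            assert labels[u] != labels[v]
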