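import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_es
from pathwayhubs.enrichment import (
    EnrichmentResult,
    build_nes_matrix,
    enrich_collection,
    enrichment_score,
    nominal_p,
    normalized_es,
    permutation_null,
)
from pathwayhubs.io_formats import GeneSetCollection, RankedList


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "gene_set,expected",
        [({"g1", "g3"}, 0.5), ({"g3", "g4"}, -1.0), ({"g1"}, 1.0)],
    )
    def test_hand_walks_weight0(self, tiny_ranked, gene_set, expected):
        es, running = enrichment_score(tiny_ranked, gene_set, weight=0)
        assert es == pytest.approx(expected)
        assert len(running) == len(tiny_ranked)
        assert running[-1] == pytest.approx(0.0)

    def test_running_sum_extreme_equals_es(self, ranked8):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(1, 7)
            genes = list(rng.choice(ranked8.genes, size=k, replace=False))
            for w in (0, 1):
                es, running = enrichment_score(ranked8, genes, weight=w)
                assert abs(es) == pytest.approx(np.abs(running).max())

    def test_unmapped_set_rejected(self, tiny_ranked):
        with pytest.raises(ValueError, match="not represented"):
            enrichment_score(tiny_ranked, {"zz"}, weight=0)

    def test_full_coverage_rejected(self, tiny_ranked):
        with pytest.raises(ValueError, match="whole ranked list"):
            enrichment_score(tiny_ranked, {"g1", "g2", "g3", "g4"}, weight=0)

    def test_reversal_negates_es_weight0(self, ranked8):
        reversed_list = RankedList.from_pairs(
            (g, -m) for g, m in zip(ranked8.genes, ranked8.metrics)
        )
        rng = np.random.default_rng(6)
        for _ in range(10):
            genes = list(rng.choice(ranked8.genes, size=3, replace=False))
            es_f, run_f = enrichment_score(ranked8, genes, weight=0)
            es_r, _ = enrichment_score(reversed_list, genes, weight=0)
            if np.isclose(run_f.max(), -run_f.min()):
                # |max| == |min| ties resolve positive in both directions
                assert abs(es_r) == pytest.approx(abs(es_f))
            else:
                assert es_r == pytest.approx(-es_f)


class TestPermutationNull:
    def test_exhaustive_matches_enumeration(self, tiny_ranked):
        null = permutation_null(tiny_ranked, 2, weight=0, exhaustive=True)
        expected = sorted(
            brute_force_es(tiny_ranked.metrics, sub, 0)
            for sub in itertools.combinations(range(4), 2)
        )
        np.testing.assert_allclose(sorted(null), expected)

    def test_same_seed_reproducible(self, ranked8):
        a = permutation_null(ranked8, 3, n_perm=50, weight=1, seed=9)
        b = permutation_null(ranked8, 3, n_perm=50, weight=1, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_es_bounded_by_one(self, ranked8):
        null = permutation_null(ranked8, 4, n_perm=200, weight=1, seed=2)
        assert np.all(np.abs(null) <= 1.0 + 1e-12)

    def test_set_size_out_of_range(self, tiny_ranked):
        with pytest.raises(ValueError):
            permutation_null(tiny_ranked, 4, n_perm=10)


class TestNominalP:
    def test_floor_with_999_same_sign_perms(self):
        null = np.linspace(0.01, 0.5, 999)
        assert nominal_p(0.9, null) == pytest.approx(1 / 1000)

    def test_direct_count(self):
        assert nominal_p(0.5, [0.6, 0.4, -0.5]) == pytest.approx(2 / 3)

    def test_no_same_sign_null_flagged_missing(self):
        assert np.isnan(nominal_p(-0.5, [0.1, 0.2, 0.3]))

    def test_super_uniform_under_null(self, ranked8):
        # p-values of null scores against their own distribution: P(p <= u) <= u
        null = permutation_null(ranked8, 3, n_perm=300, weight=0, seed=4)
        pvals = np.array([nominal_p(es, np.delete(null, i)) for i, es in enumerate(null)])
        for u in (0.05, 0.1, 0.25):
            assert (pvals <= u).mean() <= u + 0.05


class TestNormalizedES:
    def test_mean_abs_scaling(self):
        assert normalized_es(0.5, [0.25, 0.25, -0.9]) == pytest.approx(2.0)
        assert normalized_es(-0.4, [-0.4, -0.4, 0.2]) == pytest.approx(-1.0)

    def test_self_normalization_limit(self):
        assert normalized_es(0.3, [0.3] * 10) == pytest.approx(1.0)

    def test_empty_same_sign_missing(self):
        assert np.isnan(normalized_es(-0.5, [0.1, 0.2]))


@pytest.fixture(scope="module")
def ranked100():
    rng = np.random.default_rng(12)
    return RankedList.from_pairs(
        (f"G{i:03d}", float(m)) for i, m in enumerate(rng.normal(size=100))
    )


class TestEnrichCollection:
    def test_small_sets_skipped(self, ranked100):
        coll = GeneSetCollection(
            sets={
                "small": [f"G{i:03d}" for i in range(5)],
                "big": [f"G{i:03d}" for i in range(0, 40, 2)],
            }
        )
        results, skipped = enrich_collection(
            ranked100, coll, min_size=10, n_perm=50, seed=1
        )
        assert skipped == ["small"]
        assert [r.pathway for r in results] == ["big"]
        assert results[0].n_mapped == 20

    def test_set_order_independence(self, ranked100):
        rng = np.random.default_rng(8)
        sets = {
            f"S{j}": [f"G{i:03d}" for i in rng.choice(100, size=15, replace=False)]
            for j in range(6)
        }
        coll1 = GeneSetCollection(sets=dict(sets))
        coll2 = GeneSetCollection(sets=dict(reversed(list(sets.items()))))
        r1, _ = enrich_collection(ranked100, coll1, min_size=10, n_perm=100, seed=3)
        r2, _ = enrich_collection(ranked100, coll2, min_size=10, n_perm=100, seed=3)
        assert [(r.pathway, r.es, r.nes, r.nominal_p) for r in r1] == [
            (r.pathway, r.es, r.nes, r.nominal_p) for r in r2
        ]

    def test_weight1_es_matches_gseapy(self, ranked100):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        sets = {
            f"S{j}": [f"G{i:03d}" for i in rng.choice(100, size=15, replace=False)]
            for j in range(4)
        }
        rnk = pd.DataFrame(
            {"gene": list(ranked100.genes), "metric": list(ranked100.metrics)}
        )
        ref = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=4, min_size=3, max_size=50,
            seed=1, threads=1, no_plot=True, outdir=None,
        ).res2d.set_index("Term")["ES"].astype(float)
        for name, genes in sets.items():
            es, _ = enrichment_score(ranked100, genes, weight=1)
            assert es == pytest.approx(float(ref[name]), abs=1e-9)


class TestBuildNESMatrix:
    def _result(self, pathway, nes=1.5, p=0.01):
        return EnrichmentResult(pathway=pathway, es=0.5, nes=nes, nominal_p=p, n_mapped=12)

    def test_disjoint_pathways_give_missing_blocks(self):
        m = build_nes_matrix(
            {"c1": [self._result("pA")], "c2": [self._result("pB")]}
        )
        assert np.isnan(m.nes.loc["pA", "c2"]) and np.isnan(m.nes.loc["pB", "c1"])
        assert m.nes.loc["pA", "c1"] == 1.5

    def test_significance_mask_is_p_below_alpha(self):
        m = build_nes_matrix(
            {
                "c1": [self._result("pA", p=0.04), self._result("pB", p=0.05)],
            },
            alpha=0.05,
        )
        sig = m.significant()
        assert bool(sig.loc["pA", "c1"]) and not bool(sig.loc["pB", "c1"])

    def test_duplicate_condition_rejected(self):
        with pytest.raises(ValueError):
            build_nes_matrix(
                {"c1": [self._result("pA"), self._result("pA")]}
            )

    def test_round_trip_through_matrix_files(self, tmp_path):
        from pathwayhubs.io_formats import read_matrix, write_matrix

        m = build_nes_matrix(
            {"c1": [self._result("pA")], "c2": [self._result("pB", nes=-0.7)]}
        )
        write_matrix(m.nes, tmp_path / "nes.tsv")
        back = read_matrix(tmp_path / "nes.tsv")
        pd.testing.assert_frame_equal(back, m.nes)
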