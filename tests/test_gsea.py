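import itertools

import numpy as np
import pandas as pd
import pytest

import strata_tx as st
from strata_tx.errors import ValidationError
from strata_tx.gsea import RankedList, significant_pathways

from conftest import brute_force_es


def make_ranked(values, genes=None):
    n = len(values)
    if genes is None:
        genes = [f"g{i:02d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-values[i], genes[i]))
    return RankedList(
        tuple(genes[i] for i in order), np.asarray([values[i] for i in order], float)
    )


class TestRankStatistic:
    @pytest.mark.parametrize(
        "p, l2fc, expected",
        [(0.01, 2.0, 4.0), (1.0, 5.0, 0.0), (0.1, -1.0, -1.0)],
    )
    def test_values(self, p, l2fc, expected):
        assert st.compute_rank_statistic(p, l2fc) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            st.compute_rank_statistic(0.0, 1.0)


class TestBuildRankedList:
    def test_descending_order(self):
        de = pd.DataFrame(
            {"pvalue": [0.001, 0.1], "log2FC": [1.0, -1.0]}, index=["a", "b"]
        )
        ranked = st.build_ranked_list(de)
        assert ranked.genes == ("a", "b")
        assert ranked.values[0] == pytest.approx(3.0)

    def test_tie_broken_lexicographically(self):
        de = pd.DataFrame(
            {"pvalue": [0.1, 0.1], "log2FC": [1.0, 1.0]}, index=["zed", "abc"]
        )
        assert st.build_ranked_list(de).genes == ("abc", "zed")

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        de = pd.DataFrame(
            {"pvalue": rng.uniform(0.001, 1, 50), "log2FC": rng.normal(size=50)},
            index=[f"g{i}" for i in range(50)],
        )
        ranked = st.build_ranked_list(de)
        shuffled = st.build_ranked_list(de.sample(frac=1, random_state=1))
        assert ranked.genes == shuffled.genes
        assert np.array_equal(ranked.values, shuffled.values)

    def test_flagged_rows_excluded(self):
        de = pd.DataFrame(
            {"pvalue": [0.1, np.nan], "log2FC": [1.0, 2.0]}, index=["a", "b"]
        )
        assert st.build_ranked_list(de).genes == ("a",)


class TestEnrichmentScore:
    def test_top_block_set_peaks_at_k(self):
        values = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1]
        ranked = make_ranked(values)
        es, peak = st.enrichment_score(ranked, ranked.genes[:3])
        assert es > 0
        assert peak == 2

    def test_hand_enumerated_toy_example(self):
        """5-gene universe, set {1st, 3rd} with ranks (3, 2, 1, -1, -2):
        hit weights 3/4 and 1/4, miss decrement 1/3, so the running sum is
        (3/4, 5/12, 2/3, 1/3, 0) and ES = 3/4 at position 0."""
        ranked = make_ranked([3.0, 2.0, 1.0, -1.0, -2.0], list("abcde"))
        es, peak = st.enrichment_score(ranked, ["a", "c"])
        assert es == pytest.approx(0.75)
        assert peak == 0

    def test_antisymmetry_under_list_reversal(self):
        rng = np.random.default_rng(1)
        values = np.sort(rng.normal(size=20))[::-1]
        genes = [f"g{i:02d}" for i in range(20)]
        ranked = RankedList(tuple(genes), values)
        gene_set = genes[2:7]
        es, _ = st.enrichment_score(ranked, gene_set)
        flipped = RankedList(tuple(reversed(genes)), -values[::-1])
        es_flipped, _ = st.enrichment_score(flipped, gene_set)
        assert es_flipped == pytest.approx(-es)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            n = int(rng.integers(4, 30))
            values = rng.normal(size=n)
            ranked = make_ranked(list(values))
            k = int(rng.integers(1, n))
            gene_set = list(rng.choice(ranked.genes, size=k, replace=False))
            es, _ = st.enrichment_score(ranked, gene_set)
            assert abs(es) <= 1.0 + 1e-12

    def test_empty_intersection_rejected(self):
        ranked = make_ranked([1.0, 0.5])
        with pytest.raises(ValidationError, match="empty intersection"):
            st.enrichment_score(ranked, ["absent"])

    def test_matches_exhaustive_oracle_small_universes(self):
        """Implementation equals the brute-force running-sum oracle for every
        subset of universes up to size 8."""
        rng = np.random.default_rng(3)
        for n in range(2, 9):
            values = np.sort(rng.normal(size=n) * 2)[::-1]
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedList(tuple(genes), values)
            for k in range(1, n):
                for subset in itertools.combinations(range(n), k):
                    mask = np.zeros(n, dtype=bool)
                    mask[list(subset)] = True
                    _, high, low = brute_force_es(values, mask, return_extrema=True)
                    es, _ = st.enrichment_score(ranked, [genes[i] for i in subset])
                    # magnitude must match the larger extremum; when the two
                    # extrema tie to float rounding, either sign is the ES
                    assert abs(es) == pytest.approx(max(high, -low), abs=1e-9)
                    assert min(abs(es - high), abs(es - low)) < 1e-9

    def test_matches_external_reference_implementation(self):
        """Cross-check against gseapy's pre-ranked ES on a 50-gene list."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(4)
        genes = [f"G{i:03d}" for i in range(50)]
        values = np.sort(rng.normal(size=50))[::-1]
        ranked = RankedList(tuple(genes), values)
        gene_sets = {"S1": genes[5:20], "S2": [genes[i] for i in range(0, 50, 7)]}
        rnk = pd.DataFrame({"score": values}, index=genes)
        reference = gseapy.prerank(
            rnk=rnk, gene_sets=gene_sets, permutation_num=10, min_size=2,
            max_size=50, weight=1.0, seed=1, outdir=None, no_plot=True,
        ).res2d.set_index("Term")
        for name, members in gene_sets.items():
            es, _ = st.enrichment_score(ranked, members)
            assert es == pytest.approx(float(reference.loc[name, "ES"]), abs=1e-9)


class TestGseaPreranked:
    def test_same_seed_identical_tables(self):
        rng = np.random.default_rng(5)
        ranked = make_ranked(list(rng.normal(size=200)))
        coll = st.simulate_gene_sets(list(ranked.genes), 20, (15, 50), seed=6)
        a = st.gsea_preranked(ranked, coll, n_perm=200, seed=7)
        b = st.gsea_preranked(ranked, coll, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_collection_order_invariance(self):
        rng = np.random.default_rng(8)
        ranked = make_ranked(list(rng.normal(size=200)))
        coll = st.simulate_gene_sets(list(ranked.genes), 10, (15, 50), seed=9)
        reversed_coll = st.GeneSetCollection(tuple(reversed(coll.sets)))
        a = st.gsea_preranked(ranked, coll, n_perm=150, seed=10)
        b = st.gsea_preranked(ranked, reversed_coll, n_perm=150, seed=10)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_size_filter_skips_and_warns(self, caplog):
        rng = np.random.default_rng(11)
        ranked = make_ranked(list(rng.normal(size=100)))
        coll = st.GeneSetCollection(
            (st.GeneSet("TINY", "", tuple(ranked.genes[:3])),)
        )
        result = st.gsea_preranked(ranked, coll, n_perm=100, seed=12)
        assert len(result) == 0

    def test_direction_matches_es_sign(self):
        rng = np.random.default_rng(13)
        ranked = make_ranked(list(rng.normal(size=300)))
        coll = st.simulate_gene_sets(list(ranked.genes), 30, (15, 60), seed=14)
        res = st.gsea_preranked(ranked, coll, n_perm=150, seed=15)
        up = res["direction"] == "up"
        assert (res.loc[up, "ES"] >= 0).all()
        assert (res.loc[~up, "ES"] < 0).all()

    def test_mc_stability_when_doubling_permutations(self):
        rng = np.random.default_rng(16)
        ranked = make_ranked(list(rng.normal(size=300)))
        coll = st.simulate_gene_sets(list(ranked.genes), 15, (20, 60), seed=17)
        res_a = st.gsea_preranked(ranked, coll, n_perm=500, seed=18)
        res_b = st.gsea_preranked(ranked, coll, n_perm=1000, seed=19)
        p_a, p_b = res_a["pval"], res_b["pval"].reindex(res_a.index)
        se = np.sqrt(p_a * (1 - p_a) / 250)  # same-sign nulls ~ n_perm/2
        assert (np.abs(p_a - p_b) < np.maximum(4 * se, 0.02)).all()


class TestCompareStrata:
    def _result(self, sig_up=(), sig_down=(), tested=()):
        names = list(dict.fromkeys(list(sig_up) + list(sig_down) + list(tested)))
        rows = []
        for name in names:
            if name in sig_up:
                rows.append((name, 0.01, "up"))
            elif name in sig_down:
                rows.append((name, 0.01, "down"))
            else:
                rows.append((name, 0.9, "up"))
        df = pd.DataFrame(rows, columns=["pathway", "qval", "direction"]).set_index(
            "pathway"
        )
        df["ES"] = np.where(df["direction"] == "up", 0.5, -0.5)
        df["NES"] = df["ES"] * 2
        df["pval"] = df["qval"] / 2
        df["size"] = 20
        return df

    def test_basic_partition(self):
        a = self._result(sig_up=["P1", "P2"], tested=["P3"])
        b = self._result(sig_up=["P2"], tested=["P1", "P3"])
        cmp = st.compare_strata(a, b, label_a="A", label_b="B")
        assert cmp.unique_a["up"] == ("P1",)
        assert cmp.shared["up"] == ("P2",)
        assert cmp.unique_b["up"] == ()

    def test_identical_results_have_no_unique_sets(self):
        a = self._result(sig_up=["P1"], sig_down=["P2"], tested=["P3"])
        cmp = st.compare_strata(a, a.copy())
        assert cmp.unique_a["up"] == () and cmp.unique_b["down"] == ()
        assert cmp.shared["up"] == ("P1",)

    def test_differing_collections_rejected(self):
        a = self._result(sig_up=["P1"])
        b = self._result(sig_up=["P2"])
        with pytest.raises(ValidationError, match="same collection"):
            st.compare_strata(a, b)

    def test_unique_plus_shared_equals_total(self):
        rng = np.random.default_rng(20)
        universe = [f"P{i}" for i in range(60)]
        a_up = list(rng.choice(universe, 20, replace=False))
        b_up = list(rng.choice(universe, 15, replace=False))
        a = self._result(sig_up=a_up, tested=universe)
        b = self._result(sig_up=b_up, tested=universe)
        cmp = st.compare_strata(a, b, label_a="A", label_b="B")
        counts = cmp.counts()
        assert counts.loc["up", "shared"] + counts.loc["up", "unique_A"] == len(
            significant_pathways(a, "up")
        )
        assert counts.loc["up", "shared"] + counts.loc["up", "unique_B"] == len(
            significant_pathways(b, "up")
        )
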