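import numpy as np
import pandas as pd
import pytest
from _oracles import binomial_minlike_p, fisher_minlike_p
from scipy.stats import binomtest, fisher_exact

from trlmap.enrichment import (
    bonferroni,
    category_frequencies,
    exact_binomial_test,
    fisher_exact_2x2,
    pseudobulk_aggregate,
    reactive_cluster_enrichment,
)
from trlmap.errors import InputError
from trlmap.io_formats import CountMatrix


class TestExactBinomial:
    def test_mode_gives_p_one(self):
        assert exact_binomial_test(5, 10, 0.5) == 1.0

    def test_nine_of_ten_fair_coin(self):
        assert exact_binomial_test(9, 10, 0.5) == pytest.approx(22 / 1024, abs=1e-12)

    def test_degenerate_null(self):
        assert exact_binomial_test(0, 5, 0.0) == 1.0
        assert exact_binomial_test(3, 5, 0.0) == 0.0
        assert exact_binomial_test(5, 5, 1.0) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            exact_binomial_test(11, 10, 0.5)
        with pytest.raises(InputError):
            exact_binomial_test(1, 10, 1.5)

    def test_matches_exact_enumeration_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 61))
            x = int(rng.integers(0, n + 1))
            num = int(rng.integers(1, 100))
            p = exact_binomial_test(x, n, num / 100)
            assert p == pytest.approx(float(binomial_minlike_p(x, n, num, 100)), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        # independent cross-check against scipy's binom.test equivalent
        for _ in range(100):
            n = int(rng.integers(1, 200))
            x = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            assert exact_binomial_test(x, n, p0) == pytest.approx(
                binomtest(x, n, p0).pvalue, abs=1e-11
            )


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == (1.0, 1.0)

    def test_perfectly_discordant_table(self):
        odds_ratio, p = fisher_exact_2x2([[0, 5], [5, 0]])
        assert odds_ratio == 0.0
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_odds_ratio_conventions(self):
        assert fisher_exact_2x2([[4, 1], [1, 4]])[0] == pytest.approx(16.0)
        assert fisher_exact_2x2([[4, 0], [1, 4]])[0] == np.inf
        assert np.isnan(fisher_exact_2x2([[0, 0], [1, 4]])[0])

    def test_negative_entry_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[1, -1], [1, 1]])

    def test_matches_exact_enumeration_oracle(self, rng):
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(float(fisher_minlike_p(a, b, c, d)), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            t = rng.integers(0, 40, size=(2, 2))
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_exact(t)[1], abs=1e-11)


class TestBonferroni:
    def test_multiplies_by_family_size_and_caps(self):
        assert bonferroni([0.01] * 12)[0] == pytest.approx(0.12)
        assert bonferroni([0.2] * 10)[0] == 1.0

    def test_monotone_transform(self, rng):
        # order is preserved weakly (the cap at 1 creates ties)
        p = rng.uniform(size=50)
        adj = bonferroni(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= 0).all()


class TestCategoryFrequencies:
    def test_quoted_formula(self):
        cells = pd.DataFrame(
            {"cluster": ["A"] * 4 + ["B"] * 6, "category": ["reactive"] * 10}
        )
        freq = category_frequencies(cells)["reactive"].set_index("cluster")
        assert freq.loc["A", "frequency"] == pytest.approx(0.4)

    def test_single_cluster_gives_one(self):
        cells = pd.DataFrame({"cluster": ["A"] * 3, "category": ["TIL"] * 3})
        assert category_frequencies(cells)["TIL"]["frequency"].iloc[0] == 1.0

    def test_frequencies_sum_to_one(self, rng):
        cells = pd.DataFrame(
            {
                "cluster": rng.integers(0, 7, 500).astype(str),
                "category": rng.choice(["TIL", "reactive"], 500),
            }
        )
        for df in category_frequencies(cells).values():
            assert df["frequency"].sum() == pytest.approx(1.0, abs=1e-12)
            assert df["n_cells"].sum() == df["total_cells"].iloc[0]


def _enrichment_cells(rng, n_til, n_reactive, p_til, p_reactive, clusters):
    til = pd.DataFrame(
        {
            "cluster": rng.choice(clusters, size=n_til, p=p_til),
            "key": [f"T{i % 150}" for i in range(n_til)],
        }
    )
    reactive = pd.DataFrame(
        {
            "cluster": rng.choice(clusters, size=n_reactive, p=p_reactive),
            "key": [f"R{i % 40}" for i in range(n_reactive)],
        }
    )
    cells = pd.concat([til, reactive], ignore_index=True)
    cells["barcode"] = [f"B{i}-1" for i in range(len(cells))]
    til_keys = {f"T{i}" for i in range(150)}
    reactive_keys = {f"R{i}" for i in range(40)}
    return cells, reactive_keys, til_keys


class TestReactiveClusterEnrichment:
    def test_observation_at_background_rate_gives_p_one(self):
        cells = pd.DataFrame(
            {
                "barcode": [f"B{i}-1" for i in range(20)],
                "cluster": ["A"] * 4 + ["B"] * 6 + ["A"] * 4 + ["B"] * 6,
                "key": ["R1"] * 10 + ["T1"] * 10,
            }
        )
        results = reactive_cluster_enrichment(cells, {"R1"}, {"T1"})
        res_a = next(r for r in results if r.cluster == "A")
        assert res_a.x == 4 and res_a.n == 10 and res_a.p0 == pytest.approx(0.4)
        assert res_a.p_two_sided == 1.0 and res_a.direction == "none"

    def test_planted_enrichment_detected(self, rng):
        clusters = [f"C{i}" for i in range(12)]
        p_bg = np.full(12, 1 / 12)
        p_re = np.full(12, 0.2 / 11)
        p_re[0] = 0.8
        cells, rk, tk = _enrichment_cells(rng, 2000, 200, p_bg, p_re, clusters)
        results = reactive_cluster_enrichment(cells, rk, tk)
        res = next(r for r in results if r.cluster == "C0")
        assert res.direction == "over" and res.p_bonf < 1e-6

    def test_deltas_sum_to_zero(self, rng):
        clusters = list("ABCDE")
        p = np.full(5, 0.2)
        cells, rk, tk = _enrichment_cells(rng, 500, 100, p, p, clusters)
        results = reactive_cluster_enrichment(cells, rk, tk)
        assert sum(r.delta for r in results) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_background_flagged(self):
        cells = pd.DataFrame(
            {
                "barcode": ["a-1", "b-1", "c-1"],
                "cluster": ["A", "A", "B"],
                "key": ["R1", "T1", "R1"],
            }
        )
        results = reactive_cluster_enrichment(cells, {"R1"}, {"T1"})
        res_b = next(r for r in results if r.cluster == "B")
        assert res_b.degenerate_background


class TestPseudobulk:
    def _counts(self, dense):
        n, g = dense.shape
        features = pd.DataFrame(
            {"feature_id": [f"E{j}" for j in range(g)], "symbol": [f"S{j}" for j in range(g)]}
        )
        return CountMatrix([f"B{i}-1" for i in range(n)], features, dense)

    def test_sums_within_group(self):
        cm = self._counts(np.array([[1, 0], [0, 2], [5, 1]]))
        cells = pd.DataFrame({"barcode": cm.barcodes, "sample": ["g1", "g1", "g1"]})
        pb = pseudobulk_aggregate(cm, cells, "sample")
        assert pb.loc["E0", "g1"] == 6 and pb.loc["E1", "g1"] == 3

    def test_one_cell_per_group_is_identity(self):
        dense = np.array([[1, 2], [3, 4]])
        cm = self._counts(dense)
        cells = pd.DataFrame({"barcode": cm.barcodes, "sample": ["a", "b"]})
        pb = pseudobulk_aggregate(cm, cells, "sample")
        np.testing.assert_array_equal(pb[["a", "b"]].to_numpy(), dense.T)

    def test_conserves_total_and_cell_order_invariant(self, rng):
        dense = rng.integers(0, 6, size=(40, 15))
        cm = self._counts(dense)
        cells = pd.DataFrame(
            {"barcode": cm.barcodes, "sample": rng.choice(["a", "b", "c"], 40)}
        )
        pb = pseudobulk_aggregate(cm, cells, "sample")
        assert pb.to_numpy().sum() == dense.sum()
        perm = rng.permutation(40)
        cm2 = CountMatrix([cm.barcodes[i] for i in perm], cm.features, dense[perm])
        pb2 = pseudobulk_aggregate(cm2, cells, "sample")
        pd.testing.assert_frame_equal(pb, pb2)

    def test_unassigned_cell_is_error(self):
        cm = self._counts(np.array([[1, 0]]))
        cells = pd.DataFrame({"barcode": ["other-1"], "sample": ["a"]})
        with pytest.raises(InputError):
            pseudobulk_aggregate(cm, cells, "sample")
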