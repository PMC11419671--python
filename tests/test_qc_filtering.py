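import numpy as np
import pandas as pd
import pytest
from _oracles import fisher_minlike_p

from trlmap.errors import ConfigError
from trlmap.io_formats import ChainRecord, CountMatrix
from trlmap.qc_filtering import (
    BIOPSY_PROFILE,
    ERYTHROCYTE_SPEC,
    PLASMA_SPEC,
    UM1_PROFILE,
    LowRNACellTypeSpec,
    QCProfile,
    apply_global_filters,
    cluster_doublet_stats,
    default_lineage_rules,
    flag_lineage_conflicts,
    nominate_doublet_clusters,
    rescue_low_rna_celltypes,
)


def _cells(**overrides):
    base = {
        "barcode": ["A-1"],
        "sample": "s",
        "n_umi": [3000],
        "n_genes": [1000],
        "pct_mito": [5.0],
        "pct_ribo": [10.0],
        "pct_top100": [50.0],
        "cluster": ["T"],
        "doublet_flag": [False],
    }
    base.update(overrides)
    n = max(len(v) for v in base.values() if isinstance(v, list))
    expanded = {
        k: (v if isinstance(v, list) and len(v) == n else (v[0] if isinstance(v, list) else v))
        for k, v in base.items()
    }
    df = pd.DataFrame({k: (v if isinstance(v, list) else [v] * n) for k, v in expanded.items()})
    df["barcode"] = [f"X{i}-1" for i in range(n)]
    return df


class TestGlobalFilters:
    def test_biopsy_removes_low_gene_cell(self):
        cells = _cells(n_genes=[150])
        retained, report = apply_global_filters(cells, BIOPSY_PROFILE)
        assert retained.empty and report.removed_by["min_genes"] == 1

    def test_biopsy_threshold_is_strict(self):
        # exactly 200 genes is NOT >200, so the cell goes
        retained, _ = apply_global_filters(_cells(n_genes=[200, 201]), BIOPSY_PROFILE)
        assert list(retained["n_genes"]) == [201]

    def test_um1_removes_high_gene_cell(self):
        retained, report = apply_global_filters(_cells(n_genes=[7000], n_umi=[8000]), UM1_PROFILE)
        assert retained.empty and report.removed_by["max_genes"] == 1

    def test_um1_retention_is_inclusive(self):
        # removal criterion is strict ("less than 400"), so 400 stays
        retained, _ = apply_global_filters(_cells(n_genes=[400, 399]), UM1_PROFILE)
        assert list(retained["n_genes"]) == [400]

    @pytest.mark.parametrize("profile", [BIOPSY_PROFILE, UM1_PROFILE])
    def test_good_cell_retained_under_both_profiles(self, profile):
        retained, _ = apply_global_filters(_cells(), profile)
        assert len(retained) == 1

    def test_filtering_is_idempotent(self, small_atlas):
        _, (_, cells, _, _) = small_atlas
        profile = QCProfile(min_umi=100, max_pct_top100=99)
        once, _ = apply_global_filters(cells, profile)
        twice, report = apply_global_filters(once, profile)
        assert len(twice) == len(once)
        assert all(v == 0 for v in report.removed_by.values())

    def test_missing_metric_is_config_error(self):
        cells = _cells().drop(columns=["pct_ribo"])
        with pytest.raises(ConfigError):
            apply_global_filters(cells, BIOPSY_PROFILE)

    def test_report_counts_every_violated_criterion(self):
        cells = _cells(n_genes=[50], n_umi=[100])
        _, report = apply_global_filters(cells, BIOPSY_PROFILE)
        assert report.removed_by["min_genes"] == 1
        assert report.removed_by["min_umi"] == 1


def _matrix(symbol_counts: dict[str, list[int]]) -> CountMatrix:
    symbols = list(symbol_counts)
    n = len(next(iter(symbol_counts.values())))
    dense = np.array([symbol_counts[s] for s in symbols]).T
    features = pd.DataFrame({"feature_id": symbols, "symbol": symbols})
    return CountMatrix([f"B{i}-1" for i in range(n)], features, dense)


class TestLineageConflicts:
    def test_t_cell_with_melanocytic_marker_is_flagged(self):
        cm = _matrix({"CD3D": [2, 5], "MLANA": [1, 0]})
        flags = flag_lineage_conflicts(cm, [], default_lineage_rules())
        assert list(flags) == [True, False]

    def test_assembled_tcr_with_monocyte_marker_is_flagged(self):
        cm = _matrix({"CD14": [3, 3]})
        chains = [ChainRecord("B0-1", "s", "TRB", "CASSF", "TRBV1", "TRBJ1-1", 2, True)]
        flags = flag_lineage_conflicts(cm, chains, default_lineage_rules())
        assert list(flags) == [True, False]

    def test_single_lineage_cell_is_not_flagged(self):
        cm = _matrix({"CD3D": [5], "MLANA": [0], "CD14": [0], "HBB": [0]})
        flags = flag_lineage_conflicts(cm, [], default_lineage_rules())
        assert list(flags) == [False]

    def test_flags_are_monotone_in_expression(self, rng):
        # adding expressed genes can only turn flags on, never off
        symbols = ["CD3D", "CD8A", "MLANA", "PMEL", "CD14", "JCHAIN", "NCR1", "HBB"]
        base = rng.integers(0, 2, size=(20, len(symbols)))
        more = base + rng.integers(0, 2, size=base.shape)
        features = pd.DataFrame({"feature_id": symbols, "symbol": symbols})
        f_base = flag_lineage_conflicts(
            CountMatrix([f"B{i}-1" for i in range(20)], features, base), [],
            default_lineage_rules(),
        )
        f_more = flag_lineage_conflicts(
            CountMatrix([f"B{i}-1" for i in range(20)], features, more), [],
            default_lineage_rules(),
        )
        assert (f_more | f_base).equals(f_more)


class TestClusterDoubletStats:
    def _table(self, spec):
        rows = []
        for cluster, n, n_dbl in spec:
            for i in range(n):
                rows.append(
                    {"barcode": f"{cluster}{i}-1", "cluster": cluster,
                     "doublet_flag": i < n_dbl, "n_umi": 1000}
                )
        return pd.DataFrame(rows)

    def test_odds_ratio_orientation(self):
        stats = cluster_doublet_stats(self._table([("A", 20, 10), ("B", 20, 1)]))
        by = stats.set_index("cluster")
        assert by.loc["A", "odds_ratio"] > 1 > by.loc["B", "odds_ratio"]

    def test_p_matches_exact_enumeration(self):
        stats = cluster_doublet_stats(self._table([("A", 20, 10), ("B", 20, 1)]))
        by = stats.set_index("cluster")
        # cluster A: doublets 10 in / 1 out, singlets 10 in / 19 out
        assert by.loc["A", "p"] == pytest.approx(float(fisher_minlike_p(10, 1, 10, 19)), abs=1e-12)

    def test_equal_rates_give_p_one(self):
        stats = cluster_doublet_stats(self._table([("A", 20, 2), ("B", 20, 2)]))
        assert (stats["p"] == 1.0).all()


class TestNomination:
    def _stats(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "cluster": [f"C{i}" for i in range(n)],
                "n_cells": 100,
                "n_doublets": 5,
                "pct_doublets": rng.uniform(2, 8, n),
                "median_umi": rng.uniform(900, 1100, n),
                "odds_ratio": rng.uniform(0.5, 1.5, n),
                "p": rng.uniform(0.2, 1.0, n),
                "q": rng.uniform(0.3, 1.0, n),
            }
        )

    def test_max_doublet_pct_cluster_always_nominated(self):
        stats = self._stats()
        top = stats.loc[stats["pct_doublets"].idxmax(), "cluster"]
        nominated = nominate_doublet_clusters(stats)
        assert "doublet_pct" in nominated[top]

    def test_unremarkable_cluster_not_nominated(self):
        stats = self._stats()
        stats.loc[0, ["q", "pct_doublets", "median_umi"]] = [0.2, stats["pct_doublets"].median(), stats["median_umi"].median()]
        nominated = nominate_doublet_clusters(stats)
        assert stats.loc[0, "cluster"] not in nominated

    def test_fisher_direction_switch(self):
        stats = self._stats()
        stats.loc[0, ["q", "odds_ratio"]] = [0.001, 0.2]  # significantly depleted
        assert "fisher" not in nominate_doublet_clusters(stats).get("C0", set())
        literal = nominate_doublet_clusters(stats, fisher_or_direction="under")
        assert "fisher" in literal["C0"]

    def test_null_fisher_nomination_rate_controlled(self):
        # uniform doublet rate across clusters: the Fisher criterion should
        # rarely nominate anything (BH at q<0.05, conservative bound 10%)
        rng = np.random.default_rng(42)
        hits = 0
        runs = 400
        for _ in range(runs):
            n_cl = 12
            cl = rng.integers(0, n_cl, size=1200)
            dbl = rng.random(1200) < 0.05
            cells = pd.DataFrame(
                {"cluster": cl.astype(str), "doublet_flag": dbl, "n_umi": 1000}
            )
            stats = cluster_doublet_stats(cells)
            nominated = nominate_doublet_clusters(stats)
            if any("fisher" in r for r in nominated.values()):
                hits += 1
        assert hits / runs <= 0.10


class TestRescue:
    def _counts_and_cells(self, umis, markers, k_spec, extra=None, seed=0):
        rng = np.random.default_rng(seed)
        n = len(umis)
        n_genes = 30
        base = rng.poisson(2.0, size=(n, n_genes)).astype(int)
        # scale rows to hit the requested UMI totals on the filler genes
        sym = [f"G{i}" for i in range(n_genes)] + list(markers)
        mk = np.tile([3] * len(markers), (n, 1))
        dense = np.hstack([base, mk])
        scale = np.array(umis) / np.maximum(dense.sum(axis=1), 1)
        dense = np.floor(dense * scale[:, None]).astype(int)
        dense[:, -len(markers):] = np.maximum(dense[:, -len(markers):], 1)
        features = pd.DataFrame({"feature_id": sym, "symbol": sym})
        barcodes = [f"R{i}-1" for i in range(n)]
        cm = CountMatrix(barcodes, features, dense)
        cells = pd.DataFrame(
            {
                "barcode": barcodes,
                "n_umi": dense.sum(axis=1),
                "n_genes": (dense > 0).sum(axis=1),
                "doublet_flag": extra if extra is not None else [False] * n,
            }
        )
        return cm, cells

    def test_first_quartile_threshold_uses_linear_interpolation(self):
        # retained-group UMIs near [100, 200, 300, 400]: Q1 = 175 and only
        # cells strictly above pass
        cm, cells = self._counts_and_cells([100, 200, 300, 400], ["HBB"], 1)
        spec = LowRNACellTypeSpec("ery", frozenset({"HBB"}), k=1)
        res = rescue_low_rna_celltypes(cm, cells, spec)
        assert not res.skipped
        q1 = np.percentile(cells["n_umi"], 25)
        assert res.q1_umi == pytest.approx(q1)
        expected = set(cells.loc[cells["n_umi"] > q1, "barcode"]) & set(
            cells.loc[cells["n_genes"] > res.q1_genes, "barcode"]
        )
        assert set(res.retained_barcodes) == expected

    def test_plasma_candidates_require_zero_dendritic_markers(self):
        sym = ["JCHAIN", "IL3RA", "LILRA4", "G0"]
        dense = np.array(
            [[3, 0, 0, 5],   # true plasma candidate
             [3, 2, 0, 5],   # IL3RA expressed -> excluded
             [0, 0, 0, 5]]   # no JCHAIN -> excluded
        )
        features = pd.DataFrame({"feature_id": sym, "symbol": sym})
        cm = CountMatrix(["P0-1", "P1-1", "P2-1"], features, dense)
        cells = pd.DataFrame(
            {"barcode": cm.barcodes, "n_umi": dense.sum(1), "n_genes": (dense > 0).sum(1),
             "doublet_flag": False}
        )
        res = rescue_low_rna_celltypes(cm, cells, PLASMA_SPEC)
        assert res.skipped  # under 4 candidates the rescue is skipped...
        assert res.candidates == ["P0-1"]  # ...but candidacy is still correct

    def test_clean_single_group_retains_all_groups(self):
        cm, cells = self._counts_and_cells(
            [400, 500, 600, 700, 800, 900], ["HBB", "HBA1"], 1, seed=4
        )
        spec = LowRNACellTypeSpec("ery", ERYTHROCYTE_SPEC.positive_markers, k=1)
        res = rescue_low_rna_celltypes(cm, cells, spec)
        assert not res.skipped
        assert res.q1_umi == pytest.approx(np.percentile(cells["n_umi"], 25))
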