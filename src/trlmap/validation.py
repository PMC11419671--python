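"""Calibration and recovery experiments on synthetic data.

These routines rerun the pipeline's statistical machinery under controlled
planted conditions and report operating characteristics: family-wise error
under the null, power to recover a planted enriched cluster, doublet-cluster
nomination recovery and false-nomination rates, and exactness of the species
classification. They drive both the test suite and the acceptance script.

Study conditions (defaults) are fixed once: 12 phenotype clusters, 2,000
TIL-background cells and 200 reactive cells per run for the enrichment
experiments; 20 clusters of ~80 cells with two planted doublet clusters
(50% doublet fraction vs 5% ambient) for the doublet experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import reactive_cluster_enrichment
from .qc_filtering import cluster_doublet_stats, nominate_doublet_clusters
from .synthetic_data import AtlasConfig, simulate_atlas, simulate_xenograft_reads
from .xeno_split import classify_barcodes, compute_species_fractions


def _enrichment_run(rng, p_til: np.ndarray, p_reactive: np.ndarray,
                    n_til: int, n_reactive: int):
    """One enrichment analysis on independent TIL and reactive cell pools."""
    n_cl = len(p_til)
    clusters = np.array([f"C{i:02d}" for i in range(n_cl)])
    til = pd.DataFrame(
        {
            "cluster": rng.choice(clusters, size=n_til, p=p_til),
            "key": [f"TIL{i % 200}" for i in range(n_til)],
        }
    )
    reactive = pd.DataFrame(
        {
            "cluster": rng.choice(clusters, size=n_reactive, p=p_reactive),
            "key": [f"RX{i % 50}" for i in range(n_reactive)],
        }
    )
    cells = pd.concat([til, reactive], ignore_index=True)
    cells["barcode"] = [f"B{i}-1" for i in range(len(cells))]
    til_keys = {f"TIL{i}" for i in range(200)}
    reactive_keys = {f"RX{i}" for i in range(50)}
    return reactive_cluster_enrichment(cells, reactive_keys, til_keys)


def null_fwer_rate(
    n_runs: int = 1000,
    seed: int = 0,
    n_clusters: int = 12,
    n_til: int = 20000,
    n_reactive: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of null runs with any Bonferroni-significant cluster.

    Under the null, reactive cells are drawn from the same (non-uniform)
    cluster distribution as the TIL background, so any significant cluster is
    a family-wise false positive. The background pool is kept large relative
    to the reactive pool (100:1, as in real atlases where the TIL-matching
    background dwarfs the reactivity-sorted subset): the binomial test takes
    the background frequency as known, so a noisily estimated background
    would add variance the test does not model.
    """
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_clusters, 5.0))  # one shared non-uniform null
    hits = 0
    for _ in range(n_runs):
        results = _enrichment_run(rng, p, p, n_til, n_reactive)
        if any(r.p_bonf < alpha for r in results):
            hits += 1
    return hits / n_runs


def planted_enrichment_recovery(
    n_runs: int = 100,
    seed: int = 0,
    n_clusters: int = 12,
    reactive_weight: float = 0.5,
    background_weight: float = 0.1,
    n_til: int = 2000,
    n_reactive: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs recovering the planted over-represented cluster.

    One cluster holds ``reactive_weight`` of the reactive cells but only
    ``background_weight`` of the TIL background; recovery means that cluster
    is called over-represented with Bonferroni-adjusted p < alpha.
    """
    rng = np.random.default_rng(seed)
    p_til = np.full(n_clusters, (1 - background_weight) / (n_clusters - 1))
    p_til[0] = background_weight
    p_re = np.full(n_clusters, (1 - reactive_weight) / (n_clusters - 1))
    p_re[0] = reactive_weight
    hits = 0
    for _ in range(n_runs):
        results = _enrichment_run(rng, p_til, p_re, n_til, n_reactive)
        res = next(r for r in results if r.cluster == "C00")
        if res.direction == "over" and res.p_bonf < alpha:
            hits += 1
    return hits / n_runs


def doublet_cluster_experiment(
    n_runs: int = 100,
    seed: int = 0,
    n_clusters: int = 20,
    cells_per_cluster: int = 80,
    planted_rate: float = 0.5,
    background_rate: float = 0.05,
) -> tuple[float, float]:
    """(recovery rate, false-nomination-free rate) over seeded atlas runs.

    Two planted doublet clusters carry ``planted_rate`` doublets against a
    ``background_rate`` ambient rate. Recovery: both planted clusters
    nominated (any criterion). False-nomination-free: no clean cluster is
    nominated via the Fisher criterion.
    """
    recovered = 0
    clean = 0
    planted = frozenset({"C00", "C01"})
    for i in range(n_runs):
        cfg = AtlasConfig(
            n_clusters=n_clusters,
            cells_per_cluster=cells_per_cluster,
            n_genes=3 * n_clusters + 10,
            doublet_rate=background_rate,
            doublet_cluster_ids=planted,
            doublet_cluster_rate=planted_rate,
            n_clonotypes=50,
            n_reactive_clonotypes=5,
            seed=seed * 100_003 + i,
        )
        _, cells, _, truth = simulate_atlas(cfg)
        stats = cluster_doublet_stats(cells)
        nominated = nominate_doublet_clusters(stats)
        if truth.doublet_clusters <= set(nominated):
            recovered += 1
        false_fisher = [
            c for c, reasons in nominated.items()
            if "fisher" in reasons and c not in truth.doublet_clusters
        ]
        if not false_fisher:
            clean += 1
    return recovered / n_runs, clean / n_runs


def xeno_recovery_errors(
    n_seeds: int = 20,
    seed: int = 0,
    n_graft: int = 60,
    n_host: int = 50,
    n_ambiguous: int = 30,
    reads_per_barcode: int = 800,
) -> int:
    """Total misclassified barcodes across seeded host/graft simulations."""
    errors = 0
    for i in range(n_seeds):
        reads, labels = simulate_xenograft_reads(
            n_graft, n_host, n_ambiguous, reads_per_barcode, seed=seed * 99_991 + i
        )
        out = classify_barcodes(compute_species_fractions(reads))
        recovered = out.set_index("barcode")["label"]
        errors += int((recovered.loc[labels.index] != labels).sum())
    return errors
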