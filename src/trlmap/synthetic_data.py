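"""Synthetic single-cell RNA/TCR datasets with planted ground truth.

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without access to deposited sequencing data:

- clustered cell populations with marker structure: counts are negative
  binomial (the standard single-cell count family), with each cluster's
  marker panel boosted by a multiplicative factor;
- clonal TCR repertoires: clone sizes follow a truncated power law, mimicking
  clonal expansion in TIL repertoires; each non-doublet cell carries one TRB
  chain and one (or, for a configurable fraction, two) TRA chains;
- planted reactive clonotypes whose cells are placed into clusters according
  to a reactive weight vector distinct from the background weights,
  producing a known enrichment signal;
- planted doublets modeled as barcode collisions: a doublet's count vector is
  exactly the elementwise sum of its two parent cells, so lineage-conflicting
  expression arises whenever the parents differ in lineage; designated
  doublet clusters receive an elevated doublet fraction;
- planted low-RNA populations (erythrocyte/plasma-like) with scaled-down
  library depth, to exercise the rescue step;
- host/graft read mixtures for PDX barcode classification.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .clonotype import ClonotypeKey
from .errors import ConfigError
from .io_formats import ChainRecord, CountMatrix, make_cell_table

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class LowRNAPopulation:
    """A planted low-RNA cell population (erythrocyte/plasma-like).

    ``depth_scale`` < 1 scales the whole expression mean down;
    ``doublet_fraction`` of the population is emitted as within-population
    doublets (sum of two members) flagged upstream.
    """

    name: str
    markers: tuple[str, ...]
    zero_markers: tuple[str, ...] = ()
    n_cells: int = 60
    depth_scale: float = 0.3
    doublet_fraction: float = 0.0


@dataclass
class AtlasConfig:
    """Configuration of a synthetic cell atlas.

    Defaults describe a mid-sized biopsy-like dataset: 12 phenotype clusters
    of 200 cells, 400 genes with 3 markers per cluster boosted 20-fold over a
    background negative-binomial mean of 2 counts/gene, 3% ambient doublet
    rate, and a clonal repertoire of 400 clonotypes with power-law clone
    sizes (exponent 1.5) of which 25 are tumor-reactive.
    """

    n_clusters: int = 12
    cells_per_cluster: int = 200
    n_genes: int = 400
    marker_panel: dict[str, list[str]] | None = None
    base_expression_rate: float = 2.0
    marker_boost: float = 20.0
    marker_off_rate: float = 0.0
    tcr_cluster_labels: frozenset | None = None
    nb_dispersion: float = 2.0
    doublet_rate: float = 0.03
    doublet_cluster_ids: frozenset = frozenset()
    doublet_cluster_rate: float = 0.5
    lowrna_celltypes: list[LowRNAPopulation] = field(default_factory=list)
    clone_size_alpha: float = 1.5
    n_clonotypes: int = 400
    n_reactive_clonotypes: int = 25
    reactive_keys: set[ClonotypeKey] | None = None
    reactive_cluster_weights: dict[str, float] | None = None
    background_cluster_weights: dict[str, float] | None = None
    multi_alpha_fraction: float = 0.05
    sample_name: str = "S1"
    seed: int = 0

    def cluster_labels(self) -> list[str]:
        if self.marker_panel is not None:
            return list(self.marker_panel)
        return [f"C{i:02d}" for i in range(self.n_clusters)]

    def validate(self) -> None:
        labels = set(self.cluster_labels())
        for name, rates in (
            ("doublet_rate", self.doublet_rate),
            ("doublet_cluster_rate", self.doublet_cluster_rate),
            ("multi_alpha_fraction", self.multi_alpha_fraction),
        ):
            if not 0.0 <= rates <= 1.0:
                raise ConfigError(f"{name}={rates} outside [0, 1]")
        unknown = set(self.doublet_cluster_ids) - labels
        if unknown:
            raise ConfigError(f"doublet_cluster_ids reference unknown clusters {unknown}")
        if self.tcr_cluster_labels is not None:
            unknown = set(self.tcr_cluster_labels) - labels
            if unknown:
                raise ConfigError(f"tcr_cluster_labels reference unknown clusters {unknown}")
        for name, w in (
            ("reactive_cluster_weights", self.reactive_cluster_weights),
            ("background_cluster_weights", self.background_cluster_weights),
        ):
            if w is None:
                continue
            unknown = set(w) - labels
            if unknown:
                raise ConfigError(f"{name} references unknown clusters {unknown}")
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ConfigError(f"{name} weights must be nonnegative with positive sum")
        if self.marker_panel is not None and len(self.marker_panel) != self.n_clusters:
            raise ConfigError("marker_panel size differs from n_clusters")


@dataclass
class SyntheticTruth:
    """Planted parameters for recovery tests."""

    doublet_cells: set[str]
    doublet_clusters: set[str]
    enriched_clusters: set[str]
    reactive_barcodes: set[str]
    reactive_keys: set[ClonotypeKey]
    clone_assignment: dict[str, ClonotypeKey]
    doublet_parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    lowrna_barcodes: dict[str, list[str]] = field(default_factory=dict)


def _weights_vector(labels: list[str], w: dict[str, float] | None) -> np.ndarray:
    if w is None:
        v = np.ones(len(labels))
    else:
        v = np.array([w.get(lab, 0.0) for lab in labels], dtype=float)
    return v / v.sum()


def _random_cdr3(rng: np.random.Generator, lo: int = 8, hi: int = 16) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "CASS" + "".join(rng.choice(_AA, size=length)) + "EQYF"


def _make_clonotype_keys(rng: np.random.Generator, n: int) -> list[ClonotypeKey]:
    keys: list[ClonotypeKey] = []
    seen = set()
    while len(keys) < n:
        key = ClonotypeKey(
            _random_cdr3(rng),
            f"TRBV{int(rng.integers(1, 31))}-{int(rng.integers(1, 4))}",
            f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 8))}",
        )
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with given mean and shape (size) parameter."""
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_atlas(config: AtlasConfig) -> tuple[CountMatrix, pd.DataFrame, list[ChainRecord], SyntheticTruth]:
    """Generate a full synthetic atlas.

    Returns (counts, cell table, TCR chains, truth). Base cell count is
    ``n_clusters * cells_per_cluster``; planted doublets and low-RNA
    populations are appended as extra barcodes. Each non-doublet base cell
    carries one clonotype; the cluster of a cell carrying a reactive
    (background) clonotype is drawn from the reactive (background) weights.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.cluster_labels()

    # feature panel: cluster markers first, then low-RNA markers, then filler
    if config.marker_panel is None:
        panel = {lab: [f"MK{i:02d}_{j}" for j in range(3)] for i, lab in enumerate(labels)}
    else:
        panel = {lab: list(genes) for lab, genes in config.marker_panel.items()}
    symbols: list[str] = []
    for genes in panel.values():
        symbols.extend(g for g in genes if g not in symbols)
    for pop in config.lowrna_celltypes:
        symbols.extend(g for g in (*pop.markers, *pop.zero_markers) if g not in symbols)
    if len(symbols) > config.n_genes:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {len(symbols)} marker genes"
        )
    marker_symbols = list(symbols)
    symbols = symbols + [f"G{i:04d}" for i in range(config.n_genes - len(symbols))]
    features = pd.DataFrame({"feature_id": symbols, "symbol": symbols})
    col_of = {s: i for i, s in enumerate(symbols)}

    # clonal repertoire: truncated power-law clone sizes
    keys = _make_clonotype_keys(rng, config.n_clonotypes)
    size_p = np.arange(1, config.n_clonotypes + 1, dtype=float) ** (-config.clone_size_alpha)
    size_p /= size_p.sum()
    if config.reactive_keys is not None:
        reactive_keys = set(config.reactive_keys) & set(keys)
    else:
        reactive_idx = rng.choice(config.n_clonotypes, size=config.n_reactive_clonotypes, replace=False)
        reactive_keys = {keys[i] for i in reactive_idx}

    # base cells: clone first, then cluster from the clone-status weights
    n_base = config.n_clusters * config.cells_per_cluster
    clone_idx = rng.choice(config.n_clonotypes, size=n_base, p=size_p)
    is_reactive = np.array([keys[i] in reactive_keys for i in clone_idx])
    rw = _weights_vector(labels, config.reactive_cluster_weights)
    bw = _weights_vector(labels, config.background_cluster_weights)
    cluster_idx = np.empty(n_base, dtype=int)
    cluster_idx[is_reactive] = rng.choice(len(labels), size=int(is_reactive.sum()), p=rw)
    cluster_idx[~is_reactive] = rng.choice(len(labels), size=int((~is_reactive).sum()), p=bw)

    # expression: NB background, lognormal depth; marker genes are silent
    # (rate scaled by marker_off_rate) outside their own cluster and boosted
    # inside it, so lineage conflicts arise only through doublets
    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_base)
    mu = np.outer(depth, np.full(config.n_genes, config.base_expression_rate))
    marker_cols = [col_of[s] for s in marker_symbols]
    mu[:, marker_cols] *= config.marker_off_rate
    for ci, lab in enumerate(labels):
        rows = cluster_idx == ci
        cols = [col_of[g] for g in panel[lab]]
        mu[np.ix_(rows, cols)] = (
            depth[rows, None] * config.base_expression_rate * config.marker_boost
        )
    base_counts = _nb_draw(rng, mu, config.nb_dispersion)

    barcodes = [f"BC{i:06d}-1" for i in range(n_base)]
    cluster_lab = [labels[i] for i in cluster_idx]
    blocks = [base_counts]
    all_barcodes = list(barcodes)
    all_clusters = list(cluster_lab)
    doublet_flag = [False] * n_base

    truth = SyntheticTruth(
        doublet_cells=set(),
        doublet_clusters=set(config.doublet_cluster_ids),
        enriched_clusters={lab for lab, a, b in zip(labels, rw, bw) if a > b},
        reactive_barcodes={b for b, r in zip(barcodes, is_reactive) if r},
        reactive_keys=set(reactive_keys),
        clone_assignment={b: keys[i] for b, i in zip(barcodes, clone_idx)},
    )

    # planted doublets: barcode collisions appended as extra cells
    dbl_counter = 0
    for ci, lab in enumerate(labels):
        members = np.flatnonzero(cluster_idx == ci)
        if members.size == 0:
            continue
        rate = config.doublet_cluster_rate if lab in config.doublet_cluster_ids else config.doublet_rate
        n_dbl = int(round(rate / (1.0 - rate) * members.size)) if rate < 1 else members.size
        if n_dbl == 0:
            continue
        p1 = rng.choice(members, size=n_dbl)
        others = np.flatnonzero(cluster_idx != ci)
        pool = others if others.size else np.arange(n_base)
        p2 = rng.choice(pool, size=n_dbl)
        dbl_block = base_counts[p1] + base_counts[p2]
        blocks.append(dbl_block)
        for i, j in zip(p1, p2):
            bc = f"DBL{dbl_counter:05d}-1"
            dbl_counter += 1
            all_barcodes.append(bc)
            all_clusters.append(lab)
            doublet_flag.append(True)
            truth.doublet_cells.add(bc)
            truth.doublet_parents[bc] = (barcodes[i], barcodes[j])

    # planted low-RNA populations
    for pop in config.lowrna_celltypes:
        mu_pop = np.full((pop.n_cells, config.n_genes), config.base_expression_rate * pop.depth_scale)
        mu_pop[:, marker_cols] *= config.marker_off_rate
        mcols = [col_of[g] for g in pop.markers]
        mu_pop[:, mcols] = config.base_expression_rate * pop.depth_scale * config.marker_boost
        zcols = [col_of[g] for g in pop.zero_markers]
        pop_counts = _nb_draw(rng, mu_pop, config.nb_dispersion)
        pop_counts[:, zcols] = 0
        pop_barcodes = [f"{pop.name.upper()[:3]}{i:05d}-1" for i in range(pop.n_cells)]
        blocks.append(pop_counts)
        all_barcodes.extend(pop_barcodes)
        all_clusters.extend([pop.name] * pop.n_cells)
        doublet_flag.extend([False] * pop.n_cells)
        truth.lowrna_barcodes[pop.name] = list(pop_barcodes)
        n_pop_dbl = int(round(pop.doublet_fraction * pop.n_cells))
        if n_pop_dbl:
            q1 = rng.integers(0, pop.n_cells, size=n_pop_dbl)
            q2 = rng.integers(0, pop.n_cells, size=n_pop_dbl)
            blocks.append(pop_counts[q1] + pop_counts[q2])
            for i, j in zip(q1, q2):
                bc = f"{pop.name.upper()[:3]}D{dbl_counter:04d}-1"
                dbl_counter += 1
                all_barcodes.append(bc)
                all_clusters.append(pop.name)
                doublet_flag.append(True)
                truth.doublet_cells.add(bc)
                truth.doublet_parents[bc] = (pop_barcodes[i], pop_barcodes[j])
                truth.lowrna_barcodes[pop.name].append(bc)

    counts_arr = np.vstack(blocks)
    counts = CountMatrix(all_barcodes, features, sparse.csr_matrix(counts_arr))
    cells = _make_metrics_table(
        counts_arr, all_barcodes, all_clusters, doublet_flag, features, config.sample_name
    )

    chains = _make_chains(rng, config, barcodes, cluster_lab, clone_idx, keys)
    if config.tcr_cluster_labels is not None:
        with_chain = {c.barcode for c in chains}
        truth.reactive_barcodes &= with_chain
        truth.clone_assignment = {
            b: k for b, k in truth.clone_assignment.items() if b in with_chain
        }
    return counts, cells, chains, truth


def _make_metrics_table(counts_arr, barcodes, clusters, doublet_flag, features, sample) -> pd.DataFrame:
    totals = counts_arr.sum(axis=1)
    totals_safe = np.maximum(totals, 1)
    n_genes = (counts_arr > 0).sum(axis=1)
    symbols = features["symbol"].to_numpy()
    mito = np.char.startswith(symbols.astype(str), "MT-")
    ribo = np.char.startswith(symbols.astype(str), "RPS") | np.char.startswith(
        symbols.astype(str), "RPL"
    )
    pct_mito = 100.0 * counts_arr[:, mito].sum(axis=1) / totals_safe
    pct_ribo = 100.0 * counts_arr[:, ribo].sum(axis=1) / totals_safe
    k = min(100, counts_arr.shape[1])
    part = np.partition(counts_arr, counts_arr.shape[1] - k, axis=1)[:, -k:]
    pct_top100 = 100.0 * part.sum(axis=1) / totals_safe
    return make_cell_table(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "sample": sample,
                "n_umi": totals,
                "n_genes": n_genes,
                "pct_mito": pct_mito,
                "pct_ribo": pct_ribo,
                "pct_top100": pct_top100,
                "cluster": clusters,
                "doublet_flag": doublet_flag,
            }
        )
    )


def _make_chains(rng, config, barcodes, cluster_lab, clone_idx, keys) -> list[ChainRecord]:
    chains: list[ChainRecord] = []
    # a fixed TRA per clonotype, so alpha chains are clonally consistent
    tra_of_clone = {
        i: (
            _random_cdr3(rng, 6, 12),
            f"TRAV{int(rng.integers(1, 41))}",
            f"TRAJ{int(rng.integers(1, 51))}",
        )
        for i in range(config.n_clonotypes)
    }
    multi_alpha = rng.random(len(barcodes)) < config.multi_alpha_fraction
    for bi, (bc, ci) in enumerate(zip(barcodes, clone_idx)):
        if (
            config.tcr_cluster_labels is not None
            and cluster_lab[bi] not in config.tcr_cluster_labels
        ):
            continue
        key = keys[ci]
        chains.append(
            ChainRecord(
                barcode=bc,
                sample=config.sample_name,
                locus="TRB",
                cdr3_aa=key.cdr3b_aa,
                v_gene=key.vb,
                j_gene=key.jb,
                umis=int(rng.integers(2, 12)),
                productive=True,
            )
        )
        cdr3a, va, ja = tra_of_clone[ci]
        chains.append(
            ChainRecord(bc, config.sample_name, "TRA", cdr3a, va, ja, int(rng.integers(1, 8)), True)
        )
        if multi_alpha[bi]:
            chains.append(
                ChainRecord(
                    bc,
                    config.sample_name,
                    "TRA",
                    _random_cdr3(rng, 6, 12),
                    f"TRAV{int(rng.integers(1, 41))}",
                    f"TRAJ{int(rng.integers(1, 51))}",
                    int(rng.integers(1, 5)),
                    True,
                )
            )
    return chains


def simulate_reactive_sort(
    truth: SyntheticTruth, dropout: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Bulk TCR-seq clonotype table of a reactivity sort (e.g. 4-1BB+ cells).

    Each planted reactive clonotype is recovered with probability
    ``1 - dropout`` and emitted with a positive read count; non-reactive
    clonotypes are never emitted.
    """
    if not 0.0 <= dropout < 1.0:
        raise ConfigError(f"dropout={dropout} outside [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for key in sorted(truth.reactive_keys):
        if rng.random() < dropout:
            continue
        rows.append(
            {
                "cdr3b_aa": key.cdr3b_aa,
                "v_gene": key.vb,
                "j_gene": key.jb,
                "read_count": int(rng.integers(1, 200)),
            }
        )
    return pd.DataFrame(rows, columns=["cdr3b_aa", "v_gene", "j_gene", "read_count"])


def simulate_xenograft_reads(
    n_graft: int,
    n_host: int,
    n_ambiguous: int,
    reads_per_barcode: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-barcode species read counts with planted labels.

    Graft barcodes get a host-read fraction in [0, 0.1), host barcodes in
    (0.9, 1], ambiguous barcodes in [0.3, 0.7]; sampling margins keep the
    realized (integer-rounded) fractions inside their bands. Returns the read
    count table and the planted labels indexed by barcode.
    """
    if min(n_graft, n_host, n_ambiguous) < 0 or reads_per_barcode <= 0:
        raise ConfigError("counts must be nonnegative and reads_per_barcode positive")
    rng = np.random.default_rng(seed)
    eps = 1.0 / reads_per_barcode
    specs = [
        ("graft", n_graft, 0.0, max(0.0, 0.1 - eps)),
        ("host", n_host, min(1.0, 0.9 + eps), 1.0),
        ("ambiguous", n_ambiguous, 0.3 + eps, 0.7 - eps),
    ]
    rows, labels = [], {}
    i = 0
    for label, n, lo, hi in specs:
        for _ in range(n):
            f = float(rng.uniform(lo, hi))
            host_reads = int(round(f * reads_per_barcode))
            bc = f"XB{i:06d}-1"
            i += 1
            rows.append(
                {
                    "barcode": bc,
                    "host_reads": host_reads,
                    "graft_reads": reads_per_barcode - host_reads,
                }
            )
            labels[bc] = label
    df = pd.DataFrame(rows, columns=["barcode", "host_reads", "graft_reads"])
    return df, pd.Series(labels, name="true_label")
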