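"""Bespoke cell filtering for tumor biopsy and PDX single-cell data.

Four stages, applied after upstream per-cell doublet calling and clustering
(both of which are inputs here, not recomputed):

1. global metric thresholds (:func:`apply_global_filters`) — two shipped
   profiles: ``biopsy`` (detected genes > 200, UMI > 500, ribosomal % < 40,
   top-100-gene % < 80, with a pre-filter dropping cells under 200 reads) and
   ``um1`` (genes in [400, 6500], UMI in [500, 25000], mito % <= 20,
   ribo % <= 15);
2. lineage-conflict doublet flagging (:func:`flag_lineage_conflicts`) — cells
   co-expressing markers of incompatible lineages (e.g. a T-cell marker or an
   assembled TCR together with a melanocytic or hemoglobin gene) are doublets;
3. cluster-level doublet-cluster removal (:func:`cluster_doublet_stats` +
   :func:`nominate_doublet_clusters`) — per cluster, a two-sided Fisher's
   exact test for association with doublets (BH-adjusted), plus percentile
   rules on doublet fraction and UMI depth;
4. low-RNA cell-type rescue (:func:`rescue_low_rna_celltypes`) — erythrocytes
   and plasma cells have genuinely low RNA content, so marker-selected
   candidates get their own, laxer first-quartile thresholds after removal of
   doublet-contaminated candidate subgroups.

Percentiles and quartiles everywhere use linear interpolation (R type-7).
"Expressed" means raw count > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_exact_2x2
from .errors import ConfigError, InputError
from .io_formats import ChainRecord, CountMatrix

logger = logging.getLogger(__name__)

#: Sentinel gene-set member meaning "has >=1 productive assembled TCR chain".
TCR_ASSEMBLED = "TCR_ASSEMBLED"


@dataclass(frozen=True)
class QCProfile:
    """Global QC thresholds. Absent (None) thresholds are not applied.

    ``inclusive`` selects the comparison strictness for the retention rule:
    False means a cell is kept iff metric > min / metric < max (thresholds
    phrased as retention criteria); True means kept iff metric >= min /
    metric <= max (thresholds phrased as strict removal criteria).
    ``pre_filter_min_umi`` drops cells with fewer reads before anything else
    (always ``n_umi >= value`` to keep).
    """

    name: str = "custom"
    min_genes: int | None = None
    max_genes: int | None = None
    min_umi: int | None = None
    max_umi: int | None = None
    max_pct_mito: float | None = None
    max_pct_ribo: float | None = None
    max_pct_top100: float | None = None
    pre_filter_min_umi: int | None = None
    inclusive: bool = False

    def __post_init__(self):
        for lo, hi in (("min_genes", "max_genes"), ("min_umi", "max_umi")):
            a, b = getattr(self, lo), getattr(self, hi)
            if a is not None and b is not None and a >= b:
                raise ConfigError(f"{lo}={a} must be < {hi}={b}")


#: Tumor biopsy profile: retention criteria, strict comparisons.
BIOPSY_PROFILE = QCProfile(
    name="biopsy",
    min_genes=200,
    min_umi=500,
    max_pct_ribo=40,
    max_pct_top100=80,
    pre_filter_min_umi=200,
    inclusive=False,
)

#: PDX (UM1) profile: removal criteria phrased strictly, so retention is inclusive.
UM1_PROFILE = QCProfile(
    name="um1",
    min_genes=400,
    max_genes=6500,
    min_umi=500,
    max_umi=25000,
    max_pct_mito=20,
    max_pct_ribo=15,
    inclusive=True,
)

PROFILES = {"biopsy": BIOPSY_PROFILE, "um1": UM1_PROFILE}


@dataclass
class FilterReport:
    """Per-criterion removal counts (a cell may count toward several)."""

    n_in: int
    n_retained: int
    removed_by: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "n_removed": v} for k, v in self.removed_by.items()]
        rows.append({"criterion": "total_removed", "n_removed": self.n_in - self.n_retained})
        return pd.DataFrame(rows)


# (profile attribute, cell metric, kind) — kind 'min' keeps high values
_THRESHOLD_MAP = [
    ("min_genes", "n_genes", "min"),
    ("max_genes", "n_genes", "max"),
    ("min_umi", "n_umi", "min"),
    ("max_umi", "n_umi", "max"),
    ("max_pct_mito", "pct_mito", "max"),
    ("max_pct_ribo", "pct_ribo", "max"),
    ("max_pct_top100", "pct_top100", "max"),
]


def apply_global_filters(cells: pd.DataFrame, profile: QCProfile) -> tuple[pd.DataFrame, FilterReport]:
    """Keep cells satisfying every threshold present in ``profile``.

    Returns the retained table (original row order) and a report of how many
    cells each criterion removed. Thresholding a missing metric raises
    :class:`ConfigError`. Idempotent: re-filtering the result removes nothing.
    """
    report = FilterReport(n_in=len(cells), n_retained=0)
    keep = np.ones(len(cells), dtype=bool)

    if profile.pre_filter_min_umi is not None:
        if "n_umi" not in cells.columns:
            raise ConfigError("profile thresholds n_umi but cells table lacks it")
        ok = cells["n_umi"].to_numpy() >= profile.pre_filter_min_umi
        report.removed_by["pre_filter_umi"] = int((~ok).sum())
        keep &= ok

    for attr, metric, kind in _THRESHOLD_MAP:
        value = getattr(profile, attr)
        if value is None:
            continue
        if metric not in cells.columns:
            raise ConfigError(f"profile thresholds {metric} but cells table lacks it")
        col = cells[metric].to_numpy()
        if kind == "min":
            ok = col >= value if profile.inclusive else col > value
        else:
            ok = col <= value if profile.inclusive else col < value
        report.removed_by[attr] = int((~ok).sum())
        keep &= ok

    retained = cells[keep]
    report.n_retained = len(retained)
    return retained, report


@dataclass
class LineageRuleSet:
    """Pairs of incompatible marker sets.

    Each rule is ``(set_a, set_b)``: a cell expressing any member of A together
    with any member of B is a doublet. The token :data:`TCR_ASSEMBLED` in a set
    means the cell has at least one productive assembled TCR chain.
    """

    rules: list[tuple[frozenset, frozenset]]

    def __post_init__(self):
        for a, b in self.rules:
            if not a or not b:
                raise ConfigError("lineage rule with an empty marker set")


def default_lineage_rules() -> LineageRuleSet:
    """The shipped incompatible-lineage marker rules.

    T-cell identity (CD3D/CD4/CD8A/CD8B or an assembled TCR) conflicts with
    melanocytic (MLANA/PMEL/TYR) or erythroid (HBA1/HBA2/HBB) programs; an
    assembled TCR conflicts with monocyte/B/plasmacytoid markers; melanocytic
    markers conflict with monocyte/B/plasma/NK markers.
    """
    return LineageRuleSet(
        rules=[
            (
                frozenset({"CD3D", "CD4", "CD8A", "CD8B", TCR_ASSEMBLED}),
                frozenset({"MLANA", "PMEL", "TYR", "HBA1", "HBA2", "HBB"}),
            ),
            (
                frozenset({TCR_ASSEMBLED}),
                frozenset({"CD14", "CD19", "MS4A1", "JCHAIN"}),
            ),
            (
                frozenset({"MLANA", "PMEL", "TYR"}),
                frozenset({"CD14", "CD19", "MS4A1", "JCHAIN", "NCR1"}),
            ),
        ]
    )


def flag_lineage_conflicts(
    counts: CountMatrix,
    chains: list[ChainRecord],
    rules: LineageRuleSet | None = None,
) -> pd.Series:
    """Boolean per-cell flags: True iff some incompatible-lineage rule fires.

    "Expressed" means raw count > 0; rule symbols missing from the feature
    list are logged and the rule evaluated on the remaining symbols. Monotone:
    adding expressed genes can only turn flags on.
    """
    if rules is None:
        rules = default_lineage_rules()
    barcodes = counts.row_index()
    has_tcr = pd.Series(False, index=barcodes)
    tcr_barcodes = {c.barcode for c in chains if c.productive}
    has_tcr[has_tcr.index.isin(tcr_barcodes)] = True

    def set_expressed(symbols: frozenset) -> np.ndarray:
        out = np.zeros(len(barcodes), dtype=bool)
        for sym in symbols:
            if sym == TCR_ASSEMBLED:
                out |= has_tcr.to_numpy()
                continue
            cols = counts.columns_for_symbol(sym)
            if cols.size == 0:
                logger.info("lineage rule symbol %s not in features; skipped", sym)
                continue
            out |= np.asarray((counts.counts[:, cols] > 0).sum(axis=1)).ravel() > 0
        return out

    flags = np.zeros(len(barcodes), dtype=bool)
    for set_a, set_b in rules.rules:
        flags |= set_expressed(set_a) & set_expressed(set_b)
    return pd.Series(flags, index=barcodes, name="lineage_conflict")


def cluster_doublet_stats(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster doublet association statistics.

    For each cluster, a 2x2 table with rows (doublet, singlet) and columns
    (in-cluster, out-of-cluster) is tested with the two-sided Fisher's exact
    test, so OR > 1 means doublets are over-represented in the cluster.
    p-values are Benjamini-Hochberg adjusted across clusters. Requires columns
    ``cluster``, ``doublet_flag`` and ``n_umi``; empty clusters cannot occur
    (clusters are defined by their member cells).
    """
    for col in ("cluster", "doublet_flag", "n_umi"):
        if col not in cells.columns:
            raise InputError(f"cells table missing column {col!r}")
    dbl = cells["doublet_flag"].astype(bool).to_numpy()
    cl = cells["cluster"].astype(str).to_numpy()
    total_dbl = int(dbl.sum())
    total = len(cells)

    rows = []
    for cluster in sorted(pd.unique(cl)):
        in_cl = cl == cluster
        n_cells = int(in_cl.sum())
        a = int((in_cl & dbl).sum())          # doublets in cluster
        b = total_dbl - a                     # doublets outside
        c = n_cells - a                       # singlets in cluster
        d = (total - total_dbl) - c           # singlets outside
        odds_ratio, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "cluster": cluster,
                "n_cells": n_cells,
                "n_doublets": a,
                "pct_doublets": 100.0 * a / n_cells,
                "median_umi": float(np.median(cells.loc[in_cl, "n_umi"])),
                "odds_ratio": odds_ratio,
                "p": p,
            }
        )
    stats = pd.DataFrame(rows)
    stats["q"] = multipletests(stats["p"].to_numpy(), method="fdr_bh")[1]
    return stats


def nominate_doublet_clusters(
    stats: pd.DataFrame,
    q_max: float = 0.05,
    pct_percentile: float = 95,
    umi_percentile: float = 95,
    fisher_or_direction: str = "over",
) -> dict[str, set[str]]:
    """Nominate doublet clusters for removal; returns cluster -> reason set.

    Three criteria, united:

    - ``fisher``: q < q_max with doublet over-representation (OR > 1 under the
      table orientation of :func:`cluster_doublet_stats`). Setting
      ``fisher_or_direction='under'`` restores the literal OR < 1 reading.
    - ``doublet_pct``: cluster doublet percentage >= the ``pct_percentile``-th
      percentile of cluster doublet percentages (inclusive).
    - ``umi_pct``: cluster median UMI strictly above the
      ``umi_percentile``-th percentile of cluster median UMIs.
    """
    if stats.empty:
        raise InputError("empty cluster statistics")
    if fisher_or_direction not in ("over", "under"):
        raise ConfigError(f"invalid fisher_or_direction {fisher_or_direction!r}")
    if fisher_or_direction == "under":
        logger.warning(
            "fisher_or_direction='under': using the literal OR<1 removal rule"
        )
    pct_cut = np.percentile(stats["pct_doublets"].to_numpy(), pct_percentile)
    umi_cut = np.percentile(stats["median_umi"].to_numpy(), umi_percentile)

    nominated: dict[str, set[str]] = {}
    for row in stats.itertuples(index=False):
        reasons = set()
        or_hit = (
            row.odds_ratio > 1 if fisher_or_direction == "over" else row.odds_ratio < 1
        )
        if row.q < q_max and or_hit:
            reasons.add("fisher")
        if row.pct_doublets >= pct_cut:
            reasons.add("doublet_pct")
        if row.median_umi > umi_cut:
            reasons.add("umi_pct")
        if reasons:
            nominated[row.cluster] = reasons
    return nominated


@dataclass(frozen=True)
class LowRNACellTypeSpec:
    """Marker definition of a low-RNA cell type eligible for rescue.

    ``positive_markers``: candidate iff any is expressed; ``zero_markers``:
    all must be zero (plasma cells demand IL3RA and LILRA4 at zero alongside
    JCHAIN expression). ``k`` is the number of groups the candidate tree is
    cut into.
    """

    name: str
    positive_markers: frozenset
    zero_markers: frozenset = frozenset()
    k: int = 2


#: Default rescue specs: erythrocytes (hemoglobin genes) and plasma cells.
ERYTHROCYTE_SPEC = LowRNACellTypeSpec("erythrocyte", frozenset({"HBA1", "HBA2", "HBB"}))
PLASMA_SPEC = LowRNACellTypeSpec(
    "plasma_cell", frozenset({"JCHAIN"}), frozenset({"IL3RA", "LILRA4"})
)


@dataclass
class RescueResult:
    celltype: str
    skipped: bool
    q1_umi: float | None
    q1_genes: float | None
    candidates: list[str]
    retained_barcodes: list[str]


def rescue_low_rna_celltypes(
    counts: CountMatrix,
    cells: pd.DataFrame,
    spec: LowRNACellTypeSpec,
    q_max: float = 0.05,
    umi_percentile: float = 95,
) -> RescueResult:
    """Derive laxer first-quartile thresholds for a low-RNA cell type.

    Procedure: (1) select candidates by marker criteria; (2) Spearman
    correlation between candidates over all genes; (3) complete-linkage
    hierarchical clustering on 1 - rho, cut into ``spec.k`` groups; (4) discard
    groups with doublet over-representation (the cluster-level Fisher
    criterion) or median UMI above the group-level 95th percentile; (5) Q1 of
    n_umi and n_genes over cells in retained groups; (6) retained barcodes are
    candidates in retained groups with n_umi > Q1_umi and n_genes > Q1_genes.

    Fewer than 4 candidates: the rescue is skipped with a warning (quartiles
    are not robust).
    """
    cell_idx = cells.set_index("barcode")
    pos = np.zeros(len(counts.barcodes), dtype=bool)
    for sym in spec.positive_markers:
        cols = counts.columns_for_symbol(sym)
        if cols.size:
            pos |= np.asarray((counts.counts[:, cols] > 0).sum(axis=1)).ravel() > 0
        else:
            logger.info("rescue marker %s not in features", sym)
    for sym in spec.zero_markers:
        cols = counts.columns_for_symbol(sym)
        if cols.size:
            pos &= ~(np.asarray((counts.counts[:, cols] > 0).sum(axis=1)).ravel() > 0)

    candidates = [b for b, keep in zip(counts.barcodes, pos) if keep and b in cell_idx.index]
    if len(candidates) < 4:
        logger.warning(
            "rescue %s skipped: only %d candidates", spec.name, len(candidates)
        )
        return RescueResult(spec.name, True, None, None, candidates, [])

    sub = counts.subset_cells(candidates).counts.toarray().T  # genes x candidates
    rho = spearmanr(sub).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize fp noise
    groups = fcluster(linkage(squareform(dist, checks=False), method="complete"),
                      t=min(spec.k, len(candidates)), criterion="maxclust")

    cand = cell_idx.loc[candidates]
    dbl = cand["doublet_flag"].astype(bool).to_numpy()
    total_dbl, total = int(dbl.sum()), len(candidates)

    group_ids = sorted(set(groups))
    fisher_p, medians = [], {}
    for g in group_ids:
        in_g = groups == g
        a = int((in_g & dbl).sum())
        b = total_dbl - a
        c = int(in_g.sum()) - a
        d = (total - total_dbl) - c
        or_, p = fisher_exact_2x2([[a, b], [c, d]])
        fisher_p.append((g, or_, p))
        medians[g] = float(np.median(cand.loc[in_g, "n_umi"]))
    qvals = multipletests([p for _, _, p in fisher_p], method="fdr_bh")[1]
    umi_cut = np.percentile(list(medians.values()), umi_percentile)

    retained_groups = []
    for (g, or_, _p), q in zip(fisher_p, qvals):
        doublet_hit = q < q_max and or_ > 1
        umi_hit = medians[g] > umi_cut
        if not doublet_hit and not umi_hit:
            retained_groups.append(g)
    if not retained_groups:
        logger.warning("rescue %s: all candidate groups discarded", spec.name)
        return RescueResult(spec.name, True, None, None, candidates, [])

    in_retained = np.isin(groups, retained_groups)
    pool = cand.loc[in_retained]
    q1_umi = float(np.percentile(pool["n_umi"].to_numpy(), 25))
    q1_genes = float(np.percentile(pool["n_genes"].to_numpy(), 25))
    keep = (pool["n_umi"] > q1_umi) & (pool["n_genes"] > q1_genes)
    return RescueResult(
        spec.name, False, q1_umi, q1_genes, candidates, list(pool.index[keep])
    )
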