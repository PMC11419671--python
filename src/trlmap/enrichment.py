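"""Cluster-level enrichment statistics for reactive clonotypes.

The central question: after matching single-cell barcodes to clonotypes found
in reactivity sorts (4-1BB+ co-culture or MART1-dextramer), do reactive cells
fall into phenotype clusters at a different rate than cultured-TIL clonotypes
in general? For each cluster this is a two-sided exact binomial test of the
reactive cell count against the TIL-matching background frequency, with
Bonferroni adjustment across clusters.

Both exact tests use the minimum-likelihood ("minlike") two-sided rule: the
p-value sums the probabilities of all outcomes whose point probability does
not exceed that of the observed outcome, with the relative tie tolerance
``1 + 1e-7`` used by the standard reference implementations. The constant is
documented here and frozen: RELATIVE_TIE_TOLERANCE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln

from .errors import InputError
from .io_formats import CountMatrix

logger = logging.getLogger(__name__)

#: Outcomes with pmf <= pmf(observed) * RELATIVE_TIE_TOLERANCE are included in
#: the two-sided sum; absorbs floating-point asymmetry in exact ties.
RELATIVE_TIE_TOLERANCE = 1 + 1e-7

# log-factorial lookup (_LFACT[n] == log n!), grown on demand
_LFACT = gammaln(np.arange(1024, dtype=np.float64) + 1.0)


def _lfact(n: int) -> np.ndarray:
    """log-factorial table covering 0..n."""
    global _LFACT
    if n >= _LFACT.size:
        _LFACT = gammaln(np.arange(2 * n + 2, dtype=np.float64) + 1.0)
    return _LFACT


def exact_binomial_test(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial test of ``x`` successes in ``n`` trials vs ``p0``.

    Implements the minimum-likelihood rule by full enumeration of the
    Binomial(n, p0) pmf. Equivalent to R's ``binom.test`` two-sided p-value.

    Degenerate nulls (p0 in {0, 1}) give p = 1 for the certain outcome and
    p = 0 otherwise.
    """
    x, n = int(x), int(n)
    if not 0 <= x <= n:
        raise InputError(f"x={x} outside [0, n={n}]")
    if not 0.0 <= p0 <= 1.0:
        raise InputError(f"p0={p0} outside [0, 1]")
    if p0 == 0.0:
        return 1.0 if x == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if x == n else 0.0
    k = np.arange(n + 1)
    lg = _lfact(n)
    logpmf = lg[n] - lg[k] - lg[n - k] + k * np.log(p0) + (n - k) * np.log1p(-p0)
    pmf = np.exp(logpmf)
    p = pmf[pmf <= pmf[x] * RELATIVE_TIE_TOLERANCE].sum()
    return float(min(1.0, p))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample odds ratio
    ``(a*d)/(b*c)`` for table ``[[a, b], [c, d]]`` — ``inf`` when ``b*c == 0``
    and ``a*d > 0``, ``nan`` when both products are 0. The p-value follows the
    minimum-likelihood rule over the hypergeometric distribution with the
    table's margins fixed.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise InputError("negative entry in 2x2 table")
    if not np.all(np.equal(np.mod(t, 1), 0)):
        raise InputError("non-integer entry in 2x2 table")
    a, b, c, d = (int(v) for v in t.ravel())
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = float("nan") if ad == 0 else float("inf")
    else:
        odds_ratio = ad / bc
    r1, c1, total = a + b, a + c, a + b + c + d
    if total == 0 or r1 == 0 or r1 == total or c1 == 0 or c1 == total:
        return odds_ratio, 1.0  # a degenerate margin: only one table possible
    lo, hi = max(0, r1 + c1 - total), min(r1, c1)
    k = np.arange(lo, hi + 1)
    lg = _lfact(total)
    # log C(c1, k) + log C(total-c1, r1-k); the common log C(total, r1) cancels
    logw = lg[c1] - lg[k] - lg[c1 - k] + lg[total - c1] - lg[r1 - k] - lg[total - c1 - r1 + k]
    w = np.exp(logw - logw.max())
    w_obs = w[a - lo]
    p = w[w <= w_obs * RELATIVE_TIE_TOLERANCE].sum() / w.sum()
    return odds_ratio, float(min(1.0, p))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise InputError("p-values outside [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class EnrichmentResult:
    """Per-cluster attribution of reactive cells vs the TIL background.

    ``delta`` is the matching-minus-nonmatching frequency difference: the
    fraction of reactive cells in the cluster minus the fraction of
    non-reactive (clonotyped) cells in the cluster.
    """

    cluster: str
    x: int
    n: int
    p0: float
    p_two_sided: float
    p_bonf: float
    direction: str  # over / under / none
    delta: float
    degenerate_background: bool = False


def category_frequencies(cells: pd.DataFrame, clusters=None) -> dict[str, pd.DataFrame]:
    """Per-category cluster frequencies.

    A category's frequency in a cluster is the number of its cells in the
    cluster divided by the category's total cell count. Requires columns
    ``cluster`` and ``category``; clusters absent for a category appear with
    frequency 0. Categories with zero cells are skipped with a warning.
    """
    for col in ("cluster", "category"):
        if col not in cells.columns:
            raise InputError(f"cells table missing column {col!r}")
    if clusters is None:
        clusters = sorted(cells["cluster"].astype(str).unique())
    out: dict[str, pd.DataFrame] = {}
    for category, sub in cells.groupby("category"):
        total = len(sub)
        if total == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("category %s has no cells; skipped", category)
            continue
        n = sub["cluster"].astype(str).value_counts().reindex(clusters, fill_value=0)
        out[str(category)] = pd.DataFrame(
            {
                "cluster": clusters,
                "n_cells": n.to_numpy(),
                "frequency": n.to_numpy() / total,
                "total_cells": total,
            }
        )
    return out


def reactive_cluster_enrichment(
    cells: pd.DataFrame,
    reactive_keys: set,
    til_keys: set,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each cluster for over/under-representation of reactive clonotypes.

    Parameters
    ----------
    cells
        Clonotyped cells: columns ``cluster`` and ``key`` (a hashable
        clonotype key). Only cells with an assembled TRB key belong here; both
        the reactive counts and the background are defined on clonotype-matched
        cells.
    reactive_keys
        Clonotype keys recovered from reactivity sorts.
    til_keys
        Clonotype keys observed in the TIL cultures; TIL-matching cells define
        the background frequency p0 per cluster.
    alpha
        Significance level used only to annotate direction of significant
        results; p-values are reported regardless.

    For each cluster: x = reactive cells in the cluster, n = total reactive
    cells, p0 = fraction of TIL-matching cells in the cluster; two-sided exact
    binomial p, Bonferroni-adjusted across all clusters tested. Clusters with
    p0 = 0 and x > 0 are still tested and flagged ``degenerate_background``.
    """
    for col in ("cluster", "key"):
        if col not in cells.columns:
            raise InputError(f"cells table missing column {col!r}")
    clusters = sorted(cells["cluster"].astype(str).unique())
    key = cells["key"]
    cluster = cells["cluster"].astype(str)

    reactive_mask = key.isin(reactive_keys).to_numpy()
    til_mask = key.isin(til_keys).to_numpy()
    nonmatching_mask = ~reactive_mask

    n = int(reactive_mask.sum())
    n_til = int(til_mask.sum())
    n_nonmatch = int(nonmatching_mask.sum())
    if n == 0:
        raise InputError("no cells match reactive_keys")
    if n_til == 0:
        raise InputError("no cells match til_keys; background undefined")

    results = []
    pvals = []
    for cl in clusters:
        in_cl = (cluster == cl).to_numpy()
        x = int((in_cl & reactive_mask).sum())
        p0 = float((in_cl & til_mask).sum() / n_til)
        p = exact_binomial_test(x, n, p0)
        freq_match = x / n
        freq_nonmatch = (in_cl & nonmatching_mask).sum() / n_nonmatch if n_nonmatch else 0.0
        pvals.append(p)
        results.append(
            EnrichmentResult(
                cluster=cl,
                x=x,
                n=n,
                p0=p0,
                p_two_sided=p,
                p_bonf=np.nan,
                direction="none",
                delta=float(freq_match - freq_nonmatch),
                degenerate_background=(p0 == 0.0 and x > 0),
            )
        )
    adjusted = bonferroni(pvals)
    for res, p_adj in zip(results, adjusted):
        res.p_bonf = float(p_adj)
        if p_adj < alpha:
            frac = res.x / res.n
            res.direction = "over" if frac > res.p0 else ("under" if frac < res.p0 else "none")
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as a flat DataFrame (the on-disk TSV schema)."""
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "x": [r.x for r in results],
            "n": [r.n for r in results],
            "p0": [r.p0 for r in results],
            "p": [r.p_two_sided for r in results],
            "p_bonf": [r.p_bonf for r in results],
            "direction": [r.direction for r in results],
            "delta": [r.delta for r in results],
            "degenerate_background": [r.degenerate_background for r in results],
        }
    )


def pseudobulk_aggregate(
    counts: CountMatrix, cells: pd.DataFrame, group_by="sample"
) -> pd.DataFrame:
    """Sum counts per gene across all cells in each group (pseudo-bulk).

    ``group_by`` names one or more columns of ``cells``; every cell in
    ``counts`` must appear in ``cells`` and be assigned to exactly one group.
    Returns a genes-by-groups DataFrame whose grand total equals the input's.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    cells = cells.set_index("barcode") if "barcode" in cells.columns else cells
    missing = [b for b in counts.barcodes if b not in cells.index]
    if missing:
        raise InputError(
            f"{len(missing)} cells have no group assignment (e.g. {missing[0]!r})"
        )
    labels = cells.loc[counts.barcodes, group_by].astype(str).agg("|".join, axis=1)
    groups = sorted(labels.unique())
    gidx = {g: i for i, g in enumerate(groups)}
    col = np.array([gidx[g] for g in labels])
    # indicator (n_groups x n_cells) @ counts (n_cells x n_genes)
    ind = sparse.csr_matrix(
        (np.ones(len(col), dtype=np.int64), (col, np.arange(len(col)))),
        shape=(len(groups), len(counts.barcodes)),
    )
    agg = (ind @ counts.counts).T.toarray()
    return pd.DataFrame(agg, index=counts.features["feature_id"].to_numpy(), columns=groups)
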