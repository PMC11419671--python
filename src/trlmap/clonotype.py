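"""Clonotype keys, cross-assay matching, and repertoire summaries.

A clonotype is identified by the triple (CDR3β amino-acid sequence, Vβ gene,
Jβ gene) — the minimal combination available in both single-cell V(D)J data
and bulk TCRβ sequencing, since bulk protocols do not pair α and β chains.
Matching is exact string equality on the triple, after stripping allele
suffixes (``*01``) so that gene calls from different profilers are comparable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .io_formats import ChainRecord


class ClonotypeKey(NamedTuple):
    """(CDR3β amino acids, Vβ gene, Jβ gene), allele-stripped."""

    cdr3b_aa: str
    vb: str
    jb: str


def strip_allele(gene: str) -> str:
    """Drop an IMGT allele suffix: ``TRBV7-9*01`` -> ``TRBV7-9``."""
    return gene.split("*", 1)[0]


def make_key(cdr3b_aa: str, v_gene: str, j_gene: str) -> ClonotypeKey:
    if not cdr3b_aa or not v_gene or not j_gene:
        raise InputError("clonotype key fields must be non-empty")
    return ClonotypeKey(cdr3b_aa, strip_allele(v_gene), strip_allele(j_gene))


@dataclass
class CellClonotype:
    """Per-barcode clonotype summary.

    ``key`` is absent (None) iff the barcode has no productive TRB chain.
    ``multi_alpha`` cells (more than one productive TRA) are excluded only
    from specificity-group preparation, not from matching.
    """

    barcode: str
    sample: str
    key: ClonotypeKey | None
    n_tra: int
    n_trb: int

    @property
    def multi_alpha(self) -> bool:
        return self.n_tra > 1


def build_cell_clonotypes(chains: Iterable[ChainRecord]) -> list[CellClonotype]:
    """Collapse productive chains into one clonotype record per barcode.

    With several productive TRB chains, the key comes from the TRB with the
    highest UMI count; ties break to the lexicographically smallest CDR3.
    """
    grouped: dict[tuple[str, str], list[ChainRecord]] = defaultdict(list)
    for ch in chains:
        if ch.productive:
            grouped[(ch.barcode, ch.sample)].append(ch)

    out = []
    for (barcode, sample), recs in sorted(grouped.items()):
        tra = [r for r in recs if r.locus == "TRA"]
        trb = [r for r in recs if r.locus == "TRB"]
        key = None
        if trb:
            best = min(trb, key=lambda r: (-r.umis, r.cdr3_aa))
            key = make_key(best.cdr3_aa, best.v_gene, best.j_gene)
        out.append(CellClonotype(barcode, sample, key, len(tra), len(trb)))
    return out


def keys_from_bulk_table(df: pd.DataFrame) -> set[ClonotypeKey]:
    """Clonotype keys from a bulk TCR-seq table.

    Expects columns ``cdr3b_aa``, ``v_gene``, ``j_gene`` and (optionally)
    ``read_count``; presence is binary, any positive read count counts.
    """
    for col in ("cdr3b_aa", "v_gene", "j_gene"):
        if col not in df.columns:
            raise FormatError(f"bulk clonotype table missing column {col!r}")
    if "read_count" in df.columns:
        df = df[df["read_count"] > 0]
    return {
        make_key(r.cdr3b_aa, r.v_gene, r.j_gene) for r in df.itertuples(index=False)
    }


def match_clonotypes(set_a: Iterable[ClonotypeKey], set_b: Iterable[ClonotypeKey]) -> set[ClonotypeKey]:
    """Exact intersection of two clonotype key collections (as sets)."""
    return set(set_a) & set(set_b)


def sharing_matrix(samples: Mapping[str, Iterable[ClonotypeKey]]) -> pd.DataFrame:
    """Square matrix of shared unique-clonotype counts between samples.

    Entry (i, j) counts unique keys present in both samples; the diagonal is
    each sample's unique-key count. Symmetric by construction.
    """
    if not samples:
        raise InputError("sharing_matrix needs at least one sample")
    names = sorted(samples)
    uniq = {s: set(samples[s]) for s in names}
    mat = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            mat[i, j] = len(uniq[a] & uniq[b]) if i != j else len(uniq[a])
    return pd.DataFrame(mat, index=names, columns=names)


def top_clonotypes(cells: Iterable[CellClonotype], n: int = 10) -> pd.DataFrame:
    """The ``n`` most abundant clonotypes by cell count.

    Frequencies are relative to cells carrying a key; ties in count break
    lexicographically on the key.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    counts = Counter(c.key for c in cells if c.key is not None)
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(
        {
            "cdr3b_aa": [k.cdr3b_aa for k, _ in ranked],
            "v_gene": [k.vb for k, _ in ranked],
            "j_gene": [k.jb for k, _ in ranked],
            "n_cells": [c for _, c in ranked],
            "frequency": [c / total for _, c in ranked],
        }
    )


def filter_specificity_clusters(
    rows: pd.DataFrame,
    max_bias: float = 0.05,
    min_tcrs: int = 3,
    min_individuals: int = 3,
) -> pd.DataFrame:
    """High-confidence subset of specificity-grouping (GLIPH2-style) clusters.

    Keep a cluster iff its V-gene bias score is below ``max_bias`` AND it has
    at least ``min_tcrs`` unique TCRs AND at least ``min_individuals`` unique
    contributing individuals.
    """
    required = ["cluster_id", "vgene_bias_score", "n_unique_tcrs", "n_individuals"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise FormatError(f"specificity cluster table missing column(s) {missing}")
    keep = (
        (rows["vgene_bias_score"] < max_bias)
        & (rows["n_unique_tcrs"] >= min_tcrs)
        & (rows["n_individuals"] >= min_individuals)
    )
    return rows[keep]
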