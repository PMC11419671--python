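"""Readers, writers, and the shared data model.

Data model
----------
``CountMatrix``
    Sparse cell-by-gene counts with barcode and feature indices, the in-memory
    form of a 10x-style Matrix Market triplet (matrix.mtx + barcodes.tsv +
    features.tsv). MTX files are 1-based on disk; indices are converted to
    0-based in memory.
``CellTable``
    A :class:`pandas.DataFrame` with one row per cell and the columns listed in
    :data:`CELL_TABLE_COLUMNS` (barcode, sample, QC metrics, cluster label,
    doublet flag, optional category).
``ChainRecord``
    One productive TCR chain from single-cell V(D)J assembly; the raw material
    for clonotype keys.

Barcodes are opaque strings: the 10x ``-1`` suffix is preserved, never
stripped, so matching between tables is exact and reversible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

#: Required columns of a cell metadata table.
CELL_TABLE_COLUMNS = [
    "barcode",
    "sample",
    "n_umi",
    "n_genes",
    "pct_mito",
    "pct_ribo",
    "pct_top100",
    "cluster",
    "doublet_flag",
]


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer cell-by-gene count matrix.

    Parameters
    ----------
    barcodes
        Ordered cell barcodes (rows). Unique within a sample.
    features
        DataFrame with columns ``feature_id`` and ``symbol`` (columns = genes).
        Marker rules address genes by symbol; duplicate symbols resolve to the
        union of matching columns.
    counts
        ``scipy.sparse`` matrix of shape (n_cells, n_genes), integer dtype.
    """

    barcodes: list[str]
    features: pd.DataFrame
    counts: sparse.spmatrix

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if self.counts.nnz:
            data = self.counts.data
            if np.any(data < 0):
                raise FormatError("negative entry in count matrix")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise FormatError("non-integer entry in count matrix")
        self.counts = self.counts.astype(np.int64)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        """Sum of all entries."""
        return int(self.counts.sum())

    def columns_for_symbol(self, symbol: str) -> np.ndarray:
        """0-based column indices whose gene symbol equals ``symbol``."""
        return np.flatnonzero((self.features["symbol"] == symbol).to_numpy())

    def row_index(self) -> pd.Index:
        return pd.Index(self.barcodes, name="barcode")

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        """Restrict to the given barcodes, preserving their given order."""
        pos = {b: i for i, b in enumerate(self.barcodes)}
        try:
            rows = [pos[b] for b in barcodes]
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"unknown barcode {exc.args[0]!r}") from exc
        return CountMatrix(list(barcodes), self.features, self.counts[rows])

    def to_anndata(self):
        """Interoperability: return the matrix as an :class:`anndata.AnnData`."""
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        var = self.features.set_index("feature_id")
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)


@dataclass(frozen=True)
class ChainRecord:
    """A single productive TCR chain for one cell barcode."""

    barcode: str
    sample: str
    locus: str  # TRA or TRB
    cdr3_aa: str
    v_gene: str
    j_gene: str
    umis: int
    productive: bool = True

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise FormatError(f"invalid locus {self.locus!r}")
        if self.productive and not self.cdr3_aa:
            raise FormatError("productive chain with empty CDR3")


def read_counts_mtx(matrix_path, barcodes_path, features_path) -> CountMatrix:
    """Read a 10x-style MTX triplet (matrix + barcodes + features).

    The MTX file is 1-based on disk; indices are 0-based in the returned
    matrix. The declared dimensions must match the barcode and feature list
    lengths, and all entries must be nonnegative integers.
    """
    try:
        mat = mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    barcodes = _read_single_column(barcodes_path)
    features = _read_features(features_path)
    mat = sparse.coo_matrix(mat)
    if mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"MTX declares shape {mat.shape} but barcode/feature lists have "
            f"lengths {len(barcodes)}/{len(features)}"
        )
    return CountMatrix(barcodes, features, mat)


def write_counts_mtx(cm: CountMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write a CountMatrix as an MTX triplet (the layout read_counts_mtx reads)."""
    mmwrite(str(matrix_path), sparse.coo_matrix(cm.counts), field="integer")
    with open(barcodes_path, "w", encoding="utf-8") as fh:
        fh.writelines(b + "\n" for b in cm.barcodes)
    cm.features.to_csv(features_path, sep="\t", index=False, header=False)


def _read_single_column(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_features(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fid = parts[0]
            symbol = parts[1] if len(parts) > 1 else parts[0]
            rows.append((fid, symbol))
    return pd.DataFrame(rows, columns=["feature_id", "symbol"])


# Mandatory columns per V(D)J dialect.
_TENX_COLUMNS = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "umis", "productive"]
_AIRR_COLUMNS = ["cell_id", "locus", "junction_aa", "v_call", "j_call"]

_TRUTHY = {"true", "t", "yes", "1", "1.0"}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def read_vdj_contigs(path, dialect: str = "tenx_csv", sample: str = "") -> list[ChainRecord]:
    """Read TCR contig annotations in 10x CSV or AIRR rearrangement TSV form.

    Only productive TRA/TRB rows are kept; dropped rows are counted in the log.
    Missing mandatory columns raise :class:`FormatError`.
    """
    if dialect == "tenx_csv":
        df = pd.read_csv(path)
        _require_columns(df, _TENX_COLUMNS, path)
        df = df.rename(
            columns={"chain": "locus", "cdr3": "cdr3_aa", "barcode": "barcode"}
        )
    elif dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, _AIRR_COLUMNS, path)
        df = df.rename(
            columns={
                "cell_id": "barcode",
                "junction_aa": "cdr3_aa",
                "v_call": "v_gene",
                "j_call": "j_gene",
            }
        )
        if "productive" not in df.columns:
            df["productive"] = True
        if "umis" not in df.columns:
            # AIRR reports duplicate_count; fall back to 1 when absent
            df["umis"] = df.get("duplicate_count", 1)
    else:
        raise FormatError(f"unknown V(D)J dialect {dialect!r}")

    n_in = len(df)
    productive = df["productive"].map(_as_bool)
    locus_ok = df["locus"].isin(["TRA", "TRB"])
    keep = productive & locus_ok & df["cdr3_aa"].notna() & (df["cdr3_aa"] != "")
    dropped = n_in - int(keep.sum())
    if dropped:
        logger.info("read_vdj_contigs: dropped %d non-productive/other-locus rows", dropped)
    df = df[keep]
    records = [
        ChainRecord(
            barcode=str(r.barcode),
            sample=sample,
            locus=str(r.locus),
            cdr3_aa=str(r.cdr3_aa),
            v_gene=str(r.v_gene),
            j_gene=str(r.j_gene),
            umis=int(r.umis) if not pd.isna(r.umis) else 0,
            productive=True,
        )
        for r in df.itertuples(index=False)
    ]
    return records


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def write_table(records, path) -> None:
    """Write records (DataFrame or a sequence of dataclasses) as a TSV file.

    Output is tab-separated UTF-8 with a header row and round-trips through
    :func:`read_table` losslessly for the schemas used in this package.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and hasattr(records[0], "__dataclass_fields__"):
            df = pd.DataFrame([asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def make_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cell metadata table.

    Enforces the CellTable invariants: required columns, percentages within
    [0, 100], ``n_genes <= n_umi``, and unique (barcode, sample) pairs.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing column(s) {missing}")
    df = df.copy()
    for col in ("pct_mito", "pct_ribo", "pct_top100"):
        bad = (df[col] < 0) | (df[col] > 100)
        if bad.any():
            raise FormatError(f"{col} outside [0, 100] for {int(bad.sum())} cells")
    if (df["n_genes"] > df["n_umi"]).any():
        raise FormatError("n_genes exceeds n_umi for some cells")
    if df.duplicated(subset=["barcode", "sample"]).any():
        raise FormatError("(barcode, sample) pairs are not unique")
    df["doublet_flag"] = df["doublet_flag"].map(_as_bool)
    return df


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell metadata TSV."""
    return make_cell_table(read_table(path))
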