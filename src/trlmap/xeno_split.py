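"""Host/graft classification of PDX cell barcodes.

Patient-derived xenograft single-cell libraries mix human (graft) and mouse
(host) transcripts. Upstream alignment yields, per cellular barcode, the
number of reads assigned to each species; here each barcode's host-read
fraction ``host / (host + graft)`` is banded into graft, host, or ambiguous.

Thresholds are bounds on the HOST-read fraction: the default graft band
[0, 0.1] keeps barcodes that are at most 10% mouse, the host band [0.9, 1.0]
barcodes at least 90% mouse, mirroring the threshold semantics of the
alignment-based classification tools this step consumes. Band ends are
inclusive on both sides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


def compute_species_fractions(read_counts: pd.DataFrame) -> pd.DataFrame:
    """Compute each barcode's host-read fraction.

    ``read_counts`` needs columns ``barcode``, ``host_reads``, ``graft_reads``
    (nonnegative integers). Barcodes with zero total reads get ``NaN`` and are
    excluded from downstream classification.
    """
    for col in ("barcode", "host_reads", "graft_reads"):
        if col not in read_counts.columns:
            raise InputError(f"read counts table missing column {col!r}")
    host = read_counts["host_reads"].to_numpy(dtype=float)
    graft = read_counts["graft_reads"].to_numpy(dtype=float)
    if np.any(host < 0) or np.any(graft < 0):
        raise InputError("negative read count")
    total = host + graft
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, host / total, np.nan)
    out = read_counts[["barcode", "host_reads", "graft_reads"]].copy()
    out["host_fraction"] = frac
    return out


def classify_barcodes(
    fractions: pd.DataFrame,
    graft_band: tuple[float, float] = (0.0, 0.1),
    host_band: tuple[float, float] = (0.9, 1.0),
) -> pd.DataFrame:
    """Label each classified barcode graft, host, or ambiguous.

    A barcode is graft iff its host fraction lies in ``graft_band`` (inclusive
    ends), host iff in ``host_band``, otherwise ambiguous. Barcodes with an
    undefined fraction (zero total reads) are dropped. The three labels
    partition all classified barcodes.
    """
    for band, name in ((graft_band, "graft_band"), (host_band, "host_band")):
        lo, hi = band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"{name}={band} not within [0, 1]")
    if max(graft_band[0], host_band[0]) <= min(graft_band[1], host_band[1]):
        raise ConfigError(f"bands {graft_band} and {host_band} overlap")

    out = fractions.dropna(subset=["host_fraction"]).copy()
    f = out["host_fraction"].to_numpy()
    label = np.full(len(out), "ambiguous", dtype=object)
    label[(f >= graft_band[0]) & (f <= graft_band[1])] = "graft"
    label[(f >= host_band[0]) & (f <= host_band[1])] = "host"
    out["label"] = label
    return out


def classification_summary(labeled: pd.DataFrame) -> dict:
    """Per-label barcode counts for the run report."""
    counts = labeled["label"].value_counts().to_dict()
    return {lab: int(counts.get(lab, 0)) for lab in ("graft", "host", "ambiguous")}
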