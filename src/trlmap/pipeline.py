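"""End-to-end orchestration: species split -> QC -> clonotyping -> enrichment
-> pseudo-bulk.

``run_pipeline`` consumes a :class:`RunConfig` (loadable from YAML), executes
the enabled stages in order, writes each stage's outputs as TSV/JSON under the
output directory, and returns a run report. Identical config + seed produce
byte-identical outputs (the report carries no timestamps). A stage failure
aborts the run with the failing stage named; a ``<stage>.partial`` marker file
is left behind for the interrupted stage.

``make_demo`` writes a small fully synthetic workspace (data files + a config)
that exercises every stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonotype as ct
from . import enrichment as en
from . import io_formats as io
from . import qc_filtering as qc
from . import synthetic_data as syn
from . import xeno_split as xs
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage substream seed (< 2**31) from the global seed."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (global_seed * 2654435761 + h) % (2**31 - 1)


@dataclass
class RunConfig:
    """Validated pipeline run configuration (see the demo config for layout)."""

    outdir: str
    seed: int = 0
    matrix: str | None = None
    barcodes: str | None = None
    features: str | None = None
    cells: str | None = None
    vdj: str | None = None
    vdj_dialect: str = "tenx_csv"
    reactive_bulk: str | None = None
    til_bulk: str | None = None
    xeno: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "xenosplit": True,
            "qc": True,
            "clonotype": True,
            "enrichment": True,
            "pseudobulk": True,
        }
    )
    qc_profile: str = "biopsy"
    qc_rescue: bool = False
    fisher_or_direction: str = "over"
    graft_band: tuple[float, float] = (0.0, 0.1)
    host_band: tuple[float, float] = (0.9, 1.0)
    pseudobulk_group_by: str = "sample"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        for band in ("graft_band", "host_band"):
            setattr(cfg, band, tuple(getattr(cfg, band)))
        return cfg

    def validate_paths(self) -> None:
        for name in ("matrix", "barcodes", "features", "cells", "vdj", "reactive_bulk", "til_bulk", "xeno"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input {name!r} path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns the report (also written to report.json)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    state: dict = {}

    def run_stage(name, enabled, fn):
        if not enabled:
            report["stages"][name] = {"status": "skipped"}
            return
        marker = outdir / f"{name}.partial"
        marker.touch()
        try:
            summary = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        marker.unlink()
        summary["status"] = "complete"
        report["stages"][name] = summary

    run_stage("load", True, lambda: _stage_load(config, state))
    run_stage(
        "xenosplit",
        config.stages.get("xenosplit", True) and config.xeno is not None,
        lambda: _stage_xenosplit(config, state, outdir),
    )
    run_stage("qc", config.stages.get("qc", True), lambda: _stage_qc(config, state, outdir))
    run_stage(
        "clonotype",
        config.stages.get("clonotype", True),
        lambda: _stage_clonotype(config, state, outdir),
    )
    run_stage(
        "enrichment",
        config.stages.get("enrichment", True) and config.reactive_bulk is not None,
        lambda: _stage_enrichment(config, state, outdir),
    )
    run_stage(
        "pseudobulk",
        config.stages.get("pseudobulk", True),
        lambda: _stage_pseudobulk(config, state, outdir),
    )

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_load(config: RunConfig, state: dict) -> dict:
    counts = io.read_counts_mtx(config.matrix, config.barcodes, config.features)
    cells = io.read_cell_table(config.cells)
    chains = io.read_vdj_contigs(config.vdj, config.vdj_dialect) if config.vdj else []
    # cells table governs; matrix restricted to its barcodes
    counts = counts.subset_cells([b for b in counts.barcodes if b in set(cells["barcode"])])
    state.update(counts=counts, cells=cells, chains=chains)
    return {"n_cells": len(cells), "n_genes": counts.shape[1], "n_chains": len(chains)}


def _stage_xenosplit(config: RunConfig, state: dict, outdir: Path) -> dict:
    reads = io.read_table(config.xeno)
    labeled = xs.classify_barcodes(
        xs.compute_species_fractions(reads), config.graft_band, config.host_band
    )
    io.write_table(labeled, outdir / "xeno_labels.tsv")
    graft = set(labeled.loc[labeled["label"] == "graft", "barcode"])
    cells = state["cells"]
    keep = cells["barcode"].isin(graft)
    state["cells"] = cells[keep]
    state["counts"] = state["counts"].subset_cells(list(state["cells"]["barcode"]))
    state["chains"] = [c for c in state["chains"] if c.barcode in graft]
    summary = xs.classification_summary(labeled)
    summary["n_cells_retained"] = int(keep.sum())
    return summary


def _stage_qc(config: RunConfig, state: dict, outdir: Path) -> dict:
    counts, cells, chains = state["counts"], state["cells"], state["chains"]
    profile = qc.PROFILES.get(config.qc_profile)
    if profile is None:
        raise ConfigError(f"unknown QC profile {config.qc_profile!r}")

    conflicts = qc.flag_lineage_conflicts(counts, chains)
    cells = cells.copy()
    cells["doublet_flag"] = (
        cells["doublet_flag"].to_numpy()
        | conflicts.reindex(cells["barcode"]).fillna(False).to_numpy()
    )

    filtered, filter_report = qc.apply_global_filters(cells, profile)
    io.write_table(filter_report.to_frame(), outdir / "filter_report.tsv")

    stats = qc.cluster_doublet_stats(filtered)
    io.write_table(stats, outdir / "doublet_cluster_stats.tsv")
    nominated = qc.nominate_doublet_clusters(
        stats, fisher_or_direction=config.fisher_or_direction
    )
    io.write_table(
        pd.DataFrame(
            {
                "cluster": sorted(nominated),
                "reasons": [",".join(sorted(nominated[c])) for c in sorted(nominated)],
            }
        ),
        outdir / "nominated_clusters.tsv",
    )

    retained = filtered[
        ~filtered["cluster"].astype(str).isin(nominated) & ~filtered["doublet_flag"]
    ]

    rescue_summaries = {}
    if config.qc_rescue:
        rescued_frames = []
        for spec in (qc.ERYTHROCYTE_SPEC, qc.PLASMA_SPEC):
            res = qc.rescue_low_rna_celltypes(counts, cells, spec)
            rescue_summaries[spec.name] = {
                "skipped": res.skipped,
                "n_candidates": len(res.candidates),
                "n_rescued": len(res.retained_barcodes),
                "q1_umi": res.q1_umi,
                "q1_genes": res.q1_genes,
            }
            add = cells[
                cells["barcode"].isin(res.retained_barcodes)
                & ~cells["barcode"].isin(retained["barcode"])
                & ~cells["doublet_flag"]
            ]
            rescued_frames.append(add)
        if rescued_frames:
            retained = pd.concat([retained, *rescued_frames], ignore_index=True)

    retained = retained.sort_values("barcode", kind="mergesort").reset_index(drop=True)
    io.write_table(retained, outdir / "qc_cells.tsv")

    state["cells"] = retained
    state["counts"] = counts.subset_cells(list(retained["barcode"]))
    keep_bc = set(retained["barcode"])
    state["chains"] = [c for c in state["chains"] if c.barcode in keep_bc]
    return {
        "n_in": filter_report.n_in,
        "n_after_global": filter_report.n_retained,
        "n_removed": filter_report.n_in - len(retained),
        "n_retained": len(retained),
        "nominated_clusters": sorted(nominated),
        "rescue": rescue_summaries,
    }


def _stage_clonotype(config: RunConfig, state: dict, outdir: Path) -> dict:
    cellclones = ct.build_cell_clonotypes(state["chains"])
    state["cellclones"] = cellclones
    rows = pd.DataFrame(
        {
            "barcode": [c.barcode for c in cellclones],
            "sample": [c.sample for c in cellclones],
            "cdr3b_aa": [c.key.cdr3b_aa if c.key else "" for c in cellclones],
            "v_gene": [c.key.vb if c.key else "" for c in cellclones],
            "j_gene": [c.key.jb if c.key else "" for c in cellclones],
            "n_tra": [c.n_tra for c in cellclones],
            "n_trb": [c.n_trb for c in cellclones],
            "multi_alpha": [c.multi_alpha for c in cellclones],
        }
    )
    io.write_table(rows, outdir / "clonotypes.tsv")

    sample_keys: dict[str, set] = {}
    for c in cellclones:
        if c.key is not None:
            sample_keys.setdefault(c.sample or "sc", set()).add(c.key)
    for name, attr in (("reactive_bulk", "reactive_bulk"), ("til_bulk", "til_bulk")):
        path = getattr(config, attr)
        if path:
            sample_keys[name] = ct.keys_from_bulk_table(io.read_table(path))
    state["sample_keys"] = sample_keys
    if sample_keys:
        share = ct.sharing_matrix(sample_keys)
        share.index.name = "sample"
        io.write_table(share.reset_index(), outdir / "sharing_matrix.tsv")
    io.write_table(ct.top_clonotypes(cellclones, n=10), outdir / "top_clonotypes.tsv")
    n_keys = sum(1 for c in cellclones if c.key is not None)
    return {"n_clonotyped_cells": n_keys, "n_multi_alpha": sum(c.multi_alpha for c in cellclones)}


def _stage_enrichment(config: RunConfig, state: dict, outdir: Path) -> dict:
    reactive_keys = ct.keys_from_bulk_table(io.read_table(config.reactive_bulk))
    til_keys = (
        ct.keys_from_bulk_table(io.read_table(config.til_bulk))
        if config.til_bulk
        else set(state["sample_keys"].get("til_bulk", set()))
    )
    cluster_of = state["cells"].set_index("barcode")["cluster"].astype(str)
    rows = [
        {"barcode": c.barcode, "cluster": cluster_of.get(c.barcode), "key": c.key}
        for c in state["cellclones"]
        if c.key is not None and c.barcode in cluster_of.index
    ]
    cells = pd.DataFrame(rows, columns=["barcode", "cluster", "key"])
    results = en.reactive_cluster_enrichment(cells, reactive_keys, til_keys)
    io.write_table(en.enrichment_table(results), outdir / "enrichment.tsv")

    cat = cells.copy()
    cat["category"] = np.where(
        cat["key"].isin(reactive_keys),
        "reactive",
        np.where(cat["key"].isin(til_keys), "TIL", "nonmatching"),
    )
    freqs = en.category_frequencies(cat)
    long = pd.concat(
        [df.assign(category=name) for name, df in sorted(freqs.items())],
        ignore_index=True,
    )
    io.write_table(long, outdir / "frequencies.tsv")
    over = [r.cluster for r in results if r.direction == "over"]
    return {
        "n_tested_clusters": len(results),
        "overrepresented_clusters": over,
        "n_reactive_cells": results[0].n if results else 0,
    }


def _stage_pseudobulk(config: RunConfig, state: dict, outdir: Path) -> dict:
    pb = en.pseudobulk_aggregate(state["counts"], state["cells"], config.pseudobulk_group_by)
    pb.index.name = "feature_id"
    io.write_table(pb.reset_index(), outdir / "pseudobulk.tsv")
    io.write_table(
        pd.DataFrame({"group": pb.columns, "n_umi": pb.sum(axis=0).to_numpy()}),
        outdir / "pseudobulk_groups.tsv",
    )
    return {"n_groups": pb.shape[1], "total_counts": int(pb.to_numpy().sum())}


#: Demo marker panel: named phenotype clusters with canonical markers. T-cell
#: clusters carry TCR chains; melanocytic/B/monocyte markers make cross-lineage
#: doublets detectable by the shipped lineage rules.
DEMO_PANEL = {
    "CD8_exhausted": ["CD3D", "CD8A", "LAG3"],
    "CD8_memory": ["CD3D", "CD8B", "IL7R"],
    "CD4": ["CD3D", "CD4", "CCR7"],
    "NK": ["NCR1", "NCAM1", "KLRD1"],
    "B": ["CD19", "MS4A1", "CD79A"],
    "Mono": ["CD14", "LYZ", "FCN1"],
    "Melanoma": ["MLANA", "PMEL", "TYR"],
    "Cycling": ["MKI67", "TOP2A", "UBE2C"],
}

DEMO_T_CLUSTERS = frozenset({"CD8_exhausted", "CD8_memory", "CD4"})


def demo_atlas_config(seed: int) -> syn.AtlasConfig:
    """The demo study conditions: 8 phenotype clusters, one planted doublet
    cluster, reactive clones concentrated in the exhausted CD8 cluster, and
    two low-RNA populations."""
    return syn.AtlasConfig(
        n_clusters=len(DEMO_PANEL),
        cells_per_cluster=110,
        n_genes=400,
        marker_panel=DEMO_PANEL,
        doublet_rate=0.03,
        doublet_cluster_ids=frozenset({"Cycling"}),
        doublet_cluster_rate=0.45,
        lowrna_celltypes=[
            syn.LowRNAPopulation(
                "erythrocyte", ("HBA1", "HBA2", "HBB"), n_cells=50, depth_scale=0.35
            ),
            syn.LowRNAPopulation(
                "plasma_cell",
                ("JCHAIN",),
                zero_markers=("IL3RA", "LILRA4"),
                n_cells=50,
                depth_scale=0.35,
            ),
        ],
        n_clonotypes=200,
        n_reactive_clonotypes=20,
        reactive_cluster_weights={"CD8_exhausted": 0.7, "CD8_memory": 0.2, "CD4": 0.1},
        background_cluster_weights=None,
        tcr_cluster_labels=DEMO_T_CLUSTERS,
        sample_name="demo1",
        seed=stage_seed(seed, "simulate"),
    )


def make_demo(seed: int, outdir) -> Path:
    """Write a synthetic demo workspace; returns the path of its config file.

    The workspace holds an MTX triplet, a cell table, a 10x-dialect V(D)J CSV,
    bulk reactive and TIL clonotype TSVs, a host/graft read-count TSV, the
    planted truth (JSON), and a config.yaml exercising every stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = demo_atlas_config(seed)
    counts, cells, chains, truth = syn.simulate_atlas(cfg)

    io.write_counts_mtx(
        counts, outdir / "matrix.mtx", outdir / "barcodes.tsv", outdir / "features.tsv"
    )
    io.write_table(cells, outdir / "cells.tsv")

    vdj = pd.DataFrame(
        {
            "barcode": [c.barcode for c in chains],
            "chain": [c.locus for c in chains],
            "v_gene": [c.v_gene for c in chains],
            "j_gene": [c.j_gene for c in chains],
            "cdr3": [c.cdr3_aa for c in chains],
            "umis": [c.umis for c in chains],
            "productive": ["true"] * len(chains),
        }
    )
    vdj.to_csv(outdir / "contigs.csv", index=False)

    reactive = syn.simulate_reactive_sort(truth, dropout=0.1, seed=stage_seed(seed, "sort"))
    io.write_table(reactive, outdir / "reactive_bulk.tsv")

    # TIL culture repertoire: most of the single-cell clonotype space plus all
    # reactive clonotypes (reactive cells are drawn from the TIL culture)
    rng = np.random.default_rng(stage_seed(seed, "til"))
    all_keys = sorted(set(truth.clone_assignment.values()))
    til_keys = [k for k in all_keys if rng.random() < 0.85] + sorted(truth.reactive_keys)
    til = pd.DataFrame(
        {
            "cdr3b_aa": [k.cdr3b_aa for k in til_keys],
            "v_gene": [k.vb for k in til_keys],
            "j_gene": [k.jb for k in til_keys],
            "read_count": rng.integers(1, 500, size=len(til_keys)),
        }
    ).drop_duplicates(subset=["cdr3b_aa", "v_gene", "j_gene"])
    io.write_table(til, outdir / "til_bulk.tsv")

    # species mixture: every atlas barcode is graft; extra host/ambiguous ones
    xeno_extra, _ = syn.simulate_xenograft_reads(0, 40, 15, 1000, seed=stage_seed(seed, "xeno"))
    rng_x = np.random.default_rng(stage_seed(seed, "xenograft"))
    host_reads = rng_x.integers(0, 60, size=len(counts.barcodes))
    xeno = pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "host_reads": host_reads,
            "graft_reads": 1000 - host_reads,
        }
    )
    io.write_table(pd.concat([xeno, xeno_extra], ignore_index=True), outdir / "xeno.tsv")

    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "doublet_clusters": sorted(truth.doublet_clusters),
                "enriched_clusters": sorted(truth.enriched_clusters),
                "n_doublets": len(truth.doublet_cells),
                "n_reactive_cells": len(truth.reactive_barcodes),
                "n_reactive_keys": len(truth.reactive_keys),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    run_cfg = {
        "outdir": str(outdir / "out"),
        "seed": seed,
        "matrix": str(outdir / "matrix.mtx"),
        "barcodes": str(outdir / "barcodes.tsv"),
        "features": str(outdir / "features.tsv"),
        "cells": str(outdir / "cells.tsv"),
        "vdj": str(outdir / "contigs.csv"),
        "vdj_dialect": "tenx_csv",
        "reactive_bulk": str(outdir / "reactive_bulk.tsv"),
        "til_bulk": str(outdir / "til_bulk.tsv"),
        "xeno": str(outdir / "xeno.tsv"),
        "qc_profile": "biopsy",
        "qc_rescue": True,
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return cfg_path
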