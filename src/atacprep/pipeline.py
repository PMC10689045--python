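"""End-to-end preprocessing driver configured from one YAML/TOML-style mapping.

Chains tag-bam -> fragments -> feature counting -> QC/cell calling -> bundle
save, with every parameter recorded in one provenance log.  Alignment and
bulk peak calling stay external: the pipeline consumes an aligned BAM whose
read names carry barcode prefixes (or CB tags already), and optionally a
peak BED from any MACS-style caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import read_chrom_sizes
from .bundle import ExperimentBundle, save_bundle
from .features import binarize, count_matrix, load_features, make_bins
from .fragments import (
    FragmentFilterConfig,
    bam_to_fragments,
    collapse,
    read_fragments,
    write_fragments,
)
from .qc import FilterThresholds, barcode_metrics, call_cells_filter, filter_matrix, qc_summary
from .tagging import tag_bam


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def run_pipeline(config: dict | str, outdir=None) -> dict:
    """Run the full preprocessing chain; returns the provenance/summary log.

    Required config keys: ``bam``, ``chrom_sizes``, ``outdir`` (overridable).
    Feature space: ``features.bed`` or ``features.bin_size``.  Optional
    sections: ``fragments`` (min_mapq, max_fragment_size, contig lists),
    ``qc`` (thresholds, mito_contigs), ``annotations`` (name -> BED path),
    ``binarize``, ``modality``, ``separator``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = read_chrom_sizes(config["chrom_sizes"])
    log: dict = {"version": __version__, "config": config}

    tagged_bam = outdir / "tagged.bam"
    log["tagging"] = tag_bam(
        config["bam"], tagged_bam, separator=config.get("separator", "#")
    )

    frag_cfg = FragmentFilterConfig(**config.get("fragments", {}))
    frags, frag_stats = bam_to_fragments(tagged_bam, frag_cfg)
    collapsed = collapse(frags)
    frag_path = outdir / "fragments.bed"
    write_fragments(collapsed, frag_path, chrom_order=list(chrom_sizes))
    frag_stats["n_fragments"] = len(collapsed)
    log["fragments"] = {
        "path": str(frag_path),
        "min_mapq": frag_cfg.min_mapq,
        "max_fragment_size": frag_cfg.max_fragment_size,
        "stats": frag_stats,
    }

    feat_cfg = config.get("features", {})
    if "bed" in feat_cfg:
        features = load_features(feat_cfg["bed"], chrom_sizes)
    else:
        features = make_bins(chrom_sizes, int(feat_cfg.get("bin_size", 2000)))
    log["features"] = {
        "origin": features.origin,
        "bin_size": features.bin_size,
        "n_features": len(features),
    }

    frag_df = read_fragments(frag_path)
    raw = count_matrix(frag_df, features)
    log["counting"] = {
        "shape": list(raw.shape),
        "skipped_fragments": raw.n_skipped_fragments,
    }

    qc_cfg = dict(config.get("qc", {}))
    mito = qc_cfg.pop("mito_contigs", None)
    thresholds = FilterThresholds(**qc_cfg)
    annotations = {
        name: load_features(path, chrom_sizes)
        for name, path in config.get("annotations", {}).items()
    }
    qc = barcode_metrics(frag_df, features, annotations or None, mito)
    cells, labelled = call_cells_filter(qc, thresholds)
    filtered = filter_matrix(raw, cells, thresholds)
    if config.get("binarize", True):
        filtered = binarize(filtered)
    log["cell_calling"] = {
        "thresholds": thresholds.__dict__,
        "n_called_cells": len(cells),
        "filtered_shape": list(filtered.shape),
    }

    col_meta = labelled.loc[filtered.barcodes]
    row_meta = pd.DataFrame(index=pd.Index(filtered.feature_ids, name="id"))
    bundle = ExperimentBundle(
        filtered, col_meta, row_meta, provenance=log,
        modality=config.get("modality", "ATAC"),
    )
    bundle_dir = outdir / "bundle"
    save_bundle(bundle, bundle_dir)
    log["bundle"] = str(bundle_dir)

    qc_summary(
        labelled, outdir, fragment_stats=frag_stats,
        parameters={"thresholds": thresholds.__dict__, **{
            k: v for k, v in config.items() if k not in ("qc",)
        }},
        plots=bool(config.get("plots", False)),
        html=bool(config.get("html", False)),
    )
    with open(outdir / "pipeline_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log
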