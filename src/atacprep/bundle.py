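"""On-disk experiment bundles and barcode-matched multimodal integration.

A bundle is the filtered feature × cell matrix plus aligned column (cell QC)
and row (feature) metadata and the full parameter provenance — the on-disk
equivalent of a SingleCellExperiment, laid out as MTX + TSV + JSON so any
standard single-cell loader can read it.  Integration combines bundles of
different modalities (e.g. multiome ATAC + RNA) over the union of their
barcodes; barcodes missing from a modality are marked absent in an explicit
presence mask — never zero-filled, since "no data" and "zero counts" are
different facts.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .features import SparseCountMatrix

_FILES = {
    "matrix": "matrix.mtx",
    "features": "features.tsv",
    "barcodes": "barcodes.tsv",
    "col_metadata": "col_metadata.tsv",
    "provenance": "provenance.json",
}


@dataclass
class ExperimentBundle:
    """A packaged experiment: matrix + aligned metadata + provenance."""

    matrix: SparseCountMatrix
    col_metadata: pd.DataFrame
    row_metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    modality: str = "ATAC"

    def __post_init__(self):
        if list(self.col_metadata.index) != list(self.matrix.barcodes):
            raise ValueError("col_metadata rows must match matrix columns 1:1, in order")
        if list(self.row_metadata.index) != list(self.matrix.feature_ids):
            raise ValueError("row_metadata rows must match matrix rows 1:1, in order")
        if len(set(self.matrix.barcodes)) != len(self.matrix.barcodes):
            raise ValueError("duplicated barcode within bundle")

    def to_anndata(self):
        """Cells-as-observations AnnData view (transposed from feature × cell)."""
        import anndata

        return anndata.AnnData(
            X=self.matrix.matrix.T.tocsr(),
            obs=self.col_metadata.copy(),
            var=self.row_metadata.copy(),
            uns={"provenance": self.provenance, "modality": self.modality},
        )


def save_bundle(bundle: ExperimentBundle, outdir) -> str:
    """Serialise a bundle as MTX + TSVs + JSON. Deterministic byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = bundle.matrix.matrix.tocoo()
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    (outdir / _FILES["matrix"]).write_bytes(buf.getvalue())
    bundle.row_metadata.to_csv(outdir / _FILES["features"], sep="\t")
    pd.Series(bundle.matrix.barcodes, name="barcode").to_csv(
        outdir / _FILES["barcodes"], sep="\t", index=False
    )
    bundle.col_metadata.to_csv(outdir / _FILES["col_metadata"], sep="\t")
    with open(outdir / _FILES["provenance"], "w") as fh:
        json.dump(
            {
                "modality": bundle.modality,
                "binarized": bundle.matrix.binarized,
                "provenance": bundle.provenance,
            },
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
    return str(outdir)


def load_bundle(indir) -> ExperimentBundle:
    """Inverse of :func:`save_bundle`; missing component files are named."""
    indir = Path(indir)
    for key, fname in _FILES.items():
        if not (indir / fname).exists():
            raise FileNotFoundError(f"bundle at {indir} is missing {fname}")
    mat = sp.csr_matrix(scipy.io.mmread(indir / _FILES["matrix"]), dtype=np.int64)
    row_meta = pd.read_csv(indir / _FILES["features"], sep="\t", index_col=0)
    bc = pd.read_csv(indir / _FILES["barcodes"], sep="\t")
    barcodes = bc.barcode.tolist() if len(bc) else []
    col_meta = pd.read_csv(indir / _FILES["col_metadata"], sep="\t", index_col=0)
    if len(col_meta) == 0 and barcodes == []:
        col_meta = col_meta.iloc[0:0]
    with open(indir / _FILES["provenance"]) as fh:
        prov = json.load(fh)
    scm = SparseCountMatrix(
        mat, [str(i) for i in row_meta.index], [str(b) for b in barcodes],
        binarized=bool(prov.get("binarized", False)),
    )
    col_meta.index = col_meta.index.astype(str)
    row_meta.index = row_meta.index.astype(str)
    return ExperimentBundle(
        scm, col_meta, row_meta, prov.get("provenance", {}),
        prov.get("modality", "ATAC"),
    )


def bundle_digest(bundle_dir) -> str:
    """SHA-256 of the MTX payload, for determinism checks."""
    return hashlib.sha256((Path(bundle_dir) / _FILES["matrix"]).read_bytes()).hexdigest()


@dataclass
class CombinedExperiment:
    """Bundles of several modalities over one unified barcode universe."""

    bundles: dict[str, ExperimentBundle]
    barcodes: list[str]
    presence: pd.DataFrame  # modalities × universe, bool
    col_metadata: pd.DataFrame  # universe-indexed, columns prefixed by modality

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode in combined universe")


def translate_barcodes(bundle: ExperimentBundle, table: dict[str, str]) -> ExperimentBundle:
    """Rename a bundle's barcodes through a two-column translation table.

    Used when modalities carry chemistry-specific barcodes that pair 1:1
    (e.g. multiome ATAC vs GEX barcodes).  Barcodes absent from the table
    keep their name; the mapping must stay injective on this bundle.
    """
    new = [table.get(b, b) for b in bundle.matrix.barcodes]
    if len(set(new)) != len(new):
        raise ValueError("barcode translation is not injective on this bundle")
    scm = SparseCountMatrix(
        bundle.matrix.matrix, list(bundle.matrix.feature_ids), new,
        binarized=bundle.matrix.binarized,
    )
    col_meta = bundle.col_metadata.copy()
    col_meta.index = new
    return ExperimentBundle(scm, col_meta, bundle.row_metadata,
                            bundle.provenance, bundle.modality)


def integrate(
    bundles: list[ExperimentBundle],
    translations: dict[str, dict[str, str]] | None = None,
) -> CombinedExperiment:
    """Outer-join bundles on their barcodes (multiome-style combination).

    The barcode universe is the union across bundles; per-modality column
    metadata is reindexed onto the universe side by side (NaN where a
    modality lacks the barcode) and the boolean presence mask records which
    (modality, barcode) pairs actually carry data.  Modality tags must be
    unique; the result is invariant to the order of the input bundles.
    ``translations`` optionally maps a modality's barcodes into the common
    space before joining.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    tags = [b.modality for b in bundles]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate modality tags: {tags}")
    if translations:
        bundles = [
            translate_barcodes(b, translations[b.modality])
            if b.modality in translations
            else b
            for b in bundles
        ]
    universe = sorted(set().union(*(set(b.matrix.barcodes) for b in bundles)))
    presence = pd.DataFrame(
        {
            b.modality: pd.Series(
                [bc in set(b.matrix.barcodes) for bc in universe], index=universe
            )
            for b in bundles
        }
    ).T
    presence.index.name = "modality"
    parts = []
    for b in bundles:
        meta = b.col_metadata.reindex(universe)
        meta.columns = [f"{b.modality}.{c}" for c in meta.columns]
        parts.append(meta)
    col_metadata = pd.concat(parts, axis=1)
    by_tag = {b.modality: b for b in sorted(bundles, key=lambda b: b.modality)}
    return CombinedExperiment(by_tag, universe, presence, col_metadata)


def save_combined(combined: CombinedExperiment, outdir) -> str:
    """Manifest + one bundle subdirectory per modality + the presence mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tag, b in combined.bundles.items():
        save_bundle(b, outdir / tag)
    combined.presence.to_csv(outdir / "presence.tsv", sep="\t")
    combined.col_metadata.to_csv(outdir / "col_metadata.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "modalities": sorted(combined.bundles),
                "n_barcodes": len(combined.barcodes),
                "barcodes_file": "col_metadata.tsv",
            },
            fh,
            indent=2,
        )
    return str(outdir)


def load_combined(indir) -> CombinedExperiment:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    bundles = [load_bundle(indir / tag) for tag in manifest["modalities"]]
    return integrate(bundles)
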