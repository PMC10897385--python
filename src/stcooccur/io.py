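"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices arrive either as a Matrix Market triplet directory
(matrix.mtx + barcodes.tsv + features.tsv, the Space Ranger layout) or a
dense CSV; deconvolution matrices, ligand-receptor tables, sample metadata
and segment tables are plain CSV; spot positions support both
tissue_positions dialects (headerless v1, headered v2).  All tabular outputs
are UTF-8 CSV with a fixed column order and round-trip exactly.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    DeconvolutionMatrix,
    LRPairTable,
    PresenceAbsenceMatrix,
    SampleMetadata,
    SegmentTable,
    SpotCountMatrix,
    SpotPositions,
)
from .cooccurrence import COOCCURRENCE_COLUMNS, CooccurrenceTable
from .errors import FormatError, ValidationError

_MTX_NAMES = ("matrix.mtx", "barcodes.tsv", "features.tsv")


def _read_lines(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_count_matrix(
    path, format: str = "mtx_triplet_dir", orientation: str = "auto"
) -> SpotCountMatrix:
    """Read a spot x gene count matrix.

    ``format="mtx_triplet_dir"``: a directory holding matrix.mtx,
    barcodes.tsv and features.tsv (features may have 1-3 tab-separated
    columns; the gene symbol is the second column when present, as in the
    Space Ranger layout).  On-disk orientation is inferred from the sidecar
    lengths and normalized to spots x genes.

    ``format="csv_dense"``: CSV with spot ids in the first column and gene
    symbols in the header; ``orientation="genes_by_spots"`` transposes.
    """
    path = Path(path)
    if format == "mtx_triplet_dir":
        if not path.is_dir():
            raise FormatError(f"{path} is not a directory")
        files = {name: path / name for name in _MTX_NAMES}
        for name, f in files.items():
            if not f.exists():
                raise FormatError(f"missing sidecar file {name} in {path}")
        mat = scipy.io.mmread(files["matrix.mtx"])
        barcodes = _read_lines(files["barcodes.tsv"])
        feature_rows = [
            line.split("\t") for line in _read_lines(files["features.tsv"])
        ]
        genes = [
            row[1] if len(row) >= 2 else row[0] for row in feature_rows
        ]
        nb, ng = len(barcodes), len(genes)
        if nb == ng and mat.shape == (nb, ng):
            mat = mat.T  # ambiguous square: assume genes x spots (Space Ranger)
        elif mat.shape == (ng, nb):
            mat = mat.T  # features x barcodes on disk, the common layout
        elif mat.shape == (nb, ng):
            pass
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither "
                f"({nb} barcodes, {ng} features) orientation"
            )
        return SpotCountMatrix(
            spot_ids=np.array(barcodes, dtype=object),
            gene_ids=np.array(genes, dtype=object),
            counts=sp.csr_matrix(mat),
        )
    if format == "csv_dense":
        df = pd.read_csv(path, index_col=0)
        if orientation == "genes_by_spots":
            df = df.T
        elif orientation not in ("auto", "spots_by_genes"):
            raise FormatError(f"unknown orientation {orientation!r}")
        return SpotCountMatrix(
            spot_ids=df.index.to_numpy(dtype=object),
            gene_ids=df.columns.to_numpy(dtype=object),
            counts=sp.csr_matrix(df.to_numpy()),
        )
    raise FormatError(f"unknown count-matrix format {format!r}")


def read_deconvolution_matrix(path) -> DeconvolutionMatrix:
    """Read a spot x cell-type probability CSV (header: cell types; first
    column: spot ids).  Entries outside [0, 1] raise; row sums below 1 only
    warn (thresholded topic models are often unnormalized)."""
    df = pd.read_csv(path, index_col=0)
    try:
        probs = df.to_numpy(dtype=float)
    except ValueError as exc:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}: {v!r}"
                    ) from exc
        raise FormatError(str(exc)) from exc
    return DeconvolutionMatrix(
        spot_ids=df.index.to_numpy(dtype=object),
        celltype_ids=df.columns.to_numpy(dtype=object),
        probs=probs,
    )


def read_lr_table(path) -> LRPairTable:
    """Read a ligand-receptor pair CSV (columns: ligand, receptor[, source]).
    Duplicate (ligand, receptor) rows are dropped with a warning."""
    return LRPairTable(pairs=pd.read_csv(path))


V1_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_positions(path, dialect: str = "auto") -> SpotPositions:
    """Read a Visium tissue_positions CSV.

    ``v1_headerless``: six unlabeled columns (barcode, in_tissue, array_row,
    array_col, pxl_row, pxl_col).  ``v2_header``: same data with a header
    row.  ``auto`` detects the header by looking for "barcode" in the first
    line.
    """
    path = Path(path)
    if dialect == "auto":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        dialect = "v2_header" if "barcode" in first.lower() else "v1_headerless"
    if dialect == "v1_headerless":
        df = pd.read_csv(path, header=None, names=V1_POSITION_COLUMNS)
    elif dialect == "v2_header":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {}
        for col in df.columns:
            if col.startswith("pxl_row"):
                rename[col] = "pxl_row_in_fullres"
            elif col.startswith("pxl_col"):
                rename[col] = "pxl_col_in_fullres"
        df = df.rename(columns=rename)
        missing = [c for c in V1_POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"positions file missing columns {missing}")
    else:
        raise FormatError(f"unknown positions dialect {dialect!r}")
    return SpotPositions(
        spot_ids=df["barcode"].to_numpy(dtype=object),
        in_tissue=df["in_tissue"].to_numpy(),
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        pixel_x=df["pxl_col_in_fullres"].to_numpy(),
        pixel_y=df["pxl_row_in_fullres"].to_numpy(),
    )


def read_metadata(path) -> SampleMetadata:
    """Read a metadata CSV (columns: spot_id, sample_id, condition)."""
    df = pd.read_csv(path)
    required = ["spot_id", "sample_id", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    per_sample = df[["sample_id", "condition"]].drop_duplicates()
    if per_sample["sample_id"].duplicated().any():
        bad = per_sample.loc[
            per_sample["sample_id"].duplicated(), "sample_id"
        ].tolist()
        raise ValidationError(f"samples with multiple conditions: {bad}")
    return SampleMetadata(
        spot_to_sample=pd.Series(
            df["sample_id"].to_numpy(), index=df["spot_id"].to_numpy()
        ),
        sample_to_condition=pd.Series(
            per_sample["condition"].to_numpy(),
            index=per_sample["sample_id"].to_numpy(),
        ),
    )


def read_segments(path) -> SegmentTable:
    """Read a segment CSV (segment_id, roi_id, x, y, per-gene counts)."""
    return SegmentTable(data=pd.read_csv(path))


def write_segments(segments: SegmentTable, path) -> None:
    segments.data.to_csv(path, index=False)


def write_presence_absence(pa: PresenceAbsenceMatrix, path) -> None:
    pa.to_frame().to_csv(path, index_label="site_id")


def read_presence_absence(path) -> PresenceAbsenceMatrix:
    df = pd.read_csv(path, index_col="site_id")
    return PresenceAbsenceMatrix(
        site_ids=df.index.to_numpy(dtype=object),
        entity_ids=df.columns.to_numpy(dtype=object),
        values=df.to_numpy(),
    )


def write_cooccurrence_table(table: CooccurrenceTable, path) -> None:
    """CSV with an ``# alpha=`` header line; round-trips exactly (floats are
    written with full repr precision)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# alpha={table.alpha!r}\n")
        table.data.to_csv(fh, index=False)


def read_cooccurrence_table(path) -> CooccurrenceTable:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# alpha="):
            raise FormatError("missing '# alpha=' header line")
        alpha = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    missing = [c for c in COOCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"co-occurrence CSV missing columns {missing}")
    df["classification"] = df["classification"].astype(object)
    return CooccurrenceTable(data=df, alpha=alpha)


def write_deconvolution_matrix(D: DeconvolutionMatrix, path) -> None:
    D.to_frame().to_csv(path, index_label="spot_id")


def write_count_matrix_csv(counts: SpotCountMatrix, path) -> None:
    pd.DataFrame(
        counts.dense(), index=counts.spot_ids, columns=counts.gene_ids
    ).to_csv(path, index_label="spot_id")
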