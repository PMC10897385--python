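"""Shared data model: count matrices, deconvolution probabilities,
presence-absence matrices, and the sidecar tables the pipeline consumes.

All containers are thin dataclasses around numpy / scipy.sparse / pandas
objects.  Validation happens at construction time so downstream code can
assume the invariants (unique identifiers, counts >= 0, probabilities in
[0, 1]) hold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

ROW_SUM_TOLERANCE = 1e-6


def _as_id_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if len(set(arr)) != len(arr):
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {name}: {dupes}")
    return arr


@dataclass
class SpotCountMatrix:
    """Spot x gene matrix of non-negative integer counts (sparse-friendly)."""

    spot_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self):
        self.spot_ids = _as_id_array(self.spot_ids, "spot ids")
        self.gene_ids = _as_id_array(self.gene_ids, "gene ids")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValidationError(
                f"count matrix shape {m.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if m.nnz:
            data = m.data
            if np.issubdtype(data.dtype, np.floating):
                if not np.allclose(data, np.round(data)):
                    bad = np.argwhere(~np.isclose(data, np.round(data)))[0]
                    coo = m.tocoo()
                    raise ValidationError(
                        "non-integer count at "
                        f"(spot {coo.row[bad[0]]}, gene {coo.col[bad[0]]})"
                    )
            if data.min() < 0:
                coo = m.tocoo()
                i = int(np.argmin(coo.data))
                raise ValidationError(
                    f"negative count at (spot {coo.row[i]}, gene {coo.col[i]})"
                )
        self.counts = m.astype(np.int64)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._spot_index = {s: i for i, s in enumerate(self.spot_ids)}

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_column(self, gene) -> np.ndarray:
        """Dense 1-D count vector for one gene across all spots."""
        return np.asarray(
            self.counts[:, self.gene_index(gene)].todense()
        ).ravel()

    def spot_indices(self, spot_ids) -> np.ndarray:
        missing = [s for s in spot_ids if s not in self._spot_index]
        if missing:
            raise KeyError(f"spots not in matrix: {missing[:5]}")
        return np.array([self._spot_index[s] for s in spot_ids], dtype=np.intp)

    def subset_spots(self, spot_ids) -> "SpotCountMatrix":
        idx = self.spot_indices(spot_ids)
        return SpotCountMatrix(
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            counts=self.counts[idx],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class DeconvolutionMatrix:
    """Spot x cell-type identity-probability matrix from upstream deconvolution.

    Entries are probabilities in [0, 1].  Row sums above 1 (plus tolerance)
    raise; row sums below 1 only warn, because reference-free topic models can
    be unnormalized after thresholding.
    """

    spot_ids: np.ndarray
    celltype_ids: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.spot_ids = _as_id_array(self.spot_ids, "spot ids")
        self.celltype_ids = _as_id_array(self.celltype_ids, "cell-type ids")
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.spot_ids), len(self.celltype_ids)):
            raise ValidationError(
                f"probability matrix shape {p.shape} does not match identifiers"
            )
        if not np.isfinite(p).all():
            raise ValidationError("non-finite probability entry")
        if (p < 0).any() or (p > 1).any():
            i, j = np.argwhere((p < 0) | (p > 1))[0]
            raise ValidationError(
                f"probability {p[i, j]} outside [0, 1] at "
                f"(spot {self.spot_ids[i]!r}, cell type {self.celltype_ids[j]!r})"
            )
        sums = p.sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_TOLERANCE
        if off.any():
            if (sums > 1 + ROW_SUM_TOLERANCE).any():
                i = int(np.argmax(sums))
                raise ValidationError(
                    f"row sum {sums[i]:.6f} > 1 for spot {self.spot_ids[i]!r}"
                )
            warnings.warn(
                f"{int(off.sum())} spot rows have probability sums below 1 "
                "(upstream deconvolution may be unnormalized)",
                stacklevel=2,
            )
        self.probs = p

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs, index=self.spot_ids, columns=self.celltype_ids
        )

    def subset_spots(self, spot_ids) -> "DeconvolutionMatrix":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        idx = np.array([index[s] for s in spot_ids], dtype=np.intp)
        return DeconvolutionMatrix(
            self.spot_ids[idx], self.celltype_ids, self.probs[idx]
        )


@dataclass
class PresenceAbsenceMatrix:
    """Binary site x entity matrix: the sole input of the co-occurrence model.

    Sites are Visium spots or cellular neighborhoods; entities are cell types
    or genes.
    """

    site_ids: np.ndarray
    entity_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.site_ids = _as_id_array(self.site_ids, "site ids")
        self.entity_ids = _as_id_array(self.entity_ids, "entity ids")
        v = np.asarray(self.values)
        if v.shape != (len(self.site_ids), len(self.entity_ids)):
            raise ValidationError("presence matrix shape mismatch")
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.isin(uniq, [0, 1]).all():
                raise ValidationError(
                    f"presence-absence entries must be 0/1, got {uniq[:5]}"
                )
            v = v.astype(bool)
        self.values = v
        self._entity_index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def column(self, entity) -> np.ndarray:
        try:
            return self.values[:, self._entity_index[entity]]
        except KeyError:
            raise KeyError(f"entity {entity!r} not in matrix") from None

    def presence_count(self, entity) -> int:
        return int(self.column(entity).sum())

    def subset_sites(self, site_ids) -> "PresenceAbsenceMatrix":
        index = {s: i for i, s in enumerate(self.site_ids)}
        idx = np.array([index[s] for s in site_ids], dtype=np.intp)
        return PresenceAbsenceMatrix(
            self.site_ids[idx], self.entity_ids, self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.site_ids,
            columns=self.entity_ids,
        )


@dataclass
class SpotPositions:
    """Visium spot coordinate sidecar (tissue_positions CSV)."""

    spot_ids: np.ndarray
    in_tissue: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pixel_x: np.ndarray
    pixel_y: np.ndarray

    def __post_init__(self):
        self.spot_ids = _as_id_array(self.spot_ids, "spot ids")
        n = len(self.spot_ids)
        for name in ("in_tissue", "array_row", "array_col", "pixel_x", "pixel_y"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} length != number of spots")
            setattr(self, name, arr)
        self.in_tissue = self.in_tissue.astype(bool)
        for name in ("array_row", "array_col"):
            arr = getattr(self, name).astype(int)
            if (arr < 0).any():
                raise ValidationError(f"negative {name}")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.spot_ids,
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "pxl_row_in_fullres": self.pixel_y,
                "pxl_col_in_fullres": self.pixel_x,
            }
        )


@dataclass
class LRPairTable:
    """Table of annotated ligand-receptor pairs (from PPI resources such as
    NicheNet, OmniPath or CellTalkDB) consumed as a plain table."""

    pairs: pd.DataFrame  # columns: ligand, receptor, source

    def __post_init__(self):
        df = pd.DataFrame(self.pairs).copy()
        required = ["ligand", "receptor"]
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"LR table missing column {col!r}")
        if "source" not in df.columns:
            df["source"] = ""
        df = df[["ligand", "receptor", "source"]]
        for col in required:
            vals = df[col].astype(str)
            if (vals.str.strip() == "").any():
                raise ValidationError(f"empty gene symbol in column {col!r}")
            df[col] = vals
        dup = df.duplicated(subset=["ligand", "receptor"])
        if dup.any():
            warnings.warn(
                f"dropping {int(dup.sum())} duplicated ligand-receptor rows",
                stacklevel=2,
            )
            df = df[~dup]
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set:
        return set(zip(self.pairs["ligand"], self.pairs["receptor"]))

    def iter_pairs(self):
        yield from zip(self.pairs["ligand"], self.pairs["receptor"])


@dataclass
class SampleMetadata:
    """spot -> sample -> condition mapping."""

    spot_to_sample: pd.Series
    sample_to_condition: pd.Series

    def __post_init__(self):
        s2s = pd.Series(self.spot_to_sample)
        if s2s.index.duplicated().any():
            dupes = s2s.index[s2s.index.duplicated()].unique().tolist()
            raise ValidationError(f"spots mapped to multiple samples: {dupes[:5]}")
        s2c = pd.Series(self.sample_to_condition)
        if s2c.index.duplicated().any():
            dupes = s2c.index[s2c.index.duplicated()].unique().tolist()
            raise ValidationError(f"samples with multiple conditions: {dupes[:5]}")
        missing = set(s2s.values) - set(s2c.index)
        if missing:
            raise ValidationError(
                f"samples without a condition label: {sorted(missing)[:5]}"
            )
        self.spot_to_sample = s2s
        self.sample_to_condition = s2c

    def condition_of_spots(self, spot_ids) -> pd.Series:
        self.require_spots(spot_ids)
        samples = self.spot_to_sample.loc[list(spot_ids)]
        return pd.Series(
            self.sample_to_condition.loc[samples.values].values,
            index=list(spot_ids),
        )

    def require_spots(self, spot_ids):
        missing = [s for s in spot_ids if s not in self.spot_to_sample.index]
        if missing:
            raise ValidationError(f"spots missing from metadata: {missing[:10]}")

    @property
    def conditions(self) -> list:
        return sorted(set(self.sample_to_condition.values))


@dataclass
class CompositionClassAssignment:
    """Spot -> composition-class label from k-means on the deconvolution
    matrix.  Labels run 1..n_classes and are ordered by decreasing class size
    so that numbering is comparable across runs."""

    spot_ids: np.ndarray
    labels: np.ndarray
    n_classes: int
    centroids: np.ndarray
    seed: int
    inertia: float = float("nan")

    def __post_init__(self):
        self.spot_ids = _as_id_array(self.spot_ids, "spot ids")
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.spot_ids),):
            raise ValidationError("one label per spot required")
        if labels.min() < 1 or labels.max() > self.n_classes:
            raise ValidationError("labels must lie in 1..n_classes")
        if not np.isfinite(np.asarray(self.centroids, dtype=float)).all():
            raise ValidationError("non-finite centroid")
        self.labels = labels
        self.centroids = np.asarray(self.centroids, dtype=float)

    def spots_in_class(self, cc: int) -> np.ndarray:
        return self.spot_ids[self.labels == cc]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"spot_id": self.spot_ids, "cc": self.labels})


RESERVED_SEGMENT_COLUMNS = ("segment_id", "roi_id", "x", "y", "annotation")


@dataclass
class SegmentTable:
    """Single-cell FISH segments: coordinates (um), per-gene molecule counts
    and an optional cell-type annotation, one imaged ROI at a time."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        for col in ("segment_id", "roi_id", "x", "y"):
            if col not in df.columns:
                raise ValidationError(f"segment table missing column {col!r}")
        if df.duplicated(subset=["roi_id", "segment_id"]).any():
            raise ValidationError("segment_id not unique within roi")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite segment coordinate")
        counts = df[self._gene_cols(df)]
        if len(counts.columns) and (counts.to_numpy() < 0).any():
            raise ValidationError("negative molecule count")
        self.data = df.reset_index(drop=True)

    @staticmethod
    def _gene_cols(df) -> list:
        return [c for c in df.columns if c not in RESERVED_SEGMENT_COLUMNS]

    @property
    def gene_ids(self) -> list:
        return self._gene_cols(self.data)

    @property
    def roi_ids(self) -> list:
        return sorted(self.data["roi_id"].unique().tolist())

    def counts(self) -> np.ndarray:
        return self.data[self.gene_ids].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class NeighborhoodSet:
    """kNN cellular neighborhoods: per focal segment, the focal cell plus its
    k nearest neighbors within the same ROI (Euclidean distance)."""

    k: int
    metric: str
    include_focal: bool
    table: pd.DataFrame = field(repr=False)
    # table columns: roi_id, focal_id, members (tuple of segment ids), undersized

    def __post_init__(self):
        required = {"roi_id", "focal_id", "members", "undersized"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"neighborhood table needs columns {sorted(required)}"
            )

    def per_roi(self):
        for roi, grp in self.table.groupby("roi_id", sort=True):
            yield roi, grp

    def __len__(self) -> int:
        return len(self.table)
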