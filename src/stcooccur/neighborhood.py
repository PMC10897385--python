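"""Single-cell-resolution co-occurrence for hybridization-based spatial data.

Segmented cells (with planar coordinates and per-gene molecule counts) are
quality-filtered, annotated by marker expression, and grouped into kNN
cellular neighborhoods (a focal cell plus its k nearest neighbors, k = 5 by
default).  Each neighborhood is then a "site" and each annotated cell type
an "entity" of the exact co-occurrence model, applied separately per imaged
ROI.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import NeighborhoodSet, PresenceAbsenceMatrix, SegmentTable
from .cooccurrence import CooccurrenceTable, all_pairs_cooccurrence
from .errors import ValidationError

UNASSIGNED = "unassigned"


def filter_segments(
    segments: SegmentTable,
    min_molecules: int = 3,
    min_genes: int = 3,
) -> SegmentTable:
    """Quality filter: keep segments with at least ``min_molecules`` total
    molecules AND at least ``min_genes`` distinct detected genes.

    The defaults remove segments with fewer than 3 molecules or fewer than 3
    genes; a segment with exactly 3 molecules across 3 genes is retained.
    """
    counts = segments.counts()
    total = counts.sum(axis=1)
    detected = (counts > 0).sum(axis=1)
    keep = (total >= min_molecules) & (detected >= min_genes)
    if not keep.any():
        raise ValidationError("quality filter removed every segment")
    return SegmentTable(data=segments.data.loc[keep].reset_index(drop=True))


def annotate_segments(
    segments: SegmentTable,
    marker_map: dict,
) -> SegmentTable:
    """Annotate each segment with the cell type whose marker genes sum to
    the highest molecule count.

    ``marker_map`` maps cell type -> iterable of marker genes (e.g. M cells
    by SPIB, fibroblasts by PDGFRA/PDPN).  Ties and all-zero marker totals
    yield "unassigned".  Marker genes absent from the panel are ignored with
    a warning.
    """
    if not marker_map or any(len(list(v)) == 0 for v in marker_map.values()):
        raise ValidationError("marker sets must be non-empty")
    panel = set(segments.gene_ids)
    scores = {}
    for celltype, markers in marker_map.items():
        markers = list(markers)
        missing = [m for m in markers if m not in panel]
        if missing:
            warnings.warn(
                f"markers absent from panel for {celltype!r}: {missing}",
                stacklevel=2,
            )
        usable = [m for m in markers if m in panel]
        scores[celltype] = (
            segments.data[usable].sum(axis=1).to_numpy()
            if usable
            else np.zeros(len(segments))
        )
    types = list(scores)
    score_mat = np.column_stack([scores[t] for t in types])
    best = score_mat.max(axis=1)
    n_best = (score_mat == best[:, None]).sum(axis=1)
    winner = np.asarray(types, dtype=object)[score_mat.argmax(axis=1)]
    annotation = np.where((best > 0) & (n_best == 1), winner, UNASSIGNED)
    data = segments.data.copy()
    data["annotation"] = annotation
    return SegmentTable(data=data)


def _knn_one_roi(
    seg_ids: np.ndarray, xy: np.ndarray, k: int, include_focal: bool
) -> list[tuple]:
    """Neighbor lists for one ROI by brute-force distance with deterministic
    (distance, segment_id) tie-break.  Chunked to bound memory."""
    n = len(seg_ids)
    order_key = np.argsort(np.argsort(seg_ids, kind="stable"))  # id rank
    out = []
    chunk = max(1, 2_000_000 // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = cdist(xy[start:stop], xy)
        for local, focal in enumerate(range(start, stop)):
            row = d[local].copy()
            row[focal] = np.inf  # the focal cell is never its own neighbor
            ranked = np.lexsort((order_key, row))
            neighbors = ranked[:k]
            members = (
                (seg_ids[focal],) + tuple(seg_ids[neighbors])
                if include_focal
                else tuple(seg_ids[neighbors])
            )
            out.append((seg_ids[focal], members))
    return out


def build_knn_neighborhoods(
    segments: SegmentTable,
    k: int = 5,
    include_focal: bool = True,
) -> NeighborhoodSet:
    """kNN cellular neighborhoods from segment coordinates, per ROI.

    Euclidean distances in the units of the input coordinates.  Each
    neighborhood holds the focal segment plus its k nearest neighbors
    (k + 1 members) when the ROI has more than k segments; exact ties at the
    k-th distance are broken by ascending segment id.  An ROI with at most k
    segments yields a single neighborhood containing all of its segments,
    flagged ``undersized``.  Coincident coordinates are allowed (distance 0
    sorts first).
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    rows = []
    for roi in segments.roi_ids:
        grp = segments.data[segments.data["roi_id"] == roi]
        if len(grp) < 2:
            raise ValidationError(f"roi {roi!r} has fewer than 2 segments")
        seg_ids = grp["segment_id"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        if len(grp) <= k:
            rows.append(
                {
                    "roi_id": roi,
                    "focal_id": None,
                    "members": tuple(sorted(seg_ids)),
                    "undersized": True,
                }
            )
            continue
        for focal, members in _knn_one_roi(seg_ids, xy, k, include_focal):
            rows.append(
                {
                    "roi_id": roi,
                    "focal_id": focal,
                    "members": members,
                    "undersized": False,
                }
            )
    return NeighborhoodSet(
        k=k,
        metric="euclidean",
        include_focal=include_focal,
        table=pd.DataFrame(rows),
    )


def neighborhood_presence(
    neighborhoods: NeighborhoodSet,
    segments: SegmentTable,
    roi,
) -> PresenceAbsenceMatrix:
    """Neighborhood x cell-type presence matrix for one ROI.

    A cell type is present in a neighborhood iff at least one member segment
    carries that annotation.  "unassigned" segments are never entities.
    Entities are the cell types annotated anywhere in the segment table, so
    types absent from this ROI appear as empty (degenerate) columns.
    """
    if "annotation" not in segments.data.columns:
        raise ValidationError("segments must be annotated first")
    types = sorted(
        t for t in segments.data["annotation"].unique() if t != UNASSIGNED
    )
    if not types:
        raise ValidationError("no annotated cell types")
    grp = segments.data[segments.data["roi_id"] == roi]
    anno = dict(zip(grp["segment_id"], grp["annotation"]))
    nbrs = neighborhoods.table[neighborhoods.table["roi_id"] == roi]
    site_ids, values = [], []
    for row in nbrs.itertuples():
        member_types = {anno.get(m, UNASSIGNED) for m in row.members}
        site_ids.append(
            f"{roi}:{row.focal_id}" if row.focal_id is not None else f"{roi}:all"
        )
        values.append([t in member_types for t in types])
    return PresenceAbsenceMatrix(
        site_ids=np.array(site_ids, dtype=object),
        entity_ids=np.array(types, dtype=object),
        values=np.array(values, dtype=bool),
    )


def neighborhood_cooccurrence(
    neighborhoods: NeighborhoodSet,
    segments: SegmentTable,
    alpha: float = 0.05,
    pooled: bool = False,
) -> dict:
    """Cell-type co-occurrence over kNN neighborhoods, separately per ROI.

    Sites are neighborhoods; a cell type is present in a site when any
    member is annotated with it.  Returns {roi_id: CooccurrenceTable}.  With
    ``pooled=True`` neighborhoods of all ROIs are concatenated into a single
    table under the key "pooled" (useful for power studies only; the default
    per-ROI analysis never mixes ROIs).
    """
    rois = segments.roi_ids
    if pooled:
        mats = [neighborhood_presence(neighborhoods, segments, r) for r in rois]
        pa = PresenceAbsenceMatrix(
            site_ids=np.concatenate([m.site_ids for m in mats]),
            entity_ids=mats[0].entity_ids,
            values=np.vstack([m.values for m in mats]),
        )
        return {"pooled": all_pairs_cooccurrence(pa, alpha=alpha)}
    out = {}
    for roi in rois:
        pa = neighborhood_presence(neighborhoods, segments, roi)
        out[roi] = all_pairs_cooccurrence(pa, alpha=alpha)
    return out
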