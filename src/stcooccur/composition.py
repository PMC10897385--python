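"""Composition classes: clustering spots by their deconvoluted cell-type
mixtures.

A composition class (CC) is a group of spots with similar cell-type
composition — e.g. all spots capturing colonic crypts.  CCs are the stratum
within which all downstream co-occurrence tests run, so that transcriptomic
effects of differing cell-type composition are filtered out.

Clustering operates on the raw spot x cell-type probability matrix by
default.  Clustering a low-dimensional embedding instead is available via
``on_embedding=True`` (PCA), but the raw matrix is the default because it is
deterministic and avoids embedding stochasticity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import (
    CompositionClassAssignment,
    DeconvolutionMatrix,
    PresenceAbsenceMatrix,
    SampleMetadata,
)
from .errors import ValidationError


def binarize_deconvolution(
    D: DeconvolutionMatrix, threshold: float = 0.1
) -> PresenceAbsenceMatrix:
    """Convert identity probabilities to cell-type presence calls.

    A cell type is present in a spot iff its probability is strictly greater
    than ``threshold`` (default 0.1).  The strict inequality matters at the
    boundary: P = 0.10 is absence, P = 0.11 presence.
    """
    if not (0 <= threshold < 1):
        raise ValidationError("threshold must lie in [0, 1)")
    return PresenceAbsenceMatrix(
        site_ids=D.spot_ids,
        entity_ids=D.celltype_ids,
        values=D.probs > threshold,
    )


def _renumber_by_size(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Map raw k-means labels to 1..k ordered by decreasing cluster size
    (ties broken by raw label for determinism).  Returns (new_labels, order)
    where order[i] is the raw label assigned new label i+1."""
    sizes = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels], order


def cluster_composition(
    D: DeconvolutionMatrix,
    n_classes: int,
    seed: int = 0,
    n_restarts: int = 25,
    on_embedding: bool = False,
    n_components: int = 10,
) -> CompositionClassAssignment:
    """k-means clustering of the deconvolution matrix into composition classes.

    Runs ``n_restarts`` random initializations and keeps the assignment with
    the best within-cluster sum of squares.  Deterministic for a fixed seed.
    Labels are renumbered 1..n_classes by decreasing class size; the numbering
    carries no meaning beyond cross-run comparability.
    """
    if n_classes < 2:
        raise ValidationError("n_classes must be at least 2")
    if n_classes > D.n_spots:
        raise ValidationError(
            f"n_classes={n_classes} exceeds number of spots ({D.n_spots})"
        )
    X = D.probs
    if np.allclose(X, X[0]) and n_classes > 1:
        raise ValidationError(
            "degenerate input: all spot rows identical, cannot form "
            f"{n_classes} classes"
        )
    if on_embedding:
        n_comp = min(n_components, X.shape[1], X.shape[0])
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(
        n_clusters=n_classes,
        n_init=n_restarts,
        random_state=seed,
    ).fit(X)
    labels, order = _renumber_by_size(km.labels_, n_classes)
    centroids = km.cluster_centers_[order]
    return CompositionClassAssignment(
        spot_ids=D.spot_ids,
        labels=labels,
        n_classes=n_classes,
        centroids=centroids,
        seed=seed,
        inertia=float(km.inertia_),
    )


def cluster_quality_report(
    D: DeconvolutionMatrix,
    k_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Elbow / silhouette report to help choose the number of classes.

    The number of composition classes is a user decision (tissue-dependent);
    this report gives within-cluster sum of squares and mean silhouette for a
    range of k.
    """
    rows = []
    for k in k_range:
        if k >= D.n_spots:
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(
            D.probs
        )
        rows.append(
            {
                "k": k,
                "inertia": float(km.inertia_),
                "silhouette": float(silhouette_score(D.probs, km.labels_)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CCSummary:
    """Per-class composition and per-condition abundance summaries.

    ``celltype_summary``: one row per (cc, cell type) with median and
    quartiles of the identity probability.
    ``condition_abundance``: one row per (condition, cc) with the fraction of
    the condition's spots assigned to that class; fractions sum to 1 within
    each condition.
    """

    celltype_summary: pd.DataFrame
    condition_abundance: pd.DataFrame


def summarize_ccs(
    assignment: CompositionClassAssignment,
    D: DeconvolutionMatrix,
    metadata: SampleMetadata,
) -> CCSummary:
    """Summarize cell-type composition per CC and CC abundance per condition."""
    if list(assignment.spot_ids) != list(D.spot_ids):
        raise ValidationError(
            "assignment and deconvolution matrix must cover the same spots "
            "in the same order"
        )
    metadata.require_spots(D.spot_ids)

    frame = D.to_frame()
    frame["cc"] = assignment.labels
    long = frame.melt(
        id_vars="cc", var_name="celltype", value_name="probability"
    )
    summary = (
        long.groupby(["cc", "celltype"], sort=True)["probability"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )

    conditions = metadata.condition_of_spots(D.spot_ids)
    rows = []
    all_ccs = range(1, assignment.n_classes + 1)
    for condition in metadata.conditions:
        mask = (conditions == condition).to_numpy()
        n_cond = int(mask.sum())
        if n_cond == 0:
            raise ValidationError(f"condition {condition!r} has zero spots")
        labels_cond = assignment.labels[mask]
        for cc in all_ccs:
            rows.append(
                {
                    "condition": condition,
                    "cc": cc,
                    "n_spots": int((labels_cond == cc).sum()),
                    "fraction": float((labels_cond == cc).mean()),
                }
            )
    abundance = pd.DataFrame(rows)
    return CCSummary(celltype_summary=summary, condition_abundance=abundance)
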