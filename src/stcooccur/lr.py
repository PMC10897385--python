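"""Ligand-receptor co-occurrence within composition classes, Spearman
ranking, surfaceome-wide testing, and differential co-occurrence between
strata (composition classes or conditions).

Gene presence is binary (count >= min_count, default 1), so the test is
agnostic to expression magnitude; the Spearman correlation of raw ligand and
receptor counts across the same sites is reported separately as a ranking
aid for positively co-occurring pairs.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr

from .containers import LRPairTable, PresenceAbsenceMatrix, SpotCountMatrix
from .cooccurrence import bh_adjust, classify
from .errors import ValidationError

LR_COLUMNS = [
    "ligand",
    "receptor",
    "n_sites",
    "n1",
    "n2",
    "observed",
    "expected",
    "p_lt",
    "p_gt",
    "q_lt",
    "q_gt",
    "classification",
    "degenerate",
    "rho",
    "annotated",
]


def binarize_counts(
    counts: SpotCountMatrix, min_count: int = 1
) -> PresenceAbsenceMatrix:
    """Gene presence calls: present iff count >= min_count.

    The default threshold of 1 makes the analysis agnostic to expression
    levels; raising it restricts the analysis to highly expressed genes.
    """
    if min_count < 1:
        raise ValidationError("min_count must be a positive integer")
    dense = counts.dense() >= min_count
    return PresenceAbsenceMatrix(
        site_ids=counts.spot_ids,
        entity_ids=counts.gene_ids,
        values=dense,
    )


@dataclass
class LRCooccurrenceTable:
    """Co-occurrence results for gene pairs, with Spearman rho and the
    annotated-pair flag.  ``skipped_pairs`` lists (ligand, receptor) pairs
    whose genes were absent from the count matrix."""

    data: pd.DataFrame
    alpha: float
    skipped_pairs: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in LR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"LR table missing columns {missing}")
        self.data = self.data[LR_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def pair(self, ligand, receptor) -> pd.Series:
        rows = self.data[
            (self.data["ligand"] == ligand)
            & (self.data["receptor"] == receptor)
        ]
        if rows.empty:
            raise KeyError(f"pair ({ligand!r}, {receptor!r}) not in table")
        return rows.iloc[0]


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho; NaN marks the undefined case of a constant vector."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(x, y).statistic
    return float(rho)


def _gene_pairs_cooccurrence(
    counts: SpotCountMatrix,
    gene_pairs: list[tuple],
    sites,
    alpha: float,
    min_count: int,
    nonzero_only: bool,
    annotated_set: set | None,
) -> LRCooccurrenceTable:
    """Shared engine: co-occurrence + Spearman rho for explicit gene pairs."""
    if sites is not None:
        sites = list(sites)
        if len(sites) == 0:
            raise ValidationError("site subset is empty")
        counts = counts.subset_spots(sites)
    n_sites = counts.n_spots

    genes_in_matrix = set(counts.gene_ids)
    tested, skipped = [], []
    for lig, rec in gene_pairs:
        if lig == rec:
            continue
        if lig in genes_in_matrix and rec in genes_in_matrix:
            tested.append((lig, rec))
        else:
            skipped.append((lig, rec))
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} pairs with genes absent from the "
            "count matrix",
            stacklevel=3,
        )
    if not tested:
        raise ValidationError("no testable gene pairs")

    used_genes = sorted({g for pair in tested for g in pair})
    gmat = np.column_stack([counts.gene_column(g) for g in used_genes])
    gidx = {g: i for i, g in enumerate(used_genes)}
    present = gmat >= min_count
    n_per_gene = present.sum(axis=0)

    i1 = np.array([gidx[l] for l, _ in tested])
    i2 = np.array([gidx[r] for _, r in tested])
    n1 = n_per_gene[i1]
    n2 = n_per_gene[i2]
    observed = (present[:, i1] & present[:, i2]).sum(axis=0)
    p_lt = np.minimum(1.0, hypergeom.cdf(observed, n_sites, n1, n2))
    p_gt = np.minimum(1.0, hypergeom.sf(observed - 1, n_sites, n1, n2))
    degenerate = np.isin(n1, [0, n_sites]) | np.isin(n2, [0, n_sites])
    labels = np.array(
        [classify(lt, gt, alpha) for lt, gt in zip(p_lt, p_gt)], dtype=object
    )
    labels[degenerate] = "random"

    rhos = []
    for (lig, rec) in tested:
        x = gmat[:, gidx[lig]].astype(float)
        y = gmat[:, gidx[rec]].astype(float)
        if nonzero_only:
            mask = (x > 0) | (y > 0)
            if mask.sum() < 2:
                rhos.append(float("nan"))
                continue
            x, y = x[mask], y[mask]
        rhos.append(_spearman(x, y))

    df = pd.DataFrame(
        {
            "ligand": [l for l, _ in tested],
            "receptor": [r for _, r in tested],
            "n_sites": n_sites,
            "n1": n1,
            "n2": n2,
            "observed": observed,
            "expected": n1 * n2 / n_sites,
            "p_lt": p_lt,
            "p_gt": p_gt,
            "classification": labels,
            "degenerate": degenerate,
            "rho": rhos,
        }
    )
    df["q_lt"] = bh_adjust(df["p_lt"].to_numpy())
    df["q_gt"] = bh_adjust(df["p_gt"].to_numpy())
    if annotated_set is None:
        df["annotated"] = True
    else:
        df["annotated"] = [
            (l, r) in annotated_set
            for l, r in zip(df["ligand"], df["receptor"])
        ]

    # ranking of Fig-3A style output: significant pairs first, by rho
    sig = (df["q_gt"] < alpha).to_numpy()
    rho_key = df["rho"].fillna(-np.inf).to_numpy()
    order = np.lexsort((df["receptor"], df["ligand"], -rho_key, ~sig))
    df = df.iloc[order].reset_index(drop=True)
    return LRCooccurrenceTable(data=df, alpha=alpha, skipped_pairs=skipped)


def lr_cooccurrence(
    counts: SpotCountMatrix,
    lr_table: LRPairTable,
    sites=None,
    alpha: float = 0.05,
    min_count: int = 1,
    nonzero_only: bool = False,
) -> LRCooccurrenceTable:
    """Co-occurrence of annotated ligand-receptor pairs within a site stratum.

    ``sites`` restricts the analysis to one composition class (or condition);
    presence, tails, FDR and rho are all computed over that restricted site
    set only.  Pairs are ranked with positively co-occurring (q_gt < alpha)
    pairs first, ordered by descending Spearman rho.
    """
    return _gene_pairs_cooccurrence(
        counts,
        list(lr_table.iter_pairs()),
        sites,
        alpha,
        min_count,
        nonzero_only,
        annotated_set=None,
    )


def surfaceome_pairs_cooccurrence(
    counts: SpotCountMatrix,
    ligand_genes,
    receptor_genes,
    sites=None,
    alpha: float = 0.05,
    min_count: int = 1,
    lr_table: LRPairTable | None = None,
    nonzero_only: bool = False,
) -> LRCooccurrenceTable:
    """All ligand x receptor combinations, irrespective of annotated pairing.

    Every gene from ``ligand_genes`` is tested against every gene from
    ``receptor_genes`` (self-pairs excluded; a gene in both sets is tested in
    both roles but never against itself).  When an annotated pair table is
    supplied, pairs found in it carry ``annotated=True``.
    """
    ligand_genes = list(ligand_genes)
    receptor_genes = list(receptor_genes)
    if not ligand_genes or not receptor_genes:
        raise ValidationError("ligand and receptor gene sets must be non-empty")
    pairs = [
        (l, r) for l, r in itertools.product(ligand_genes, receptor_genes)
        if l != r
    ]
    annotated = lr_table.pair_set() if lr_table is not None else set()
    return _gene_pairs_cooccurrence(
        counts, pairs, sites, alpha, min_count, nonzero_only,
        annotated_set=annotated,
    )


DIFF_COLUMNS = [
    "ligand",
    "receptor",
    "q_target",
    "q_other",
    "missing_in_target",
    "missing_in_other",
    "selected",
    "score",
]


def differential_cooccurrence(
    table_target: LRCooccurrenceTable,
    table_other: LRCooccurrenceTable,
    fdr_threshold: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Pairs positively co-occurring in the target stratum but not the other.

    A pair is selected iff ``q_target < fdr_threshold`` and
    ``q_other > fdr_threshold`` (positive-tail FDR in each stratum).  The
    differential score is ``q_other - q_target``, so selected pairs always
    score positive; both q values are reported so the opposite sign
    convention is recoverable.  The output is sorted by descending score.

    Pairs tested in only one stratum get q = 1 on the missing side, flagged.
    If the two pair universes are disjoint this is an error under
    ``strict=True``, otherwise a warning and a join on the intersection.
    """
    t = table_target.data[["ligand", "receptor", "q_gt"]].rename(
        columns={"q_gt": "q_target"}
    )
    o = table_other.data[["ligand", "receptor", "q_gt"]].rename(
        columns={"q_gt": "q_other"}
    )
    keys_t = set(zip(t["ligand"], t["receptor"]))
    keys_o = set(zip(o["ligand"], o["receptor"]))
    if not keys_t & keys_o:
        if strict:
            raise ValidationError(
                "the two tables share no ligand-receptor pairs"
            )
        warnings.warn(
            "the two tables share no ligand-receptor pairs; result is empty",
            stacklevel=2,
        )
        merged = t.merge(o, on=["ligand", "receptor"], how="inner")
    else:
        merged = t.merge(o, on=["ligand", "receptor"], how="outer")
    merged["missing_in_target"] = merged["q_target"].isna()
    merged["missing_in_other"] = merged["q_other"].isna()
    merged["q_target"] = merged["q_target"].fillna(1.0)
    merged["q_other"] = merged["q_other"].fillna(1.0)
    merged["selected"] = (merged["q_target"] < fdr_threshold) & (
        merged["q_other"] > fdr_threshold
    )
    merged["score"] = merged["q_other"] - merged["q_target"]
    merged = merged.sort_values(
        ["score", "ligand", "receptor"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return merged[DIFF_COLUMNS]


def cooccurrence_edges(
    table: LRCooccurrenceTable,
    min_spots: int = 20,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Edge list for network rendering: one edge per positively co-occurring
    pair, with an attribute marking whether the pair co-occurs in at least
    ``min_spots`` sites and the annotated-pair flag."""
    df = table.data
    sig = df["q_gt"] < table.alpha if use_fdr else df["classification"] == "positive"
    edges = df.loc[
        sig, ["ligand", "receptor", "observed", "rho", "annotated"]
    ].copy()
    edges["high_support"] = edges["observed"] >= min_spots
    return edges.reset_index(drop=True)
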