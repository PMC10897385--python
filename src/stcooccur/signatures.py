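"""LR-associated gene signatures: differential expression between spots
double positive and double negative for a ligand-receptor pair, with a
permutation-based Monte Carlo FDR.

Within one composition class, spots are split into those expressing both
members of an LR pair (double positive, DP) and those expressing neither
(double negative, DN); spots expressing exactly one member are excluded.
Per-gene differential expression uses the two-sided Wilcoxon rank-sum test.
Specificity of the resulting DEGs is then assessed against a permutation
null: spots are repeatedly re-split at random into groups of the observed
sizes, per-gene p-values are recomputed, and each gene's Monte Carlo p-value
is the (add-one) fraction of null p-values at or below its observed one.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata, tiecorrect

from .containers import SpotCountMatrix
from .cooccurrence import bh_adjust
from .errors import ValidationError

DEG_COLUMNS = [
    "gene",
    "n_dp",
    "n_dn",
    "statistic",
    "p",
    "log2fc",
    "monte_carlo_p",
    "q",
]


def split_spots_by_lr(
    counts: SpotCountMatrix,
    ligand: str,
    receptor: str,
    sites=None,
    min_count: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Split sites into LR double-positive and double-negative spot sets.

    DP: both genes at count >= min_count; DN: both below; single-positive
    spots are excluded from both groups.
    """
    if sites is not None:
        counts = counts.subset_spots(list(sites))
    lig = counts.gene_column(ligand) >= min_count
    rec = counts.gene_column(receptor) >= min_count
    dp = counts.spot_ids[lig & rec]
    dn = counts.spot_ids[~lig & ~rec]
    if len(dp) == 0:
        raise ValidationError(
            f"no double-positive spots for ({ligand}, {receptor})"
        )
    if len(dn) == 0:
        raise ValidationError(
            f"no double-negative spots for ({ligand}, {receptor})"
        )
    return dp, dn


def _normalize(dense: np.ndarray, method: str) -> np.ndarray:
    """Per-spot normalization of a dense spots x genes count matrix."""
    if method == "none":
        return dense.astype(float)
    if method == "log_cpm":
        lib = dense.sum(axis=1, keepdims=True).astype(float)
        lib[lib == 0] = 1.0
        return np.log1p(dense / lib * 1e6)
    raise ValidationError(f"unknown normalization {method!r}")


def lr_associated_degs(
    counts: SpotCountMatrix,
    dp_sites,
    dn_sites,
    normalization: str = "log_cpm",
    min_group_size: int = 3,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between DP and DN spots.

    The exact null distribution (shift algorithm; not tie-corrected) is used
    when both groups have at most ``exact_max_n`` spots; larger groups use
    the normal approximation with tie correction.  With heavy ties the exact
    small-sample p is conservative, which errs on the safe side for
    signature calling.  Genes with zero counts in every spot
    of both groups are skipped.  The log2 fold change is computed on raw
    count means with pseudocount 1; the test runs on normalized values
    (default log CPM, guarding against library-size differences between the
    groups — ``normalization='none'`` tests raw counts).
    """
    dp_sites, dn_sites = list(dp_sites), list(dn_sites)
    if len(dp_sites) < min_group_size or len(dn_sites) < min_group_size:
        raise ValidationError(
            f"both groups need >= {min_group_size} spots "
            f"(got {len(dp_sites)} DP, {len(dn_sites)} DN)"
        )
    sub = counts.subset_spots(dp_sites + dn_sites)
    raw = sub.dense()
    values = _normalize(raw, normalization)
    n1 = len(dp_sites)

    rows = []
    for j, gene in enumerate(sub.gene_ids):
        col_raw = raw[:, j]
        if not col_raw.any():
            continue
        x, y = values[:n1, j], values[n1:, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = float(n1 * len(y) / 2), 1.0
        else:
            method = (
                "exact"
                if (len(x) <= exact_max_n and len(y) <= exact_max_n)
                else "asymptotic"
            )
            res = mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        log2fc = float(
            np.log2((col_raw[:n1].mean() + 1) / (col_raw[n1:].mean() + 1))
        )
        rows.append(
            {
                "gene": gene,
                "n_dp": n1,
                "n_dn": len(dn_sites),
                "statistic": stat,
                "p": p,
                "log2fc": log2fc,
                "monte_carlo_p": np.nan,
                "q": np.nan,
            }
        )
    if not rows:
        raise ValidationError("no gene with non-zero counts in either group")
    df = pd.DataFrame(rows)[DEG_COLUMNS]
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def _tie_sigma(ranks: np.ndarray, n1: int) -> float:
    """Tie-corrected standard deviation of U for each rank column."""
    n = ranks.shape[0]
    n2 = n - n1
    tie = np.array([tiecorrect(ranks[:, j]) for j in range(ranks.shape[1])])
    return np.sqrt(tie * n1 * n2 * (n + 1) / 12)


def _p_from_ranksums(r1, n1: int, n2: int, sigma) -> np.ndarray:
    """Two-sided p from group-1 rank sums (continuity-corrected normal)."""
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / sigma
    p = 2 * norm.sf(z)
    p = np.where(sigma == 0, 1.0, p)  # all values tied: no evidence
    return np.clip(p, 0.0, 1.0)


def ranksum_pvalues(values: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, one per column.

    Normal approximation with tie correction and continuity correction
    (matches scipy's asymptotic Mann-Whitney U).  ``values`` is an
    (n1 + n2) x genes array with group 1 in the first ``n1`` rows.
    """
    n2 = values.shape[0] - n1
    ranks = rankdata(values, axis=0)
    sigma = _tie_sigma(ranks, n1)
    return _p_from_ranksums(ranks[:n1].sum(axis=0), n1, n2, sigma)


def monte_carlo_fdr(
    counts: SpotCountMatrix,
    sites,
    group_sizes: tuple[int, int],
    observed: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    pooled: bool = False,
    normalization: str = "log_cpm",
) -> pd.DataFrame:
    """Permutation null for LR-associated DEGs; fills monte_carlo_p and q.

    For each of ``n_permutations`` rounds, ``sites`` are randomly split into
    two groups of the observed DP/DN sizes and per-gene rank-sum p-values are
    recomputed.  Per gene g,

        monte_carlo_p(g) = (1 + #{null p of g <= observed p of g}) / (B + 1)

    (add-one estimator, so the smallest achievable value is 1/(B+1)).
    ``pooled=True`` compares each gene's observed p against the null
    p-values of all genes pooled together instead.  q is Benjamini-Hochberg
    over the genes' Monte Carlo p-values.  Deterministic given the seed.
    """
    sites = list(sites)
    n1, n2 = group_sizes
    if n1 + n2 > len(sites):
        raise ValidationError(
            f"group sizes {group_sizes} exceed available sites ({len(sites)})"
        )
    if n_permutations < 100:
        warnings.warn(
            f"only {n_permutations} permutations; Monte Carlo p-values will "
            "be coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    genes = observed["gene"].tolist()
    sub = counts.subset_spots(sites)
    gidx = [sub.gene_index(g) for g in genes]
    values = _normalize(sub.dense(), normalization)[:, gidx]
    obs_p = observed["p"].to_numpy()

    B = n_permutations
    exceed = np.zeros(len(genes), dtype=np.int64)
    pooled_null = [] if pooled else None
    exact_split = n1 + n2 == len(sites)
    if exact_split:
        # site set identical across permutations: rank once, then each
        # permutation only re-sums ranks over a random group-1 index set
        ranks = rankdata(values, axis=0)
        sigma = _tie_sigma(ranks, n1)
        chunk = max(1, min(B, 64_000_000 // max(1, n1 * len(genes) * 8)))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            picks = np.argsort(rng.random((b, len(sites))), axis=1)[:, :n1]
            r1 = ranks[picks].sum(axis=1)  # (b, genes)
            null_p = _p_from_ranksums(r1, n1, n2, sigma)
            if pooled:
                pooled_null.append(null_p.ravel())
            else:
                exceed += (null_p <= obs_p).sum(axis=0)
            done += b
    else:
        for _ in range(B):
            idx = rng.permutation(len(sites))[: n1 + n2]
            null_p = ranksum_pvalues(values[idx], n1)
            if pooled:
                pooled_null.append(null_p)
            else:
                exceed += null_p <= obs_p

    out = observed.copy()
    if pooled:
        all_null = np.sort(np.concatenate(pooled_null))
        counts_le = np.searchsorted(all_null, obs_p, side="right")
        out["monte_carlo_p"] = (1 + counts_le) / (all_null.size + 1)
    else:
        out["monte_carlo_p"] = (1 + exceed) / (B + 1)
    out["q"] = bh_adjust(out["monte_carlo_p"].to_numpy())
    return out
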