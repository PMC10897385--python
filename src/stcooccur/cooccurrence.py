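"""Exact probabilistic co-occurrence model on a binary site x entity matrix.

The model treats the placement of each entity across the N sites as a random
draw without replacement: given entity 1 present at n1 sites and entity 2 at
n2 sites, the number j of sites where both are present follows the
hypergeometric distribution

    P_j = C(n1, j) * C(N - n1, n2 - j) / C(N, n2)

with support max(0, n1 + n2 - N) <= j <= min(n1, n2).  The observed joint
count is compared to this distribution through two inclusive tails:
p_lt = P(J <= observed) and p_gt = P(J >= observed).  A pair is classified
positive when p_gt <= alpha (observed co-occurrence higher than expected
under random placement), negative when p_lt <= alpha, random otherwise.
Because the two tails share the probability mass at the observed value,
p_lt + p_gt = 1 + P_observed >= 1 always holds.

The expected co-occurrence is E = n1 * n2 / N, i.e. the product of the two
per-site presence probabilities times the number of sites.  The test depends
on (N, n1, n2, observed) only, which makes the classification independent of
entity abundance: a pair whose joint count matches the product of its
marginal frequencies is random no matter how abundant either entity is.

Probabilities are evaluated through scipy's hypergeometric distribution
(log-gamma based), which is stable for site counts well beyond 1e5.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import PresenceAbsenceMatrix
from .errors import ValidationError

#: fixed column order of every co-occurrence table written by this package
COOCCURRENCE_COLUMNS = [
    "entity_1",
    "entity_2",
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
    "low_expected",
]


def cooccurrence_distribution(
    n_sites: int, n1: int, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the joint-presence count.

    Returns the support ``j`` (all achievable joint counts) and the
    probability of each, computed in log space and exponentiated per term.

    Raises
    ------
    ValidationError
        if either presence count exceeds the number of sites.
    """
    if not (0 <= n1 <= n_sites and 0 <= n2 <= n_sites):
        raise ValidationError(
            f"presence counts ({n1}, {n2}) must lie in [0, N={n_sites}]"
        )
    j_min = max(0, n1 + n2 - n_sites)
    j_max = min(n1, n2)
    support = np.arange(j_min, j_max + 1)
    probs = np.exp(hypergeom.logpmf(support, n_sites, n1, n2))
    return support, probs


def tail_probabilities(
    n_sites: int, n1: int, n2: int, observed: int
) -> tuple[float, float]:
    """Inclusive lower and upper tail probabilities of the observed count.

    ``p_lt = P(J <= observed)``, ``p_gt = P(J >= observed)``.  Both tails
    include the observed value; borderline classifications are sensitive to
    this convention, which follows the ecology formulation of the model.
    """
    j_min = max(0, n1 + n2 - n_sites)
    j_max = min(n1, n2)
    if not (j_min <= observed <= j_max):
        raise ValidationError(
            f"observed={observed} outside achievable range [{j_min}, {j_max}] "
            f"for (N={n_sites}, n1={n1}, n2={n2})"
        )
    p_lt = float(min(1.0, hypergeom.cdf(observed, n_sites, n1, n2)))
    p_gt = float(min(1.0, hypergeom.sf(observed - 1, n_sites, n1, n2)))
    return p_lt, p_gt


def classify(p_lt: float, p_gt: float, alpha: float) -> str:
    """positive / random / negative call from the two tails at level alpha.

    If both tails fall at or below alpha (possible only in degenerate tiny
    cases) the smaller tail wins; an exact tie is called random.
    """
    sig_gt = p_gt <= alpha
    sig_lt = p_lt <= alpha
    if sig_gt and sig_lt:
        if p_gt < p_lt:
            return "positive"
        if p_lt < p_gt:
            return "negative"
        return "random"
    if sig_gt:
        return "positive"
    if sig_lt:
        return "negative"
    return "random"


@dataclass
class PairCooccurrence:
    """Exact co-occurrence result for one unordered entity pair."""

    entity_1: object
    entity_2: object
    n_sites: int
    n1: int
    n2: int
    observed: int
    expected: float
    p_lt: float
    p_gt: float
    classification: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "entity_1": self.entity_1,
            "entity_2": self.entity_2,
            "n_sites": self.n_sites,
            "n1": self.n1,
            "n2": self.n2,
            "observed": self.observed,
            "expected": self.expected,
            "p_lt": self.p_lt,
            "p_gt": self.p_gt,
            "classification": self.classification,
            "degenerate": self.degenerate,
        }


def pair_cooccurrence_counts(
    n_sites: int, n1: int, n2: int, observed: int, alpha: float = 0.05,
    entity_1="entity_1", entity_2="entity_2",
) -> PairCooccurrence:
    """Test a pair directly from its summary counts (N, n1, n2, observed)."""
    expected = n1 * n2 / n_sites if n_sites else float("nan")
    p_lt, p_gt = tail_probabilities(n_sites, n1, n2, observed)
    degenerate = n1 in (0, n_sites) or n2 in (0, n_sites)
    label = "random" if degenerate else classify(p_lt, p_gt, alpha)
    return PairCooccurrence(
        entity_1=entity_1,
        entity_2=entity_2,
        n_sites=n_sites,
        n1=n1,
        n2=n2,
        observed=observed,
        expected=expected,
        p_lt=p_lt,
        p_gt=p_gt,
        classification=label,
        degenerate=degenerate,
    )


def pair_cooccurrence(
    pa: PresenceAbsenceMatrix, e1, e2, alpha: float = 0.05
) -> PairCooccurrence:
    """Exact co-occurrence test of two entities of a presence-absence matrix.

    Entities present at zero sites or at every site carry no information and
    are reported as random with the degenerate flag set, never dropped.
    """
    if e1 == e2:
        raise ValidationError("self-pairs are undefined")
    col1 = pa.column(e1)
    col2 = pa.column(e2)
    n_sites = pa.n_sites
    n1 = int(col1.sum())
    n2 = int(col2.sum())
    observed = int((col1 & col2).sum())
    return pair_cooccurrence_counts(
        n_sites, n1, n2, observed, alpha=alpha, entity_1=e1, entity_2=e2
    )


@dataclass
class CooccurrenceTable:
    """All-pairs co-occurrence results with BH-FDR columns.

    ``data`` has one row per unordered entity pair in lexicographic order and
    the fixed column order :data:`COOCCURRENCE_COLUMNS`.  ``q_gt`` and
    ``q_lt`` are Benjamini-Hochberg adjusted versions of the two tails,
    computed separately over the tested (non-filtered) pairs.
    """

    data: pd.DataFrame
    alpha: float

    def __post_init__(self):
        missing = [c for c in COOCCURRENCE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"co-occurrence table missing {missing}")
        self.data = self.data[COOCCURRENCE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def pair(self, e1, e2) -> pd.Series:
        a, b = sorted([e1, e2], key=str)
        rows = self.data[
            (self.data["entity_1"] == a) & (self.data["entity_2"] == b)
        ]
        if rows.empty:
            raise KeyError(f"pair ({e1!r}, {e2!r}) not in table")
        return rows.iloc[0]

    def positive_pairs(self, use_fdr: bool = False) -> pd.DataFrame:
        if use_fdr:
            return self.data[self.data["q_gt"] < self.alpha]
        return self.data[self.data["classification"] == "positive"]

    def classification_matrix(self) -> pd.DataFrame:
        """Square entity x entity matrix of classifications (diagonal empty)."""
        entities = sorted(
            set(self.data["entity_1"]) | set(self.data["entity_2"]), key=str
        )
        mat = pd.DataFrame("", index=entities, columns=entities)
        for row in self.data.itertuples():
            mat.loc[row.entity_1, row.entity_2] = row.classification
            mat.loc[row.entity_2, row.entity_1] = row.classification
        return mat


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def all_pairs_cooccurrence(
    pa: PresenceAbsenceMatrix,
    entities=None,
    alpha: float = 0.05,
    expected_min: float | None = None,
    apply_expected_filter: bool = False,
) -> CooccurrenceTable:
    """Exact co-occurrence test of every unordered entity pair.

    Parameters
    ----------
    pa
        Binary site x entity matrix.
    entities
        Optional subset of entity ids to test (default: all).
    alpha
        Significance level of the tail classification.
    expected_min
        If given, pairs with expected co-occurrence below this value are
        flagged ``low_expected``.  The ecology convention drops such pairs;
        here they are only excluded from the FDR computation when
        ``apply_expected_filter`` is True (their q values become NaN), and
        always remain in the table.
    """
    if entities is None:
        entities = list(pa.entity_ids)
    else:
        entities = list(entities)
    if len(entities) == 0:
        raise ValidationError("empty entity subset")
    if len(entities) < 2:
        raise ValidationError("need at least two entities to form pairs")
    if pa.n_sites < 1:
        raise ValidationError("need at least one site")

    entities = sorted(entities, key=str)
    mat = np.column_stack([pa.column(e) for e in entities])
    n = mat.sum(axis=0).astype(int)
    joint = mat.T.astype(int) @ mat.astype(int)
    n_sites = pa.n_sites

    idx1, idx2 = map(
        np.array, zip(*itertools.combinations(range(len(entities)), 2))
    )
    n1 = n[idx1]
    n2 = n[idx2]
    observed = joint[idx1, idx2]
    p_lt = np.minimum(1.0, hypergeom.cdf(observed, n_sites, n1, n2))
    p_gt = np.minimum(1.0, hypergeom.sf(observed - 1, n_sites, n1, n2))
    degenerate = np.isin(n1, [0, n_sites]) | np.isin(n2, [0, n_sites])
    labels = np.array(
        [classify(lt, gt, alpha) for lt, gt in zip(p_lt, p_gt)], dtype=object
    )
    labels[degenerate] = "random"
    df = pd.DataFrame(
        {
            "entity_1": [entities[i] for i in idx1],
            "entity_2": [entities[i] for i in idx2],
            "n_sites": n_sites,
            "n1": n1,
            "n2": n2,
            "observed": observed,
            "expected": n1 * n2 / n_sites,
            "p_lt": p_lt,
            "p_gt": p_gt,
            "classification": labels,
            "degenerate": degenerate,
        }
    )

    if expected_min is not None:
        df["low_expected"] = df["expected"] < expected_min
    else:
        df["low_expected"] = False

    tested = ~(df["low_expected"] & apply_expected_filter)
    df["q_lt"] = np.nan
    df["q_gt"] = np.nan
    df.loc[tested, "q_lt"] = bh_adjust(df.loc[tested, "p_lt"].to_numpy())
    df.loc[tested, "q_gt"] = bh_adjust(df.loc[tested, "p_gt"].to_numpy())
    return CooccurrenceTable(data=df, alpha=alpha)
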