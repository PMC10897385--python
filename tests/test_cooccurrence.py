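"""The exact hypergeometric co-occurrence model, checked against independent
enumeration and shuffle oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import stcooccur as st
from stcooccur.cooccurrence import COOCCURRENCE_COLUMNS

from conftest import enumeration_cooccurrence_distribution


class TestDistribution:
    def test_matches_exhaustive_enumeration_small(self):
        """Analytic distribution equals brute-force placement enumeration."""
        for n_sites in range(1, 8):
            for n1 in range(n_sites + 1):
                for n2 in range(n_sites + 1):
                    oracle = enumeration_cooccurrence_distribution(
                        n_sites, n1, n2
                    )
                    support, probs = st.cooccurrence_distribution(
                        n_sites, n1, n2
                    )
                    assert set(support.tolist()) == set(oracle)
                    for j, p in zip(support, probs):
                        assert p == pytest.approx(oracle[int(j)], abs=1e-12)

    def test_known_distribution_n4(self):
        """N=4, n1=n2=2: overlap 0/1/2 with probabilities 1/6, 2/3, 1/6."""
        support, probs = st.cooccurrence_distribution(4, 2, 2)
        assert support.tolist() == [0, 1, 2]
        np.testing.assert_allclose(probs, [1 / 6, 2 / 3, 1 / 6], atol=1e-12)

    def test_entity_everywhere_gives_point_mass(self):
        support, probs = st.cooccurrence_distribution(10, 10, 3)
        assert support.tolist() == [3]
        assert probs[0] == pytest.approx(1.0)

    def test_pigeonhole_support(self):
        """N=5, n1=3, n2=4: both entities crowd the sites, overlap >= 2."""
        support, _ = st.cooccurrence_distribution(5, 3, 4)
        assert support.tolist() == [2, 3]

    def test_presence_count_exceeding_sites_rejected(self):
        with pytest.raises(st.ValidationError):
            st.cooccurrence_distribution(5, 6, 2)

    @settings(deadline=None, max_examples=60)
    @given(hs.data())
    def test_normalization_and_tail_identity(self, data):
        """Sum of P_j is 1; inclusive tails satisfy
        p_lt + p_gt - P(observed) = 1."""
        n_sites = data.draw(hs.integers(1, 2000))
        n1 = data.draw(hs.integers(0, n_sites))
        n2 = data.draw(hs.integers(0, n_sites))
        support, probs = st.cooccurrence_distribution(n_sites, n1, n2)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        observed = int(data.draw(hs.sampled_from(support.tolist())))
        p_lt, p_gt = st.tail_probabilities(n_sites, n1, n2, observed)
        pmf = probs[support.tolist().index(observed)]
        assert p_lt + p_gt - pmf == pytest.approx(1.0, abs=1e-9)

    def test_stable_at_large_site_counts(self):
        support, probs = st.cooccurrence_distribution(100_000, 40_000, 30_000)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(probs).all()


class TestPair:
    def test_expected_is_product_rule(self, small_pa):
        pc = st.pair_cooccurrence_counts(10, 5, 4, 2)
        assert pc.expected == pytest.approx(2.0)

    def test_upper_tail_from_enumerated_distribution(self):
        """N=4, n1=n2=2, observed=2: p_gt is the top cell 1/6."""
        pc = st.pair_cooccurrence_counts(4, 2, 2, 2)
        assert pc.p_gt == pytest.approx(1 / 6, abs=1e-12)

    def test_empty_column_is_degenerate_random(self, small_pa):
        pa = st.PresenceAbsenceMatrix(
            site_ids=small_pa.site_ids,
            entity_ids=["a", "empty"],
            values=np.column_stack(
                [small_pa.column("a"), np.zeros(10, dtype=bool)]
            ),
        )
        pc = st.pair_cooccurrence(pa, "a", "empty")
        assert (pc.observed, pc.expected) == (0, 0)
        assert pc.p_lt == pc.p_gt == 1.0
        assert pc.classification == "random"
        assert pc.degenerate

    def test_self_pair_rejected(self, small_pa):
        with pytest.raises(st.ValidationError):
            st.pair_cooccurrence(small_pa, "a", "a")

    def test_symmetry(self, small_pa):
        ab = st.pair_cooccurrence(small_pa, "a", "b")
        ba = st.pair_cooccurrence(small_pa, "b", "a")
        for field in ("n_sites", "observed", "expected", "p_lt", "p_gt",
                      "classification"):
            assert getattr(ab, field) == getattr(ba, field)
        assert {ab.n1, ab.n2} == {ba.n1, ba.n2}

    def test_identical_columns_positive_disjoint_negative(self):
        """Perfect overlap / perfect avoidance at N=100, n1=n2=50."""
        half = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        pa = st.PresenceAbsenceMatrix(
            site_ids=[f"s{i}" for i in range(100)],
            entity_ids=["a", "b", "c"],
            values=np.column_stack([half, half, ~half]),
        )
        assert st.pair_cooccurrence(pa, "a", "b").classification == "positive"
        assert st.pair_cooccurrence(pa, "a", "c").classification == "negative"

    def test_classification_depends_only_on_summary_counts(self, rng):
        """Abundance independence: the call is a function of
        (N, n1, n2, observed) only, however the presence pattern looks."""
        n_sites = 200
        for _ in range(20):
            n1, n2 = rng.integers(10, 190, size=2)
            lo = max(0, n1 + n2 - n_sites)
            hi = min(n1, n2)
            obs = int(rng.integers(lo, hi + 1))
            a = st.pair_cooccurrence_counts(n_sites, int(n1), int(n2), obs)
            # realize the same counts as an explicit matrix
            col1 = np.zeros(n_sites, bool)
            col1[:n1] = True
            col2 = np.zeros(n_sites, bool)
            col2[:obs] = True
            col2[n1:n1 + n2 - obs] = True
            pa = st.PresenceAbsenceMatrix(
                site_ids=[f"s{i}" for i in range(n_sites)],
                entity_ids=["x", "y"],
                values=np.column_stack([col1, col2]),
            )
            b = st.pair_cooccurrence(pa, "x", "y")
            assert a.classification == b.classification
            assert a.p_gt == pytest.approx(b.p_gt)


class TestAllPairs:
    def test_row_per_unordered_pair_in_lexicographic_order(self, small_pa):
        table = st.all_pairs_cooccurrence(small_pa)
        assert len(table) == 3
        pairs = list(zip(table.data["entity_1"], table.data["entity_2"]))
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]
        assert list(table.data.columns) == COOCCURRENCE_COLUMNS

    def test_fdr_at_least_raw_p(self, rng):
        values = rng.random((80, 6)) < 0.4
        pa = st.PresenceAbsenceMatrix(
            site_ids=[f"s{i}" for i in range(80)],
            entity_ids=list("abcdef"),
            values=values,
        )
        table = st.all_pairs_cooccurrence(pa)
        assert (table.data["q_gt"] >= table.data["p_gt"] - 1e-12).all()
        assert (table.data["q_lt"] >= table.data["p_lt"] - 1e-12).all()

    def test_expected_min_flags_but_keeps_pairs(self):
        sparse = np.zeros((50, 3), bool)
        sparse[:2, 0] = True
        sparse[2:4, 1] = True
        sparse[:30, 2] = True
        pa = st.PresenceAbsenceMatrix(
            site_ids=[f"s{i}" for i in range(50)],
            entity_ids=["rare1", "rare2", "common"],
            values=sparse,
        )
        table = st.all_pairs_cooccurrence(pa, expected_min=1.0)
        row = table.pair("rare1", "rare2")
        assert row["low_expected"] and row["expected"] < 1
        assert len(table) == 3
        filtered = st.all_pairs_cooccurrence(
            pa, expected_min=1.0, apply_expected_filter=True
        )
        assert np.isnan(filtered.pair("rare1", "rare2")["q_gt"])
        assert len(filtered) == 3

    def test_empty_entity_subset_rejected(self, small_pa):
        with pytest.raises(st.ValidationError):
            st.all_pairs_cooccurrence(small_pa, entities=[])

    def test_classification_matrix_is_symmetric(self, small_pa):
        mat = st.all_pairs_cooccurrence(small_pa).classification_matrix()
        assert (mat.values == mat.values.T).all()


class TestMonteCarloAgreement:
    def test_tails_match_column_shuffles(self, rng):
        """Shuffle oracle: empirical tails from random column placements
        agree with the exact tails within 3 binomial standard errors."""
        n_sites, n_shuffles = 200, 20_000
        for _ in range(5):
            n1 = int(rng.integers(10, 190))
            n2 = int(rng.integers(10, 190))
            col1 = np.zeros(n_sites, dtype=np.int8)
            col1[:n1] = 1
            col2 = np.zeros(n_sites, dtype=np.int8)
            col2[rng.choice(n_sites, n2, replace=False)] = 1
            observed = int((col1 & col2).sum())
            tiled = np.tile(col2, (n_shuffles, 1))
            shuffled = rng.permuted(tiled, axis=1)
            overlaps = shuffled[:, :n1].sum(axis=1)
            emp_gt = float((overlaps >= observed).mean())
            emp_lt = float((overlaps <= observed).mean())
            p_lt, p_gt = st.tail_probabilities(n_sites, n1, n2, observed)
            for emp, exact in ((emp_gt, p_gt), (emp_lt, p_lt)):
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / n_shuffles)
                assert abs(emp - exact) <= 3 * se + 1e-12
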