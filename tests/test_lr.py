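"""Ligand-receptor co-occurrence, Spearman ranking and differential
co-occurrence between strata."""
import numpy as np
import pandas as pd
import pytest

import stcooccur as st
from stcooccur.lr import LR_COLUMNS


def lr_table(pairs):
    return st.LRPairTable(
        pairs=pd.DataFrame(pairs, columns=["ligand", "receptor"])
    )


class TestBinarizeCounts:
    def test_count_threshold_inclusive(self, toy_counts):
        """A single transcript already counts as presence at min_count=1."""
        pa = st.binarize_counts(toy_counts, min_count=1)
        assert pa.values[0, 3]  # count 1 -> present
        pa2 = st.binarize_counts(toy_counts, min_count=2)
        assert not pa2.values[0, 3]  # count 1 < 2 -> absent

    def test_zero_gene_all_absent(self):
        counts = st.SpotCountMatrix(
            spot_ids=["s0", "s1"], gene_ids=["g0", "g1"],
            counts=np.array([[0, 2], [0, 1]]),
        )
        pa = st.binarize_counts(counts)
        assert not pa.column("g0").any()

    def test_min_count_must_be_positive(self, toy_counts):
        with pytest.raises(st.ValidationError):
            st.binarize_counts(toy_counts, min_count=0)


class TestLRCooccurrence:
    def _planted(self, seed=0, joint=0.40, marg=0.45, n=500):
        planted = [
            st.PlantedLR(
                "G0000", "G0001",
                {"all": st.PlantedPair("G0000", "G0001", joint, marg, marg)},
            )
        ]
        spec = st.SimulationSpec(seed=seed, n_spots=n, n_genes=40)
        return st.simulate_counts(spec, planted_lr=planted)

    def test_planted_pair_positive_with_correlated_expression(self):
        counts, _ = self._planted()
        table = st.lr_cooccurrence(counts, lr_table([("G0000", "G0001")]))
        row = table.pair("G0000", "G0001")
        assert row["classification"] == "positive"
        assert row["q_gt"] < 0.05
        assert row["rho"] > 0.5

    def test_constant_gene_has_undefined_rho_but_is_retained(self):
        counts = st.SpotCountMatrix(
            spot_ids=[f"s{i}" for i in range(6)],
            gene_ids=["L", "R"],
            counts=np.column_stack([np.full(6, 2), [0, 1, 0, 2, 1, 0]]),
        )
        table = st.lr_cooccurrence(counts, lr_table([("L", "R")]))
        row = table.pair("L", "R")
        assert np.isnan(row["rho"])
        assert row["n1"] == 6 and row["degenerate"]

    def test_missing_genes_skipped_with_warning(self, toy_counts):
        with pytest.warns(UserWarning, match="skipping"):
            table = st.lr_cooccurrence(
                toy_counts, lr_table([("LIG", "REC"), ("LIG", "ABSENT")])
            )
        assert len(table) == 1
        assert table.skipped_pairs == [("LIG", "ABSENT")]

    def test_empty_site_subset_rejected(self, toy_counts):
        with pytest.raises(st.ValidationError):
            st.lr_cooccurrence(
                toy_counts, lr_table([("LIG", "REC")]), sites=[]
            )

    def test_site_restriction_equals_presliced_matrix(self):
        counts, _ = self._planted(seed=3, n=200)
        half = list(counts.spot_ids[:100])
        a = st.lr_cooccurrence(
            counts, lr_table([("G0000", "G0001")]), sites=half
        )
        b = st.lr_cooccurrence(
            counts.subset_spots(half), lr_table([("G0000", "G0001")])
        )
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_rho_invariant_under_monotone_transform(self):
        counts, _ = self._planted(seed=4, n=150)
        squared = st.SpotCountMatrix(
            spot_ids=counts.spot_ids,
            gene_ids=counts.gene_ids,
            counts=counts.dense() ** 2,
        )
        a = st.lr_cooccurrence(counts, lr_table([("G0000", "G0001")]))
        b = st.lr_cooccurrence(squared, lr_table([("G0000", "G0001")]))
        assert a.pair("G0000", "G0001")["rho"] == pytest.approx(
            b.pair("G0000", "G0001")["rho"]
        )

    def test_independent_genes_mostly_random(self):
        """Type-I behaviour: two independent 30%-prevalence genes over 500
        sites are classified random in the vast majority of replicates."""
        rng = np.random.default_rng(5)
        n_random = 0
        reps = 60
        for _ in range(reps):
            vals = (rng.random((500, 2)) < 0.3).astype(int) * (
                1 + rng.poisson(2.0, size=(500, 2))
            )
            counts = st.SpotCountMatrix(
                spot_ids=[f"s{i}" for i in range(500)],
                gene_ids=["L", "R"],
                counts=vals,
            )
            table = st.lr_cooccurrence(counts, lr_table([("L", "R")]))
            n_random += table.pair("L", "R")["classification"] == "random"
        assert n_random / reps >= 0.90


class TestSurfaceome:
    def test_all_combinations_minus_self_pairs(self, rng):
        counts = st.SpotCountMatrix(
            spot_ids=[f"s{i}" for i in range(30)],
            gene_ids=list("ABCDEFG"),
            counts=rng.poisson(1.0, size=(30, 7)),
        )
        table = st.surfaceome_pairs_cooccurrence(
            counts, ["A", "B", "C"], ["C", "D", "E", "F"]
        )
        assert len(table) == 3 * 4 - 1  # C x C self-pair dropped
        assert list(table.data.columns) == LR_COLUMNS

    def test_annotated_flag_from_pair_table(self, rng):
        counts = st.SpotCountMatrix(
            spot_ids=[f"s{i}" for i in range(30)],
            gene_ids=["A", "B", "C"],
            counts=rng.poisson(1.0, size=(30, 3)),
        )
        table = st.surfaceome_pairs_cooccurrence(
            counts, ["A"], ["B", "C"], lr_table=lr_table([("A", "B")])
        )
        assert bool(table.pair("A", "B")["annotated"])
        assert not bool(table.pair("A", "C")["annotated"])

    def test_empty_gene_set_rejected(self, toy_counts):
        with pytest.raises(st.ValidationError):
            st.surfaceome_pairs_cooccurrence(toy_counts, [], ["REC"])


def make_lr_result(rows, alpha=0.05):
    df = pd.DataFrame(rows)
    for col in LR_COLUMNS:
        if col not in df.columns:
            df[col] = {
                "n_sites": 100, "n1": 10, "n2": 10, "observed": 5,
                "expected": 1.0, "p_lt": 1.0, "p_gt": 0.5, "q_lt": 1.0,
                "classification": "random", "degenerate": False,
                "rho": 0.0, "annotated": True,
            }.get(col, np.nan)
    return st.LRCooccurrenceTable(data=df, alpha=alpha)


class TestDifferential:
    def test_selection_rule_and_score(self):
        target = make_lr_result(
            [{"ligand": "L1", "receptor": "R1", "q_gt": 0.01},
             {"ligand": "L2", "receptor": "R2", "q_gt": 0.01},
             {"ligand": "L3", "receptor": "R3", "q_gt": 0.20}]
        )
        other = make_lr_result(
            [{"ligand": "L1", "receptor": "R1", "q_gt": 0.50},
             {"ligand": "L2", "receptor": "R2", "q_gt": 0.03},
             {"ligand": "L3", "receptor": "R3", "q_gt": 0.90}]
        )
        diff = st.differential_cooccurrence(target, other)
        by_pair = diff.set_index(["ligand", "receptor"])
        # q_target=0.01, q_other=0.50: selected, score 0.49
        assert bool(by_pair.loc[("L1", "R1"), "selected"])
        assert by_pair.loc[("L1", "R1"), "score"] == pytest.approx(0.49)
        # co-occurs in both strata: not differential
        assert not by_pair.loc[("L2", "R2"), "selected"]
        # not significant in the target stratum
        assert not by_pair.loc[("L3", "R3"), "selected"]
        # selected pairs sort first (descending score)
        assert diff.iloc[0]["score"] == diff["score"].max()
        assert (~diff["selected"] | (diff["score"] > 0)).all()

    def test_missing_side_gets_q_one_with_flag(self):
        target = make_lr_result(
            [{"ligand": "L1", "receptor": "R1", "q_gt": 0.01},
             {"ligand": "L2", "receptor": "R2", "q_gt": 0.02}]
        )
        other = make_lr_result(
            [{"ligand": "L1", "receptor": "R1", "q_gt": 0.80}]
        )
        diff = st.differential_cooccurrence(target, other)
        row = diff.set_index(["ligand", "receptor"]).loc[("L2", "R2")]
        assert row["q_other"] == 1.0 and row["missing_in_other"]
        assert row["selected"]

    def test_disjoint_universes_warn_or_raise(self):
        a = make_lr_result([{"ligand": "L1", "receptor": "R1", "q_gt": 0.01}])
        b = make_lr_result([{"ligand": "L9", "receptor": "R9", "q_gt": 0.5}])
        with pytest.warns(UserWarning):
            diff = st.differential_cooccurrence(a, b)
        assert diff.empty
        with pytest.raises(st.ValidationError):
            st.differential_cooccurrence(a, b, strict=True)

    def test_edge_list_marks_support_and_annotation(self):
        table = make_lr_result(
            [{"ligand": "L1", "receptor": "R1", "q_gt": 0.01,
              "observed": 25, "annotated": True},
             {"ligand": "L2", "receptor": "R2", "q_gt": 0.01,
              "observed": 3, "annotated": False},
             {"ligand": "L3", "receptor": "R3", "q_gt": 0.90,
              "observed": 50, "annotated": True}]
        )
        edges = st.cooccurrence_edges(table, min_spots=20)
        assert len(edges) == 2  # only significant pairs become edges
        by = edges.set_index("ligand")
        assert bool(by.loc["L1", "high_support"])
        assert not bool(by.loc["L2", "high_support"])
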