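"""LR-associated gene signature with permutation Monte Carlo FDR.

Simulates 160 spots with a planted LR pair and 20 genes whose expression
doubles in spots double-positive (DP) for the pair.  Splits spots into DP
and double-negative (DN) groups, runs per-gene rank-sum tests, and then
checks specificity against a 1000-fold random re-splitting null.
"""
import stcooccur as st

spec = st.SimulationSpec(seed=0, n_spots=160, n_genes=500)
planted = [
    st.PlantedLR(
        "G0000", "G0001",
        {"all": st.PlantedPair("G0000", "G0001", 0.40, 0.50, 0.50)},
    )
]
counts, truth = st.simulate_counts(spec, planted_lr=planted, n_planted_degs=20)

dp, dn = st.split_spots_by_lr(counts, "G0000", "G0001", min_count=1)
print(f"{len(dp)} double-positive and {len(dn)} double-negative spots "
      "(single-positive spots are excluded)")

degs = st.lr_associated_degs(counts, dp, dn, normalization="log_cpm")
degs = st.monte_carlo_fdr(
    counts, list(dp) + list(dn), (len(dp), len(dn)), degs,
    n_permutations=1000, seed=0,
)
hits = degs[degs["q"] < 0.05].sort_values("monte_carlo_p")
true_set = set(truth["deg_genes"])
n_true = sum(g in true_set for g in hits["gene"])
print(f"\n{len(hits)} genes at Monte Carlo FDR q < 0.05; "
      f"{n_true} of the 20 planted DE genes recovered "
      f"(sensitivity {n_true / 20:.2f})")
print("\nTop signature genes:")
cols = ["gene", "p", "log2fc", "monte_carlo_p", "q"]
print(hits[cols].head(8).round(4).to_string(index=False))
print("\nmonte_carlo_p is floored at 1/(B+1) = 1/1001 ~ 0.001, the smallest "
      "value 1000 permutations can resolve.")
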