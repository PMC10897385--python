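"""Single-cell co-occurrence in kNN neighborhoods (FISH-style data).

Simulates one imaged ROI of 300 segmented cells in which fibroblasts are
placed within ~15 um of M cells (co-localized), and a second ROI where the
two types occupy opposite halves of the window (segregated).  After QC and
marker annotation, each cell plus its 5 nearest neighbors forms a
neighborhood; cell-type co-occurrence is tested per ROI.
"""
import pandas as pd

import stcooccur as st
from stcooccur.simulate import DEFAULT_MARKERS

frames = []
for pattern in ("colocalized", "segregated"):
    spec = st.SimulationSpec(seed=0, n_rois=1, n_cells_per_roi=300)
    seg, _ = st.simulate_point_pattern(spec, pattern=pattern)
    seg = st.filter_segments(seg, min_molecules=3, min_genes=3)
    seg = st.annotate_segments(seg, DEFAULT_MARKERS)
    nbrs = st.build_knn_neighborhoods(seg, k=5, include_focal=True)
    table = st.neighborhood_cooccurrence(nbrs, seg)["roi1"]
    row = table.pair("M_cell", "Fibroblast")
    frames.append(
        {"pattern": pattern, "n_neighborhoods": row["n_sites"],
         "observed": row["observed"], "expected": round(row["expected"], 1),
         "p_gt": f"{row['p_gt']:.2e}", "p_lt": f"{row['p_lt']:.2e}",
         "classification": row["classification"]}
    )

print(pd.DataFrame(frames).to_string(index=False))
print(
    "\nEach neighborhood holds a focal cell plus its 5 nearest neighbors. "
    "Interleaved types share far more neighborhoods than their frequencies "
    "predict (positive); spatially separated types share almost none "
    "(negative)."
)
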