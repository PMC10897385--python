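"""Seeded generators for every input the pipeline consumes, with planted
structure so that all statistical claims are testable without external data.

Three generators mirror the three data modalities:

* :func:`simulate_deconvolution` — spot x cell-type probability matrices
  drawn from Dirichlet mixtures around archetype compositions (the ground
  truth for composition-class recovery), optionally with planted
  co-occurring cell-type pairs realized directly on the presence scale.
* :func:`simulate_counts` — negative-binomial spot x gene count matrices
  with log-normal gene means and library sizes, planted ligand-receptor
  co-expression per stratum and planted DE genes between LR
  double-positive and double-negative spots.
* :func:`simulate_point_pattern` — 2-D segment tables per ROI with
  co-localized, segregated, or uniformly mixed cell-type pairs, and marker
  counts chosen so that annotation recovers the true type.

Every generator takes an integer seed (or a numpy Generator) and is
deterministic given it.  Truth is always returned alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import DeconvolutionMatrix, SegmentTable, SpotCountMatrix
from .errors import ValidationError


@dataclass
class PlantedPair:
    """A pair of entities with controlled joint-presence structure.

    ``joint`` is the probability that both entities are present at a site;
    ``marginal_a``/``marginal_b`` the per-entity presence probabilities.
    Independence corresponds to joint = marginal_a * marginal_b.
    """

    entity_a: str
    entity_b: str
    joint: float
    marginal_a: float
    marginal_b: float

    def __post_init__(self):
        for name in ("joint", "marginal_a", "marginal_b"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.joint > min(self.marginal_a, self.marginal_b) + 1e-12:
            raise ValidationError(
                "joint prevalence cannot exceed either marginal"
            )
        if self.marginal_a + self.marginal_b - self.joint > 1 + 1e-12:
            raise ValidationError(
                "infeasible prevalences: P(A or B) would exceed 1"
            )


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults describe a modest spot-based experiment: 600 spots, 6 cell
    types mixing 3 archetypal compositions with Dirichlet concentration 30
    (tight, well-separated communities), 100 genes with log-normal
    negative-binomial means (dispersion 0.5, typical overdispersion of spot
    data) and log-normal library-size variation; FISH ROIs of 300 cells in a
    500 um square window with a 15 um co-localization kernel.
    """

    seed: int = 0
    # deconvolution
    n_spots: int = 600
    n_celltypes: int = 6
    n_archetypes: int = 3
    archetypes: np.ndarray | None = None
    dirichlet_concentration: float = 30.0
    planted_celltype_pairs: list = field(default_factory=list)
    # counts
    n_genes: int = 100
    nb_dispersion: float = 0.5  # dispersion of a typical (median-mean) gene
    nb_dispersion_asymptote: float = 0.1  # floor of the dispersion-mean trend
    log_mean_mu: float = 1.0
    log_mean_sigma: float = 1.0
    libsize_sigma: float = 0.3
    planted_lr_mean: float = 3.0
    planted_deg_mean: float = 20.0
    deg_fold_change: float = 2.0
    # point patterns
    n_rois: int = 2
    n_cells_per_roi: int = 300
    window_um: float = 500.0
    colocalization_bandwidth_um: float = 15.0


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_joint_presence(
    rng: np.random.Generator, n: int, pair: PlantedPair
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two boolean presence vectors with exact target joint structure.

    Sites are assigned to the four cells of the 2x2 presence table with
    probabilities (joint, pa - joint, pb - joint, remainder), which realizes
    the requested marginals and joint prevalence simultaneously.
    """
    p_both = pair.joint
    p_a_only = pair.marginal_a - pair.joint
    p_b_only = pair.marginal_b - pair.joint
    p_none = 1 - p_both - p_a_only - p_b_only
    cell = rng.choice(4, size=n, p=[p_both, p_a_only, p_b_only, p_none])
    a = (cell == 0) | (cell == 1)
    b = (cell == 0) | (cell == 2)
    return a, b


def default_archetypes(n_archetypes: int, n_celltypes: int) -> np.ndarray:
    """Archetype composition profiles: each archetype is dominated by its
    own subset of cell types over a small common baseline."""
    if n_archetypes > n_celltypes:
        raise ValidationError("need at least one dominant cell type each")
    profiles = np.full((n_archetypes, n_celltypes), 0.05)
    for a in range(n_archetypes):
        dominant = np.arange(a, n_celltypes, n_archetypes)
        profiles[a, dominant] = 1.0
    return profiles / profiles.sum(axis=1, keepdims=True)


def simulate_deconvolution(
    spec: SimulationSpec, seed=None
) -> tuple[DeconvolutionMatrix, dict]:
    """Spot x cell-type probabilities from archetype mixtures.

    Each spot picks an archetype uniformly at random (the true composition
    class) and draws its composition from
    Dirichlet(concentration * archetype profile).  Planted cell-type pairs
    replace the corresponding probability columns: presence of a planted
    entity puts its probability above the 0.1 presence threshold
    (uniform in [0.12, 0.35]) and absence below it (uniform in [0, 0.08]);
    the remaining columns are rescaled so each row still sums to 1.

    Returns the matrix and a truth dict with ``cc_labels`` (archetype index
    per spot) and ``planted_presence`` (DataFrame of true presence calls).
    """
    rng = _rng(spec.seed if seed is None else seed)
    arch = (
        np.asarray(spec.archetypes, dtype=float)
        if spec.archetypes is not None
        else default_archetypes(spec.n_archetypes, spec.n_celltypes)
    )
    n_arch, n_ct = arch.shape
    labels = rng.integers(0, n_arch, size=spec.n_spots)
    alpha = spec.dirichlet_concentration * arch + 1e-3
    probs = np.vstack(
        [rng.dirichlet(alpha[lab]) for lab in labels]
    )
    celltypes = np.array([f"CT{i + 1}" for i in range(n_ct)], dtype=object)
    spots = np.array([f"spot{i:05d}" for i in range(spec.n_spots)], dtype=object)

    presence_truth = {}
    planted_cols = []
    for pair in spec.planted_celltype_pairs:
        ia = int(np.where(celltypes == pair.entity_a)[0][0])
        ib = int(np.where(celltypes == pair.entity_b)[0][0])
        a, b = sample_joint_presence(rng, spec.n_spots, pair)
        for idx, present in ((ia, a), (ib, b)):
            col = np.where(
                present,
                rng.uniform(0.12, 0.35, size=spec.n_spots),
                rng.uniform(0.0, 0.08, size=spec.n_spots),
            )
            probs[:, idx] = col
            planted_cols.append(idx)
        presence_truth[pair.entity_a] = a
        presence_truth[pair.entity_b] = b
    if planted_cols:
        planted_cols = sorted(set(planted_cols))
        other = [j for j in range(n_ct) if j not in planted_cols]
        if not other:
            raise ValidationError("at least one non-planted cell type required")
        remaining = 1.0 - probs[:, planted_cols].sum(axis=1)
        if (remaining <= 0).any():
            raise ValidationError("planted probabilities exceed row budget")
        row_other = probs[:, other].sum(axis=1)
        probs[:, other] *= (remaining / row_other)[:, None]

    D = DeconvolutionMatrix(spot_ids=spots, celltype_ids=celltypes, probs=probs)
    truth = {
        "cc_labels": labels,
        "planted_presence": pd.DataFrame(presence_truth, index=spots),
    }
    return D, truth


@dataclass
class PlantedLR:
    """A ligand-receptor pair planted into the count matrix.

    ``presence_by_stratum`` maps stratum label -> PlantedPair-style presence
    structure for the two genes in that stratum.  Strata absent from the map
    leave both genes at zero.
    """

    ligand: str
    receptor: str
    presence_by_stratum: dict


def simulate_counts(
    spec: SimulationSpec,
    strata=None,
    planted_lr: list | None = None,
    n_planted_degs: int = 0,
    seed=None,
) -> tuple[SpotCountMatrix, dict]:
    """Negative-binomial count matrix with planted LR pairs and DE genes.

    Background genes draw per-gene means from a log-normal and counts from
    NB(mean * library factor, dispersion).  Gene-wise dispersion follows the
    usual decreasing dispersion-mean trend,
    ``disp(mean) = asymptote + slope / mean``, with the slope calibrated so
    that a typical gene (mean at the log-normal median) has dispersion
    ``nb_dispersion``.  Planted LR genes are generated on the presence scale
    first (joint Bernoulli structure per stratum) and receive counts
    1 + Poisson with a spot-level shared log-normal amplitude when present,
    giving correlated ligand/receptor expression.  Planted DE genes
    (moderately high expression, mean ``planted_deg_mean``, hence low trend
    dispersion) have their mean multiplied by ``deg_fold_change`` in spots
    double-positive for the first planted pair.

    ``strata`` is an optional array of per-spot stratum labels (e.g. CC
    labels or conditions); default: one stratum "all".
    """
    rng = _rng(spec.seed if seed is None else seed)
    n = spec.n_spots
    strata = (
        np.asarray(strata, dtype=object)
        if strata is not None
        else np.full(n, "all", dtype=object)
    )
    if len(strata) != n:
        raise ValidationError("strata length must equal n_spots")
    planted_lr = planted_lr or []

    genes = np.array([f"G{i:04d}" for i in range(spec.n_genes)], dtype=object)
    spots = np.array([f"spot{i:05d}" for i in range(n)], dtype=object)
    gene_index = {g: i for i, g in enumerate(genes)}

    means = rng.lognormal(spec.log_mean_mu, spec.log_mean_sigma, size=spec.n_genes)
    lib = rng.lognormal(0.0, spec.libsize_sigma, size=n)

    disp_asym = min(spec.nb_dispersion_asymptote, spec.nb_dispersion)
    disp_slope = (spec.nb_dispersion - disp_asym) * np.exp(spec.log_mean_mu)

    def _dispersion(m):
        return disp_asym + disp_slope / np.maximum(m, 1e-9)

    lr_gene_idx = set()
    presence = {}
    for planted in planted_lr:
        for g in (planted.ligand, planted.receptor):
            if g not in gene_index:
                raise ValidationError(f"planted gene {g!r} not in gene set")
            lr_gene_idx.add(gene_index[g])
        a_all = np.zeros(n, dtype=bool)
        b_all = np.zeros(n, dtype=bool)
        for stratum, pair in planted.presence_by_stratum.items():
            mask = strata == stratum
            if not mask.any():
                raise ValidationError(f"stratum {stratum!r} has no spots")
            a, b = sample_joint_presence(rng, int(mask.sum()), pair)
            a_all[mask] = a
            b_all[mask] = b
        presence[planted.ligand] = a_all
        presence[planted.receptor] = b_all

    deg_genes = []
    if n_planted_degs:
        if not planted_lr:
            raise ValidationError("planted DE genes require a planted LR pair")
        candidates = [
            i for i in range(spec.n_genes) if i not in lr_gene_idx
        ]
        deg_idx = rng.choice(candidates, size=n_planted_degs, replace=False)
        deg_genes = [genes[i] for i in deg_idx]
        # moderately expressed so a 2-fold shift is a realistic DE signal
        means[deg_idx] = rng.lognormal(
            np.log(spec.planted_deg_mean), 0.3, size=n_planted_degs
        )

    mu = np.outer(lib, means)
    if len(deg_genes):
        first = planted_lr[0]
        dp = presence[first.ligand] & presence[first.receptor]
        mu[np.ix_(dp, [gene_index[g] for g in deg_genes])] *= spec.deg_fold_change

    size = 1.0 / _dispersion(means)  # per gene, from the base mean
    counts = rng.negative_binomial(size[None, :], size[None, :] / (size[None, :] + mu))

    for gene, present in presence.items():
        j = gene_index[gene]
        amp = rng.lognormal(0.0, 0.5, size=n)
        vals = 1 + rng.poisson(spec.planted_lr_mean * amp)
        counts[:, j] = np.where(present, vals, 0)

    matrix = SpotCountMatrix(
        spot_ids=spots, gene_ids=genes, counts=sp.csr_matrix(counts)
    )
    truth = {
        "strata": strata,
        "planted_lr": planted_lr,
        "planted_presence": pd.DataFrame(presence, index=spots),
        "deg_genes": list(deg_genes),
    }
    return matrix, truth


DEFAULT_MARKERS = {
    "M_cell": ["SPIB", "CCL20", "TNFAIP2"],
    "Fibroblast": ["PDGFRA", "PDPN", "COL1A1"],
    "Epithelial": ["EPCAM", "KRT8", "CDH1"],
    "T_cell": ["CD3D", "CD3E", "TRAC"],
}


def simulate_point_pattern(
    spec: SimulationSpec,
    pattern: str = "uniform",
    pair: tuple[str, str] = ("M_cell", "Fibroblast"),
    marker_map: dict | None = None,
    seed=None,
) -> tuple[SegmentTable, dict]:
    """2-D segment tables with controlled spatial structure per ROI.

    Patterns for the chosen cell-type ``pair``:

    * ``"uniform"``   — every cell placed uniformly, types i.i.d. (null);
    * ``"colocalized"`` — each cell of the second type is placed at a
      Gaussian offset (bandwidth ``colocalization_bandwidth_um``) from a
      random cell of the first type;
    * ``"segregated"`` — the two types occupy opposite halves of the window.

    Cell types are drawn uniformly from the marker map's types.  Each
    segment receives 1 + Poisson(1) molecules of each of its own type's
    marker genes (so the QC filter passes and annotation recovers truth)
    plus sparse Poisson(0.05) background on the full panel.
    """
    rng = _rng(spec.seed if seed is None else seed)
    markers = marker_map or DEFAULT_MARKERS
    types = list(markers)
    for t in pair:
        if t not in types:
            raise ValidationError(f"pattern pair type {t!r} not in marker map")
    panel = sorted({g for genes in markers.values() for g in genes})
    w = spec.window_um

    rows = []
    for roi_i in range(spec.n_rois):
        roi = f"roi{roi_i + 1}"
        labels = rng.choice(types, size=spec.n_cells_per_roi)
        xy = rng.uniform(0, w, size=(spec.n_cells_per_roi, 2))
        a_name, b_name = pair
        a_mask = labels == a_name
        b_mask = labels == b_name
        if pattern == "colocalized":
            anchors = np.flatnonzero(a_mask)
            if anchors.size:
                for i in np.flatnonzero(b_mask):
                    anchor = xy[rng.choice(anchors)]
                    xy[i] = np.clip(
                        anchor
                        + rng.normal(
                            0, spec.colocalization_bandwidth_um, size=2
                        ),
                        0,
                        w,
                    )
        elif pattern == "segregated":
            xy[a_mask, 0] = rng.uniform(0, w / 2, size=int(a_mask.sum()))
            xy[b_mask, 0] = rng.uniform(w / 2, w, size=int(b_mask.sum()))
        elif pattern != "uniform":
            raise ValidationError(f"unknown pattern {pattern!r}")

        counts = rng.poisson(0.05, size=(spec.n_cells_per_roi, len(panel)))
        gcol = {g: j for j, g in enumerate(panel)}
        for i, lab in enumerate(labels):
            for g in markers[lab]:
                counts[i, gcol[g]] += 1 + rng.poisson(1.0)
        for i in range(spec.n_cells_per_roi):
            row = {
                "segment_id": f"{roi}_seg{i:04d}",
                "roi_id": roi,
                "x": xy[i, 0],
                "y": xy[i, 1],
            }
            row.update({g: int(counts[i, gcol[g]]) for g in panel})
            row["_true_type"] = labels[i]
            rows.append(row)

    df = pd.DataFrame(rows)
    truth_types = df.pop("_true_type")
    table = SegmentTable(data=df)
    truth = {
        "true_types": pd.Series(
            truth_types.to_numpy(), index=df["segment_id"].to_numpy()
        ),
        "pattern": pattern,
        "pair": pair,
    }
    return table, truth
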