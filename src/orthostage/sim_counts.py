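"""Stage-structured two-species count simulator with known truth.

The model: every gene has a baseline weight shared by both species. A fraction
of genes are stage markers (up-regulated by ``stage_effect`` log2 units in
exactly one stage); a further fraction follow smooth profiles across the
ordered stages — half strictly monotone ("trajectory"), half arch-shaped
(peaking mid-trajectory) — so that the stage structure is a curve in
expression space, as in embryo data, rather than a set of orthogonal blobs.
It is this curve that makes stage order recoverable from two principal
components.

Species-specific effects: a monotone power-law distortion of expected
expression (``gamma``; the platform/batch effect the rank harmonization must
nullify exactly), per-cell log-normal library sizes, negative-binomial
sampling noise, and independent Bernoulli dropout. The UMI-based platform
(species A) gets lower dispersion and dropout than the non-UMI platform
(species B).

Truth returned per run: stage label per cell (also in cell_meta), the marker
gene list per stage, the trajectory/arch gene lists, and the noise-free
relative expression matrices from which the counts were sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CountMatrix

DEFAULT_STAGES = ("ICM", "preEPI", "postEPI-early", "postEPI-late", "Gast1")


@dataclass
class ExpressionSimConfig:
    stages: tuple = DEFAULT_STAGES
    cells_per_stage: int = 40           # per species
    n_genes: int = 2_000
    stage_marker_fraction: float = 0.15
    trajectory_fraction: float = 0.10
    stage_effect: float = 1.5           # log2 units
    gamma: dict = field(default_factory=lambda: {"A": 1.0, "B": 1.6})
    library_size_log_mean: dict = field(
        default_factory=lambda: {"A": np.log(25_000.0), "B": np.log(30_000.0)}
    )
    library_size_log_sd: dict = field(default_factory=lambda: {"A": 0.25, "B": 0.25})
    dropout_rate: dict = field(default_factory=lambda: {"A": 0.10, "B": 0.30})
    nb_dispersion: dict = field(default_factory=lambda: {"A": 0.10, "B": 0.30})
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    marker_baseline_floor: float = 1.0  # informative genes are decently expressed
    embryos_per_stage: int = 4
    noiseless: bool = False             # counts = round(expected); no dropout
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_stage <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        for d in (self.dropout_rate,):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("dropout rates must be probabilities")
        if self.stage_marker_fraction + self.trajectory_fraction > 1.0:
            raise ValueError("marker + trajectory fractions exceed 1")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")


@dataclass
class ExpressionTruth:
    stage_of_cell: dict
    markers: pd.DataFrame            # gene_id, role, stage, direction
    expected_expression: dict        # species -> cells x genes relative expression
    config: ExpressionSimConfig = field(repr=False, default=None)

    def marker_genes(self, stage: str) -> list:
        sub = self.markers[(self.markers.role == "marker") & (self.markers.stage == stage)]
        return sub.gene_id.tolist()


def _stage_multipliers(config: ExpressionSimConfig, rng) -> tuple:
    """Per-gene, per-stage log2 effect matrix plus the gene-role table."""
    n_stages = len(config.stages)
    n_marker = int(round(config.n_genes * config.stage_marker_fraction))
    n_traj = int(round(config.n_genes * config.trajectory_fraction))
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]

    perm = rng.permutation(config.n_genes)
    marker_idx = perm[:n_marker]
    traj_idx = perm[n_marker : n_marker + n_traj]

    log2_effect = np.zeros((config.n_genes, n_stages))
    rows = []
    for j, gi in enumerate(marker_idx):
        s = j % n_stages
        log2_effect[gi, s] = config.stage_effect
        rows.append({"gene_id": gene_ids[gi], "role": "marker",
                     "stage": config.stages[s], "direction": 1})
    t = np.linspace(0.0, 1.0, n_stages)
    for j, gi in enumerate(traj_idx):
        direction = 1 if rng.random() < 0.5 else -1
        if j % 2 == 0:
            profile = t                      # strictly monotone across stages
            role = "trajectory"
        else:
            # Arch, peaking mid-trajectory, at reduced amplitude: the curvature
            # of a developmental trajectory is secondary to its principal axis,
            # which keeps the monotone axis dominant in the PC plane while the
            # arch still spreads the stages in two dimensions.
            profile = 0.7 * (1.0 - np.abs(2.0 * t - 1.0))
            role = "arch"
        log2_effect[gi] = config.stage_effect * direction * profile
        rows.append({"gene_id": gene_ids[gi], "role": role, "stage": "", "direction": direction})
    markers = pd.DataFrame(rows, columns=["gene_id", "role", "stage", "direction"])
    return gene_ids, log2_effect, markers


def simulate_counts(config: ExpressionSimConfig):
    """Simulate both species' count matrices.

    Returns ({"A": CountMatrix, "B": CountMatrix}, ExpressionTruth). The same
    seed yields identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, log2_effect, markers = _stage_multipliers(config, rng)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    informative = markers.gene_id.tolist()
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g in informative:
        baseline[pos[g]] = max(baseline[pos[g]], config.marker_baseline_floor)

    stage_means = {
        s: baseline * np.exp2(log2_effect[:, k]) for k, s in enumerate(config.stages)
    }

    matrices = {}
    expected = {}
    stage_of_cell = {}
    for species in ("A", "B"):
        gamma = config.gamma[species]
        counts_rows, cell_ids, meta_rows, expected_rows = [], [], [], []
        for s_idx, stage in enumerate(config.stages):
            m = stage_means[stage] ** gamma
            p = m / m.sum()
            for c in range(config.cells_per_stage):
                cid = f"{species}_{stage}_c{c:03d}"
                lib = float(
                    np.exp(
                        rng.normal(
                            config.library_size_log_mean[species],
                            config.library_size_log_sd[species],
                        )
                    )
                )
                mu = p * lib
                if config.noiseless:
                    counts = np.round(mu).astype(np.int64)
                else:
                    disp = config.nb_dispersion[species]
                    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp) if disp > 0 else mu
                    counts = rng.poisson(lam).astype(np.int64)
                    drop = config.dropout_rate[species]
                    if drop > 0:
                        counts[rng.random(config.n_genes) < drop] = 0
                counts_rows.append(counts)
                expected_rows.append(p)
                cell_ids.append(cid)
                stage_of_cell[cid] = stage
                meta_rows.append(
                    {
                        "species": species,
                        "phenotype": stage,
                        "individual": f"{species}_{stage}_emb{c % config.embryos_per_stage}",
                    }
                )
        meta = pd.DataFrame(meta_rows, index=cell_ids)
        matrices[species] = CountMatrix(
            np.vstack(counts_rows), cell_ids, list(gene_ids), meta
        )
        expected[species] = np.vstack(expected_rows)

    truth = ExpressionTruth(
        stage_of_cell=stage_of_cell,
        markers=markers,
        expected_expression=expected,
        config=config,
    )
    return matrices, truth
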