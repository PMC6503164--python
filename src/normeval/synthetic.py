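"""Seeded count-matrix simulator with known ground truth.

Counts for gene i in sample j are negative binomial with mean
``mu_i * e_ij * d_j`` where d_j is the true per-sample depth (log-uniform)
and e_ij a group fold change for the DE genes; low-mean entries are then
zeroed with a dropout probability decreasing in the mean.  Spike-in rows
use a fixed concentration ladder scaled by a spike depth independent of the
cellular depth, mimicking fixed-volume spike-in addition; housekeeping rows
are non-DE with low dispersion and the first seven reuse the HG7 gene names
so control-set methods work out of the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import (
    HG7_GENES,
    CountMatrix,
    GeneAnnotation,
    SampleMeta,
)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_samples: int = 20
    depth_log_range: tuple[float, float] = (np.log(0.25), np.log(4.0))
    de_fraction: float = 0.1
    de_fold_sd: float = 1.0
    dropout: float = 0.0            # max zero-inflation probability
    dropout_scale: float = 20.0     # mean at which dropout decays by 1/e
    n_spikein: int = 50
    n_hk: int = 7
    n_mito: int = 10
    dispersion: float = 0.2
    mean_log_mu: float = 3.0        # log-normal location of gene base means
    sd_log_mu: float = 1.6
    mu_floor: float = 0.0           # lower bound on gene base means
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 4 or self.n_samples < 2:
            raise ValueError("need n_genes >= 4 and n_samples >= 2")
        if self.n_spikein + self.n_hk + self.n_mito >= self.n_genes:
            raise ValueError("special rows must leave room for regular genes")
        for frac in (self.de_fraction, self.dropout):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.de_fraction >= 1:
            raise ValueError("all-DE configuration is degenerate")
        if self.depth_log_range[0] >= self.depth_log_range[1]:
            raise ValueError("depth_log_range must be a proper interval")


def scrna_config(**overrides) -> SimConfig:
    """Sparse single-cell-like preset (substantial dropout and zero count)."""
    base = SimConfig(
        dropout=0.98, dropout_scale=170.0, mean_log_mu=4.0, sd_log_mu=1.5,
        mu_floor=50.0, dispersion=0.2,
    )
    return replace(base, **overrides)


def bulk_config(**overrides) -> SimConfig:
    """Dense bulk-like preset (no dropout, high means, low dispersion)."""
    base = SimConfig(
        dropout=0.0, mean_log_mu=4.0, sd_log_mu=1.2, dispersion=0.1,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class SimTruth:
    true_depths: np.ndarray
    de_gene_ids: tuple[str, ...]
    standardized_true_factors: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.standardized_true_factors is None:
            inv = 1.0 / np.asarray(self.true_depths, dtype=float)
            gm = np.exp(np.mean(np.log(inv)))
            object.__setattr__(self, "standardized_true_factors", inv / gm)


def _negative_binomial(rng, mean, dispersion):
    """NB with Var = mean + dispersion * mean^2 (gamma-Poisson mixture)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig):
    """Generate ``(CountMatrix, GeneAnnotation, SampleMeta, SimTruth)``."""
    rng = np.random.default_rng(config.seed)
    m, n = config.n_genes, config.n_samples
    n_regular = m - config.n_spikein - config.n_hk - config.n_mito

    depths = np.exp(rng.uniform(*config.depth_log_range, size=n))

    gene_ids, classes, rows = [], [], []

    # regular nuclear genes, a fraction of which are DE between two groups
    mu = config.mu_floor + rng.lognormal(
        config.mean_log_mu, config.sd_log_mu, size=n_regular
    )
    group = (np.arange(n) >= n // 2).astype(float)
    n_de = int(round(config.de_fraction * n_regular))
    de_rows = rng.choice(n_regular, size=n_de, replace=False)
    effect = np.ones((n_regular, n))
    folds = np.exp(rng.normal(0.0, config.de_fold_sd, size=n_de))
    effect[de_rows, :] = np.where(group[None, :] > 0, folds[:, None], 1.0)
    reg_mean = mu[:, None] * effect * depths[None, :]
    reg_counts = _negative_binomial(rng, reg_mean, config.dispersion)
    for i in range(n_regular):
        gene_ids.append(f"G{i + 1:05d}")
        classes.append("nuclear")
    rows.append((reg_counts, reg_mean))
    de_gene_ids = tuple(f"G{i + 1:05d}" for i in sorted(de_rows))

    # housekeeping genes: high mean, low dispersion, never DE
    if config.n_hk:
        hk_mu = rng.lognormal(config.mean_log_mu + 2.0, 0.4, size=config.n_hk)
        hk_mean = hk_mu[:, None] * depths[None, :]
        hk_counts = _negative_binomial(rng, hk_mean, min(config.dispersion, 0.05))
        for i in range(config.n_hk):
            gene_ids.append(HG7_GENES[i] if i < len(HG7_GENES) else f"HK{i + 1}")
            classes.append("nuclear")
        rows.append((hk_counts, hk_mean))

    # mitochondrial genes: very high expression, scale with cellular depth
    if config.n_mito:
        mt_mu = rng.lognormal(config.mean_log_mu + 3.0, 0.8, size=config.n_mito)
        mt_mean = mt_mu[:, None] * depths[None, :]
        mt_counts = _negative_binomial(rng, mt_mean, config.dispersion)
        for i in range(config.n_mito):
            gene_ids.append(f"MT{i + 1:03d}")
            classes.append("mitochondrial")
        rows.append((mt_counts, mt_mean))

    # spike-ins: fixed concentration ladder, depth independent of d_j
    if config.n_spikein:
        conc = 2.0 ** np.linspace(1, 12, config.n_spikein)
        spike_depth = np.exp(rng.normal(0.0, 0.15, size=n))
        sp_mean = conc[:, None] * spike_depth[None, :]
        sp_counts = _negative_binomial(rng, sp_mean, config.dispersion)
        for i in range(config.n_spikein):
            gene_ids.append(f"ERCC-{i + 1:05d}")
            classes.append("spike_in")
        rows.append((sp_counts, sp_mean))

    counts = np.vstack([c for c, _ in rows]).astype(float)
    means = np.vstack([mn for _, mn in rows])

    if config.dropout > 0:
        # detectability depends on the gene's underlying abundance, not on
        # the sample depth, so depth factors stay identifiable from the
        # zero-ignoring ratio methods
        base_abundance = means / depths[None, :]
        p_drop = config.dropout * np.exp(-base_abundance / config.dropout_scale)
        counts[rng.random(counts.shape) < p_drop] = 0.0

    matrix = CountMatrix(counts, tuple(gene_ids), tuple(_sample_names(n)))

    annotation = GeneAnnotation(
        gene_class=dict(zip(gene_ids, classes)),
        control_sets={
            "ERCC": [g for g, c in zip(gene_ids, classes) if c == "spike_in"],
        },
    )

    aligned = counts.sum(axis=0)
    unassigned = rng.uniform(0.1, 0.3, size=n)
    total_reads = np.maximum(np.round(aligned * (1 + unassigned)), 1.0)
    meta = SampleMeta(matrix.sample_ids, total_reads)

    truth = SimTruth(depths, de_gene_ids)
    return matrix, annotation, meta, truth


def _sample_names(n: int) -> list[str]:
    return [f"S{j + 1:03d}" for j in range(n)]
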