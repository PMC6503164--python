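"""Evaluation metrics for normalized matrices.

* ``cv_raw`` — sample standard deviation over mean, across all samples
  including zeros.
* ``cv_log2`` — sd/mean of log2 of the strictly positive values only
  (zeros do not contribute to n*); this is the CV that feeds the threshold
  curve.
* AUCVC — area under the curve of uniform-gene counts against the
  min-max-normalized CV cutoff, computed as the grid-mean uniform fraction
  on an even grid in (0, 1] (default 1000 points), so it lives in [0, 1].
* mSCC — median Spearman correlation over seeded, distinct, unordered
  ubiquitous gene pairs.
* RLE_MED / RLE_IQR — mean squared per-sample median and variance of the
  per-sample IQR of relative log expression (natural log, positive entries
  only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import rankdata

from .core_data import CountMatrix, FactorVector
from .gene_sets import GeneSet, non_zero_ratio

logger = logging.getLogger(__name__)

_EPS = 1e-9


class MetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


@dataclass(frozen=True)
class CVRecord:
    gene_id: str
    cv: float
    n_star: int


@dataclass(frozen=True)
class CVCurve:
    """Uniform-gene counts at each normalized-CV cutoff on an even grid."""

    cutoffs: np.ndarray
    counts: np.ndarray
    n_eligible: int

    def __post_init__(self):
        if np.any(np.diff(self.counts) < 0):
            raise MetricError("counts must be non-decreasing in the cutoff")


def cv_raw(values) -> float:
    """Coefficient of variation over all values (zeros included)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise MetricError("cv_raw needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        return math.nan  # undefined; callers treat as not-uniform
    return float(v.std(ddof=1) / mean)


def cv_log2(values, gene_id: str = "") -> CVRecord:
    """CV of log2 of the strictly positive values (zeros ignored)."""
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    n_star = int(pos.size)
    if n_star < 2:
        return CVRecord(gene_id, math.nan, n_star)
    logs = np.log2(pos)
    mean = logs.mean()
    if mean <= 0:
        return CVRecord(gene_id, math.nan, n_star)
    return CVRecord(gene_id, float(logs.std(ddof=1) / mean), n_star)


def log2_cv_by_gene(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`cv_log2` over the rows of a genes x samples array.

    Returns NaN for genes with fewer than two positive values or a
    non-positive mean of log2 values (excluded from curves).
    """
    X = np.asarray(values, dtype=float)
    pos = X > 0
    n_star = pos.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(pos, np.log2(X, where=pos, out=np.zeros_like(X)), 0.0)
    ok = n_star >= 2
    mean = np.full(X.shape[0], np.nan)
    mean[ok] = L[ok].sum(axis=1) / n_star[ok]
    dev = np.where(pos, L - mean[:, None], 0.0)
    var = np.full(X.shape[0], np.nan)
    var[ok] = (dev[ok] ** 2).sum(axis=1) / (n_star[ok] - 1)
    cv = np.sqrt(var) / mean
    cv[~ok | (mean <= 0)] = np.nan
    return cv


def normalize_cvs(cvs) -> np.ndarray:
    """Min-max scale CVs into [0, 1]; a constant vector maps to all zeros."""
    cvs = np.asarray(cvs, dtype=float)
    if cvs.size < 2 or not np.isfinite(cvs).all():
        raise MetricError("normalize_cvs needs >= 2 finite CVs")
    lo, hi = cvs.min(), cvs.max()
    if hi == lo:
        logger.warning("all CVs identical; normalized CVs degenerate to 0")
        return np.zeros_like(cvs)
    return (cvs - lo) / (hi - lo)


def cv_threshold_curve(
    matrix: CountMatrix, nzr_cutoff: float, grid_size: int = 1000
) -> CVCurve:
    """Uniform-gene counts over the normalized-CV cutoff grid t/grid_size."""
    ratios = non_zero_ratio(matrix)
    rows = np.flatnonzero(ratios >= nzr_cutoff - _EPS)
    cvs = log2_cv_by_gene(matrix.values[rows, :])
    valid = np.isfinite(cvs)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.debug("%d eligible genes had undefined log2 CV", n_excluded)
    cvs = cvs[valid]
    if cvs.size < 2:
        raise MetricError(
            f"fewer than 2 genes with a defined CV at nzr cutoff {nzr_cutoff}"
        )
    ncv = np.sort(normalize_cvs(cvs))
    cutoffs = np.arange(1, grid_size + 1) / grid_size
    counts = np.searchsorted(ncv, cutoffs + _EPS, side="left")
    return CVCurve(cutoffs, counts.astype(int), int(ncv.size))


def aucvc(curve: CVCurve) -> float:
    """Grid-mean uniform fraction: sum(counts) / (grid_size * n_eligible)."""
    if curve.n_eligible == 0:
        raise MetricError("AUCVC undefined for an empty eligible set")
    return float(curve.counts.sum() / (len(curve.cutoffs) * curve.n_eligible))


def aucvc_score(
    matrix: CountMatrix, nzr_cutoff: float, grid_size: int = 1000
) -> float:
    """Convenience: AUCVC of a (normalized) matrix at one nzr cutoff."""
    return aucvc(cv_threshold_curve(matrix, nzr_cutoff, grid_size))


def _pair_index_to_ij(k: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode linear indices of the upper triangle (i < j) of a g x g grid."""
    # row i starts at linear offset i*(2g-i-1)/2; invert the triangular number
    i = ((2 * g - 1 - np.sqrt((2 * g - 1) ** 2 - 8 * k)) // 2).astype(np.int64)
    k = k.astype(np.int64)
    first = i * (2 * g - i - 1) // 2
    # guard against float round-off in the inversion
    i = np.where(first > k, i - 1, i)
    over = (i + 1) * (2 * g - i - 2) // 2
    i = np.where(k >= over, i + 1, i)
    first = i * (2 * g - i - 1) // 2
    j = (k - first) + i + 1
    return i, j.astype(np.int64)


def sample_gene_pairs(n_genes: int, n_pairs: int, seed: int):
    """Distinct unordered gene-index pairs from a seeded generator.

    All pairs are returned (in canonical order) when the total number of
    pairs does not exceed ``n_pairs``.
    """
    total = n_genes * (n_genes - 1) // 2
    if total <= n_pairs:
        ks = np.arange(total, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        if total <= 50_000_000:
            ks = np.sort(rng.choice(total, size=n_pairs, replace=False))
        else:  # rejection sampling keeps memory bounded for huge gene sets
            seen = np.unique(rng.integers(0, total, size=int(n_pairs * 1.3)))
            while seen.size < n_pairs:
                extra = rng.integers(0, total, size=n_pairs)
                seen = np.unique(np.concatenate([seen, extra]))
            ks = np.sort(rng.permutation(seen)[:n_pairs])
    return _pair_index_to_ij(ks.astype(np.float64), n_genes)


def mscc(
    matrix: CountMatrix,
    ubiq: GeneSet,
    n_pairs: int = 1_000_000,
    seed: int = 1,
) -> float:
    """Median Spearman correlation over sampled ubiquitous gene pairs.

    Gene order is fixed (lexicographic) so results are reproducible for a
    given seed.  Pairs involving a gene constant across samples have an
    undefined correlation and are dropped (count logged).
    """
    ids = sorted(ubiq.gene_ids)
    if len(ids) < 2:
        raise MetricError("mSCC needs at least 2 ubiquitous genes")
    sub = matrix.subset_genes(ids)
    ranks = rankdata(sub.values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ii, jj = sample_gene_pairs(len(ids), n_pairs, seed)
    defined = (norms[ii] > 0) & (norms[jj] > 0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("mSCC: dropped %d pairs with a constant gene", n_dropped)
    ii, jj = ii[defined], jj[defined]
    if ii.size == 0:
        raise MetricError("mSCC: no pair has a defined correlation")
    sccs = np.einsum("ij,ij->i", centered[ii], centered[jj]) / (norms[ii] * norms[jj])
    # identical / reversed rankings are exactly +/-1; undo float round-off
    # (the nearest achievable distinct correlation is ~6/(n^3) away)
    sccs[np.abs(sccs - 1.0) < 1e-12] = 1.0
    sccs[np.abs(sccs + 1.0) < 1e-12] = -1.0
    return float(np.median(sccs))


def _rle_values(matrix: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Relative log expression on positive entries (natural log)."""
    X = matrix.values
    pos = X > 0
    with np.errstate(divide="ignore"):
        logX = np.where(pos, np.log(X, where=pos, out=np.zeros_like(X)), np.nan)
    med = np.full(X.shape[0], np.nan)
    has_pos = pos.any(axis=1)
    if has_pos.any():
        med[has_pos] = np.nanmedian(
            np.where(pos[has_pos], logX[has_pos], np.nan), axis=1
        )
    return logX - med[:, None], pos


def _per_sample_rle_stats(matrix: CountMatrix):
    R, pos = _rle_values(matrix)
    medians = np.empty(matrix.n_samples)
    iqrs = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        vals = R[pos[:, j], j]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise MetricError(
                f"sample {matrix.sample_ids[j]!r} has fewer than 2 usable genes "
                f"for RLE metrics"
            )
        medians[j] = np.median(vals)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqrs[j] = q3 - q1
    return medians, iqrs


def rle_med(matrix: CountMatrix) -> float:
    """Mean over samples of the squared per-sample median RLE."""
    medians, _ = _per_sample_rle_stats(matrix)
    return float(np.mean(medians**2))


def rle_iqr(matrix: CountMatrix) -> float:
    """Variance over samples of the per-sample IQR of RLE."""
    _, iqrs = _per_sample_rle_stats(matrix)
    return float(np.var(iqrs, ddof=1))


def cluster_factors(factor_vectors: list[FactorVector]):
    """Average-linkage hierarchical clustering of factor vectors with
    distance 1 - Spearman correlation.

    Returns ``(linkage_matrix, labels)``; methods with a constant factor
    vector are excluded with a warning.
    """
    usable = []
    for fv in factor_vectors:
        if np.ptp(fv.factors) == 0:
            logger.warning(
                "cluster_factors: method %s has constant factors; excluded",
                fv.method,
            )
        else:
            usable.append(fv)
    if len(usable) < 2:
        raise MetricError("cluster_factors needs >= 2 non-constant methods")
    labels = [fv.method for fv in usable]
    ranks = np.vstack([rankdata(fv.factors) for fv in usable])
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = (centered @ centered.T) / np.outer(norms, norms)
    dist = 1.0 - corr
    k = len(usable)
    condensed = dist[np.triu_indices(k, 1)]
    condensed = np.clip(condensed, 0.0, None)
    Z = linkage(condensed, method="average")
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        dl = node.dist - left.dist
        dr = node.dist - right.dist
        return f"({render(left)}:{dl:.10g},{render(right)}:{dr:.10g})"

    return render(tree) + ";"


def write_cv_curve(curve: CVCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_eligible={curve.n_eligible}\n")
        fh.write("cutoff\tcount\n")
        for c, n in zip(curve.cutoffs, curve.counts):
            fh.write(f"{c:.10g}\t{n}\n")
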