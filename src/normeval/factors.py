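"""Global normalization factors: library-size, control-set, ratio-based and TU.

All methods yield one positive factor per sample.  Library-size style
methods return ``1e6 / N_j`` (counts-per-million scale); edgeR-style
methods (UQ, TMM, RLE) return ``1e6 / (N_j * s_j)`` where ``s_j`` rescales
the library size.  Every per-gene or per-sample statistic (geometric means,
ratios, quantiles, M/A values) ignores zero entries, so the methods remain
usable on sparse single-cell matrices.  Factors are reported unstandardized;
:func:`standardize_geomean` divides by the geometric mean, after which the
vector's geometric mean is 1.  Quantiles use linear interpolation between
order statistics (numpy's default, "type 7") — UQ factors depend on this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import CountMatrix, FactorVector, GeneAnnotation, SampleMeta
from .gene_sets import TrimParams, ubiquitous_genes

logger = logging.getLogger(__name__)

MILLION = 1.0e6

LIBRARY_SIZE_MODES = ("TN", "TC", "CR", "NR")


class FactorError(ValueError):
    """Raised when a normalization factor cannot be computed."""


@dataclass(frozen=True)
class LibrarySizeSpec:
    mode: str
    annotation: GeneAnnotation | None = None
    sample_meta: SampleMeta | None = None

    def __post_init__(self):
        if self.mode not in LIBRARY_SIZE_MODES:
            raise ValueError(f"mode must be one of {LIBRARY_SIZE_MODES}")
        if self.mode == "TN" and (
            self.sample_meta is None or self.sample_meta.total_reads is None
        ):
            raise FactorError("TN requires sample_meta with total_reads")


def _require_two_samples(matrix: CountMatrix) -> None:
    if matrix.n_samples < 2:
        raise FactorError("factor computation requires at least 2 samples")


def _class_sums(matrix: CountMatrix, annotation: GeneAnnotation, classes) -> np.ndarray:
    rows = [
        i for i, g in enumerate(matrix.gene_ids)
        if annotation.class_of(g) in classes
    ]
    if not rows:
        return np.zeros(matrix.n_samples)
    return matrix.values[rows, :].sum(axis=0)


def library_size(matrix: CountMatrix, spec: LibrarySizeSpec) -> np.ndarray:
    """Per-sample library sizes N_j for modes TN / TC / CR / NR.

    NR sums nuclear genes only; CR adds mitochondrial; TC adds spike-ins
    (TC = CR + spike-in sum); TN is the externally supplied total aligned
    read count.
    """
    if spec.mode == "TN":
        sizes = np.asarray(spec.sample_meta.total_reads, dtype=float)
        if len(sizes) != matrix.n_samples:
            raise FactorError("total_reads length does not match sample count")
    else:
        ann = spec.annotation if spec.annotation is not None else GeneAnnotation()
        if spec.mode == "NR":
            sizes = _class_sums(matrix, ann, {"nuclear"})
        elif spec.mode == "CR":
            sizes = _class_sums(matrix, ann, {"nuclear", "mitochondrial"})
        else:  # TC
            sizes = _class_sums(
                matrix, ann, {"nuclear", "mitochondrial", "spike_in"}
            )
    zero = np.flatnonzero(sizes <= 0)
    if zero.size:
        raise FactorError(
            f"{spec.mode}: zero library size for sample "
            f"{matrix.sample_ids[zero[0]]!r}"
        )
    return sizes


def size_based_factors(matrix: CountMatrix, spec: LibrarySizeSpec) -> FactorVector:
    """f_j = 1e6 / N_j for the chosen library-size mode."""
    _require_two_samples(matrix)
    sizes = library_size(matrix, spec)
    return FactorVector(spec.mode, MILLION / sizes, matrix.sample_ids)


def control_set_factors(
    matrix: CountMatrix, set_name: str, annotation: GeneAnnotation
) -> FactorVector:
    """Pseudo library size = sum over a pre-selected control gene set."""
    _require_two_samples(matrix)
    genes = annotation.resolve_set(set_name, matrix)
    sub = matrix.subset_genes(genes)
    sizes = sub.values.sum(axis=0)
    zero = np.flatnonzero(sizes <= 0)
    if zero.size:
        raise FactorError(
            f"{set_name}: control-set sum is zero for sample "
            f"{matrix.sample_ids[zero[0]]!r}"
        )
    return FactorVector(set_name, MILLION / sizes, matrix.sample_ids)


def _median_of_ratios_sizes(matrix: CountMatrix) -> np.ndarray:
    """Zero-ignoring median-of-ratios pseudo library sizes N*_j.

    The per-gene reference is the geometric mean over samples where the gene
    is non-zero; each sample's pseudo size is the median of x_ij/reference_i
    over its non-zero genes.
    """
    X = matrix.values
    pos = X > 0
    npos = pos.sum(axis=1)
    with np.errstate(divide="ignore"):
        logX = np.where(pos, np.log(X, where=pos, out=np.zeros_like(X)), 0.0)
    usable = npos > 0
    ref_log = np.full(matrix.n_genes, np.nan)
    ref_log[usable] = logX[usable].sum(axis=1) / npos[usable]
    sizes = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        mask = pos[:, j] & usable
        if not mask.any():
            raise FactorError(
                f"sample {matrix.sample_ids[j]!r} has no usable ratios"
            )
        sizes[j] = np.median(np.exp(logX[mask, j] - ref_log[mask]))
    return sizes


def deseq_factors(matrix: CountMatrix) -> FactorVector:
    """Median-of-ratios factors, f_j = 1 / N*_j (scale fixed by standardization)."""
    _require_two_samples(matrix)
    sizes = _median_of_ratios_sizes(matrix)
    return FactorVector("DESeq", 1.0 / sizes, matrix.sample_ids)


def rle_factors(matrix: CountMatrix, lib_sizes: np.ndarray | None = None) -> FactorVector:
    """RLE: s_j = N*_j / N_j so f_j = 1e6 / (N_j s_j) = 1e6 / N*_j.

    After geometric-mean standardization this is identical to DESeq.
    """
    _require_two_samples(matrix)
    sizes = _median_of_ratios_sizes(matrix)
    return FactorVector("RLE", MILLION / sizes, matrix.sample_ids)


def _nr_or_column_sums(matrix: CountMatrix, lib_sizes) -> np.ndarray:
    if lib_sizes is None:
        sizes = matrix.values.sum(axis=0)
    else:
        sizes = np.asarray(lib_sizes, dtype=float)
        if len(sizes) != matrix.n_samples:
            raise FactorError("lib_sizes length does not match sample count")
    if (sizes <= 0).any():
        j = int(np.flatnonzero(sizes <= 0)[0])
        raise FactorError(f"zero library size for sample {matrix.sample_ids[j]!r}")
    return sizes


def uq_factors(matrix: CountMatrix, lib_sizes: np.ndarray | None = None) -> FactorVector:
    """Upper-quartile: s_j = Q75 of the non-zero relative counts x_ij / N_j."""
    _require_two_samples(matrix)
    N = _nr_or_column_sums(matrix, lib_sizes)
    factors = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        col = matrix.values[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise FactorError(
                f"UQ: sample {matrix.sample_ids[j]!r} has no non-zero genes"
            )
        s = np.quantile(nz / N[j], 0.75)
        factors[j] = MILLION / (N[j] * s)
    return FactorVector("UQ", factors, matrix.sample_ids)


def _tmm_reference(matrix: CountMatrix, N: np.ndarray) -> int:
    """Sample whose upper quartile of non-zero relative counts is closest to
    the mean of those quartiles; ties broken by lowest sample index."""
    q = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        col = matrix.values[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise FactorError(
                f"TMM: sample {matrix.sample_ids[j]!r} has no non-zero genes"
            )
        q[j] = np.quantile(nz / N[j], 0.75)
    return int(np.argmin(np.abs(q - q.mean())))


def tmm_factors(
    matrix: CountMatrix,
    lib_sizes: np.ndarray | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> FactorVector:
    """Trimmed mean of M values, restricted to genes non-zero in both samples.

    For sample j against reference r, genes carry
    ``M = log2((x_j/N_j)/(x_r/N_r))`` and ``A = 0.5*log2((x_j/N_j)*(x_r/N_r))``;
    the top and bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A
    are discarded and the surviving M are averaged with
    inverse-asymptotic-variance weights
    ``1 / ((N_j-x_j)/(N_j x_j) + (N_r-x_r)/(N_r x_r))``,
    giving ``s_j = 2**mean`` and ``f_j = 1e6 / (N_j s_j)``.
    """
    _require_two_samples(matrix)
    N = _nr_or_column_sums(matrix, lib_sizes)
    r = _tmm_reference(matrix, N)
    X = matrix.values
    factors = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == r:
            factors[j] = MILLION / N[j]
            continue
        both = (X[:, j] > 0) & (X[:, r] > 0)
        xj, xr = X[both, j], X[both, r]
        n_genes = xj.size
        if n_genes == 0:
            logger.warning(
                "TMM: no shared non-zero genes for sample %s; s_j = 1",
                matrix.sample_ids[j],
            )
            factors[j] = MILLION / N[j]
            continue
        M = np.log2((xj / N[j]) / (xr / N[r]))
        A = 0.5 * np.log2((xj / N[j]) * (xr / N[r]))
        keep = _double_trim_mask(M, A, trim_m, trim_a)
        if not keep.any():
            logger.warning(
                "TMM: no genes survive trimming for sample %s; s_j = 1",
                matrix.sample_ids[j],
            )
            factors[j] = MILLION / N[j]
            continue
        w = 1.0 / (
            (N[j] - xj[keep]) / (N[j] * xj[keep])
            + (N[r] - xr[keep]) / (N[r] * xr[keep])
        )
        s = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
        factors[j] = MILLION / (N[j] * s)
    return FactorVector("TMM", factors, matrix.sample_ids)


def _double_trim_mask(M: np.ndarray, A: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes inside both the M-trim and the A-trim windows (rank based)."""
    from scipy.stats import rankdata

    n = M.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    return (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)


def tu_factors(matrix: CountMatrix, params: TrimParams) -> FactorVector:
    """Total-ubiquitous factors: pseudo size = sum over the ubiquitous genes."""
    _require_two_samples(matrix)
    ubiq = ubiquitous_genes(matrix, params)
    return tu_factors_from_set(matrix, ubiq.sorted_ids())


def tu_factors_from_set(matrix: CountMatrix, gene_ids) -> FactorVector:
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise FactorError("empty ubiquitous gene set")
    sub = matrix.subset_genes(gene_ids)
    sizes = sub.values.sum(axis=0)
    zero = np.flatnonzero(sizes <= 0)
    if zero.size:
        raise FactorError(
            f"TU: zero ubiquitous-gene sum for sample "
            f"{matrix.sample_ids[zero[0]]!r}"
        )
    return FactorVector("TU", MILLION / sizes, matrix.sample_ids)


def unit_factors(matrix: CountMatrix) -> FactorVector:
    """The 'None' baseline: raw data, all factors 1 (already standardized)."""
    return FactorVector(
        "None", np.ones(matrix.n_samples), matrix.sample_ids, standardized=True
    )


def standardize_geomean(fv: FactorVector) -> FactorVector:
    """Divide factors by their geometric mean (idempotent)."""
    gm = np.exp(np.mean(np.log(fv.factors)))
    return FactorVector(fv.method, fv.factors / gm, fv.sample_ids, standardized=True)


def apply_factors(matrix: CountMatrix, fv: FactorVector) -> CountMatrix:
    """Multiply each sample column by its factor; zeros stay zero."""
    if fv.sample_ids != matrix.sample_ids:
        raise FactorError(
            f"factor vector {fv.method!r} is not aligned to the matrix samples"
        )
    return CountMatrix(
        matrix.values * fv.factors[np.newaxis, :],
        matrix.gene_ids,
        matrix.sample_ids,
    )
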