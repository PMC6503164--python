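"""Non-zero ratios, per-sample trimmed gene sets and ubiquitous-gene selection.

Trimming is rank based: within a sample the non-zero genes are sorted
ascending by expression (ties broken by gene id so results are
deterministic) and, with k non-zero genes ranked 1..k, ranks r with
``floor(lower*k) < r <= floor(upper*k)`` are kept.  A gene is ubiquitous
when it appears in at least ``ceil(occurrence_rate * n)`` of the n
per-sample trimmed sets; occurrence_rate = 1 gives the plain intersection.

Ubiquitous genes are always derived from the RAW matrix, never from a
normalized one, and the same set is reused to evaluate every method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_data import CountMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9  # guards floor/ceil of products like 0.3 * 10 against FP noise


def _floor(x: float) -> int:
    return int(math.floor(x + _EPS))


def _ceil(x: float) -> int:
    return int(math.ceil(x - _EPS))


@dataclass(frozen=True)
class TrimParams:
    """Occurrence-rate / lower / upper cutoffs for ubiquitous-gene selection."""

    occurrence_rate: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 < self.occurrence_rate <= 1):
            raise ValueError(f"occurrence_rate {self.occurrence_rate} not in (0, 1]")
        if not (0 <= self.lower < 0.5):
            raise ValueError(f"lower {self.lower} not in [0, 0.5)")
        if not (0.5 < self.upper <= 1):
            raise ValueError(f"upper {self.upper} not in (0.5, 1]")
        if self.lower >= self.upper:
            raise ValueError("lower must be < upper")


@dataclass(frozen=True)
class GeneSet:
    """An unordered set of gene ids plus the parameters that produced it."""

    gene_ids: frozenset[str]
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def sorted_ids(self) -> list[str]:
        return sorted(self.gene_ids)


def non_zero_ratio(matrix: CountMatrix) -> np.ndarray:
    """Per-gene fraction of samples with a strictly positive value."""
    return (matrix.values > 0).sum(axis=1) / matrix.n_samples


def eligible_genes(matrix: CountMatrix, nzr_cutoff: float) -> GeneSet:
    """Genes whose non-zero ratio is at least ``nzr_cutoff``."""
    if not (0 < nzr_cutoff <= 1):
        raise ValueError(f"nzr_cutoff {nzr_cutoff} not in (0, 1]")
    ratios = non_zero_ratio(matrix)
    keep = ratios >= nzr_cutoff - _EPS
    ids = frozenset(g for g, k in zip(matrix.gene_ids, keep) if k)
    if not ids:
        logger.warning("no genes pass non-zero-ratio cutoff %.3g", nzr_cutoff)
    return GeneSet(ids, {"nzr_cutoff": nzr_cutoff})


def trimmed_set(values, gene_ids, lower: float, upper: float) -> frozenset[str]:
    """Trimmed gene set for one sample column (see module docstring)."""
    if lower >= upper:
        raise ValueError("lower must be < upper")
    values = np.asarray(values, dtype=float)
    ids = np.asarray(gene_ids, dtype=object)
    nz = values > 0
    k = int(nz.sum())
    if k == 0:
        logger.warning("all-zero sample column: empty trimmed set")
        return frozenset()
    v, g = values[nz], ids[nz]
    order = np.lexsort((g, v))  # ascending by value, ties by gene id
    lo, hi = _floor(lower * k), _floor(upper * k)
    return frozenset(g[order[lo:hi]])


def sample_trimmed_sets(matrix: CountMatrix, lower: float, upper: float):
    """Trimmed set for every sample column, in sample order."""
    gene_ids = np.asarray(matrix.gene_ids, dtype=object)
    return [
        trimmed_set(matrix.values[:, j], gene_ids, lower, upper)
        for j in range(matrix.n_samples)
    ]


def ubiquitous_genes(matrix: CountMatrix, params: TrimParams) -> GeneSet:
    """Genes present in at least ceil(occurrence_rate * n) trimmed sets."""
    n = matrix.n_samples
    threshold = _ceil(params.occurrence_rate * n)
    counts: dict[str, int] = {}
    for tset in sample_trimmed_sets(matrix, params.lower, params.upper):
        for g in tset:
            counts[g] = counts.get(g, 0) + 1
    ids = frozenset(g for g, c in counts.items() if c >= threshold)
    if not ids:
        logger.warning("empty ubiquitous set for params %s", params)
    return GeneSet(
        ids,
        {
            "occurrence_rate": params.occurrence_rate,
            "lower": params.lower,
            "upper": params.upper,
            "threshold": threshold,
        },
    )


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        prov = " ".join(f"{k}={v}" for k, v in sorted(gene_set.provenance.items()))
        fh.write(f"#provenance {prov}\n")
        for g in gene_set.sorted_ids():
            fh.write(f"{g}\n")
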