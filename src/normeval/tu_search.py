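"""Grid search for TU trim parameters maximizing AUCVC.

Every combination of (occurrence rate, lower cutoff, upper cutoff) on the
configured grids is tried; combinations whose ubiquitous set is too small
are skipped but recorded.  Surviving combinations are scored by the AUCVC
of the TU-normalized matrix at the configured non-zero-ratio cutoff.  Ties
on AUCVC prefer the larger ubiquitous set, then the lexicographically
smallest (occurrence, lower, upper), so the result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .core_data import CountMatrix, FactorVector
from .factors import FactorError, apply_factors, standardize_geomean, tu_factors_from_set
from .gene_sets import GeneSet, TrimParams, ubiquitous_genes
from .metrics import MetricError, aucvc_score

logger = logging.getLogger(__name__)


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


#: occurrence 0.2-0.6 step 0.1, trims 5-40% / 60-95% step 5%, >100 ubiquitous genes
SCRNA_PRESET = dict(
    occurrence_grid=_grid(0.2, 0.6, 0.1),
    lower_grid=_grid(0.05, 0.40, 0.05),
    upper_grid=_grid(0.60, 0.95, 0.05),
    min_ubiquitous=100,
)

#: occurrence fixed at 1, same trim grids, >1000 ubiquitous genes
BULK_PRESET = dict(
    occurrence_grid=(1.0,),
    lower_grid=_grid(0.05, 0.40, 0.05),
    upper_grid=_grid(0.60, 0.95, 0.05),
    min_ubiquitous=1000,
)

#: non-zero-ratio cutoff grids used by the evaluation layer
SCRNA_NZR_CUTOFFS = _grid(0.2, 0.9, 0.1)
BULK_NZR_CUTOFFS = _grid(0.7, 1.0, 0.1)


@dataclass(frozen=True)
class SearchConfig:
    occurrence_grid: tuple[float, ...]
    lower_grid: tuple[float, ...]
    upper_grid: tuple[float, ...]
    min_ubiquitous: int = 100
    nzr_cutoff: float = 0.2
    grid_size: int = 1000
    strict: bool = True  # "> min" when True, ">= min" when False

    def __post_init__(self):
        for name in ("occurrence_grid", "lower_grid", "upper_grid"):
            grid = getattr(self, name)
            if not grid:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(float(x) for x in grid))
        if self.min_ubiquitous < 2:
            raise ValueError("min_ubiquitous must be >= 2")
        # validate grid values eagerly via TrimParams
        for occ, lo, up in product(
            self.occurrence_grid, self.lower_grid, self.upper_grid
        ):
            TrimParams(occ, lo, up)

    def accepts(self, n_ubiquitous: int) -> bool:
        if self.strict:
            return n_ubiquitous > self.min_ubiquitous
        return n_ubiquitous >= self.min_ubiquitous

    @classmethod
    def preset(cls, name: str, **overrides) -> "SearchConfig":
        presets = {"scrna": SCRNA_PRESET, "bulk": BULK_PRESET}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {list(presets)}")
        kwargs = dict(presets[name])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class TraceRow:
    params: TrimParams
    n_ubiquitous: int
    aucvc: float | None
    status: str  # "ok" or a skip reason


@dataclass(frozen=True)
class SearchResult:
    best_params: TrimParams
    best_aucvc: float
    ubiquitous: GeneSet
    factors: FactorVector  # standardized TU factors
    trace: tuple[TraceRow, ...] = field(repr=False)


def tu_search(matrix: CountMatrix, config: SearchConfig) -> SearchResult:
    """Exhaustive grid search; returns the AUCVC-maximizing TU parameters."""
    trace: list[TraceRow] = []
    best = None  # (aucvc, n_ubiq, -grid position) comparisons done explicitly
    for occ, lo, up in product(
        config.occurrence_grid, config.lower_grid, config.upper_grid
    ):
        params = TrimParams(occ, lo, up)
        ubiq = ubiquitous_genes(matrix, params)
        n_ubiq = len(ubiq)
        if not config.accepts(n_ubiq):
            trace.append(TraceRow(params, n_ubiq, None, "too_few_ubiquitous"))
            continue
        try:
            fv = standardize_geomean(tu_factors_from_set(matrix, ubiq.sorted_ids()))
        except FactorError as exc:
            trace.append(TraceRow(params, n_ubiq, None, f"factor_error:{exc}"))
            continue
        try:
            score = aucvc_score(
                apply_factors(matrix, fv), config.nzr_cutoff, config.grid_size
            )
        except MetricError as exc:
            trace.append(TraceRow(params, n_ubiq, None, f"metric_error:{exc}"))
            continue
        trace.append(TraceRow(params, n_ubiq, score, "ok"))
        candidate = (score, n_ubiq)
        # grid iteration order is lexicographic, so strict improvement only
        if best is None or candidate > best[0]:
            best = (candidate, params, ubiq, fv)
    if best is None:
        raise FactorError(
            "every parameter combination was skipped; widen the grids or "
            "lower min_ubiquitous"
        )
    (_, _), params, ubiq, fv = best
    score = best[0][0]
    logger.info(
        "TU search: best AUCVC %.4f at occurrence=%g lower=%g upper=%g "
        "(%d ubiquitous genes)",
        score, params.occurrence_rate, params.lower, params.upper, len(ubiq),
    )
    return SearchResult(params, score, ubiq, fv, tuple(trace))


def write_trace(trace, path) -> None:
    with open(path, "w") as fh:
        fh.write("occurrence\tlower\tupper\tn_ubiquitous\taucvc\tstatus\n")
        for row in trace:
            score = "NA" if row.aucvc is None else f"{row.aucvc:.12g}"
            fh.write(
                f"{row.params.occurrence_rate:g}\t{row.params.lower:g}\t"
                f"{row.params.upper:g}\t{row.n_ubiquitous}\t{score}\t{row.status}\n"
            )
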