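"""Orchestration of the three usage modes and method ranking.

Mode 1 normalizes with TU only.  Mode 2 scores the library-size,
control-set and ratio-based methods (plus the raw-data baseline "None") by
AUCVC over a grid of non-zero-ratio cutoffs; TU is deliberately excluded
here and TN participates only when total read counts are supplied.  Mode 3
adds TU plus mSCC / RLE_MED / RLE_IQR and reports whether the per-metric
three-group classifications agree (consistency of metrics).  The ubiquitous
set used for mSCC is derived once from the raw matrix — by the best TU
parameters — and shared by every method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_data import CountMatrix, FactorVector, GeneAnnotation, SampleMeta
from .factors import (
    FactorError,
    LibrarySizeSpec,
    apply_factors,
    control_set_factors,
    deseq_factors,
    size_based_factors,
    standardize_geomean,
    tmm_factors,
    tu_factors_from_set,
    unit_factors,
    uq_factors,
)
from .gene_sets import GeneSet
from .metrics import MetricError, aucvc_score, mscc, rle_iqr, rle_med
from .tu_search import SearchConfig, SearchResult, tu_search

logger = logging.getLogger(__name__)

#: metrics where smaller (or nearer ascending-first) is better
_ASCENDING_METRICS = {"mscc", "rle_med", "rle_iqr"}


@dataclass
class EvaluationTable:
    """Method x cutoff AUCVC grid plus optional per-method scalar metrics."""

    aucvc: pd.DataFrame                       # methods x nzr cutoffs
    mscc: pd.Series | None = None             # per method
    rle_med: pd.Series | None = None
    rle_iqr: pd.Series | None = None
    unavailable: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def methods(self) -> list[str]:
        return list(self.aucvc.index)

    def metric_values(self, metric: str) -> pd.Series:
        if metric == "aucvc":
            return self.aucvc.mean(axis=1)
        series = getattr(self, metric)
        if series is None:
            raise ValueError(f"metric {metric!r} not computed for this table")
        return series


def rank_methods(table: EvaluationTable, metric: str) -> list[str]:
    """Methods ordered best-first: AUCVC descending, the rest ascending.

    Ties are broken by method name so the ordering is deterministic.
    """
    values = table.metric_values(metric)
    ascending = metric in _ASCENDING_METRICS
    return [
        m for m, _ in sorted(
            values.items(),
            key=lambda kv: ((kv[1] if ascending else -kv[1]), kv[0]),
        )
    ]


def three_group_split(values: pd.Series, ascending: bool) -> pd.Series:
    """Classify scores into 3 groups (1 = best) by 1-D average-linkage
    clustering; with fewer than 3 methods each gets its own group."""
    v = values.to_numpy(dtype=float)
    if len(v) < 3:
        order = np.argsort(v if ascending else -v, kind="stable")
        groups = np.empty(len(v), dtype=int)
        groups[order] = np.arange(1, len(v) + 1)
        return pd.Series(groups, index=values.index)
    Z = linkage(v[:, None], method="average")
    raw = fcluster(Z, t=3, criterion="maxclust")
    means = {c: v[raw == c].mean() for c in np.unique(raw)}
    ordered = sorted(means, key=lambda c: means[c] if ascending else -means[c])
    remap = {c: rank + 1 for rank, c in enumerate(ordered)}
    return pd.Series([remap[c] for c in raw], index=values.index)


def consistency_report(table: EvaluationTable) -> pd.DataFrame:
    """Per-method group under each metric plus a consistent/inconsistent flag
    comparing the AUCVC grouping with the mSCC grouping."""
    out = pd.DataFrame(index=table.aucvc.index)
    out["aucvc_group"] = three_group_split(table.metric_values("aucvc"), False)
    if table.mscc is not None:
        out["mscc_group"] = three_group_split(table.mscc, True)
        out["consistent"] = np.where(
            out["aucvc_group"] == out["mscc_group"], "consistent", "inconsistent"
        )
    if table.rle_med is not None:
        out["rle_med_group"] = three_group_split(table.rle_med, True)
    if table.rle_iqr is not None:
        out["rle_iqr_group"] = three_group_split(table.rle_iqr, True)
    return out


# ---------------------------------------------------------------------------
# factor assembly
# ---------------------------------------------------------------------------

def compute_method_factors(
    matrix: CountMatrix,
    annotation: GeneAnnotation,
    sample_meta: SampleMeta | None = None,
) -> tuple[dict[str, FactorVector], dict[str, str]]:
    """Standardized factors for every applicable mode-2 method.

    Returns ``(factors, unavailable)`` where unavailable maps a method name
    to the reason it could not be computed (e.g. no spike-in rows for ERCC,
    missing total_reads for TN).  A failing method is recorded, not fatal.
    """
    factors: dict[str, FactorVector] = {}
    unavailable: dict[str, str] = {}

    def attempt(name, fn):
        try:
            factors[name] = standardize_geomean(fn())
        except (FactorError, ValueError) as exc:
            logger.warning("method %s unavailable: %s", name, exc)
            unavailable[name] = str(exc)

    for mode in ("NR", "CR", "TC"):
        attempt(mode, lambda m=mode: size_based_factors(
            matrix, LibrarySizeSpec(m, annotation=annotation)))
    if sample_meta is not None and sample_meta.total_reads is not None:
        attempt("TN", lambda: size_based_factors(
            matrix, LibrarySizeSpec(
                "TN", annotation=annotation, sample_meta=sample_meta)))
    else:
        unavailable["TN"] = "total_reads not supplied"

    attempt("HG7", lambda: control_set_factors(matrix, "HG7", annotation))
    if annotation.control_sets.get("ERCC"):
        attempt("ERCC", lambda: control_set_factors(matrix, "ERCC", annotation))
    else:
        unavailable["ERCC"] = "no spike-in genes annotated"

    from .factors import library_size
    try:
        nr_sizes = library_size(matrix, LibrarySizeSpec("NR", annotation=annotation))
    except FactorError as exc:
        nr_sizes = None
        logger.warning("NR library sizes unavailable (%s); edgeR-style methods "
                       "fall back to column sums", exc)

    attempt("DESeq(RLE)", lambda: deseq_factors(matrix))
    attempt("UQ", lambda: uq_factors(matrix, nr_sizes))
    attempt("TMM", lambda: tmm_factors(matrix, nr_sizes))
    factors["None"] = unit_factors(matrix)
    return factors, unavailable


# ---------------------------------------------------------------------------
# modes
# ---------------------------------------------------------------------------

def run_mode1(matrix: CountMatrix, config: SearchConfig):
    """Normalization without evaluation: TU only.

    Returns ``(normalized_matrix, standardized_tu_factors, search_result)``.
    """
    result = tu_search(matrix, config)
    normalized = apply_factors(matrix, result.factors)
    return normalized, result.factors, result


def run_mode2(
    matrix: CountMatrix,
    annotation: GeneAnnotation,
    sample_meta: SampleMeta | None,
    nzr_cutoffs,
    grid_size: int = 1000,
) -> tuple[EvaluationTable, str]:
    """Normalization with simple evaluation: AUCVC over the cutoff grid.

    Returns the table and the best method (highest mean AUCVC across the
    grid; ties broken by name).
    """
    factors, unavailable = compute_method_factors(matrix, annotation, sample_meta)
    cutoffs = [float(c) for c in nzr_cutoffs]
    rows = {}
    for name, fv in sorted(factors.items()):
        normalized = apply_factors(matrix, fv)
        scores = []
        for cutoff in cutoffs:
            try:
                scores.append(aucvc_score(normalized, cutoff, grid_size))
            except MetricError as exc:
                logger.warning("AUCVC undefined for %s at cutoff %g: %s",
                               name, cutoff, exc)
                scores.append(np.nan)
        rows[name] = scores
    table = EvaluationTable(
        aucvc=pd.DataFrame.from_dict(rows, orient="index", columns=cutoffs),
        unavailable=unavailable,
        params={"nzr_cutoffs": cutoffs, "grid_size": grid_size},
    )
    best = rank_methods(table, "aucvc")[0]
    return table, best


def run_mode3(
    matrix: CountMatrix,
    annotation: GeneAnnotation,
    sample_meta: SampleMeta | None,
    nzr_cutoffs,
    search_config: SearchConfig,
    n_pairs: int = 1_000_000,
    seed: int = 1,
    grid_size: int = 1000,
):
    """Normalization with complete evaluation.

    Runs mode 2's methods plus TU (searched per non-zero-ratio cutoff),
    adds mSCC on a single raw-matrix ubiquitous set shared by all methods,
    plus RLE_MED / RLE_IQR, and attaches the consistency report.

    Returns ``(EvaluationTable, consistency DataFrame, best_search_result)``.
    """
    factors, unavailable = compute_method_factors(matrix, annotation, sample_meta)
    cutoffs = [float(c) for c in nzr_cutoffs]

    # per-cutoff TU search; the overall best (highest AUCVC, earliest cutoff)
    # supplies the shared ubiquitous set and the reported TU factors
    tu_scores: list[float] = []
    best_result: SearchResult | None = None
    for cutoff in cutoffs:
        cfg = SearchConfig(
            occurrence_grid=search_config.occurrence_grid,
            lower_grid=search_config.lower_grid,
            upper_grid=search_config.upper_grid,
            min_ubiquitous=search_config.min_ubiquitous,
            nzr_cutoff=cutoff,
            grid_size=search_config.grid_size,
            strict=search_config.strict,
        )
        try:
            result = tu_search(matrix, cfg)
        except FactorError as exc:
            logger.warning("TU unavailable at cutoff %g: %s", cutoff, exc)
            tu_scores.append(np.nan)
            continue
        tu_scores.append(result.best_aucvc)
        if best_result is None or result.best_aucvc > best_result.best_aucvc:
            best_result = result
    if best_result is None:
        unavailable["TU"] = "TU search failed at every cutoff"

    rows = {}
    method_factors = dict(sorted(factors.items()))
    if best_result is not None:
        method_factors["TU"] = best_result.factors
    for name, fv in method_factors.items():
        if name == "TU":
            rows[name] = tu_scores
            continue
        normalized = apply_factors(matrix, fv)
        scores = []
        for cutoff in cutoffs:
            try:
                scores.append(aucvc_score(normalized, cutoff, grid_size))
            except MetricError:
                scores.append(np.nan)
        rows[name] = scores

    ubiq: GeneSet | None = best_result.ubiquitous if best_result else None
    msccs, rmeds, riqrs = {}, {}, {}
    for name, fv in method_factors.items():
        normalized = apply_factors(matrix, fv)
        if ubiq is not None:
            try:
                msccs[name] = mscc(normalized, ubiq, n_pairs=n_pairs, seed=seed)
            except MetricError as exc:
                logger.warning("mSCC undefined for %s: %s", name, exc)
                msccs[name] = np.nan
        try:
            rmeds[name] = rle_med(normalized)
            riqrs[name] = rle_iqr(normalized)
        except MetricError as exc:
            logger.warning("RLE metrics undefined for %s: %s", name, exc)
            rmeds[name] = np.nan
            riqrs[name] = np.nan

    table = EvaluationTable(
        aucvc=pd.DataFrame.from_dict(rows, orient="index", columns=cutoffs),
        mscc=pd.Series(msccs) if msccs else None,
        rle_med=pd.Series(rmeds),
        rle_iqr=pd.Series(riqrs),
        unavailable=unavailable,
        params={
            "nzr_cutoffs": cutoffs,
            "grid_size": grid_size,
            "n_pairs": n_pairs,
            "seed": seed,
            "ubiquitous_provenance": dict(ubiq.provenance) if ubiq else None,
            "n_ubiquitous": len(ubiq) if ubiq else 0,
        },
    )
    consistency = consistency_report(table)
    return table, consistency, best_result


def write_report(table: EvaluationTable, path, consistency: pd.DataFrame | None = None) -> None:
    """Write the evaluation report: AUCVC table, metric tables, rankings."""
    if not table.methods():
        raise ValueError("empty method list")
    with open(path, "w") as fh:
        fh.write("# evaluation report\n")
        for k, v in table.params.items():
            fh.write(f"# {k}={v}\n")
        for name, reason in sorted(table.unavailable.items()):
            fh.write(f"# unavailable: {name}: {reason}\n")
        fh.write("\n[AUCVC]\n")
        fh.write(table.aucvc.to_csv(sep="\t", float_format="%.12g"))
        fh.write(f"\n[ranking aucvc]\t" + "\t".join(rank_methods(table, "aucvc")) + "\n")
        for metric in ("mscc", "rle_med", "rle_iqr"):
            series = getattr(table, metric)
            if series is None:
                continue
            fh.write(f"\n[{metric.upper()}]\n")
            fh.write(series.to_csv(sep="\t", float_format="%.12g", header=False))
            fh.write(
                f"\n[ranking {metric}]\t"
                + "\t".join(rank_methods(table, metric)) + "\n"
            )
        if consistency is not None:
            fh.write("\n[consistency]\n")
            fh.write(consistency.to_csv(sep="\t"))
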