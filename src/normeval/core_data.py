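"""Data model and plain-text IO for count matrices, gene annotations and factor tables.

Conventions used throughout the package:

* genes are rows, samples are columns;
* zeros are data (there is no missing-value representation);
* all files are UTF-8 delimited text, floats written with 17 significant
  digits so write -> read round-trips are exact at double precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

#: the seven-gene housekeeping control set (fixed membership)
HG7_GENES = ("UBC", "HMBS", "TBP", "GAPDH", "HPRT1", "RPL13A", "ACTB")

GENE_CLASSES = ("nuclear", "mitochondrial", "spike_in")

FLOAT_FMT = "%.17g"


class DataFormatError(ValueError):
    """Raised when an input file or in-memory structure violates the data model."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DataFormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative genes x samples expression matrix with row/column identifiers."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DataFormatError(f"matrix must be 2-D, got shape {values.shape}")
        m, n = values.shape
        if len(self.gene_ids) != m:
            raise DataFormatError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise DataFormatError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataFormatError(
                f"non-finite entry at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise DataFormatError(
                f"negative entry {values[i, j]} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(self.values[rows, :], tuple(gene_ids), self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass
class GeneAnnotation:
    """Per-gene class labels plus named control sets.

    ``gene_class`` maps gene id -> one of :data:`GENE_CLASSES`.  Genes absent
    from the mapping are treated as nuclear by consumers.  Built-in control
    sets: ``HG7`` (fixed seven genes), ``GAPDH`` (the single gene) and
    ``ERCC`` (all spike_in-classified genes, auto-derived when not given).
    """

    gene_class: dict[str, str] = field(default_factory=dict)
    control_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for g, c in self.gene_class.items():
            if c not in GENE_CLASSES:
                raise DataFormatError(
                    f"unknown gene class {c!r} for gene {g!r}; "
                    f"allowed: {GENE_CLASSES}"
                )
        self._install_builtins()

    def _install_builtins(self) -> None:
        if "HG7" not in self.control_sets:
            self.control_sets["HG7"] = list(HG7_GENES)
        if "GAPDH" not in self.control_sets:
            self.control_sets["GAPDH"] = ["GAPDH"]
        if "ERCC" not in self.control_sets:
            spikes = [g for g, c in self.gene_class.items() if c == "spike_in"]
            self.control_sets["ERCC"] = spikes

    def class_of(self, gene_id: str) -> str:
        return self.gene_class.get(gene_id, "nuclear")

    def genes_of_class(self, matrix: CountMatrix, cls: str):
        """Row indices of matrix genes carrying class ``cls``."""
        return [i for i, g in enumerate(matrix.gene_ids) if self.class_of(g) == cls]

    def resolve_set(self, set_name: str, matrix: CountMatrix) -> list[str]:
        """Control-set members present in the matrix; error if none resolve."""
        if set_name not in self.control_sets:
            raise DataFormatError(f"unknown control set {set_name!r}")
        members = self.control_sets[set_name]
        present = set(matrix.gene_ids)
        found = [g for g in members if g in present]
        missing = [g for g in members if g not in present]
        if missing:
            logger.warning(
                "control set %s: %d/%d ids not in matrix (e.g. %s)",
                set_name, len(missing), len(members), missing[:5],
            )
        if not found:
            raise DataFormatError(
                f"control set {set_name!r}: none of its {len(members)} genes "
                f"are present in the matrix"
            )
        return found


@dataclass(frozen=True)
class FactorVector:
    """One positive global normalization factor per sample.

    When ``standardized`` is true the factors have geometric mean 1 (checked
    at construction within 1e-9 relative tolerance).
    """

    method: str
    factors: np.ndarray
    sample_ids: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if f.ndim != 1 or len(f) != len(self.sample_ids):
            raise DataFormatError("factors must be 1-D and aligned to sample_ids")
        if not np.isfinite(f).all() or (f <= 0).any():
            bad = np.argwhere(~(np.isfinite(f) & (f > 0)))[0][0]
            raise DataFormatError(
                f"method {self.method!r}: factor for sample "
                f"{self.sample_ids[bad]!r} is {f[bad]} (must be finite and > 0)"
            )
        if self.standardized:
            gm = float(np.exp(np.mean(np.log(f))))
            if not math.isclose(gm, 1.0, rel_tol=1e-9):
                raise DataFormatError(
                    f"method {self.method!r}: flagged standardized but geometric "
                    f"mean is {gm!r}"
                )


@dataclass(frozen=True)
class SampleMeta:
    """Optional per-sample metadata: total aligned read counts (used by TN)."""

    sample_ids: tuple[str, ...]
    total_reads: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.total_reads is not None:
            tr = np.asarray(self.total_reads, dtype=float)
            object.__setattr__(self, "total_reads", tr)
            if tr.ndim != 1 or len(tr) != len(self.sample_ids):
                raise DataFormatError("total_reads must align to sample_ids")
            if not np.isfinite(tr).all() or (tr <= 0).any():
                raise DataFormatError("total_reads must be finite and > 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DELIMS = {".tsv": "\t", ".csv": ",", ".txt": "\t"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV/CSV (gene ids in first column, sample ids
    in the header) or MatrixMarket coordinate format with ``<stem>.rownames``
    and ``<stem>.colnames`` sidecar files (one id per line)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        rown = path.with_suffix(".rownames")
        coln = path.with_suffix(".colnames")
        for side in (rown, coln):
            if not side.exists():
                raise FileNotFoundError(
                    f"MatrixMarket sidecar {side} is required alongside {path}"
                )
        # mmread returns coo for coordinate files, ndarray for array files
        mat = mmread(path)
        values = mat.toarray() if hasattr(mat, "toarray") else np.asarray(mat)
        gene_ids = rown.read_text().split()
        sample_ids = coln.read_text().split()
        return CountMatrix(values, tuple(gene_ids), tuple(sample_ids))
    if fmt not in ("tsv", "csv"):
        raise DataFormatError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample")  # pandas would silently rename dups
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError(f"{path}: no sample columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric entry ({exc})") from exc
    return CountMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_counts(matrix: CountMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        sparse = coo_matrix(matrix.values)
        mmwrite(path, sparse, precision=17)
        path.with_suffix(".rownames").write_text("\n".join(matrix.gene_ids) + "\n")
        path.with_suffix(".colnames").write_text("\n".join(matrix.sample_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    matrix.to_frame().to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="gene")


# keep the op name from the public surface
write_normalized = write_counts


def read_annotation(path) -> GeneAnnotation:
    """Read a gene annotation file.

    Format: ``gene_id<TAB>class`` lines (class in nuclear / mitochondrial /
    spike_in), plus optional control-set blocks introduced by ``#set:<name>``
    followed by one gene id per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gene_class: dict[str, str] = {}
    control_sets: dict[str, list[str]] = {}
    current_set: str | None = None
    lines = path.read_text().splitlines()
    if not any(ln.strip() for ln in lines):
        raise DataFormatError(f"{path}: empty annotation file")
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#set:"):
            current_set = line[len("#set:"):].strip()
            control_sets.setdefault(current_set, [])
            continue
        if line.startswith("#"):
            continue
        if "\t" in line:
            current_set = None
            gene, cls = (tok.strip() for tok in line.split("\t", 1))
            if cls not in GENE_CLASSES:
                raise DataFormatError(
                    f"{path}:{lineno}: unknown class {cls!r} for gene {gene!r}"
                )
            gene_class[gene] = cls
        elif current_set is not None:
            control_sets[current_set].append(line)
        else:
            raise DataFormatError(
                f"{path}:{lineno}: expected 'gene<TAB>class' or a #set: block"
            )
    return GeneAnnotation(gene_class=gene_class, control_sets=control_sets)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene, cls in annotation.gene_class.items():
            fh.write(f"{gene}\t{cls}\n")
        for name, members in annotation.control_sets.items():
            fh.write(f"#set:{name}\n")
            for g in members:
                fh.write(f"{g}\n")


def write_factors(table: list[FactorVector], path, header_comments=()) -> None:
    """Write factor vectors as TSV: samples as rows, methods as columns."""
    if not table:
        raise DataFormatError("empty factor table")
    sample_ids = table[0].sample_ids
    for fv in table:
        if fv.sample_ids != sample_ids:
            raise DataFormatError(
                f"factor vector {fv.method!r} is not aligned to the table samples"
            )
    path = Path(path)
    with path.open("w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for fv in table:
            fh.write(f"# method={fv.method} standardized={fv.standardized}\n")
        fh.write("sample\t" + "\t".join(fv.method for fv in table) + "\n")
        for j, sid in enumerate(sample_ids):
            row = "\t".join(FLOAT_FMT % fv.factors[j] for fv in table)
            fh.write(f"{sid}\t{row}\n")


def read_factors(path) -> list[FactorVector]:
    path = Path(path)
    standardized: dict[str, bool] = {}
    rows = []
    header = None
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            body = raw.lstrip("# ").strip()
            if body.startswith("method="):
                toks = dict(tok.split("=", 1) for tok in body.split())
                standardized[toks["method"]] = toks.get("standardized") == "True"
            continue
        toks = raw.rstrip("\n").split("\t")
        if header is None:
            header = toks
        elif raw.strip():
            rows.append(toks)
    if header is None or not rows:
        raise DataFormatError(f"{path}: no factor table found")
    sample_ids = tuple(r[0] for r in rows)
    out = []
    for k, method in enumerate(header[1:], start=1):
        factors = np.array([float(r[k]) for r in rows])
        out.append(
            FactorVector(method, factors, sample_ids,
                         standardized=standardized.get(method, False))
        )
    return out


def write_report(table, path) -> None:
    """Write an evaluation report (delegates to the evaluation module)."""
    from .evaluation import write_report as _write
    _write(table, path)
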