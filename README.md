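# normeval

Global normalization factors for gene-expression count matrices (bulk and
single-cell), plus metric-based evaluation and ranking of normalization
methods.

## What it does

Given a raw genes × samples count matrix, `normeval` computes one positive
global normalization factor per sample by any of eleven methods:

* **library size**: TN (total aligned reads, from external metadata),
  TC (nuclear + mitochondrial + spike-in), CR (nuclear + mitochondrial),
  NR (nuclear only) — factor `1e6 / N_j`;
* **control sets**: HG7 (seven fixed housekeeping genes), ERCC spike-ins,
  GAPDH, or any user-defined gene set — factor `1e6 / (control sum)`;
* **ratio-based**: DESeq-style median of ratios, RLE, upper quartile (UQ)
  and trimmed mean of M values (TMM), all modified to ignore zero entries
  so they remain usable on sparse single-cell data (RLE/UQ/TMM use NR
  library sizes and are converted to global factors as `1e6 / (N_j s_j)`);
* **TU (total ubiquitous)**: the sum over a data-driven "ubiquitous" gene
  set selected by trimming each sample's non-zero expression distribution
  and intersecting across samples under an occurrence-rate threshold; the
  three trim parameters are chosen by exhaustive grid search maximizing
  AUCVC.

All factors are standardized to geometric mean 1 before application
(after which DESeq and RLE are identical and reported as one method).

Methods are evaluated with:

* **AUCVC** — area under the curve of uniform-gene counts vs. the
  min-max-normalized coefficient of variation (of log2 non-zero values)
  cutoff; higher is better;
* **mSCC** — median Spearman correlation over sampled ubiquitous gene
  pairs in the normalized matrix; closer to 0 is better;
* **RLE_MED / RLE_IQR** — mean squared per-sample median and variance of
  the per-sample IQR of relative log expression;
* hierarchical clustering of factor vectors with 1 − Spearman distances
  (Newick export).

A seeded negative-binomial simulator with known per-sample depth factors,
spike-in/housekeeping/mitochondrial rows, DE fraction and dropout provides
ground-truthed fixtures for all of the above.

## CLI

```bash
# generate a ground-truthed synthetic dataset
normeval simulate --preset scrna --genes 2000 --samples 20 --seed 1 --out-dir sim/

# mode 1: TU normalization without evaluation
normeval normalize --matrix sim/matrix.tsv --annotation sim/annotation.tsv \
    --preset scrna --out-dir norm/

# mode 2: simple evaluation (AUCVC over a non-zero-ratio cutoff grid)
normeval evaluate --mode 2 --matrix sim/matrix.tsv --annotation sim/annotation.tsv \
    --total-reads sim/total_reads.tsv --out-dir eval2/

# mode 3: complete evaluation (adds TU, mSCC, RLE metrics, consistency report)
normeval evaluate --mode 3 --matrix sim/matrix.tsv --annotation sim/annotation.tsv \
    --preset scrna --seed 1 --out-dir eval3/
```

Matrices are TSV/CSV (gene ids in the first column, sample ids in the
header) or MatrixMarket `.mtx` with `.rownames`/`.colnames` sidecars; use
`--transpose` for samples-as-rows input.  Annotations are
`gene_id<TAB>class` lines (`nuclear`, `mitochondrial`, `spike_in`) plus
optional `#set:<name>` control-set blocks.  A YAML config file
(`--config`) can supply any option; command-line flags win.

Presets mirror the two supported regimes: `scrna` (occurrence rate grid
0.2–0.6, >100 ubiquitous genes, non-zero-ratio cutoffs 0.2–0.9) and `bulk`
(occurrence rate 1, >1000 ubiquitous genes, cutoffs 0.7–1.0).

## Layout

```
src/normeval/
  core_data.py    data model + TSV/CSV/MTX/annotation/factor-table IO
  gene_sets.py    non-zero ratios, trimmed sets, ubiquitous genes
  factors.py      the eleven factor methods + standardization/application
  metrics.py      CV curves, AUCVC, mSCC, RLE metrics, factor clustering
  tu_search.py    AUCVC-maximizing grid search for TU trim parameters
  evaluation.py   the three usage modes, ranking, consistency report
  synthetic.py    ground-truthed count simulator (scrna / bulk presets)
  cli.py          click CLI (`normeval`)
```
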