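# Methods

## Scope and model

`gexmap` implements a gene–disease annotation and expression-analysis
workflow over RSEM gene-level quantifications. The underlying data model is
two relations:

* **gene_expression** — one row per (sample, gene) holding TPM, FPKM, the
  posterior expected fragment count, and the mean (effective) expressed
  transcript length from RSEM's `*.genes.results` output;
* **gene_disease_annotation** — one row per (gene, disease) pairing with an
  HGNC-style symbol, an unversioned Ensembl accession, and a coding
  category (`protein_coding` / `non_protein_coding`).

A query selects samples and an abundance type, restricts the gene universe
by coding category and/or disease terms, applies an inclusive abundance
window `[min, max]` under a pruning condition, joins survivors back to
their diseases, and exports the result as CSV and as a heat map. There is
deliberately no statistics here: no differential expression, no clustering,
no multiple-testing machinery. The method is a deterministic
select–filter–join, and everything downstream (ordering, coloring,
serialization) is fixed so that identical inputs give byte-identical
outputs.

## Pruning conditions and thresholds

Three condition modes decide whether a gene's row passes the window:

* `any_sample` — ∃ sample with `min ≤ v ≤ max`;
* `all_samples` — ∀ samples `min ≤ v ≤ max`;
* `mean_of_samples` — the row mean lies in the window.

Comparisons are inclusive on both bounds: a gene at exactly 100 TPM passes
a `min=100` filter. The canonical screen — "at least 100 TPM in at least
one sample" — is `min_value=100, condition=any_sample`. `all_samples`
results are always a subset of `any_sample` results for the same bounds,
and raising `min` can only shrink the retained set; both properties are
tested.

`abundance` may be `tpm`, `fpkm`, `expected_count` or `transcript_length`
(the last uses RSEM's `length` column, i.e. the mean expressed transcript
length). Cohort labels (control vs diseased) are carried through to output
grouping only; they never change filtering, because no between-cohort
statistic is defined.

## Missing data and normalization choices

* Ensembl version suffixes (`ENSG…​.14`) are stripped on ingest so the two
  relations join on unversioned accessions.
* (sample, gene) pairs absent from a subset file are materialized as 0.0
  when matrices are built (`zero_fill`, RSEM's own convention for
  unexpressed genes); `exclude_missing` instead drops genes not quantified
  in every selected sample.
* Per-sample TPM totals are checked against 1e6 at relative tolerance 1e-3;
  a deviation is a warning, not an error, because subset files are legal
  inputs.
* Disease terms are matched exactly after normalization (trim, collapse
  internal whitespace, case-fold); there is no fuzzy or ontology matching.
  A gene may carry records of both coding categories when sources disagree;
  category filters act per record.
* Result rows are ordered by descending mean abundance, ties broken
  alphabetically by gene symbol then accession. The rule is arbitrary but
  fixed, which is what reproducible exports need.

## Scaled TPM

`scaled_tpm_matrix` multiplies gene-level TPM by the sample's library size
in millions: `value = TPM × N / 1e6`. On a complete quantification each
column then totals its library size exactly, restoring the
sequencing-depth information that within-sample TPM normalization removes;
a library of exactly one million reads is the identity. Gene-level TPM is
taken directly from the gene results file — RSEM has already summed
transcript TPMs within genes.

## Heat maps

Colors come from named gradients: ≥ 2 RGB anchors at evenly spaced
positions in [0, 1], piecewise-linearly interpolated at
`t = clamp((v − vmin)/(vmax − vmin), 0, 1)`, each channel rounded half-up.
Half-up rounding is fixed and documented because it makes renders
deterministic down to the byte; the black→white midpoint is exactly
(128, 128, 128). Thirty gradients ship in the registry (simple ramps,
diverging schemes including the classic green–black–red microarray
palette, and 5-anchor approximations of viridis/magma/inferno/plasma/
cividis); user gradients can be registered at run time.

`vmin`/`vmax` default to the matrix min/max after the value transform
(`linear` by default; `log10(x+1)` offered because TPM spans orders of
magnitude). A constant matrix under auto-range maps every cell to the
first anchor. Transforms change colors only — never the retained gene set
or the row order.

Rendering uses Pillow directly with its built-in bitmap font: the data
region is exactly `cols × cell_size` by `rows × cell_size` pixels, margins
are added only for non-empty titles/labels, PNG output is byte-stable
across identical runs, and TIFF is written uncompressed. An empty result
renders as a small annotated "no genes" canvas rather than failing.

CSV export writes `gene_symbol, ensembl_id, <one column per sample>,
mean_transcript_length, diseases` with RFC-4180 quoting, disease terms
joined by `"; "`, and floats at full round-trip precision (`repr`), so
export → import is lossless.

## Synthetic cohorts and what they do (not) show

The generator emulates the workflow's reference study shape: 31 RNA-seq
samples, 500 genes, nine disjoint disease panels screened at a 100-TPM
any-sample cutoff. Panel "expressed" genes draw TPM uniformly from
[cutoff, 10 × cutoff] in at least one sample (each further sample is high
with probability 0.5, reflecting genes expressed in most but not all
patients); everything else stays below `background_tpm_max` (default 80,
i.e. clearly under the cutoff but the same order of magnitude). The default
expressed panel sizes are 34, 51, 32, 43, 2, 0, 2, 20 and 184, spanning the
realistic range of a chronic-disease screen and including two edge panels
(an empty one and a two-gene one).

A complete quantification must total 1e6 TPM per sample, which a few
hundred sub-cutoff genes cannot do on their own. A small set of
unannotated housekeeping genes (default 8) therefore absorbs each sample's
residual TPM mass, split by random weights, mirroring the real
transcriptome where a handful of mitochondrial/ribosomal genes dominate
the TPM budget. Housekeeping genes are above the cutoff by construction
but carry no disease annotation, so category- or disease-restricted
queries never see them. The draw is retried if a housekeeping share would
fall below the cutoff; the feasibility check on the configuration makes
this effectively unreachable at the default sizes.

Derived fields are self-consistent rather than simulated:
`count = TPM × efflen × N / Σ(TPM × efflen)` (counts total the library
size, 15–40 M reads per sample) and `FPKM = TPM × 1e9 / Σ(TPM × efflen)`;
gene lengths are uniform in 400–5000 bp with `efflen = length − 180`
(floored at 50). Roughly half the background genes receive decoy
annotations to exercise the join without touching recovery.

What passing tests show: the pipeline recovers planted above-cutoff
structure exactly, formats round-trip losslessly, and rendering is
deterministic. What they do not show: robustness to biological covariance
between genes, isoform-level effects, batch effects, or real annotation
noise — the generator deliberately models none of these, and files are
syntactically clean apart from the dedicated malformed-fixture suite.

## Numerical and degenerate-input choices

* Floats are serialized with Python's shortest round-trip `repr`; all
  round-trip contracts are exact, not approximate.
* `max_value` omitted means +∞; `min=0, max=∞` is the vacuous filter.
* Empty candidate sets and empty result tables flow through every stage
  (empty matrix → header-only CSV → placeholder image) without errors.
* Duplicate (ensembl_id, disease) annotation rows collapse silently on
  import (counted and reported); duplicate genes within one RSEM file are
  an integrity error, as are duplicate sample labels in a cohort.
* The embedded store is a single-file SQLite database with upsert
  semantics on both primary keys, so imports are idempotent.

## Problem sizes

Default test and verification sizes are the study shape itself (31 × 500
per cohort; the recovery suite runs 20 seeds) plus smaller 3–5-sample
cohorts for format and rendering contracts — large enough to exercise
every code path, small enough that the whole suite runs in seconds.

## Known limitations

* Annotation lookups are exact-term; synonymous disease names are distinct
  labels.
* The ENSG accession pattern is enforced on ingest, so quantifications
  against non-Ensembl references are rejected rather than passed through.
* `mean_transcript_length` averages only samples that actually carry a
  record for the gene (0.0 when none do under zero-fill).
* No vector output (SVG/PDF), no dendrograms or clustering on the heat
  maps, and no differential analysis.
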