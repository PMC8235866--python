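"""Synthetic RSEM cohorts and annotation tables with planted ground truth.

The generator emulates a bulk RNA-seq study in which disjoint panels of
genes are annotated to disease terms and a known subset of each panel is
"expressed": driven above a TPM cutoff in at least one sample.  All other
panel and background genes stay strictly below the cutoff in every sample.
Because a complete quantification must still total one million TPM per
sample while a few hundred sub-cutoff genes cannot, a small set of
unannotated housekeeping genes absorbs the residual TPM mass per sample —
mirroring the real transcriptome, where a handful of genes (mitochondrial,
ribosomal) dominate the TPM budget.  Housekeeping genes are above the
cutoff by construction but carry no disease annotation, so they never
perturb per-disease recovery.

Everything is deterministic given the seed: running the generator twice
with the same configuration produces byte-identical files and truth.

FPKM, expected counts and lengths are derived self-consistently:
``count_gs = TPM_gs * efflen_g * N_s / sum_g(TPM_gs * efflen_g)`` (counts
total the library size N_s) and ``FPKM_gs = TPM_gs * 1e9 /
sum_g(TPM_gs * efflen_g)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .annotation_store import Category
from .errors import FormatError, IntegrityError, ParseError, ValidationError

__all__ = [
    "DiseasePanel",
    "FixtureConfig",
    "FixtureTruth",
    "generate_cohort",
    "chronic_disease_study_config",
    "write_malformed_fixture",
    "MALFORMED_KINDS",
]

TPM_TOTAL = 1e6


@dataclass(frozen=True)
class DiseasePanel:
    """One disease term with its annotated panel and expressed fraction."""

    term: str
    panel_size: int
    expressed_fraction: float

    @property
    def n_expressed(self) -> int:
        return int(round(self.panel_size * self.expressed_fraction))


@dataclass
class FixtureConfig:
    """Study design for a synthetic cohort.

    ``cutoff`` is the TPM threshold the planting targets (expressed genes
    exceed it in >= 1 sample, everything else stays below in all samples);
    ``background_tpm_max`` bounds all sub-cutoff draws and must be below
    the cutoff.  ``n_housekeeping`` unannotated genes absorb the residual
    per-sample TPM mass so complete files total 1e6.
    """

    n_samples: int = 31
    n_genes: int = 500
    diseases: list[DiseasePanel] = field(default_factory=list)
    cutoff: float = 100.0
    background_tpm_max: float = 80.0
    n_housekeeping: int = 8
    high_sample_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValidationError("n_samples and n_genes must be positive")
        if not 0 < self.background_tpm_max < self.cutoff:
            raise ValidationError(
                f"background_tpm_max ({self.background_tpm_max}) must lie in (0, cutoff)"
            )
        if self.n_housekeeping < 1:
            raise ValidationError("at least one housekeeping gene is required")
        terms = [p.term for p in self.diseases]
        if len(set(terms)) != len(terms):
            raise ValidationError("disease panel terms must be distinct (panels are disjoint)")
        for panel in self.diseases:
            if panel.panel_size < 0 or not 0 <= panel.expressed_fraction <= 1:
                raise ValidationError(f"panel {panel.term!r}: invalid size or fraction")
        total_panel = sum(p.panel_size for p in self.diseases)
        if total_panel + self.n_housekeeping > self.n_genes:
            raise ValidationError(
                f"panels ({total_panel}) + housekeeping ({self.n_housekeeping}) "
                f"exceed n_genes ({self.n_genes})"
            )


@dataclass
class FixtureTruth:
    """Generator-recorded ground truth used as the recovery oracle."""

    samples: list[str]
    genes: list[str]
    symbols: dict[str, str]
    panel_genes: dict[str, list[str]]
    expressed_genes: dict[str, list[str]]
    housekeeping_genes: list[str]
    library_sizes: dict[str, int]
    cutoff: float
    tpm: dict[str, dict[str, float]]  # sample -> gene -> TPM as written

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=None, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        return cls(**json.loads(Path(path).read_text()))


def chronic_disease_study_config(seed: int = 0) -> FixtureConfig:
    """The default study design: a 31-sample cohort and nine disease
    panels whose expressed-set sizes span the headline range of a chronic
    disease screen, including one panel with no gene above the cutoff and
    one with exactly two."""
    return FixtureConfig(
        n_samples=31,
        n_genes=500,
        diseases=[
            DiseasePanel("Alzheimer's disease", 40, 34 / 40),
            DiseasePanel("arthritis", 60, 51 / 60),
            DiseasePanel("asthma", 40, 32 / 40),
            DiseasePanel("diabetes mellitus", 50, 43 / 50),
            DiseasePanel("obesity", 10, 2 / 10),
            DiseasePanel("osteoporosis", 12, 0.0),
            DiseasePanel("heart failure", 5, 2 / 5),
            DiseasePanel("hypertension", 25, 20 / 25),
            DiseasePanel("multiple cancer disorders", 200, 184 / 200),
        ],
        cutoff=100.0,
        seed=seed,
    )


def _fmt(value: float) -> str:
    return repr(float(value))


def generate_cohort(
    config: FixtureConfig, directory: str | Path
) -> tuple[dict[str, Path], Path, FixtureTruth]:
    """Write one RSEM ``.genes.results`` file per sample, an annotation CSV
    and a truth JSON under *directory*.

    Returns ``(sample -> expression path, annotation CSV path, truth)``.
    Expressed panel genes are drawn uniformly in [cutoff, 10 x cutoff] in
    their high samples and below ``background_tpm_max`` elsewhere;
    housekeeping genes split the residual mass so every sample's TPM totals
    exactly 1e6 (the draw is retried if a housekeeping share would fall
    below the cutoff, which the feasibility check makes vanishingly rare).
    """
    config.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_g, n_s = config.n_genes, config.n_samples
    gene_ids = [f"ENSG{i + 1:011d}" for i in range(n_g)]
    versions = rng.integers(1, 16, size=n_g)
    symbols = {gene_ids[i]: f"SYG{i + 1:04d}" for i in range(n_g)}
    samples = [f"S{j + 1:02d}" for j in range(n_s)]

    order = rng.permutation(n_g)
    cursor = 0
    panel_genes: dict[str, list[str]] = {}
    expressed: dict[str, list[str]] = {}
    for panel in config.diseases:
        members = sorted(gene_ids[i] for i in order[cursor:cursor + panel.panel_size])
        cursor += panel.panel_size
        panel_genes[panel.term] = members
        picked = rng.permutation(len(members))[: panel.n_expressed]
        expressed[panel.term] = sorted(members[i] for i in picked)
    housekeeping = sorted(gene_ids[i] for i in order[cursor:cursor + config.n_housekeeping])
    cursor += config.n_housekeeping
    background = sorted(gene_ids[i] for i in order[cursor:])

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    hk_idx = np.array([gene_index[g] for g in housekeeping])
    expressed_all = [g for terms in expressed.values() for g in terms]

    # lengths fixed per gene; effective length = length minus mean fragment
    lengths = rng.integers(400, 5001, size=n_g).astype(float)
    eff_lengths = np.maximum(lengths - 180.0, 50.0)
    library_sizes = {s: int(rng.integers(15_000_000, 40_000_001)) for s in samples}

    # background draws everywhere, then carve in the planted high cells
    tpm = rng.uniform(0.0, config.background_tpm_max, size=(n_g, n_s))
    for gene in expressed_all:
        gi = gene_index[gene]
        extra = rng.binomial(n_s - 1, config.high_sample_fraction)
        high_cols = rng.permutation(n_s)[: 1 + extra]
        tpm[gi, high_cols] = rng.uniform(config.cutoff, 10 * config.cutoff, size=len(high_cols))

    # housekeeping genes absorb the per-sample residual so totals hit 1e6
    tpm[hk_idx, :] = 0.0
    for j in range(n_s):
        for _attempt in range(100):
            residual = TPM_TOTAL - tpm[:, j].sum()
            weights = rng.uniform(0.5, 1.5, size=len(hk_idx))
            shares = residual * weights / weights.sum()
            if residual > 0 and (shares >= config.cutoff).all():
                tpm[hk_idx, j] = shares
                break
        else:
            raise ValidationError(
                f"sample {samples[j]}: could not balance TPM mass — the design leaves "
                "too little residual for the housekeeping genes; reduce n_genes, "
                "background_tpm_max or panel sizes"
            )

    # self-consistent counts and FPKM (see module docstring)
    denom = (tpm * eff_lengths[:, np.newaxis]).sum(axis=0)
    counts = tpm * eff_lengths[:, np.newaxis] / denom[np.newaxis, :]
    counts = counts * np.array([library_sizes[s] for s in samples])[np.newaxis, :]
    fpkm = tpm * 1e9 / denom[np.newaxis, :]

    # round-trip through the written decimal text so truth == parsed values
    header = "\t".join(("gene_id", "transcript_id(s)", "length", "effective_length",
                        "expected_count", "TPM", "FPKM"))
    expression_paths: dict[str, Path] = {}
    tpm_truth: dict[str, dict[str, float]] = {}
    for j, sid in enumerate(samples):
        lines = [header]
        per_gene: dict[str, float] = {}
        for i, gid in enumerate(gene_ids):
            written_tpm = float(_fmt(tpm[i, j]))
            per_gene[gid] = written_tpm
            lines.append("\t".join((
                f"{gid}.{versions[i]}", "",
                _fmt(lengths[i]), _fmt(eff_lengths[i]),
                _fmt(counts[i, j]), _fmt(tpm[i, j]), _fmt(fpkm[i, j]),
            )))
        path = directory / f"{sid}.genes.results"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        expression_paths[sid] = path
        tpm_truth[sid] = per_gene

    annotation_path = directory / "annotations.csv"
    _write_annotations(
        annotation_path, config, rng, symbols, panel_genes, background
    )

    truth = FixtureTruth(
        samples=samples,
        genes=gene_ids,
        symbols=symbols,
        panel_genes=panel_genes,
        expressed_genes=expressed,
        housekeeping_genes=housekeeping,
        library_sizes=library_sizes,
        cutoff=config.cutoff,
        tpm=tpm_truth,
    )
    truth.to_json(directory / "truth.json")
    return expression_paths, annotation_path, truth


def _write_annotations(
    path: Path,
    config: FixtureConfig,
    rng: np.random.Generator,
    symbols: dict[str, str],
    panel_genes: dict[str, list[str]],
    background: list[str],
) -> None:
    """Panel genes annotated to their disease, plus decoy annotations for
    roughly half the background genes (decoy diseases never overlap panel
    terms, so they exercise the join without touching recovery)."""
    decoy_terms = [f"synthetic decoy condition {k + 1}" for k in range(5)]
    categories: dict[str, str] = {}

    def cat(gene: str) -> str:
        if gene not in categories:
            coding = rng.random() < 0.6
            categories[gene] = (Category.PROTEIN_CODING if coding
                                else Category.NON_PROTEIN_CODING).value
        return categories[gene]

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["gene_symbol", "ensembl_id", "category", "disease"])
        for term, members in panel_genes.items():
            for gene in members:
                writer.writerow([symbols[gene], gene, cat(gene), term])
        for gene in background:
            if rng.random() < 0.5:
                term = decoy_terms[int(rng.integers(len(decoy_terms)))]
                writer.writerow([symbols[gene], gene, cat(gene), term])


# ---------------------------------------------------------------------------
# malformed fixtures for error-path testing

def _malformed_missing_column(path: Path) -> None:
    # RSEM file without the TPM column
    path.write_text(
        "gene_id\tlength\teffective_length\texpected_count\tFPKM\n"
        "ENSG00000000001\t1000\t820\t55\t12.5\n"
    )


def _malformed_non_numeric(path: Path) -> None:
    path.write_text(
        "gene_id\tlength\teffective_length\texpected_count\tTPM\tFPKM\n"
        "ENSG00000000001\t1000\t820\t55\tNA\t12.5\n"
    )


def _malformed_duplicate_gene(path: Path) -> None:
    path.write_text(
        "gene_id\tlength\teffective_length\texpected_count\tTPM\tFPKM\n"
        "ENSG00000000001.3\t1000\t820\t55\t10\t12.5\n"
        "ENSG00000000001.4\t900\t720\t25\t5\t6.5\n"
    )


def _malformed_bad_category(path: Path) -> None:
    path.write_text(
        "gene_symbol,ensembl_id,category,disease\n"
        "SYG0001,ENSG00000000001,coding-ish,asthma\n"
    )


def _malformed_missing_annotation_column(path: Path) -> None:
    path.write_text(
        "gene_symbol,ensembl_id,category\n"
        "SYG0001,ENSG00000000001,protein_coding\n"
    )


#: kind -> (writer, suggested filename, exception the parser must raise)
MALFORMED_KINDS: dict[str, tuple[Callable[[Path], None], str, type[Exception]]] = {
    "missing_column": (_malformed_missing_column, "missing_column.genes.results", FormatError),
    "non_numeric": (_malformed_non_numeric, "non_numeric.genes.results", ParseError),
    "duplicate_gene": (_malformed_duplicate_gene, "duplicate_gene.genes.results", IntegrityError),
    "bad_category": (_malformed_bad_category, "bad_category.csv", ValidationError),
    "missing_annotation_column": (
        _malformed_missing_annotation_column, "missing_annotation_column.csv", FormatError,
    ),
}


def write_malformed_fixture(kind: str, directory: str | Path) -> Path:
    """Write one deliberately malformed input file; returns its path."""
    try:
        writer, filename, _exc = MALFORMED_KINDS[kind]
    except KeyError:
        raise ValidationError(
            f"unknown malformed-fixture kind {kind!r} "
            f"(known: {', '.join(sorted(MALFORMED_KINDS))})"
        ) from None
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / filename
    writer(path)
    return path
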