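"""Cohort expression queries: matrix building, threshold filtering,
disease annotation and per-disease summaries.

The analysis follows the classic annotate-and-filter design: choose an
abundance type and a set of samples, restrict the gene universe by coding
category and/or disease terms via the annotation store, apply an inclusive
[min, max] abundance window under one of three pruning conditions
(``any_sample``, ``all_samples``, ``mean_of_samples``), and join the
surviving genes back to their annotated diseases.  The reference analysis
style — "at least 100 TPM in at least one sample" — corresponds to
``min_value=100, condition=any_sample``.

A scaled-TPM transform is provided for downstream count-based tools: gene
TPM multiplied by the sample's library size in millions, which restores
sequencing-depth information that TPM normalization removes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_store import AnnotationStore, GeneCategoryFilter
from .errors import UnknownReferenceError, ValidationError
from .rsem_io import ExpressionDataset

__all__ = [
    "Abundance",
    "Condition",
    "FillPolicy",
    "QuerySpec",
    "ExpressionMatrix",
    "ResultRow",
    "AnnotatedResultTable",
    "UNANNOTATED_KEY",
    "build_matrix",
    "apply_threshold",
    "annotate_result",
    "summarize_by_disease",
    "scaled_tpm_matrix",
    "run_query",
]

#: Reserved summary key for retained genes with no disease annotation.
UNANNOTATED_KEY = "(unannotated)"


class Abundance(enum.Enum):
    """Which quantification field populates the matrix."""

    TPM = "tpm"
    FPKM = "fpkm"
    EXPECTED_COUNT = "expected_count"
    TRANSCRIPT_LENGTH = "transcript_length"

    @property
    def record_field(self) -> str:
        # mean expressed transcript length lives in RSEM's `length` column
        return "length" if self is Abundance.TRANSCRIPT_LENGTH else self.value


class Condition(enum.Enum):
    """Pruning condition deciding whether a gene's row passes the window."""

    ANY_SAMPLE = "any_sample"
    ALL_SAMPLES = "all_samples"
    MEAN_OF_SAMPLES = "mean_of_samples"


class FillPolicy(enum.Enum):
    """How (sample, gene) pairs absent from the dataset are treated:
    materialized as 0.0, or the gene excluded when any selected sample
    lacks a record."""

    ZERO_FILL = "zero_fill"
    EXCLUDE_MISSING = "exclude_missing"


@dataclass
class QuerySpec:
    """A full analysis design.

    ``cohorts`` optionally partitions ``samples`` into labeled groups
    (e.g. control vs diseased); it affects output grouping and labels only,
    never filtering.  Empty ``diseases`` means no disease restriction.
    """

    samples: list[str]
    abundance: Abundance = Abundance.TPM
    min_value: float = 0.0
    max_value: float = math.inf
    condition: Condition = Condition.ANY_SAMPLE
    cohorts: dict[str, list[str]] | None = None
    category: GeneCategoryFilter = GeneCategoryFilter.ALL
    diseases: list[str] = field(default_factory=list)
    fill_policy: FillPolicy = FillPolicy.ZERO_FILL

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.samples:
            raise ValidationError("QuerySpec.samples must be non-empty")
        if self.min_value < 0:
            raise ValidationError(f"min_value must be >= 0, got {self.min_value}")
        if self.max_value <= 0:
            raise ValidationError(f"max_value must be > 0, got {self.max_value}")
        if self.min_value > self.max_value:
            raise ValidationError(
                f"min_value ({self.min_value}) must not exceed max_value ({self.max_value})"
            )
        if self.cohorts is not None:
            pooled: list[str] = [s for members in self.cohorts.values() for s in members]
            if sorted(pooled) != sorted(self.samples):
                raise ValidationError("cohort labels must partition the sample list exactly")

    def to_dict(self) -> dict:
        return {
            "samples": list(self.samples),
            "abundance": self.abundance.value,
            "min_value": self.min_value,
            "max_value": None if math.isinf(self.max_value) else self.max_value,
            "condition": self.condition.value,
            "cohorts": None if self.cohorts is None else {k: list(v) for k, v in self.cohorts.items()},
            "category": self.category.value,
            "diseases": list(self.diseases),
            "fill_policy": self.fill_policy.value,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "QuerySpec":
        def _enum(enum_cls, key, default):
            raw = data.get(key, default)
            if isinstance(raw, enum_cls):
                return raw
            try:
                return enum_cls(str(raw))
            except ValueError:
                choices = ", ".join(e.value for e in enum_cls)
                raise ValidationError(
                    f"invalid {key} {raw!r} (expected one of: {choices})"
                ) from None

        max_value = data.get("max_value", None)
        return cls(
            samples=list(data.get("samples", [])),
            abundance=_enum(Abundance, "abundance", Abundance.TPM.value),
            min_value=float(data.get("min_value", 0.0)),
            max_value=math.inf if max_value is None else float(max_value),
            condition=_enum(Condition, "condition", Condition.ANY_SAMPLE.value),
            cohorts={k: list(v) for k, v in data["cohorts"].items()} if data.get("cohorts") else None,
            category=_enum(GeneCategoryFilter, "category", GeneCategoryFilter.ALL.value),
            diseases=[str(d) for d in data.get("diseases", [])],
            fill_policy=_enum(FillPolicy, "fill_policy", FillPolicy.ZERO_FILL.value),
        )


@dataclass
class ExpressionMatrix:
    """Dense genes x samples abundance matrix with parallel row metadata."""

    gene_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    fill_policy: FillPolicy = FillPolicy.ZERO_FILL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_symbols) != len(self.gene_ids):
            raise ValidationError("gene_symbols must parallel gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_rows(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(mask)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            fill_policy=self.fill_policy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True, slots=True)
class ResultRow:
    gene_symbol: str
    ensembl_id: str
    abundances: tuple[float, ...]
    mean_transcript_length: float
    diseases: tuple[str, ...]


@dataclass
class AnnotatedResultTable:
    """Filtered genes x samples with abundances, lengths and disease terms.

    Rows are ordered descending by mean abundance, ties broken
    alphabetically by gene symbol then accession — a fixed rule so exports
    are reproducible.
    """

    sample_ids: list[str]
    rows: list[ResultRow]
    abundance: Abundance = Abundance.TPM

    def __len__(self) -> int:
        return len(self.rows)

    def values_matrix(self) -> np.ndarray:
        if not self.rows:
            return np.zeros((0, len(self.sample_ids)))
        return np.array([row.abundances for row in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "gene_symbol": [r.gene_symbol for r in self.rows],
            "ensembl_id": [r.ensembl_id for r in self.rows],
        }
        values = self.values_matrix()
        for j, sid in enumerate(self.sample_ids):
            data[sid] = values[:, j] if len(self.rows) else []
        data["mean_transcript_length"] = [r.mean_transcript_length for r in self.rows]
        data["diseases"] = ["; ".join(r.diseases) for r in self.rows]
        return pd.DataFrame(data)


def _candidate_genes(
    dataset: ExpressionDataset, spec: QuerySpec, store: AnnotationStore | None
) -> list[str]:
    """Gene universe for a query, in dataset order."""
    if spec.category is GeneCategoryFilter.ALL and not spec.diseases:
        return list(dataset.genes)
    if store is None:
        raise ValidationError(
            "an annotation store is required for category or disease restrictions"
        )
    if spec.diseases:
        wanted: set[str] = set()
        for term in spec.diseases:
            wanted.update(ensg for _sym, ensg in store.genes_for_disease(term, spec.category))
    else:
        wanted = set(store.genes(spec.category))
    return [g for g in dataset.genes if g in wanted]


def build_matrix(
    dataset: ExpressionDataset, spec: QuerySpec, store: AnnotationStore | None = None
) -> ExpressionMatrix:
    """Assemble the abundance matrix for a query's samples and candidate genes.

    An empty candidate set yields an empty (0-row) matrix, not an error;
    an unknown sample raises :class:`UnknownReferenceError`.
    """
    unknown = [s for s in spec.samples if s not in dataset.samples]
    if unknown:
        raise UnknownReferenceError(f"unknown sample_id(s): {', '.join(unknown)}")
    genes = _candidate_genes(dataset, spec, store)
    field_name = spec.abundance.record_field

    if spec.fill_policy is FillPolicy.EXCLUDE_MISSING:
        genes = [
            g for g in genes
            if all((s, g) in dataset.records for s in spec.samples)
        ]
    values = dataset.matrix(field_name, samples=spec.samples, genes=genes, fill=0.0)
    symbols = [
        (store.symbol_for(g) if store is not None else None) or g for g in genes
    ]
    return ExpressionMatrix(
        gene_ids=genes,
        gene_symbols=symbols,
        sample_ids=list(spec.samples),
        values=values,
        fill_policy=spec.fill_policy,
    )


def apply_threshold(
    matrix: ExpressionMatrix,
    min_value: float = 0.0,
    max_value: float = math.inf,
    condition: Condition = Condition.ANY_SAMPLE,
) -> ExpressionMatrix:
    """Retain gene rows passing the inclusive [min_value, max_value] window.

    ``any_sample``: some sample's value lies in the window;
    ``all_samples``: every sample's value does;
    ``mean_of_samples``: the row mean does.  Columns are never dropped.
    """
    if min_value > max_value:
        raise ValidationError(f"min_value ({min_value}) must not exceed max_value ({max_value})")
    if matrix.n_genes == 0:
        return matrix
    inside = (matrix.values >= min_value) & (matrix.values <= max_value)
    if condition is Condition.ANY_SAMPLE:
        keep = inside.any(axis=1)
    elif condition is Condition.ALL_SAMPLES:
        keep = inside.all(axis=1)
    else:
        means = matrix.values.mean(axis=1)
        keep = (means >= min_value) & (means <= max_value)
    return matrix.take_rows(keep)


def annotate_result(
    matrix: ExpressionMatrix,
    store: AnnotationStore | None,
    dataset: ExpressionDataset,
    abundance: Abundance = Abundance.TPM,
) -> AnnotatedResultTable:
    """Join post-filter matrix rows with transcript lengths and disease terms.

    The mean transcript length averages RSEM's ``length`` over the matrix's
    samples that actually carry a record for the gene (0.0 when none do).
    Genes absent from the store are kept with an empty disease list.
    """
    rows: list[ResultRow] = []
    for i, gene_id in enumerate(matrix.gene_ids):
        lengths = [
            dataset.records[(s, gene_id)].length
            for s in matrix.sample_ids
            if (s, gene_id) in dataset.records
        ]
        mean_len = float(np.mean(lengths)) if lengths else 0.0
        diseases = tuple(store.diseases_for_gene(gene_id)) if store is not None else ()
        rows.append(ResultRow(
            gene_symbol=matrix.gene_symbols[i],
            ensembl_id=gene_id,
            abundances=tuple(float(v) for v in matrix.values[i, :]),
            mean_transcript_length=mean_len,
            diseases=diseases,
        ))
    rows.sort(key=lambda r: (-float(np.mean(r.abundances)) if r.abundances else 0.0,
                             r.gene_symbol, r.ensembl_id))
    return AnnotatedResultTable(sample_ids=list(matrix.sample_ids), rows=rows,
                                abundance=abundance)


def summarize_by_disease(table: AnnotatedResultTable) -> dict[str, int]:
    """Distinct retained genes per disease term; genes carrying no
    annotation are tallied under :data:`UNANNOTATED_KEY`."""
    genes_by_disease: dict[str, set[str]] = {}
    for row in table.rows:
        if not row.diseases:
            genes_by_disease.setdefault(UNANNOTATED_KEY, set()).add(row.ensembl_id)
            continue
        for term in row.diseases:
            genes_by_disease.setdefault(term, set()).add(row.ensembl_id)
    return {term: len(genes) for term, genes in sorted(genes_by_disease.items())}


def scaled_tpm_matrix(
    dataset: ExpressionDataset,
    library_sizes: Mapping[str, float],
    samples: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Scale gene-level TPM by library size in millions.

    Cell value = TPM x (library_size / 1e6); with a complete quantification
    each column then totals its sample's library size.  Gene-level TPM is
    read directly from the gene results (RSEM has already summed transcript
    TPMs within genes).  Non-positive or missing library sizes raise
    :class:`ValidationError`.
    """
    samples = list(dataset.samples) if samples is None else list(samples)
    unknown = [s for s in samples if s not in dataset.samples]
    if unknown:
        raise UnknownReferenceError(f"unknown sample_id(s): {', '.join(unknown)}")
    factors = []
    for sid in samples:
        size = library_sizes.get(sid)
        if size is None or size <= 0:
            raise ValidationError(f"sample {sid!r}: library size must be positive, got {size!r}")
        factors.append(size / 1e6)
    tpm = dataset.matrix("tpm", samples=samples)
    return ExpressionMatrix(
        gene_ids=list(dataset.genes),
        gene_symbols=list(dataset.genes),
        sample_ids=samples,
        values=tpm * np.asarray(factors)[np.newaxis, :],
    )


def run_query(
    dataset: ExpressionDataset, spec: QuerySpec, store: AnnotationStore | None = None
) -> AnnotatedResultTable:
    """Convenience pipeline: build matrix, apply the window, annotate."""
    matrix = build_matrix(dataset, spec, store)
    filtered = apply_threshold(matrix, spec.min_value, spec.max_value, spec.condition)
    return annotate_result(filtered, store, dataset, abundance=spec.abundance)
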