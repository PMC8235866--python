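"""Reading and writing RSEM gene-level quantification files.

RSEM's ``*.genes.results`` output is a tab-separated table with one row per
gene carrying the estimated abundances (TPM, FPKM), the posterior expected
fragment count, and the (effective) transcript lengths.  This module parses
those files into :class:`GeneExpressionRecord` rows, assembles per-sample
files into an :class:`ExpressionDataset` — the in-memory form of the "gene
expression" relation — and writes datasets back out in the same dialect.

Ensembl gene accessions are normalized on ingest: a trailing ``.version``
suffix is always stripped so that expression rows join against annotation
rows on unversioned ENSG identifiers.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import FormatError, IntegrityError, ParseError, ValidationError

__all__ = [
    "GeneExpressionRecord",
    "ExpressionDataset",
    "TpmSumWarning",
    "parse_genes_results",
    "load_cohort",
    "write_genes_results",
    "write_cohort",
    "normalize_gene_id",
]

#: Columns every gene-level RSEM file must provide (order-independent;
#: extra columns such as ``transcript_id(s)`` are ignored).
REQUIRED_COLUMNS = ("gene_id", "length", "effective_length", "expected_count", "TPM", "FPKM")

#: TPM values of a complete quantification sum to one million per sample.
TPM_TOTAL = 1e6
TPM_SUM_RTOL = 1e-3

_ENSG_PATTERN = re.compile(r"^ENSG\d+$")


class TpmSumWarning(UserWarning):
    """Per-sample TPM total deviates from 1e6 — legal for subset files."""


def normalize_gene_id(raw: str) -> str:
    """Strip a trailing ``.version`` suffix from an Ensembl gene accession."""
    return raw.strip().split(".", 1)[0]


@dataclass(frozen=True, slots=True)
class GeneExpressionRecord:
    """One gene's quantification in one sample (a row of the expression relation)."""

    sample_id: str
    gene_id: str
    length: float
    effective_length: float
    expected_count: float
    tpm: float
    fpkm: float

    def validate(self) -> None:
        if not _ENSG_PATTERN.match(self.gene_id):
            raise ValidationError(
                f"gene_id {self.gene_id!r} is not an unversioned ENSG accession"
            )
        if self.length <= 0:
            raise ValidationError(f"{self.gene_id}: length must be > 0, got {self.length}")
        if self.effective_length < 0:
            raise ValidationError(
                f"{self.gene_id}: effective_length must be >= 0, got {self.effective_length}"
            )
        for name in ("expected_count", "tpm", "fpkm"):
            value = getattr(self, name)
            if value < 0 or math.isnan(value):
                raise ValidationError(f"{self.gene_id}: {name} must be >= 0, got {value}")


@dataclass
class ExpressionDataset:
    """A cohort's expression relation: records keyed by (sample, gene).

    ``samples`` preserves load order; ``genes`` is the union of per-sample
    gene sets in first-seen order.  Pairs absent from ``records`` represent
    genes a subset file did not report; matrix builders zero-fill them by
    default (RSEM itself reports 0 for unexpressed genes).
    """

    samples: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    records: dict[tuple[str, str], GeneExpressionRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sample_set, gene_set = set(self.samples), set(self.genes)
        for (sid, gid), rec in self.records.items():
            if sid not in sample_set or gid not in gene_set:
                raise IntegrityError(f"record ({sid}, {gid}) outside declared sample/gene universe")
            if (rec.sample_id, rec.gene_id) != (sid, gid):
                raise IntegrityError(f"record key ({sid}, {gid}) disagrees with record fields")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def get(self, sample_id: str, gene_id: str) -> GeneExpressionRecord | None:
        return self.records.get((sample_id, gene_id))

    def value(self, sample_id: str, gene_id: str, field_name: str, fill: float = 0.0) -> float:
        """Abundance/length lookup for one cell, zero-filled when absent."""
        rec = self.records.get((sample_id, gene_id))
        return fill if rec is None else getattr(rec, field_name)

    def matrix(self, field_name: str, samples: list[str] | None = None,
               genes: list[str] | None = None, fill: float = 0.0) -> np.ndarray:
        """Dense genes x samples matrix of one numeric field."""
        samples = self.samples if samples is None else samples
        genes = self.genes if genes is None else genes
        out = np.full((len(genes), len(samples)), fill, dtype=float)
        for i, g in enumerate(genes):
            for j, s in enumerate(samples):
                rec = self.records.get((s, g))
                if rec is not None:
                    out[i, j] = getattr(rec, field_name)
        return out

    def tpm_sum(self, sample_id: str) -> float:
        return sum(r.tpm for (s, _g), r in self.records.items() if s == sample_id)

    def check_tpm_totals(self) -> None:
        """Warn (never fail) for samples whose TPM total strays from 1e6."""
        for sid in self.samples:
            total = self.tpm_sum(sid)
            if not math.isclose(total, TPM_TOTAL, rel_tol=TPM_SUM_RTOL):
                warnings.warn(
                    f"sample {sid!r}: TPM total {total:.1f} deviates from 1e6 "
                    "(expected for subset files, suspicious for complete RSEM output)",
                    TpmSumWarning,
                    stacklevel=2,
                )


def parse_genes_results(path: str | Path, sample_id: str) -> list[GeneExpressionRecord]:
    """Parse one RSEM ``.genes.results`` file into records for *sample_id*.

    The header must contain every column in :data:`REQUIRED_COLUMNS`
    (any order, extras ignored).  Gene accessions are version-stripped.

    Raises
    ------
    FormatError
        Missing required column or empty file.
    ParseError
        Non-numeric value in a numeric column (message carries the line number).
    IntegrityError
        The same gene appears twice within the file.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file, expected an RSEM header line")
        header = [col.strip() for col in header]
        missing = [col for col in REQUIRED_COLUMNS if col not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        index = {col: header.index(col) for col in REQUIRED_COLUMNS}

        records: list[GeneExpressionRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise ParseError(f"{path}, line {lineno}: expected {len(header)} fields, got {len(row)}")
            gene_id = normalize_gene_id(row[index["gene_id"]])
            if gene_id in seen:
                raise IntegrityError(f"{path}, line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            numeric: dict[str, float] = {}
            for col in REQUIRED_COLUMNS[1:]:
                raw = row[index[col]].strip()
                try:
                    numeric[col] = float(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric value {raw!r} in column {col!r}"
                    ) from None
            record = GeneExpressionRecord(
                sample_id=sample_id,
                gene_id=gene_id,
                length=numeric["length"],
                effective_length=numeric["effective_length"],
                expected_count=numeric["expected_count"],
                tpm=numeric["TPM"],
                fpkm=numeric["FPKM"],
            )
            record.validate()
            records.append(record)
    return records


def load_cohort(
    sample_map: Mapping[str, str | Path] | Iterable[tuple[str, str | Path]],
) -> ExpressionDataset:
    """Assemble per-sample RSEM files into one :class:`ExpressionDataset`.

    ``sample_map`` maps sample labels to file paths (a mapping, or pairs when
    order matters beyond insertion order).  Sample order follows the mapping;
    the gene universe is the union of per-file gene sets in first-seen order.
    Parse failures propagate with the sample label attached; a repeated
    sample label raises :class:`IntegrityError`.
    """
    pairs = list(sample_map.items()) if isinstance(sample_map, Mapping) else list(sample_map)
    if not pairs:
        raise ValidationError("load_cohort requires at least one sample")

    samples: list[str] = []
    genes: list[str] = []
    gene_seen: set[str] = set()
    records: dict[tuple[str, str], GeneExpressionRecord] = {}
    for sample_id, path in pairs:
        if sample_id in samples:
            raise IntegrityError(f"duplicate sample_id {sample_id!r} in cohort")
        samples.append(sample_id)
        try:
            sample_records = parse_genes_results(path, sample_id)
        except (FormatError, ParseError, IntegrityError) as exc:
            raise type(exc)(f"sample {sample_id!r}: {exc}") from exc
        for rec in sample_records:
            if rec.gene_id not in gene_seen:
                gene_seen.add(rec.gene_id)
                genes.append(rec.gene_id)
            records[(sample_id, rec.gene_id)] = rec
    dataset = ExpressionDataset(samples=samples, genes=genes, records=records)
    dataset.check_tpm_totals()
    return dataset


def _fmt(value: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(value))


def write_genes_results(records: Iterable[GeneExpressionRecord], path: str | Path) -> None:
    """Write records (one sample) as an RSEM-dialect ``.genes.results`` file."""
    path = Path(path)
    lines = ["\t".join(("gene_id", "transcript_id(s)", "length", "effective_length",
                        "expected_count", "TPM", "FPKM"))]
    for rec in records:
        lines.append("\t".join((
            rec.gene_id, "",
            _fmt(rec.length), _fmt(rec.effective_length),
            _fmt(rec.expected_count), _fmt(rec.tpm), _fmt(rec.fpkm),
        )))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort(dataset: ExpressionDataset, directory: str | Path,
                 suffix: str = ".genes.results") -> dict[str, Path]:
    """Write one RSEM-format file per sample; returns the sample -> path map.

    Only (sample, gene) pairs present in the dataset are written, so subset
    datasets round-trip without inventing zero rows.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid in dataset.samples:
        recs = [dataset.records[(sid, g)] for g in dataset.genes if (sid, g) in dataset.records]
        out = directory / f"{sid}{suffix}"
        write_genes_results(recs, out)
        paths[sid] = out
    return paths
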