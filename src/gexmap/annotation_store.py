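"""The gene-disease annotation relation: import, index, query, export.

Each :class:`AnnotationRecord` pairs a gene (HGNC-style symbol plus
unversioned Ensembl accession) with one disease term and a coding category.
A store holds the distinct set of such pairings — duplicates on
``(ensembl_id, disease)`` collapse on import — and answers the two query
directions the analysis needs: which genes are linked to a disease, and
which diseases a gene is linked to.

Disease terms are normalized for matching (trimmed, internal whitespace
collapsed, compared case-insensitively) but stored with their original
case.  A gene may legitimately carry both a protein-coding and a
non-protein-coding record when heterogeneous sources disagree; category
filters therefore act per record, never per gene.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import FormatError, ValidationError

__all__ = [
    "Category",
    "GeneCategoryFilter",
    "AnnotationRecord",
    "AnnotationStore",
    "ImportStats",
    "import_annotations",
    "export_annotations",
    "normalize_disease",
]


class Category(enum.Enum):
    PROTEIN_CODING = "protein_coding"
    NON_PROTEIN_CODING = "non_protein_coding"


class GeneCategoryFilter(enum.Enum):
    """Gene-category selector for queries.

    ``coding`` / ``non_coding`` match records of that category only;
    ``both`` matches any annotated record regardless of category; ``all``
    additionally admits genes with no annotation at all (meaningful when
    selecting genes from an expression dataset, equivalent to ``both``
    when scanning the annotation store itself).
    """

    CODING = "coding"
    NON_CODING = "non_coding"
    BOTH = "both"
    ALL = "all"


def normalize_disease(term: str) -> str:
    """Collapse internal whitespace and trim; case is preserved here and
    folded only at comparison time."""
    return " ".join(term.split())


def _disease_key(term: str) -> str:
    return normalize_disease(term).lower()


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """One (gene, disease) pairing — a row of the annotation relation."""

    gene_symbol: str
    ensembl_id: str
    category: Category
    disease: str

    def validate(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if not self.ensembl_id.startswith("ENSG") or "." in self.ensembl_id:
            raise ValidationError(
                f"ensembl_id {self.ensembl_id!r} must be an unversioned ENSG accession"
            )
        if not normalize_disease(self.disease):
            raise ValidationError(f"{self.ensembl_id}: disease term must be non-empty")


@dataclass(frozen=True, slots=True)
class ImportStats:
    rows_read: int
    collapsed: int


class AnnotationStore:
    """Indexed collection of distinct (ensembl_id, disease) annotation records."""

    def __init__(self, records: Iterable[AnnotationRecord] = ()) -> None:
        self._records: dict[tuple[str, str], AnnotationRecord] = {}
        self._by_disease: dict[str, list[AnnotationRecord]] = {}
        self._by_symbol: dict[str, list[AnnotationRecord]] = {}
        self._by_ensembl: dict[str, list[AnnotationRecord]] = {}
        self.import_stats: ImportStats | None = None
        collapsed = 0
        for rec in records:
            collapsed += 0 if self.add(rec) else 1
        self._initial_collapsed = collapsed

    def add(self, record: AnnotationRecord) -> bool:
        """Insert a record; returns False when it collapses onto an existing
        (ensembl_id, disease) pair."""
        record = AnnotationRecord(
            gene_symbol=record.gene_symbol.strip(),
            ensembl_id=record.ensembl_id.strip(),
            category=record.category,
            disease=normalize_disease(record.disease),
        )
        record.validate()
        key = (record.ensembl_id, _disease_key(record.disease))
        if key in self._records:
            return False
        self._records[key] = record
        self._by_disease.setdefault(_disease_key(record.disease), []).append(record)
        self._by_symbol.setdefault(record.gene_symbol.lower(), []).append(record)
        self._by_ensembl.setdefault(record.ensembl_id, []).append(record)
        return True

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self._records.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        ensg, disease = pair
        return (ensg, _disease_key(disease)) in self._records

    @staticmethod
    def _passes(record: AnnotationRecord, category: GeneCategoryFilter) -> bool:
        if category is GeneCategoryFilter.CODING:
            return record.category is Category.PROTEIN_CODING
        if category is GeneCategoryFilter.NON_CODING:
            return record.category is Category.NON_PROTEIN_CODING
        return True  # both / all admit any annotated record

    def genes_for_disease(
        self, disease: str, category: GeneCategoryFilter = GeneCategoryFilter.ALL
    ) -> list[tuple[str, str]]:
        """Distinct (gene_symbol, ensembl_id) pairs annotated to *disease*,
        sorted by symbol then accession.  Unknown diseases yield []."""
        hits = {
            (r.gene_symbol, r.ensembl_id)
            for r in self._by_disease.get(_disease_key(disease), [])
            if self._passes(r, category)
        }
        return sorted(hits)

    def diseases_for_gene(self, gene: str) -> list[str]:
        """Sorted distinct disease terms for a gene given by symbol (matched
        case-insensitively) or by unversioned ENSG accession."""
        records = self._by_ensembl.get(gene.strip(), None)
        if records is None:
            records = self._by_symbol.get(gene.strip().lower(), [])
        return sorted({r.disease for r in records})

    def genes(self, category: GeneCategoryFilter = GeneCategoryFilter.ALL) -> list[str]:
        """Distinct annotated ENSG accessions passing the category filter, sorted."""
        return sorted({r.ensembl_id for r in self if self._passes(r, category)})

    def symbol_for(self, ensembl_id: str) -> str | None:
        """The gene symbol recorded for an accession (alphabetically first
        when sources disagree); None for unannotated genes."""
        records = self._by_ensembl.get(ensembl_id)
        if not records:
            return None
        return min(r.gene_symbol for r in records)


_CSV_COLUMNS = ("gene_symbol", "ensembl_id", "category", "disease")
_CATEGORY_TOKENS = {c.value: c for c in Category}


def import_annotations(path: str | Path) -> AnnotationStore:
    """Load an annotation CSV into a store, collapsing duplicate pairs.

    The header must contain ``gene_symbol, ensembl_id, category, disease``
    in any order.  ``category`` must be ``protein_coding`` or
    ``non_protein_coding``.  The returned store carries an
    :class:`ImportStats` with the rows read and duplicates collapsed.
    """
    path = Path(path)
    store = AnnotationStore()
    rows_read = 0
    collapsed = 0
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a CSV header")
        fieldnames = [f.strip() for f in reader.fieldnames]
        missing = [c for c in _CSV_COLUMNS if c not in fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            token = (row.get("category") or "").strip()
            category = _CATEGORY_TOKENS.get(token)
            if category is None:
                raise ValidationError(
                    f"{path}, line {lineno}: unknown category {token!r} "
                    f"(expected one of: {', '.join(sorted(_CATEGORY_TOKENS))})"
                )
            record = AnnotationRecord(
                gene_symbol=(row.get("gene_symbol") or "").strip(),
                ensembl_id=(row.get("ensembl_id") or "").strip(),
                category=category,
                disease=row.get("disease") or "",
            )
            try:
                added = store.add(record)
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
            rows_read += 1
            collapsed += 0 if added else 1
    store.import_stats = ImportStats(rows_read=rows_read, collapsed=collapsed)
    return store


def export_annotations(store: AnnotationStore, path: str | Path) -> None:
    """Write the store back out as a UTF-8, RFC-4180 CSV."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for rec in sorted(store, key=lambda r: (r.ensembl_id, r.disease.lower())):
            writer.writerow([rec.gene_symbol, rec.ensembl_id, rec.category.value, rec.disease])
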