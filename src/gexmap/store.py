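"""Single-file embedded relational store (SQLite).

Two tables mirror the analysis' two relations:

* ``gene_expression`` — sample_id, gene_id, length, effective_length,
  expected_count, tpm, fpkm; primary key (sample_id, gene_id)
* ``gene_disease_annotation`` — gene_symbol, ensembl_id, category,
  disease; primary key (ensembl_id, disease)

Schema creation and loading are idempotent: re-importing identical inputs
leaves the store unchanged (upsert semantics on the primary keys).
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

from .annotation_store import AnnotationRecord, AnnotationStore, Category
from .rsem_io import ExpressionDataset, GeneExpressionRecord

__all__ = [
    "open_store",
    "save_dataset",
    "load_dataset",
    "save_annotations",
    "load_annotations",
    "store_summary",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS gene_expression (
    sample_id        TEXT NOT NULL,
    gene_id          TEXT NOT NULL,
    length           REAL NOT NULL,
    effective_length REAL NOT NULL,
    expected_count   REAL NOT NULL,
    tpm              REAL NOT NULL,
    fpkm             REAL NOT NULL,
    PRIMARY KEY (sample_id, gene_id)
);
CREATE TABLE IF NOT EXISTS gene_disease_annotation (
    gene_symbol TEXT NOT NULL,
    ensembl_id  TEXT NOT NULL,
    category    TEXT NOT NULL,
    disease     TEXT NOT NULL,
    PRIMARY KEY (ensembl_id, disease)
);
CREATE TABLE IF NOT EXISTS sample_order (
    position  INTEGER PRIMARY KEY,
    sample_id TEXT NOT NULL UNIQUE
);
"""


def open_store(path: str | Path) -> sqlite3.Connection:
    """Open (creating if needed) the embedded store and ensure the schema."""
    conn = sqlite3.connect(str(path))
    conn.executescript(_SCHEMA)
    conn.commit()
    return conn


def save_dataset(conn: sqlite3.Connection, dataset: ExpressionDataset) -> None:
    conn.executemany(
        "INSERT OR REPLACE INTO gene_expression VALUES (?,?,?,?,?,?,?)",
        [
            (r.sample_id, r.gene_id, r.length, r.effective_length,
             r.expected_count, r.tpm, r.fpkm)
            for r in dataset.records.values()
        ],
    )
    known = {row[0] for row in conn.execute("SELECT sample_id FROM sample_order")}
    start = conn.execute("SELECT COALESCE(MAX(position), -1) FROM sample_order").fetchone()[0] + 1
    new = [(start + i, s) for i, s in enumerate(s for s in dataset.samples if s not in known)]
    conn.executemany("INSERT INTO sample_order VALUES (?,?)", new)
    conn.commit()


def load_dataset(conn: sqlite3.Connection) -> ExpressionDataset:
    samples = [row[0] for row in
               conn.execute("SELECT sample_id FROM sample_order ORDER BY position")]
    records: dict[tuple[str, str], GeneExpressionRecord] = {}
    genes: list[str] = []
    seen: set[str] = set()
    rows = conn.execute(
        "SELECT sample_id, gene_id, length, effective_length, expected_count, tpm, fpkm "
        "FROM gene_expression ORDER BY sample_id, gene_id"
    )
    for sid, gid, length, eff, count, tpm, fpkm in rows:
        if gid not in seen:
            seen.add(gid)
            genes.append(gid)
        records[(sid, gid)] = GeneExpressionRecord(
            sample_id=sid, gene_id=gid, length=length, effective_length=eff,
            expected_count=count, tpm=tpm, fpkm=fpkm,
        )
    if not samples:  # legacy store without explicit ordering
        samples = sorted({sid for sid, _ in records})
    return ExpressionDataset(samples=samples, genes=sorted(genes), records=records)


def save_annotations(conn: sqlite3.Connection, store: AnnotationStore) -> None:
    conn.executemany(
        "INSERT OR REPLACE INTO gene_disease_annotation VALUES (?,?,?,?)",
        [(r.gene_symbol, r.ensembl_id, r.category.value, r.disease) for r in store],
    )
    conn.commit()


def load_annotations(conn: sqlite3.Connection) -> AnnotationStore:
    rows = conn.execute(
        "SELECT gene_symbol, ensembl_id, category, disease FROM gene_disease_annotation"
    )
    return AnnotationStore(
        AnnotationRecord(gene_symbol=sym, ensembl_id=ensg,
                         category=Category(cat), disease=term)
        for sym, ensg, cat, term in rows
    )


def store_summary(conn: sqlite3.Connection) -> dict[str, int]:
    return {
        "samples": conn.execute(
            "SELECT COUNT(DISTINCT sample_id) FROM gene_expression").fetchone()[0],
        "genes": conn.execute(
            "SELECT COUNT(DISTINCT gene_id) FROM gene_expression").fetchone()[0],
        "expression_rows": conn.execute(
            "SELECT COUNT(*) FROM gene_expression").fetchone()[0],
        "annotation_rows": conn.execute(
            "SELECT COUNT(*) FROM gene_disease_annotation").fetchone()[0],
    }
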