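"""Canonical intron-chain identity and the persistent relational store.

An isoform's identity is its intron chain: chromosome, strand, and the
ordered list of intron intervals. Transcripts truncated at either end but
sharing every splice junction collapse onto one identity; their distinct
(start, end) pairs are tracked separately as *ends variants* with IDs of
the form ``x_y_z`` (isoform ID, start, end). Monoexonic transcripts have
no introns, so they are keyed by chromosome + strand + gene instead.

The store is a single-file SQLite database with tables::

    isoform    one row per intron chain (id, chain, annotations)
    ends       one row per (isoform, start, end) combination
    counts     reads per (variant, experiment)
    sc_counts  reads per (variant, experiment, cell_type, barcode)
    exp        experiment metadata
    sampleData sample metadata
    meta       schema version etc.
    ingest_log JSON ingest reports
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from .io_formats import GenomicTranscript

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE sampleData (
    sample_name TEXT PRIMARY KEY,
    attrs TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE exp (
    exp_name TEXT PRIMARY KEY,
    sample_name TEXT NOT NULL REFERENCES sampleData(sample_name),
    platform TEXT NOT NULL DEFAULT '',
    prep TEXT NOT NULL DEFAULT '',
    date TEXT NOT NULL DEFAULT '',
    extras TEXT NOT NULL DEFAULT '{}',
    is_single_cell INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE isoform (
    id INTEGER PRIMARY KEY,
    chain TEXT NOT NULL UNIQUE,
    chrom TEXT NOT NULL,
    strand TEXT NOT NULL,
    structural_category TEXT NOT NULL,
    associated_gene TEXT NOT NULL,
    associated_transcript TEXT,
    subcategory TEXT NOT NULL DEFAULT '',
    first_seen_exp TEXT NOT NULL
);
CREATE TABLE ends (
    variant_id TEXT PRIMARY KEY,
    isoform_id INTEGER NOT NULL REFERENCES isoform(id),
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    UNIQUE (isoform_id, start, end)
);
CREATE TABLE counts (
    variant_id TEXT NOT NULL REFERENCES ends(variant_id),
    exp_name TEXT NOT NULL REFERENCES exp(exp_name),
    reads INTEGER NOT NULL CHECK (reads >= 0),
    PRIMARY KEY (variant_id, exp_name)
);
CREATE TABLE sc_counts (
    variant_id TEXT NOT NULL REFERENCES ends(variant_id),
    exp_name TEXT NOT NULL REFERENCES exp(exp_name),
    cell_type TEXT NOT NULL,
    barcode TEXT NOT NULL,
    reads INTEGER NOT NULL CHECK (reads >= 0),
    PRIMARY KEY (variant_id, exp_name, cell_type, barcode)
);
CREATE TABLE ingest_log (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    exp_name TEXT NOT NULL,
    report TEXT NOT NULL
);
CREATE INDEX idx_ends_isoform ON ends(isoform_id);
CREATE INDEX idx_counts_exp ON counts(exp_name);
CREATE INDEX idx_sc_counts_exp ON sc_counts(exp_name);
"""


@dataclass(frozen=True)
class IntronChainKey:
    """Canonical identity of an isoform.

    ``introns`` is empty iff the transcript is monoexonic, in which case
    ``monoexonic_gene`` anchors the key to a gene.
    """

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]
    monoexonic_gene: str | None = None

    def __post_init__(self) -> None:
        if (len(self.introns) == 0) != (self.monoexonic_gene is not None):
            raise ValueError("introns empty iff monoexonic_gene is set")

    def serialize(self) -> str:
        if self.monoexonic_gene is not None:
            return f"{self.chrom}:{self.strand}:mono:{self.monoexonic_gene}"
        body = ",".join(f"{s}-{e}" for s, e in self.introns)
        return f"{self.chrom}:{self.strand}:{body}"

    @classmethod
    def deserialize(cls, text: str) -> "IntronChainKey":
        chrom, strand, body = text.split(":", 2)
        if body.startswith("mono:"):
            return cls(chrom, strand, (), body[len("mono:"):])
        introns = tuple(
            (int(s), int(e))
            for s, e in (pair.split("-") for pair in body.split(",") if pair)
        )
        return cls(chrom, strand, introns, None)


def chain_key(t: GenomicTranscript, gene_hint: str = "") -> IntronChainKey:
    """Derive the intron-chain identity of a transcript.

    Multiexonic transcripts are keyed by their introns (the gaps between
    consecutive exons); 5'/3' truncations that preserve every junction map
    to the same key. Monoexonic transcripts are keyed by
    chromosome + strand + gene (``gene_hint``, falling back to the
    transcript's own gene_id).
    """
    introns = t.introns
    if introns:
        return IntronChainKey(t.chrom, t.strand, introns, None)
    gene = gene_hint or t.gene_id or t.transcript_id
    return IntronChainKey(t.chrom, t.strand, (), gene)


def canonical_partition(
    transcripts: list[GenomicTranscript],
    gene_hints: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Group transcript IDs by chain serialization (order-independent)."""
    gene_hints = gene_hints or {}
    groups: dict[str, list[str]] = {}
    for t in transcripts:
        key = chain_key(t, gene_hints.get(t.transcript_id, "")).serialize()
        groups.setdefault(key, []).append(t.transcript_id)
    for ids in groups.values():
        ids.sort()
    return groups


def variant_id(isoform_id: int, start: int, end: int) -> str:
    """Ends-variant ID ``x_y_z``: isoform ID, start coordinate, end coordinate."""
    return f"{isoform_id}_{start}_{end}"


class StoreError(RuntimeError):
    pass


class Store:
    """Handle over the SQLite database; thin convenience layer over sqlite3."""

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- basic lookups -----------------------------------------------------

    def n_isoforms(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM isoform").fetchone()[0]

    def n_variants(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM ends").fetchone()[0]

    def experiments(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute("SELECT exp_name FROM exp ORDER BY rowid")
        ]

    def isoform_id_for_chain(self, chain: str) -> int | None:
        row = self.conn.execute(
            "SELECT id FROM isoform WHERE chain = ?", (chain,)
        ).fetchone()
        return row[0] if row else None

    def chain_for_isoform(self, isoform_id: int) -> str:
        row = self.conn.execute(
            "SELECT chain FROM isoform WHERE id = ?", (isoform_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown isoform id {isoform_id}")
        return row[0]

    def log_ingest(self, exp_name: str, report: dict) -> None:
        self.conn.execute(
            "INSERT INTO ingest_log (exp_name, report) VALUES (?, ?)",
            (exp_name, json.dumps(report)),
        )
        self.conn.commit()


def init_store(path: str | Path) -> Store:
    """Create a new store at ``path``, or open an existing compatible one.

    Opening an existing store is non-destructive; files that are not
    stores of a compatible schema version are refused.
    """
    path = Path(path)
    exists = path.exists() and path.stat().st_size > 0
    try:
        conn = sqlite3.connect(path)
        if exists:
            try:
                row = conn.execute(
                    "SELECT value FROM meta WHERE key = 'schema_version'"
                ).fetchone()
            except sqlite3.DatabaseError:
                conn.close()
                raise StoreError(f"{path} is not an isochaindb store")
            if row is None or row[0] != SCHEMA_VERSION:
                conn.close()
                raise StoreError(
                    f"{path} has schema version {row[0] if row else 'missing'!r}, "
                    f"expected {SCHEMA_VERSION!r}"
                )
        else:
            conn.executescript(_SCHEMA)
            conn.execute(
                "INSERT INTO meta (key, value) VALUES ('schema_version', ?)",
                (SCHEMA_VERSION,),
            )
            conn.commit()
    except sqlite3.DatabaseError as exc:
        raise StoreError(f"cannot open {path}: {exc}") from None
    return Store(conn, str(path))
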