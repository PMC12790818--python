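"""Add one annotated sample (bulk or single-cell) to the store.

Each input isoform's intron chain is looked up in the isoform table: if
present, only the count tables are updated under the new experiment; if
absent, a new isoform entry is created. Its (start, end) pair is
registered as an ends variant when unseen. Annotations are stored once
per chain, from the first experiment that introduced it; later
conflicting annotations are logged in the ingest report, never
overwritten. Read totals are conserved exactly: the sum stored for an
experiment equals the classification file's count-column sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import (
    CellTypeAssignment,
    ExperimentMeta,
    GenomicTranscript,
    SampleMeta,
    SqantiRecord,
)
from .isoform_model import Store, StoreError, chain_key, variant_id

import json


class IngestError(ValueError):
    pass


@dataclass
class IngestReport:
    """Accounting of one ingest: what matched, what was created, conservation."""

    exp_name: str
    n_input_isoforms: int = 0
    n_new_chains: int = 0
    n_matched_chains: int = 0
    n_new_variants: int = 0
    total_reads_in: int = 0
    total_reads_stored: int = 0
    annotation_conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_variant_warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exp_name": self.exp_name,
            "n_input_isoforms": self.n_input_isoforms,
            "n_new_chains": self.n_new_chains,
            "n_matched_chains": self.n_matched_chains,
            "n_new_variants": self.n_new_variants,
            "total_reads_in": self.total_reads_in,
            "total_reads_stored": self.total_reads_stored,
            "annotation_conflicts": [list(c) for c in self.annotation_conflicts],
            "duplicate_variant_warnings": self.duplicate_variant_warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _pair_inputs(
    classification: list[SqantiRecord], transcripts: list[GenomicTranscript]
) -> list[tuple[SqantiRecord, GenomicTranscript]]:
    by_id = {t.transcript_id: t for t in transcripts}
    class_ids = {r.isoform_id for r in classification}
    orphan_class = sorted(class_ids - set(by_id))
    orphan_tx = sorted(set(by_id) - class_ids)
    if orphan_class or orphan_tx:
        raise IngestError(
            "classification/genePred ID mismatch; "
            f"classification-only: {orphan_class[:10]}, genePred-only: {orphan_tx[:10]}"
        )
    return [(r, by_id[r.isoform_id]) for r in classification]


def _register_metadata(
    store: Store, exp: ExperimentMeta, sample: SampleMeta,
    replace: bool, single_cell: bool,
) -> None:
    cur = store.conn
    existing = cur.execute(
        "SELECT 1 FROM exp WHERE exp_name = ?", (exp.exp_name,)
    ).fetchone()
    if existing and not replace:
        raise IngestError(
            f"experiment {exp.exp_name!r} already in store (use replace to re-ingest)"
        )
    if existing and replace:
        cur.execute("DELETE FROM counts WHERE exp_name = ?", (exp.exp_name,))
        cur.execute("DELETE FROM sc_counts WHERE exp_name = ?", (exp.exp_name,))
        cur.execute("DELETE FROM exp WHERE exp_name = ?", (exp.exp_name,))
    if exp.sample_name != sample.sample_name:
        raise IngestError(
            f"experiment config names sample {exp.sample_name!r} but sample "
            f"config is for {sample.sample_name!r}"
        )
    cur.execute(
        "INSERT OR REPLACE INTO sampleData (sample_name, attrs) VALUES (?, ?)",
        (sample.sample_name, json.dumps(sample.attributes)),
    )
    cur.execute(
        "INSERT INTO exp (exp_name, sample_name, platform, prep, date, extras,"
        " is_single_cell) VALUES (?, ?, ?, ?, ?, ?, ?)",
        (exp.exp_name, exp.sample_name, exp.platform, exp.prep, exp.date,
         json.dumps(exp.extras), int(single_cell)),
    )


def add_sample(
    store: Store,
    classification: list[SqantiRecord],
    transcripts: list[GenomicTranscript],
    exp: ExperimentMeta,
    sample: SampleMeta,
    replace: bool = False,
    _single_cell: bool = False,
) -> IngestReport:
    """Ingest one bulk sample; returns the accounting report.

    Preconditions: classification rows and genePred transcripts are in
    1:1 correspondence by sample-local isoform ID, and ``exp.exp_name``
    is not already present (unless ``replace``).
    """
    pairs = _pair_inputs(classification, transcripts)
    report = IngestReport(exp_name=exp.exp_name, n_input_isoforms=len(pairs))
    _register_metadata(store, exp, sample, replace, _single_cell)

    cur = store.conn
    seen_chains: dict[str, int] = {}  # chain -> isoform_id, this ingest
    variant_reads: dict[str, int] = {}
    for rec, tx in pairs:
        report.total_reads_in += rec.fl_count
        key = chain_key(tx, gene_hint=rec.associated_gene).serialize()
        if key in seen_chains:
            iso_id = seen_chains[key]
        else:
            row = cur.execute(
                "SELECT id, structural_category, associated_gene FROM isoform"
                " WHERE chain = ?", (key,)
            ).fetchone()
            if row is not None:
                iso_id = row[0]
                report.n_matched_chains += 1
                stored = f"{row[1]}/{row[2]}"
                incoming = f"{rec.structural_category}/{rec.associated_gene}"
                if stored != incoming:
                    report.annotation_conflicts.append((key, stored, incoming))
            else:
                cur.execute(
                    "INSERT INTO isoform (chain, chrom, strand, structural_category,"
                    " associated_gene, associated_transcript, subcategory,"
                    " first_seen_exp) VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (key, tx.chrom, tx.strand, rec.structural_category,
                     rec.associated_gene, rec.associated_transcript,
                     rec.subcategory, exp.exp_name),
                )
                iso_id = cur.execute(
                    "SELECT id FROM isoform WHERE chain = ?", (key,)
                ).fetchone()[0]
                report.n_new_chains += 1
            seen_chains[key] = iso_id
        vid = variant_id(iso_id, tx.tx_start, tx.tx_end)
        exists = cur.execute(
            "SELECT 1 FROM ends WHERE variant_id = ?", (vid,)
        ).fetchone()
        if not exists:
            cur.execute(
                "INSERT INTO ends (variant_id, isoform_id, start, end)"
                " VALUES (?, ?, ?, ?)",
                (vid, iso_id, tx.tx_start, tx.tx_end),
            )
            report.n_new_variants += 1
        if vid in variant_reads:
            # uncollapsed input: same chain+ends twice within one sample
            report.duplicate_variant_warnings.append(
                f"{rec.isoform_id}: duplicate (chain, start, end) {vid}; counts summed"
            )
        variant_reads[vid] = variant_reads.get(vid, 0) + rec.fl_count

    for vid, reads in variant_reads.items():
        cur.execute(
            "INSERT INTO counts (variant_id, exp_name, reads) VALUES (?, ?, ?)",
            (vid, exp.exp_name, reads),
        )
        report.total_reads_stored += reads
    store.conn.commit()
    store.log_ingest(exp.exp_name, report.to_dict())
    assert report.total_reads_in == report.total_reads_stored
    return report


def add_single_cell_sample(
    store: Store,
    classification: list[SqantiRecord],
    transcripts: list[GenomicTranscript],
    exp: ExperimentMeta,
    sample: SampleMeta,
    assignments: list[CellTypeAssignment],
    replace: bool = False,
    strict: bool = True,
) -> IngestReport:
    """Ingest a single-cell sample: bulk-style counts plus per-cell splits.

    Every assignment must reference a classification isoform. Under
    ``strict`` (default) the per-isoform assignment sums must equal that
    isoform's FL count, so the pseudobulk view equals the bulk counts by
    construction; with ``strict=False`` a mismatch is tolerated and noted
    in the report.
    """
    class_by_id = {r.isoform_id: r for r in classification}
    unknown = sorted({a.isoform_id for a in assignments} - set(class_by_id))
    if unknown:
        raise IngestError(f"cell-type assignments reference unknown isoforms: {unknown[:10]}")
    per_iso: dict[str, int] = {}
    for a in assignments:
        per_iso[a.isoform_id] = per_iso.get(a.isoform_id, 0) + a.count
    mismatches = [
        (iid, class_by_id[iid].fl_count, total)
        for iid, total in sorted(per_iso.items())
        if total != class_by_id[iid].fl_count
    ]
    if mismatches and strict:
        raise IngestError(
            "assignment sums differ from FL counts (strict mode): "
            + ", ".join(f"{i}: FL={fl} vs assigned={tot}" for i, fl, tot in mismatches[:5])
        )

    report = add_sample(
        store, classification, transcripts, exp, sample,
        replace=replace, _single_cell=True,
    )
    if mismatches:
        report.duplicate_variant_warnings.extend(
            f"{i}: FL={fl} but cell assignments sum to {tot}" for i, fl, tot in mismatches
        )

    # map sample-local isoform IDs to variant IDs
    tx_by_id = {t.transcript_id: t for t in transcripts}
    cur = store.conn
    vid_of: dict[str, str] = {}
    for rec in classification:
        tx = tx_by_id[rec.isoform_id]
        key = chain_key(tx, gene_hint=rec.associated_gene).serialize()
        iso_id = store.isoform_id_for_chain(key)
        if iso_id is None:
            raise StoreError(f"chain vanished during ingest: {key}")
        vid_of[rec.isoform_id] = variant_id(iso_id, tx.tx_start, tx.tx_end)

    acc: dict[tuple[str, str, str], int] = {}
    for a in assignments:
        k = (vid_of[a.isoform_id], a.cell_type, a.barcode)
        acc[k] = acc.get(k, 0) + a.count
    for (vid, cell_type, barcode), reads in acc.items():
        cur.execute(
            "INSERT INTO sc_counts (variant_id, exp_name, cell_type, barcode, reads)"
            " VALUES (?, ?, ?, ?, ?)"
            " ON CONFLICT(variant_id, exp_name, cell_type, barcode)"
            " DO UPDATE SET reads = reads + excluded.reads",
            (vid, exp.exp_name, cell_type, barcode, reads),
        )
    store.conn.commit()
    return report
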