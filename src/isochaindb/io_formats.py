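"""Readers and writers for the external file formats the tool touches.

All genomic coordinates are held internally as 0-based half-open intervals
(the genePred native convention); GTF (1-based inclusive) is converted at
the boundary in both directions so a transcript round-trips exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

# SQANTI3 structural-category vocabulary. FSM/ISM carry a reference
# transcript; NIC/NNC are the "novel" categories.
STRUCTURAL_CATEGORIES = (
    "full-splice_match",
    "incomplete-splice_match",
    "novel_in_catalog",
    "novel_not_in_catalog",
    "genic",
    "antisense",
    "fusion",
    "intergenic",
    "genic_intron",
)

NOVEL_CATEGORIES = ("novel_in_catalog", "novel_not_in_catalog")


class ParseError(ValueError):
    """Malformed input file; message names the offending line or record."""


@dataclass(frozen=True)
class GenomicTranscript:
    """A transcript model: ordered exons on one strand of one chromosome.

    Exons are 0-based half-open ``(start, end)`` tuples, sorted ascending,
    non-overlapping. ``tx_start``/``tx_end`` are derived properties.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ParseError(f"transcript {self.transcript_id!r}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ParseError(
                    f"transcript {self.transcript_id!r}: exon start {s} >= end {e}"
                )
            if prev_end is not None and s < prev_end:
                raise ParseError(
                    f"transcript {self.transcript_id!r}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, ascending genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class SqantiRecord:
    """One row of a SQANTI3 classification file."""

    isoform_id: str
    chrom: str
    strand: str
    n_exons: int
    structural_category: str
    associated_gene: str
    associated_transcript: str | None
    subcategory: str
    fl_count: int
    extra_annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structural_category not in STRUCTURAL_CATEGORIES:
            raise ParseError(
                f"isoform {self.isoform_id!r}: unknown structural_category "
                f"{self.structural_category!r}"
            )
        if self.fl_count < 0:
            raise ParseError(f"isoform {self.isoform_id!r}: negative FL count")
        if self.n_exons < 1:
            raise ParseError(f"isoform {self.isoform_id!r}: exons must be >= 1")
        if (
            self.structural_category
            in ("full-splice_match", "incomplete-splice_match")
            and self.associated_transcript is None
        ):
            raise ParseError(
                f"isoform {self.isoform_id!r}: {self.structural_category} requires "
                "an associated_transcript"
            )


@dataclass
class ExperimentMeta:
    """One sequencing experiment (library/run) of one biological sample."""

    exp_name: str
    sample_name: str
    platform: str = ""
    prep: str = ""
    date: str = ""
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class SampleMeta:
    """One biological sample; free-form attributes (sex, age, tissue, ...)."""

    sample_name: str
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class CellTypeAssignment:
    """Reads of one sample-local isoform in one cell (barcode) of a cell type."""

    isoform_id: str
    barcode: str
    cell_type: str
    count: int = 1


# ---------------------------------------------------------------------------
# genePred


def _split_coord_list(text: str, line_no: int, label: str) -> list[int]:
    parts = [p for p in text.strip().split(",") if p != ""]
    try:
        return [int(p) for p in parts]
    except ValueError:
        raise ParseError(f"line {line_no}: non-integer {label} list {text!r}") from None


def read_genepred(path: str | Path) -> list[GenomicTranscript]:
    """Parse a genePred file (standard 10-column or extended).

    Extended genePred (``genePredExt``, with name2/score columns) is
    auto-detected per line by locating the strand column: standard files
    carry it in column 3 (index 2); refFlat-style files prepend a gene
    name, shifting everything right by one.
    """
    out: list[GenomicTranscript] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(
                    f"line {line_no}: expected >= 10 tab-separated fields, got {len(f)}"
                )
            if f[2] in ("+", "-"):
                gene_id = ""  # standard genePred: name chrom strand ...
            elif f[3] in ("+", "-") and len(f) >= 11:
                gene_id, f = f[0], f[1:]  # refFlat: geneName name chrom strand ...
            else:
                raise ParseError(f"line {line_no}: cannot locate strand column")
            name, chrom, strand = f[0], f[1], f[2]
            try:
                exon_count = int(f[7])
            except ValueError:
                raise ParseError(f"line {line_no}: non-integer exonCount {f[7]!r}") from None
            starts = _split_coord_list(f[8], line_no, "exonStarts")
            ends = _split_coord_list(f[9], line_no, "exonEnds")
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ParseError(
                    f"line {line_no}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            try:
                tx = GenomicTranscript(
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(zip(starts, ends)),
                    gene_id=gene_id,
                )
            except ParseError as exc:
                raise ParseError(f"line {line_no}: {exc}") from None
            out.append(tx)
    return out


def write_genepred(transcripts: Iterable[GenomicTranscript], path: str | Path) -> None:
    """Write standard 10-column genePred (CDS set to tx bounds, unused)."""
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.tx_start),
                        str(t.tx_end),
                        str(len(t.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SQANTI3 classification

_REQUIRED_CLASS_COLS = (
    "isoform",
    "chrom",
    "strand",
    "exons",
    "structural_category",
    "associated_gene",
    "associated_transcript",
    "subcategory",
)


def read_classification(
    path: str | Path, fl_column: str = "FL"
) -> list[SqantiRecord]:
    """Parse a SQANTI3 classification TSV.

    ``fl_column`` names the read-count column; SQANTI3 emits ``FL`` for a
    single sample but ``FL.<biosample>`` after demultiplexing. Unknown
    columns are preserved verbatim in ``extra_annotations``.
    """
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in (*_REQUIRED_CLASS_COLS, fl_column) if c not in header]
        if missing:
            raise ParseError(f"classification file missing columns: {', '.join(missing)}")
        known = set(_REQUIRED_CLASS_COLS) | {fl_column}
        out: list[SqantiRecord] = []
        for row_no, row in enumerate(reader, start=2):
            raw_count = row[fl_column]
            try:
                fl = int(raw_count)
            except (TypeError, ValueError):
                raise ParseError(
                    f"line {row_no}: non-integer count {raw_count!r} in column {fl_column!r}"
                ) from None
            assoc_tx = row["associated_transcript"]
            if assoc_tx in ("NA", ""):
                assoc_tx = None
            try:
                rec = SqantiRecord(
                    isoform_id=row["isoform"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    n_exons=int(row["exons"]),
                    structural_category=row["structural_category"],
                    associated_gene=row["associated_gene"],
                    associated_transcript=assoc_tx,
                    subcategory=row["subcategory"],
                    fl_count=fl,
                    extra_annotations={
                        k: v for k, v in row.items() if k not in known and k is not None
                    },
                )
            except ParseError as exc:
                raise ParseError(f"line {row_no}: {exc}") from None
            out.append(rec)
    return out


def write_classification(
    records: Iterable[SqantiRecord], path: str | Path, fl_column: str = "FL"
) -> None:
    records = list(records)
    extra_cols: list[str] = []
    for r in records:
        for k in r.extra_annotations:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = list(_REQUIRED_CLASS_COLS) + [fl_column] + extra_cols
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = {
                "isoform": r.isoform_id,
                "chrom": r.chrom,
                "strand": r.strand,
                "exons": str(r.n_exons),
                "structural_category": r.structural_category,
                "associated_gene": r.associated_gene,
                "associated_transcript": r.associated_transcript or "NA",
                "subcategory": r.subcategory,
                fl_column: str(r.fl_count),
            }
            row.update(r.extra_annotations)
            fh.write("\t".join(row.get(c, "NA") for c in cols) + "\n")


# ---------------------------------------------------------------------------
# GTF


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GenomicTranscript]:
    """Parse exon features of a GTF into transcripts.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open here (start-1, end unchanged). Non-exon features are ignored.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"line {line_no}: expected 9 GTF fields, got {len(f)}")
            if f[2] != "exon":
                continue
            attrs = _gtf_attributes(f[8])
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(f"line {line_no}: exon feature without transcript_id")
            try:
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError:
                raise ParseError(f"line {line_no}: non-integer coordinates") from None
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = (f[0], f[6], attrs.get("gene_id", ""))
            exons[tid].append((start, end))
    out: list[GenomicTranscript] = []
    for tid in order:
        chrom, strand, gene = meta[tid]
        ivs = sorted(exons[tid])
        for i in range(len(ivs) - 1):
            if ivs[i + 1][0] < ivs[i][1]:
                raise ParseError(f"transcript {tid!r}: overlapping exons")
        out.append(
            GenomicTranscript(
                transcript_id=tid, chrom=chrom, strand=strand,
                exons=tuple(ivs), gene_id=gene,
            )
        )
    return out


def write_gtf(
    transcripts: Iterable[GenomicTranscript], path: str | Path, source: str = "isochaindb"
) -> None:
    """Write transcript+exon features; converts back to 1-based inclusive."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id or t.transcript_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.tx_start + 1),
                     str(t.tx_end), ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(s + 1), str(e),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# metadata configs and cell-type file


def _read_kv(path: str | Path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if "\t" not in line:
                raise ParseError(f"line {line_no}: expected key<TAB>value")
            key, _, val = line.partition("\t")
            if key in pairs:
                raise ParseError(f"line {line_no}: duplicate key {key!r}")
            pairs[key] = val
    return pairs


def read_config(path: str | Path, kind: str) -> ExperimentMeta | SampleMeta:
    """Read a key<TAB>value metadata config of ``kind`` experiment|sample."""
    pairs = _read_kv(path)
    if kind == "experiment":
        for req in ("exp_name", "sample_name"):
            if req not in pairs:
                raise ParseError(f"experiment config missing required key {req!r}")
        known = ("exp_name", "sample_name", "platform", "prep", "date")
        return ExperimentMeta(
            exp_name=pairs["exp_name"],
            sample_name=pairs["sample_name"],
            platform=pairs.get("platform", ""),
            prep=pairs.get("prep", ""),
            date=pairs.get("date", ""),
            extras={k: v for k, v in pairs.items() if k not in known},
        )
    if kind == "sample":
        if "sample_name" not in pairs:
            raise ParseError("sample config missing required key 'sample_name'")
        return SampleMeta(
            sample_name=pairs["sample_name"],
            attributes={k: v for k, v in pairs.items() if k != "sample_name"},
        )
    raise ValueError(f"kind must be 'experiment' or 'sample', got {kind!r}")


def write_config(meta: ExperimentMeta | SampleMeta, path: str | Path) -> None:
    with open(path, "w") as fh:
        if isinstance(meta, ExperimentMeta):
            fh.write(f"exp_name\t{meta.exp_name}\n")
            fh.write(f"sample_name\t{meta.sample_name}\n")
            for k in ("platform", "prep", "date"):
                v = getattr(meta, k)
                if v:
                    fh.write(f"{k}\t{v}\n")
            for k, v in meta.extras.items():
                fh.write(f"{k}\t{v}\n")
        else:
            fh.write(f"sample_name\t{meta.sample_name}\n")
            for k, v in meta.attributes.items():
                fh.write(f"{k}\t{v}\n")


def read_celltype_file(path: str | Path) -> list[CellTypeAssignment]:
    """Read the isoform/barcode/cell-type TSV; duplicate triples are summed."""
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in ("isoform", "barcode", "cell_type") if c not in header]
        if missing:
            raise ParseError(f"cell-type file missing columns: {', '.join(missing)}")
        has_count = "count" in header
        acc: dict[tuple[str, str, str], int] = {}
        order: list[tuple[str, str, str]] = []
        for row_no, row in enumerate(reader, start=2):
            if not row["cell_type"]:
                raise ParseError(f"line {row_no}: empty cell_type")
            if has_count:
                try:
                    n = int(row["count"])
                except (TypeError, ValueError):
                    raise ParseError(f"line {row_no}: non-integer count") from None
            else:
                n = 1
            if n <= 0:
                raise ParseError(f"line {row_no}: count must be positive, got {n}")
            key = (row["isoform"], row["barcode"], row["cell_type"])
            if key not in acc:
                acc[key] = 0
                order.append(key)
            acc[key] += n
    return [
        CellTypeAssignment(isoform_id=i, barcode=b, cell_type=c, count=acc[(i, b, c)])
        for i, b, c in order
    ]


def write_celltype_file(
    assignments: Iterable[CellTypeAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("isoform\tbarcode\tcell_type\tcount\n")
        for a in assignments:
            fh.write(f"{a.isoform_id}\t{a.barcode}\t{a.cell_type}\t{a.count}\n")
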