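"""Shared fixtures: tiny hand-built samples, random transcript pools, and
brute-force oracles kept deliberately independent of the implementation."""

from __future__ import annotations

import random

import pytest

from isochaindb import (
    ExperimentMeta,
    GenomicTranscript,
    SampleMeta,
    SqantiRecord,
    add_sample,
    init_store,
)


def make_tx(tid, exons, chrom="chr1", strand="+", gene=""):
    return GenomicTranscript(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=tuple(tuple(e) for e in exons), gene_id=gene,
    )


def make_rec(iid, tx, category="full-splice_match", gene="GENEX",
             transcript="GENEX.T1", fl=10, subcategory="sim"):
    return SqantiRecord(
        isoform_id=iid, chrom=tx.chrom, strand=tx.strand, n_exons=len(tx.exons),
        structural_category=category, associated_gene=gene,
        associated_transcript=(
            transcript if category in ("full-splice_match", "incomplete-splice_match")
            else None
        ),
        subcategory=subcategory, fl_count=fl,
    )


def random_transcripts(rng: random.Random, n: int, n_chain_templates: int = 12):
    """Random transcripts drawn from a small pool of intron-chain templates
    with jittered ends, so chain sharing occurs by construction."""
    templates = []
    for t in range(n_chain_templates):
        chrom = f"chr{rng.randint(1, 3)}"
        strand = rng.choice("+-")
        n_ex = rng.randint(1, 4)
        pos = rng.randint(500, 2000)
        exons = []
        for _ in range(n_ex):
            length = rng.randint(200, 500)
            exons.append((pos, pos + length))
            pos += length + rng.randint(300, 800)
        templates.append((chrom, strand, tuple(exons), f"G{t}"))
    out = []
    for i in range(n):
        chrom, strand, exons, gene = templates[rng.randrange(len(templates))]
        exons = [list(e) for e in exons]
        exons[0][0] += rng.randint(0, min(150, exons[0][1] - exons[0][0] - 1))
        exons[-1][1] -= rng.randint(0, min(150, exons[-1][1] - exons[-1][0] - 1))
        out.append(make_tx(f"T{i}", exons, chrom=chrom, strand=strand, gene=gene))
    return out


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_partition(transcripts):
    """O(n^2) pairwise grouping by direct structural comparison."""

    def same_chain(a, b):
        if (a.chrom, a.strand) != (b.chrom, b.strand):
            return False
        a_introns = [(a.exons[i][1], a.exons[i + 1][0]) for i in range(len(a.exons) - 1)]
        b_introns = [(b.exons[i][1], b.exons[i + 1][0]) for i in range(len(b.exons) - 1)]
        if not a_introns and not b_introns:
            return (a.gene_id or a.transcript_id) == (b.gene_id or b.transcript_id)
        return a_introns == b_introns

    groups: list[list[GenomicTranscript]] = []
    for t in transcripts:
        for g in groups:
            if same_chain(t, g[0]):
                g.append(t)
                break
        else:
            groups.append([t])
    return sorted(sorted(t.transcript_id for t in g) for g in groups)


def brute_force_exclusive_intersections(membership: dict):
    """Tally chains by their exact experiment set; membership maps any
    chain identifier to the set of experiments detecting it."""
    tally: dict[frozenset, int] = {}
    for members in membership.values():
        key = frozenset(members)
        if key:
            tally[key] = tally.get(key, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# tiny canonical store: 2 experiments, 3 chains, one with 2 ends variants


@pytest.fixture()
def toy_store(tmp_path):
    """expA: chains c1 (two ends variants, FL 5+7), c2 (FSM, FL 90).
    expB: chains c2 (FL 10), c3 (NIC, FL 10)."""
    store = init_store(tmp_path / "toy.db")
    c1a = make_tx("PB.1.1", [(100, 200), (500, 900)])
    c1b = make_tx("PB.1.2", [(150, 200), (500, 800)])
    c2 = make_tx("PB.2.1", [(1000, 1200), (1500, 1900)])
    add_sample(
        store,
        [
            make_rec("PB.1.1", c1a, gene="GA", transcript="GA.T1", fl=5),
            make_rec("PB.1.2", c1b, gene="GA", transcript="GA.T1", fl=7),
            make_rec("PB.2.1", c2, gene="GB", transcript="GB.T1", fl=90),
        ],
        [c1a, c1b, c2],
        ExperimentMeta(exp_name="expA", sample_name="sA"),
        SampleMeta(sample_name="sA"),
    )
    c2b = make_tx("PB.1.1", [(1000, 1200), (1500, 1900)])
    c3 = make_tx("PB.2.1", [(3000, 3200), (3500, 3900)])
    add_sample(
        store,
        [
            make_rec("PB.1.1", c2b, gene="GB", transcript="GB.T1", fl=10),
            make_rec("PB.2.1", c3, category="novel_in_catalog", gene="GB", fl=10),
        ],
        [c2b, c3],
        ExperimentMeta(exp_name="expB", sample_name="sB"),
        SampleMeta(sample_name="sB"),
    )
    yield store
    store.close()
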