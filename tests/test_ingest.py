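"""Ingest semantics: chain matching, ends variants, conservation, replace."""

import pytest

from isochaindb import (
    CellTypeAssignment,
    CohortSpec,
    ExperimentMeta,
    SampleMeta,
    add_sample,
    add_single_cell_sample,
    ingest_bundle,
    init_store,
    make_cohort,
)
from isochaindb.ingest import IngestError

from conftest import make_rec, make_tx


def _three_chain_sample(exp="expA", sample="sA", fls=(5, 7, 9)):
    txs = [
        make_tx("PB.1.1", [(100, 200), (500, 900)]),
        make_tx("PB.2.1", [(1000, 1200), (1500, 1900)]),
        make_tx("PB.3.1", [(2000, 2200), (2500, 2900)]),
    ]
    recs = [
        make_rec(t.transcript_id, t, gene=f"G{i}", transcript=f"G{i}.T1", fl=fl)
        for i, (t, fl) in enumerate(zip(txs, fls))
    ]
    return recs, txs, ExperimentMeta(exp_name=exp, sample_name=sample), SampleMeta(sample)


class TestAddSample:
    def test_three_new_chains(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        report = add_sample(store, *_three_chain_sample())
        assert (report.n_new_chains, report.n_matched_chains) == (3, 0)
        assert report.total_reads_stored == 21

    def test_reingest_matches_existing_ids(self, tmp_path):
        """A second experiment with the same files updates only counts."""
        store = init_store(tmp_path / "s.db")
        add_sample(store, *_three_chain_sample())
        ids_before = {
            r[0]: r[1] for r in store.conn.execute("SELECT chain, id FROM isoform")
        }
        report = add_sample(store, *_three_chain_sample(exp="expB", sample="sB"))
        assert (report.n_new_chains, report.n_matched_chains) == (0, 3)
        assert store.experiments() == ["expA", "expB"]
        ids_after = {
            r[0]: r[1] for r in store.conn.execute("SELECT chain, id FROM isoform")
        }
        assert ids_after == ids_before

    def test_shared_chain_two_ends_counts_summed(self, tmp_path):
        """Chain-level reads are the sum over all its ends variants."""
        store = init_store(tmp_path / "s.db")
        t1 = make_tx("PB.1.1", [(100, 200), (500, 900)])
        t2 = make_tx("PB.1.2", [(150, 200), (500, 800)])
        recs = [make_rec("PB.1.1", t1, fl=5), make_rec("PB.1.2", t2, fl=7)]
        report = add_sample(
            store, recs, [t1, t2],
            ExperimentMeta("e1", "s1"), SampleMeta("s1"),
        )
        assert report.n_new_chains == 1
        assert store.n_variants() == 2
        total = store.conn.execute("SELECT SUM(reads) FROM counts").fetchone()[0]
        assert total == 12

    def test_duplicate_exp_name_refused_unless_replace(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        add_sample(store, *_three_chain_sample())
        with pytest.raises(IngestError, match="already in store"):
            add_sample(store, *_three_chain_sample())
        report = add_sample(store, *_three_chain_sample(fls=(1, 1, 1)), replace=True)
        assert report.total_reads_stored == 3
        total = store.conn.execute("SELECT SUM(reads) FROM counts").fetchone()[0]
        assert total == 3  # old counts gone, chains retained
        assert store.n_isoforms() == 3

    def test_id_mismatch_lists_orphans(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        recs, txs, exp, sample = _three_chain_sample()
        with pytest.raises(IngestError, match="PB.3.1"):
            add_sample(store, recs, txs[:2], exp, sample)

    def test_within_sample_duplicate_variant_summed_with_warning(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        t1 = make_tx("PB.1.1", [(100, 200), (500, 900)])
        t2 = make_tx("PB.1.2", [(100, 200), (500, 900)])
        recs = [make_rec("PB.1.1", t1, fl=4), make_rec("PB.1.2", t2, fl=6)]
        report = add_sample(
            store, recs, [t1, t2], ExperimentMeta("e1", "s1"), SampleMeta("s1")
        )
        assert store.n_variants() == 1
        assert report.total_reads_stored == 10
        assert report.duplicate_variant_warnings

    def test_annotation_conflict_first_seen_wins(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        t = make_tx("PB.1.1", [(100, 200), (500, 900)])
        add_sample(
            store, [make_rec("PB.1.1", t, category="novel_in_catalog", gene="GA")],
            [t], ExperimentMeta("e1", "s1"), SampleMeta("s1"),
        )
        report = add_sample(
            store, [make_rec("PB.1.1", t, category="full-splice_match", gene="GA")],
            [t], ExperimentMeta("e2", "s2"), SampleMeta("s2"),
        )
        assert len(report.annotation_conflicts) == 1
        cat = store.conn.execute(
            "SELECT structural_category FROM isoform"
        ).fetchone()[0]
        assert cat == "novel_in_catalog"


class TestSingleCell:
    def _inputs(self):
        t = make_tx("PB.1.1", [(100, 200), (500, 900)])
        rec = make_rec("PB.1.1", t, fl=10)
        return [rec], [t], ExperimentMeta("sc1", "s1"), SampleMeta("s1")

    def test_cell_type_split_and_pseudobulk(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        assignments = [
            CellTypeAssignment("PB.1.1", "AAAC", "B cells", 6),
            CellTypeAssignment("PB.1.1", "AAAG", "NK", 4),
        ]
        add_single_cell_sample(store, *self._inputs(), assignments)
        by_ct = dict(
            store.conn.execute(
                "SELECT cell_type, SUM(reads) FROM sc_counts GROUP BY cell_type"
            )
        )
        assert by_ct == {"B cells": 6, "NK": 4}
        pseudobulk = store.conn.execute("SELECT SUM(reads) FROM counts").fetchone()[0]
        assert pseudobulk == 10

    def test_strict_sum_mismatch_rejected(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        assignments = [CellTypeAssignment("PB.1.1", "AAAC", "B cells", 9)]
        with pytest.raises(IngestError, match="FL=10"):
            add_single_cell_sample(store, *self._inputs(), assignments)
        # lenient mode tolerates and notes the mismatch
        store2 = init_store(tmp_path / "s2.db")
        report = add_single_cell_sample(
            store2, *self._inputs(), assignments, strict=False
        )
        assert any("sum to 9" in w for w in report.duplicate_variant_warnings)

    def test_unknown_isoform_rejected(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        assignments = [CellTypeAssignment("PB.9.9", "AAAC", "B cells", 10)]
        with pytest.raises(IngestError, match="PB.9.9"):
            add_single_cell_sample(store, *self._inputs(), assignments)


class TestCohortIngestInvariants:
    def test_conservation_and_order_invariance(self, tmp_path):
        """Totals are conserved and identity content is ingestion-order-free."""
        bundle = make_cohort(CohortSpec(seed=42, n_genes=12), tmp_path / "coh")

        def content(order):
            store = init_store(tmp_path / f"{'_'.join(order)}.db")
            reports = ingest_bundle(store, bundle, order=order)
            for r in reports:
                assert r.total_reads_in == r.total_reads_stored
            rows = store.conn.execute(
                """SELECT i.chain, e.start, e.end, c.exp_name, c.reads
                   FROM counts c JOIN ends e ON c.variant_id = e.variant_id
                   JOIN isoform i ON e.isoform_id = i.id"""
            ).fetchall()
            store.close()
            return sorted(rows)

        forward = content(bundle.experiments)
        backward = content(list(reversed(bundle.experiments)))
        assert forward == backward

    def test_stored_totals_match_truth(self, tmp_path):
        bundle = make_cohort(CohortSpec(seed=8, n_genes=10), tmp_path / "coh")
        store = init_store(tmp_path / "c.db")
        ingest_bundle(store, bundle)
        for exp in bundle.experiments:
            stored = store.conn.execute(
                "SELECT COALESCE(SUM(reads), 0) FROM counts WHERE exp_name = ?",
                (exp,),
            ).fetchone()[0]
            expected = sum(
                info["counts"].get(exp, 0) for info in bundle.truth["chains"].values()
            )
            assert stored == expected
        store.close()
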