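"""Comparative queries: matrices, summaries, intersections, ends, switches."""

import random

import pandas as pd
import pytest

from isochaindb import (
    CohortSpec,
    ExperimentMeta,
    SampleMeta,
    add_sample,
    category_summary,
    chain_key,
    count_matrix,
    ends_variability,
    export_gtf,
    gene_isoform_proportions,
    ingest_bundle,
    init_store,
    major_isoform_switches,
    make_cohort,
    read_gtf,
    sample_sharing,
    upset_intersections,
)
from isochaindb.queries import QueryError

from conftest import brute_force_exclusive_intersections, make_rec, make_tx


class TestCountMatrix:
    def test_chain_level_sums_variants(self, toy_store):
        cm = count_matrix(toy_store)
        # chain c1 has two variants with FL 5 and 7 in expA
        row = cm.df.loc[1]
        assert row["expA"] == 12
        assert row["expB"] == 0

    def test_cpm_columns_sum_to_million(self, toy_store):
        cm = count_matrix(toy_store, normalization="cpm")
        assert cm.df.sum(axis=0).round(6).eq(1e6).all()

    def test_threshold_semantics(self, tmp_path):
        """A chain with counts (2, 5, 0) fails min_reads=3 in min_experiments=2."""
        store = init_store(tmp_path / "s.db")
        t = make_tx("PB.1.1", [(100, 200), (500, 900)])
        for exp, fl in (("e1", 2), ("e2", 5), ("e3", 0)):
            add_sample(
                store, [make_rec("PB.1.1", t, fl=fl)], [t],
                ExperimentMeta(exp, exp), SampleMeta(exp),
            )
        cm = count_matrix(store, min_reads=3, min_experiments=2)
        assert cm.df.empty
        cm2 = count_matrix(store, min_reads=2, min_experiments=2)
        assert len(cm2.df) == 1
        store.close()

    def test_unknown_experiment_rejected(self, toy_store):
        with pytest.raises(QueryError, match="nope"):
            count_matrix(toy_store, experiments=["expA", "nope"])

    def test_variant_level_rows_are_variant_ids(self, toy_store):
        cm = count_matrix(toy_store, level="variant")
        assert len(cm.df) == toy_store.n_variants()
        assert all("_" in str(i) for i in cm.df.index)


class TestCategorySummary:
    def test_isoform_weighted(self, toy_store):
        tab = category_summary(toy_store, weight="isoforms")
        # expB detects 1 FSM chain + 1 NIC chain
        assert tab.loc["expB", "full-splice_match"] == pytest.approx(0.5)
        assert tab.loc["expB", "novel_in_catalog"] == pytest.approx(0.5)

    def test_read_weighted(self, toy_store):
        tab = category_summary(toy_store, weight="reads")
        # expA reads: 12 on c1 + 90 on c2, all FSM
        assert tab.loc["expA", "full-splice_match"] == pytest.approx(1.0)
        assert tab.loc["expB", "novel_in_catalog"] == pytest.approx(0.5)

    def test_dense_output_with_zero_categories(self, toy_store):
        tab = category_summary(toy_store)
        assert "genic_intron" in tab.columns
        assert (tab["genic_intron"] == 0).all()
        assert tab.sum(axis=1).round(9).eq(1.0).all()


class TestUpset:
    def test_toy_example(self, toy_store):
        """expA detects {c1, c2}, expB detects {c2, c3}."""
        inter = upset_intersections(toy_store)
        sizes = {tuple(sorted(s.member_set)): s.size for s in inter}
        assert sizes == {("expA",): 1, ("expB",): 1, ("expA", "expB"): 1}

    def test_matches_brute_force_on_cohorts(self, tmp_path):
        for seed in (1, 2):
            bundle = make_cohort(
                CohortSpec(seed=seed, n_genes=15, n_experiments=6), tmp_path / f"c{seed}"
            )
            store = init_store(tmp_path / f"c{seed}.db")
            ingest_bundle(store, bundle)
            truth_membership = {
                chain: {e for e, n in info["counts"].items() if n > 0}
                for chain, info in bundle.truth["chains"].items()
            }
            expected = brute_force_exclusive_intersections(truth_membership)
            got = {
                s.member_set: s.size
                for s in upset_intersections(store, top_n=10**6)
            }
            assert got == expected
            store.close()

    def test_partition_property_and_top_n(self, toy_store):
        inter = upset_intersections(toy_store, top_n=10**6)
        assert sum(s.size for s in inter) == 3  # every detected chain once
        for s in inter:
            assert sum(s.category_breakdown.values()) == s.size
        top1 = upset_intersections(toy_store, top_n=1)
        assert len(top1) == 1
        assert top1[0].size == max(s.size for s in inter)


class TestEndsVariability:
    def test_marginal_proportions(self, toy_store):
        """Variants (100,900):5 and (150,800):7 of chain 1 in expA."""
        starts, ends = ends_variability(toy_store, 1)
        assert starts.loc["expA", 100] == pytest.approx(5 / 12)
        assert starts.loc["expA", 150] == pytest.approx(7 / 12)
        assert ends.loc["expA", 900] == pytest.approx(5 / 12)
        assert starts.sum(axis=1).round(9).eq(1.0).all()
        assert ends.sum(axis=1).round(9).eq(1.0).all()

    def test_absent_experiment_omitted(self, toy_store):
        starts, _ = ends_variability(toy_store, 1)
        assert "expB" not in starts.index

    def test_single_variant_is_certain(self, toy_store):
        starts, ends = ends_variability(toy_store, 3)  # c3: only in expB
        assert starts.loc["expB"].max() == pytest.approx(1.0)
        assert ends.loc["expB"].max() == pytest.approx(1.0)

    def test_unknown_isoform_rejected(self, toy_store):
        with pytest.raises(Exception, match="unknown isoform"):
            ends_variability(toy_store, 999)


class TestSampleSharing:
    def test_novel_preset(self, toy_store):
        hist, frac = sample_sharing(toy_store)
        assert hist == {1: 1}  # single NIC chain, detected only in expB
        assert frac == 1.0

    def test_category_subset(self, toy_store):
        hist, frac = sample_sharing(toy_store, categories=["full-splice_match"])
        assert hist == {1: 1, 2: 1}
        assert frac == pytest.approx(0.5)

    def test_histogram_total_counts_qualifying_chains(self, tmp_path):
        bundle = make_cohort(CohortSpec(seed=5, n_genes=20), tmp_path / "c")
        store = init_store(tmp_path / "c.db")
        ingest_bundle(store, bundle)
        hist, _ = sample_sharing(store)
        assert sum(hist.values()) == bundle.truth["n_novel"]
        store.close()


class TestGeneProportions:
    def test_read_proportions_and_totals(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        t1 = make_tx("PB.1.1", [(100, 200), (500, 900)])
        t2 = make_tx("PB.2.1", [(100, 200), (600, 900)])
        recs = [
            make_rec("PB.1.1", t1, gene="G", transcript="G.T1", fl=80),
            make_rec("PB.2.1", t2, gene="G", transcript="G.T2", fl=20),
        ]
        add_sample(store, recs, [t1, t2], ExperimentMeta("e1", "s1"), SampleMeta("s1"))
        props, totals = gene_isoform_proportions(store, "G")
        assert props.loc["e1", "G.T1"] == pytest.approx(0.8)
        assert props.loc["e1", "G.T2"] == pytest.approx(0.2)
        assert totals.loc["e1"] == 100
        store.close()

    def test_known_only_excludes_novel(self, tmp_path):
        store = init_store(tmp_path / "s.db")
        t1 = make_tx("PB.1.1", [(100, 200), (500, 900)])
        t2 = make_tx("PB.2.1", [(100, 200), (600, 900)])
        recs = [
            make_rec("PB.1.1", t1, gene="G", transcript="G.T1", fl=60),
            make_rec("PB.2.1", t2, gene="G", category="novel_in_catalog", fl=40),
        ]
        add_sample(store, recs, [t1, t2], ExperimentMeta("e1", "s1"), SampleMeta("s1"))
        props, totals = gene_isoform_proportions(store, "G", known_only=True)
        assert list(props.columns) == ["G.T1"]
        assert props.loc["e1", "G.T1"] == pytest.approx(1.0)
        assert totals.loc["e1"] == 60
        store.close()

    def test_unknown_gene_rejected(self, toy_store):
        with pytest.raises(QueryError, match="NOGENE"):
            gene_isoform_proportions(toy_store, "NOGENE")

    def test_cell_type_grouping_requires_sc_data(self, toy_store):
        with pytest.raises(QueryError, match="single-cell"):
            gene_isoform_proportions(toy_store, "GA", group_by="cell_type")


class TestSwitches:
    def _two_group_store(self, tmp_path, g1, g2, min_store=True):
        store = init_store(tmp_path / "sw.db")
        t1 = make_tx("PB.1.1", [(100, 200), (500, 900)])
        t2 = make_tx("PB.2.1", [(100, 200), (600, 900)])
        for exp, (x, y) in (("grp1", g1), ("grp2", g2)):
            recs = [
                make_rec("PB.1.1", t1, gene="G", transcript="G.X", fl=x),
                make_rec("PB.2.1", t2, gene="G", transcript="G.Y", fl=y),
            ]
            add_sample(store, recs, [t1, t2], ExperimentMeta(exp, exp), SampleMeta(exp))
        return store

    def test_switch_detected(self, tmp_path):
        store = self._two_group_store(tmp_path, (10, 2), (1, 8))
        (res,) = major_isoform_switches(store, group_by="experiment", min_reads=5)
        assert res.majors == {"grp1": "G.X", "grp2": "G.Y"}
        store.close()

    def test_same_major_not_reported(self, tmp_path):
        store = self._two_group_store(tmp_path, (10, 2), (8, 1))
        assert major_isoform_switches(store, group_by="experiment", min_reads=5) == []
        store.close()

    def test_low_depth_group_excluded(self, tmp_path):
        store = self._two_group_store(tmp_path, (10, 2), (1, 3))  # grp2 total 4
        assert major_isoform_switches(store, group_by="experiment", min_reads=5) == []
        store.close()

    def test_tie_flagged_and_broken_lexicographically(self, tmp_path):
        """grp2 ties X/Y; the tie resolves to the smaller label (X), which
        differs from grp1's major (Y), so the gene is reported with a flag."""
        store = self._two_group_store(tmp_path, (2, 10), (6, 6))
        (res,) = major_isoform_switches(store, group_by="experiment", min_reads=5)
        assert res.majors == {"grp1": "G.Y", "grp2": "G.X"}
        assert res.ties == ["grp2"]
        store.close()


class TestExportGtf:
    def test_all_variants_matches_ends_table(self, toy_store, tmp_path):
        out = tmp_path / "all.gtf"
        n = export_gtf(toy_store, out, mode="all_variants")
        assert n == toy_store.n_variants()

    def test_round_trip_recovers_chains(self, toy_store, tmp_path):
        out = tmp_path / "all.gtf"
        export_gtf(toy_store, out, mode="all_variants")
        chains_back = {
            chain_key(t, t.gene_id).serialize() for t in read_gtf(out)
        }
        chains_stored = {
            r[0] for r in toy_store.conn.execute("SELECT chain FROM isoform")
        }
        assert chains_back == chains_stored

    def test_longest_spans_variant_extremes(self, toy_store, tmp_path):
        out = tmp_path / "long.gtf"
        export_gtf(toy_store, out, mode="longest")
        txs = {t.transcript_id: t for t in read_gtf(out)}
        # chain 1: variants (100,900) and (150,800) -> longest spans 100..900
        assert txs["isoform_1"].tx_start == 100
        assert txs["isoform_1"].tx_end == 900

    def test_empty_store_rejected(self, tmp_path):
        store = init_store(tmp_path / "e.db")
        with pytest.raises(QueryError, match="empty"):
            export_gtf(store, tmp_path / "x.gtf")
        store.close()
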