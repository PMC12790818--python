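"""Comparative analytics over the store.

All chain-level quantities sum read counts across a chain's ends
variants: the reads of an isoform are the reads of every transcript
sharing its intron chain, regardless of start/end. "Detected in an
experiment" means chain-level reads >= detect_threshold (default 1)
in that experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    NOVEL_CATEGORIES,
    STRUCTURAL_CATEGORIES,
    GenomicTranscript,
    write_gtf,
)
from .isoform_model import IntronChainKey, Store, StoreError


class QueryError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Rows = isoform (chain) or variant IDs, columns = experiments."""

    df: pd.DataFrame
    level: str
    normalization: str


@dataclass
class IntersectionSummary:
    """One exclusive intersection: the exact set of experiments detecting
    each member chain, its size, and a structural-category breakdown."""

    member_set: frozenset[str]
    size: int
    category_breakdown: dict[str, int]


def _check_experiments(store: Store, experiments: list[str] | None) -> list[str]:
    known = store.experiments()
    if experiments is None:
        return known
    unknown = [e for e in experiments if e not in known]
    if unknown:
        raise QueryError(f"unknown experiment(s): {unknown}")
    return list(experiments)


def _chain_counts(store: Store, experiments: list[str]) -> pd.DataFrame:
    """Long-format chain-level counts: isoform_id x exp_name -> reads."""
    ph = ",".join("?" * len(experiments))
    df = pd.read_sql_query(
        f"""SELECT e.isoform_id, c.exp_name, SUM(c.reads) AS reads
            FROM counts c JOIN ends e ON c.variant_id = e.variant_id
            WHERE c.exp_name IN ({ph})
            GROUP BY e.isoform_id, c.exp_name""",
        store.conn,
        params=experiments,
    )
    return df


def _variant_counts(store: Store, experiments: list[str]) -> pd.DataFrame:
    ph = ",".join("?" * len(experiments))
    return pd.read_sql_query(
        f"""SELECT c.variant_id, c.exp_name, c.reads
            FROM counts c WHERE c.exp_name IN ({ph})""",
        store.conn,
        params=experiments,
    )


def count_matrix(
    store: Store,
    experiments: list[str] | None = None,
    level: str = "chain",
    normalization: str = "raw",
    min_reads: int = 0,
    min_experiments: int = 0,
) -> CountMatrix:
    """Build an isoform x experiment count matrix.

    Rows are kept when at least ``min_experiments`` of the selected
    experiments show >= ``min_reads`` reads. CPM normalization divides by
    the *pre-filter* per-experiment totals (so filtering never changes
    the depth scale) and multiplies by 1e6.
    """
    experiments = _check_experiments(store, experiments)
    if level == "chain":
        long = _chain_counts(store, experiments)
        index_col = "isoform_id"
    elif level == "variant":
        long = _variant_counts(store, experiments)
        index_col = "variant_id"
    else:
        raise QueryError(f"level must be 'chain' or 'variant', got {level!r}")
    if long.empty:
        mat = pd.DataFrame(0, index=pd.Index([], name=index_col), columns=experiments)
    else:
        mat = (
            long.pivot_table(
                index=index_col, columns="exp_name", values="reads",
                aggfunc="sum", fill_value=0,
            )
            .reindex(columns=experiments, fill_value=0)
            .astype(int)
        )
        mat.columns.name = None
    col_totals = mat.sum(axis=0)
    if min_experiments > 0 or min_reads > 0:
        keep = (mat >= max(min_reads, 1)).sum(axis=1) >= min_experiments
        mat = mat.loc[keep]
    if normalization == "cpm":
        denom = col_totals.astype(float).replace(0, float("nan"))
        mat = (mat / denom * 1e6).astype(float).fillna(0.0)
    elif normalization != "raw":
        raise QueryError(f"normalization must be 'raw' or 'cpm', got {normalization!r}")
    return CountMatrix(df=mat, level=level, normalization=normalization)


def _detected_chains(
    store: Store, experiments: list[str], detect_threshold: int = 1
) -> dict[int, set[str]]:
    """isoform_id -> set of experiments detecting it."""
    long = _chain_counts(store, experiments)
    det: dict[int, set[str]] = {}
    for row in long.itertuples(index=False):
        if row.reads >= detect_threshold:
            det.setdefault(int(row.isoform_id), set()).add(row.exp_name)
    return {k: v for k, v in det.items() if v}


def _isoform_annotations(store: Store) -> pd.DataFrame:
    return pd.read_sql_query(
        "SELECT id, chain, chrom, strand, structural_category, associated_gene,"
        " associated_transcript FROM isoform",
        store.conn,
        index_col="id",
    )


def category_summary(
    store: Store,
    experiments: list[str] | None = None,
    weight: str = "isoforms",
) -> pd.DataFrame:
    """Per-experiment structural-category proportions.

    ``weight='isoforms'`` counts each detected chain once;
    ``weight='reads'`` weights categories by read support. The output is
    dense (every category column present, zeros included) and each row
    sums to 1. Experiments with zero reads are omitted with a warning.
    """
    if weight not in ("isoforms", "reads"):
        raise QueryError(f"weight must be 'isoforms' or 'reads', got {weight!r}")
    experiments = _check_experiments(store, experiments)
    long = _chain_counts(store, experiments)
    anns = _isoform_annotations(store)
    rows = {}
    for exp in experiments:
        sub = long[(long.exp_name == exp) & (long.reads > 0)]
        if sub.empty:
            warnings.warn(f"experiment {exp!r} has zero reads; omitted from summary")
            continue
        cats = anns.loc[sub.isoform_id, "structural_category"].to_numpy()
        w = (sub.reads.to_numpy() if weight == "reads" else None)
        s = pd.Series(w if w is not None else 1, index=cats).groupby(level=0).sum()
        rows[exp] = s / s.sum()
    out = pd.DataFrame(rows).T.reindex(columns=list(STRUCTURAL_CATEGORIES), fill_value=0.0)
    out = out.fillna(0.0)
    out.index.name = "exp_name"
    return out


def upset_intersections(
    store: Store,
    experiments: list[str] | None = None,
    top_n: int = 10,
    detect_threshold: int = 1,
) -> list[IntersectionSummary]:
    """Exclusive intersections of detected chains across experiments.

    Each chain is counted once, under the exact set of experiments that
    detect it. Sorted by size descending (ties: higher degree first, then
    lexicographic member set) and truncated to ``top_n``.
    """
    experiments = _check_experiments(store, experiments)
    if len(experiments) < 2:
        raise QueryError("upset_intersections needs >= 2 experiments")
    det = _detected_chains(store, experiments, detect_threshold)
    anns = _isoform_annotations(store)
    groups: dict[frozenset[str], list[int]] = {}
    for iso_id, members in det.items():
        groups.setdefault(frozenset(members), []).append(iso_id)
    summaries = []
    for members, iso_ids in groups.items():
        breakdown: dict[str, int] = {}
        for iso in iso_ids:
            cat = anns.at[iso, "structural_category"]
            breakdown[cat] = breakdown.get(cat, 0) + 1
        summaries.append(
            IntersectionSummary(member_set=members, size=len(iso_ids),
                                category_breakdown=breakdown)
        )
    summaries.sort(
        key=lambda s: (-s.size, -len(s.member_set), tuple(sorted(s.member_set)))
    )
    return summaries[:top_n]


def ends_variability(
    store: Store, isoform_id: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Start- and end-coordinate read-support proportions per experiment.

    Returns ``(starts, ends)`` tables: rows are experiments with >= 1
    read for this isoform, columns are distinct coordinates, values are
    the proportion of that experiment's reads for the isoform supporting
    each coordinate (marginalizing over the other end). Each row sums
    to 1.
    """
    store.chain_for_isoform(isoform_id)  # raises on unknown isoform
    df = pd.read_sql_query(
        """SELECT e.start, e.end, c.exp_name, c.reads
           FROM ends e JOIN counts c ON c.variant_id = e.variant_id
           WHERE e.isoform_id = ? AND c.reads > 0""",
        store.conn,
        params=(isoform_id,),
    )
    if df.empty:
        empty = pd.DataFrame()
        return empty, empty
    totals = df.groupby("exp_name").reads.sum()
    starts = df.pivot_table(index="exp_name", columns="start", values="reads",
                            aggfunc="sum", fill_value=0)
    ends = df.pivot_table(index="exp_name", columns="end", values="reads",
                          aggfunc="sum", fill_value=0)
    return starts.div(totals, axis=0), ends.div(totals, axis=0)


def sample_sharing(
    store: Store,
    categories: list[str] | str = "novel",
    experiments: list[str] | None = None,
    detect_threshold: int = 1,
) -> tuple[dict[int, int], float]:
    """Histogram of chains by the number of experiments detecting them.

    ``categories`` is a list of structural categories or the preset
    ``"novel"`` = {novel_in_catalog, novel_not_in_catalog}. Returns
    ``(histogram, single_fraction)`` where ``single_fraction`` is the
    fraction of qualifying chains detected in exactly one experiment.
    """
    if categories == "novel":
        cats = set(NOVEL_CATEGORIES)
    else:
        cats = set(categories)
        bad = cats - set(STRUCTURAL_CATEGORIES)
        if bad:
            raise QueryError(f"unknown categories: {sorted(bad)}")
    experiments = _check_experiments(store, experiments)
    det = _detected_chains(store, experiments, detect_threshold)
    anns = _isoform_annotations(store)
    hist: dict[int, int] = {}
    for iso_id, members in det.items():
        if anns.at[iso_id, "structural_category"] in cats:
            n = len(members)
            hist[n] = hist.get(n, 0) + 1
    total = sum(hist.values())
    frac_single = hist.get(1, 0) / total if total else 0.0
    return hist, frac_single


def _gene_group_counts(
    store: Store, gene: str, group_by: str, experiments: list[str] | None
) -> pd.DataFrame:
    """Long table: isoform_id, group, reads for one gene."""
    experiments = _check_experiments(store, experiments)
    ph = ",".join("?" * len(experiments))
    if group_by == "experiment":
        return pd.read_sql_query(
            f"""SELECT e.isoform_id, c.exp_name AS grp, SUM(c.reads) AS reads
                FROM counts c
                JOIN ends e ON c.variant_id = e.variant_id
                JOIN isoform i ON e.isoform_id = i.id
                WHERE i.associated_gene = ? AND c.exp_name IN ({ph})
                GROUP BY e.isoform_id, c.exp_name""",
            store.conn,
            params=(gene, *experiments),
        )
    if group_by == "cell_type":
        n_sc = store.conn.execute("SELECT COUNT(*) FROM sc_counts").fetchone()[0]
        if n_sc == 0:
            raise QueryError("store has no single-cell data; cannot group by cell_type")
        return pd.read_sql_query(
            f"""SELECT e.isoform_id, s.cell_type AS grp, SUM(s.reads) AS reads
                FROM sc_counts s
                JOIN ends e ON s.variant_id = e.variant_id
                JOIN isoform i ON e.isoform_id = i.id
                WHERE i.associated_gene = ? AND s.exp_name IN ({ph})
                GROUP BY e.isoform_id, s.cell_type""",
            store.conn,
            params=(gene, *experiments),
        )
    raise QueryError(f"group_by must be 'experiment' or 'cell_type', got {group_by!r}")


def _isoform_label(ann_row) -> str:
    if (
        ann_row["structural_category"] == "full-splice_match"
        and ann_row["associated_transcript"]
    ):
        return ann_row["associated_transcript"]
    return f"isoform_{ann_row.name}"


def gene_isoform_proportions(
    store: Store,
    gene: str,
    group_by: str = "experiment",
    known_only: bool = False,
    experiments: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group read proportions of one gene's isoforms.

    Groups are experiments (pseudobulk for single-cell stores) or cell
    types. Known isoforms (full-splice matches) are labeled by their
    reference transcript ID; others by their store isoform ID.
    ``known_only`` restricts the denominator to full-splice-match
    isoforms. Returns ``(proportions, group_totals)``; each proportion
    row sums to 1 and ``group_totals`` holds the read sums the
    proportions were computed over.
    """
    long = _gene_group_counts(store, gene, group_by, experiments)
    long = long[long.reads > 0]
    if long.empty:
        raise QueryError(f"gene {gene!r} has no detected isoforms in scope")
    anns = _isoform_annotations(store)
    if known_only:
        fsm = anns.index[anns.structural_category == "full-splice_match"]
        long = long[long.isoform_id.isin(fsm)]
        if long.empty:
            raise QueryError(f"gene {gene!r} has no known (full-splice match) isoforms")
    labels = {iso: _isoform_label(anns.loc[iso]) for iso in long.isoform_id.unique()}
    long = long.assign(label=long.isoform_id.map(labels))
    mat = long.pivot_table(index="grp", columns="label", values="reads",
                           aggfunc="sum", fill_value=0)
    totals = mat.sum(axis=1)
    props = mat.div(totals, axis=0)
    props.index.name = group_by
    return props, totals.rename("total_reads")


@dataclass
class SwitchResult:
    gene: str
    majors: dict[str, str]  # group -> major isoform label
    ties: list[str]  # groups where the argmax was tied (lexicographic pick)


def major_isoform_switches(
    store: Store,
    group_by: str = "cell_type",
    genes: list[str] | None = None,
    min_reads: int = 10,
    experiments: list[str] | None = None,
    known_only: bool = False,
) -> list[SwitchResult]:
    """Genes whose major (highest-read) isoform differs between groups.

    A group enters the comparison for a gene only when its total gene
    reads >= ``min_reads``. Ties for the argmax are broken toward the
    lexicographically smallest label and flagged. Only genes with >= 2
    qualifying groups and >= 2 distinct majors are reported.
    """
    if genes is None:
        genes = [
            r[0]
            for r in store.conn.execute(
                "SELECT DISTINCT associated_gene FROM isoform ORDER BY associated_gene"
            )
        ]
    results: list[SwitchResult] = []
    for gene in genes:
        try:
            props, totals = gene_isoform_proportions(
                store, gene, group_by=group_by, known_only=known_only,
                experiments=experiments,
            )
        except QueryError:
            continue
        reads = props.mul(totals, axis=0)
        qualifying = totals[totals >= min_reads].index
        if len(qualifying) < 2:
            continue
        majors: dict[str, str] = {}
        ties: list[str] = []
        for grp in qualifying:
            row = reads.loc[grp]
            best = row.max()
            winners = sorted(row.index[row == best])
            majors[grp] = winners[0]
            if len(winners) > 1:
                ties.append(grp)
        if len(set(majors.values())) >= 2:
            results.append(SwitchResult(gene=gene, majors=majors, ties=ties))
    return results


def _exons_from_chain(
    key: IntronChainKey, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    """Rebuild exon intervals from an intron chain plus transcript bounds."""
    if key.monoexonic_gene is not None:
        return ((start, end),)
    bounds = [start]
    for s, e in key.introns:
        bounds.extend([s, e])
    bounds.append(end)
    return tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))


def export_gtf(store: Store, path, mode: str = "longest") -> int:
    """Export the store's isoforms as a GTF file; returns records written.

    ``mode='longest'`` emits one transcript per chain spanning the
    minimal start / maximal end over its ends variants (the behavior of
    merge tools that keep only the full-length representative);
    ``mode='all_variants'`` emits one transcript per ends variant, named
    by its ``x_y_z`` variant ID.
    """
    if mode not in ("longest", "all_variants"):
        raise QueryError(f"mode must be 'longest' or 'all_variants', got {mode!r}")
    if store.n_isoforms() == 0:
        raise QueryError("store is empty; nothing to export")
    anns = _isoform_annotations(store)
    ends = pd.read_sql_query(
        "SELECT variant_id, isoform_id, start, end FROM ends", store.conn
    )
    out: list[GenomicTranscript] = []
    for iso_id, grp in ends.groupby("isoform_id"):
        key = IntronChainKey.deserialize(anns.at[iso_id, "chain"])
        gene = anns.at[iso_id, "associated_gene"]
        if mode == "longest":
            s, e = int(grp.start.min()), int(grp.end.max())
            out.append(
                GenomicTranscript(
                    transcript_id=f"isoform_{iso_id}", chrom=key.chrom,
                    strand=key.strand, exons=_exons_from_chain(key, s, e),
                    gene_id=gene,
                )
            )
        else:
            for row in grp.itertuples(index=False):
                out.append(
                    GenomicTranscript(
                        transcript_id=row.variant_id, chrom=key.chrom,
                        strand=key.strand,
                        exons=_exons_from_chain(key, int(row.start), int(row.end)),
                        gene_id=gene,
                    )
                )
    out.sort(key=lambda t: (t.chrom, t.tx_start, t.transcript_id))
    write_gtf(out, path)
    return len(out)
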