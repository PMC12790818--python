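"""Synthetic fixture generation.

Everything the ingest pipeline consumes — classification TSVs, genePred
files, metadata configs, cell-type tables — can be generated here with
controlled structure: how many chains are shared between which
experiments, how much start/end jitter each chain carries, the
structural-category mix, read depths, and (for single-cell cohorts)
planted major-isoform switches between cell types. Each bundle carries a
truth table that exactly describes the emitted files, so tests compare
query output against construction, not against sampling.

Counts are written directly into the classification FL column (the tool
consumes counts, not reads), and coordinates live on one artificial
chromosome per gene, so no reference sequence is ever needed. All
randomness flows from a single seed; the same seed yields byte-identical
bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CellTypeAssignment,
    ExperimentMeta,
    GenomicTranscript,
    SampleMeta,
    SqantiRecord,
    write_celltype_file,
    write_classification,
    write_config,
    write_genepred,
)
from .isoform_model import chain_key

# Stated-world defaults: a four-way comparison of one cell line in which
# novel chains are overwhelmingly private to a single experiment (97.2%
# of novel isoforms were single-sample in the motivating bulk analysis),
# known full-splice matches dominate read mass, and novel isoforms make
# up a substantial minority of detected chains.
DEFAULT_CATEGORY_MIX = {
    "full-splice_match": 0.55,
    "incomplete-splice_match": 0.12,
    "novel_in_catalog": 0.18,
    "novel_not_in_catalog": 0.10,
    "genic": 0.03,
    "antisense": 0.02,
}
DEFAULT_NOVEL_SINGLE_FRACTION = 0.972


class SimulationError(ValueError):
    pass


@dataclass
class SingleCellSpec:
    """Cell-type layer for a cohort: which cell types exist, how many
    barcodes each has, and which genes carry a planted isoform switch."""

    cell_types: tuple[str, ...] = ("B cells", "NK cells", "CD14+ monocytes")
    barcodes_per_type: int = 20
    n_switch_genes: int = 2
    reads_per_cell_type: int = 200


@dataclass
class CohortSpec:
    """Declarative description of a multi-experiment synthetic cohort."""

    n_genes: int = 30
    isoforms_per_gene: tuple[int, int] = (1, 4)  # uniform inclusive range
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    n_experiments: int = 4
    novel_single_fraction: float = DEFAULT_NOVEL_SINGLE_FRACTION
    fsm_mean_reads: float = 50.0
    novel_mean_reads: float = 3.0
    ends_jitter_prob: float = 0.3
    ends_jitter_max: int = 80
    single_cell: SingleCellSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"category_mix must sum to 1, got {total}")
        if not 0.0 <= self.novel_single_fraction <= 1.0:
            raise SimulationError("novel_single_fraction must be in [0, 1]")
        if self.n_experiments < 1:
            raise SimulationError("need >= 1 experiment")


@dataclass
class FixtureBundle:
    """Paths of the emitted per-experiment files plus the truth table."""

    out_dir: Path
    experiments: list[str]
    files: dict[str, dict[str, Path]]
    truth: dict

    def write_truth(self) -> Path:
        path = self.out_dir / "truth.json"
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)
        return path


def default_truncation_base() -> GenomicTranscript:
    """A two-exon transcript on a synthetic locus, the classic substrate
    for end-truncation demonstrations (coordinates are illustrative)."""
    return GenomicTranscript(
        transcript_id="REF.two_exon.1",
        chrom="chrSim1",
        strand="+",
        exons=((1000, 1600), (4000, 5200)),
        gene_id="LPAR3",
    )


def _truncate(
    base: GenomicTranscript, truncs: tuple[tuple[str, int], ...], tag: str
) -> GenomicTranscript:
    """Apply (end, bp) truncations to ``base`` without touching any junction."""
    exons = [list(iv) for iv in base.exons]
    for end, bp in truncs:
        if end not in ("5p", "3p"):
            raise SimulationError(f"truncation end must be '5p' or '3p', got {end!r}")
        if bp < 0:
            raise SimulationError("truncation bp must be >= 0")
        # 5' is the start side on '+', the end side on '-'
        left = (end == "5p") == (base.strand == "+")
        if left:
            first = exons[0]
            if bp >= first[1] - first[0]:
                raise SimulationError(
                    f"truncating {bp} bp from the left would alter the intron chain "
                    f"(first exon is {first[1] - first[0]} bp)"
                )
            first[0] += bp
        else:
            last = exons[-1]
            if bp >= last[1] - last[0]:
                raise SimulationError(
                    f"truncating {bp} bp from the right would alter the intron chain "
                    f"(last exon is {last[1] - last[0]} bp)"
                )
            last[1] -= bp
    return GenomicTranscript(
        transcript_id=tag,
        chrom=base.chrom,
        strand=base.strand,
        exons=tuple(tuple(iv) for iv in exons),
        gene_id=base.gene_id,
    )


def make_truncation_scenario(
    out_dir: str | Path,
    base: GenomicTranscript | None = None,
    sample_a_truncs: list[tuple[tuple[str, int], ...]] = (
        (), (("5p", 50),), (("3p", 100),),
    ),
    sample_b_truncs: list[tuple[tuple[str, int], ...]] = (
        (), (("3p", 100),),
    ),
    reads_per_tx: int = 10,
) -> FixtureBundle:
    """Two samples whose transcripts are end-truncations of one base.

    Every emitted transcript preserves the base's intron chain, so
    ingesting the bundle must yield exactly one isoform entry with one
    ends variant per distinct (start, end) pair. ``sample_*_truncs`` list
    one transcript each as a tuple of (end, bp) truncations; ``()`` is
    the full-length transcript.
    """
    if base is None:
        base = default_truncation_base()
    if len(base.exons) < 2:
        raise SimulationError("truncation base must have >= 2 exons")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chain = chain_key(base, base.gene_id).serialize()
    truth = {
        "chain": chain,
        "full_length": [base.tx_start, base.tx_end],
        "per_experiment": {},
        "variants": {},
    }
    files: dict[str, dict[str, Path]] = {}
    experiments: list[str] = []
    for label, truncs_list in (("sampleA", sample_a_truncs), ("sampleB", sample_b_truncs)):
        exp_name = f"trunc_{label}"
        experiments.append(exp_name)
        transcripts, records = [], []
        per_variant: dict[str, int] = {}
        for i, truncs in enumerate(truncs_list, start=1):
            tx = _truncate(base, tuple(truncs), tag=f"PB.1.{i}")
            transcripts.append(tx)
            records.append(
                SqantiRecord(
                    isoform_id=tx.transcript_id,
                    chrom=tx.chrom,
                    strand=tx.strand,
                    n_exons=len(tx.exons),
                    structural_category="full-splice_match",
                    associated_gene=base.gene_id,
                    associated_transcript=base.transcript_id,
                    subcategory="reference_match",
                    fl_count=reads_per_tx,
                )
            )
            vkey = f"{tx.tx_start}_{tx.tx_end}"
            per_variant[vkey] = per_variant.get(vkey, 0) + reads_per_tx
        truth["per_experiment"][exp_name] = reads_per_tx * len(truncs_list)
        truth["variants"][exp_name] = per_variant
        d = {
            "classification": out_dir / f"{exp_name}_classification.txt",
            "genepred": out_dir / f"{exp_name}.genePred",
            "exp_config": out_dir / f"{exp_name}_exp.config",
            "sample_config": out_dir / f"{exp_name}_sample.config",
        }
        write_classification(records, d["classification"])
        write_genepred(transcripts, d["genepred"])
        write_config(
            ExperimentMeta(exp_name=exp_name, sample_name=label, platform="simulated"),
            d["exp_config"],
        )
        write_config(SampleMeta(sample_name=label), d["sample_config"])
        files[exp_name] = d
    all_variants = sorted(
        {v for per in truth["variants"].values() for v in per}
    )
    truth["n_distinct_variants"] = len(all_variants)
    return FixtureBundle(out_dir=out_dir, experiments=experiments, files=files, truth=truth)


# ---------------------------------------------------------------------------
# cohort generation


def _gene_locus(gene_idx: int, iso_idx: int, n_exons: int = 3):
    """Deterministic exon skeleton; the middle exon shifts per isoform so
    every isoform of a gene has a distinct intron chain."""
    shift = 40 * iso_idx
    if n_exons == 2:
        return ((1000, 1600), (4000 + shift, 5200 + shift))
    return ((1000, 1600), (2500 + shift, 2900 + shift), (5000, 6200))


def _apportion(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder integer split of ``total`` by ``weights``."""
    raw = [total * w for w in weights]
    out = [int(x) for x in raw]
    rem = total - sum(out)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - out[i]), i))
    for i in order[:rem]:
        out[i] += 1
    return out


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> FixtureBundle:
    """Emit a multi-experiment cohort with designed sharing and switches.

    Novel chains (NIC/NNC) are planted single-experiment at exactly
    ``round(novel_single_fraction * n_novel)``; the rest are detected in
    >= 2 experiments. Known chains are detected in every experiment. For
    single-cell cohorts, per-cell-type counts are apportioned from fixed
    per-isoform weights (identical across cell types), except in planted
    switch genes where the top two isoforms swap weights in half the
    cell types — so exactly those genes show a major-isoform switch.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exps = [f"exp{i + 1}" for i in range(spec.n_experiments)]
    cats = list(spec.category_mix)
    cat_p = np.array([spec.category_mix[c] for c in cats])

    # -- plan isoforms ------------------------------------------------------
    isoforms = []  # dicts: gene, chrom, strand, exons, category, chain
    sc = spec.single_cell
    for g in range(spec.n_genes):
        gene = f"GENE{g:04d}"
        chrom = f"chrS{g:04d}"  # one artificial chromosome per gene
        strand = "+" if g % 2 == 0 else "-"
        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        for i in range(n_iso):
            category = cats[int(rng.choice(len(cats), p=cat_p))]
            if sc is not None and i == 0:
                category = "full-splice_match"  # switch plants need known isoforms
            tx_exons = _gene_locus(g, i)
            isoforms.append(
                {
                    "gene": gene, "chrom": chrom, "strand": strand,
                    "exons": tx_exons, "category": category, "iso_idx": i,
                }
            )
    for iso in isoforms:
        t = GenomicTranscript("tmp", iso["chrom"], iso["strand"], iso["exons"])
        iso["chain"] = chain_key(t, iso["gene"]).serialize()

    # -- plan detection -----------------------------------------------------
    novel = [iso for iso in isoforms if iso["category"] in
             ("novel_in_catalog", "novel_not_in_catalog")]
    n_single = round(spec.novel_single_fraction * len(novel))
    order = rng.permutation(len(novel))
    for rank, idx in enumerate(order):
        iso = novel[idx]
        if rank < n_single or spec.n_experiments == 1:
            iso["detected_in"] = [exps[int(rng.integers(len(exps)))]]
        else:
            k = int(rng.integers(2, spec.n_experiments + 1))
            picks = rng.choice(len(exps), size=k, replace=False)
            iso["detected_in"] = [exps[j] for j in sorted(picks)]
    for iso in isoforms:
        if "detected_in" not in iso:
            iso["detected_in"] = list(exps)

    # -- plan reads ---------------------------------------------------------
    for iso in isoforms:
        mean = (
            spec.fsm_mean_reads
            if iso["category"] == "full-splice_match"
            else spec.novel_mean_reads
        )
        iso["reads"] = {
            e: int(rng.poisson(mean)) + 1 for e in iso["detected_in"]
        }

    # -- plant single-cell structure ---------------------------------------
    switch_truth: dict[str, dict[str, str]] = {}
    if sc is not None:
        genes_by_name: dict[str, list[dict]] = {}
        for iso in isoforms:
            genes_by_name.setdefault(iso["gene"], []).append(iso)
        multi_fsm = [
            g for g, il in sorted(genes_by_name.items())
            if sum(1 for x in il if x["category"] == "full-splice_match") >= 2
        ]
        if len(multi_fsm) < sc.n_switch_genes:
            raise SimulationError(
                f"cannot plant {sc.n_switch_genes} switch genes: only "
                f"{len(multi_fsm)} genes have >= 2 known isoforms"
            )
        switch_genes = list(rng.choice(multi_fsm, size=sc.n_switch_genes, replace=False))
        half = len(sc.cell_types) // 2
        for gene, iso_list in sorted(genes_by_name.items()):
            iso_list = sorted(iso_list, key=lambda x: x["iso_idx"])
            base_w = [0.55, 0.25] + [0.2 / max(1, len(iso_list) - 2)] * (len(iso_list) - 2)
            base_w = [w / sum(base_w) for w in base_w[: len(iso_list)]]
            is_switch = gene in switch_genes
            for iso in iso_list:
                iso["ct_reads"] = {e: {} for e in exps}
            for e in exps:
                for ct_i, ct in enumerate(sc.cell_types):
                    w = list(base_w)
                    if is_switch and ct_i < half and len(iso_list) >= 2:
                        w[0], w[1] = w[1], w[0]
                    split = _apportion(sc.reads_per_cell_type, w)
                    for iso, n in zip(iso_list, split):
                        if n > 0:
                            iso["ct_reads"][e][ct] = n
            if is_switch:
                labels = {}
                for iso in iso_list:
                    labels[iso["iso_idx"]] = _fsm_label(gene, iso)
                switch_truth[gene] = {
                    ct: labels[1 if ct_i < half else 0]
                    for ct_i, ct in enumerate(sc.cell_types)
                }
        for iso in isoforms:  # FL counts follow the cell-type plan exactly
            iso["detected_in"] = list(exps)
            iso["reads"] = {
                e: sum(iso["ct_reads"][e].values()) for e in exps
                if sum(iso["ct_reads"][e].values()) > 0
            }
            iso["detected_in"] = sorted(iso["reads"], key=exps.index)

    # -- ends jitter --------------------------------------------------------
    # per (isoform, experiment): optionally split reads over extra variants
    for iso in isoforms:
        iso["variants"] = {}
        first_len = iso["exons"][0][1] - iso["exons"][0][0]
        last_len = iso["exons"][-1][1] - iso["exons"][-1][0]
        full = (iso["exons"][0][0], iso["exons"][-1][1])
        for e in iso["detected_in"]:
            reads = iso["reads"][e]
            variants = {full: reads}
            if reads >= 2 and rng.random() < spec.ends_jitter_prob:
                off_s = int(rng.integers(1, min(spec.ends_jitter_max, first_len)))
                off_e = int(rng.integers(1, min(spec.ends_jitter_max, last_len)))
                alt = (full[0] + off_s, full[1] - off_e)
                moved = reads // 2
                variants[full] -= moved
                variants[alt] = moved
            iso["variants"][e] = {k: v for k, v in variants.items() if v > 0}

    # -- emit files ---------------------------------------------------------
    files: dict[str, dict[str, Path]] = {}
    truth_chains: dict[str, dict] = {}
    for iso in isoforms:
        truth_chains[iso["chain"]] = {
            "gene": iso["gene"],
            "category": iso["category"],
            "counts": {e: sum(iso["variants"][e].values()) for e in iso["detected_in"]},
            "variants": {
                e: {f"{s}_{t}": n for (s, t), n in iso["variants"][e].items()}
                for e in iso["detected_in"]
            },
        }
    for e in exps:
        records, transcripts, assignments = [], [], []
        pb = 1
        local_ids: dict[int, str] = {}
        for iso_i, iso in enumerate(isoforms):
            if e not in iso["detected_in"]:
                continue
            for (s, t), n in sorted(iso["variants"][e].items()):
                local_id = f"PB.{pb}.1"
                pb += 1
                exons = _clip_exons(iso["exons"], s, t)
                transcripts.append(
                    GenomicTranscript(local_id, iso["chrom"], iso["strand"], exons)
                )
                records.append(
                    SqantiRecord(
                        isoform_id=local_id,
                        chrom=iso["chrom"],
                        strand=iso["strand"],
                        n_exons=len(exons),
                        structural_category=iso["category"],
                        associated_gene=iso["gene"],
                        associated_transcript=(
                            _fsm_label(iso["gene"], iso)
                            if iso["category"] in
                            ("full-splice_match", "incomplete-splice_match")
                            else None
                        ),
                        subcategory="sim",
                        fl_count=n,
                    )
                )
                local_ids.setdefault(iso_i, local_id)
                if sc is not None:
                    assignments.extend(
                        _barcode_split(local_id, iso["ct_reads"][e], n,
                                       sum(iso["variants"][e].values()),
                                       sc.barcodes_per_type, e)
                    )
        d = {
            "classification": out_dir / f"{e}_classification.txt",
            "genepred": out_dir / f"{e}.genePred",
            "exp_config": out_dir / f"{e}_exp.config",
            "sample_config": out_dir / f"{e}_sample.config",
        }
        write_classification(records, d["classification"])
        write_genepred(transcripts, d["genepred"])
        write_config(
            ExperimentMeta(exp_name=e, sample_name=f"sample_{e}", platform="simulated"),
            d["exp_config"],
        )
        write_config(SampleMeta(sample_name=f"sample_{e}"), d["sample_config"])
        if sc is not None:
            d["celltypes"] = out_dir / f"{e}_celltypes.txt"
            write_celltype_file(assignments, d["celltypes"])
        files[e] = d

    n_novel = len(novel)
    truth = {
        "chains": truth_chains,
        "n_novel": n_novel,
        "n_novel_single": sum(
            1 for iso in novel if len(iso["detected_in"]) == 1
        ),
        "novel_single_fraction": (
            sum(1 for iso in novel if len(iso["detected_in"]) == 1) / n_novel
            if n_novel else 0.0
        ),
        "switch_genes": switch_truth,
        "seed": spec.seed,
    }
    return FixtureBundle(out_dir=out_dir, experiments=exps, files=files, truth=truth)


def _fsm_label(gene: str, iso: dict) -> str:
    return f"{gene}.T{iso['iso_idx'] + 1}"


def _clip_exons(exons, start: int, end: int):
    out = []
    for s, e in exons:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2))
    out[0] = (start, out[0][1])
    out[-1] = (out[-1][0], end)
    return tuple(out)


def _barcode_split(
    local_id: str, ct_reads: dict[str, int], variant_reads: int,
    iso_total: int, barcodes_per_type: int, exp: str,
) -> list[CellTypeAssignment]:
    """Distribute one variant's reads over cell types proportionally to the
    isoform's cell-type plan, then round-robin over that type's barcodes."""
    if iso_total == 0:
        return []
    weights = [ct_reads.get(ct, 0) / iso_total for ct in sorted(ct_reads)]
    cts = sorted(ct_reads)
    split = _apportion(variant_reads, weights)
    out = []
    for ct, n in zip(cts, split):
        if n == 0:
            continue
        per_bc = _apportion(n, [1 / barcodes_per_type] * barcodes_per_type)
        for bc_i, m in enumerate(per_bc):
            if m > 0:
                bc = f"{exp}_{ct.replace(' ', '')}_{bc_i:03d}"
                out.append(CellTypeAssignment(local_id, bc, ct, m))
    return out


# ---------------------------------------------------------------------------
# convenience: ingest a bundle through the file parsers


def ingest_bundle(store, bundle: FixtureBundle, order: list[str] | None = None):
    """Parse every emitted file and add each experiment to ``store``.

    Routes through the real readers so fixture files exercise the parsers.
    Returns the list of ingest reports.
    """
    from .ingest import add_sample, add_single_cell_sample
    from .io_formats import (
        read_celltype_file,
        read_classification,
        read_config,
        read_genepred,
    )

    reports = []
    for e in order or bundle.experiments:
        d = bundle.files[e]
        classification = read_classification(d["classification"])
        transcripts = read_genepred(d["genepred"])
        exp = read_config(d["exp_config"], "experiment")
        sample = read_config(d["sample_config"], "sample")
        if "celltypes" in d:
            assignments = read_celltype_file(d["celltypes"])
            reports.append(
                add_single_cell_sample(
                    store, classification, transcripts, exp, sample, assignments
                )
            )
        else:
            reports.append(add_sample(store, classification, transcripts, exp, sample))
    return reports
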