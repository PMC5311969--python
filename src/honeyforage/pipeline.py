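"""End-to-end orchestration: simulate datasets, run the analysis, report.

The analysis chain per sample is trim -> merge -> >450 bp filter ->
reference search -> lowest-common-rank assignment -> regional checklist
filter -> proportions. Month-level results pool the hives, classify
major/minor forage, and join the floral survey for availability,
phenology and the statistical layer.

Everything is deterministic: a config plus seed reproduces identical
outputs, and read accounting is logged at every stage so no read is
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import composition as comp
from . import read_processing as rp
from . import stats as st
from . import survey_analysis as sa
from . import synthetic_data as syn
from . import taxonomic_assignment as ta
from .formats_io import (
    FloralSurvey,
    ReadPairBatch,
    ReferenceLibrary,
    RegionalChecklist,
    load_reference,
    read_checklist,
    read_fastq_pairs,
    read_survey_tables,
    write_checklist,
    write_fasta,
    write_fastq_pairs,
    write_survey_table,
    write_taxonomy_table,
    normalize_label,
)
from .reference_search import AlignmentParams, SearchEngine

logger = logging.getLogger("honeyforage")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    reference_fasta: str = "reference.fasta"
    taxonomy: str = "taxonomy.tsv"
    checklist: str = "checklist.tsv"
    survey: str = "survey.tsv"
    reads_dir: str = "reads"
    output_dir: str = "results"
    samples: list[dict] = field(default_factory=list)  # {hive, month, r1, r2}
    # read processing
    trim_threshold_q: int = rp.DEFAULT_TRIM_Q
    trim_window: int = rp.DEFAULT_TRIM_WINDOW
    min_overlap: int = rp.DEFAULT_MIN_OVERLAP
    max_mismatch_fraction: float = rp.DEFAULT_MAX_MISMATCH_FRACTION
    min_length: int = rp.DEFAULT_MIN_LENGTH
    # search
    engine: str = "seeded"  # exhaustive | seeded
    kmer_size: int = 16
    match_reward: float = 1.0
    mismatch_penalty: float = -2.0
    gap_open: float = -2.0
    gap_extend: float = -2.0
    # composition
    pool_mode: str = "pooled-counts"
    major_threshold_pct: float = comp.MAJOR_THRESHOLD_PCT
    seed: int = 0

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            match_reward=self.match_reward,
            mismatch_penalty=self.mismatch_penalty,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


@dataclass
class SampleResult:
    hive: str
    month: str
    accounting: rp.BatchAccounting
    identifiable_pct: float
    retained_counts: dict[str, int]
    removed_counts: dict[str, int]
    composition: comp.SampleComposition
    assignments: list[ta.Assignment] = field(default_factory=list)


@dataclass
class StudyResults:
    samples: list[SampleResult]
    pooled_by_month: dict[str, comp.SampleComposition]
    pooled_combined: comp.SampleComposition
    major_minor_by_month: dict[str, dict[str, str]]
    major_minor_combined: dict[str, str]
    availability: sa.Availability
    availability_table: pd.DataFrame
    phenology: pd.DataFrame
    stat_results: list[st.StatResult]

    @property
    def identifiable_pct_overall(self) -> float:
        total = sum(s.accounting.kept for s in self.samples)
        ok = sum(
            s.accounting.kept * s.identifiable_pct / 100.0 for s in self.samples
        )
        return 100.0 * ok / total if total else 0.0


def analyze_sample(
    hive: str,
    month: str,
    batch: ReadPairBatch,
    engine: SearchEngine,
    checklist: RegionalChecklist,
    config: RunConfig,
) -> SampleResult:
    """Run one sample through trim/merge/filter/search/assign/filter."""
    kept, _rejections, acct = rp.process_batch(
        batch,
        threshold_q=config.trim_threshold_q,
        window=config.trim_window,
        min_overlap=config.min_overlap,
        max_mismatch_fraction=config.max_mismatch_fraction,
        min_length=config.min_length,
    )
    if not kept:
        raise ValueError(f"sample {hive}/{month}: no merged reads passed the filters")
    taxonomy = engine.library.taxonomy
    # identical merged sequences share one search + assignment
    by_seq: dict[str, list[str]] = {}
    for read in kept:
        by_seq.setdefault(read.sequence, []).append(read.read_id)
    assignments: list[ta.Assignment] = []
    for seq, read_ids in by_seq.items():
        hit_set = engine.search(read_ids[0], seq)
        a = ta.assign(hit_set, taxonomy)
        for rid in read_ids:
            assignments.append(
                ta.Assignment(rid, a.rank, a.label, a.family, a.genus_group)
            )
    ident_pct = ta.identifiable_fraction(assignments)
    counts = ta.taxon_counts(assignments)
    retained, removed = ta.regional_filter(counts, checklist)
    sample_comp = comp.proportions(retained, hive_id=hive, month=month)
    logger.info(
        "sample %s/%s: pairs_in=%d merged=%d kept=%d identifiable=%.2f%% "
        "retained_taxa=%d removed_taxa=%d",
        hive,
        month,
        acct.pairs_in,
        acct.merged,
        acct.kept,
        ident_pct,
        len(retained),
        len(removed),
    )
    return SampleResult(
        hive=hive,
        month=month,
        accounting=acct,
        identifiable_pct=ident_pct,
        retained_counts=retained,
        removed_counts=removed,
        composition=sample_comp,
        assignments=assignments,
    )


def analyze_study(
    batches: Sequence[tuple[str, str, ReadPairBatch]],
    reference: ReferenceLibrary,
    checklist: RegionalChecklist,
    survey: FloralSurvey,
    config: RunConfig | None = None,
) -> StudyResults:
    """Run the full analysis over (hive, month, batch) samples."""
    if config is None:
        config = RunConfig()
    engine = SearchEngine(
        reference,
        params=config.alignment_params(),
        engine=config.engine,
        k=config.kmer_size,
    )
    samples = [
        analyze_sample(hive, month, batch, engine, checklist, config)
        for hive, month, batch in batches
    ]
    months = [m for m in survey.months if any(s.month == m for s in samples)]

    pooled_by_month = {
        m: comp.pool_samples(
            [s.composition for s in samples if s.month == m], mode=config.pool_mode
        )
        for m in months
    }
    pooled_combined = comp.pool_samples(
        [s.composition for s in samples], mode=config.pool_mode
    )
    mm_by_month = {
        m: comp.classify_major_minor(pooled_by_month[m], config.major_threshold_pct)
        for m in months
    }
    mm_combined = comp.classify_major_minor(pooled_combined, config.major_threshold_pct)

    genus_to_family = {
        t.genus: t.family for t in reference.taxonomy.values()
    }
    avail = sa.availability(survey, genus_to_family)
    honey_by_month = {m: sorted(pooled_by_month[m].taxa) for m in months}
    avail_table = sa.availability_table(avail, honey_by_month, months)
    phenology = (
        sa.phenology_concordance(pooled_by_month, avail)
        if len(months) >= 2
        else pd.DataFrame()
    )

    stat_results: list[st.StatResult] = []
    for m in months:
        month_comps = [s.composition for s in samples if s.month == m]
        if len(month_comps) >= 2:
            stat_results.extend(st.hive_concordance(month_comps, month=m))
    # adjust hive concordance over all pairs x months together
    if stat_results:
        adjusted = st.bonferroni([r.p_value for r in stat_results])
        for r, p_adj in zip(stat_results, adjusted):
            r.p_adjusted = p_adj
    if len(months) == 2:
        hives = sorted({s.hive for s in samples})
        rich = {
            m: [
                comp.richness(s.composition)
                for h in hives
                for s in samples
                if s.hive == h and s.month == m
            ]
            for m in months
        }
        div = {
            m: [
                comp.simpson_diversity(s.composition)
                for h in hives
                for s in samples
                if s.hive == h and s.month == m
            ]
            for m in months
        }
        for metric, values in (("richness", rich), ("simpson", div)):
            try:
                stat_results.append(
                    st.mann_whitney_u(
                        values[months[0]],
                        values[months[1]],
                        name=f"mwu_{metric}_{months[0]}_vs_{months[1]}",
                    )
                )
            except ValueError:
                pass
    try:
        stat_results.append(st.status_association(checklist, mm_combined))
    except ValueError as exc:
        logger.warning("status association skipped: %s", exc)
    # area of occurrence vs DNA abundance, per hive x month
    area_results: list[st.StatResult] = []
    for s in samples:
        taxa = sorted(s.composition.proportions)
        if len(taxa) < 3:
            continue
        areas = [sa.area_of_occurrence(survey, t, s.month) for t in taxa]
        props = [s.composition.proportions[t] for t in taxa]
        try:
            area_results.append(
                st.spearman_rho(
                    areas, props, name=f"spearman_area_vs_abundance_{s.hive}_{s.month}"
                )
            )
        except ValueError:
            continue
    if area_results:
        adjusted = st.bonferroni([r.p_value for r in area_results])
        for r, p_adj in zip(area_results, adjusted):
            r.p_adjusted = p_adj
        stat_results.extend(area_results)

    return StudyResults(
        samples=samples,
        pooled_by_month=pooled_by_month,
        pooled_combined=pooled_combined,
        major_minor_by_month=mm_by_month,
        major_minor_combined=mm_combined,
        availability=avail,
        availability_table=avail_table,
        phenology=phenology,
        stat_results=stat_results,
    )


# ---------------------------------------------------------------------------
# File-based commands
# ---------------------------------------------------------------------------


def cmd_simulate(
    outdir: str | Path,
    seed: int = 0,
    n_read_pairs: int = 10_000,
    error_rate: float = 0.005,
    n_taxa: int = 10,
    mixture_ratio: float = 0.5,
) -> Path:
    """Write a complete simulated dataset (reference, survey, reads, truth)."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    design = syn.default_study(
        seed=seed,
        n_read_pairs=n_read_pairs,
        error_rate=error_rate,
        n_taxa=n_taxa,
        mixture_ratio=mixture_ratio,
    )
    write_fasta(
        outdir / "reference.fasta",
        [(sid, seq) for sid, seq, _ in design.reference.entries],
    )
    write_taxonomy_table(outdir / "taxonomy.tsv", design.reference.taxonomy)
    write_checklist(outdir / "checklist.tsv", design.checklist)
    write_survey_table(outdir / "survey.tsv", design.survey)
    syn.write_truth_table(outdir / "truth.tsv", design.mixtures)
    samples = []
    for mixture in design.mixtures:
        batch, _ = syn.simulate_reads(
            design.reference, mixture, read_length=design.config.read_length
        )
        r1 = f"reads/{mixture.sample_id}_R1.fastq"
        r2 = f"reads/{mixture.sample_id}_R2.fastq"
        write_fastq_pairs(outdir / r1, outdir / r2, batch)
        hive, month = mixture.sample_id.split("_", 1)
        samples.append({"hive": hive, "month": month, "r1": r1, "r2": r2})
    config = RunConfig(samples=samples, seed=seed)
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "seed": seed,
        "n_read_pairs": n_read_pairs,
        "error_rate": error_rate,
        "n_taxa": n_taxa,
        "mixture_ratio": mixture_ratio,
        "reference": asdict(design.config),
        "hives": list(design.hives),
        "months": list(design.months),
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    with open(outdir / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return outdir


def load_run_inputs(base: Path, config: RunConfig):
    """Resolve and validate all input paths before any compute."""
    paths = {
        "reference_fasta": base / config.reference_fasta,
        "taxonomy": base / config.taxonomy,
        "checklist": base / config.checklist,
        "survey": base / config.survey,
    }
    missing = [str(p) for p in paths.values() if not p.exists()]
    for sample in config.samples:
        for key in ("r1", "r2"):
            p = base / sample[key]
            if not p.exists():
                missing.append(str(p))
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    if not config.samples:
        raise ValueError("config lists no samples")
    reference = load_reference(paths["reference_fasta"], paths["taxonomy"])
    checklist = read_checklist(paths["checklist"])
    survey = read_survey_tables(paths["survey"])
    batches = [
        (
            s["hive"],
            s["month"],
            read_fastq_pairs(base / s["r1"], base / s["r2"]),
        )
        for s in config.samples
    ]
    return reference, checklist, survey, batches


def cmd_run(config: RunConfig, base_dir: str | Path = ".") -> Path:
    """Execute the full pipeline and write result tables."""
    base = Path(base_dir)
    reference, checklist, survey, batches = load_run_inputs(base, config)
    results = analyze_study(batches, reference, checklist, survey, config)
    outdir = base / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(outdir, results, config)
    return outdir


def write_results(outdir: Path, results: StudyResults, config: RunConfig) -> None:
    acct_rows = [
        (
            s.hive,
            s.month,
            s.accounting.pairs_in,
            s.accounting.merged,
            s.accounting.rejected,
            s.accounting.kept,
            s.accounting.length_filtered,
            s.identifiable_pct,
            sum(s.removed_counts.values()),
        )
        for s in results.samples
    ]
    pd.DataFrame(
        acct_rows,
        columns=[
            "hive",
            "month",
            "pairs_in",
            "merged",
            "rejected",
            "kept",
            "length_filtered",
            "identifiable_pct",
            "reads_removed_by_checklist",
        ],
    ).to_csv(outdir / "accounting.tsv", sep="\t", index=False)

    assign_rows = [
        (s.hive, s.month, a.read_id, a.rank, a.label, "/".join(sorted(a.genus_group)))
        for s in results.samples
        for a in s.assignments
    ]
    pd.DataFrame(
        assign_rows, columns=["hive", "month", "read_id", "rank", "label", "genus_group"]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    all_comps = [s.composition for s in results.samples]
    all_comps += list(results.pooled_by_month.values()) + [results.pooled_combined]
    comp.composition_table(all_comps, config.major_threshold_pct).to_csv(
        outdir / "composition.tsv", sep="\t", index=False
    )
    results.availability_table.to_csv(
        outdir / "availability.tsv", sep="\t", index=False
    )
    if not results.phenology.empty:
        results.phenology.to_csv(outdir / "phenology.tsv", sep="\t", index=False)
    st.stats_report(results.stat_results).to_csv(
        outdir / "stats.tsv", sep="\t", index=False
    )
    summary = {
        "identifiable_pct_overall": round(results.identifiable_pct_overall, 3),
        "months": {
            m: {
                "richness": comp.richness(c),
                "simpson": round(comp.simpson_diversity(c), 4),
                "major_taxa": sorted(
                    t
                    for t, cls in results.major_minor_by_month[m].items()
                    if cls == "major"
                ),
            }
            for m, c in results.pooled_by_month.items()
        },
    }
    with open(outdir / "summary.yaml", "w") as handle:
        yaml.safe_dump(summary, handle, sort_keys=True)


EXPECTED_RESULT_FILES = (
    "accounting.tsv",
    "assignments.tsv",
    "composition.tsv",
    "availability.tsv",
    "stats.tsv",
    "summary.yaml",
)


def cmd_report(results_dir: str | Path) -> str:
    """Render a human-readable summary from a results directory."""
    results_dir = Path(results_dir)
    missing = [f for f in EXPECTED_RESULT_FILES if not (results_dir / f).exists()]
    if missing:
        return "incomplete results directory; missing stages: " + ", ".join(missing)
    lines = ["# Honey metabarcoding run summary", ""]
    with open(results_dir / "summary.yaml") as handle:
        summary = yaml.safe_load(handle)
    lines.append(
        f"Overall identifiable reads: {summary['identifiable_pct_overall']:.2f}%"
    )
    for month, info in summary["months"].items():
        lines.append(
            f"{month}: richness={info['richness']} Simpson's D={info['simpson']:.3f}"
        )
        lines.append(f"  major forage: {', '.join(info['major_taxa'])}")
    avail = pd.read_csv(results_dir / "availability.tsv", sep="\t")
    lines.append("")
    lines.append("Use versus availability:")
    for _, row in avail.iterrows():
        lines.append(
            f"  {row['month']:>9} {row['rank']:>6}: {row['n_in_honey']} of "
            f"{row['n_in_flower']} in flower ({row['pct_used']}%)"
        )
    phen_path = results_dir / "phenology.tsv"
    if phen_path.exists():
        phen = pd.read_csv(phen_path, sep="\t")
        flagged = phen.loc[phen["carry_over"], "taxon"].tolist()
        lines.append("")
        lines.append(
            "Carry-over flagged taxa: " + (", ".join(flagged) if flagged else "none")
        )
    stats_df = pd.read_csv(results_dir / "stats.tsv", sep="\t")
    lines.append("")
    lines.append("Statistics:")
    for _, row in stats_df.iterrows():
        lines.append(
            f"  {row['test']}: statistic={row['statistic']:.4g} "
            f"p={row['p']:.4g} (n={row['n']}, {row['method']})"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Externally published per-hive proportion tables
# ---------------------------------------------------------------------------


def published_table_statistics(df: pd.DataFrame) -> dict:
    """Diversity and concordance statistics from a per-hive proportion table.

    Expects the long format of :func:`~honeyforage.formats_io.read_proportion_table`
    (hive, month, taxon, proportion-in-percent). Per month, the combined
    composition is the unweighted mean of hive proportions (counts are
    unavailable in published tables) and pairwise hive correlations use
    the full taxon union across months with absent taxa as zero.
    """
    df = df.copy()
    df["taxon"] = df["taxon"].map(normalize_label)
    months = sorted(df["month"].unique())
    hives = sorted(df["hive"].unique())
    all_taxa = sorted(df["taxon"].unique())
    out: dict = {"simpson": {}, "spearman": {}}
    for month in months:
        sub = df[df["month"] == month]
        comps = []
        for hive in hives:
            props = dict(
                zip(sub.loc[sub["hive"] == hive, "taxon"],
                    sub.loc[sub["hive"] == hive, "proportion"])
            )
            full = {t: float(props.get(t, 0.0)) for t in all_taxa}
            total = sum(full.values())
            if total <= 0:
                continue
            scaled = {t: 100.0 * v / total for t, v in full.items()}
            comps.append(
                comp.SampleComposition(hive, month, counts={}, _proportions=scaled)
            )
        pooled = comp.pool_samples(comps, mode="mean-of-proportions")
        out["simpson"][month] = comp.simpson_diversity(pooled)
        for r in st.hive_concordance(comps, month=month):
            out["spearman"][r.name] = r
    return out
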