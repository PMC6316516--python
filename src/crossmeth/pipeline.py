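"""End-to-end orchestration: simulate -> analyze -> report.

``run_simulate`` writes the seeded synthetic dataset (FASTQ pairs plus
ground truth). ``run_analyze`` runs reference annotation, read QC,
allele assignment, methylation quantification and the inheritance
statistics over a directory of per-individual FASTQ pairs, writing all
result tables as TSV plus a machine-readable run manifest.
``mutant_table`` computes the region-level fractional-methylation
surface from external per-site methylation tables (wild type vs
epigenetic-regulation mutants).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .quant import (
    extract_calls,
    ingest_sitetable,
    methylation_levels,
    region_fractional_levels,
)
from .reads import (
    assign_pair,
    filter_mapping_error,
    quality_filter,
    read_fastq_pairs,
    summarize_assignments,
)
from .reference import COL, LER, CONTEXTS, Region, default_regions, read_region_fasta, sites_table
from .simulate import simulate_dataset, default_profiles
from .stats import (
    allele_correlation,
    call_genotype,
    plot_allele_correlation,
    plot_population_boxplots,
    reciprocal_comparison,
    segregation_test,
    summarize_population,
)

logger = logging.getLogger(__name__)


def load_regions(config: PipelineConfig) -> list[Region]:
    if config.reference_fasta is None:
        return default_regions()
    flanks = {k: (v[0], v[1]) for k, v in config.flanks.items()}
    return read_region_fasta(config.reference_fasta, flanks=flanks)


def _write_manifest(outdir: Path, config: PipelineConfig, outputs: list[str],
                    extra: dict | None = None) -> None:
    manifest = {
        "package": "crossmeth",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "outputs": sorted(outputs),
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, outdir: str | Path):
    """Simulate the full design to ``outdir``; returns the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = load_regions(config)
    truth = simulate_dataset(
        config.design, regions, default_profiles(), config.params, outdir
    )
    outputs = [p.name for p in outdir.iterdir()]
    _write_manifest(outdir, config, outputs)
    logger.info(
        "simulated %d individuals x %d regions into %s",
        config.design.n_individuals,
        len(regions),
        outdir,
    )
    return truth


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _discover_individuals(fastq_dir: Path) -> list[tuple[str, Path, Path]]:
    r1_files = sorted(fastq_dir.glob("*_R1.fastq"))
    if not r1_files:
        raise FileNotFoundError(f"no *_R1.fastq files found in {fastq_dir}")
    out = []
    for r1 in r1_files:
        ind = re.sub(r"_R1\.fastq$", "", r1.name)
        r2 = r1.with_name(f"{ind}_R2.fastq")
        if not r2.exists():
            raise FileNotFoundError(f"individual {ind}: missing mate file {r2.name}")
        out.append((ind, r1, r2))
    return out


def _group_label(generation: str, population: str, genotype: str, merged: bool) -> str:
    """Table-2-style population group for summaries."""
    if generation == "P":
        return population
    if merged:
        return generation if generation == "F1" else f"F2_{genotype}"
    return population if generation == "F1" else f"{population}_{genotype}"


def run_analyze(
    config: PipelineConfig, fastq_dir: str | Path, outdir: str | Path
) -> dict[str, pd.DataFrame]:
    """Analyze a directory of per-individual FASTQ pairs.

    Writes (per region where applicable): reference site annotations,
    mapping summaries, genotype calls, segregation tests, reciprocal-
    cross tests, population summaries, trans-allelic correlations, a
    read-accounting reconciliation and the run manifest. Returns the
    tables keyed by name.
    """
    fastq_dir = Path(fastq_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = load_regions(config)
    thr = config.thresholds
    pop_by_label = {p.label: p for p in config.design.populations}

    individuals = _discover_individuals(fastq_dir)
    logger.info("analyzing %d individuals, %d regions", len(individuals), len(regions))

    site_rows = pd.concat([sites_table(r) for r in regions], ignore_index=True)

    mapping_rows = []
    genotype_rows = []
    level_frames = []
    recon_rows = []
    for ind, r1_path, r2_path in individuals:
        pop_label = ind.rsplit("_", 1)[0]
        pop = pop_by_label.get(pop_label)
        generation = pop.generation if pop else "unknown"
        pairs = read_fastq_pairs(r1_path, r2_path)
        kept, dropped_pairs = quality_filter(pairs, thr.min_quality, thr.min_length)
        by_region: dict[str, list] = {r.region_id: [] for r in regions}
        for pair in kept:
            a1, a2 = assign_pair(pair, regions, thr.max_mismatch)
            by_region[a1.region_id].extend((a1, a2))
        for region in regions:
            assigned = by_region[region.region_id]
            summary = summarize_assignments(ind, region.region_id, assigned)
            summary = filter_mapping_error(summary, thr.mapping_error)
            if summary.total_mapped < thr.min_mapped_reads:
                logger.debug(
                    "%s/%s: %d mapped reads below the %d QC warning level",
                    ind, region.region_id, summary.total_mapped, thr.min_mapped_reads,
                )
            genotype = call_genotype(summary, thr.genotype)
            usable = [
                a
                for a in assigned
                if a.allele in (COL, LER) and a.allele != summary.excluded_allele
            ]
            counts = extract_calls(usable, region.shared_sites, individual=ind)
            levels = methylation_levels(counts)
            if not levels.empty:
                levels.insert(1, "region", region.region_id)
                levels.insert(2, "population", pop_label)
                levels.insert(3, "generation", generation)
                levels.insert(4, "genotype", genotype)
                level_frames.append(levels)
            mapping_rows.append(
                {
                    "individual": ind,
                    "population": pop_label,
                    "region": region.region_id,
                    "n_col": summary.n_col,
                    "n_ler": summary.n_ler,
                    "n_ambiguous": summary.n_ambiguous,
                    "n_unmapped": summary.n_unmapped,
                    "minor_fraction": summary.minor_fraction,
                    "excluded_allele": summary.excluded_allele or "",
                    "n_discarded": summary.n_discarded,
                    "failed_qc": summary.failed_qc,
                }
            )
            genotype_rows.append(
                {
                    "individual": ind,
                    "population": pop_label,
                    "generation": generation,
                    "region": region.region_id,
                    "genotype": genotype or "NA",
                }
            )
        # read accounting: every input mate ends up in exactly one bin
        n_assigned = sum(len(v) for v in by_region.values())
        recon_rows.append(
            {
                "individual": ind,
                "mates_in": 2 * len(pairs),
                "quality_dropped": 2 * dropped_pairs,
                "assigned_bins": n_assigned,
                "balanced": 2 * len(pairs) == 2 * dropped_pairs + n_assigned,
            }
        )

    mapping_df = pd.DataFrame(mapping_rows)
    genotype_df = pd.DataFrame(genotype_rows)
    recon_df = pd.DataFrame(recon_rows)
    levels_df = (
        pd.concat(level_frames, ignore_index=True)
        if level_frames
        else pd.DataFrame(
            columns=["individual", "region", "population", "generation",
                     "genotype", "allele", "motif", "level", "n_sites", "coverage"]
        )
    )

    # segregation per F2 population x region
    seg_rows = []
    f2 = genotype_df[(genotype_df["generation"] == "F2") & (genotype_df["genotype"] != "NA")]
    for (pop_label, region_id), grp in f2.groupby(["population", "region"]):
        counts = grp["genotype"].value_counts()
        cc, cl, ll = int(counts.get("CC", 0)), int(counts.get("CL", 0)), int(counts.get("LL", 0))
        stat, p = segregation_test(cc, cl, ll)
        seg_rows.append(
            {
                "population": pop_label,
                "region": region_id,
                "CC": cc,
                "CL": cl,
                "LL": ll,
                "chi_square": stat,
                "p_value": p,
            }
        )
    seg_df = pd.DataFrame(seg_rows)

    # reciprocal-cross comparison on F1 levels, per region x allele x motif
    recip_rows = []
    f1_levels = levels_df[levels_df["generation"] == "F1"]
    f1_pops = [p.label for p in config.design.populations if p.generation == "F1"]
    merged_by_region: dict[str, bool] = {}
    for region in regions:
        merged = True
        if len(f1_pops) == 2:
            sub = f1_levels[f1_levels["region"] == region.region_id]
            for allele in (COL, LER):
                for motif in CONTEXTS:
                    a = sub[(sub["population"] == f1_pops[0])
                            & (sub["allele"] == allele) & (sub["motif"] == motif)]["level"]
                    b = sub[(sub["population"] == f1_pops[1])
                            & (sub["allele"] == allele) & (sub["motif"] == motif)]["level"]
                    res = reciprocal_comparison(a, b, thr.reciprocal_alpha)
                    merged &= res.merged
                    recip_rows.append(
                        {
                            "region": region.region_id,
                            "allele": allele,
                            "motif": motif,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "merged": res.merged,
                            "n_a": res.n_a,
                            "n_b": res.n_b,
                        }
                    )
        merged_by_region[region.region_id] = merged
    recip_df = pd.DataFrame(recip_rows)

    # population summary (Table-2-style surface), merge-aware
    summaries = []
    for region in regions:
        sub = levels_df[levels_df["region"] == region.region_id].copy()
        if sub.empty:
            continue
        merged = merged_by_region[region.region_id]
        sub["population"] = [
            _group_label(g, p, gt if isinstance(gt, str) else "NA", merged)
            for g, p, gt in zip(sub["generation"], sub["population"], sub["genotype"])
        ]
        summary = summarize_population(sub)
        summary.insert(0, "region", region.region_id)
        summaries.append(summary)
    summary_df = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )

    # trans-allelic correlation in F2 heterozygotes, per region x motif
    corr_rows = []
    het = levels_df[(levels_df["generation"] == "F2") & (levels_df["genotype"] == "CL")]
    for region in regions:
        for motif in CONTEXTS:
            sub = het[(het["region"] == region.region_id) & (het["motif"] == motif)]
            wide = sub.pivot_table(
                index="individual", columns="allele", values="level"
            ).dropna()
            if len(wide) < 3 or COL not in wide or LER not in wide:
                continue
            res = allele_correlation(wide[COL], wide[LER], motif=motif)
            corr_rows.append(
                {
                    "region": region.region_id,
                    "motif": motif,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n_heterozygotes": res.n,
                }
            )
            if config.make_plots and res.defined:
                plot_allele_correlation(
                    res, wide[COL], wide[LER],
                    str(outdir / f"correlation_{region.region_id}_{motif}.png"),
                )
    corr_df = pd.DataFrame(corr_rows)

    tables = {
        "sites": site_rows,
        "mapping_summary": mapping_df,
        "genotypes": genotype_df,
        "segregation": seg_df,
        "reciprocal_tests": recip_df,
        "population_summary": summary_df,
        "correlation": corr_df,
        "levels": levels_df,
        "reconciliation": recon_df,
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if config.make_plots and not levels_df.empty:
        for region in regions:
            sub = levels_df[levels_df["region"] == region.region_id]
            if not sub.empty:
                plot_population_boxplots(
                    sub, str(outdir / f"boxplots_{region.region_id}.png")
                )

    # genotype accuracy against simulator truth, when present
    truth_path = fastq_dir / "truth_genotypes.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        merged_gt = genotype_df.merge(
            truth[["individual", "genotype"]].rename(columns={"genotype": "true"}),
            on="individual",
        )
        merged_gt["correct"] = merged_gt["genotype"] == merged_gt["true"]
        acc = merged_gt.groupby("region")["correct"].mean().reset_index()
        acc.columns = ["region", "genotype_accuracy"]
        acc.to_csv(outdir / "genotype_accuracy.tsv", sep="\t", index=False)
        tables["genotype_accuracy"] = acc

    if not recon_df.empty and not recon_df["balanced"].all():
        logger.error("read accounting does not reconcile for some individuals")
    outputs = [p.name for p in outdir.iterdir()]
    _write_manifest(
        outdir,
        config,
        outputs,
        extra={
            "n_individuals": len(individuals),
            "reconciliation_ok": bool(recon_df["balanced"].all())
            if not recon_df.empty
            else True,
            "merged_reciprocal": merged_by_region,
        },
    )
    return tables


# ---------------------------------------------------------------------------
# mutant comparison (region-level fractional methylation surface)
# ---------------------------------------------------------------------------


def mutant_table(
    strain_tables: dict[str, str | Path],
    regions: dict[str, tuple[str, int, int]],
) -> pd.DataFrame:
    """Region x strain x motif fractional methylation from site tables.

    ``strain_tables`` maps strain name (WT, ago4, ...) to a per-site
    TSV; ``regions`` maps region id to (chrom, start, end), 1-based
    inclusive. Regions with no covered site for a motif are flagged
    with a NaN level.
    """
    rows = []
    for region_id, (chrom, start, end) in regions.items():
        for strain, path in strain_tables.items():
            table = ingest_sitetable(path, chrom, start, end)
            if table.empty:
                logger.warning("%s/%s: no rows in region span", region_id, strain)
            levels = region_fractional_levels(table)
            for motif in CONTEXTS:
                rows.append(
                    {
                        "region": region_id,
                        "strain": strain,
                        "motif": motif,
                        "fractional_level": levels[motif],
                        "n_sites": int(
                            (
                                (table["context"] == motif) & (table["total"] > 0)
                            ).sum()
                        )
                        if not table.empty
                        else 0,
                    }
                )
    return pd.DataFrame(rows)
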