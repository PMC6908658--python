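"""End-to-end orchestration: QC → rarefaction → diversity → PERMANOVA →
occupancy → prevalence → phylogenetic diversity.

Stage order matches the analysis sequence the pipeline reproduces: the
noise threshold is calibrated on the mock community *before* any removal,
low-read samples are dropped, rare OTUs removed dataset-wide, controls set
aside, the table rarefied once at the reference depth, outliers screened,
and only then do the statistical stages run.  Every stage draws its seed
deterministically from the config seed, so a report is regenerable
bit-identically from config + inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import qc
from .community import PermanovaResult, braycurtis, permanova
from .datamodel import CountTable, PipelineConfig, SampleMeta, join_meta
from .occupancy import (ALLREAD, OccupancySummary, global_shared_fraction,
                        host_overlap, occupancy_depth_curve, organ_overlap,
                        presence_profile)
from .phylo import PDNullResult, pd_null
from .prevalence import (PrevalenceAggregate, aggregate_conserved,
                         classify_prevalence, fit_family, standard_families)
from .rarefaction import alpha_diversity, compare_diversity, rarefy

logger = logging.getLogger("phyllocom")


@dataclass
class RunReport:
    config: PipelineConfig
    filter_report: qc.FilterReport | None = None
    noise_threshold: int | None = None
    diversity_records: pd.DataFrame | None = None
    diversity_models: list = field(default_factory=list)
    permanova_result: PermanovaResult | None = None
    occupancy_summaries: list[OccupancySummary] = field(default_factory=list)
    occupancy_curves: list[pd.DataFrame] = field(default_factory=list)
    global_shared: float | None = None
    prevalence_aggregate: PrevalenceAggregate | None = None
    pd_result: PDNullResult | None = None
    failures: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    table: CountTable,
    meta: SampleMeta,
    tree: dendropy.Tree | None = None,
    declared_mock_members: set[str] | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    table, meta = join_meta(table, meta)
    report = RunReport(config=config)
    seed = config.rng_seed

    # ------------------------------------------------------------------ QC
    fr = qc.FilterReport()
    mock_ids = [s for s in meta.sample_ids if meta.df.at[s, "control"] == "mock"]
    if config.noise_rule == "mock-calibrated" and mock_ids:
        threshold = qc.calibrate_noise_threshold(
            table, mock_ids[0], declared_mock_members or set()
        )
    elif config.noise_rule == "explicit":
        threshold = config.explicit_noise_threshold
    else:
        threshold = 1
        logger.warning("no mock sample found; OTU noise threshold defaults to 1")
    report.noise_threshold = threshold

    table, low = qc.filter_low_read_samples(table, config.min_sample_reads)
    fr.samples_removed_low_reads = low.samples_removed_low_reads
    table, rare = qc.filter_rare_otus(table, threshold)
    fr.otu_min_count_threshold = threshold
    fr.otus_removed = rare.otus_removed
    fr.fraction_of_data_removed_per_otu_max = rare.fraction_of_data_removed_per_otu_max

    # controls leave the analysis set after calibration
    ctrl = [s for s in table.sample_ids
            if s in set(meta.df.index[meta.df["control"] != "none"])]
    if ctrl:
        table = table.drop_samples(ctrl)
    meta = meta.select(table.sample_ids)

    rarefied = rarefy(table, config.rarefaction_depth, rng_seed=seed,
                      draw_mode=config.draw_mode)
    div = alpha_diversity(rarefied)
    fr.outliers_flagged_iqr = qc.flag_iqr_outliers(div["richness"])
    bc_flags = qc.flag_braycurtis_outliers(
        rarefied.table, meta.select(rarefied.sample_ids),
        config.bc_outlier_threshold,
    )
    if config.remove_bc_outliers and bc_flags:
        fr.outliers_removed_braycurtis = bc_flags
        table = table.drop_samples(bc_flags)
        meta = meta.select(table.sample_ids)
        rarefied = rarefy(table, config.rarefaction_depth, rng_seed=seed,
                          draw_mode=config.draw_mode)
        div = alpha_diversity(rarefied)
    report.filter_report = fr
    report.diversity_records = div

    def stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report.failures[name] = str(exc)

    # ----------------------------------------------------------- diversity
    def _diversity():
        for response in ("richness", "evenness"):
            for factor in ("organ", "host"):
                report.diversity_models.append(
                    compare_diversity(div, meta, response, factor)
                )

    stage("diversity", _diversity)

    # ----------------------------------------------------------- PERMANOVA
    def _permanova():
        d = braycurtis(rarefied)
        report.permanova_result = permanova(
            d, meta, config.permanova_terms,
            n_permutations=config.permutations, rng_seed=seed + 1,
        )

    stage("permanova", _permanova)

    # ------------------------------------------------------------ occupancy
    def _occupancy():
        profile = presence_profile(
            table, config.depth_grid, config.rarefaction_depth,
            rng_seed=seed + 2, draw_mode=config.draw_mode,
        )
        for host in meta.hosts(include_pooled=True):
            try:
                report.occupancy_summaries.append(organ_overlap(profile, meta, host))
                report.occupancy_curves.append(
                    occupancy_depth_curve(profile, meta, "organ-within-host", host)
                )
            except ValueError as exc:
                logger.warning("organ overlap skipped for %s: %s", host, exc)
        for organ in ("leaf", "flower"):
            try:
                report.occupancy_summaries.append(host_overlap(profile, meta, organ))
                report.occupancy_curves.append(
                    occupancy_depth_curve(profile, meta, "host-within-organ", organ)
                )
            except ValueError as exc:
                logger.warning("host overlap skipped for %s: %s", organ, exc)
        report.global_shared = global_shared_fraction(profile, meta)

    stage("occupancy", _occupancy)

    # ----------------------------------------------------------- prevalence
    def _prevalence():
        classified = {}
        for spec in standard_families(meta, config.glmm_data_per_parameter_floor):
            try:
                results = fit_family(table, meta, spec)
            except ValueError as exc:
                logger.warning("family %s skipped: %s", spec.label(), exc)
                continue
            classified[spec.label()] = classify_prevalence(
                results, alpha=config.alpha,
                correction=config.multiple_testing,
            )
        report.prevalence_aggregate = aggregate_conserved(
            classified, table, meta, alpha=config.alpha
        )

    stage("prevalence", _prevalence)

    # ---------------------------------------------------------------- phylo
    def _phylo():
        if tree is None:
            logger.info("no tree supplied; phylogenetic stage skipped")
            return
        hosts = meta.hosts(include_pooled=False)
        keep = meta.df.index[meta.df["host"].isin(hosts)]
        presence = (rarefied.data.loc[rarefied.data.index.intersection(keep)] > 0)
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        presence = presence[[c for c in presence.columns if c in tips]]
        presence = presence.loc[presence.any(axis=1)]
        report.pd_result = pd_null(
            tree, presence, n_reps=config.pd_replicates, rng_seed=seed + 3
        )

    stage("phylo", _phylo)

    if outdir is not None:
        write_report(report, outdir)
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_report(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    Path(out, "config.yaml").write_text(
        yaml.safe_dump(asdict(report.config), sort_keys=False)
    )
    if report.filter_report is not None:
        report.filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                               index=False)
    if report.diversity_records is not None:
        report.diversity_records.to_csv(out / "diversity_records.tsv", sep="\t")
    if report.diversity_models:
        rows = []
        for m in report.diversity_models:
            for term, row in m.fixed_effects.iterrows():
                rows.append(dict(response=m.response, family=m.family, term=term,
                                 converged=m.converged, **row.to_dict()))
        pd.DataFrame(rows).to_csv(out / "diversity_models.tsv", sep="\t", index=False)
    if report.permanova_result is not None:
        report.permanova_result.table.to_csv(out / "permanova.tsv", sep="\t",
                                             index=False)
    if report.occupancy_summaries:
        rows = []
        for s in report.occupancy_summaries:
            for region, count in s.venn_region_counts.items():
                rows.append(dict(grouping=s.grouping, level=s.level, depth=s.depth,
                                 region=region, n_otus=count,
                                 shared_fraction=s.shared_fraction))
        pd.DataFrame(rows).to_csv(out / "occupancy_venn.tsv", sep="\t", index=False)
    if report.occupancy_curves:
        frames = []
        for c in report.occupancy_curves:
            c = c.copy()
            c["grouping"] = c.attrs.get("grouping")
            c["level"] = c.attrs.get("level")
            frames.append(c)
        pd.concat(frames).to_csv(out / "occupancy_curves.tsv", sep="\t", index=False)
    if report.prevalence_aggregate is not None:
        agg = report.prevalence_aggregate
        rows = [
            dict(family=fam, classification=cls, proportion=p)
            for fam, props in agg.family_proportions.items()
            for cls, p in props.items()
        ]
        pd.DataFrame(rows).to_csv(out / "prevalence_families.tsv", sep="\t",
                                  index=False)
        summary = dict(
            global_conserved_fraction=agg.global_conserved_fraction,
            global_conserved_fraction_uncorrected=(
                agg.global_conserved_fraction_uncorrected),
            n_otus_total=agg.n_otus_total,
            **{f"breakdown_{k}": v for k, v in agg.global_breakdown.items()},
        )
        pd.Series(summary).to_csv(out / "prevalence_summary.tsv", sep="\t",
                                  header=False)
    if report.pd_result is not None:
        report.pd_result.frame.to_csv(out / "pd_null.tsv", sep="\t")
        pd.Series(
            dict(mean_ses=report.pd_result.mean_ses(),
                 max_p_low=report.pd_result.max_p_low(),
                 n_reps=report.pd_result.n_reps)
        ).to_csv(out / "pd_summary.tsv", sep="\t", header=False)
    log_lines = [f"seed: {report.config.rng_seed}",
                 f"noise_threshold: {report.noise_threshold}"]
    if report.failures:
        log_lines += [f"FAILED {k}: {v}" for k, v in report.failures.items()]
    Path(out, "run_log.txt").write_text("\n".join(log_lines) + "\n")
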