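"""Noise removal and outlier screening for raw count tables.

The pipeline applies these steps in a fixed order: low-read sample removal,
mock-calibrated per-OTU noise threshold, rarefaction (in
:mod:`phyllocom.rarefaction`), then outlier screening.  The noise threshold
is the read count of the most abundant OTU in the mock-community sample
that is *not* a declared mock member — any OTU whose dataset-wide total
falls below that level is indistinguishable from carry-over noise and is
dropped.  OTUs that merely appear in negative controls are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .datamodel import CountTable, SampleMeta

logger = logging.getLogger("phyllocom")


@dataclass
class FilterReport:
    """Record of every exclusion decision taken on a table."""

    samples_removed_low_reads: list[str] = field(default_factory=list)
    otu_min_count_threshold: int = 1
    otus_removed: list[str] = field(default_factory=list)
    outliers_flagged_iqr: list[str] = field(default_factory=list)
    outliers_removed_braycurtis: list[str] = field(default_factory=list)
    fraction_of_data_removed_per_otu_max: float = 0.0
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.samples_removed_low_reads:
            rows.append(("sample", sid, "low_read_count"))
        for oid in self.otus_removed:
            rows.append(("otu", oid, f"total_below_{self.otu_min_count_threshold}"))
        for sid in self.outliers_flagged_iqr:
            rows.append(("sample", sid, "iqr_flag_only"))
        for sid in self.outliers_removed_braycurtis:
            rows.append(("sample", sid, "braycurtis_outlier"))
        return pd.DataFrame(rows, columns=["kind", "id", "rule"])


def filter_low_read_samples(
    table: CountTable, min_reads: int = 1000
) -> tuple[CountTable, FilterReport]:
    """Drop samples with fewer than ``min_reads`` total reads.

    The boundary is strict: a sample with exactly ``min_reads`` reads stays.
    """
    sizes = table.library_sizes()
    removed = list(sizes.index[sizes < min_reads])
    if len(removed) == table.n_samples:
        raise ValueError(f"all samples have < {min_reads} reads")
    report = FilterReport(samples_removed_low_reads=removed)
    if removed:
        logger.info("removed %d samples with < %d reads", len(removed), min_reads)
    return table.drop_samples(removed), report


def calibrate_noise_threshold(
    table: CountTable, mock_sample_id: str, declared_mock_members: set[str]
) -> int:
    """Per-OTU minimum total read count, calibrated on the mock community.

    Returns the read count, within the mock sample, of its most abundant
    OTU that is not a declared member — the level at which false positives
    demonstrably arise.  Invariant to sample/OTU ordering.  With no alien
    OTU in the mock the threshold degenerates to 1 (no filtering).
    """
    if mock_sample_id not in table.sample_ids:
        raise KeyError(f"mock sample {mock_sample_id!r} not in table")
    row = table.data.loc[mock_sample_id]
    aliens = row[~row.index.isin(declared_mock_members) & (row > 0)]
    if aliens.empty:
        logger.warning("mock sample contains only declared members; threshold = 1")
        return 1
    return int(aliens.max())


def filter_rare_otus(
    table: CountTable, min_total: int
) -> tuple[CountTable, FilterReport]:
    """Remove OTUs whose dataset-wide total is below ``min_total``.

    The report records the largest removed total as a fraction of the grand
    total — the quantity that bounds how much signal the filter can cost.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = table.otu_totals()
    removed = list(totals.index[totals < min_total])
    grand = int(totals.sum())
    max_removed = int(totals[removed].max()) if removed else 0
    report = FilterReport(
        otu_min_count_threshold=min_total,
        otus_removed=removed,
        fraction_of_data_removed_per_otu_max=(max_removed / grand if grand else 0.0),
    )
    if removed:
        logger.info(
            "removed %d OTUs with total < %d (max removed fraction %.3g)",
            len(removed), min_total, report.fraction_of_data_removed_per_otu_max,
        )
    return table.drop_otus(removed), report


def flag_iqr_outliers(values: pd.Series) -> list[str]:
    """Ids outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolation quartiles).

    Flags only: the reference analysis found no biological ground to
    exclude richness outliers, so neither does the pipeline.
    """
    if len(values) < 4:
        logger.warning("flag_iqr_outliers: fewer than 4 values, nothing flagged")
        return []
    q1, q3 = np.percentile(values.to_numpy(dtype=float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return list(values.index[(values < lo) | (values > hi)])


def flag_braycurtis_outliers(
    table: CountTable,
    meta: SampleMeta,
    distance_threshold: float = 0.95,
) -> list[str]:
    """Samples compositionally alien to their own host x organ group.

    A sample is flagged when its *minimum* Bray-Curtis distance to every
    other sample of the same host and organ reaches the threshold: at the
    maximal threshold 1.0 exactly the samples sharing no OTUs with their
    group are flagged.  Groups with fewer than two samples are skipped with
    a warning.
    """
    flagged: list[str] = []
    bio = meta.biological()
    bio = bio[bio.index.isin(table.sample_ids)]
    for (host, organ), grp in bio.groupby(["host", "organ"], observed=True):
        ids = list(grp.index)
        if len(ids) < 2:
            logger.warning("singleton group %s/%s skipped in outlier scan", host, organ)
            continue
        counts = table.data.loc[ids].to_numpy(dtype=float)
        d = squareform(pdist(counts, metric="braycurtis"))
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        flagged.extend(np.array(ids)[nearest >= distance_threshold])
    return flagged
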