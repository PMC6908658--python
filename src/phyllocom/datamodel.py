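"""Core data containers and plain-text I/O.

Every downstream analysis consumes the types defined here:

* :class:`CountTable` — samples × OTUs matrix of non-negative read counts,
* :class:`SampleMeta` — per-sample factors (host species, organ, time point,
  time series, control status, pooled flag),
* phylogenies as :class:`dendropy.Tree` objects read from newick text,
* :class:`PipelineConfig` — all tunable constants of the pipeline.

Files are tab-separated text (count table, metadata) and newick (tree); no
module outside this one parses files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phyllocom")

#: Sentinel host/organ level used for control samples.
NOT_APPLICABLE = "na"

ORGANS = ("leaf", "flower")
CONTROL_LEVELS = ("none", "negative", "mock")

META_COLUMNS = ("host", "organ", "time_point", "time_series", "control", "pooled")


class FormatError(ValueError):
    """Malformed input file (duplicate identifiers, non-integer cells, ...)."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


class CountTable:
    """Samples × OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as the index and OTU identifiers
        as columns.  Values must be non-negative integers.  Empty rows and
        columns are preserved: filtering is always an explicit, logged step.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate OTU id: {dup!r}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integers")
            values = np.round(values).astype(np.int64)
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        self._data = pd.DataFrame(
            values.astype(np.int64),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )
        self._data.index.name = "sample_id"

    # -- accessors ----------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_otus(self) -> int:
        return self._data.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total read counts (row sums)."""
        return self._data.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        """Per-OTU dataset-wide total read counts (column sums)."""
        return self._data.sum(axis=0)

    # -- manipulation -------------------------------------------------------
    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        return CountTable(self._data.loc[list(sample_ids)])

    def select_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        return CountTable(self._data[list(otu_ids)])

    def drop_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        return CountTable(self._data.drop(index=list(sample_ids)))

    def drop_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        return CountTable(self._data.drop(columns=list(otu_ids)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_samples} samples x {self.n_otus} OTUs)"


def read_count_table(path: str | Path, samples_as_rows: bool = True) -> CountTable:
    """Read a tab-separated count table.

    The first row holds OTU identifiers and the first column sample
    identifiers when ``samples_as_rows`` (the internal canonical
    orientation); set it to ``False`` for the transposed layout.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not samples_as_rows:
        df = df.T
    try:
        values = df.astype(np.int64)
    except (ValueError, TypeError):
        bad = _first_non_integer(df)
        raise FormatError(
            f"non-integer count at sample {bad[0]!r}, OTU {bad[1]!r}: {bad[2]!r}"
        ) from None
    return CountTable(values)


def _first_non_integer(df: pd.DataFrame) -> tuple[str, str, str]:
    for row in df.index:
        for col in df.columns:
            cell = df.at[row, col]
            try:
                int(cell)
            except (ValueError, TypeError):
                return str(row), str(col), str(cell)
    return "?", "?", "?"


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleMeta
# ---------------------------------------------------------------------------


class SampleMeta:
    """Per-sample factors driving every grouped analysis.

    Wraps a DataFrame indexed by sample id with columns ``host``, ``organ``,
    ``time_point`` (ordinal day index), ``time_series`` (1 or 2), ``control``
    (none / negative / mock) and ``pooled`` (True when several plant
    individuals were pooled into the sample, which excludes the host from
    host-to-host comparisons).  Control samples carry the sentinel host and
    organ level :data:`NOT_APPLICABLE`.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in metadata: {dup!r}")
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        df["control"] = df["control"].astype(str)
        bad = set(df["control"]) - set(CONTROL_LEVELS)
        if bad:
            raise FormatError(f"unknown control levels: {sorted(bad)}")
        ctrl = df["control"] != "none"
        if not (
            (df.loc[ctrl, "host"] == NOT_APPLICABLE).all()
            and (df.loc[ctrl, "organ"] == NOT_APPLICABLE).all()
        ):
            raise FormatError(
                f"control samples must have host/organ set to {NOT_APPLICABLE!r}"
            )
        df["time_point"] = df["time_point"].astype(int)
        df["time_series"] = df["time_series"].astype(int)
        if df["pooled"].dtype != bool:
            df["pooled"] = df["pooled"].astype(str).str.lower().isin(("true", "1"))
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    def loc(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        return self._df.loc[list(sample_ids)]

    def select(self, sample_ids: Iterable[str]) -> "SampleMeta":
        return SampleMeta(self._df.loc[list(sample_ids)])

    def biological(self) -> pd.DataFrame:
        """Rows for non-control samples."""
        return self._df[self._df["control"] == "none"]

    def hosts(self, include_pooled: bool = True) -> list[str]:
        bio = self.biological()
        if not include_pooled:
            bio = bio[~bio["pooled"]]
        return sorted(bio["host"].unique())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleMeta) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"SampleMeta({len(self._df)} samples)"


def read_sample_meta(path: str | Path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.df.to_csv(path, sep="\t")


def join_meta(table: CountTable, meta: SampleMeta) -> tuple[CountTable, SampleMeta]:
    """Match every table sample to exactly one metadata record.

    Unmatched samples (either direction) are excluded with a logged warning;
    zero matches is fatal.
    """
    shared = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise ValueError("no sample ids shared between count table and metadata")
    dropped = [s for s in table.sample_ids if s not in set(shared)]
    if dropped:
        logger.warning(
            "join_meta: %d samples without metadata excluded: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    extra = [s for s in meta.sample_ids if s not in set(shared)]
    if extra:
        logger.info("join_meta: %d metadata records without counts ignored", len(extra))
    return table.select_samples(shared), meta.select(shared)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

PhyloTree = dendropy.Tree


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a newick tree with branch lengths.

    Unrooted trees are treated as rooted at the basal polytomy with a
    zero-length root edge, which is the rooting Faith's PD requires.
    Negative branch lengths are rejected.
    """
    text = str(path_or_string)
    if not text.lstrip().startswith("("):
        text = Path(path_or_string).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length: {edge.length}")
    tree.seed_node.edge.length = tree.seed_node.edge.length or 0.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick", suppress_rooting=True))


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all edge lengths in the tree (the root edge counts as zero)."""
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline.

    Defaults mirror the reference field study: samples with fewer than 1000
    reads are discarded, the noise threshold is calibrated on a mock
    community, the dataset is rarefied at 6955 reads (the smallest retained
    sample), occupancy is profiled on a 1000-read incremental grid, and all
    permutation procedures use 1000 replicates at alpha 0.05 with Bonferroni
    correction.
    """

    rarefaction_depth: int = 6955
    depth_grid: list[int] = field(
        default_factory=lambda: [1000, 2000, 3000, 4000, 5000, 6000, 6955]
    )
    min_sample_reads: int = 1000
    noise_rule: str = "mock-calibrated"  # or "explicit"
    explicit_noise_threshold: int = 1
    permutations: int = 1000
    pd_replicates: int = 1000
    rng_seed: int = 0
    alpha: float = 0.05
    multiple_testing: str = "bonferroni"  # or "none"
    bc_outlier_threshold: float = 0.95
    remove_bc_outliers: bool = True
    draw_mode: str = "independent"  # or "nested"
    glmm_data_per_parameter_floor: float = 17.0
    permanova_terms: list[str] = field(
        default_factory=lambda: ["time_point", "host", "organ"]
    )
    stages: list[str] = field(
        default_factory=lambda: [
            "qc",
            "diversity",
            "permanova",
            "occupancy",
            "prevalence",
            "phylo",
        ]
    )

    def __post_init__(self) -> None:
        if self.rarefaction_depth < min(self.depth_grid):
            raise ValueError("rarefaction_depth must be >= min(depth_grid)")
        if self.permutations < 1 or self.pd_replicates < 1:
            raise ValueError("permutation counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
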