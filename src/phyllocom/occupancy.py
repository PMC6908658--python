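"""Organ and host occupancy from depth-resolved presence/absence matrices.

Detection effort in amplicon data grows with sequencing depth, so an OTU's
apparent occupancy (which organs and hosts it is found in) depends on the
rarefaction depth.  This module profiles presence at an incremental depth
grid and adds the "all-read" layer: presence judged on unrarefied counts,
restricted to the OTUs detected at the reference depth — the best detection
the data allow for OTUs that survive rarefaction.  Venn-region accounting
over organs and hosts is computed from any layer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMeta
from .rarefaction import rarefy

logger = logging.getLogger("phyllocom")

ALLREAD = "allread"


@dataclass
class PresenceProfile:
    depth_grid: list[int]
    presence: dict[int, pd.DataFrame]  # depth -> samples x OTUs booleans
    allread: pd.DataFrame
    reference_depth: int
    rng_seed: int
    draw_mode: str

    def layer(self, depth: int | str) -> pd.DataFrame:
        return self.allread if depth == ALLREAD else self.presence[int(depth)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.allread.index)


def presence_profile(
    table: CountTable,
    depth_grid: list[int],
    reference_depth: int = 6955,
    rng_seed: int = 0,
    draw_mode: str = "independent",
) -> PresenceProfile:
    """One seeded rarefaction per grid depth, plus the all-read layer.

    Samples below the reference depth are excluded up front so every layer
    shares sample indexing.  The all-read layer's OTU set is exactly the
    set detected anywhere at the reference depth: an OTU with nonzero raw
    counts that is never drawn at the reference depth is excluded from it.
    """
    if reference_depth not in depth_grid:
        raise ValueError("reference_depth must be a member of depth_grid")
    sizes = table.library_sizes()
    shallow = list(sizes.index[sizes < reference_depth])
    if shallow:
        logger.warning(
            "presence_profile: %d samples below reference depth excluded", len(shallow)
        )
        table = table.drop_samples(shallow)
    layers: dict[int, pd.DataFrame] = {}
    for depth in sorted(depth_grid):
        rt = rarefy(table, depth, rng_seed=rng_seed, draw_mode=draw_mode)
        layers[depth] = rt.data > 0
    ref = layers[reference_depth]
    detected = ref.columns[ref.any(axis=0)]
    allread = (table.data[detected] > 0)
    return PresenceProfile(
        depth_grid=sorted(depth_grid), presence=layers, allread=allread,
        reference_depth=reference_depth, rng_seed=rng_seed, draw_mode=draw_mode,
    )


@dataclass
class OccupancySummary:
    grouping: str  # organ-within-host | host-within-organ | global
    level: str  # the host (or organ) analysed
    venn_region_counts: dict[str, int]
    shared_fraction: float
    depth: int | str

    @property
    def total_otus(self) -> int:
        return sum(self.venn_region_counts.values())


def _detected_sets(
    layer: pd.DataFrame, meta: SampleMeta, factor: str, scope: pd.Index
) -> dict[str, set[str]]:
    """OTU set detected in >= 1 sample of each level of ``factor``."""
    mf = meta.loc(list(scope))
    out: dict[str, set[str]] = {}
    for level, grp in mf.groupby(factor, observed=True):
        sub = layer.loc[layer.index.intersection(grp.index)]
        out[str(level)] = set(sub.columns[sub.any(axis=0)])
    return out


def organ_overlap(
    profile: PresenceProfile,
    meta: SampleMeta,
    host: str,
    depth: int | str = ALLREAD,
) -> OccupancySummary:
    """Leaf-only / flower-only / both partition of one host's microbiota."""
    layer = profile.layer(depth)
    bio = meta.biological()
    scope = bio.index[(bio["host"] == host)].intersection(layer.index)
    sets = _detected_sets(layer, meta, "organ", scope)
    if set(sets) != {"leaf", "flower"}:
        raise ValueError(f"host {host!r} lacks samples of both organs at {depth}")
    leaf, flower = sets["leaf"], sets["flower"]
    both = leaf & flower
    counts = {
        "leaf_only": len(leaf - flower),
        "flower_only": len(flower - leaf),
        "both": len(both),
    }
    total = len(leaf | flower)
    return OccupancySummary(
        grouping="organ-within-host", level=host, venn_region_counts=counts,
        shared_fraction=(len(both) / total if total else np.nan), depth=depth,
    )


def host_overlap(
    profile: PresenceProfile,
    meta: SampleMeta,
    organ: str,
    depth: int | str = ALLREAD,
    hosts: list[str] | None = None,
) -> OccupancySummary:
    """k-host Venn partition of one organ's microbiota.

    ``shared_fraction`` is the fraction of the organ's detected OTUs found
    in at least two host species.
    """
    layer = profile.layer(depth)
    bio = meta.biological()
    scope = bio.index[bio["organ"] == organ].intersection(layer.index)
    sets = _detected_sets(layer, meta, "host", scope)
    if hosts is not None:
        sets = {h: sets[h] for h in hosts if h in sets}
    if len(sets) < 2:
        raise ValueError(f"need >= 2 hosts with {organ} samples, got {sorted(sets)}")
    host_names = sorted(sets)
    counts: dict[str, int] = {}
    shared = 0
    total = len(set().union(*sets.values()))
    for r in range(1, len(host_names) + 1):
        for combo in itertools.combinations(host_names, r):
            inside = set.intersection(*(sets[h] for h in combo))
            outside = set().union(
                *(sets[h] for h in host_names if h not in combo), set()
            )
            region = inside - outside
            counts["&".join(combo)] = len(region)
            if r >= 2:
                shared += len(region)
    return OccupancySummary(
        grouping="host-within-organ", level=organ, venn_region_counts=counts,
        shared_fraction=(shared / total if total else np.nan), depth=depth,
    )


def global_shared_fraction(
    profile: PresenceProfile, meta: SampleMeta, depth: int | str = ALLREAD
) -> float:
    """Fraction of detected OTUs present in more than one host x organ cell.

    Computed both as 1 - (fraction exclusive to exactly one cell) and by
    direct counting; the two must agree (double-counting check).
    """
    layer = profile.layer(depth)
    bio = meta.biological()
    scope = bio.index.intersection(layer.index)
    mf = meta.loc(list(scope))
    cell_sets = []
    for (_, _), grp in mf.groupby(["host", "organ"], observed=True):
        sub = layer.loc[layer.index.intersection(grp.index)]
        cell_sets.append(set(sub.columns[sub.any(axis=0)]))
    all_detected = set().union(*cell_sets)
    if not all_detected:
        return np.nan
    n_cells = {
        otu: sum(otu in s for s in cell_sets) for otu in all_detected
    }
    direct = sum(v > 1 for v in n_cells.values()) / len(all_detected)
    complement = 1.0 - sum(v == 1 for v in n_cells.values()) / len(all_detected)
    assert np.isclose(direct, complement), "occupancy double-counting check failed"
    return direct


def occupancy_depth_curve(
    profile: PresenceProfile,
    meta: SampleMeta,
    grouping: str,
    level: str,
) -> pd.DataFrame:
    """Shared fraction at every grid depth plus the all-read layer.

    ``grouping`` is ``"organ-within-host"`` (level = host) or
    ``"host-within-organ"`` (level = organ).  The returned frame also
    carries the max-min spread of the curve, the quantity that measures how
    strongly occupancy conclusions depend on sequencing depth.
    """
    fns = {
        "organ-within-host": lambda d: organ_overlap(profile, meta, level, d),
        "host-within-organ": lambda d: host_overlap(profile, meta, level, d),
    }
    if grouping not in fns:
        raise ValueError(f"unknown grouping: {grouping}")
    rows = []
    for depth in [*profile.depth_grid, ALLREAD]:
        summ = fns[grouping](depth)
        rows.append(dict(depth=depth, shared_fraction=summ.shared_fraction))
    out = pd.DataFrame(rows)
    out.attrs["spread"] = float(
        out["shared_fraction"].max() - out["shared_fraction"].min()
    )
    out.attrs["grouping"] = grouping
    out.attrs["level"] = level
    return out
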