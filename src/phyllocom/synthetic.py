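"""Synthetic phyllosphere datasets with known ground truth.

The generator emulates the sampling design of a meadow field study — three
host species (one of them sampled as pools of individuals), two organs
(leaf, flower), thirteen time points in two collection series, a few
hundred OTUs dominated by generalists — so that every pipeline stage can be
exercised against a known answer without any sequencing data.

Model
-----
Each OTU gets a lognormal base relative abundance and an occupancy class
(generalist, organ-specialist or host-specialist).  For a sample with host
``h`` and organ ``o`` the OTU's inclusion log-odds are

    eta = incl_base + penalty(class, h, o) + conservatism * trait * [o == flower]
          + time_effect(t)

where the penalty subtracts ``organ_effect_logit`` (resp.
``host_effect_logit``) when a specialist is off its preferred organ (resp.
host), and ``trait`` is a Brownian-motion character evolved on a simulated
coalescent tree, so that a positive ``conservatism_strength`` makes flower
occupancy phylogenetically clustered.  The same shifts scale relative
abundance; counts are multinomial at a library size drawn uniformly from
``depth_range``.  Effects act on both the inclusion and abundance channels
because detection in real amplicon data is depth-dependent.

All randomness flows from ``rng_seed``; identical seeds give byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import NOT_APPLICABLE, CountTable, SampleMeta

DEFAULT_HOSTS = ("R_acris", "T_pratense", "H_lanatus")


@dataclass
class SyntheticDesign:
    """Parameters of the simulated study.

    Defaults reproduce the scale of the emulated field design: 3 hosts x 2
    organs x 13 time points (7 in series 1, 6 in series 2) x 4 samples per
    cell, with flower samples of the first host absent from series 2, for
    288 samples; 476 OTUs with 90% generalists; per-sample depths uniform
    on [1000, 40000] reads.
    """

    hosts: tuple[str, ...] = DEFAULT_HOSTS
    pooled_hosts: tuple[str, ...] = ("H_lanatus",)
    time_points_per_series: tuple[int, ...] = (7, 6)
    samples_per_cell: int = 4
    n_otus: int = 476
    generalist_fraction: float = 0.9
    specialist_kind_weights: tuple[float, float] = (0.5, 0.5)  # organ, host
    organ_effect_logit: float = 3.0
    host_effect_logit: float = 3.0
    incl_base_logit: float = 2.0
    depth_range: tuple[int, int] = (1000, 40000)
    lognormal_abundance_params: tuple[float, float] = (0.0, 1.5)
    conservatism_strength: float = 0.0
    time_effect_sd: float = 0.5
    #: (host, organ, series) cells with no samples; the default mirrors the
    #: emulated collection where the first host did not flower in series 2.
    missing_cells: tuple[tuple[str, str, int], ...] = (("R_acris", "flower", 2),)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.generalist_fraction <= 1.0:
            raise ValueError("generalist_fraction must be in [0, 1]")
        if self.n_otus < 2:
            raise ValueError("need at least 2 OTUs")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (low, high)")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    occupancy_class: pd.Series  # generalist / organ_specialist / host_specialist
    preferred: pd.Series  # preferred organ or host ("" for generalists)
    trait: pd.Series  # Brownian habitat-preference character
    prevalence_logit: pd.DataFrame  # (host|organ cells) x OTUs inclusion log-odds
    tree: dendropy.Tree

    def true_shared_fraction(self) -> float:
        """Fraction of OTUs whose class makes them organ-generalists."""
        return float((self.occupancy_class != "organ_specialist").mean())


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_otus: int, rng_seed: int = 0) -> dendropy.Tree:
    """Random coalescent-style tree over ``OTU_1 .. OTU_n``.

    Lineages are merged by uniform random joins; inter-join waiting times
    are exponential with rate n_active (standard coalescent scaling), so the
    tree is ultrametric with 2n-1 nodes.  Deterministic under the seed.
    """
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    rng = np.random.default_rng(rng_seed)
    taxa = dendropy.TaxonNamespace([f"OTU_{i + 1}" for i in range(n_otus)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    active: list[tuple[dendropy.Node, float]] = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        active.append((node, 0.0))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = active[i], active[j]
        parent = dendropy.Node()
        a.edge.length = t - ha
        b.edge.length = t - hb
        parent.add_child(a)
        parent.add_child(b)
        active[i] = (parent, t)
        del active[j]
    root = active[0][0]
    root.edge.length = 0.0
    tree.seed_node = root
    return tree


def _brownian_trait(tree: dendropy.Tree, rng: np.random.Generator) -> pd.Series:
    """Brownian character at the tips; variance accumulates with path length."""
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(max(node.edge.length or 0.0, 1e-12)))
        values[id(node)] = parent_val + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    series = pd.Series(out)
    sd = series.std()
    return (series - series.mean()) / sd if sd > 0 else series * 0.0


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------


def _design_cells(design: SyntheticDesign):
    """Yield (host, organ, series, time_point) sample cells in a fixed order."""
    missing = set(design.missing_cells)
    tp = 0
    for series, n_tp in enumerate(design.time_points_per_series, start=1):
        for _ in range(n_tp):
            tp += 1
            for host in design.hosts:
                for organ in ("leaf", "flower"):
                    if (host, organ, series) in missing:
                        continue
                    yield host, organ, series, tp


def simulate_community(
    design: SyntheticDesign,
) -> tuple[CountTable, SampleMeta, GroundTruth]:
    """Simulate a count table, matching metadata, and the ground truth."""
    rng = np.random.default_rng(design.rng_seed)
    n = design.n_otus
    otu_ids = [f"OTU_{i + 1}" for i in range(n)]
    tree = simulate_tree(n, rng_seed=int(rng.integers(2**31)))
    trait = _brownian_trait(tree, rng).reindex(otu_ids)

    base_abund = rng.lognormal(*design.lognormal_abundance_params, size=n)

    # occupancy classes
    n_gen = int(round(design.generalist_fraction * n))
    classes = np.array(["generalist"] * n, dtype=object)
    spec_idx = rng.choice(n, size=n - n_gen, replace=False)
    w_org, w_host = design.specialist_kind_weights
    total_w = (w_org + w_host) or 1.0
    kinds = rng.choice(
        ["organ_specialist", "host_specialist"],
        size=n - n_gen,
        p=[w_org / total_w, w_host / total_w],
    )
    classes[spec_idx] = kinds
    preferred = np.array([""] * n, dtype=object)
    for i in spec_idx:
        if classes[i] == "organ_specialist":
            preferred[i] = rng.choice(["leaf", "flower"])
        else:
            preferred[i] = rng.choice(list(design.hosts))

    cells = list(dict.fromkeys((h, o) for h, o, _, _ in _design_cells(design)))
    trait_vals = trait.to_numpy()

    def cell_logit(host: str, organ: str) -> np.ndarray:
        eta = np.full(n, design.incl_base_logit, dtype=float)
        is_org = classes == "organ_specialist"
        off_organ = is_org & (preferred != organ)
        eta[off_organ] -= design.organ_effect_logit
        is_host = classes == "host_specialist"
        off_host = is_host & (preferred != host)
        eta[off_host] -= design.host_effect_logit
        if organ == "flower":
            eta = eta + design.conservatism_strength * trait_vals
        return eta

    prevalence_logit = pd.DataFrame(
        {f"{h}|{o}": cell_logit(h, o) for h, o in cells}, index=otu_ids
    ).T

    all_cells = list(_design_cells(design))
    time_points = sorted({tp for _, _, _, tp in all_cells})
    time_shift = dict(
        zip(time_points, rng.normal(0.0, design.time_effect_sd, len(time_points)))
    )

    rows, meta_rows, sample_ids = [], [], []
    idx = 0
    for host, organ, series, tp in all_cells:
        eta_cell = cell_logit(host, organ)
        for _ in range(design.samples_per_cell):
            idx += 1
            sid = f"S{idx:03d}"
            depth = int(rng.integers(design.depth_range[0], design.depth_range[1] + 1))
            eta = eta_cell + time_shift[tp]
            incl = rng.random(n) < expit(eta)
            shift = eta - design.incl_base_logit - time_shift[tp]
            w = base_abund * np.exp(shift) * incl
            if w.sum() <= 0:  # pathological designs: keep the sample valid
                w = base_abund.copy()
            counts = rng.multinomial(depth, w / w.sum())
            rows.append(counts)
            sample_ids.append(sid)
            meta_rows.append(
                dict(host=host, organ=organ, time_point=tp, time_series=series,
                     control="none", pooled=host in design.pooled_hosts)
            )
    table = CountTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=otu_ids)
    )
    meta = SampleMeta(pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id")))
    truth = GroundTruth(
        occupancy_class=pd.Series(classes, index=otu_ids),
        preferred=pd.Series(preferred, index=otu_ids),
        trait=trait,
        prevalence_logit=prevalence_logit,
        tree=tree,
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# Control samples
# ---------------------------------------------------------------------------


def simulate_controls(
    table: CountTable,
    mock_members: int = 8,
    false_positive_reads: tuple[int, ...] = (63, 34, 1),
    negative_totals: tuple[int, ...] = (19, 20),
    mock_member_reads: int = 5000,
    rng_seed: int = 0,
) -> tuple[CountTable, SampleMeta, list[str]]:
    """Append a mock-community sample and near-empty negative controls.

    The mock sample holds ``mock_members`` declared members (dedicated
    ``MOCK_*`` columns) at high equal counts, plus one alien community OTU
    per entry of ``false_positive_reads`` — low-level false positives such
    as index hopping produces.  Negative controls spread their few reads
    over a handful of community OTUs.

    Returns the augmented table, metadata for the control samples only, and
    the declared-member id list.
    """
    fp = list(false_positive_reads)
    if fp != sorted(fp, reverse=True):
        raise ValueError("false_positive_reads must be sorted descending")
    rng = np.random.default_rng(rng_seed)
    declared = [f"MOCK_{i + 1}" for i in range(mock_members)]
    otus = table.otu_ids
    df = table.data.copy()
    for m in declared:
        df[m] = 0

    mock_id, neg_ids = "CTRL_MOCK", [f"CTRL_NEG{i + 1}" for i in range(len(negative_totals))]
    mock_row = pd.Series(0, index=df.columns, dtype=np.int64)
    mock_row[declared] = mock_member_reads
    aliens = rng.choice(otus, size=len(fp), replace=False)
    for otu, reads in zip(aliens, fp):
        mock_row[otu] = reads
    df.loc[mock_id] = mock_row

    for neg_id, total in zip(neg_ids, negative_totals):
        row = pd.Series(0, index=df.columns, dtype=np.int64)
        carriers = rng.choice(otus, size=min(6, len(otus)), replace=False)
        row[carriers] = rng.multinomial(total, np.full(len(carriers), 1 / len(carriers)))
        df.loc[neg_id] = row

    ctrl_ids = [mock_id] + neg_ids
    meta = SampleMeta(
        pd.DataFrame(
            dict(
                host=NOT_APPLICABLE, organ=NOT_APPLICABLE, time_point=0,
                time_series=1,
                control=["mock"] + ["negative"] * len(neg_ids), pooled=False,
            ),
            index=pd.Index(ctrl_ids, name="sample_id"),
        )
    )
    return CountTable(df), meta, declared


# ---------------------------------------------------------------------------
# Community presence matrices for phylogenetic null-model checks
# ---------------------------------------------------------------------------


def random_communities(
    tip_ids: list[str],
    n_communities: int,
    richness_range: tuple[int, int] = (5, 40),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Presence matrix of communities drawn uniformly at random from tips."""
    rng = np.random.default_rng(rng_seed)
    mat = np.zeros((n_communities, len(tip_ids)), dtype=bool)
    for i in range(n_communities):
        k = int(rng.integers(richness_range[0], richness_range[1] + 1))
        mat[i, rng.choice(len(tip_ids), size=k, replace=False)] = True
    return pd.DataFrame(
        mat, index=[f"C{i + 1}" for i in range(n_communities)], columns=tip_ids
    )


def clade_communities(
    tree: dendropy.Tree,
    n_communities: int,
    richness: int = 12,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Communities of closely related tips: each drawn from one small clade.

    For every community a random internal clade with at least ``richness``
    tips (preferring the smallest admissible clades) supplies all members —
    the strongest form of phylogenetic clustering the tree allows.
    """
    rng = np.random.default_rng(rng_seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    tip_index = {t: i for i, t in enumerate(tips)}
    clades = []
    for node in tree.preorder_internal_node_iter():
        below = [leaf.taxon.label for leaf in node.leaf_iter()]
        if richness <= len(below) <= max(3 * richness, richness + 2):
            clades.append(below)
    if not clades:
        raise ValueError("no clade large enough for the requested richness")
    mat = np.zeros((n_communities, len(tips)), dtype=bool)
    for i in range(n_communities):
        clade = clades[int(rng.integers(len(clades)))]
        chosen = rng.choice(len(clade), size=richness, replace=False)
        for j in chosen:
            mat[i, tip_index[clade[j]]] = True
    return pd.DataFrame(
        mat, index=[f"C{i + 1}" for i in range(n_communities)], columns=tips
    )
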