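"""Faith's phylogenetic diversity and a tip-label randomization null model.

Faith's PD of a community is the total branch length of the minimal
subtree spanning its tips.  With ``include_root=True`` (the default,
matching the usual community-phylogenetics convention) the path from the
spanning subtree to the root is counted as well.

The null model keeps the tree's topology and branch lengths fixed and
permutes the tip labels uniformly; each community's PD is recomputed under
every permutation, giving per-sample lower/upper-tail p-values and the
standardized effect size SES = (PD_obs - mean_null) / sd_null.  Negative
SES with a small lower-tail p is phylogenetic clustering: community
members more closely related than chance.  One shared permutation per
replicate is applied to all communities (the randomized object is the
tree, so co-occurrence structure is preserved); ``per_community=True``
switches to independent permutations per community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("phyllocom")


def _edge_arrays(tree: dendropy.Tree):
    """Tip order, edge x tip membership matrix, and edge lengths.

    Row e of the membership matrix marks the tips below edge e (the edge
    above each non-root node); the edge's length contributes to a
    community's PD when at least one community tip lies below it.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    tip_index = {t: i for i, t in enumerate(tips)}
    edges = []
    lengths = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = np.zeros(len(tips), dtype=bool)
        for leaf in node.leaf_iter():
            below[tip_index[leaf.taxon.label]] = True
        edges.append(below)
        lengths.append(node.edge.length or 0.0)
    return tips, np.array(edges), np.array(lengths, dtype=float)


def _community_indices(tips: list[str], community) -> np.ndarray:
    idx = []
    tip_index = {t: i for i, t in enumerate(tips)}
    for label in community:
        if label not in tip_index:
            raise KeyError(f"community member {label!r} is not a tree tip")
    return np.array([tip_index[label] for label in community], dtype=int)


def faith_pd(
    tree: dendropy.Tree, community, include_root: bool = True
) -> float:
    """Faith's PD of a set of tip labels.

    With ``include_root`` every edge with a community tip below it counts;
    without it, edges on the root-to-MRCA path (those with *all* community
    tips below, or none) are excluded, leaving the unrooted spanning
    subtree.
    """
    community = list(community)
    if not community:
        raise ValueError("community must be non-empty")
    tips, M, L = _edge_arrays(tree)
    idx = _community_indices(tips, community)
    n_below = M[:, idx].sum(axis=1)
    if include_root:
        mask = n_below > 0
    else:
        mask = (n_below > 0) & (n_below < len(idx))
    return float(L[mask].sum())


def pd_bruteforce_oracle(
    tree: dendropy.Tree, community, include_root: bool = True
) -> float:
    """Independent PD computation by explicit edge bipartitions.

    For every edge the tree is split into the tip set below and the tip set
    above (the latter containing the root); the edge lies on the spanning
    subtree exactly when both sides intersect the community — with the root
    counted as a community member when ``include_root``.  Restricted to
    trees of <= 32 tips; exists as a test oracle for :func:`faith_pd`.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) > 32:
        raise ValueError("brute-force oracle restricted to trees of <= 32 tips")
    community = set(community)
    if not community:
        raise ValueError("community must be non-empty")
    unknown = community - set(tips)
    if unknown:
        raise KeyError(f"community members not in tree: {sorted(unknown)}")
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        above = set(tips) - below
        below_hit = bool(below & community)
        above_hit = bool(above & community) or include_root
        if below_hit and above_hit:
            total += node.edge.length or 0.0
    return total


@dataclass
class PDNullResult:
    frame: pd.DataFrame  # per community: pd_obs, null_mean, null_sd, ses, p_low, p_high
    n_reps: int
    rng_seed: int
    per_community: bool

    def mean_ses(self) -> float:
        return float(self.frame["ses"].mean())

    def max_p_low(self) -> float:
        return float(self.frame["p_low"].max())


def pd_null(
    tree: dendropy.Tree,
    communities: pd.DataFrame,
    n_reps: int = 1000,
    rng_seed: int = 0,
    include_root: bool = True,
    per_community: bool = False,
) -> PDNullResult:
    """Tip-swap null distribution of Faith's PD for many communities.

    ``communities`` is a boolean presence matrix (communities x tip labels;
    its columns must be tree tips).  Both tail p-values include the
    observed value in the count, so min attainable p is 1/(n_reps+1).  A
    community spanning every tip has a degenerate null (sd = 0): its SES is
    undefined and reported NaN with a warning.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tips, M, L = _edge_arrays(tree)
    extra = [c for c in communities.columns if c not in set(tips)]
    if extra:
        raise KeyError(f"community columns not in tree: {extra[:5]}")
    P = communities.reindex(columns=tips, fill_value=False).to_numpy().astype(bool)
    richness = P.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("empty community in presence matrix")
    Mf = M.T.astype(float)  # tips x edges

    def pd_of(presence: np.ndarray) -> np.ndarray:
        counts = presence.astype(float) @ Mf  # communities x edges
        if include_root:
            mask = counts > 0
        else:
            mask = (counts > 0) & (counts < richness[:, None])
        return mask @ L

    pd_obs = pd_of(P)
    rng = np.random.default_rng(rng_seed)
    null = np.empty((n_reps, P.shape[0]))
    n_tips = len(tips)
    for r in range(n_reps):
        if per_community:
            perm = np.argsort(rng.random((P.shape[0], n_tips)), axis=1)
            Pp = np.take_along_axis(P, perm, axis=1)
        else:
            Pp = P[:, rng.permutation(n_tips)]
        null[r] = pd_of(Pp)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(null_sd > 0, (pd_obs - null_mean) / null_sd, np.nan)
    if (null_sd == 0).any():
        logger.warning(
            "pd_null: %d communities have a degenerate null (sd = 0); SES undefined",
            int((null_sd == 0).sum()),
        )
    p_low = ((null <= pd_obs[None, :]).sum(axis=0) + 1.0) / (n_reps + 1.0)
    p_high = ((null >= pd_obs[None, :]).sum(axis=0) + 1.0) / (n_reps + 1.0)
    frame = pd.DataFrame(
        dict(
            pd_obs=pd_obs, null_mean=null_mean, null_sd=null_sd, ses=ses,
            p_low=p_low, p_high=p_high, richness=richness,
        ),
        index=pd.Index(communities.index, name="sample_id"),
    )
    return PDNullResult(
        frame=frame, n_reps=n_reps, rng_seed=rng_seed, per_community=per_community
    )
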