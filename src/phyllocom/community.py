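"""Bray-Curtis dissimilarity and sequential multi-term PERMANOVA.

The PERMANOVA follows the distance-based linear-model construction: the
squared-distance matrix is Gower-centred into an inner-product matrix G
whose trace is the total sum of squares, and each term of the (ordered)
model contributes the increase in tr(H G) when its dummy columns join the
cumulative hat matrix H.  Sums of squares are therefore sequential
(order-of-entry, Type I), matching the convention of the variance splits
this pipeline reports.  Significance comes from free permutation of sample
labels (optionally restricted within strata), recomputing every term's
pseudo-F, with p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import CountTable, SampleMeta
from .rarefaction import RarefiedTable

logger = logging.getLogger("phyllocom")


class ConfoundedTermsError(ValueError):
    """Two model terms are linearly confounded (rank-deficient design)."""


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if d.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        if d.max() > 1 + 1e-12:
            # Bray-Curtis lives in [0, 1]; other metrics are allowed through
            logger.info("distance matrix exceeds 1: not a Bray-Curtis matrix")
        self.values = d


def braycurtis(table: RarefiedTable | CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  Expects uniform row
    sums (rarefied input); warns otherwise, and rejects all-zero samples.
    """
    ct = table.table if isinstance(table, RarefiedTable) else table
    counts = ct.counts.astype(float)
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        bad = np.asarray(ct.sample_ids)[sums == 0]
        raise ValueError(f"samples with zero total reads: {list(bad)}")
    if not np.allclose(sums, sums[0]):
        logger.warning("braycurtis: row sums are not uniform; rarefy first")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(sample_ids=ct.sample_ids, values=d)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, ss, r2, pseudo_F, pvalue (+ residual/total)
    total_ss: float
    n_permutations: int
    rng_seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[self.table["term"] == term, "r2"].iloc[0])


def _dummy_columns(labels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy block for one factor (first level dropped)."""
    dummies = pd.get_dummies(labels.astype("category"), drop_first=True, dtype=float)
    return dummies.to_numpy()


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def permanova(
    d: DistanceMatrix,
    meta: SampleMeta,
    formula_terms: list[str],
    n_permutations: int = 1000,
    rng_seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    ``formula_terms`` name metadata columns entered in order; ``strata``
    optionally names a column within whose levels permutations are
    restricted.  The Gower identity tr(G) = (1/n) sum_{i<j} d_ij^2 is
    asserted on every run.
    """
    ids = d.sample_ids
    mf = meta.loc(ids)
    n = len(ids)
    G = _gower_center(d.values)
    total_ss = float(np.trace(G))
    gower_check = float((d.values[np.triu_indices(n, 1)] ** 2).sum() / n)
    assert np.isclose(total_ss, gower_check, rtol=1e-8, atol=1e-10), "Gower identity violated"

    # cumulative hat matrices: intercept, then each term's dummy block
    X = np.ones((n, 1))
    hats = []
    dfs = []
    prev_rank = 1
    for term in formula_terms:
        if term not in mf.columns:
            raise KeyError(f"unknown metadata column: {term}")
        block = _dummy_columns(mf[term])
        X = np.column_stack([X, block])
        rank = np.linalg.matrix_rank(X)
        added = rank - prev_rank
        if added < block.shape[1]:
            raise ConfoundedTermsError(
                f"term {term!r} is confounded with preceding terms "
                f"({', '.join(formula_terms[: formula_terms.index(term)]) or 'intercept'})"
            )
        q, _ = np.linalg.qr(X)
        hats.append(q[:, :rank] @ q[:, :rank].T)
        dfs.append(added)
        prev_rank = rank
    df_resid = n - prev_rank
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    hat0 = np.full((n, n), 1.0 / n)  # intercept-only projection

    def term_stats(Gmat: np.ndarray):
        traces = [float((h * Gmat).sum()) for h in hats]
        prev = float((hat0 * Gmat).sum())
        ss = []
        for t in traces:
            ss.append(t - prev)
            prev = t
        ss_resid = float(np.trace(Gmat)) - traces[-1]
        f = np.array(
            [(s / df) / (ss_resid / df_resid) for s, df in zip(ss, dfs)]
        )
        return np.array(ss), ss_resid, f

    ss_obs, ss_resid_obs, f_obs = term_stats(G)

    rng = np.random.default_rng(rng_seed)
    if strata is not None:
        strata_labels = mf[strata].to_numpy()
        groups = [np.flatnonzero(strata_labels == g) for g in np.unique(strata_labels)]

        def draw_perm():
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            return perm

    else:

        def draw_perm():
            return rng.permutation(n)

    exceed = np.zeros(len(formula_terms))
    # ties count as exceedances (conservative); the tolerance keeps exact
    # ties from being split by floating-point noise in the projections
    f_tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))
    for _ in range(n_permutations):
        perm = draw_perm()
        Gp = G[np.ix_(perm, perm)]
        _, _, f_perm = term_stats(Gp)
        exceed += f_perm >= f_obs - f_tol
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    rows = [
        dict(term=t, df=df, ss=s, r2=s / total_ss, pseudo_F=f, pvalue=p)
        for t, df, s, f, p in zip(formula_terms, dfs, ss_obs, f_obs, pvals)
    ]
    rows.append(
        dict(term="Residual", df=df_resid, ss=ss_resid_obs,
             r2=ss_resid_obs / total_ss, pseudo_F=np.nan, pvalue=np.nan)
    )
    rows.append(
        dict(term="Total", df=n - 1, ss=total_ss, r2=1.0,
             pseudo_F=np.nan, pvalue=np.nan)
    )
    out = pd.DataFrame(rows)
    assert np.isclose(out.loc[out["term"] != "Total", "r2"].sum(), 1.0, atol=1e-8)
    return PermanovaResult(
        table=out, total_ss=total_ss, n_permutations=n_permutations, rng_seed=rng_seed
    )
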