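"""Rarefaction engine and alpha-diversity statistics with mixed-model tests.

Rarefaction draws, for every sample, a uniform subsample of ``depth`` reads
without replacement (a multivariate hypergeometric draw).  One seeded draw
is taken per (sample, depth) — the reference workflow rarefies once, not an
average — but ``n_draws`` in :func:`detection_frequency` supports the
repeated-draw checks of the hypergeometric detection probability.

``draw_mode="nested"`` derives every sample's subsample from a single
seeded shuffle of its reads, so the depth-d subsample is contained in the
depth-d' subsample for d <= d'; this makes depth-monotonicity of detection
exactly testable.  Per-sample substreams are keyed on a CRC of the sample
id, so draws do not depend on sample order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datamodel import CountTable, SampleMeta
from .glmm import fit_glmm

logger = logging.getLogger("phyllocom")


@dataclass
class RarefiedTable:
    """A count table whose every row sums to exactly ``depth``."""

    table: CountTable
    depth: int
    rng_seed: int
    draw_mode: str

    @property
    def data(self) -> pd.DataFrame:
        return self.table.data

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids


def _sample_rng(rng_seed: int, sample_id: str) -> np.random.Generator:
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence([rng_seed, key]))


def rarefy(
    table: CountTable,
    depth: int,
    rng_seed: int = 0,
    draw_mode: str = "independent",
) -> RarefiedTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if draw_mode not in ("independent", "nested"):
        raise ValueError(f"unknown draw_mode: {draw_mode}")
    sizes = table.library_sizes()
    shallow = list(sizes.index[sizes < depth])
    if shallow:
        logger.warning("rarefy: dropped %d samples below depth %d", len(shallow), depth)
    kept = table.drop_samples(shallow)
    if kept.n_samples == 0:
        raise ValueError("no sample reaches the rarefaction depth")
    out = np.empty_like(kept.counts)
    for i, sid in enumerate(kept.sample_ids):
        row = kept.counts[i]
        rng = _sample_rng(rng_seed, sid)
        if row.sum() == depth:
            out[i] = row
        elif draw_mode == "independent":
            out[i] = rng.multivariate_hypergeometric(row, depth)
        else:  # nested: one shuffle, take the prefix
            reads = np.repeat(np.arange(kept.n_otus), row)
            rng.shuffle(reads)
            out[i] = np.bincount(reads[:depth], minlength=kept.n_otus)
    rarefied = CountTable(
        pd.DataFrame(out, index=kept.sample_ids, columns=kept.otu_ids)
    )
    return RarefiedTable(rarefied, depth=depth, rng_seed=rng_seed, draw_mode=draw_mode)


def detection_frequency(
    counts: np.ndarray, depth: int, otu_index: int, n_draws: int, rng_seed: int = 0
) -> float:
    """Fraction of repeated rarefaction draws detecting one OTU in a sample."""
    rng = np.random.default_rng(rng_seed)
    hits = 0
    counts = np.asarray(counts, dtype=np.int64)
    for _ in range(n_draws):
        hits += rng.multivariate_hypergeometric(counts, depth)[otu_index] > 0
    return hits / n_draws


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(rarefied: RarefiedTable) -> pd.DataFrame:
    """Richness S, Shannon entropy H (natural log) and Pielou evenness J.

    J = H / ln S is undefined (NaN) for samples with S <= 1.
    """
    counts = rarefied.table.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    p = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    s = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(s > 1, h / np.log(np.maximum(s, 2)), np.nan)
    return pd.DataFrame(
        {"richness": s, "shannon": h, "pielou": j},
        index=pd.Index(rarefied.sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Mixed-model comparisons
# ---------------------------------------------------------------------------


@dataclass
class DiversityModelResult:
    response: str
    family: str
    fixed_effects: pd.DataFrame  # estimate / se / pvalue per term
    random_structure: str
    converged: bool
    message: str = ""


def compare_diversity(
    records: pd.DataFrame,
    meta: SampleMeta,
    response: str,
    grouping_factor: str,
) -> DiversityModelResult:
    """Test a diversity response against organ or host with time as random.

    Richness is fitted with a Poisson GLMM (log link, random time-point
    intercept); evenness with a linear mixed model that first attempts a
    random slope of the factor over time points and falls back to a random
    intercept when that fit does not converge.  Host comparisons exclude
    pooled samples, whose diversity is not comparable across hosts.
    """
    if response not in ("richness", "evenness"):
        raise ValueError("response must be 'richness' or 'evenness'")
    if grouping_factor not in ("organ", "host"):
        raise ValueError("grouping_factor must be 'organ' or 'host'")
    col = "richness" if response == "richness" else "pielou"
    df = records.join(meta.df, how="inner")
    df = df[df["control"] == "none"]
    if grouping_factor == "host":
        df = df[~df["pooled"]]
    df = df.dropna(subset=[col])
    levels = sorted(df[grouping_factor].unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels of {grouping_factor}, got {levels}")

    if response == "richness":
        dummies = pd.get_dummies(df[grouping_factor], drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(df)), dummies.to_numpy()])
        names = ["Intercept"] + [f"{grouping_factor}[{c}]" for c in dummies.columns]
        res = fit_glmm(
            df[col].to_numpy(float), X, df["time_point"].to_numpy(),
            family="poisson", exog_names=names,
        )
        fixed = pd.DataFrame(
            {"estimate": res.params, "se": res.se, "pvalue": res.pvalues}
        )
        return DiversityModelResult(
            response=response, family="poisson-GLMM", fixed_effects=fixed,
            random_structure="time_point random intercept",
            converged=res.converged, message=res.message,
        )

    # evenness: linear mixed model via statsmodels
    data = df.rename(columns={col: "y"})
    formula = f"y ~ C({grouping_factor})"
    for re_formula, label in (
        (f"~C({grouping_factor})", "time_point random intercept + factor slope"),
        (None, "time_point random intercept"),
    ):
        try:
            model = smf.mixedlm(formula, data, groups=data["time_point"],
                                re_formula=re_formula)
            fit = model.fit(reml=True, method="lbfgs")
            if not fit.converged:
                raise RuntimeError("LMM did not converge")
            fe = fit.fe_params
            fixed = pd.DataFrame(
                {
                    "estimate": fe,
                    "se": fit.bse_fe.reindex(fe.index),
                    "pvalue": fit.pvalues.reindex(fe.index),
                }
            )
            return DiversityModelResult(
                response=response, family="linear-MM", fixed_effects=fixed,
                random_structure=label, converged=True,
            )
        except Exception as exc:  # fall back to the simpler random structure
            last_error = str(exc)
            logger.warning("evenness LMM (%s) failed: %s", label, exc)
    return DiversityModelResult(
        response=response, family="linear-MM",
        fixed_effects=pd.DataFrame(columns=["estimate", "se", "pvalue"]),
        random_structure="none", converged=False, message=last_error,
    )
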