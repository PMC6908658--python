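"""Per-OTU prevalence modelling with binomial mixed models.

Prevalence here is detection: for each OTU, each sample contributes a
binary outcome (>= 1 read in unrarefied data).  Because detection rises
with sequencing effort, every model carries the centred and rescaled
library size as a fixed covariate, and a random intercept for the time of
collection absorbs temporal dependence.  Three model families are fitted:

* ``joint`` — host species, organ, their interaction and depth, on the
  first collection series only (the second series lacks flowers of one
  host, which would unbalance the random effect);
* ``per_host`` — organ + depth (+ series when both are present), within one
  host species;
* ``per_organ`` — host species + depth (+ series), within one organ,
  excluding pooled hosts.

Per-effect Wald p-values are Bonferroni-corrected across the converged
models of a family (the correction count m is the converged-model count;
sensitivity to no correction is reported by the aggregation step).  OTUs
whose fits fail — including quasi-separation, which saturated detection
patterns produce routinely — form their own reported category rather than
an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMeta
from .glmm import GLMMResult, fit_glmm

logger = logging.getLogger("phyllocom")

CONSERVED = "conserved"
NOT_CONVERGED = "not-converged"


@dataclass
class PrevalenceModelSpec:
    """One model family, optionally pinned to a host or organ level."""

    family: str  # joint | per_host | per_organ
    level: str | None = None  # host name for per_host, organ for per_organ
    data_per_parameter_floor: float = 17.0
    modeled_hosts: tuple[str, ...] | None = None  # default: non-pooled hosts

    def label(self) -> str:
        return self.family if self.level is None else f"{self.family}:{self.level}"


@dataclass
class PrevalenceResult:
    otu_id: str
    family: str
    params: pd.Series | None
    pvalues: pd.Series | None
    converged: bool
    reason: str = ""
    classification: str | None = None
    alpha_corrected: float | None = None


@dataclass
class PrevalenceAggregate:
    family_proportions: dict[str, dict[str, float]]
    family_convergence: dict[str, float]
    #: conserved proportion with converged models as denominator — the
    #: estimator of a design's generalist fraction (failed fits carry no
    #: prevalence information)
    family_conserved_among_converged: dict[str, float]
    global_conserved_fraction: float
    global_breakdown: dict[str, float]
    global_conserved_fraction_uncorrected: float
    n_otus_total: int


# ---------------------------------------------------------------------------
# Response construction
# ---------------------------------------------------------------------------


def detection_response(
    table: CountTable, otu_id: str, sample_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary detection outcome and standardized depth covariate.

    Depth is centred and rescaled by the population standard deviation over
    the model's data scope; a zero-variance depth yields an all-zero
    covariate with a warning.
    """
    if otu_id not in table.otu_ids:
        raise KeyError(f"unknown OTU: {otu_id}")
    sub = table.data if sample_ids is None else table.data.loc[sample_ids]
    y = (sub[otu_id] >= 1).to_numpy(dtype=float)
    depth = sub.sum(axis=1).to_numpy(dtype=float)
    sd = depth.std()  # population convention (ddof=0)
    if sd == 0:
        logger.warning("detection_response: zero-variance depth; covariate set to 0")
        return y, np.zeros_like(depth)
    return y, (depth - depth.mean()) / sd


def _scope(meta: SampleMeta, spec: PrevalenceModelSpec) -> pd.DataFrame:
    bio = meta.biological()
    hosts = spec.modeled_hosts or tuple(meta.hosts(include_pooled=False))
    if spec.family == "joint":
        return bio[
            bio["host"].isin(hosts) & (bio["time_series"] == 1)
        ]
    if spec.family == "per_host":
        return bio[bio["host"] == spec.level]
    if spec.family == "per_organ":
        return bio[(bio["organ"] == spec.level) & bio["host"].isin(hosts)]
    raise ValueError(f"unknown family: {spec.family}")


def _design(mf: pd.DataFrame, depth_std: np.ndarray, spec: PrevalenceModelSpec):
    cols = [np.ones(len(mf))]
    names = ["Intercept"]

    def add_factor(col: str, prefix: str):
        dummies = pd.get_dummies(mf[col].astype("category"), drop_first=True, dtype=float)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy())
            names.append(f"{prefix}[{level}]")
        return dummies

    if spec.family == "joint":
        h = add_factor("host", "host")
        o = add_factor("organ", "organ")
        for hl in h.columns:
            for ol in o.columns:
                cols.append((h[hl] * o[ol]).to_numpy())
                names.append(f"host[{hl}]:organ[{ol}]")
    elif spec.family == "per_host":
        add_factor("organ", "organ")
    else:
        add_factor("host", "host")
    cols.append(depth_std)
    names.append("depth_std")
    if spec.family in ("per_host", "per_organ") and mf["time_series"].nunique() > 1:
        add_factor("time_series", "series")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_prevalence_glmm(
    table: CountTable,
    meta: SampleMeta,
    otu_id: str,
    spec: PrevalenceModelSpec,
) -> PrevalenceResult:
    """Fit one OTU's detection GLMM under a model family."""
    return fit_family(table, meta, spec, otu_ids=[otu_id])[0]


def fit_family(
    table: CountTable,
    meta: SampleMeta,
    spec: PrevalenceModelSpec,
    otu_ids: list[str] | None = None,
) -> list[PrevalenceResult]:
    """Fit a family of per-OTU detection GLMMs sharing one design matrix.

    OTUs never detected in the family's data scope are not tested; OTUs
    detected in every sample (or none) are reported as failed fits
    (complete separation of the intercept).  The whole family is skipped
    with reason ``insufficient data`` when the observation/parameter ratio
    falls below the configured floor.
    """
    mf = _scope(meta, spec)
    ids = [s for s in table.sample_ids if s in set(mf.index)]
    mf = mf.loc[ids]
    if len(ids) == 0:
        raise ValueError(f"no samples in scope for family {spec.label()}")
    sub = table.data.loc[ids]
    depth = sub.sum(axis=1).to_numpy(dtype=float)
    sd = depth.std()
    depth_std = (depth - depth.mean()) / sd if sd > 0 else np.zeros_like(depth)
    X, names = _design(mf, depth_std, spec)
    groups = mf["time_point"].to_numpy()
    n_params = X.shape[1] + 1  # + random-intercept standard deviation
    label = spec.label()

    if otu_ids is None:
        totals = sub.sum(axis=0)
        otu_ids = list(totals.index[totals > 0])

    if len(ids) / n_params < spec.data_per_parameter_floor:
        logger.warning(
            "family %s skipped: %d obs / %d params below floor %.1f",
            label, len(ids), n_params, spec.data_per_parameter_floor,
        )
        return [
            PrevalenceResult(otu, label, None, None, False, reason="insufficient data")
            for otu in otu_ids
        ]

    results = []
    for otu in otu_ids:
        y = (sub[otu] >= 1).to_numpy(dtype=float)
        if y.sum() == 0:
            results.append(
                PrevalenceResult(otu, label, None, None, False,
                                 reason="never detected in scope")
            )
            continue
        res = fit_glmm(y, X, groups, family="binomial", exog_names=names)
        results.append(
            PrevalenceResult(
                otu, label,
                params=res.params if res.converged else None,
                pvalues=res.pvalues if res.converged else None,
                converged=res.converged, reason=res.message,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Classification and aggregation
# ---------------------------------------------------------------------------

_RELEVANT_PREFIXES = ("organ[", "host[")


def _classify_one(result: PrevalenceResult, alpha_corr: float) -> str:
    """Label one converged model by its significant main effects.

    A significant organ (host) dummy with positive sign marks prevalence on
    the dummy level; negative sign marks the reference level.  Interaction
    terms do not set the label on their own.
    """
    sig = []
    for name, p in result.pvalues.items():
        if ":" in name or not name.startswith(_RELEVANT_PREFIXES):
            continue
        if p < alpha_corr:
            sig.append((p, name))
    if not sig:
        return CONSERVED
    _, name = min(sig)
    kind = "organ" if name.startswith("organ[") else "host"
    level = name[name.index("[") + 1 : -1]
    sign = result.params[name]
    if sign > 0:
        return f"{kind}-prevalent({level})"
    other = "leaf" if (kind == "organ" and level == "flower") else (
        "flower" if kind == "organ" else "reference")
    return f"{kind}-prevalent({other})"


def classify_prevalence(
    results: list[PrevalenceResult],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[PrevalenceResult]:
    """Classify every OTU of one family as conserved / prevalent / failed.

    Bonferroni m = number of converged models in the family.
    """
    tested = [r for r in results if r.reason != "never detected in scope"]
    m = sum(r.converged for r in tested)
    if correction == "bonferroni":
        alpha_corr = alpha / m if m else alpha
    elif correction == "none":
        alpha_corr = alpha
    else:
        raise ValueError(f"unknown correction: {correction}")
    out = []
    for r in results:
        if not r.converged:
            out.append(replace(r, classification=NOT_CONVERGED,
                               alpha_corrected=alpha_corr))
        else:
            out.append(
                replace(r, classification=_classify_one(r, alpha_corr),
                        alpha_corrected=alpha_corr)
            )
    return out


def standard_families(
    meta: SampleMeta, floor: float = 17.0
) -> list[PrevalenceModelSpec]:
    """The joint family plus one per-host and one per-organ family per level."""
    hosts_all = meta.hosts(include_pooled=True)
    specs = [PrevalenceModelSpec("joint", data_per_parameter_floor=floor)]
    specs += [
        PrevalenceModelSpec("per_host", level=h, data_per_parameter_floor=floor)
        for h in hosts_all
    ]
    specs += [
        PrevalenceModelSpec("per_organ", level=o, data_per_parameter_floor=floor)
        for o in ("leaf", "flower")
    ]
    return specs


def aggregate_conserved(
    classified: dict[str, list[PrevalenceResult]],
    table: CountTable,
    meta: SampleMeta,
    alpha: float = 0.05,
) -> PrevalenceAggregate:
    """Pool family classifications into the global conserved fraction.

    An OTU is globally conserved when any converged model family finds it
    comparably prevalent in at least two host/organ combinations; OTUs with
    only significant-effect models are "prevalent-somewhere"; OTUs never
    tested or never converged form the "remaining" class (detected only
    outside the modelled hosts, or intractable fits).  The same aggregation
    at uncorrected alpha is reported as a robustness check.
    """
    bio_ids = [s for s in table.sample_ids if s in set(meta.biological().index)]
    totals = table.data.loc[bio_ids].sum(axis=0)
    all_otus = list(totals.index[totals > 0])

    family_proportions: dict[str, dict[str, float]] = {}
    family_convergence: dict[str, float] = {}
    family_conserved_among_converged: dict[str, float] = {}
    for fam, results in classified.items():
        tested = [r for r in results if r.reason != "never detected in scope"]
        if not tested:
            continue
        counts = pd.Series([r.classification for r in tested]).value_counts()
        family_proportions[fam] = (counts / len(tested)).to_dict()
        family_convergence[fam] = sum(r.converged for r in tested) / len(tested)
        n_conv = sum(r.converged for r in tested)
        family_conserved_among_converged[fam] = (
            sum(r.classification == CONSERVED for r in tested) / n_conv
            if n_conv else np.nan
        )

    def global_fraction(per_family: dict[str, list[PrevalenceResult]]):
        status: dict[str, str] = {}
        for fam, results in per_family.items():
            for r in results:
                if r.classification == CONSERVED:
                    status[r.otu_id] = CONSERVED
                elif r.converged and status.get(r.otu_id) != CONSERVED:
                    status[r.otu_id] = "prevalent-somewhere"
        breakdown = {CONSERVED: 0, "prevalent-somewhere": 0, "remaining": 0}
        for otu in all_otus:
            breakdown[status.get(otu, "remaining")] += 1
        n = len(all_otus)
        return (
            breakdown[CONSERVED] / n if n else np.nan,
            {k: v / n if n else np.nan for k, v in breakdown.items()},
        )

    conserved_frac, breakdown = global_fraction(classified)
    relaxed = {
        fam: classify_prevalence(results, alpha=alpha, correction="none")
        for fam, results in classified.items()
    }
    conserved_frac_unc, _ = global_fraction(relaxed)
    return PrevalenceAggregate(
        family_proportions=family_proportions,
        family_convergence=family_convergence,
        family_conserved_among_converged=family_conserved_among_converged,
        global_conserved_fraction=conserved_frac,
        global_breakdown=breakdown,
        global_conserved_fraction_uncorrected=conserved_frac_unc,
        n_otus_total=len(all_otus),
    )
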