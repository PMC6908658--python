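import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from phyllocom.datamodel import CountTable
from phyllocom.glmm import fit_glmm
from phyllocom.prevalence import (PrevalenceModelSpec, PrevalenceResult,
                                  aggregate_conserved, classify_prevalence,
                                  detection_response, fit_family,
                                  fit_prevalence_glmm)
from phyllocom.synthetic import SyntheticDesign, simulate_community

from conftest import make_meta


def table_of(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return CountTable(
        pd.DataFrame(rows, index=ids, columns=[f"o{j}" for j in range(rows.shape[1])])
    )


class TestDetectionResponse:
    def test_binary_outcomes(self):
        table = table_of([[0, 100], [1, 100], [50, 100]])
        y, _ = detection_response(table, "o0")
        assert y.tolist() == [0.0, 1.0, 1.0]

    def test_equal_depths_zero_covariate(self, caplog):
        table = table_of([[10, 90], [40, 60], [90, 10]])
        _, depth = detection_response(table, "o0")
        assert (depth == 0).all()

    def test_population_sd_standardization(self):
        table = table_of([[1000], [2000], [3000]])
        _, depth = detection_response(table, "o0")
        assert depth == pytest.approx([-np.sqrt(1.5), 0, np.sqrt(1.5)])
        # population-sd convention: sd([1000,2000,3000], ddof=0) = 1000*sqrt(2/3)
        assert depth.std() == pytest.approx(1.0)


class TestGlmmFitting:
    def test_glmm_matches_lme4(self, tmp_path):
        """Coefficients and random-intercept SD agree with R glmer (nAGQ=25)."""
        rng = np.random.default_rng(0)
        n, g = 120, np.repeat(np.arange(8), 15)
        b = rng.normal(0, 0.7, 8)[g]
        x = rng.normal(size=n)
        eta = -0.3 + 0.8 * x + b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_glmm(y, np.column_stack([np.ones(n), x]), g,
                       exog_names=["Intercept", "x"])
        assert res.converged

        data = tmp_path / "d.txt"
        np.savetxt(data, np.column_stack([y, x, g]))
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.table('{data}'); names(d) <- c('y','x','g')
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep='\\n')
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        if out.returncode != 0:
            pytest.fail(f"Rscript failed: {out.stderr[-500:]}")
        ref = [float(v) for v in out.stdout.split()]
        assert res.params["Intercept"] == pytest.approx(ref[0], abs=2e-3)
        assert res.params["x"] == pytest.approx(ref[1], abs=2e-3)
        assert res.sigma_re == pytest.approx(ref[2], abs=5e-3)

    def test_complete_separation_reported_not_raised(self):
        d = SyntheticDesign(n_otus=20, samples_per_cell=5, rng_seed=2)
        table, meta, _ = simulate_community(d)
        # force an always-detected OTU
        df = table.data.copy()
        df["o_sat"] = 1000
        table = CountTable(df)
        res = fit_prevalence_glmm(
            table, meta, "o_sat",
            PrevalenceModelSpec("per_host", level="R_acris",
                                data_per_parameter_floor=2),
        )
        assert not res.converged
        assert res.reason

    def test_never_detected_otu_not_tested(self):
        d = SyntheticDesign(n_otus=20, samples_per_cell=5, rng_seed=2)
        table, meta, _ = simulate_community(d)
        df = table.data.copy()
        df["o_zero"] = 0
        res = fit_prevalence_glmm(
            CountTable(df), meta, "o_zero",
            PrevalenceModelSpec("per_host", level="R_acris",
                                data_per_parameter_floor=2),
        )
        assert not res.converged
        assert res.reason == "never detected in scope"

    def test_data_per_parameter_floor(self):
        d = SyntheticDesign(n_otus=10, samples_per_cell=1,
                            time_points_per_series=(2,), missing_cells=(),
                            rng_seed=1)
        table, meta, _ = simulate_community(d)
        results = fit_family(table, meta,
                             PrevalenceModelSpec("joint",
                                                 data_per_parameter_floor=17))
        assert all(r.reason == "insufficient data" for r in results)


def _fake_result(otu, p_organ, coef=1.0, converged=True):
    if not converged:
        return PrevalenceResult(otu, "per_host:h", None, None, False,
                                reason="boundary")
    idx = ["Intercept", "organ[leaf]", "depth_std"]
    return PrevalenceResult(
        otu, "per_host:h",
        params=pd.Series([0.0, coef, 0.0], index=idx),
        pvalues=pd.Series([0.5, p_organ, 0.5], index=idx),
        converged=True,
    )


class TestClassification:
    def test_bonferroni_threshold_is_alpha_over_converged(self):
        results = [_fake_result(f"o{i}", 1.0) for i in range(100)]
        out = classify_prevalence(results, alpha=0.05)
        assert out[0].alpha_corrected == pytest.approx(5e-4)

    def test_all_p_one_all_conserved(self):
        out = classify_prevalence([_fake_result(f"o{i}", 1.0) for i in range(5)])
        assert all(r.classification == "conserved" for r in out)

    def test_sign_determines_prevalent_level(self):
        strong = [_fake_result("up", 1e-10, coef=2.0),
                  _fake_result("down", 1e-10, coef=-2.0)]
        out = classify_prevalence(strong, alpha=0.05)
        by_id = {r.otu_id: r.classification for r in out}
        assert by_id["up"] == "organ-prevalent(leaf)"
        assert by_id["down"] == "organ-prevalent(flower)"

    def test_bonferroni_never_less_conserved_than_uncorrected(self):
        rng = np.random.default_rng(4)
        results = [_fake_result(f"o{i}", p) for i, p in
                   enumerate(rng.uniform(0, 0.2, 50))]
        bonf = classify_prevalence(results, correction="bonferroni")
        none = classify_prevalence(results, correction="none")
        n_cons = sum(r.classification == "conserved" for r in bonf)
        n_cons_unc = sum(r.classification == "conserved" for r in none)
        assert n_cons >= n_cons_unc

    def test_classification_invariant_to_processing_order(self):
        results = [_fake_result(f"o{i}", p)
                   for i, p in enumerate([1e-9, 0.5, 0.2, 1e-6])]
        fwd = {r.otu_id: r.classification
               for r in classify_prevalence(results)}
        rev = {r.otu_id: r.classification
               for r in classify_prevalence(results[::-1])}
        assert fwd == rev


class TestAggregate:
    def _community(self):
        d = SyntheticDesign(n_otus=30, samples_per_cell=2,
                            time_points_per_series=(2,), missing_cells=(),
                            rng_seed=9)
        return simulate_community(d)

    def test_all_conserved_gives_fraction_one(self):
        table, meta, _ = self._community()
        otus = [o for o in table.otu_ids if table.data[o].sum() > 0]
        classified = {
            "per_host:h": classify_prevalence([_fake_result(o, 1.0) for o in otus]),
        }
        agg = aggregate_conserved(classified, table, meta)
        assert agg.global_conserved_fraction == pytest.approx(1.0)
        assert sum(agg.global_breakdown.values()) == pytest.approx(1.0)

    def test_family_proportions_sum_to_one(self):
        table, meta, _ = self._community()
        otus = [o for o in table.otu_ids if table.data[o].sum() > 0]
        mix = classify_prevalence(
            [_fake_result(o, 1e-9) if i % 3 == 0
             else _fake_result(o, 1.0, converged=(i % 5 != 0))
             for i, o in enumerate(otus)]
        )
        agg = aggregate_conserved({"per_host:h": mix}, table, meta)
        assert sum(agg.family_proportions["per_host:h"].values()) == pytest.approx(1.0)
        assert 0 < agg.family_convergence["per_host:h"] <= 1

    def test_conserved_under_correction_but_not_uncorrected(self):
        table, meta, _ = self._community()
        otus = [o for o in table.otu_ids if table.data[o].sum() > 0]
        # p = 0.01: conserved at bonferroni (0.05/m), prevalent uncorrected
        classified = {
            "per_host:h": classify_prevalence(
                [_fake_result(o, 0.01) for o in otus], correction="bonferroni"
            )
        }
        agg = aggregate_conserved(classified, table, meta)
        assert agg.global_conserved_fraction == pytest.approx(1.0)
        assert agg.global_conserved_fraction_uncorrected == pytest.approx(0.0)
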