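import json
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from mguard import inference
from mguard.inference import GuardingModel, MODEL_SPECS, build_ac_term, lrt, standardize, vif
from mguard.simulate import generate_model_table


def fit_quiet(table, spec, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return inference.fit_model(table, spec, **kw)


class TestStandardize:
    def test_three_point_column(self):
        assert standardize(pd.Series([1.0, 2.0, 3.0])) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_errors_with_name(self):
        with pytest.raises(ValueError, match="rainfall"):
            standardize(pd.Series([2.0, 2.0, 2.0], name="rainfall"))

    def test_output_moments(self, rng):
        z = standardize(rng.exponential(3, size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestAcTerm:
    def test_single_row_male_gets_zero(self):
        ac = build_ac_term(pd.Series(["2021-02-01"]), ["M1"], np.array([1.7]), 2.0)
        assert ac == pytest.approx([0.0])

    def test_single_neighbour_contributes_verbatim(self):
        """With one same-male neighbour the normalized weight is 1, so the
        AC value equals the neighbour's residual for any kernel width."""
        dates = pd.Series(["2021-02-01", "2021-02-02"])
        for sigma in (0.5, 2.0, 16.0):
            ac = build_ac_term(dates, ["M1", "M1"], np.array([0.3, -1.1]), sigma)
            assert ac == pytest.approx([-1.1, 0.3])

    def test_other_males_never_contribute(self):
        dates = pd.Series(["2021-02-01"] * 2 + ["2021-02-02"] * 2)
        ac = build_ac_term(dates, ["M1", "M2", "M1", "M2"], np.array([1.0, 9.0, 2.0, 9.0]), 1.0)
        assert ac[0] == pytest.approx(2.0)
        assert ac[2] == pytest.approx(1.0)

    def test_ac_term_raises_likelihood_under_ar1_residuals(self):
        """With AR(1) day-to-day residuals (rho = 0.6), adding the AC
        covariate raises the mixed-model log-likelihood in >= 95 % of
        replicates."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            t = generate_model_table(n_rows=300, rho=0.6, seed=rep + 1)
            model = GuardingModel(t, "feeding", ac_sigma_grid=(2.0,))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                with_ac = model.fit()
                without = inference._fit_mixedlm(model.table, "pct_feeding", ["mg_pct", "fruit_index", "rainfall_mm"])
            wins += with_ac.llf > without.llf
        assert wins >= 0.95 * n_rep


class TestLrt:
    def test_identical_models_give_zero(self):
        t = generate_model_table(n_rows=120, seed=4)
        res = fit_quiet(t, "feeding")
        same = lrt(res, res)
        assert same.chi2 == 0.0
        assert same.pvalue == 1.0

    def test_df_counts_dropped_terms(self):
        t = generate_model_table(n_rows=200, beta_mg=-1.0, seed=5)
        res = fit_quiet(t, "feeding")
        assert res.lrt_full_null.df == 1

    def test_chi2_equals_hand_computed_2dll(self):
        t = generate_model_table(n_rows=150, beta_mg=-1.0, seed=6)
        res = fit_quiet(t, "feeding")
        hand = 2.0 * (res.llf - res.null_result.llf)
        assert res.lrt_full_null.chi2 == pytest.approx(max(0.0, hand))

    def test_invariant_to_affine_predictor_rescaling(self):
        """Standardization makes the full-vs-null LRT invariant to affine
        rescaling of the raw predictors."""
        t = generate_model_table(n_rows=200, beta_mg=-0.8, seed=7)
        res_a = fit_quiet(t, "feeding", ac_sigma=2.0)
        t2 = t.copy()
        t2["mg_pct"] = t2["mg_pct"] * 12.5 + 40.0
        t2["fruit_index"] = -t2["fruit_index"] / 3.0
        res_b = fit_quiet(t2, "feeding", ac_sigma=2.0)
        assert res_a.lrt_full_null.chi2 == pytest.approx(res_b.lrt_full_null.chi2, rel=1e-4)


class TestVif:
    def test_orthogonal_predictors_are_one(self):
        n = 400
        t = pd.DataFrame(
            {
                "a": np.repeat([1.0, -1.0], n // 2),
                "b": np.tile([1.0, -1.0], n // 2),
            }
        )
        t["c"] = t["a"] * t["b"]
        v = vif(t, ["a", "b", "c"])
        assert v.to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_duplicated_predictor_flags_infinite(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        t["b"] = t["a"]
        v = vif(t, ["a", "b"])
        assert np.isinf(v).all()

    def test_correlation_08_gives_278(self):
        # exact construction: b = 0.8 a + sqrt(1-0.64) e with a, e orthonormal
        n = 1000
        a = np.sin(np.arange(n))
        e = np.cos(np.arange(n))
        a = (a - a.mean()) / a.std(ddof=0)
        e = e - e.mean()
        e -= a * (e @ a) / (a @ a)
        e /= e.std(ddof=0)
        b = 0.8 * a + np.sqrt(1 - 0.64) * e
        v = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert v["a"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)

    def test_needs_two_predictors(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


class TestModelSpecs:
    def test_battery_matches_study_structure(self):
        """Snapshot of the predefined battery: five daily behavioural
        responses tested against MG time with fruit + rainfall controls
        and an MG x fruit interaction, plus the two UCP models."""
        assert set(MODEL_SPECS) == {
            "feeding",
            "fruit_diet",
            "distance",
            "vertical",
            "restlessness",
            "ucp_mg",
            "ucp_rank",
        }
        for name in ("feeding", "fruit_diet", "distance", "vertical", "restlessness"):
            s = MODEL_SPECS[name]
            assert s.test_terms == ("mg_pct",)
            assert s.controls == ("fruit_index", "rainfall_mm")
            assert s.interaction == ("mg_pct", "fruit_index")
            assert s.use_ac_term
        ucp_mg = MODEL_SPECS["ucp_mg"]
        assert ucp_mg.test_terms == ("mg_pct",)
        assert set(ucp_mg.controls) == {
            "fruit_index",
            "rainfall_mm",
            "collection_time",
            "storage_months",
            "hourly_vertical_m",
            "pct_feeding",
        }
        ucp_rank = MODEL_SPECS["ucp_rank"]
        assert ucp_rank.test_terms == ("rank_class",)
        assert set(ucp_rank.controls) == {"fruit_index", "collection_time", "storage_months"}
        assert ucp_rank.categorical == ("rank_class",)

    def test_responses_unique_per_behavioural_model(self):
        responses = [MODEL_SPECS[n].response for n in MODEL_SPECS]
        assert len(set(responses)) == 6  # two UCP models share the UCP response


class TestFitting:
    def test_planted_effect_recovered_single_fit(self):
        t = generate_model_table(n_rows=580, beta_mg=-2.0, seed=17)
        res = fit_quiet(t, "feeding")
        assert res.fe_params["mg_pct"] == pytest.approx(-2.0, abs=0.25)
        assert res.lrt_full_null.pvalue < 1e-6

    def test_small_cluster_warning_always_emitted(self):
        t = generate_model_table(n_rows=120, seed=8)
        with pytest.warns(UserWarning, match="few clusters"):
            GuardingModel(t, "feeding", ac_sigma_grid=(2.0,)).fit()

    def test_missing_rows_dropped_and_counted(self):
        t = generate_model_table(n_rows=150, seed=9)
        t.loc[:9, "fruit_index"] = np.nan
        model = GuardingModel(t, "feeding")
        assert model.n_dropped == 10
        assert len(model.table) == 140

    def test_interaction_gate_reports_pvalue(self):
        t = generate_model_table(n_rows=200, beta_mg=-1.0, seed=10)
        p = GuardingModel(t, "feeding", ac_sigma_grid=(2.0,)).interaction_pvalue()
        assert 0.0 <= p <= 1.0

    def test_lme4_cross_check(self, tmp_path):
        """The ML fit agrees with lme4 (independent route) on the same
        table: log-likelihood and fixed effects to 4 significant digits."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        t = generate_model_table(n_rows=240, beta_mg=-1.2, seed=21)
        model = GuardingModel(t, "feeding")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = inference._fit_mixedlm(model.table, "pct_feeding", ["mg_pct", "fruit_index", "rainfall_mm"])
        csv = tmp_path / "table.csv"
        model.table.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            """
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            args <- commandArgs(trailingOnly=TRUE)
            d <- read.csv(args[1])
            m <- lmer(pct_feeding ~ mg_pct + fruit_index + rainfall_mm
                      + (1|group_id) + (1|male_id), data=d, REML=FALSE)
            cat(toJSON(list(llf=logLik(m)[1], fe=as.list(fixef(m))), digits=10, auto_unbox=TRUE))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript), str(csv)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        assert full.llf == pytest.approx(ref["llf"], abs=1e-3)
        for name in ("mg_pct", "fruit_index", "rainfall_mm"):
            assert full.fe_params[name] == pytest.approx(ref["fe"][name], abs=1e-4)

    def test_summary_mentions_key_quantities(self):
        t = generate_model_table(n_rows=150, beta_mg=-1.0, seed=11)
        res = fit_quiet(t, "feeding", ac_sigma=2.0)
        text = res.summary()
        assert "full vs null LRT" in text
        assert "mg_pct" in text
        assert "VIF" in text
        d = res.to_dict()
        assert set(d["lrt"]) == {"chi2", "df", "p"}
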