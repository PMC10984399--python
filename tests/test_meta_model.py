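import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from evofit.meta_model import (
    FitOptions,
    fit_known_variance_model,
    fit_meta_model,
    generation_regression,
    incidence_matrix,
    predicted_group_means,
    reml_objective,
)
from evofit.study_design import DesignError

LOG2PI = np.log(2 * np.pi)


def dense_neg2_reml(sig2, y, X, v, pop=None, block=None):
    """Independent dense-matrix evaluation of −2·restricted log-likelihood."""
    n, p = X.shape
    V = np.diag(np.asarray(v, float) + sig2[2])
    if pop is not None:
        Zp = incidence_matrix(pop)
        V = V + sig2[0] * Zp @ Zp.T
    if block is not None:
        Zb = incidence_matrix(block)
        V = V + sig2[1] * Zb @ Zb.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (
        (n - p) * LOG2PI
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


class TestRemlObjective:
    def test_matches_dense_oracle_small_instance(self, rng):
        # 6 observations in 2 blocks, 3 populations
        y = rng.normal(size=6)
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        v = rng.uniform(0.5, 1.5, size=6)
        pop = ["p1", "p1", "p2", "p2", "p3", "p3"]
        block = ["b1", "b2", "b1", "b2", "b1", "b2"]
        sig2 = np.array([0.3, 0.2, 0.4])
        ours = reml_objective(
            np.log(sig2), y, X, v, incidence_matrix(pop), incidence_matrix(block)
        )
        assert ours == pytest.approx(
            dense_neg2_reml(sig2, y, X, v, pop, block), abs=1e-8
        )

    def test_no_random_effects_closed_form(self, rng):
        # σ² → 0, equal v: restricted likelihood of plain GLS, evaluated densely
        y = rng.normal(size=8)
        X = np.ones((8, 1))
        v = np.full(8, 1.3)
        tiny = np.full(3, np.log(1e-12))
        ours = reml_objective(tiny, y, X, v, None, None)
        assert ours == pytest.approx(
            dense_neg2_reml(np.zeros(3), y, X, v), abs=1e-8
        )

    def test_observation_component_aliases_with_constant_v_shift(self, rng):
        # V depends on v and σ²_obs only through their sum on the diagonal
        y = rng.normal(size=10)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        v = rng.uniform(0.8, 1.2, size=10)
        a = reml_objective(np.log([1e-12, 1e-12, 0.5]), y, X, v, None, None)
        b = reml_objective(np.log([1e-12, 1e-12, 0.3]), y, X, v + 0.2, None, None)
        assert a == pytest.approx(b, abs=1e-10)

    def test_full_covariance_input(self, rng):
        y = rng.normal(size=6)
        X = np.ones((6, 1))
        v = rng.uniform(0.5, 1.5, size=6)
        diag_obj = reml_objective(np.log([1e-12, 1e-12, 0.2]), y, X, v, None, None)
        full_obj = reml_objective(
            np.log([1e-12, 1e-12, 0.2]), y, X, np.diag(v), None, None
        )
        assert full_obj == pytest.approx(diag_obj, abs=1e-10)


class TestFitKnownVarianceModel:
    def test_intercept_only_limit_is_arithmetic_mean(self, rng):
        # no covariates, no random effects, equal v: the weighted mean
        # degenerates to the arithmetic mean with SE sqrt(v/n)
        y = rng.normal(0.4, 1.0, size=12)
        v = np.full(12, 0.9)
        fit = fit_known_variance_model(
            y, np.ones((12, 1)), v,
            options=FitOptions(include_population=False, include_block=False,
                               include_observation=False),
        )
        assert fit.coefficients["estimate"].iloc[0] == pytest.approx(y.mean(), abs=1e-10)
        assert fit.coefficients["SE"].iloc[0] == pytest.approx(
            np.sqrt(0.9 / 12), abs=1e-10
        )

    def test_gls_matches_dense_brute_force(self, rng):
        # ≤10 observations: production solver vs explicit dense inverse
        n = 9
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        v = rng.uniform(0.5, 2.0, size=n)
        pop = list("aabbccdde")
        block = ["b1", "b2"] * 4 + ["b1"]
        fit = fit_known_variance_model(y, X, v, pop_ids=pop, block_ids=block)
        sig2 = np.array([
            fit.variance_components["population"]["sigma2"],
            fit.variance_components["block"]["sigma2"],
            fit.variance_components["observation"]["sigma2"],
        ])
        Zp, Zb = incidence_matrix(pop), incidence_matrix(block)
        V = np.diag(v + sig2[2]) + sig2[0] * Zp @ Zp.T + sig2[1] * Zb @ Zb.T
        Vi = np.linalg.inv(V)
        beta_dense = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(
            fit.coefficients["estimate"].to_numpy(), beta_dense, atol=1e-8
        )
        cov_dense = np.linalg.inv(X.T @ Vi @ X)
        np.testing.assert_allclose(fit.cov_beta, cov_dense, atol=1e-8)

    def test_rank_deficient_matrix_rejected(self, rng):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(DesignError, match="rank deficient"):
            fit_known_variance_model(rng.normal(size=6), X, np.ones(6))


class TestFitMetaModel:
    def test_fit_converges_on_simulated_data(self, effect_frame):
        fit = fit_meta_model(effect_frame)
        assert fit.convergence["converged"]
        assert len(fit.coefficients) == 13
        for comp in fit.variance_components.values():
            assert comp["sigma2"] >= 0.0
        assert fit.variance_components["population"]["levels"] == 35
        assert fit.variance_components["block"]["levels"] == 8
        assert fit.variance_components["observation"]["levels"] == 80

    def test_wald_columns_consistent(self, effect_frame):
        coef = fit_meta_model(effect_frame).coefficients
        np.testing.assert_allclose(coef["Z"], coef["estimate"] / coef["SE"])
        assert ((coef["CI_low"] < coef["estimate"])
                & (coef["estimate"] < coef["CI_high"])).all()

    def test_invariant_to_row_order_and_block_labels(self, effect_frame):
        base = fit_meta_model(effect_frame)
        shuffled = effect_frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabeled = shuffled.assign(
            block=shuffled["block"].map(lambda b: f"session_{b}")
        )
        alt = fit_meta_model(relabeled)
        np.testing.assert_allclose(
            base.coefficients["estimate"], alt.coefficients["estimate"], atol=1e-6
        )
        np.testing.assert_allclose(
            base.coefficients["SE"], alt.coefficients["SE"], atol=1e-6
        )

    def test_profile_refit_leaves_coefficients_fixed(self, effect_frame):
        from evofit.meta_model import _build_V, _gls

        fit = fit_meta_model(effect_frame)
        sig2 = np.array([
            fit.variance_components["population"]["sigma2"],
            fit.variance_components["block"]["sigma2"],
            fit.variance_components["observation"]["sigma2"],
        ])
        from evofit.study_design import build_design_matrix

        X, _ = build_design_matrix(effect_frame)
        Zp = incidence_matrix(effect_frame["population"].to_numpy())
        Zb = incidence_matrix(effect_frame["block"].to_numpy())
        V = _build_V(effect_frame["var_d"].to_numpy(float), sig2, Zp, Zb)
        beta, _ = _gls(effect_frame["d"].to_numpy(float), X, V)
        np.testing.assert_allclose(
            beta, fit.coefficients["estimate"].to_numpy(), atol=1e-10
        )

    def test_sampling_covariance_mode_runs(self, effect_frame):
        fit = fit_meta_model(effect_frame, FitOptions(use_sampling_covariance=True))
        assert fit.convergence["converged"]

    def test_matches_metafor_oracle(self, effect_frame, tmp_path):
        # independent cross-check against the reference mixed-model
        # meta-analysis implementation (rma.mv), same model specification
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the independent oracle")
        csv = tmp_path / "effects.csv"
        effect_frame.to_csv(csv, index=False)
        r_code = textwrap.dedent(f"""
        suppressMessages(library(metafor))
        df <- read.csv("{csv}")
        df$iso <- relevel(factor(df$isoline), ref = "6")
        df$temp <- factor(df$treatment, levels = c("control_20C", "elevated_24C"))
        df$rt <- factor(df$repro_type, levels = c("wt", "fog"))
        df$obs <- seq_len(nrow(df))
        m <- rma.mv(d, var_d, mods = ~ iso * temp * rt + generation,
                    random = list(~1 | population, ~1 | block, ~1 | obs),
                    data = df, method = "REML")
        cat(jsonlite::toJSON(list(b = as.vector(m$b), se = as.vector(m$se),
                                  labels = rownames(m$b)), digits = 12))
        """)
        res = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=600
        )
        assert res.returncode == 0, res.stderr[-1000:]
        oracle = json.loads(res.stdout)
        label_map = {
            "intrcpt": "Intercept",
            "iso8": "isoline 8",
            "iso9": "isoline 9",
            "tempelevated_24C": "temperature 24",
            "rtfog": "repr.type fog",
            "generation": "generation nr",
            "iso8:tempelevated_24C": "isoline 8 × temperature 24",
            "iso9:tempelevated_24C": "isoline 9 × temperature 24",
            "iso8:rtfog": "isoline 8 × repr.type fog",
            "iso9:rtfog": "isoline 9 × repr.type fog",
            "tempelevated_24C:rtfog": "temperature 24 × repr.type fog",
            "iso8:tempelevated_24C:rtfog": "isoline 8 × temperature 24 × repr.type fog",
            "iso9:tempelevated_24C:rtfog": "isoline 9 × temperature 24 × repr.type fog",
        }
        fit = fit_meta_model(effect_frame)
        coef = fit.coefficients.set_index("label")
        for rlab, b, se in zip(oracle["labels"], oracle["b"], oracle["se"]):
            ours = coef.loc[label_map[rlab]]
            assert ours["estimate"] == pytest.approx(b, abs=2e-3), rlab
            assert ours["SE"] == pytest.approx(se, rel=2e-3), rlab


class TestPredictedGroupMeans:
    def test_reference_cell_is_intercept_plus_generation(self, effect_frame):
        fit = fit_meta_model(effect_frame)
        preds = predicted_group_means(fit, at_generation=120.0)
        coef = fit.coefficients.set_index("label")["estimate"]
        ref = preds[
            (preds.isoline == "6") & (preds.repro_type == "wt")
            & (preds.treatment == "control_20C")
        ]
        assert ref["predicted"].iloc[0] == pytest.approx(
            coef["Intercept"] + 120.0 * coef["generation nr"], abs=1e-10
        )

    def test_cell_differences_reproduce_coefficient_sums(self, effect_frame):
        fit = fit_meta_model(effect_frame)
        preds = predicted_group_means(fit, at_generation=130.0).set_index(
            ["isoline", "repro_type", "treatment"]
        )
        coef = fit.coefficients.set_index("label")["estimate"]
        diff = (
            preds.loc[("9", "fog", "elevated_24C"), "predicted"]
            - preds.loc[("6", "wt", "control_20C"), "predicted"]
        )
        expected = (
            coef["isoline 9"] + coef["temperature 24"] + coef["repr.type fog"]
            + coef["isoline 9 × temperature 24"] + coef["isoline 9 × repr.type fog"]
            + coef["temperature 24 × repr.type fog"]
            + coef["isoline 9 × temperature 24 × repr.type fog"]
        )
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_twelve_cells_with_cis(self, effect_frame):
        preds = predicted_group_means(fit_meta_model(effect_frame))
        assert len(preds) == 12
        assert ((preds["CI_low"] < preds["predicted"])
                & (preds["predicted"] < preds["CI_high"])).all()


class TestGenerationRegression:
    def _line_frame(self, a=0.5, b=0.01, n=8, noise=None):
        gens = np.linspace(100, 170, n)
        d = a + b * gens if noise is None else a + b * gens + noise
        return pd.DataFrame(
            {
                "population": [f"P{i}" for i in range(n)],
                "block": [f"b{i}" for i in range(n)],
                "isoline": "6", "treatment": "control_20C", "repro_type": "wt",
                "generation": gens, "d": d, "var_d": 1.0,
                "W_ee": 0.0, "var_ee": 0.0016, "W_anc": 0.0, "var_anc": 0.0016,
                "s_pooled": 0.04, "J": 0.8696,
            }
        )

    @pytest.mark.parametrize("method", ["gls", "wls"])
    def test_constant_d_gives_zero_slope(self, method):
        frame = self._line_frame(b=0.0)
        assert generation_regression(frame, method=method)["slope"] == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("method", ["gls", "wls"])
    def test_exact_line_recovered(self, method):
        res = generation_regression(self._line_frame(a=0.4, b=0.0123), method=method)
        assert res["slope"] == pytest.approx(0.0123, abs=1e-10)
        assert res["intercept"] == pytest.approx(0.4, abs=1e-7)

    def test_constant_generation_rejected(self):
        frame = self._line_frame()
        frame["generation"] = 130.0
        with pytest.raises(DesignError, match="distinct"):
            generation_regression(frame)
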