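"""Simulation studies: parameter recovery, CI coverage, type-I calibration.

Each replicate simulates a full experiment shaped like the packaged design
(raw image counts), runs it through the scoring → effect-size →
meta-regression pipeline, and compares the REML estimates to the generating
truth.  Two canned studies are provided:

* :func:`parameter_recovery_study` — nonzero fixed effects; reports per-
  coefficient bias (in Monte-Carlo SEs) and Wald 95% CI coverage.
* :func:`null_calibration_study` — all fixed effects zero; reports per-
  coefficient Wald rejection rates at α and the rejection rate of the
  weighted generation-slope test.

Both studies run the estimator in its correctly-specified configuration:
constant 2J² effect-size variances (the pooled SD is propagated, not
empirical, so the d²/(2·df) term would misattribute variance and its
outcome-dependent weights shrink large coefficients) and the known
shared-ancestor sampling covariance (effect sizes within a block share
their ancestral score, correlating their errors by ≈ 1/2).  See the
methods note for the sensitivity of the field-convention diagonal mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_sizes import EffectSizeConfig, effect_size_table, effects_to_frame
from .fitness_scores import PropagationConfig, score_dataset
from .meta_model import (
    FitOptions,
    MetaModelFit,
    fit_meta_model,
    generation_regression,
)
from .study_design import DESIGN_MATRIX_COLUMNS, ExperimentDesign, load_packaged_design
from .synthetic_assays import SimulationConfig, TrueParameters, simulate_experiment

#: fixed effects used by the recovery study: realistic magnitudes for every
#: term, with an isoline-9 main effect of 2.0 and a 2.5 three-way interaction
RECOVERY_BETA = np.array(
    [-1.343, 0.433, 2.0, 0.238, 0.171, 0.008,
     -0.408, -1.623, -1.074, -1.104, -0.018, 1.727, 2.5]
)


@dataclass
class StudyResult:
    """Aggregated per-coefficient results of a simulation study."""

    summary: pd.DataFrame
    n_sims: int
    n_failed: int
    generation_slope_rejection: float | None = None
    extras: dict = field(default_factory=dict)


def simulate_and_fit(
    design: ExperimentDesign,
    truth: TrueParameters,
    seed: int,
    propagation: PropagationConfig | None = None,
    effect_cfg: EffectSizeConfig | None = None,
    fit_options: FitOptions | None = None,
) -> tuple[MetaModelFit, pd.DataFrame, pd.DataFrame]:
    """One replicate: simulate counts, score, build effect sizes, fit.

    Returns the fit, the effect-size table and the truth table.
    """
    cfg = SimulationConfig(design=design, truth=truth, seed=seed)
    counts, truth_table, _info = simulate_experiment(cfg)
    scores = score_dataset(counts, propagation)
    effects, missing = effect_size_table(scores, design, effect_cfg)
    if missing:
        raise RuntimeError(f"simulated dataset is missing pairs: {missing}")
    frame = effects_to_frame(effects)
    fit = fit_meta_model(frame, fit_options)
    return fit, frame, truth_table


def _run_study(
    n_sims: int,
    beta_true: np.ndarray,
    seed: int,
    design: ExperimentDesign | None,
    alpha: float,
    with_generation_test: bool,
) -> StudyResult:
    if design is None:
        design = load_packaged_design()
    truth = TrueParameters(beta=beta_true)
    labels = list(DESIGN_MATRIX_COLUMNS)
    estimates = np.full((n_sims, len(labels)), np.nan)
    covered = np.zeros((n_sims, len(labels)), dtype=bool)
    rejected = np.zeros((n_sims, len(labels)), dtype=bool)
    slope_rejects = []
    n_failed = 0
    rng = np.random.default_rng(seed)
    # distinct sub-seeds below 2**31 for each replicate
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    effect_cfg = EffectSizeConfig(variance_mode="constant")
    fit_options = FitOptions(use_sampling_covariance=True)

    for i in range(n_sims):
        try:
            fit, frame, _ = simulate_and_fit(
                design, truth, int(sub_seeds[i]),
                effect_cfg=effect_cfg, fit_options=fit_options,
            )
        except Exception:
            n_failed += 1
            continue
        coef = fit.coefficients
        estimates[i] = coef["estimate"].to_numpy()
        covered[i] = (coef["CI_low"].to_numpy() <= beta_true) & (
            beta_true <= coef["CI_high"].to_numpy()
        )
        rejected[i] = coef["p"].to_numpy() < alpha
        if with_generation_test:
            slope_rejects.append(generation_regression(frame)["p"] < alpha)

    ok = ~np.isnan(estimates[:, 0])
    n_ok = int(ok.sum())
    est = estimates[ok]
    summary = pd.DataFrame(
        {
            "label": labels,
            "beta_true": beta_true,
            "mean_estimate": est.mean(axis=0),
            "sd_estimate": est.std(axis=0, ddof=1),
            "mc_se": est.std(axis=0, ddof=1) / np.sqrt(n_ok),
            "bias": est.mean(axis=0) - beta_true,
            "coverage": covered[ok].mean(axis=0),
            "rejection_rate": rejected[ok].mean(axis=0),
        }
    )
    summary["bias_in_mc_se"] = summary["bias"] / summary["mc_se"]
    slope_rate = float(np.mean(slope_rejects)) if slope_rejects else None
    return StudyResult(
        summary=summary,
        n_sims=n_ok,
        n_failed=n_failed,
        generation_slope_rejection=slope_rate,
    )


def parameter_recovery_study(
    n_sims: int = 500,
    seed: int = 0,
    beta_true: np.ndarray | None = None,
    design: ExperimentDesign | None = None,
    alpha: float = 0.05,
) -> StudyResult:
    """Recovery of nonzero fixed effects over repeated simulated experiments."""
    if beta_true is None:
        beta_true = RECOVERY_BETA
    return _run_study(
        n_sims, np.asarray(beta_true, float), seed, design, alpha,
        with_generation_test=False,
    )


def null_calibration_study(
    n_sims: int = 1000,
    seed: int = 0,
    design: ExperimentDesign | None = None,
    alpha: float = 0.05,
) -> StudyResult:
    """Type-I error of the Wald tests and the generation-slope test under the null."""
    beta = np.zeros(len(DESIGN_MATRIX_COLUMNS))
    return _run_study(
        n_sims, beta, seed, design, alpha, with_generation_test=True
    )
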