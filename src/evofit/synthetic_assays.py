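"""Synthetic competition-assay generator with known ground truth.

Emulates the raw data of a GFP-competition fitness assay so that every
downstream stage (scoring, effect sizes, meta-regression) can be tested
against known truth: parameter-recovery studies, type-I-error calibration,
and variance-propagation oracle checks.

The generative model mirrors the assay workflow.  For each focal population
in each block, larvae are seeded at a nominal 3:1 focal:GFP ratio (1500 +
500 per plate, four replicate plates); the realized seeding proportion
jitters around 0.75.  The parental proportion is checked on one slide
sample (~10 images); each offspring plate is sampled on its own slide after
4 days of competition.  Measured proportions carry three error layers:

* a *shared* plate-environment deviation common to the four plates of one
  assay (producing the within-block replicate correlation ρ),
* *slide-sampling* noise — a 5 µl drop is not a perfectly representative
  subsample,
* *binomial counting* error over the worms classified on the images.

The layers are calibrated so the total per-sample proportion sampling
variance matches the propagation model's assumed constant (5e-4 by default)
with replicate correlation ρ = 0.8, making the attributed and actual
sampling variances agree — which is what variance-oracle and coverage tests
require.

True divergences are imposed on the Cohen's-d scale, d = x'β + u_pop +
u_block + e_obs, with x the fixed-effects design row and the u/e the
population, block and observation random effects.  They are mapped to the
log-ratio fitness scale by ΔW = d · s_ref / J, where s_ref is the
propagation-based reference pooled SD and J the small-sample correction the
estimator will apply, so downstream d estimates are centred on the truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .effect_sizes import hedges_J
from .fitness_scores import (
    ASSUMED_PROPORTION_VARIANCE,
    WITHIN_BLOCK_CORRELATION,
    CountSample,
    correlated_mean_variance,
    log_ratio_variance,
)
from .study_design import ExperimentDesign, build_design_matrix

N_DESIGN_COLUMNS = 13


def reference_pooled_sd(
    p: float = 0.75,
    sample_variance: float = ASSUMED_PROPORTION_VARIANCE,
    rho: float = WITHIN_BLOCK_CORRELATION,
    n_replicates: int = 4,
) -> float:
    """Propagation-based pooled SD of W at the assay's operating point.

    Evaluates the variance-propagation closed forms at parental = offspring
    proportion ``p`` with the default per-sample variance and replicate
    correlation; used to convert d-scale truth to the W scale.
    """
    v1 = correlated_mean_variance([sample_variance] * n_replicates, rho)
    return math.sqrt(log_ratio_variance(p, sample_variance, p, v1))


@dataclass
class TrueParameters:
    """Ground-truth parameters of a simulated experiment.

    ``beta`` are the fixed effects on the Cohen's-d scale in design-matrix
    column order; the variance components are on the d² scale.  Ancestral
    baseline fitness (log-ratio units) is set per isoline, with a block-level
    environmental shift of SD ``w_block_shift_sd`` shared by every population
    assayed in a block (it cancels from divergences but shapes the raw
    fitness scores, as strong block effects do in real assays).
    """

    beta: np.ndarray = field(
        default_factory=lambda: np.zeros(N_DESIGN_COLUMNS)
    )
    sigma2_pop: float = 0.0
    sigma2_block: float = 0.0066
    sigma2_obs: float = 0.0208
    w_anc_by_isoline: dict[str, float] = field(
        default_factory=lambda: {"6": 0.0, "8": 0.0, "9": 0.0}
    )
    w_block_shift_sd: float = 0.05
    d_to_w_scale: float | None = None
    df: float = 6.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        if self.beta.shape != (N_DESIGN_COLUMNS,):
            raise ValueError(
                f"beta must have {N_DESIGN_COLUMNS} entries matching the "
                "design-matrix columns"
            )
        if min(self.sigma2_pop, self.sigma2_block, self.sigma2_obs) < 0:
            raise ValueError("variance components must be non-negative")
        if self.d_to_w_scale is None:
            self.d_to_w_scale = reference_pooled_sd()

    @property
    def w_per_d(self) -> float:
        """W-scale shift per unit of true d (s_ref / J)."""
        return float(self.d_to_w_scale) / hedges_J(self.df)


@dataclass
class SimulationConfig:
    """Assay structure and noise settings for one simulated experiment.

    Defaults follow the assay protocol: 1500 focal + 500 GFP larvae on each
    of 4 replicate plates, proportions read off ~10 images per slide.  The
    number of worms classified per image is overdispersed
    (negative-binomial, mean ``mean_worms_per_image``, shape
    ``nb_dispersion``).  ``plate_proportion_variance`` is the target total
    per-sample sampling variance and ``rho_within_block`` the target
    replicate correlation; the generator allocates shared-environment and
    slide-noise variance around the binomial part to hit both.
    """

    design: ExperimentDesign
    truth: TrueParameters
    n_focal_seeded: int = 1500
    n_gfp_seeded: int = 500
    n_plates: int = 4
    n_images: int = 10
    mean_worms_per_image: int = 200
    nb_dispersion: float = 10.0
    rho_within_block: float = WITHIN_BLOCK_CORRELATION
    plate_proportion_variance: float = ASSUMED_PROPORTION_VARIANCE
    parental_proportion_variance: float = ASSUMED_PROPORTION_VARIANCE
    seeding_jitter_sd: float = 0.02
    clip_bounds: tuple[float, float] = (0.001, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_within_block < 1.0:
            raise ValueError("rho_within_block must lie in [0, 1)")
        if min(self.n_plates, self.n_images, self.mean_worms_per_image) <= 0:
            raise ValueError("counts must be positive")

    @property
    def seeding_proportion(self) -> float:
        return self.n_focal_seeded / (self.n_focal_seeded + self.n_gfp_seeded)

    @property
    def expected_total_worms(self) -> float:
        return self.n_images * self.mean_worms_per_image


def simulate_counts(
    p_true: float,
    n_images: int,
    mean_worms_per_image: int,
    rng: np.random.Generator,
    nb_dispersion: float = 10.0,
) -> CountSample:
    """Simulate one slide sample: per-image worm totals and classified counts.

    Worms per image are negative-binomial (overdispersed); given each image's
    total, the focal count is binomial at ``p_true``, so the aggregated
    proportion is exactly binomial conditional on the realized total.
    """
    if not 0.0 < p_true < 1.0:
        raise ValueError(f"p_true must lie strictly inside (0, 1), got {p_true}")
    for _attempt in range(2):
        totals = _nb_counts(rng, n_images, mean_worms_per_image, nb_dispersion)
        if totals.sum() > 0:
            focal = rng.binomial(totals, p_true)
            return CountSample.from_counts(
                int(focal.sum()), int((totals - focal).sum()), n_images
            )
    raise ValueError("zero worms counted across all images, twice in a row")


def _nb_counts(rng, n, mean, dispersion) -> np.ndarray:
    if not np.isfinite(dispersion) or dispersion <= 0:
        return np.full(n, mean, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _image_rows(
    rows: list,
    population: str,
    block: str,
    plate: int,
    role: str,
    p_obs: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Append per-image count rows for one slide sample."""
    totals = _nb_counts(rng, cfg.n_images, cfg.mean_worms_per_image, cfg.nb_dispersion)
    if totals.sum() == 0:
        totals = _nb_counts(
            rng, cfg.n_images, cfg.mean_worms_per_image, cfg.nb_dispersion
        )
    focal = rng.binomial(totals, p_obs)
    for img in range(cfg.n_images):
        rows.append(
            (
                population,
                block,
                plate,
                role,
                img + 1,
                int(focal[img]),
                int(totals[img] - focal[img]),
            )
        )


def _slide_noise_sd(total_var: float, binom_var: float) -> float:
    """SD of slide-sampling noise topping binomial error up to ``total_var``."""
    return math.sqrt(max(total_var - binom_var, 0.0))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate raw assay counts for every population × block of the design.

    Returns ``(counts, truth_table, info)``: the raw counts in the assay
    schema (one row per image), a truth table keyed by (population, block)
    holding every latent quantity (true W, true d, realized random effects),
    and a dictionary of run-level information (clipping fraction, seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    truth = cfg.truth

    ee = design.ee_records
    X, _ = build_design_matrix(
        pd.DataFrame(
            {
                "isoline": [r.isoline for r in ee],
                "treatment": [r.treatment for r in ee],
                "repro_type": [r.repro_type for r in ee],
                "generation": [r.generation for r in ee],
            }
        ),
        allow_rank_deficient=True,
    )
    cell_mean = {r.population_id: float(m) for r, m in zip(ee, X @ truth.beta)}

    u_pop = {
        r.population_id: rng.normal(0.0, math.sqrt(truth.sigma2_pop)) for r in ee
    }
    u_block = {b: rng.normal(0.0, math.sqrt(truth.sigma2_block)) for b in design.blocks}
    w_shift = {b: rng.normal(0.0, truth.w_block_shift_sd) for b in design.blocks}

    p_nominal = cfg.seeding_proportion
    binom_var_at = lambda p: p * (1.0 - p) / cfg.expected_total_worms

    rows: list = []
    truth_rows: list[dict] = []
    n_samples = 0
    n_clipped = 0

    for rec in design.records:
        for block in rec.blocks:
            if rec.is_ancestral:
                d_true = 0.0
                w_true = truth.w_anc_by_isoline[rec.isoline] + w_shift[block]
            else:
                e_obs = rng.normal(0.0, math.sqrt(truth.sigma2_obs))
                d_true = (
                    cell_mean[rec.population_id]
                    + u_pop[rec.population_id]
                    + u_block[block]
                    + e_obs
                )
                w_true = (
                    truth.w_anc_by_isoline[rec.isoline]
                    + w_shift[block]
                    + d_true * truth.w_per_d
                )

            # realized seeding proportion for this assay (shared by plates
            # and the parental check; cancels from W by construction)
            p0_true = float(
                np.clip(
                    rng.normal(p_nominal, cfg.seeding_jitter_sd), 0.55, 0.92
                )
            )

            # parental slide sample: slide noise + binomial counting
            slide_sd0 = _slide_noise_sd(
                cfg.parental_proportion_variance, binom_var_at(p0_true)
            )
            p0_obs = float(
                np.clip(rng.normal(p0_true, slide_sd0), *cfg.clip_bounds)
            )
            _image_rows(rows, rec.population_id, block, 0, "parental", p0_obs, cfg, rng)
            n_samples += 1

            # offspring plates: shared environment + slide noise + binomial
            p1_center = p0_true * math.exp(w_true)
            var_shared = cfg.rho_within_block * cfg.plate_proportion_variance
            var_indep = _slide_noise_sd(
                (1.0 - cfg.rho_within_block) * cfg.plate_proportion_variance,
                binom_var_at(min(max(p1_center, 0.05), 0.95)),
            ) ** 2
            shared = rng.normal(0.0, math.sqrt(var_shared))
            for plate in range(1, cfg.n_plates + 1):
                p1_plate = p1_center + shared + rng.normal(0.0, math.sqrt(var_indep))
                clipped = not (cfg.clip_bounds[0] < p1_plate < cfg.clip_bounds[1])
                n_clipped += clipped
                p1_plate = float(np.clip(p1_plate, *cfg.clip_bounds))
                _image_rows(
                    rows, rec.population_id, block, plate, "offspring", p1_plate,
                    cfg, rng,
                )
                n_samples += 1

            truth_rows.append(
                {
                    "population": rec.population_id,
                    "block": block,
                    "is_ancestral": rec.is_ancestral,
                    "isoline": rec.isoline,
                    "treatment": rec.treatment,
                    "repro_type": rec.repro_type,
                    "generation": rec.generation,
                    "d_true": d_true,
                    "W_true": w_true,
                    "p0_true": p0_true,
                    "u_pop": 0.0 if rec.is_ancestral else u_pop[rec.population_id],
                    "u_block": 0.0 if rec.is_ancestral else u_block[block],
                    "w_block_shift": w_shift[block],
                }
            )

    clip_fraction = n_clipped / max(n_samples, 1)
    if clip_fraction > 0.05:
        warnings.warn(
            f"{clip_fraction:.1%} of samples hit the proportion clip bounds; "
            "the configured truth scale is too extreme for the counting model",
            RuntimeWarning,
            stacklevel=2,
        )

    counts = pd.DataFrame(
        rows,
        columns=[
            "population", "block", "plate", "sample_role", "image",
            "focal_count", "competitor_count",
        ],
    )
    truth_table = pd.DataFrame(truth_rows)
    info = {
        "seed": cfg.seed,
        "clip_fraction": clip_fraction,
        "n_samples": n_samples,
        "beta_true": truth.beta.tolist(),
        "sigma2_pop": truth.sigma2_pop,
        "sigma2_block": truth.sigma2_block,
        "sigma2_obs": truth.sigma2_obs,
        "d_to_w_scale": truth.d_to_w_scale,
    }
    return counts, truth_table, info
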