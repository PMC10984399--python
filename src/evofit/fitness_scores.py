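"""Log-ratio competitive fitness scores with propagated sampling variances.

A focal population's fitness against the GFP competitor over one generation
of competition is

    W = ln(p1 / p0)

where ``p0`` is the proportion of focal (non-fluorescent) individuals among
the seeded parents and ``p1`` the proportion among their offspring.  Each
proportion is estimated by classifying worms on ~10 microscope images, so it
carries binomial counting error; the four replicate competition plates of a
block share micro-environment, so their offspring proportions are
correlated.  This module propagates those sampling variances into a variance
for W: the variance of the correlated replicate mean, then the delta-method
variance of the log ratio.

The default propagation follows the study's simplification — a constant
per-sample proportion variance of 5e-4 and a within-block replicate
correlation of 0.8 — with the observed per-sample binomial variance
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: study defaults: assumed per-sample proportion variance and replicate correlation
ASSUMED_PROPORTION_VARIANCE = 0.0005
WITHIN_BLOCK_CORRELATION = 0.8


class CountError(ValueError):
    """Raised for degenerate counts or proportions outside the open unit interval."""


@dataclass(frozen=True)
class CountSample:
    """Classified worm counts for one microscopy sample (totals across images)."""

    focal_count: int
    competitor_count: int
    n_images: int = 1
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.focal_count < 0 or self.competitor_count < 0:
            raise CountError("negative counts")
        if self.total == 0:
            raise CountError("zero total count in sample")
        if self.n_images <= 0:
            raise CountError("n_images must be positive")

    @property
    def total(self) -> float:
        return self.focal_count + self.competitor_count

    @property
    def proportion(self) -> float:
        return self.focal_count / self.total

    @property
    def binomial_variance(self) -> float:
        p = self.proportion
        return p * (1.0 - p) / self.total

    @classmethod
    def from_counts(cls, focal: int, competitor: int, n_images: int = 1) -> "CountSample":
        """Build a sample, applying a continuity correction when a class is empty.

        If either class count is zero, 0.5 is added to both counts so the
        proportion stays inside (0, 1) and the log-ratio is defined; the
        correction is flagged on the returned sample.
        """
        if focal == 0 or competitor == 0:
            return cls(focal + 0.5, competitor + 0.5, n_images, True)  # type: ignore[arg-type]
        return cls(focal, competitor, n_images)


@dataclass(frozen=True)
class PropagationConfig:
    """Variance-propagation settings.

    ``assumed_proportion_variance`` is the constant per-sample sampling
    variance used by default; setting ``use_observed_binomial`` replaces it
    with each sample's own binomial variance p(1−p)/n.
    ``rho_within_block`` is the correlation among the replicate plates'
    offspring proportions within one block.
    """

    assumed_proportion_variance: float = ASSUMED_PROPORTION_VARIANCE
    rho_within_block: float = WITHIN_BLOCK_CORRELATION
    use_observed_binomial: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_within_block < 1.0:
            raise ValueError("rho_within_block must lie in [0, 1)")
        if self.assumed_proportion_variance <= 0:
            raise ValueError("assumed_proportion_variance must be positive")

    def sample_variance(self, sample: CountSample) -> float:
        if self.use_observed_binomial:
            return sample.binomial_variance
        return self.assumed_proportion_variance


@dataclass(frozen=True)
class FitnessScore:
    """Block-level mean fitness for one population × block."""

    population_id: str
    block_id: str
    W: float
    sampling_variance: float
    p0_mean: float
    p1_mean: float
    n_replicates: int
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not math.isfinite(self.W):
            raise CountError("non-finite fitness score")
        if self.sampling_variance <= 0:
            raise CountError("sampling variance must be positive")


def replicate_fitness(p0: float, p1: float) -> float:
    """ln(p1/p0): positive when the focal population gained share.

    Both proportions must lie strictly inside (0, 1); boundary values should
    have been continuity-corrected upstream (``CountSample.from_counts``).
    """
    if not 0.0 < p0 < 1.0 or not 0.0 < p1 < 1.0:
        raise CountError(
            f"proportions must lie in (0, 1), got p0={p0}, p1={p1}; apply the "
            "continuity correction upstream for boundary counts"
        )
    return math.log(p1 / p0)


def correlated_mean_variance(variances: Sequence[float], rho: float) -> float:
    """Variance of the mean of m equally-weighted, pairwise-correlated estimates.

    Var(mean) = (1/m²)[Σ vᵢ + ρ Σ_{i≠j} √(vᵢ vⱼ)]; for equal variances v this
    is v(1 + (m−1)ρ)/m, reducing to v/m at ρ=0 and approaching v as ρ→1.
    """
    v = np.asarray(variances, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one variance")
    if np.any(v < 0):
        raise ValueError("negative sampling variance")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    s = np.sqrt(v)
    m = v.size
    return float((v.sum() + rho * (s.sum() ** 2 - v.sum())) / m**2)


def log_ratio_variance(p0: float, v0: float, p1: float, v1: float) -> float:
    """Delta-method variance of ln(p1/p0) for independent p̂0, p̂1.

    Var(W) ≈ v1/p1² + v0/p0².  Correlation among replicate plates is handled
    before this step, in the variance of the replicate mean.
    """
    if not 0.0 < p0 < 1.0 or not 0.0 < p1 < 1.0:
        raise CountError("proportions must lie strictly inside (0, 1)")
    if v0 < 0 or v1 < 0:
        raise ValueError("negative sampling variance")
    return v1 / p1**2 + v0 / p0**2


def block_mean_fitness(
    parental: CountSample,
    offspring: Sequence[CountSample],
    cfg: PropagationConfig | None = None,
    population_id: str = "",
    block_id: str = "",
    expected_replicates: int = 4,
) -> FitnessScore:
    """Block-level mean fitness score with propagated sampling variance.

    The offspring proportion is the arithmetic mean over the replicate
    plates; W = ln(p1_mean / p0_mean).  The sampling variance combines the
    correlation-corrected variance of the offspring mean with the parental
    sample's variance through the delta method.  The single parental sample
    (the seeding-mix check) is shared by all plates, so its variance enters
    once.
    """
    if cfg is None:
        cfg = PropagationConfig()
    if len(offspring) == 0:
        raise CountError("need at least one offspring replicate")

    warnings: list[str] = []
    if len(offspring) < expected_replicates:
        warnings.append(
            f"only {len(offspring)} of {expected_replicates} replicate plates present"
        )
    if parental.continuity_corrected or any(o.continuity_corrected for o in offspring):
        warnings.append("continuity correction applied to a boundary count")

    p0 = parental.proportion
    p1s = np.array([o.proportion for o in offspring])
    p1 = float(p1s.mean())
    if not 0.0 < p0 < 1.0 or not 0.0 < p1 < 1.0:
        raise CountError(
            f"degenerate proportions for {population_id}/{block_id}: "
            f"p0={p0}, p1={p1}"
        )

    v0 = cfg.sample_variance(parental)
    v1 = correlated_mean_variance(
        [cfg.sample_variance(o) for o in offspring], cfg.rho_within_block
    )
    return FitnessScore(
        population_id=population_id,
        block_id=block_id,
        W=replicate_fitness(p0, p1),
        sampling_variance=log_ratio_variance(p0, v0, p1, v1),
        p0_mean=p0,
        p1_mean=p1,
        n_replicates=len(offspring),
        warnings=tuple(warnings),
    )


def score_dataset(
    counts: pd.DataFrame, cfg: PropagationConfig | None = None
) -> list[FitnessScore]:
    """Score a raw-counts table into block-level fitness scores.

    ``counts`` uses the raw assay schema: one row per image with columns
    ``population, block, plate, sample_role, image, focal_count,
    competitor_count``; ``sample_role`` is ``parental`` (one sample per
    population × block) or ``offspring`` (one sample per replicate plate).
    Image rows are summed into per-sample totals before scoring.
    """
    required = {
        "population", "block", "plate", "sample_role", "focal_count",
        "competitor_count",
    }
    missing = required - set(counts.columns)
    if missing:
        raise CountError(f"raw counts table missing column(s): {sorted(missing)}")

    per_sample = (
        counts.groupby(["population", "block", "plate", "sample_role"], sort=True)
        .agg(
            focal=("focal_count", "sum"),
            competitor=("competitor_count", "sum"),
            n_images=("focal_count", "size"),
        )
        .reset_index()
    )

    scores: list[FitnessScore] = []
    for (pop, block), grp in per_sample.groupby(["population", "block"], sort=True):
        parental_rows = grp[grp["sample_role"] == "parental"]
        offspring_rows = grp[grp["sample_role"] == "offspring"]
        if len(parental_rows) != 1:
            raise CountError(
                f"{pop}/{block}: expected exactly 1 parental sample, "
                f"found {len(parental_rows)}"
            )
        if offspring_rows.empty:
            raise CountError(f"{pop}/{block}: no offspring samples")
        parental = CountSample.from_counts(
            int(parental_rows["focal"].iloc[0]),
            int(parental_rows["competitor"].iloc[0]),
            int(parental_rows["n_images"].iloc[0]),
        )
        offspring = [
            CountSample.from_counts(int(r.focal), int(r.competitor), int(r.n_images))
            for r in offspring_rows.itertuples()
        ]
        scores.append(
            block_mean_fitness(
                parental, offspring, cfg, population_id=str(pop), block_id=str(block)
            )
        )
    return scores


def scores_to_frame(scores: Sequence[FitnessScore]) -> pd.DataFrame:
    """Tabular form of the fitness scores (the ``score`` stage output schema)."""
    return pd.DataFrame(
        {
            "population": [s.population_id for s in scores],
            "block": [s.block_id for s in scores],
            "W": [s.W for s in scores],
            "var_W": [s.sampling_variance for s in scores],
            "p0_mean": [s.p0_mean for s in scores],
            "p1_mean": [s.p1_mean for s in scores],
            "n_replicates": [s.n_replicates for s in scores],
            "warnings": ["|".join(s.warnings) for s in scores],
        }
    )
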