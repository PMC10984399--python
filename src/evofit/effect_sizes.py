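"""Standardized fitness-divergence effect sizes (Cohen's d with Hedges' correction).

Each evolved population's divergence from its ancestor, within one assay
block, is expressed as

    d = (W_ee − W_anc) / s_pooled · J

where the two W are the block-level mean fitness scores of the evolved and
the matching ancestral population, s_pooled = √((v_ee + v_anc)/2) is the
pooled standard deviation built from their propagated sampling variances,
and J = 1 − 3/(4·df − 1) is the small-sample bias correction.  The default
degrees of freedom follow the two-sample convention df = n_ee + n_anc − 2
(6 with four replicate plates each).

The attached sampling variance, Var(d) = J²(v_ee + v_anc)/s_pooled² +
d²/(2·df), is what the meta-regression treats as known; with the pooled-SD
definition its first term reduces to 2J², and a "constant 2J²" mode is
available for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitness_scores import FitnessScore
from .study_design import DesignRecord, ExperimentDesign


class PairingError(ValueError):
    """Raised when evolved and ancestral scores cannot be matched."""


@dataclass(frozen=True)
class EffectSizeConfig:
    """Effect-size conventions.

    ``df`` enters both the Hedges correction J and the d²/(2·df) variance
    term.  ``variance_mode`` selects the Var(d) formula: ``"standard"`` for
    J²(v_ee+v_anc)/s² + d²/(2df), ``"constant"`` for the simplified 2J².
    """

    df: float = 6.0
    variance_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.variance_mode not in ("standard", "constant"):
            raise ValueError("variance_mode must be 'standard' or 'constant'")


@dataclass(frozen=True)
class EffectSize:
    """Divergence of one evolved population from its ancestor in one block."""

    population_id: str
    block_id: str
    d: float
    sampling_variance: float
    isoline: str
    treatment: str
    repro_type: str
    generation: int
    W_ee: float
    var_ee: float
    W_anc: float
    var_anc: float
    s_pooled: float
    J: float

    def __post_init__(self) -> None:
        if self.sampling_variance <= 0:
            raise ValueError("effect-size sampling variance must be positive")
        if self.s_pooled <= 0:
            raise ValueError("pooled SD must be positive")


def pooled_sd(var_ee: float, var_anc: float) -> float:
    """√((v_ee + v_anc)/2) from the two scores' sampling variances."""
    if var_ee <= 0 or var_anc <= 0:
        raise ValueError(
            "pooled SD requires strictly positive sampling variances "
            f"(got {var_ee}, {var_anc})"
        )
    return math.sqrt((var_ee + var_anc) / 2.0)


def hedges_J(df: float) -> float:
    """Small-sample bias correction J = 1 − 3/(4·df − 1); → 1 as df → ∞."""
    if df <= 1:
        raise ValueError("Hedges correction requires df > 1")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def cohens_d(
    ee: FitnessScore,
    anc: FitnessScore,
    cfg: EffectSizeConfig | None = None,
    record: DesignRecord | None = None,
) -> EffectSize:
    """Standardized divergence of ``ee`` from ``anc`` within their shared block.

    ``record`` supplies the evolved population's covariates; when omitted the
    covariate fields are left blank (useful for unit-level computation).
    """
    if cfg is None:
        cfg = EffectSizeConfig()
    if ee.block_id != anc.block_id:
        raise PairingError(
            f"block mismatch: {ee.population_id}@{ee.block_id} vs "
            f"{anc.population_id}@{anc.block_id}"
        )
    s = pooled_sd(ee.sampling_variance, anc.sampling_variance)
    J = hedges_J(cfg.df)
    d = (ee.W - anc.W) / s * J
    if cfg.variance_mode == "constant":
        var_d = 2.0 * J**2
    else:
        var_d = (
            J**2 * (ee.sampling_variance + anc.sampling_variance) / s**2
            + d**2 / (2.0 * cfg.df)
        )
    return EffectSize(
        population_id=ee.population_id,
        block_id=ee.block_id,
        d=d,
        sampling_variance=var_d,
        isoline=record.isoline if record else "",
        treatment=record.treatment if record else "",
        repro_type=record.repro_type if record else "",
        generation=record.generation if record else 0,
        W_ee=ee.W,
        var_ee=ee.sampling_variance,
        W_anc=anc.W,
        var_anc=anc.sampling_variance,
        s_pooled=s,
        J=J,
    )


def effect_size_table(
    scores: Sequence[FitnessScore],
    design: ExperimentDesign,
    cfg: EffectSizeConfig | None = None,
) -> tuple[list[EffectSize], list[tuple[str, str]]]:
    """One effect size per evolved population × block, paired with its ancestor.

    Matching uses (isoline, reproductive type, block): fog populations are
    compared to the fog ancestor of their isoline, wt to wt, assayed in the
    same block.  Returns the effect sizes and a list of (population, block)
    pairs that could not be formed because a score was missing — missing
    pairs are reported, never silently dropped.
    """
    if cfg is None:
        cfg = EffectSizeConfig()
    by_key: dict[tuple[str, str], FitnessScore] = {}
    for s in scores:
        key = (s.population_id, s.block_id)
        if key in by_key:
            raise PairingError(f"duplicate score for population×block {key}")
        by_key[key] = s

    effects: list[EffectSize] = []
    missing: list[tuple[str, str]] = []
    for rec in design.ee_records:
        anc_rec = design.ancestor_of(rec)
        for block in rec.blocks:
            ee_score = by_key.get((rec.population_id, block))
            anc_score = by_key.get((anc_rec.population_id, block))
            if ee_score is None or anc_score is None:
                missing.append((rec.population_id, block))
                continue
            effects.append(cohens_d(ee_score, anc_score, cfg, record=rec))
    return effects, missing


def sampling_covariance(effects: Sequence[EffectSize]) -> "np.ndarray":
    """Full known sampling covariance of a set of effect sizes.

    Effect sizes from the same block share the single ancestral fitness
    score of their reproductive type, so their sampling errors covary:

        Cov(d_i, d_j) = J_i J_j · var_anc / (s_i · s_j)

    for i ≠ j sharing an ancestor score, with the per-effect sampling
    variances on the diagonal.  Fitting the meta-regression against this
    matrix (instead of its diagonal) accounts for the shared-ancestor
    correlation, which approaches 1/2 when evolved and ancestral scores are
    measured with equal precision.
    """
    n = len(effects)
    V = np.zeros((n, n))
    for i, e in enumerate(effects):
        V[i, i] = e.sampling_variance
    for i in range(n):
        ei = effects[i]
        for j in range(i + 1, n):
            ej = effects[j]
            if (
                ei.block_id == ej.block_id
                and ei.repro_type == ej.repro_type
                and ei.isoline == ej.isoline
            ):
                V[i, j] = V[j, i] = (
                    ei.J * ej.J * ei.var_anc / (ei.s_pooled * ej.s_pooled)
                )
    return V


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Tabular form of the effect sizes (the ``effects`` stage output schema)."""
    return pd.DataFrame(
        {
            "population": [e.population_id for e in effects],
            "block": [e.block_id for e in effects],
            "isoline": [e.isoline for e in effects],
            "treatment": [e.treatment for e in effects],
            "repro_type": [e.repro_type for e in effects],
            "generation": [e.generation for e in effects],
            "d": [e.d for e in effects],
            "var_d": [e.sampling_variance for e in effects],
            "W_ee": [e.W_ee for e in effects],
            "var_ee": [e.var_ee for e in effects],
            "W_anc": [e.W_anc for e in effects],
            "var_anc": [e.var_anc for e in effects],
            "s_pooled": [e.s_pooled for e in effects],
            "J": [e.J for e in effects],
        }
    )


def effects_from_frame(frame: pd.DataFrame) -> list[EffectSize]:
    """Rebuild :class:`EffectSize` objects from the effects CSV schema."""
    effects = []
    for r in frame.itertuples():
        J = float(getattr(r, "J", hedges_J(6.0)))
        s = float(getattr(r, "s_pooled", 1.0))
        effects.append(
            EffectSize(
                population_id=str(r.population),
                block_id=str(r.block),
                d=float(r.d),
                sampling_variance=float(r.var_d),
                isoline=str(r.isoline),
                treatment=str(r.treatment),
                repro_type=str(r.repro_type),
                generation=int(r.generation),
                W_ee=float(getattr(r, "W_ee", 0.0)),
                var_ee=float(getattr(r, "var_ee", s**2)),
                W_anc=float(getattr(r, "W_anc", 0.0)),
                var_anc=float(getattr(r, "var_anc", s**2)),
                s_pooled=s,
                J=J,
            )
        )
    return effects
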