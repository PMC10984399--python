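"""Multilevel random-effects meta-regression with known sampling variances.

The divergence effect sizes d_i come with sampling variances v_i propagated
from the counting process, so the model is a known-variance (meta-analytic)
Gaussian mixed model:

    d ~ N(Xβ, V),   V = diag(v) + σ²_pop Z_pop Z_popᵀ + σ²_block Z_block Z_blockᵀ + σ²_obs I

with crossed random intercepts for population (each evolved population is
measured in 2–4 blocks) and block (each assay session), plus an
observation-level component capturing residual heterogeneity beyond the
attributed sampling variances.  Variance components are estimated by REML —
a bounded quasi-Newton search on the log-variance scale, so non-negativity
holds by parameterization and near-zero components sit cleanly on the
boundary — and fixed effects by GLS at the optimum.  Inference is Wald:
Z = estimate/SE against a standard normal, with 95% confidence intervals.

Fixed effects are the treatment-coded isoline × temperature × reproductive
system factors with all first- and second-order interactions and the
generation-number covariate (see :mod:`evofit.study_design`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .effect_sizes import EffectSize
from .study_design import (
    CodingConfig,
    DesignError,
    build_design_matrix,
    group_cells,
)

_LOG2PI = float(np.log(2.0 * np.pi))
#: bounds for log variance components; the lower bound is an effective zero
_THETA_BOUNDS = (np.log(1e-12), np.log(1e4))


class ConvergenceError(RuntimeError):
    pass


def incidence_matrix(labels: Sequence) -> np.ndarray:
    """0/1 incidence matrix mapping observations to grouping levels."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _build_V(
    v: np.ndarray,
    sig2: np.ndarray,
    Z_pop: np.ndarray | None,
    Z_block: np.ndarray | None,
) -> np.ndarray:
    # v may be a vector of sampling variances or a full sampling covariance
    if v.ndim == 2:
        V = v + sig2[2] * np.eye(v.shape[0])
    else:
        V = np.diag(v + sig2[2])
    if Z_pop is not None:
        V += sig2[0] * (Z_pop @ Z_pop.T)
    if Z_block is not None:
        V += sig2[1] * (Z_block @ Z_block.T)
    return V


def reml_objective(
    theta: Sequence[float],
    y: np.ndarray,
    X: np.ndarray,
    v: np.ndarray,
    Z_pop: np.ndarray | None,
    Z_block: np.ndarray | None,
) -> float:
    """−2 × restricted log-likelihood at log-variance components ``theta``.

    ``theta`` is (log σ²_pop, log σ²_block, log σ²_obs); pass ``None`` for an
    incidence matrix to drop that component from the covariance (its theta
    entry is then ignored).  ``v`` is either the vector of known sampling
    variances or a full known sampling covariance matrix (e.g. including the
    shared-ancestor covariances of :func:`evofit.effect_sizes.sampling_covariance`).
    β is profiled out by GLS:

    −2ℓ_R = (n−p)·ln 2π + ln|V| + ln|XᵀV⁻¹X| + (y−Xβ̂)ᵀV⁻¹(y−Xβ̂)
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    v = np.asarray(v, float)
    n, p = X.shape
    if y.shape[0] != n or v.shape[0] != n or (v.ndim == 2 and v.shape[1] != n):
        raise ValueError("inconsistent dimensions for y, X, v")
    sig2 = np.exp(np.asarray(theta, float))
    V = _build_V(v, sig2, Z_pop, Z_block)
    try:
        c, low = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular (condition number ≈ "
            f"{np.linalg.cond(V):.3g}); check sampling variances and "
            "variance-component bounds"
        ) from exc
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv_X = sla.cho_solve((c, low), X)
    Vinv_y = sla.cho_solve((c, low), y)
    XtViX = X.T @ Vinv_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise DesignError("XᵀV⁻¹X is not positive definite; X may be rank deficient")
    beta = np.linalg.solve(XtViX, X.T @ Vinv_y)
    r = y - X @ beta
    quad = float(r @ sla.cho_solve((c, low), r))
    return (n - p) * _LOG2PI + logdet_V + logdet_XtViX + quad


def _gls(y, X, V):
    """GLS estimates and covariance given a full covariance matrix."""
    c, low = sla.cho_factor(V, lower=True)
    Vinv_X = sla.cho_solve((c, low), X)
    XtViX = X.T @ Vinv_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ sla.cho_solve((c, low), y))
    return beta, cov_beta


@dataclass(frozen=True)
class FitOptions:
    """Meta-model fitting options.

    Random components can be switched off individually (used by the
    closed-form limiting cases and by sensitivity fits).  The optimizer runs
    ``n_starts`` bounded L-BFGS-B searches on log variances from dispersed
    starting points and keeps the best optimum.
    """

    include_population: bool = True
    include_block: bool = True
    include_observation: bool = True
    use_sampling_covariance: bool = False
    ci_level: float = 0.95
    n_starts: int = 3
    tol: float = 1e-10
    coding: CodingConfig = field(default_factory=CodingConfig)
    allow_rank_deficient: bool = False


@dataclass
class MetaModelFit:
    """REML fit: coefficient table, variance components, and diagnostics."""

    coefficients: pd.DataFrame
    variance_components: dict[str, dict[str, float]]
    convergence: dict
    fitted: np.ndarray
    residuals: np.ndarray
    cov_beta: np.ndarray
    labels: list[str]
    generation_mean: float
    ci_level: float

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()

    def coefficient(self, label: str) -> pd.Series:
        return self.coefficients.set_index("label").loc[label]


def fit_known_variance_model(
    y: Sequence[float],
    X: np.ndarray,
    v: Sequence[float],
    pop_ids: Sequence | None = None,
    block_ids: Sequence | None = None,
    labels: Sequence[str] | None = None,
    options: FitOptions | None = None,
    generation_mean: float = 0.0,
) -> MetaModelFit:
    """Fit the known-variance mixed model to arbitrary y, X, v arrays.

    This is the computational core behind :func:`fit_meta_model`; it accepts
    any design matrix, so degenerate limiting cases (intercept-only, no
    random effects) fit through the same code path.
    """
    if options is None:
        options = FitOptions()
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    v = np.asarray(v, float)
    n, p = X.shape
    if labels is None:
        labels = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("fixed-effects matrix is rank deficient")

    Z_pop = incidence_matrix(pop_ids) if (options.include_population and pop_ids is not None) else None
    Z_block = incidence_matrix(block_ids) if (options.include_block and block_ids is not None) else None

    free = [Z_pop is not None, Z_block is not None, options.include_observation]
    v_diag = np.diag(v) if v.ndim == 2 else v
    scale = max(float(np.var(y)), float(np.mean(v_diag)), 1e-8)

    def objective(theta_free: np.ndarray) -> float:
        theta = np.full(3, _THETA_BOUNDS[0])
        theta[np.array(free)] = theta_free
        return reml_objective(theta, y, X, v, Z_pop, Z_block)

    n_free = sum(free)
    if n_free == 0:
        best_theta_free = np.empty(0)
        best_obj = objective(best_theta_free)
        conv = {"converged": True, "status": "no free variance components",
                "iterations": 0, "n_starts": 0}
    else:
        rel_starts = [np.full(n_free, np.log(scale) - 2.0),
                      np.full(n_free, np.log(scale) + 1.0),
                      np.full(n_free, np.log(scale) - 6.0)]
        best = None
        total_iter = 0
        for start in rel_starts[: max(options.n_starts, 1)]:
            res = optimize.minimize(
                objective,
                start,
                method="L-BFGS-B",
                bounds=[_THETA_BOUNDS] * n_free,
                options={"ftol": options.tol, "gtol": 1e-10, "maxiter": 500},
            )
            total_iter += int(res.nit)
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None
        best_theta_free = best.x
        best_obj = float(best.fun)
        conv = {
            "converged": bool(best.success),
            "status": str(best.message),
            "iterations": total_iter,
            "n_starts": max(options.n_starts, 1),
        }
        if not best.success:
            conv["status"] = f"non-convergence: {best.message}"

    theta = np.full(3, _THETA_BOUNDS[0])
    theta[np.array(free)] = best_theta_free
    sig2 = np.exp(theta)
    # components at the effective-zero bound are reported as exactly 0
    sig2[sig2 <= 2e-12] = 0.0
    sig2[~np.array(free)] = 0.0

    V = _build_V(v, sig2, Z_pop, Z_block)
    beta, cov_beta = _gls(y, X, V)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(0.5 + options.ci_level / 2.0)
    coef = pd.DataFrame(
        {
            "label": list(labels),
            "estimate": beta,
            "SE": se,
            "Z": z,
            "p": pvals,
            "CI_low": beta - zq * se,
            "CI_high": beta + zq * se,
        }
    )
    fitted = X @ beta
    vc = {
        "population": {
            "sigma2": float(sig2[0]),
            "levels": int(Z_pop.shape[1]) if Z_pop is not None else 0,
        },
        "block": {
            "sigma2": float(sig2[1]),
            "levels": int(Z_block.shape[1]) if Z_block is not None else 0,
        },
        "observation": {
            "sigma2": float(sig2[2]) if options.include_observation else 0.0,
            "levels": n,
        },
    }
    conv["neg2_reml"] = best_obj
    conv["log_reml"] = -0.5 * best_obj
    return MetaModelFit(
        coefficients=coef,
        variance_components=vc,
        convergence=conv,
        fitted=fitted,
        residuals=y - fitted,
        cov_beta=cov_beta,
        labels=list(labels),
        generation_mean=generation_mean,
        ci_level=options.ci_level,
    )


def fit_meta_model(
    effects: Sequence[EffectSize] | pd.DataFrame,
    options: FitOptions | None = None,
) -> MetaModelFit:
    """Fit the divergence meta-regression to an effect-size table.

    Builds the 13-column treatment-coded design matrix (isoline, temperature,
    reproductive system, interactions, generation covariate), attaches
    crossed random intercepts for population and block and the
    observation-level component, and estimates by REML.
    """
    if options is None:
        options = FitOptions()
    if isinstance(effects, pd.DataFrame):
        frame = effects
        effect_objs = None
    else:
        from .effect_sizes import effects_to_frame

        frame = effects_to_frame(effects)
        effect_objs = list(effects)
    if len(frame) < 2:
        raise DesignError("need at least 2 effect sizes to fit the model")
    v: np.ndarray = frame["var_d"].to_numpy(float)
    if options.use_sampling_covariance:
        from .effect_sizes import effects_from_frame, sampling_covariance

        if effect_objs is None:
            effect_objs = effects_from_frame(frame)
        v = sampling_covariance(effect_objs)
    X, labels = build_design_matrix(
        frame, options.coding, allow_rank_deficient=options.allow_rank_deficient
    )
    dropped: list[str] = []
    if options.allow_rank_deficient and np.linalg.matrix_rank(X) < X.shape[1]:
        from .study_design import _aliased_columns

        dropped = _aliased_columns(X, labels)
        keep = [j for j, lab in enumerate(labels) if lab not in dropped]
        X = X[:, keep]
        labels = [labels[j] for j in keep]
    fit = fit_known_variance_model(
        y=frame["d"].to_numpy(float),
        X=X,
        v=v,
        pop_ids=frame["population"].to_numpy(),
        block_ids=frame["block"].to_numpy(),
        labels=labels,
        options=options,
        generation_mean=float(frame["generation"].astype(float).mean()),
    )
    if dropped:
        fit.convergence["dropped_columns"] = dropped
    return fit


def predicted_group_means(
    fit: MetaModelFit,
    at_generation: float | None = None,
    generation_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Model-predicted divergence for the 12 isoline × treatment × repro cells.

    Predictions are x'β at ``at_generation`` (default: the mean generation of
    the fitted data) with delta-method Wald confidence intervals x'Σx.
    A warning column flags extrapolation outside ``generation_range``.
    """
    if not fit.convergence.get("converged", False):
        raise ConvergenceError("cannot predict from a non-converged fit")
    gen = fit.generation_mean if at_generation is None else float(at_generation)
    cells = pd.DataFrame(group_cells())
    cells["generation"] = gen
    X, labels = build_design_matrix(cells, allow_rank_deficient=True)
    keep = [j for j, lab in enumerate(labels) if lab in fit.labels]
    X = X[:, keep]
    pred = X @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X))
    zq = stats.norm.ppf(0.5 + fit.ci_level / 2.0)
    out = cells.copy()
    out["predicted"] = pred
    out["SE"] = se
    out["CI_low"] = pred - zq * se
    out["CI_high"] = pred + zq * se
    if generation_range is not None and not (
        generation_range[0] <= gen <= generation_range[1]
    ):
        out["warning"] = (
            f"generation {gen} outside observed range {generation_range}"
        )
    return out


def generation_regression(
    effects: Sequence[EffectSize] | pd.DataFrame,
    method: str = "gls",
) -> dict[str, float]:
    """Slope of divergence d on generation number, with a two-sided test.

    A descriptive companion check of whether divergence scales with the
    number of generations evolved.  The default fits intercept + generation
    through the same known-covariance REML machinery as the full model
    (shared-ancestor sampling covariance plus population/block/observation
    components), which keeps the test calibrated despite the clustered
    errors; ``method="wls"`` gives the naive inverse-variance weighted
    least-squares slope, whose nominal test is anticonservative here because
    effect sizes from the same population, block and ancestor are correlated.
    Returns slope, SE, Z and two-sided normal p.
    """
    if isinstance(effects, pd.DataFrame):
        frame = effects
    else:
        from .effect_sizes import effects_to_frame

        frame = effects_to_frame(effects)
    gen = frame["generation"].astype(float).to_numpy()
    if np.unique(gen).size < 3:
        raise DesignError(
            "generation regression needs at least 3 distinct generation values"
        )
    y = frame["d"].to_numpy(float)

    if method == "wls":
        import statsmodels.api as sm

        w = 1.0 / frame["var_d"].to_numpy(float)
        res = sm.WLS(y, sm.add_constant(gen), weights=w).fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        intercept = float(res.params[0])
    elif method == "gls":
        from .effect_sizes import effects_from_frame, sampling_covariance

        V = sampling_covariance(effects_from_frame(frame))
        Xg = np.column_stack([np.ones_like(gen), gen])
        fit = fit_known_variance_model(
            y, Xg, V,
            pop_ids=frame["population"].to_numpy(),
            block_ids=frame["block"].to_numpy(),
            labels=["intercept", "generation"],
        )
        coef = fit.coefficients.set_index("label")
        slope = float(coef.loc["generation", "estimate"])
        se = float(coef.loc["generation", "SE"])
        intercept = float(coef.loc["intercept", "estimate"])
    else:
        raise ValueError("method must be 'gls' or 'wls'")
    z = slope / se
    return {
        "slope": slope,
        "SE": se,
        "Z": z,
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "intercept": intercept,
    }
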