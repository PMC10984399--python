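"""Diagnostic figures: raw scores by block, effect-size forest, predicted
cell means, and divergence versus generations evolved."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .meta_model import MetaModelFit, predicted_group_means


def plot_raw_scores(scores: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Raw W per population, colour-coded by block (block-effect diagnostic)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    pops = sorted(scores["population"].unique())
    xpos = {p: i for i, p in enumerate(pops)}
    for block, grp in scores.groupby("block"):
        ax.scatter(
            [xpos[p] for p in grp["population"]], grp["W"], label=str(block), s=18
        )
    ax.set_xticks(range(len(pops)))
    ax.set_xticklabels(pops, rotation=90, fontsize=6)
    ax.set_ylabel("fitness score W")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.legend(title="block", fontsize=6, ncol=4)
    return ax


def plot_effect_forest(effects: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Effect sizes with ±1.96·SE bars, grouped by isoline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    frame = effects.sort_values(["isoline", "population", "block"]).reset_index(drop=True)
    y = np.arange(len(frame))
    se = np.sqrt(frame["var_d"])
    colors = {"6": "C0", "8": "C1", "9": "C2"}
    ax.errorbar(
        frame["d"], y, xerr=1.96 * se, fmt="none",
        ecolor=[colors.get(str(i), "C3") for i in frame["isoline"]], alpha=0.6,
    )
    ax.scatter(frame["d"], y, c=[colors.get(str(i), "C3") for i in frame["isoline"]], s=10)
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("divergence from ancestor (d)")
    ax.set_yticks([])
    return ax


def plot_predicted_means(fit: MetaModelFit, ax: plt.Axes | None = None) -> plt.Axes:
    """Model-predicted divergence for the 12 design cells with 95% CIs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    preds = predicted_group_means(fit)
    labels = [
        f"iso{r.isoline}\n{r.repro_type}\n{'24°C' if r.treatment == 'elevated_24C' else '20°C'}"
        for r in preds.itertuples()
    ]
    x = np.arange(len(preds))
    ax.errorbar(
        x, preds["predicted"],
        yerr=[preds["predicted"] - preds["CI_low"], preds["CI_high"] - preds["predicted"]],
        fmt="o", capsize=3,
    )
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=6)
    ax.set_ylabel("predicted divergence (d)")
    return ax


def plot_generation_trend(effects: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Effect sizes against generations of evolution completed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(effects["generation"], effects["d"], s=12, alpha=0.7)
    ax.set_xlabel("EE generations completed")
    ax.set_ylabel("divergence from ancestor (d)")
    ax.axhline(0.0, color="grey", lw=0.6)
    return ax


def write_report_figures(
    scores: pd.DataFrame,
    effects: pd.DataFrame,
    fit: MetaModelFit,
    out_dir: str | Path,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn, data in [
        ("raw_scores.png", plot_raw_scores, scores),
        ("effect_forest.png", plot_effect_forest, effects),
        ("predicted_means.png", plot_predicted_means, fit),
        ("generation_trend.png", plot_generation_trend, effects),
    ]:
        ax = fn(data)
        path = out / name
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
    return written
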