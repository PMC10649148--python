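"""Report figures.

Five figures mirror the analysis outputs: per-sex shrinkage trend, excess
BMI trend, a 2x2 misclassification panel, and relative-risk-by-age curves
for the glycemic outcomes and for hypertension (current BMI solid,
corrected BMI dashed).  Figures are presentation artifacts only — all
quantitative outputs live in the CSV/JSON files.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trends import TrendFit

_SEX_COLORS = {"F": "tab:red", "M": "tab:blue"}
_SEX_NAMES = {"F": "women", "M": "men"}


def _scatter_sample(df: pd.DataFrame, n_max: int = 4000) -> pd.DataFrame:
    if len(df) <= n_max:
        return df
    return df.sample(n=n_max, random_state=0)


def plot_shrinkage_trend(summaries: pd.DataFrame, fits: dict[str, TrendFit],
                         reference_age: float = 35.0):
    """Shrinkage vs age with the fitted linear trend per sex."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for sex, fit in fits.items():
        df = _scatter_sample(summaries[summaries["sex"] == sex])
        ax.plot(df["age"], df["shrinkage"], ".", ms=2, alpha=0.15,
                color=_SEX_COLORS.get(sex, "gray"))
        grid = np.linspace(summaries["age"].min(), summaries["age"].max(), 100)
        ax.plot(grid, fit.predict(grid - reference_age), "-",
                color=_SEX_COLORS.get(sex, "gray"),
                label=f"{_SEX_NAMES.get(sex, sex)} (slope {fit.coefficients[1]:.3f} cm/yr)")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("height loss from young height (cm)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_excess_bmi_trend(summaries: pd.DataFrame, fits: dict[str, TrendFit]):
    """Excess BMI vs age with the linear fit per sex."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for sex, fit in fits.items():
        df = _scatter_sample(summaries[(summaries["sex"] == sex)
                                       & summaries["excess_bmi"].notna()])
        ax.plot(df["age"], df["excess_bmi"], ".", ms=2, alpha=0.15,
                color=_SEX_COLORS.get(sex, "gray"))
        grid = np.linspace(summaries["age"].min(), summaries["age"].max(), 100)
        ax.plot(grid, fit.predict(grid), "-", color=_SEX_COLORS.get(sex, "gray"),
                label=_SEX_NAMES.get(sex, sex))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("excess BMI (kg/m²)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_misclassification(curves: pd.DataFrame):
    """2x2 panel: wrong-overweight / wrong-obese, population / category."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True)
    layout = [("overweight", "population"), ("overweight", "category"),
              ("obese", "population"), ("obese", "category")]
    for ax, (cat, mode) in zip(axes.ravel(), layout):
        sub = curves[(curves["category"] == cat)
                     & (curves["denominator_mode"] == mode)]
        for sex, grp in sub.groupby("sex"):
            grp = grp.sort_values("age_bin")
            ax.plot(grp["age_bin"], grp["fraction"], "o-",
                    color=_SEX_COLORS.get(sex, "gray"),
                    label=_SEX_NAMES.get(sex, sex))
        ax.set_title(f"wrong {cat} / {mode}")
        ax.set_ylabel("fraction")
        ax.legend()
    for ax in axes[1]:
        ax.set_xlabel("age (years)")
    fig.tight_layout()
    return fig


def _plot_rr(curves: pd.DataFrame, diseases, title: str):
    fig, axes = plt.subplots(1, len(diseases), figsize=(6 * len(diseases), 5),
                             squeeze=False)
    for ax, disease in zip(axes.ravel(), diseases):
        sub = curves[curves["disease"] == disease]
        for (sex, mode), grp in sub.groupby(["sex", "bmi_mode"]):
            grp = grp.sort_values("age_bin")
            ax.plot(grp["age_bin"], grp["rr"],
                    "-" if mode == "current" else "--",
                    color=_SEX_COLORS.get(sex, "gray"),
                    label=f"{_SEX_NAMES.get(sex, sex)}, {mode} BMI")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_title(disease)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("relative risk (obese vs non-obese)")
        ax.legend(fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_glycemic_rr(curves: pd.DataFrame):
    return _plot_rr(curves, ["prediabetes", "diabetes"],
                    "Relative risk of glycemic outcomes")


def plot_hypertension_rr(curves: pd.DataFrame):
    return _plot_rr(curves, ["hypertension"], "Relative risk of hypertension")


def save_report_figures(outdir, summaries, shrink_fits, excess_fits,
                        misclass_curves, rr_curve_table,
                        reference_age: float = 35.0) -> list:
    """Render and save the five report figures; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jobs = [
        ("fig1_shrinkage_trend.png",
         plot_shrinkage_trend(summaries, shrink_fits, reference_age)),
        ("fig2_excess_bmi.png", plot_excess_bmi_trend(summaries, excess_fits)),
        ("fig3_misclassification.png", plot_misclassification(misclass_curves)),
        ("fig4_glycemic_rr.png", plot_glycemic_rr(rr_curve_table)),
        ("fig5_hypertension_rr.png", plot_hypertension_rr(rr_curve_table)),
    ]
    paths = []
    for name, fig in jobs:
        path = outdir / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
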