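"""End-to-end orchestration: simulate/load -> smooth -> metrics ->
misclassification -> risk -> trends -> figures, with a run manifest.

Every run writes, under ``outdir``: the exam table (when simulated, plus the
truth tables), the per-exam subject summary CSV, the per-subject QC CSV, the
misclassification and relative-risk curve CSVs, trend fits as JSON, five
figures, and ``manifest.json`` recording the config hash, seed, versions and
per-stage record counts.  Identical config + seed reproduce identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig, SimConfig, config_hash
from .errors import YoungBMIError
from .io import read_cohort, write_cohort, write_truth
from .metrics import eligibility_filter, summarize_cohort
from .misclassification import misclassification_curves
from .risk import add_disease_flags, rr_curves
from .simulate import simulate_cohort
from .trends import fit_excess_bmi_trend, fit_shrinkage_trend, total_loss_40_80

logger = logging.getLogger("youngbmi")


@dataclass
class RunManifest:
    """Record of a pipeline run sufficient to reproduce it."""

    config_hash: str
    seed: int | None
    versions: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _versions() -> dict:
    import numpy
    import scipy
    import statsmodels

    return {
        "youngbmi": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _done(name: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %s done in %.2fs%s", name, time.perf_counter() - t0,
                f" ({extra})" if extra else "")


def analyze_cohort(exams: pd.DataFrame, analysis: AnalysisConfig | None = None):
    """Run the analysis stages on an exam table; returns a dict of results.

    Keys: summaries, qc, misclassification, rr, shrink_fits (per sex,
    degrees 1 and 2), excess_fits, total_loss (per sex, from the degree-1
    fit).
    """
    analysis = analysis or AnalysisConfig()
    t0 = _stage("smoothing + metrics")
    summaries, qc = summarize_cohort(exams, analysis)
    flagged = add_disease_flags(exams)
    summaries = summaries.merge(
        flagged[["subject_id", "age", "prediabetes", "diabetes", "hypertension"]],
        on=["subject_id", "age"], how="left", validate="one_to_one")
    _done("smoothing + metrics", t0, subjects=qc.shape[0], exams=len(summaries))

    t0 = _stage("misclassification")
    mis = misclassification_curves(summaries, analysis.age_bin_width)
    _done("misclassification", t0, rows=len(mis))

    t0 = _stage("relative risk")
    rr = rr_curves(summaries, analysis.age_bin_width, analysis.obese_cutoff)
    _done("relative risk", t0, rows=len(rr))

    t0 = _stage("trend fits")
    shrink_fits, shrink_fits_q, excess_fits, total_loss = {}, {}, {}, {}
    for sex in sorted(summaries["sex"].unique()):
        shrink_fits[sex] = fit_shrinkage_trend(
            summaries, sex, degree=1, reference_age=analysis.trend_reference_age)
        shrink_fits_q[sex] = fit_shrinkage_trend(
            summaries, sex, degree=2, reference_age=analysis.trend_reference_age)
        sub = summaries[summaries["sex"] == sex]
        excess_fits[sex], _ = fit_excess_bmi_trend(
            sub["age"], sub["excess_bmi"], sub["shrinkage"], sex=sex)
        total_loss[sex] = total_loss_40_80(shrink_fits[sex],
                                           analysis.trend_reference_age)
    _done("trend fits", t0)

    return {
        "summaries": summaries, "qc": qc, "misclassification": mis, "rr": rr,
        "shrink_fits": shrink_fits, "shrink_fits_quadratic": shrink_fits_q,
        "excess_fits": excess_fits, "total_loss": total_loss,
    }


def run_pipeline(outdir,
                 sim_config: SimConfig | None = None,
                 input_csv=None,
                 analysis: AnalysisConfig | None = None,
                 make_figures: bool = True) -> RunManifest:
    """Full pipeline: simulate (or load) a cohort, analyze, write outputs."""
    if (sim_config is None) == (input_csv is None):
        raise YoungBMIError("provide exactly one of sim_config or input_csv")
    analysis = analysis or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=config_hash(sim_config, analysis),
        seed=sim_config.seed if sim_config is not None else None,
        versions=_versions(),
    )

    if sim_config is not None:
        t0 = _stage("simulate")
        exams, truth = simulate_cohort(sim_config)
        write_cohort(exams, outdir / "exams.csv")
        write_truth(truth, outdir / "truth_subjects.csv", outdir / "truth_exams.csv")
        manifest.inputs["simulated"] = True
        manifest.outputs["exams"] = str(outdir / "exams.csv")
        _done("simulate", t0, subjects=sim_config.n_subjects, exams=len(exams))
    else:
        t0 = _stage("load cohort")
        exams = read_cohort(input_csv)
        manifest.inputs["cohort_csv"] = str(input_csv)
        _done("load cohort", t0, exams=len(exams))

    n_subjects = exams["subject_id"].nunique()
    n_eligible = eligibility_filter(exams, analysis.young_age_cutoff).size

    results = analyze_cohort(exams, analysis)
    summaries, qc = results["summaries"], results["qc"]

    summaries.to_csv(outdir / "subject_summaries.csv", index=False,
                     float_format="%.6f")
    qc.to_csv(outdir / "qc.csv", index=False)
    results["misclassification"].to_csv(outdir / "misclassification_curves.csv",
                                        index=False, float_format="%.6f")
    results["rr"].to_csv(outdir / "rr_curves.csv", index=False,
                         float_format="%.6f")
    fits_payload = {
        "shrinkage_linear": {s: f.to_dict() for s, f in results["shrink_fits"].items()},
        "shrinkage_quadratic": {s: f.to_dict()
                                for s, f in results["shrink_fits_quadratic"].items()},
        "excess_bmi_vs_age": {s: f.to_dict() for s, f in results["excess_fits"].items()},
        "total_loss_40_80_cm": results["total_loss"],
    }
    (outdir / "trend_fits.json").write_text(
        json.dumps(fits_payload, indent=2, sort_keys=True) + "\n")

    if make_figures:
        t0 = _stage("figures")
        from .plots import save_report_figures

        paths = save_report_figures(outdir, summaries, results["shrink_fits"],
                                    results["excess_fits"],
                                    results["misclassification"], results["rr"],
                                    analysis.trend_reference_age)
        manifest.outputs["figures"] = [str(p) for p in paths]
        _done("figures", t0)

    manifest.outputs.update({
        "subject_summaries": str(outdir / "subject_summaries.csv"),
        "qc": str(outdir / "qc.csv"),
        "misclassification_curves": str(outdir / "misclassification_curves.csv"),
        "rr_curves": str(outdir / "rr_curves.csv"),
        "trend_fits": str(outdir / "trend_fits.json"),
    })
    manifest.counts = {
        "subjects": int(n_subjects),
        "subjects_eligible": int(n_eligible),
        "subjects_summarized": int(qc.shape[0]),
        "subjects_height_smoothed": int(qc["height_smoothed"].sum()) if len(qc) else 0,
        "exams": int(len(exams)),
        "exams_summarized": int(len(summaries)),
        "exams_bmi_excluded": int(qc["n_bmi_excluded"].sum()) if len(qc) else 0,
        "height_outliers": int(qc["n_height_outliers"].sum()) if len(qc) else 0,
        "bmi_outliers": int(qc["n_bmi_outliers"].sum()) if len(qc) else 0,
    }
    manifest.write(outdir / "manifest.json")
    return manifest
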