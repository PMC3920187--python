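"""Full reproduction run: both conditions, summaries, fits, delay sweep.

``reproduce_paper`` executes the complete simulated study — a control and a
patient ensemble, the RT summaries, cumulative distributions, reciprobit fits
and line comparisons, the Wilcoxon group-distribution tests, and the
planned-onset sweep — and writes a deterministic JSON/CSV report including a
side-by-side table against the published simulated reference values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis, io
from .exceptions import DegenerateDataError, InvalidInputError
from .experiment import (
    control_condition,
    count_correct_then_error,
    patient_condition,
    run_ensemble,
    sweep_delay,
)

#: Published simulated reference values (medians in ms, rates in %, CVs
#: dimensionless), used only for the side-by-side comparison table.
REFERENCE_SIMULATED = {
    "control": {
        "median_error_ms": 212.85,
        "median_anti_ms": 308.10,
        "median_corrected_ms": 181.17,
        "error_rate_percent": 15.72,
        "percent_errors_corrected": 98.09,
        "cv_error": 0.21,
        "cv_anti": 0.17,
        "cv_corrected": 0.44,
    },
    "patient": {
        "median_error_ms": 230.32,
        "median_anti_ms": 372.33,
        "median_corrected_ms": 250.07,
        "error_rate_percent": 40.12,
        "percent_errors_corrected": 58.13,
        "cv_error": 0.36,
        "cv_anti": 0.28,
        "cv_corrected": 0.5,
    },
}

_CATEGORIES = ("error_prosaccade", "antisaccade", "corrected_antisaccade")


def _summary_dict(summ: analysis.RTSummary) -> dict:
    out = {
        "error_rate_percent": summ.error_rate_percent,
        "percent_errors_corrected": summ.percent_errors_corrected,
        "n_valid_trials": summ.n_valid_trials,
        "n_trials": summ.n_trials,
    }
    for cat in _CATEGORIES:
        stats = getattr(summ, cat)
        out[cat] = None if stats is None else dataclasses.asdict(stats)
    return out


def _measures(summ: analysis.RTSummary) -> dict:
    def med(s):
        return None if s is None else s.median_ms

    def cv(s):
        return None if s is None else s.cv

    return {
        "median_error_ms": med(summ.error_prosaccade),
        "median_anti_ms": med(summ.antisaccade),
        "median_corrected_ms": med(summ.corrected_antisaccade),
        "error_rate_percent": summ.error_rate_percent,
        "percent_errors_corrected": summ.percent_errors_corrected,
        "cv_error": cv(summ.error_prosaccade),
        "cv_anti": cv(summ.antisaccade),
        "cv_corrected": cv(summ.corrected_antisaccade),
    }


def _fits(ensemble) -> dict:
    out = {}
    for cat in _CATEGORIES:
        rts = analysis.category_rts(ensemble.trials, cat)
        if rts.size < 3:
            out[cat] = None
            continue
        dist = analysis.cumulative_distribution(rts)
        try:
            fit = analysis.reciprobit_fit(dist)
        except InvalidInputError:
            out[cat] = None
            continue
        out[cat] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r": fit.r,
            "n_points": fit.n_points,
            "fitted_median_ms": analysis.fitted_median_ms(fit),
            "percentiles": dist.percentiles.tolist(),
            "rt_at_percentile": dist.rt_at_percentile.tolist(),
        }
    return out


def reproduce_paper(
    out_dir,
    ntrials: int = 5000,
    seed: int = 12345,
    sweep_ntrials: Optional[int] = None,
) -> dict:
    """Run the full simulated study and write the report to ``out_dir``.

    Small ``ntrials`` runs are flagged (wide Monte-Carlo uncertainty) but
    never fail.  Identical seeds produce byte-identical reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sweep_n = ntrials if sweep_ntrials is None else sweep_ntrials

    ensembles = {
        "control": run_ensemble(control_condition(), ntrials=ntrials, master_seed=seed),
        "patient": run_ensemble(patient_condition(), ntrials=ntrials, master_seed=seed + 1),
    }
    report: dict = {
        "ntrials": ntrials,
        "seed": seed,
        "monte_carlo_warning": ntrials < 1000,
        "conditions": {},
        "comparisons": {},
    }
    rows = []
    for name, ens in ensembles.items():
        summ = analysis.summarize(ens)
        report["conditions"][name] = {
            "summary": _summary_dict(summ),
            "outcome_counts": ens.outcome_counts(),
            "reciprobit": _fits(ens),
            "correct_then_error_trials": count_correct_then_error(ens),
        }
        io.write_ensemble(ens, out_dir / f"trials_{name}.csv")
        for measure, got in _measures(summ).items():
            ref = REFERENCE_SIMULATED[name][measure]
            rows.append(
                {
                    "condition": name,
                    "measure": measure,
                    "simulated": got,
                    "reference": ref,
                    "abs_deviation": None if got is None else got - ref,
                    "rel_deviation": None if got is None else (got - ref) / ref,
                }
            )

    # group-distribution comparisons (control vs patient percentiles)
    for cat in _CATEGORIES:
        fits_c = report["conditions"]["control"]["reciprobit"][cat]
        fits_p = report["conditions"]["patient"]["reciprobit"][cat]
        if fits_c is None or fits_p is None:
            report["comparisons"][cat] = None
            continue
        rt_c = np.array(fits_c["rt_at_percentile"])
        rt_p = np.array(fits_p["rt_at_percentile"])
        try:
            wil = analysis.wilcoxon_signed_rank(rt_p, rt_c)
            wilcoxon = {"z": wil.z, "p": wil.p, "n": wil.n}
        except DegenerateDataError:
            wilcoxon = None
        dist_c = analysis.CumulativeDistribution(analysis.PERCENTILE_GRID, rt_c)
        dist_p = analysis.CumulativeDistribution(analysis.PERCENTILE_GRID, rt_p)
        comp = analysis.compare_lines(
            analysis.reciprobit_points(dist_c), analysis.reciprobit_points(dist_p)
        )
        report["comparisons"][cat] = {
            "wilcoxon": wilcoxon,
            "t_slope": comp.t_slope,
            "p_slope": comp.p_slope,
            "df_slope": comp.df_slope,
            "t_intercept": comp.t_intercept,
            "p_intercept": comp.p_intercept,
            "df_intercept": comp.df_intercept,
        }

    # planned-onset sweep: the competition must never let an error follow a
    # completed antisaccade, at any onset delay, in either condition
    sweep_report = {}
    for name, cond in (
        ("control", control_condition()),
        ("patient", patient_condition()),
    ):
        per_delay = {}
        swept = sweep_delay(cond, ntrials=sweep_n, master_seed=seed + 100)
        for d, ens in swept.items():
            per_delay[str(d)] = {
                "correct_then_error_trials": count_correct_then_error(ens),
                "outcome_counts": ens.outcome_counts(),
            }
        sweep_report[name] = per_delay
    report["delay_sweep"] = sweep_report

    comparison = pd.DataFrame(rows)
    comparison.to_csv(out_dir / "comparison_vs_reference.csv", index=False, float_format="%.6f")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
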