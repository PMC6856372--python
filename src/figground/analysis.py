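"""End-to-end analysis of a cohort table.

Reproduces the structure of the behavioural analysis: test-retest noise
ceiling of the speech measure, Pearson correlations (with Fisher-z CIs) of
speech thresholds against the audiogram and each figure-ground task,
run-level regression models pairing runs within vs across tasks, the
hierarchical audiogram + figure-ground models, forward-stepwise selection
over all predictors, age partial correlations, a subsample comparison of
the audiogram correlation, and paired t-tests between tasks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .stats import (
    compare_independent_correlations,
    hierarchical_regression,
    noise_ceiling,
    paired_t_dz,
    partial_correlation,
    pearson,
    stepwise_forward,
    variance_explained_percent,
)

__all__ = ["analyze_cohort", "MIN_COHORT_N"]

MIN_COHORT_N = 10

#: speech-threshold predictors analysed at task level (run/block averages)
PREDICTORS = ("hf_avg", "sf_disc", "cr_disc", "cx_disc", "sf_det_dprime")


def _task_averages(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["speech"] = df[["speech_b1", "speech_b2"]].mean(axis=1)
    out["sf_disc"] = df[["sf_disc_r1", "sf_disc_r2"]].mean(axis=1)
    out["cr_disc"] = df[["cr_disc_r1", "cr_disc_r2"]].mean(axis=1)
    out["cx_disc"] = df[["cx_disc_r1", "cx_disc_r2"]].mean(axis=1)
    out["hf_avg"] = df["hf_avg"]
    out["sf_det_dprime"] = df["sf_det_dprime"]
    out["age"] = df["age"]
    return out


def _check_schema(df: pd.DataFrame) -> None:
    needed = [
        "speech_b1", "speech_b2", "hf_avg", "age", "sf_det_dprime",
        "sf_disc_r1", "sf_disc_r2", "cr_disc_r1", "cr_disc_r2",
        "cx_disc_r1", "cx_disc_r2",
    ]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if len(df) < MIN_COHORT_N:
        raise ValueError(f"cohort too small: n={len(df)} < {MIN_COHORT_N}")
    for c in needed:
        col = df[c].to_numpy(dtype=float)
        if not np.isfinite(col).all():
            raise ValueError(f"non-finite values in column {c!r}")
        if col.std() == 0:
            raise stats.DegenerateDataError(f"column {c!r} has zero variance")


def _run_level_models(df: pd.DataFrame, y: np.ndarray) -> list[dict]:
    """Models pairing individual runs within vs across tasks: do two runs of
    the same task explain speech as well as one run from each of two tasks?"""
    pairs = [
        ("sf_disc_r1", "sf_disc_r2"),
        ("sf_disc_r2", "sf_disc_r1"),
        ("sf_disc_r1", "cr_disc_r1"),
        ("sf_disc_r2", "cr_disc_r1"),
    ]
    rows = []
    for v1, v2 in pairs:
        steps = hierarchical_regression(
            y,
            [((v1,), df[v1].to_numpy(float)), ((v2,), df[v2].to_numpy(float))],
        )
        rows.append(
            {
                "variable_1": v1,
                "variable_1_r": steps[0].r,
                "variable_2": v2,
                "combined_r": steps[1].r,
                "r2_change": steps[1].r2_change,
                "p_change": steps[1].p_change,
            }
        )
    return rows


def analyze_cohort(df: pd.DataFrame, hf_exclusion_db: float = 20.0) -> dict:
    """Run the full statistical battery on a cohort table; returns a JSON-
    serialisable report."""
    _check_schema(df)
    av = _task_averages(df)
    n = len(df)
    y = av["speech"].to_numpy(float)

    report: dict = {"n": n}

    ceiling = noise_ceiling(df["speech_b1"], df["speech_b2"])
    report["noise_ceiling"] = {
        "r": ceiling["correlation"].r,
        "p": ceiling["correlation"].p,
        "ci95": list(ceiling["correlation"].ci95),
        "explainable_variance": ceiling["explainable_variance"],
    }

    corr_block = {}
    for var in PREDICTORS + ("age",):
        res = pearson(av["speech"], av[var])
        corr_block[var] = res.to_dict() | {
            "variance_explained_pct": variance_explained_percent(res.r)
        }
    report["speech_correlations"] = corr_block

    report["run_level_models"] = _run_level_models(df, y)

    # hierarchical models: audiogram first, then the figure-ground tasks
    steps = hierarchical_regression(
        y,
        [
            (("hf_avg",), av["hf_avg"].to_numpy(float)),
            (("sf_disc",), av["sf_disc"].to_numpy(float)),
            (("cr_disc",), av["cr_disc"].to_numpy(float)),
        ],
    )
    report["hierarchical_regression"] = [s.to_dict() for s in steps]

    sel = stepwise_forward(
        y, {v: av[v].to_numpy(float) for v in PREDICTORS}
    )
    report["stepwise"] = {
        "path": [s.to_dict() for s in sel["path"]],
        "excluded": sel["excluded"],
    }

    # age: zero-order and partial correlations
    age = av["age"].to_numpy(float)
    partials = {}
    for var in ("hf_avg", "sf_disc", "cr_disc"):
        partials[var] = partial_correlation(
            av["speech"], av[var], age
        ).to_dict()
    partials["sf_disc_age_and_audiogram"] = partial_correlation(
        av["speech"], av["sf_disc"],
        np.column_stack([age, av["hf_avg"].to_numpy(float)]),
    ).to_dict()
    partials["cr_disc_age_and_audiogram"] = partial_correlation(
        av["speech"], av["cr_disc"],
        np.column_stack([age, av["hf_avg"].to_numpy(float)]),
    ).to_dict()
    report["age_partials"] = partials

    # subsample check: drop listeners with any 4/8-kHz threshold above the
    # cutoff and compare the audiogram correlation across the two samples
    hf_cols = [c for c in ("aud_l_4000", "aud_l_8000", "aud_r_4000", "aud_r_8000")
               if c in df.columns]
    if hf_cols:
        keep = (df[hf_cols] <= hf_exclusion_db).all(axis=1)
        sub = av[keep.to_numpy()]
        if len(sub) >= MIN_COHORT_N and len(sub) < n:
            full = pearson(av["speech"], av["hf_avg"])
            restricted = pearson(sub["speech"], sub["hf_avg"])
            z, p = compare_independent_correlations(
                full.r, full.n, restricted.r, restricted.n
            )
            report["audiogram_subsample"] = {
                "full": full.to_dict(),
                "restricted": restricted.to_dict(),
                "n_excluded": int(n - len(sub)),
                "fisher_z": z,
                "p": p,
            }

    report["task_contrasts"] = {
        "sf_vs_cr": paired_t_dz(av["cr_disc"], av["sf_disc"]),
        "sf_vs_cx": paired_t_dz(av["cx_disc"], av["sf_disc"]),
        "cr_vs_cx": paired_t_dz(av["cr_disc"], av["cx_disc"]),
    }
    return report
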