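"""Two-level (summary-statistics) GLM for trial-level behavioral data.

Level 1 fits an ordinary least-squares model within each subject; level 2
tests the subject-level coefficients against zero with a one-sample
t-test.  This is the classic summary-statistics approach to repeated-
measures designs: it is exact when within-subject designs are balanced
and is the convention behind group reports of the form
"beta [95% CI], t(n-1), p, Cohen's d".

Cue predictors are expected on a -1/+1 coding and temperature on
-1/0/+1; "time" in cue-by-time interactions is, by default, the trial
counter within each cue condition (1..n per condition), matching how
learning curves are displayed per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import within_condition_index

__all__ = [
    "GroupEffect",
    "one_sample_group",
    "paired_contrast",
    "fit_multilevel_glm",
    "fit_time_interaction",
    "condition_timecourse",
]


@dataclass(frozen=True)
class GroupEffect:
    """Group-level summary of one predictor's subject betas."""

    name: str
    beta: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    cohens_d: float
    n_subjects: int
    subject_betas: np.ndarray

    def as_dict(self) -> dict:
        return {
            "predictor": self.name, "beta": self.beta,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "t": self.t, "df": self.df, "p": self.p,
            "cohens_d": self.cohens_d, "n_subjects": self.n_subjects,
        }


def one_sample_group(betas: np.ndarray, name: str = "",
                     alpha: float = 0.05) -> GroupEffect:
    """One-sample t-test of subject-level betas against zero.

    Cohen's d is the mean over the SD of the subject betas, so
    d * sqrt(n) = t.
    """
    betas = np.asarray(betas, float)
    betas = betas[np.isfinite(betas)]
    n = len(betas)
    if n < 2:
        raise ValueError("need at least 2 subjects for a group test")
    mean = float(betas.mean())
    sd = float(betas.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0:
        warnings.warn("zero between-subject variance", stacklevel=2)
        t = np.inf if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        return GroupEffect(name, mean, mean, mean, t, n - 1, p,
                           np.inf if mean != 0 else 0.0, n, betas)
    t = mean / se
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return GroupEffect(name, mean, mean - tcrit * se, mean + tcrit * se,
                       float(t), df, p, mean / sd, n, betas)


def paired_contrast(effect_a: GroupEffect, effect_b: GroupEffect,
                    name: str | None = None) -> GroupEffect:
    """Paired t-test of two effects' subject betas (difference a - b)."""
    if effect_a.n_subjects != effect_b.n_subjects:
        raise ValueError("paired contrast requires matched subjects")
    diff = effect_a.subject_betas - effect_b.subject_betas
    return one_sample_group(
        diff, name or f"{effect_a.name} - {effect_b.name}")


def _subject_ols(y: np.ndarray, X: np.ndarray) -> np.ndarray | None:
    """OLS coefficients, or None when the design is not estimable."""
    if len(y) < X.shape[1] + 1:
        return None
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_multilevel_glm(
    trials: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    trial_filter: str | None = None,
    subject_col: str = "subject",
    add_intercept: bool = True,
) -> dict[str, GroupEffect]:
    """Per-subject OLS of ``outcome`` on ``predictors``; group t-tests.

    ``trial_filter`` is a pandas query string (e.g. ``"temperature ==
    49"``).  Subjects with an unestimable first-level model (rank
    deficiency or too few trials) are excluded with a warning.
    """
    data = trials.query(trial_filter) if trial_filter else trials
    rows = []
    dropped = []
    for subj, grp in data.groupby(subject_col, sort=True):
        X = grp[predictors].to_numpy(float)
        if add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        beta = _subject_ols(grp[outcome].to_numpy(float), X)
        if beta is None:
            dropped.append(subj)
            continue
        rows.append([subj] + list(beta[1:] if add_intercept else beta))
    if dropped:
        warnings.warn(
            f"excluded subjects with unestimable betas: {dropped}",
            stacklevel=2)
    if len(rows) < 2:
        raise ValueError("fewer than 2 subjects with estimable betas; "
                         "no between-subject variance to test")
    mat = np.array([r[1:] for r in rows], float)
    return {p: one_sample_group(mat[:, j], p)
            for j, p in enumerate(predictors)}


def fit_time_interaction(
    trials: pd.DataFrame,
    outcome: str,
    cue: str,
    trial_filter: str | None = None,
    time_mode: str = "within_condition",
    subject_col: str = "subject",
) -> GroupEffect:
    """Group test of a cue x time interaction.

    ``time_mode='within_condition'`` uses the trial counter within each
    cue level (centered per subject); ``'absolute'`` uses the raw trial
    index.  A positive interaction beta means the cue effect grows over
    time.
    """
    data = trials.copy()
    if time_mode == "within_condition":
        data["_time"] = within_condition_index(data, cue).astype(float)
    elif time_mode == "absolute":
        data["_time"] = data["trial"].astype(float)
    else:
        raise ValueError(f"unknown time_mode {time_mode!r}")
    if trial_filter:
        data = data.query(trial_filter)

    betas = {}
    dropped = []
    for subj, grp in data.groupby(subject_col, sort=True):
        t = grp["_time"].to_numpy(float)
        t = t - t.mean()
        c = grp[cue].to_numpy(float)
        X = np.column_stack([np.ones(len(grp)), c, t, c * t])
        beta = _subject_ols(grp[outcome].to_numpy(float), X)
        if beta is None:
            dropped.append(subj)
            continue
        betas[subj] = beta[3]
    if dropped:
        warnings.warn(
            f"excluded subjects with unestimable betas: {dropped}",
            stacklevel=2)
    return one_sample_group(np.array(list(betas.values())),
                            f"{cue} x time")


def condition_timecourse(
    trials: pd.DataFrame,
    outcome: str,
    cue: str,
    window: int = 1,
    n_boot: int = 1000,
    seed: int = 0,
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Per-condition trial-binned group means with bootstrap 95% bands.

    The x-axis is the within-condition trial index; a centered running
    mean of length ``window`` smooths each subject's trace before
    averaging; bands come from resampling subjects with replacement.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    data = trials.copy()
    data["_time"] = within_condition_index(data, cue)
    rng = np.random.default_rng(seed)
    out = []
    for level, grp in data.groupby(cue, sort=True):
        pivot = grp.pivot_table(index=subject_col, columns="_time",
                                values=outcome)
        arr = pivot.to_numpy(float)
        if window > 1:
            kernel = np.ones(window) / window
            sm = np.full_like(arr, np.nan)
            for i in range(arr.shape[0]):
                valid = np.isfinite(arr[i])
                if valid.all():
                    sm[i] = np.convolve(arr[i], kernel, mode="same")
                else:
                    sm[i] = arr[i]
            arr = sm
        mean = np.nanmean(arr, axis=0)
        idx = rng.integers(0, arr.shape[0], size=(n_boot, arr.shape[0]))
        boot = np.nanmean(arr[idx], axis=1)
        lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
        for j, t in enumerate(pivot.columns):
            out.append({cue: level, "within_trial": int(t),
                        "mean": mean[j], "ci_low": lo[j], "ci_high": hi[j]})
    return pd.DataFrame(out)
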