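"""Multilevel three-path mediation with bootstrap inference.

The model is estimated in two stages.  Within each subject, three OLS
regressions with a shared covariate set give the path coefficients

    M = i1 + a X + f1' Cov            (path a: treatment -> mediator)
    Y = i2 + b M + c' X + f2' Cov     (paths b and c': controlling X)
    Y = i3 + c X + f3' Cov            (path c: total effect)

which satisfy the exact OLS identity c = c' + a*b.  At the group stage,
each path's subject-level estimates are tested by a bias-corrected
percentile bootstrap over subjects (resampling subjects with
replacement).  The mediated effect ab is tested as the mean of the
subject-level products a_i * b_i, so the group estimate carries both the
product-of-means and the between-subject covariance component:

    mean(a_i b_i) = mean(a) mean(b) + (n-1)/n cov(a, b).

A fast one-sample-t fallback on the subject estimates is provided for
smoke-scale runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multilevel import one_sample_group

__all__ = [
    "BootstrapSettings",
    "MediationResult",
    "ModerationResult",
    "fit_subject_paths",
    "fit_paths_by_subject",
    "group_mediation",
    "moderated_mediation",
    "boot_bca_pvalues",
]

PATHS = ("a", "b", "c", "cprime", "ab")


@dataclass(frozen=True)
class BootstrapSettings:
    """Group-stage inference settings.

    ``method='bootstrap'`` is the bias-corrected percentile bootstrap
    over subjects; ``'t'`` is a one-sample t-test on the subject-level
    estimates (fast fallback with the same point estimates).
    """

    n_resamples: int = 10000
    seed: int = 0
    method: str = "bootstrap"
    alpha: float = 0.05


@dataclass
class MediationResult:
    """Group mediation estimates for paths a, b, c, c', ab."""

    estimates: dict[str, float]
    ses: dict[str, float]
    pvalues: dict[str, float]
    cis: dict[str, tuple[float, float]]
    n_subjects: int
    subject_paths: pd.DataFrame
    settings: BootstrapSettings
    decomposition: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "paths": {
                p: {"estimate": self.estimates[p], "se": self.ses[p],
                    "p": self.pvalues[p], "ci": list(self.cis[p])}
                for p in PATHS
            },
            "n_subjects": self.n_subjects,
            "decomposition": self.decomposition,
            "method": self.settings.method,
        }


def fit_subject_paths(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, float]:
    """Three-regression path estimates for one subject.

    ``covariates`` (n_trials x k) enter all three regressions, so the
    c = c' + ab identity holds to machine precision.  Raises on rank
    deficiency or too few trials.
    """
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if len(m) != n or len(y) != n:
        raise ValueError("X, M, Y must be aligned per trial")
    cov = (np.empty((n, 0)) if covariates is None
           else np.atleast_2d(np.asarray(covariates, float)))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariates not aligned with trials")

    Z = np.column_stack([np.ones(n), x, cov])        # for M~X and Y~X
    Zm = np.column_stack([np.ones(n), m, x, cov])    # for Y~M+X
    p = Zm.shape[1]
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} trials, got {n}")
    if (np.linalg.matrix_rank(Z) < Z.shape[1]
            or np.linalg.matrix_rank(Zm) < p):
        raise ValueError("rank-deficient first-level design")

    beta1, *_ = np.linalg.lstsq(Z, m, rcond=None)
    beta2, *_ = np.linalg.lstsq(Zm, y, rcond=None)
    beta3, *_ = np.linalg.lstsq(Z, y, rcond=None)
    a = float(beta1[1])
    b = float(beta2[1])
    cprime = float(beta2[2])
    c = float(beta3[1])
    return {"a": a, "b": b, "c": c, "cprime": cprime, "ab": a * b}


def fit_paths_by_subject(
    trials: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    trial_filter: str | None = None,
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Per-subject mediation paths from a tidy trial table.

    Subjects whose first-level fit fails are excluded with a warning.
    """
    data = trials.query(trial_filter) if trial_filter else trials
    rows, dropped = [], []
    for subj, grp in data.groupby(subject_col, sort=True):
        cov = grp[covariates].to_numpy(float) if covariates else None
        try:
            paths = fit_subject_paths(
                grp[x].to_numpy(float), grp[m].to_numpy(float),
                grp[y].to_numpy(float), cov)
        except ValueError as err:
            dropped.append((subj, str(err)))
            continue
        rows.append({"subject": subj, **paths})
    if dropped:
        warnings.warn(f"excluded subjects from mediation: {dropped}",
                      stacklevel=2)
    return pd.DataFrame(rows)


def boot_bca_pvalues(
    values: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
    resample_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bias-corrected bootstrap test of column means against zero.

    ``values`` is (n_subjects, k); one common subject-resampling plan is
    used for all k columns.  Returns (estimate, se, p, boot_means) where
    ``boot_means`` is the (n_resamples, k) bootstrap distribution.

    The two-sided p-value inverts the bias-corrected percentile CI:
    with G the bootstrap CDF and z0 = Phi^-1(G(theta_hat)),
    p = 2 min{Phi(w), 1 - Phi(w)} for w = Phi^-1(G(0)) - 2 z0.
    """
    values = np.atleast_2d(np.asarray(values, float))
    if values.ndim == 1:
        values = values[:, None]
    n, k = values.shape
    est = values.mean(axis=0)
    if resample_idx is None:
        resample_idx = rng.integers(0, n, size=(n_resamples, n))
    # counts matrix keeps memory at (B x n) + (B x k)
    counts = np.zeros((resample_idx.shape[0], n))
    np.add.at(counts, (np.arange(resample_idx.shape[0])[:, None],
                       resample_idx), 1.0)
    boot = (counts @ values) / n
    B = boot.shape[0]

    se = boot.std(axis=0, ddof=1)
    eps = 1.0 / (B + 1)

    def _cdf_at(q):
        return np.clip(((boot < q).sum(axis=0)
                        + 0.5 * (boot == q).sum(axis=0)) / B, eps, 1 - eps)

    z0 = stats.norm.ppf(_cdf_at(est))
    w = stats.norm.ppf(_cdf_at(0.0)) - 2 * z0
    p = 2 * np.minimum(stats.norm.cdf(w), stats.norm.sf(w))
    # degenerate columns: no bootstrap variability
    degen = se == 0
    if degen.any():
        p = p.copy()
        p[degen] = np.where(est[degen] != 0, 0.0, 1.0)
    return est, se, np.clip(p, 2 * eps, 1.0), boot


def _bca_ci(boot: np.ndarray, est: float, alpha: float) -> tuple[float, float]:
    B = len(boot)
    eps = 1.0 / (B + 1)
    g = np.clip(((boot < est).sum() + 0.5 * (boot == est).sum()) / B,
                eps, 1 - eps)
    z0 = stats.norm.ppf(g)
    zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    qlo = stats.norm.cdf(2 * z0 + zlo)
    qhi = stats.norm.cdf(2 * z0 + zhi)
    return tuple(np.percentile(boot, [100 * qlo, 100 * qhi]))


def group_mediation(
    subject_paths: pd.DataFrame,
    settings: BootstrapSettings | None = None,
) -> MediationResult:
    """Group-level inference on subject path estimates.

    Resamples subjects with replacement (one common plan across paths)
    and tests each path mean against zero with the bias-corrected
    percentile bootstrap; deterministic given the settings seed.
    """
    settings = settings or BootstrapSettings()
    paths = subject_paths.dropna(subset=list(PATHS))
    n = len(paths)
    if n < 3:
        raise ValueError("need at least 3 subjects for group mediation")
    mat = paths[list(PATHS)].to_numpy(float)

    a = mat[:, PATHS.index("a")]
    b = mat[:, PATHS.index("b")]
    decomposition = {
        "mean_a_mean_b": float(a.mean() * b.mean()),
        "cov_ab": float(((n - 1) / n) * np.cov(a, b, ddof=1)[0, 1]),
    }

    if settings.method == "t":
        est, ses, ps, cis = {}, {}, {}, {}
        for j, pth in enumerate(PATHS):
            eff = one_sample_group(mat[:, j], pth, settings.alpha)
            est[pth] = eff.beta
            ses[pth] = (eff.beta / eff.t if eff.t not in (0.0, np.inf)
                        else float(mat[:, j].std(ddof=1) / np.sqrt(n)))
            ps[pth] = eff.p
            cis[pth] = (eff.ci_low, eff.ci_high)
        return MediationResult(est, ses, ps, cis, n, paths, settings,
                               decomposition)
    if settings.method != "bootstrap":
        raise ValueError(f"unknown method {settings.method!r}")

    if np.allclose(mat, mat[0], atol=0):
        warnings.warn("zero between-subject variance; bootstrap is "
                      "degenerate", stacklevel=2)
    rng = np.random.default_rng(settings.seed)
    est, se, p, boot = boot_bca_pvalues(mat, settings.n_resamples, rng)
    cis = {pth: _bca_ci(boot[:, j], est[j], settings.alpha)
           for j, pth in enumerate(PATHS)}
    return MediationResult(
        dict(zip(PATHS, est)), dict(zip(PATHS, se)), dict(zip(PATHS, p)),
        cis, n, paths, settings, decomposition)


@dataclass
class ModerationResult:
    """Second-level moderation of subject slopes by a subject covariate."""

    beta: float
    se: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    flagged_subjects: list
    leverage: np.ndarray
    student_resid: np.ndarray


def moderated_mediation(
    subject_values: np.ndarray,
    moderator: np.ndarray,
    subjects: np.ndarray | None = None,
    flag_sd: float = 3.0,
    alpha: float = 0.05,
) -> ModerationResult:
    """Regress subject-level slopes on a subject-level moderator.

    Flags influential subjects: standardized values of either variable
    beyond ``flag_sd`` SDs, or leverage above three times its mean —
    individual-difference moderation at this sample size is fragile to
    single extreme participants.
    """
    yv = np.asarray(subject_values, float).ravel()
    mo = np.asarray(moderator, float).ravel()
    if len(yv) != len(mo):
        raise ValueError("one moderator value per subject required")
    if np.std(mo) == 0:
        raise ValueError("constant moderator")
    n = len(yv)
    subjects = np.arange(n) if subjects is None else np.asarray(subjects)

    X = np.column_stack([np.ones(n), mo])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    H = X @ xtx_inv @ X.T
    lev = np.diag(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        stud = resid / np.sqrt(sigma2 * (1 - lev))
    zy = (yv - yv.mean()) / yv.std(ddof=1)
    zm = (mo - mo.mean()) / mo.std(ddof=1)
    flagged = np.flatnonzero(
        (np.abs(zy) > flag_sd) | (np.abs(zm) > flag_sd)
        | (lev > 3 * lev.mean()))
    return ModerationResult(
        float(beta[1]), se, t, df, p,
        (float(beta[1] - tcrit * se), float(beta[1] + tcrit * se)),
        list(subjects[flagged]), lev, stud)
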