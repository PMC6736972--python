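"""First-level estimation: outlier time points, single-trial GLMs, SCR.

Covers the rules applied before any group statistic: recursive
("step-down") identification of outlier time points on robust global and
Mahalanobis criteria, single-trial OLS with per-trial variance inflation
factors, exclusion of trials whose regressors exceed VIF 2.5, and
single-trial skin-conductance amplitude estimation by deconvolution with
a canonical response kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TimeSeriesRun",
    "SpikeReport",
    "detect_spikes",
    "fit_single_trial_glm",
    "apply_vif_filter",
    "compute_vifs",
    "scr_canonical_kernel",
    "lowpass_filter",
    "fit_scr_glm",
]

#: scale factor making the m.a.d. a consistent SD estimate under normality
MAD_NORMAL_SCALE = 1.4826


@dataclass
class TimeSeriesRun:
    """One run of multichannel time-series data (time x channels).

    For fMRI, channels are voxels (or slice summaries) and
    ``slice_labels`` assigns each channel to an acquisition slice; for
    SCR, a single channel.
    """

    data: np.ndarray
    sampling_rate: float
    label: str = ""
    slice_labels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channels)")
        if self.data.shape[0] == 1 and self.data.shape[1] > 1:
            # a single channel passed as a row vector
            self.data = self.data.T
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if np.isnan(self.data).any():
            raise ValueError("missing samples are not supported")


@dataclass
class SpikeReport:
    """Flagged outlier time points with the criterion and iteration."""

    indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    criteria: list[str] = field(default_factory=list)
    iterations: list[int] = field(default_factory=list)
    n_samples: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.indices,
                             "criterion": self.criteria,
                             "iteration": self.iterations})

    def indicator_columns(self) -> np.ndarray:
        """Unit-indicator nuisance columns, one per flagged time point."""
        cols = np.zeros((self.n_samples, len(self.indices)))
        cols[self.indices, np.arange(len(self.indices))] = 1.0
        return cols


def _mad(x: np.ndarray, scale: float) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)) * scale)


def _robust_deviation(x: np.ndarray, keep: np.ndarray,
                      scale: float) -> np.ndarray:
    """|x - median| / m.a.d., statistics computed over kept samples only."""
    med = np.median(x[keep])
    mad = _mad(x[keep], scale)
    if mad == 0:
        # degenerate reference: any deviation is infinitely surprising
        dev = np.abs(x - med)
        return np.where(dev > 0, np.inf, 0.0)
    return np.abs(x - med) / mad


def _slice_features(data: np.ndarray,
                    slice_labels: np.ndarray | None) -> np.ndarray:
    """Per-time-point feature matrix of slice-wise means and spatial SDs."""
    if slice_labels is None:
        slice_labels = np.zeros(data.shape[1], int)
    feats = []
    for lab in np.unique(slice_labels):
        cols = data[:, slice_labels == lab]
        feats.append(cols.mean(axis=1))
        feats.append(cols.std(axis=1))
    return np.column_stack(feats)


def _mahalanobis(features: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each row from the kept rows' centroid.

    Covariance is estimated on kept rows only and shrunk toward its
    diagonal when ill-conditioned.
    """
    ref = features[keep]
    mu = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False)
    cov = np.atleast_2d(cov)
    diag = np.diag(np.diag(cov))
    lam = 0.0
    while np.linalg.cond(cov * (1 - lam) + diag * lam + 1e-12 *
                         np.eye(len(cov))) > 1e8 and lam < 1:
        lam = min(1.0, lam + 0.1)
    cov = cov * (1 - lam) + diag * lam + 1e-12 * np.eye(len(cov))
    vi = np.linalg.inv(cov)
    d = features - mu
    return np.sqrt(np.einsum("ij,jk,ik->i", d, vi, d))


def detect_spikes(
    run: TimeSeriesRun,
    mad_threshold: float = 10.0,
    max_iter: int = 3,
    use_mahalanobis: bool = True,
    mad_scale: float = MAD_NORMAL_SCALE,
) -> SpikeReport:
    """Recursive outlier time-point detection (step-down test).

    A time point is flagged when either (a) the global (cross-channel
    mean) signal deviates from the run median by more than
    ``mad_threshold`` m.a.d., or (b) its Mahalanobis distance over
    slice-wise means and spatial SDs deviates by more than the same
    number of m.a.d.  After each iteration flagged points are removed
    from the reference statistics and the test repeats, up to
    ``max_iter`` iterations, so that large outliers cannot mask smaller
    ones.

    Set ``mad_scale=1.0`` for a raw (unscaled) m.a.d. convention.
    """
    data = run.data
    n = data.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for spike detection")
    global_sig = data.mean(axis=1)

    features = None
    if use_mahalanobis:
        features = _slice_features(data, run.slice_labels)
        if n <= features.shape[1]:
            warnings.warn(
                "fewer time points than Mahalanobis features; falling back "
                "to the global criterion only", stacklevel=2)
            features = None

    report = SpikeReport(n_samples=n)
    flagged = np.zeros(n, bool)
    for it in range(1, max_iter + 1):
        keep = ~flagged
        new: dict[int, str] = {}
        dev = _robust_deviation(global_sig, keep, mad_scale)
        for idx in np.flatnonzero((dev > mad_threshold) & keep):
            new[int(idx)] = "global-mad"
        if features is not None:
            d = _mahalanobis(features, keep)
            ddev = _robust_deviation(d, keep, mad_scale)
            for idx in np.flatnonzero((ddev > mad_threshold) & keep):
                new.setdefault(int(idx), "mahalanobis-mad")
        if not new:
            break
        for idx in sorted(new):
            flagged[idx] = True
            report.criteria.append(new[idx])
            report.iterations.append(it)
        report.indices = np.append(report.indices,
                                   sorted(new)).astype(int)
    return report


# --------------------------------------------------------------------------
# single-trial GLM + VIF
# --------------------------------------------------------------------------

def compute_vifs(design: np.ndarray,
                 columns: np.ndarray | None = None) -> np.ndarray:
    """Variance inflation factor of each requested column vs. all others.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing column j on
    the remaining columns.  Exactly collinear columns get ``inf``.
    """
    design = np.asarray(design, float)
    p = design.shape[1]
    cols = np.arange(p) if columns is None else np.asarray(columns, int)
    vifs = np.empty(len(cols))
    for k, j in enumerate(cols):
        y = design[:, j]
        X = np.delete(design, j, axis=1)
        if X.shape[1] == 0:
            vifs[k] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = float(y @ y)
        if sst == 0:
            vifs[k] = np.inf
            continue
        r2 = 1 - float(resid @ resid) / sst
        vifs[k] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def fit_single_trial_glm(
    data: np.ndarray,
    design: np.ndarray,
    trial_columns: np.ndarray,
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS single-trial betas plus per-trial VIFs.

    ``data`` is (time x channels), ``design`` the full matrix including
    trial, condition, and nuisance columns, and ``trial_columns`` the
    column indices of the single-trial regressors.  Returns
    ``(betas, vifs)`` with betas of shape (n_trials, n_channels).

    Exactly collinear *trial* regressors are tolerated (their VIF is
    ``inf``, so the VIF filter removes them); rank deficiency among the
    remaining columns raises with the offending column names.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] != design.shape[0]:
        raise ValueError("data and design have incompatible lengths")
    trial_columns = np.asarray(trial_columns, int)
    names = (column_names if column_names is not None
             else [f"col{j}" for j in range(design.shape[1])])

    vifs = compute_vifs(design, trial_columns)

    other = np.setdiff1d(np.arange(design.shape[1]), trial_columns)
    ok_trials = trial_columns[np.isfinite(vifs)]
    reduced = design[:, np.concatenate([ok_trials, other])]
    rank = np.linalg.matrix_rank(reduced)
    if rank < reduced.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        basis = np.empty((design.shape[0], 0))
        for j in np.concatenate([ok_trials, other]):
            cand = np.column_stack([basis, design[:, j]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                basis = cand
            else:
                bad.append(names[j])
        raise ValueError(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(bad))

    betas, *_ = np.linalg.lstsq(design, data, rcond=None)
    return betas[trial_columns], vifs


def apply_vif_filter(
    betas: np.ndarray,
    vifs: np.ndarray,
    threshold: float = 2.5,
    subject: int | str | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Drop trials whose regressor VIF exceeds the threshold (strict >).

    Returns (filtered betas, kept trial indices, exclusion log).
    """
    vifs = np.asarray(vifs, float)
    betas = np.asarray(betas)
    if len(vifs) != betas.shape[0]:
        raise ValueError("betas and vifs are not aligned")
    keep = ~(vifs > threshold)
    log = pd.DataFrame({
        "subject": subject if subject is not None else "",
        "trial": np.flatnonzero(~keep),
        "vif": vifs[~keep],
    })
    if not keep.any():
        warnings.warn("all trials excluded by the VIF filter", stacklevel=2)
    return betas[keep], np.flatnonzero(keep), log


# --------------------------------------------------------------------------
# SCR
# --------------------------------------------------------------------------

def scr_canonical_kernel(
    sampling_rate: float,
    shape: float = 3.0,
    scale: float = 1.3,
    duration: float = 20.0,
) -> np.ndarray:
    """Canonical skin-conductance response kernel (gamma family).

    ``k(t) = t^(shape-1) exp(-t/scale)``, normalized to unit peak, over
    ``duration`` seconds.  The two parameters set onset/rise and decay;
    defaults give a rise to peak at ~2.6 s and a slow decay, a
    conventional phasic SCR shape.
    """
    t = np.arange(0, duration, 1.0 / sampling_rate)
    k = t ** (shape - 1) * np.exp(-t / scale)
    peak = k.max()
    if peak == 0:
        raise ValueError("degenerate kernel")
    return k / peak


def lowpass_filter(x: np.ndarray, sampling_rate: float,
                   cutoff: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter."""
    sos = signal.butter(order, cutoff, fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float))


def fit_scr_glm(
    scr: np.ndarray | TimeSeriesRun,
    onsets: np.ndarray,
    sampling_rate: float | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Single-trial SCR amplitudes by GLM deconvolution.

    Each onset (in seconds) contributes one stick regressor convolved
    with the canonical kernel; overlapping responses are separated by the
    joint OLS fit.  The series is expected to be low-pass filtered and
    normalized upstream (see :func:`lowpass_filter`).
    """
    if isinstance(scr, TimeSeriesRun):
        sampling_rate = scr.sampling_rate
        series = scr.data[:, 0]
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        series = np.asarray(scr, float).ravel()
    onsets = np.asarray(onsets, float)
    n = len(series)
    if kernel is None:
        kernel = scr_canonical_kernel(sampling_rate)
    samples = np.round(onsets * sampling_rate).astype(int)
    if (samples < 0).any() or (samples >= n).any():
        raise ValueError("onsets fall outside the run")

    design = np.zeros((n, len(onsets) + 1))
    design[:, -1] = 1.0  # baseline
    for j, s in enumerate(samples):
        stick = np.zeros(n)
        stick[s] = 1.0
        design[:, j] = np.convolve(stick, kernel)[:n]
    betas, *_ = np.linalg.lstsq(design, series, rcond=None)
    return betas[:-1]
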