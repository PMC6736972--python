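"""Voxelwise mediation maps: thresholding, conjunction, overlap, signatures.

Applies the two-level mediation model independently at every in-mask
voxel (the voxel's single-trial betas are the mediator), then controls
the false discovery rate with Benjamini-Hochberg step-up — by
convention pooled across the tested mediation paths of a model — and
prunes lenient display tiers (p < .01, p < .05 uncorrected) to connected
components that touch at least one FDR-significant voxel.  Also provides
conjunction-null intersections, the Dice overlap coefficient, and
dot-product scoring of signature weight maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .mediation import boot_bca_pvalues

__all__ = [
    "StatMaps",
    "ThresholdedMap",
    "voxelwise_mediation",
    "fdr_threshold",
    "prune_display",
    "threshold_map",
    "conjunction",
    "dice",
    "score_signature",
    "to_volume",
]

#: paths entering the pooled FDR correction
MAP_PATHS = ("a", "b", "ab")
#: all paths carried on the maps (c' is reported but not FDR-tested)
ALL_PATHS = ("a", "b", "ab", "cprime")
TIER_NONE, TIER_P05, TIER_P01, TIER_FDR = 0, 1, 2, 3


def to_volume(values: np.ndarray, mask: np.ndarray,
              fill: float = 0.0) -> np.ndarray:
    """Embed an in-mask vector into the 3-D grid."""
    vol = np.full(mask.shape, fill, dtype=float)
    vol[mask] = values
    return vol


@dataclass
class StatMaps:
    """Per-voxel mediation statistics for one model (Social or CS).

    ``effects``/``pvalues`` map path name -> in-mask vector;
    ``subject_effects`` keeps the per-subject path estimates
    (n_subjects x n_voxels) for downstream subnetwork and classification
    analyses.
    """

    model: str
    effects: dict[str, np.ndarray]
    pvalues: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray
    subject_effects: dict[str, np.ndarray] = field(default_factory=dict)
    n_flagged_voxels: int = 0


@dataclass
class ThresholdedMap:
    """Tiered threshold result for one statistic map.

    ``tier`` per in-mask voxel: 3 = FDR-significant, 2 = p < .01 within a
    retained component, 1 = p < .05 within a retained component, 0 =
    none.  ``sign`` carries the effect sign.  ``attained_p`` is the
    realized voxel-level p cutoff of the FDR tier.
    """

    tier: np.ndarray
    sign: np.ndarray
    attained_p: float
    mask: np.ndarray
    affine: np.ndarray
    model: str = ""
    path: str = ""

    def binary(self, min_tier: int = TIER_FDR) -> np.ndarray:
        return self.tier >= min_tier

    def display_values(self, effects: np.ndarray) -> np.ndarray:
        """Signed effects zeroed outside surviving tiers."""
        return np.where(self.tier > 0, effects, 0.0)


def _subject_voxel_paths(
    data: np.ndarray, x: np.ndarray, y: np.ndarray, cov: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-voxel paths (a, b, ab, c') for one subject.

    Path a comes from M ~ 1 + X + cov for every voxel at once; path b
    uses the Frisch-Waugh residualization of M and Y on [1, X, cov],
    which is algebraically identical to the full OLS of
    Y ~ 1 + M + X + cov, and c' follows from the exact identity
    c' = c - a*b.  Voxels with zero residual mediator variance return
    NaN.
    """
    n = len(x)
    Z = np.column_stack([np.ones(n), x] if cov is None
                        else [np.ones(n), x, cov])
    pinv = np.linalg.pinv(Z)
    coefs = pinv @ data            # (k, V)
    a = coefs[1]
    resid_m = data - Z @ coefs
    gamma = pinv @ y
    c = float(gamma[1])
    resid_y = y - Z @ gamma
    mm = np.einsum("ij,ij->j", resid_m, resid_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.einsum("ij,i->j", resid_m, resid_y) / mm
    b[mm <= 1e-300] = np.nan
    ab = a * b
    return a, b, ab, c - ab


def voxelwise_mediation(
    datasets: dict[int, np.ndarray],
    trials: pd.DataFrame,
    x: str,
    y: str = "pain",
    covariates: list[str] | None = None,
    trial_filter: str | None = "temperature == 49",
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    n_resamples: int = 2000,
    seed: int = 0,
    model: str | None = None,
    method: str = "t",
) -> StatMaps:
    """Mass-univariate mediation across voxels for one cue model.

    ``datasets[subject]`` is a (n_trials, n_voxels) array aligned
    row-wise with that subject's rows in ``trials`` (sorted by trial).
    Only trials passing ``trial_filter`` (default: the medium-temperature
    trials, controlling for stimulus intensity) enter the model.

    Group inference per path defaults to a vectorized one-sample t-test
    on the subject estimates (``method='t'``), whose tail p-values are
    well calibrated and keep the downstream FDR control valid at this
    sample size; ``method='bootstrap'`` uses the bias-corrected subject
    bootstrap with one common resampling plan across voxels (the
    mediation-toolbox convention), whose extreme-tail p-values run
    anti-conservative with a few dozen subjects.
    """
    trials = trials.sort_values(["subject", "trial"])
    subjects = sorted(datasets)
    n_vox = next(iter(datasets.values())).shape[1]

    per_subject = {p: [] for p in ALL_PATHS}
    for subj in subjects:
        grp = trials[trials["subject"] == subj].reset_index(drop=True)
        data = datasets[subj]
        if len(grp) != data.shape[0]:
            raise ValueError(
                f"subject {subj}: trial table and dataset are misaligned")
        sel = (grp.query(trial_filter).index.to_numpy()
               if trial_filter else grp.index.to_numpy())
        xv = grp.loc[sel, x].to_numpy(float)
        yv = grp.loc[sel, y].to_numpy(float)
        cov = (grp.loc[sel, covariates].to_numpy(float)
               if covariates else None)
        a, b, ab, cprime = _subject_voxel_paths(data[sel], xv, yv, cov)
        per_subject["a"].append(a)
        per_subject["b"].append(b)
        per_subject["ab"].append(ab)
        per_subject["cprime"].append(cprime)

    subject_effects = {p: np.vstack(v) for p, v in per_subject.items()}
    bad = ~np.isfinite(subject_effects["b"])
    n_flagged = int(bad.any(axis=0).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} voxels with zero mediator variance in "
                      "some subject; p set to 1 there", stacklevel=2)

    if method not in ("bootstrap", "t"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n_subj = len(subjects)
    resample_idx = rng.integers(0, n_subj, size=(n_resamples, n_subj))
    effects, pvalues = {}, {}
    for p in ALL_PATHS:
        vals = subject_effects[p]
        valid = np.isfinite(vals).all(axis=0)
        est = np.full(n_vox, np.nan)
        pv = np.ones(n_vox)
        if valid.any():
            if method == "t":
                sub = vals[:, valid]
                e = sub.mean(axis=0)
                se = sub.std(axis=0, ddof=1) / np.sqrt(n_subj)
                with np.errstate(divide="ignore", invalid="ignore"):
                    tstat = e / se
                pcol = 2 * stats.t.sf(np.abs(tstat), n_subj - 1)
                pcol[se == 0] = np.where(e[se == 0] != 0, 0.0, 1.0)
            else:
                e, _, pcol, _ = boot_bca_pvalues(
                    vals[:, valid], n_resamples, rng,
                    resample_idx=resample_idx)
            est[valid] = e
            pv[valid] = pcol
        effects[p] = est
        pvalues[p] = pv

    if mask is None:
        mask = np.ones((n_vox, 1, 1), bool)
    if affine is None:
        affine = np.eye(4)
    return StatMaps(model or x, effects, pvalues, mask, affine,
                    subject_effects, n_flagged)


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

def fdr_threshold(
    pvalues: np.ndarray | list[np.ndarray],
    q: float = 0.05,
) -> tuple[list[np.ndarray], float]:
    """Benjamini-Hochberg step-up over (optionally pooled) p-vectors.

    Pass one vector per tested path to pool the correction across paths
    (the convention for mediation maps corrected "across the whole brain
    and mediation paths"); a single vector gives a per-map correction.
    Returns per-vector rejection masks and the attained voxel-level p
    cutoff (largest rejected p; 0.0 when nothing is rejected).
    """
    if isinstance(pvalues, np.ndarray):
        pvalues = [pvalues]
    lengths = [len(p) for p in pvalues]
    if sum(lengths) == 0:
        raise ValueError("empty p-value input (empty mask?)")
    pooled = np.concatenate([np.asarray(p, float) for p in pvalues])
    if (pooled < 0).any() or (pooled > 1).any() or np.isnan(pooled).any():
        raise ValueError("invalid p-values")
    reject = multipletests(pooled, alpha=q, method="fdr_bh")[0]
    attained = float(pooled[reject].max()) if reject.any() else 0.0
    out = []
    start = 0
    for ln in lengths:
        out.append(reject[start:start + ln])
        start += ln
    return out, attained


def prune_display(
    pvalues: np.ndarray,
    fdr_mask: np.ndarray,
    mask: np.ndarray,
    p01: float = 0.01,
    p05: float = 0.05,
    connectivity: int = 26,
) -> np.ndarray:
    """Display-tier assignment with component pruning.

    Connected components of the lenient (p < ``p05``) map are retained
    only if they contain at least one FDR-significant voxel; within
    retained components voxels are tiered by p < ``p01`` vs p < ``p05``.
    FDR voxels always keep the top tier.  Returns the in-mask tier
    vector.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(
        3, {6: 1, 18: 2, 26: 3}[connectivity])
    lenient = to_volume((pvalues < p05).astype(float), mask) > 0
    labels, n_comp = ndimage.label(lenient, structure=structure)
    fdr_vol = to_volume(fdr_mask.astype(float), mask) > 0
    keep_ids = np.unique(labels[fdr_vol])
    keep_ids = keep_ids[keep_ids > 0]
    retained = np.isin(labels, keep_ids)

    tier_vol = np.zeros(mask.shape, int)
    p01_vol = to_volume((pvalues < p01).astype(float), mask) > 0
    tier_vol[retained] = TIER_P05
    tier_vol[retained & p01_vol] = TIER_P01
    tier_vol[fdr_vol] = TIER_FDR
    return tier_vol[mask]


def threshold_map(
    stat_maps: StatMaps,
    path: str,
    q: float = 0.05,
    pool_paths: bool = True,
    p01: float = 0.01,
    p05: float = 0.05,
    connectivity: int = 26,
) -> ThresholdedMap:
    """FDR tiering of one path's map with pruned display tiers."""
    if pool_paths:
        vecs = [stat_maps.pvalues[p] for p in MAP_PATHS]
        rejects, attained = fdr_threshold(vecs, q)
        fdr_mask = rejects[MAP_PATHS.index(path)]
    else:
        (fdr_mask,), attained = fdr_threshold(stat_maps.pvalues[path], q)
    tier = prune_display(stat_maps.pvalues[path], fdr_mask, stat_maps.mask,
                         p01, p05, connectivity)
    sign = np.sign(np.nan_to_num(stat_maps.effects[path]))
    return ThresholdedMap(tier, sign, attained, stat_maps.mask,
                          stat_maps.affine, stat_maps.model, path)


# --------------------------------------------------------------------------
# conjunction / overlap / signatures
# --------------------------------------------------------------------------

def _as_binary(m, min_tier: int = 1) -> np.ndarray:
    if isinstance(m, ThresholdedMap):
        return m.binary(min_tier)
    return np.asarray(m, bool)


def conjunction(map1, map2, min_tier: int = 1) -> np.ndarray:
    """Conjunction-null intersection: significant in BOTH maps.

    Inputs are boolean vectors or :class:`ThresholdedMap` (any surviving
    display tier counts by default; pass ``min_tier=3`` for FDR-only).
    """
    b1, b2 = _as_binary(map1, min_tier), _as_binary(map2, min_tier)
    if b1.shape != b2.shape:
        raise ValueError("conjunction requires maps on the same grid")
    return b1 & b2


def dice(mask1, mask2) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 0 when both sets are empty."""
    a, b = _as_binary(mask1), _as_binary(mask2)
    if a.shape != b.shape:
        raise ValueError("dice requires masks on the same grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def score_signature(dataset: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Per-trial signature responses: dot product of weights with images.

    ``dataset`` is (n_trials, n_voxels) and ``pattern`` a weight vector
    on the same in-mask grid.
    """
    dataset = np.asarray(dataset, float)
    pattern = np.asarray(pattern, float).ravel()
    if dataset.shape[1] != pattern.shape[0]:
        raise ValueError("pattern and data grids do not overlap")
    if not np.isfinite(pattern).all():
        raise ValueError("pattern weights must be finite")
    return dataset @ pattern
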