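"""Synthetic pain-learning experiments with known ground truth.

Emulates a within-subject cue-conditioning design in which every trial
presents two cues — symbolic social information (other people's pain
ratings, nonpredictive of the stimulus) and a partially reinforced
conditioned stimulus (CS, predictive of stimulus intensity) — followed by
thermal stimulation at 48, 49 or 50 degC, an expectation rating, a pain
rating, and a skin-conductance response.  Behavior is generated with an
explicit mediation structure (cues -> expectation -> pain) plus direct
cue effects and time-varying cue weights, and single-trial "beta" brain
volumes carry planted voxel populations (social mediators, CS mediators,
pain-only voxels, pure-noise voxels) whose generative path coefficients
are returned so that every downstream stage can be scored for recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignConfig",
    "SocialStimulus",
    "BehaviorParams",
    "BehaviorData",
    "BrainParams",
    "BrainData",
    "generate_design",
    "generate_social_stimuli",
    "generate_behavior",
    "generate_brain",
    "behavior_ground_truth",
    "default_social_time_profile",
    "default_cs_time_profile",
]

LOW, HIGH = -1, 1


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConfig:
    """Trial-structure parameters of the pain-learning task.

    The default configuration is the study design: 36 subjects, 6 runs of
    16 trials, temperatures 48/49/50 degC with marginal probabilities
    25/50/25%, CS_LOW reinforced with 48 or 49 degC (50/50) and CS_HIGH
    with 49 or 50 degC (50/50), and the social cue counterbalanced to be
    statistically independent of temperature.
    """

    n_subjects: int = 36
    n_trials: int = 96
    n_runs: int = 6
    trials_per_run: int = 16
    temperatures: tuple[float, ...] = (48.0, 49.0, 50.0)
    # CS level (-1 low / +1 high) -> {temperature: probability}
    cs_contingency: Mapping[int, Mapping[float, float]] = field(
        default_factory=lambda: {
            LOW: {48.0: 0.5, 49.0: 0.5},
            HIGH: {49.0: 0.5, 50.0: 0.5},
        }
    )
    rng_seed: int = 0

    def validate(self) -> None:
        if self.trials_per_run * self.n_runs != self.n_trials:
            raise ValueError(
                f"trials_per_run ({self.trials_per_run}) x n_runs "
                f"({self.n_runs}) != n_trials ({self.n_trials})"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for level, dist in self.cs_contingency.items():
            total = float(sum(dist.values()))
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"cs_contingency for CS level {level} sums to {total}, "
                    "probabilities must sum to 1"
                )
            unknown = set(dist) - set(self.temperatures)
            if unknown:
                raise ValueError(
                    f"cs_contingency for CS level {level} references "
                    f"temperatures {sorted(unknown)} not in {self.temperatures}"
                )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (sum to 1)."""
    raw = weights * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Generate the counterbalanced trial table for all subjects.

    Cell counts (CS x temperature x social) are allocated deterministically
    from the configured contingencies, so the design marginals are exact
    for every seed; the seed only randomizes trial order within subject.

    Returns a tidy DataFrame with columns ``subject``, ``run``, ``trial``
    (1-based within subject), ``social`` (+/-1), ``cs`` (+/-1) and
    ``temperature``.
    """
    config = config or DesignConfig()
    config.validate()

    # per-CS-level trial budget: social is 50/50 and crossed with CS, so
    # each CS level gets half the trials
    if config.n_trials % 4:
        raise ValueError("n_trials must be divisible by 4 for a 2x2 cue design")
    per_cs = config.n_trials // 2

    cells: list[tuple[int, float]] = []  # (cs, temperature) per trial
    for level in (LOW, HIGH):
        dist = config.cs_contingency[level]
        temps = sorted(dist)
        counts = _largest_remainder(
            np.array([dist[t] for t in temps], float), per_cs
        )
        for t, k in zip(temps, counts):
            cells.extend([(level, t)] * int(k))

    # social assigned within each (cs, temperature) cell half low / half
    # high -> independence of social and temperature by construction
    base = pd.DataFrame(cells, columns=["cs", "temperature"])
    parts = []
    for _, grp in base.groupby(["cs", "temperature"], sort=True):
        n = len(grp)
        if n % 2:
            raise ValueError(
                "cell sizes must be even to counterbalance the social cue; "
                f"got {n} trials for cs={grp['cs'].iloc[0]}, "
                f"T={grp['temperature'].iloc[0]}"
            )
        g = grp.copy()
        g["social"] = [LOW] * (n // 2) + [HIGH] * (n // 2)
        parts.append(g)
    template = pd.concat(parts, ignore_index=True)

    master = np.random.SeedSequence(config.rng_seed)
    frames = []
    for subj, child in enumerate(master.spawn(config.n_subjects), start=1):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(template))
        tab = template.iloc[order].reset_index(drop=True)
        tab.insert(0, "subject", subj)
        tab.insert(1, "run", np.repeat(
            np.arange(1, config.n_runs + 1), config.trials_per_run))
        tab.insert(2, "trial", np.arange(1, config.n_trials + 1))
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    return out[["subject", "run", "trial", "social", "cs", "temperature"]]


# --------------------------------------------------------------------------
# social stimuli
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SocialStimulus:
    """Ten vicarious pain ratings rendered as line positions on a 0-1 scale."""

    positions: np.ndarray
    condition: str  # "low" | "high"

    def __post_init__(self):
        p = np.asarray(self.positions, float)
        if p.shape != (10,):
            raise ValueError("a social stimulus has exactly 10 positions")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("positions must lie in [0, 1]")
        object.__setattr__(self, "positions", p)


def generate_social_stimuli(
    n_per_condition: int,
    seed: int = 0,
    mean_low: float = 0.3,
    mean_high: float = 0.7,
    sd: float = 0.15,
) -> list[SocialStimulus]:
    """Draw social-information stimuli for both conditions.

    Each stimulus is 10 values from N(mean, sd) restricted to [0, 1] by
    rejection resampling (so the realized marginal is the truncated
    normal on [0, 1]).
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[SocialStimulus] = []
    for cond, mu in (("low", mean_low), ("high", mean_high)):
        for _ in range(n_per_condition):
            vals = rng.normal(mu, sd, size=10)
            bad = (vals < 0) | (vals > 1)
            while bad.any():
                vals[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                bad = (vals < 0) | (vals > 1)
            out.append(SocialStimulus(vals, cond))
    return out


def truncated_normal_mean(mu: float, sd: float, lo: float = 0.0,
                          hi: float = 1.0) -> float:
    """Closed-form mean of N(mu, sd) truncated to [lo, hi]."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def default_social_time_profile(t: np.ndarray, n: int = 48) -> np.ndarray:
    """Social cue weight over within-condition trials: linear decay to 60%."""
    t = np.asarray(t, float)
    if n <= 1:
        return np.ones_like(t)
    return 1.0 - 0.4 * (t - 1) / (n - 1)


def default_cs_time_profile(t: np.ndarray, tau: float = 12.0) -> np.ndarray:
    """CS learning curve: saturating exponential, zero before any feedback."""
    t = np.asarray(t, float)
    return 1.0 - np.exp(-(t - 1) / tau)


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters for ratings and skin conductance.

    Cue coefficients are on the +/-1 coding, so the high-minus-low
    difference equals twice the coefficient.  Defaults produce effect
    magnitudes of the order observed in the study: a strong social effect
    on expectations (difference ~11-12 rating points), a small CS effect
    that emerges with learning (~1.5 points on average), a temperature
    slope of ~7.5 points per coded degree and an expectation-to-pain
    transfer of ~0.47 points per point.
    """

    # expectation model
    expect_intercept: float = 40.0
    expect_social: float = 7.3        # modulated by the social time profile
    expect_cs: float = 1.0            # modulated by the learning curve
    expect_noise_sd: float = 13.0
    # pain model
    pain_intercept: float = 22.0
    pain_temperature: float = 7.55    # per temperature code -1/0/+1
    expect_to_pain: float = 0.47      # path b of the behavioral mediation
    pain_social_direct: float = -0.4  # direct (unmediated) cue effects
    pain_cs_direct: float = 0.1
    pain_noise_sd: float = 10.0
    # SCR model (microsiemens-like arbitrary units)
    scr_intercept: float = 0.5
    scr_social: float = 0.04
    scr_noise_sd: float = 0.25
    # between-subject SDs of the corresponding coefficients
    sd_expect_intercept: float = 8.0
    sd_expect_social: float = 3.0
    sd_expect_cs: float = 1.4
    sd_pain_intercept: float = 6.0
    sd_pain_temperature: float = 2.5
    sd_expect_to_pain: float = 0.12
    sd_pain_social_direct: float = 0.5
    sd_pain_cs_direct: float = 0.3
    sd_scr_social: float = 0.10
    # across-subject covariance between the social path a (expect_social)
    # and path b (expect_to_pain) coefficients
    cov_social_gamma: float = 0.0
    # time modulation (None disables -> constant weight 1)
    social_time_profile: Callable[[np.ndarray], np.ndarray] | None = (
        default_social_time_profile)
    cs_time_profile: Callable[[np.ndarray], np.ndarray] | None = (
        default_cs_time_profile)
    rating_bounds: tuple[float, float] = (0.0, 100.0)

    def validate(self) -> None:
        for name in (
            "expect_noise_sd", "pain_noise_sd", "scr_noise_sd",
            "sd_expect_intercept", "sd_expect_social", "sd_expect_cs",
            "sd_pain_intercept", "sd_pain_temperature", "sd_expect_to_pain",
            "sd_pain_social_direct", "sd_pain_cs_direct", "sd_scr_social",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BehaviorData:
    """Synthetic behavior: trial table plus per-subject generative truth."""

    trials: pd.DataFrame
    subject_effects: pd.DataFrame
    clip_fraction: float


def within_condition_index(trials: pd.DataFrame, cue_col: str) -> np.ndarray:
    """1-based trial counter within each level of a cue, per subject.

    Rank is taken over the ``trial`` column, so the result is independent
    of row order.
    """
    return (
        trials.groupby(["subject", cue_col])["trial"]
        .rank(method="first").astype(int).to_numpy()
    )


def generate_behavior(
    design: pd.DataFrame,
    params: BehaviorParams | None = None,
    seed: int = 0,
) -> BehaviorData:
    """Fill a design with expectation ratings, pain ratings, and SCR.

    expectation = a0_i + bS_i g(t_S) S + bC_i h(t_C) C + noise
    pain        = p0_i + bT_i T + g_i * expectation + dS_i S + dC_i C + noise
    scr         = s0   + sS_i S + noise

    with per-subject random coefficients.  Ratings are clipped to the
    rating bounds after noise; the realized clipping fraction is recorded
    because heavy clipping biases downstream mediation recovery.
    """
    params = params or BehaviorParams()
    params.validate()
    trials = design.sort_values(["subject", "trial"]).reset_index(drop=True)
    subjects = trials["subject"].unique()

    master = np.random.SeedSequence(seed)
    # subject coefficient draws use one stream so the planted cov(a, b)
    # between the social path a and path b is honored
    rng = np.random.default_rng(master.spawn(1)[0])
    n = len(subjects)
    cov = np.array([
        [params.sd_expect_social ** 2, params.cov_social_gamma],
        [params.cov_social_gamma, params.sd_expect_to_pain ** 2],
    ])
    social_gamma = rng.multivariate_normal(
        [params.expect_social, params.expect_to_pain], cov, size=n,
        method="cholesky" if np.all(np.linalg.eigvalsh(cov) > 0) else "svd",
    )
    eff = pd.DataFrame({
        "subject": subjects,
        "expect_intercept": params.expect_intercept
        + params.sd_expect_intercept * rng.standard_normal(n),
        "expect_social": social_gamma[:, 0],
        "expect_cs": params.expect_cs
        + params.sd_expect_cs * rng.standard_normal(n),
        "pain_intercept": params.pain_intercept
        + params.sd_pain_intercept * rng.standard_normal(n),
        "pain_temperature": params.pain_temperature
        + params.sd_pain_temperature * rng.standard_normal(n),
        "expect_to_pain": social_gamma[:, 1],
        "pain_social_direct": params.pain_social_direct
        + params.sd_pain_social_direct * rng.standard_normal(n),
        "pain_cs_direct": params.pain_cs_direct
        + params.sd_pain_cs_direct * rng.standard_normal(n),
        "scr_social": params.scr_social
        + params.sd_scr_social * rng.standard_normal(n),
    })

    t_social = within_condition_index(trials, "social").astype(float)
    t_cs = within_condition_index(trials, "cs").astype(float)
    g = (params.social_time_profile(t_social)
         if params.social_time_profile is not None else np.ones_like(t_social))
    h = (params.cs_time_profile(t_cs)
         if params.cs_time_profile is not None else np.ones_like(t_cs))

    e = eff.set_index("subject").loc[trials["subject"]].reset_index()
    noise_rng = np.random.default_rng(master.spawn(2)[1])
    lo, hi = params.rating_bounds

    S = trials["social"].to_numpy(float)
    C = trials["cs"].to_numpy(float)
    T = _temperature_code(trials["temperature"].to_numpy(float))

    expectation = (
        e["expect_intercept"].to_numpy()
        + e["expect_social"].to_numpy() * g * S
        + e["expect_cs"].to_numpy() * h * C
        + params.expect_noise_sd * noise_rng.standard_normal(len(trials))
    )
    clipped = np.count_nonzero((expectation < lo) | (expectation > hi))
    expectation = np.clip(expectation, lo, hi)

    pain = (
        e["pain_intercept"].to_numpy()
        + e["pain_temperature"].to_numpy() * T
        + e["expect_to_pain"].to_numpy() * expectation
        + e["pain_social_direct"].to_numpy() * S
        + e["pain_cs_direct"].to_numpy() * C
        + params.pain_noise_sd * noise_rng.standard_normal(len(trials))
    )
    clipped += np.count_nonzero((pain < lo) | (pain > hi))
    pain = np.clip(pain, lo, hi)

    scr = (
        params.scr_intercept
        + e["scr_social"].to_numpy() * S
        + params.scr_noise_sd * noise_rng.standard_normal(len(trials))
    )

    out = trials.copy()
    out["expectation"] = expectation
    out["pain"] = pain
    out["scr"] = scr
    clip_fraction = clipped / (2 * len(trials))
    if clip_fraction > 0.05:
        warnings.warn(
            f"{clip_fraction:.1%} of ratings were clipped to the rating "
            "bounds; mediation recovery may be biased", stacklevel=2)
    return BehaviorData(out, eff, clip_fraction)


def _temperature_code(temp: np.ndarray) -> np.ndarray:
    """Map temperatures to the -1/0/+1 coding (low/medium/high)."""
    levels = np.unique(temp)
    if len(levels) > 3:
        raise ValueError("temperature coding expects at most 3 levels")
    code = np.zeros_like(temp, dtype=float)
    if len(levels) == 3:
        code[temp == levels[0]] = -1.0
        code[temp == levels[2]] = 1.0
    elif len(levels) == 2:
        code[temp == levels[0]] = -1.0
        code[temp == levels[1]] = 1.0
    return code


def behavior_ground_truth(
    params: BehaviorParams, design: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Expected group-level mediation paths implied by the generator.

    Averages the time-varying cue weights over the within-condition trial
    indices actually present in the medium-temperature (49 degC) subset,
    which is the subset the mediation analysis uses.  Ignores rating
    clipping (negligible at the default noise levels).
    """
    trials = design.sort_values(["subject", "trial"]).reset_index(drop=True)
    t_social = within_condition_index(trials, "social").astype(float)
    t_cs = within_condition_index(trials, "cs").astype(float)
    med = trials["temperature"] == np.sort(trials["temperature"].unique())[
        len(trials["temperature"].unique()) // 2]
    g = (params.social_time_profile(t_social[med])
         if params.social_time_profile is not None else np.ones(med.sum()))
    h = (params.cs_time_profile(t_cs[med])
         if params.cs_time_profile is not None else np.ones(med.sum()))

    out = {}
    for cue, beta, mod, direct in (
        ("social", params.expect_social, float(np.mean(g)),
         params.pain_social_direct),
        ("cs", params.expect_cs, float(np.mean(h)), params.pain_cs_direct),
    ):
        a = beta * mod
        b = params.expect_to_pain
        cov_ab = params.cov_social_gamma * mod if cue == "social" else 0.0
        ab = a * b + cov_ab
        out[cue] = {"a": a, "b": b, "ab": ab,
                    "cprime": direct, "c": ab + direct}
    return out


# --------------------------------------------------------------------------
# brain
# --------------------------------------------------------------------------

# ground-truth label codes for the planted voxel populations
LABEL_NULL, LABEL_SOCIAL, LABEL_CS, LABEL_PAIN = 0, 1, 2, 3


@dataclass(frozen=True)
class BrainParams:
    """Planted voxel populations on a small 3-D grid.

    Social- and CS-mediator populations track a latent per-trial mediator
    ``L = a_i * cue + eta`` and feed pain through ``b_i * L``; pain-only
    voxels track a cue-independent latent that feeds pain; null voxels
    are pure noise.  Per-subject (a_i, b_i) are drawn with configurable
    means, SDs and covariance, so the group mediated effect is
    E[a_i b_i] = mean(a) mean(b) + cov(a, b).
    """

    shape: tuple[int, int, int] = (20, 20, 20)
    n_social: int = 200
    n_cs: int = 200
    n_pain: int = 200
    a_mean: float = 0.5
    a_sd: float = 0.2
    b_mean: float = 3.0
    b_sd: float = 0.8
    cov_ab: float = 0.0
    latent_noise_sd: float = 1.0
    voxel_noise_sd: float = 1.0

    def validate(self) -> None:
        n_planted = self.n_social + self.n_cs + self.n_pain
        if n_planted > int(np.prod(self.shape)):
            raise ValueError("planted populations exceed grid size "
                             "(populations must be disjoint)")
        for name in ("latent_noise_sd", "voxel_noise_sd", "a_sd", "b_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cov = np.array([[self.a_sd ** 2, self.cov_ab],
                        [self.cov_ab, self.b_sd ** 2]])
        if np.linalg.eigvalsh(cov)[0] < -1e-12:
            raise ValueError("cov_ab incompatible with a_sd/b_sd")


@dataclass
class BrainData:
    """Synthetic single-trial brain betas plus ground truth.

    ``datasets`` maps subject id to a (n_trials, n_voxels) array aligned
    row-wise with that subject's rows of ``trials``; ``truth_labels`` is
    the in-mask population label per voxel; ``trials`` is the behavior
    table with pain regenerated to include the brain mediator terms.
    """

    trials: pd.DataFrame
    datasets: dict[int, np.ndarray]
    mask: np.ndarray                 # 3-D bool
    affine: np.ndarray
    truth_labels: np.ndarray         # 1-D int, in-mask voxel order
    subject_effects: pd.DataFrame    # subject, population, a, b
    params: BrainParams


def _draw_ab(rng, n, params: BrainParams) -> np.ndarray:
    cov = np.array([[params.a_sd ** 2, params.cov_ab],
                    [params.cov_ab, params.b_sd ** 2]])
    return rng.multivariate_normal(
        [params.a_mean, params.b_mean], cov, size=n, method="svd")


def generate_brain(
    behavior: BehaviorData | pd.DataFrame,
    params: BrainParams | None = None,
    seed: int = 0,
) -> BrainData:
    """Generate per-subject trials x voxels matrices with planted mediators.

    Pain ratings are regenerated to include the latent-mediator
    contributions (``pain += b_i * L`` for each mediating population), so
    the returned trial table — not the input one — is the outcome to use
    for brain mediation.
    """
    params = params or BrainParams()
    params.validate()
    trials = (behavior.trials if isinstance(behavior, BehaviorData)
              else behavior).sort_values(["subject", "trial"]).reset_index(
        drop=True)
    if "pain" not in trials.columns:
        raise ValueError("behavior must be generated before brain data")

    n_vox = int(np.prod(params.shape))
    mask = np.ones(params.shape, dtype=bool)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm grid, origin at corner

    master = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(master.spawn(1)[0])
    perm = label_rng.permutation(n_vox)
    labels = np.zeros(n_vox, dtype=int)
    i = 0
    for lab, count in ((LABEL_SOCIAL, params.n_social),
                       (LABEL_CS, params.n_cs),
                       (LABEL_PAIN, params.n_pain)):
        labels[perm[i:i + count]] = lab
        i += count
    pop_idx = {lab: np.flatnonzero(labels == lab)
               for lab in (LABEL_SOCIAL, LABEL_CS, LABEL_PAIN)}

    subjects = trials["subject"].unique()
    ab_rng = np.random.default_rng(master.spawn(2)[1])
    ab = {
        "social": _draw_ab(ab_rng, len(subjects), params),
        "cs": _draw_ab(ab_rng, len(subjects), params),
        "pain": np.column_stack([
            np.zeros(len(subjects)),
            params.b_mean + params.b_sd * ab_rng.standard_normal(
                len(subjects)),
        ]),
    }

    datasets: dict[int, np.ndarray] = {}
    new_pain = trials["pain"].to_numpy(float).copy()
    eff_rows = []
    children = np.random.SeedSequence((seed, 7)).spawn(len(subjects))
    for si, (subj, child) in enumerate(zip(subjects, children)):
        rng = np.random.default_rng(child)
        rows = trials.index[trials["subject"] == subj].to_numpy()
        nt = len(rows)
        data = params.voxel_noise_sd * rng.standard_normal((nt, n_vox))

        for pop, xcol, lab in (("social", "social", LABEL_SOCIAL),
                               ("cs", "cs", LABEL_CS),
                               ("pain", None, LABEL_PAIN)):
            a_i, b_i = ab[pop][si]
            x = (trials.loc[rows, xcol].to_numpy(float)
                 if xcol is not None else np.zeros(nt))
            latent = a_i * x + params.latent_noise_sd * rng.standard_normal(nt)
            data[:, pop_idx[lab]] += latent[:, None]
            new_pain[rows] += b_i * latent
            eff_rows.append({"subject": subj, "population": pop,
                             "a": a_i, "b": b_i})
        datasets[subj] = data

    out_trials = trials.copy()
    bounds = (0.0, 100.0)
    out_trials["pain"] = np.clip(new_pain, *bounds)
    return BrainData(
        trials=out_trials,
        datasets=datasets,
        mask=mask,
        affine=affine,
        truth_labels=labels,
        subject_effects=pd.DataFrame(eff_rows),
        params=params,
    )
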