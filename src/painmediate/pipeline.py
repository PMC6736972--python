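"""End-to-end orchestration of the synthetic analysis chain.

One config drives: synthetic experiment generation -> trial filtering ->
behavioral multilevel stats and mediation -> voxelwise mediation for the
Social and CS models -> FDR thresholding, conjunctions and Dice ->
network similarity, subnetwork contrasts and octant summaries ->
leave-one-subject-out classification.  Every stochastic stage has an
explicit seed derived from the master seed, outputs are written per
stage, and a manifest records the config and a checksum of every
artifact so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import loso_forced_choice
from .maps import (StatMaps, ThresholdedMap, conjunction, dice,
                   threshold_map, to_volume, voxelwise_mediation)
from .mediation import BootstrapSettings, fit_paths_by_subject, group_mediation
from .multilevel import fit_multilevel_glm, fit_time_interaction
from .networks import (NetworkPartition, network_similarity, octant_summary,
                       subnetwork_contrast)
from .single_trial import apply_vif_filter
from .synthetic import (BehaviorParams, BrainParams, DesignConfig,
                        generate_behavior, generate_brain, generate_design)

log = logging.getLogger("painmediate")

__all__ = ["RunConfig", "run_all", "synthetic_partition"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic (or file-driven) run.

    ``design``, ``behavior`` and ``brain`` hold keyword overrides for the
    corresponding synthetic generators; thresholds mirror the analysis
    conventions (FDR q, display tiers, VIF cutoff, spike m.a.d. cutoff).
    The ``smoke`` profile shrinks the cohort and grid and switches the
    group stage to the t fallback for minutes-scale runs.
    """

    seed: int = 0
    out_dir: str = "painmediate_out"
    design: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    brain: dict = field(default_factory=dict)
    q: float = 0.05
    p01: float = 0.01
    p05: float = 0.05
    vif_threshold: float = 2.5
    mad_threshold: float = 10.0
    connectivity: int = 26
    n_boot_behavior: int = 10000
    n_boot_voxel: int = 2000
    mediation_method: str = "bootstrap"
    voxel_method: str = "t"
    write_beta_series: bool = False
    run_brain: bool = True

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str = "painmediate_out") -> "RunConfig":
        return cls(
            seed=seed, out_dir=out_dir,
            design={"n_subjects": 6},
            brain={"shape": (10, 10, 10), "n_social": 40, "n_cs": 40,
                   "n_pain": 40},
            n_boot_behavior=2000, n_boot_voxel=500,
            mediation_method="t",
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if "shape" in cfg.brain:
            cfg.brain["shape"] = tuple(cfg.brain["shape"])
        return cfg


def synthetic_partition(truth_labels: np.ndarray,
                        seed: int = 0) -> tuple[NetworkPartition,
                                                NetworkPartition]:
    """Network partitions derived from the planted populations.

    The coarse partition assigns each planted population its own
    "network" (frontoparietal-like for the social mediators, limbic-like
    for the CS mediators, somatomotor-like for the pain-only voxels) and
    splits the remaining voxels into four filler networks, emulating a
    7-network parcellation.  The fine partition additionally splits the
    social-mediator network into three subnetworks per "hemisphere"
    (first/second half of the voxel list), emulating the left/right
    Control A/B/C subdivision of a frontoparietal network.
    """
    labels = np.asarray(truth_labels, int).ravel()
    rng = np.random.default_rng(seed)
    coarse = np.zeros_like(labels)
    coarse[labels == 1] = 1  # frontoparietal-like
    coarse[labels == 2] = 2  # limbic-like
    coarse[labels == 3] = 3  # somatomotor-like
    null_idx = np.flatnonzero(labels == 0)
    chunks = np.array_split(rng.permutation(null_idx), 4)
    for j, ch in enumerate(chunks, start=4):
        coarse[ch] = j
    coarse_names = {1: "frontoparietal", 2: "limbic", 3: "somatomotor",
                    4: "visual", 5: "default", 6: "dorsal attention",
                    7: "ventral attention"}

    fine = np.zeros_like(labels)
    soc = np.flatnonzero(labels == 1)
    half = len(soc) // 2
    sides = {"L": soc[:half], "R": soc[half:]}
    fine_names = {}
    nid = 1
    for side, idx in sides.items():
        for sub, part in zip("ABC", np.array_split(idx, 3)):
            fine[part] = nid
            fine_names[nid] = f"Control {sub} {side}"
            nid += 1
    fine[labels == 2] = nid
    fine_names[nid] = "limbic"
    return (NetworkPartition(coarse, coarse_names),
            NetworkPartition(fine, fine_names))


def _effect_frame(effects: dict) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in effects.values()])


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict = {"seed": config.seed}
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["design", "behavior", "brain", "behav_med", "voxel",
                  "partition", "timecourse"],
                 np.random.SeedSequence(config.seed).spawn(7))}

    # ---- stage: synthetic data -------------------------------------
    log.info("stage=synthetic seed=%s", seeds["design"])
    design_cfg = DesignConfig(**{"rng_seed": seeds["design"],
                                 **config.design})
    design = generate_design(design_cfg)
    behavior = generate_behavior(
        design, BehaviorParams(**config.behavior), seed=seeds["behavior"])
    trials = behavior.trials
    brain = None
    if config.run_brain:
        brain = generate_brain(behavior, BrainParams(**config.brain),
                               seed=seeds["brain"])
        trials = brain.trials
    artifacts += pio.write_trials_tsv(trials, out / "trials")
    pio.write_json(out / "trials" / "generation.json", {
        "design": design_cfg, "clip_fraction": behavior.clip_fraction,
        "seeds": seeds})
    artifacts.append(out / "trials" / "generation.json")

    # ---- stage: single-trial filters -------------------------------
    if "vif" in trials.columns:
        kept_parts, logs = [], []
        for subj, grp in trials.groupby("subject"):
            _, keep, excl = apply_vif_filter(
                grp.index.to_numpy(), grp["vif"].to_numpy(),
                config.vif_threshold, subject=subj)
            kept_parts.append(grp.iloc[keep])
            logs.append(excl)
        trials = pd.concat(kept_parts, ignore_index=True)
        pd.concat(logs).to_csv(out / "vif_exclusions.tsv", sep="\t",
                               index=False)
        artifacts.append(out / "vif_exclusions.tsv")
        log.info("stage=vif_filter excluded=%d",
                 sum(len(l) for l in logs))
    else:
        log.info("stage=vif_filter skipped (no vif column)")

    # ---- stage: behavioral stats -----------------------------------
    log.info("stage=behavior")
    trials = trials.copy()
    codes = np.select(
        [trials["temperature"] == trials["temperature"].min(),
         trials["temperature"] == trials["temperature"].max()],
        [-1.0, 1.0], default=0.0)
    trials["temperature_code"] = codes
    behav_effects = {}
    behav_effects["temperature->pain"] = fit_multilevel_glm(
        trials, "pain", ["temperature_code"])["temperature_code"]
    exp_eff = fit_multilevel_glm(trials, "expectation", ["social", "cs"])
    behav_effects["social->expectation"] = exp_eff["social"]
    behav_effects["cs->expectation"] = exp_eff["cs"]
    pain_eff = fit_multilevel_glm(trials, "pain", ["social", "cs"],
                                  trial_filter="temperature == 49")
    behav_effects["social->pain"] = pain_eff["social"]
    behav_effects["cs->pain"] = pain_eff["cs"]
    scr_eff = fit_multilevel_glm(trials, "scr", ["social", "cs"],
                                 trial_filter="temperature == 49")
    behav_effects["social->scr"] = scr_eff["social"]
    behav_effects["cs->scr"] = scr_eff["cs"]
    behav_effects["social x time (expectation)"] = fit_time_interaction(
        trials, "expectation", "social")
    behav_effects["cs x time (expectation)"] = fit_time_interaction(
        trials, "expectation", "cs")
    frame = pd.DataFrame([{"effect": k, **e.as_dict()}
                          for k, e in behav_effects.items()])
    frame.to_csv(out / "behavior_effects.tsv", sep="\t", index=False)
    artifacts.append(out / "behavior_effects.tsv")
    summary["behavior"] = {k: e.beta for k, e in behav_effects.items()}

    # ---- stage: behavioral mediation -------------------------------
    log.info("stage=behavioral_mediation")
    settings = BootstrapSettings(config.n_boot_behavior, seeds["behav_med"],
                                 config.mediation_method)
    behav_mediation = {}
    for cue, cov in (("social", "cs"), ("cs", "social")):
        paths = fit_paths_by_subject(
            trials, cue, "expectation", "pain", [cov],
            trial_filter="temperature == 49")
        behav_mediation[cue] = group_mediation(paths, settings)
    pio.write_json(out / "behavior_mediation.json",
                   {cue: r.as_dict() for cue, r in behav_mediation.items()})
    artifacts.append(out / "behavior_mediation.json")
    summary["behavior_mediation"] = {
        cue: r.estimates for cue, r in behav_mediation.items()}

    if brain is None:
        _write_manifest(out, config, artifacts)
        return summary

    # ---- stage: voxelwise mediation --------------------------------
    log.info("stage=voxelwise_mediation")
    stat_maps: dict[str, StatMaps] = {}
    for cue, cov in (("social", "cs"), ("cs", "social")):
        stat_maps[cue] = voxelwise_mediation(
            brain.datasets, trials, cue, "pain", [cov],
            mask=brain.mask, affine=brain.affine,
            n_resamples=config.n_boot_voxel, seed=seeds["voxel"],
            model=cue, method=config.voxel_method)
    if config.write_beta_series:
        for subj, data in brain.datasets.items():
            artifacts.append(pio.write_beta_series(
                out / "betas" / f"sub-{subj:02d}_betas.nii.gz",
                data, brain.mask, brain.affine))

    # ---- stage: thresholding / conjunction / dice ------------------
    log.info("stage=thresholding")
    thresholded: dict[tuple[str, str], ThresholdedMap] = {}
    report = {"attained_p": {}, "tier_counts": {}, "dice": {}}
    for cue in ("social", "cs"):
        for path in ("a", "b", "ab"):
            tm = threshold_map(stat_maps[cue], path, q=config.q,
                               p01=config.p01, p05=config.p05,
                               connectivity=config.connectivity)
            thresholded[(cue, path)] = tm
            report["attained_p"][f"{cue}_{path}"] = tm.attained_p
            report["tier_counts"][f"{cue}_{path}"] = {
                "fdr": int((tm.tier == 3).sum()),
                "p01": int((tm.tier == 2).sum()),
                "p05": int((tm.tier == 1).sum()),
            }
            artifacts.append(pio.write_volume(
                out / "maps" / f"{cue}_path-{path}_tier.nii.gz",
                to_volume(tm.tier, brain.mask), brain.affine))
            artifacts.append(pio.write_volume(
                out / "maps" / f"{cue}_path-{path}_effect.nii.gz",
                to_volume(np.nan_to_num(stat_maps[cue].effects[path]),
                          brain.mask), brain.affine))

    conj = {
        "social_a_and_ab": conjunction(thresholded[("social", "a")],
                                       thresholded[("social", "ab")]),
        "cs_a_and_ab": conjunction(thresholded[("cs", "a")],
                                   thresholded[("cs", "ab")]),
        "a_social_and_cs": conjunction(thresholded[("social", "a")],
                                       thresholded[("cs", "a")]),
        "ab_social_and_cs": conjunction(thresholded[("social", "ab")],
                                        thresholded[("cs", "ab")]),
    }
    for name, m in conj.items():
        artifacts.append(pio.write_volume(
            out / "maps" / f"conjunction_{name}.nii.gz",
            to_volume(m.astype(float), brain.mask), brain.affine))
    report["dice"]["path_a_social_vs_cs"] = dice(
        thresholded[("social", "a")], thresholded[("cs", "a")])
    report["dice"]["path_ab_social_vs_cs"] = dice(
        thresholded[("social", "ab")], thresholded[("cs", "ab")])
    pio.write_json(out / "maps" / "threshold_report.json", report)
    artifacts.append(out / "maps" / "threshold_report.json")
    summary["maps"] = report

    # recovery scoring against the planted populations
    truth = brain.truth_labels
    summary["recovery"] = {}
    for cue, lab in (("social", 1), ("cs", 2)):
        sig = thresholded[(cue, "ab")].binary()
        planted = truth == lab
        nulls = truth == 0
        n_disc = int(sig.sum())
        summary["recovery"][cue] = {
            "ab_sensitivity": float(sig[planted].mean()),
            "null_discovery_fraction": (
                float(sig[nulls].sum() / n_disc) if n_disc else 0.0),
        }

    # ---- stage: network analysis -----------------------------------
    log.info("stage=networks")
    coarse, fine = synthetic_partition(truth, seeds["partition"])
    wedges = []
    for (cue, path), tm in thresholded.items():
        vals = tm.display_values(
            np.nan_to_num(stat_maps[cue].effects[path]))
        w = network_similarity(vals, coarse)
        w.insert(0, "map", f"{cue}_{path}")
        wedges.append(w)
    wedge_frame = pd.concat(wedges, ignore_index=True)
    wedge_frame.to_csv(out / "network_wedges.tsv", sep="\t", index=False)
    artifacts.append(out / "network_wedges.tsv")

    contrasts = subnetwork_contrast(stat_maps["social"].subject_effects["a"],
                                    stat_maps["cs"].subject_effects["a"],
                                    fine)
    pd.DataFrame([c.as_dict() for c in contrasts.values()]).to_csv(
        out / "subnetwork_contrasts.tsv", sep="\t", index=False)
    artifacts.append(out / "subnetwork_contrasts.tsv")

    octants = octant_summary(np.nan_to_num(stat_maps["social"].effects["ab"]),
                             np.nan_to_num(stat_maps["cs"].effects["ab"]),
                             coarse)
    octants.to_csv(out / "octant_summary.tsv", sep="\t", index=False)
    artifacts.append(out / "octant_summary.tsv")
    summary["octant_peaks"] = {
        net: int(g.loc[g["peak"], "octant"].iloc[0])
        for net, g in octants.groupby("network")}

    # ---- stage: classification -------------------------------------
    log.info("stage=classification")
    union = conj["social_a_and_ab"] | conj["cs_a_and_ab"]
    if not union.any():
        union = (thresholded[("social", "ab")].binary()
                 | thresholded[("cs", "ab")].binary())
    if not union.any():
        union = np.ones_like(union, bool)
    clf = loso_forced_choice(
        stat_maps["social"].subject_effects["a"][:, union],
        stat_maps["cs"].subject_effects["a"][:, union])
    pio.write_json(out / "classification.json", clf.as_dict())
    artifacts.append(out / "classification.json")
    summary["classification"] = {"accuracy": clf.accuracy, "p": clf.p,
                                 "n_features": int(union.sum())}

    _write_manifest(out, config, artifacts)
    return summary


def _write_manifest(out: Path, config: RunConfig,
                    artifacts: list[Path]) -> None:
    manifest = {
        "config": dataclasses.asdict(config),
        "artifacts": {str(p.relative_to(out)): pio.sha256_of(p)
                      for p in artifacts if p.exists()},
    }
    pio.write_json(out / "manifest.json", manifest)
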