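"""Synthetic-experiment generator: design marginals, stimuli, behavior, brain."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import painmediate as pm
from painmediate.synthetic import (BehaviorParams, BrainParams, DesignConfig,
                                   behavior_ground_truth, generate_behavior,
                                   generate_brain, generate_design,
                                   generate_social_stimuli,
                                   truncated_normal_mean)


class TestDesign:
    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_exact_marginals_every_seed(self, seed):
        """Temperature marginals are counted, not approximate: 24/48/24
        per subject, with the medium temperature on exactly half the
        trials."""
        d = generate_design(DesignConfig(n_subjects=3, rng_seed=seed))
        for _, sub in d.groupby("subject"):
            counts = sub["temperature"].value_counts()
            assert counts[49.0] == 48
            assert counts[48.0] == 24
            assert counts[50.0] == 24

    def test_cs_contingency_and_social_independence(self):
        d = generate_design(DesignConfig(n_subjects=2, rng_seed=3))
        sub = d[d.subject == 1]
        # CS_LOW -> only 48/49 at 24 each; CS_HIGH -> only 49/50
        low = sub[sub.cs == -1]["temperature"].value_counts()
        high = sub[sub.cs == 1]["temperature"].value_counts()
        assert dict(low) == {48.0: 24, 49.0: 24}
        assert dict(high) == {49.0: 24, 50.0: 24}
        # social counterbalanced within every temperature level
        tab = sub.groupby(["temperature", "social"]).size().unstack()
        assert (tab[-1] == tab[1]).all()

    def test_deterministic_given_seed(self):
        cfg = DesignConfig(n_subjects=4, rng_seed=9)
        pd.testing.assert_frame_equal(generate_design(cfg),
                                      generate_design(cfg))

    def test_subject_tables_stable_under_cohort_growth(self):
        """Child seeds are spawned per subject, so adding subjects does
        not reshuffle earlier ones."""
        d6 = generate_design(DesignConfig(n_subjects=6, rng_seed=5))
        d3 = generate_design(DesignConfig(n_subjects=3, rng_seed=5))
        pd.testing.assert_frame_equal(d6[d6.subject <= 3].reset_index(drop=True),
                                      d3.reset_index(drop=True))

    def test_invalid_contingency_raises(self):
        cfg = DesignConfig(cs_contingency={-1: {48.0: 0.6, 49.0: 0.6},
                                           1: {49.0: 0.5, 50.0: 0.5}})
        with pytest.raises(ValueError, match="sum"):
            generate_design(cfg)

    def test_run_structure(self):
        d = generate_design(DesignConfig(n_subjects=1, rng_seed=0))
        assert d.groupby("run").size().eq(16).all()
        with pytest.raises(ValueError, match="n_trials"):
            DesignConfig(n_runs=5).validate()


class TestSocialStimuli:
    def test_counts_conditions_and_bounds(self):
        stims = generate_social_stimuli(48, seed=0)
        assert len(stims) == 96
        assert sum(s.condition == "low" for s in stims) == 48
        allpos = np.concatenate([s.positions for s in stims])
        assert allpos.min() >= 0 and allpos.max() <= 1
        assert all(len(s.positions) == 10 for s in stims)

    def test_low_condition_mean_matches_truncated_normal(self):
        """Rejection resampling realizes the truncated normal, so the
        grand mean over many stimuli matches the closed form."""
        stims = generate_social_stimuli(20000, seed=1)
        low = np.concatenate([s.positions for s in stims
                              if s.condition == "low"])
        expected = truncated_normal_mean(0.3, 0.15)
        assert low.mean() == pytest.approx(expected, abs=4e-3)
        high = np.concatenate([s.positions for s in stims
                               if s.condition == "high"])
        assert high.mean() == pytest.approx(
            truncated_normal_mean(0.7, 0.15), abs=4e-3)


class TestBehavior:
    def test_zero_noise_mediation_identity(self, small_design):
        """With no noise, no direct effects, gamma=1 and constant cue
        weights, the social effect on pain equals the planted weight at
        every medium-temperature trial pair."""
        p = BehaviorParams(
            expect_social=5.0, expect_cs=0.0, expect_to_pain=1.0,
            pain_social_direct=0.0, pain_cs_direct=0.0,
            expect_noise_sd=0.0, pain_noise_sd=0.0,
            sd_expect_intercept=0.0, sd_expect_social=0.0, sd_expect_cs=0.0,
            sd_pain_intercept=0.0, sd_pain_temperature=0.0,
            sd_expect_to_pain=0.0, sd_pain_social_direct=0.0,
            sd_pain_cs_direct=0.0,
            social_time_profile=None, cs_time_profile=None)
        beh = generate_behavior(small_design, p, seed=0)
        t49 = beh.trials.query("temperature == 49")
        diff = (t49[t49.social == 1].groupby("subject")["pain"].mean()
                - t49[t49.social == -1].groupby("subject")["pain"].mean())
        np.testing.assert_allclose(diff, 10.0, atol=1e-10)  # 2 * 5.0

    def test_flat_learning_curve_kills_cs_effect(self, small_design):
        p = BehaviorParams(cs_time_profile=lambda t: np.zeros_like(t),
                           social_time_profile=None,
                           expect_noise_sd=0.0, sd_expect_cs=0.0)
        beh = generate_behavior(small_design, p, seed=0)
        t = beh.trials
        by_cs = t.groupby(["subject", "cs"])["expectation"].mean().unstack()
        np.testing.assert_allclose(by_cs[1] - by_cs[-1], 0.0, atol=1e-10)

    def test_learning_curve_starts_at_zero(self):
        from painmediate.synthetic import default_cs_time_profile
        assert default_cs_time_profile(np.array([1.0]))[0] == 0.0

    def test_reproducible_and_clipped(self, small_design):
        b1 = generate_behavior(small_design, seed=4)
        b2 = generate_behavior(small_design, seed=4)
        pd.testing.assert_frame_equal(b1.trials, b2.trials)
        assert b1.trials["pain"].between(0, 100).all()
        assert b1.clip_fraction < 0.05

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="must be >= 0"):
            BehaviorParams(pain_noise_sd=-1.0).validate()


class TestBrain:
    def test_zero_noise_recovers_planted_a_exactly(self, small_design):
        beh = generate_behavior(small_design, seed=1)
        params = BrainParams(shape=(6, 6, 6), n_social=10, n_cs=10,
                             n_pain=10, latent_noise_sd=0.0,
                             voxel_noise_sd=0.0, a_sd=0.3)
        brain = generate_brain(beh, params, seed=2)
        labels = brain.truth_labels
        soc_vox = np.flatnonzero(labels == 1)[0]
        eff = brain.subject_effects
        for subj, data in brain.datasets.items():
            g = brain.trials[brain.trials.subject == subj]
            x = g["social"].to_numpy(float)
            a_hat = (x @ data[:, soc_vox]) / (x @ x)
            a_true = eff.query("subject == @subj and population == 'social'")
            assert a_hat == pytest.approx(float(a_true["a"].iloc[0]),
                                          abs=1e-10)

    def test_populations_disjoint_and_sized(self, small_brain):
        labels = small_brain.truth_labels
        counts = np.bincount(labels, minlength=4)
        assert list(counts[1:]) == [60, 60, 60]

    def test_overlapping_populations_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            BrainParams(shape=(4, 4, 4), n_social=30, n_cs=30,
                        n_pain=30).validate()

    def test_null_voxel_path_a_pvalues_uniform(self):
        """Group path-a p-values at pure-noise voxels are uniform (KS)."""
        d = pm.generate_design(pm.DesignConfig(n_subjects=12, rng_seed=21))
        beh = generate_behavior(d, seed=22)
        params = BrainParams(shape=(10, 10, 10), n_social=0, n_cs=0,
                             n_pain=0)
        brain = generate_brain(beh, params, seed=23)
        sm = pm.voxelwise_mediation(
            brain.datasets, brain.trials, "social", "pain", ["cs"],
            mask=brain.mask, affine=brain.affine, seed=24, method="t")
        ks = stats.kstest(sm.pvalues["a"], "uniform")
        assert ks.pvalue > 1e-3

    def test_planted_covariance_yields_group_ab(self):
        """mean(a)=mean(b)=0 with cov(a,b)>0 still produces a positive
        group mediated effect (the covariance component)."""
        d = pm.generate_design(pm.DesignConfig(n_subjects=30, rng_seed=31))
        beh = generate_behavior(d, seed=32)
        params = BrainParams(shape=(5, 5, 5), n_social=20, n_cs=0, n_pain=0,
                             a_mean=0.0, b_mean=0.0, a_sd=0.6, b_sd=2.0,
                             cov_ab=1.0)
        brain = generate_brain(beh, params, seed=33)
        sm = pm.voxelwise_mediation(
            brain.datasets, brain.trials, "social", "pain", ["cs"],
            mask=brain.mask, affine=brain.affine, seed=34, method="t")
        planted = brain.truth_labels == 1
        assert sm.effects["ab"][planted].mean() > 0.2  # E[ab] = cov = 1.0
        # and the a/b means themselves hover near zero
        assert abs(sm.effects["a"][planted].mean()) < 0.3

    def test_ground_truth_helper_consistent(self, small_design):
        truth = behavior_ground_truth(BehaviorParams(), small_design)
        for cue in ("social", "cs"):
            t = truth[cue]
            assert t["c"] == pytest.approx(t["cprime"] + t["ab"])
        assert truth["social"]["a"] > truth["cs"]["a"]
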