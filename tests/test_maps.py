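"""Voxelwise maps: FDR, display pruning, conjunction, Dice, signatures."""

import numpy as np
import pytest

import painmediate as pm
from painmediate.maps import (ALL_PATHS, MAP_PATHS, TIER_FDR, TIER_NONE,
                              TIER_P01, TIER_P05, StatMaps, conjunction, dice,
                              fdr_threshold, prune_display, score_signature,
                              threshold_map, to_volume, voxelwise_mediation)


def bh_oracle(pvals, q):
    """Independent Benjamini-Hochberg step-up, written from the definition:
    reject p_(1..k*) with k* = max{k : p_(k) <= k q / m}."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = np.flatnonzero(ranked <= (np.arange(1, m + 1) * q / m))
    reject = np.zeros(m, bool)
    if len(below):
        reject[order[: below[-1] + 1]] = True
    return reject


class TestFDR:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 21))
            (mask,), attained = fdr_threshold(p, q=0.05)
            ref = bh_oracle(p, 0.05)
            np.testing.assert_array_equal(mask, ref)
            if ref.any():
                assert attained == p[ref].max()
            else:
                assert attained == 0.0

    def test_textbook_example_all_rejected(self):
        """Every p_(k) <= k q / m with q = 0.5 here, so all four pass."""
        (mask,), attained = fdr_threshold(
            np.array([0.01, 0.02, 0.03, 0.04]), q=0.5)
        assert mask.all()
        assert attained == 0.04

    def test_step_up_behavior(self):
        """Step-up accepts p_(2)=0.04 at rank 2 (<= 2q/m = 0.05) even
        though it exceeds q/m; p_(2)=0.06 fails and only p_(1) survives."""
        (mask,), _ = fdr_threshold(np.array([0.01, 0.04]), q=0.05)
        assert mask.all()
        (mask2,), _ = fdr_threshold(np.array([0.01, 0.06]), q=0.05)
        assert mask2[0] and not mask2[1]

    def test_pooled_across_paths(self, rng):
        pa = rng.uniform(size=50)
        pb = rng.uniform(0, 0.001, size=50)
        masks, attained = fdr_threshold([pa, pb], q=0.05)
        pooled_ref = bh_oracle(np.concatenate([pa, pb]), 0.05)
        np.testing.assert_array_equal(np.concatenate(masks), pooled_ref)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError, match="invalid"):
            fdr_threshold(np.array([0.1, 1.2]))
        with pytest.raises(ValueError, match="empty"):
            fdr_threshold(np.array([]))


class TestPruneDisplay:
    def _grid(self, shape=(8, 8, 8)):
        return np.ones(shape, bool)

    def test_component_without_fdr_voxel_dropped(self):
        mask = self._grid()
        p = np.ones(mask.sum())
        vol = np.ones(mask.shape)
        # component A: corner blob containing one FDR voxel
        vol[0:2, 0:2, 0] = 0.03
        vol[0, 0, 0] = 1e-6
        # component B: far blob, lenient only
        vol[6:8, 6:8, 7] = 0.03
        p = vol[mask]
        fdr = p < 1e-5
        tier = prune_display(p, fdr, mask)
        tvol = to_volume(tier, mask)
        assert tvol[0, 0, 0] == TIER_FDR
        assert tvol[1, 1, 0] == TIER_P05
        assert (tvol[6:8, 6:8, 7] == TIER_NONE).all()

    def test_p01_tier_inside_retained_component(self):
        mask = self._grid()
        vol = np.ones(mask.shape)
        vol[3, 3, 3] = 1e-6   # FDR seed
        vol[3, 3, 4] = 0.005  # p01 neighbor
        vol[3, 3, 5] = 0.03   # p05 neighbor
        p = vol[mask]
        tier = prune_display(p, p < 1e-5, mask)
        tvol = to_volume(tier, mask)
        assert tvol[3, 3, 3] == TIER_FDR
        assert tvol[3, 3, 4] == TIER_P01
        assert tvol[3, 3, 5] == TIER_P05

    def test_connectivity_6_separates_diagonal(self):
        mask = self._grid()
        vol = np.ones(mask.shape)
        vol[0, 0, 0] = 1e-6
        vol[1, 1, 1] = 0.03  # diagonal neighbor only
        p = vol[mask]
        t26 = to_volume(prune_display(p, p < 1e-5, mask, connectivity=26),
                        mask)
        t6 = to_volume(prune_display(p, p < 1e-5, mask, connectivity=6),
                       mask)
        assert t26[1, 1, 1] == TIER_P05
        assert t6[1, 1, 1] == TIER_NONE

    def test_bad_connectivity(self):
        mask = self._grid()
        with pytest.raises(ValueError, match="connectivity"):
            prune_display(np.ones(mask.sum()), np.zeros(mask.sum(), bool),
                          mask, connectivity=8)


class TestVoxelwise:
    def test_recovers_planted_populations(self, small_brain):
        sm = voxelwise_mediation(
            small_brain.datasets, small_brain.trials, "social", "pain",
            ["cs"], mask=small_brain.mask, affine=small_brain.affine,
            seed=0, method="t")
        labels = small_brain.truth_labels
        soc, null = labels == 1, labels == 0
        assert np.median(sm.pvalues["ab"][soc]) < 0.01
        assert 0.3 < np.median(sm.pvalues["ab"][null]) < 0.7
        # pain-only voxels respond to pain (path b) but not the cue
        pain = labels == 3
        assert np.median(sm.pvalues["b"][pain]) < 0.01
        assert np.median(sm.pvalues["a"][pain]) > 0.1

    def test_methods_share_estimates(self, small_brain):
        kw = dict(datasets=small_brain.datasets, trials=small_brain.trials,
                  x="social", covariates=["cs"], mask=small_brain.mask,
                  affine=small_brain.affine, seed=1, n_resamples=200)
        t = voxelwise_mediation(method="t", **kw)
        b = voxelwise_mediation(method="bootstrap", **kw)
        for p in ALL_PATHS:
            np.testing.assert_allclose(t.effects[p], b.effects[p])

    def test_misaligned_dataset_raises(self, small_brain):
        bad = {s: d[:-1] for s, d in small_brain.datasets.items()}
        with pytest.raises(ValueError, match="misaligned"):
            voxelwise_mediation(bad, small_brain.trials, "social")

    def test_unknown_method(self, small_brain):
        with pytest.raises(ValueError, match="unknown method"):
            voxelwise_mediation(small_brain.datasets, small_brain.trials,
                                "social", method="wald")

    def test_threshold_map_finds_planted(self, small_brain):
        sm = voxelwise_mediation(
            small_brain.datasets, small_brain.trials, "social", "pain",
            ["cs"], mask=small_brain.mask, affine=small_brain.affine,
            seed=2, method="t")
        planted = small_brain.truth_labels == 1
        null = small_brain.truth_labels == 0
        tm_a = threshold_map(sm, "a")
        hits = tm_a.binary(TIER_FDR)
        assert hits[planted].mean() > 0.9   # path a is strong at n=12
        assert hits[null].mean() < 0.05
        assert 0 < tm_a.attained_p < 0.05
        # the mediated-effect map is weaker at this sample size but its
        # display tiers still cover most of the planted population
        tm_ab = threshold_map(sm, "ab")
        assert tm_ab.binary(TIER_P05)[planted].mean() > 0.4
        assert tm_ab.binary(TIER_P05)[null].mean() < 0.05


class TestConjunctionDiceSignature:
    def test_conjunction_is_logical_and(self, rng):
        a = rng.uniform(size=100) < 0.3
        b = rng.uniform(size=100) < 0.3
        np.testing.assert_array_equal(conjunction(a, b), a & b)

    def test_conjunction_shape_mismatch(self):
        with pytest.raises(ValueError, match="same grid"):
            conjunction(np.zeros(5, bool), np.zeros(6, bool))

    def test_dice_hand_formula(self):
        a = np.array([1, 1, 1, 0, 0], bool)
        b = np.array([0, 1, 1, 1, 1], bool)
        assert dice(a, b) == pytest.approx(2 * 2 / (3 + 4))
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0

    def test_dice_empty_warns_zero(self):
        with pytest.warns(UserWarning, match="both masks empty"):
            assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 0.0

    def test_signature_is_dot_product(self, rng):
        data = rng.standard_normal((7, 40))
        w = rng.standard_normal(40)
        np.testing.assert_allclose(score_signature(data, w), data @ w)

    def test_signature_grid_mismatch(self, rng):
        with pytest.raises(ValueError, match="do not overlap"):
            score_signature(rng.standard_normal((3, 10)),
                            rng.standard_normal(11))

    def test_signature_separates_conditions(self, small_brain):
        """Scoring with the planted social-population indicator yields
        higher responses on social-high trials."""
        labels = small_brain.truth_labels
        w = (labels == 1).astype(float)
        diffs = []
        for subj, data in small_brain.datasets.items():
            g = small_brain.trials[small_brain.trials.subject == subj]
            s = score_signature(data, w)
            diffs.append(s[g["social"].to_numpy() == 1].mean()
                         - s[g["social"].to_numpy() == -1].mean())
        assert np.mean(diffs) > 0
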