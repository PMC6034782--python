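"""Generator correctness: count law, masks, covariates, determinism, I/O."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from tdekit import (SimulationConfig, generate_cohort, generate_covariates,
                    generate_masks, generate_subject, read_manifest,
                    write_cohort)
from tdekit.synthetic import COVARIATE_NAMES, SimulationError


def count_law(t, tau, C, t_shift):
    """Closed-form cumulative count, clipped below onset."""
    return C * np.clip(1.0 - np.exp(-np.clip(t - t_shift, 0, None) / tau), 0, None)


class TestGenerateSubject:
    def test_count_series_matches_law_within_one_pixel(self, reference_subject):
        s = reference_subject
        times = s.video.times
        finite = s.onset_quantized[np.isfinite(s.onset_quantized)]
        counts = np.searchsorted(np.sort(finite), times, side="right")
        expected = np.round(count_law(times, 92.0, 284.0, 0.7))
        assert np.all(np.abs(counts - expected) <= 1)

    def test_final_count_equals_round_C(self, reference_subject):
        assert reference_subject.footprint.sum() == 284

    def test_csf_pixels_never_ablate(self, default_subject):
        assert not np.any(default_subject.footprint & default_subject.csf_mask)

    def test_symmetric_growth_selects_nearest_pixels(self):
        """With no asymmetry/CSF the footprint is the distance ball: its
        pixel distances to the laser are exactly the K smallest on the grid
        (ties permuted)."""
        cfg = SimulationConfig(n_subjects=1, asymmetry_ratio=1.0,
                               csf_fraction=0.0, seed=3)
        s = generate_subject(cfg, 0)
        from tdekit import laser_frame
        _, _, seg = laser_frame(cfg.grid_shape, s.laser, cfg.pixel_spacing)
        K = int(s.footprint.sum())
        sel = np.sort(seg[s.footprint])
        best = np.sort(seg.ravel())[:K]
        assert np.allclose(sel, best)

    def test_lateral_allocation_exceeds_mesial_for_ratio_above_one(self):
        cfg = SimulationConfig(n_subjects=1, asymmetry_ratio=1.4,
                               csf_fraction=0.0, seed=3)
        s = generate_subject(cfg, 0)
        from tdekit import onset_map, partition_rois
        om = onset_map(s.video)
        rois = partition_rois(om)
        assert (s.footprint & rois["lateral"]).sum() > (s.footprint & rois["mesial"]).sum()

    def test_excessive_C_raises(self):
        cfg = SimulationConfig(n_subjects=1, grid_shape=(64, 64), seed=0)
        with pytest.raises(SimulationError):
            generate_subject(cfg, 0, C=5000.0)

    def test_nonpositive_tau_raises(self):
        with pytest.raises(SimulationError):
            generate_subject(SimulationConfig(n_subjects=1), 0, tau=-5.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_subjects=0)
        with pytest.raises(SimulationError):
            SimulationConfig(n_frames=10)  # shorter than 5*tau_mean
        with pytest.raises(SimulationError):
            SimulationConfig(covariate_effects={"bogus": 1.0})

    def test_determinism_same_seed_byte_identical(self, fast_config):
        a = generate_subject(fast_config, 0)
        b = generate_subject(fast_config, 0)
        assert np.array_equal(a.video.frames, b.video.frames)
        assert np.array_equal(a.onset_exact, b.onset_exact)
        assert a.truth == b.truth


class TestGenerateMasks:
    def test_unit_ratios_zero_noise_reproduce_footprint(self, default_subject):
        cfg = SimulationConfig(immediate_area_ratio=1.0, delayed_area_ratio=1.0,
                               mask_noise_sd=0.0)
        imm, dl = generate_masks(default_subject, cfg, 0)
        assert np.array_equal(imm, default_subject.footprint)
        assert np.array_equal(dl, default_subject.footprint)

    def test_area_ratios_within_two_percent(self, default_subject):
        s = default_subject
        area = s.footprint.sum()
        assert abs(s.immediate_mask.sum() / area - 565 / 493) < 0.02 * 565 / 493
        assert abs(s.delayed_mask.sum() / area - 386 / 495) < 0.02 * 386 / 495

    def test_large_footprint_dilation_area_oracle(self):
        """1.146 dilation of a 10,000-pixel disc lands in [11230, 11690]."""
        rr, cc = np.meshgrid(np.arange(150), np.arange(150), indexing="ij")
        r = np.sqrt(10_000 / np.pi)
        fp = (rr - 75.0) ** 2 + (cc - 75.0) ** 2 <= r**2
        # trim to exactly 10,000 pixels
        dist = (rr - 75.0) ** 2 + (cc - 75.0) ** 2
        sel = np.argsort(dist.ravel(), kind="stable")[:10_000]
        fp = np.zeros(150 * 150, dtype=bool)
        fp[sel] = True
        fp = fp.reshape(150, 150)
        cfg = SimulationConfig(immediate_area_ratio=1.146)
        imm, _ = generate_masks(SimpleNamespace(footprint=fp), cfg, 0)
        assert 11_230 <= imm.sum() <= 11_690

    def test_masks_connected_and_delayed_strict_subset(self, default_subject):
        s = default_subject
        eight = np.ones((3, 3))
        assert ndimage.label(s.immediate_mask, structure=eight)[1] == 1
        assert ndimage.label(s.delayed_mask, structure=eight)[1] == 1
        assert np.all(~s.delayed_mask | s.footprint)  # delayed within footprint
        assert 0 < s.delayed_mask.sum() < s.footprint.sum()


class TestGenerateCovariates:
    @staticmethod
    def _truths(rng, n, tau_mean=92.0, tau_sd=40.0):
        taus = np.clip(rng.normal(tau_mean, tau_sd, n), 20, 170)
        return [{"tau": t, "inv_tau": 1.0 / t} for t in taus]

    def test_all_sixteen_columns_present(self, rng):
        cfg = SimulationConfig()
        df = generate_covariates(cfg, self._truths(rng, 20), seed=0)
        assert list(df.columns[1:]) == list(COVARIATE_NAMES)

    def test_null_effects_leave_covariates_uncorrelated(self, rng):
        cfg = SimulationConfig()
        truths = self._truths(rng, 400)
        df = generate_covariates(cfg, truths, seed=1)
        tau_inv = np.array([t["inv_tau"] for t in truths])
        for name in ("age", "t2_signal", "mean_power"):
            r = np.corrcoef(df[name], tau_inv)[0, 1]
            assert abs(r) < 0.15

    def test_planted_negative_t2_effect_recovered(self, rng):
        cfg = SimulationConfig(covariate_effects={"t2_signal": -0.002},
                               noise_sd=0.001)
        truths = self._truths(rng, 200)
        df = generate_covariates(cfg, truths, seed=2)
        tau_inv = np.array([t["inv_tau"] for t in truths])
        from tdekit import univariate_screen
        table = df.assign(inv_tau=tau_inv)
        rep = univariate_screen(table, "inv_tau", predictors=["t2_signal"])[0]
        assert rep.coefficients["t2_signal"] < 0
        assert rep.p_overall < 0.01

    def test_planted_relation_holds_identically(self, rng):
        """tau^-1 - base - sum(beta*(x-mu)) is N(0, noise_sd) by construction."""
        beta = -0.002
        cfg = SimulationConfig(covariate_effects={"t2_signal": beta},
                               noise_sd=0.0005)
        truths = self._truths(rng, 100)
        df = generate_covariates(cfg, truths, seed=5)
        tau_inv = np.array([t["inv_tau"] for t in truths])
        from tdekit.synthetic import DEFAULT_MARGINALS
        mu = DEFAULT_MARGINALS["t2_signal"][0]
        eps = tau_inv - 1 / cfg.tau_mean - beta * (df["t2_signal"] - mu)
        assert abs(eps.mean()) < 3 * 0.0005
        assert eps.std() < 3 * 0.0005

    def test_seed_determinism(self, rng):
        cfg = SimulationConfig()
        truths = self._truths(rng, 10)
        a = generate_covariates(cfg, truths, seed=3)
        b = generate_covariates(cfg, truths, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestWriteCohort:
    def test_round_trip(self, fast_config, tmp_path):
        cohort = generate_cohort(fast_config)
        manifest = write_cohort(cohort, tmp_path)
        assert manifest["n_subjects"] == fast_config.n_subjects
        assert len(manifest["subjects"]) == fast_config.n_subjects

        loaded = read_manifest(tmp_path / "manifest.json")
        assert loaded["seed"] == fast_config.seed

        # frames round-trip bit-identically
        import imageio.v3 as iio
        sub = cohort.subjects[0]
        for j in (0, 10, -1):
            frame = iio.imread(tmp_path / manifest["subjects"][0]["frames"][j])
            assert np.array_equal(frame, sub.video.frames[j])

        # truth CSV round-trips tau exactly (to float repr)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert np.allclose(truth["tau"].to_numpy(),
                           [s.truth["tau"] for s in cohort.subjects])
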