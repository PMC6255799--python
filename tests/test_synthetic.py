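"""Phantom generator: determinism, bookkeeping, biomarker statistics."""

import numpy as np
import pytest

from qcest.calibration import CalibrationModel
from qcest.synthetic import (
    generate_biomarker_table,
    make_disc_phantom,
    simulate_rq_values,
)


@pytest.fixture(scope="module")
def small_phantom():
    return make_disc_phantom(n_healthy=2, n_degen=3, n_voxels=4, seed=7)


class TestPhantomBookkeeping:
    def test_counts_and_group_labels(self):
        ds = make_disc_phantom(n_healthy=4, n_degen=12, seed=7, simulate_mri=False)
        assert len(ds.discs) == 16
        groups = [d.group for d in ds.discs]
        assert groups.count("healthy") == 4
        assert groups.count("degenerated") == 12

    def test_same_seed_reproduces_bit_identically(self):
        a = make_disc_phantom(n_healthy=2, n_degen=2, n_voxels=4, seed=3)
        b = make_disc_phantom(n_healthy=2, n_degen=2, n_voxels=4, seed=3)
        for da, db in zip(a.discs, b.discs):
            assert da.ph_true == db.ph_true
            np.testing.assert_array_equal(da.z_obs, db.z_obs)
            np.testing.assert_array_equal(da.ir_obs, db.ir_obs)

    def test_different_seeds_differ(self):
        a = make_disc_phantom(n_healthy=1, n_degen=1, seed=1, simulate_mri=False)
        b = make_disc_phantom(n_healthy=1, n_degen=1, seed=2, simulate_mri=False)
        assert a.discs[0].ph_true != b.discs[0].ph_true

    def test_ph_bounded_support(self):
        ds = make_disc_phantom(n_healthy=5, n_degen=20, ph_degen=(6.0, 0.6),
                               seed=13, simulate_mri=False)
        for d in ds.discs:
            assert 5.5 <= d.ph_true <= 8.0

    def test_degenerated_mean_ksw_exceeds_healthy_over_seeds(self):
        # calibration is strictly decreasing in pH, so the acidic group must
        # carry the higher ground-truth exchange rate in expectation
        diffs = []
        for seed in range(100):
            ds = make_disc_phantom(n_healthy=4, n_degen=12, seed=seed,
                                   simulate_mri=False)
            k = {"healthy": [], "degenerated": []}
            for d in ds.discs:
                k[d.group].append(d.ksw_true)
            diffs.append(np.mean(k["degenerated"]) - np.mean(k["healthy"]))
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.95

    def test_ground_truth_kept_next_to_observations(self, small_phantom):
        d = small_phantom.discs[0]
        assert d.z_obs.shape == (4, 4, 10)
        assert d.z_clean.shape == (4, 10)
        assert not np.array_equal(d.z_obs[0], d.z_clean)  # noise applied

    def test_manifest_columns(self, small_phantom):
        m = small_phantom.manifest()
        assert {"disc_id", "group", "ph_true", "ksw_true", "seed"} <= set(m.columns)
        assert len(m) == 5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            make_disc_phantom(n_healthy=0, n_degen=3)

    def test_rician_noise_supported(self):
        ds = make_disc_phantom(n_healthy=1, n_degen=1, n_voxels=4,
                               noise_model="rician", noise_sd=0.05, seed=5)
        assert np.all(ds.discs[0].z_obs >= 0)


class TestBiomarkerGenerator:
    def test_zero_noise_limit_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(300, 1500, 40)
        rq = simulate_rq_values(k, 0.999999, rng=1)
        r2 = np.corrcoef(k, rq)[0, 1] ** 2
        assert r2 == pytest.approx(1.0, abs=1e-4)

    def test_zero_slope_gives_null_correlation(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(300, 1500, 60)
        r2s = []
        for s in range(100):
            rq = 5.0 + np.random.default_rng(s).normal(0, 1, 60)
            r2s.append(np.corrcoef(k, rq)[0, 1] ** 2)
        assert np.mean(r2s) < 0.05

    def test_target_r2_hit_in_expectation(self):
        # COMT-level population R^2 over Monte-Carlo replicates
        rng = np.random.default_rng(10)
        r2s = []
        for _ in range(200):
            k = rng.uniform(300, 1500, 48)
            rq = simulate_rq_values(k, 0.9025, rng=rng)
            r2s.append(np.corrcoef(k, rq)[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.9025, abs=0.03)

    def test_rq_positive_and_markers_complete(self, small_phantom):
        table = generate_biomarker_table(small_phantom, seed=2)
        assert set(table["marker"]) == {"CGRP", "BDKRB1", "COMT", "IL6", "BDNF"}
        assert set(table["compartment"]) == {"AF", "NP"}
        assert (table["rq"] > 0).all()
        assert len(table) == 5 * 2 * 5

    def test_degenerate_constant_ksw_rejected(self):
        with pytest.raises(ValueError):
            simulate_rq_values(np.full(10, 400.0), 0.9)

    def test_invalid_target_r2_rejected(self):
        with pytest.raises(ValueError):
            simulate_rq_values(np.array([1.0, 2.0]), 1.5)
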