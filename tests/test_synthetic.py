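"""Synthetic digital-reference-object cohort generator."""

import numpy as np
import pytest

from dcequant import (B1RatioMap, CohortDesign, fit_ssm, fit_vfa_r1,
                      generate_truth_maps, simulate_dce_series,
                      simulate_vfa_and_b1, spgr_signal)
from dcequant.synthetic import DEFAULT_EFFECT_TABLE, rician


def zero_jitter_design(**kwargs):
    effects = {p: {v: {"pCR": -50.0 if p == "ktrans" else 0.0,
                       "non-pCR": 0.0}
                   for v in ("V2", "V3", "V4")}
               for p in ("ktrans", "ve", "kio", "r10")}
    zeros = {p: {v: {"pCR": 0.0, "non-pCR": 0.0}
                 for v in ("V2", "V3", "V4")}
             for p in ("ktrans", "ve", "kio", "r10")}
    defaults = dict(n_pcr=1, n_nonpcr=1, n_voxels=40, grid_shape=(8, 8, 6),
                    effect_table=effects, jitter_sd=zeros,
                    voxel_jitter_cv=0.0, seed=11)
    defaults.update(kwargs)
    return CohortDesign(**defaults)


class TestTruthMaps:
    def test_effect_scaling_without_jitter(self):
        # -50% Ktrans at V3, zero jitter: V3 voxel values are exactly half
        design = zero_jitter_design()
        v1 = generate_truth_maps(design, 0, "V1")
        v3 = generate_truth_maps(design, 0, "V3")
        roi = v1.roi_mask
        np.testing.assert_allclose(v3.ktrans_map[roi],
                                   0.5 * v1.ktrans_map[roi], rtol=1e-12)
        np.testing.assert_allclose(v3.ve_map[roi], v1.ve_map[roi], rtol=1e-12)

    def test_determinism(self):
        design = CohortDesign(n_voxels=60, grid_shape=(8, 8, 6), seed=5)
        a = generate_truth_maps(design, 2, "V2")
        b = generate_truth_maps(design, 2, "V2")
        for name in ("ktrans_map", "ve_map", "kio_map", "r10_map"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_sample_median_matches_design(self):
        design = CohortDesign(n_voxels=10_000, grid_shape=(32, 32, 20), seed=3)
        truth = generate_truth_maps(design, 0, "V1")
        roi = truth.roi_mask
        assert abs(np.median(truth.ktrans_map[roi]) / 0.25 - 1) < 0.05
        assert abs(np.median(truth.r10_map[roi]) / 0.6 - 1) < 0.05

    def test_invariants_inside_roi(self):
        design = CohortDesign(n_voxels=500, seed=1)
        t = generate_truth_maps(design, 0, "V1")
        roi = t.roi_mask
        assert np.all(t.ve_map[roi] > 0) and np.all(t.ve_map[roi] <= 1)
        assert np.all(t.kio_map > 0) and np.all(t.r10_map > 0)
        assert np.all(t.ktrans_map >= 0)

    def test_unknown_visit_rejected(self):
        with pytest.raises(ValueError):
            generate_truth_maps(CohortDesign(), 0, "V9")

    def test_effect_table_bound_enforced(self):
        bad = {"ktrans": {"V2": {"pCR": -120.0, "non-pCR": 0.0}}}
        with pytest.raises(ValueError):
            CohortDesign(effect_table=bad)


class TestSimulateDCE:
    def test_no_extravasation_gives_flat_curves(self, protocol):
        design = zero_jitter_design(median_ktrans=0.0)
        # median 0 forces ktrans = 0 everywhere (lognormal scale collapses)
        truth = generate_truth_maps(design, 0, "V1")
        dce = simulate_dce_series(truth, protocol, noise_sigma=0.0)
        assert np.ptp(dce, axis=-1).max() == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_ssm_round_trip_on_interior_voxels(self, protocol, aif):
        design = zero_jitter_design(n_voxels=30, seed=2)
        truth = generate_truth_maps(design, 0, "V1")
        dce = simulate_dce_series(truth, protocol, aif, noise_sigma=0.0)
        for i, j, k in np.argwhere(truth.roi_mask)[:6]:
            res = fit_ssm(dce[i, j, k], truth.r10_map[i, j, k], aif, protocol)
            assert res.ktrans == pytest.approx(truth.ktrans_map[i, j, k],
                                               rel=1e-2)
            assert res.ve == pytest.approx(truth.ve_map[i, j, k], rel=1e-2)
            assert res.kio == pytest.approx(truth.kio_map[i, j, k], rel=1e-2)

    def test_seeded_noise_reproducible(self, protocol):
        design = zero_jitter_design(seed=8)
        truth = generate_truth_maps(design, 0, "V1")
        a = simulate_dce_series(truth, protocol, noise_sigma=0.02, seed=9)
        b = simulate_dce_series(truth, protocol, noise_sigma=0.02, seed=9)
        c = simulate_dce_series(truth, protocol, noise_sigma=0.02, seed=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_noise_rejected(self, protocol):
        truth = generate_truth_maps(zero_jitter_design(), 0, "V1")
        with pytest.raises(ValueError):
            simulate_dce_series(truth, protocol, noise_sigma=-0.1)

    def test_rician_matches_gaussian_at_high_snr(self):
        # at SNR 50 the Rician mean deviates from the signal by ~sigma^2/2S,
        # i.e. well under 1%
        rng = np.random.default_rng(0)
        s = 100.0
        draws = rician(np.full(200_000, s), s / 50.0, rng)
        assert abs(draws.mean() / s - 1) < 0.01
        assert abs(draws.mean() / s - 1) == pytest.approx(
            (s / 50.0) ** 2 / (2 * s**2), abs=2e-4)


class TestSimulateVFA:
    def test_identity_field_matches_spgr(self, protocol):
        truth = generate_truth_maps(zero_jitter_design(), 0, "V1")
        vfa, b1 = simulate_vfa_and_b1(truth, protocol, b1_field=1.0)
        expected = spgr_signal(1000.0, truth.r10_map[..., None],
                               np.asarray(protocol.vfa_angles),
                               protocol.tr_vfa)
        np.testing.assert_allclose(vfa.signals, expected, rtol=1e-12)
        assert np.all(b1.ratio == 1.0)

    def test_consistent_field_and_map_recover_r1(self, protocol):
        truth = generate_truth_maps(zero_jitter_design(), 0, "V1")
        vfa, b1 = simulate_vfa_and_b1(truth, protocol, b1_field=1.2)
        assert np.all(b1.ratio == 1.2)
        m = fit_vfa_r1(vfa, b1, protocol, mask=truth.roi_mask)
        roi = truth.roi_mask
        np.testing.assert_allclose(m.r1[roi], truth.r10_map[roi], rtol=1e-6)

    def test_miscalibrated_map_biases_fit_as_oracle_predicts(self, protocol):
        # actual excitation 1.2x nominal, emitted map claims 1.0: the fit
        # trusts the map and lands where a brute-force grid search over the
        # forward model (at nominal angles) puts it - biased low
        truth = generate_truth_maps(zero_jitter_design(), 0, "V1")
        vfa, b1 = simulate_vfa_and_b1(truth, protocol, b1_field=1.2,
                                      bias_mode="miscalibrated")
        assert np.all(b1.ratio == 1.0)
        m = fit_vfa_r1(vfa, b1, protocol, mask=truth.roi_mask)
        i, j, k = np.argwhere(truth.roi_mask)[0]
        r10_true = truth.r10_map[i, j, k]
        sig = vfa.signals[i, j, k]

        r1_grid = np.linspace(0.05, 2.0, 2000)
        s0_grid = np.linspace(500, 2000, 600)
        model = spgr_signal(s0_grid[:, None, None], r1_grid[None, :, None],
                            np.asarray(protocol.vfa_angles)[None, None, :],
                            protocol.tr_vfa)
        sse = ((model - sig) ** 2).sum(axis=-1)
        _, jj = np.unravel_index(np.argmin(sse), sse.shape)
        assert m.r1[i, j, k] == pytest.approx(r1_grid[jj], abs=2e-3)
        assert m.r1[i, j, k] < r10_true  # bias direction

    def test_nonpositive_field_rejected(self, protocol):
        truth = generate_truth_maps(zero_jitter_design(), 0, "V1")
        with pytest.raises(ValueError):
            simulate_vfa_and_b1(truth, protocol, b1_field=0.0)


def test_default_effect_table_matches_reported_group_medians():
    kt = DEFAULT_EFFECT_TABLE["ktrans"]
    assert kt["V2"] == {"pCR": -71.0, "non-pCR": 1.0}
    assert kt["V3"] == {"pCR": -91.0, "non-pCR": -27.0}
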