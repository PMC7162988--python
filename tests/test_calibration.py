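"""Crosstalk ratios, the single-step plane fit and its bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quantifret as qf
from quantifret.calibration import (
    CollinearityError,
    bootstrap_calibration,
    corrected_fret_image,
    crosstalk_factor,
    fit_plane,
)
from quantifret.forward_model import CameraModel, instrument_from_factors


def masked_fields(stoichiometry, n_fields=2, camera=None, e_mean=0.0,
                  seed=0):
    inst = instrument_from_factors()
    camera = camera or CameraModel.ideal()
    rng = np.random.default_rng(seed)
    trips = []
    for _ in range(n_fields):
        sc = qf.generate_scene(shape=(200, 200), n_cells=3,
                               stoichiometry=stoichiometry, e_mean=e_mean,
                               e_cell_sd=0.0, e_pixel_sd=0.0, rng=rng)
        raw = qf.render_triplet(sc, inst, camera, rng=rng)
        trips.append(qf.ImageTriplet(*raw, mask=sc.cell_label > 0))
    return trips, inst


class TestCrosstalk:
    def test_donor_only_noise_free_is_exact(self):
        trips, inst = masked_fields(1.0)
        res = crosstalk_factor(trips, "donor_only", n_boot=50, rng=0)
        truth = qf.true_correction_factors(inst)
        assert res.factor == pytest.approx(truth.alpha_BT, rel=1e-12)
        assert res.n_cells == 6

    def test_acceptor_only_with_shot_noise_within_one_percent(self):
        trips, inst = masked_fields(
            0.0, camera=CameraModel(dark_count=0, read_noise_sd=0), seed=3)
        res = crosstalk_factor(trips, "acceptor_only", n_boot=50, rng=0)
        truth = qf.true_correction_factors(inst)
        assert res.factor == pytest.approx(truth.delta_DE, rel=0.01)
        assert res.sd < 0.01 * truth.delta_DE * 5

    def test_zero_sensitized_channel_gives_zero(self):
        img = np.full((64, 64), 500.0)
        trip = qf.ImageTriplet(img, np.zeros_like(img), np.zeros_like(img),
                               mask=np.ones_like(img, dtype=bool))
        with pytest.warns(UserWarning):  # fewer than 5 cells
            res = crosstalk_factor([trip], "donor_only", n_boot=10, rng=0)
        assert res.factor == 0.0

    def test_scale_invariance_of_pooled_median(self):
        """Per-cell intensity scaling leaves the ratio median unchanged."""
        trips, _ = masked_fields(1.0)
        scaled = [qf.ImageTriplet(10 * t.I_DD, 10 * t.I_DA, 10 * t.I_AA,
                                  mask=t.mask) for t in trips]
        a = crosstalk_factor(trips, "donor_only", n_boot=2, rng=0).factor
        b = crosstalk_factor(scaled, "donor_only", n_boot=2, rng=0).factor
        assert a == pytest.approx(b, rel=1e-12)

    def test_kind_mismatch_warns(self):
        trips, _ = masked_fields(0.0)  # acceptor-only data
        with pytest.warns(UserWarning, match="check sample kind"):
            # I_DD is empty for acceptor-only cells, so after the warning
            # the ratio has no usable denominator pixels either
            with pytest.raises(ValueError, match="no usable pixels"):
                crosstalk_factor(trips, "donor_only", n_boot=2, rng=0)


class TestCorrectedFretImage:
    def test_zero_factors_identity(self):
        trips, _ = masked_fields(0.5, e_mean=0.4)
        t = trips[0]
        np.testing.assert_array_equal(corrected_fret_image(t, 0, 0), t.I_DA)

    @pytest.mark.parametrize("stoich", [1.0, 0.0])
    def test_single_fluorophore_pixels_cancel_exactly(self, stoich):
        trips, inst = masked_fields(stoich)
        truth = qf.true_correction_factors(inst)
        for t in trips:
            c = corrected_fret_image(t, truth.alpha_BT, truth.delta_DE)
            np.testing.assert_allclose(c[t.mask], 0, atol=1e-8)


def plane_pixels(inst, e_levels, s=0.5, n_per=300, seed=0, noisy=False):
    rng = np.random.default_rng(seed)
    truth = qf.true_correction_factors(inst)
    dd, cc, aa = [], [], []
    for e0 in e_levels:
        n_tot = 10 ** rng.uniform(4.5, 6.5, n_per)
        exp = qf.expected_intensities(s * n_tot, (1 - s) * n_tot,
                                      np.full(n_per, e0), inst)
        i_dd, i_da, i_aa = exp.I_DD, exp.I_DA, exp.I_AA
        if noisy:
            i_dd = rng.poisson(i_dd).astype(float)
            i_da = rng.poisson(i_da).astype(float)
            i_aa = rng.poisson(i_aa).astype(float)
        dd.append(i_dd)
        cc.append(i_da - truth.alpha_BT * i_dd - truth.delta_DE * i_aa)
        aa.append(i_aa)
    return (np.concatenate(dd), np.concatenate(cc), np.concatenate(aa),
            truth)


class TestFitPlane:
    def test_noise_free_three_level_recovery_is_exact(self):
        inst = instrument_from_factors()
        dd, c, aa, truth = plane_pixels(inst, (0.35, 0.42, 0.50))
        fit = fit_plane(dd, c, aa, s0=0.5)
        assert fit.gamma_M == pytest.approx(2.10, rel=1e-10)
        assert fit.beta_X == pytest.approx(1.167, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_fret_level_is_collinear(self):
        inst = instrument_from_factors()
        dd, c, aa, _ = plane_pixels(inst, (0.42,))
        with pytest.raises(CollinearityError, match="FRET range"):
            fit_plane(dd, c, aa)

    def test_non_half_stoichiometry_recovers_same_factors(self):
        """A 2:1 donor:acceptor standard constrains the same plane."""
        inst = instrument_from_factors()
        dd, c, aa, truth = plane_pixels(inst, (0.35, 0.50), s=2 / 3)
        fit = fit_plane(dd, c, aa, s0=2 / 3)
        assert fit.gamma_M == pytest.approx(truth.gamma_M, rel=1e-9)
        assert fit.beta_X == pytest.approx(truth.beta_X, rel=1e-9)

    @pytest.mark.parametrize("s0", [0.0, 1.0])
    def test_degenerate_s0_rejected(self, s0):
        with pytest.raises(ValueError):
            fit_plane(np.ones(4), np.ones(4), np.ones(4), s0=s0)

    @given(gamma=st.floats(0.5, 4.0), beta=st.floats(0.5, 4.0),
           seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_recovery_over_randomized_instruments(self, gamma, beta, seed):
        """Noise-free plane fit matches the instrument ratios to 1e-8."""
        inst = instrument_from_factors(0.4, 0.1, gamma, beta)
        dd, c, aa, truth = plane_pixels(inst, (0.3, 0.5), n_per=60,
                                        seed=seed)
        fit = fit_plane(dd, c, aa)
        assert fit.gamma_M == pytest.approx(truth.gamma_M, rel=1e-8)
        assert fit.beta_X == pytest.approx(truth.beta_X, rel=1e-8)

    def test_noisy_fit_asymptotically_unbiased(self):
        """Bias below 2% with shot noise at high SNR and 1e5 pixels."""
        inst = instrument_from_factors(photon_scale=4.0)  # SNR >= 30
        dd, c, aa, truth = plane_pixels(inst, (0.35, 0.42, 0.50),
                                        n_per=34_000, seed=2, noisy=True)
        fit = fit_plane(dd, c, aa)
        assert fit.gamma_M == pytest.approx(truth.gamma_M, rel=0.02)
        assert fit.beta_X == pytest.approx(truth.beta_X, rel=0.02)


class TestBootstrapCalibration:
    def test_noise_free_dispersion_is_negligible(self):
        inst = instrument_from_factors()
        dd, c, aa, _ = plane_pixels(inst, (0.35, 0.50), n_per=2000)
        tab = bootstrap_calibration(dd, c, aa, sample_sizes=(200, 1000),
                                    n_reps=30, rng=0)
        assert (tab["sd_gamma"] < 1e-8).all()
        assert (tab["sd_beta"] < 1e-8).all()

    def test_dispersion_decreases_with_sample_size(self):
        inst = instrument_from_factors()
        dd, c, aa, _ = plane_pixels(inst, (0.35, 0.42, 0.50), n_per=20_000,
                                    seed=4, noisy=True)
        tab = bootstrap_calibration(dd, c, aa, sample_sizes=(1000, 30_000),
                                    n_reps=60, rng=1)
        assert tab.loc[0, "sd_gamma"] > tab.loc[1, "sd_gamma"]
        assert tab.loc[0, "sd_beta"] > tab.loc[1, "sd_beta"]

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_calibration(np.ones(10), np.ones(10), np.ones(10),
                                  sample_sizes=(100,), n_reps=2, rng=0)


class TestCalibrateDataset:
    def test_full_calibration_on_study_scale_data(self, study_scale):
        """The complete pipeline recovers the generating factors closely."""
        _, _, analysis = study_scale
        f = analysis.factors
        assert f.alpha_BT == pytest.approx(0.421, rel=0.01)
        assert f.delta_DE == pytest.approx(0.110, rel=0.01)
        assert f.gamma_M == pytest.approx(2.10, rel=0.01)
        assert f.beta_X == pytest.approx(1.167, rel=0.01)
        assert f.r_squared > 0.99
        assert f.n_pixels > 1e5
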