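"""Signal model, correction-factor ratios and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quantifret as qf
from quantifret.forward_model import (
    CameraModel,
    InstrumentModel,
    expected_intensities,
    generate_scene,
    instrument_from_factors,
    render_triplet,
    true_correction_factors,
)


def unit_instrument(**overrides):
    """Crosstalk-free instrument with every parameter equal to one."""
    params = dict(L_D=1, L_A=1, sigma_Dex_D=1, sigma_Dex_A=0, sigma_Aex_A=1,
                  phi_D=1, phi_A=1, eta_Ddet_Dem=1, eta_Adet_Dem=0,
                  eta_Adet_Aem=1)
    params.update(overrides)
    return InstrumentModel(**params)


class TestExpectedIntensities:
    def test_crosstalk_free_symmetric_instrument(self):
        out = expected_intensities(100, 100, 0.5, unit_instrument())
        assert out.I_AA == pytest.approx(100)
        assert out.I_DD == pytest.approx(50)
        assert out.I_DA == pytest.approx(50)

    def test_donor_only_limit_is_pure_bleedthrough(self):
        inst = unit_instrument(eta_Adet_Dem=0.3)
        out = expected_intensities(100, 0, 0.0, inst)
        assert out.I_AA == 0
        assert out.I_DA == pytest.approx(100 * 0.3)

    def test_reference_instrument_against_term_by_term_oracle(self):
        # independent hand evaluation of the three terms for an instrument
        # realising alpha=0.421, delta=0.110, gamma=2.10, beta=1.167
        inst = InstrumentModel(
            L_D=1.0, L_A=1.167, sigma_Dex_D=1.0, sigma_Aex_A=1.0,
            sigma_Dex_A=0.110 * 1.167,
            phi_D=0.4, phi_A=0.6,
            eta_Ddet_Dem=0.5, eta_Adet_Dem=0.421 * 0.5, eta_Adet_Aem=0.7,
        )
        f = true_correction_factors(inst)
        assert f.alpha_BT == pytest.approx(0.421)
        assert f.delta_DE == pytest.approx(0.110)
        assert f.gamma_M == pytest.approx(2.10)
        assert f.beta_X == pytest.approx(1.167)

        n_d = n_a = 200.0
        e = 0.35
        out = expected_intensities(n_d, n_a, e, inst)
        i_aa = 200.0 * 1.167 * 1.0 * 0.6 * 0.7
        i_dd = 200.0 * 1.0 * 1.0 * (1 - 0.35) * 0.4 * 0.5
        i_da = (200.0 * 1.0 * 1.0 * 0.35 * 0.6 * 0.7
                + 200.0 * 1.0 * 1.0 * 0.65 * 0.4 * (0.421 * 0.5)
                + 200.0 * 1.0 * (0.110 * 1.167) * 0.6 * 0.7)
        assert out.I_AA == pytest.approx(i_aa, rel=1e-12)
        assert out.I_DD == pytest.approx(i_dd, rel=1e-12)
        assert out.I_DA == pytest.approx(i_da, rel=1e-12)

    @pytest.mark.parametrize("n_d,n_a,e", [(-1, 0, 0.5), (0, -1, 0.5),
                                           (1, 1, 1.5), (1, 1, -0.1)])
    def test_domain_errors(self, n_d, n_a, e):
        with pytest.raises(ValueError):
            expected_intensities(n_d, n_a, e, unit_instrument())

    @given(c=st.floats(0.01, 100), e=st.floats(0, 1),
           n=st.floats(1, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_counts(self, c, e, n):
        """Joint scaling of the counts scales all intensities linearly."""
        inst = instrument_from_factors()
        base = expected_intensities(n, n, e, inst)
        scaled = expected_intensities(c * n, c * n, e, inst)
        for a, b in zip(base, scaled):
            assert b == pytest.approx(c * a, rel=1e-9)


class TestTrueCorrectionFactors:
    def test_unit_instrument_gives_unit_factors(self):
        inst = unit_instrument(sigma_Dex_A=1, eta_Adet_Dem=1)
        f = true_correction_factors(inst)
        assert (f.alpha_BT, f.delta_DE, f.gamma_M, f.beta_X) == (1, 1, 1, 1)

    def test_bleedthrough_is_detection_ratio(self):
        inst = unit_instrument(eta_Adet_Dem=0.4)
        assert true_correction_factors(inst).alpha_BT == pytest.approx(0.4)

    def test_gamma_is_brightness_ratio(self):
        inst = unit_instrument(phi_A=0.6, eta_Adet_Aem=0.7, phi_D=0.4,
                               eta_Ddet_Dem=0.5)
        # hand evaluation: (0.6*0.7)/(0.4*0.5)
        assert true_correction_factors(inst).gamma_M == pytest.approx(2.1)

    def test_instrument_from_factors_round_trips(self):
        f = true_correction_factors(
            instrument_from_factors(0.3, 0.2, 3.1, 0.8))
        assert f.alpha_BT == pytest.approx(0.3)
        assert f.delta_DE == pytest.approx(0.2)
        assert f.gamma_M == pytest.approx(3.1)
        assert f.beta_X == pytest.approx(0.8)


class TestGenerateScene:
    def test_empty_scene(self):
        sc = generate_scene(shape=(64, 64), n_cells=0, rng=0)
        assert not sc.n_D.any() and not sc.n_A.any()
        assert not sc.cell_label.any()

    def test_one_to_one_stoichiometry_by_construction(self):
        sc = generate_scene(shape=(160, 160), n_cells=3, stoichiometry=0.5,
                            e_mean=0.5, e_cell_sd=0, e_pixel_sd=0, rng=1)
        inside = sc.cell_label > 0
        assert inside.any()
        np.testing.assert_allclose(sc.n_D[inside], sc.n_A[inside])
        np.testing.assert_allclose(sc.E_true[inside], 0.5)
        assert sc.n_D[~inside].max() == 0  # background is empty

    def test_three_population_means_match_targets(self):
        # emulates the C5V/C17V/C32V standards as generative targets
        rng = np.random.default_rng(7)
        for e0 in (0.503, 0.417, 0.351):
            sc = generate_scene(shape=(320, 320), n_cells=8, e_mean=e0,
                                e_cell_sd=0.015, e_pixel_sd=0.02, rng=rng)
            inside = sc.cell_label > 0
            # mean over ~1e4 pixels: sampling error ~ cell sd / sqrt(8)
            assert np.mean(sc.E_true[inside]) == pytest.approx(e0, abs=0.03)

    def test_seed_determinism(self):
        a = generate_scene(shape=(96, 96), n_cells=2, radius_range=(8, 14),
                           rng=5)
        b = generate_scene(shape=(96, 96), n_cells=2, radius_range=(8, 14),
                           rng=5)
        np.testing.assert_array_equal(a.n_D, b.n_D)
        np.testing.assert_array_equal(a.E_true, b.E_true)

    def test_cells_are_connected_regions(self):
        from skimage import measure

        sc = generate_scene(shape=(200, 200), n_cells=4, rng=3)
        for k in range(1, 5):
            comp = measure.label(sc.cell_label == k)
            assert comp.max() == 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_scene(n_cells=1, stoichiometry=1.5, rng=0)
        with pytest.raises(ValueError):
            generate_scene(shape=(32, 32), n_cells=50, rng=0)  # no room


class TestRenderTriplet:
    def test_ideal_camera_equals_expected_intensities(self, ref_instrument):
        sc = generate_scene(shape=(128, 128), n_cells=2, rng=2)
        raw = render_triplet(sc, ref_instrument, CameraModel.ideal(), rng=0)
        exp = expected_intensities(sc.n_D, sc.n_A, sc.E_true, ref_instrument)
        np.testing.assert_array_equal(raw.I_DD, exp.I_DD)
        np.testing.assert_array_equal(raw.I_DA, exp.I_DA)
        np.testing.assert_array_equal(raw.I_AA, exp.I_AA)

    def test_dark_offset_only(self, ref_instrument):
        sc = generate_scene(shape=(32, 32), n_cells=0, rng=0)
        cam = CameraModel(dark_count=100.0, read_noise_sd=0.0,
                          shot_noise=False)
        raw = render_triplet(sc, ref_instrument, cam, rng=0)
        np.testing.assert_allclose(raw.I_DD, 100.0)
        np.testing.assert_allclose(raw.I_AA, 100.0)

    def test_poisson_moments(self, ref_instrument):
        """Sample mean ~ expectation, variance/mean ~ gain (Poisson)."""
        n = np.full((100, 100), 10_000.0 / 0.2)  # I_DD = n*(1-E)*0.25... use AA
        sc = qf.GroundTruthScene(
            n_D=np.zeros((100, 100)), n_A=n, E_true=np.zeros((100, 100)),
            cell_label=np.ones((100, 100), dtype=int))
        gain = 2.0
        cam = CameraModel(dark_count=0.0, read_noise_sd=0.0, gain=gain,
                          shot_noise=True)
        raw = render_triplet(sc, ref_instrument, cam, rng=11)
        exp = expected_intensities(sc.n_D, sc.n_A, sc.E_true,
                                   ref_instrument).I_AA * gain
        assert raw.I_AA.mean() == pytest.approx(exp.mean(), rel=0.01)
        assert raw.I_AA.var() / raw.I_AA.mean() == pytest.approx(gain,
                                                                 rel=0.05)

    def test_flat_field_multiplies(self, ref_instrument):
        sc = generate_scene(shape=(64, 64), n_cells=1, rng=4)
        flat = np.full((64, 64), 1.0)
        flat[:, :32] = 2.0
        cam = CameraModel(dark_count=0, read_noise_sd=0, flat_field=flat,
                          shot_noise=False)
        raw = render_triplet(sc, ref_instrument, cam, rng=0)
        exp = expected_intensities(sc.n_D, sc.n_A, sc.E_true, ref_instrument)
        np.testing.assert_allclose(raw.I_DD, exp.I_DD * flat)

    def test_seed_determinism_bit_identical(self, ref_instrument):
        sc = generate_scene(shape=(64, 64), n_cells=1, rng=9)
        a = render_triplet(sc, ref_instrument, CameraModel(), rng=21)
        b = render_triplet(sc, ref_instrument, CameraModel(), rng=21)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestRoundTripInversion:
    def test_noise_free_closed_form_inversion(self, ref_instrument):
        """E and S master equations invert the exact forward model."""
        sc = generate_scene(shape=(160, 160), n_cells=3, e_mean=0.4,
                            e_cell_sd=0.05, e_pixel_sd=0.05, rng=6)
        raw = render_triplet(sc, ref_instrument, CameraModel.ideal(), rng=0)
        trip = qf.ImageTriplet(*raw, mask=sc.cell_label > 0)
        truth = true_correction_factors(ref_instrument)
        e, ve = qf.fret_efficiency(trip, truth)
        s, vs = qf.stoichiometry(trip, truth)
        inside = (sc.cell_label > 0) & ve & vs
        np.testing.assert_allclose(e[inside], sc.E_true[inside],
                                   rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(s[inside], 0.5, rtol=1e-10)
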