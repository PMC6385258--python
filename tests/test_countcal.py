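"""Calibration arithmetic: window sums, backgrounds, counts, AF, AUROC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdc3dm import countcal as C, deconv, spotdetect as SD, synthscope as S


class TestSpotIntensity:
    def test_uniform_stack_cancels_background(self):
        stack = np.full((15, 9, 9), 4.0)
        assert C.spot_intensity_3dd(stack, (4, 4, 7), 99 * 4.0) == pytest.approx(0.0)

    def test_delta_spot_on_zero_background(self):
        stack = np.zeros((15, 9, 9))
        stack[7, 4, 4] = 123.0
        assert C.spot_intensity_3dd(stack, (4, 4, 7), 0.0) == pytest.approx(123.0)

    def test_border_window_rejected(self):
        with pytest.raises(ValueError, match="border"):
            C.spot_intensity_3dd(np.zeros((15, 9, 9)), (4, 4, 2), 0.0)


class TestEstimateBackground:
    def test_constant_stack(self):
        stack = np.full((15, 32, 32), 3.0)
        bg = C.estimate_background(stack, [], seed=0)
        assert bg["3x3x11"] == pytest.approx(99 * 3.0)
        assert bg["3x3"] == pytest.approx(9 * 3.0)

    def test_bright_spot_is_masked_out(self):
        stack = np.full((15, 48, 48), 3.0)
        stack[7, 20, 20] = 1e6
        spot = SD.SpotRecord(centroid=(20.0, 20.0, 7.0))
        with_spot = C.estimate_background(stack, [spot], seed=0)["3x3x11"]
        assert with_spot == pytest.approx(99 * 3.0, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            C.estimate_background(np.zeros((15, 32, 32)), [], mask=np.zeros((32, 32), bool))

    def test_insufficient_background_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            C.estimate_background(np.zeros((15, 6, 6)), [], seed=0)


class TestCalibration:
    def test_trivial_mean_and_sd(self):
        cal = C.calibrate_single_qd([900.0, 900.0, 900.0])
        assert cal.mean_i_1qd_3dd == 900.0
        assert cal.dispersion == 0.0
        assert cal.n_single == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            C.calibrate_single_qd([])

    def test_72_single_qds_match_analytic_window_mass(self, optics):
        """Window sums of isolated always-on QDs equal brightness x PSF mass."""
        scene = S.make_spot_field(72, (220, 220), n_planes=40, seed=6)
        for em in scene.emitters:
            em.states = np.ones((1, 40), dtype=np.uint8)
        stack = S.render_stack3d(scene, optics, 40, seed=7)
        bg = C.estimate_background(
            stack, [SD.SpotRecord(centroid=em.position) for em in scene.emitters], seed=0
        )
        vals, masses = [], []
        for em in scene.emitters:
            r = tuple(int(np.floor(v + 0.5)) for v in em.position)
            vals.append(C.spot_intensity_3dd(stack, r, bg["3x3x11"]))
            masses.append(S.psf_window_mass(optics, em.position, half_xy=1, half_z=5))
        cal = C.calibrate_single_qd(vals)
        expected = em.brightness_per_qd * np.mean(masses)
        assert cal.mean_i_1qd_3dd == pytest.approx(expected, rel=0.03)


class TestPerSpotCounts:
    def test_unit_and_triple(self):
        cal = C.Calibration(mean_i_1qd_3dd=500.0, n_single=10, dispersion=10.0)
        assert C.qds_per_spot(500.0, cal) == pytest.approx(1.0)
        assert C.qds_per_spot(1500.0, cal) == pytest.approx(3.0)

    def test_background_overshoot_clamps_with_warning(self):
        cal = C.Calibration(mean_i_1qd_3dd=500.0, n_single=10, dispersion=10.0)
        with pytest.warns(UserWarning, match="clamping"):
            assert C.qds_per_spot(-20.0, cal) == 0.0

    def test_count_cell_sums_spots(self):
        cal = C.Calibration(mean_i_1qd_3dd=100.0, n_single=5, dispersion=0.0)
        spots = [SD.SpotRecord(centroid=(0, 0, 0), i_spot_3dd=v) for v in (100.0, 100.0, 200.0)]
        cell = C.count_cell(spots, cal)
        assert cell.n_qd_cell == pytest.approx(4.0)
        assert cell.n_qd_cell_int == 4
        assert cell.n_egf_cell == cell.n_qd_cell

    def test_empty_cell_counts_zero(self):
        cal = C.Calibration(mean_i_1qd_3dd=100.0, n_single=5, dispersion=0.0)
        assert C.count_cell([], cal).n_qd_cell == 0.0


class TestDepthInvariance:
    def test_calibrated_intensity_independent_of_z(self, optics, psf):
        """Single-QD window intensity after deconvolution has no z-trend."""
        zs = np.linspace(10.0, 30.0, 8)
        vals = []
        for i, z in enumerate(zs):
            em = S.EmitterTruth(
                position=(16.0 + 0.1 * i, 16.0, float(z)),
                n_qd=1,
                states=np.ones((1, 40), dtype=np.uint8),
            )
            scene = S.SceneTruth(emitters=[em], autofluorescence_field=np.zeros((32, 32)), seed=0)
            stack = S.render_stack3d(scene, optics, 40, seed=0, apply_noise=False)
            dec = deconv.richardson_lucy(stack, psf, 60)
            vals.append(C.spot_intensity_3dd(dec, em.rounded if hasattr(em, "rounded") else tuple(int(np.floor(v + 0.5)) for v in em.position), 0.0))
        slope = np.polyfit(zs, vals, 1)[0]
        assert abs(slope) * (zs[-1] - zs[0]) < 0.05 * np.mean(vals)


class TestAutofluorescence:
    def _channels(self):
        curve = np.array([[400.0, 0.8], [800.0, 0.8]])
        return [
            C.SpectralChannel(lambda_em=lam, band=(lam - 20, lam + 20), qe_curve=curve)
            for lam in (562.0, 600.0, 732.0)
        ]

    def test_reference_channel_is_unity(self):
        tab = C.autofluorescence_spectrum(
            {562.0: 50, 600.0: 40, 732.0: 20},
            {562.0: 10, 600.0: 10, 732.0: 10},
            self._channels(),
        )
        assert tab.set_index("lambda_em").loc[562.0, "i_af_norm"] == pytest.approx(1.0)

    def test_cell_equal_background_gives_zero(self):
        tab = C.autofluorescence_spectrum(
            {562.0: 10, 600.0: 10, 732.0: 7},
            {562.0: 5, 600.0: 10, 732.0: 7},
            self._channels(),
        )
        idx = tab.set_index("lambda_em")
        assert idx.loc[600.0, "i_af_norm"] == 0.0
        assert idx.loc[732.0, "i_af_norm"] == 0.0

    def test_normalized_table_invariant_to_uniform_qe_scaling(self):
        cell = {562.0: 50, 600.0: 40, 732.0: 20}
        bg = {562.0: 10, 600.0: 10, 732.0: 10}
        halved = []
        for lam in (562.0, 600.0, 732.0):
            halved.append(
                C.SpectralChannel(
                    lambda_em=lam,
                    band=(lam - 20, lam + 20),
                    qe_curve=np.array([[400.0, 0.4], [800.0, 0.4]]),
                )
            )
        a = C.autofluorescence_spectrum(cell, bg, self._channels())
        b = C.autofluorescence_spectrum(cell, bg, halved)
        np.testing.assert_allclose(a["i_af_norm"], b["i_af_norm"])
        np.testing.assert_allclose(b["i_af_raw"], 2 * a["i_af_raw"])

    def test_missing_reference_rejected(self):
        chans = self._channels()[1:]
        with pytest.raises(ValueError, match="reference"):
            C.autofluorescence_spectrum({600.0: 1, 732.0: 1}, {600.0: 0, 732.0: 0}, chans)

    def test_spot_intensity_scaling(self):
        frame = np.full((9, 9), 2.0)
        assert C.autofluorescence_spot_intensity(frame, (4, 4), 18.0, 1.0) == pytest.approx(0.0)
        v1 = C.autofluorescence_spot_intensity(frame, (4, 4), 9.0, 1.0)
        v2 = C.autofluorescence_spot_intensity(frame, (4, 4), 9.0, 0.5)
        assert v2 == pytest.approx(2 * v1)

    def test_diffuse_field_expectation(self):
        rng = np.random.default_rng(0)
        field_mean = 6.0
        frame = rng.poisson(field_mean, (200, 200)).astype(float)
        vals = [
            C.autofluorescence_spot_intensity(frame, (x, y), 0.0, 0.8)
            for x in range(5, 195, 10)
            for y in range(5, 195, 10)
        ]
        assert np.mean(vals) == pytest.approx(9 * field_mean / 0.8, rel=0.02)


def brute_force_auroc(signal, background):
    wins = 0.0
    for s in signal:
        for b in background:
            wins += 1.0 if s > b else (0.5 if s == b else 0.0)
    return wins / (len(signal) * len(background))


class TestAuroc:
    def test_perfect_separation(self):
        assert C.detection_auroc([10, 11, 12], [1, 2, 3]) == 1.0

    def test_null_case(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(0, 1, 2000)
        assert C.detection_auroc(a, b) == pytest.approx(0.5, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            C.detection_auroc([], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        sig=st.lists(st.integers(0, 20), min_size=1, max_size=30),
        bg=st.lists(st.integers(0, 20), min_size=1, max_size=30),
    )
    def test_matches_pairwise_comparison_oracle(self, sig, bg):
        assert C.detection_auroc(sig, bg) == pytest.approx(
            brute_force_auroc(sig, bg), abs=1e-12
        )

    def test_high_contrast_normal_model(self):
        """40-fold intensity contrast at sd = mean/3: near-perfect detection."""
        rng = np.random.default_rng(2)
        m = 30.0
        sig = rng.normal(40 * m, m / 3, 5000)
        bg = rng.normal(m, m / 3, 5000)
        assert C.detection_auroc(sig, bg) >= 0.99
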