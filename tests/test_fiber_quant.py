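"""ROI intensity measurement and ratiometric microtubule counting."""

import numpy as np
import pytest

from spindlequant.core import ImageStack, InvalidParameterError, OpticsParams, OutOfBoundsError
from spindlequant import fiber_quant as fq
from spindlequant.experiments import fiber_recovery_experiment
from spindlequant.synthetic_spindle import FiberClass, FiberSpec, SpindleModel, render


def make_stack(plane, optics=None):
    data = np.zeros((3, 1) + plane.shape, dtype=float)
    data[0, 0] = plane
    return ImageStack(data=data, optics=optics or OpticsParams())


class TestSquareRoi:
    def test_constant_plane_returns_constant(self):
        st = make_stack(np.full((30, 30), 7.0))
        assert fq.measure_square_roi(st, "tubulin", (0, 15, 15), 5) == 7.0
        assert fq.measure_square_roi(st, "tubulin", (0, 15, 15), 25) == 7.0

    def test_checkerboard_mean_matches_hand_count(self):
        plane = np.indices((20, 20)).sum(axis=0) % 2.0  # checkerboard of 0/1
        block = plane[3:8, 4:9]
        assert block.sum() == 13  # 5x5 checkerboard starting on a one
        st = make_stack(plane)
        assert fq.measure_square_roi(st, "tubulin", (0, 5, 6), 5) == pytest.approx(13 / 25)

    def test_matches_pixel_loop_oracle_on_rendered_fiber(self, sted):
        fiber = FiberSpec(FiberClass.K_FIBER, 12.6,
                          np.array([[-1.5, 0.0, 0.0], [1.5, 0.0, 0.0]]))
        m = SpindleModel(np.array([[-1.5, 0, 0], [1.5, 0, 0]]), [], [fiber])
        st = render(m, sted, shape=(5, 80, 170), seed=0, noise=False,
                    origin=(-85 * 0.02, -40 * 0.02, -2 * sted.z_sample_step))
        got = fq.measure_square_roi(st, "tubulin", (2, 40, 85), 25)
        plane = st.channel("tubulin")[2]
        acc = 0.0
        for r in range(40 - 12, 40 + 13):
            for c in range(85 - 12, 85 + 13):
                acc += plane[r, c]
        assert got == pytest.approx(acc / 625, rel=1e-12)

    def test_roi_crossing_border_rejected(self):
        st = make_stack(np.zeros((10, 10)))
        with pytest.raises(OutOfBoundsError):
            fq.measure_square_roi(st, "tubulin", (0, 1, 5), 5)


class TestBackground:
    def test_uniform_background_recovered(self):
        st = make_stack(np.full((60, 60), 11.5))
        pts = [(0, r, c) for r, c in zip(range(5, 55, 5), range(5, 55, 5))]
        assert fq.background_square(st, "tubulin", pts, 5) == pytest.approx(11.5)

    def test_mean_of_two_rois(self):
        plane = np.zeros((40, 40))
        plane[:20] = 10.0
        plane[20:] = 14.0
        st = make_stack(plane)
        got = fq.background_square(st, "tubulin", [(0, 10, 10), (0, 30, 30)], 5)
        assert got == pytest.approx(12.0)

    def test_strict_mode_enforces_modality_count(self):
        st = make_stack(np.zeros((40, 40)))
        pts = [(0, 10, 10), (0, 20, 20), (0, 30, 30)]
        with pytest.raises(InvalidParameterError):
            fq.background_square(st, "tubulin", pts, 5, modality="sted", strict=True)
        with pytest.raises(InvalidParameterError):
            fq.background_square(st, "tubulin", [], 5)


class TestCorrectionAndEstimation:
    def test_background_subtraction(self):
        assert fq.corrected_fiber_intensity(50.0, 20.0) == 30.0
        assert fq.corrected_fiber_intensity([90.0, 110.0], 20.0) == 80.0
        assert fq.corrected_fiber_intensity(20.0, 20.0) == 0.0

    @pytest.mark.parametrize("I_x,I_k,expected", [
        (30.0, 100.0, 3.78),
        (100.0, 100.0, 12.6),
        (0.0, 50.0, 0.0),
    ])
    def test_mt_number_formula(self, I_x, I_k, expected):
        assert fq.estimate_mt_number(I_x, I_k) == pytest.approx(expected)

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(InvalidParameterError):
            fq.estimate_mt_number(10.0, 0.0)

    def test_scale_invariance_of_count_estimates(self, rng):
        for _ in range(25):
            raw_b, raw_k1, raw_k2, bcg = rng.uniform(10, 200, 4)
            gamma = rng.uniform(0.1, 10)
            I_k = fq.corrected_fiber_intensity([raw_k1, raw_k2], bcg)
            if I_k <= 0:
                continue
            I_b = fq.corrected_fiber_intensity(raw_b, bcg)
            n1 = fq.estimate_mt_number(I_b, I_k)
            I_k_g = fq.corrected_fiber_intensity(
                [gamma * raw_k1, gamma * raw_k2], gamma * bcg)
            n2 = fq.estimate_mt_number(gamma * I_b, I_k_g)
            assert n2 == pytest.approx(n1, rel=1e-9)

    def test_detection_is_strictly_above_floor(self):
        assert not fq.detect_bridging(-3.0)
        assert not fq.detect_bridging(0.0)
        assert fq.detect_bridging(1e-9)
        assert not fq.detect_bridging(1.0, sigma_bcg=1.0, z_threshold=2.0)
        assert fq.detect_bridging(2.5, sigma_bcg=1.0, z_threshold=2.0)


class TestLineProfile:
    def build_stack(self, values, px=0.083):
        """A stack whose intensity varies only along x by `values` (per µm)."""
        optics = OpticsParams(pixel_size_xy=px)
        n = len(values)
        plane = np.tile(np.asarray(values, float), (21, 1))
        data = np.zeros((3, 3, 21, n))
        data[0] = plane
        return ImageStack(data=data, optics=optics, origin=(0.0, 0.0, 0.0))

    def test_plateau_with_central_dip(self):
        px = 0.083
        n = 60
        xs = np.arange(n) * px
        vals = np.full(n, 100.0)
        center = xs[n // 2]
        vals[np.abs(xs - center) <= 0.3] = 40.0
        st = self.build_stack(vals, px)
        contour = [(0.1, 0.9), (xs[-2], 0.9)]
        midzone = [(0.1, 1.3), (xs[-2], 1.3)]
        pm = fq.line_profile_method(st, "tubulin", contour, 1, midzone,
                                    window_halfwidth=0.2, flank_offset=1.5)
        assert pm.midzone_min == pytest.approx(40.0)
        assert pm.I_b == pytest.approx(0.0, abs=1.0)  # dip minus background
        assert pm.I_bk == pytest.approx(60.0, abs=1.0)
        assert pm.I_k == pytest.approx(pm.I_bk - pm.I_b)
        # bridge_center is arclength from the contour start at x = 0.1
        assert abs((pm.bridge_center + 0.1) - center) < 0.1

    def test_flat_profile_degenerate(self):
        st = self.build_stack(np.full(60, 80.0))
        contour = [(0.1, 0.9), (4.8, 0.9)]
        pm = fq.line_profile_method(st, "tubulin", contour, 1, contour)
        assert pm.degenerate_center
        assert pm.I_k == pytest.approx(0.0, abs=1e-6)

    def test_window_means_match_quadrature_oracle(self):
        # analytic profile f(x) = 100 - 60 exp(-x^2/0.18) around the centre;
        # grid-aligned sampling so the window is a midpoint rule over ±(w+h/2)
        px = 0.005
        n = 1600
        xs = (np.arange(n) - n / 2) * px
        vals = 100.0 - 60.0 * np.exp(-(xs**2) / 0.18)
        st = self.build_stack(vals, px)
        contour = [(0.05, 0.2), (0.05 + (n - 21) * px, 0.2)]
        w = 0.2501
        pm = fq.line_profile_method(st, "tubulin", contour, 1, contour,
                                    window_halfwidth=w, flank_offset=1.5)
        from scipy.integrate import quad
        f = lambda x: 100.0 - 60.0 * np.exp(-(x**2) / 0.18)
        bg = min(vals)
        a = 0.25 + px / 2
        I_b_oracle = quad(f, -a, a)[0] / (2 * a) - bg
        flank = 0.5 * sum(
            quad(f, s - a, s + a)[0] / (2 * a) for s in (-1.5, 1.5)
        ) - bg
        assert pm.I_b == pytest.approx(I_b_oracle, rel=0.01)
        assert pm.I_bk == pytest.approx(flank, rel=0.01)

    def test_short_contour_rejected(self):
        st = self.build_stack(np.full(20, 10.0))
        contour = [(0.1, 0.5), (1.0, 0.5)]
        with pytest.raises(InvalidParameterError):
            fq.line_profile_method(st, "tubulin", contour, 1, contour)


class TestDepletionSummary:
    def test_printed_bookkeeping_reproduced(self):
        out = fq.depletion_summary([3.8], [12.6], [1.2], [9.6])
        assert round(out["percent_reduction_bridging"]) == 68
        assert round(out["percent_reduction_k"]) == 24
        assert out["n_b_augmin"] == pytest.approx(2.6)
        assert out["n_k_augmin"] == pytest.approx(3.0)

    def test_remaining_from_printed_reductions(self):
        assert fq.remaining_from_reduction(3.8, 68.0) == pytest.approx(1.2, abs=0.05)
        assert fq.remaining_from_reduction(12.6, 24.0) == pytest.approx(9.6, abs=0.05)

    def test_identical_lists_give_zero_reduction(self):
        vals = [3.5, 4.0, 3.9]
        out = fq.depletion_summary(vals, [12.0, 13.0], vals, [12.0, 13.0])
        assert out["percent_reduction_bridging"] == pytest.approx(0.0)
        assert out["percent_reduction_k"] == pytest.approx(0.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            fq.depletion_summary([0.0], [12.6], [1.0], [9.6])


class TestRecoveryOnPhantoms:
    def test_noiseless_recovery_within_5_percent(self):
        df = fiber_recovery_experiment(noise=False)
        for _, row in df.iterrows():
            assert row["estimated_mt"] == pytest.approx(row["planted_mt"], rel=0.05)

    def test_square_roi_and_line_profile_agree_on_straight_fibers(self, confocal):
        # one bright lane: both schemes should report the same I_b within 10%
        half = 2.6
        fibers = [
            FiberSpec(FiberClass.K_FIBER, 12.6, np.array([[-half, -1.2, 0], [half, -1.2, 0]])),
            FiberSpec(FiberClass.BRIDGING, 3.8, np.array([[-half, 1.2, 0], [half, 1.2, 0]])),
        ]
        m = SpindleModel(np.array([[-half, 0, 0], [half, 0, 0]]), [], fibers)
        nz, ny, nx = 7, 64, 70
        origin = (-nx / 2 * 0.083, -ny / 2 * 0.083, -(nz // 2) * confocal.z_sample_step)
        st = render(m, confocal, shape=(nz, ny, nx), seed=0, noise=False, origin=origin)
        zc = nz // 2
        b_row = int(round((1.2 - origin[1]) / 0.083))
        bcg = fq.background_square(st, "tubulin", [(zc, ny // 2, nx // 2)], 5)
        I_b_roi = fq.measure_square_roi(st, "tubulin", (zc, b_row, nx // 2), 5) - bcg

        # profile across the bridging lane (transverse), background from an
        # empty lane; compare the window mean at the lane centre
        contour = [(-2.0, 1.2), (2.0, 1.2)]
        midzone = [(-2.0, 0.0), (2.0, 0.0)]
        pm = fq.line_profile_method(st, "tubulin", contour, zc, midzone,
                                    line_width_px=5, flank_offset=1.9)
        profile_peak = pm.contour_profile.max() + pm.midzone_min - bcg
        assert profile_peak == pytest.approx(I_b_roi, rel=0.10)
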