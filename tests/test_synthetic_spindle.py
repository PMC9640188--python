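"""Generator tests: seeded determinism, planted truth, forward-model physics."""

import numpy as np
import pandas as pd
import pytest

from spindlequant.core import InvalidParameterError, OpticsParams
from spindlequant.synthetic_spindle import (
    AnaphaseKinetics,
    FiberClass,
    FiberSpec,
    KinetochorePair,
    SpindleModel,
    apply_depletion,
    ground_truth_table,
    make_anaphase_timelapse,
    make_photoactivation_series,
    make_spindle_model,
    render,
)


class TestMakeSpindleModel:
    def test_zero_tilt_spread_gives_axis_parallel_pair(self):
        m = make_spindle_model(n_pairs=1, tilt_spread_deg=0.0, seed=3)
        assert m.kinetochore_pairs[0].tilt_deg == pytest.approx(0.0)
        s = m.kinetochore_pairs[0].sister2 - m.kinetochore_pairs[0].sister1
        axis = m.pole_positions[1] - m.pole_positions[0]
        cosang = abs(s @ axis) / (np.linalg.norm(s) * np.linalg.norm(axis))
        assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_default_mt_counts_planted_in_truth_table(self):
        m = make_spindle_model(n_pairs=3, seed=0)
        truth = ground_truth_table(m)
        fibers = truth[truth["object"] == "fiber"]
        counts = {
            cls: set(fibers.loc[fibers["fiber_class"] == cls, "mt_count"])
            for cls in ("k_fiber", "bridging", "astral")
        }
        assert counts["k_fiber"] == {12.6}
        assert counts["bridging"] == {3.8}
        assert counts["astral"] == {1.0}

    def test_same_seed_identical_model(self):
        m1 = make_spindle_model(n_pairs=5, seed=42)
        m2 = make_spindle_model(n_pairs=5, seed=42)
        np.testing.assert_array_equal(m1.pole_positions, m2.pole_positions)
        for p1, p2 in zip(m1.kinetochore_pairs, m2.kinetochore_pairs):
            np.testing.assert_array_equal(p1.sister1, p2.sister1)
            np.testing.assert_array_equal(p1.sister2, p2.sister2)
        assert not np.allclose(
            make_spindle_model(n_pairs=5, seed=43).kinetochore_pairs[0].sister1,
            m1.kinetochore_pairs[0].sister1,
        )

    def test_bridging_fraction_controls_bridge_count(self):
        m = make_spindle_model(n_pairs=10, bridging_fraction=0.5, seed=0)
        assert len(m.bridging_pair_ids()) == 5

    @pytest.mark.parametrize("kwargs", [
        dict(n_pairs=0), dict(spindle_length=-1.0),
        dict(bridging_fraction=1.5), dict(spindle_length=0.5, mean_separation=0.98),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            make_spindle_model(**kwargs)


class TestApplyDepletion:
    def test_identity_when_all_retained(self, small_model):
        out = apply_depletion(small_model, retained={}, bridging_removal_fraction=0.0)
        assert len(out.fibers) == len(small_model.fibers)
        for f_in, f_out in zip(small_model.fibers, out.fibers):
            assert f_out.mt_count == f_in.mt_count

    def test_default_preset_scales_bridging_to_1_2(self, small_model):
        out = apply_depletion(small_model, bridging_removal_fraction=0.0)
        bridging = [f for f in out.fibers if f.fiber_class is FiberClass.BRIDGING]
        assert all(f.mt_count == pytest.approx(1.2) for f in bridging)
        kf = [f for f in out.fibers if f.fiber_class is FiberClass.K_FIBER]
        assert all(f.mt_count == pytest.approx(9.6) for f in kf)

    def test_removal_fraction_flags_exact_count(self):
        m = make_spindle_model(n_pairs=100, bridging_fraction=1.0, seed=7)
        out = apply_depletion(m, retained={}, bridging_removal_fraction=0.41, seed=5)
        truth = ground_truth_table(out)
        pairs = truth[truth["object"] == "pair"]
        assert int((~pairs["bridging_present"].astype(bool)).sum()) == 41


class TestRender:
    def test_empty_model_noiseless_is_flat_background(self, confocal):
        m = SpindleModel(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), [], [])
        st = render(m, confocal, shape=(4, 16, 16), seed=0, noise=False,
                    origin=(-0.6, -0.6, -0.6))
        assert np.allclose(st.data, confocal.background_level)

    def test_roi_intensity_ratio_tracks_mt_ratio(self, confocal):
        half = 1.4
        fibers = [
            FiberSpec(FiberClass.K_FIBER, 12.6, np.array([[-half, -0.8, 0], [half, -0.8, 0]])),
            FiberSpec(FiberClass.BRIDGING, 3.8, np.array([[-half, 0.8, 0], [half, 0.8, 0]])),
        ]
        m = SpindleModel(np.array([[-half, 0, 0], [half, 0, 0]]), [], fibers)
        nz, ny, nx = 9, 40, 40
        origin = (-nx / 2 * 0.083, -ny / 2 * 0.083, -(nz // 2) * confocal.z_sample_step)
        st = render(m, confocal, shape=(nz, ny, nx), seed=0, noise=False, origin=origin)
        plane = st.channel("tubulin")[nz // 2]

        def roi_mean(y_um):
            row = int(round((y_um - origin[1]) / 0.083))
            col = nx // 2
            return plane[row - 2 : row + 3, col - 2 : col + 3].mean()

        ratio = (roi_mean(0.8) - confocal.background_level) / (
            roi_mean(-0.8) - confocal.background_level
        )
        assert ratio == pytest.approx(3.8 / 12.6, rel=0.02)

    def test_axial_placement_follows_081_compression(self, confocal):
        # two puncta 2.0 µm apart in true z -> 2.0/(0.81*0.5) ≈ 4.94 planes
        pair = KinetochorePair(0, np.array([0.0, 0, -1.0]), np.array([0.0, 0, 1.0]),
                               90.0, 2.0)
        m = SpindleModel(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), [pair], [])
        st = render(m, confocal, shape=(17, 24, 24), seed=0, noise=False,
                    origin=(-1.0, -1.0, -8 * confocal.z_sample_step))
        vol = st.channel("kinetochore") - confocal.background_level
        upper = vol[:, :, :].sum(axis=(1, 2))
        planes = np.arange(len(upper))
        # split at the midplane and take each blob's centroid
        mid = len(upper) // 2
        c_low = (upper[:mid] * planes[:mid]).sum() / upper[:mid].sum()
        c_high = (upper[mid:] * planes[mid:]).sum() / upper[mid:].sum()
        assert c_high - c_low == pytest.approx(2.0 / (0.81 * 0.5), abs=0.15)

    def test_seeded_noise_reproducible(self, confocal):
        m = SpindleModel(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), [], [])
        kw = dict(shape=(4, 16, 16), origin=(-0.6, -0.6, -0.6))
        a = render(m, confocal, seed=9, **kw)
        b = render(m, confocal, seed=9, **kw)
        c = render(m, confocal, seed=10, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestAnaphaseTimelapse:
    def kinetics(self):
        return AnaphaseKinetics(anaphase_A_speed=1.0, anaphase_B_speed=0.8,
                                onset_frame=4)

    def test_planted_labels_read_back_exactly(self):
        m = make_spindle_model(n_pairs=40, seed=1)
        spec = [(0, "lagging", True), (1, "lagging", False), (2, "lagging", True),
                (3, "misaligned", True), (4, "misaligned", False)]
        _, truth = make_anaphase_timelapse(m, spec, self.kinetics(), seed=0)
        lab = truth.set_index("pair_id")["error_class"]
        assert list(lab.loc[[0, 1, 2]]) == ["lagging"] * 3
        assert list(lab.loc[[3, 4]]) == ["misaligned"] * 2
        assert (lab.drop([0, 1, 2, 3, 4]) == "none").all()

    def test_noiseless_anaphase_A_slope_is_exact(self):
        m = make_spindle_model(n_pairs=2, tilt_spread_deg=0.0, seed=2)
        traj, _ = make_anaphase_timelapse(
            m, None, self.kinetics(), n_frames=12, dt=30.0, seed=0,
            position_noise=0.0)
        poles = traj[traj["track_id"] == "pole_A"].sort_values("frame")
        s = traj[(traj["track_id"] == 0) & (traj["sister"] == 1)].sort_values("frame")
        d = np.linalg.norm(
            s[["x", "y", "z"]].to_numpy() - poles[["x", "y", "z"]].to_numpy(), axis=1)
        post = d[5:11]  # strictly inside the linear anaphase A regime
        slopes = np.diff(post) / 0.5  # µm per min at 30 s cadence
        assert np.allclose(slopes, -1.0, atol=1e-9)

    def test_interkc_distance_nondecreasing_after_onset(self):
        m = make_spindle_model(n_pairs=8, seed=3)
        traj, _ = make_anaphase_timelapse(m, None, self.kinetics(), seed=4)
        for pid in range(8):
            sub = traj[traj["track_id"] == pid]
            s1 = sub[sub["sister"] == 1].sort_values("frame")[["x", "y", "z"]].to_numpy()
            s2 = sub[sub["sister"] == 2].sort_values("frame")[["x", "y", "z"]].to_numpy()
            sep = np.linalg.norm(s1 - s2, axis=1)
            assert np.all(np.diff(sep[4:]) > -0.1)

    def test_rejects_bad_dt(self):
        m = make_spindle_model(n_pairs=1, seed=0)
        with pytest.raises(InvalidParameterError):
            make_anaphase_timelapse(m, None, self.kinetics(), dt=0.0)


class TestPhotoactivation:
    def test_zero_flux_keeps_mark_pole_distance_constant(self, confocal):
        _, truth = make_photoactivation_series(flux_speed=0.0, n_frames=5,
                                               optics=confocal, noise=False)
        assert truth["mark_pole_distance"].nunique() == 1

    def test_mark_displaces_one_sixth_um_per_10s_frame(self, confocal):
        _, truth = make_photoactivation_series(flux_speed=1.0, dt=10.0,
                                               n_frames=6, optics=confocal,
                                               noise=False)
        steps = -np.diff(truth["mark_x"])
        assert np.allclose(steps, 1.0 / 6.0)

    def test_same_seed_identical_noisy_series(self, confocal):
        a, _ = make_photoactivation_series(seed=5, optics=confocal, n_frames=3)
        b, _ = make_photoactivation_series(seed=5, optics=confocal, n_frames=3)
        np.testing.assert_array_equal(a.data, b.data)
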