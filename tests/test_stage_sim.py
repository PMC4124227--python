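import numpy as np
import pytest

from markalign.align_control import detect_mark, DetectionParams
from markalign.errors import ParameterError
from markalign.stage_sim import (
    DeviceGeometry,
    NoiseModel,
    apply_drift,
    capture_view,
    make_stage,
    move_stage,
    serpentine_path,
)

QUIET = NoiseModel(sigma_move_um=0.0, sigma_rel=0.0, pitch_bias=0.0, drift_um=(0.0, 0.0))


class TestMoveStage:
    def test_noiseless_move(self):
        stage = make_stage(QUIET, seed=0)
        stage = move_stage(stage, (100.0, 0.0))
        assert np.allclose(stage.true_um, [100.0, 0.0])
        assert np.allclose(stage.believed_um, [100.0, 0.0])

    def test_bias_contract(self):
        stage = make_stage(NoiseModel(0.0, 0.0, 0.01, (0, 0)), seed=0)
        stage = move_stage(stage, (1000.0, 0.0))
        assert np.allclose(stage.true_um, [1010.0, 0.0])
        assert np.allclose(stage.believed_um, [1000.0, 0.0])

    def test_rms_of_flat_noise_model(self):
        # flat sigma = 6.6 um per axis: 2-D per-move discrepancy RMS = sigma*sqrt(2)
        sigma = 6.6
        stage = make_stage(NoiseModel(sigma, 0.0, 0.0, (0, 0)), seed=42)
        sq = []
        for _ in range(1000):
            before = stage.true_um.copy()
            stage = move_stage(stage, (500.0, 0.0))
            delta = stage.true_um - before - np.array([500.0, 0.0])
            sq.append(delta @ delta)
        rms = np.sqrt(np.mean(sq))
        assert rms == pytest.approx(sigma * np.sqrt(2), rel=0.10)

    def test_distance_proportional_noise_scales(self):
        noise = NoiseModel(0.0, 0.01, 0.0, (0, 0))
        spreads = []
        for dist in (100.0, 1000.0):
            stage = make_stage(noise, seed=7)
            deltas = []
            for _ in range(300):
                before = stage.true_um.copy()
                stage = move_stage(stage, (dist, 0.0))
                deltas.append(stage.true_um - before - [dist, 0.0])
            spreads.append(np.std(np.asarray(deltas)[:, 0]))
        assert spreads[1] / spreads[0] == pytest.approx(10.0, rel=0.25)

    def test_rejects_bad_displacement(self):
        stage = make_stage(QUIET, seed=0)
        with pytest.raises(ParameterError):
            move_stage(stage, (np.nan, 0.0))
        with pytest.raises(ParameterError):
            move_stage(stage, (1.0, 2.0, 3.0))

    def test_believed_diverges_only_through_noise(self):
        stage = make_stage(QUIET, seed=0)
        for d in [(100, 0), (0, -50), (-30, 30)]:
            stage = move_stage(stage, np.asarray(d, dtype=float))
        assert np.allclose(stage.true_um, stage.believed_um)

    def test_drift_accumulates_on_true_only(self):
        stage = make_stage(NoiseModel(0, 0, 0, (5.0, -3.0)), seed=0)
        stage = apply_drift(stage, steps=2)
        assert np.allclose(stage.true_um, [10.0, -6.0])
        assert np.allclose(stage.believed_um, [0.0, 0.0])


class TestSerpentinePath:
    def test_two_by_two(self):
        geom = DeviceGeometry(rows=2, cols=2)
        assert serpentine_path(geom, 0) == [(0, 0), (0, 1), (1, 1), (1, 0)]

    def test_even_scan_is_reverse(self):
        geom = DeviceGeometry(rows=2, cols=2)
        assert serpentine_path(geom, 1) == list(reversed(serpentine_path(geom, 0)))

    def test_full_grid_adjacency(self):
        geom = DeviceGeometry()
        path = serpentine_path(geom, 0)
        assert len(path) == 32
        assert len(set(path)) == 32
        for (r0, c0), (r1, c1) in zip(path, path[1:]):
            assert abs(r0 - r1) + abs(c0 - c1) == 1

    def test_consecutive_scans_join(self):
        geom = DeviceGeometry()
        assert serpentine_path(geom, 0)[-1] == serpentine_path(geom, 1)[0]


class TestCaptureView:
    def test_mark_appears_at_true_offset(self):
        geom = DeviceGeometry()
        stage = make_stage(QUIET, seed=0)
        offset_px = np.array([12.0, -9.0])
        stage.true_um += offset_px * geom.pixel_width_um
        img, truth = capture_view(stage, geom, (0, 0), frame_px=200, noise_sigma=0.0)
        center = (200 - 1) / 2
        assert truth.x_ref == pytest.approx(center + 12.0)
        assert truth.y_ref == pytest.approx(center - 9.0)
        pose = detect_mark(img, DetectionParams.for_geometry(geom))
        assert np.hypot(pose.x_ref - truth.x_ref, pose.y_ref - truth.y_ref) < 1.0

    def test_out_of_grid_chamber(self):
        geom = DeviceGeometry()
        stage = make_stage(QUIET, seed=0)
        with pytest.raises(ParameterError):
            capture_view(stage, geom, (4, 0))

    def test_seeded_reproducibility(self):
        geom = DeviceGeometry()
        imgs = []
        for _ in range(2):
            stage = make_stage(NoiseModel(), seed=99)
            stage = move_stage(stage, (50.0, 20.0))
            stage.true_um -= [50.0, 20.0]  # come back near the mark
            img, _ = capture_view(stage, geom, (0, 0), frame_px=160, noise_sigma=5.0)
            imgs.append(img)
        assert np.array_equal(imgs[0], imgs[1])


class TestDriftPhenomenology:
    def test_unaligned_error_grows_with_scans(self):
        # expected final-chamber error is non-decreasing in scan count
        from markalign.stage_sim import mark_offset_px

        geom = DeviceGeometry(rows=2, cols=2)
        finals = np.zeros(4)
        reps = 8
        for rep in range(reps):
            stage = make_stage(NoiseModel(sigma_move_um=2.0, drift_um=(8.0, 8.0)),
                               seed=rep)
            errs = []
            for scan in range(4):
                stage = apply_drift(stage)
                prev = serpentine_path(geom, scan)[0]
                for chamber in serpentine_path(geom, scan):
                    d = np.array([
                        (chamber[1] - prev[1]) * geom.pitch_x_um,
                        (chamber[0] - prev[0]) * geom.pitch_y_um,
                    ])
                    if d.any():
                        stage = move_stage(stage, d)
                    prev = chamber
                errs.append(np.hypot(*mark_offset_px(stage, geom, prev)))
            finals += np.asarray(errs)
        finals /= reps
        assert all(finals[i] <= finals[i + 1] for i in range(3))

    def test_zero_noise_zero_error_forever(self):
        from markalign.stage_sim import mark_offset_px

        geom = DeviceGeometry(rows=2, cols=2)
        stage = make_stage(QUIET, seed=0)
        for scan in range(3):
            prev = serpentine_path(geom, scan)[0]
            for chamber in serpentine_path(geom, scan):
                d = np.array([
                    (chamber[1] - prev[1]) * geom.pitch_x_um,
                    (chamber[0] - prev[0]) * geom.pitch_y_um,
                ])
                if d.any():
                    stage = move_stage(stage, d)
                prev = chamber
                assert np.hypot(*mark_offset_px(stage, geom, chamber)) < 1e-9
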