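"""Pipeline orchestration: estimators, reference modes, channels, batch,
streaming."""

import numpy as np
import pytest
from sklearn.base import clone

from driftcorr import io as dio
from driftcorr import synthetic as syn
from driftcorr.io import DriftTable, RegistrationSettings, VideoStack
from driftcorr.registration import (
    ChannelAligner,
    DriftCorrector,
    batch_register,
    estimate_axial,
    estimate_lateral,
    register_channels,
    register_file,
    register_second_channel,
    register_video,
)
from driftcorr.xcorr import ZeroVarianceError


@pytest.fixture(scope="module")
def lateral_video(small_volume):
    volume, _ = small_volume
    traj = np.zeros((8, 3))
    traj[:, 0] = np.arange(8)  # dx = +1 px / frame
    traj[:, 1] = -(np.arange(8) // 2)
    video, truth = syn.generate_drifting_video(
        volume, 8, syn.DriftSpec(kind="explicit", explicit=traj)
    )
    return video, truth


class TestEstimateLateral:
    def test_zero_drift_gives_near_zero_table(self, small_volume):
        volume, _ = small_volume
        video, _ = syn.generate_drifting_video(volume, 5, syn.DriftSpec())
        table = estimate_lateral(video, RegistrationSettings(upscale_factor=10))
        assert np.max(np.abs(table.dx)) <= 0.1
        assert np.max(np.abs(table.dy)) <= 0.1
        assert np.all(table.dz == 0)

    def test_exact_integer_recovery(self, lateral_video):
        video, truth = lateral_video
        table = estimate_lateral(video, RegistrationSettings(upscale_factor=1))
        np.testing.assert_array_equal(table.dx, truth.dx)
        np.testing.assert_array_equal(table.dy, truth.dy)

    def test_reference_modes_agree_on_static_content(self, lateral_video):
        video, truth = lateral_video
        first = estimate_lateral(
            video, RegistrationSettings(reference_mode="first_frame", upscale_factor=1)
        )
        prev = estimate_lateral(
            video, RegistrationSettings(reference_mode="previous_frame", upscale_factor=1)
        )
        np.testing.assert_allclose(first.dx, prev.dx, atol=1e-9)
        np.testing.assert_allclose(first.dy, prev.dy, atol=1e-9)

    def test_constant_frame_error_names_stage(self, small_volume):
        volume, _ = small_volume
        video, _ = syn.generate_drifting_video(volume, 4, syn.DriftSpec())
        data = video.data.copy().astype(float)
        data[2] = 5.0  # one constant time point
        with pytest.raises(ZeroVarianceError, match="lateral"):
            estimate_lateral(VideoStack(data), RegistrationSettings())


class TestEstimateAxial:
    def test_integer_z_drift_recovered_exactly(self, small_volume):
        volume, _ = small_volume
        traj = np.zeros((5, 3))
        traj[:, 2] = np.arange(5)  # dz = +1 slice / frame
        video, truth = syn.generate_drifting_video(
            volume, 5, syn.DriftSpec(kind="explicit", explicit=traj)
        )
        table = estimate_axial(video, RegistrationSettings(upscale_factor=1))
        np.testing.assert_array_equal(table.dz, truth.dz)
        assert np.all(table.dx == 0) and np.all(table.dy == 0)

    def test_x_component_never_reaches_the_table(self, small_volume):
        # pure x drift: the axial stage sees it in its columns and must
        # discard it
        volume, _ = small_volume
        traj = np.zeros((5, 3))
        traj[:, 0] = 2 * np.arange(5)
        video, _ = syn.generate_drifting_video(
            volume, 5, syn.DriftSpec(kind="explicit", explicit=traj)
        )
        table = estimate_axial(video, RegistrationSettings(upscale_factor=1))
        np.testing.assert_array_equal(table.dz, np.zeros(5))


class TestRegisterVideo:
    def test_full_pipeline_recovers_integer_drift(self, integer_drift_video):
        video, truth = integer_drift_video
        result = register_video(video, RegistrationSettings(upscale_factor=1))
        assert result.table == truth
        assert len(result.diagnostics) == 2 * (video.n_frames - 1)

    def test_corrected_video_is_static_on_crop(self, integer_drift_video):
        video, truth = integer_drift_video
        result = register_video(
            video, RegistrationSettings(upscale_factor=1, edge_mode="crop")
        )
        for t in range(1, result.corrected.n_frames):
            np.testing.assert_array_equal(
                result.corrected.data[t], result.corrected.data[0]
            )

    def test_axial_only_leaves_lateral_zero(self, integer_drift_video):
        video, _ = integer_drift_video
        result = register_video(
            video,
            RegistrationSettings(upscale_factor=1, axes_corrected=("axial",)),
        )
        assert np.all(result.table.dx == 0)
        assert np.all(result.table.dy == 0)

    def test_determinism(self, integer_drift_video):
        video, _ = integer_drift_video
        s = RegistrationSettings(upscale_factor=2)
        t1 = register_video(video, s).table
        t2 = register_video(video, s).table
        assert t1 == t2


class TestDriftCorrectorEstimatorAPI:
    def test_get_set_params_and_clone(self):
        est = DriftCorrector(projection_method="average", upscale_factor=4)
        assert est.get_params()["projection_method"] == "average"
        est2 = clone(est).set_params(upscale_factor=2)
        assert est2.get_params()["upscale_factor"] == 2
        assert est.upscale_factor == 4

    def test_fitted_attributes_and_transform(self, integer_drift_video):
        video, truth = integer_drift_video
        est = DriftCorrector(upscale_factor=1)
        with pytest.raises(RuntimeError, match="fitted"):
            est.transform(video)
        est.fit(video)
        assert est.drift_table_ == truth
        assert est.n_frames_ == video.n_frames
        corrected = est.transform(video)
        assert corrected.data.shape == video.data.shape

    def test_invalid_params_rejected_at_fit(self, integer_drift_video):
        video, _ = integer_drift_video
        with pytest.raises(ValueError):
            DriftCorrector(projection_method="median").fit(video)


class TestSecondChannel:
    def test_pure_application_matches_ground_truth(self, tmp_path, small_volume):
        volume, _ = small_volume
        rng = np.random.default_rng(4)
        other = (volume * 0.5).astype(volume.dtype)
        traj = np.zeros((6, 3))
        traj[:, 1] = np.arange(6)
        spec = syn.DriftSpec(kind="explicit", explicit=traj)
        ch1, _ = syn.generate_drifting_video(volume, 6, spec)
        ch2, _ = syn.generate_drifting_video(other, 6, spec)

        result = register_video(ch1, RegistrationSettings(upscale_factor=1))
        table_path = tmp_path / "drift_table.csv"
        dio.write_drift_table(result.table, table_path)
        settings = RegistrationSettings(drift_table_path=str(table_path))

        corrected = register_second_channel(ch2, settings)
        residual = estimate_lateral(corrected, RegistrationSettings(upscale_factor=10))
        assert np.max(np.abs(residual.dx)) <= 0.1
        assert np.max(np.abs(residual.dy)) <= 0.1

    def test_requires_table_path(self, integer_drift_video):
        video, _ = integer_drift_video
        with pytest.raises(ValueError, match="drift_table_path"):
            register_second_channel(video, RegistrationSettings())


class TestChannelAligner:
    def test_integer_offsets_recovered_exactly(self):
        image, offsets = syn.generate_bead_channels(
            offsets=((0, 0, 0), (3.0, -2.0, 1.0), (-1.0, 2.0, -2.0)), seed=5
        )
        aligner = ChannelAligner(upscale_factor=1).fit(image)
        np.testing.assert_array_equal(aligner.channel_shifts_, offsets)
        aligned = aligner.transform(image)
        assert aligned.shape == image.shape

    def test_identical_channels_give_zero_table(self):
        image, _ = syn.generate_bead_channels(offsets=((0, 0, 0),) * 3, seed=6)
        corrected, table = register_channels(image)
        assert np.all(table.dx == 0) and np.all(table.dy == 0) and np.all(table.dz == 0)
        np.testing.assert_array_equal(corrected, image)

    def test_single_channel_rejected(self):
        image, _ = syn.generate_bead_channels(offsets=((0, 0, 0),), seed=7)
        with pytest.raises(ValueError, match="at least 2"):
            ChannelAligner().fit(image)

    def test_nondefault_reference_channel(self):
        image, offsets = syn.generate_bead_channels(
            offsets=((0, 0, 0), (2.0, 1.0, 0.0), (-2.0, -1.0, 1.0)), seed=8
        )
        aligner = ChannelAligner(reference_channel=1, upscale_factor=1).fit(image)
        # shifts are relative to channel 1
        np.testing.assert_array_equal(aligner.channel_shifts_[1], np.zeros(3))
        np.testing.assert_array_equal(
            aligner.channel_shifts_[0], offsets[0] - offsets[1]
        )


class TestBatchAndStreaming:
    def test_identical_files_give_identical_tables(self, tmp_path, integer_drift_video):
        video, _ = integer_drift_video
        p1, p2 = tmp_path / "a.tif", tmp_path / "b.tif"
        dio.save_stack(video, p1)
        dio.save_stack(video, p2)
        results, failures = batch_register(
            [p1, p2], RegistrationSettings(upscale_factor=1), out_root=tmp_path / "out"
        )
        assert not failures
        assert results[str(p1)].table == results[str(p2)].table
        for stem in ("a", "b"):
            out = tmp_path / "out" / stem
            for name in ("corrected.tif", "drift_table.csv", "drift_plot.png", "settings.json"):
                assert (out / name).exists()

    def test_empty_batch_is_noop(self):
        results, failures = batch_register([])
        assert results == {} and failures == {}

    def test_corrupt_file_does_not_stop_batch(self, tmp_path, integer_drift_video):
        video, _ = integer_drift_video
        good1, bad, good2 = tmp_path / "g1.tif", tmp_path / "bad.tif", tmp_path / "g2.tif"
        dio.save_stack(video, good1)
        bad.write_text("not a tiff")
        dio.save_stack(video, good2)
        results, failures = batch_register(
            [good1, bad, good2], RegistrationSettings(upscale_factor=1)
        )
        assert set(results) == {str(good1), str(good2)}
        assert set(failures) == {str(bad)}

    def test_streaming_and_in_memory_tables_bit_identical(self, tmp_path, integer_drift_video):
        video, _ = integer_drift_video
        path = tmp_path / "v.tif"
        dio.save_stack(video, path)
        s = RegistrationSettings(upscale_factor=2)
        in_mem = register_file(path, s, low_memory=False)
        streamed = register_file(path, s, low_memory=True)
        assert in_mem.table == streamed.table
        np.testing.assert_array_equal(in_mem.corrected.data, streamed.corrected.data)
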