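"""Reconstruction: oracle equivalence, inverse-model identity, unit I/O."""

import json
import time

import numpy as np
import pytest
import tifffile

from scopeflow.acquisition import AcquisitionMetadata, save_raw
from scopeflow.filewatch import WatchConfig
from scopeflow.reconstruction import (
    ReconParams,
    process_raw_file,
    read_ome_zarr,
    reconstruct_stack,
    run_reconstruction_unit,
)
from scopeflow.simulator import RawStack, ScanConfig, acquire_stack, make_sample
from tests.conftest import FAST_POLL, random_sample, wait_until


def oracle_reconstruct(stack: RawStack, params: ReconParams) -> np.ndarray:
    """Naive per-focus triple loop; the independent reference the
    vectorized implementation is checked against."""
    s, p = stack.scan.steps_per_axis, stack.scan.foci_pitch_px
    w = params.window_halfwidth_px
    frames = stack.frames.astype(np.float64)
    b = frames.min() if params.background_mode == "global_min" else 0.0
    H, W = stack.frame_shape
    out = np.zeros((H, W))
    for k in range(stack.n_frames):
        ky, kx = divmod(k, s)
        for y in range(ky, H, p):
            for x in range(kx, W, p):
                acc = 0.0
                for dy in range(-w, w + 1):
                    for dx in range(-w, w + 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < H and 0 <= xx < W:
                            acc += frames[k, yy, xx] - b
                out[y, x] = acc
    return out


def _random_stack(seed, s=8, p=None, shape=(24, 24)):
    rng = np.random.default_rng(seed)
    scan = ScanConfig(steps_per_axis=s, foci_pitch_px=p or s, frame_period_ms=1)
    frames = rng.integers(0, 4000, size=(scan.n_frames, *shape)).astype(np.uint16)
    return RawStack(frames=frames, scan=scan)


class TestReconstructStack:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Exact integer agreement with the triple-loop oracle on random
        8×8-step stacks."""
        stack = _random_stack(seed)
        params = ReconParams()
        assert np.array_equal(reconstruct_stack(stack, params),
                              oracle_reconstruct(stack, params))

    @pytest.mark.parametrize("w,background", [(1, "none"), (2, "global_min")])
    def test_windowed_and_background_modes_match_oracle(self, w, background):
        stack = _random_stack(99, s=4, p=8, shape=(20, 20))
        params = ReconParams(window_halfwidth_px=w, background_mode=background)
        assert np.allclose(reconstruct_stack(stack, params),
                           oracle_reconstruct(stack, params))

    def test_constant_sample_reconstructs_uniform(self):
        scan = ScanConfig(steps_per_axis=6, foci_pitch_px=6, frame_period_ms=1)
        sample = make_sample("constant", 64, value=77)
        stack = acquire_stack(sample, (0, 0), scan, fov_px=(30, 30))
        assert np.all(reconstruct_stack(stack) == 77)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inverse_of_forward_model(self, seed):
        """simulate → reconstruct is the identity for noiseless stacks
        with pitch == steps and w = 0, whatever the sample."""
        sample = random_sample(seed, size=64)
        scan = ScanConfig(steps_per_axis=8, foci_pitch_px=8, frame_period_ms=1)
        stack = acquire_stack(sample, (0, 0), scan, fov_px=(32, 32))
        assert np.array_equal(reconstruct_stack(stack), sample.image[:32, :32])

    def test_zero_stack_gives_zero_image(self, small_scan):
        stack = RawStack(frames=np.zeros((64, 16, 16), dtype=np.uint16), scan=small_scan)
        assert not reconstruct_stack(stack).any()

    def test_unlit_pixels_stay_zero_with_sparse_pitch(self):
        stack = _random_stack(5, s=2, p=4, shape=(16, 16))
        r = reconstruct_stack(stack)
        # foci occupy only the s×s corner of each p×p cell
        for y in range(16):
            for x in range(16):
                if y % 4 >= 2 or x % 4 >= 2:
                    assert r[y, x] == 0

    def test_window_overlapping_neighbor_focus_rejected(self):
        stack = _random_stack(1, s=4, p=4)
        with pytest.raises(ValueError, match="overlaps neighboring foci"):
            reconstruct_stack(stack, ReconParams(window_halfwidth_px=2))

    def test_unknown_algorithm_rejected(self, small_stack):
        with pytest.raises(ValueError, match="algorithm_id"):
            reconstruct_stack(small_stack, ReconParams(algorithm_id="mystery"))

    def test_conservation_of_focus_signal(self):
        """With w=0 and no background subtraction, sum(R) equals the sum
        of focus-pixel values over all frames."""
        stack = _random_stack(17)
        r = reconstruct_stack(stack)
        from scopeflow.simulator import focus_mask

        total = sum(
            stack.frames[k][focus_mask(stack.scan, k, stack.frame_shape)].sum()
            for k in range(stack.n_frames)
        )
        assert r.sum() == total

    def test_noise_error_shrinks_with_signal_level(self):
        """Relative reconstruction error under Poisson noise decreases
        monotonically over three increasing signal amplitudes."""
        sample = make_sample("constant", 64, value=50)
        errors = []
        for amplitude in (1.0, 10.0, 100.0):
            scan = ScanConfig(steps_per_axis=4, foci_pitch_px=4, frame_period_ms=1,
                              amplitude=amplitude, noise="poisson")
            stack = acquire_stack(sample, (0, 0), scan, fov_px=(32, 32),
                                  rng=np.random.default_rng(8))
            r = reconstruct_stack(stack) / amplitude
            errors.append(np.abs(r - sample.image[:32, :32]).mean())
        assert errors[0] > errors[1] > errors[2]


@pytest.fixture
def raw_file(tmp_path, small_stack):
    meta = AcquisitionMetadata(
        stage_position_um=(0.0, 0.0, 0.0),
        scan=small_stack.scan,
        detector_shape_px=small_stack.frame_shape,
    )
    return save_raw(small_stack, meta, tmp_path / "data", "zarr", stem="t0")


class TestProcessRawFile:
    def test_outputs_tiff_and_zarr_with_identical_pixels(self, tmp_path, raw_file, small_stack):
        tiff_path, zarr_path = process_raw_file(raw_file, rec_root=tmp_path / "rec")
        assert tiff_path.name == "t0_rec.tiff" and zarr_path.name == "t0_rec.zarr"
        tiff_img = tifffile.imread(tiff_path)
        zarr_img, attrs = read_ome_zarr(zarr_path)
        assert np.array_equal(tiff_img, zarr_img)
        assert np.array_equal(tiff_img, reconstruct_stack(small_stack).astype(np.float32))
        meta = json.loads(attrs)
        assert "acquisition" in meta and "recon" in meta

    def test_hdf5_input_is_format_agnostic(self, tmp_path, small_stack):
        meta = AcquisitionMetadata(scan=small_stack.scan,
                                   detector_shape_px=small_stack.frame_shape)
        h5 = save_raw(small_stack, meta, tmp_path / "data", "hdf5", stem="t0")
        za = save_raw(small_stack, meta, tmp_path / "data", "zarr", stem="t0")
        t1, _ = process_raw_file(h5, rec_root=tmp_path / "rec_a")
        t2, _ = process_raw_file(za, rec_root=tmp_path / "rec_b")
        assert np.array_equal(tifffile.imread(t1), tifffile.imread(t2))

    def test_ngff_multiscales_metadata_present(self, tmp_path, raw_file):
        import zarr as _zarr

        _, zarr_path = process_raw_file(raw_file, rec_root=tmp_path / "rec")
        group = _zarr.open_group(str(zarr_path), mode="r")
        ms = group.attrs["multiscales"]
        assert ms[0]["version"] == "0.4"
        assert [a["name"] for a in ms[0]["axes"]] == ["y", "x"]
        assert ms[0]["datasets"][0]["path"] == "0"

    def test_corrupt_input_leaves_no_partial_outputs(self, tmp_path):
        bad = tmp_path / "data" / "broken.h5"
        bad.parent.mkdir()
        bad.write_bytes(b"not hdf5 at all")
        rec = tmp_path / "rec"
        with pytest.raises(Exception):
            process_raw_file(bad, rec_root=rec)
        assert list(rec.iterdir()) == []


class TestReconstructionUnit:
    def test_dropped_stacks_all_reconstructed_with_records(self, tmp_path, small_scan):
        """25 simulated tile stacks → 25 output pairs in rec/ and 25 ok
        log records; rec outputs are never re-ingested."""
        data = tmp_path / "data"
        data.mkdir()
        sample = make_sample("spots", 96, seed=2)
        unit = run_reconstruction_unit(
            WatchConfig(folder=data, extensions=(".zarr", ".h5"), poll_interval_s=FAST_POLL)
        )
        for i in range(25):
            stack = acquire_stack(sample, (float(i), 0.0), small_scan, fov_px=(32, 32))
            meta = AcquisitionMetadata(stage_position_um=(float(i), 0.0, 0.0),
                                       scan=small_scan, detector_shape_px=(32, 32))
            save_raw(stack, meta, data, "zarr" if i % 2 else "hdf5", stem=f"tile{i:02d}")
        wait_until(lambda: len(unit.outputs) == 25, timeout=30, message="25 reconstructions")
        time.sleep(4 * FAST_POLL)  # would re-ingest rec outputs if it ever did
        unit.stop_and_join()
        assert len(unit.outputs) == 25
        assert len(unit.log.records) == 25
        assert all(r.status == "ok" for r in unit.log.records)
        rec_files = sorted(p.name for p in (data / "rec").iterdir())
        assert len(rec_files) == 50  # 25 TIFF + 25 OME-Zarr

    def test_empty_folder_stays_quiet(self, tmp_path):
        data = tmp_path / "data"
        data.mkdir()
        unit = run_reconstruction_unit(
            WatchConfig(folder=data, extensions=(".zarr",), poll_interval_s=FAST_POLL)
        )
        time.sleep(3 * FAST_POLL)
        unit.stop_and_join()
        assert unit.outputs == [] and unit.log.records == []
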