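"""Oblique-plane acquisition and lateral movies."""

import numpy as np
import pytest

from opmflow.flow import AcousticConfig, apply_focusing
from opmflow.geometry import ChannelGeometry
from opmflow.imaging import (FrameStack, MovieConfig, OpticsConfig,
                             acquire_frame, acquire_lateral_movie,
                             acquire_stack, plane_coords,
                             transit_sampling_factor)
from opmflow.scene import sample_population

from conftest import make_cell, make_flowing_population

SMALL = OpticsConfig(n_rows=64, n_cols=96, offset=50.0, read_noise_sd=2.0)


class TestPlaneCoords:
    def test_origin(self):
        assert plane_coords(0, 0, SMALL) == (0.0, 0.0, 0.0)

    def test_default_roi_spans_38_um(self):
        optics = OpticsConfig()
        x, y_off, z = plane_coords(127, 0, optics)
        assert z == pytest.approx(37.7, abs=0.05)
        assert optics.z_coverage == pytest.approx(38.0, abs=0.05)

    def test_vertical_sheet_has_no_shear(self):
        optics = OpticsConfig(tilt_theta=90.0, n_rows=64, n_cols=96)
        assert plane_coords(40, 10, optics)[1] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            plane_coords(64, 0, SMALL)


class TestAcquireFrame:
    def test_empty_scene_is_offset_plus_noise(self):
        pop = make_flowing_population([])
        rng = np.random.default_rng(0)
        frame = acquire_frame(pop, SMALL, channels=("cyto",), rng=rng)
        n = frame.size
        sem = SMALL.read_noise_sd / np.sqrt(n)
        assert frame.mean() == pytest.approx(SMALL.offset, abs=3 * sem)

    def test_point_emitter_maps_to_predicted_pixel(self):
        """A small emitter on the plane appears at the row/col predicted by
        the plane geometry."""
        row, col = 24, 40
        x = col * SMALL.px_x
        z = row * SMALL.row_dz
        y = -row * SMALL.row_dy  # the plane is sheared toward -y
        cell = make_cell([x, y, z], radius=0.3,
                         budgets={"cyto": 1e5, "dna": 0.0, "mitotic_marker": 0.0})
        pop = make_flowing_population([cell])
        frame = acquire_frame(pop, SMALL, channels=("cyto",), rng=None)
        peak = np.unravel_index(np.argmax(frame[..., 0]), frame.shape[:2])
        assert peak == (row, col)

    def test_signal_linear_in_budget(self):
        def total(budget):
            cell = make_cell([10.0, -2.0, 8.0], radius=3.0,
                             budgets={"cyto": budget, "dna": 0.0, "mitotic_marker": 0.0})
            pop = make_flowing_population([cell])
            frame = acquire_frame(pop, SMALL, channels=("cyto",), rng=None)
            return (frame[..., 0] - SMALL.offset).sum()

        assert total(2e5) == pytest.approx(2 * total(1e5), rel=1e-3)


class TestAcquireStack:
    def test_600_frames_at_720fps_is_833_ms(self):
        pop = make_flowing_population([])
        optics = OpticsConfig(n_rows=4, n_cols=4)
        stack = acquire_stack(pop, optics, 600, channels=("cyto",), seed=None)
        assert stack.duration == pytest.approx(0.8333, abs=5e-4)

    def test_point_emitter_appearance_duration(self):
        """A point-like emitter stays visible for ≈ sheet_fwhm·f/v frames."""
        v = 500.0
        optics = OpticsConfig(n_rows=64, n_cols=32, offset=0.0, read_noise_sd=0.0)
        cell = make_cell([5.0, 40.0, 9.0], radius=0.3,
                         budgets={"cyto": 1e6, "dna": 0.0, "mitotic_marker": 0.0})
        pop = make_flowing_population([cell], speeds=[v])
        n_frames = int(80.0 / (v / optics.frame_rate_f))
        stack = acquire_stack(pop, optics, n_frames, channels=("cyto",), seed=None)
        per_frame = stack.data[..., 0].sum(axis=(1, 2))
        visible = (per_frame > 0.05 * per_frame.max()).sum()
        expected = optics.sheet_fwhm * optics.frame_rate_f / v
        assert visible == pytest.approx(expected, abs=3)

    def test_static_scene_gives_identical_frames(self):
        cell = make_cell([10.0, -5.0, 9.0], radius=3.0)
        pop = make_flowing_population([cell], speeds=[0.0])
        stack = acquire_stack(pop, SMALL, 5, channels=("cyto",), seed=None)
        for i in range(1, 5):
            assert np.array_equal(stack.data[i], stack.data[0])

    @pytest.mark.parametrize("v", [250.0, 500.0])
    def test_photon_conservation_over_transit(self, v):
        """Background-subtracted stack total equals gain x budget x the
        sheet sampling factor within 5%, independent of speed."""
        optics = OpticsConfig(n_rows=64, n_cols=48, offset=0.0, read_noise_sd=0.0)
        budget = 1e5
        cell = make_cell([7.0, 30.0, 9.5], radius=4.0,
                         budgets={"cyto": budget, "dna": 0.0, "mitotic_marker": 0.0})
        pop = make_flowing_population([cell], speeds=[v])
        n_frames = int((40.0 + 64 * optics.row_dy + 10) / (v / optics.frame_rate_f))
        stack = acquire_stack(pop, optics, n_frames, channels=("cyto",), seed=None)
        expected = optics.gain * budget * transit_sampling_factor(optics, v)
        assert stack.data.sum() == pytest.approx(expected, rel=0.05)

    def test_roi_capture_focused_vs_unfocused(self):
        """Mid-height focusing confines ≥99% of cells to the 38 μm ROI
        placed at the node; without focusing most fall outside it."""
        geo = ChannelGeometry()
        roi_lo, roi_hi = 81.0, 119.0  # 38 um centred on the node
        pop = sample_population(3000, geo, seed=0)
        apply_focusing(pop, AcousticConfig(), seed=1)
        inside_on = np.mean((pop.kinematics.z >= roi_lo) & (pop.kinematics.z <= roi_hi))
        pop2 = sample_population(3000, geo, seed=0)
        apply_focusing(pop2, AcousticConfig(pzt_on=False), seed=1)
        inside_off = np.mean((pop2.kinematics.z >= roi_lo) & (pop2.kinematics.z <= roi_hi))
        assert inside_on >= 0.99
        assert inside_off < 0.5


class TestLateralMovie:
    def test_focused_cell_displacement_per_frame(self):
        """At 625 μm/s and 44 fps the centroid advances 14.2 μm per frame."""
        movie = MovieConfig(nx=128, ny=128, origin_x=0.0, origin_y=0.0)
        cell = make_cell([64.0, 120.0, 100.0], radius=5.0)
        pop = make_flowing_population([cell], speeds=[625.0])
        frames = acquire_lateral_movie(pop, movie, 4, seed=None)
        cents = []
        for f in frames:
            img = f - movie.offset
            ii, jj = np.meshgrid(*map(np.arange, img.shape), indexing="ij")
            cents.append((img * ii).sum() / img.sum())
        steps = -np.diff(cents) * movie.px
        assert np.allclose(steps, 625.0 / 44.0, atol=0.1)

    def test_empty_scene_is_background(self):
        movie = MovieConfig(nx=64, ny=64)
        pop = make_flowing_population([])
        frames = acquire_lateral_movie(pop, movie, 2, seed=0)
        assert frames.mean() == pytest.approx(movie.offset, abs=0.5)

    def test_cells_at_same_height_share_displacement(self):
        movie = MovieConfig(nx=128, ny=256, origin_x=0.0, origin_y=0.0)
        cells = [make_cell([40.0, 220.0, 100.0]), make_cell([90.0, 200.0, 100.0])]
        pop = make_flowing_population(cells, speeds=[400.0, 400.0])
        frames = acquire_lateral_movie(pop, movie, 3, seed=None)
        # both blobs move by the same number of rows between frames
        shift01 = _best_row_shift(frames[0], frames[1])
        shift12 = _best_row_shift(frames[1], frames[2])
        assert shift01 == shift12


def _best_row_shift(a, b):
    prof_a = a.sum(axis=1) - np.median(a.sum(axis=1))
    prof_b = b.sum(axis=1) - np.median(b.sum(axis=1))
    corr = np.correlate(prof_b, prof_a, mode="full")
    return int(np.argmax(corr)) - (len(prof_a) - 1)


class TestStackIO:
    def test_tiff_roundtrip(self, tmp_path):
        cell = make_cell([10.0, -5.0, 9.0], radius=3.0)
        pop = make_flowing_population([cell])
        stack = acquire_stack(pop, SMALL, 3, channels=("cyto", "dna"), seed=1)
        stack.save(tmp_path / "stack")
        back = FrameStack.load(tmp_path / "stack")
        assert np.array_equal(back.data, stack.data)
        assert back.optics == stack.optics
        assert back.motion == stack.motion
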