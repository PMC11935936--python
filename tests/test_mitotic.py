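"""Gating, DNA-region counting, principal axes, aspect ratios, phase calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opmflow.experiments import _ellipsoid_coords, _random_rotations
from opmflow.geometry import ChannelGeometry
from opmflow.mitotic import (ClassifyParams, Gate, PhaseCall,
                             aspect_ratio_2d, aspect_ratio_3d, classify_phase,
                             count_dna_regions, gate_positive, population_report,
                             principal_axes, rotate_to_principal)
from opmflow.scene import PhaseLabel, ScenePopulation, voxelize
from opmflow.segment import CellRecord, SegParams, segment_cells

from conftest import make_cell


def _record(label, marker, dna=1000.0, centroid=(0, 0, 0), clipped=False,
            volume=500.0):
    return CellRecord(label=label, centroid=np.asarray(centroid, float),
                      volume=volume, intensities={"mitotic_marker": marker,
                                                  "dna": dna},
                      bbox=(0, 0, 0, 1, 1, 1), clipped=clipped)


class TestGate:
    def test_threshold_above_all_empty(self):
        recs = [_record(i, 100.0) for i in range(5)]
        pos, scatter = gate_positive(recs, Gate(marker_threshold=1e6))
        assert pos == []
        assert not scatter["positive"].any()

    def test_threshold_zero_all_positive(self):
        recs = [_record(i, 100.0) for i in range(5)]
        pos, _ = gate_positive(recs, Gate(marker_threshold=0.0))
        assert len(pos) == 5

    def test_bimodal_population_perfectly_gated(self):
        rng = np.random.default_rng(0)
        neg = [_record(i, rng.lognormal(np.log(150), 0.2)) for i in range(40)]
        mit = [_record(100 + i, rng.lognormal(np.log(6000), 0.2)) for i in range(10)]
        pos, _ = gate_positive(neg + mit, Gate(marker_threshold=1000.0))
        assert {r.label for r in pos} == {100 + i for i in range(10)}

    def test_polygon_gate(self):
        poly = np.array([[3.0, 2.0], [4.5, 2.0], [4.5, 4.5], [3.0, 4.5]])
        inside = _record(0, 10 ** 3.5, dna=10 ** 3.0)
        outside = _record(1, 10 ** 2.0, dna=10 ** 3.0)
        pos, _ = gate_positive([inside, outside], Gate(polygon=poly))
        assert [r.label for r in pos] == [0]

    def test_gate_requires_a_rule(self):
        with pytest.raises(ValueError):
            Gate()


def _segmented_phantom(phase, orientation=(0.0, 0.0, 0.0, 1.0), voxel=0.4):
    geo = ChannelGeometry(height_h=200.0, width_w=2000.0, length_l=200.0)
    cell = make_cell([20.0, 20.0, 100.0], radius=5.0, phase=phase,
                     orientation=orientation,
                     budgets={"cyto": 2e4, "dna": 1e4, "mitotic_marker": 6e3})
    scene = ScenePopulation([cell], geo, 0.0, 0)
    vol = voxelize(scene, (voxel, voxel, voxel),
                   ((12, 28), (12, 28), (92, 108)),
                   channels=("cyto", "dna", "mitotic_marker"))
    labels, records = segment_cells(
        vol, "cyto", SegParams(smooth_sigma=0.8, min_seed_separation=7.0,
                               min_volume=50.0, clip_margin=0))
    assert len(records) == 1
    return cell, vol, labels, records[0]


class TestCountDnaRegions:
    def test_interphase_one_region(self):
        _, vol, labels, rec = _segmented_phantom(PhaseLabel.INTERPHASE)
        assert len(count_dna_regions(rec, labels, vol)) == 1

    def test_anaphase_two_regions(self):
        rng = np.random.default_rng(2)
        q = rng.normal(size=4)
        _, vol, labels, rec = _segmented_phantom(PhaseLabel.ANAPHASE,
                                                 orientation=q / np.linalg.norm(q))
        assert len(count_dna_regions(rec, labels, vol)) == 2

    def test_empty_dna_channel_zero_regions(self):
        cell, vol, labels, rec = _segmented_phantom(PhaseLabel.INTERPHASE)
        vol.data[..., vol.channels.index("dna")] = 0.0
        assert count_dna_regions(rec, labels, vol) == []


class TestPrincipalAxes:
    def test_axis_aligned_oblate_ellipsoid(self):
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), np.eye(3), voxel=0.4)
        reg = principal_axes(coords, w)
        # eigenvectors along grid axes; sqrt-eigenvalue ratios = semi-axis ratios
        assert abs(reg.eigvecs[2, 2]) > 0.999
        ratios = np.sqrt(reg.eigvals / reg.eigvals[0])
        assert ratios[2] == pytest.approx(0.35, rel=0.03)
        assert ratios[1] == pytest.approx(1.0, rel=0.03)

    def test_sphere_is_isotropic(self):
        coords, w = _ellipsoid_coords((6.0, 6.0, 6.0), np.eye(3), voxel=0.4)
        reg = principal_axes(coords, w)
        assert reg.eigvals[0] / reg.eigvals[2] == pytest.approx(1.0, rel=0.03)

    def test_rotation_equivariance(self):
        """Axes of a rotated region equal the rotated axes of the original
        within 1 degree."""
        rng = np.random.default_rng(5)
        for rot in _random_rotations(rng, 5):
            coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), rot, voxel=0.4)
            reg = principal_axes(coords, w)
            cos = abs(float(reg.eigvecs[:, 2] @ rot[:, 2]))
            assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            principal_axes(np.zeros((3, 3)))

    def test_degenerate_region_flagged(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        reg = principal_axes(coords)
        assert reg.degenerate
        with pytest.raises(ValueError):
            aspect_ratio_3d(reg)


class TestAspectRatios:
    def test_sphere_unity(self):
        coords, w = _ellipsoid_coords((6.0, 6.0, 6.0), np.eye(3), voxel=0.4)
        reg = principal_axes(coords, w)
        assert aspect_ratio_3d(reg) == pytest.approx(1.0, rel=0.02)
        assert aspect_ratio_2d(reg) == pytest.approx(1.0, rel=0.02)

    def test_oblate_value(self):
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), np.eye(3), voxel=0.4)
        assert aspect_ratio_3d(principal_axes(coords, w)) == pytest.approx(0.35, abs=0.01)

    def test_prolate_value(self):
        coords, w = _ellipsoid_coords((12.0, 6.0, 6.0), np.eye(3), voxel=0.4)
        assert aspect_ratio_3d(principal_axes(coords, w)) == pytest.approx(2 / 3, abs=0.01)

    def test_plate_in_xy_plane_hides_short_axis(self):
        # short axis along z: the xy projection is a circle -> ar2d = 1
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), np.eye(3), voxel=0.4)
        reg = principal_axes(coords, w)
        assert aspect_ratio_2d(reg) == pytest.approx(1.0, rel=0.02)
        assert aspect_ratio_3d(reg) == pytest.approx(0.35, abs=0.01)

    def test_plate_with_short_axis_in_plane_shows_true_ratio(self):
        # short axis along x: projected ellipse has semi-axes (c, a)
        rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), rot, voxel=0.4)
        reg = principal_axes(coords, w)
        assert aspect_ratio_2d(reg) == pytest.approx(0.35, abs=0.01)
        assert aspect_ratio_2d(reg) == pytest.approx(aspect_ratio_3d(reg), abs=0.01)

    @given(scale=st.floats(0.2, 20.0), shift=st.floats(-50.0, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_ar3d_invariant_to_intensity_scale_and_translation(self, scale, shift):
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), np.eye(3), voxel=0.6)
        a = aspect_ratio_3d(principal_axes(coords, w))
        b = aspect_ratio_3d(principal_axes(coords + shift, w * scale))
        assert b == pytest.approx(a, rel=1e-9)


class TestRotateToPrincipal:
    def test_rotated_covariance_is_diagonal(self):
        rng = np.random.default_rng(7)
        rot = _random_rotations(rng, 1)[0]
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), rot, voxel=0.5)
        reg = principal_axes(coords, w)
        rotated, projections = rotate_to_principal(reg)
        wn = reg.weights
        d = rotated - (rotated * wn[:, None]).sum(axis=0)
        cov = (d * wn[:, None]).T @ d
        off = np.abs(cov - np.diag(np.diag(cov))).sum()
        assert off / np.trace(cov) < 1e-6
        assert len(projections) == 3

    def test_plate_projection_areas_ordered(self):
        """Viewing along the short axis shows the largest shadow; along the
        long axis the smallest."""
        rng = np.random.default_rng(8)
        rot = _random_rotations(rng, 1)[0]
        coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), rot, voxel=0.5)
        reg = principal_axes(coords, w)
        _, projections = rotate_to_principal(reg, bin_size=0.5)
        areas = [(p > 0).sum() for p in projections]
        # axis 2 = shortest axis -> largest area; axis 0 = longest -> smallest
        assert areas[2] > areas[0]


class TestClassifyPhase:
    def _single_region(self, label, centroid, ar_shape, clipped=False):
        rec = _record(label, 6000.0, centroid=centroid, clipped=clipped)
        coords, w = _ellipsoid_coords(ar_shape, np.eye(3), voxel=0.5)
        from opmflow.mitotic import DnaRegion
        region = DnaRegion(coords_um=coords + np.asarray(centroid, float),
                           intensities=w, n_voxels=len(coords))
        return rec, [region]

    def test_decision_tree_on_constructed_cells(self):
        recs, regions = [], {}
        # prophase-like (round), metaphase-like (flat), anaphase (2 regions),
        # telophase pair (adjacent rounds), clipped cell
        r, g = self._single_region(1, (0, 0, 0), (3.0, 3.0, 3.0))
        recs.append(r); regions[1] = g
        r, g = self._single_region(2, (100, 0, 0), (4.0, 4.0, 1.4))
        recs.append(r); regions[2] = g
        r, g = self._single_region(3, (200, 0, 0), (3.0, 3.0, 3.0))
        recs.append(r); regions[3] = g + g  # two regions
        r, g = self._single_region(4, (300, 0, 0), (3.0, 3.0, 3.0))
        recs.append(r); regions[4] = g
        r, g = self._single_region(5, (308, 0, 0), (3.0, 3.0, 3.0))
        recs.append(r); regions[5] = g
        r, g = self._single_region(6, (400, 0, 0), (3.0, 3.0, 3.0), clipped=True)
        recs.append(r); regions[6] = g
        calls = {c.label: c for c in classify_phase(
            recs, regions, ClassifyParams(pair_distance=15.0))}
        assert calls[1].phase == "prophase"
        assert calls[2].phase == "metaphase"
        assert calls[3].phase == "anaphase"
        assert calls[4].phase == "telophase" and calls[4].partner_label == 5
        assert calls[5].phase == "telophase" and calls[5].partner_label == 4
        assert calls[6].phase == "omitted_clipped"

    def test_phantom_anaphase_called_anaphase(self):
        rng = np.random.default_rng(3)
        q = rng.normal(size=4)
        _, vol, labels, rec = _segmented_phantom(PhaseLabel.ANAPHASE,
                                                 orientation=q / np.linalg.norm(q))
        regions = {rec.label: count_dna_regions(rec, labels, vol)}
        calls = classify_phase([rec], regions)
        assert calls[0].phase == "anaphase"


class TestPopulationReport:
    def test_empty_inputs(self):
        rep = population_report([], [], duration=1.0)
        assert rep["n_cells"] == 0 and rep["n_positive"] == 0

    def test_all_interphase_cohort_no_positives(self):
        recs = [_record(i, 150.0) for i in range(20)]
        pos, _ = gate_positive(recs, Gate(marker_threshold=1000.0))
        rep = population_report([], recs, duration=2.0)
        assert pos == [] and rep["phase_counts"]["prophase"] == 0
        assert rep["throughput_cells_per_s"] == pytest.approx(10.0)

    def test_random_oblate_cohort_2d_overestimates(self):
        """Over randomly oriented oblate plates the projected (2D) aspect
        ratio exceeds the true 3D one on average and per cell."""
        rng = np.random.default_rng(11)
        calls = []
        for i, rot in enumerate(_random_rotations(rng, 50)):
            coords, w = _ellipsoid_coords((10.0, 10.0, 3.5), rot, voxel=0.6)
            reg = principal_axes(coords, w)
            calls.append(PhaseCall(label=i, phase="metaphase", n_regions=1,
                                   ar3d=aspect_ratio_3d(reg),
                                   ar2d=aspect_ratio_2d(reg)))
        rep = population_report(calls, [], duration=1.0)
        assert rep["ar2d_mean"] > rep["ar3d_mean"]
        assert all(c.ar2d >= c.ar3d - 1e-4 for c in calls)
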