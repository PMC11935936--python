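"""Pre-configured study scenarios.

Each function here composes the simulator and the analysis pipeline into one
self-contained numerical experiment (reconstruction round trip, paired
PZT-on/off velocimetry, large-field segmentation, morphometry recovery,
mitotic-phase recovery) at problem sizes chosen to run on a single CPU in
minutes.  They are used by the test suite and by ``scripts/acceptance.py``;
all randomness is seeded through the ``seed`` argument.
"""

from __future__ import annotations

import math

import numpy as np

from .config import RunConfig, SceneSection, TrackingSection
from .flow import AcousticConfig, FlowConfig, apply_focusing, axial_velocity
from .geometry import ChannelGeometry
from .imaging import MovieConfig, OpticsConfig, acquire_stack
from .mitotic import (ClassifyParams, Gate, classify_phase, count_dna_regions,
                      gate_positive, principal_axes, aspect_ratio_2d,
                      aspect_ratio_3d)
from .pipeline import compare_pzt_modes
from .reconstruct import DeskewCalibration, deskew
from .scene import (CellSpec, KinematicState, PhaseLabel, ScenePopulation,
                    sample_population, voxelize)
from .segment import (SegParams, count_check, detection_throughput,
                      match_to_truth, segment_cells)
from .tracking import Track, velocity_stats


# ---------------------------------------------------------------------------
# Worked examples (printed-number arithmetic)


def worked_throughputs() -> dict:
    """The two headline detection throughputs, from their printed inputs:
    1927 cells over a 600-frame / 720 fps acquisition, and 2682 cells over
    the printed 833 ms."""
    flow_run = detection_throughput(1927, 600 / 720)
    stage_run = detection_throughput(2682, 0.833)
    return {"flow_cells_per_s": flow_run, "stage_cells_per_s": stage_run}


def worked_velocity_cv(mean: float = 171.0, sd: float = 126.0) -> float:
    """CV of a velocity sample with the given mean and (population) SD,
    computed through the velocimetry statistics path on a constructed
    two-step track."""
    # positions spaced so consecutive step speeds are mean − sd and mean + sd
    f = 44.0
    track = Track(particle_id=0, frames=[0, 1, 2],
                  positions=[np.array([0.0, 0.0]),
                             np.array([(mean - sd) / f, 0.0]),
                             np.array([(mean - sd) / f + (mean + sd) / f, 0.0])])
    return velocity_stats([track], frame_rate=f).cv


def midplane_speed(Q: float = 10.0, height: float = 200.0, width: float = 2000.0) -> float:
    """Plane-Poiseuille mid-height speed for the given channel, μm s⁻¹."""
    flow = FlowConfig(flow_rate_Q=Q, geometry=ChannelGeometry(height, width))
    return axial_velocity(height / 2.0, flow)


# ---------------------------------------------------------------------------
# Paired PZT-on/off velocimetry


def pzt_contrast(seed: int = 0, n_cells: int = 250, n_frames: int = 100) -> dict:
    """Simulate paired lateral movies (PZT on/off, identical cells) and
    return the tracked CV pair."""
    cfg = RunConfig(
        seed=seed,
        scene=SceneSection(n_cells=n_cells, length_l=2000.0),
        movie=MovieConfig(nx=400, ny=400, origin_x=200.0, origin_y=0.0, px=1.0),
        tracking=TrackingSection(n_frames=n_frames, max_displacement=20.0, memory=1),
    )
    res = compare_pzt_modes(cfg)
    return {"cv_on": res["cv_on"], "cv_off": res["cv_off"],
            "mean_on": res["pzt_on"]["mean"], "mean_off": res["pzt_off"]["mean"]}


# ---------------------------------------------------------------------------
# Reconstruction round trip


def _single_cell_population(center, radius, speed, budgets=None,
                            geometry: ChannelGeometry | None = None) -> ScenePopulation:
    geometry = geometry or ChannelGeometry(height_h=200.0, width_w=2000.0, length_l=500.0)
    cell = CellSpec(id=0, center=np.asarray(center, float), cell_radius=radius,
                    phase=PhaseLabel.INTERPHASE,
                    orientation=np.array([0.0, 0.0, 0.0, 1.0]),
                    budgets=budgets or {"cyto": 2e5, "dna": 1e5, "mitotic_marker": 0.0})
    pop = ScenePopulation([cell], geometry, 0.0, 0)
    pop.kinematics = KinematicState(z=np.array([center[2]]),
                                    speed_u=np.array([speed]),
                                    spin_omega=np.zeros(1))
    return pop


def roundtrip_sphere_recovery(seed: int = 0,
                              velocities=(250.0, 500.0, 750.0),
                              radius: float = 4.0) -> dict:
    """Phantom → oblique acquisition → deskew for several flow speeds.

    Returns the worst-case centroid error (in output voxels, per axis
    maximum) and worst-case relative volume error of a half-maximum
    isosurface estimate, under shot + read noise at SNR ≥ 10.
    """
    optics = OpticsConfig(n_rows=64, n_cols=128)
    center = np.array([17.0, 30.0, 9.5])
    worst_centroid = 0.0
    worst_vol = 0.0
    for i, v in enumerate(velocities):
        pop = _single_cell_population(center, radius, v)
        n_frames = int((center[1] + radius + 8.0 + optics.n_rows * optics.row_dy)
                       / (v / optics.frame_rate_f))
        stack = acquire_stack(pop, optics, n_frames, channels=("cyto",),
                              seed=seed * 997 + i)
        vol = deskew(stack, DeskewCalibration.from_optics(optics, v))
        img = vol.channel("cyto").astype(float) - optics.offset
        cen = vol.centroid_um("cyto", background=optics.offset + 6.0)
        err_vox = np.abs(cen - center) / np.array(vol.voxel)
        worst_centroid = max(worst_centroid, float(err_vox.max()))
        from scipy.ndimage import gaussian_filter
        sm = gaussian_filter(img, [0.5 / s for s in (vol.voxel[2], vol.voxel[1], vol.voxel[0])])
        # half-maximum isosurface (robust to noise spikes via a high
        # percentile), then the first-order curvature correction for a
        # blurred ball: the isosurface sits inward by sigma^2 / R
        est_hm = (sm > 0.5 * np.percentile(sm, 99.99)).sum() * vol.voxel_volume
        r_hm = (3.0 * est_hm / (4.0 * math.pi)) ** (1.0 / 3.0)
        r_corr = r_hm + optics.sheet_sigma ** 2 / r_hm
        est = 4.0 / 3.0 * math.pi * r_corr ** 3
        truth = 4.0 / 3.0 * math.pi * radius ** 3
        worst_vol = max(worst_vol, abs(est - truth) / truth)
    return {"max_centroid_error_voxels": worst_centroid,
            "max_volume_error_fraction": worst_vol}


def reconstruction_extents(v: float = 500.0, n_frames: int = 600) -> dict:
    """y/z extents of a default-calibration reconstruction (600 frames at
    720 fps, 128 rows).  Only y and z depend on the deskew; the column count
    is reduced since x-extent is n_cols × px_x by construction."""
    optics = OpticsConfig(n_cols=64)
    from .imaging import FrameStack
    stack = FrameStack(data=np.zeros((n_frames, optics.n_rows, optics.n_cols, 1),
                                     dtype=np.float32),
                       channels=("cyto",), t0=0.0, frame_rate=optics.frame_rate_f,
                       optics=optics, motion=v)
    vol = deskew(stack, DeskewCalibration.from_optics(optics, v))
    ex = vol.extent_um()
    full_x = 2560 * optics.px_x
    return {"x_extent_um_full_roi": full_x, "y_extent_um": ex[1], "z_extent_um": ex[2]}


# ---------------------------------------------------------------------------
# Large-field segmentation + counting


def segmentation_study(seed: int = 0, n_cells: int = 500) -> dict:
    """Focused population → oblique stack → deskew → watershed; detection
    scored against the generator's ground truth.

    Uses ≈1 μm sampling (coarser than the instrument calibration) so a
    ≈500-cell field fits one stack; the 40-row ROI is centred on the
    acoustic node.
    """
    geo = ChannelGeometry(height_h=200.0, width_w=1000.0, length_l=2200.0)
    pop = sample_population(n_cells, geo, phase_fractions={"interphase": 1.0},
                            seed=seed * 31 + 1)
    flow = FlowConfig(geometry=geo)
    apply_focusing(pop, AcousticConfig(), flow, seed=seed * 31 + 2)
    optics = OpticsConfig(px_x=1.0, row_dz=1.0, n_rows=40, n_cols=600,
                          origin_x=200.0, origin_z=80.0)
    v = float(pop.kinematics.speed_u.mean())
    n_frames = int((geo.length_l + optics.n_rows * optics.row_dy + 30.0)
                   / (v / optics.frame_rate_f))
    stack = acquire_stack(pop, optics, n_frames, channels=("cyto",),
                          seed=seed * 31 + 3)
    vol = deskew(stack, DeskewCalibration.from_optics(optics, v))
    duration = stack.duration
    del stack
    labels, records = segment_cells(
        vol, "cyto", SegParams(min_seed_separation=8.0, min_volume=100.0))
    recall, precision, _ = match_to_truth(records, pop.positions, max_distance=5.0)
    chk = count_check(records)
    return {
        "n_true": len(pop), "n_detected": chk.count,
        "recall": recall, "precision": precision,
        "count_ratio": chk.ratio,
        "count_ratio_rel_dev": abs(chk.ratio - chk.count) / chk.count,
        "throughput_cells_per_s": detection_throughput(chk.count, duration),
    }


# ---------------------------------------------------------------------------
# Morphometry recovery


def _ellipsoid_coords(semi_axes, rotation, voxel=0.5, antialias=True):
    """Voxel centres and occupancy weights of a rotated solid ellipsoid.

    With ``antialias`` the boundary voxels get fractional weights from a
    first-order signed-distance estimate, which suppresses the grid-induced
    anisotropy of a hard inside/outside test.
    """
    r = max(semi_axes) + voxel
    g = np.arange(-r, r + voxel, voxel)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    local = pts @ rotation  # rotation columns = ellipsoid axes in lab frame
    s = np.asarray(semi_axes)
    f = np.sqrt(np.sum((local / s) ** 2, axis=1))
    if not antialias:
        keep = f <= 1.0
        return pts[keep], np.ones(int(keep.sum()))
    grad = np.linalg.norm(local / s ** 2, axis=1) / np.maximum(f, 1e-12)
    dist = (1.0 - f) / np.maximum(grad, 1e-12)   # signed distance to surface
    w = np.clip(0.5 + dist / voxel, 0.0, 1.0)
    keep = w > 0
    return pts[keep], w[keep]


def _random_rotations(rng, n):
    from .scene import random_unit_quaternions, _quat_to_matrix
    qs = random_unit_quaternions(rng, n)
    return [_quat_to_matrix(q) for q in qs]


def morphometry_recovery(seed: int = 0, n_orientations: int = 1000,
                         semi_axes=(10.0, 10.0, 3.5)) -> dict:
    """PCA axis recovery on voxelized oblate phantoms.

    Checks (i) orientation recovery of the short (symmetry) axis against the
    applied rotation, (ii) the 3D aspect ratio of the axis-aligned phantom
    against c/a, and (iii) the projection inequality ar2d ≥ ar3d over random
    orientations.
    """
    rng = np.random.default_rng(seed)
    a, b, c = semi_axes

    # (ii) axis-aligned phantom
    coords, w = _ellipsoid_coords(semi_axes, np.eye(3), voxel=0.4)
    region = principal_axes(coords, w)
    ar3_aligned = aspect_ratio_3d(region)

    # (i) orientation recovery over a modest number of rotations
    worst_angle = 0.0
    for rot in _random_rotations(rng, 25):
        coords, w = _ellipsoid_coords(semi_axes, rot, voxel=0.4)
        reg = principal_axes(coords, w)
        short_true = rot[:, 2]
        short_est = reg.eigvecs[:, 2]
        cosang = abs(float(np.dot(short_true, short_est)))
        worst_angle = max(worst_angle, math.degrees(math.acos(min(1.0, cosang))))

    # (iii) projection inequality at scale
    margins = np.empty(n_orientations)
    for i, rot in enumerate(_random_rotations(rng, n_orientations)):
        coords, w = _ellipsoid_coords(semi_axes, rot, voxel=0.6)
        reg = principal_axes(coords, w)
        margins[i] = aspect_ratio_2d(reg) - aspect_ratio_3d(reg)
    return {
        "ar3d_axis_aligned": ar3_aligned,
        "max_orientation_error_deg": worst_angle,
        "min_ar2d_minus_ar3d": float(margins.min()),
        "frac_ar2d_ge_ar3d": float((margins >= 0).mean()),
        "mean_ar2d_minus_ar3d": float(margins.mean()),
    }


# ---------------------------------------------------------------------------
# Mitotic-phase recovery cohort


MITOTIC_FRACTIONS = {"prophase": 0.26, "metaphase": 0.26,
                     "anaphase": 0.24, "telophase": 0.24}


def archetype_phantom_classification(voxel: float = 0.4) -> dict:
    """Noise-free classification of one isolated phantom per mitotic phase
    (plus a telophase partner pair), far apart so the decision tree is
    exercised purely on nuclear shape.  Expected accuracy: 1.0 — the tree
    separates the generator's shape classes by construction."""
    geo = ChannelGeometry(height_h=200.0, width_w=2000.0, length_l=2000.0)
    rng = np.random.default_rng(12345)
    cells = []
    phases = [PhaseLabel.PROPHASE, PhaseLabel.METAPHASE, PhaseLabel.ANAPHASE,
              PhaseLabel.TELOPHASE, PhaseLabel.TELOPHASE]
    from .scene import random_unit_quaternions
    quats = random_unit_quaternions(rng, len(phases))
    for i, ph in enumerate(phases):
        cells.append(CellSpec(
            id=i, center=np.array([500.0 + 200.0 * i, 500.0, 100.0]),
            cell_radius=5.0, phase=ph, orientation=quats[i],
            budgets={"cyto": 2e4, "dna": 1e4, "mitotic_marker": 6e3}))
    # telophase partners: adjacent at 1.2 diameters (12 μm)
    direction = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    cells[4].center = cells[3].center + 12.0 * direction
    cells[3].partner_id, cells[4].partner_id = 4, 3
    pop = ScenePopulation(cells, geo, 0.0, 0)

    seg = SegParams(smooth_sigma=0.8, min_seed_separation=7.0, min_volume=50.0,
                    clip_margin=0)
    records, regions, truth = [], {}, {}
    next_label = 1
    # phantoms: the anaphase/telophase groups each get their own volume
    groups = [[cells[0]], [cells[1]], [cells[2]], [cells[3], cells[4]]]
    for grp in groups:
        centers = np.stack([c.center for c in grp])
        pad = 8.0
        lo, hi = centers.min(axis=0) - pad, centers.max(axis=0) + pad
        sub = ScenePopulation(grp, geo, 0.0, 0)
        vol = voxelize(sub, (voxel, voxel, voxel),
                       ((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2])),
                       channels=("cyto", "dna", "mitotic_marker"))
        labels, recs = segment_cells(vol, "cyto", seg)
        for rec in recs:
            old = rec.label
            rec.label = next_label
            labels = np.where(labels == old, next_label, labels) if old != next_label else labels
            next_label += 1
        for rec in recs:
            regions[rec.label] = count_dna_regions(rec, labels, vol)
            d = np.linalg.norm(centers - rec.centroid, axis=1)
            truth[rec.label] = grp[int(d.argmin())]
        records.extend(recs)

    positives, _ = gate_positive(records, Gate(marker_threshold=1000.0))
    calls = classify_phase(positives, regions, ClassifyParams())
    call_by_label = {c.label: c for c in calls}
    correct = sum(1 for rec in records
                  if call_by_label.get(rec.label) is not None
                  and call_by_label[rec.label].phase == truth[rec.label].phase.value)
    return {"n_cells": len(cells), "n_detected": len(records),
            "accuracy": correct / len(cells)}


def phase_cohort_study(seed: int = 0, n_mitotic: int = 200, noisy: bool = True,
                       exposure: float = 20.0, voxel: float = 0.4) -> dict:
    """Recovery of generator phase labels by the analysis decision tree.

    Each cell (telophase partners share a group) is voxelized into a local
    phantom at ``voxel`` μm sampling; under ``noisy`` the phantom receives
    Poisson shot noise at an integration level ``exposure`` photons per
    phantom photon (peak-voxel SNR ≥ 10 at the defaults).  The phantoms run
    through watershed segmentation, marker gating, DNA-region counting and
    the phase decision tree; accuracy is scored against the generator truth.
    """
    geo = ChannelGeometry(height_h=200.0, width_w=2000.0, length_l=4000.0)
    pop = sample_population(n_mitotic, geo, phase_fractions=MITOTIC_FRACTIONS,
                            seed=seed * 101 + 7)
    rng = np.random.default_rng(seed * 101 + 8)

    # group telophase partners into shared phantoms
    by_id = {c.id: c for c in pop.cells}
    groups, used = [], set()
    for cell in pop.cells:
        if cell.id in used:
            continue
        grp = [cell]
        used.add(cell.id)
        if cell.partner_id is not None and cell.partner_id not in used:
            grp.append(by_id[cell.partner_id])
            used.add(cell.partner_id)
        groups.append(grp)

    all_records, regions_by_label, truth_by_label = [], {}, {}
    next_label = 1
    seg = SegParams(smooth_sigma=0.8, min_seed_separation=7.0, min_volume=50.0,
                    clip_margin=0)
    for grp in groups:
        centers = np.stack([c.center for c in grp])
        pad = max(c.cell_radius for c in grp) + 3.0
        lo, hi = centers.min(axis=0) - pad, centers.max(axis=0) + pad
        lo[2] = max(lo[2], 0.0)
        hi[2] = min(hi[2], geo.height_h)
        sub = ScenePopulation(grp, geo, 0.0, 0)
        vol = voxelize(sub, (voxel, voxel, voxel),
                       ((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2])),
                       channels=("cyto", "dna", "mitotic_marker"))
        if noisy:
            vol.data = (rng.poisson(np.clip(vol.data, 0, None) * exposure)
                        / exposure).astype(np.float32)
        labels, records = segment_cells(vol, "cyto", seg)
        # remap group-local labels to global ones
        remap = {}
        for rec in records:
            remap[rec.label] = next_label
            rec.label = next_label
            next_label += 1
        relabeled = np.zeros_like(labels)
        for old, new in remap.items():
            relabeled[labels == old] = new

        for rec in records:
            regions_by_label[rec.label] = count_dna_regions(rec, relabeled, vol)
            d = np.linalg.norm(centers - rec.centroid, axis=1)
            truth_by_label[rec.label] = grp[int(d.argmin())] if d.min() <= 4.0 else None
        all_records.extend(records)

    positives, _ = gate_positive(all_records, Gate(marker_threshold=1000.0))
    calls = classify_phase(positives, regions_by_label, ClassifyParams())
    call_by_label = {c.label: c for c in calls}

    n_scored = n_correct = 0
    for rec in all_records:
        truth = truth_by_label.get(rec.label)
        if truth is None:
            continue
        n_scored += 1
        call = call_by_label.get(rec.label)
        if call is not None and call.phase == truth.phase.value:
            n_correct += 1
    return {
        "n_cells": n_mitotic,
        "n_scored": n_scored,
        "accuracy": n_correct / n_scored if n_scored else 0.0,
    }
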