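"""Image-based particle velocimetry on lateral-plane movies.

Detection: Gaussian-difference band-pass → local maxima above a mass
threshold → subpixel refinement by intensity-weighted centroid within the
feature radius.  Linking: per-frame globally optimal assignment (minimum
total squared displacement, solved with the Hungarian algorithm) with a hard
search radius and optional gap-closing memory.  Per-step speeds are
|Δposition| between consecutive linked detections times the frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max


@dataclass(frozen=True)
class DetectParams:
    diameter: float = 10.0        # um, feature size
    mass_threshold: float = 50.0  # integrated band-passed counts
    min_amplitude: float = 5.0    # counts, band-passed peak height
    noise_sigma: float = 1.0      # px, small scale of the band-pass


@dataclass
class Detection:
    frame: int
    position: np.ndarray  # (x, y) um
    mass: float


@dataclass
class Track:
    particle_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def step_speeds(self, frame_rate: float) -> np.ndarray:
        """Speeds between consecutive detections (n − 1 values), μm s⁻¹;
        displacement over gap-closed steps is divided by the gap duration."""
        if len(self) < 2:
            return np.zeros(0)
        pos = np.stack(self.positions)
        frames = np.asarray(self.frames, dtype=float)
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        dt = np.diff(frames) / frame_rate
        return disp / dt


@dataclass
class VelocityStats:
    mean: float
    sd: float
    cv: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_steps: int

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "cv": self.cv,
                "n_steps": self.n_steps,
                "bin_edges": self.bin_edges.tolist(),
                "counts": self.counts.tolist()}


def detect_particles(
    frame: np.ndarray,
    px: float = 1.0,
    params: DetectParams = DetectParams(),
    frame_index: int = 0,
) -> list[Detection]:
    """Detect bright blobs in one movie frame; positions returned in μm."""
    img = frame.astype(np.float64)
    diam_px = params.diameter / px
    bp = gaussian_filter(img, params.noise_sigma) - gaussian_filter(img, diam_px)
    bp = np.clip(bp, 0.0, None)
    if bp.max() <= 0:
        return []
    rad = max(1, int(round(diam_px / 2)))
    peaks = peak_local_max(bp, min_distance=rad, threshold_abs=params.min_amplitude,
                           exclude_border=False)
    out: list[Detection] = []
    for i, j in peaks:
        i0, i1 = max(0, i - rad), min(bp.shape[0], i + rad + 1)
        j0, j1 = max(0, j - rad), min(bp.shape[1], j + rad + 1)
        win = bp[i0:i1, j0:j1]
        mass = float(win.sum())
        if mass < params.mass_threshold:
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        ci = (win * ii).sum() / mass
        cj = (win * jj).sum() / mass
        out.append(Detection(frame=frame_index,
                             position=np.array([cj * px, ci * px]), mass=mass))
    return out


def detect_movie(frames: np.ndarray, px: float = 1.0,
                 params: DetectParams = DetectParams()) -> list[Detection]:
    dets: list[Detection] = []
    for fi, frame in enumerate(frames):
        dets.extend(detect_particles(frame, px=px, params=params, frame_index=fi))
    return dets


def link_tracks(
    detections: list[Detection],
    max_displacement: float = 20.0,
    memory: int = 0,
) -> list[Track]:
    """Link detections across frames into tracks.

    Each frame solves the globally optimal assignment between live tracks and
    new detections under a hard per-step search radius ``max_displacement``
    (μm); unmatched detections start new tracks, and a track survives up to
    ``memory`` missed frames before terminating.
    """
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []

    tracks: list[Track] = []
    live: list[Track] = []
    next_id = 0
    big = 1e12

    for fr in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(fr, [])
        candidates = [t for t in live if fr - t.frames[-1] <= memory + 1]
        nt, nd = len(candidates), len(dets)
        assigned_det = [False] * nd
        if nt and nd:
            # square cost matrix with birth/death padding at the gate cost
            size = nt + nd
            cost = np.full((size, size), max_displacement ** 2, dtype=float)
            cost[nt:, nd:] = 0.0
            for i, t in enumerate(candidates):
                gap = fr - t.frames[-1]
                allowed = max_displacement * gap
                for j, d in enumerate(dets):
                    d2 = float(np.sum((d.position - t.positions[-1]) ** 2))
                    # compare per-frame displacements so gap-closed links
                    # compete fairly with single-frame links
                    cost[i, j] = d2 / gap ** 2 if d2 <= allowed ** 2 else big
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < nt and j < nd and cost[i, j] < big:
                    candidates[i].frames.append(fr)
                    candidates[i].positions.append(dets[j].position)
                    assigned_det[j] = True
        for j, d in enumerate(dets):
            if not assigned_det[j]:
                t = Track(particle_id=next_id, frames=[fr], positions=[d.position])
                next_id += 1
                tracks.append(t)
                live.append(t)
        live = [t for t in live if fr - t.frames[-1] <= memory]
    return tracks


def velocity_stats(
    tracks: list[Track],
    frame_rate: float,
    bin_width: float = 25.0,
    hist_range: tuple[float, float] = (0.0, 1000.0),
    min_track_length: int = 2,
) -> VelocityStats:
    """Pooled per-step speed statistics over all tracks.

    Mean, population SD (ddof = 0) and CV = sd/mean over every step of every
    track of at least ``min_track_length`` detections, plus a fixed-width
    histogram (25 μm s⁻¹ bins over 0–1000 by default).
    """
    speeds = [t.step_speeds(frame_rate) for t in tracks if len(t) >= min_track_length]
    speeds = np.concatenate(speeds) if speeds else np.zeros(0)
    if speeds.size == 0:
        raise ValueError("no track steps; cannot compute velocity statistics")
    mean = float(speeds.mean())
    sd = float(speeds.std(ddof=0))
    cv = sd / mean if mean > 0 else float("nan")
    edges = np.arange(hist_range[0], hist_range[1] + bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    return VelocityStats(mean=mean, sd=sd, cv=cv, bin_edges=edges,
                         counts=counts, n_steps=int(speeds.size))


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for fr, p in zip(t.frames, t.positions):
            rows.append({"particle": t.particle_id, "frame": fr,
                         "x": p[0], "y": p[1]})
    return pd.DataFrame(rows)
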