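"""Oblique-plane acquisition simulator.

A light sheet tilted by ``tilt_theta`` from the lateral (xy) plane is held
stationary while cells translate through it toward −y; each camera frame is
one oblique optical section, and the sequence of frames forms a diagonal
stack that :mod:`opmflow.reconstruct` deskews into a Cartesian volume.

Geometry of pixel (row r, col c), in lab coordinates with the plane anchored
at y = 0 for row 0:

* x = c · px_x
* z = r · row_dz
* y = −r · row_dy, with row_dy = row_dz / tan(θ) (the in-plane shear of the
  row direction relative to vertical).

The sheet-normal unit vector is (0, sin θ, cos θ).  A pixel integrates the
scene's emission density along that normal under a Gaussian excitation
profile of FWHM ``sheet_fwhm`` (peak-normalised), times the in-plane pixel
area px_x · row_dz/sin θ; frames are then blurred by the lateral PSF, scaled
by gain, offset, and given Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .scene import CellSpec, ScenePopulation, emission_density, cell_support_radius
from .flow import advected_positions

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Gauss–Hermite order for the sheet-normal quadrature.
_GH_ORDER = 11


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry, sampling and camera model.

    Defaults are calibration-consistent with the instrument being modelled:
    px_x = 724 μm / 2560 columns, row_dz = 38 μm / 128 rows (the refractive
    axial-scale correction is folded into this calibration), 720 frames s⁻¹,
    and a 67° tilt.
    """

    tilt_theta: float = 67.0       # degrees from the lateral plane
    sheet_fwhm: float = 1.5        # um, excitation-sheet thickness
    lateral_psf_fwhm: float = 0.5  # um, in-plane blur
    px_x: float = 0.283            # um per column
    row_dz: float = 0.297          # um of z per row
    n_rows: int = 128
    n_cols: int = 2560
    frame_rate_f: float = 720.0    # frames/s
    origin_x: float = 0.0          # um, lab x of column 0
    origin_z: float = 0.0          # um, lab z of row 0 (ROI placement)
    gain: float = 1.0              # counts per photon
    offset: float = 100.0          # counts
    read_noise_sd: float = 2.0     # counts

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_theta <= 90.0:
            raise ValueError("tilt_theta must be in (0, 90] degrees")
        if min(self.px_x, self.row_dz, self.frame_rate_f) <= 0:
            raise ValueError("pitches and frame rate must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("sensor ROI must have at least one row and column")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.tilt_theta)

    @property
    def row_dy(self) -> float:
        """In-plane shear: μm of y per row (0 in the vertical-sheet limit)."""
        if abs(self.tilt_theta - 90.0) < 1e-9:
            return 0.0
        return self.row_dz / math.tan(self.theta_rad)

    @property
    def sheet_sigma(self) -> float:
        return self.sheet_fwhm * _FWHM_TO_SIGMA

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel: px_x × (row pitch along the plane)."""
        return self.px_x * self.row_dz / math.sin(self.theta_rad)

    @property
    def z_coverage(self) -> float:
        return self.n_rows * self.row_dz

    @property
    def normal(self) -> np.ndarray:
        th = self.theta_rad
        return np.array([0.0, math.sin(th), math.cos(th)])

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tilt_theta", "sheet_fwhm", "lateral_psf_fwhm", "px_x", "row_dz",
            "n_rows", "n_cols", "frame_rate_f", "origin_x", "origin_z",
            "gain", "offset", "read_noise_sd")}


@dataclass
class FrameStack:
    """Diagonal stack of oblique frames: ``data[frame, row, col, channel]``."""

    data: np.ndarray
    channels: tuple[str, ...]
    t0: float
    frame_rate: float
    optics: OpticsConfig
    motion: float  # cell speed assumed for reconstruction, um/s

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channels.index(name)]

    def save(self, base_path: str | Path) -> list[Path]:
        base = Path(base_path)
        base.parent.mkdir(parents=True, exist_ok=True)
        written = []
        for ci, ch in enumerate(self.channels):
            p = base.with_name(f"{base.stem}_{ch}.tif")
            tifffile.imwrite(p, self.data[..., ci].astype(np.float32),
                             photometric="minisblack")
            written.append(p)
        sidecar = {
            "channels": list(self.channels),
            "t0": self.t0,
            "frame_rate": self.frame_rate,
            "motion_um_per_s": self.motion,
            "optics": self.optics.to_dict(),
        }
        meta = base.with_suffix(".json")
        meta.write_text(json.dumps(sidecar, indent=2))
        written.append(meta)
        return written

    @classmethod
    def load(cls, base_path: str | Path) -> "FrameStack":
        base = Path(base_path)
        meta = json.loads(base.with_suffix(".json").read_text())
        chans = tuple(meta["channels"])
        data = np.stack(
            [tifffile.imread(base.with_name(f"{base.stem}_{ch}.tif")) for ch in chans],
            axis=-1,
        )
        return cls(data=data, channels=chans, t0=meta["t0"],
                   frame_rate=meta["frame_rate"], optics=OpticsConfig(**meta["optics"]),
                   motion=meta["motion_um_per_s"])


def plane_coords(row: int, col: int, optics: OpticsConfig) -> tuple[float, float, float]:
    """(x, y_offset, z) of a pixel centre.  ``y_offset`` is the magnitude of
    the in-plane shear; the plane physically lies at lab y = −y_offset."""
    if not (0 <= row < optics.n_rows and 0 <= col < optics.n_cols):
        raise ValueError("pixel index outside the sensor ROI")
    return (col * optics.px_x, row * optics.row_dy, row * optics.row_dz)


def _render_frame(cells, positions, optics: OpticsConfig, channels) -> np.ndarray:
    """Noise-free expected photon counts, shape (rows, cols, nc)."""
    nr, nc_px = optics.n_rows, optics.n_cols
    photons = np.zeros((nr, nc_px, len(channels)), dtype=np.float64)
    if not cells:
        return photons

    th = optics.theta_rad
    normal = optics.normal
    sigma = optics.sheet_sigma
    nodes, weights = np.polynomial.hermite.hermgauss(_GH_ORDER)
    s_scale = sigma * math.sqrt(2.0)
    reach_pad = s_scale * nodes.max() + 1.0

    rows = np.arange(nr)
    row_y = -rows * optics.row_dy
    row_z = optics.origin_z + rows * optics.row_dz

    for cell, center in zip(cells, positions):
        cell = replace_center(cell, center)
        for ci, ch in enumerate(channels):
            R = cell_support_radius(cell, ch)
            if cell.budgets.get(ch, 0.0) <= 0:
                continue
            # distance from the cell centre to each row's sampling segment
            dy = center[1] - row_y
            dz = center[2] - row_z
            # in-plane (row-direction) and normal components
            s0 = dy * normal[1] + dz * normal[2]
            tau = -dy * math.cos(th) + dz * math.sin(th)
            active = (np.abs(s0) <= R + reach_pad) & (np.abs(tau) <= R + 1.0)
            r_idx = rows[active]
            if r_idx.size == 0:
                continue
            cx = center[0] - optics.origin_x
            c_lo = max(0, int(math.floor((cx - R - 1.0) / optics.px_x)))
            c_hi = min(nc_px, int(math.ceil((cx + R + 1.0) / optics.px_x)) + 1)
            if c_hi <= c_lo:
                continue
            c_idx = np.arange(c_lo, c_hi)
            px = optics.origin_x + c_idx * optics.px_x
            py = row_y[r_idx]
            pz = row_z[r_idx]
            # sample points: (rows, cols, K, 3)
            base = np.empty((r_idx.size, c_idx.size, 3))
            base[..., 0] = px[None, :]
            base[..., 1] = py[:, None]
            base[..., 2] = pz[:, None]
            acc = np.zeros((r_idx.size, c_idx.size))
            for u, wgt in zip(nodes, weights):
                pts = base + (s_scale * u) * normal
                acc += wgt * emission_density(cell, pts.reshape(-1, 3), ch).reshape(acc.shape)
            # ∫ exp(-s²/2σ²) ρ ds = σ√2 Σ w_k ρ(σ√2 u_k)
            photons[np.ix_(r_idx, c_idx, [ci])] += (acc * s_scale * optics.pixel_area)[..., None]
    return photons


def replace_center(cell: CellSpec, center) -> CellSpec:
    if np.array_equal(cell.center, center):
        return cell
    return CellSpec(id=cell.id, center=np.asarray(center, float),
                    cell_radius=cell.cell_radius, phase=cell.phase,
                    orientation=cell.orientation, budgets=cell.budgets,
                    nucleus_params=cell.nucleus_params, partner_id=cell.partner_id)


def _camera(photons: np.ndarray, optics: OpticsConfig, rng: np.random.Generator | None) -> np.ndarray:
    """In-plane PSF blur, then gain/offset and (optionally) noise."""
    sig_px = optics.lateral_psf_fwhm * _FWHM_TO_SIGMA
    sigmas = (sig_px / (optics.row_dz / math.sin(optics.theta_rad)), sig_px / optics.px_x)
    out = np.empty_like(photons)
    for ci in range(photons.shape[-1]):
        out[..., ci] = gaussian_filter(photons[..., ci], sigmas)
    if rng is None:
        counts = optics.gain * out + optics.offset
    else:
        counts = (optics.gain * rng.poisson(np.clip(out, 0, None)).astype(np.float64)
                  + optics.offset
                  + rng.normal(0.0, optics.read_noise_sd, size=out.shape))
    return counts.astype(np.float32)


def acquire_frame(
    pop: ScenePopulation,
    optics: OpticsConfig,
    channels=("cyto", "dna"),
    t: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One oblique frame of the population advected to time ``t``."""
    channels = tuple(channels)
    positions = advected_positions(pop, t) if pop.kinematics is not None else pop.positions
    photons = _render_frame(pop.cells, positions, optics, channels)
    return _camera(photons, optics, rng)


def acquire_stack(
    pop: ScenePopulation,
    optics: OpticsConfig,
    n_frames: int,
    channels=("cyto", "dna"),
    seed: int | None = 0,
    t0: float = 0.0,
) -> FrameStack:
    """Acquire ``n_frames`` consecutive oblique frames while cells flow.

    A cell of diameter D at speed v stays in the sheet for about
    (D + sheet_fwhm)·f/v consecutive frames.  ``seed=None`` disables noise.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if pop.kinematics is None:
        raise ValueError("population needs kinematics (apply_focusing) first")
    channels = tuple(channels)
    rng = None if seed is None else np.random.default_rng(seed)
    f = optics.frame_rate_f

    speeds = pop.kinematics.speed_u
    motion = float(np.mean(speeds)) if len(pop) else 0.0

    # precompute, per cell, the frame interval during which it can touch the
    # sheet: the sheet spans lab y in [-(n_rows-1)·row_dy, 0] plus reach
    active_lists: list[list[int]] = [[] for _ in range(n_frames)]
    pad = 0.0
    if len(pop):
        reach = np.array([c.cell_radius for c in pop.cells]) + 3.0 * optics.sheet_sigma + 1.0
        pad = reach / np.sin(optics.theta_rad)
        y0 = pop.positions[:, 1] - speeds * t0
        y_lo = -(optics.n_rows - 1) * optics.row_dy - pad
        y_hi = pad
        with np.errstate(divide="ignore", invalid="ignore"):
            n_start = np.where(speeds > 0, (y0 - y_hi) * f / speeds, 0.0)
            n_stop = np.where(speeds > 0, (y0 - y_lo) * f / speeds, n_frames - 1.0)
        n_start = np.clip(np.floor(n_start), 0, n_frames).astype(int)
        n_stop = np.clip(np.ceil(n_stop) + 1, 0, n_frames).astype(int)
        for i in range(len(pop)):
            for fr in range(n_start[i], n_stop[i]):
                active_lists[fr].append(i)

    data = np.empty((n_frames, optics.n_rows, optics.n_cols, len(channels)), dtype=np.float32)
    cells = pop.cells
    base_pos = pop.positions
    for fr in range(n_frames):
        t = t0 + fr / f
        idx = active_lists[fr]
        pos = base_pos[idx].copy()
        pos[:, 1] -= speeds[idx] * t
        photons = _render_frame([cells[i] for i in idx], pos, optics, channels)
        data[fr] = _camera(photons, optics, rng)

    return FrameStack(data=data, channels=channels, t0=t0,
                      frame_rate=f, optics=optics, motion=motion)


def transit_sampling_factor(optics: OpticsConfig, v: float) -> float:
    """Expected (background-subtracted stack sum) / (gain × photon budget)
    for one complete cell transit: σ_sheet √(2π) · f / (v · sin θ)."""
    if v <= 0:
        raise ValueError("v must be positive")
    return (optics.sheet_sigma * math.sqrt(2.0 * math.pi) * optics.frame_rate_f
            / (v * math.sin(optics.theta_rad)))


# ---------------------------------------------------------------------------
# Lateral-plane widefield movies (velocity-tracking input)


@dataclass(frozen=True)
class MovieConfig:
    """Widefield lateral (xy) movie for particle velocimetry; 44 fps default
    matches a 10×-objective CMOS setup."""

    frame_rate: float = 44.0   # frames/s
    px: float = 1.0            # um per pixel
    nx: int = 512
    ny: int = 512
    origin_x: float = 0.0
    origin_y: float = 0.0
    psf_fwhm: float = 2.0      # um
    gain: float = 1.0
    offset: float = 100.0
    read_noise_sd: float = 2.0
    #: fraction of each cell's cyto budget collected per frame
    collection: float = 0.05


def acquire_lateral_movie(
    pop: ScenePopulation,
    movie: MovieConfig,
    n_frames: int,
    channel: str = "cyto",
    seed: int | None = 0,
    t0: float = 0.0,
) -> np.ndarray:
    """Render an (n_frames, ny, nx) widefield movie of the flowing cells.

    Each cell appears as its z-projected column density (a disk profile),
    blurred by the widefield PSF; same Poisson + read-noise camera model as
    the oblique path.
    """
    if pop.kinematics is None:
        raise ValueError("population needs kinematics (apply_focusing) first")
    rng = None if seed is None else np.random.default_rng(seed)
    frames = np.empty((n_frames, movie.ny, movie.nx), dtype=np.float32)
    sig_px = movie.psf_fwhm * _FWHM_TO_SIGMA / movie.px
    speeds = pop.kinematics.speed_u

    for fr in range(n_frames):
        t = t0 + fr / movie.frame_rate
        img = np.zeros((movie.ny, movie.nx))
        pos = pop.positions.copy()
        if len(pop):
            pos[:, 1] -= speeds * t
        for cell, p in zip(pop.cells, pos):
            flux = movie.collection * cell.budgets.get(channel, 0.0)
            if flux <= 0:
                continue
            R = cell.cell_radius
            jc = (p[0] - movie.origin_x) / movie.px
            ic = (p[1] - movie.origin_y) / movie.px
            rad = int(math.ceil(R / movie.px)) + 1
            j0, j1 = int(jc) - rad, int(jc) + rad + 1
            i0, i1 = int(ic) - rad, int(ic) + rad + 1
            if j1 <= 0 or i1 <= 0 or j0 >= movie.nx or i0 >= movie.ny:
                continue
            j0, j1 = max(j0, 0), min(j1, movie.nx)
            i0, i1 = max(i0, 0), min(i1, movie.ny)
            jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
            d2 = ((jj - jc) ** 2 + (ii - ic) ** 2) * movie.px ** 2
            # column density of a uniform sphere: 2√(R²−ρ²)·ρ0, normalised
            col = np.sqrt(np.clip(R ** 2 - d2, 0.0, None))
            dens = flux * 3.0 / (2.0 * np.pi * R ** 3) * col * movie.px ** 2
            img[i0:i1, j0:j1] += dens
        img = gaussian_filter(img, sig_px)
        if rng is None:
            frames[fr] = (movie.gain * img + movie.offset).astype(np.float32)
        else:
            frames[fr] = (movie.gain * rng.poisson(np.clip(img, 0, None)).astype(float)
                          + movie.offset
                          + rng.normal(0.0, movie.read_noise_sd, img.shape)).astype(np.float32)
    return frames


def save_movie(frames: np.ndarray, movie: MovieConfig, base_path: str | Path) -> list[Path]:
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    tif = base.with_suffix(".tif")
    tifffile.imwrite(tif, frames.astype(np.float32), photometric="minisblack")
    meta = base.with_suffix(".json")
    meta.write_text(json.dumps({
        "frame_rate": movie.frame_rate, "px_um": movie.px,
        "origin_um": [movie.origin_x, movie.origin_y],
    }, indent=2))
    return [tif, meta]
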