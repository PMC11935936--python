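"""Synthetic populations of fluorescent cells and ground-truth phantoms.

A :class:`ScenePopulation` is the simulator's ground truth: every cell has a
position inside the channel, a size, a mitotic-phase label with a
phase-specific nuclear geometry, a 3D orientation, and per-channel photon
budgets for the three simulated stains (cytoplasmic dye, DNA dye, and a
mitosis-specific marker).  :func:`emission_density` evaluates the resulting
fluorophore density at arbitrary points, and :func:`voxelize` integrates it
onto a Cartesian grid to produce noise-free phantoms used as oracles by the
reconstruction and analysis tests.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry
from .volume import Volume

CHANNELS = ("cyto", "dna", "mitotic_marker")


class PhaseLabel(str, enum.Enum):
    INTERPHASE = "interphase"
    PROPHASE = "prophase"
    METAPHASE = "metaphase"
    ANAPHASE = "anaphase"
    TELOPHASE = "telophase"


PHASE_ORDER = (
    PhaseLabel.INTERPHASE,
    PhaseLabel.PROPHASE,
    PhaseLabel.METAPHASE,
    PhaseLabel.ANAPHASE,
    PhaseLabel.TELOPHASE,
)

MITOTIC_PHASES = frozenset(
    {PhaseLabel.PROPHASE, PhaseLabel.METAPHASE, PhaseLabel.ANAPHASE, PhaseLabel.TELOPHASE}
)

#: Default mitotic-phase composition.  The mitotic fraction (~4%) is a
#: plausible value for an unsynchronised proliferating culture; the split
#: between mitotic phases follows their relative durations (prophase longest,
#: anaphase shortest).
DEFAULT_PHASE_FRACTIONS = {
    PhaseLabel.INTERPHASE: 0.960,
    PhaseLabel.PROPHASE: 0.027,
    PhaseLabel.METAPHASE: 0.008,
    PhaseLabel.ANAPHASE: 0.002,
    PhaseLabel.TELOPHASE: 0.003,
}

#: Mean photon budgets per channel.  The marker budget is bimodal: interphase
#: cells carry only nonspecific background binding, mitotic cells are bright.
DEFAULT_BUDGETS = {"cyto": 2.0e4, "dna": 1.0e4}
MARKER_BUDGET_NEGATIVE = 150.0
MARKER_BUDGET_MITOTIC = 6.0e3

#: Nuclear geometry defaults (fractions of cell radius / nuclear radius).
NUCLEUS_DEFAULTS = {
    "r_n_frac": 0.6,        # nuclear radius / cell radius (interphase)
    "prophase_shrink": 0.8,  # condensed-chromatin sphere radius / r_n
    "metaphase_c_over_a": 0.35,  # oblate metaphase plate flattening
    "anaphase_sep_frac": 2.0,    # spot-centre separation / r_n
    "anaphase_spot_a_frac": 0.7,  # anaphase spot in-plane semi-axis / r_n
    "anaphase_spot_c_over_a": 0.5,
}

#: Telophase partner-pair centre separation, in units of cell diameter.
TELOPHASE_PAIR_SEP_DIAMETERS = 1.2

#: Minimum lateral (x, y) centre separation between sampled cells, in units of
#: mean cell diameter.  Lateral spacing is what matters because acoustic
#: focusing later collapses the z coordinate onto the mid-plane node.
MIN_SEPARATION_DIAMETERS = 0.8


@dataclass
class CellSpec:
    """Ground truth for a single cell."""

    id: int
    center: np.ndarray            # (3,) um, lab frame (x, y, z)
    cell_radius: float            # um
    phase: PhaseLabel
    orientation: np.ndarray       # unit quaternion, scalar-last (x, y, z, w)
    budgets: dict[str, float]     # photons per channel
    nucleus_params: dict[str, float] = field(default_factory=lambda: dict(NUCLEUS_DEFAULTS))
    partner_id: int | None = None

    @property
    def nuclear_radius(self) -> float:
        return self.nucleus_params["r_n_frac"] * self.cell_radius

    def rotation_matrix(self) -> np.ndarray:
        return _quat_to_matrix(self.orientation)

    @property
    def spindle_axis(self) -> np.ndarray:
        """Unit vector of the cell's symmetry / spindle axis (rotated +z)."""
        return self.rotation_matrix()[:, 2]


@dataclass
class KinematicState:
    """Per-cell flow kinematics (parallel arrays, one entry per cell)."""

    z: np.ndarray          # um
    speed_u: np.ndarray    # um/s, magnitude of the −y velocity
    spin_omega: np.ndarray  # rad/s, tumbling about the x axis


@dataclass
class ScenePopulation:
    cells: list[CellSpec]
    geometry: ChannelGeometry
    concentration: float   # cells per mL of the simulated channel segment
    seed: int
    kinematics: KinematicState | None = None

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 3))
        return np.stack([c.center for c in self.cells])

    def set_positions(self, pos: np.ndarray) -> None:
        for cell, p in zip(self.cells, pos):
            cell.center = np.asarray(p, dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([c.cell_radius for c in self.cells])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cells):
            row = {
                "id": c.id,
                "x": c.center[0], "y": c.center[1], "z": c.center[2],
                "radius": c.cell_radius,
                "phase": c.phase.value,
                "qx": c.orientation[0], "qy": c.orientation[1],
                "qz": c.orientation[2], "qw": c.orientation[3],
                "budget_cyto": c.budgets["cyto"],
                "budget_dna": c.budgets["dna"],
                "budget_mitotic_marker": c.budgets["mitotic_marker"],
                "partner_id": -1 if c.partner_id is None else c.partner_id,
            }
            if self.kinematics is not None:
                row["kin_z"] = self.kinematics.z[i]
                row["speed_u"] = self.kinematics.speed_u[i]
                row["spin_omega"] = self.kinematics.spin_omega[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, csv_path: str | Path) -> None:
        """Write the population CSV plus a JSON sidecar (geometry + seed)."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "geometry": {
                "height_h": self.geometry.height_h,
                "width_w": self.geometry.width_w,
                "length_l": self.geometry.length_l,
            },
            "concentration_per_ml": self.concentration,
            "seed": self.seed,
            "n_cells": len(self.cells),
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "ScenePopulation":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        df = pd.read_csv(csv_path)
        geometry = ChannelGeometry(**meta["geometry"])
        cells = []
        for _, r in df.iterrows():
            cells.append(CellSpec(
                id=int(r["id"]),
                center=np.array([r["x"], r["y"], r["z"]]),
                cell_radius=float(r["radius"]),
                phase=PhaseLabel(r["phase"]),
                orientation=np.array([r["qx"], r["qy"], r["qz"], r["qw"]]),
                budgets={
                    "cyto": float(r["budget_cyto"]),
                    "dna": float(r["budget_dna"]),
                    "mitotic_marker": float(r["budget_mitotic_marker"]),
                },
                partner_id=None if int(r["partner_id"]) < 0 else int(r["partner_id"]),
            ))
        pop = cls(cells=cells, geometry=geometry,
                  concentration=meta["concentration_per_ml"], seed=meta["seed"])
        if "speed_u" in df.columns:
            pop.kinematics = KinematicState(
                z=df["kin_z"].to_numpy(float),
                speed_u=df["speed_u"].to_numpy(float),
                spin_omega=df["spin_omega"].to_numpy(float),
            )
        return pop


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = np.asarray(q, dtype=float) / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def random_unit_quaternions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform samples from SO(3) via normalised 4D Gaussians (scalar-last)."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def _normalize_fractions(phase_fractions) -> np.ndarray:
    if phase_fractions is None:
        phase_fractions = DEFAULT_PHASE_FRACTIONS
    p = np.array([float(phase_fractions.get(ph, 0.0)) for ph in PHASE_ORDER])
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("phase fractions must be nonnegative and sum to 1")
    unknown = set(phase_fractions) - {ph for ph in PHASE_ORDER} - {ph.value for ph in PHASE_ORDER}
    if unknown:
        raise ValueError(f"unknown phase labels: {unknown}")
    return p


def draw_phase_counts(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    """One multinomial draw of per-phase counts, with the parity rule that an
    odd telophase count is decremented (the odd cell becomes interphase) so
    telophase cells always pair up."""
    counts = rng.multinomial(n, p)
    if counts[-1] % 2 == 1:
        counts[-1] -= 1
        counts[0] += 1
    return counts


def sample_population(
    n: int,
    geometry: ChannelGeometry | None = None,
    phase_fractions=None,
    size_distribution: tuple[float, float] = (10.0, 1.0),
    seed: int = 0,
) -> ScenePopulation:
    """Sample ``n`` cells uniformly in the channel interior.

    ``size_distribution`` is the (mean, sd) of the cell *diameter* in μm.
    Positions avoid the side-wall margin and keep a minimum lateral centre
    separation of 0.8 cell diameters so that downstream watershed splitting
    remains well-posed after acoustic focusing flattens the population in z.
    Telophase draws are emitted as mutual partner pairs separated by
    1.2 cell diameters.  Fully deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    geometry = geometry or ChannelGeometry()
    p = _normalize_fractions(phase_fractions)
    mean_d, sd_d = size_distribution
    rng = np.random.default_rng(seed)

    if n == 0:
        return ScenePopulation([], geometry, 0.0, seed)

    counts = draw_phase_counts(rng, n, p)
    phases = np.repeat(np.arange(len(PHASE_ORDER)), counts)
    phases = phases[rng.permutation(n)]

    min_sep = MIN_SEPARATION_DIAMETERS * mean_d
    positions, radii = _sample_positions(rng, n, geometry,
                                         (mean_d, sd_d), min_sep)

    quats = random_unit_quaternions(rng, n)

    budget_scatter = rng.lognormal(mean=0.0, sigma=0.1, size=(n, 3))
    is_mitotic = np.array([PHASE_ORDER[i] in MITOTIC_PHASES for i in phases])
    marker_mean = np.where(is_mitotic, MARKER_BUDGET_MITOTIC, MARKER_BUDGET_NEGATIVE)

    cells: list[CellSpec] = []
    for i in range(n):
        cells.append(CellSpec(
            id=i,
            center=positions[i].copy(),
            cell_radius=float(radii[i]),
            phase=PHASE_ORDER[phases[i]],
            orientation=quats[i],
            budgets={
                "cyto": DEFAULT_BUDGETS["cyto"] * budget_scatter[i, 0],
                "dna": DEFAULT_BUDGETS["dna"] * budget_scatter[i, 1],
                "mitotic_marker": float(marker_mean[i] * budget_scatter[i, 2]),
            },
        ))

    _pair_telophase(rng, cells, geometry, mean_d)

    concentration = n / geometry.segment_volume_ml
    return ScenePopulation(cells, geometry, concentration, seed)


def _sample_positions(rng, n, geometry: ChannelGeometry, size_distribution,
                      min_sep) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing with a minimum lateral centre separation; each candidate
    carries its own radius so position bounds always match the cell size."""
    h, w, L = geometry.height_h, geometry.width_w, geometry.length_l
    mean_d, sd_d = size_distribution
    margin = geometry.side_margin
    accepted = np.empty((n, 3))
    acc_radii = np.empty(n)
    count = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while count < n:
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place cells at the requested density with the "
                "minimum-separation constraint; lower n or enlarge the segment"
            )
        m = n - count
        r = np.clip(rng.normal(mean_d, sd_d, size=m), 0.2 * mean_d, None) / 2.0
        cand = np.column_stack([
            rng.uniform(margin + r, w - margin - r),
            rng.uniform(0.0, L, size=m),
            rng.uniform(r, h - r),
        ])
        for ci, c in enumerate(cand):  # greedy acceptance, lateral separation
            if count:
                d2 = np.sum((accepted[:count, :2] - c[:2]) ** 2, axis=1)
                if d2.min() < min_sep ** 2:
                    continue
            accepted[count] = c
            acc_radii[count] = r[ci]
            count += 1
        attempts += 1
    return accepted, acc_radii


def _pair_telophase(rng, cells: list[CellSpec], geometry: ChannelGeometry, mean_d: float) -> None:
    telo = [c for c in cells if c.phase is PhaseLabel.TELOPHASE]
    sep = TELOPHASE_PAIR_SEP_DIAMETERS * mean_d
    for a, b in zip(telo[::2], telo[1::2]):
        z_lo, z_hi = b.cell_radius, geometry.height_h - b.cell_radius
        x_lo = geometry.side_margin + b.cell_radius
        x_hi = geometry.width_w - geometry.side_margin - b.cell_radius
        # redraw the pair direction until the partner stays inside the channel
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = a.center + sep * direction
            if z_lo <= cand[2] <= z_hi and x_lo <= cand[0] <= x_hi:
                break
        b.center = cand
        a.partner_id, b.partner_id = b.id, a.id
        # partners share the division axis
        b.orientation = a.orientation.copy()


# ---------------------------------------------------------------------------
# Emission model


def _ellipsoid_density(points, center, semi_axes, rotation, total) -> np.ndarray:
    """Uniform density inside a rotated ellipsoid integrating to ``total``."""
    a, b, c = semi_axes
    local = (points - center) @ rotation  # rotate into the ellipsoid frame
    inside = (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 + (local[:, 2] / c) ** 2 <= 1.0
    rho = total / (4.0 / 3.0 * np.pi * a * b * c)
    return np.where(inside, rho, 0.0)


def _sphere_density(points, center, radius, total) -> np.ndarray:
    d2 = np.sum((points - center) ** 2, axis=1)
    rho = total / (4.0 / 3.0 * np.pi * radius ** 3)
    return np.where(d2 <= radius ** 2, rho, 0.0)


def emission_density(cell: CellSpec, points: np.ndarray, channel: str) -> np.ndarray:
    """Photon emission density (photons / μm³) of ``cell`` at ``points``.

    DNA-channel geometry encodes the mitotic phase: interphase nucleus,
    condensed prophase sphere, oblate metaphase plate, two separating
    anaphase masses along the spindle axis, and a prophase-like nucleus for
    each telophase partner.  Points outside every structure return 0.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    budget = cell.budgets.get(channel, 0.0)
    if budget <= 0:
        return np.zeros(len(points))

    if channel == "cyto" or channel == "mitotic_marker":
        # whole-cell stain (CFSE-like); the marker antibody is likewise
        # distributed through the cell, only its budget is phase-dependent
        return _sphere_density(points, cell.center, cell.cell_radius, budget)

    # DNA channel
    npar = cell.nucleus_params
    r_n = cell.nuclear_radius
    R = cell.rotation_matrix()
    phase = cell.phase
    if phase is PhaseLabel.INTERPHASE:
        return _sphere_density(points, cell.center, r_n, budget)
    if phase is PhaseLabel.PROPHASE or phase is PhaseLabel.TELOPHASE:
        return _sphere_density(points, cell.center, npar["prophase_shrink"] * r_n, budget)
    if phase is PhaseLabel.METAPHASE:
        a = r_n
        c = npar["metaphase_c_over_a"] * a
        return _ellipsoid_density(points, cell.center, (a, a, c), R, budget)
    if phase is PhaseLabel.ANAPHASE:
        axis = R[:, 2]
        d = npar["anaphase_sep_frac"] * r_n
        a = npar["anaphase_spot_a_frac"] * r_n
        c = npar["anaphase_spot_c_over_a"] * a
        rho = _ellipsoid_density(points, cell.center + 0.5 * d * axis, (a, a, c), R, budget / 2)
        rho += _ellipsoid_density(points, cell.center - 0.5 * d * axis, (a, a, c), R, budget / 2)
        return rho
    raise AssertionError(f"unhandled phase {phase}")


def cell_support_radius(cell: CellSpec, channel: str) -> float:
    """Radius of a sphere around the cell centre containing all emission."""
    if channel != "dna":
        return cell.cell_radius
    npar = cell.nucleus_params
    r_n = cell.nuclear_radius
    if cell.phase is PhaseLabel.ANAPHASE:
        return 0.5 * npar["anaphase_sep_frac"] * r_n + npar["anaphase_spot_a_frac"] * r_n
    return r_n


def voxelize(
    scene: ScenePopulation,
    voxel_size: Sequence[float],
    bbox: Sequence[Sequence[float]],
    channels: Iterable[str] = ("cyto", "dna"),
    supersample: int = 2,
) -> Volume:
    """Integrate the scene's emission density on a Cartesian grid.

    ``voxel_size`` is (vx, vy, vz) in μm and ``bbox`` is
    ((x0, x1), (y0, y1), (z0, z1)).  Each voxel value is the emission density
    integrated over the voxel (photons), estimated by ``supersample``³
    midpoint samples.  Noise-free.
    """
    vx, vy, vz = (float(v) for v in voxel_size)
    if min(vx, vy, vz) <= 0:
        raise ValueError("voxel sizes must be positive")
    (x0, x1), (y0, y1), (z0, z1) = [tuple(map(float, b)) for b in bbox]
    geo = scene.geometry
    if z0 < -1e-9 or z1 > geo.height_h + 1e-9 or x0 < -1e-9 or x1 > geo.width_w + 1e-9:
        raise ValueError("bbox extends outside the channel cross-section")

    channels = tuple(channels)
    nx = max(1, int(round((x1 - x0) / vx)))
    ny = max(1, int(round((y1 - y0) / vy)))
    nz = max(1, int(round((z1 - z0) / vz)))
    data = np.zeros((nz, ny, nx, len(channels)), dtype=np.float32)
    origin = np.array([x0, y0, z0])
    voxel = np.array([vx, vy, vz])
    vol_um3 = vx * vy * vz

    s = int(supersample)
    # midpoint offsets of the s^3 sub-samples inside one voxel, in voxel units
    offs = (np.arange(s) + 0.5) / s
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)

    for cell in scene.cells:
        for ci, ch in enumerate(channels):
            reach = cell_support_radius(cell, ch)
            lo = cell.center - reach - voxel
            hi = cell.center + reach + voxel
            i0 = np.maximum(np.floor((lo - origin) / voxel), 0).astype(int)
            i1 = np.minimum(np.ceil((hi - origin) / voxel), [nx, ny, nz]).astype(int)
            if np.any(i1 <= i0):
                continue
            ix = np.arange(i0[0], i1[0])
            iy = np.arange(i0[1], i1[1])
            iz = np.arange(i0[2], i1[2])
            gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
            base = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
            acc = np.zeros(len(base))
            for off in sub:
                pts = origin + (base + off) * voxel
                acc += emission_density(cell, pts, ch)
            vals = acc / len(sub) * vol_um3
            data[gz.ravel(), gy.ravel(), gx.ravel(), ci] += vals.astype(np.float32)

    return Volume(data=data, channels=channels, voxel=(vx, vy, vz), origin=(x0, y0, z0))
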