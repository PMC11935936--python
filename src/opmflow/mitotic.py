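"""Mitotic-phase morphometry and classification.

Workflow on segmented cells: gate marker-positive cells from their
integrated marker intensity (threshold or polygon over log marker vs log DNA
intensity) → count connected DNA-stained regions inside each positive cell →
principal-axes analysis (intensity-weighted PCA of voxel coordinates in
physical μm) of single regions → decision tree:

* clipped cell → omitted;
* two DNA regions → anaphase (separated chromosome masses);
* two adjacent positive cells that are mutual nearest positives → telophase
  pair;
* remaining single-region cells: 3D aspect ratio ≤ τ → metaphase (flat
  plate), otherwise prophase (condensed but round).

The 3D aspect ratio is the shortest principal axis divided by the mean of
the other two; the 2D aspect ratio is the shorter/longer axis of the
xy-projected region's 2D PCA, emulating what a lateral-only (2D) imaging
flow cytometer would measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .scene import PhaseLabel
from .segment import CellRecord
from .volume import Volume

#: Full axis length of the uniform ellipsoid with coordinate variance λ along
#: a principal direction: a uniform ellipsoid of semi-axis a has variance
#: a²/5, so a = √5·√λ ≈ 2.24√λ and L = 2a.  We use the convention L = 4√λ;
#: every statistic in this module is a ratio of axis lengths, so the constant
#: cancels and only sorted-√λ ratios matter.
AXIS_LENGTH_FACTOR = 4.0


@dataclass(frozen=True)
class Gate:
    """Marker-positivity gate: intensity threshold or polygon in
    (log10 marker, log10 DNA) space."""

    marker_threshold: float | None = None
    polygon: np.ndarray | None = None  # (N, 2) vertices in log10 space

    def __post_init__(self) -> None:
        if self.marker_threshold is None and self.polygon is None:
            raise ValueError("gate needs a threshold or a polygon")
        if self.marker_threshold is not None and self.marker_threshold < 0:
            raise ValueError("marker threshold must be >= 0")


def gate_positive(
    records: list[CellRecord],
    gate: Gate,
    marker_channel: str = "mitotic_marker",
    dna_channel: str = "dna",
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Split records into marker-positive cells and a scatter table."""
    marker = np.array([r.intensities.get(marker_channel, 0.0) for r in records])
    dna = np.array([r.intensities.get(dna_channel, 0.0) for r in records])
    if gate.polygon is not None:
        import shapely
        from shapely.geometry import Polygon
        poly = Polygon(gate.polygon)
        with np.errstate(divide="ignore"):
            lx = np.log10(np.clip(marker, 1e-12, None))
            ly = np.log10(np.clip(dna, 1e-12, None))
        positive = shapely.contains_xy(poly, lx, ly)
    else:
        positive = marker > gate.marker_threshold
    scatter = pd.DataFrame({
        "label": [r.label for r in records],
        "marker_intensity": marker,
        "dna_intensity": dna,
        "positive": positive,
    })
    return [r for r, p in zip(records, positive) if p], scatter


@dataclass
class DnaRegion:
    coords_um: np.ndarray    # (N, 3) lab-frame voxel centres, um
    intensities: np.ndarray  # (N,)
    n_voxels: int

    @property
    def centroid(self) -> np.ndarray:
        w = self.intensities / self.intensities.sum()
        return (self.coords_um * w[:, None]).sum(axis=0)


def count_dna_regions(
    record: CellRecord,
    labels: np.ndarray,
    volume: Volume,
    dna_channel: str = "dna",
    region_threshold: float | str = "half_max",
    min_region_volume: float = 2.0,
) -> list[DnaRegion]:
    """Connected DNA-stained regions inside one segmented cell.

    Thresholds the background-subtracted DNA intensity inside the cell's
    watershed mask (default: half the cell's peak), labels 26-connected
    components, and drops components smaller than ``min_region_volume`` μm³.
    """
    z0, y0, x0, z1, y1, x1 = record.bbox
    sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    cell_mask = labels[sl] == record.label
    dna = volume.channel(dna_channel)[sl].astype(np.float64)
    dna = dna - np.median(volume.channel(dna_channel))
    dna[~cell_mask] = 0.0
    dna = np.clip(dna, 0.0, None)
    if dna.max() <= 0:
        return []
    thr = 0.5 * dna.max() if region_threshold == "half_max" else float(region_threshold)
    fg = dna > thr
    comp, n = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return []
    voxel = np.array(volume.voxel)           # (vx, vy, vz)
    origin = np.asarray(volume.origin)
    out: list[DnaRegion] = []
    for lab in range(1, n + 1):
        zz, yy, xx = np.nonzero(comp == lab)
        vol = zz.size * volume.voxel_volume
        if vol < min_region_volume:
            continue
        idx = np.column_stack([xx + x0, yy + y0, zz + z0]).astype(float)
        coords = origin + idx * voxel
        out.append(DnaRegion(coords_um=coords,
                             intensities=dna[zz, yy, xx], n_voxels=zz.size))
    return out


@dataclass
class NuclearRegion:
    """Eigen-system of a DNA region's intensity-weighted coordinate
    covariance.  Eigenvalues are sorted descending (λ1 ≥ λ2 ≥ λ3, μm²);
    ``eigvecs[:, i]`` is the unit eigenvector of λ_{i+1}; axis lengths are
    L_i = 4√λ_i."""

    centroid: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    coords_um: np.ndarray
    weights: np.ndarray
    degenerate: bool = False

    @property
    def axis_lengths(self) -> np.ndarray:
        return AXIS_LENGTH_FACTOR * np.sqrt(np.clip(self.eigvals, 0.0, None))


def principal_axes(
    coords_um: np.ndarray,
    weights: np.ndarray | None = None,
) -> NuclearRegion:
    """Weighted PCA of region voxel coordinates (physical μm).

    Raises for regions with fewer than 4 voxels; flags ``degenerate`` when
    the region is effectively coplanar/collinear (λ3 ≈ 0).
    """
    coords = np.asarray(coords_um, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 4:
        raise ValueError("need at least 4 three-dimensional voxel coordinates")
    if weights is None:
        weights = np.ones(len(coords))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    mu = (coords * w[:, None]).sum(axis=0)
    d = coords - mu
    cov = (d * w[:, None]).T @ d
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    degenerate = vals[0] <= 0 or vals[2] / vals[0] < 1e-9
    return NuclearRegion(centroid=mu, eigvals=vals, eigvecs=vecs,
                         coords_um=coords, weights=w, degenerate=degenerate)


def region_axes(region: DnaRegion, weighted: bool = True) -> NuclearRegion:
    return principal_axes(region.coords_um,
                          region.intensities if weighted else None)


def aspect_ratio_3d(region: NuclearRegion) -> float:
    """Shortest axis over the mean of the other two: L3 / ((L1 + L2)/2)."""
    if region.degenerate:
        raise ValueError("degenerate region has no defined 3D aspect ratio")
    L = region.axis_lengths
    return float(L[2] / ((L[0] + L[1]) / 2.0))


def aspect_ratio_2d(region: NuclearRegion, projection_axis: str = "z") -> float:
    """Shorter/longer axis of the region projected along ``projection_axis``
    (intensity-weighted 2D PCA) — the lateral-only (2D-imaging) estimate."""
    ax = {"x": 0, "y": 1, "z": 2}[projection_axis]
    keep = [i for i in range(3) if i != ax]
    coords = region.coords_um[:, keep]
    w = region.weights
    mu = (coords * w[:, None]).sum(axis=0)
    d = coords - mu
    cov = (d * w[:, None]).T @ d
    vals = np.sort(np.linalg.eigvalsh(cov))
    if vals[1] <= 0:
        raise ValueError("degenerate projection")
    return float(np.sqrt(max(vals[0], 0.0) / vals[1]))


def rotate_to_principal(region: NuclearRegion, bin_size: float = 0.5):
    """Coordinates in the principal-axis frame plus 2D projections.

    Returns ``(rotated_coords, projections)`` where ``projections[i]`` is the
    intensity histogram of the region viewed along principal axis λ_{i+1}.
    """
    if region.degenerate:
        raise ValueError("degenerate region cannot be reoriented")
    rot = (region.coords_um - region.centroid) @ region.eigvecs
    projections = []
    for axis in range(3):
        keep = [i for i in range(3) if i != axis]
        pts = rot[:, keep]
        lo = pts.min(axis=0) - bin_size
        hi = pts.max(axis=0) + bin_size
        nb = np.maximum(((hi - lo) / bin_size).astype(int), 1)
        H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=nb,
                                 range=[[lo[0], hi[0]], [lo[1], hi[1]]],
                                 weights=region.weights)
        projections.append(H)
    return rot, projections


OMITTED_CLIPPED = "omitted_clipped"


@dataclass
class PhaseCall:
    label: int
    phase: str                     # PhaseLabel value or "omitted_clipped"
    n_regions: int
    ar3d: float | None = None
    ar2d: float | None = None
    partner_label: int | None = None


@dataclass(frozen=True)
class ClassifyParams:
    ratio_threshold: float = 0.6     # τ: metaphase if ar3d <= τ
    pair_distance: float | None = None  # um; None → 1.5 × median cell diameter


def classify_phase(
    positives: list[CellRecord],
    regions_by_label: dict[int, list[DnaRegion]],
    params: ClassifyParams = ClassifyParams(),
    weighted: bool = True,
) -> list[PhaseCall]:
    """Apply the phase decision tree to gated (marker-positive) cells."""
    calls: dict[int, PhaseCall] = {}
    usable: list[CellRecord] = []
    for rec in positives:
        regs = regions_by_label.get(rec.label, [])
        if rec.clipped:
            calls[rec.label] = PhaseCall(rec.label, OMITTED_CLIPPED, len(regs))
            continue
        if len(regs) >= 2:
            calls[rec.label] = PhaseCall(rec.label, PhaseLabel.ANAPHASE.value, len(regs))
            continue
        if not regs:
            calls[rec.label] = PhaseCall(rec.label, OMITTED_CLIPPED, 0)
            continue
        usable.append(rec)

    if params.pair_distance is None:
        diam = np.median([r.equivalent_diameter for r in positives]) if positives else 10.0
        pair_distance = 1.5 * float(diam)
    else:
        pair_distance = params.pair_distance

    # telophase: mutual nearest positive neighbours within the pair distance
    paired: set[int] = set()
    if len(usable) >= 2:
        cents = np.stack([r.centroid for r in usable])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        for i, rec in enumerate(usable):
            j = nearest[i]
            if nearest[j] == i and d[i, j] <= pair_distance and i < j:
                a, b = usable[i], usable[j]
                calls[a.label] = PhaseCall(a.label, PhaseLabel.TELOPHASE.value, 1,
                                           partner_label=b.label)
                calls[b.label] = PhaseCall(b.label, PhaseLabel.TELOPHASE.value, 1,
                                           partner_label=a.label)
                paired.update((i, j))

    for i, rec in enumerate(usable):
        if i in paired:
            continue
        region = region_axes(regions_by_label[rec.label][0], weighted=weighted)
        try:
            ar3 = aspect_ratio_3d(region)
            ar2 = aspect_ratio_2d(region)
        except ValueError:
            calls[rec.label] = PhaseCall(rec.label, OMITTED_CLIPPED, 1)
            continue
        phase = PhaseLabel.METAPHASE if ar3 <= params.ratio_threshold else PhaseLabel.PROPHASE
        calls[rec.label] = PhaseCall(rec.label, phase.value, 1, ar3d=ar3, ar2d=ar2)

    return [calls[rec.label] for rec in positives]


def population_report(
    calls: list[PhaseCall],
    records: list[CellRecord],
    duration: float,
    ar_bin_width: float = 0.05,
) -> dict:
    """Summary of one analysis run: phase counts, positives, throughput, and
    paired 3D/2D aspect-ratio histograms for single-region cells."""
    phase_counts = {ph.value: 0 for ph in PhaseLabel}
    phase_counts[OMITTED_CLIPPED] = 0
    for c in calls:
        phase_counts[c.phase] = phase_counts.get(c.phase, 0) + 1
    ar3 = np.array([c.ar3d for c in calls if c.ar3d is not None])
    ar2 = np.array([c.ar2d for c in calls if c.ar2d is not None])
    edges = np.arange(0.0, 1.0 + ar_bin_width, ar_bin_width)
    report = {
        "n_cells": len(records),
        "n_positive": len(calls),
        "throughput_cells_per_s": (len(records) / duration) if duration > 0 else 0.0,
        "phase_counts": phase_counts,
        "ar3d_mean": float(ar3.mean()) if ar3.size else None,
        "ar2d_mean": float(ar2.mean()) if ar2.size else None,
        "ar_hist_edges": edges.tolist(),
        "ar3d_hist": np.histogram(ar3, bins=edges)[0].tolist(),
        "ar2d_hist": np.histogram(ar2, bins=edges)[0].tolist(),
    }
    return report
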