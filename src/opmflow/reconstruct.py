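"""Deskew: diagonal oblique-frame stacks → Cartesian volumes.

During acquisition the flow translates cells through a stationary tilted
plane, so frame index is a proxy for the flow axis: sample (frame n, row r,
col c) saw the lab-frame point

    x = c · px_x,   z = r · row_dz,   y = flow_sign · n · frame_dy − r · row_dy

with frame_dy = v/f (the distance the flow advances per frame) and
row_dy = row_dz/tan θ (the in-plane shear of the tilted rows).  Because cells
move toward −y while the plane is sheared toward −y as well, this mapping
already reads in +y with ``flow_sign = +1``.  Deskewing is therefore a pure
shear: each z-slice of the output is the corresponding sensor row's
time-series shifted along y by a constant offset, which we evaluate by
inverse-mapped (gather) interpolation.  The output voxel grid is
(vx, vy, vz) = (px_x, frame_dy, row_dz) — deliberately anisotropic; all
morphometry downstream uses physical voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import FrameStack, OpticsConfig
from .volume import Volume


def frame_pitch(v: float, f: float) -> float:
    """Flow advance per frame Δy = v/f (μm)."""
    if f <= 0:
        raise ValueError("frame rate must be positive")
    return v / f


@dataclass(frozen=True)
class DeskewCalibration:
    px_x: float
    row_dz: float
    row_dy: float
    frame_dy: float
    flow_sign: int = 1
    interpolation: str = "linear"   # or "nearest"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_dy <= 0:
            raise ValueError("frame_dy must be positive; is the velocity zero?")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")
        if self.flow_sign not in (1, -1):
            raise ValueError("flow_sign must be ±1")

    @classmethod
    def from_optics(cls, optics: OpticsConfig, v: float, **kw) -> "DeskewCalibration":
        return cls(px_x=optics.px_x, row_dz=optics.row_dz, row_dy=optics.row_dy,
                   frame_dy=frame_pitch(v, optics.frame_rate_f), **kw)


def _check_consistent(stack: FrameStack, calib: DeskewCalibration, v_tolerance: float = 0.05):
    o = stack.optics
    if abs(o.px_x - calib.px_x) > 1e-9 or abs(o.row_dz - calib.row_dz) > 1e-9 \
            or abs(o.row_dy - calib.row_dy) > 1e-9:
        raise ValueError("calibration pitches disagree with the stack's optics")
    if stack.motion > 0:
        v_meta = stack.motion / stack.frame_rate
        if abs(calib.frame_dy - v_meta) / v_meta > v_tolerance:
            import warnings
            warnings.warn(
                "deskew velocity differs from stack metadata by more than "
                f"{v_tolerance:.0%}; reconstructed cells will be sheared",
                stacklevel=3,
            )


def deskew(stack: FrameStack, calib: DeskewCalibration) -> Volume:
    """Reconstruct a Cartesian :class:`Volume` from a diagonal stack.

    Output voxels outside the acquired wedge are set to ``calib.fill_value``
    and flagged False in ``volume.mask``.
    """
    _check_consistent(stack, calib)
    nf, nr, nc, nch = stack.data.shape
    fdy, rdy = calib.frame_dy, calib.row_dy

    y_min = -(nr - 1) * rdy
    y_max = (nf - 1) * fdy
    ny = int(np.floor((y_max - y_min) / fdy)) + 1

    data = np.full((nr, ny, nc, nch), calib.fill_value, dtype=np.float32)
    mask = np.zeros((nr, ny, nc), dtype=bool)
    iy = np.arange(ny)

    for iz in range(nr):
        # frame coordinate sampled by output row (iz, iy, :):
        # n = (y + iz*row_dy)/frame_dy with y = y_min + iy*frame_dy
        n_float = iy + (y_min + iz * rdy) / fdy
        if calib.interpolation == "nearest":
            n_idx = np.round(n_float).astype(int)
            valid = (n_idx >= 0) & (n_idx < nf)
            data[iz, valid] = stack.data[n_idx[valid], iz]
        else:
            n0 = np.floor(n_float).astype(int)
            w = (n_float - n0).astype(np.float32)
            valid = (n_float >= 0) & (n_float <= nf - 1)
            n0c = np.clip(n0, 0, nf - 1)
            n1c = np.clip(n0 + 1, 0, nf - 1)
            sl = (stack.data[n0c, iz] * (1.0 - w)[:, None, None]
                  + stack.data[n1c, iz] * w[:, None, None])
            data[iz, valid] = sl[valid]
        mask[iz, valid] = True

    if calib.flow_sign < 0:
        data = data[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    o = stack.optics
    return Volume(data=data, channels=stack.channels,
                  voxel=(calib.px_x, fdy, calib.row_dz),
                  origin=(o.origin_x, y_min, o.origin_z), mask=mask)


def reconstruct_two_channel(stacks: dict[str, FrameStack] | list[FrameStack],
                            calib: DeskewCalibration) -> Volume:
    """Deskew simultaneously acquired single-channel stacks (one per camera)
    into one multi-channel volume.  No registration: the cameras are
    hardware-synchronised, so the shear mapping is shared."""
    if isinstance(stacks, dict):
        stacks = list(stacks.values())
    if not stacks:
        raise ValueError("need at least one stack")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.data.shape[:3] != ref.data.shape[:3] or s.frame_rate != ref.frame_rate:
            raise ValueError("channel stacks must share shape and frame rate")
    vols = [deskew(s, calib) for s in stacks]
    data = np.concatenate([v.data for v in vols], axis=-1)
    channels = tuple(ch for v in vols for ch in v.channels)
    return Volume(data=data, channels=channels, voxel=vols[0].voxel,
                  origin=vols[0].origin, mask=vols[0].mask)


def isotropize(volume: Volume, voxel: float | None = None, order: int = 1) -> Volume:
    """Resample to cubic voxels (display convenience only; analysis always
    runs on the native anisotropic grid)."""
    from scipy.ndimage import zoom
    target = voxel or min(volume.voxel)
    vx, vy, vz = volume.voxel
    factors = (vz / target, vy / target, vx / target)
    out = np.stack(
        [zoom(volume.data[..., c], factors, order=order) for c in range(volume.data.shape[-1])],
        axis=-1,
    )
    return Volume(data=out, channels=volume.channels,
                  voxel=(target, target, target), origin=volume.origin)
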