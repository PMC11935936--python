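"""Cartesian multi-channel 3D intensity volumes."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Volume:
    """3D intensity grid, indexed ``data[z, y, x, channel]``.

    ``voxel`` is (vx, vy, vz) in μm and ``origin`` the lab-frame position of
    the centre of voxel (0, 0, 0).  ``mask`` (optional) marks voxels backed by
    acquired data; reconstruction leaves sheared-off corners unmasked.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    voxel: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.shape[-1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if min(self.voxel) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel
        return vx * vy * vz

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError as exc:
            raise KeyError(f"no channel {name!r} in {self.channels}") from exc
        return self.data[..., idx]

    def extent_um(self) -> tuple[float, float, float]:
        """Physical (x, y, z) extent spanned by the grid."""
        nz, ny, nx = self.shape_zyx
        vx, vy, vz = self.voxel
        return (nx * vx, ny * vy, nz * vz)

    def centroid_um(self, channel: str, background: float = 0.0) -> np.ndarray:
        """Intensity-weighted centroid of one channel in lab coordinates."""
        img = np.clip(self.channel(channel).astype(float) - background, 0.0, None)
        if self.mask is not None:
            img = img * self.mask
        total = img.sum()
        if total <= 0:
            raise ValueError("cannot take centroid of an empty channel")
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in self.shape_zyx], indexing="ij")
        idx = np.array([(img * a).sum() / total for a in (xx, yy, zz)])
        return np.asarray(self.origin) + idx * np.asarray(self.voxel)

    # -- persistence --------------------------------------------------------

    def save(self, base_path: str | Path) -> list[Path]:
        """Write one multi-page TIFF per channel (page = z) + JSON sidecar."""
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
            "voxel_um": list(self.voxel),
            "origin_um": list(self.origin),
            "shape_zyx": list(self.shape_zyx),
        }
        meta = base.with_suffix(".json")
        meta.write_text(json.dumps(sidecar, indent=2))
        written.append(meta)
        return written

    @classmethod
    def load(cls, base_path: str | Path) -> "Volume":
        base = Path(base_path)
        meta = json.loads(base.with_suffix(".json").read_text())
        chans = tuple(meta["channels"])
        planes = [tifffile.imread(base.with_name(f"{base.stem}_{ch}.tif")) for ch in chans]
        data = np.stack(planes, axis=-1)
        return cls(data=data, channels=chans, voxel=tuple(meta["voxel_um"]),
                   origin=tuple(meta["origin_um"]))
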