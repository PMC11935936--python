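"""Microchannel geometry.

Coordinate convention used throughout the package (lab frame, micrometres):

* ``x`` — across the channel width (camera columns),
* ``y`` — the flow axis; cells translate toward −y,
* ``z`` — channel height (0 at the bottom wall, ``height_h`` at the top).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelGeometry:
    """Wide, shallow rectangular flow channel.

    The default 200 μm × 2 mm cross-section is the glass-capillary channel of
    the instrument being simulated.  ``length_l`` is the length of the channel
    segment populated with cells, not the physical capillary length.

    The wide-channel constraint ``width_w >= 5 * height_h`` keeps the
    plane-Poiseuille (parallel-plate) velocity profile valid away from the
    side walls; cells are only placed at least ``height_h`` away from either
    side wall (see :attr:`side_margin`).
    """

    height_h: float = 200.0
    width_w: float = 2000.0
    length_l: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.height_h > 0 and self.width_w > 0 and self.length_l > 0):
            raise ValueError("channel dimensions must be positive")
        if self.width_w < 5.0 * self.height_h:
            raise ValueError(
                "wide-channel regime requires width_w >= 5 * height_h "
                f"(got w={self.width_w}, h={self.height_h})"
            )

    @property
    def side_margin(self) -> float:
        """Distance from each side wall inside which the 1D parabola is not
        trusted and no cells are placed (one channel height)."""
        return self.height_h

    @property
    def segment_volume_um3(self) -> float:
        return self.height_h * self.width_w * self.length_l

    @property
    def segment_volume_ml(self) -> float:
        # 1 mL = 1e12 um^3
        return self.segment_volume_um3 / 1e12
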