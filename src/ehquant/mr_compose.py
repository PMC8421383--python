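"""HYDROPS / HYDROPS-Mi2 image algebra and the display window transform.

HYDROPS = PPI - PEI (endolymph comes out negative, perilymph positive);
HYDROPS-Mi2 = HYDROPS x MRC, which suppresses non-fluid background and
boosts the contrast-to-noise ratio.  All arithmetic is done in floating
point; negative values are preserved throughout.  The window/level map
is for display export only — endolymph classification is always done on
raw HYDROPS-Mi2 values, since windowing destroys sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Volume


@dataclass(frozen=True)
class WindowLevel:
    """Display window: `level` maps to mid-gray, `width` spans [0, 1]."""

    level: float = 400.0
    width: float = 1000.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")


def _check_grids(a: Volume, b: Volume) -> None:
    if a.data.shape != b.data.shape or not np.allclose(
        a.voxel_size_mm, b.voxel_size_mm
    ):
        raise ValueError(
            "grid mismatch: "
            f"{a.contrast} {a.data.shape} @ {a.voxel_size_mm} vs "
            f"{b.contrast} {b.data.shape} @ {b.voxel_size_mm}"
        )


def compose_hydrops(ppi: Volume, pei: Volume) -> Volume:
    """Element-wise PPI - PEI; no clipping, negative values preserved."""
    if ppi.contrast != "PPI" or pei.contrast != "PEI":
        raise ValueError(f"expected PPI and PEI volumes, got {ppi.contrast}/{pei.contrast}")
    _check_grids(ppi, pei)
    return Volume(ppi.data - pei.data, ppi.voxel_size_mm, "HYDROPS")


def compose_mi2(hydrops: Volume, mrc: Volume) -> Volume:
    """Element-wise HYDROPS x MRC."""
    if hydrops.contrast != "HYDROPS" or mrc.contrast != "MRC":
        raise ValueError(
            f"expected HYDROPS and MRC volumes, got {hydrops.contrast}/{mrc.contrast}"
        )
    _check_grids(hydrops, mrc)
    return Volume(hydrops.data * mrc.data, hydrops.voxel_size_mm, "HYDROPS-Mi2")


def apply_window(volume: Volume, wl: WindowLevel = WindowLevel()) -> np.ndarray:
    """Linear window/level map to [0, 1] for figure export.

    Values at or below level - width/2 clamp to 0, at or above
    level + width/2 clamp to 1.  Never used for pixel counting.
    """
    lo = wl.level - wl.width / 2.0
    return np.clip((volume.data - lo) / wl.width, 0.0, 1.0)
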