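"""In-memory containers for MR volumes, label volumes and section images.

Array layout: volumes are (ny, nx, nz) with axial slices along the last
axis; the last axis is the inferior-to-superior direction by default
(slice 0 is the lowest).  2D arrays are (ny, nx).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import labels as L

CONTRAST_TAGS = ("MRC", "PPI", "PEI", "HYDROPS", "HYDROPS-Mi2", "other")


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and a contrast tag."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    contrast: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        if self.contrast not in CONTRAST_TAGS:
            raise ValueError(f"unknown contrast tag {self.contrast!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume | LabelVolume") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
        )


@dataclass
class LabelVolume:
    """Integer anatomy labels on the same grid as the MR volumes.

    `territory` is the geometric extent of the lateral-canal lumen
    outside the vestibule boundary; herniated organ pixels keep their
    organ label but fall inside this mask.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    territory: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.territory is None:
            self.territory = np.zeros(self.data.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, which: int | frozenset | set | tuple | list) -> np.ndarray:
        if isinstance(which, (int, np.integer)):
            return self.data == which
        return np.isin(self.data, list(which))

    def endolymph_mask(self) -> np.ndarray:
        return self.mask(L.ENDOLYMPH_LABELS)

    def perilymph_mask(self) -> np.ndarray:
        return self.mask(L.PERILYMPH_LABELS)


@dataclass
class SectionImage:
    """A 2D labeled histology-style section with polygon ground truth.

    `polygons` maps region names to (N, 2) vertex arrays in pixel units;
    they are the analytic outlines the raster was generated from and
    serve as the area ground truth for the rasterized regions.
    """

    labels: np.ndarray
    pixel_size_mm: float
    polygons: dict[str, np.ndarray] = field(default_factory=dict)
    territory: np.ndarray | None = None
    site: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("SectionImage labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.territory is None:
            self.territory = np.zeros(self.labels.shape, dtype=bool)

    def mask(self, which: int | frozenset | set | tuple | list) -> np.ndarray:
        if isinstance(which, (int, np.integer)):
            return self.labels == which
        return np.isin(self.labels, list(which))

    def area_mm2(self, which) -> float:
        """Region area as pixel count times pixel area."""
        return float(self.mask(which).sum()) * self.pixel_size_mm**2

    def polygon_area_mm2(self, name: str) -> float:
        """Analytic (polygon) area of a named region, in mm^2."""
        from shapely.geometry import Polygon

        return Polygon(self.polygons[name]).area * self.pixel_size_mm**2
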