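"""Rule-based selection of the representative cochlear and vestibular
ROI slices.

The cochlear rule: among slices showing all three cochlear turns, take
the one with the largest in-plane modiolus extent (pixel count; ties go
to the lower slice).  The vestibular rule: take the lowest slice on
which the lateral-canal ring is visible over more than 240 degrees of
arc, and exclude ampulla pixels from the vestibular ROI.  Slices are
ordered along the configured inferior axis (default: ascending index
along the last axis = inferior to superior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import labels as L
from .volumes import LabelVolume

ARC_CRITERION_DEG = 240.0  # strict: coverage must exceed this
ARC_BIN_DEG = 1.0


@dataclass
class ROIMask:
    """A 2D boolean ROI on one slice, with the rule that produced it."""

    mask: np.ndarray
    slice_index: int
    site: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("empty ROI")


@dataclass(frozen=True)
class ArcCoverage:
    degrees: float
    center: tuple[float, float]
    bin_width_deg: float = ARC_BIN_DEG

    def __post_init__(self) -> None:
        if not 0.0 <= self.degrees <= 360.0:
            raise ValueError("arc coverage must be within [0, 360] degrees")


def arc_coverage(
    mask_2d: np.ndarray, center: tuple[float, float], bin_deg: float = ARC_BIN_DEG
) -> ArcCoverage:
    """Angular coverage of a mask around `center` = (x, y) in pixels.

    Coverage is the number of angular bins (default 1 degree, over
    [0, 360)) intersected by the angular extent of any mask pixel.  The
    extent of a pixel is the angle range subtended by its four corners,
    so thin bins between pixel centers still count as covered.  An
    empty mask has coverage 0 (not an error).
    """
    mask_2d = np.asarray(mask_2d, dtype=bool)
    ii, jj = np.nonzero(mask_2d)
    if ii.size == 0:
        return ArcCoverage(0.0, center, bin_deg)
    nbins = int(round(360.0 / bin_deg))
    corner_angles = []
    for dx, dy in ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)):
        ang = np.degrees(np.arctan2(ii + dy - center[1], jj + dx - center[0]))
        corner_angles.append(np.mod(ang, 360.0))
    amin = np.minimum.reduce(corner_angles)
    amax = np.maximum.reduce(corner_angles)
    wraps = (amax - amin) > 180.0  # pixel straddles the 0-degree ray
    lo = np.where(wraps, amax, amin)
    hi = np.where(wraps, amin + 360.0, amax)
    b_lo = np.minimum((lo / bin_deg).astype(int), nbins - 1)
    b_hi = (hi / bin_deg).astype(int)
    # range-fill via difference array; wrapped ranges spill past nbins
    diff = np.zeros(2 * nbins + 2, dtype=np.int64)
    np.add.at(diff, b_lo, 1)
    np.add.at(diff, b_hi + 1, -1)
    filled = np.cumsum(diff)[: 2 * nbins] > 0
    occupied = filled[:nbins] | filled[nbins:]
    return ArcCoverage(float(occupied.sum() * bin_deg), center, bin_deg)


def _slice_order(n_slices: int, inferior_axis: str = "z-") -> range:
    """Slice indices from most inferior to most superior.

    'z-' means low index is inferior (the default grid convention);
    'z+' reverses it.
    """
    if inferior_axis == "z-":
        return range(n_slices)
    if inferior_axis == "z+":
        return range(n_slices - 1, -1, -1)
    raise ValueError(f"unknown inferior_axis {inferior_axis!r}")


def select_cochlea_slice(labels: LabelVolume) -> int:
    """Representative cochlear slice: all three turns visible, modiolus
    extent maximal (ties broken toward the lower slice index)."""
    data = labels.data
    turn_masks = [
        np.isin(data, [L.COCHLEA_PERI[t], L.SCALA_MEDIA[t]]) for t in L.TURNS
    ]
    candidates = []
    for z in range(data.shape[2]):
        if all(m[:, :, z].any() for m in turn_masks):
            candidates.append(z)
    if not candidates:
        raise ValueError("no representative cochlear slice: not all turns visible")
    if len(candidates) == 1:
        return candidates[0]
    counts = [(int((data[:, :, z] == L.MODIOLUS).sum()), -z) for z in candidates]
    best = max(zip(counts, candidates))[1]
    return best


def select_vestibule_slice(
    labels: LabelVolume, inferior_axis: str = "z-"
) -> tuple[int, ROIMask]:
    """Lowest slice whose lateral-canal ring covers > 240 degrees of arc;
    the vestibular ROI is the vestibule (perilymph + saccule + utricle)
    on that slice minus any ampulla pixels."""
    data = labels.data
    ring3d = data == L.LSCC_RING
    if not ring3d.any():
        raise ValueError("no qualifying vestibular slice: no canal ring labels")
    # centroid of the full 3D ring projected in-plane: stable even on
    # slices where only a partial arc is visible
    ii, jj, _ = np.nonzero(ring3d)
    center = (float(jj.mean() + 0.5), float(ii.mean() + 0.5))
    # the ampulla is part of the canal lumen and counts toward visibility
    visible3d = ring3d | (data == L.LSCC_AMPULLA)
    for z in _slice_order(data.shape[2], inferior_axis):
        cov = arc_coverage(visible3d[:, :, z], center)
        if cov.degrees > ARC_CRITERION_DEG:
            plane = data[:, :, z]
            roi = np.isin(plane, [L.VESTIBULE_PERI, L.SACCULE, L.UTRICLE])
            roi &= plane != L.LSCC_AMPULLA
            return z, ROIMask(
                roi,
                z,
                "vestibule",
                provenance=(
                    f"lowest slice with LSCC arc coverage {cov.degrees:.0f} deg "
                    f"> {ARC_CRITERION_DEG:.0f} deg; ampulla excluded"
                ),
            )
    raise ValueError(
        f"no qualifying vestibular slice: no slice exceeds {ARC_CRITERION_DEG} deg"
    )


def cochlea_roi(labels: LabelVolume, slice_index: int | None = None) -> ROIMask:
    """Cochlear ROI: the fluid (turn) labels on the representative slice.

    The modiolus core is not fluid and is excluded, mirroring a contour
    of the bright cochlear fluid on the MRC image.
    """
    if slice_index is None:
        slice_index = select_cochlea_slice(labels)
    plane = labels.data[:, :, slice_index]
    fluid = [L.COCHLEA_PERI[t] for t in L.TURNS] + [L.SCALA_MEDIA[t] for t in L.TURNS]
    return ROIMask(
        np.isin(plane, fluid),
        slice_index,
        "cochlea",
        provenance="all-turns slice with greatest modiolus extent",
    )
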