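"""Negative-pixel EH-ratio measurement on HYDROPS-Mi2 images.

The EH ratio of an ROI is the number of strictly negative pixels
(endolymph suppressed below zero by the PPI - PEI subtraction) divided
by the total number of ROI pixels.  Zero-valued pixels — background and
anything with zero MRC signal — count as non-endolymph.  Counting is
done on raw composed values, never on windowed display values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi_select import ROIMask
from .volumes import Volume


@dataclass(frozen=True)
class EHMeasurement:
    """One measured EH ratio with its provenance."""

    site: str
    side: str
    ratio: float
    numerator_pixels: int
    denominator_pixels: int
    method: str  # 'mri_negative_pixel' or 'histo_area'
    ear_id: str = ""

    def __post_init__(self) -> None:
        if self.denominator_pixels <= 0:
            raise ValueError("denominator must be positive")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")


def _roi_values(mi2: Volume, roi: ROIMask) -> np.ndarray:
    if not 0 <= roi.slice_index < mi2.data.shape[2]:
        raise ValueError(
            f"ROI slice {roi.slice_index} outside volume with {mi2.data.shape[2]} slices"
        )
    if roi.mask.shape != mi2.data.shape[:2]:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match volume plane {mi2.data.shape[:2]}"
        )
    return mi2.data[:, :, roi.slice_index][roi.mask]


def eh_ratio_mri(
    mi2: Volume, roi: ROIMask, side: str = "affected", ear_id: str = ""
) -> EHMeasurement:
    """EH ratio = (# ROI pixels with value < 0) / (# ROI pixels)."""
    values = _roi_values(mi2, roi)
    numerator = int((values < 0).sum())
    denominator = int(values.size)
    return EHMeasurement(
        site=roi.site,
        side=side,
        ratio=numerator / denominator,
        numerator_pixels=numerator,
        denominator_pixels=denominator,
        method="mri_negative_pixel",
        ear_id=ear_id,
    )


def negative_pixel_histogram(
    mi2: Volume, roi: ROIMask, bins_per_side: int = 32
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Histogram of ROI values with a bin edge pinned at zero.

    Returns (edges, counts, n_negative, n_total); n_negative is the sum
    of counts of the bins left of zero and equals the `eh_ratio_mri`
    numerator by construction.
    """
    values = _roi_values(mi2, roi)
    lo = min(float(values.min()), 0.0)
    hi = max(float(values.max()), 1e-9)  # keep a bin right of zero so that
    # exact zeros are never counted as negative
    neg_edges = np.linspace(lo, 0.0, bins_per_side + 1) if lo < 0 else np.array([0.0])
    pos_edges = np.linspace(0.0, hi, bins_per_side + 1)
    edges = np.unique(np.concatenate([neg_edges, pos_edges]))
    counts, edges = np.histogram(values, bins=edges)
    n_negative = int(counts[edges[1:] <= 0].sum())
    return edges, counts, n_negative, int(values.size)
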