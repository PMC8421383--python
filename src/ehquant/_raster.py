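"""Supersampled rasterization of analytic 2D shapes onto integer label grids.

Shapes are membership predicates evaluated at supersampled pixel centres;
the final label image takes, per output pixel, the majority label among
its subsamples (ties broken toward the label painted earlier).  With the
default 4x supersampling the area bias of a convex region stays well
below one boundary-pixel row, which is what the downstream area-ratio
tolerances assume.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Membership = Callable[[np.ndarray, np.ndarray], np.ndarray]

DEFAULT_SUPERSAMPLE = 4


def _super_centres(n: int, factor: int) -> np.ndarray:
    """Coordinates of supersample centres along an axis of n pixels."""
    return (np.arange(n * factor, dtype=np.float64) + 0.5) / factor


def paint_labels(
    shape: tuple[int, int],
    layers: Sequence[tuple[int, Membership]],
    supersample: int = DEFAULT_SUPERSAMPLE,
    background: int = 0,
) -> np.ndarray:
    """Rasterize ordered (label, membership) layers to an int16 image.

    Later layers overwrite earlier ones at supersample resolution, then
    each output pixel is assigned its majority subsample label.
    `shape` is (ny, nx); membership functions receive (X, Y) arrays in
    pixel units with the centre of pixel [i, j] at (j + 0.5, i + 0.5).
    """
    ny, nx = shape
    xs = _super_centres(nx, supersample)
    ys = _super_centres(ny, supersample)
    X, Y = np.meshgrid(xs, ys)
    hi = np.full(X.shape, background, dtype=np.int16)
    for label, member in layers:
        hi[member(X, Y)] = label
    return majority_downsample(hi, supersample)


def majority_downsample(hi: np.ndarray, factor: int) -> np.ndarray:
    """Majority vote over factor x factor blocks of an integer image."""
    if factor == 1:
        return hi.copy()
    ny, nx = hi.shape[0] // factor, hi.shape[1] // factor
    blocks = hi.reshape(ny, factor, nx, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(ny, nx, factor * factor)
    values = np.unique(blocks)
    counts = np.zeros((ny, nx, values.size), dtype=np.int16)
    for k, v in enumerate(values):
        counts[:, :, k] = (blocks == v).sum(axis=2)
    return values[np.argmax(counts, axis=2)].astype(np.int16)


def rasterize_mask(
    shape: tuple[int, int], member: Membership, supersample: int = DEFAULT_SUPERSAMPLE
) -> np.ndarray:
    """Boolean rasterization of a single membership predicate."""
    return paint_labels(shape, [(1, member)], supersample=supersample) == 1


# ---------------------------------------------------------------------------
# membership constructors


def ellipse(cx: float, cy: float, a: float, b: float) -> Membership:
    def member(X, Y):
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0

    return member


def disk(cx: float, cy: float, r: float) -> Membership:
    return ellipse(cx, cy, r, r)


def annulus(cx: float, cy: float, r_in: float, r_out: float) -> Membership:
    def member(X, Y):
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        return (r2 >= r_in**2) & (r2 <= r_out**2)

    return member


def annular_sector(
    cx: float, cy: float, r_in: float, r_out: float, start_deg: float, span_deg: float
) -> Membership:
    """Annulus restricted to angles in [start, start + span) (degrees, CCW)."""
    ring = annulus(cx, cy, r_in, r_out)

    def member(X, Y):
        ang = np.degrees(np.arctan2(Y - cy, X - cx))
        rel = np.mod(ang - start_deg, 360.0)
        return ring(X, Y) & (rel < span_deg)

    return member


def scaled_half_ellipse(
    cx: float, cy: float, a: float, b: float, side: str, scale: float
) -> Membership:
    """A half-ellipse (split by the vertical line x = cx) shrunk about its
    own centroid by `scale`; stays inside the parent half since the half
    is convex."""
    sx, sy = half_ellipse_centroid(cx, cy, a, b, side)

    def member(X, Y):
        Xi = sx + (X - sx) / scale
        Yi = sy + (Y - sy) / scale
        inside = ((Xi - cx) / a) ** 2 + ((Yi - cy) / b) ** 2 <= 1.0
        half = Xi <= cx if side == "left" else Xi >= cx
        return inside & half

    return member


def rectangle(x0: float, x1: float, y0: float, y1: float) -> Membership:
    def member(X, Y):
        return (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)

    return member


def intersection(*members: Membership) -> Membership:
    def member(X, Y):
        out = members[0](X, Y)
        for m in members[1:]:
            out &= m(X, Y)
        return out

    return member


def half_ellipse_centroid(
    cx: float, cy: float, a: float, b: float, side: str
) -> tuple[float, float]:
    off = 4.0 * a / (3.0 * np.pi)
    return (cx - off, cy) if side == "left" else (cx + off, cy)


# ---------------------------------------------------------------------------
# polygon ground truth


def ellipse_polygon(
    cx: float, cy: float, a: float, b: float, n: int = 360
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])


def annular_sector_polygon(
    cx: float,
    cy: float,
    r_in: float,
    r_out: float,
    start_deg: float,
    span_deg: float,
    step_deg: float = 0.5,
) -> np.ndarray:
    n = max(int(np.ceil(span_deg / step_deg)) + 1, 2)
    ang = np.radians(np.linspace(start_deg, start_deg + span_deg, n))
    outer = np.column_stack([cx + r_out * np.cos(ang), cy + r_out * np.sin(ang)])
    inner = np.column_stack([cx + r_in * np.cos(ang[::-1]), cy + r_in * np.sin(ang[::-1])])
    return np.vstack([outer, inner])


def half_ellipse_polygon(
    cx: float, cy: float, a: float, b: float, side: str, scale: float, n: int = 360
) -> np.ndarray:
    if side == "left":
        t = np.linspace(np.pi / 2.0, 3.0 * np.pi / 2.0, n)
    else:
        t = np.linspace(-np.pi / 2.0, np.pi / 2.0, n)
    pts = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])
    sx, sy = half_ellipse_centroid(cx, cy, a, b, side)
    return np.column_stack([sx + (pts[:, 0] - sx) * scale, sy + (pts[:, 1] - sy) * scale])
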