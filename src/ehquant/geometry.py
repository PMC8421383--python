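"""Stylized inner-ear layout shared by the MR and histology renderers.

The anatomy is deliberately schematic — cochlear turns are concentric
annuli around a central modiolus core, the otolithic organs are scaled
elliptical segments inside a vestibule ellipse, the lateral canal is an
annulus with an elliptical ampulla — because the quantities under study
are area *fractions*, not shapes.  Every region is defined analytically
so that its target fraction is met by construction and its polygon
outline can serve as ground truth for the rasterized areas.

Coordinates are in in-plane pixel units; (x, y) = (column, row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _raster as R
from . import labels as L

HERNIATION_KINDS = ("none", "saccular", "utricular", "both")


def _unit_circle_segment_area(u: float) -> float:
    """Area of the unit disk left of the vertical chord x = u."""
    u = float(np.clip(u, -1.0, 1.0))
    return u * math.sqrt(max(1.0 - u * u, 0.0)) + math.asin(u) + math.pi / 2.0


def _solve_chord(left_share: float) -> float:
    """Chord position u with disk area fraction `left_share` to its left."""
    return brentq(
        lambda u: _unit_circle_segment_area(u) / math.pi - left_share,
        -1.0 + 1e-9,
        1.0 - 1e-9,
        xtol=1e-12,
    )


def _segment_centroid_x(u: float, side: str) -> float:
    """Normalized x-centroid of the unit-disk segment on `side` of chord u."""
    mx_left = -(2.0 / 3.0) * (1.0 - u * u) ** 1.5
    area_left = _unit_circle_segment_area(u)
    if side == "left":
        return mx_left / area_left
    return -mx_left / (math.pi - area_left)


@dataclass(frozen=True)
class GeometryConfig:
    """Placement and sizing of all phantom structures, in pixel units.

    Defaults assume a 160 x 160 in-plane grid with 12 axial slices; the
    last axis runs inferior to superior (slice 0 lowest).
    """

    # cochlea: modiolus core + three turn annuli (apical innermost)
    cochlea_center: tuple[float, float] = (44.0, 44.0)
    modiolus_max_radius: float = 6.0
    turn_radii: tuple[tuple[float, float], ...] = (
        (24.0, 30.0),  # basal
        (16.0, 24.0),  # middle
        (6.0, 16.0),  # apical
    )
    scala_media_start_deg: float = 90.0
    cochlea_slices: tuple[int, int] = (2, 8)  # inclusive
    modiolus_peak_slice: int = 5
    modiolus_taper_per_slice: float = 0.08

    # vestibule ellipse and otolithic organs
    vestibule_center: tuple[float, float] = (110.0, 52.0)
    vestibule_axes: tuple[float, float] = (26.0, 20.0)
    vestibule_slices: tuple[int, int] = (3, 9)  # inclusive

    # lateral semicircular canal ring, ampulla, and herniation territory
    lscc_center: tuple[float, float] = (110.0, 118.0)
    lscc_radii: tuple[float, float] = (18.0, 24.0)
    # visible arc span (degrees) per vestibule slice, lowest first
    lscc_arc_spans: tuple[float, ...] = (140.0, 210.0, 250.0, 300.0, 360.0, 360.0, 360.0)
    ampulla_axes: tuple[float, float] = (8.0, 6.0)
    ampulla_angle_deg: float = 45.0  # rotation off the vestibule direction
    territory_half_width: float = 6.0
    protrusion_fraction: float = 0.2  # of the outer ring radius

    # 2D canal cross-sections (histology only)
    canal_section_center: tuple[float, float] = (80.0, 80.0)
    canal_lumen_ampullary_axes: tuple[float, float] = (58.0, 46.0)
    canal_lumen_nonampullary_radius: float = 40.0

    # ------------------------------------------------------------------
    def modiolus_radius(self, z: int) -> float:
        taper = 1.0 - self.modiolus_taper_per_slice * abs(z - self.modiolus_peak_slice)
        return self.modiolus_max_radius * max(taper, 0.2)

    def lscc_span(self, z: int) -> float:
        z0 = self.vestibule_slices[0]
        if not (z0 <= z <= self.vestibule_slices[1]):
            return 0.0
        idx = min(z - z0, len(self.lscc_arc_spans) - 1)
        return self.lscc_arc_spans[idx]

    # ------------------------------------------------------------------
    def check_bounds(self, grid_shape: tuple[int, int, int]) -> None:
        """Raise if any structure would be clipped by the grid."""
        ny, nx, nz = grid_shape
        boxes = {
            "cochlea": self._box_circle(self.cochlea_center, self.turn_radii[0][1]),
            "vestibule": self._box_ellipse(self.vestibule_center, self.vestibule_axes),
            "lateral canal ring": self._box_circle(self.lscc_center, self.lscc_radii[1]),
            "lateral canal ampulla": self._box_ellipse(
                self.ampulla_center(), self.ampulla_axes
            ),
        }
        for name, (x0, x1, y0, y1) in boxes.items():
            if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
                raise ValueError(f"{name} is clipped by the grid {grid_shape!r}")
        for name, (z0, z1) in {
            "cochlea": self.cochlea_slices,
            "vestibule": self.vestibule_slices,
        }.items():
            if z0 < 0 or z1 >= nz:
                raise ValueError(f"{name} slice range {z0}..{z1} exceeds {nz} slices")

    @staticmethod
    def _box_circle(c, r):
        return (c[0] - r, c[0] + r, c[1] - r, c[1] + r)

    @staticmethod
    def _box_ellipse(c, ab):
        return (c[0] - ab[0], c[0] + ab[0], c[1] - ab[1], c[1] + ab[1])

    def ampulla_center(self) -> tuple[float, float]:
        cx, cy = self.lscc_center
        vx, vy = self.vestibule_center
        d = np.array([vx - cx, vy - cy])
        d = d / np.linalg.norm(d)
        th = math.radians(self.ampulla_angle_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        u = rot @ d
        r_mid = 0.5 * (self.lscc_radii[0] + self.lscc_radii[1])
        return (cx + r_mid * u[0], cy + r_mid * u[1])


@dataclass
class SlicePlan:
    """Paint layers plus polygon ground truth for one 2D plane."""

    layers: list = field(default_factory=list)
    polygons: dict[str, np.ndarray] = field(default_factory=dict)
    territory: object = None  # membership predicate or None


# ---------------------------------------------------------------------------
# cochlea


def cochlea_plan(
    cfg: GeometryConfig, fraction: float, modiolus_radius: float | None = None
) -> SlicePlan:
    """Three turn annuli, each with a scala-media sector of angular span
    360 * fraction, so that total scala-media area over total turn area
    equals `fraction` exactly (the modiolus core is not fluid and is not
    part of the denominator)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("cochlea fraction must be in (0, 1)")
    cx, cy = cfg.cochlea_center
    if modiolus_radius is None:
        modiolus_radius = cfg.modiolus_max_radius
    span = 360.0 * fraction
    start = cfg.scala_media_start_deg
    plan = SlicePlan()
    for turn, (r_in, r_out) in zip(L.TURNS, cfg.turn_radii):
        plan.layers.append((L.COCHLEA_PERI[turn], R.annulus(cx, cy, r_in, r_out)))
        plan.polygons[f"cochlea_turn_{turn}"] = R.annular_sector_polygon(
            cx, cy, r_in, r_out, 0.0, 360.0
        )
    for turn, (r_in, r_out) in zip(L.TURNS, cfg.turn_radii):
        plan.layers.append(
            (L.SCALA_MEDIA[turn], R.annular_sector(cx, cy, r_in, r_out, start, span))
        )
        plan.polygons[f"scala_media_{turn}"] = R.annular_sector_polygon(
            cx, cy, r_in, r_out, start, span
        )
    plan.layers.append((L.MODIOLUS, R.disk(cx, cy, modiolus_radius)))
    plan.polygons["modiolus"] = R.ellipse_polygon(cx, cy, modiolus_radius, modiolus_radius)
    return plan


# ---------------------------------------------------------------------------
# vestibule + lateral canal


def _organ_geometry(cfg: GeometryConfig, f_sac: float, f_utr: float):
    """Chord split and per-organ scale so the saccule (left segment) and
    utricle (right segment) realize their target vestibule-area shares.

    The free (perilymphatic) share is split evenly between the two
    sides, then each segment is shrunk about its own centroid."""
    free = 1.0 - f_sac - f_utr
    if free <= 0.0:
        raise ValueError("saccule + utricle fractions must sum below 1")
    left_share = f_sac + free / 2.0
    u = _solve_chord(left_share)
    cx, cy = cfg.vestibule_center
    a, b = cfg.vestibule_axes
    out = {}
    for name, side, share, f in (
        ("saccule", "left", left_share, f_sac),
        ("utricle", "right", 1.0 - left_share, f_utr),
    ):
        scale = math.sqrt(f / share)
        gx = cx + a * _segment_centroid_x(u, side)
        out[name] = dict(side=side, scale=scale, centroid=(gx, cy), chord=u)
    return out


def _segment_member(cfg, side, u, scale, centroid):
    cx, cy = cfg.vestibule_center
    a, b = cfg.vestibule_axes
    gx, gy = centroid

    def member(X, Y):
        Xi = gx + (X - gx) / scale
        Yi = gy + (Y - gy) / scale
        xn = (Xi - cx) / a
        yn = (Yi - cy) / b
        inside = xn * xn + yn * yn <= 1.0
        half = xn <= u if side == "left" else xn >= u
        return inside & half

    return member


def _segment_polygon(cfg, side, u, scale, centroid, n=720):
    cx, cy = cfg.vestibule_center
    a, b = cfg.vestibule_axes
    t0 = math.acos(u)
    if side == "left":
        t = np.linspace(t0, 2.0 * math.pi - t0, n)
    else:
        t = np.linspace(-t0, t0, n)
    pts = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])
    gx, gy = centroid
    return np.column_stack(
        [gx + (pts[:, 0] - gx) * scale, gy + (pts[:, 1] - gy) * scale]
    )


def _territory_bounds(cfg: GeometryConfig):
    vx, vy = cfg.vestibule_center
    b = cfg.vestibule_axes[1]
    y0 = vy + b + 0.01  # strictly below the vestibule boundary
    y1 = cfg.lscc_center[1] - cfg.lscc_radii[1] - 0.01  # stops short of the ring
    w = cfg.territory_half_width
    return vx - w, vx + w, y0, y1


def vestibule_plan(
    cfg: GeometryConfig,
    f_sac: float,
    f_utr: float,
    herniation: str = "none",
    ring_span_deg: float = 360.0,
) -> SlicePlan:
    """Vestibule ellipse with saccule/utricle segments, the LSCC ring
    (possibly a partial arc), its ampulla, the canal territory, and an
    optional organ protrusion into the territory."""
    if herniation not in HERNIATION_KINDS:
        raise ValueError(f"unknown herniation kind {herniation!r}")
    cx, cy = cfg.vestibule_center
    a, b = cfg.vestibule_axes
    plan = SlicePlan()

    # canal structures first; the vestibule group paints over nothing of
    # them (all disjoint by construction)
    rx, ry = cfg.lscc_center
    r_in, r_out = cfg.lscc_radii
    if ring_span_deg > 0.0:
        if ring_span_deg >= 360.0:
            plan.layers.append((L.LSCC_RING, R.annulus(rx, ry, r_in, r_out)))
        else:
            start = 90.0 + 0.5 * (360.0 - ring_span_deg)
            plan.layers.append(
                (L.LSCC_RING, R.annular_sector(rx, ry, r_in, r_out, start, ring_span_deg))
            )
        ax, ay = cfg.ampulla_center()
        plan.layers.append((L.LSCC_AMPULLA, R.ellipse(ax, ay, *cfg.ampulla_axes)))
        plan.polygons["lscc_ampulla"] = R.ellipse_polygon(ax, ay, *cfg.ampulla_axes)

    x0, x1, y0, y1 = _territory_bounds(cfg)
    territory = R.rectangle(x0, x1, y0, y1)
    plan.territory = territory
    plan.layers.append((L.CANAL_TERRITORY, territory))
    plan.polygons["canal_territory"] = np.array(
        [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]
    )

    plan.layers.append((L.VESTIBULE_PERI, R.ellipse(cx, cy, a, b)))
    plan.polygons["vestibule"] = R.ellipse_polygon(cx, cy, a, b)

    organs = _organ_geometry(cfg, f_sac, f_utr)
    for name, label in (("saccule", L.SACCULE), ("utricle", L.UTRICLE)):
        g = organs[name]
        plan.layers.append(
            (label, _segment_member(cfg, g["side"], g["chord"], g["scale"], g["centroid"]))
        )
        plan.polygons[name] = _segment_polygon(
            cfg, g["side"], g["chord"], g["scale"], g["centroid"]
        )

    # herniation: a protrusion of the organ label into the canal territory
    r_p = cfg.protrusion_fraction * r_out
    vx = cfg.vestibule_center[0]
    prot_y = y0 + 0.6 * r_p
    if herniation in ("saccular", "both"):
        blob = R.intersection(R.disk(vx - 3.0, prot_y, r_p), territory)
        plan.layers.append((L.SACCULE, blob))
    if herniation in ("utricular", "both"):
        blob = R.intersection(R.disk(vx + 3.0, prot_y, r_p), territory)
        plan.layers.append((L.UTRICLE, blob))
    return plan


# ---------------------------------------------------------------------------
# 2D canal cross-sections


def canal_section_plan(
    cfg: GeometryConfig, canal: str, region: str, duct_fraction: float
) -> SlicePlan:
    """Bony cross-section (lumen) containing a membranous duct whose area
    share of the lumen is `duct_fraction` by construction; the lumen is
    larger and elliptical at ampullary sites."""
    if canal not in L.CANALS:
        raise ValueError(f"unknown canal {canal!r}")
    if region not in ("ampullary", "nonampullary"):
        raise ValueError(f"unknown canal region {region!r}")
    if not 0.0 < duct_fraction < 1.0:
        raise ValueError("duct fraction must be in (0, 1)")
    cx, cy = cfg.canal_section_center
    if region == "ampullary":
        a, b = cfg.canal_lumen_ampullary_axes
    else:
        a = b = cfg.canal_lumen_nonampullary_radius
    s = math.sqrt(duct_fraction)
    plan = SlicePlan()
    plan.layers.append((L.CANAL_CROSS[canal], R.ellipse(cx, cy, a, b)))
    plan.layers.append((L.CANAL_DUCT[canal], R.ellipse(cx, cy, a * s, b * s)))
    plan.polygons["canal_cross"] = R.ellipse_polygon(cx, cy, a, b)
    plan.polygons["canal_duct"] = R.ellipse_polygon(cx, cy, a * s, b * s)
    return plan
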