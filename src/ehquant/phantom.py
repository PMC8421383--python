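"""Synthetic inner-ear phantoms with known ground truth.

One `PhantomSpec` describes a single ear: target endolymph-area
fractions per structure, an MR signal model, noise, and optional
herniation of an otolithic organ into the lateral canal.  Renderers
produce either the three MR contrast volumes (MRC / PPI / PEI) on a
common label grid, or 2D histology-style labeled sections per site.
`simulate_cohort` draws whole cohorts of such ears from per-group
truncated (clipped) normal distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import _raster as R
from . import geometry as G
from . import labels as L
from .volumes import LabelVolume, SectionImage, Volume

SIDES = ("affected", "unaffected", "control")

MR_SUPERSAMPLE = 4
HISTO_SUPERSAMPLE = 8
HISTO_PIXEL_SIZE_MM = 0.01

HISTO_SITES = ("cochlea", "vestibule") + tuple(
    f"canal_{c}_{r}" for c in L.CANALS for r in ("ampullary", "nonampullary")
)


@dataclass(frozen=True)
class SignalModel:
    """Mean signal per tissue class for each contrast (arbitrary units).

    The orderings encode the acquisition logic: on the PPI the enhanced
    perilymph is bright and endolymph dark, on the PEI the contrast is
    reversed, and on the cisternographic MRC all fluid is bright against
    bone.  Consequently PPI - PEI (the HYDROPS image) is positive in
    perilymph and negative in endolymph.
    """

    mrc: dict = field(
        default_factory=lambda: {"bone": 0.0, "perilymph": 600.0, "endolymph": 450.0}
    )
    ppi: dict = field(
        default_factory=lambda: {"bone": 5.0, "perilymph": 400.0, "endolymph": 20.0}
    )
    pei: dict = field(
        default_factory=lambda: {"bone": 5.0, "perilymph": 20.0, "endolymph": 400.0}
    )

    def validate(self) -> None:
        if not self.ppi["perilymph"] > self.pei["perilymph"]:
            raise ValueError("signal model: perilymph must be positive on PPI - PEI")
        if not self.ppi["endolymph"] < self.pei["endolymph"]:
            raise ValueError("signal model: endolymph must be negative on PPI - PEI")
        if not (
            self.mrc["perilymph"] > self.mrc["bone"]
            and self.mrc["endolymph"] > self.mrc["bone"]
        ):
            raise ValueError("signal model: fluid must be bright on MRC")

    def min_contrast(self) -> float:
        """Smallest absolute inter-class signal difference, all contrasts."""
        diffs = []
        for c in (self.mrc, self.ppi, self.pei):
            vals = sorted(c.values())
            diffs += [b - a for a, b in zip(vals, vals[1:])]
        return min(abs(d) for d in diffs)


@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic ear."""

    ear_id: str = "ear-000"
    side: str = "affected"
    grid_shape: tuple[int, int, int] = (160, 160, 12)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    cochlea_true_fraction: float = 0.314
    saccule_true_fraction: float = 0.513
    utricle_true_fraction: float = 0.242
    canal_duct_fraction_ampullary: dict = field(
        default_factory=lambda: {"anterior": 0.565, "lateral": 0.511, "posterior": 0.518}
    )
    canal_duct_fraction_nonampullary: dict = field(
        default_factory=lambda: {"anterior": 0.565, "lateral": 0.511, "posterior": 0.518}
    )
    herniation: str = "none"
    signal: SignalModel = field(default_factory=SignalModel)
    noise_sd: float = 20.0
    seed: int = 0
    geometry: G.GeometryConfig = field(default_factory=G.GeometryConfig)

    def validate(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.herniation not in G.HERNIATION_KINDS:
            raise ValueError(f"unknown herniation {self.herniation!r}")
        fr = {
            "cochlea": self.cochlea_true_fraction,
            "saccule": self.saccule_true_fraction,
            "utricle": self.utricle_true_fraction,
            **{f"{c} ampullary": v for c, v in self.canal_duct_fraction_ampullary.items()},
            **{
                f"{c} nonampullary": v
                for c, v in self.canal_duct_fraction_nonampullary.items()
            },
        }
        for name, f in fr.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} fraction {f} outside (0, 1)")
        if self.saccule_true_fraction + self.utricle_true_fraction >= 1.0:
            raise ValueError("saccule + utricle fractions must sum below 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.signal.validate()
        self.geometry.check_bounds(self.grid_shape)


# ---------------------------------------------------------------------------
# rendering


def _slice_plan(spec: PhantomSpec, z: int) -> G.SlicePlan:
    cfg = spec.geometry
    plan = G.SlicePlan()
    if cfg.cochlea_slices[0] <= z <= cfg.cochlea_slices[1]:
        sub = G.cochlea_plan(cfg, spec.cochlea_true_fraction, cfg.modiolus_radius(z))
        plan.layers += sub.layers
    if cfg.vestibule_slices[0] <= z <= cfg.vestibule_slices[1]:
        sub = G.vestibule_plan(
            cfg,
            spec.saccule_true_fraction,
            spec.utricle_true_fraction,
            herniation=spec.herniation,
            ring_span_deg=cfg.lscc_span(z),
        )
        plan.layers += sub.layers
        plan.territory = sub.territory
    return plan


def render_labels(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the full 3D anatomy label volume for one ear."""
    spec.validate()
    ny, nx, nz = spec.grid_shape
    data = np.zeros((ny, nx, nz), dtype=np.int16)
    territory = np.zeros((ny, nx, nz), dtype=bool)
    for z in range(nz):
        plan = _slice_plan(spec, z)
        if plan.layers:
            data[:, :, z] = R.paint_labels((ny, nx), plan.layers, MR_SUPERSAMPLE)
        if plan.territory is not None:
            territory[:, :, z] = R.rasterize_mask((ny, nx), plan.territory, MR_SUPERSAMPLE)
    return LabelVolume(data, spec.voxel_size_mm, territory)


def render_mr_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, Volume, Volume, LabelVolume]:
    """Render the three MR contrasts plus the ground-truth labels.

    Each contrast is the per-voxel tissue-class mean from the signal
    model plus independent zero-mean Gaussian noise of SD `noise_sd`.
    Bit-identical for identical specs (seeded).
    """
    labels = render_labels(spec)
    max_label = max(L.NAMES)
    rng = np.random.default_rng(spec.seed)
    vols = []
    for tag, table in (
        ("MRC", spec.signal.mrc),
        ("PPI", spec.signal.ppi),
        ("PEI", spec.signal.pei),
    ):
        lut = np.zeros(max_label + 1, dtype=np.float64)
        for lab in L.NAMES:
            lut[lab] = table[L.tissue_class(lab)]
        data = lut[labels.data]
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        vols.append(Volume(data, spec.voxel_size_mm, tag))
    mrc, ppi, pei = vols
    return mrc, ppi, pei, labels


def render_histo_section(spec: PhantomSpec, site: str) -> SectionImage:
    """Render one 2D labeled histology-style section for `site`.

    Sites: 'cochlea', 'vestibule', or 'canal_<name>_<region>' with name
    in anterior/lateral/posterior and region ampullary/nonampullary.
    """
    spec.validate()
    cfg = spec.geometry
    if site == "cochlea":
        plan = G.cochlea_plan(cfg, spec.cochlea_true_fraction)
    elif site == "vestibule":
        plan = G.vestibule_plan(
            cfg,
            spec.saccule_true_fraction,
            spec.utricle_true_fraction,
            herniation=spec.herniation,
            ring_span_deg=360.0,
        )
    elif site.startswith("canal_"):
        try:
            _, canal, region = site.split("_")
        except ValueError:
            raise ValueError(f"unknown site {site!r}; expected one of {HISTO_SITES}")
        table = (
            spec.canal_duct_fraction_ampullary
            if region == "ampullary"
            else spec.canal_duct_fraction_nonampullary
        )
        if canal not in table:
            raise ValueError(f"unknown site {site!r}; expected one of {HISTO_SITES}")
        plan = G.canal_section_plan(cfg, canal, region, table[canal])
    else:
        raise ValueError(f"unknown site {site!r}; expected one of {HISTO_SITES}")

    shape = spec.grid_shape[:2]
    labels = R.paint_labels(shape, plan.layers, HISTO_SUPERSAMPLE)
    territory = None
    if plan.territory is not None:
        territory = R.rasterize_mask(shape, plan.territory, HISTO_SUPERSAMPLE)
    return SectionImage(
        labels,
        HISTO_PIXEL_SIZE_MM,
        polygons=dict(plan.polygons),
        territory=territory,
        site=site,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupParams:
    """Distribution parameters (mean, SD) per site for one side group.

    Vestibular fractions can be specified either as independent saccule
    and utricle components ('components') or as a combined vestibular
    distribution split in a fixed saccule:utricle proportion
    ('combined_split').
    """

    n: int = 0
    cochlea: tuple[float, float] | None = None
    saccule: tuple[float, float] | None = None
    utricle: tuple[float, float] | None = None
    vestibule: tuple[float, float] | None = None
    vestibule_mode: str = "components"
    saccule_share: float = 0.513 / 0.755
    canal_ampullary: dict | None = None
    canal_nonampullary: dict | None = None
    herniation_probs: dict = field(default_factory=dict)  # kind -> probability

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be nonnegative")
        for name in ("cochlea", "saccule", "utricle", "vestibule"):
            p = getattr(self, name)
            if p is not None and p[1] < 0:
                raise ValueError(f"{name} SD must be nonnegative")
        if self.vestibule_mode not in ("components", "combined_split"):
            raise ValueError(f"unknown vestibule_mode {self.vestibule_mode!r}")
        total = sum(self.herniation_probs.values())
        if not 0.0 <= total <= 1.0 + 1e-12:
            raise ValueError("herniation probabilities must sum to at most 1")


@dataclass
class CohortSpec:
    """Cohort layout: one GroupParams per side plus a master seed."""

    groups: dict[str, GroupParams] = field(default_factory=dict)
    seed: int = 0
    clip_bounds: tuple[float, float] = (0.001, 0.999)
    pair_sum_cap: float = 0.98  # max saccule + utricle after rescaling
    grid_shape: tuple[int, int, int] = (160, 160, 12)
    noise_sd: float = 20.0

    def validate(self) -> None:
        lo, hi = self.clip_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("clip bounds must satisfy 0 < lo < hi < 1")
        for side, g in self.groups.items():
            if side not in SIDES:
                raise ValueError(f"unknown side {side!r}")
            g.validate()


@lru_cache(maxsize=256)
def _compensated_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Proposal mean whose clipped-normal expectation equals `target`.

    Clipping to (lo, hi) pulls the expectation toward the interval
    centre; the exact expectation of a clipped normal has a closed
    form, so the proposal mean solving E[clip(N(m, sd))] = target is
    found by bracketed root-finding.  Keeps every site's draws
    converging to the stated group mean.
    """
    if sd == 0.0:
        return target
    from scipy.optimize import brentq
    from scipy.stats import norm

    def clipped_expectation(m: float) -> float:
        a = (lo - m) / sd
        b = (hi - m) / sd
        return (
            m
            + sd * (norm.pdf(a) - norm.pdf(b))
            + (lo - m) * norm.cdf(a)
            + (hi - m) * (1.0 - norm.cdf(b))
        )

    span = 10.0 * sd
    return float(brentq(lambda m: clipped_expectation(m) - target, lo - span, hi + span))


def _clipped_normal(rng, mean, sd, lo, hi) -> float:
    """One clipped-normal draw, mean-compensated for the clipping."""
    m = _compensated_mean(mean, sd, lo, hi)
    return float(np.clip(rng.normal(m, sd), lo, hi))


@lru_cache(maxsize=64)
def _calibrated_pair_means(
    mean_s: float, sd_s: float, mean_u: float, sd_u: float,
    cap: float, lo: float, hi: float,
) -> tuple[float, float]:
    """Proposal means for the saccule/utricle pair such that, after
    clipping and sum-rescaling, the realized marginal means equal the
    requested ones.

    The rescaling needed to keep every pair inside the vestibule pulls
    the marginal means down; this compensates by shifting the proposal
    means up via a deterministic fixed-point iteration on a common
    random-number stream.  Infeasible targets (sum at or above the cap)
    are returned unchanged.
    """
    if mean_s + mean_u >= cap - 0.01 or (sd_s == 0.0 and sd_u == 0.0):
        return mean_s, mean_u
    rng = np.random.default_rng(987654321)  # internal stream, not cohort seed
    zs = rng.standard_normal(60_000)
    zu = rng.standard_normal(60_000)
    ms, mu = mean_s, mean_u
    for _ in range(6):
        s = np.clip(ms + sd_s * zs, lo, hi)
        u = np.clip(mu + sd_u * zu, lo, hi)
        t = s + u
        f = np.where(t >= cap, cap / t, 1.0)
        ms += mean_s - float(np.maximum(s * f, lo).mean())
        mu += mean_u - float(np.maximum(u * f, lo).mean())
    return ms, mu


def simulate_cohort(
    cohort: CohortSpec,
) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Draw per-ear true fractions and herniation flags for a cohort.

    Fractions are normal draws clipped to `clip_bounds`; a saccule +
    utricle pair whose sum reaches `pair_sum_cap` is rescaled
    proportionally (preserving the saccule:utricle ratio) so the pair
    always fits inside the vestibule.  Fully reproducible from the
    master seed.  Returns a long-format table (one row per ear and
    site) and the matching PhantomSpec list.
    """
    cohort.validate()
    lo, hi = cohort.clip_bounds
    master = np.random.SeedSequence(cohort.seed)
    children = master.spawn(sum(g.n for g in cohort.groups.values()))
    rows: list[dict] = []
    specs: list[PhantomSpec] = []
    idx = 0
    for side in SIDES:
        if side not in cohort.groups:
            continue
        g = cohort.groups[side]
        for k in range(g.n):
            child = children[idx]
            rng = np.random.default_rng(child)
            ear_seed = int(child.generate_state(1)[0] % (2**31))
            ear_id = f"{side}-{k:03d}"
            idx += 1

            draws: dict[str, float] = {}
            if g.cochlea is not None:
                draws["cochlea"] = _clipped_normal(rng, *g.cochlea, lo, hi)
            if g.vestibule_mode == "components" and g.saccule is not None:
                ms, mu = _calibrated_pair_means(
                    g.saccule[0], g.saccule[1], g.utricle[0], g.utricle[1],
                    cohort.pair_sum_cap, lo, hi,
                )
                # raw clip here: the pair calibration already targets the
                # final post-rescale means
                s = float(np.clip(rng.normal(ms, g.saccule[1]), lo, hi))
                u = float(np.clip(rng.normal(mu, g.utricle[1]), lo, hi))
                if s + u >= cohort.pair_sum_cap:
                    f = cohort.pair_sum_cap / (s + u)
                    s, u = max(s * f, lo), max(u * f, lo)
                draws["saccule"], draws["utricle"] = s, u
                draws["vestibule"] = s + u
            elif g.vestibule_mode == "combined_split" and g.vestibule is not None:
                c = _clipped_normal(rng, *g.vestibule, lo, hi)
                draws["vestibule"] = c
                draws["saccule"] = max(c * g.saccule_share, lo)
                draws["utricle"] = max(c * (1.0 - g.saccule_share), lo)
            for region, table in (
                ("ampullary", g.canal_ampullary),
                ("nonampullary", g.canal_nonampullary),
            ):
                if table:
                    for canal, (m, sd) in table.items():
                        draws[f"canal_{canal}_{region}"] = _clipped_normal(
                            rng, m, sd, lo, hi
                        )

            kinds = list(g.herniation_probs)
            probs = [g.herniation_probs[kk] for kk in kinds]
            p_none = 1.0 - sum(probs)
            herniation = str(
                rng.choice(kinds + ["none"], p=probs + [p_none])
            ) if kinds else "none"

            spec = PhantomSpec(
                ear_id=ear_id,
                side=side,
                grid_shape=cohort.grid_shape,
                cochlea_true_fraction=draws.get("cochlea", 0.2),
                saccule_true_fraction=draws.get("saccule", 0.3),
                utricle_true_fraction=draws.get("utricle", 0.2),
                canal_duct_fraction_ampullary={
                    c: draws.get(f"canal_{c}_ampullary", 0.5) for c in L.CANALS
                },
                canal_duct_fraction_nonampullary={
                    c: draws.get(f"canal_{c}_nonampullary", 0.5) for c in L.CANALS
                },
                herniation=herniation,
                noise_sd=cohort.noise_sd,
                seed=ear_seed,
            )
            specs.append(spec)
            for site, value in draws.items():
                rows.append(
                    dict(
                        ear_id=ear_id,
                        side=side,
                        site=site,
                        true_fraction=value,
                        herniation=herniation,
                    )
                )
    table = pd.DataFrame(rows, columns=["ear_id", "side", "site", "true_fraction", "herniation"])
    return table, specs


def cohort_from_dict(config: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (e.g. parsed YAML).

    Schema: top-level keys seed, clip_bounds, pair_sum_cap, grid_shape,
    noise_sd, and groups: {side: {n, cochlea: [mean, sd], saccule,
    utricle, vestibule, vestibule_mode, saccule_share, canal_ampullary:
    {canal: [mean, sd]}, canal_nonampullary, herniation_probs}}.
    """
    groups = {}
    for side, g in dict(config.get("groups", {})).items():
        kwargs: dict = {"n": int(g.get("n", 0))}
        for site in ("cochlea", "saccule", "utricle", "vestibule"):
            if g.get(site) is not None:
                m, sd = g[site]
                kwargs[site] = (float(m), float(sd))
        for key in ("vestibule_mode", "saccule_share"):
            if key in g:
                kwargs[key] = g[key]
        for key in ("canal_ampullary", "canal_nonampullary"):
            if g.get(key):
                kwargs[key] = {c: (float(m), float(sd)) for c, (m, sd) in g[key].items()}
        if g.get("herniation_probs"):
            kwargs["herniation_probs"] = {
                k: float(v) for k, v in g["herniation_probs"].items()
            }
        groups[side] = GroupParams(**kwargs)
    kwargs = {"groups": groups}
    for key in ("seed", "noise_sd", "pair_sum_cap"):
        if key in config:
            kwargs[key] = config[key]
    for key in ("clip_bounds", "grid_shape"):
        if key in config:
            kwargs[key] = tuple(config[key])
    return CohortSpec(**kwargs)


# ---------------------------------------------------------------------------
# reference cohorts: the two study populations the generator emulates


def histology_reference_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """Temporal-bone series: 54 affected ears, 18 unaffected, 17 controls."""
    affected = GroupParams(
        n=54,
        cochlea=(0.314, 0.118),
        saccule=(0.513, 0.214),
        utricle=(0.242, 0.124),
        vestibule_mode="components",
        canal_ampullary={
            "anterior": (0.565, 0.096),
            "lateral": (0.511, 0.158),
            "posterior": (0.518, 0.068),
        },
        canal_nonampullary={
            "anterior": (0.565, 0.096),
            "lateral": (0.511, 0.158),
            "posterior": (0.518, 0.068),
        },
        herniation_probs={"saccular": 15 / 54, "utricular": 9 / 54},
    )
    unaffected = GroupParams(
        n=18,
        canal_ampullary={
            "anterior": (0.515, 0.050),
            "lateral": (0.456, 0.092),
            "posterior": (0.491, 0.080),
        },
        canal_nonampullary={
            "anterior": (0.515, 0.050),
            "lateral": (0.456, 0.092),
            "posterior": (0.491, 0.080),
        },
    )
    control = GroupParams(
        n=17,
        cochlea=(0.064, 0.022),
        vestibule=(0.289, 0.062),
        vestibule_mode="combined_split",
        canal_ampullary=dict(unaffected.canal_ampullary),
        canal_nonampullary=dict(unaffected.canal_nonampullary),
    )
    spec = CohortSpec(
        groups={"affected": affected, "unaffected": unaffected, "control": control},
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def mri_reference_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """MR imaging series: 72 affected ears, negative-pixel measurement."""
    affected = GroupParams(
        n=72,
        cochlea=(0.372, 0.164),
        vestibule=(0.533, 0.250),
        vestibule_mode="combined_split",
        herniation_probs={"saccular": 29 / 72},
    )
    spec = CohortSpec(groups={"affected": affected}, seed=seed)
    return replace(spec, **overrides) if overrides else spec
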