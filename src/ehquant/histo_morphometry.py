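"""Area-ratio morphometry on labeled histology-style sections.

All areas are label pixel counts times pixel area; ratios therefore
cancel the pixel size.  The cochlear EH ratio sums the scala-media area
over the basal, middle and apical turns and divides by the whole
(fluid) cochlear area.  Vestibular ratios divide the saccule and
utricle areas (separately and combined) by the entire vestibule area.
Canal ratios divide the membranous duct area by the canal
cross-sectional area, the orientation that keeps the value in [0, 1].
Herniation of an otolithic organ into the lateral canal is called from
its pixel overlap with the canal-territory region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import labels as L
from .eh_ratio import EHMeasurement
from .volumes import LabelVolume, SectionImage

HERNIATION_CALLS = ("none", "saccular", "utricular", "both")


@dataclass(frozen=True)
class HerniationCall:
    ear_id: str
    call: str
    saccule_overlap_pixels: int
    utricle_overlap_pixels: int

    def __post_init__(self) -> None:
        if self.call not in HERNIATION_CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _measure(site, side, num, den, ear_id) -> EHMeasurement:
    return EHMeasurement(
        site=site,
        side=side,
        ratio=num / den,
        numerator_pixels=int(num),
        denominator_pixels=int(den),
        method="histo_area",
        ear_id=ear_id,
    )


def histo_cochlea_ratio(
    section: SectionImage, side: str = "affected", ear_id: str = ""
) -> EHMeasurement:
    """Sum of scala-media areas over the three turns, divided by the
    whole cochlear fluid area."""
    sm = 0
    total = 0
    for turn in L.TURNS:
        n_sm = int(section.mask(L.SCALA_MEDIA[turn]).sum())
        n_peri = int(section.mask(L.COCHLEA_PERI[turn]).sum())
        if n_sm + n_peri == 0:
            raise ValueError(f"missing {turn} turn in section")
        sm += n_sm
        total += n_sm + n_peri
    return _measure("cochlea", side, sm, total, ear_id)


def histo_vestibule_ratios(
    section: SectionImage, side: str = "affected", ear_id: str = ""
) -> tuple[EHMeasurement, EHMeasurement, EHMeasurement]:
    """(combined, saccular, utricular) vestibular EH ratios.

    The denominator is the entire vestibule area (perilymph plus both
    organ contours); combined = saccular + utricular exactly, by
    additivity of disjoint label counts.
    """
    n_sac = int(section.mask(L.SACCULE).sum())
    n_utr = int(section.mask(L.UTRICLE).sum())
    n_peri = int(section.mask(L.VESTIBULE_PERI).sum())
    vestibule = n_sac + n_utr + n_peri
    if vestibule == 0:
        raise ValueError("vestibule area is zero")
    combined = _measure("vestibule", side, n_sac + n_utr, vestibule, ear_id)
    saccular = _measure("saccule", side, n_sac, vestibule, ear_id)
    utricular = _measure("utricle", side, n_utr, vestibule, ear_id)
    return combined, saccular, utricular


def histo_canal_ratio(
    section: SectionImage,
    canal: str,
    region: str,
    side: str = "affected",
    ear_id: str = "",
) -> EHMeasurement:
    """Membranous duct area / canal cross-sectional area for one canal
    at the ampullary or non-ampullary region."""
    if canal not in L.CANALS:
        raise ValueError(f"unknown canal {canal!r}")
    if region not in ("ampullary", "nonampullary"):
        raise ValueError(f"unknown region {region!r}")
    n_duct = int(section.mask(L.CANAL_DUCT[canal]).sum())
    n_cross = n_duct + int(section.mask(L.CANAL_CROSS[canal]).sum())
    if n_cross == 0:
        raise ValueError(f"{canal} canal cross-section area is zero")
    return _measure(f"canal_{canal}_{region}", side, n_duct, n_cross, ear_id)


def detect_herniation(
    section_or_labels: SectionImage | LabelVolume,
    min_overlap_pixels: int = 1,
    ear_id: str = "",
) -> HerniationCall:
    """Flag an organ as herniated when its overlap with the lateral-canal
    territory reaches `min_overlap_pixels` (default: any protrusion)."""
    obj = section_or_labels
    territory = obj.territory
    if isinstance(obj, SectionImage):
        lab = obj.labels
    else:
        lab = obj.data
    sac = int(((lab == L.SACCULE) & territory).sum())
    utr = int(((lab == L.UTRICLE) & territory).sum())
    sac_h = sac >= min_overlap_pixels
    utr_h = utr >= min_overlap_pixels
    call = {
        (False, False): "none",
        (True, False): "saccular",
        (False, True): "utricular",
        (True, True): "both",
    }[(sac_h, utr_h)]
    return HerniationCall(ear_id, call, sac, utr)


def measurements_frame(measurements: list[EHMeasurement]) -> pd.DataFrame:
    """Tidy table of EHMeasurement records."""
    return pd.DataFrame(
        [
            dict(
                ear_id=m.ear_id,
                site=m.site,
                side=m.side,
                method=m.method,
                numerator=m.numerator_pixels,
                denominator=m.denominator_pixels,
                ratio=m.ratio,
            )
            for m in measurements
        ]
    )


def summarize_cohort(
    measurements: pd.DataFrame | list[EHMeasurement],
    calls: list[HerniationCall] | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary (n, mean, SD per site/side/method) plus
    herniation proportions with numerators and denominators recorded.

    SD uses the n-1 convention and is reported as NaN for n = 1.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = measurements_frame(measurements)
    if measurements.empty:
        raise ValueError("no measurements to summarize")
    bad = set(measurements["side"]) - {"affected", "unaffected", "control"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    summary = (
        measurements.groupby(["site", "side", "method"])["ratio"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )

    if calls is None:
        return summary, pd.DataFrame(
            columns=["call", "count", "total", "proportion"]
        )
    if isinstance(calls, pd.DataFrame):
        call_series = calls["call"]
    else:
        call_series = pd.Series([c.call for c in calls])
    total = int(call_series.size)
    if total == 0:
        raise ValueError("no herniation calls to summarize")
    rows = []
    for kind in ("saccular", "utricular", "both"):
        cnt = int((call_series == kind).sum())
        rows.append(dict(call=kind, count=cnt, total=total, proportion=cnt / total))
    any_cnt = int((call_series != "none").sum())
    rows.append(
        dict(call="any_extension", count=any_cnt, total=total, proportion=any_cnt / total)
    )
    return summary, pd.DataFrame(rows)
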