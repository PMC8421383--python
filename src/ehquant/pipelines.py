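"""End-to-end cohort pipelines: generate phantoms, measure, tabulate.

These are the orchestration routines the command-line interface and the
reproduction script drive: render each synthetic ear, run the relevant
measurement route (histology area ratios or MRI negative-pixel ratios),
and collect tidy measurement tables ready for `summarize_cohort` and
`run_validation_suite`.
"""

from __future__ import annotations

import pandas as pd

from . import phantom as P
from .eh_ratio import eh_ratio_mri
from .histo_morphometry import (
    HerniationCall,
    detect_herniation,
    histo_canal_ratio,
    histo_cochlea_ratio,
    histo_vestibule_ratios,
    measurements_frame,
)
from .mr_compose import compose_hydrops, compose_mi2
from .roi_select import cochlea_roi, select_vestibule_slice

VESTIBULE_SITES = {"vestibule", "saccule", "utricle"}


def measure_histology_cohort(
    cohort: P.CohortSpec, sites: set[str] | None = None
) -> tuple[pd.DataFrame, list[HerniationCall]]:
    """Render histology sections for every ear and measure area ratios.

    `sites` restricts which measurement sites are rendered (default: all
    sites the cohort draws fractions for).  Returns the tidy measurement
    table and per-ear herniation calls (for ears with a vestibule site).
    """
    table, specs = P.simulate_cohort(cohort)
    by_ear = dict(tuple(table.groupby("ear_id", sort=False)))
    measurements = []
    calls: list[HerniationCall] = []
    for spec in specs:
        ear_sites = set(by_ear[spec.ear_id]["site"])
        if sites is not None:
            ear_sites &= sites
        if "cochlea" in ear_sites:
            section = P.render_histo_section(spec, "cochlea")
            measurements.append(histo_cochlea_ratio(section, spec.side, spec.ear_id))
        if ear_sites & VESTIBULE_SITES:
            section = P.render_histo_section(spec, "vestibule")
            measurements.extend(histo_vestibule_ratios(section, spec.side, spec.ear_id))
            calls.append(detect_herniation(section, ear_id=spec.ear_id))
        for site in sorted(ear_sites):
            if site.startswith("canal_"):
                _, canal, region = site.split("_")
                section = P.render_histo_section(spec, site)
                measurements.append(
                    histo_canal_ratio(section, canal, region, spec.side, spec.ear_id)
                )
    return measurements_frame(measurements), calls


def measure_mri_cohort(
    cohort: P.CohortSpec, sites: set[str] | None = None
) -> pd.DataFrame:
    """Full MR route per ear: render contrasts, compose HYDROPS and
    HYDROPS-Mi2, select the rule-based ROI slices, count negative pixels."""
    if sites is None:
        sites = {"cochlea", "vestibule"}
    table, specs = P.simulate_cohort(cohort)
    by_ear = dict(tuple(table.groupby("ear_id", sort=False)))
    measurements = []
    for spec in specs:
        ear_sites = set(by_ear[spec.ear_id]["site"]) & sites
        if not ear_sites:
            continue
        mrc, ppi, pei, labels = P.render_mr_phantom(spec)
        mi2 = compose_mi2(compose_hydrops(ppi, pei), mrc)
        if "cochlea" in ear_sites:
            roi = cochlea_roi(labels)
            measurements.append(eh_ratio_mri(mi2, roi, spec.side, spec.ear_id))
        if "vestibule" in ear_sites:
            _, roi = select_vestibule_slice(labels)
            measurements.append(eh_ratio_mri(mi2, roi, spec.side, spec.ear_id))
    return measurements_frame(measurements)
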