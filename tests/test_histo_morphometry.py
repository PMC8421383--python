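"""Area-ratio morphometry and herniation calling on labeled sections."""

import numpy as np
import pandas as pd
import pytest

import ehquant as eq
from ehquant import labels as L
from ehquant.eh_ratio import EHMeasurement
from ehquant.volumes import SectionImage


def section_from_counts(counts: dict[int, int], shape=(40, 40)) -> SectionImage:
    """Flat section with exact pixel counts per label."""
    data = np.zeros(shape, dtype=np.int16).ravel()
    pos = 0
    for label, n in counts.items():
        data[pos : pos + n] = label
        pos += n
    assert pos <= data.size
    return SectionImage(data.reshape(shape), pixel_size_mm=0.01)


class TestCochleaRatio:
    def test_all_scala_media_gives_one(self):
        sec = section_from_counts(
            {L.SCALA_MEDIA_BASAL: 30, L.SCALA_MEDIA_MIDDLE: 20, L.SCALA_MEDIA_APICAL: 10}
        )
        assert eq.histo_cochlea_ratio(sec).ratio == 1.0

    def test_no_scala_media_gives_zero(self):
        sec = section_from_counts(
            {L.COCHLEA_PERI_BASAL: 30, L.COCHLEA_PERI_MIDDLE: 20, L.COCHLEA_PERI_APICAL: 10}
        )
        assert eq.histo_cochlea_ratio(sec).ratio == 0.0

    def test_missing_turn_names_it(self):
        sec = section_from_counts(
            {L.COCHLEA_PERI_BASAL: 30, L.COCHLEA_PERI_MIDDLE: 20}
        )
        with pytest.raises(ValueError, match="apical"):
            eq.histo_cochlea_ratio(sec)

    def test_rendered_section_recovers_group_mean_fraction(self):
        spec = eq.PhantomSpec(cochlea_true_fraction=0.314, noise_sd=0.0, seed=2)
        sec = eq.render_histo_section(spec, "cochlea")
        assert abs(eq.histo_cochlea_ratio(sec).ratio - 0.314) < 0.01


class TestVestibuleRatios:
    def test_printed_group_consistency(self):
        """Saccule 0.513 V and utricle 0.242 V combine to 0.755 V."""
        sec = section_from_counts({L.SACCULE: 513, L.UTRICLE: 242, L.VESTIBULE_PERI: 245})
        combined, sac, utr = eq.histo_vestibule_ratios(sec)
        assert sac.ratio == pytest.approx(0.513)
        assert utr.ratio == pytest.approx(0.242)
        assert combined.ratio == pytest.approx(0.755)

    def test_no_organs_gives_zeros(self):
        sec = section_from_counts({L.VESTIBULE_PERI: 100})
        combined, sac, utr = eq.histo_vestibule_ratios(sec)
        assert (combined.ratio, sac.ratio, utr.ratio) == (0.0, 0.0, 0.0)

    def test_zero_vestibule_area_rejected(self):
        sec = section_from_counts({L.MODIOLUS: 10})
        with pytest.raises(ValueError, match="vestibule"):
            eq.histo_vestibule_ratios(sec)

    def test_combined_is_exact_sum(self, vestibule_section):
        combined, sac, utr = eq.histo_vestibule_ratios(vestibule_section)
        assert combined.ratio == sac.ratio + utr.ratio  # exact, same denominator
        assert (
            combined.numerator_pixels
            == sac.numerator_pixels + utr.numerator_pixels
        )


class TestCanalRatio:
    def test_duct_fills_cross_section(self):
        sec = section_from_counts({L.CANAL_DUCT_ANTERIOR: 50})
        assert eq.histo_canal_ratio(sec, "anterior", "ampullary").ratio == 1.0

    def test_duct_absent(self):
        sec = section_from_counts({L.CANAL_CROSS_ANTERIOR: 50})
        assert eq.histo_canal_ratio(sec, "anterior", "ampullary").ratio == 0.0

    def test_rendered_duct_fraction_recovered(self):
        spec = eq.PhantomSpec(
            noise_sd=0.0,
            seed=4,
            canal_duct_fraction_ampullary={
                "anterior": 0.565, "lateral": 0.5, "posterior": 0.5
            },
        )
        sec = eq.render_histo_section(spec, "canal_anterior_ampullary")
        m = eq.histo_canal_ratio(sec, "anterior", "ampullary")
        assert abs(m.ratio - 0.565) < 0.01

    def test_zero_cross_section_rejected(self):
        sec = section_from_counts({L.VESTIBULE_PERI: 10})
        with pytest.raises(ValueError, match="cross-section"):
            eq.histo_canal_ratio(sec, "lateral", "nonampullary")


class TestHerniationDetection:
    def make_section(self, overlap_sac=0, overlap_utr=0):
        data = np.zeros((20, 20), dtype=np.int16)
        territory = np.zeros((20, 20), dtype=bool)
        territory[10:, :] = True
        data[0, :5] = L.SACCULE
        data[1, :5] = L.UTRICLE
        if overlap_sac:
            data[10, :overlap_sac] = L.SACCULE
        if overlap_utr:
            data[11, :overlap_utr] = L.UTRICLE
        return SectionImage(data, 0.01, territory=territory)

    @pytest.mark.parametrize(
        "sac,utr,expected",
        [(0, 0, "none"), (3, 0, "saccular"), (0, 2, "utricular"), (2, 2, "both")],
    )
    def test_calls_from_overlap(self, sac, utr, expected):
        call = eq.detect_herniation(self.make_section(sac, utr))
        assert call.call == expected
        assert call.saccule_overlap_pixels == sac
        assert call.utricle_overlap_pixels == utr

    def test_min_overlap_threshold(self):
        sec = self.make_section(overlap_sac=2)
        assert eq.detect_herniation(sec, min_overlap_pixels=3).call == "none"

    def test_translation_invariance(self):
        sec = self.make_section(overlap_sac=3)
        shifted = SectionImage(
            np.roll(sec.labels, (2, 3), axis=(0, 1)),
            sec.pixel_size_mm,
            territory=np.roll(sec.territory, (2, 3), axis=(0, 1)),
        )
        assert eq.detect_herniation(shifted).call == eq.detect_herniation(sec).call


def fixture_measurements(side, site, values):
    return [
        EHMeasurement(site, side, v, int(v * 1000), 1000, "histo_area", f"e{i}")
        for i, v in enumerate(values)
    ]


class TestSummarizeCohort:
    def test_single_measurement_sd_not_available(self):
        summary, _ = eq.summarize_cohort(fixture_measurements("affected", "cochlea", [0.4]))
        row = summary.iloc[0]
        assert row["n"] == 1 and row["mean"] == 0.4 and np.isnan(row["sd"])

    def test_constant_groups_exact_means(self):
        ms = fixture_measurements("affected", "cochlea", [0.3, 0.3]) + fixture_measurements(
            "control", "cochlea", [0.1, 0.1]
        )
        summary, _ = eq.summarize_cohort(ms)
        by_side = summary.set_index("side")["mean"]
        assert by_side["affected"] == 0.3 and by_side["control"] == 0.1

    def test_printed_extension_proportions_exact(self):
        """Herniation fixture counts reproduce the printed percentages:
        24/54 = 44.4% on histology, 29/72 = 40.3% on MRI."""
        histo_calls = pd.DataFrame(
            {"call": ["saccular"] * 15 + ["utricular"] * 9 + ["none"] * 30}
        )
        ms = fixture_measurements("affected", "vestibule", [0.5] * 3)
        _, props = eq.summarize_cohort(ms, histo_calls)
        any_row = props.set_index("call").loc["any_extension"]
        assert (any_row["count"], any_row["total"]) == (24, 54)
        assert round(100 * any_row["proportion"], 1) == 44.4

        mri_calls = pd.DataFrame({"call": ["saccular"] * 29 + ["none"] * 43})
        _, props = eq.summarize_cohort(ms, mri_calls)
        any_row = props.set_index("call").loc["any_extension"]
        assert (any_row["count"], any_row["total"]) == (29, 72)
        assert round(100 * any_row["proportion"], 1) == 40.3

    def test_unknown_group_label_rejected(self):
        from ehquant.histo_morphometry import measurements_frame

        frame = measurements_frame(fixture_measurements("affected", "cochlea", [0.3] * 2))
        frame.loc[0, "side"] = "sick"
        with pytest.raises(ValueError, match="sick"):
            eq.summarize_cohort(frame)

    def test_empty_measurements_rejected(self):
        with pytest.raises(ValueError):
            eq.summarize_cohort(pd.DataFrame(columns=["site", "side", "method", "ratio"]))
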