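"""Phantom generator: geometry fidelity, determinism, cohort sampling."""

import numpy as np
import pytest

import ehquant as eq
from ehquant import labels as L
from ehquant.phantom import GroupParams

from conftest import shoelace_area


def small_spec(**kw):
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("seed", 3)
    return eq.PhantomSpec(**kw)


class TestMRPhantom:
    def test_same_seed_bit_identical(self):
        spec = eq.PhantomSpec(seed=11, noise_sd=15.0)
        a = eq.render_mr_phantom(spec)
        b = eq.render_mr_phantom(spec)
        for va, vb in zip(a[:3], b[:3]):
            np.testing.assert_array_equal(va.data, vb.data)
        np.testing.assert_array_equal(a[3].data, b[3].data)

    def test_noiseless_subtraction_signs(self, noiseless_mr):
        """Perilymph strictly positive, endolymph strictly negative, and
        background zero on PPI - PEI, voxel by voxel."""
        mrc, ppi, pei, labels = noiseless_mr
        diff = ppi.data - pei.data
        endo = labels.endolymph_mask()
        peri = labels.perilymph_mask()
        assert (diff[endo] < 0).all()
        assert (diff[peri] > 0).all()
        assert (diff[~endo & ~peri] == 0).all()

    def test_vestibular_label_fraction_matches_spec(self):
        """Saccule 0.5 + utricle 0.25 yields an endolymph fraction of
        0.75 on the selected vestibular slice, within raster tolerance."""
        spec = small_spec(saccule_true_fraction=0.5, utricle_true_fraction=0.25)
        labels = eq.render_labels(spec)
        _, roi = eq.select_vestibule_slice(labels)
        plane = labels.data[:, :, roi.slice_index]
        frac = np.isin(plane[roi.mask], [L.SACCULE, L.UTRICLE]).mean()
        assert abs(frac - 0.75) < 0.02

    def test_vestibule_area_conservation(self, noiseless_mr):
        """Saccule + utricle + vestibular perilymph partition the
        vestibule exactly on the label grid (no herniation)."""
        labels = noiseless_mr[3]
        n = [int((labels.data == lab).sum()) for lab in (L.SACCULE, L.UTRICLE, L.VESTIBULE_PERI)]
        total = int(np.isin(labels.data, [L.SACCULE, L.UTRICLE, L.VESTIBULE_PERI]).sum())
        assert sum(n) == total
        # organs never leak into the canal territory without herniation
        organs = np.isin(labels.data, [L.SACCULE, L.UTRICLE])
        assert not (organs & labels.territory).any()

    def test_territory_disjoint_from_vestibule(self, noiseless_mr):
        labels = noiseless_mr[3]
        vest = np.isin(labels.data, [L.VESTIBULE_PERI, L.SACCULE, L.UTRICLE])
        assert not (vest & labels.territory).any()

    def test_clipped_geometry_raises_with_structure_name(self):
        with pytest.raises(ValueError, match="vestibule"):
            eq.render_labels(small_spec(grid_shape=(160, 120, 12)))
        with pytest.raises(ValueError, match="ring"):
            eq.render_labels(small_spec(grid_shape=(140, 160, 12)))

    def test_invalid_signal_ordering_rejected(self):
        bad = eq.SignalModel(ppi={"bone": 5.0, "perilymph": 400.0, "endolymph": 500.0})
        with pytest.raises(ValueError, match="endolymph"):
            eq.render_mr_phantom(small_spec(signal=bad))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            eq.render_labels(small_spec(cochlea_true_fraction=1.2))
        with pytest.raises(ValueError):
            eq.render_labels(
                small_spec(saccule_true_fraction=0.6, utricle_true_fraction=0.5)
            )


class TestHistoSections:
    def test_cochlea_fraction_against_polygon_oracle(self):
        """Rasterized scala-media share matches both the requested
        fraction and the shoelace area of the generating polygons."""
        spec = small_spec(cochlea_true_fraction=0.5)
        sec = eq.render_histo_section(spec, "cochlea")
        m = eq.histo_cochlea_ratio(sec)
        assert abs(m.ratio - 0.5) < 0.01
        poly_sm = sum(shoelace_area(sec.polygons[f"scala_media_{t}"]) for t in L.TURNS)
        poly_total = sum(
            shoelace_area(sec.polygons[f"cochlea_turn_{t}"]) for t in L.TURNS
        )
        assert abs(m.ratio - poly_sm / poly_total) < 0.01

    def test_polygon_areas_agree_with_raster(self, vestibule_section):
        sec = vestibule_section
        for name, lab in (("saccule", L.SACCULE), ("utricle", L.UTRICLE)):
            raster = float(sec.mask(lab).sum())
            poly = shoelace_area(sec.polygons[name])
            assert abs(raster - poly) / poly < 0.02

    def test_herniation_round_trip(self):
        for kind, expected in (
            ("none", "none"),
            ("saccular", "saccular"),
            ("utricular", "utricular"),
            ("both", "both"),
        ):
            sec = eq.render_histo_section(small_spec(herniation=kind), "vestibule")
            assert eq.detect_herniation(sec).call == expected

    def test_herniated_organ_pixels_inside_territory(self):
        sec = eq.render_histo_section(small_spec(herniation="saccular"), "vestibule")
        assert ((sec.labels == L.SACCULE) & sec.territory).sum() >= 1

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError, match="site"):
            eq.render_histo_section(small_spec(), "stapes")

    @pytest.mark.parametrize("seed", range(8))
    def test_fraction_round_trip_random_specs(self, seed):
        """Noiseless phantoms: measured ratios recover the spec's true
        fractions within rasterization tolerance."""
        rng = np.random.default_rng(seed)
        f_c = rng.uniform(0.05, 0.95)
        f_s = rng.uniform(0.05, 0.6)
        f_u = rng.uniform(0.05, min(0.9 - f_s, 0.4))
        f_k = rng.uniform(0.05, 0.95)
        spec = small_spec(
            cochlea_true_fraction=f_c,
            saccule_true_fraction=f_s,
            utricle_true_fraction=f_u,
            canal_duct_fraction_ampullary={
                "anterior": f_k, "lateral": f_k, "posterior": f_k
            },
            seed=seed,
        )
        assert abs(eq.histo_cochlea_ratio(
            eq.render_histo_section(spec, "cochlea")).ratio - f_c) < 0.01
        comb, sac, utr = eq.histo_vestibule_ratios(
            eq.render_histo_section(spec, "vestibule"))
        assert abs(sac.ratio - f_s) < 0.01
        assert abs(utr.ratio - f_u) < 0.01
        assert abs(comb.ratio - (f_s + f_u)) < 0.015
        m = eq.histo_canal_ratio(
            eq.render_histo_section(spec, "canal_anterior_ampullary"),
            "anterior", "ampullary")
        assert abs(m.ratio - f_k) < 0.01


class TestCohortSimulation:
    def test_same_seed_identical_tables(self):
        cohort = eq.histology_reference_cohort(seed=5)
        t1, s1 = eq.simulate_cohort(cohort)
        t2, s2 = eq.simulate_cohort(cohort)
        assert t1.equals(t2)
        assert [s.seed for s in s1] == [s.seed for s in s2]

    def test_zero_sd_draws_equal_mean(self):
        cohort = eq.CohortSpec(
            groups={"affected": GroupParams(n=5, cochlea=(0.3, 0.0))}, seed=1
        )
        table, _ = eq.simulate_cohort(cohort)
        assert (table.loc[table.site == "cochlea", "true_fraction"] == 0.3).all()

    def test_large_cohort_mean_recovers_parameter(self):
        """Clipped-normal draws at mean 0.314, SD 0.118: the n = 10 000
        sample mean stays within 0.004 of the parameter."""
        cohort = eq.CohortSpec(
            groups={"affected": GroupParams(n=10_000, cochlea=(0.314, 0.118))}, seed=2
        )
        table, _ = eq.simulate_cohort(cohort)
        mean = table.loc[table.site == "cochlea", "true_fraction"].mean()
        assert abs(mean - 0.314) <= 0.004

    def test_component_pair_means_converge_despite_sum_constraint(self):
        """The saccule/utricle pair sampler is mean-unbiased: at
        n = 20 000 both realized means sit within 0.01 of the group
        parameters even though ~18% of raw pairs need rescaling."""
        cohort = eq.CohortSpec(
            groups={
                "affected": GroupParams(
                    n=20_000, saccule=(0.513, 0.214), utricle=(0.242, 0.124)
                )
            },
            seed=9,
        )
        table, _ = eq.simulate_cohort(cohort)
        sac = table[table.site == "saccule"]["true_fraction"]
        utr = table[table.site == "utricle"]["true_fraction"]
        assert abs(sac.mean() - 0.513) < 0.01
        assert abs(utr.mean() - 0.242) < 0.01

    def test_draws_respect_bounds_and_pair_cap(self):
        cohort = eq.CohortSpec(
            groups={
                "affected": GroupParams(
                    n=400, saccule=(0.7, 0.3), utricle=(0.5, 0.3)
                )
            },
            seed=3,
        )
        table, specs = eq.simulate_cohort(cohort)
        f = table["true_fraction"]
        assert ((f >= 0.001) & (f <= 0.999)).all()
        for s in specs:
            assert s.saccule_true_fraction + s.utricle_true_fraction < 1.0

    def test_herniation_probabilities_draw_flags(self):
        cohort = eq.CohortSpec(
            groups={
                "affected": GroupParams(
                    n=300,
                    cochlea=(0.3, 0.1),
                    herniation_probs={"saccular": 0.5, "utricular": 0.25},
                )
            },
            seed=4,
        )
        table, _ = eq.simulate_cohort(cohort)
        per_ear = table.groupby("ear_id")["herniation"].first()
        frac_sac = (per_ear == "saccular").mean()
        assert abs(frac_sac - 0.5) < 0.1
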