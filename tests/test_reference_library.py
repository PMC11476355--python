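"""Compound records, band assignments, formula masses and the generator."""

import numpy as np
import pytest

from steviaraman import (BlendSpec, compounds, get_compound, list_assignments,
                         mw_from_formula, synth_spectrum)
from steviaraman.bandfit import Band
from steviaraman.reference_library import (ASSIGNMENTS, CARBONYL_CLASS_CENTERS,
                                           DEFAULT_NOISE_SIGMA)


class TestCompoundTable:
    def test_exactly_twelve_unique_records(self):
        recs = compounds()
        assert len(recs) == 12
        assert len({c.name for c in recs}) == 12

    def test_ring_totals_are_consistent(self):
        for c in compounds():
            assert c.rings_total == c.rings_c19 + c.rings_c13
            assert c.rings_c19 >= 0 and c.rings_c13 >= 0

    def test_every_mass_matches_its_formula(self):
        for c in compounds():
            assert mw_from_formula(c.formula) == pytest.approx(c.mw, abs=0.05)

    @pytest.mark.parametrize("name,c19,c13,mw", [
        ("Rebaudioside M", 3, 3, 1291.29),
        ("Rubusoside", 1, 1, 642.73),
        ("Dulcoside A", 1, 2, 788.87),
    ])
    def test_reference_records(self, name, c19, c13, mw):
        rec = get_compound(name)
        assert (rec.rings_c19, rec.rings_c13) == (c19, c13)
        assert rec.mw == pytest.approx(mw, abs=0.01)

    def test_lookup_is_case_insensitive_with_alias(self):
        assert get_compound("rebaudioside m").name == "Rebaudioside M"
        assert get_compound("Rebaudioside X").name == "Rebaudioside M"

    def test_unknown_name_lists_valid_compounds(self):
        with pytest.raises(KeyError, match="Rebaudioside A"):
            get_compound("Sucrose")


class TestFormulaMass:
    @pytest.mark.parametrize("formula,expected,tol", [
        ("C44H70O23", 967.01, 0.02),
        ("C56H90O33", 1291.29, 0.02),
        ("C38H60O17", 788.87, 0.02),
        ("H2O", 18.02, 0.01),
    ])
    def test_reference_masses(self, formula, expected, tol):
        assert mw_from_formula(formula) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", ["", "C44H70N2", "44C", "CxH2", "C0H2"])
    def test_malformed_or_unsupported_formulas(self, bad):
        with pytest.raises(ValueError):
            mw_from_formula(bad)


class TestAssignments:
    def test_parameter_defining_centers_present_once(self):
        for center in (887.0, 898.0, 1192.0, 1204.0, 1215.0):
            hits = [a for a in ASSIGNMENTS if a.center == center]
            assert len(hits) == 1, center

    def test_every_center_inside_its_window(self):
        for a in list_assignments():
            lo, hi = a.window
            assert lo <= a.center <= hi

    def test_aglycone_filter_includes_core_modes(self):
        centers = {a.center for a in list_assignments("aglycone_core")}
        assert {740.0, 898.0, 1204.0, 1670.0, 1738.0} <= centers

    def test_extraneous_filter_includes_adulterant_marker(self):
        centers = {a.center for a in list_assignments("extraneous")}
        assert 869.0 in centers

    def test_carbonyl_class_anchors(self):
        assert CARBONYL_CLASS_CENTERS[0] == 1706.0
        assert CARBONYL_CLASS_CENTERS[1] == 1719.0
        assert CARBONYL_CLASS_CENTERS["linked"] == 1738.0


class TestGenerator:
    def test_pure_compound_truth_round_trip(self):
        s, truth = synth_spectrum("Rebaudioside M")
        # carbonyl placed at the 3-ring class center
        assert truth.nu_co == CARBONYL_CLASS_CENTERS[3]
        # recomputing R1 from the injected areas reproduces the stored ratio
        assert truth.r1 == pytest.approx(truth.areas[887.0] / truth.areas[898.0],
                                         abs=1e-12)
        assert np.isfinite(s.intensity).all()

    def test_determinism_per_seed(self):
        spec = BlendSpec(components=(("Stevioside", 0.5), ("Rebaudioside A", 0.5)),
                         noise_sigma=DEFAULT_NOISE_SIGMA, seed=11)
        s1, _ = synth_spectrum(spec)
        s2, _ = synth_spectrum(spec)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_blend_r1_lies_between_pure_components(self):
        _, t_stev = synth_spectrum("Stevioside")
        _, t_reba = synth_spectrum("Rebaudioside A")
        blend = BlendSpec(components=(("Stevioside", 0.5), ("Rebaudioside A", 0.5)),
                          noise_sigma=0.0)
        _, t_mix = synth_spectrum(blend)
        lo, hi = sorted((t_stev.r1, t_reba.r1))
        assert lo < t_mix.r1 < hi

    def test_injected_ratios_increase_with_total_rings(self):
        by_rings = {}
        for rec in compounds():
            _, t = synth_spectrum(rec.name)
            by_rings.setdefault(rec.rings_total, []).append((t.r1, t.r2))
        totals = sorted(by_rings)
        r1s = [np.mean([v[0] for v in by_rings[n]]) for n in totals]
        r2s = [np.mean([v[1] for v in by_rings[n]]) for n in totals]
        assert all(np.diff(r1s) > 0)
        assert all(np.diff(r2s) > 0)

    def test_steviolbioside_has_two_carbonyl_bands(self):
        _, t = synth_spectrum("Steviolbioside")
        assert set(t.carbonyl_areas) == {1706.0, 1738.0}
        # linked 1738 band excluded from the centroid
        assert t.nu_co == pytest.approx(1706.0, abs=1e-9)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum"):
            BlendSpec(components=(("Stevioside", 0.4), ("Rebaudioside A", 0.5)))
        with pytest.raises(ValueError):
            BlendSpec(components=(("Stevioside", -0.5), ("Rebaudioside A", 1.5)))
        with pytest.raises(KeyError):
            BlendSpec(components=(("Aspartame", 1.0),))

    def test_extra_bands_are_injected(self):
        adu = Band(center=869.0, fwhm=8.0, height=0.02, eta=0.5)
        spec = BlendSpec(components=(("Rebaudioside A", 1.0),), noise_sigma=0.0,
                         extra_bands=(adu,))
        s_adu, _ = synth_spectrum(spec)
        s_clean, _ = synth_spectrum("Rebaudioside A")
        i = np.argmin(np.abs(s_adu.wavenumber - 869.0))
        assert s_adu.intensity[i] - s_clean.intensity[i] == pytest.approx(0.02, rel=1e-9)


class TestFullPipelineRoundTrip:
    def test_noiseless_library_recovers_injected_parameters(self):
        # preprocess + deconvolution must give back the generator's truth:
        # R1/R2 within 1%, carbonyl centroid within 0.2 cm^-1
        from steviaraman import compute_parameters, preprocess
        for rec in compounds():
            s, truth = synth_spectrum(rec.name)
            p = compute_parameters(preprocess(s))
            assert p.r1 == pytest.approx(truth.r1, rel=0.01), rec.name
            assert p.r2 == pytest.approx(truth.r2, rel=0.01), rec.name
            assert p.nu_co == pytest.approx(truth.nu_co, abs=0.2), rec.name
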