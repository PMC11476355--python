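"""Parameter extraction, ring estimation, composition, flags and reports."""

import numpy as np
import pytest

from steviaraman import (Band, BlendSpec, RingEstimate, Spectrum, classify_taste,
                         compute_parameters, carbonyl_composition,
                         detect_extraneous_band, estimate_rings, preprocess,
                         run_qc, synth_spectrum)
from steviaraman.bandfit import BandFitResult, pseudo_voigt
from steviaraman.preprocess import normalize_to_max
from steviaraman.qc_pipeline import REFERENCE_PRODUCT_RINGS


def _custom_spectrum(area_map, step=0.5):
    """Spectrum with pseudo-Voigt bands of given areal intensities."""
    nu = np.arange(700.0, 1800.0 + step / 2, step)
    y = np.zeros_like(nu)
    for center, area in area_map.items():
        unit = Band(center=center, fwhm=8.0, height=1.0, eta=0.5).area
        y += pseudo_voigt(nu, Band(center=center, fwhm=8.0,
                                   height=area / unit, eta=0.5))
    return normalize_to_max(Spectrum(nu, y))


class TestComputeParameters:
    def test_r1_and_r2_from_injected_areas(self):
        s = _custom_spectrum({887.0: 2.0, 898.0: 1.0,
                              1192.0: 0.6, 1204.0: 1.0, 1215.0: 0.9,
                              1670.0: 0.5, 1706.0: 0.7})
        p = compute_parameters(s)
        assert p.r1 == pytest.approx(2.0, abs=0.05)
        assert p.r2 == pytest.approx(1.5, abs=0.05)
        assert p.nu_co == pytest.approx(1706.0, abs=0.3)

    def test_zero_ring_class_center_recovered(self):
        # a 0-C19-ring compound carries its carbonyl at 1706 cm^-1
        s, _ = synth_spectrum("Rebaudioside B")
        p = compute_parameters(preprocess(s))
        assert p.nu_co == pytest.approx(1706.0, abs=0.3)

    def test_missing_aglycone_denominator_raises(self):
        from steviaraman import MissingBandError
        s = _custom_spectrum({887.0: 2.0, 1192.0: 0.6, 1204.0: 1.0,
                              1215.0: 0.9, 1706.0: 0.7})
        with pytest.raises(MissingBandError):
            compute_parameters(s)


class TestRingEstimate:
    @pytest.mark.parametrize("name,n19,ntot1,ratio", [
        ("Morita 1", 1.15, 3.31, 1.88),
        ("China 2", 0.63, 2.29, 2.63),
    ])
    def test_ratio_arithmetic_matches_reference_products(self, name, n19, ntot1, ratio):
        est = RingEstimate(n19=n19, ntot_r1=ntot1, ntot_r2=ntot1)
        assert est.n13 == pytest.approx(ntot1 - n19)
        assert round(est.ratio_c13_c19, 2) == ratio

    def test_ratio_undefined_for_vanishing_n19(self):
        est = RingEstimate(n19=0.01, ntot_r1=2.0, ntot_r2=2.0)
        assert est.ratio_c13_c19 is None

    def test_generator_round_trip_through_calibrations(self, library_models):
        s, _ = synth_spectrum("Rebaudioside M")
        p = compute_parameters(preprocess(s))
        est = estimate_rings(p, library_models["nu_co"], library_models["R1"],
                             library_models["R2"])
        assert est.n19 == pytest.approx(3.0, abs=0.25)
        assert est.ntot_r1 == pytest.approx(6.0, abs=0.25)
        assert est.n13 + est.n19 == pytest.approx(est.ntot_r1, abs=1e-12)

    def test_r1_and_r2_totals_agree_on_noiseless_data(self, library_models):
        for name in ("Rubusoside", "Rebaudioside D"):
            s, _ = synth_spectrum(name)
            p = compute_parameters(preprocess(s))
            est = estimate_rings(p, library_models["nu_co"], library_models["R1"],
                                 library_models["R2"])
            assert abs(est.ntot_r1 - est.ntot_r2) < 0.1


class TestCarbonylComposition:
    def _fit(self, *bands):
        return BandFitResult(window=(1690, 1760), bands=list(bands),
                             residual_rms=0.0, converged=True)

    def test_single_band_is_whole(self):
        comp = carbonyl_composition(self._fit(Band(1706.0, 8.0, 1.0)))
        assert len(comp.entries) == 1
        assert comp.entries[0].fraction == pytest.approx(1.0)
        assert comp.entries[0].ring_class == "0-ring"

    def test_fractions_follow_area_ratios(self):
        h = 1.0 / Band(1700.0, 8.0, 1.0, eta=0.5).area  # unit-area height
        comp = carbonyl_composition(self._fit(
            Band(1706.0, 8.0, 1.0 * h), Band(1719.0, 8.0, 2.0 * h),
            Band(1733.0, 8.0, 7.0 * h)))
        fr = sorted(e.fraction for e in comp.entries)
        assert fr == pytest.approx([0.1, 0.2, 0.7])
        assert sum(e.fraction for e in comp.entries) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_area_errors(self):
        with pytest.raises(ValueError):
            carbonyl_composition(self._fit(Band(1706.0, 8.0, 0.0)))

    def test_blend_fraction_recovery_with_replicate_averaging(self):
        # a blend injecting 18.1% of its carbonyl area below 1710 cm^-1
        from steviaraman import average_replicates
        reps = []
        for k in range(10):
            spec = BlendSpec(components=(("Rebaudioside B", 0.181),
                                         ("Stevioside", 0.819)), seed=500 + k)
            s, truth = synth_spectrum(spec)
            reps.append(s)
        assert truth.carbonyl_fraction_below(1710.0) == pytest.approx(0.181)
        p = compute_parameters(preprocess(average_replicates(reps)))
        comp = carbonyl_composition(p.window_fits["carbonyl"])
        assert comp.fraction_below(1710.0) == pytest.approx(0.181, abs=0.02)


class TestAdulterantFlag:
    def _prepped(self, extra=(), seed=9):
        spec = BlendSpec(components=(("Rebaudioside A", 1.0),), seed=seed,
                         extra_bands=tuple(extra))
        s, _ = synth_spectrum(spec)
        return preprocess(s)

    def test_clean_spectrum_not_flagged(self):
        sp = self._prepped()
        p = compute_parameters(sp)
        assert not detect_extraneous_band(sp, p.window_fits["glucose_stretch"]).flagged

    def test_injected_869_band_flagged_with_center(self):
        sp = self._prepped(extra=[Band(center=869.0, fwhm=8.0, height=0.012)])
        p = compute_parameters(sp)
        flag = detect_extraneous_band(sp, p.window_fits["glucose_stretch"])
        assert flag.flagged
        assert flag.center == pytest.approx(869.0, abs=1.0)
        assert flag.relative_area >= 0.01

    def test_extra_intensity_at_assigned_band_not_flagged(self):
        # more 887 cm^-1 intensity belongs to the glucose assignment
        sp = self._prepped(extra=[Band(center=887.0, fwhm=8.0, height=0.012)])
        p = compute_parameters(sp)
        assert not detect_extraneous_band(sp, p.window_fits["glucose_stretch"]).flagged


class TestTasteClassifier:
    def _batch(self):
        return [(name, RingEstimate(n19=v[0], ntot_r1=v[1], ntot_r2=v[2]))
                for name, v in REFERENCE_PRODUCT_RINGS.items()]

    def test_best_product_takes_all_three_superlatives(self):
        labels = classify_taste(self._batch())
        assert labels["Morita 1"] == {"sweetness": "highest",
                                      "sweet_perception": "fastest",
                                      "bitter_perception": "shortest"}

    def test_poorest_products_group_together(self):
        labels = classify_taste(self._batch())
        for name in ("Morita 2", "China 2", "Fermented"):
            assert labels[name]["sweetness"] == "lowest"
            assert labels[name]["sweet_perception"] == "slowest"
            assert labels[name]["bitter_perception"] == "longest"

    def test_intermediate_product_is_distinguished(self):
        assert classify_taste(self._batch())["China 1"]["sweetness"] == "intermediate"

    def test_identical_estimates_share_labels(self):
        a = RingEstimate(n19=1.0, ntot_r1=4.0, ntot_r2=4.0)
        b = RingEstimate(n19=1.0, ntot_r1=4.0, ntot_r2=4.0)
        labels = classify_taste([("A", a), ("B", b)])
        assert labels["A"] == labels["B"]

    def test_single_product_batch_rejected(self):
        with pytest.raises(ValueError):
            classify_taste([("solo", RingEstimate(1.0, 3.0, 3.0))])


class TestRunQC:
    def test_pure_compound_report(self, library_models):
        s, _ = synth_spectrum("Rebaudioside M")
        reports = run_qc({"RebM": [s]}, library_models)
        (r,) = reports
        assert r.error is None
        assert r.rings.ntot_r1 == pytest.approx(6.0, abs=0.25)
        assert not r.adulterant.flagged
        assert r.taste is None  # single product: no comparative labels

    def test_unreadable_file_becomes_structured_failure(self, library_models, tmp_path):
        s1, _ = synth_spectrum("Rebaudioside A")
        s2, _ = synth_spectrum("Stevioside")
        reports = run_qc({"a": [s1], "broken": [tmp_path / "missing.csv"],
                          "b": [s2]}, library_models)
        by_name = {r.product: r for r in reports}
        assert by_name["broken"].error is not None
        assert by_name["a"].error is None and by_name["b"].error is None
        # the two healthy products still get comparative labels
        assert by_name["a"].taste is not None

    def test_reports_are_deterministic(self, library_models):
        import json
        spec = BlendSpec(components=(("Stevioside", 0.6), ("Rebaudioside A", 0.4)),
                         seed=21)
        s, _ = synth_spectrum(spec)
        dumps = []
        for _ in range(2):
            (r,) = run_qc({"blend": [s.copy()]}, library_models)
            dumps.append(json.dumps(r.to_dict(), sort_keys=True))
        assert dumps[0] == dumps[1]

    def test_increasing_injected_rings_give_nondecreasing_totals(self, library_models):
        # blend series sweeping the injected mean total ring count upward
        fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
        totals = []
        for i, f in enumerate(fracs):
            comps = []
            if f < 1.0:
                comps.append(("Rubusoside", round(1.0 - f, 6)))  # 2 rings
            if f > 0.0:
                comps.append(("Rebaudioside M", round(f, 6)))  # 6 rings
            spec = BlendSpec(components=tuple(comps), noise_sigma=0.0, seed=i)
            s, _ = synth_spectrum(spec)
            p = compute_parameters(preprocess(s))
            est = estimate_rings(p, library_models["nu_co"], library_models["R1"],
                                 library_models["R2"])
            totals.append(est.ntot_r1)
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))
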