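"""Synthetic PK generator: kinetics, assay noise, cohorts, spectra."""

import numpy as np
import pytest

import aucpool as ap
from aucpool.errors import ValidationError
from aucpool.io import write_peak_table

PARENT = ap.PKParameters(dose=100.0, F=1.0, ka=1.0, ke=0.1, V=10.0)


class TestParentKinetics:
    def test_zero_dose_gives_flat_profile(self):
        p = ap.PKParameters(dose=0.0, F=1.0, ka=1.0, ke=0.1, V=10.0)
        prof = ap.simulate_parent(p, (0, 1, 2, 4))
        assert all(v == 0 for v in prof.values)

    def test_concentration_zero_at_dosing(self):
        prof = ap.simulate_parent(PARENT, (0.0, 0.5, 1.0))
        assert prof.values[0] == 0.0

    def test_profile_is_single_peaked(self):
        t = np.linspace(0, 48, 500)
        v = np.asarray(ap.simulate_parent(PARENT, t).values)
        peak = int(np.argmax(v))
        assert np.all(np.diff(v[: peak + 1]) >= 0)
        assert np.all(np.diff(v[peak:]) <= 0)

    def test_dense_trapezoid_matches_closed_form_auc(self):
        """AUC(0,∞) = F·D/(V·ke); the dense numerical integral must agree."""
        t = np.linspace(0.0, 200.0, 20001)
        prof = ap.simulate_parent(PARENT, t)
        auc = np.trapezoid(prof.values, t)
        expected = PARENT.F * PARENT.dose / (PARENT.V * PARENT.ke)
        assert abs(auc - expected) / expected < 0.005

    def test_equal_absorption_elimination_rates_rejected(self):
        with pytest.raises(ValidationError):
            ap.PKParameters(dose=1.0, F=1.0, ka=0.5, ke=0.5, V=1.0)


class TestMetaboliteKinetics:
    def test_zero_formation_fraction_gives_flat_profile(self):
        spec = ap.MetaboliteSpec("P", "M", "sulfation", 0.0, 0.2)
        prof = ap.simulate_metabolite(PARENT, spec, (0, 1, 2, 4))
        assert all(v == 0 for v in prof.values)

    def test_metabolite_absent_at_dosing(self):
        spec = ap.MetaboliteSpec("P", "M", "glucuronidation", 0.4, 0.3)
        assert ap.simulate_metabolite(PARENT, spec, (0.0, 1.0)).values[0] == 0.0

    def test_mass_balance_when_km_equals_ke(self):
        """With km = ke the AUC ratio metabolite/parent equals the formation
        fraction (the ke/km factor cancels); exercised via the numerical
        fallback path for the degenerate rate equality."""
        spec = ap.MetaboliteSpec("P", "M", "sulfation", 0.5, PARENT.ke)
        t = np.linspace(0.0, 400.0, 40001)
        met = np.trapezoid(ap.simulate_metabolite(PARENT, spec, t).values, t)
        par = np.trapezoid(ap.simulate_parent(PARENT, t).values, t)
        assert met / par == pytest.approx(0.5, rel=0.01)

    def test_mass_balance_general_rates(self):
        """Metabolite AUC(0,∞) = fraction × parent AUC(0,∞) × ke/km."""
        spec = ap.MetaboliteSpec("P", "M", "oxidation", 0.3, 0.25)
        t = np.linspace(0.0, 400.0, 40001)
        met = np.trapezoid(ap.simulate_metabolite(PARENT, spec, t).values, t)
        par = np.trapezoid(ap.simulate_parent(PARENT, t).values, t)
        assert met / par == pytest.approx(0.3 * PARENT.ke / spec.km, rel=0.01)

    def test_closed_form_and_numerical_paths_agree(self):
        t = np.linspace(0.0, 48.0, 97)
        closed = ap.simulate_metabolite(
            PARENT, ap.MetaboliteSpec("P", "M", "sulfation", 0.4, 0.30), t
        )
        near_degenerate = ap.simulate_metabolite(
            PARENT, ap.MetaboliteSpec("P", "M", "sulfation", 0.4, 0.30000001), t
        )
        np.testing.assert_allclose(closed.values, near_degenerate.values, rtol=1e-4)


class TestAssayModel:
    def test_noiseless_assay_scales_by_response_factor(self):
        prof = ap.simulate_parent(PARENT, (0, 1, 2, 4))
        assay = ap.AssayModel(default_factor=2.5, cv=0.0)
        out = ap.apply_assay(prof, assay, seed=0)
        np.testing.assert_allclose(out.values, 2.5 * np.asarray(prof.values))

    def test_lloq_above_everything_censors_all(self):
        prof = ap.simulate_parent(PARENT, (0, 1, 2, 4))
        assay = ap.AssayModel(cv=0.0, lloq=1e9)
        out = ap.apply_assay(prof, assay, seed=0)
        assert all(out.below_lloq)
        assert all(v == 0 for v in out.values)

    def test_sample_cv_matches_requested_cv(self):
        prof = ap.ConcentrationProfile("x", tuple(range(10000)), (10.0,) * 10000)
        out = ap.apply_assay(prof, ap.AssayModel(cv=0.10), seed=123)
        v = np.asarray(out.values)
        assert 0.095 <= v.std() / v.mean() <= 0.105

    def test_same_seed_reproduces_output(self):
        prof = ap.simulate_parent(PARENT, (0, 1, 2, 4, 8))
        assay = ap.AssayModel(cv=0.2)
        a = ap.apply_assay(prof, assay, seed=9)
        b = ap.apply_assay(prof, assay, seed=9)
        assert a.values == b.values

    def test_internal_standard_ratio(self):
        prof = ap.ConcentrationProfile("x", (0, 1), (0.0, 10.0))
        out = ap.apply_assay(prof, ap.AssayModel(cv=0.0, is_area=4.0), seed=0)
        assert out.values[1] == pytest.approx(2.5)
        assert out.unit_label == "area ratio"


class TestCohort:
    def schedule(self):
        return ap.SamplingSchedule(ap.DEFAULT_TIMES_H)

    def test_triplicate_shape(self):
        panel = ap.default_panel()
        m = ap.simulate_cohort(
            ["human"], panel, self.schedule(), ap.AssayModel(cv=0.1), 3, seed=1
        )
        assert len(m.data) == 3 * len(panel.compound_ids())
        one = m.data[m.data["compound_id"] == "P1"]
        assert sorted(one["replicate"]) == [1, 2, 3]

    def test_fixed_seed_gives_byte_identical_table(self, tmp_path):
        panel = ap.default_panel()
        args = (["human", "rat"], panel, self.schedule(), ap.AssayModel(cv=0.1), 3)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_peak_table(ap.simulate_cohort(*args, seed=5), a)
        write_peak_table(ap.simulate_cohort(*args, seed=5), b)
        assert a.read_bytes() == b.read_bytes()

    def test_species_pathway_preference_flips_conjugate_ratio(self):
        """Swapped sulfation/glucuronidation scaling puts the sulfate:
        glucuronide pooled-area ratio on opposite sides of 1."""
        panel = ap.default_panel()
        m = ap.simulate_cohort(
            ["human", "rat"], panel, self.schedule(), ap.AssayModel(cv=0.0), 1, seed=0
        )
        d = m.data.set_index(["species", "compound_id"])["area"]
        human = d["human"]["P1-sulfate"] / d["human"]["P1-glucuronide"]
        rat = d["rat"]["P1-sulfate"] / d["rat"]["P1-glucuronide"]
        assert human > 1 > rat

    def test_noiseless_cohort_reproduces_serial_trapezoid(self):
        """With CV = 0 and exact pooling, pooled area × span equals the
        serial trapezoid AUC for every compound (end-to-end identity)."""
        panel = ap.default_panel()
        sched = self.schedule()
        m = ap.simulate_cohort(["human"], panel, sched, ap.AssayModel(cv=0.0), 1, seed=0)
        profiles = panel.species_profiles("human", sched.times)
        for cid, prof in profiles.items():
            area = float(m.data[m.data["compound_id"] == cid]["area"].iloc[0])
            pooled = ap.pooled_auc(area, sched).value
            trap = ap.trapezoid_auc(prof).value
            assert abs(pooled - trap) / trap < 1e-10

    def test_pooled_estimate_is_unbiased_under_noise(self):
        """Mean pooled AUC over 200 seeded cohorts with CV 10% and triplicates
        lies within 2% of the true truncated AUC."""
        sched = self.schedule()
        design = ap.pooling_volumes(sched, 480.0, 0)
        truth = ap.trapezoid_auc(ap.simulate_parent(PARENT, sched.times)).value
        panel = ap.CompoundPanel(parents={"P1": PARENT}, metabolites=())
        means = []
        for seed in range(200):
            m = ap.simulate_cohort(
                ["human"], panel, sched, ap.AssayModel(cv=0.10), 3,
                seed=seed, design=design,
            )
            means.append(ap.pooled_auc(m.data["area"].mean(), sched).value)
        assert np.mean(means) == pytest.approx(truth, rel=0.02)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            ap.CompoundPanel(parents={}, metabolites=())

    def test_overweight_pathway_fractions_rejected(self):
        panel = ap.CompoundPanel(
            parents={"P": PARENT},
            metabolites=(ap.MetaboliteSpec("P", "M1", "sulfation", 0.7, 0.2),
                         ap.MetaboliteSpec("P", "M2", "sulfation", 0.6, 0.3)),
        )
        with pytest.raises(ValidationError, match="sum"):
            panel.validate_for_species(["human"])


class TestSerialVsPooledTrial:
    def test_differences_mostly_within_fifteen_percent(self):
        diffs = ap.pooled_vs_serial_trial(
            PARENT, ap.SamplingSchedule(ap.DEFAULT_TIMES_H),
            cv=0.10, replicates=3, n_cohorts=200, seed=2,
        )
        assert np.mean(diffs <= 15.0) >= 0.95

    def test_noiseless_trial_has_zero_difference(self):
        diffs = ap.pooled_vs_serial_trial(
            PARENT, ap.SamplingSchedule(ap.DEFAULT_TIMES_H),
            cv=0.0, replicates=1, n_cohorts=3, seed=0,
        )
        np.testing.assert_allclose(diffs, 0.0, atol=1e-10)


class TestSyntheticSpectra:
    def test_empty_panel_yields_empty_centroid_lists(self):
        spectra = ap.synth_spectra([], 0.0, 10.0, 11)
        assert all(len(s.mz) == 0 for s in spectra)

    def test_gaussian_peak_area_matches_analytic_value(self):
        peak = ap.SpectralPeakSpec("c", mz=283.0, rt_min=5.0, height=1000.0, sigma_min=0.1)
        spectra = ap.synth_spectra([peak], 4.0, 6.0, 401)  # ±10σ span
        trace = ap.extract_eic(spectra, 283.0, 5.0)
        area = ap.integrate_eic(trace, (4.0, 6.0), "c").area
        analytic = 1000.0 * 0.1 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(analytic, rel=0.02)

    def test_well_separated_mz_give_independent_areas(self):
        peaks = [
            ap.SpectralPeakSpec("a", 300.0, 5.0, 500.0, 0.1),
            ap.SpectralPeakSpec("b", 300.0 * (1 + 50e-6), 5.0, 800.0, 0.1),
        ]
        spectra = ap.synth_spectra(peaks, 4.0, 6.0, 401)
        area_a = ap.integrate_eic(ap.extract_eic(spectra, peaks[0].mz, 5.0), (4, 6)).area
        area_b = ap.integrate_eic(ap.extract_eic(spectra, peaks[1].mz, 5.0), (4, 6)).area
        assert area_b / area_a == pytest.approx(800.0 / 500.0, rel=1e-9)

    def test_nearby_mz_emit_overlap_warning(self):
        peaks = [
            ap.SpectralPeakSpec("a", 300.0, 5.0, 500.0, 0.1),
            ap.SpectralPeakSpec("b", 300.0 * (1 + 8e-6), 5.0, 800.0, 0.1),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            ap.synth_spectra(peaks, 4.0, 6.0, 11, ppm_tolerance=5.0)
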