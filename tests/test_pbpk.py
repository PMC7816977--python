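import numpy as np
import pytest

from dissolvekit.pbpk import (
    FormulationInput,
    PopulationSpec,
    SubjectPhysiology,
    auc_to_inf,
    diacerein,
    draw_subject,
    pk_params,
    relative_bioavailability,
    simulate_population,
    simulate_subject,
    simulated_observed_ratio,
)
from dissolvekit.profiles import XYSeries
from dissolvekit.synthetic import ProfileSpec, gen_dissolution_profile

COMPOUND = diacerein()
FAST = FormulationInput(label="fast", k_diss_per_min=0.449)
SLOW = FormulationInput(label="slow", k_diss_per_min=0.012)


class TestSubjectSimulation:
    def test_mass_conservation(self):
        for form in (FAST, SLOW):
            res = simulate_subject(COMPOUND, form, dose_mg=50.0)
            assert res.mass_balance_error < 1e-3  # within 0.1% of dose at all times

    def test_instant_absorption_matches_one_compartment_bolus(self):
        """ka, dissolution and emptying pushed to their fast limits with F=1:
        the curve collapses onto C(t) = (D/V) exp(-CL/V t)."""
        subj = SubjectPhysiology(
            gastric_emptying_rate=1000.0, intestinal_transit_rate=100.0, ka=2000.0, F=1.0
        )
        res = simulate_subject(COMPOUND, FormulationInput(label="i", k_diss_per_min=200.0),
                               subj, dose_mg=50.0)
        V = COMPOUND.vss * subj.body_weight
        ke = COMPOUND.cl / V
        t = res.curve.x
        ref = 50.0 / V * np.exp(-ke * t)
        mask = t >= 0.5  # past the (vanishingly short) absorption transient
        rel = np.abs(res.curve.y[mask] - ref[mask]) / ref[mask]
        assert rel.max() < 0.01

    def test_auc_inf_equals_f_dose_over_cl_for_complete_absorption(self):
        subj = SubjectPhysiology(ka=50.0, F=0.45)
        res = simulate_subject(COMPOUND, FAST, subj, dose_mg=50.0)
        V = COMPOUND.vss * subj.body_weight
        auc_inf = auc_to_inf(res.curve, COMPOUND.cl / V)
        assert auc_inf == pytest.approx(0.45 * 50.0 / COMPOUND.cl, rel=5e-3)

    def test_auc_inf_independent_of_absorption_kinetics(self):
        """F*D/CL is fixed; ka and dissolution only shape the curve — provided
        absorption is complete (ka large enough that colonic loss is nil)."""
        V = COMPOUND.vss * 81.0
        ref = None
        for ka, kd in [(60.0, 5.0), (120.0, 1.0), (40.0, 20.0)]:
            subj = SubjectPhysiology(ka=ka, F=0.45)
            res = simulate_subject(COMPOUND, FormulationInput(label="x", k_diss_per_min=kd),
                                   subj, dose_mg=50.0)
            auc = auc_to_inf(res.curve, COMPOUND.cl / V)
            if ref is None:
                ref = auc
            assert auc == pytest.approx(ref, rel=0.01)

    def test_slower_dissolution_lowers_cmax_and_delays_tmax(self):
        halves = FormulationInput(label="half", k_diss_per_min=0.449 / 2.0)
        # slow-enough regime that dissolution is rate-limiting
        a = simulate_subject(COMPOUND, FormulationInput(label="a", k_diss_per_min=0.02))
        b = simulate_subject(COMPOUND, FormulationInput(label="b", k_diss_per_min=0.01))
        assert b.pk.cmax < a.pk.cmax
        assert b.pk.tmax > a.pk.tmax
        fast = simulate_subject(COMPOUND, FAST)
        half = simulate_subject(COMPOUND, halves)
        assert half.pk.cmax < fast.pk.cmax
        assert half.pk.tmax >= fast.pk.tmax

    def test_grid_convergence(self):
        coarse = simulate_subject(COMPOUND, FAST, grid_h=0.05)
        fine = simulate_subject(COMPOUND, FAST, grid_h=0.025)
        assert fine.pk.cmax == pytest.approx(coarse.pk.cmax, rel=2e-3)
        assert fine.pk.auc_0_24 == pytest.approx(coarse.pk.auc_0_24, rel=2e-3)

    def test_profile_mode_uses_first_order_fit(self):
        profile = gen_dissolution_profile(ProfileSpec(model="first_order", k=0.05))
        form = FormulationInput(label="p", profile=profile)
        assert form.dissolution_rate_per_h == pytest.approx(3.0, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            FormulationInput(label="x")  # neither source
        with pytest.raises(ValueError):
            simulate_subject(COMPOUND, FAST, dose_mg=-1.0)
        with pytest.raises(ValueError):
            simulate_subject(COMPOUND, FAST, grid_h=0.5)


class TestPkParams:
    def test_constant_curve(self):
        c = XYSeries(np.linspace(0, 24, 481), np.full(481, 2.0))
        pk = pk_params(c)
        assert pk.auc_0_24 == pytest.approx(48.0)
        assert pk.tmax == 0.0 and pk.cmax == 2.0

    def test_triangle_curve(self):
        x = np.array([0.0, 2.0, 6.0])
        c = XYSeries(x, np.array([0.0, 5.0, 0.0]))
        pk = pk_params(c)
        assert (pk.cmax, pk.tmax) == (5.0, 2.0)
        assert pk.auc_0_24 == pytest.approx(15.0)  # area of the triangle

    def test_earliest_tmax_on_plateau(self):
        c = XYSeries(np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 4.0, 4.0, 1.0]))
        assert pk_params(c).tmax == 1.0


class TestPopulation:
    SMALL = dict(n_trials=2, n_subjects=5, dose_mg=50.0)

    def test_deterministic_given_seed(self):
        spec = PopulationSpec(seed=123, **self.SMALL)
        a = simulate_population(COMPOUND, FAST, spec)
        b = simulate_population(COMPOUND, FAST, spec)
        assert a.summary == b.summary  # bit-identical

    def test_zero_cv_gives_identical_subjects(self):
        spec = PopulationSpec(seed=5, cv_cl=0.0, cv_ka=0.0, cv_v=0.0, weight_sd=0.0,
                              **self.SMALL)
        res = simulate_population(COMPOUND, FAST, spec)
        assert res.summary.cmax_sd == pytest.approx(0.0, abs=1e-12)
        assert res.summary.auc_sd == pytest.approx(0.0, abs=1e-12)

    def test_geriatric_auc_exceeds_adult_at_same_seed(self):
        adult = simulate_population(COMPOUND, FAST, PopulationSpec(group="healthy_adult",
                                                                   seed=7, **self.SMALL))
        geri = simulate_population(COMPOUND, FAST, PopulationSpec(group="geriatric",
                                                                  seed=7, **self.SMALL))
        assert geri.summary.auc_mean > adult.summary.auc_mean

    def test_subject_reproducible_in_isolation(self):
        spec = PopulationSpec(seed=99, **self.SMALL)
        assert draw_subject(spec, 1, 3) == draw_subject(spec, 1, 3)
        assert draw_subject(spec, 1, 3) != draw_subject(spec, 1, 4)

    def test_auc_cv_tracks_clearance_cv(self):
        """With 30% CV on CL, the empirical CV of AUC lands in [20%, 40%]."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = PopulationSpec(seed=seed, n_trials=5, n_subjects=10)
            aucs = np.array([
                0.45 * 50.0 / (COMPOUND.cl * draw_subject(spec, t, s).cl_multiplier)
                for t in range(spec.n_trials) for s in range(spec.n_subjects)
            ])
            cv = aucs.std(ddof=1) / aucs.mean()
            hits += 0.20 <= cv <= 0.40
        assert hits >= 19


class TestReportingRatios:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(35.53, 15.48, 229.52), (40.56, 15.48, 262.02), (10.0, 10.0, 100.00)],
    )
    def test_relative_bioavailability(self, test, ref, expected):
        assert relative_bioavailability(test, ref) == expected

    @pytest.mark.parametrize(
        "sim,obs,expected",
        [(1.80, 2.50, 0.72), (35.53, 31.11, 1.14), (5.70, 5.47, 1.04),
         (40.56, 31.11, 1.30), (3.3, 3.3, 1.00)],
    )
    def test_simulated_observed_ratio(self, sim, obs, expected):
        assert simulated_observed_ratio(sim, obs) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_bioavailability(1.0, 0.0)
        with pytest.raises(ValueError):
            simulated_observed_ratio(1.0, -2.0)
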