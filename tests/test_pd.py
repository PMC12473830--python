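"""Population PD: Emax algebra, likelihood, EBEs, model selection, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from dermapk.core import InvalidInputError, ModelConfigError
from dermapk.pkpd import (
    EmaxParams,
    ErrorModel,
    PopulationModel,
    SubjectRecord,
    band_coverage,
    ebe_by_formulation,
    emax_effect,
    estimate_ebes,
    fit_population,
    individual_neg2ll,
    information_criteria,
    simulated_band,
    vpc,
)


def make_record(times, obs, exposure, sid="S1", form="F"):
    return SubjectRecord(sid, form, np.asarray(times), np.asarray(obs), np.asarray(exposure))


class TestEmaxEffect:
    def test_zero_exposure_returns_baseline(self):
        p = EmaxParams(emax=10.0, ec50=2.0, e0=3.0, n=2.0)
        assert emax_effect(p, 0.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [0.5, 1.0, 3.0])
    def test_half_maximal_at_ec50(self, n):
        p = EmaxParams(emax=10.0, ec50=7.0, e0=1.0, n=n)
        assert emax_effect(p, 7.0) == pytest.approx(1.0 + 5.0)

    def test_direct_substitution(self):
        p = EmaxParams(emax=10.0, ec50=1.0, e0=0.0, n=1.0)
        assert emax_effect(p, 9.0) == pytest.approx(9.0)

    def test_half_of_asymptote_identity(self):
        """E(EC50) - E0 equals half of the large-c plateau above baseline."""
        for n in (0.7, 1.0, 2.5):
            p = EmaxParams(emax=-6.0, ec50=3.0, e0=20.0, n=n)
            plateau = emax_effect(p, 1e6 * p.ec50) - p.e0
            assert emax_effect(p, p.ec50) - p.e0 == pytest.approx(plateau / 2.0, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            emax_effect(EmaxParams(1.0, 1.0, 0.0), -0.1)


class TestLikelihood:
    def test_zero_residual_closed_form(self):
        p = EmaxParams(emax=5.0, ec50=2.0, e0=10.0)
        c = np.array([0.0, 1.0, 4.0])
        f = emax_effect(p, c)
        rec = make_record(c, f, c)
        b = 0.2
        expected = -2.0 * np.sum(np.log(1.0 / (np.sqrt(2 * np.pi) * b * f)))
        assert individual_neg2ll(rec, p, ErrorModel(b)) == pytest.approx(expected, rel=1e-12)

    def test_doubling_b_adds_scale_term(self):
        p = EmaxParams(emax=5.0, ec50=2.0, e0=10.0)
        c = np.array([0.0, 1.0, 4.0])
        rec = make_record(c, emax_effect(p, c), c)
        n2_1 = individual_neg2ll(rec, p, ErrorModel(0.1))
        n2_2 = individual_neg2ll(rec, p, ErrorModel(0.2))
        assert n2_2 - n2_1 == pytest.approx(2.0 * len(c) * math.log(2.0), rel=1e-12)

    def test_one_sigma_observation(self):
        p = EmaxParams(emax=5.0, ec50=2.0, e0=10.0)
        b = 0.15
        c = np.array([1.0, 3.0])
        f = emax_effect(p, c)
        base = individual_neg2ll(make_record(c, f, c), p, ErrorModel(b))
        y = f.copy()
        y[0] = f[0] * (1.0 + b)
        shifted = individual_neg2ll(make_record(c, y, c), p, ErrorModel(b))
        assert shifted - base == pytest.approx(1.0, rel=1e-9)

    def test_brute_force_density_product(self, rng):
        """-2 log of the product of normal densities, computed independently."""
        p = EmaxParams(emax=-4.0, ec50=10.0, e0=20.0, n=1.3)
        b = 0.12
        for _ in range(20):
            c = rng.uniform(0.0, 50.0, 5)
            f = emax_effect(p, c)
            y = np.abs(f * (1 + b * rng.standard_normal(5))) + 1e-6
            rec = make_record(c, y, c)
            ref = -2.0 * np.sum(stats.norm.logpdf(y, loc=f, scale=b * f))
            assert individual_neg2ll(rec, p, ErrorModel(b)) == pytest.approx(ref, rel=1e-10)


class TestEBEs:
    def pop(self, omega=0.09, b=0.01):
        # small b: the proportional-error likelihood's scale term biases the
        # MAP away from zero residual by O(b^2), so the noiseless identities
        # below are exact only in the small-noise limit
        return PopulationModel(
            EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0),
            {"emax": omega, "ec50": omega},
            ErrorModel(b),
            sigmoidicity=False,
        )

    def test_population_typical_subject_has_zero_eta(self):
        pop = self.pop()
        c = np.linspace(0.0, 100.0, 8)
        f = emax_effect(pop.theta_pop, c)
        eta, params = estimate_ebes(make_record(c, f, c), pop)
        assert all(abs(v) < 1e-3 for v in eta.values())
        assert params.emax == pytest.approx(pop.theta_pop.emax, rel=1e-3)

    def test_degenerate_prior_pins_eta_at_zero(self):
        pop = PopulationModel(
            EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0), {},
            ErrorModel(0.08), sigmoidicity=False,
        )
        c = np.linspace(0.0, 100.0, 8)
        y = emax_effect(pop.theta_pop, c) * 1.2
        eta, params = estimate_ebes(make_record(c, y, c), pop)
        assert eta == {}
        assert params == pop.theta_pop

    def test_flat_prior_recovers_true_eta(self):
        """Rich noiseless data from theta_i = theta_pop * e^0.3; MAP -> MLE."""
        pop = self.pop(omega=100.0)
        c = np.linspace(0.0, 200.0, 24)
        true_eta = {"emax": 0.3, "ec50": 0.3}
        f = emax_effect(pop.theta_pop.with_eta(true_eta), c)
        eta, _ = estimate_ebes(make_record(c, f, c), pop)
        assert eta["emax"] == pytest.approx(0.3, abs=0.01)
        assert eta["ec50"] == pytest.approx(0.3, abs=0.03)

    def test_shrinkage_monotone_in_omega(self):
        c = np.linspace(0.0, 100.0, 8)
        y = emax_effect(EmaxParams(-8.0, 50.0, 20.0, 1.0).with_eta({"emax": 0.4}), c)
        rec = make_record(c, y, c)
        mags = []
        for omega in (1.0, 0.25, 0.04, 0.0025):
            pop = PopulationModel(
                EmaxParams(-8.0, 50.0, 20.0, 1.0), {"emax": omega},
                ErrorModel(0.08), sigmoidicity=False,
            )
            eta, _ = estimate_ebes(rec, pop)
            mags.append(abs(eta["emax"]))
        assert all(a >= b - 1e-9 for a, b in zip(mags, mags[1:]))


class TestInformationCriteria:
    def test_aic_identity(self):
        rep = information_criteria(100.0, 5, 6, 18)
        assert rep.aic == pytest.approx(110.0)
        assert rep.aic - rep.ofv == pytest.approx(2 * rep.n_parameters)

    def test_bic_penalty(self):
        rep = information_criteria(100.0, 5, 6, 18)
        assert rep.bic - rep.ofv == pytest.approx(5 * math.log(6), rel=1e-10)
        assert rep.bic - rep.ofv == pytest.approx(8.9588, abs=1e-4)

    def test_no_parameters(self):
        rep = information_criteria(42.0, 0, 6, 18)
        assert rep.aic == rep.bic == rep.bicc == pytest.approx(42.0)

    def test_bicc_splits_penalty(self):
        rep = information_criteria(0.0, 4, 6, 18)
        # 3 subject-level parameters at ln(6), 1 observation-level at ln(18)
        assert rep.bicc == pytest.approx(3 * math.log(6) + math.log(18))


class TestFitPopulation:
    def test_no_bsv_reduces_to_weighted_least_squares(self):
        """With omega^2 = 0 the fit matches pooled proportional-weighted NLS."""
        from scipy.optimize import least_squares

        truth = EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0)
        c = np.linspace(0.0, 100.0, 10)
        f = emax_effect(truth, c)
        recs = [make_record(c, f, c, sid=f"S{i}") for i in range(3)]
        init = PopulationModel(
            EmaxParams(emax=-6.0, ec50=70.0, e0=22.0, n=1.0), {},
            ErrorModel(0.1), sigmoidicity=False,
        )
        fit = fit_population(recs, init, max_iter=600)
        m = fit["model"].theta_pop

        def resid(x):
            p = EmaxParams(emax=x[0], ec50=x[1], e0=x[2], n=1.0)
            fx = emax_effect(p, c)
            return (f - fx) / fx

        nls = least_squares(resid, [-6.0, 70.0, 22.0]).x
        assert m.emax == pytest.approx(nls[0], rel=0.01)
        assert m.ec50 == pytest.approx(nls[1], rel=0.01)
        assert m.e0 == pytest.approx(nls[2], rel=0.01)

    def test_ofv_trace_is_monotone(self, pd_truth, pd_exposure):
        from dermapk.synthetic import StudyDesign, gen_pd_dataset

        t, c = pd_exposure
        design = StudyDesign(pd_n_subjects=8, pd_observation_times=tuple(t), pd_formulations=("F",))
        recs, _ = gen_pd_dataset(pd_truth, {"F": (t, c)}, design, seed=4)
        fit = fit_population(recs, pd_truth, seed=0, max_iter=60)
        tr = fit["ofv_trace"]
        assert all(b <= a + 1e-6 for a, b in zip(tr, tr[1:]))
        assert fit["report"].aic - fit["report"].ofv == pytest.approx(2 * fit["report"].n_parameters)


class TestSimulationDiagnostics:
    def test_vpc_collapses_without_variability(self):
        pop = PopulationModel(
            EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0), {},
            ErrorModel(1e-8), sigmoidicity=False,
        )
        t = np.array([0.0, 24.0, 48.0])
        c = np.array([0.0, 40.0, 80.0])
        df = vpc(pop, t, c, n_subjects=10, n_replicates=100, seed=0)
        f = emax_effect(pop.theta_pop, c)
        for pct in (10.0, 50.0, 90.0):
            sub = df[df.percentile == pct]
            assert np.allclose(sub["value"].to_numpy(), f, rtol=1e-5)

    def test_doubling_b_widens_band(self):
        t = np.array([0.0, 24.0, 48.0])
        c = np.array([0.0, 40.0, 80.0])
        widths = []
        for b in (0.05, 0.10):
            pop = PopulationModel(
                EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0), {},
                ErrorModel(b), sigmoidicity=False,
            )
            lo, hi = simulated_band(pop, c, n_replicates=400, n_subjects=10, seed=9)
            widths.append(hi - lo)
        assert np.all(widths[1] > widths[0])

    def test_iwres_zero_and_one_sigma(self, pd_truth):
        from dermapk.pkpd import residual_diagnostics

        c = np.linspace(0.0, 100.0, 5)
        f = emax_effect(pd_truth.theta_pop, c)
        rec = make_record(c, f, c)
        ebes = {"S1": {"eta": {}, "params": pd_truth.theta_pop, "formulation": "F"}}
        diag = residual_diagnostics([rec], pd_truth, ebes, seed=0, n_sim=50)
        assert np.allclose(diag["iwres"], 0.0, atol=1e-12)
        rec2 = make_record(c, f * (1.0 + pd_truth.error.b), c)
        diag2 = residual_diagnostics([rec2], pd_truth, ebes, seed=0, n_sim=50)
        assert np.allclose(diag2["iwres"], 1.0, atol=1e-12)


class TestEbeSummaries:
    def test_zero_etas_give_population_medians(self, pd_truth):
        ebes = {
            f"S{i}": {"eta": {}, "params": pd_truth.theta_pop, "formulation": form}
            for i, form in enumerate(["A", "A", "B", "B"])
        }
        df = ebe_by_formulation(ebes, "emax")
        assert np.allclose(df["median"], pd_truth.theta_pop.emax)

    def test_shifted_group_median(self, pd_truth):
        shifted = pd_truth.theta_pop.with_eta({"emax": 0.5})
        ebes = {
            "S1": {"eta": {}, "params": pd_truth.theta_pop, "formulation": "A"},
            "S2": {"eta": {}, "params": pd_truth.theta_pop, "formulation": "A"},
            "S3": {"eta": {"emax": 0.5}, "params": shifted, "formulation": "B"},
            "S4": {"eta": {"emax": 0.5}, "params": shifted, "formulation": "B"},
        }
        df = ebe_by_formulation(ebes, "emax").set_index("formulation")
        assert df.loc["B", "median"] == pytest.approx(pd_truth.theta_pop.emax * math.exp(0.5))

    def test_unknown_parameter_rejected(self, pd_truth):
        with pytest.raises(ModelConfigError):
            ebe_by_formulation({}, "gamma_factor")
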