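"""Calibration stage: metric battery, parameter recovery, Morris screening."""

import numpy as np
import pytest
from scipy import stats

from dermapk.calibration import (
    CalibrationSpec,
    compute_metrics,
    calibrate,
    fit_release_parameters,
    fit_skin_parameters,
    morris_screen,
)
from dermapk.core import ModelConfigError
from dermapk.synthetic import NoiseSpec, StudyDesign, gen_ivrt_dataset, gen_ivpt_dataset


def naive_metrics(pred, obs):
    """Independent brute-force reimplementation of the six-metric battery."""
    p, o = np.asarray(pred, float), np.asarray(obs, float)
    out = {}
    out["rmse"] = np.sqrt(sum((pi - oi) ** 2 for pi, oi in zip(p, o)) / len(p))
    out["bias"] = sum(pi - oi for pi, oi in zip(p, o)) / len(p)
    pairs_m = [(pi, oi) for pi, oi in zip(p, o) if oi > 0]
    out["mape"] = 100.0 * sum(abs(pi - oi) / oi for pi, oi in pairs_m) / len(pairs_m)
    pairs_f = [(pi, oi) for pi, oi in zip(p, o) if oi > 0 and pi > 0]
    out["afe"] = 10.0 ** (sum(np.log10(pi / oi) for pi, oi in pairs_f) / len(pairs_f))
    obar = o.mean()
    out["r_squared"] = 1.0 - sum((oi - pi) ** 2 for pi, oi in zip(p, o)) / sum(
        (oi - obar) ** 2 for oi in o
    )
    out["pearson_r"] = stats.pearsonr(p, o)[0]
    return out


class TestComputeMetrics:
    def test_identity(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.rmse, m.mape, m.afe, m.bias) == pytest.approx((0.0, 0.0, 1.0, 0.0))
        assert (m.r_squared, m.pearson_r) == pytest.approx((1.0, 1.0))

    def test_constant_fold(self):
        obs = np.array([1.0, 2.0, 4.0])
        m = compute_metrics(2.0 * obs, obs)
        assert m.afe == pytest.approx(2.0)
        assert m.aafe == pytest.approx(2.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_negative_r_squared(self):
        # R^2 = 1 - 5/2 = -1.5 for a flat prediction of a trending series
        m = compute_metrics([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r_squared == pytest.approx(-1.5)

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            obs = rng.uniform(0.1, 10.0, n)
            pred = obs * rng.lognormal(0.0, 0.3, n)
            m = compute_metrics(pred, obs)
            ref = naive_metrics(pred, obs)
            for key, val in ref.items():
                got = getattr(m, key)
                assert got == pytest.approx(val, rel=1e-10), key

    def test_zeros_excluded_from_ratio_metrics(self):
        m = compute_metrics([1.0, 2.0, 3.0, 4.0], [0.0, 2.1, 2.9, 4.2])
        assert m.n_points["mape"] == 3
        assert m.n_points["afe"] == 3
        assert np.isfinite(m.mape) and np.isfinite(m.afe)

    def test_undefined_metrics_are_nan_not_zero(self):
        m = compute_metrics([1.0, 2.0, 3.0], [0.0, 0.0, 1.0])
        assert np.isnan(m.mape) and np.isnan(m.afe)  # only one usable pair
        m2 = compute_metrics([1.0, 2.0], [0.0, 0.0])
        assert np.isnan(m2.mape) and np.isnan(m2.afe)


class TestCalibrationSpec:
    def test_release_stage_limits_free_parameters(self):
        with pytest.raises(ModelConfigError):
            CalibrationSpec(stage="release", free_parameters={"kp_cp_sc": (0.1, 10.0, 1.0)})

    def test_skin_stage_rejects_release_parameter(self):
        with pytest.raises(ModelConfigError):
            CalibrationSpec(stage="skin", free_parameters={"p_dp_cp": (1e-6, 1.0, 1e-3)})

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ModelConfigError):
            CalibrationSpec(stage="release", free_parameters={"p_dp_cp": (0.1, 1.0, 5.0)})


class TestCalibrate:
    def test_data_at_start_needs_no_improvement(self):
        spec = CalibrationSpec(
            stage="release", free_parameters={"p_dp_cp": (1e-4, 1.0, 0.1)}
        )
        obs = np.array([0.1, 0.2, 0.3])

        def predictor(params):
            return params["p_dp_cp"] * np.array([1.0, 2.0, 3.0])

        fit = calibrate(spec, predictor, obs)
        assert fit.objective_initial == pytest.approx(0.0, abs=1e-20)
        assert fit.objective_value <= fit.objective_initial + 1e-20
        assert fit.values["p_dp_cp"] == pytest.approx(0.1, rel=1e-5)

    def test_noiseless_release_recovery_within_1pct(self, forms, cell):
        """Stage-1 calibration recovers the generating release parameters."""
        truth = forms["AcneFree"]
        profiles, _ = gen_ivrt_dataset(
            truth, cell, StudyDesign(ivrt_n_replicates=1),
            NoiseSpec(proportional_cv=0.0, additive_sd=0.0, loq=0.0, seed=0),
        )
        start = truth.with_params(
            kp_dp_cp=truth.kp_dp_cp * 2.5, p_dp_cp=truth.p_dp_cp / 3.0, release_lag=1.0
        )
        fit = fit_release_parameters(profiles, start, cell)
        assert fit.values["kp_dp_cp"] == pytest.approx(truth.kp_dp_cp, rel=0.01)
        assert fit.values["p_dp_cp"] == pytest.approx(truth.p_dp_cp, rel=0.01)
        assert fit.values["release_lag"] == pytest.approx(truth.release_lag, abs=0.05)

    def test_stepwise_separation_release_params_untouched(self, forms, cell, skin, transport):
        """The skin fit consumes release parameters as-is and never mutates them."""
        form = forms["Differin"]
        accs, _ = gen_ivpt_dataset(
            form, skin, transport, StudyDesign(ivpt_n_replicates=1),
            NoiseSpec(proportional_cv=0.0, loq=0.0, seed=0),
        )
        tr_start = transport.with_params(kp_cp_sc=transport.kp_cp_sc * 2.0)
        fit = fit_skin_parameters(
            {form.name: accs}, {form.name: form}, skin, tr_start,
            free={"kp_cp_sc": (1.0, 1e4, tr_start.kp_cp_sc)},
        )
        assert set(fit.values) == {"kp_cp_sc"}
        assert fit.values["kp_cp_sc"] == pytest.approx(transport.kp_cp_sc, rel=0.02)
        # the formulation object is frozen; its release parameters are bit-identical
        assert form == forms["Differin"]


class TestMorris:
    def test_additive_linear_function(self):
        res = morris_screen(
            lambda p: 2.0 * p["x1"] + 0.0 * p["x2"],
            {"x1": (0.0, 1.0), "x2": (0.0, 1.0)},
            n_trajectories=6,
            seed=5,
        )
        i1, i2 = res.parameters.index("x1"), res.parameters.index("x2")
        assert res.mu_star[i1] == pytest.approx(2.0, rel=1e-10)
        assert res.mu_star[i2] == pytest.approx(0.0, abs=1e-12)
        assert res.sigma[i1] == pytest.approx(0.0, abs=1e-10)

    def test_interaction_inflates_sigma(self):
        res = morris_screen(
            lambda p: p["x1"] * p["x2"],
            {"x1": (0.0, 1.0), "x2": (0.0, 1.0)},
            n_trajectories=20,
            seed=5,
        )
        assert res.sigma[res.parameters.index("x1")] > 0.01

    def test_deterministic_under_seed(self):
        kwargs = dict(
            parameter_ranges={"a": (0.0, 2.0), "b": (1.0, 3.0)}, n_trajectories=8, seed=42
        )
        f = lambda p: p["a"] ** 2 + np.sin(p["b"])
        r1, r2 = morris_screen(f, **kwargs), morris_screen(f, **kwargs)
        assert np.array_equal(r1.mu_star, r2.mu_star)
        assert np.array_equal(r1.sigma, r2.sigma)

    def test_ivpt_ranking_flags_sc_partition(self, forms, skin, transport):
        """kp CP->SC must out-rank an inert parameter on the shipped default."""
        from dermapk.core import simulate
        from dermapk.ivpt import build_ivpt_system, layer_accumulation

        base = transport.with_params(p_cp_sb=0.0)  # sebum feed disabled -> p_sb_dm inert

        def output(params):
            tr = base.with_params(kp_cp_sc=params["kp_cp_sc"], p_sb_dm=params["p_sb_dm"])
            res = simulate(build_ivpt_system(forms["Differin"], skin, tr), [0.0, 18.0, 36.0])
            return layer_accumulation(res, skin).epidermis_amount_per_weight[-1]

        res = morris_screen(
            output,
            {"kp_cp_sc": (100.0, 1000.0), "p_sb_dm": (0.0, 1e-3)},
            n_trajectories=4,
            seed=3,
        )
        ms = dict(zip(res.parameters, res.mu_star))
        # fluxes are bidirectional, so the dangling sebum link is only near-inert
        assert ms["kp_cp_sc"] > 100.0 * ms["p_sb_dm"]
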