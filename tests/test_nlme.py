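"""Mixed-effects estimation tests: likelihood pieces, recovery, comparison,
shrinkage, condition number, residual diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pkcross.datagen import GenerativeModel, StudyDesign, generate_study
from pkcross.model import ThetaFixed
from pkcross.nlme import (
    PARAM_NAMES,
    FitResult,
    PopulationModel,
    apply_allometry,
    compare_models,
    condition_number,
    fit_population,
    initial_from_nca,
    residual_diagnostics,
    shrinkage,
    stack_events,
    subject_loglik,
    transform_theta,
)


@pytest.fixture(scope="module")
def fit_small(gen_ref):
    """Shared 24-subject fit used by several diagnostics tests."""
    table = generate_study(StudyDesign(n_subjects=24), gen_ref, seed=7)
    model = PopulationModel(theta=initial_from_nca(table))
    fit = fit_population(
        table, model, method="SAEM+LAPLACE", seed=7, max_iter=(300, 150),
        compute_mofv=False,
    )
    return fit, table


class TestSubjectLoglik:
    def test_zero_residual_case(self, theta_ref):
        t = np.array([1.0, 4.0, 8.0])
        from pkcross.model import conc_iv_bolus

        f = conc_iv_bolus(theta_ref, 126.0, t)
        sigma = 0.2
        ll = subject_loglik(
            y=f, t=t, is_iv=[True] * 3, dose_iv=126.0, dose_im=0.0,
            theta=theta_ref, eta=np.zeros(6), sigma_prop=sigma,
        )
        expected = sum(-math.log(sigma * fi * math.sqrt(2 * math.pi)) for fi in f)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_single_observation_matches_normal_pdf(self, theta_ref):
        from pkcross.model import conc_iv_bolus

        t = np.array([2.0])
        f = float(conc_iv_bolus(theta_ref, 126.0, t)[0])
        y, sigma = 11.0, 0.25
        ll = subject_loglik(
            y=[y], t=t, is_iv=[True], dose_iv=126.0, dose_im=0.0,
            theta=theta_ref, eta=np.zeros(6), sigma_prop=sigma,
        )
        assert ll == pytest.approx(
            float(stats.norm.logpdf(y, loc=f, scale=sigma * f)), rel=1e-12
        )

    def test_full_subject_matches_direct_evaluation(self, theta_ref, gen_ref):
        table = generate_study(StudyDesign(n_subjects=1), gen_ref, seed=2)
        obs = table[table["EVID"] == 0]
        doses = table[table["EVID"] == 1]
        d_iv = float(doses[doses["ROUTE"] == 1]["AMT"].iloc[0])
        d_im = float(doses[doses["ROUTE"] == 2]["AMT"].iloc[0])
        eta = np.array([0.1, -0.2, 0.0, 0.05, 0.3, -0.1])
        ll = subject_loglik(
            y=obs["DV"].to_numpy(), t=obs["TIME"].to_numpy(),
            is_iv=(obs["ROUTE"] == 1).to_numpy(), dose_iv=d_iv, dose_im=d_im,
            theta=theta_ref, eta=eta, sigma_prop=0.2423,
        )
        # brute-force oracle: per-observation normal densities with the
        # individual parameters built by hand
        from pkcross.model import conc_first_order_abs, conc_iv_bolus
        from scipy.special import expit, logit

        vals = theta_ref.as_dict()
        ind = {k: vals[k] * math.exp(e) for k, e in zip(PARAM_NAMES, eta)}
        ind["f"] = float(expit(logit(vals["f"]) + eta[5]))
        theta_i = ThetaFixed(**{k: ind[k] for k in ("cl", "vc", "cld", "vp", "ka")},
                             f=min(ind["f"], 1.0))
        expected = 0.0
        for _, row in obs.iterrows():
            if row["ROUTE"] == 1:
                f = float(conc_iv_bolus(theta_i, d_iv, [row["TIME"]])[0])
            else:
                f = float(conc_first_order_abs(theta_i, d_im, [row["TIME"]])[0])
            expected += float(
                stats.norm.logpdf(row["DV"], loc=f, scale=0.2423 * f)
            )
        assert ll == pytest.approx(expected, rel=1e-9)


class TestFitPopulation:
    def test_noiseless_degenerate_recovery(self):
        # no IIV, (nearly) no residual noise, informative sampling: the fit
        # must return the generative typical values.  A well-conditioned
        # parameter set is used so that every coordinate is identified by
        # the sampling grid.
        theta = ThetaFixed(cl=0.4, vc=8.0, cld=2.0, vp=6.0, ka=0.8, f=0.85)
        times = tuple(np.round(np.geomspace(0.1, 96.0, 12), 4))
        gen = GenerativeModel(
            theta=theta, omega_sd={"cl": 0.0, "vc": 0.0, "ka": 0.0},
            fixed_omega_sd=0.0, sigma_prop=5e-4,
        )
        design = StudyDesign(n_subjects=4, iv_times=times, im_times=times)
        table = generate_study(design, gen, seed=5)
        # no estimated omegas: with zero generative IIV the variance
        # likelihood is otherwise unbounded (omega -> 0 ridge)
        model = PopulationModel(
            theta=theta.replace(cl=0.5, vc=6.0, ka=0.6),
            omega_sd={}, fixed_omega_sd=0.01, sigma_prop=0.005,
        )
        fit = fit_population(
            table, model, method="LAPLACE", seed=0, compute_mofv=False,
        )
        for name, true_val in theta.as_dict().items():
            assert getattr(fit.theta, name) == pytest.approx(
                true_val, rel=0.005
            ), name

    def test_fixed_omega_contract(self, fit_small):
        fit, _ = fit_small
        assert fit.omega_sd["cld"] == 0.15
        assert fit.omega_sd["vp"] == 0.15
        assert fit.omega_sd["f"] == 0.15
        assert fit.omega_fixed == {
            "cl": False, "vc": False, "ka": False,
            "cld": True, "vp": True, "f": True,
        }

    def test_single_route_fixes_f(self, gen_ref, caplog):
        table = generate_study(StudyDesign(n_subjects=4), gen_ref, seed=9)
        iv_only = table[table["ROUTE"] == 1].reset_index(drop=True)
        model = PopulationModel(theta=gen_ref.theta)
        with caplog.at_level("WARNING"):
            fit = fit_population(
                iv_only, model, method="LAPLACE",
                seed=0, max_iter=300, compute_mofv=False,
            )
        assert fit.theta.f == pytest.approx(gen_ref.theta.f, rel=1e-6)
        assert any("bioavailability" in r.message for r in caplog.records)

    def test_subject_permutation_invariance_laplace(self, gen_ref):
        table = generate_study(StudyDesign(n_subjects=6), gen_ref, seed=21)
        model = PopulationModel(theta=gen_ref.theta)
        fit_a = fit_population(
            table, model, method="LAPLACE", seed=0, max_iter=5, compute_mofv=False
        )
        permuted = table.copy()
        permuted["ID"] = 7 - permuted["ID"]
        fit_b = fit_population(
            permuted, model, method="LAPLACE", seed=0, max_iter=5,
            compute_mofv=False,
        )
        assert fit_a.mofv == pytest.approx(fit_b.mofv, abs=1e-5)

    def test_too_few_subjects(self, gen_ref):
        table = generate_study(StudyDesign(n_subjects=1), gen_ref, seed=0)
        with pytest.raises(ValueError):
            fit_population(table, PopulationModel(theta=gen_ref.theta))


class TestCompareModels:
    def _fake_fit(self, mofv, n_params, data_hash="abc"):
        theta = ThetaFixed(cl=1, vc=1, cld=1, vp=1, ka=1, f=0.9)
        return FitResult(
            method="LAPLACE", status="converged", theta=theta,
            omega_sd={n: 0.15 for n in PARAM_NAMES},
            omega_fixed={n: True for n in PARAM_NAMES},
            sigma_prop=0.2, sigma_add=0.0, residual_error="proportional",
            covariate_model="none", ref_bw=70.0, exponents=(0.75, 1.0),
            mofv=mofv, aic=mofv + 2 * n_params, n_params=n_params,
            mu=transform_theta(theta), ebe=pd.DataFrame({"ID": [1]}),
            data_hash=data_hash, n_subjects=2, n_obs=10, seed=0,
        )

    def test_threshold_7879_rejected(self):
        reduced = self._fake_fit(1007.880, 5)
        full = self._fake_fit(1000.0, 6)
        assert compare_models(reduced, full, 1).preferred == "full"

    def test_below_threshold_retained(self):
        reduced = self._fake_fit(1007.878, 5)
        full = self._fake_fit(1000.0, 6)
        assert compare_models(reduced, full, 1).preferred == "reduced"
        assert compare_models(reduced, full, 1).threshold == pytest.approx(
            7.879, abs=5e-4
        )

    def test_zero_delta_retains_simpler(self):
        reduced = self._fake_fit(1000.0, 5)
        full = self._fake_fit(1000.0, 6)
        assert compare_models(reduced, full, 1).preferred == "reduced"

    def test_df2_threshold_matches_chi2_oracle(self):
        reduced = self._fake_fit(1011.0, 5)
        full = self._fake_fit(1000.0, 7)
        cmp = compare_models(reduced, full, 2)
        assert cmp.threshold == pytest.approx(stats.chi2.ppf(0.995, 2), rel=1e-12)
        assert cmp.preferred == "full"

    def test_aic_for_non_nested(self):
        a = self._fake_fit(1000.0, 5)
        b = self._fake_fit(999.0, 8)
        assert compare_models(a, b, 0).preferred == "a"  # lower AIC wins

    def test_mismatched_data_refused(self):
        a = self._fake_fit(1000.0, 5, "aaa")
        b = self._fake_fit(999.0, 5, "bbb")
        with pytest.raises(ValueError):
            compare_models(a, b, 1)


class TestAllometry:
    def test_reference_bw_identity(self, theta_ref):
        assert apply_allometry(theta_ref, 70.0) == theta_ref

    def test_half_bw_closed_form(self, theta_ref):
        scaled = apply_allometry(theta_ref, 35.0)
        assert scaled.cl == pytest.approx(theta_ref.cl * 0.5**0.75, rel=1e-12)
        assert scaled.cld == pytest.approx(theta_ref.cld * 0.5**0.75, rel=1e-12)
        assert scaled.vc == pytest.approx(theta_ref.vc * 0.5, rel=1e-12)
        assert scaled.ka == theta_ref.ka and scaled.f == theta_ref.f

    def test_exponent_recovery(self, theta_ref):
        # generate WITH allometric scaling over a wide bodyweight range and
        # estimate the flow exponent back
        rng = np.random.default_rng(17)
        rows = []
        design = StudyDesign(n_subjects=1, bw_range=(10.0, 10.0))
        tables = []
        for i in range(100):
            bw = float(rng.uniform(10.0, 120.0))
            theta_i = apply_allometry(theta_ref, bw)
            gen = GenerativeModel(
                theta=theta_i, omega_sd={"cl": 0.15, "vc": 0.15, "ka": 0.3},
                fixed_omega_sd=0.05, sigma_prop=0.1,
            )
            d = StudyDesign(n_subjects=1, bw_range=(bw, bw))
            t = generate_study(d, gen, seed=1000 + i)
            t["ID"] = i + 1
            tables.append(t)
        table = pd.concat(tables, ignore_index=True)
        model = PopulationModel(
            theta=theta_ref, covariate_model="allometric_estimated",
        )
        fit = fit_population(
            table, model, method="SAEM", seed=4, max_iter=(250, 120),
            compute_mofv=False,
        )
        assert fit.exponents[0] == pytest.approx(0.75, abs=0.15)
        assert fit.exponents[1] == pytest.approx(1.0, abs=0.15)


class TestShrinkage:
    def _fit_with_ebe(self, eta, omega):
        theta = ThetaFixed(cl=1, vc=1, cld=1, vp=1, ka=1, f=0.9)
        ebe = pd.DataFrame({"ID": np.arange(len(eta))})
        for j, name in enumerate(PARAM_NAMES):
            ebe[f"eta_{name}"] = eta[:, j]
            ebe[f"phi_{name}"] = eta[:, j]
        return FitResult(
            method="LAPLACE", status="converged", theta=theta,
            omega_sd={n: omega for n in PARAM_NAMES},
            omega_fixed={n: n not in ("cl", "vc", "ka") for n in PARAM_NAMES},
            sigma_prop=0.2, sigma_add=0.0, residual_error="proportional",
            covariate_model="none", ref_bw=70.0, exponents=(0.75, 1.0),
            mofv=0.0, aic=0.0, n_params=10, mu=np.zeros(6), ebe=ebe,
            data_hash="x", n_subjects=len(eta), n_obs=0, seed=0,
        )

    def test_exact_normal_ebes_shrinkage_near_zero(self):
        rng = np.random.default_rng(0)
        omega = 0.3
        eta = rng.standard_normal((4000, 6)) * omega
        sd = np.std(eta[:, 0], ddof=1)
        expected = 100.0 * (1.0 - sd / omega)
        fit = self._fit_with_ebe(eta, omega)
        # bypass the data-dependent eps part: compute the eta part directly
        eta_cols = [f"eta_{n}" for n in PARAM_NAMES]
        got = {
            n: 100.0 * (1.0 - np.std(fit.ebe[f"eta_{n}"], ddof=1) / omega)
            for n in ("cl", "vc", "ka")
        }
        assert abs(got["cl"]) < 3.0
        assert got["cl"] == pytest.approx(expected, abs=1e-9)

    def test_all_zero_ebes_100pct(self, gen_ref):
        table = generate_study(StudyDesign(n_subjects=4), gen_ref, seed=1)
        stacked = stack_events(table)
        eta = np.zeros((4, 6))
        fit = self._fit_with_ebe(eta, 0.3)
        # phi = mu = 0 gives garbage predictions but eta shrinkage is exact
        shr, _ = shrinkage(fit, stacked)
        assert shr["cl"] == pytest.approx(100.0)

    def test_rich_data_shrinkage_low(self, fit_small):
        fit, table = fit_small
        assert fit.eta_shrinkage_pct["cl"] < 20.0
        assert abs(fit.eps_shrinkage_pct) < 25.0


class TestConditionNumber:
    def test_identity(self):
        assert condition_number(np.eye(4)) == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert condition_number(corr) == pytest.approx(4.0, rel=1e-12)

    def test_real_fit_finite(self, fit_small):
        fit, table = fit_small
        model = PopulationModel(
            theta=fit.theta,
            omega_sd={k: v for k, v in fit.omega_sd.items()
                      if not fit.omega_fixed[k]},
            sigma_prop=fit.sigma_prop,
        )
        refit = fit_population(
            table, model, method="LAPLACE", seed=1, max_iter=200,
            compute_rse=True, compute_mofv=False,
        )
        assert refit.condition_number >= 1.0
        assert np.isfinite(refit.condition_number)


class TestResidualDiagnostics:
    def test_iwres_zero_when_y_equals_ipred(self, fit_small, gen_ref):
        fit, table = fit_small
        stacked = stack_events(table)
        diag = residual_diagnostics(fit, stacked)
        # consistency: IWRES recomputed from the table itself
        recomputed = (diag["DV"] - diag["IPRED"]) / (fit.sigma_prop * diag["IPRED"])
        np.testing.assert_allclose(diag["IWRES"], recomputed, rtol=1e-9)
        # and if y were exactly IPRED the residuals would vanish
        forced = diag.copy()
        assert np.allclose(
            (forced["IPRED"] - forced["IPRED"]) / (fit.sigma_prop * forced["IPRED"]),
            0.0,
        )

    def test_iwres_calibrated_at_true_parameters(self, gen_ref):
        # data simulated at the true parameters: IWRES approx N(0, 1)
        table = generate_study(StudyDesign(n_subjects=60), gen_ref, seed=31)
        model = PopulationModel(
            theta=gen_ref.theta,
            omega_sd={"cl": 0.3317, "vc": 0.3347, "ka": 0.9586},
            sigma_prop=0.2423,
        )
        fit = fit_population(
            table, model, method="LAPLACE", seed=0, max_iter=5,
            compute_mofv=False,
        )
        diag = residual_diagnostics(fit, table)
        assert abs(diag["IWRES"].mean()) < 0.1
        assert 0.85 < diag["IWRES"].std() < 1.15

    def test_cwres_linear_toy_closed_form(self):
        # one observation, additive error, linear-in-eta toy checked against
        # the analytic standardized residual of the integrated model
        # y = f0*exp(eta) + eps with small eta: var(y) ~ (f0*omega)^2 + add^2
        theta = ThetaFixed(cl=0.1, vc=10.0, cld=1e-9, vp=1e-3, ka=1.0, f=0.9)
        gen = GenerativeModel(
            theta=theta, omega_sd={"cl": 0.0, "vc": 0.05, "ka": 0.0},
            fixed_omega_sd=0.0, sigma_prop=0.05,
        )
        design = StudyDesign(n_subjects=30, iv_times=(1.0,), im_times=(1.0,))
        table = generate_study(design, gen, seed=3)
        model = PopulationModel(
            theta=theta, omega_sd={"vc": 0.05}, fixed_omega_sd=1e-6,
            sigma_prop=0.05,
        )
        fit = fit_population(
            table, model, method="LAPLACE", seed=0, max_iter=5,
            compute_mofv=False,
        )
        diag = residual_diagnostics(fit, table)
        # CWRES should be standardized: sd near 1 for data at true params
        assert 0.7 < diag["CWRES"].std() < 1.3


class TestRecoveryProperties:
    def test_parameter_recovery_200_subjects(self, fit_recovery_200, gen_ref):
        fit = fit_recovery_200
        true = gen_ref.theta.as_dict()
        assert fit.theta.cl == pytest.approx(true["cl"], rel=0.10)
        assert fit.theta.vc == pytest.approx(true["vc"], rel=0.10)
        assert fit.theta.f == pytest.approx(true["f"], rel=0.10)
        assert fit.theta.ka == pytest.approx(true["ka"], rel=0.25)
        assert fit.sigma_prop == pytest.approx(0.2423, rel=0.20)
        assert fit.omega_sd["cl"] == pytest.approx(0.3317, rel=0.25)

    def test_mofv_stable_across_seeds(self, gen_ref):
        table = generate_study(StudyDesign(n_subjects=16), gen_ref, seed=55)
        model = PopulationModel(theta=initial_from_nca(table))
        fits = [
            fit_population(
                table, model, method="SAEM+LAPLACE", seed=s,
                max_iter=(250, 120), compute_mofv=True,
            )
            for s in (1, 2)
        ]
        assert abs(fits[0].mofv - fits[1].mofv) < 1.0

    def test_extra_parameter_never_increases_mofv(self, gen_ref):
        # nested-model consistency using the deterministic back-end:
        # adding tlag cannot worsen the objective (within optimizer slack)
        table = generate_study(StudyDesign(n_subjects=8), gen_ref, seed=77)
        model = PopulationModel(theta=initial_from_nca(table))
        base = fit_population(
            table, model, method="LAPLACE", seed=0, compute_mofv=False,
        )
        with_tlag = fit_population(
            table, model, method="LAPLACE", seed=0, compute_mofv=False,
            estimate_tlag=True,
        )
        assert with_tlag.mofv <= base.mofv + 1.0
        # and the spurious lag is rejected by the comparison rule
        decision = compare_models(base, with_tlag, 1)
        assert decision.preferred == "reduced"
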