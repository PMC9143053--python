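"""NCA tests against closed-form/analytic oracles."""

import math

import numpy as np
import pytest

from pkcross.datagen import GenerativeModel, StudyDesign, generate_study
from pkcross.model import (
    ThetaFixed,
    conc_iv_bolus,
    conc_first_order_abs,
    macro_to_micro,
)
from pkcross.nca import (
    auc_extrapolate,
    auc_linlog,
    bioavailability,
    fit_lambda_z,
    half_life,
    moments_and_volumes,
    nca_profile,
    nca_summary,
    run_nca,
)


class TestLambdaZ:
    def test_pure_monoexponential_exact(self):
        t = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 80.0])
        c = 10.0 * np.exp(-0.02 * t)
        lz = fit_lambda_z(t, c)
        assert lz.status == "ok"
        assert lz.lambda_z == pytest.approx(0.02, abs=1e-12)

    def test_terminal_subset_approaches_beta(self, theta_ref):
        m = macro_to_micro(theta_ref)
        t = np.array([8.0, 24.0, 48.0, 72.0])
        c = conc_iv_bolus(theta_ref, 126.0, t)
        lz = fit_lambda_z(t, c, exclude_cmax=False)
        assert lz.lambda_z == pytest.approx(m.beta, rel=0.05)

    def test_increasing_profile_flagged(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        lz = fit_lambda_z(t, c)
        assert lz.status != "ok"

    def test_too_few_points(self):
        lz = fit_lambda_z(np.array([0.0, 1.0, 2.0]), np.array([1.0, 5.0, 4.0]))
        assert lz.status == "too_few_points"


class TestHalfLife:
    def test_reference_absorption_half_life(self):
        # ln(2)/0.471 prints as 1.47 at two decimals
        assert round(half_life(0.471), 2) == 1.47

    def test_ln2(self):
        assert half_life(math.log(2.0)) == pytest.approx(1.0, rel=1e-15)

    def test_beta_oracle(self, theta_ref):
        m = macro_to_micro(theta_ref)
        assert half_life(m.beta) == pytest.approx(math.log(2) / m.beta, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestAUCLinLog:
    def test_constant_profile_linear_rule(self):
        t = np.linspace(0, 10, 6)
        c = np.full_like(t, 5.0)
        assert auc_linlog(t, c) == pytest.approx(50.0, rel=1e-12)

    def test_log_rule_exact_for_exponential(self):
        t = np.array([0.0, 10.0])
        c = 10.0 * np.exp(-0.1 * t)
        exact = 10.0 * (1.0 - np.exp(-1.0)) / 0.1
        assert auc_linlog(t, c) == pytest.approx(exact, rel=1e-12)

    def test_dense_profile_matches_analytic_auc(self, theta_ref):
        t = np.arange(0.0, 2000.0, 0.01)
        c = conc_iv_bolus(theta_ref, 126.0, t)
        lz = fit_lambda_z(t[-1000:], c[-1000:], exclude_cmax=False)
        auc_inf, _ = auc_extrapolate(auc_linlog(t, c), lz.conc_at(t[-1]), lz.lambda_z)
        assert auc_inf == pytest.approx(126.0 / theta_ref.cl, rel=0.005)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            auc_linlog(np.array([0.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestAUCExtrapolate:
    def test_zero_tail(self):
        auc_inf, pct = auc_extrapolate(100.0, 0.0, 0.1)
        assert auc_inf == 100.0 and pct == 0.0

    def test_degenerate_all_tail(self):
        auc_inf, pct = auc_extrapolate(0.0, 1.0, 0.1)
        assert pct == pytest.approx(100.0)

    def test_one_half_life_truncation_gives_50pct(self):
        # mono-exponential C = C0*exp(-k t) truncated at t1/2: observed and
        # extrapolated areas are equal
        k, c0 = 0.1, 20.0
        t_half = math.log(2) / k
        t = np.linspace(0, t_half, 20_000)
        c = c0 * np.exp(-k * t)
        auc_t = np.trapezoid(c, t)
        _, pct = auc_extrapolate(auc_t, c[-1], k)
        assert pct == pytest.approx(50.0, abs=1e-4)


class TestMomentsAndVolumes:
    def test_one_compartment_closed_form(self):
        theta = ThetaFixed(cl=0.5, vc=10.0, cld=1e-9, vp=1.0, ka=1.0, f=1.0)
        k10 = theta.cl / theta.vc
        t = np.arange(0.0, 400.0, 0.01)
        c = conc_iv_bolus(theta, 100.0, t)
        lz = fit_lambda_z(t[-2000:], c[-2000:], exclude_cmax=False)
        auc_inf, _ = auc_extrapolate(auc_linlog(t, c), lz.conc_at(t[-1]), lz.lambda_z)
        mv = moments_and_volumes(t, c, 100.0, lz, auc_inf)
        assert mv["mrt"] == pytest.approx(1.0 / k10, rel=0.01)
        assert mv["vss"] == pytest.approx(theta.vc, rel=0.01)

    def test_dose_linearity(self, theta_ref):
        t = np.arange(0.0, 500.0, 0.05)
        results = []
        for dose in (100.0, 200.0):
            c = conc_iv_bolus(theta_ref, dose, t)
            lz = fit_lambda_z(t[-2000:], c[-2000:], exclude_cmax=False)
            auc_inf, _ = auc_extrapolate(
                auc_linlog(t, c), lz.conc_at(t[-1]), lz.lambda_z
            )
            results.append((auc_inf, moments_and_volumes(t, c, dose, lz, auc_inf)))
        assert results[1][0] == pytest.approx(2 * results[0][0], rel=1e-6)
        assert results[1][1]["cl"] == pytest.approx(results[0][1]["cl"], rel=1e-6)

    def test_vss_matches_vc_plus_vp(self, theta_ref):
        t = np.arange(0.0, 1500.0, 0.01)
        c = conc_iv_bolus(theta_ref, 126.0, t)
        lz = fit_lambda_z(t[-2000:], c[-2000:], exclude_cmax=False)
        auc_inf, _ = auc_extrapolate(auc_linlog(t, c), lz.conc_at(t[-1]), lz.lambda_z)
        mv = moments_and_volumes(t, c, 126.0, lz, auc_inf)
        assert mv["vss"] == pytest.approx(theta_ref.vc + theta_ref.vp, rel=0.02)


class TestBioavailability:
    def test_equal_profiles(self):
        assert bioavailability(100.0, 10.0, 100.0, 10.0) == 100.0

    def test_ninety_percent(self):
        assert bioavailability(90.0, 10.0, 100.0, 10.0) == pytest.approx(90.0)

    def test_guards(self):
        with pytest.raises(ValueError):
            bioavailability(0.0, 1.0, 1.0, 1.0)

    def test_simulation_round_trip(self, theta_ref):
        # dense noise-free profiles: recovered F close to the generative 90.8%
        t = np.arange(0.0, 3000.0, 0.05)
        c_iv = conc_iv_bolus(theta_ref, 126.0, t)
        c_im = conc_first_order_abs(theta_ref, 126.0, t)
        aucs = {}
        for key, c in (("iv", c_iv), ("im", c_im)):
            sel = c > 0
            lz = fit_lambda_z(t[sel][-2000:], c[sel][-2000:], exclude_cmax=False)
            aucs[key], _ = auc_extrapolate(
                auc_linlog(t[sel], c[sel]), lz.conc_at(t[sel][-1]), lz.lambda_z
            )
        f = bioavailability(aucs["im"], 126.0, aucs["iv"], 126.0)
        assert f == pytest.approx(90.80, rel=0.02)


class TestRunNCA:
    def test_sparse_iv_schedule_has_large_extrapolation(self, theta_ref):
        # with the 24 h last sample << 3 half-lives the extrapolated area
        # exceeds 30% (the documented sparse-sampling caveat)
        gen = GenerativeModel(
            theta=theta_ref, omega_sd={"cl": 0.0, "vc": 0.0, "ka": 0.0},
            fixed_omega_sd=0.0, sigma_prop=0.0,
        )
        table = generate_study(StudyDesign(n_subjects=2), gen, seed=0)
        res = run_nca(table, route="iv")
        assert (res["auc_extrap_pct"] > 30.0).all()

    def test_recovery_on_dense_profiles(self, theta_ref):
        times = tuple(np.round(np.geomspace(0.01, 2000.0, 400), 6))
        gen = GenerativeModel(
            theta=theta_ref, omega_sd={"cl": 0.0, "vc": 0.0, "ka": 0.0},
            fixed_omega_sd=0.0, sigma_prop=0.0,
        )
        design = StudyDesign(n_subjects=1, iv_times=times, im_times=times)
        table = generate_study(design, gen, seed=0)
        res = run_nca(table, route="both")
        iv = res[res["route"] == "iv"].iloc[0]
        im = res[res["route"] == "im"].iloc[0]
        dose = table[(table["EVID"] == 1) & (table["ROUTE"] == 1)]["AMT"].iloc[0]
        assert iv["cl"] == pytest.approx(theta_ref.cl, rel=0.02)
        assert iv["vss"] == pytest.approx(theta_ref.vc + theta_ref.vp, rel=0.02)
        assert im["f_pct"] == pytest.approx(100.0 * theta_ref.f, rel=0.02)

    def test_extrapolation_decreases_with_longer_sampling(self, theta_ref):
        gen = GenerativeModel(
            theta=theta_ref, omega_sd={"cl": 0.0}, fixed_omega_sd=0.0,
            sigma_prop=0.0,
        )
        extraps = []
        for last in (24.0, 96.0, 480.0):
            times = tuple(np.linspace(0.5, last, 12))
            design = StudyDesign(n_subjects=1, iv_times=times, im_times=times)
            table = generate_study(design, gen, seed=0)
            res = run_nca(table, route="iv")
            extraps.append(res["auc_extrap_pct"].iloc[0])
        assert extraps[0] > extraps[1] > extraps[2]

    def test_summary_shapes(self, study_default):
        res = run_nca(study_default, route="both")
        summary = nca_summary(res)
        assert {"route", "parameter", "n"} <= set(summary.columns)
        # recompute oracle: the summary mean equals the per-subject mean
        ok_iv = res[(res["route"] == "iv") & (res["status"] == "ok")]
        row = summary[
            (summary["route"] == "iv") & (summary["parameter"] == "auc_inf")
        ].iloc[0]
        assert row["mean"] == pytest.approx(ok_iv["auc_inf"].mean())
        assert row["sd"] == pytest.approx(ok_iv["auc_inf"].std(ddof=1))

    def test_single_subject_summary_sd_blank(self, theta_ref):
        gen = GenerativeModel(
            theta=theta_ref, omega_sd={"cl": 0.0}, fixed_omega_sd=0.0,
            sigma_prop=0.0,
        )
        table = generate_study(StudyDesign(n_subjects=1), gen, seed=0)
        summary = nca_summary(run_nca(table, route="iv"))
        assert summary[summary["parameter"] == "auc_inf"]["sd"].isna().all()

    def test_two_identical_subjects_sd_zero(self, theta_ref):
        gen = GenerativeModel(
            theta=theta_ref, omega_sd={"cl": 0.0, "vc": 0.0, "ka": 0.0},
            fixed_omega_sd=0.0, sigma_prop=0.0,
        )
        design = StudyDesign(n_subjects=2, bw_range=(30.0, 30.0))
        table = generate_study(design, gen, seed=0)
        summary = nca_summary(run_nca(table, route="iv"))
        row = summary[summary["parameter"] == "auc_inf"].iloc[0]
        assert row["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_cmax_is_observed_value_earliest_tie(self):
        res = nca_profile(
            np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0]),
            np.array([3.0, 5.0, 5.0, 4.0, 2.0, 1.0]),
            dose=100.0, route="im",
        )
        assert res.cmax == 5.0 and res.tmax == 1.0
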