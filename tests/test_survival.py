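"""Censored MLE, Kaplan-Meier, AIC selection, tail classes, AFT effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from neosleep import (
    CovariateSpec,
    FitResult,
    acceleration_factor,
    classify_tail,
    fit_censored,
    fit_family,
    fitted_survival,
    km_estimate,
    likelihood_ratio_test,
    neg_loglik_censored,
    select_model,
)
from tests.conftest import make_bout


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_censoring_hand_values(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        assert list(c.times) == [0, 1, 2, 3]
        assert c.survival == pytest.approx([1, 2 / 3, 1 / 3, 0])

    def test_censored_product_limit(self):
        # at t=1: S = 2/3; the censored 2 leaves one at risk at t=3 -> S drops to 0
        c = km_estimate([1, 2, 3], [1, 0, 1])
        assert c.survival_at(1.5) == pytest.approx(2 / 3)
        assert c.survival_at(2.5) == pytest.approx(2 / 3)
        assert c.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        c = km_estimate([5, 8, 13], [0, 0, 0])
        assert np.all(c.survival == 1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_empirical_survival_without_censoring(self, rng):
        t = rng.lognormal(2.0, 0.8, 200)
        c = km_estimate(t, np.ones_like(t))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert c.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_band_contains_estimate(self, rng):
        t = rng.exponential(5.0, 100)
        e = rng.integers(0, 2, 100)
        e[0] = 1
        c = km_estimate(t, e)
        assert np.all(c.ci_low <= c.survival + 1e-12)
        assert np.all(c.ci_high >= c.survival - 1e-12)


# --------------------------------------------------------------------------
# censored likelihood
# --------------------------------------------------------------------------


def _oracle_pdf(family, params, x_min=1.0):
    """Independent density formulas (not the fitting code's scipy path)."""
    if family == "exponential":
        (lam,) = params
        return lambda t: lam * np.exp(-lam * t)
    if family == "weibull":
        k, lam = params
        return lambda t: (k / lam) * (t / lam) ** (k - 1) * np.exp(-((t / lam) ** k))
    if family == "lognormal":
        mu, s = params
        return lambda t: np.exp(-((np.log(t) - mu) ** 2) / (2 * s**2)) / (
            t * s * np.sqrt(2 * np.pi)
        )
    if family == "powerlaw":
        (a,) = params
        return lambda t: (a - 1) * x_min ** (a - 1) * t ** (-a)
    raise ValueError(family)


class TestNegLoglik:
    def test_exponential_closed_form(self):
        t = np.array([2.0, 5.0, 1.0, 7.0])
        lam = 0.3
        expected = -(len(t) * np.log(lam) - lam * t.sum())
        assert neg_loglik_censored("exponential", [lam], t, np.ones(4)) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize(
        "family, params",
        [
            ("exponential", [0.25]),
            ("weibull", [2.181, 34.243]),
            ("lognormal", [4.137, 0.891]),
            ("powerlaw", [2.5]),
        ],
    )
    def test_zero_coefficients_identity(self, family, params):
        t = np.array([2.0, 4.0, 8.0, 16.0, 32.0])
        e = np.array([1, 0, 1, 1, 0.0])
        X = np.linspace(-1, 1, 5).reshape(-1, 1)
        a = neg_loglik_censored(family, params, t, e)
        b = neg_loglik_censored(family, params, t, e, covariates=X, coefficients=[0.0])
        assert a == pytest.approx(b)

    @pytest.mark.parametrize(
        "family, params",
        [
            ("weibull", [1.7, 20.0]),
            ("lognormal", [3.0, 0.9]),
            ("exponential", [0.05]),
        ],
    )
    def test_matches_quadrature_oracle(self, family, params):
        t = np.array([3.0, 10.0, 25.0, 40.0, 60.0])
        e = np.array([1, 1, 0, 1, 0.0])
        X = np.array([[-0.5], [0.0], [0.5], [1.0], [-1.0]])
        beta = [0.2]
        pdf = _oracle_pdf(family, params)
        total = 0.0
        for ti, ei, xi in zip(t, e, X[:, 0]):
            a = np.exp(beta[0] * xi)
            z = ti / a
            if ei:
                total += np.log(pdf(z) / a)
            else:
                surv, _ = integrate.quad(pdf, z, np.inf)
                total += np.log(surv)
        got = neg_loglik_censored(
            family, params, t, e, covariates=X, coefficients=beta
        )
        assert got == pytest.approx(-total, rel=1e-6)

    @pytest.mark.parametrize(
        "family, params",
        [("exponential", [-1.0]), ("weibull", [0.0, 5.0]), ("lognormal", [1.0, 0.0]),
         ("powerlaw", [1.0])],
    )
    def test_out_of_support_params_signalled(self, family, params):
        with pytest.raises(ValueError):
            neg_loglik_censored(family, params, [1.0, 2.0], [1, 1])


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


class TestFitting:
    def test_exponential_mle_closed_form(self):
        r = fit_censored("exponential", [2, 4, 6], [1, 1, 1])
        assert r.baseline_params["rate"] == pytest.approx(0.25, abs=1e-8)

    def test_exponential_censored_mle_closed_form(self):
        r = fit_censored("exponential", [2, 4, 6], [1, 0, 1])
        assert r.baseline_params["rate"] == pytest.approx(2 / 12, abs=1e-8)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_censored("exponential", [2, 4, 6], [0, 0, 0])

    def test_lognormal_recovery_under_censoring(self, default_config, rng):
        frame = __import__("neosleep").sample_bout_frame(
            default_config, "AS", 5000, rng, censor_range=(30, 70)
        )
        r = fit_censored("lognormal", frame["duration_min"], frame["event_observed"])
        # truth inside the Wald 95% CI
        assert abs(r.baseline_params["meanlog"] - 4.137) < 1.96 * r.se["meanlog"]
        assert abs(r.baseline_params["sdlog"] - 0.891) < 1.96 * r.se["sdlog"]

    @pytest.mark.parametrize("family", ["exponential", "weibull", "lognormal"])
    def test_aft_scaling_equivariance(self, family, rng):
        t = rng.lognormal(2.5, 0.7, 300)
        c = rng.uniform(10, 40, 300)
        e = (t <= c).astype(float)
        d = np.minimum(t, c)
        X = pd.DataFrame({"z": rng.normal(size=300)})
        base = fit_censored(family, d, e, X=X)
        scaled = fit_censored(family, 3.0 * d, e, X=X)
        if family == "lognormal":
            assert scaled.baseline_params["meanlog"] == pytest.approx(
                base.baseline_params["meanlog"] + np.log(3.0), abs=1e-5
            )
            assert scaled.baseline_params["sdlog"] == pytest.approx(
                base.baseline_params["sdlog"], rel=1e-5
            )
        elif family == "weibull":
            assert scaled.baseline_params["scale"] == pytest.approx(
                3.0 * base.baseline_params["scale"], rel=1e-5
            )
            assert scaled.baseline_params["shape"] == pytest.approx(
                base.baseline_params["shape"], rel=1e-5
            )
        else:
            assert scaled.baseline_params["rate"] == pytest.approx(
                base.baseline_params["rate"] / 3.0, rel=1e-5
            )
        assert scaled.coefficients["z"] == pytest.approx(
            base.coefficients["z"], abs=1e-5
        )

    def test_weibull_loglik_dominates_exponential(self, rng):
        # the exponential is Weibull with shape fixed at 1: nesting bound
        for _ in range(3):
            t = rng.weibull(1.6, 150) * 20
            c = rng.uniform(10, 50, 150)
            e = (t <= c).astype(float)
            d = np.minimum(t, c)
            we = fit_censored("weibull", d, e)
            ex = fit_censored("exponential", d, e)
            assert we.loglik >= ex.loglik - 1e-8

    def test_cross_check_against_lifelines(self, rng):
        from lifelines import LogNormalAFTFitter, WeibullAFTFitter

        n = 400
        x = rng.uniform(-6, 6, n)
        t = rng.lognormal(3.2 + 0.13 * x, 1.0)
        c = rng.uniform(40, 80, n)
        e = (t <= c).astype(float)
        d = np.minimum(t, c)
        mine = fit_censored("lognormal", d, e, X=pd.DataFrame({"x": x}))
        ref = LogNormalAFTFitter()
        ref.fit(pd.DataFrame({"T": d, "E": e, "x": x}), "T", "E")
        assert mine.baseline_params["meanlog"] == pytest.approx(
            ref.params_[("mu_", "Intercept")], abs=1e-4
        )
        assert mine.baseline_params["sdlog"] == pytest.approx(
            np.exp(ref.params_[("sigma_", "Intercept")]), abs=1e-4
        )
        assert mine.coefficients["x"] == pytest.approx(
            ref.params_[("mu_", "x")], abs=1e-4
        )

        t2 = 30 * rng.weibull(2.0, n) * np.exp(0.05 * x)
        e2 = (t2 <= c).astype(float)
        d2 = np.minimum(t2, c)
        mine2 = fit_censored("weibull", d2, e2, X=pd.DataFrame({"x": x}))
        ref2 = WeibullAFTFitter()
        ref2.fit(pd.DataFrame({"T": d2, "E": e2, "x": x}), "T", "E")
        assert mine2.baseline_params["scale"] == pytest.approx(
            np.exp(ref2.params_[("lambda_", "Intercept")]), rel=1e-4
        )
        assert mine2.baseline_params["shape"] == pytest.approx(
            np.exp(ref2.params_[("rho_", "Intercept")]), rel=1e-4
        )
        assert mine2.coefficients["x"] == pytest.approx(
            ref2.params_[("lambda_", "x")], abs=1e-4
        )

    def test_fit_family_applies_centering(self):
        bouts = [
            make_bout(state="W", duration=d, observed=True, next_state="AS", pma_weeks=p)
            for d, p in zip([5, 9, 14, 22, 31, 8, 12, 19], [30, 32, 33, 35, 36, 38, 39, 40])
        ]
        r = fit_family("lognormal", bouts, CovariateSpec(("pma_weeks",)))
        assert r.centering == {"pma_weeks": 35.0}
        assert "pma_weeks" in r.coefficients


# --------------------------------------------------------------------------
# model selection / tails / effects
# --------------------------------------------------------------------------


def _mk_fit(family, aic, k=2, loglik=None, n=183, ne=75, params=None):
    names = {"exponential": ("rate",), "weibull": ("shape", "scale"),
             "lognormal": ("meanlog", "sdlog"), "powerlaw": ("alpha",)}[family]
    vals = params or [1.0] * len(names)
    return FitResult(
        family=family,
        baseline_params=dict(zip(names, vals)),
        coefficients={},
        se={},
        loglik=loglik if loglik is not None else (2 * len(names) - aic) / 2,
        aic=aic,
        n_bouts=n,
        n_events=ne,
    )


class TestSelection:
    def test_wakefulness_aic_ranking(self):
        # printed AICs for the wake bout fits: lognormal wins with these deltas
        fits = [
            _mk_fit("lognormal", 264.629),
            _mk_fit("weibull", 273.282),
            _mk_fit("exponential", 271.608, k=1),
        ]
        sel = select_model(fits)
        assert [f.family for f in sel.ranked] == ["lognormal", "exponential", "weibull"]
        assert sel.deltas == pytest.approx([0.0, 6.979, 8.653])

    def test_single_fit_delta_zero(self):
        sel = select_model([_mk_fit("weibull", 100.0)])
        assert sel.deltas == [0.0]

    def test_mismatched_bout_sets_rejected(self):
        with pytest.raises(ValueError, match="different bout sets"):
            select_model([_mk_fit("weibull", 10.0), _mk_fit("lognormal", 11.0, n=99)])

    def test_aic_tie_broken_by_fewer_parameters(self):
        sel = select_model([_mk_fit("weibull", 100.0), _mk_fit("exponential", 100.0)])
        assert sel.best.family == "exponential"

    def test_null_covariate_never_wins(self, rng):
        t = rng.exponential(10.0, 300)
        e = np.ones(300)
        junk = pd.DataFrame({"noise": rng.normal(size=300)})
        plain = fit_censored("exponential", t, e)
        with_junk = fit_censored("exponential", t, e, X=junk)
        assert with_junk.loglik >= plain.loglik
        assert with_junk.aic > plain.aic  # the 2-unit penalty dominates


class TestTailClass:
    @pytest.mark.parametrize(
        "family, params, label",
        [
            ("weibull", [2.181, 34.243], "light"),
            ("lognormal", [4.137, 0.891], "heavy"),
            ("exponential", [0.1], "exponential-like"),
            ("weibull", [1.0, 10.0], "exponential-like"),
            ("powerlaw", [2.5], "heavy"),
        ],
    )
    def test_taxonomy(self, family, params, label):
        fit = _mk_fit(family, 100.0, params=params)
        assert classify_tail(fit).label == label

    def test_sub_unit_weibull_shape_flagged(self):
        tc = classify_tail(_mk_fit("weibull", 100.0, params=[0.8, 10.0]))
        assert tc.label == "heavy" and tc.flagged


class TestAccelerationFactor:
    def test_zero_coefficient_unit_factor(self):
        fit = _mk_fit("lognormal", 10.0)
        fit.coefficients = {"pma_weeks": 0.0}
        fit.se = {"pma_weeks": 0.05}
        assert acceleration_factor(fit, "pma_weeks").factor == pytest.approx(1.0)

    def test_wake_pma_factor_from_log(self):
        fit = _mk_fit("lognormal", 10.0)
        fit.coefficients = {"pma_weeks": np.log(1.146)}
        fit.se = {"pma_weeks": 0.0575}
        af = acceleration_factor(fit, "pma_weeks")
        assert af.factor == pytest.approx(1.146)
        assert af.ci_low < 1.146 < af.ci_high

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            acceleration_factor(_mk_fit("lognormal", 10.0), "nope")


class TestLikelihoodRatio:
    def test_identical_models(self):
        a = _mk_fit("weibull", 100.0, loglik=-48.0)
        res = likelihood_ratio_test(a, a)
        assert (res.statistic, res.df, res.p) == (0.0, 0, 1.0)

    def test_rejects_non_nested(self):
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(_mk_fit("lognormal", 10.0), _mk_fit("weibull", 9.0))

    def test_detects_weibull_shape(self, rng):
        # strongly non-exponential data: the shape term should be needed
        for _ in range(5):
            t = 34.243 * rng.weibull(2.181, 500)
            e = np.ones(500)
            ex = fit_censored("exponential", t, e)
            we = fit_censored("weibull", t, e)
            res = likelihood_ratio_test(ex, we)
            assert res.df == 1 and res.p < 0.05

    def test_null_statistic_distribution(self, rng):
        # under exponential truth the statistic is small chi-square-ish
        stats_ = []
        for _ in range(40):
            t = rng.exponential(10, 200)
            e = np.ones(200)
            ex = fit_censored("exponential", t, e)
            we = fit_censored("weibull", t, e)
            stats_.append(likelihood_ratio_test(ex, we).statistic)
        # median of chi2(1) is 0.455; allow the boundary-pileup to shrink it
        assert np.median(stats_) < 1.5
        assert np.mean(np.array(stats_) > 3.84) < 0.25


class TestFittedSurvival:
    def test_exponential_closed_form(self):
        fit = _mk_fit("exponential", 10.0, params=[0.25])
        c = fitted_survival(fit, None, [0.0, 4.0])
        assert c.survival[1] == pytest.approx(np.exp(-1.0))
        assert c.kind == "fitted"

    def test_lognormal_median_property(self):
        fit = _mk_fit("lognormal", 10.0, params=[4.137, 0.891])
        c = fitted_survival(fit, None, [np.exp(4.137)])
        assert c.survival[0] == pytest.approx(0.5)

    def test_weibull_scale_is_e_folding_time(self):
        fit = _mk_fit("weibull", 10.0, params=[2.181, 34.243])
        c = fitted_survival(fit, None, [34.243])
        assert c.survival[0] == pytest.approx(np.exp(-1.0))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            fitted_survival(_mk_fit("exponential", 1.0, params=[0.2]), None, [-1.0, 2.0])

    def test_covariates_shift_curve(self, rng):
        t = rng.lognormal(3.0 + 0.1 * np.arange(-5, 5).repeat(30), 0.8)
        X = pd.DataFrame({"pma_weeks": np.arange(-5, 5).repeat(30)})
        fit = fit_censored("lognormal", t, np.ones_like(t), X=X)
        fit.centering = {"pma_weeks": 35.0}
        lo = fitted_survival(fit, {"pma_weeks": 30.0}, [20.0])
        hi = fitted_survival(fit, {"pma_weeks": 40.0}, [20.0])
        assert hi.survival[0] > lo.survival[0]
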