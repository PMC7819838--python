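"""Censored maximum-likelihood fitting of bout-duration laws with AFT covariates.

Bout durations are modelled with parametric survival ("accelerated failure
time", AFT) models.  Candidate duration laws, in increasing right-skew:

* ``weibull`` (shape > 1: light-tailed — extra-long bouts are suppressed),
* ``exponential`` (memoryless exits),
* ``lognormal`` (heavy-tailed — exit rate plateaus, extra-long bouts occur),
* ``powerlaw`` (continuous Pareto with fixed lower bound; heavy-tailed).

Right-censored bouts (offset not captured before the recording ended)
contribute survival mass S(t) instead of density mass f(t).  Covariates act
multiplicatively on duration: with covariate row ``x`` and coefficients
``beta``, a bout's time scale is stretched by ``a = exp(beta @ x)``, so the
log-likelihood term is ``log f(t/a) - log a`` for events and ``log S(t/a)``
for censored observations.  ``exp(coefficient)`` is therefore a duration
ratio per covariate unit.

The family laws are AIC-compared per state, and the winner's identity (plus
the Weibull shape) classifies the state's right tail as light,
exponential-like or heavy.

The fitting engine is the sklearn-style estimator :class:`CensoredAFT`;
module-level functions (:func:`fit_family`, :func:`km_estimate`, ...) are
thin wrappers over it and over :class:`KaplanMeier`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .hypnogram import Bout

FAMILIES = ("exponential", "weibull", "lognormal", "powerlaw")

FAMILY_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "powerlaw": ("alpha",),
}

#: reference values subtracted from covariates before fitting, so baseline
#: parameters describe an interpretable reference subject
DEFAULT_CENTERING = {
    "pma_weeks": 35.0,  # weeks PMA
    "cortisol10": 2.0,  # cortisol in 0.1 ug/dL units, i.e. 0.2 ug/dL
}


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge after restarts; carries diagnostics."""


# --------------------------------------------------------------------------
# family log-likelihood terms
# --------------------------------------------------------------------------

def _validate_params(family: str, params: Sequence[float]) -> None:
    names = FAMILY_PARAM_NAMES[family]
    if len(params) != len(names):
        raise ValueError(f"{family} expects {len(names)} parameters {names}")
    p = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{family} parameters must be finite, got {params}")
    if family == "exponential" and p[0] <= 0:
        raise ValueError("exponential rate must be > 0")
    if family == "weibull" and (p[0] <= 0 or p[1] <= 0):
        raise ValueError("weibull shape and scale must be > 0")
    if family == "lognormal" and p[1] <= 0:
        raise ValueError("lognormal sdlog must be > 0")
    if family == "powerlaw" and p[0] <= 1:
        raise ValueError("powerlaw exponent must be > 1")


def _log_terms(
    family: str,
    params: Sequence[float],
    z: np.ndarray,
    x_min: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(logpdf(z), logsf(z)) for the baseline law at acceleration-adjusted times."""
    if family == "exponential":
        (rate,) = params
        dist = stats.expon(scale=1.0 / rate)
    elif family == "weibull":
        shape, scale = params
        dist = stats.weibull_min(shape, scale=scale)
    elif family == "lognormal":
        meanlog, sdlog = params
        dist = stats.lognorm(sdlog, scale=np.exp(meanlog))
    elif family == "powerlaw":
        (alpha,) = params
        dist = stats.pareto(alpha - 1.0, scale=x_min)
    else:
        raise ValueError(f"unknown family {family!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        return dist.logpdf(z), dist.logsf(z)


def neg_loglik_censored(
    family: str,
    params: Sequence[float],
    durations: Sequence[float],
    event_observed: Sequence[float],
    covariates: np.ndarray | None = None,
    coefficients: Sequence[float] | None = None,
    x_min: float = 1.0,
) -> float:
    """Negative log-likelihood of right-censored durations under an AFT law.

    ``covariates`` is an (n, k) design matrix (already centered) and
    ``coefficients`` the k log-acceleration values; each bout's time scale
    is multiplied by ``exp(covariates @ coefficients)``.  Out-of-support
    parameters raise; durations outside the family's support yield ``inf``
    (never silently clipped).
    """
    _validate_params(family, params)
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=float)
    if t.shape != e.shape:
        raise ValueError("durations and event_observed must have equal length")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    if covariates is not None and coefficients is not None and len(coefficients):
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        beta = np.asarray(coefficients, dtype=float)
        eta = X @ beta
    else:
        eta = np.zeros_like(t)
    z = t * np.exp(-eta)
    logpdf, logsf = _log_terms(family, params, z, x_min)
    ll = np.where(e > 0, logpdf - eta, logsf)
    total = float(np.sum(ll))
    return -total


# --------------------------------------------------------------------------
# working-scale transforms (optimization on unconstrained scale)
# --------------------------------------------------------------------------

def _to_working(family: str, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if family == "exponential":
        return np.log(p)
    if family == "weibull":
        return np.log(p)
    if family == "lognormal":
        return np.array([p[0], np.log(p[1])])
    if family == "powerlaw":
        return np.array([np.log(p[0] - 1.0)])
    raise ValueError(family)


def _from_working(family: str, w: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.exp(w)
    if family == "weibull":
        return np.exp(w)
    if family == "lognormal":
        return np.array([w[0], np.exp(w[1])])
    if family == "powerlaw":
        return np.array([1.0 + np.exp(w[0])])
    raise ValueError(family)


def _natural_jacobian_diag(family: str, natural: np.ndarray) -> np.ndarray:
    """d(natural)/d(working), diagonal, for delta-method standard errors."""
    if family == "lognormal":
        return np.array([1.0, natural[1]])
    if family == "powerlaw":
        return np.array([natural[0] - 1.0])
    return np.asarray(natural, dtype=float)  # log-transformed: d exp(w)/dw = value


def _numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) + fun(x - ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted duration law with AFT covariate effects.

    ``baseline_params`` are the family parameters at the covariate reference
    (all centered covariates zero); ``coefficients`` map covariate names to
    log-acceleration values, so ``exp(coefficient)`` is the duration ratio
    per unit of that covariate.
    """

    family: str
    baseline_params: dict[str, float]
    coefficients: dict[str, float]
    se: dict[str, float]
    loglik: float
    aic: float
    n_bouts: int
    n_events: int
    centering: dict[str, float] = field(default_factory=dict)
    x_min: float = 1.0
    cov_working: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        """Number of estimated parameters."""
        return len(self.baseline_params) + len(self.coefficients)

    @property
    def param_values(self) -> np.ndarray:
        return np.array(list(self.baseline_params.values()))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "baseline_params": dict(self.baseline_params),
            "coefficients": dict(self.coefficients),
            "se": {k: (None if not np.isfinite(v) else v) for k, v in self.se.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "k": self.k,
            "n_bouts": self.n_bouts,
            "n_events": self.n_events,
            "centering": dict(self.centering),
        }


@dataclass
class SurvivalCurve:
    """A step/smooth survival estimate with a pointwise confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: str  # "empirical" | "fitted"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.survival > 1 + 1e-12) or np.any(self.survival < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-10):
            raise ValueError("survival must be non-increasing")
        if np.any(self.ci_low > self.survival + 1e-10) or np.any(
            self.ci_high < self.survival - 1e-10
        ):
            raise ValueError("confidence band must contain the point estimate")

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "kind": self.kind,
            }
        )


@dataclass(frozen=True)
class TailClass:
    """Right-tail classification implied by the AIC-selected family."""

    label: str  # "light" | "exponential-like" | "heavy"
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class AccelerationFactor:
    covariate: str
    factor: float
    ci_low: float
    ci_high: float
    coefficient: float
    se: float


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class CovariateSpec:
    """Named covariates with per-covariate centering reference values."""

    names: tuple[str, ...]
    centering: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")

    def center_of(self, name: str) -> float:
        if self.centering is not None and name in self.centering:
            return float(self.centering[name])
        return DEFAULT_CENTERING.get(name, 0.0)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

class KaplanMeier(BaseEstimator):
    """Product-limit survival estimator with a Greenwood pointwise band.

    Thin sklearn-style wrapper over ``lifelines.KaplanMeierFitter``; the
    confidence band uses the plain Greenwood variance,
    ``Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i))``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, durations, event_observed) -> "KaplanMeier":
        t = np.asarray(durations, dtype=float)
        e = np.asarray(event_observed, dtype=int)
        if t.size == 0:
            raise ValueError("empty input")
        if t.shape != e.shape:
            raise ValueError("durations and event_observed must have equal length")
        if np.any(t <= 0):
            raise ValueError("durations must be positive")
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        table = kmf.event_table
        times = table.index.to_numpy(dtype=float)
        surv = kmf.survival_function_["KM_estimate"].to_numpy()
        d = table["observed"].to_numpy(dtype=float)
        n = table["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n - d > 0, d / (n * (n - d)), 0.0)
        var = surv**2 * np.cumsum(terms)
        var = np.where(surv <= 0, 0.0, var)
        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        half = z * np.sqrt(var)
        self.curve_ = SurvivalCurve(
            times=times,
            survival=surv,
            ci_low=np.clip(surv - half, 0.0, 1.0),
            ci_high=np.clip(surv + half, 0.0, 1.0),
            kind="empirical",
        )
        self.n_ = int(t.size)
        self.n_events_ = int(e.sum())
        return self


def km_estimate(durations, event_observed, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier survival curve with Greenwood pointwise band."""
    return KaplanMeier(alpha=alpha).fit(durations, event_observed).curve_


# --------------------------------------------------------------------------
# censored AFT maximum likelihood
# --------------------------------------------------------------------------

class CensoredAFT(BaseEstimator):
    """Censored maximum-likelihood AFT fit of one parametric duration law.

    Parameters
    ----------
    family : str
        One of ``exponential``, ``weibull``, ``lognormal``, ``powerlaw``.
    x_min : float
        Fixed lower bound of the power-law (Pareto) family, in minutes;
        ignored by the other families.  Default 1.0, the minimum scoreable
        bout length.
    n_restarts : int
        Jittered restarts attempted on optimizer failure.
    restart_seed : int
        Seed of the jitter stream, fixed so fits are deterministic.
    use_aicc : bool
        Report the small-sample corrected AICc instead of AIC.

    The estimator is fitted with ``fit(X, y)`` where ``y`` is an (n, 2)
    array of ``[duration_min, event_observed]`` and ``X`` an optional
    (n, k) centered design matrix (DataFrame columns become covariate
    names).  Fitted attributes follow sklearn conventions (``params_``,
    ``coef_``, ``loglik_``, ``aic_``, ...) and ``result_`` bundles them as
    a :class:`FitResult`.
    """

    def __init__(
        self,
        family: str = "lognormal",
        x_min: float = 1.0,
        n_restarts: int = 3,
        restart_seed: int = 0,
        use_aicc: bool = False,
    ):
        self.family = family
        self.x_min = x_min
        self.n_restarts = n_restarts
        self.restart_seed = restart_seed
        self.use_aicc = use_aicc

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _check_y(y) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of [duration, event_observed]")
        t = arr[:, 0]
        e = arr[:, 1]
        if np.any(t <= 0):
            raise ValueError("durations must be positive")
        if not np.all(np.isin(e, (0.0, 1.0))):
            raise ValueError("event_observed must be 0/1")
        return t, e

    def _init_params(self, t: np.ndarray, e: np.ndarray) -> np.ndarray:
        """Moment/rank-based starting values (events only), per family."""
        fam = self.family
        te = t[e > 0]
        if fam == "exponential":
            return np.array([e.sum() / t.sum()])
        if fam == "lognormal":
            logs = np.log(te)
            mu0 = float(np.mean(logs))
            s0 = float(np.std(logs))
            return np.array([mu0, max(s0, 0.1)])
        if fam == "weibull":
            # rank regression of log(-log S_km) on log t at event times
            try:
                curve = km_estimate(t, e)
                mask = (curve.survival > 0) & (curve.survival < 1) & (curve.times > 0)
                xs = np.log(curve.times[mask])
                ys = np.log(-np.log(curve.survival[mask]))
                if xs.size >= 2 and np.ptp(xs) > 0:
                    shape0, intercept = np.polyfit(xs, ys, 1)
                    if shape0 > 0:
                        scale0 = np.exp(-intercept / shape0)
                        return np.array([shape0, scale0])
            except Exception:
                pass
            return np.array([1.0, float(np.mean(te))])
        if fam == "powerlaw":
            logs = np.log(np.maximum(t, self.x_min) / self.x_min)
            denom = float(np.sum(logs))
            alpha0 = 1.0 + (e.sum() / denom if denom > 0 else 1.0)
            return np.array([min(max(alpha0, 1.05), 20.0)])
        raise ValueError(f"unknown family {fam!r}")

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "CensoredAFT":
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        t, e = self._check_y(y)
        if isinstance(X, pd.DataFrame):
            names = tuple(map(str, X.columns))
            Xa = X.to_numpy(dtype=float)
        elif X is None:
            names = ()
            Xa = np.empty((t.size, 0))
        else:
            Xa = np.atleast_2d(np.asarray(X, dtype=float))
            if Xa.shape[0] != t.size and Xa.shape[1] == t.size:
                Xa = Xa.T
            names = tuple(f"x{i}" for i in range(Xa.shape[1]))
        if Xa.shape[0] != t.size:
            raise ValueError("X rows must match number of durations")
        if not np.all(np.isfinite(Xa)):
            raise ValueError("covariates must be finite (missing values not allowed)")
        k_cov = Xa.shape[1]
        n_base = len(FAMILY_PARAM_NAMES[self.family])
        n_params = n_base + k_cov
        n_events = int(e.sum())
        if n_events == 0:
            raise ValueError("all observations censored; cannot fit")
        if t.size < n_params + 2:
            raise ValueError(
                f"need at least {n_params + 2} bouts to fit {n_params} parameters"
            )

        fam = self.family
        x_min = self.x_min

        def nll_working(w: np.ndarray) -> float:
            natural = _from_working(fam, w[:n_base])
            beta = w[n_base:]
            eta = Xa @ beta if k_cov else 0.0
            z = t * np.exp(-eta)
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                logpdf, logsf = _log_terms(fam, natural, z, x_min)
                ll = np.where(e > 0, logpdf - (eta if k_cov else 0.0), logsf)
                total = np.sum(ll)
            if not np.isfinite(total):
                return 1e12  # optimizer barrier only; public API never clips
            return -float(total)

        w0 = np.concatenate([_to_working(fam, self._init_params(t, e)), np.zeros(k_cov)])
        rng = np.random.default_rng(self.restart_seed)
        attempts = []
        best = None
        for attempt in range(1 + self.n_restarts):
            start = w0 if attempt == 0 else w0 + rng.normal(scale=0.5, size=w0.size)
            res = optimize.minimize(
                nll_working,
                start,
                method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            attempts.append((attempt, res.success, float(res.fun)))
            if res.success and np.isfinite(res.fun) and res.fun < 1e11:
                best = res
                break
            if (
                np.isfinite(res.fun)
                and res.fun < 1e11
                and (best is None or res.fun < best.fun)
            ):
                best = res  # keep best non-divergent attempt as fallback
        if best is None:
            raise ConvergenceError(
                f"{fam} fit failed to converge after {1 + self.n_restarts} starts: {attempts}"
            )

        w_hat = best.x
        natural = _from_working(fam, w_hat[:n_base])
        beta = np.asarray(w_hat[n_base:], dtype=float)
        loglik = -float(nll_working(w_hat))

        # covariance: inverse numerical Hessian on the working scale
        cov_w = np.full((n_params, n_params), np.nan)
        se_working = np.full(n_params, np.nan)
        try:
            H = _numerical_hessian(nll_working, w_hat)
            cov_w = np.linalg.inv(H)
            diag = np.diag(cov_w)
            if np.all(diag > 0):
                se_working = np.sqrt(diag)
            else:
                warnings.warn("Hessian not positive definite; standard errors unavailable")
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; standard errors unavailable")

        jac = _natural_jacobian_diag(fam, natural)
        se_natural = np.abs(jac) * se_working[:n_base]

        param_names = FAMILY_PARAM_NAMES[fam]
        aic = 2.0 * n_params - 2.0 * loglik
        if self.use_aicc:
            n = t.size
            aic += 2.0 * n_params * (n_params + 1) / max(n - n_params - 1, 1)

        self.feature_names_in_ = names
        self.params_ = dict(zip(param_names, map(float, natural)))
        self.coef_ = beta
        self.se_params_ = dict(zip(param_names, map(float, se_natural)))
        self.se_coef_ = se_working[n_base:]
        self.loglik_ = loglik
        self.aic_ = float(aic)
        self.n_bouts_ = int(t.size)
        self.n_events_ = n_events
        self.cov_working_ = cov_w
        se_all = dict(self.se_params_)
        se_all.update(dict(zip(names, map(float, self.se_coef_))))
        self.result_ = FitResult(
            family=fam,
            baseline_params=dict(self.params_),
            coefficients=dict(zip(names, map(float, beta))),
            se=se_all,
            loglik=loglik,
            aic=float(aic),
            n_bouts=int(t.size),
            n_events=n_events,
            x_min=x_min,
            cov_working=cov_w,
        )
        return self

    # -- prediction --------------------------------------------------------

    def _acceleration(self, X) -> np.ndarray:
        if X is None or len(self.coef_) == 0:
            return np.ones(1)
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        return np.exp(Xa @ self.coef_)

    def predict(self, X=None) -> np.ndarray:
        """Median bout duration (minutes) at the given centered covariates."""
        a = self._acceleration(X)
        p = self.params_
        if self.family == "exponential":
            base = np.log(2.0) / p["rate"]
        elif self.family == "weibull":
            base = p["scale"] * np.log(2.0) ** (1.0 / p["shape"])
        elif self.family == "lognormal":
            base = np.exp(p["meanlog"])
        else:
            base = self.x_min * 2.0 ** (1.0 / (p["alpha"] - 1.0))
        return base * a


# --------------------------------------------------------------------------
# design matrices from bouts
# --------------------------------------------------------------------------

def covariate_value(bout: Bout, name: str) -> float:
    """Extract a named covariate from a bout, in modelling units.

    ``cortisol10`` is cortisol in 0.1 ug/dL units (the per-mcg/10 dL AFT
    convention); ``dest_qs`` is the active-sleep destination indicator
    (1 if the bout offsets into quiet sleep), defined only for observed
    offsets.
    """
    c = bout.covariates
    if name == "pma_weeks":
        v = c.pma_weeks
    elif name == "postnatal_age_days":
        v = c.postnatal_age_days
    elif name == "risk_high":
        v = c.risk_high
    elif name == "cortisol10":
        v = None if c.cortisol_ug_dl is None else 10.0 * c.cortisol_ug_dl
    elif name == "dest_qs":
        v = None if bout.next_state is None else float(bout.next_state == "QS")
    else:
        raise KeyError(f"unknown covariate {name!r}")
    if v is None:
        raise ValueError(f"bout for {bout.subject_id!r} lacks covariate {name!r}")
    return float(v)


def design_matrix(bouts: Sequence[Bout], spec: CovariateSpec) -> pd.DataFrame:
    """Centered design matrix for the named covariates, one row per bout."""
    data = {
        name: [covariate_value(b, name) - spec.center_of(name) for b in bouts]
        for name in spec.names
    }
    return pd.DataFrame(data)


def fit_family(
    family: str,
    bouts: Sequence[Bout],
    covariate_spec: CovariateSpec | None = None,
    **estimator_kwargs,
) -> FitResult:
    """Censored-MLE fit of one family to a set of bouts (spec applied with centering)."""
    t = np.array([b.duration_min for b in bouts])
    e = np.array([float(b.offset_captured) for b in bouts])
    if covariate_spec is not None and covariate_spec.names:
        X = design_matrix(bouts, covariate_spec)
        centering = {n: covariate_spec.center_of(n) for n in covariate_spec.names}
    else:
        X, centering = None, {}
    result = fit_censored(family, t, e, X=X, **estimator_kwargs)
    result.centering = centering
    return result


def fit_censored(
    family: str,
    durations,
    event_observed,
    X=None,
    **estimator_kwargs,
) -> FitResult:
    """Array-level censored AFT fit; returns the :class:`FitResult`."""
    y = np.column_stack(
        [np.asarray(durations, dtype=float), np.asarray(event_observed, dtype=float)]
    )
    est = CensoredAFT(family=family, **estimator_kwargs)
    est.fit(X, y)
    return est.result_


# --------------------------------------------------------------------------
# model comparison, tail class, covariate effects
# --------------------------------------------------------------------------

@dataclass
class ModelSelection:
    """AIC-ranked candidate fits (ascending AIC; deltas relative to the best)."""

    ranked: list[FitResult]
    deltas: list[float]

    @property
    def best(self) -> FitResult:
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [f.family for f in self.ranked],
                "aic": [f.aic for f in self.ranked],
                "k": [f.k for f in self.ranked],
                "delta": self.deltas,
            }
        )


def select_model(fits: Sequence[FitResult]) -> ModelSelection:
    """Rank fits by AIC; ties broken by fewer parameters, then family order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select among")
    sizes = {(f.n_bouts, f.n_events) for f in fits}
    if len(sizes) != 1:
        raise ValueError(f"fits computed on different bout sets: {sorted(sizes)}")
    order = sorted(
        fits, key=lambda f: (f.aic, f.k, FAMILIES.index(f.family))
    )
    best_aic = order[0].aic
    return ModelSelection(ranked=order, deltas=[f.aic - best_aic for f in order])


def classify_tail(best: FitResult) -> TailClass:
    """Map the AIC-selected family (and Weibull shape) to a tail class."""
    if best.family in ("lognormal", "powerlaw"):
        return TailClass("heavy")
    if best.family == "exponential":
        return TailClass("exponential-like")
    shape = best.baseline_params["shape"]
    if shape > 1.0:
        return TailClass("light")
    if shape == 1.0:
        return TailClass("exponential-like", note="Weibull shape exactly 1 (boundary)")
    return TailClass(
        "heavy",
        flagged=True,
        note="Weibull shape < 1: heavier-skewed than exponential but outside the "
        "light/exponential/heavy taxonomy assumed here",
    )


def acceleration_factor(fit: FitResult, covariate: str, alpha: float = 0.05) -> AccelerationFactor:
    """Duration ratio per covariate unit, exp(coefficient), with Wald CI."""
    if covariate not in fit.coefficients:
        raise KeyError(f"covariate {covariate!r} not in fit ({list(fit.coefficients)})")
    b = fit.coefficients[covariate]
    se = fit.se.get(covariate, np.nan)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AccelerationFactor(
        covariate=covariate,
        factor=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        coefficient=float(b),
        se=float(se),
    )


_NESTED_FAMILIES = {("exponential", "weibull"), ("exponential", "exponential"),
                    ("weibull", "weibull"), ("lognormal", "lognormal"),
                    ("powerlaw", "powerlaw")}


def likelihood_ratio_test(nested: FitResult, full: FitResult) -> LRTResult:
    """2*(loglik_full - loglik_nested) against chi-square with df = delta k.

    The nested model must be a genuine restriction of the full one: same
    bout set, covariates a subset, and the family pair either identical or
    exponential-within-Weibull (shape fixed at 1).
    """
    if (nested.n_bouts, nested.n_events) != (full.n_bouts, full.n_events):
        raise ValueError("models fitted on different bout sets")
    if (nested.family, full.family) not in _NESTED_FAMILIES:
        raise ValueError(f"{nested.family} is not nested in {full.family}")
    if not set(nested.coefficients) <= set(full.coefficients):
        raise ValueError("nested model's covariates are not a subset of the full model's")
    df = full.k - nested.k
    statistic = 2.0 * (full.loglik - nested.loglik)
    if df == 0:
        if statistic < 1e-6:
            return LRTResult(0.0, 0, 1.0)
        raise ValueError("models have equal parameter counts but differ; not nested")
    statistic = max(statistic, 0.0)
    return LRTResult(float(statistic), int(df), float(stats.chi2.sf(statistic, df)))


def fitted_survival(
    fit: FitResult,
    covariate_values: Mapping[str, float] | None,
    times,
    alpha: float = 0.05,
) -> SurvivalCurve:
    """Model survival curve at given covariate values, with delta-method band.

    ``covariate_values`` are in natural (uncentered) units; the fit's
    centering is subtracted internally.  Omitted covariates sit at their
    reference values.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be increasing")
    cov_names = list(fit.coefficients)
    x = np.array(
        [
            (covariate_values or {}).get(n, fit.centering.get(n, 0.0))
            - fit.centering.get(n, 0.0)
            for n in cov_names
        ]
    )
    n_base = len(fit.baseline_params)

    def surv_from_working(w: np.ndarray) -> np.ndarray:
        natural = _from_working(fit.family, w[:n_base])
        beta = w[n_base:]
        a = float(np.exp(x @ beta)) if len(beta) else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            _, logsf = _log_terms(fit.family, natural, np.maximum(times, 1e-300) / a, fit.x_min)
        s = np.exp(logsf)
        s[times == 0] = 1.0
        return s

    w_hat = np.concatenate(
        [_to_working(fit.family, fit.param_values), np.array(list(fit.coefficients.values()))]
    )
    s = surv_from_working(w_hat)
    cov = fit.cov_working
    if cov is not None and np.all(np.isfinite(cov)):
        # delta method: gradient of S(t) wrt working parameters
        h = 1e-5 * np.maximum(1.0, np.abs(w_hat))
        grads = np.empty((len(w_hat), times.size))
        for i in range(len(w_hat)):
            ei = np.zeros_like(w_hat)
            ei[i] = h[i]
            grads[i] = (surv_from_working(w_hat + ei) - surv_from_working(w_hat - ei)) / (
                2.0 * h[i]
            )
        var = np.einsum("it,ij,jt->t", grads, cov, grads)
        var = np.maximum(var, 0.0)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * np.sqrt(var)
    else:
        half = np.zeros_like(s)
    return SurvivalCurve(
        times=times,
        survival=s,
        ci_low=np.clip(s - half, 0.0, 1.0),
        ci_high=np.clip(s + half, 0.0, 1.0),
        kind="fitted",
    )


def forward_select_covariates(
    family: str,
    durations,
    event_observed,
    X: pd.DataFrame,
    base: Sequence[str] = ("pma_weeks",),
    candidates: Sequence[str] = (),
    **estimator_kwargs,
) -> tuple[list[str], FitResult, pd.DataFrame]:
    """Forward inclusion of covariates, one at a time, accepting AIC reductions.

    Starts from the model containing ``base`` (the maturational-age-only
    model) and greedily adds the candidate that most reduces AIC until no
    addition helps.  ``X`` holds centered covariate columns.
    """
    selected = list(base)
    remaining = [c for c in candidates if c not in selected]
    current = fit_censored(
        family, durations, event_observed, X=X[selected] if selected else None,
        **estimator_kwargs,
    )
    trace_rows = [{"step": 0, "added": "", "aic": current.aic}]
    step = 1
    while remaining:
        trials = []
        for c in remaining:
            try:
                f = fit_censored(
                    family, durations, event_observed, X=X[selected + [c]],
                    **estimator_kwargs,
                )
                trials.append((f.aic, c, f))
            except (ValueError, ConvergenceError):
                continue
        if not trials:
            break
        trials.sort(key=lambda r: r[0])
        best_aic, best_c, best_fit = trials[0]
        if best_aic >= current.aic:
            break
        selected.append(best_c)
        remaining.remove(best_c)
        current = best_fit
        trace_rows.append({"step": step, "added": best_c, "aic": best_aic})
        step += 1
    return selected, current, pd.DataFrame(trace_rows)
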