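"""Stress-strength reliability R = P(Y < X) for the power-modified Lindley.

With strength X ~ PML(alpha, theta1) and stress Y ~ PML(alpha, theta2)
independent and sharing the power exponent, the substitution t = x**alpha
removes alpha entirely and R depends on the two rates alone:

    R = 1 - I1 - theta2/(theta2+1) * I2,

where (writing t1 = theta1, t2 = theta2)

    I1 = t1/(t1+1) * [ (1+t1)/(t1+t2) + 2*t1/(2*t1+t2)**2 - 1/(2*t1+t2) ]
    I2 = t1/(t1+1) * [ (1+t1)/(t1+2*t2)**2 + t1/(2*(t1+t2)**3)
                       - 1/(4*(t1+t2)**2) ]

each term the integral of the base modified-Lindley cdf against the base
pdf.  This form satisfies R = 1/2 at t1 = t2 (i.i.d. continuous margins)
and matches adaptive quadrature of int F_Y f_X to ~1e-12; it is the default
everywhere.  A second evaluator transcribes the commonly circulated but
erroneous closed form (see :func:`reliability_as_printed`): it violates the
1/2 identity and is retained for diagnosis only.

Estimation: joint MLE of (alpha, theta1, theta2), a delta-method confidence
interval for R built from the analytic gradient (dR/dalpha = 0 identically),
and a three-parameter Metropolis-Hastings sampler with loss-based Bayes
estimates of R.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bayes import (
    GammaPrior,
    HPDInterval,
    PosteriorChain,
    default_losses,
    elicit_hyperparameters,
    hpd_interval,
    loss_estimate,
    random_walk_metropolis,
)
from .distribution import PML
from .estimation import (
    FitResult,
    _observed_information,
    _wald,
    as_sample,
    fit_mle,
    loglik,
    score,
)

__all__ = [
    "StressStrengthParams",
    "ReliabilityEstimate",
    "reliability",
    "reliability_gradient",
    "reliability_as_printed",
    "ss_loglik",
    "ss_score",
    "ss_fit_mle",
    "ss_fit_bayes",
    "SSFitResult",
    "SSBayesResult",
]


@dataclass(frozen=True)
class StressStrengthParams:
    """Common shape alpha with strength rate theta1 and stress rate theta2."""

    alpha: float
    theta1: float
    theta2: float

    def __post_init__(self):
        for name in ("alpha", "theta1", "theta2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive real, got {v!r}")

    @property
    def strength(self) -> PML:
        return PML(self.alpha, self.theta1)

    @property
    def stress(self) -> PML:
        return PML(self.alpha, self.theta2)

    @property
    def reliability(self) -> float:
        return reliability(self.theta1, self.theta2)


def _check_rates(theta1, theta2):
    t1 = float(theta1)
    t2 = float(theta2)
    if not (t1 > 0 and t2 > 0 and math.isfinite(t1) and math.isfinite(t2)):
        raise ValueError("both rates must be finite positive reals")
    return t1, t2


def reliability(theta1: float, theta2: float) -> float:
    """P(Y < X): validated closed form, independent of the shared alpha."""
    t1, t2 = _check_rates(theta1, theta2)
    I1 = t1 / (t1 + 1.0) * (
        (1.0 + t1) / (t1 + t2)
        + 2.0 * t1 / (2.0 * t1 + t2) ** 2
        - 1.0 / (2.0 * t1 + t2)
    )
    I2 = t1 / (t1 + 1.0) * (
        (1.0 + t1) / (t1 + 2.0 * t2) ** 2
        + t1 / (2.0 * (t1 + t2) ** 3)
        - 1.0 / (4.0 * (t1 + t2) ** 2)
    )
    return 1.0 - I1 - t2 / (t2 + 1.0) * I2


def reliability_gradient(theta1: float, theta2: float) -> tuple[float, float]:
    """Analytic (dR/dtheta1, dR/dtheta2), term-by-term from the closed form.

    dR/dalpha is identically zero and is not returned here; the delta-method
    gradient vector is (0, dR/dtheta1, dR/dtheta2).
    """
    t1, t2 = _check_rates(theta1, theta2)
    s = t1 + t2
    d = 2.0 * t1 + t2
    e = t1 + 2.0 * t2
    A = (1.0 + t1) / s + 2.0 * t1 / d**2 - 1.0 / d
    C = (1.0 + t1) / e**2 + t1 / (2.0 * s**3) - 1.0 / (4.0 * s**2)
    dA_dt1 = (t2 - 1.0) / s**2 + (2.0 * t2 - 4.0 * t1) / d**3 + 2.0 / d**2
    dA_dt2 = -(1.0 + t1) / s**2 - 4.0 * t1 / d**3 + 1.0 / d**2
    dC_dt1 = (
        1.0 / e**2
        - 2.0 * (1.0 + t1) / e**3
        + 1.0 / (2.0 * s**3)
        - 3.0 * t1 / (2.0 * s**4)
        + 1.0 / (2.0 * s**3)
    )
    dC_dt2 = -4.0 * (1.0 + t1) / e**3 - 3.0 * t1 / (2.0 * s**4) + 1.0 / (2.0 * s**3)
    w = t1 / (t1 + 1.0)
    dw = 1.0 / (t1 + 1.0) ** 2
    dI1_dt1 = dw * A + w * dA_dt1
    dI1_dt2 = w * dA_dt2
    dI2_dt1 = dw * C + w * dC_dt1
    dI2_dt2 = w * dC_dt2
    I2 = w * C
    g1 = -dI1_dt1 - t2 / (t2 + 1.0) * dI2_dt1
    g2 = -dI1_dt2 - I2 / (t2 + 1.0) ** 2 - t2 / (t2 + 1.0) * dI2_dt2
    return g1, g2


def reliability_as_printed(theta1: float, theta2: float) -> float:
    """The erroneous closed form for R as commonly typeset (non-validated).

    Kept verbatim for diagnosing published tables that report it: it fails
    the theta1 = theta2 -> 1/2 identity (giving ~0.396 at equal unit rates)
    and disagrees with the quadrature of int F_Y f_X.  Every call emits a
    warning; never use this for inference.
    """
    t1, t2 = _check_rates(theta1, theta2)
    warnings.warn(
        "reliability_as_printed is a non-validated transcription kept for "
        "diagnosis; use reliability() for inference",
        UserWarning,
        stacklevel=2,
    )
    first = t1 / (t1 + 1.0) * (
        (1.0 + t1) / (t1 + t2)
        + 2.0 * t1 / (2.0 * t1 + t2) ** 2
        - 1.0 / (2.0 * t1 + t2)
    )
    second = (t1 * t2) / ((t1 + 1.0) * (t2 + 1.0)) * (
        (1.0 + t1) / (t1 + 2.0 * t2)
        + 2.0 * t1 / (2.0 * t1 + t2) ** 2
        - 1.0 / (2.0 * (t1 + t2))
    )
    return 1.0 - first - second


# ----------------------------------------------------------------------
# joint likelihood
# ----------------------------------------------------------------------
def ss_loglik(params: StressStrengthParams, x, y) -> float:
    """Joint log-likelihood: strength and stress samples share alpha."""
    return loglik(params.strength, x) + loglik(params.stress, y)


def ss_score(params: StressStrengthParams, x, y) -> np.ndarray:
    """Analytic score (d/dalpha, d/dtheta1, d/dtheta2) of the joint model."""
    sx = score(params.strength, x)
    sy = score(params.stress, y)
    return np.array([sx[0] + sy[0], sx[1], sy[1]])


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Point estimate of R with its uncertainty."""

    r: float
    se: float
    ci: tuple[float, float]
    method: str  # "mle_delta" or "bayes"
    ci_unclipped: tuple[float, float] | None = None
    chain: PosteriorChain | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        if not self.ci[0] <= self.r <= self.ci[1]:
            raise ValueError("R must lie inside its confidence interval")


@dataclass
class SSFitResult:
    """Joint MLE of the stress-strength model plus the delta-method R."""

    params: StressStrengthParams
    param_names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    ci: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    level: float
    n: int
    m: int
    reliability: ReliabilityEstimate

    def as_dict(self) -> dict:
        return {
            "params": dict(zip(self.param_names, map(float, self.estimates))),
            "se": dict(zip(self.param_names, map(float, self.se))),
            "ci": {
                k: [float(lo), float(hi)]
                for k, (lo, hi) in zip(self.param_names, self.ci)
            },
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "R": {
                "estimate": self.reliability.r,
                "se": self.reliability.se,
                "ci": list(self.reliability.ci),
                "method": self.reliability.method,
            },
            "level": float(self.level),
            "n": self.n,
            "m": self.m,
        }


def ss_fit_mle(x, y, level: float = 0.95) -> SSFitResult:
    """Joint maximum likelihood for (alpha, theta1, theta2) and delta-method R.

    Optimises in log-parameter space with analytic gradients from multiple
    deterministic starts; alpha is seeded at the average of the two marginal
    shape fits and each theta at its marginal value.  sigma_R^2 = B' I^-1 B
    with B = (0, dR/dtheta1, dR/dtheta2) and I the observed information; the
    confidence interval for R is clipped to [0, 1] (the unclipped one is
    retained for coverage studies).
    """
    xs = as_sample(x)
    ys = as_sample(y)
    if xs.size < 3 or ys.size < 3:
        raise ValueError("both samples need at least 3 observations")
    fx = fit_mle(xs, level=level)
    fy = fit_mle(ys, level=level)

    def nll_z(z):
        try:
            p = StressStrengthParams(*np.exp(z))
            return -ss_loglik(p, xs, ys)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12

    def grad_z(z):
        p = np.exp(z)
        try:
            return -ss_score(StressStrengthParams(*p), xs, ys) * p
        except (ValueError, OverflowError, FloatingPointError):
            return np.zeros(3)

    a_bar = 0.5 * (fx.estimates[0] + fy.estimates[0])
    starts = [
        np.log([a_bar, fx.estimates[1], fy.estimates[1]]),
        np.log([fx.estimates[0], fx.estimates[1], fy.estimates[1]]),
        np.log([fy.estimates[0], fx.estimates[1], fy.estimates[1]]),
    ]
    best = None
    n_iter = 0
    for z0 in starts:
        res = optimize.minimize(
            nll_z,
            z0,
            jac=grad_z,
            method="L-BFGS-B",
            options={"maxiter": 600, "ftol": 1e-14, "gtol": 1e-10},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    # Nelder-Mead polish only when the quasi-Newton stop is not yet sharp
    if np.linalg.norm(grad_z(best.x)) > 1e-7 * (xs.size + ys.size):
        polish = optimize.minimize(
            nll_z,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 4000},
        )
        n_iter += polish.nit
        if polish.fun <= best.fun:
            best = polish
    estimates = np.exp(best.x)
    if not np.isfinite(best.fun):
        raise RuntimeError("joint stress-strength optimisation failed")
    params = StressStrengthParams(*estimates)
    gnorm = np.linalg.norm(ss_score(params, xs, ys))
    converged = gnorm < 1e-4 * max(1.0, xs.size + ys.size)

    H = _observed_information(
        lambda p: ss_score(StressStrengthParams(*p), xs, ys), estimates
    )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
        converged = False
    se, ci = _wald(estimates, cov, level)

    r_hat = reliability(estimates[1], estimates[2])
    g1, g2 = reliability_gradient(estimates[1], estimates[2])
    B = np.array([0.0, g1, g2])  # dR/dalpha vanishes identically
    var_r = float(B @ cov @ B)
    se_r = math.sqrt(max(var_r, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = r_hat - z * se_r, r_hat + z * se_r
    rel = ReliabilityEstimate(
        r=r_hat,
        se=se_r,
        ci=(max(lo, 0.0), min(hi, 1.0)),
        ci_unclipped=(lo, hi),
        method="mle_delta",
    )
    return SSFitResult(
        params=params,
        param_names=("alpha", "theta1", "theta2"),
        estimates=estimates,
        se=se,
        cov=cov,
        ci=ci,
        loglik=-best.fun,
        converged=converged,
        n_iter=n_iter,
        level=level,
        n=xs.size,
        m=ys.size,
        reliability=rel,
    )


# ----------------------------------------------------------------------
# Bayesian stress-strength
# ----------------------------------------------------------------------
@dataclass
class SSBayesResult:
    """Posterior chain for (alpha, theta1, theta2) and Bayes estimates of R."""

    chain: PosteriorChain
    priors: tuple[GammaPrior, GammaPrior, GammaPrior]
    r_draws: np.ndarray
    r_estimates: dict[str, float]  # loss label -> estimate
    r_sd: float
    r_hpd: HPDInterval
    param_estimates: dict[str, dict[str, float]]
    param_hpd: dict[str, HPDInterval]
    level: float

    @property
    def reliability(self) -> ReliabilityEstimate:
        r = self.r_estimates["self"]
        return ReliabilityEstimate(
            r=r,
            se=self.r_sd,
            ci=(self.r_hpd.lower, self.r_hpd.upper),
            method="bayes",
            chain=self.chain,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in self.chain.param_names:
            rows.append(
                {
                    "parameter": name,
                    **self.param_estimates[name],
                    "hpd_lower": self.param_hpd[name].lower,
                    "hpd_upper": self.param_hpd[name].upper,
                }
            )
        rows.append(
            {
                "parameter": "R",
                **self.r_estimates,
                "hpd_lower": self.r_hpd.lower,
                "hpd_upper": self.r_hpd.upper,
            }
        )
        return pd.DataFrame(rows).set_index("parameter")


def ss_bootstrap_replicates(x, y, k: int = 100, seed=None) -> np.ndarray:
    """Bootstrap the joint MLE: resample both samples, refit, k times."""
    xs = as_sample(x)
    ys = as_sample(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(int(k)):
        xb = rng.choice(xs, size=xs.size, replace=True)
        yb = rng.choice(ys, size=ys.size, replace=True)
        try:
            out.append(ss_fit_mle(xb, yb).estimates)
        except Exception:
            continue
    if len(out) < 2:
        raise RuntimeError("bootstrap elicitation failed for the joint model")
    return np.vstack(out)


def ss_fit_bayes(
    x,
    y,
    priors=None,
    c_values=(-1.5, 1.5),
    b_values=(-1.5, 1.5),
    level: float = 0.95,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    k_boot: int = 50,
    seed=None,
) -> SSBayesResult:
    """Three-parameter MH sampler for the stress-strength posterior.

    The random walk runs on (log alpha, log theta1, log theta2) with the
    Jacobian in the target; R is evaluated draw by draw through the
    validated closed form, and SELF/LINEX/entropy estimates plus an HPD
    interval summarise the R draws.
    """
    xs = as_sample(x)
    ys = as_sample(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mle = ss_fit_mle(xs, ys, level=level)
    if priors is None:
        reps = ss_bootstrap_replicates(xs, ys, k=k_boot, seed=rng)
        priors = elicit_hyperparameters(reps)

    pa, p1, p2 = priors

    def log_target(z):
        a, t1, t2 = np.exp(z)
        if not all(map(math.isfinite, (a, t1, t2))):
            return -np.inf
        try:
            p = StressStrengthParams(a, t1, t2)
            ll = ss_loglik(p, xs, ys)
        except (ValueError, OverflowError):
            return -np.inf
        return (
            ll
            + pa.logpdf_unnorm(a)
            + p1.logpdf_unnorm(t1)
            + p2.logpdf_unnorm(t2)
            + z.sum()
        )

    with np.errstate(invalid="ignore"):
        rel_se = mle.se / mle.estimates
    scale = np.where(np.isfinite(rel_se) & (rel_se > 0), 2.0 * rel_se, 0.1)
    z0 = np.log(mle.estimates)
    states, accepted, _ = random_walk_metropolis(
        log_target, z0, scale, n_iter, rng, adapt_until=burn_in
    )
    kept = np.exp(states[burn_in:])
    chain = PosteriorChain(
        draws=kept,
        acceptance_rate=float(np.mean(accepted[burn_in:])),
        burn_in=burn_in,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        param_names=("alpha", "theta1", "theta2"),
    )
    r_draws = np.array([reliability(t1, t2) for t1, t2 in kept[:, 1:]])
    losses = default_losses(c_values, b_values)
    r_estimates = {spec.label: loss_estimate(r_draws, spec) for spec in losses}
    param_estimates = {}
    param_hpd = {}
    for name in chain.param_names:
        w = chain.draw(name)
        param_estimates[name] = {spec.label: loss_estimate(w, spec) for spec in losses}
        param_hpd[name] = hpd_interval(w, level)
    return SSBayesResult(
        chain=chain,
        priors=tuple(priors),
        r_draws=r_draws,
        r_estimates=r_estimates,
        r_sd=float(np.std(r_draws, ddof=1)),
        r_hpd=hpd_interval(r_draws, level),
        param_estimates=param_estimates,
        param_hpd=param_hpd,
        level=level,
    )
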