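"""Bayesian estimation for the power-modified Lindley model.

Independent gamma priors on (alpha, theta), hyperparameters elicited by
moment-matching against bootstrap replicates of the MLE, a random-walk
Metropolis-Hastings sampler on log-parameters, point estimation under the
squared-error (SELF), LINEX and entropy loss functions, and Chen-Shao
highest-posterior-density intervals.

The posterior kernel is built directly as likelihood x prior; the
normalising constant is intractable and never needed (only posterior
differences enter the sampler).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distribution import PML
from .estimation import as_sample, fit_mle, loglik

__all__ = [
    "GammaPrior",
    "LossSpec",
    "PosteriorChain",
    "HPDInterval",
    "elicit_hyperparameters",
    "bootstrap_mle_replicates",
    "log_posterior",
    "random_walk_metropolis",
    "mh_sample",
    "loss_estimate",
    "hpd_interval",
    "bayes_fit",
    "BayesFit",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior with shape ``w`` and rate ``q`` (mean w/q, variance w/q^2)."""

    w: float
    q: float

    def __post_init__(self):
        if not (self.w > 0 and math.isfinite(self.w)):
            raise ValueError("prior shape w must be finite and > 0")
        if not (self.q > 0 and math.isfinite(self.q)):
            raise ValueError("prior rate q must be finite and > 0")

    @property
    def mean(self) -> float:
        return self.w / self.q

    @property
    def var(self) -> float:
        return self.w / self.q**2

    def logpdf_unnorm(self, x: float) -> float:
        """Log-density up to the normalising constant."""
        if x <= 0:
            return -np.inf
        return (self.w - 1.0) * math.log(x) - self.q * x

    @classmethod
    def diffuse(cls, q: float = 1e-4) -> "GammaPrior":
        """A near-flat prior (shape 1, tiny rate): exp(1/q) with huge mean."""
        return cls(1.0, q)


@dataclass(frozen=True)
class LossSpec:
    """A loss function for Bayesian point estimation.

    kind "self": squared error, estimator = posterior mean.
    kind "linex": asymmetric exp-linear with shape c != 0,
        estimator = -(1/c) log E[exp(-c Omega)].
    kind "entropy": ratio loss with power b != 0,
        estimator = (E[Omega^-b])^(-1/b).
    """

    kind: str
    c: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.kind not in ("self", "linex", "entropy"):
            raise ValueError("loss kind must be 'self', 'linex' or 'entropy'")
        if self.kind == "linex" and (self.c is None or self.c == 0):
            raise ValueError("LINEX loss requires nonzero c")
        if self.kind == "entropy" and (self.b is None or self.b == 0):
            raise ValueError("entropy loss requires nonzero b")

    @property
    def label(self) -> str:
        if self.kind == "self":
            return "self"
        if self.kind == "linex":
            return f"linex(c={self.c:g})"
        return f"entropy(b={self.b:g})"


@dataclass
class PosteriorChain:
    """Post-burn-in MCMC draws (iterations x parameters), all positive."""

    draws: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int | None
    param_names: tuple[str, ...]

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if np.any(self.draws <= 0):
            raise ValueError("posterior draws must be strictly positive")
        if not 0.0 < self.acceptance_rate < 1.0:
            raise ValueError("acceptance rate must lie strictly in (0, 1)")

    def draw(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.param_names))

    def plot_trace(self, path: str) -> None:
        """Write a trace + histogram diagnostic figure to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k = len(self.param_names)
        fig, axes = plt.subplots(k, 2, figsize=(9, 2.4 * k), squeeze=False)
        for j, name in enumerate(self.param_names):
            axes[j][0].plot(self.draws[:, j], lw=0.4)
            axes[j][0].set_ylabel(name)
            axes[j][1].hist(self.draws[:, j], bins=40, density=True)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("HPD lower bound exceeds upper bound")

    @property
    def length(self) -> float:
        return self.upper - self.lower


# ----------------------------------------------------------------------
# prior elicitation
# ----------------------------------------------------------------------
def elicit_hyperparameters(replicates):
    """Moment-match gamma priors to a collection of MLE replicates.

    For each parameter, with replicate mean m and sample variance s^2
    (denominator k-1): shape w = m^2/s^2 and rate q = m/s^2, so the prior
    reproduces the replicate mean and variance exactly.

    A 1-D input yields one prior; a (k, p) array yields one prior per column.
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        squeeze = True
    else:
        squeeze = False
    if arr.shape[0] < 2:
        raise ValueError("elicitation requires at least 2 replicates")
    priors = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        m = float(np.mean(col))
        v = float(np.var(col, ddof=1))
        if v <= 0 or not math.isfinite(v):
            raise ValueError(
                "replicates have zero variance; supply a prior manually"
            )
        priors.append(GammaPrior(w=m**2 / v, q=m / v))
    return priors[0] if squeeze else tuple(priors)


def bootstrap_mle_replicates(data, k: int = 100, seed=None, fitter=None) -> np.ndarray:
    """Nonparametric bootstrap: resample the data, refit by MLE, k times.

    Returns a (k_ok, p) array of parameter estimates (failed refits are
    dropped; at least 2 successes are required).
    """
    x = as_sample(data)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fitter is None:
        full = fit_mle(x)
        init = full.pml
        fitter = lambda xb: fit_mle(xb, init=init).estimates
    out = []
    for _ in range(int(k)):
        xb = rng.choice(x, size=x.size, replace=True)
        try:
            out.append(np.asarray(fitter(xb), dtype=float))
        except Exception:
            continue
    if len(out) < 2:
        raise RuntimeError("bootstrap elicitation failed: fewer than 2 successful refits")
    return np.vstack(out)


# ----------------------------------------------------------------------
# posterior kernel and sampler
# ----------------------------------------------------------------------
def log_posterior(params, priors, data) -> float:
    """Unnormalised log posterior: log-likelihood plus log gamma priors.

    ``params`` is a PML instance or an (alpha, theta) pair; ``priors`` is the
    (alpha prior, theta prior) pair.  Invalid parameter values return -inf,
    a sentinel meant for use inside the sampler only.
    """
    if isinstance(params, PML):
        a, th = params.alpha, params.theta
    else:
        a, th = params
    if not (a > 0 and th > 0 and math.isfinite(a) and math.isfinite(th)):
        return -np.inf
    pa, pt = priors
    try:
        ll = loglik(PML(a, th), data)
    except (ValueError, OverflowError):
        return -np.inf
    return ll + pa.logpdf_unnorm(a) + pt.logpdf_unnorm(th)


def random_walk_metropolis(
    log_target,
    x0,
    scale,
    n_iter: int,
    rng: np.random.Generator,
    adapt_until: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian random-walk Metropolis on an unconstrained vector.

    Proposal scales are tuned toward an acceptance rate near 0.3 every 100
    iterations during the first ``adapt_until`` iterations, then frozen, so
    detailed balance holds for the retained part of the chain.

    Returns (states, accepted flags, final scales).
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    scale = np.atleast_1d(np.asarray(scale, dtype=float)).copy()
    d = x.size
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError("log target is not finite at the initial state")
    states = np.empty((n_iter, d))
    accepted = np.zeros(n_iter, dtype=bool)
    window_acc = 0
    for i in range(n_iter):
        prop = x + scale * rng.standard_normal(d)
        lp_prop = float(log_target(prop))
        if math.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted[i] = True
            window_acc += 1
        states[i] = x
        if i < adapt_until and (i + 1) % 100 == 0:
            rate = window_acc / 100.0
            scale *= math.exp(rate - 0.3)
            window_acc = 0
    return states, accepted, scale


def mh_sample(
    data,
    priors=None,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    proposal_scale=None,
    seed=None,
    init: PML | None = None,
) -> PosteriorChain:
    """Metropolis-Hastings sampler for the PML posterior.

    The random walk runs on (log alpha, log theta); the log-parameter
    Jacobian (+ log alpha + log theta) enters the target, so the acceptance
    ratio is exactly that of a positive-constrained chain.  The chain starts
    at the MLE and proposal scales undergo pilot adaptation during burn-in
    only.  With ``priors=None``, near-flat gamma priors are used.
    """
    x = as_sample(data)
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if priors is None:
        priors = (GammaPrior.diffuse(), GammaPrior.diffuse())
    if init is None:
        mle = fit_mle(x)
        if not mle.converged:
            raise RuntimeError("MLE failed to converge; cannot initialise the sampler")
        init = mle.pml
        if proposal_scale is None:
            # relative SE approximates the posterior sd on the log scale
            with np.errstate(invalid="ignore"):
                rel = mle.se / mle.estimates
            proposal_scale = np.where(np.isfinite(rel) & (rel > 0), 2.4 * rel, 0.1)
    if proposal_scale is None:
        proposal_scale = np.array([0.1, 0.1])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def log_target(z):
        a, th = np.exp(z)
        return log_posterior((a, th), priors, x) + z[0] + z[1]

    z0 = np.log([init.alpha, init.theta])
    states, accepted, _ = random_walk_metropolis(
        log_target, z0, proposal_scale, n_iter, rng, adapt_until=burn_in
    )
    kept = np.exp(states[burn_in:])
    rate = float(np.mean(accepted[burn_in:]))
    return PosteriorChain(
        draws=kept,
        acceptance_rate=rate,
        burn_in=burn_in,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        param_names=("alpha", "theta"),
    )


# ----------------------------------------------------------------------
# loss-based estimators and intervals
# ----------------------------------------------------------------------
def loss_estimate(draws, loss: LossSpec) -> float:
    """Bayes point estimate from posterior draws under a loss function.

    SELF yields the posterior mean; LINEX -(1/c) log E[exp(-c Omega)]
    (log-sum-exp, overflow-safe); entropy (E[Omega^-b])^(-1/b), which at
    b = -1 coincides with the posterior mean exactly.
    """
    w = np.asarray(draws, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty draw vector")
    if loss.kind == "self":
        return float(np.mean(w))
    if loss.kind == "linex":
        c = float(loss.c)
        return float(-(logsumexp(-c * w) - math.log(w.size)) / c)
    # entropy
    if np.any(w <= 0):
        raise ValueError("entropy loss requires strictly positive draws")
    b = float(loss.b)
    if b == -1.0:
        return float(np.mean(w))
    return float(np.mean(w ** (-b)) ** (-1.0 / b))


def hpd_interval(draws, level: float = 0.95) -> HPDInterval:
    """Shortest interval containing a ``level`` fraction of sorted draws.

    Among the windows (w_(j), w_(j+m)) with m = ceil(level * A), the
    narrowest wins; ties go to the smallest j.
    """
    w = np.sort(np.asarray(draws, dtype=float).ravel())
    A = w.size
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m = math.ceil(level * A)
    if A < 1.0 / (1.0 - level) or m >= A:
        raise ValueError(f"too few draws ({A}) for a {level:.0%} HPD interval")
    widths = w[m:] - w[: A - m]
    j = int(np.argmin(widths))  # argmin returns the first minimiser
    return HPDInterval(lower=float(w[j]), upper=float(w[j + m]), level=level)


# ----------------------------------------------------------------------
# one-call Bayesian analysis
# ----------------------------------------------------------------------
@dataclass
class BayesFit:
    """Bayesian fit report: loss-based estimates, posterior SDs and HPDs."""

    chain: PosteriorChain
    priors: tuple[GammaPrior, GammaPrior]
    estimates: dict[str, dict[str, float]]  # param -> loss label -> estimate
    posterior_sd: dict[str, float]
    hpd: dict[str, HPDInterval]
    level: float
    mle: object = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in self.chain.param_names:
            row = {"parameter": name, **self.estimates[name]}
            row["posterior_sd"] = self.posterior_sd[name]
            row["hpd_lower"] = self.hpd[name].lower
            row["hpd_upper"] = self.hpd[name].upper
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def as_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "posterior_sd": self.posterior_sd,
            "hpd": {
                k: {"lower": v.lower, "upper": v.upper, "level": v.level}
                for k, v in self.hpd.items()
            },
            "acceptance_rate": self.chain.acceptance_rate,
            "priors": [
                {"w": p.w, "q": p.q} for p in self.priors
            ],
            "level": self.level,
        }


def default_losses(c_values=(-1.5, 1.5), b_values=(-1.5, 1.5)) -> list[LossSpec]:
    losses = [LossSpec("self")]
    losses += [LossSpec("linex", c=c) for c in c_values]
    losses += [LossSpec("entropy", b=b) for b in b_values]
    return losses


def bayes_fit(
    data,
    priors=None,
    c_values=(-1.5, 1.5),
    b_values=(-1.5, 1.5),
    level: float = 0.95,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    k_boot: int = 100,
    seed=None,
) -> BayesFit:
    """Full Bayesian analysis of one sample.

    Unless priors are given, hyperparameters are elicited by moment-matching
    against ``k_boot`` bootstrap MLE replicates of the same data.  The report
    carries SELF, LINEX and entropy estimates (at every requested c and b),
    posterior standard deviations, and HPD intervals per parameter.
    """
    x = as_sample(data)
    rng = np.random.default_rng(seed)
    if priors is None:
        reps = bootstrap_mle_replicates(x, k=k_boot, seed=rng)
        priors = elicit_hyperparameters(reps)
    chain = mh_sample(
        x, priors=priors, n_iter=n_iter, burn_in=burn_in, seed=rng
    )
    losses = default_losses(c_values, b_values)
    estimates = {}
    posterior_sd = {}
    hpd = {}
    for name in chain.param_names:
        w = chain.draw(name)
        estimates[name] = {spec.label: loss_estimate(w, spec) for spec in losses}
        posterior_sd[name] = float(np.std(w, ddof=1))
        hpd[name] = hpd_interval(w, level)
    return BayesFit(
        chain=chain,
        priors=priors,
        estimates=estimates,
        posterior_sd=posterior_sd,
        hpd=hpd,
        level=level,
    )
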