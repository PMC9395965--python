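"""Parametric survival fitting for right-censored time-to-event data.

Six families are supported, with one pinned parameterization each (times in
months throughout the package):

======================  ==========================  =============================
family                  params (natural scale)      survival function
======================  ==========================  =============================
exponential             (rate,)                     S(t) = exp(-rate*t)
weibull                 (shape, scale)              S(t) = exp(-(t/scale)^shape)
lognormal               (mu, sigma)                 S(t) = 1 - Phi((ln t - mu)/sigma)
loglogistic             (shape, scale)              S(t) = 1 / (1 + (t/scale)^shape)
gompertz                (shape, rate)               S(t) = exp(-rate*(e^{shape*t}-1)/shape)
generalized_gamma       (a, c, scale)               scipy.stats.gengamma(a, c, scale)
======================  ==========================  =============================

Maximum likelihood is computed on an unconstrained ("transformed") scale —
positive parameters are optimized and sampled as logs, sign-free shape
parameters (lognormal mu, gompertz shape, generalized-gamma c) as-is.  The
parameter covariance (``vcov``) is the inverse observed information on that
transformed scale, which is also the scale on which probabilistic-sensitivity
draws are made (draws are back-transformed before use), so positive
parameters stay positive by construction.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "EstimationError",
    "DecompositionError",
    "fit_parametric",
    "rank_fits",
    "survival_at",
    "hazard_at",
    "cumulative_hazard_at",
    "loglikelihood",
    "sample_parameters",
    "save_fits",
    "load_fits",
]


class EstimationError(RuntimeError):
    """Maximum-likelihood estimation failed (no events, non-convergence)."""


class DecompositionError(RuntimeError):
    """The parameter covariance is not positive definite beyond jitter."""


_EXP_CLIP = 700.0  # exp() overflow guard


def _logsf_gompertz(t, shape, rate):
    # H(t) = rate*(exp(shape*t)-1)/shape, with the shape->0 limit rate*t
    st = np.clip(shape * t, -_EXP_CLIP, _EXP_CLIP)
    if abs(shape) < 1e-12:
        return -rate * t
    return -rate * np.expm1(st) / shape


def _family_logsf(family, params, t):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return -rate * t
    if family == "weibull":
        shape, scale = params
        return -np.power(t / scale, shape)
    if family == "lognormal":
        mu, sigma = params
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
        return stats.norm.logsf(z)
    if family == "loglogistic":
        shape, scale = params
        with np.errstate(divide="ignore"):
            return -np.log1p(np.power(t / scale, shape))
    if family == "gompertz":
        shape, rate = params
        return _logsf_gompertz(t, shape, rate)
    if family == "generalized_gamma":
        # Stacy form matching scipy.stats.gengamma(a, c, scale):
        # T = scale * G^(1/c), G ~ Gamma(a); z = (t/scale)^c
        a, c, scale = params
        with np.errstate(all="ignore"):
            z = np.power(t / scale, c)
            sf = special.gammaincc(a, z) if c > 0 else special.gammainc(a, z)
            return np.log(sf)
    raise ValueError(f"unknown family: {family!r}")


def _family_logpdf(family, params, t):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return np.log(rate) - rate * t
    if family == "weibull":
        shape, scale = params
        z = t / scale
        return np.log(shape / scale) + (shape - 1.0) * np.log(z) - np.power(z, shape)
    if family == "lognormal":
        mu, sigma = params
        logt = np.log(t)
        z = (logt - mu) / sigma
        return stats.norm.logpdf(z) - np.log(sigma) - logt
    if family == "loglogistic":
        shape, scale = params
        z = t / scale
        za = np.power(z, shape)
        return np.log(shape / scale) + (shape - 1.0) * np.log(z) - 2.0 * np.log1p(za)
    if family == "gompertz":
        shape, rate = params
        st = np.clip(shape * t, -_EXP_CLIP, _EXP_CLIP)
        return np.log(rate) + st + _logsf_gompertz(t, shape, rate)
    if family == "generalized_gamma":
        a, c, scale = params
        with np.errstate(all="ignore"):
            logz = np.log(t / scale)
            return (np.log(abs(c)) - np.log(scale) + (c * a - 1.0) * logz
                    - np.exp(c * logz) - special.gammaln(a))
    raise ValueError(f"unknown family: {family!r}")


# transform codes per parameter: 'log' (positive) or 'id' (unconstrained)
FAMILIES: dict[str, dict] = {
    "exponential": {"names": ("rate",), "transforms": ("log",)},
    "weibull": {"names": ("shape", "scale"), "transforms": ("log", "log")},
    "lognormal": {"names": ("mu", "sigma"), "transforms": ("id", "log")},
    "loglogistic": {"names": ("shape", "scale"), "transforms": ("log", "log")},
    "gompertz": {"names": ("shape", "rate"), "transforms": ("id", "log")},
    "generalized_gamma": {"names": ("a", "c", "scale"), "transforms": ("log", "id", "log")},
}


def _to_unconstrained(family, params):
    tr = FAMILIES[family]["transforms"]
    return np.array([math.log(p) if c == "log" else p for p, c in zip(params, tr)])


def _to_natural(family, theta):
    tr = FAMILIES[family]["transforms"]
    theta = np.atleast_2d(theta)
    out = np.empty_like(theta)
    for j, code in enumerate(tr):
        out[:, j] = np.exp(theta[:, j]) if code == "log" else theta[:, j]
    return out


@dataclass
class ParametricSurvival:
    """A fitted parametric survival distribution.

    ``params`` are on the natural scale; ``vcov`` is the observed-information
    covariance on the transformed (unconstrained) scale used for sampling.
    """

    family: str
    params: np.ndarray
    loglik: float
    n: int
    vcov: np.ndarray
    param_names: tuple = field(default=())

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if not self.param_names:
            self.param_names = FAMILIES[self.family]["names"]

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik

    def to_dict(self):
        return {
            "family": self.family,
            "params": list(map(float, self.params)),
            "loglik": float(self.loglik),
            "n": int(self.n),
            "vcov": [list(map(float, row)) for row in self.vcov],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["family"], np.array(d["params"]), d["loglik"], d["n"], np.array(d["vcov"]))


def loglikelihood(family: str, params, times, events) -> float:
    """Right-censored log-likelihood of ``params`` (natural scale)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    with np.errstate(all="ignore"):
        ll = np.where(events,
                      _family_logpdf(family, params, times),
                      _family_logsf(family, params, times))
    if not np.all(np.isfinite(ll)):
        return -np.inf
    return float(ll.sum())


def _initial_values(family, times, events):
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    d = max(e.sum(), 1)
    rate0 = d / t.sum()
    obs = t[e] if e.any() else t
    logs = np.log(np.maximum(obs, 1e-8))
    mu0, sd0 = float(logs.mean()), float(max(logs.std(), 0.2))
    med = float(np.median(obs))
    inits = {
        "exponential": [(rate0,)],
        "weibull": [(1.0, 1.0 / rate0), (1.5, med / math.log(2) ** (1 / 1.5)), (0.7, 1.0 / rate0)],
        "lognormal": [(mu0, sd0), (mu0, 1.0)],
        "loglogistic": [(1.0, med), (2.0, med)],
        "gompertz": [(1e-3, rate0), (0.05, rate0 * 0.8), (-0.02, rate0)],
        "generalized_gamma": [(1.0, 1.0, 1.0 / rate0), (2.0, 0.7, med), (1.0, -0.5, med), (0.8, 1.5, med)],
    }
    return [ _to_unconstrained(family, p) for p in inits[family] ]


def _numeric_hessian(f, x, rel_step=1e-4):
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_parametric(times, events, family: str) -> ParametricSurvival:
    """Maximum-likelihood fit of ``family`` to right-censored data.

    Multi-start (method-of-moments style initial values plus alternates):
    each start is refined by Nelder–Mead and polished with BFGS; the best
    attained maximum is kept.  Raises :class:`EstimationError` when fewer
    than two events are observed or no start converges to a finite optimum.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family: {family!r}; choose from {sorted(FAMILIES)}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    if events.sum() < 2:
        raise EstimationError("need at least 2 observed events to fit")

    def nll(theta):
        params = _to_natural(family, theta)[0]
        with np.errstate(all="ignore"):
            ll = loglikelihood(family, params, times, events)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    for theta0 in _initial_values(family, times, events):
        try:
            r1 = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                   options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10})
            r2 = optimize.minimize(nll, r1.x, method="BFGS",
                                   options={"gtol": 1e-8, "maxiter": 500})
            cand = r2 if r2.fun <= r1.fun else r1
        except Exception:
            continue
        if np.isfinite(cand.fun) and (best is None or cand.fun < best.fun):
            best = cand
    if best is None:
        raise EstimationError(f"{family}: no optimizer start converged")

    theta_hat = best.x
    H = _numeric_hessian(nll, theta_hat)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    vcov = 0.5 * (vcov + vcov.T)

    params = _to_natural(family, theta_hat)[0]
    return ParametricSurvival(family, params, -best.fun, len(times), vcov)


def rank_fits(fits) -> "pandas.DataFrame":
    """Rank fits on the same data ascending by AIC (BIC alongside).

    Ties are broken by fewer parameters, then family name.  Fits with
    mismatched sample size ``n`` cannot come from the same data and raise.
    """
    import pandas as pd

    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different data (n = {sorted(ns)})")
    rows = sorted(fits, key=lambda f: (f.aic, f.k, f.family))
    return pd.DataFrame(
        {
            "family": [f.family for f in rows],
            "k": [f.k for f in rows],
            "loglik": [f.loglik for f in rows],
            "aic": [f.aic for f in rows],
            "bic": [f.bic for f in rows],
        }
    )


def survival_at(fit: ParametricSurvival, t):
    """S(t) for a fitted distribution; t in months, scalar or vector, >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    with np.errstate(all="ignore"):
        s = np.exp(_family_logsf(fit.family, fit.params, np.maximum(t, 0.0)))
    s = np.where(t == 0, 1.0, s)
    return np.clip(s, 0.0, 1.0)


def cumulative_hazard_at(fit: ParametricSurvival, t):
    """H(t) = -log S(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return -_family_logsf(fit.family, fit.params, t)


def hazard_at(fit: ParametricSurvival, t):
    """h(t) = f(t)/S(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return np.exp(_family_logpdf(fit.family, fit.params, t) - _family_logsf(fit.family, fit.params, t))


def sample_parameters(fit: ParametricSurvival, n_draws: int, seed) -> np.ndarray:
    """Correlated parameter draws via Cholesky decomposition of ``vcov``.

    Draws are made on the transformed scale (theta_hat + L z, z ~ N(0, I))
    and back-transformed, so scale-type parameters remain positive.  A single
    jitter of 1e-10 on the diagonal is applied; a covariance still indefinite
    after that raises :class:`DecompositionError` rather than being silently
    repaired.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    theta0 = _to_unconstrained(fit.family, fit.params)
    k = len(theta0)
    vcov = np.asarray(fit.vcov, dtype=float)
    if vcov.shape != (k, k):
        raise ValueError("vcov shape does not match parameter count")
    if np.allclose(vcov, 0.0):
        return np.tile(fit.params, (n_draws, 1))
    try:
        L = np.linalg.cholesky(vcov + 1e-10 * np.eye(k))
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(
            f"{fit.family}: vcov not positive definite after jitter"
        ) from exc
    z = rng.standard_normal((n_draws, k))
    theta = theta0 + z @ L.T
    return _to_natural(fit.family, theta)


def save_fits(fits: dict, path) -> None:
    """Serialize a mapping of label -> ParametricSurvival to JSON text."""
    with open(path, "w") as fh:
        json.dump({k: f.to_dict() for k, f in fits.items()}, fh, indent=1)


def load_fits(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: ParametricSurvival.from_dict(d) for k, d in raw.items()}
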