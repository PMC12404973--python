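"""Parametric survival distributions for extrapolating digitized trial curves.

Eight families are supported, in the parameterizations conventional in
health-economic survival extrapolation (the same dialects used by the R
``flexsurv`` package, so that published shape/scale/meanlog/sdlog/mu/sigma/Q
tables can be transcribed directly):

========================  =====================  =========================================
family                    parameters             survival function S(t)
========================  =====================  =========================================
exponential               rate λ > 0             exp(-λt)
weibull (AFT)             shape k, scale s > 0   exp(-(t/s)^k)
weibull_ph                shape k, scale λ > 0   exp(-λ t^k)
gamma                     shape a, rate b > 0    1 - P(a, bt)
generalized_gamma         mu, sigma > 0, Q       Prentice form (see ``_gengamma_logsf``)
gompertz                  shape a, rate b > 0    exp(-(b/a)(e^{at} - 1)); a may be <= 0
lognormal                 meanlog, sdlog > 0     1 - Φ((ln t - meanlog)/sdlog)
loglogistic               shape k, scale s > 0   1 / (1 + (t/s)^k)
========================  =====================  =========================================

P is the regularized lower incomplete gamma function and Φ the standard
normal CDF.  Time is a nonnegative real in whatever unit the parameters were
fitted on (the cohort model documents its own grid convention).

A negative Gompertz shape gives an improper distribution (a surviving
fraction exp(b/a) > 0); this is accepted, as is standard when extrapolating
flattening curves, and flagged by :func:`is_improper`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "DistributionSpec",
    "FitResult",
    "UnfitDataError",
    "ConvergenceError",
    "survival_at",
    "log_density_at",
    "quantile",
    "fit_mle",
    "information_criteria",
    "select_best",
]


class Family(str, Enum):
    """Supported parametric families, in canonical (tie-breaking) order."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    WEIBULL_PH = "weibull_ph"
    GAMMA = "gamma"
    GENERALIZED_GAMMA = "generalized_gamma"
    GOMPERTZ = "gompertz"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


#: parameter names per family, in fixed order
PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.EXPONENTIAL: ("rate",),
    Family.WEIBULL: ("shape", "scale"),
    Family.WEIBULL_PH: ("shape", "scale"),
    Family.GAMMA: ("shape", "rate"),
    Family.GENERALIZED_GAMMA: ("mu", "sigma", "Q"),
    Family.GOMPERTZ: ("shape", "rate"),
    Family.LOGNORMAL: ("meanlog", "sdlog"),
    Family.LOGLOGISTIC: ("shape", "scale"),
}

#: parameters constrained strictly positive; the rest are unconstrained reals
_POSITIVE: dict[Family, tuple[str, ...]] = {
    Family.EXPONENTIAL: ("rate",),
    Family.WEIBULL: ("shape", "scale"),
    Family.WEIBULL_PH: ("shape", "scale"),
    Family.GAMMA: ("shape", "rate"),
    Family.GENERALIZED_GAMMA: ("sigma",),
    Family.GOMPERTZ: ("rate",),
    Family.LOGNORMAL: ("sdlog",),
    Family.LOGLOGISTIC: ("shape", "scale"),
}


class UnfitDataError(ValueError):
    """Raised when the data cannot identify a fit (e.g. no observed events)."""


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails to converge."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric survival family plus its parameter vector."""

    family: Family
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        family = Family(self.family)
        object.__setattr__(self, "family", family)
        names = PARAM_NAMES[family]
        got = tuple(self.params)
        if set(got) != set(names):
            raise ValueError(
                f"{family.value} expects parameters {names}, got {got}"
            )
        clean = {k: float(self.params[k]) for k in names}
        for k, v in clean.items():
            if not math.isfinite(v):
                raise ValueError(f"{family.value} parameter {k!r} is not finite")
            if k in _POSITIVE[family] and v <= 0:
                raise ValueError(
                    f"{family.value} parameter {k!r} must be strictly positive, got {v}"
                )
        object.__setattr__(self, "params", clean)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(self.params[k] for k in PARAM_NAMES[self.family])

    def __repr__(self) -> str:  # keep scenario logs compact
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"DistributionSpec({self.family.value}: {inner})"


def is_improper(spec: DistributionSpec) -> bool:
    """True when S(t) does not tend to zero (negative-shape Gompertz)."""
    return spec.family is Family.GOMPERTZ and spec.params["shape"] < 0


def _gengamma_logsf(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    """log S(t) for the Prentice generalized gamma.

    With w = (ln t - mu)/sigma and a = Q^-2, the CDF is P(a, a e^{Qw}) for
    Q > 0 and 1 - P(a, a e^{Qw}) for Q < 0; Q -> 0 recovers the lognormal.
    """
    if abs(q) < 1e-8:
        z = (np.log(t) - mu) / sigma
        return stats.norm.logsf(z)
    a = q**-2.0
    w = (np.log(t) - mu) / sigma
    u = a * np.exp(q * w)
    if q > 0:
        return np.log(special.gammaincc(a, u))
    return np.log(special.gammainc(a, u))


def survival_at(spec: DistributionSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate S(t).  ``t`` may be a scalar or array; must be >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.ones_like(t_arr)
    pos = t_arr > 0
    tp = t_arr[pos]
    p = spec.params
    fam = spec.family
    if fam is Family.EXPONENTIAL:
        out[pos] = np.exp(-p["rate"] * tp)
    elif fam is Family.WEIBULL:
        out[pos] = np.exp(-((tp / p["scale"]) ** p["shape"]))
    elif fam is Family.WEIBULL_PH:
        out[pos] = np.exp(-p["scale"] * tp ** p["shape"])
    elif fam is Family.GAMMA:
        out[pos] = special.gammaincc(p["shape"], p["rate"] * tp)
    elif fam is Family.GENERALIZED_GAMMA:
        out[pos] = np.exp(_gengamma_logsf(tp, p["mu"], p["sigma"], p["Q"]))
    elif fam is Family.GOMPERTZ:
        a, b = p["shape"], p["rate"]
        if abs(a) < 1e-12:
            out[pos] = np.exp(-b * tp)
        else:
            out[pos] = np.exp(-(b / a) * np.expm1(a * tp))
    elif fam is Family.LOGNORMAL:
        out[pos] = special.ndtr(-(np.log(tp) - p["meanlog"]) / p["sdlog"])
    elif fam is Family.LOGLOGISTIC:
        out[pos] = 1.0 / (1.0 + (tp / p["scale"]) ** p["shape"])
    else:  # pragma: no cover
        raise AssertionError(fam)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def log_density_at(spec: DistributionSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Natural log of the density f(t) = -dS/dt, for t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("log_density_at requires t > 0")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    p = spec.params
    fam = spec.family
    with np.errstate(over="ignore"):
        if fam is Family.EXPONENTIAL:
            out = np.log(p["rate"]) - p["rate"] * t_arr
        elif fam is Family.WEIBULL:
            k, s = p["shape"], p["scale"]
            z = t_arr / s
            out = np.log(k / s) + (k - 1) * np.log(z) - z**k
        elif fam is Family.WEIBULL_PH:
            k, lam = p["shape"], p["scale"]
            out = np.log(lam * k) + (k - 1) * np.log(t_arr) - lam * t_arr**k
        elif fam is Family.GAMMA:
            a, b = p["shape"], p["rate"]
            out = a * np.log(b) + (a - 1) * np.log(t_arr) - b * t_arr - special.gammaln(a)
        elif fam is Family.GENERALIZED_GAMMA:
            mu, sigma, q = p["mu"], p["sigma"], p["Q"]
            if abs(q) < 1e-8:
                z = (np.log(t_arr) - mu) / sigma
                out = -np.log(t_arr * sigma) + stats.norm.logpdf(z)
            else:
                a = q**-2.0
                w = (np.log(t_arr) - mu) / sigma
                out = (
                    np.log(abs(q))
                    + a * np.log(a)
                    - np.log(sigma * t_arr)
                    - special.gammaln(a)
                    + a * (q * w - np.exp(q * w))
                )
        elif fam is Family.GOMPERTZ:
            a, b = p["shape"], p["rate"]
            if abs(a) < 1e-12:
                out = np.log(b) - b * t_arr
            else:
                out = np.log(b) + a * t_arr - (b / a) * np.expm1(a * t_arr)
        elif fam is Family.LOGNORMAL:
            m, sd = p["meanlog"], p["sdlog"]
            z = (np.log(t_arr) - m) / sd
            out = -np.log(t_arr * sd) + stats.norm.logpdf(z)
        elif fam is Family.LOGLOGISTIC:
            k, s = p["shape"], p["scale"]
            z = t_arr / s
            out = np.log(k / s) + (k - 1) * np.log(z) - 2 * np.log1p(z**k)
        else:  # pragma: no cover
            raise AssertionError(fam)
    return float(out[0]) if scalar else out


def quantile(spec: DistributionSpec, p_surv: float | np.ndarray) -> float | np.ndarray:
    """Inverse survival function: the time t with S(t) = p_surv.

    Returns ``inf`` where an improper (negative-shape Gompertz) curve never
    reaches ``p_surv``.
    """
    s = np.asarray(p_surv, dtype=float)
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("quantile requires survival probabilities in (0, 1]")
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    p = spec.params
    fam = spec.family
    if fam is Family.EXPONENTIAL:
        out = -np.log(s) / p["rate"]
    elif fam is Family.WEIBULL:
        out = p["scale"] * (-np.log(s)) ** (1.0 / p["shape"])
    elif fam is Family.WEIBULL_PH:
        out = (-np.log(s) / p["scale"]) ** (1.0 / p["shape"])
    elif fam is Family.GAMMA:
        out = stats.gamma.isf(s, p["shape"], scale=1.0 / p["rate"])
    elif fam is Family.GENERALIZED_GAMMA:
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        if abs(q) < 1e-8:
            out = np.exp(mu + sigma * special.ndtri(1.0 - s))
        else:
            a = q**-2.0
            u = special.gammainccinv(a, s) if q > 0 else special.gammaincinv(a, s)
            out = np.exp(mu + sigma * np.log(u / a) / q)
    elif fam is Family.GOMPERTZ:
        a, b = p["shape"], p["rate"]
        if abs(a) < 1e-12:
            out = -np.log(s) / b
        else:
            arg = 1.0 - (a / b) * np.log(s)
            out = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)
    elif fam is Family.LOGNORMAL:
        out = np.exp(p["meanlog"] + p["sdlog"] * special.ndtri(1.0 - s))
    elif fam is Family.LOGLOGISTIC:
        out = p["scale"] * ((1.0 - s) / s) ** (1.0 / p["shape"])
    else:  # pragma: no cover
        raise AssertionError(fam)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class FitResult:
    """Converged maximum-likelihood fit with its information criteria."""

    spec: DistributionSpec
    loglik: float
    k: int
    n: int
    aic: float = field(default=math.nan)
    bic: float = field(default=math.nan)

    def __post_init__(self) -> None:
        aic, bic = information_criteria(self.loglik, self.k, self.n)
        object.__setattr__(self, "aic", aic)
        object.__setattr__(self, "bic", bic)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 loglik and BIC = k ln(n) - 2 loglik."""
    if n < 1:
        raise ValueError(f"information criteria need n >= 1, got {n}")
    if k < 0:
        raise ValueError(f"parameter count must be >= 0, got {k}")
    return 2.0 * k - 2.0 * loglik, k * math.log(n) - 2.0 * loglik


def _start_values(times: np.ndarray, events: np.ndarray, family: Family) -> dict[str, float]:
    """Moment-style starting values; crude but inside the basin for clean data."""
    ev = times[events == 1]
    rate0 = max(events.sum() / times.sum(), 1e-8)
    logs = np.log(ev)
    mlog, sdlog = float(logs.mean()), float(max(logs.std(), 0.1))
    med = float(np.median(ev))
    if family is Family.EXPONENTIAL:
        return {"rate": rate0}
    if family is Family.WEIBULL:
        return {"shape": 1.2, "scale": 1.0 / rate0}
    if family is Family.WEIBULL_PH:
        return {"shape": 1.2, "scale": rate0}
    if family is Family.GAMMA:
        return {"shape": 1.2, "rate": rate0}
    if family is Family.GENERALIZED_GAMMA:
        return {"mu": mlog, "sigma": sdlog, "Q": 1.0}
    if family is Family.GOMPERTZ:
        return {"shape": 1e-3, "rate": rate0}
    if family is Family.LOGNORMAL:
        return {"meanlog": mlog, "sdlog": sdlog}
    if family is Family.LOGLOGISTIC:
        return {"shape": 1.5, "scale": med}
    raise AssertionError(family)  # pragma: no cover


def _pack(params: dict[str, float], family: Family) -> np.ndarray:
    names = PARAM_NAMES[family]
    pos = _POSITIVE[family]
    return np.array(
        [math.log(params[k]) if k in pos else params[k] for k in names], dtype=float
    )


def _unpack(theta: np.ndarray, family: Family) -> dict[str, float]:
    names = PARAM_NAMES[family]
    pos = _POSITIVE[family]
    return {
        k: float(np.exp(v)) if k in pos else float(v)
        for k, v in zip(names, theta)
    }


def fit_mle(data: "IpdSample", family: Family | str) -> FitResult:
    """Fit one family to right-censored data by maximum likelihood.

    The log-likelihood is sum over events of log f(t_i) plus sum over
    censored observations of log S(t_i), maximized by L-BFGS-B on
    log-transformed positive parameters with up to three restarts.
    """
    family = Family(family)
    times = np.asarray(data.times, dtype=float)
    events = np.asarray(data.events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise UnfitDataError("all observation times must be strictly positive")
    n_events = int(events.sum())
    if n_events < 2:
        raise UnfitDataError(
            f"need at least 2 observed events to fit, got {n_events}"
        )
    is_event = events == 1

    def nll(theta: np.ndarray) -> float:
        params = _unpack(theta, family)
        try:
            spec = DistributionSpec(family, params)
        except ValueError:
            return np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_ev = log_density_at(spec, times[is_event])
            ll = float(np.sum(ll_ev))
            if np.any(~is_event):
                s_cens = survival_at(spec, times[~is_event])
                ll += float(np.sum(np.log(np.maximum(s_cens, 1e-300))))
        return np.inf if not np.isfinite(ll) else -ll

    start = _start_values(times, events, family)
    theta0 = _pack(start, family)
    rng = np.random.default_rng(0)
    best = None
    last_status = ""
    for attempt in range(4):
        x0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, theta0.shape)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", options={"maxiter": 500, "gtol": 1e-8}
        )
        last_status = res.message
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            f"MLE for {family.value} failed to converge: {last_status}"
        )
    if not best.success:
        warnings.warn(
            f"MLE for {family.value}: optimizer stopped without formal "
            f"convergence ({best.message}); using best point found",
            RuntimeWarning,
            stacklevel=2,
        )
    spec = DistributionSpec(family, _unpack(best.x, family))
    k = len(PARAM_NAMES[family])
    return FitResult(spec=spec, loglik=-float(best.fun), k=k, n=len(times))


def select_best(fits: Sequence[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the fit minimizing AIC or BIC.

    Ties are broken by fewer parameters, then by family declaration order.
    """
    if not fits:
        raise ValueError("select_best needs at least one fit")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    order = list(Family)

    def key(f: FitResult) -> tuple[float, int, int]:
        return (getattr(f, criterion), f.k, order.index(f.spec.family))

    return min(fits, key=key)
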