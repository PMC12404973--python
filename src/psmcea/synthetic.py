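"""Synthetic censored survival data and emulated digitized Kaplan-Meier curves.

The published survival parameters in this package were fitted, by the
original analysts, to pseudo individual-patient data (IPD) reconstructed
from digitized Kaplan-Meier figures whose coordinates were never published.
This module closes that gap for testing purposes: it generates censored IPD
with known ground truth, computes the product-limit estimator, emulates the
manual read-off noise of a graph digitizer, and reconstructs pseudo-IPD from
a digitized curve (a simplified Guyot-style allocation that uses no
number-at-risk table, since none is available in the source figures).
Together these let the whole fitting pathway be exercised end to end:

    simulate_ipd -> km_estimate -> digitize_curve -> pseudo_ipd -> fit_mle
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import integrate, optimize

from .survival import DistributionSpec, is_improper, quantile, survival_at

__all__ = [
    "IpdSample",
    "KmCurve",
    "DegenerateCurveError",
    "NoInformationError",
    "simulate_ipd",
    "km_estimate",
    "digitize_curve",
    "pseudo_ipd",
]


class DegenerateCurveError(ValueError):
    """Raised when a KM curve cannot be formed (no observed events)."""


class NoInformationError(ValueError):
    """Raised when a curve carries no event information (never drops below 1)."""


@dataclass(frozen=True)
class IpdSample:
    """Right-censored individual-patient times with event indicators."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if np.any(t <= 0):
            raise ValueError("all times must be strictly positive")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "event": self.events}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IpdSample":
        df = pd.read_csv(path)
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"IPD file {path} lacks required columns {sorted(missing)}")
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass(frozen=True)
class KmCurve:
    """A survival step function: right-continuous, starting at (0, 1)."""

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or len(t) == 0:
            raise ValueError("times and surv must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be nonnegative")
        if s[0] > 1 + 1e-12 or np.any(s < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", np.clip(s, 0.0, 1.0))

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function lookup (right-continuous); 1 before the first point."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.surv}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "KmCurve":
        df = pd.read_csv(path)
        missing = {"time", "survival"} - set(df.columns)
        if missing:
            raise ValueError(f"curve file {path} lacks required columns {sorted(missing)}")
        return cls(df["time"].to_numpy(), df["survival"].to_numpy())


def _censoring_rate_for(
    spec: DistributionSpec, censor_rate: float, admin_cutoff: float
) -> float:
    """Exponential-censoring hazard giving the target pre-cutoff censored fraction.

    Solves P(C < T, C < cutoff) = censor_rate with C ~ Exp(theta), i.e.
    integral over (0, cutoff) of theta e^{-theta c} S(c) dc = censor_rate.
    """
    upper = admin_cutoff if np.isfinite(admin_cutoff) else float(quantile(spec, 1e-9))

    def frac(theta: float) -> float:
        val, _ = integrate.quad(
            lambda c: theta * np.exp(-theta * c) * survival_at(spec, c),
            0.0,
            upper,
            limit=200,
        )
        return val

    lo, hi = 1e-10, 1e-10
    while frac(hi) < censor_rate:
        hi *= 10.0
        if hi > 1e8:  # pragma: no cover - unreachable for censor_rate < 1
            raise RuntimeError("could not bracket censoring hazard")
    return float(optimize.brentq(lambda th: frac(th) - censor_rate, lo, hi, xtol=1e-12))


def simulate_ipd(
    spec: DistributionSpec,
    n: int,
    censor_rate: float = 0.0,
    admin_cutoff: float = np.inf,
    seed: int | None = None,
) -> IpdSample:
    """Draw censored IPD from a parametric truth.

    Event times come from ``spec`` by inverse-CDF sampling.  Independent
    exponential censoring is calibrated so the expected fraction censored
    before ``admin_cutoff`` is approximately ``censor_rate``; everything still
    at risk at ``admin_cutoff`` is administratively censored there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    if admin_cutoff <= 0:
        raise ValueError("admin_cutoff must be positive")
    if is_improper(spec) and not np.isfinite(admin_cutoff):
        raise ValueError(
            "improper (negative-shape Gompertz) truth requires a finite admin_cutoff"
        )
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.asarray(quantile(spec, 1.0 - u * (1 - 1e-12)))
    if censor_rate > 0:
        theta = _censoring_rate_for(spec, censor_rate, admin_cutoff)
        c = rng.exponential(1.0 / theta, size=n)
    else:
        c = np.full(n, np.inf)
    cut = np.minimum(c, admin_cutoff)
    observed = np.minimum(t_event, cut)
    events = (t_event <= cut).astype(int)
    observed = np.maximum(observed, 1e-12)
    return IpdSample(times=observed, events=events)


def km_estimate(data: IpdSample) -> KmCurve:
    """Product-limit (Kaplan-Meier) estimate; drops only at event times."""
    if data.n_events < 1:
        raise DegenerateCurveError("Kaplan-Meier curve needs at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    event_times = np.unique(data.times[data.events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    times = np.concatenate([[0.0], event_times])
    surv = np.concatenate([[1.0], surv])
    return KmCurve(times=times, surv=surv)


def digitize_curve(
    curve: KmCurve,
    grid_step: float,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> KmCurve:
    """Emulate manual digitization: sample the step function on a regular grid
    and add truncated Gaussian read-off noise.

    Noise is clipped to [0, 1] and monotonized by a running minimum, mirroring
    how a digitizer operator never lets the traced curve rise.  The anchor
    point at t = 0 is kept exact.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    t_max = float(curve.times[-1])
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    vals = curve.evaluate(grid).astype(float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = vals + rng.normal(0.0, jitter_sd, size=vals.shape)
        noisy[0] = vals[0]
        vals = np.minimum.accumulate(np.clip(noisy, 0.0, 1.0))
    return KmCurve(times=grid, surv=vals)


def pseudo_ipd(curve: KmCurve, n_assumed: int) -> IpdSample:
    """Reconstruct pseudo-IPD whose empirical KM matches a digitized curve.

    Events are allocated by cumulative rounding so that the empirical survival
    at each grid point matches the input within 1/(2 n).  Mass remaining after
    the last grid point becomes observations censored there.  Without a
    number-at-risk table no within-follow-up censoring can be inferred, so the
    reconstruction treats the curve as fully observed up to its last point.
    """
    if n_assumed < 2:
        raise ValueError("n_assumed must be >= 2")
    if np.min(curve.surv) >= 1.0 - 1e-12:
        raise NoInformationError("curve never drops below 1; no events to place")
    cum_events = np.round(n_assumed * (1.0 - curve.surv)).astype(int)
    cum_events = np.maximum.accumulate(cum_events)
    d = np.diff(np.concatenate([[0], cum_events]))
    times: list[float] = []
    events: list[int] = []
    for t, cnt in zip(curve.times, d):
        if cnt > 0:
            tt = max(float(t), 1e-9)  # an event exactly at t=0 is not representable
            times.extend([tt] * int(cnt))
            events.extend([1] * int(cnt))
    n_cens = n_assumed - int(cum_events[-1])
    if n_cens > 0:
        times.extend([float(curve.times[-1])] * n_cens)
        events.extend([0] * n_cens)
    return IpdSample(times=np.array(times), events=np.array(events))
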