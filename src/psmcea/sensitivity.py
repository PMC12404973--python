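"""One-way (tornado) and probabilistic sensitivity analysis.

The parameter registry maps each uncertain input to a location inside the
strategy scenarios or settings, its base value, its published low/high range
and its sampling family.  Conventions follow standard health-economic
practice for this kind of model:

* one-way analysis re-runs the full model at each parameter's low and high
  values with everything else at base, and ranks parameters by the absolute
  spread they induce in the chosen metric;
* probabilistic analysis draws gamma-distributed costs and beta-distributed
  probabilities/utilities with mean equal to the base value and standard
  deviation (high - low)/3.92, reading the published range as a 95%
  interval, then records the incremental cost/effect pair per iteration;
* survival-curve parameters carry no published ranges and are held fixed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, is_dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import ConfigurationError, ModelSettings, StrategyScenario, run_totals

__all__ = [
    "Param",
    "ParamRegistry",
    "PsaIterationSet",
    "owsa",
    "draw_parameters",
    "run_psa",
    "ceac",
]

_TARGETS = ("both", "treat", "comp", "settings")
_DISTS = ("gamma", "beta", "fixed")


@dataclass(frozen=True)
class Param:
    """One uncertain parameter: where it lives, its base and its range."""

    name: str
    path: str  # dotted path inside the target object, e.g. "costs.drug.toripalimab"
    base: float
    low: float
    high: float
    dist: str = "fixed"
    target: str = "both"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: range [{self.low}, {self.high}] must bracket "
                f"base {self.base}"
            )
        if self.dist not in _DISTS:
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.target not in _TARGETS:
            raise ValueError(f"{self.name}: unknown target {self.target!r}")
        if self.dist == "beta" and not 0.0 <= self.base <= 1.0:
            raise ValueError(f"{self.name}: beta base must be in [0, 1]")

    @property
    def sd(self) -> float:
        """Range read as a 95% interval: sd = (high - low) / (2 x 1.96)."""
        return (self.high - self.low) / 3.92


class ParamRegistry:
    """An ordered collection of :class:`Param` with unique names."""

    def __init__(self, params: Iterable[Param]):
        self.params = list(params)
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    def __iter__(self):
        return iter(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def __getitem__(self, name: str) -> Param:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def varied(self) -> list[Param]:
        return [p for p in self.params if p.dist != "fixed"]


def _set_path(obj, path: str, value: float, param_name: str) -> None:
    parts = path.split(".")
    here = obj
    for seg in parts[:-1]:
        if isinstance(here, dict):
            if seg not in here:
                raise ConfigurationError(
                    f"parameter {param_name!r}: path segment {seg!r} not found"
                )
            here = here[seg]
        elif is_dataclass(here) and hasattr(here, seg):
            here = getattr(here, seg)
        else:
            raise ConfigurationError(
                f"parameter {param_name!r}: cannot resolve segment {seg!r} in path {path!r}"
            )
    leaf = parts[-1]
    if isinstance(here, dict):
        if leaf not in here:
            raise ConfigurationError(
                f"parameter {param_name!r}: key {leaf!r} not found at end of {path!r}"
            )
        here[leaf] = value
    elif is_dataclass(here) and hasattr(here, leaf):
        # frozen dataclasses: bypass immutability on private deep copies
        object.__setattr__(here, leaf, value)
    else:
        raise ConfigurationError(
            f"parameter {param_name!r}: cannot set {leaf!r} at end of {path!r}"
        )


def _apply(
    values: dict[str, float],
    registry: ParamRegistry,
    treat: StrategyScenario,
    comp: StrategyScenario,
    settings: ModelSettings,
) -> tuple[StrategyScenario, StrategyScenario, ModelSettings]:
    treat = copy.deepcopy(treat)
    comp = copy.deepcopy(comp)
    settings = copy.deepcopy(settings)
    for name, value in values.items():
        p = registry[name]
        if p.target in ("both", "treat"):
            _set_path(treat, p.path, value, p.name)
        if p.target in ("both", "comp"):
            _set_path(comp, p.path, value, p.name)
        if p.target == "settings":
            _set_path(settings, p.path, value, p.name)
    return treat, comp, settings


def _evaluate(
    treat: StrategyScenario, comp: StrategyScenario, settings: ModelSettings
) -> tuple[float, float]:
    """(delta cost, delta effect) of treatment vs comparator."""
    cost_t, qaly_t = run_totals(treat, settings)
    cost_c, qaly_c = run_totals(comp, settings)
    return cost_t - cost_c, qaly_t - qaly_c


def owsa(
    treat: StrategyScenario,
    comp: StrategyScenario,
    settings: ModelSettings,
    registry: ParamRegistry,
    metric: str = "icer",
) -> pd.DataFrame:
    """One-way sensitivity analysis over every non-fixed registry parameter.

    Returns a tornado table with one row per parameter, sorted by descending
    absolute spread of the chosen metric (``icer`` or ``inmb``).  ICER is the
    published default; INMB is the robust alternative when the effect
    difference approaches zero.
    """
    if metric not in ("icer", "inmb"):
        raise ValueError(f"metric must be 'icer' or 'inmb', got {metric!r}")

    def run_at(values: dict[str, float]) -> float:
        t, c, s = _apply(values, registry, treat, comp, settings)
        d_cost, d_eff = _evaluate(t, c, s)
        if metric == "icer":
            return d_cost / d_eff if d_eff != 0 else np.nan
        return d_eff * s.wtp - d_cost

    rows = []
    base_val = run_at({})
    for p in registry.varied():
        lo = run_at({p.name: p.low})
        hi = run_at({p.name: p.high})
        rows.append(
            {
                "parameter": p.name,
                "low_input": p.low,
                "high_input": p.high,
                f"{metric}_low": lo,
                f"{metric}_high": hi,
                f"{metric}_base": base_val,
                "spread": abs(hi - lo),
            }
        )
    out = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    return out


def draw_parameters(
    registry: ParamRegistry, seed: int | np.random.Generator | None = None
) -> dict[str, float]:
    """One Monte-Carlo draw of every non-fixed parameter.

    Gamma for costs (mean = base, sd = range/3.92, via shape/scale moment
    matching); beta for probabilities and utilities by method of moments with
    the same mean and sd.  Infeasible beta moments (sd too large for the mean)
    fall back to a shrunk sd with a warning.  Fixed parameters are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, float] = {}
    for p in registry.varied():
        sd = p.sd
        if sd == 0 or p.base == 0:
            out[p.name] = p.base
            continue
        if p.dist == "gamma":
            shape = (p.base / sd) ** 2
            scale = sd**2 / p.base
            out[p.name] = float(rng.gamma(shape, scale))
        else:  # beta
            m = p.base
            if m >= 1.0:
                out[p.name] = m
                continue
            v_max = m * (1.0 - m)
            v = sd**2
            if v >= v_max:
                warnings.warn(
                    f"{p.name}: beta moments infeasible (sd {sd:.4g} too large "
                    f"for mean {m:.4g}); shrinking sd",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = 0.81 * v_max
            nu = v_max / v - 1.0
            out[p.name] = float(rng.beta(m * nu, (1.0 - m) * nu))
    return out


@dataclass(frozen=True)
class PsaIterationSet:
    """Paired incremental (cost, effect) draws from a probabilistic analysis."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    wtp: float
    seed: int | None = None

    def __post_init__(self) -> None:
        dc = np.asarray(self.delta_cost, dtype=float)
        de = np.asarray(self.delta_effect, dtype=float)
        if dc.shape != de.shape or dc.ndim != 1 or len(dc) == 0:
            raise ValueError("delta_cost and delta_effect must be equal-length 1-d arrays")
        if not (np.all(np.isfinite(dc)) and np.all(np.isfinite(de))):
            raise ValueError("PSA iterations must be finite")
        object.__setattr__(self, "delta_cost", dc)
        object.__setattr__(self, "delta_effect", de)

    @property
    def n_iter(self) -> int:
        return len(self.delta_cost)

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of iterations with strictly positive net monetary benefit."""
        lam = self.wtp if wtp is None else wtp
        return float(np.mean(self.delta_effect * lam - self.delta_cost > 0))


def run_psa(
    treat: StrategyScenario,
    comp: StrategyScenario,
    settings: ModelSettings,
    registry: ParamRegistry,
    n_iter: int,
    seed: int | None = None,
    wtp: float | None = None,
) -> PsaIterationSet:
    """Joint Monte-Carlo resampling of all non-fixed parameters.

    Each iteration draws every parameter, rebuilds both arms, runs the full
    model and records the incremental (cost, effect) pair.  Deterministic for
    a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_iter)
    d_eff = np.empty(n_iter)
    for i in range(n_iter):
        values = draw_parameters(registry, rng)
        try:
            t, c, s = _apply(values, registry, treat, comp, settings)
            d_cost[i], d_eff[i] = _evaluate(t, c, s)
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
    return PsaIterationSet(
        delta_cost=d_cost,
        delta_effect=d_eff,
        wtp=wtp if wtp is not None else settings.wtp,
        seed=seed,
    )


def ceac(iters: PsaIterationSet, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a threshold grid.

    For each threshold, the fraction of iterations with positive net monetary
    benefit; a net benefit of exactly zero counts as not cost-effective.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    probs = [iters.prob_cost_effective(lam) for lam in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})
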