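"""Three-state partitioned-survival cohort model.

The cohort starts in the progression-free (PFS) state and is partitioned at
every cycle boundary directly from the overall-survival and progression-free
survival curves:

    pfs(t)   = min(S_PFS(t), S_OS(t))        (clamped: PFS cannot exceed OS)
    death(t) = 1 - S_OS(t)
    pd(t)    = S_OS(t) - pfs(t)

Costs and quality-adjusted life-years accrue per 21-day cycle on
start-of-cycle occupancy and are discounted continuously at an annual rate.

Time-grid convention
--------------------
``ModelSettings.curve_time_per_cycle`` controls how much of the survival
curves' time axis one model cycle covers.  The packaged scenario parameters
were calibrated by the original analysis on the model's own cycle grid, so
their natural reading is one curve-time unit per cycle (the default, 1.0).
Curves fitted on a calendar-month axis should use
``cycle_length_days / 30.4375`` instead.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survival import DistributionSpec, survival_at

__all__ = [
    "ModelSettings",
    "AdminCosts",
    "CostInputs",
    "UtilityInputs",
    "SubsequentTreatment",
    "Schedule",
    "StrategyScenario",
    "CohortTrace",
    "ConfigurationError",
    "state_occupancy",
    "expected_ae_burden",
    "cycle_cost",
    "run_model",
    "run_totals",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

#: cost categories reported in a trace, in output order
COST_CATEGORIES = (
    "drug",
    "administration",
    "laboratory",
    "imaging",
    "progressed_care",
    "end_of_life",
    "adverse_events",
)


class ConfigurationError(ValueError):
    """Raised when scenario components are mutually inconsistent."""


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings shared by both strategies."""

    discount_rate: float
    wtp: float
    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    half_cycle_correction: bool = False
    curve_time_per_cycle: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must be in [0, 1)")
        if self.wtp <= 0:
            raise ValueError("willingness-to-pay must be positive")
        if self.curve_time_per_cycle <= 0:
            raise ValueError("curve_time_per_cycle must be positive")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        n = int(math.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days))
        if n < 1:
            raise ValueError("horizon shorter than one cycle")
        return n


@dataclass(frozen=True)
class AdminCosts:
    """Drug-administration unit costs.

    Two fee structures occur in practice: a per-infusion-event structure
    (infusion fee plus prophylactic medication per IV day, plus a per-cycle
    prophylaxis charge) and a per-hour structure (first hour vs each
    additional hour).  ``mode`` selects which unit costs apply.
    """

    mode: str  # "per_infusion" | "per_hour"
    prophylaxis_per_infusion: float = 0.0
    infusion_fee: float = 0.0
    prophylaxis_per_cycle: float = 0.0
    first_hour: float = 0.0
    additional_hour: float = 0.0
    day1_hours: int = 3  # multi-agent day-1 infusion duration, hours

    def __post_init__(self) -> None:
        if self.mode not in ("per_infusion", "per_hour"):
            raise ValueError(f"unknown administration mode {self.mode!r}")
        for name in (
            "prophylaxis_per_infusion",
            "infusion_fee",
            "prophylaxis_per_cycle",
            "first_hour",
            "additional_hour",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"administration cost {name} must be >= 0")

    def cycle_admin_cost(self, infusion_days: int) -> float:
        """Administration cost of one treatment cycle with the given IV days."""
        if infusion_days <= 0:
            return 0.0
        if self.mode == "per_infusion":
            return (
                infusion_days * (self.prophylaxis_per_infusion + self.infusion_fee)
                + self.prophylaxis_per_cycle
            )
        day1 = self.first_hour + (self.day1_hours - 1) * self.additional_hour
        return day1 + (infusion_days - 1) * self.first_hour


@dataclass(frozen=True)
class CostInputs:
    """Per-cycle and one-time direct medical costs (USD)."""

    drug: dict[str, float]  # per-cycle cost by agent
    administration: AdminCosts
    laboratory_per_cycle: float
    imaging_per_scan: float
    best_supportive_care_per_cycle: float
    end_of_life: float
    ae_unit_costs: dict[str, float]

    def __post_init__(self) -> None:
        for group in (self.drug, self.ae_unit_costs):
            for k, v in group.items():
                if v < 0:
                    raise ValueError(f"cost {k!r} must be >= 0, got {v}")
        for name in (
            "laboratory_per_cycle",
            "imaging_per_scan",
            "best_supportive_care_per_cycle",
            "end_of_life",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name} must be >= 0")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities plus this arm's adverse-event profile."""

    u_pfs: float
    u_pd: float
    ae_disutilities: dict[str, float]
    ae_incidences: dict[str, float]

    def __post_init__(self) -> None:
        for name, u in (("u_pfs", self.u_pfs), ("u_pd", self.u_pd)):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {u}")
        for k, v in self.ae_disutilities.items():
            if v < 0:
                raise ValueError(f"disutility {k!r} must be >= 0")
        for k, v in self.ae_incidences.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AE incidence {k!r} must be in [0, 1]")


@dataclass(frozen=True)
class SubsequentTreatment:
    """Post-progression therapy mix for one arm.

    ``shares`` are the published proportions by regimen class among treated
    patients; they are renormalized to sum to one (the published shares
    describe overlapping therapy lines and do not sum to 100%).
    """

    proportion: float
    shares: dict[str, float]  # keys: cytotoxic, tki, pd1

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("subsequent-treatment proportion must be in [0, 1]")
        expected = {"cytotoxic", "tki", "pd1"}
        if set(self.shares) != expected:
            raise ConfigurationError(
                f"subsequent-treatment shares need keys {sorted(expected)}"
            )
        if any(v < 0 for v in self.shares.values()) or sum(self.shares.values()) <= 0:
            raise ValueError("shares must be nonnegative with positive sum")

    def blended_cycle_cost(self, costs: CostInputs) -> float:
        """Per-cycle progressed-disease cost: treated fraction gets the
        renormalized regimen mix, the rest best supportive care."""
        total = sum(self.shares.values())
        w = {k: v / total for k, v in self.shares.items()}
        regimen = {
            "cytotoxic": costs.drug["topotecan"] + costs.drug["cisplatin"],
            "tki": costs.drug["anlotinib"],
            "pd1": costs.drug["toripalimab"],
        }
        mix = sum(w[k] * regimen[k] for k in w)
        return (
            self.proportion * mix
            + (1.0 - self.proportion) * costs.best_supportive_care_per_cycle
        )


@dataclass(frozen=True)
class Schedule:
    """Treatment and surveillance schedule, in cycles."""

    induction_cycles: int = 4
    induction_infusion_days: int = 3  # etoposide days 1-3; platinum + antibody day 1
    maintenance_infusion_days: int = 1
    imaging_interval_early: int = 2  # scans every 6 weeks ...
    imaging_switch_cycle: int = 18  # ... through week 54 ...
    imaging_interval_late: int = 4  # ... then every 12 weeks

    def __post_init__(self) -> None:
        if self.induction_cycles < 0:
            raise ValueError("induction_cycles must be >= 0")
        for name in (
            "induction_infusion_days",
            "maintenance_infusion_days",
            "imaging_interval_early",
            "imaging_interval_late",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def imaging_cycles(self, n_cycles: int) -> np.ndarray:
        """Boolean mask of cycles in which a surveillance scan occurs."""
        k = np.arange(n_cycles)
        early = (k > 0) & (k <= self.imaging_switch_cycle) & (k % self.imaging_interval_early == 0)
        late = (k > self.imaging_switch_cycle) & (
            (k - self.imaging_switch_cycle) % self.imaging_interval_late == 0
        )
        return early | late


@dataclass(frozen=True)
class StrategyScenario:
    """One treatment arm: survival curves, costs, utilities, AE profile."""

    label: str
    os_spec: DistributionSpec
    pfs_spec: DistributionSpec
    costs: CostInputs
    utilities: UtilityInputs
    subsequent: SubsequentTreatment
    maintenance_drug: str | None = None  # agent continued past induction, or None
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        if self.maintenance_drug is not None and self.maintenance_drug not in self.costs.drug:
            raise ConfigurationError(
                f"maintenance drug {self.maintenance_drug!r} has no per-cycle cost"
            )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancies and discounted cost/QALY ledgers."""

    cycles: pd.DataFrame
    total_cost: float
    total_qalys: float
    total_life_years: float
    undiscounted_cost: float
    undiscounted_qalys: float

    def cost_by_category(self) -> pd.Series:
        return self.cycles[[f"cost_{c}" for c in COST_CATEGORIES]].sum()


def state_occupancy(
    os_spec: DistributionSpec,
    pfs_spec: DistributionSpec,
    settings: ModelSettings,
) -> pd.DataFrame:
    """Partitioned state occupancies at each cycle boundary (n_cycles + 1 rows)."""
    k = np.arange(settings.n_cycles + 1)
    t_curve = k * settings.curve_time_per_cycle
    s_os = np.asarray(survival_at(os_spec, t_curve))
    s_pfs = np.asarray(survival_at(pfs_spec, t_curve))
    pfs = np.minimum(s_pfs, s_os)
    return pd.DataFrame(
        {
            "cycle": k,
            "time_curve": t_curve,
            "time_years": k * settings.cycle_years,
            "pfs": pfs,
            "pd": s_os - pfs,
            "death": 1.0 - s_os,
        }
    )


def expected_ae_burden(
    utilities: UtilityInputs,
    costs: CostInputs,
    settings: ModelSettings,
) -> tuple[float, float]:
    """One-time adverse-event cost and QALY loss, applied in the first cycle.

    cost = sum of incidence_j x unit_cost_j;
    qaly_loss = sum of incidence_j x disutility_j x cycle length in years.
    """
    inc = utilities.ae_incidences
    if set(inc) != set(costs.ae_unit_costs) or set(inc) != set(utilities.ae_disutilities):
        raise ConfigurationError(
            "AE incidence, unit-cost and disutility vectors must cover the same events; "
            f"got incidences {sorted(inc)}, costs {sorted(costs.ae_unit_costs)}, "
            f"disutilities {sorted(utilities.ae_disutilities)}"
        )
    cost = sum(inc[j] * costs.ae_unit_costs[j] for j in inc)
    qaly_loss = sum(
        inc[j] * utilities.ae_disutilities[j] * settings.cycle_years for j in inc
    )
    return cost, qaly_loss


def _cost_arrays(
    scenario: StrategyScenario,
    settings: ModelSettings,
    pfs: np.ndarray,
    pd_occ: np.ndarray,
    incident_deaths: np.ndarray,
) -> dict[str, np.ndarray]:
    """Undiscounted cost per cycle by category, on start-of-cycle occupancy."""
    n = len(pfs)
    sched = scenario.schedule
    costs = scenario.costs
    k = np.arange(n)
    induction = k < sched.induction_cycles

    chemo_per_cycle = costs.drug["carboplatin"] + 3 * costs.drug["etoposide"]
    drug_rate = np.zeros(n)
    drug_rate[induction] = chemo_per_cycle
    if scenario.maintenance_drug is not None:
        drug_rate += costs.drug[scenario.maintenance_drug]

    admin_rate = np.zeros(n)
    admin_rate[induction] = costs.administration.cycle_admin_cost(
        sched.induction_infusion_days
    )
    if scenario.maintenance_drug is not None:
        admin_rate[~induction] = costs.administration.cycle_admin_cost(
            sched.maintenance_infusion_days
        )

    imaging_rate = np.where(
        sched.imaging_cycles(n), costs.imaging_per_scan, 0.0
    )
    pd_rate = scenario.subsequent.blended_cycle_cost(costs)

    ae_cost, _ = expected_ae_burden(scenario.utilities, costs, settings)
    ae = np.zeros(n)
    ae[0] = ae_cost

    return {
        "drug": drug_rate * pfs,
        "administration": admin_rate * pfs,
        "laboratory": costs.laboratory_per_cycle * pfs,
        "imaging": imaging_rate * pfs,
        "progressed_care": pd_rate * pd_occ,
        "end_of_life": costs.end_of_life * incident_deaths,
        "adverse_events": ae,
    }


def cycle_cost(
    scenario: StrategyScenario,
    cycle_index: int,
    occupancy: Mapping[str, float],
    settings: ModelSettings,
) -> dict[str, float]:
    """Undiscounted cost of a single cycle, by category.

    ``occupancy`` needs keys ``pfs``, ``pd`` and ``incident_deaths`` (the
    death-occupancy increment over this cycle, which accrues the one-time
    end-of-life cost).
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    n = cycle_index + 1
    pfs = np.zeros(n)
    pd_occ = np.zeros(n)
    deaths = np.zeros(n)
    pfs[-1] = occupancy["pfs"]
    pd_occ[-1] = occupancy["pd"]
    deaths[-1] = occupancy.get("incident_deaths", 0.0)
    arrays = _cost_arrays(scenario, settings, pfs, pd_occ, deaths)
    out = {cat: float(arr[-1]) for cat, arr in arrays.items()}
    if cycle_index > 0:  # AE burden belongs to cycle 0 only
        out["adverse_events"] = 0.0
    return out


def _engine(
    scenario: StrategyScenario, settings: ModelSettings
) -> dict[str, np.ndarray]:
    """Vectorized model core: per-cycle QALY and cost arrays (discounted)."""
    n = settings.n_cycles
    k = np.arange(n + 1)
    t_curve = k * settings.curve_time_per_cycle
    s_os = np.asarray(survival_at(scenario.os_spec, t_curve))
    s_pfs = np.asarray(survival_at(scenario.pfs_spec, t_curve))
    pfs_b = np.minimum(s_pfs, s_os)
    pd_b = s_os - pfs_b
    death_b = 1.0 - s_os
    incident_deaths = np.diff(death_b)  # deaths during cycle k, charged at k

    if settings.half_cycle_correction:
        pfs_c = 0.5 * (pfs_b[:-1] + pfs_b[1:])
        pd_c = 0.5 * (pd_b[:-1] + pd_b[1:])
        alive_c = 0.5 * ((1 - death_b[:-1]) + (1 - death_b[1:]))
    else:
        pfs_c, pd_c = pfs_b[:-1], pd_b[:-1]
        alive_c = 1.0 - death_b[:-1]

    k = np.arange(n)
    t_years = k * settings.cycle_years
    disc = (1.0 + settings.discount_rate) ** (-t_years)

    u = scenario.utilities
    qaly_cycle = (u.u_pfs * pfs_c + u.u_pd * pd_c) * settings.cycle_years
    _, ae_qloss = expected_ae_burden(u, scenario.costs, settings)
    qaly_cycle[0] -= ae_qloss

    cost_arrays = _cost_arrays(scenario, settings, pfs_c, pd_c, incident_deaths)
    return {
        "cycle": k,
        "t_years": t_years,
        "pfs_b": pfs_b[:-1],
        "pd_b": pd_b[:-1],
        "death_b": death_b[:-1],
        "incident_deaths": incident_deaths,
        "disc": disc,
        "alive_c": alive_c,
        "qaly_cycle": qaly_cycle,
        **{f"cost_{cat}": arr for cat, arr in cost_arrays.items()},
    }


def run_totals(
    scenario: StrategyScenario, settings: ModelSettings
) -> tuple[float, float]:
    """Total discounted (cost, QALYs) without assembling a trace table.

    Identical numbers to :func:`run_model`; used by the sensitivity loops
    where only the totals matter.
    """
    e = _engine(scenario, settings)
    disc = e["disc"]
    cost = sum(
        float((e[f"cost_{cat}"] * disc).sum()) for cat in COST_CATEGORIES
    )
    return cost, float((e["qaly_cycle"] * disc).sum())


def run_model(scenario: StrategyScenario, settings: ModelSettings) -> CohortTrace:
    """Run one strategy arm over the full horizon.

    Deterministic: builds the occupancy table, applies the one-time
    adverse-event burden at cycle 0, accrues per-cycle costs and QALYs on
    start-of-cycle occupancy (or cycle-average occupancy when half-cycle
    correction is on) and discounts each cycle at its start time.
    """
    e = _engine(scenario, settings)
    k = e["cycle"]
    t_years = e["t_years"]
    disc = e["disc"]
    qaly_cycle = e["qaly_cycle"]
    cost_arrays = {cat: e[f"cost_{cat}"] for cat in COST_CATEGORIES}

    cycles = pd.DataFrame(
        {
            "cycle": k,
            "time_years": t_years,
            "pfs": e["pfs_b"],
            "pd": e["pd_b"],
            "death": e["death_b"],
            "incident_deaths": e["incident_deaths"],
            "discount": disc,
            "qalys": qaly_cycle,
            "qalys_disc": qaly_cycle * disc,
        }
    )
    total_undisc_cost = 0.0
    total_disc_cost = 0.0
    for cat, arr in cost_arrays.items():
        cycles[f"cost_{cat}"] = arr * disc
        total_undisc_cost += float(arr.sum())
        total_disc_cost += float((arr * disc).sum())

    return CohortTrace(
        cycles=cycles,
        total_cost=total_disc_cost,
        total_qalys=float((qaly_cycle * disc).sum()),
        total_life_years=float((e["alive_c"] * settings.cycle_years).sum()),
        undiscounted_cost=total_undisc_cost,
        undiscounted_qalys=float(qaly_cycle.sum()),
    )
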