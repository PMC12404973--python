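"""Independent brute-force oracles used by the test suite.

These reimplement model quantities by direct accumulation at daily
resolution, deliberately sharing no code with the cohort engine: state
occupancy is evaluated continuously on a per-day grid, per-cycle cost rates
are spread uniformly over the days of their cycle, point costs (scans,
adverse events, end-of-life) are charged on the day they occur, and
discounting is applied day by day.
"""

from __future__ import annotations

import numpy as np

from psmcea.cohort import DAYS_PER_YEAR, ModelSettings, StrategyScenario
from psmcea.survival import survival_at


def daily_riemann_totals(
    scenario: StrategyScenario,
    settings: ModelSettings,
    occupancy: str = "start_of_cycle",
) -> tuple[float, float]:
    """Total discounted (cost, QALYs) by one-day-step accumulation.

    ``occupancy`` selects the accrual basis: ``"start_of_cycle"`` mirrors the
    model's stated accrual rule (occupancy frozen at each cycle start) while
    everything else (discounting, death increments, scan days) is re-derived
    daily; ``"continuous"`` evaluates occupancy on every day, i.e. the exact
    time integral that a half-cycle-corrected model approximates.
    """
    cyc_days = settings.cycle_length_days
    n_days = int(settings.n_cycles * cyc_days)
    day = np.arange(n_days)
    cycle_of_day = (day / cyc_days).astype(int)
    if occupancy == "continuous":
        t_curve = (day / cyc_days) * settings.curve_time_per_cycle
    elif occupancy == "start_of_cycle":
        t_curve = cycle_of_day * settings.curve_time_per_cycle
    else:
        raise ValueError(occupancy)
    s_os = np.asarray(survival_at(scenario.os_spec, t_curve))
    s_pfs = np.minimum(np.asarray(survival_at(scenario.pfs_spec, t_curve)), s_os)
    pd_occ = s_os - s_pfs
    disc = (1.0 + settings.discount_rate) ** (-(day / DAYS_PER_YEAR))

    u = scenario.utilities
    qalys = float(
        np.sum((u.u_pfs * s_pfs + u.u_pd * pd_occ) / DAYS_PER_YEAR * disc)
    )
    ae_qloss = sum(
        u.ae_incidences[j] * u.ae_disutilities[j] * cyc_days / DAYS_PER_YEAR
        for j in u.ae_incidences
    )
    qalys -= ae_qloss  # charged on day 0, discount factor 1

    costs = scenario.costs
    sched = scenario.schedule
    induction = cycle_of_day < sched.induction_cycles
    chemo = costs.drug["carboplatin"] + 3 * costs.drug["etoposide"]
    drug_daily = np.where(induction, chemo / cyc_days, 0.0)
    admin_daily = np.where(
        induction,
        costs.administration.cycle_admin_cost(sched.induction_infusion_days) / cyc_days,
        0.0,
    )
    if scenario.maintenance_drug is not None:
        drug_daily = drug_daily + costs.drug[scenario.maintenance_drug] / cyc_days
        admin_daily = admin_daily + np.where(
            ~induction,
            costs.administration.cycle_admin_cost(sched.maintenance_infusion_days)
            / cyc_days,
            0.0,
        )
    lab_daily = costs.laboratory_per_cycle / cyc_days

    total = float(np.sum((drug_daily + admin_daily + lab_daily) * s_pfs * disc))

    # scans: point cost on the first day of each imaging cycle
    scan_cycles = np.nonzero(scenario.schedule.imaging_cycles(settings.n_cycles))[0]
    scan_days = (scan_cycles * cyc_days).astype(int)
    total += float(
        np.sum(costs.imaging_per_scan * s_pfs[scan_days] * disc[scan_days])
    )

    pd_rate = scenario.subsequent.blended_cycle_cost(costs) / cyc_days
    total += float(np.sum(pd_rate * pd_occ * disc))

    # end of life: deaths during each day (continuous curve), discounted that day
    s_os_day = np.asarray(
        survival_at(scenario.os_spec, day / cyc_days * settings.curve_time_per_cycle)
    )
    s_os_next = np.asarray(
        survival_at(scenario.os_spec, (day + 1) / cyc_days * settings.curve_time_per_cycle)
    )
    deaths = s_os_day - s_os_next
    total += float(np.sum(costs.end_of_life * deaths * disc))

    total += sum(
        u.ae_incidences[j] * costs.ae_unit_costs[j] for j in u.ae_incidences
    )
    return total, qalys
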