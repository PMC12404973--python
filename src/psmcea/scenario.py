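"""Scenario configuration files, result writers and the packaged parameter sets.

Six scenario files ship with the package ({china, us} x {overall, ith_l,
a11_b62}), transcribing the published model-parameter tables cell by cell;
each file carries provenance comments and flags the known inconsistencies of
the source tables inline.  A scenario file is a YAML document whose numeric
leaves are either plain numbers (held fixed in sensitivity analyses) or
``{value, range: [low, high], dist: gamma|beta}`` mappings, from which the
sensitivity-analysis parameter registry is built automatically.

Subgroup files may declare ``extends: <id>`` and override only the sections
that differ (their survival parameter sets).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    AdminCosts,
    CohortTrace,
    CostInputs,
    ModelSettings,
    Schedule,
    StrategyScenario,
    SubsequentTreatment,
    UtilityInputs,
)
from .econ import IncrementalResult
from .sensitivity import Param, ParamRegistry, PsaIterationSet
from .survival import DistributionSpec

__all__ = [
    "SchemaError",
    "LoadedScenario",
    "packaged_scenario_ids",
    "load_scenario",
    "write_results",
    "read_results",
    "summary_table",
]

_ARMS = ("treat", "comp")
_AE_EVENTS = (
    "anaemia",
    "decreased_platelet_count",
    "decreased_neutrophil_count",
    "hyponatraemia",
    "hypokalaemia",
    "pneumonia",
)


class SchemaError(ValueError):
    """A scenario file failed validation; the message names the offending key."""


@dataclass(frozen=True)
class LoadedScenario:
    """A fully validated scenario pair plus its sensitivity registry."""

    id: str
    treat: StrategyScenario
    comp: StrategyScenario
    settings: ModelSettings
    registry: ParamRegistry


def packaged_scenario_ids() -> list[str]:
    """Identifiers of the scenario files shipped with the package."""
    root = importlib.resources.files("psmcea") / "scenarios"
    return sorted(
        p.name[: -len(".yaml")]
        for p in root.iterdir()
        if p.name.endswith(".yaml")
    )


def _packaged_path(scenario_id: str) -> Path:
    return Path(str(importlib.resources.files("psmcea") / "scenarios" / f"{scenario_id}.yaml"))


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        # distribution specs replace atomically (families differ in their
        # parameter names, so merging parent params would corrupt them)
        if isinstance(v, dict) and isinstance(out.get(k), dict) and "family" not in v:
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _load_raw(source: str | Path) -> tuple[str, dict]:
    path = Path(source)
    if not path.exists():
        candidate = _packaged_path(str(source))
        if candidate.exists():
            path = candidate
        else:
            raise SchemaError(f"scenario {source!r}: file not found")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"scenario {path}: document must be a mapping")
    if "extends" in doc:
        parent_id = doc.pop("extends")
        parent_path = path.with_name(f"{parent_id}.yaml")
        _, parent = _load_raw(parent_path if parent_path.exists() else parent_id)
        doc = _deep_merge(parent, doc)
    scenario_id = doc.get("id")
    if not isinstance(scenario_id, str):
        raise SchemaError(f"scenario {path}: missing key 'id'")
    return scenario_id, doc


class _Reader:
    """Walks the raw document, collecting values and registry parameters."""

    def __init__(self, scenario_id: str, doc: Mapping[str, Any]):
        self.id = scenario_id
        self.doc = doc
        self.params: list[Param] = []

    def section(self, *keys: str) -> Any:
        here: Any = self.doc
        for k in keys:
            if not isinstance(here, Mapping) or k not in here:
                raise SchemaError(f"scenario {self.id}: missing key {'.'.join(keys)!r}")
            here = here[k]
        return here

    def leaf(
        self,
        keys: tuple[str, ...],
        *,
        path: str,
        target: str,
        nonnegative: bool = True,
        registry_name: str | None = None,
    ) -> float:
        """Parse a numeric leaf; register it when it carries a distribution."""
        raw = self.section(*keys)
        keyname = ".".join(keys)
        if isinstance(raw, Mapping):
            for req in ("value", "range", "dist"):
                if req not in raw:
                    raise SchemaError(
                        f"scenario {self.id}: key {keyname!r} missing field {req!r}"
                    )
            value = raw["value"]
            rng = raw["range"]
            dist = raw["dist"]
            if (
                not isinstance(rng, (list, tuple))
                or len(rng) != 2
                or not all(isinstance(x, (int, float)) for x in rng)
            ):
                raise SchemaError(
                    f"scenario {self.id}: key {keyname!r} range must be [low, high]"
                )
        elif isinstance(raw, (int, float)) and not isinstance(raw, bool):
            value, rng, dist = raw, (raw, raw), "fixed"
        else:
            raise SchemaError(
                f"scenario {self.id}: key {keyname!r} must be a number or "
                "{value, range, dist} mapping"
            )
        value = float(value)
        if nonnegative and value < 0:
            raise SchemaError(f"scenario {self.id}: key {keyname!r} must be >= 0")
        low, high = float(rng[0]), float(rng[1])
        if not low <= value <= high:
            raise SchemaError(
                f"scenario {self.id}: key {keyname!r} range [{low}, {high}] "
                f"does not bracket value {value}"
            )
        try:
            self.params.append(
                Param(
                    name=registry_name or keyname,
                    path=path,
                    base=value,
                    low=low,
                    high=high,
                    dist=dist,
                    target=target,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"scenario {self.id}: key {keyname!r}: {exc}") from exc
        return value


def _survival_spec(reader: _Reader, arm: str, endpoint: str) -> DistributionSpec:
    raw = reader.section("survival", arm, endpoint)
    if not isinstance(raw, Mapping) or "family" not in raw or "params" not in raw:
        raise SchemaError(
            f"scenario {reader.id}: survival.{arm}.{endpoint} needs 'family' and 'params'"
        )
    try:
        return DistributionSpec(raw["family"], dict(raw["params"]))
    except ValueError as exc:
        raise SchemaError(
            f"scenario {reader.id}: survival.{arm}.{endpoint}: {exc}"
        ) from exc


def load_scenario(source: str | Path) -> LoadedScenario:
    """Load and validate a scenario file (packaged id or explicit path).

    Returns the two strategy arms, the shared model settings and the
    sensitivity-analysis parameter registry assembled from every leaf that
    declares a sampling distribution.
    """
    scenario_id, doc = _load_raw(source)
    r = _Reader(scenario_id, doc)

    discount = r.leaf(
        ("settings", "discount_rate"),
        path="discount_rate",
        target="settings",
        registry_name="discount_rate",
    )
    try:
        settings = ModelSettings(
            discount_rate=discount,
            wtp=float(r.section("settings", "wtp")),
            cycle_length_days=float(r.section("settings", "cycle_length_days")),
            horizon_years=float(r.section("settings", "horizon_years")),
            curve_time_per_cycle=float(r.section("settings", "curve_time_per_cycle")),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"scenario {scenario_id}: settings: {exc}") from exc

    admin_raw = r.section("costs", "administration")
    mode = admin_raw.get("mode")
    admin_fields: dict[str, float] = {}
    if mode == "per_infusion":
        unit_keys = ("prophylaxis_per_infusion", "infusion_fee", "prophylaxis_per_cycle")
    elif mode == "per_hour":
        unit_keys = ("first_hour", "additional_hour")
    else:
        raise SchemaError(
            f"scenario {scenario_id}: costs.administration.mode must be "
            f"'per_infusion' or 'per_hour', got {mode!r}"
        )
    for key in unit_keys:
        admin_fields[key] = r.leaf(
            ("costs", "administration", key),
            path=f"costs.administration.{key}",
            target="both",
            registry_name=f"cost.administration.{key}",
        )

    drug = {}
    for agent in ("toripalimab", "carboplatin", "cisplatin", "etoposide", "topotecan", "anlotinib"):
        drug[agent] = r.leaf(
            ("costs", "drug", agent),
            path=f"costs.drug.{agent}",
            target="both",
            registry_name=f"cost.drug.{agent}",
        )
    ae_costs = {}
    for ev in _AE_EVENTS:
        ae_costs[ev] = r.leaf(
            ("costs", "adverse_events", ev),
            path=f"costs.ae_unit_costs.{ev}",
            target="both",
            registry_name=f"cost.ae.{ev}",
        )
    simple_costs = {}
    for key in (
        "laboratory_per_cycle",
        "imaging_per_scan",
        "best_supportive_care_per_cycle",
        "end_of_life",
    ):
        simple_costs[key] = r.leaf(
            ("costs", key),
            path=f"costs.{key}",
            target="both",
            registry_name=f"cost.{key}",
        )
    try:
        costs = CostInputs(
            drug=drug,
            administration=AdminCosts(mode=mode, **admin_fields),
            ae_unit_costs=ae_costs,
            **simple_costs,
        )
    except ValueError as exc:
        raise SchemaError(f"scenario {scenario_id}: costs: {exc}") from exc

    u_pfs = r.leaf(("utilities", "pfs"), path="utilities.u_pfs", target="both",
                   registry_name="utility.pfs")
    u_pd = r.leaf(("utilities", "pd"), path="utilities.u_pd", target="both",
                  registry_name="utility.pd")
    disutilities = {
        ev: r.leaf(
            ("disutilities", ev),
            path=f"utilities.ae_disutilities.{ev}",
            target="both",
            registry_name=f"disutility.{ev}",
        )
        for ev in _AE_EVENTS
    }

    sched_raw = r.section("schedule")
    try:
        schedule = Schedule(**{k: int(v) for k, v in sched_raw.items()})
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"scenario {scenario_id}: schedule: {exc}") from exc

    arms: dict[str, StrategyScenario] = {}
    for arm in _ARMS:
        incidences = {
            ev: r.leaf(
                ("adverse_event_incidence", arm, ev),
                path=f"utilities.ae_incidences.{ev}",
                target=arm,
                registry_name=f"ae_incidence.{arm}.{ev}",
            )
            for ev in _AE_EVENTS
        }
        proportion = r.leaf(
            ("subsequent_treatment", arm, "proportion"),
            path="subsequent.proportion",
            target=arm,
            registry_name=f"subsequent.{arm}.proportion",
        )
        shares = {
            cls: r.leaf(
                ("subsequent_treatment", arm, "shares", cls),
                path=f"subsequent.shares.{cls}",
                target=arm,
                registry_name=f"subsequent.{arm}.share_{cls}",
            )
            for cls in ("cytotoxic", "tki", "pd1")
        }
        maintenance = r.section("maintenance_drug", arm)
        if maintenance is not None and not isinstance(maintenance, str):
            raise SchemaError(
                f"scenario {scenario_id}: maintenance_drug.{arm} must be an agent name or null"
            )
        try:
            arms[arm] = StrategyScenario(
                label=str(r.section("labels", arm)),
                os_spec=_survival_spec(r, arm, "os"),
                pfs_spec=_survival_spec(r, arm, "pfs"),
                costs=costs,
                utilities=UtilityInputs(
                    u_pfs=u_pfs,
                    u_pd=u_pd,
                    ae_disutilities=dict(disutilities),
                    ae_incidences=incidences,
                ),
                subsequent=SubsequentTreatment(proportion=proportion, shares=shares),
                maintenance_drug=maintenance,
                schedule=schedule,
            )
        except ValueError as exc:
            raise SchemaError(f"scenario {scenario_id}: arm {arm!r}: {exc}") from exc

    return LoadedScenario(
        id=scenario_id,
        treat=arms["treat"],
        comp=arms["comp"],
        settings=settings,
        registry=ParamRegistry(r.params),
    )


# ---------------------------------------------------------------------------
# result writers

_FORMATS = ("summary_table", "trace", "tornado", "ceac", "scatter")


def summary_table(rows: list[dict[str, Any]]) -> pd.DataFrame:
    """Assemble per-scenario incremental results into a base-case-style table."""
    cols = [
        "scenario",
        "treat_cost",
        "treat_qalys",
        "comp_cost",
        "comp_qalys",
        "delta_cost",
        "delta_effect",
        "inhb",
        "inmb",
        "icer",
    ]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


def _as_frame(results: Any, fmt: str) -> pd.DataFrame:
    if fmt == "summary_table":
        if isinstance(results, pd.DataFrame):
            return results
        return summary_table(list(results))
    if fmt == "trace":
        if not isinstance(results, CohortTrace):
            raise TypeError("trace format expects a CohortTrace")
        return results.cycles
    if fmt in ("tornado", "ceac"):
        if not isinstance(results, pd.DataFrame):
            raise TypeError(f"{fmt} format expects a DataFrame")
        return results
    if fmt == "scatter":
        if not isinstance(results, PsaIterationSet):
            raise TypeError("scatter format expects a PsaIterationSet")
        return pd.DataFrame(
            {"delta_cost": results.delta_cost, "delta_effect": results.delta_effect}
        )
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_results(
    results: Any,
    path: str | Path,
    fmt: str,
    *,
    scenario_id: str | None = None,
    seed: int | None = None,
) -> Path:
    """Write a result object as commented CSV; deterministic byte output.

    Header comment lines record the package version and, when given, the
    scenario id and random seed the results came from.
    """
    df = _as_frame(results, fmt)
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# psmcea {__version__} format={fmt}\n")
            if scenario_id is not None:
                fh.write(f"# scenario={scenario_id}\n")
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            df.to_csv(fh, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a file produced by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
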