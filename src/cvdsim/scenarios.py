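"""Intervention levers, scenario runs, differencing, and scenario translation.

A lever is a 0-1 control whose movement shifts one or more model parameters
linearly: parameter' = parameter + movement * max_effect.  Movement 0 is the
status quo exactly; movements are constant over the horizon (no ramp-in).
Scenario outcomes are cumulative base-minus-intervention differences over a
closed outcome window, 2018-2040 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .disease import DiseaseModel
from .economics import (
    CostLedger,
    cost_per_death_averted,
    medical_cost_change,
    net_cost,
    present_value,
    report_cost_per_death,
)
from .engine import SimulationClock, Trajectory
from .errors import DomainError, SpecificationError

#: outcome classes whose counts enter attributable-fraction medical costing
COSTED_MEASURES = (
    "cvd_events",
    "smoking_noncvd_hosp",
    "diabetes_noncvd_hosp",
    "distress_noncvd_hosp",
)


@dataclass(frozen=True)
class Lever:
    """A policy lever: movement in [0, 1] shifts each target parameter linearly."""

    name: str
    targets: Mapping[str, float]  # parameter -> change at movement 1 (max_effect)


def apply_levers(
    params: Mapping[str, float],
    levers: Mapping[str, Lever],
    settings: Mapping[str, float],
) -> dict[str, float]:
    """Return a new parameter mapping with lever movements applied.

    Untouched parameters are returned identically; movement 0 is exactly the
    identity (no floating-point drift is introduced).
    """
    out = dict(params)
    for name, movement in settings.items():
        if name not in levers:
            raise SpecificationError(f"unknown lever {name!r}")
        if not 0.0 <= movement <= 1.0:
            raise DomainError(f"lever {name!r} movement {movement} outside [0, 1]")
        if movement == 0.0:
            continue
        for param, max_effect in levers[name].targets.items():
            out[param] = out.get(param, 0.0) + movement * float(max_effect)
    return out


def translate_price_policy(price_change: float, consumption_share: float) -> float:
    """Translate a price policy into a pricing-lever movement.

    The movement is the relative price change scaled by the share of the
    targeted consumption category, e.g. a 7.8% price rise applying to 24.5%
    of energy-dense food consumption gives a 0.0191 (1.9%) movement.
    """
    for label, value in (("price_change", price_change), ("consumption_share", consumption_share)):
        if not 0.0 <= value <= 1.0:
            raise DomainError(f"{label} {value} outside [0, 1]")
    return price_change * consumption_share


def movement_as_percent(movement: float) -> str:
    """Report a lever movement to one decimal in percent, e.g. '1.9%'."""
    return f"{movement * 100:.1f}%"


@dataclass
class ScenarioResult:
    base: Trajectory
    intervention: Trajectory
    window: tuple[int, int]
    settings: dict[str, float]
    deltas: dict[str, float]

    def window_years(self) -> np.ndarray:
        lo, hi = self.window
        return np.arange(lo, hi + 1)


def run_scenario(
    params: Mapping[str, float],
    levers: Mapping[str, Lever],
    settings: Mapping[str, float],
    clock: SimulationClock | None = None,
    window: tuple[int, int] = (2018, 2040),
    multipliers: Mapping[str, float | np.ndarray] | None = None,
) -> ScenarioResult:
    """Run paired base (all levers 0) and intervention trajectories and difference them.

    Deltas are cumulative over the closed window: deaths/events averted are
    (base - intervention) sums, so avoided harm is positive.
    """
    clock = clock or SimulationClock()
    lo, hi = window
    if not (clock.start_year <= lo <= hi <= clock.end_year):
        raise DomainError(f"window {window} outside clock {clock.start_year}-{clock.end_year}")
    base_traj = DiseaseModel(params, clock=clock, multipliers=multipliers).run()
    scen_params = apply_levers(params, levers, settings)
    scen_traj = DiseaseModel(scen_params, clock=clock, multipliers=multipliers).run()
    deltas = {
        "deaths_averted": base_traj.window_sum("total_deaths", lo, hi)
        - scen_traj.window_sum("total_deaths", lo, hi),
        "cvd_deaths_averted": base_traj.window_sum("cvd_deaths", lo, hi)
        - scen_traj.window_sum("cvd_deaths", lo, hi),
        "events_averted": base_traj.window_sum("cvd_events", lo, hi)
        - scen_traj.window_sum("cvd_events", lo, hi),
    }
    return ScenarioResult(
        base=base_traj,
        intervention=scen_traj,
        window=(lo, hi),
        settings=dict(settings),
        deltas=deltas,
    )


def scenario_report(result: ScenarioResult, ledger: CostLedger) -> dict:
    """Comparison record: implementation PV, medical change PV, net cost,
    deaths averted and cost per death averted over the outcome window."""
    lo, hi = result.window
    years = range(lo, hi + 1)
    base_year = lo
    implementation_annual = sum(
        float(ledger.implementation.get(name, 0.0)) * movement
        for name, movement in result.settings.items()
    )
    implementation_pv = present_value(
        {y: implementation_annual for y in years}, ledger.discount_rate, base_year
    )
    unit_costs = {m: float(ledger.unit_costs.get(m, 0.0)) for m in COSTED_MEASURES}
    i, j = result.base.clock.index(lo), result.base.clock.index(hi)
    base_counts = {m: result.base.series(m)[i : j + 1] for m in COSTED_MEASURES}
    scen_counts = {m: result.intervention.series(m)[i : j + 1] for m in COSTED_MEASURES}
    medical_by_year = medical_cost_change(base_counts, scen_counts, unit_costs)
    medical_pv = present_value(
        dict(zip(years, medical_by_year)), ledger.discount_rate, base_year
    )
    total = net_cost(
        implementation_pv, medical_pv,
        implementation_year=ledger.cost_year, medical_year=ledger.cost_year,
    )
    deaths = result.deltas["deaths_averted"]
    per_death = cost_per_death_averted(total, deaths)
    return {
        "window": [lo, hi],
        "cost_year": ledger.cost_year,
        "discount_rate": ledger.discount_rate,
        "implementation_pv": implementation_pv,
        "medical_change_pv": medical_pv,
        "net_cost": total,
        "deaths_averted": deaths,
        "cvd_deaths_averted": result.deltas["cvd_deaths_averted"],
        "events_averted": result.deltas["events_averted"],
        "cost_per_death_averted": per_death,
        "cost_per_death_averted_reported": report_cost_per_death(per_death),
        "cost_per_death_defined": deaths > 0,
        "settings": dict(result.settings),
    }
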