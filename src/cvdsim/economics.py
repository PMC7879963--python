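"""Costing: implementation costs, attributable-fraction medical costs, discounting.

All monetary quantities in a comparison must share a cost base year; the
ledger tags it explicitly and mismatches raise rather than silently convert.
Discounting is end-of-year: a payment in the base year itself has exponent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, SpecificationError, UnitError

#: sentinel returned when cost per death averted is undefined (no deaths averted)
UNDEFINED_COST = float("nan")


@dataclass(frozen=True)
class CostLedger:
    """Per-lever implementation costs and per-outcome-class unit medical costs.

    ``implementation[lever]`` is the annual cost (currency/yr) of running the
    lever at full movement; the stream scales linearly with movement.
    ``unit_costs[measure]`` is the medical cost per counted outcome.
    """

    implementation: Mapping[str, float] = field(default_factory=dict)
    unit_costs: Mapping[str, float] = field(default_factory=dict)
    cost_year: int = 2012
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise DomainError("discount rate must be >= 0")
        for name, value in {**dict(self.implementation), **dict(self.unit_costs)}.items():
            if not math.isfinite(float(value)):
                raise DomainError(f"cost for {name!r} is not finite")


def present_value(series: Mapping[int, float], rate: float, base_year: int) -> float:
    """Present value at ``base_year`` of an annual cash-flow series.

    End-of-year convention: the base year's cash flow is undiscounted and a
    flow ``k`` years later is divided by ``(1 + rate)**k``.  At rate 0 this is
    the plain sum.
    """
    if rate < 0:
        raise DomainError("discount rate must be >= 0")
    total = 0.0
    for year, amount in series.items():
        if year < base_year:
            raise DomainError(f"cash flow in {year} precedes base year {base_year}")
        if not math.isfinite(float(amount)):
            raise DomainError(f"non-finite cash flow in {year}")
        total += float(amount) / (1.0 + rate) ** (int(year) - int(base_year))
    return total


def medical_cost_change(
    base_counts: Mapping[str, np.ndarray],
    scenario_counts: Mapping[str, np.ndarray],
    unit_costs: Mapping[str, float],
) -> np.ndarray:
    """Annual change in medical costs versus the base run (negative = savings).

    change_t = sum over outcome classes of unit_cost * (scenario_t - base_t).
    Every class present in the counts must have a unit cost.
    """
    change = None
    for measure, base in base_counts.items():
        if measure not in unit_costs:
            raise SpecificationError(f"outcome class {measure!r} has no unit cost")
        unit = float(unit_costs[measure])
        if unit < 0:
            raise DomainError(f"unit cost for {measure!r} must be >= 0")
        delta = unit * (np.asarray(scenario_counts[measure], float) - np.asarray(base, float))
        change = delta if change is None else change + delta
    if change is None:
        raise SpecificationError("no outcome classes supplied")
    return change


def net_cost(
    implementation_pv: float,
    medical_change_pv: float,
    implementation_year: int | None = None,
    medical_year: int | None = None,
) -> float:
    """Net cost = implementation PV + medical change PV (savings enter negative)."""
    if (
        implementation_year is not None
        and medical_year is not None
        and implementation_year != medical_year
    ):
        raise UnitError(
            f"cost base years differ: implementation {implementation_year}, "
            f"medical {medical_year}"
        )
    return float(implementation_pv) + float(medical_change_pv)


def cost_per_death_averted(net: float, deaths_averted: float) -> float:
    """Cost per death averted; ``nan`` sentinel when deaths averted <= 0."""
    if deaths_averted <= 0:
        return UNDEFINED_COST
    return float(net) / float(deaths_averted)


def report_cost_per_death(value: float) -> float | None:
    """Reporting helper: round to the nearest $10,000 (half up); None for the sentinel."""
    if math.isnan(value):
        return None
    return math.floor(value / 10_000.0 + 0.5) * 10_000.0
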