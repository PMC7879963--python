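"""Annual-step stock-flow simulation core.

A model is a set of *stocks* (population compartments, measured at January 1
of each year) connected by *flows* (persons per year, acting over the
following year).  Flow rates are small arithmetic expressions over parameter
and stock names, parsed once at load time.  Integration is forward Euler with
a fixed one-year step; all flows are evaluated simultaneously from the prior
year's state, so the result does not depend on flow ordering.

Negative levels are never allowed: any deficit produced by an overdrawn
outflow is clamped to zero and logged on the trajectory, making mass-balance
violations visible instead of silently redistributing persons.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import NumericError, SpecificationError

#: name used in flow source/target to denote the world outside the system
EXTERNAL = "external"

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_UNARYOPS = (ast.UAdd, ast.USub)


@dataclass(frozen=True)
class SimulationClock:
    """Annual clock: simulate from ``start_year`` through ``end_year`` inclusive."""

    start_year: int = 2010
    end_year: int = 2060
    step: int = 1

    def __post_init__(self) -> None:
        if self.step != 1:
            raise SpecificationError("clock step is fixed at 1 year")
        if not self.start_year < self.end_year:
            raise SpecificationError(
                f"start_year {self.start_year} must precede end_year {self.end_year}"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def index(self, year: int) -> int:
        if not self.start_year <= year <= self.end_year:
            raise SpecificationError(
                f"year {year} outside clock {self.start_year}-{self.end_year}"
            )
        return int(year) - self.start_year


def compile_rate(text: str) -> tuple[Callable[[Mapping[str, float]], float], frozenset[str]]:
    """Compile a rate expression to an evaluator, returning (fn, symbols).

    Only +, -, *, /, unary signs, parentheses, numeric literals and bare names
    are accepted; anything else raises :class:`SpecificationError`.
    """
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise SpecificationError(f"cannot parse rate expression {text!r}: {exc.msg}") from exc
    symbols: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Expression):
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARYOPS):
            continue
        if isinstance(node, (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.UAdd, ast.USub, ast.Load)):
            continue
        if isinstance(node, ast.Constant):
            if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
                continue
            raise SpecificationError(f"non-numeric literal {node.value!r} in {text!r}")
        if isinstance(node, ast.Name):
            symbols.add(node.id)
            continue
        raise SpecificationError(
            f"disallowed syntax {type(node).__name__} in rate expression {text!r}"
        )
    code = compile(tree, "<rate>", "eval")
    empty_globals = {"__builtins__": {}}

    def fn(env: Mapping[str, float]) -> float:
        return eval(code, empty_globals, dict(env))  # noqa: S307 - whitelisted AST

    return fn, frozenset(symbols)


@dataclass
class Stock:
    name: str
    initial: float
    units: str = "persons"


@dataclass
class Parameter:
    """A named scalar, or a per-year path of length ``clock.n_years``."""

    name: str
    value: float | np.ndarray


@dataclass
class Flow:
    """Directed flow in persons/year; ``external`` denotes the outside world."""

    name: str
    source: str
    target: str
    rate: str
    _fn: Callable[[Mapping[str, float]], float] | None = field(default=None, repr=False)
    _symbols: frozenset[str] = field(default_factory=frozenset, repr=False)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    location: str
    message: str


@dataclass
class StockFlowSpec:
    stocks: list[Stock]
    flows: list[Flow]
    parameters: list[Parameter]

    @property
    def stock_names(self) -> list[str]:
        return [s.name for s in self.stocks]

    @property
    def param_map(self) -> dict[str, float | np.ndarray]:
        return {p.name: p.value for p in self.parameters}

    def param_at(self, name: str, t: int) -> float:
        value = self.param_map[name]
        if np.ndim(value) == 0:
            return float(value)
        return float(np.asarray(value)[t])

    def compile(self) -> None:
        """Parse every flow's rate expression once; raises on unknown symbols."""
        known = set(self.stock_names) | {p.name for p in self.parameters}
        for flow in self.flows:
            fn, symbols = compile_rate(flow.rate)
            unknown = symbols - known
            if unknown:
                raise SpecificationError(
                    f"flow {flow.name!r}: unresolvable symbol(s) {sorted(unknown)}"
                )
            flow._fn = fn
            flow._symbols = symbols


def validate_spec(spec: StockFlowSpec) -> list[Finding]:
    """Check all structural invariants; returns findings rather than raising."""
    findings: list[Finding] = []
    seen_stocks: set[str] = set()
    for stock in spec.stocks:
        if stock.name in seen_stocks:
            findings.append(Finding("error", f"stock:{stock.name}", "stock defined twice"))
        seen_stocks.add(stock.name)
        if stock.name == EXTERNAL:
            findings.append(Finding("error", f"stock:{stock.name}", "'external' is reserved"))
        if not math.isfinite(stock.initial) or stock.initial < 0:
            findings.append(
                Finding("error", f"stock:{stock.name}", f"initial value {stock.initial} not a non-negative finite number")
            )
        if stock.units not in ("persons", "fraction"):
            findings.append(Finding("error", f"stock:{stock.name}", f"unknown units {stock.units!r}"))
    seen_params: set[str] = set()
    for param in spec.parameters:
        if param.name in seen_params:
            findings.append(Finding("error", f"parameter:{param.name}", "parameter defined twice"))
        seen_params.add(param.name)
        if np.ndim(param.value) == 0 and not math.isfinite(float(param.value)):
            findings.append(Finding("error", f"parameter:{param.name}", "non-finite value"))
    known = seen_stocks | seen_params
    seen_flows: set[str] = set()
    for flow in spec.flows:
        loc = f"flow:{flow.name}"
        if flow.name in seen_flows:
            findings.append(Finding("error", loc, "flow defined twice"))
        seen_flows.add(flow.name)
        for endpoint, label in ((flow.source, "source"), (flow.target, "target")):
            if endpoint != EXTERNAL and endpoint not in seen_stocks:
                findings.append(
                    Finding("error", loc, f"{label} names missing stock {endpoint!r}")
                )
        if flow.source == EXTERNAL and flow.target == EXTERNAL:
            findings.append(Finding("warning", loc, "flow from external to external has no effect"))
        try:
            _, symbols = compile_rate(flow.rate)
        except SpecificationError as exc:
            findings.append(Finding("error", loc, str(exc)))
            continue
        unknown = symbols - known
        for sym in sorted(unknown):
            findings.append(Finding("error", loc, f"unresolvable symbol {sym!r} in rate"))
    return findings


def _require_valid(spec: StockFlowSpec) -> None:
    errors = [f for f in validate_spec(spec) if f.severity == "error"]
    if errors:
        detail = "; ".join(f"{f.location}: {f.message}" for f in errors)
        raise SpecificationError(f"invalid stock-flow spec: {detail}")


def evaluate_flows(
    state: Mapping[str, float], spec: StockFlowSpec, year: int, t: int = 0
) -> dict[str, float]:
    """Evaluate every flow's rate (persons/yr) at the given state and year index."""
    env = {name: float(level) for name, level in state.items()}
    for param in spec.parameters:
        env[param.name] = spec.param_at(param.name, t)
    rates: dict[str, float] = {}
    for flow in spec.flows:
        if flow._fn is None:
            spec.compile()
        try:
            rate = float(flow._fn(env))
        except ZeroDivisionError as exc:
            raise NumericError(f"flow {flow.name!r} divides by zero in year {year}") from exc
        except NameError as exc:  # pragma: no cover - compile() catches this earlier
            raise SpecificationError(str(exc)) from exc
        if not math.isfinite(rate):
            raise NumericError(f"flow {flow.name!r} produced non-finite rate in year {year}")
        rates[flow.name] = rate
    return rates


def step(
    state: Mapping[str, float], spec: StockFlowSpec, year: int, t: int = 0
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Advance one year: returns (next_state, flow_values, clamp_deficits).

    Flows are all evaluated from ``state`` (the January 1 levels), then applied
    simultaneously.  Any stock driven negative is clamped to zero with the
    deficit reported, never redistributed.
    """
    missing = [s.name for s in spec.stocks if s.name not in state]
    if missing:
        raise SpecificationError(f"state missing stock level(s) {missing}")
    rates = evaluate_flows(state, spec, year, t)
    delta = {name: 0.0 for name in spec.stock_names}
    for flow in spec.flows:
        rate = rates[flow.name]
        if flow.source != EXTERNAL:
            delta[flow.source] -= rate
        if flow.target != EXTERNAL:
            delta[flow.target] += rate
    nxt: dict[str, float] = {}
    deficits: dict[str, float] = {}
    for name in spec.stock_names:
        level = float(state[name]) + delta[name]
        if level < 0.0:
            deficits[name] = -level
            level = 0.0
        nxt[name] = level
    return nxt, rates, deficits


@dataclass
class Trajectory:
    """Annual time-indexed stock levels, flow values and derived output series."""

    clock: SimulationClock
    stocks: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    derived: dict[str, np.ndarray] = field(default_factory=dict)
    clamp_log: list[tuple[str, int, float]] = field(default_factory=list)

    def series(self, measure: str) -> np.ndarray:
        for table in (self.derived, self.stocks, self.flows):
            if measure in table:
                return table[measure]
        raise KeyError(f"no measure {measure!r} in trajectory")

    @property
    def measures(self) -> list[str]:
        return list(self.stocks) + list(self.flows) + list(self.derived)

    def value_at(self, measure: str, year: int) -> float:
        return float(self.series(measure)[self.clock.index(year)])

    def window_sum(self, measure: str, start_year: int, end_year: int) -> float:
        """Sum of a series over [start_year, end_year], closed on both ends."""
        i, j = self.clock.index(start_year), self.clock.index(end_year)
        return float(self.series(measure)[i : j + 1].sum())

    def total_persons(self) -> np.ndarray:
        return np.sum(list(self.stocks.values()), axis=0)

    def clamp_total(self) -> float:
        return float(sum(d for _, _, d in self.clamp_log))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export with columns (measure, year, value)."""
        rows = []
        years = self.clock.years
        for table in (self.stocks, self.flows, self.derived):
            for measure, values in table.items():
                for year, value in zip(years, values):
                    rows.append((measure, int(year), float(value)))
        return pd.DataFrame(rows, columns=["measure", "year", "value"])


def simulate(spec: StockFlowSpec, clock: SimulationClock) -> Trajectory:
    """Run the annual recurrence over the whole clock.

    The initial state is recorded at ``start_year``; flow values are recorded
    for every year in the clock (the final year's flows are evaluated but the
    resulting state falls outside the horizon and is not recorded).  The
    function is pure: identical inputs give bit-identical trajectories.
    """
    _require_valid(spec)
    spec.compile()
    n = clock.n_years
    stocks = {s.name: np.empty(n) for s in spec.stocks}
    flows = {f.name: np.empty(n) for f in spec.flows}
    clamp_log: list[tuple[str, int, float]] = []
    state = {s.name: float(s.initial) for s in spec.stocks}
    for t, year in enumerate(clock.years):
        for name in stocks:
            stocks[name][t] = state[name]
        try:
            nxt, rates, deficits = step(state, spec, int(year), t)
        except NumericError:
            raise
        for name, rate in rates.items():
            flows[name][t] = rate
        for name, deficit in deficits.items():
            clamp_log.append((name, int(year), deficit))
        if t < n - 1:
            state = nxt
    return Trajectory(clock=clock, stocks=stocks, flows=flows, clamp_log=clamp_log)


def spec_from_dict(data: Mapping) -> StockFlowSpec:
    """Build a StockFlowSpec from the documented mapping form (YAML/JSON).

    Shape::

        stocks:     [{name, initial, units?}, ...]
        flows:      [{name, source, target, rate}, ...]
        parameters: {name: scalar | [per-year values], ...}
    """
    stocks = [
        Stock(str(s["name"]), float(s["initial"]), str(s.get("units", "persons")))
        for s in data.get("stocks", [])
    ]
    flows = [
        Flow(str(f["name"]), str(f["source"]), str(f["target"]), str(f["rate"]))
        for f in data.get("flows", [])
    ]
    raw_params = data.get("parameters", {})
    if isinstance(raw_params, Mapping):
        items: Iterable[tuple[str, object]] = raw_params.items()
    else:  # list of {name, value} rows preserves duplicates for validation
        items = [(str(p["name"]), p["value"]) for p in raw_params]
    parameters = []
    for name, value in items:
        if isinstance(value, (list, tuple, np.ndarray)):
            parameters.append(Parameter(str(name), np.asarray(value, dtype=float)))
        else:
            parameters.append(Parameter(str(name), float(value)))
    return StockFlowSpec(stocks=stocks, flows=flows, parameters=parameters)
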