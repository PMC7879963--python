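"""Deterministic desk-scale "toy nation" fixture.

Generates a complete, openly fictitious parameterization of the disease
model — risk-factor prevalences and trends, relative risks, compartment
rates, attribution baselines, costs, the lever set and one-way sensitivity
bounds — plus a synthetic surveillance panel with the shape of national
survey and vital-statistics series (biennial prevalence points, annual
death and hospitalization counts).

The panel plants known calibration multipliers: four measures carry a
persistent multiplier (constant 1.3) or a log-linear drift, three carry an
alternating transient wobble that a sound recalibration review must refuse
to chase, and the rest are the model's own output under lognormal
observation noise.  Everything is reproducible from a single integer seed;
planted multipliers are part of the plan, not the random stream, so two
seeds differ only in noise.

Plausible-range bands for the sensitivity bounds follow provenance:
surveillance-derived rates get tight bands (±5%), survey prevalences ±10%,
literature relative risks ±10% of the excess risk, and soft effect or
coupling parameters ±30-50%; the quality acute/rehabilitation care effect
uses its published bound pair (0.43, 0.90) verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .disease import (
    ATTRIBUTION_MAP,
    DISABILITY_MAP,
    MEASURES,
    MEASURE_KIND,
    PREVALENCE_MEASURES,
    DiseaseModel,
)
from .economics import CostLedger
from .engine import SimulationClock, Trajectory
from .errors import DomainError
from .scenarios import Lever, run_scenario
from .sensitivity import ParameterBound
from .surveillance import SurveillanceSeries

DEFAULT_WINDOW = (2018, 2040)

#: measures whose synthetic observations carry a persistent planted deviation
DEFAULT_DEVIATORS: dict[str, tuple[str, float]] = {
    "adult_obesity": ("constant", 1.3),
    "cvd_deaths": ("constant", 1.3),
    "diabetes_noncvd_deaths": ("drift", 0.05),
    "distress_noncvd_deaths": ("drift", 0.05),
}

#: measures whose observations wobble transiently around the model
DEFAULT_WOBBLERS: dict[str, float] = {
    "secondhand_smoke": 0.15,
    "borderline_chol": 0.15,
    "smoking_noncvd_hosp": 0.15,
}


@dataclass(frozen=True)
class FixtureConfig:
    population: float = 1_000_000.0
    clock: SimulationClock = field(default_factory=SimulationClock)
    seed: int = 7
    noise: float = 0.02  # relative sd of lognormal observation noise
    deviators: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEVIATORS)
    )
    wobblers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WOBBLERS))

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise DomainError("noise must be >= 0")
        if self.population <= 0:
            raise DomainError("population must be positive")


# (factor, 2010 prevalence, absolute trend per year)
_FACTOR_TABLE = [
    ("youth_obesity", 0.17, 0.002),
    ("adult_obesity", 0.35, 0.004),
    ("current_smoker", 0.19, -0.003),
    ("former_smoker", 0.21, 0.001),
    ("secondhand_smoke", 0.25, -0.004),
    ("high_bp", 0.30, 0.001),
    ("borderline_bp", 0.25, 0.0005),
    ("high_chol", 0.12, -0.002),
    ("borderline_chol", 0.30, -0.001),
    ("diabetes", 0.10, 0.002),
    ("prediabetes", 0.33, 0.002),
    ("distress", 0.04, 0.0005),
]

_RR_TABLE = {
    "rr.current_smoker.cvd_event": 2.0,
    "rr.former_smoker.cvd_event": 1.2,
    "rr.adult_obesity.cvd_event": 1.5,
    "rr.secondhand_smoke.cvd_event": 1.25,
    "rr.high_bp.cvd_event": 1.8,
    "rr.borderline_bp.cvd_event": 1.3,
    "rr.high_chol.cvd_event": 1.6,
    "rr.borderline_chol.cvd_event": 1.2,
    "rr.diabetes.cvd_event": 1.8,
    "rr.prediabetes.cvd_event": 1.2,
    "rr.distress.cvd_event": 1.3,
    "rr.current_smoker.noncvd_death": 1.9,
    "rr.diabetes.noncvd_death": 1.6,
    "rr.distress.noncvd_death": 1.4,
    "rr.current_smoker.noncvd_hosp": 1.7,
    "rr.diabetes.noncvd_hosp": 1.5,
    "rr.distress.noncvd_hosp": 1.3,
}

_RATES = {
    "post0": 0.08,
    "inflow": 12_000.0,
    "cvd_event_rate0": 0.006,
    "cvd_case_fatality": 0.25,
    "post_event_ratio": 4.0,
    "post_fatality_ratio": 1.3,
    "noncvd_death_rate0": 0.008,
    "noncvd_post_ratio": 1.5,
    "youth_to_adult_transfer": 0.03,
    "adult_turnover": 0.04,
}

_QUALITY = {
    "quality_care_uptake": 0.0,  # moved by the quality-care lever
    "quality_care_reach": 0.04,
    "quality_care_effect": 0.665,  # midpoint of the published bound pair
}

_BASELINES = {
    "baseline.smoking_noncvd_deaths": 9_000.0,
    "baseline.diabetes_noncvd_deaths": 8_000.0,
    "baseline.distress_noncvd_deaths": 7_000.0,
    "baseline.smoking_noncvd_hosp": 60_000.0,
    "baseline.diabetes_noncvd_hosp": 70_000.0,
    "baseline.distress_noncvd_hosp": 40_000.0,
}

_DISABILITY = {
    "disab.hypertension_disability": 0.08,
    "disab.smoking_disability": 0.10,
    "disab.diabetes_disability": 0.20,
    "disab.obesity_disability": 0.12,
    "disab.post_cvd_disability": 0.35,
}

_UNIT_COSTS = {
    "unit_cost.cvd_events": 45_000.0,
    "unit_cost.smoking_noncvd_hosp": 12_000.0,
    "unit_cost.diabetes_noncvd_hosp": 15_000.0,
    "unit_cost.distress_noncvd_hosp": 9_000.0,
}

_IMPL_COSTS = {
    "impl_cost.smoking_quit_services": 6.0e6,
    "impl_cost.energy_dense_food_pricing": 1.0e6,
    "impl_cost.physical_activity_schools": 4.0e6,
    "impl_cost.physical_activity_childcare": 2.0e6,
    "impl_cost.blood_pressure_control": 8.0e6,
    "impl_cost.quality_acute_rehab_care": 10.0e6,
}


def default_levers() -> dict[str, Lever]:
    """Representative lever subset; every direction satisfies 'no change or better'."""
    levers = [
        Lever("smoking_quit_services", {"prev0.current_smoker": -0.02, "prev0.former_smoker": 0.02}),
        Lever("energy_dense_food_pricing", {"prev0.adult_obesity": -0.04, "prev0.youth_obesity": -0.02}),
        Lever("physical_activity_schools", {"prev0.youth_obesity": -0.03}),
        Lever("physical_activity_childcare", {"prev0.youth_obesity": -0.02}),
        Lever("blood_pressure_control", {"prev0.high_bp": -0.05}),
        Lever("quality_acute_rehab_care", {"quality_care_uptake": 1.0}),
    ]
    return {lever.name: lever for lever in levers}


def default_params(population: float = 1_000_000.0) -> dict[str, float]:
    scale = population / 1_000_000.0
    params: dict[str, float] = {"population": population}
    for factor, prev0, trend in _FACTOR_TABLE:
        params[f"prev0.{factor}"] = prev0
        params[f"trend.{factor}"] = trend
        params[f"ref.{factor}"] = prev0
    params.update(_RR_TABLE)
    params.update(_RATES)
    params["inflow"] *= scale
    params.update(_QUALITY)
    for key, value in _BASELINES.items():
        params[key] = value * scale
    params.update(_DISABILITY)
    params.update(_UNIT_COSTS)
    for key, value in _IMPL_COSTS.items():
        params[key] = value * scale
    return params


def default_bounds(params: Mapping[str, float]) -> list[ParameterBound]:
    """86 plausible-range rows, provenance-banded; order is deterministic."""
    bounds: list[ParameterBound] = []

    def band(name: str, low: float, high: float, note: str) -> None:
        bounds.append(ParameterBound(name, float(params[name]), low, high, note))

    for factor, *_ in _FACTOR_TABLE:
        v = params[f"prev0.{factor}"]
        band(f"prev0.{factor}", 0.9 * v, min(1.1 * v, 1.0), "survey prevalence band +/-10%")
    for factor, *_ in _FACTOR_TABLE:
        v = params[f"trend.{factor}"]
        lo, hi = sorted((0.5 * v, 1.5 * v))
        band(f"trend.{factor}", lo, hi, "secular trend band +/-50%")
    for factor, *_ in _FACTOR_TABLE:
        v = params[f"ref.{factor}"]
        band(f"ref.{factor}", 0.95 * v, min(1.05 * v, 1.0), "normalization reference band +/-5%")
    for key in _RR_TABLE:
        v = params[key]
        band(key, 1.0 + 0.9 * (v - 1.0), 1.0 + 1.1 * (v - 1.0), "literature excess-RR band +/-10%")
    for key in _RATES:
        v = params[key]
        band(key, 0.95 * v, 1.05 * v, "surveillance-derived rate band +/-5%")
    band("quality_care_reach", 0.7 * params["quality_care_reach"],
         1.3 * params["quality_care_reach"], "soft coupling band +/-30%")
    band("quality_care_effect", 0.43, 0.90, "published sensitivity bound pair")
    for key in _BASELINES:
        v = params[key]
        band(key, 0.85 * v, 1.15 * v, "outcome baseline band +/-15%")
    for key in _DISABILITY:
        v = params[key]
        band(key, 0.9 * v, 1.1 * v, "disability link band +/-10%")
    for key in _UNIT_COSTS:
        v = params[key]
        band(key, 0.8 * v, 1.2 * v, "unit cost band +/-20%")
    for key in _IMPL_COSTS:
        v = params[key]
        band(key, 0.8 * v, 1.2 * v, "implementation cost band +/-20%")
    return bounds


def ledger_from_params(
    params: Mapping[str, float], cost_year: int = 2012, discount_rate: float = 0.03
) -> CostLedger:
    implementation = {
        key.removeprefix("impl_cost."): float(value)
        for key, value in params.items()
        if key.startswith("impl_cost.")
    }
    unit_costs = {
        key.removeprefix("unit_cost."): float(value)
        for key, value in params.items()
        if key.startswith("unit_cost.")
    }
    return CostLedger(
        implementation=implementation,
        unit_costs=unit_costs,
        cost_year=cost_year,
        discount_rate=discount_rate,
    )


@dataclass
class ToyNation:
    """Bundle of everything needed to drive the full validation pipeline."""

    config: FixtureConfig
    params: dict[str, float]
    levers: dict[str, Lever]
    bounds: list[ParameterBound]

    @property
    def clock(self) -> SimulationClock:
        return self.config.clock

    @property
    def ledger(self) -> CostLedger:
        return ledger_from_params(self.params)

    @property
    def all_max_settings(self) -> dict[str, float]:
        return {name: 1.0 for name in self.levers}

    def model(
        self,
        params: Mapping[str, float] | None = None,
        multipliers: Mapping[str, float | np.ndarray] | None = None,
    ) -> DiseaseModel:
        return DiseaseModel(params or self.params, clock=self.clock, multipliers=multipliers)

    def base_trajectory(
        self, multipliers: Mapping[str, float | np.ndarray] | None = None
    ) -> Trajectory:
        return self.model(multipliers=multipliers).run()

    def run_with_multipliers(self, multipliers: Mapping[str, float | np.ndarray]) -> Trajectory:
        return self.model(multipliers=multipliers).run()

    def deaths_averted_runner(
        self,
        settings: Mapping[str, float] | None = None,
        window: tuple[int, int] = DEFAULT_WINDOW,
        outcome: str = "deaths_averted",
    ) -> Callable[[Mapping[str, float]], float]:
        """Runner for the one-way sweep: params -> cumulative outcome delta."""
        settings = dict(settings if settings is not None else self.all_max_settings)

        def runner(params: Mapping[str, float]) -> float:
            result = run_scenario(params, self.levers, settings, clock=self.clock, window=window)
            return result.deltas[outcome]

        return runner


def make_toy_nation(config: FixtureConfig | None = None) -> ToyNation:
    config = config or FixtureConfig()
    params = default_params(config.population)
    return ToyNation(
        config=config,
        params=params,
        levers=default_levers(),
        bounds=default_bounds(params),
    )


def _sample_years(measure: str, clock: SimulationClock) -> np.ndarray:
    """Table-1-style observation windows: biennial survey points for prevalence
    measures, annual series for counts and the post-CVD interview measures."""
    if MEASURE_KIND[measure] == "count" or measure.startswith("post_cvd"):
        return np.arange(clock.start_year, clock.start_year + 7)  # 2010-2016
    return np.array([clock.start_year + 1, clock.start_year + 3, clock.start_year + 5])


def planted_multiplier(config: FixtureConfig, measure: str, years: np.ndarray) -> np.ndarray:
    """Multiplier path planted on a measure's observations (1.0 if unplanned)."""
    if measure in config.deviators:
        mode, value = config.deviators[measure]
        if mode == "constant":
            return np.full(len(years), float(value))
        if mode == "drift":
            return np.exp(float(value) * (years - config.clock.start_year))
        raise DomainError(f"unknown deviator mode {mode!r} for {measure!r}")
    if measure in config.wobblers:
        amp = float(config.wobblers[measure])
        return 1.0 + amp * np.where(np.arange(len(years)) % 2 == 0, 1.0, -1.0)
    return np.ones(len(years))


_SOURCE_TAGS = {
    "count": "synthetic:vital-statistics",
    "percent": "synthetic:health-survey",
}


def make_surveillance_panel(
    config: FixtureConfig, trajectory: Trajectory
) -> dict[str, SurveillanceSeries]:
    """Synthetic observed series for all 25 measures.

    observations = model output x planted multiplier x lognormal noise.  The
    noise stream is spawned per measure from the seed, so changing the seed
    changes the noise but never the planted multipliers.
    """
    clock = config.clock
    panel: dict[str, SurveillanceSeries] = {}
    for idx, measure in enumerate(MEASURES):
        years = _sample_years(measure, clock)
        model = np.array([trajectory.series(measure)[clock.index(int(y))] for y in years])
        mult = planted_multiplier(config, measure, years)
        rng = np.random.default_rng([int(config.seed), idx])
        if config.noise > 0:
            sigma = config.noise
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(years))
        else:
            noise = np.ones(len(years))
        values = model * mult * noise
        kind = MEASURE_KIND[measure]
        if kind == "percent":
            values = np.clip(values, 0.0, 100.0)
        panel[measure] = SurveillanceSeries(
            measure=measure,
            years=years,
            values=values,
            kind=kind,
            source=_SOURCE_TAGS[kind],
        )
    return panel
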