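"""Epidemiological structure on top of the stock-flow engine.

The population is split into adults with no prior cardiovascular event
(``non_cvd``) and adults with at least one (``post_cvd``).  Non-CVD adults
experience first CVD events at a rate driven by risk-factor prevalences; a
case-fatality fraction die and the survivors move to ``post_cvd``, which
faces recurrent-event and death rates at least as high as the non-CVD rates.
Both compartments lose persons to non-CVD mortality and the non-CVD
compartment receives a net aging/in-migration inflow.

Risk factors enter event rates through an independent multiplicative
relative-risk combination normalized to a fixed reference prevalence, so the
base rate parameter is the rate when every prevalence sits at its reference
value.  Non-CVD outcome burdens (deaths, hospitalizations, disability) linked
to individual factors are reported with Levin attributable fractions applied
to fixed annual baseline totals; each reported measure carries a calibration
multiplier that scales only its own output series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import engine
from .engine import EXTERNAL, Flow, Parameter, SimulationClock, Stock, StockFlowSpec, Trajectory
from .errors import DomainError, SpecificationError

# --------------------------------------------------------------------------
# Measure catalogue (the reported output series)

PREVALENCE_MEASURES = [
    "youth_obesity",
    "adult_obesity",
    "current_smoker",
    "former_smoker",
    "secondhand_smoke",
    "high_bp",
    "borderline_bp",
    "high_chol",
    "borderline_chol",
    "diabetes",
    "prediabetes",
    "distress",
]

#: categories of one underlying factor whose prevalences must sum to <= 1
EXCLUSIVE_GROUPS = [
    ("current_smoker", "former_smoker"),
    ("high_bp", "borderline_bp"),
    ("high_chol", "borderline_chol"),
    ("diabetes", "prediabetes"),
]

#: attributed non-CVD outcome measures -> (exposure factor, outcome class)
ATTRIBUTION_MAP = {
    "smoking_noncvd_deaths": ("current_smoker", "noncvd_death"),
    "diabetes_noncvd_deaths": ("diabetes", "noncvd_death"),
    "distress_noncvd_deaths": ("distress", "noncvd_death"),
    "smoking_noncvd_hosp": ("current_smoker", "noncvd_hosp"),
    "diabetes_noncvd_hosp": ("diabetes", "noncvd_hosp"),
    "distress_noncvd_hosp": ("distress", "noncvd_hosp"),
}

#: non-CVD disability measures -> driving factor
DISABILITY_MAP = {
    "hypertension_disability": "high_bp",
    "smoking_disability": "current_smoker",
    "diabetes_disability": "diabetes",
    "obesity_disability": "adult_obesity",
}

MEASURES = (
    PREVALENCE_MEASURES
    + ["cvd_deaths", "post_cvd_prevalence", "post_cvd_disability"]
    + list(ATTRIBUTION_MAP)
    + list(DISABILITY_MAP)
)

MEASURE_KIND = {
    m: ("count" if m == "cvd_deaths" or m in ATTRIBUTION_MAP else "percent")
    for m in MEASURES
}


# --------------------------------------------------------------------------
# Risk-factor table and rate aggregation


@dataclass
class RiskFactorTable:
    """Per-factor prevalence paths, normalization references, and relative risks.

    ``prevalence[f]`` and ``reference[f]`` are fractions per simulated year;
    ``rr[(factor, outcome)]`` is the relative risk linking a factor to an
    outcome class ("cvd_event", "noncvd_death", "noncvd_hosp").
    """

    prevalence: dict[str, np.ndarray]
    reference: dict[str, np.ndarray]
    rr: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems: list[str] = []
        for name, path in self.prevalence.items():
            if np.any(path < 0) or np.any(path > 1):
                problems.append(f"prevalence of {name} outside [0, 1]")
        for a, b in EXCLUSIVE_GROUPS:
            if a in self.prevalence and b in self.prevalence:
                if np.any(self.prevalence[a] + self.prevalence[b] > 1 + 1e-12):
                    problems.append(f"exclusive categories {a}+{b} exceed 1")
        for (factor, outcome), value in self.rr.items():
            if not np.isfinite(value) or value < 0:
                problems.append(f"relative risk for ({factor}, {outcome}) not finite and >= 0")
        return problems


def event_rate(
    base_rate: float, factors: RiskFactorTable, outcome: str, t: int
) -> float:
    """Population-average event rate at year index ``t``.

    Multiplicative combination across factors, normalized so that the rate
    equals ``base_rate`` when every prevalence equals its reference value:

        rate = base * prod_f [1 + p_f(RR_f - 1)] / [1 + ref_f(RR_f - 1)]

    Monotone non-decreasing in each prevalence when its RR >= 1.
    """
    return float(event_rate_path(base_rate, factors, outcome)[t])


def event_rate_path(base_rate: float, factors: RiskFactorTable, outcome: str) -> np.ndarray:
    if base_rate < 0:
        raise DomainError(f"base_rate {base_rate} must be >= 0")
    n = None
    for path in factors.prevalence.values():
        n = len(path)
        break
    if n is None:
        return np.asarray([base_rate], dtype=float)
    rate = np.full(n, float(base_rate))
    for (factor, linked_outcome), rr in factors.rr.items():
        if linked_outcome != outcome or factor not in factors.prevalence:
            continue
        if rr < 0:
            raise DomainError(f"relative risk for {factor} is negative")
        p = factors.prevalence[factor]
        ref = factors.reference.get(factor, np.zeros(n))
        rate *= (1.0 + p * (rr - 1.0)) / (1.0 + ref * (rr - 1.0))
    return rate


def attributable_fraction(p, rr):
    """Levin population attributable fraction p(RR-1) / (1 + p(RR-1)).

    Accepts scalars or arrays for ``p``; ``rr`` must be >= 1 (protective
    exposures are not attributable).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("prevalence must lie in [0, 1]")
    if rr < 1:
        raise DomainError("protective exposures not attributable (rr < 1)")
    excess = p * (rr - 1.0)
    out = excess / (1.0 + excess)
    return float(out) if out.ndim == 0 else out


@dataclass
class AttributionSpec:
    """One attributed-outcome accounting rule.

    ``baseline`` is the annual total of the outcome; the attributed count is
    the attributable fraction of that total given the exposure's prevalence.
    """

    outcome: str
    factor: str
    rr: float
    baseline: float

    def __post_init__(self) -> None:
        if self.rr < 1:
            raise DomainError(f"attribution rr for {self.outcome} must be >= 1")
        if self.baseline < 0:
            raise DomainError(f"attribution baseline for {self.outcome} must be >= 0")


def attributed_outcomes(
    spec: AttributionSpec,
    factors: RiskFactorTable,
    t: int | None = None,
    multiplier: float | np.ndarray = 1.0,
):
    """Attributed outcome count per year: baseline * PAF(p_t, rr) * multiplier."""
    if spec.factor not in factors.prevalence:
        raise SpecificationError(
            f"attribution {spec.outcome!r} names missing exposure factor {spec.factor!r}"
        )
    p = factors.prevalence[spec.factor]
    counts = spec.baseline * attributable_fraction(p, spec.rr) * np.asarray(multiplier, dtype=float)
    if t is None:
        return counts
    return float(np.asarray(counts).flat[t]) if np.ndim(counts) else float(counts)


# --------------------------------------------------------------------------
# The integrated population model


@dataclass
class SubpopulationState:
    non_cvd: float
    post_cvd: float
    deaths_cvd: float = 0.0
    deaths_non_cvd: float = 0.0


_RATE_DEFAULTS = {
    "population": 1_000_000.0,
    "post0": 0.0,  # initial post-CVD share of the population
    "inflow": 0.0,  # net aging/in-migration, persons per year into non_cvd
    "cvd_event_rate0": 0.0,  # first-event rate at reference prevalences, /person/yr
    "cvd_case_fatality": 0.0,  # fraction of first events that are fatal
    "post_event_ratio": 1.0,  # recurrent-event rate ratio, >= 1
    "post_fatality_ratio": 1.0,  # recurrent-event fatality ratio, >= 1
    "noncvd_death_rate0": 0.0,  # non-CVD mortality at reference prevalences
    "noncvd_post_ratio": 1.0,  # non-CVD mortality ratio post- vs non-CVD, >= 1
    "quality_care_uptake": 0.0,  # lever-set fraction of events reached by upgraded care
    "quality_care_reach": 0.0,  # fatality-reduction scale of upgraded care
    "quality_care_effect": 0.0,  # effect size of quality acute/rehab care
    "youth_to_adult_transfer": 0.0,  # annual aging transfer of youth-obesity excess
    "adult_turnover": 0.0,  # annual decay of carried adult-obesity excess
}


class DiseaseModel:
    """Builds and runs the two-compartment model from a flat parameter mapping.

    Parameter keys: ``prev0.<factor>`` / ``trend.<factor>`` / ``ref.<factor>``
    for prevalence paths, ``rr.<factor>.<outcome>`` for relative risks,
    ``baseline.<measure>`` for attribution totals, ``disab.<measure>`` for
    disability link fractions, plus the scalar rates listed in
    ``_RATE_DEFAULTS``.  ``multipliers`` maps measure name to a calibration
    factor (scalar or per-year path) applied to that measure's reported
    series only.
    """

    def __init__(
        self,
        params: Mapping[str, float],
        clock: SimulationClock | None = None,
        multipliers: Mapping[str, float | np.ndarray] | None = None,
        factors: RiskFactorTable | None = None,
    ) -> None:
        self.params = dict(params)
        self.clock = clock or SimulationClock()
        self.multipliers = dict(multipliers or {})
        self._factors = factors

    # -- parameter access ---------------------------------------------------

    def rate(self, name: str) -> float:
        return float(self.params.get(name, _RATE_DEFAULTS[name]))

    def multiplier_path(self, measure: str) -> np.ndarray:
        value = np.asarray(self.multipliers.get(measure, 1.0), dtype=float)
        if value.ndim == 0:
            return np.full(self.clock.n_years, float(value))
        if len(value) != self.clock.n_years:
            raise SpecificationError(
                f"multiplier path for {measure!r} has length {len(value)}, "
                f"expected {self.clock.n_years}"
            )
        if np.any(value <= 0):
            raise DomainError(f"multiplier path for {measure!r} must be strictly positive")
        return value

    # -- risk-factor paths --------------------------------------------------

    @property
    def factor_table(self) -> RiskFactorTable:
        if self._factors is None:
            self._factors = self._build_factors()
        return self._factors

    def _linear_path(self, factor: str) -> np.ndarray:
        base = float(self.params.get(f"prev0.{factor}", 0.0))
        trend = float(self.params.get(f"trend.{factor}", 0.0))
        steps = np.arange(self.clock.n_years, dtype=float)
        return np.clip(base + trend * steps, 0.0, 1.0)

    def _build_factors(self) -> RiskFactorTable:
        n = self.clock.n_years
        prevalence: dict[str, np.ndarray] = {}
        reference: dict[str, np.ndarray] = {}
        for factor in PREVALENCE_MEASURES:
            prevalence[factor] = self._linear_path(factor)
            reference[factor] = np.full(n, float(self.params.get(f"ref.{factor}", 0.0)))
        # Youth obesity feeds adult obesity through an annual aging transfer:
        # the carried excess decays at the adult turnover rate while each
        # year's youth excess over its reference adds to it.
        transfer = self.rate("youth_to_adult_transfer")
        if transfer > 0 and "youth_obesity" in prevalence:
            turnover = self.rate("adult_turnover")
            youth_excess = prevalence["youth_obesity"] - reference["youth_obesity"]
            carry = np.zeros(n)
            for t in range(1, n):
                carry[t] = carry[t - 1] * (1.0 - turnover) + transfer * youth_excess[t - 1]
            prevalence["adult_obesity"] = np.clip(prevalence["adult_obesity"] + carry, 0.0, 1.0)
        rr: dict[tuple[str, str], float] = {}
        for key, value in self.params.items():
            if key.startswith("rr."):
                _, factor, outcome = key.split(".", 2)
                rr[(factor, outcome)] = float(value)
        return RiskFactorTable(prevalence=prevalence, reference=reference, rr=rr)

    # -- rate paths and stock-flow spec --------------------------------------

    def rate_paths(self) -> dict[str, np.ndarray]:
        factors = self.factor_table
        n = self.clock.n_years
        cvd_rate = event_rate_path(self.rate("cvd_event_rate0"), factors, "cvd_event")
        if len(cvd_rate) != n:
            cvd_rate = np.full(n, cvd_rate[0])
        ncd = event_rate_path(self.rate("noncvd_death_rate0"), factors, "noncvd_death")
        if len(ncd) != n:
            ncd = np.full(n, ncd[0])
        fatality_scale = 1.0 - (
            self.rate("quality_care_uptake")
            * self.rate("quality_care_reach")
            * self.rate("quality_care_effect")
        )
        fatality = np.clip(self.rate("cvd_case_fatality") * fatality_scale, 0.0, 1.0)
        return {
            "cvd_rate": cvd_rate,
            "cvd_fat": np.full(n, fatality),
            "post_rate": cvd_rate * self.rate("post_event_ratio"),
            "post_fat": np.clip(np.full(n, fatality) * self.rate("post_fatality_ratio"), 0.0, 1.0),
            "ncd_nc": ncd,
            "ncd_pc": ncd * self.rate("noncvd_post_ratio"),
        }

    def build_spec(self) -> StockFlowSpec:
        population = self.rate("population")
        post0 = self.rate("post0")
        paths = self.rate_paths()
        parameters = [Parameter(name, path) for name, path in paths.items()]
        parameters.append(Parameter("inflow", self.rate("inflow")))
        spec = StockFlowSpec(
            stocks=[
                Stock("non_cvd", population * (1.0 - post0)),
                Stock("post_cvd", population * post0),
            ],
            flows=[
                Flow("net_inflow", EXTERNAL, "non_cvd", "inflow"),
                Flow("first_events_fatal", "non_cvd", EXTERNAL, "cvd_rate * cvd_fat * non_cvd"),
                Flow(
                    "first_events_survive",
                    "non_cvd",
                    "post_cvd",
                    "cvd_rate * (1 - cvd_fat) * non_cvd",
                ),
                Flow("recurrent_fatal", "post_cvd", EXTERNAL, "post_rate * post_fat * post_cvd"),
                Flow("noncvd_deaths_nc", "non_cvd", EXTERNAL, "ncd_nc * non_cvd"),
                Flow("noncvd_deaths_pc", "post_cvd", EXTERNAL, "ncd_pc * post_cvd"),
            ],
            parameters=parameters,
        )
        spec.compile()
        return spec

    def attribution_specs(self) -> list[AttributionSpec]:
        specs = []
        for measure, (factor, outcome_class) in ATTRIBUTION_MAP.items():
            baseline = float(self.params.get(f"baseline.{measure}", 0.0))
            rr = float(self.params.get(f"rr.{factor}.{outcome_class}", 1.0))
            specs.append(AttributionSpec(measure, factor, max(rr, 1.0), baseline))
        return specs

    # -- full run -------------------------------------------------------------

    def run(self) -> Trajectory:
        traj = engine.simulate(self.build_spec(), self.clock)
        factors = self.factor_table
        paths = self.rate_paths()
        derived = traj.derived
        for factor in PREVALENCE_MEASURES:
            derived[factor] = 100.0 * factors.prevalence[factor] * self.multiplier_path(factor)
        total = traj.total_persons()
        alive = np.where(total > 0, total, 1.0)
        post_share = traj.stocks["post_cvd"] / alive
        derived["cvd_deaths"] = (
            traj.flows["first_events_fatal"] + traj.flows["recurrent_fatal"]
        ) * self.multiplier_path("cvd_deaths")
        derived["post_cvd_prevalence"] = (
            100.0 * post_share * self.multiplier_path("post_cvd_prevalence")
        )
        derived["post_cvd_disability"] = (
            100.0
            * post_share
            * float(self.params.get("disab.post_cvd_disability", 0.0))
            * self.multiplier_path("post_cvd_disability")
        )
        for spec in self.attribution_specs():
            derived[spec.outcome] = attributed_outcomes(
                spec, factors, multiplier=self.multiplier_path(spec.outcome)
            )
        for measure, factor in DISABILITY_MAP.items():
            derived[measure] = (
                100.0
                * factors.prevalence[factor]
                * float(self.params.get(f"disab.{measure}", 0.0))
                * self.multiplier_path(measure)
            )
        # bookkeeping series used for scenario differencing (no multipliers)
        derived["cvd_events"] = (
            traj.flows["first_events_fatal"]
            + traj.flows["first_events_survive"]
            + paths["post_rate"] * traj.stocks["post_cvd"]
        )
        derived["total_deaths"] = (
            traj.flows["first_events_fatal"]
            + traj.flows["recurrent_fatal"]
            + traj.flows["noncvd_deaths_nc"]
            + traj.flows["noncvd_deaths_pc"]
        )
        return traj


def advance_population(
    state: SubpopulationState,
    params: Mapping[str, float],
    year: int = 2010,
    clock: SimulationClock | None = None,
    factors: RiskFactorTable | None = None,
) -> SubpopulationState:
    """Advance the two-compartment population by one year.

    Delegates to the engine's step on the stock-flow spec the model builds,
    so the standalone operation and the full simulation share one code path.
    """
    model = DiseaseModel(params, clock=clock, factors=factors)
    spec = model.build_spec()
    t = model.clock.index(year)
    levels = {"non_cvd": state.non_cvd, "post_cvd": state.post_cvd}
    nxt, rates, _ = engine.step(levels, spec, year, t)
    return SubpopulationState(
        non_cvd=nxt["non_cvd"],
        post_cvd=nxt["post_cvd"],
        deaths_cvd=rates["first_events_fatal"] + rates["recurrent_fatal"],
        deaths_non_cvd=rates["noncvd_deaths_nc"] + rates["noncvd_deaths_pc"],
    )
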