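"""One-way sensitivity analysis over parameter bounds, with tornado ordering.

Each parameter is varied alone between its lowest and highest plausible
value, all others held at defaults; the focal outcome's relative change is
recorded against a single shared base run.  Influence is the maximum
absolute relative change over the two bound runs; records at or above the
influence threshold (default 0.5%) form the tornado set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import math

from .errors import DomainError

#: default influence threshold: relative change of 0.5% or more
INFLUENCE_THRESHOLD = 0.005


@dataclass(frozen=True)
class ParameterBound:
    """Plausible range for one parameter: low <= default <= high, all finite."""

    parameter: str
    default: float
    low: float
    high: float
    note: str = ""

    def __post_init__(self) -> None:
        values = (self.default, self.low, self.high)
        if not all(math.isfinite(v) for v in values):
            raise DomainError(f"bound for {self.parameter!r} has non-finite values")
        if not self.low <= self.default <= self.high:
            raise DomainError(
                f"bound for {self.parameter!r} violates low <= default <= high: "
                f"{self.low}, {self.default}, {self.high}"
            )


@dataclass
class SensitivityRecord:
    """Low/high bound runs for one parameter and relative changes vs the base run.

    ``change_low``/``change_high`` are relative fractions (0.046 = +4.6%);
    ``influence`` is the maximum of their absolute values.
    """

    parameter: str
    outcome: str
    base: float
    low_value: float = math.nan
    high_value: float = math.nan
    change_low: float = math.nan
    change_high: float = math.nan
    influence: float = math.nan
    failed: bool = False
    message: str = ""


def one_way(
    runner: Callable[[Mapping[str, float]], float],
    defaults: Mapping[str, float],
    bounds: Sequence[ParameterBound],
    outcome: str = "outcome",
) -> list[SensitivityRecord]:
    """Run the one-way sweep; order of ``bounds`` is preserved in the output.

    ``runner`` maps a full parameter mapping to the focal outcome value (the
    scenario settings are baked into the runner).  The shared base run is
    computed exactly once.  A failing bound run produces a flagged record and
    the sweep continues.
    """
    base = float(runner(defaults))
    records: list[SensitivityRecord] = []
    for bound in bounds:
        record = SensitivityRecord(parameter=bound.parameter, outcome=outcome, base=base)
        try:
            low_params = {**defaults, bound.parameter: bound.low}
            high_params = {**defaults, bound.parameter: bound.high}
            record.low_value = float(runner(low_params))
            record.high_value = float(runner(high_params))
        except Exception as exc:  # noqa: BLE001 - sweep must be restartable/auditable
            record.failed = True
            record.message = f"{type(exc).__name__}: {exc}"
            records.append(record)
            continue
        if base == 0.0:
            record.failed = True
            record.message = "base outcome is zero; relative change undefined"
            records.append(record)
            continue
        record.change_low = (record.low_value - base) / base
        record.change_high = (record.high_value - base) / base
        record.influence = max(abs(record.change_low), abs(record.change_high))
        records.append(record)
    return records


def influential(
    records: Iterable[SensitivityRecord], threshold: float = INFLUENCE_THRESHOLD
) -> list[SensitivityRecord]:
    """Records with influence >= threshold, in tornado order.

    Sorted descending by influence; ties broken alphabetically by parameter
    name.  Flagged records never qualify.
    """
    kept = [
        r
        for r in records
        if not r.failed and not math.isnan(r.influence) and r.influence >= threshold
    ]
    return sorted(kept, key=lambda r: (-r.influence, r.parameter))


def tornado_table(records: Sequence[SensitivityRecord]) -> dict:
    """Export record for a horizontal-bar (tornado) chart.

    Rows are ordered by influence descending; metadata carries the focal
    outcome name and the shared base-run value used as the denominator.
    """
    if not records:
        raise DomainError("tornado_table requires at least one record")
    ordered = sorted(
        [r for r in records if not r.failed],
        key=lambda r: (-(r.influence if not math.isnan(r.influence) else -1.0), r.parameter),
    )
    return {
        "outcome": records[0].outcome,
        "base_outcome": records[0].base,
        "rows": [
            {
                "parameter": r.parameter,
                "change_low": r.change_low,
                "change_high": r.change_high,
                "influence": r.influence,
            }
            for r in ordered
        ],
    }
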