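"""Route-specific dose schedules.

Oral intake is delivered as meal-time boluses infused at constant rate
over 30 minutes into the gut lumen (absorbed first-order at kgut);
dermal and inhalation exposures are continuous infusions into skin and
lung tissue respectively.  All events are piecewise-constant rates on
half-open intervals [start, start + duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROUTES",
    "ROUTE_TARGETS",
    "DoseEvent",
    "DoseSchedule",
    "oral_schedule",
    "continuous_dose",
    "input_rate",
    "DEFAULT_ORAL_TOTAL_MG",
    "DEFAULT_MEAL_RATIOS",
    "DEFAULT_MEAL_TIMES_H",
    "DEFAULT_MEAL_DURATION_H",
    "DEFAULT_DERMAL_RATE_MG_PER_H",
    "DEFAULT_INHALATION_RATE_MG_PER_H",
]

ROUTES = ("oral", "dermal", "inhalation")

#: Compartment each route delivers into.
ROUTE_TARGETS = {"oral": "gut_lumen", "dermal": "skin", "inhalation": "lungs"}

DEFAULT_ORAL_TOTAL_MG = 1.95
DEFAULT_MEAL_RATIOS = (0.5, 0.8, 0.65)
DEFAULT_MEAL_TIMES_H = (8.0, 12.0, 18.0)
DEFAULT_MEAL_DURATION_H = 0.5
DEFAULT_DERMAL_RATE_MG_PER_H = 0.68
DEFAULT_INHALATION_RATE_MG_PER_H = 0.53


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate input on [start, start + duration)."""

    route: str
    start_h: float
    duration_h: float
    amount_mg: float

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.amount_mg < 0:
            raise ValueError("amount_mg must be >= 0")

    @property
    def rate_mg_per_h(self) -> float:
        return self.amount_mg / self.duration_h

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h

    def active(self, t: float) -> bool:
        return self.start_h <= t < self.end_h


@dataclass
class DoseSchedule:
    """An ordered collection of dose events (order is immaterial:
    simultaneous events sum)."""

    events: list[DoseEvent] = field(default_factory=list)
    days: int = 1

    def input_rate(self, t: float) -> dict[str, float]:
        """Instantaneous input rate per route at time ``t`` (mg/h)."""
        rates = dict.fromkeys(ROUTES, 0.0)
        for e in self.events:
            if e.active(t):
                rates[e.route] += e.rate_mg_per_h
        return rates

    def total_by_route(self) -> dict[str, float]:
        totals = dict.fromkeys(ROUTES, 0.0)
        for e in self.events:
            totals[e.route] += e.amount_mg
        return totals

    def cumulative_input_mg(self, t: float | np.ndarray) -> np.ndarray | float:
        """Exact cumulative input over all routes up to time ``t``."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for e in self.events:
            active_time = np.clip(t - e.start_h, 0.0, e.duration_h)
            total += e.rate_mg_per_h * active_time
        return total if total.ndim else float(total)

    def boundaries(self, t_end: float) -> np.ndarray:
        """Sorted unique event on/off times within [0, t_end]."""
        pts = {0.0, float(t_end)}
        for e in self.events:
            for p in (e.start_h, e.end_h):
                if 0.0 < p < t_end:
                    pts.add(float(p))
        return np.array(sorted(pts))

    def merged(self, other: "DoseSchedule") -> "DoseSchedule":
        return DoseSchedule(events=self.events + other.events,
                            days=max(self.days, other.days))


def oral_schedule(
    total_mg_per_day: float = DEFAULT_ORAL_TOTAL_MG,
    ratios: tuple[float, ...] = DEFAULT_MEAL_RATIOS,
    meal_times_h: tuple[float, ...] = DEFAULT_MEAL_TIMES_H,
    duration_h: float = DEFAULT_MEAL_DURATION_H,
    days: int = 1,
) -> DoseSchedule:
    """Daily meal-bolus schedule.

    The default reproduces the study diet: 1.95 mg/day split
    0.5 : 0.8 : 0.65 over breakfast (8 h), lunch (12 h) and supper
    (18 h), each infused over 30 min.
    """
    if len(ratios) != len(meal_times_h):
        raise ValueError("ratios and meal_times_h must have equal length")
    if total_mg_per_day <= 0:
        raise ValueError("total_mg_per_day must be > 0")
    if any(not (0 <= m < 24) for m in meal_times_h):
        raise ValueError("meal times must lie in [0, 24)")
    if days < 0:
        raise ValueError("days must be >= 0")

    ratio_sum = sum(ratios)
    amounts = [total_mg_per_day * r / ratio_sum for r in ratios]
    events = [
        DoseEvent("oral", 24.0 * day + m, duration_h, a)
        for day in range(days)
        for m, a in zip(meal_times_h, amounts)
    ]
    return DoseSchedule(events=events, days=days)


def continuous_dose(route: str, rate_mg_per_h: float, t_end_h: float) -> DoseSchedule:
    """One constant infusion covering [0, t_end_h)."""
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    if rate_mg_per_h < 0:
        raise ValueError("rate_mg_per_h must be >= 0")
    if t_end_h <= 0:
        raise ValueError("t_end_h must be > 0")
    event = DoseEvent(route, 0.0, t_end_h, rate_mg_per_h * t_end_h)
    return DoseSchedule(events=[event], days=max(1, int(np.ceil(t_end_h / 24.0))))


def input_rate(schedule: DoseSchedule, t: float) -> dict[str, float]:
    """Module-level convenience wrapper around ``schedule.input_rate``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return schedule.input_rate(t)
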