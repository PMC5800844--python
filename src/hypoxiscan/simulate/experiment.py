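"""Stepped-oxygen contraction experiments with known truth.

The generator emulates the flow-through respirometry setup: a stepped
%air-saturation schedule (e.g. 100 → 10 → 5 → 2 → 0.25 %AS held for many
hours each), dissolved O2 sampled every 30 s with first-order relaxation
between steps, and a projected-area trace in which contraction events
appear as smooth dips.  Events are drawn from a Poisson process whose rate
may depend on the O2 level, thinned to enforce a 20-minute refractory gap
so that contraction cycles never overlap.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from hypoxiscan.oxygen import OxygenConditions, percent_as_to_uM

__all__ = [
    "PlannedEvent",
    "ExperimentTruth",
    "make_experiment_truth",
    "simulate_experiment",
]

#: minimum gap between the end of one event and the onset of the next
REFRACTORY_S = 20.0 * 60.0

#: amplitude conventions for the two contraction classes
FULL_BODY_AMPLITUDE = (0.55, 0.75)
SUB_AMPLITUDE = (0.15, 0.40)


@dataclass(frozen=True)
class PlannedEvent:
    onset_s: float
    duration_s: float
    amplitude: float  # relative area reduction at trough, in (0, 1)
    klass: str  # "full_body" | "sub"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def trough_s(self) -> float:
        return self.onset_s + self.duration_s / 2.0


@dataclass
class ExperimentTruth:
    """Everything needed to render (and to grade) one experiment."""

    schedule: tuple[tuple[float, float], ...]  # (duration_hr, percent_AS)
    events: tuple[PlannedEvent, ...]
    rates_per_day: dict[float, float]  # percent_AS -> full-body events/day
    sub_rates_per_day: dict[float, float]
    noise_sd: float  # area noise, px
    o2_noise_sd: float  # O2 noise, µM
    seed: int
    baseline_area_px: float = 5000.0
    cadence_s: float = 30.0
    o2_tau_s: float = 1800.0
    event_duration_s: float = 720.0
    conditions: OxygenConditions = field(
        default_factory=lambda: OxygenConditions(26.0, 32.0)
    )

    def __post_init__(self) -> None:
        if not self.schedule or sum(d for d, _ in self.schedule) <= 0:
            raise ValueError("schedule must have positive total duration")
        for _, pct in self.schedule:
            if not (0.0 <= pct <= 100.0):
                raise ValueError("percent AS must be in [0, 100]")
        for lam in list(self.rates_per_day.values()) + list(
            self.sub_rates_per_day.values()
        ):
            if lam < 0:
                raise ValueError("event rates must be >= 0")

    @property
    def total_s(self) -> float:
        return sum(d for d, _ in self.schedule) * 3600.0

    def level_at(self, t_s: float) -> float:
        """Scheduled %AS level at time t."""
        acc = 0.0
        for dur_hr, pct in self.schedule:
            acc += dur_hr * 3600.0
            if t_s < acc:
                return pct
        return self.schedule[-1][1]


def make_experiment_truth(
    schedule: tuple[tuple[float, float], ...],
    rates_per_day: Mapping[float, float] | float,
    seed: int,
    sub_rates_per_day: Mapping[float, float] | float = 0.0,
    noise_sd: float = 0.0,
    o2_noise_sd: float = 0.0,
    baseline_area_px: float = 5000.0,
    event_duration_s: float = 720.0,
    events: Optional[tuple[PlannedEvent, ...]] = None,
) -> ExperimentTruth:
    """Draw the true event list for a stepped-O2 schedule.

    ``rates_per_day`` is either a single rate or a mapping %AS -> rate for
    full-body contractions (``sub_rates_per_day`` likewise for
    sub-contractions).  Pass ``events`` explicitly to plant a fixed list
    instead of drawing one.
    """
    levels = sorted({pct for _, pct in schedule})

    def as_map(r) -> dict[float, float]:
        if isinstance(r, Mapping):
            return {float(k): float(v) for k, v in r.items()}
        return {lvl: float(r) for lvl in levels}

    rates = as_map(rates_per_day)
    sub_rates = as_map(sub_rates_per_day)
    rng = random.Random(seed)
    if events is None:
        events = _draw_events(schedule, rates, sub_rates, event_duration_s, rng)
    return ExperimentTruth(
        schedule=tuple(schedule),
        events=events,
        rates_per_day=rates,
        sub_rates_per_day=sub_rates,
        noise_sd=noise_sd,
        o2_noise_sd=o2_noise_sd,
        seed=seed,
        baseline_area_px=baseline_area_px,
        event_duration_s=event_duration_s,
    )


def _draw_events(
    schedule,
    rates: dict[float, float],
    sub_rates: dict[float, float],
    duration_s: float,
    rng: random.Random,
) -> tuple[PlannedEvent, ...]:
    arrivals: list[tuple[float, str]] = []
    t0 = 0.0
    for dur_hr, pct in schedule:
        seg_s = dur_hr * 3600.0
        for klass, rate_map in (("full_body", rates), ("sub", sub_rates)):
            lam_per_s = rate_map.get(pct, 0.0) / 86400.0
            if lam_per_s <= 0:
                continue
            t = t0
            while True:
                t += rng.expovariate(lam_per_s)
                if t >= t0 + seg_s:
                    break
                arrivals.append((t, klass))
        t0 += seg_s
    arrivals.sort()
    events: list[PlannedEvent] = []
    last_end = -math.inf
    for onset, klass in arrivals:
        if onset < last_end + REFRACTORY_S:
            continue  # refractory thinning
        lo, hi = FULL_BODY_AMPLITUDE if klass == "full_body" else SUB_AMPLITUDE
        amp = rng.uniform(lo, hi)
        if onset + duration_s > t0:
            continue  # event would run past the experiment end
        events.append(PlannedEvent(onset, duration_s, amp, klass))
        last_end = onset + duration_s
    return tuple(events)


def _dip_factor(t: float, events: tuple[PlannedEvent, ...]) -> float:
    for ev in events:
        if ev.onset_s <= t <= ev.end_s:
            phase = (t - ev.onset_s) / ev.duration_s
            return 1.0 - ev.amplitude * 0.5 * (1.0 - math.cos(2.0 * math.pi * phase))
    return 1.0


def simulate_experiment(
    truth: ExperimentTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the area and O2 traces for one experiment.

    Returns two DataFrames with columns (timestamp_s, value): projected
    area in px and dissolved O2 in µM, both at the truth's cadence.
    """
    if truth.cadence_s <= 0:
        raise ValueError("cadence must be > 0")
    n = int(truth.total_s // truth.cadence_s) + 1
    ts = np.arange(n) * truth.cadence_s
    rng = np.random.default_rng(truth.seed)

    area = np.array(
        [truth.baseline_area_px * _dip_factor(t, truth.events) for t in ts]
    )
    if truth.noise_sd > 0:
        area = area + rng.normal(0.0, truth.noise_sd, size=n)

    targets = np.array(
        [percent_as_to_uM(truth.level_at(t), truth.conditions) for t in ts]
    )
    o2 = np.empty(n)
    o2[0] = targets[0]
    decay = math.exp(-truth.cadence_s / truth.o2_tau_s)
    for i in range(1, n):
        o2[i] = targets[i] + (o2[i - 1] - targets[i]) * decay
    if truth.o2_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, truth.o2_noise_sd, size=n)
    o2 = np.clip(o2, 0.0, None)

    area_df = pd.DataFrame({"timestamp_s": ts, "value": area})
    o2_df = pd.DataFrame({"timestamp_s": ts, "value": o2})
    return area_df, o2_df
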