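"""Appointment schedules and stochastic patient arrivals.

Both clinic types run a fixed appointment book over an eight-hour day
(480 minutes, clock 0 = opening): mass vaccination hubs issue appointments
on the hour (8 hourly slots), GP clinics every ten minutes (48 slots).
Realised arrival times add random noise to the booked slot time — most
people turn up somewhat early, a small fraction on time or late — and a
small proportion of bookings (2% by default) never show up.

One vaccine dose is demanded per *booking* and released into the parallel
preparation queue at the slot start time: preparation staff work from the
appointment book and cannot foresee no-shows, so doses prepared for
absentees show up downstream as wastage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .distributions import ConfigurationError, DistributionSpec, normal

__all__ = [
    "AppointmentSchedule",
    "ArrivalSpec",
    "ArrivalSet",
    "build_schedule",
    "increment_schedule",
    "generate_arrivals",
    "generate_dose_demand",
    "DEFAULT_NOISE",
]

CLINIC_MINUTES = 480  # eight-hour clinic day

#: booked-slot offsets: arrival = slot + noise, so a mean of -10 minutes
#: puts the median patient 10 minutes early, with ~2.3% arriving on or late
DEFAULT_NOISE = normal(-10.0, 5.0)

#: appointments issued per slot, by site and capacity level
BOOKING_LEVELS = {
    "hub": {"low": 60, "medium": 120, "high": 180},
    "gp": {"low": 2, "medium": 4, "high": 6},
}
SLOT_INTERVALS = {"hub": 60, "gp": 10}


@dataclass(frozen=True)
class AppointmentSchedule:
    """A day's appointment book: equally spaced slots, equal bookings each."""

    slot_interval: float  # minutes between slot starts
    n_slots: int
    bookings_per_slot: int
    clinic_open: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slots < 0 or self.bookings_per_slot < 0:
            raise ConfigurationError("n_slots and bookings_per_slot must be >= 0")
        if self.slot_interval <= 0:
            raise ConfigurationError("slot_interval must be > 0")

    @property
    def slot_times(self) -> np.ndarray:
        """Slot start times in minutes from clinic open."""
        return self.clinic_open + self.slot_interval * np.arange(self.n_slots)

    @property
    def total_bookings(self) -> int:
        return self.n_slots * self.bookings_per_slot

    def booking_slot_times(self) -> np.ndarray:
        """One entry per booking: the slot time of each booked patient."""
        return np.repeat(self.slot_times, self.bookings_per_slot)


@dataclass(frozen=True)
class ArrivalSpec:
    """Arrival noise distribution and the no-show probability."""

    noise: DistributionSpec = DEFAULT_NOISE
    no_show_prob: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.no_show_prob <= 1.0:
            raise ConfigurationError(
                f"no_show_prob must be in [0, 1], got {self.no_show_prob}"
            )


@dataclass(frozen=True)
class ArrivalSet:
    """Realised bookings for one simulated day.

    ``patients`` has one row per booking — columns ``patient_id``,
    ``slot_time``, ``arrival_time`` (NaN for no-shows) and ``attended`` —
    sorted so that attended patients appear in arrival order.
    """

    patients: pd.DataFrame

    @property
    def attended(self) -> pd.DataFrame:
        """Attended patients only, in non-decreasing arrival order."""
        return self.patients[self.patients["attended"]]

    @property
    def n_attended(self) -> int:
        return int(self.patients["attended"].sum())

    @property
    def n_bookings(self) -> int:
        return len(self.patients)


def build_schedule(
    site: str,
    level: str | None = None,
    bookings_per_slot: int | None = None,
) -> AppointmentSchedule:
    """Appointment book for a site at a named capacity level.

    ``level`` picks the published booking density (hub: 60/120/180 per hour;
    GP: 2/4/6 per ten-minute slot); an explicit ``bookings_per_slot``
    overrides it.
    """
    if site not in SLOT_INTERVALS:
        raise ConfigurationError(f"unknown site {site!r}; expected 'hub' or 'gp'")
    interval = SLOT_INTERVALS[site]
    if bookings_per_slot is None:
        if level not in BOOKING_LEVELS[site]:
            raise ConfigurationError(
                f"unknown level {level!r}; expected 'low', 'medium' or 'high'"
            )
        bookings_per_slot = BOOKING_LEVELS[site][level]
    if bookings_per_slot < 0:
        raise ConfigurationError("bookings_per_slot must be >= 0")
    return AppointmentSchedule(
        slot_interval=interval,
        n_slots=CLINIC_MINUTES // interval,
        bookings_per_slot=int(bookings_per_slot),
    )


def increment_schedule(
    schedule: AppointmentSchedule, extra_per_slot: int
) -> AppointmentSchedule:
    """Add ``extra_per_slot`` bookings to every slot (what-if demand surge)."""
    if extra_per_slot < 0:
        raise ValueError(f"extra_per_slot must be >= 0, got {extra_per_slot}")
    return replace(
        schedule, bookings_per_slot=schedule.bookings_per_slot + int(extra_per_slot)
    )


def generate_arrivals(
    schedule: AppointmentSchedule,
    spec: ArrivalSpec,
    rng: np.random.Generator,
) -> ArrivalSet:
    """Realise one day of arrivals from the appointment book.

    Every booking independently attends with probability
    ``1 - no_show_prob``.  An attendee's arrival time is its slot time plus
    a noise draw, clamped below at clinic open (early birds wait at the
    door).  No-shows keep their booking row with a NaN arrival.
    """
    slot_times = schedule.booking_slot_times()
    n = len(slot_times)
    attended = rng.random(n) >= spec.no_show_prob
    # raw draws (not sample_service_times): arrival offsets may be negative
    noise = spec.noise.shift + np.asarray(
        spec.noise._frozen().rvs(size=n, random_state=rng), dtype=float
    )
    arrival = np.maximum(schedule.clinic_open, slot_times + noise)
    arrival[~attended] = np.nan

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "slot_time": slot_times,
            "arrival_time": arrival,
            "attended": attended,
        }
    )
    # attended patients in arrival order first; no-shows trail in id order
    df = df.sort_values(
        ["attended", "arrival_time", "patient_id"],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return ArrivalSet(patients=df)


def generate_dose_demand(
    schedule: AppointmentSchedule, lead_time: float = 0.0
) -> np.ndarray:
    """Dose-request release times for the preparation queue.

    One dose per booking, released ``lead_time`` minutes before its slot's
    start (never before clinic open): the preparation team works from the
    appointment book, drawing up doses ahead of each appointment block.
    Sorted non-decreasing.
    """
    if lead_time < 0:
        raise ValueError(f"lead_time must be >= 0, got {lead_time}")
    release = np.maximum(schedule.clinic_open, schedule.booking_slot_times() - lead_time)
    return np.sort(release)
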