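"""The two published clinic layouts and their staffing presets.

A mass vaccination hub routes patients through five stations — Entrance,
Registration, Assessment, Vaccination, Observation — with a short walking
lag between stations and a parallel dose-preparation queue joining at
Vaccination.  A GP clinic compresses the same tasks into three stations —
Registration, Vaccination, Observation — with negligible walking time.
Observation "servers" are seats, not staff, and the staff supervising the
observation area are not counted in staffing totals.

Each site ships three staffing levels (low / medium / high) whose
station-to-station staff ratios are identical — e.g. a hub always has three
registration staff per preparation staff member — so sites of different
size are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

from .distributions import (
    ConfigurationError,
    DistributionSpec,
    ObservationMixtureSpec,
    normal,
    shifted_exponential,
    uniform,
)
from .queue_engine import LagSpec

__all__ = [
    "StationConfig",
    "NetworkConfig",
    "InfeasibleScenarioError",
    "make_hub_network",
    "make_gp_network",
    "reduce_staff",
    "HUB_SERVICES",
    "GP_SERVICES",
    "OBSERVATION_MIXTURE",
    "DEFAULT_WALK_LAG",
]


class InfeasibleScenarioError(ValueError):
    """Raised when a scenario edit would leave a station unstaffed."""


ServiceSpec = Union[DistributionSpec, ObservationMixtureSpec]


@dataclass(frozen=True)
class StationConfig:
    """One station: a name, a server count, and a service-time spec."""

    name: str
    n_servers: int
    service: ServiceSpec

    def __post_init__(self) -> None:
        if self.n_servers < 1:
            raise ConfigurationError(
                f"station {self.name!r} needs at least 1 server, got {self.n_servers}"
            )


@dataclass(frozen=True)
class NetworkConfig:
    """A complete queue network: patient path, preparation queue, seats, lag."""

    site: str
    patient_stations: tuple[StationConfig, ...]  # last one is observation
    prep_station: StationConfig
    walk_lag: LagSpec | None = None
    join_before: str = "vaccination"

    @property
    def observation(self) -> StationConfig:
        return self.patient_stations[-1]

    @property
    def staffed_stations(self) -> tuple[StationConfig, ...]:
        """Stations whose servers are staff: preparation + all but observation."""
        return (self.prep_station,) + self.patient_stations[:-1]

    @property
    def total_staff(self) -> int:
        return sum(s.n_servers for s in self.staffed_stations)

    @property
    def staffing(self) -> dict[str, int]:
        return {s.name: s.n_servers for s in self.staffed_stations}

    def with_staffing(self, staffing: dict[str, int]) -> "NetworkConfig":
        """Copy with server counts replaced per the given name -> count map."""
        unknown = set(staffing) - {s.name for s in self.staffed_stations}
        if unknown:
            raise ConfigurationError(f"unknown station(s) in staffing: {sorted(unknown)}")

        def edit(st: StationConfig) -> StationConfig:
            if st.name in staffing:
                return replace(st, n_servers=int(staffing[st.name]))
            return st

        return replace(
            self,
            prep_station=edit(self.prep_station),
            patient_stations=tuple(
                edit(s) if s.name != self.observation.name else s
                for s in self.patient_stations
            ),
        )


# Service-time assumptions (minutes): fixed minimum + exponential tail,
# reflecting that most patients are quick and a minority take much longer.
HUB_SERVICES: dict[str, DistributionSpec] = {
    "preparation": shifted_exponential(1.0, 3.0),
    "entrance": shifted_exponential(2.0, 1.0),
    "registration": shifted_exponential(3.0, 0.7),
    "assessment": shifted_exponential(2.0, 1.0),
    "vaccination": shifted_exponential(3.0, 1.0),
}
GP_SERVICES: dict[str, DistributionSpec] = {
    "preparation": shifted_exponential(1.0, 3.0),
    "registration": shifted_exponential(3.0, 1.0),
    "vaccination": shifted_exponential(5.0, 0.5),
}
#: bimodal observation stay: ~20 min for most, 20 + Exp(0.1) after an
#: adverse reaction (2% of patients)
OBSERVATION_MIXTURE = ObservationMixtureSpec(
    main=normal(20.0, 0.5),
    adverse=shifted_exponential(20.0, 0.1),
    adverse_prob=0.02,
)

#: hub walking time between consecutive stations; GP walking is negligible
DEFAULT_WALK_LAG = LagSpec(uniform(0.5, 2.0))

#: staff per station (and observation seats) by capacity level
HUB_STAFFING = {
    "low": {"preparation": 2, "entrance": 4, "registration": 6, "assessment": 4, "vaccination": 5},
    "medium": {"preparation": 4, "entrance": 8, "registration": 12, "assessment": 8, "vaccination": 10},
    "high": {"preparation": 6, "entrance": 12, "registration": 18, "assessment": 12, "vaccination": 15},
}
HUB_SEATS = {"low": 25, "medium": 50, "high": 75}
GP_STAFFING = {
    "low": {"preparation": 1, "registration": 1, "vaccination": 2},
    "medium": {"preparation": 2, "registration": 2, "vaccination": 4},
    "high": {"preparation": 3, "registration": 3, "vaccination": 6},
}
GP_SEATS = {"low": 5, "medium": 10, "high": 15}


def _check_level(level: str, table: dict) -> None:
    if level not in table:
        raise ConfigurationError(
            f"unknown staffing level {level!r}; expected 'low', 'medium' or 'high'"
        )


def make_hub_network(
    level: str,
    adverse_prob: float = 0.02,
    walk_lag: LagSpec | None = DEFAULT_WALK_LAG,
) -> NetworkConfig:
    """Mass-vaccination-hub network at a named staffing level."""
    _check_level(level, HUB_STAFFING)
    staff = HUB_STAFFING[level]
    obs = replace(OBSERVATION_MIXTURE, adverse_prob=adverse_prob)
    stations = tuple(
        StationConfig(name, staff[name], HUB_SERVICES[name])
        for name in ("entrance", "registration", "assessment", "vaccination")
    ) + (StationConfig("observation", HUB_SEATS[level], obs),)
    return NetworkConfig(
        site="hub",
        patient_stations=stations,
        prep_station=StationConfig("preparation", staff["preparation"], HUB_SERVICES["preparation"]),
        walk_lag=walk_lag,
    )


def make_gp_network(level: str, adverse_prob: float = 0.02) -> NetworkConfig:
    """GP-clinic network at a named staffing level (no walking lag)."""
    _check_level(level, GP_STAFFING)
    staff = GP_STAFFING[level]
    obs = replace(OBSERVATION_MIXTURE, adverse_prob=adverse_prob)
    stations = (
        StationConfig("registration", staff["registration"], GP_SERVICES["registration"]),
        StationConfig("vaccination", staff["vaccination"], GP_SERVICES["vaccination"]),
        StationConfig("observation", GP_SEATS[level], obs),
    )
    return NetworkConfig(
        site="gp",
        patient_stations=stations,
        prep_station=StationConfig("preparation", staff["preparation"], GP_SERVICES["preparation"]),
        walk_lag=None,
    )


def reduce_staff(network: NetworkConfig, k: int) -> NetworkConfig:
    """Remove ``k`` staff, spread to preserve the network's shape.

    Staff are removed one at a time in passes: within each pass every
    station loses at most one member, visited in descending order of
    current server count (ties go to the station later on the patient
    path), skipping stations already down to a single server.  No station
    may drop below one server.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    staffing = network.staffing
    removable = sum(c - 1 for c in staffing.values())
    if k > removable:
        raise InfeasibleScenarioError(
            f"cannot remove {k} staff: only {removable} removable before a "
            "station drops below 1 server"
        )
    # position on the patient path (prep treated as position -1, reduced last
    # among ties by the later-position rule below favouring later stations)
    position = {s.name: i for i, s in enumerate(network.patient_stations)}
    position[network.prep_station.name] = -1

    remaining = k
    while remaining > 0:
        candidates = sorted(
            (name for name, c in staffing.items() if c > 1),
            key=lambda name: (-staffing[name], -position[name]),
        )
        for name in candidates:
            if remaining == 0:
                break
            staffing[name] -= 1
            remaining -= 1
    return network.with_staffing(staffing)
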