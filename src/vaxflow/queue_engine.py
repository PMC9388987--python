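"""Core queueing computation.

The building block is :func:`queue_step`: customers sorted by arrival time
are assigned to the earliest-free of ``c`` identical servers on a
first-come-first-served basis.  Because customers are processed in arrival
order, each assignment needs only the current server free times, so a whole
station resolves in one pass over a heap — no event calendar required.

A clinic is a chain of such steps.  Between hub stations a stochastic
walking *lag* (a delay that consumes time but no server) shifts each
patient's ready time, after which patients are re-ranked — FCFS applies at
each station on that station's arrival order.  The dose-preparation queue
runs in parallel off the appointment book and joins the patient stream at
vaccination: the i-th patient to reach the vaccination queue consumes the
i-th prepared dose, waiting for it if necessary (fork/join).  The
observation area is a queue whose "servers" are seats.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .arrivals import ArrivalSet
from .distributions import DistributionSpec, sample_observation, sample_service_times

if TYPE_CHECKING:  # pragma: no cover
    from .networks import NetworkConfig

__all__ = [
    "QueueStepResult",
    "LagSpec",
    "PatientLog",
    "InsufficientResourceError",
    "queue_step",
    "apply_lag",
    "fork_join",
    "simulate_network",
]


class InsufficientResourceError(RuntimeError):
    """Raised when the join runs out of prepared doses."""


@dataclass(frozen=True)
class QueueStepResult:
    """Per-customer outcome of one station, in station-arrival order."""

    arrival: np.ndarray
    start: np.ndarray
    departure: np.ndarray
    server: np.ndarray  # index of the serving server (0-based)

    @property
    def wait(self) -> np.ndarray:
        return self.start - self.arrival


@dataclass(frozen=True)
class LagSpec:
    """A serverless inter-station delay (walking time)."""

    spec: DistributionSpec

    def __post_init__(self) -> None:
        lo = quantile_floor(self.spec)
        if lo < 0:
            raise ValueError("lag distribution must be non-negative")


def quantile_floor(spec: DistributionSpec) -> float:
    """Lower support bound of a shifted spec (shift for the usual families)."""
    if spec.family == "normal":
        return 0.0  # negative normal draws are resampled
    if spec.family == "uniform":
        return spec.shift + spec.params["low"]
    return spec.shift


def queue_step(
    arrival_times: np.ndarray,
    service_times: np.ndarray,
    n_servers: int,
) -> QueueStepResult:
    """Resolve one FCFS multi-server station.

    Customers are taken in the given (sorted) arrival order; each is
    assigned to the server that frees up earliest, with ties broken by the
    lowest server index.  Deterministic given its inputs.
    """
    arrival = np.asarray(arrival_times, dtype=float)
    service = np.asarray(service_times, dtype=float)
    if arrival.shape != service.shape:
        raise ValueError(
            f"length mismatch: {arrival.size} arrivals vs {service.size} service times"
        )
    if n_servers < 1:
        raise ValueError(f"n_servers must be >= 1, got {n_servers}")
    if np.any(np.diff(arrival) < 0):
        raise ValueError("arrival_times must be sorted non-decreasing")
    if np.any(service < 0):
        raise ValueError("service times must be >= 0")

    n = arrival.size
    start = np.empty(n)
    depart = np.empty(n)
    server = np.empty(n, dtype=np.int64)
    # (free_time, server_index): heap order is earliest-free, then lowest index
    free = [(0.0, i) for i in range(n_servers)]
    for j in range(n):
        t_free, idx = heapq.heappop(free)
        s = arrival[j] if arrival[j] > t_free else t_free
        d = s + service[j]
        start[j] = s
        depart[j] = d
        server[j] = idx
        heapq.heappush(free, (d, idx))
    return QueueStepResult(arrival=arrival, start=start, departure=depart, server=server)


def apply_lag(
    times: np.ndarray, lag: LagSpec, rng: np.random.Generator
) -> np.ndarray:
    """Add an independent non-negative lag draw to each time.

    The result is *not* re-sorted here; callers re-rank patients by their
    post-lag ready time before the next station.
    """
    times = np.asarray(times, dtype=float)
    return times + sample_service_times(lag.spec, times.size, rng)


def fork_join(
    patient_ready: np.ndarray, resource_ready: np.ndarray
) -> np.ndarray:
    """Join a patient stream with a prepared-resource stream.

    Both inputs sorted non-decreasing; the i-th patient consumes the i-th
    completed resource, so the effective arrival at the joined station is
    the elementwise maximum.  Raises if there are fewer resources than
    patients.
    """
    patient_ready = np.asarray(patient_ready, dtype=float)
    resource_ready = np.asarray(resource_ready, dtype=float)
    n, m = patient_ready.size, resource_ready.size
    if m < n:
        raise InsufficientResourceError(
            f"{n} patients but only {m} prepared doses: short by {n - m}"
        )
    return np.maximum(patient_ready, resource_ready[:n])


@dataclass(frozen=True)
class PatientLog:
    """Full timestamp record of one simulated clinic day.

    ``patients`` has one row per attended patient with, for each station
    ``<s>`` on the patient path, columns ``<s>_arrival``, ``<s>_start`` and
    ``<s>_departure`` (minutes from clinic open), plus ``adverse`` and
    ``processing_time``.  The parallel preparation queue is kept separately
    in ``prep`` (doses, not patients); ``dose_wastage`` counts doses
    prepared for no-shows.
    """

    site: str
    stations: tuple[str, ...]  # patient-path station names, in order
    patients: pd.DataFrame
    prep: QueueStepResult
    n_no_shows: int

    @property
    def dose_wastage(self) -> int:
        return self.prep.arrival.size - len(self.patients)


def _sort_by_ready(
    ready: np.ndarray, patient_id: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stable re-rank of patients by ready time (ties keep id order)."""
    order = np.lexsort((patient_id, ready))
    return ready[order], order


def simulate_network(
    network: "NetworkConfig",
    arrivals: ArrivalSet,
    dose_releases: np.ndarray,
    rng: np.random.Generator,
) -> PatientLog:
    """Run one clinic day through a configured queue network.

    Patients chain through the network's stations in FCFS order; hub
    networks insert a walking lag between consecutive stations.  The
    preparation station is simulated first from ``dose_releases``; its
    (sorted) completion times meet the patient stream at the vaccination
    station via :func:`fork_join`.  All booked patients are processed to
    completion even past closing time (overtime), so reported processing
    times include any end-of-day spillover.
    """
    attended = arrivals.attended
    n = len(attended)
    patient_id = attended["patient_id"].to_numpy()
    ready = attended["arrival_time"].to_numpy(dtype=float)
    order = np.arange(n)  # permutation: row -> position in current queue

    # parallel dose-preparation queue, driven by the appointment book
    prep = queue_step(
        dose_releases,
        sample_service_times(network.prep_station.service, dose_releases.size, rng),
        network.prep_station.n_servers,
    )
    dose_ready = np.sort(prep.departure)

    records: dict[str, np.ndarray] = {"patient_id": patient_id[order]}
    adverse = np.zeros(n, dtype=bool)

    station_names = tuple(s.name for s in network.patient_stations)
    last = len(network.patient_stations) - 1
    for k, station in enumerate(network.patient_stations):
        ready_sorted, perm = _sort_by_ready(ready[order], patient_id[order])
        order = order[perm]
        if station.name == network.join_before:
            ready_sorted = fork_join(ready_sorted, dose_ready)
        if k == last:  # observation: bimodal stay + per-patient adverse flag
            service, flags = sample_observation(station.service, n, rng)
            adverse[order] = flags
        else:
            service = sample_service_times(station.service, n, rng)
        res = queue_step(ready_sorted, service, station.n_servers)
        for col, vals in (
            ("arrival", res.arrival),
            ("start", res.start),
            ("departure", res.departure),
        ):
            out = np.empty(n)
            out[order] = vals
            records[f"{station.name}_{col}"] = out
        ready = np.empty(n)
        ready[order] = res.departure
        if network.walk_lag is not None and k < last:
            ready[order] = apply_lag(ready[order], network.walk_lag, rng)

    df = pd.DataFrame(records)
    df["adverse"] = adverse
    first, final = station_names[0], station_names[-1]
    df["processing_time"] = df[f"{final}_departure"] - df[f"{first}_arrival"]
    # present rows in clinic-arrival order
    df = df.sort_values([f"{first}_arrival", "patient_id"], kind="stable").reset_index(
        drop=True
    )
    return PatientLog(
        site=network.site,
        stations=station_names,
        patients=df,
        prep=prep,
        n_no_shows=arrivals.n_bookings - n,
    )
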