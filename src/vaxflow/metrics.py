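"""Queue-performance measures and replication pooling.

Two headline measures summarise a simulated clinic day:

* **processing time** — per patient, the total minutes from arrival at the
  first station to departure from the observation area;
* **staff utilisation** — per station, the fraction of server capacity
  spent actually serving, computed over that station's busy horizon (first
  arrival to last departure at the station, so end-of-day overtime is
  counted rather than deflating the figure).

Daily **throughput** is the count of patients who complete the network.
Scenario estimates pool 20 independently simulated days: percentiles are
taken on the concatenated patient-level processing times, and per-day
metrics are reported as mean and range across replications.

Sample percentiles use the median-unbiased quantile convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import NetworkConfig
from .queue_engine import PatientLog

__all__ = [
    "SimulationSummary",
    "PooledSummary",
    "processing_times",
    "staff_utilisation",
    "throughput",
    "summarize",
    "summarize_reps",
]

_QUANTILE_METHOD = "median_unbiased"


def _percentile(x: np.ndarray, p: float) -> float:
    return float(np.quantile(x, p, method=_QUANTILE_METHOD))


def processing_times(log: PatientLog) -> np.ndarray:
    """Per-patient total time (minutes) from first-station arrival to exit."""
    first, last = log.stations[0], log.stations[-1]
    cols = [f"{first}_arrival", f"{last}_departure"]
    for c in cols:
        if c not in log.patients.columns or log.patients[c].isna().any():
            raise ValueError(f"patient log is incomplete: bad column {c!r}")
    return (log.patients[cols[1]] - log.patients[cols[0]]).to_numpy(dtype=float)


def staff_utilisation(log: PatientLog, network: NetworkConfig) -> dict[str, float]:
    """Average busy fraction per station across the simulation run.

    For each station: total service minutes delivered divided by
    ``n_servers`` times the run horizon — from the first arrival anywhere
    in the network (clinic open, in practice) to the last departure from
    it, overtime included.  Staff are on duty for the whole run, so a
    station's idle ramp-up and wind-down count against its utilisation.
    Includes the preparation queue and the (seat-served) observation area.
    """
    prep = log.prep
    df = log.patients
    first = f"{log.stations[0]}_arrival"
    last = f"{log.stations[-1]}_departure"
    t0 = min(
        float(df[first].min()) if len(df) else np.inf,
        float(prep.arrival.min()) if prep.arrival.size else np.inf,
    )
    t1 = max(
        float(df[last].max()) if len(df) else -np.inf,
        float(prep.departure.max()) if prep.arrival.size else -np.inf,
    )
    horizon = t1 - t0

    util: dict[str, float] = {}
    if prep.arrival.size:
        util[network.prep_station.name] = _busy_fraction(
            prep.start, prep.departure, network.prep_station.n_servers, horizon
        )
    for st in network.patient_stations:
        if len(df):
            util[st.name] = _busy_fraction(
                df[f"{st.name}_start"].to_numpy(dtype=float),
                df[f"{st.name}_departure"].to_numpy(dtype=float),
                st.n_servers,
                horizon,
            )
    return util


def _busy_fraction(
    start: np.ndarray, departure: np.ndarray, n_servers: int, horizon: float
) -> float:
    busy = float((departure - start).sum())
    if horizon <= 0:
        if busy > 0:
            raise ValueError("zero run horizon with nonzero service time")
        return 0.0
    return busy / (n_servers * horizon)


def throughput(log: PatientLog) -> int:
    """Patients departing observation in the day (= vaccinated attendees)."""
    return len(log.patients)


@dataclass(frozen=True)
class SimulationSummary:
    """Metrics of a single replication (one simulated clinic day)."""

    replication: int
    processing: np.ndarray = field(repr=False)
    utilisation: dict[str, float]
    throughput: int
    dose_wastage: int
    n_no_shows: int

    @property
    def median_processing(self) -> float:
        return _percentile(self.processing, 0.5)

    @property
    def p95_processing(self) -> float:
        return _percentile(self.processing, 0.95)

    def percentile(self, p: float) -> float:
        return _percentile(self.processing, p)


@dataclass(frozen=True)
class PooledSummary:
    """Replication-pooled metrics with between-replication spread."""

    n_reps: int
    processing: np.ndarray = field(repr=False)  # concatenated patient-level
    utilisation: dict[str, float]  # mean across replications, per station
    max_utilisation: float
    throughput_mean: float
    throughput_range: tuple[int, int]
    dose_wastage_mean: float
    median_range: tuple[float, float]  # per-replication median spread

    @property
    def median_processing(self) -> float:
        return _percentile(self.processing, 0.5)

    @property
    def p95_processing(self) -> float:
        return _percentile(self.processing, 0.95)

    def percentile(self, p: float) -> float:
        return _percentile(self.processing, p)


def summarize(log: PatientLog, network: NetworkConfig, replication: int = 0) -> SimulationSummary:
    """Reduce one day's patient log to its summary metrics."""
    return SimulationSummary(
        replication=replication,
        processing=processing_times(log),
        utilisation=staff_utilisation(log, network),
        throughput=throughput(log),
        dose_wastage=log.dose_wastage,
        n_no_shows=log.n_no_shows,
    )


def summarize_reps(summaries: list[SimulationSummary]) -> PooledSummary:
    """Pool replication summaries.

    Percentiles are computed on the concatenation of all replications'
    patient-level processing times; utilisation is averaged per station;
    throughput and wastage are reported as mean (and range for
    throughput).
    """
    if not summaries:
        raise ValueError("need at least one replication to pool")
    pooled = np.concatenate([s.processing for s in summaries])
    stations = list(summaries[0].utilisation)
    util = {
        st: float(np.mean([s.utilisation[st] for s in summaries])) for st in stations
    }
    thr = [s.throughput for s in summaries]
    medians = [s.median_processing for s in summaries]
    return PooledSummary(
        n_reps=len(summaries),
        processing=pooled,
        utilisation=util,
        max_utilisation=max(util.values()) if util else 0.0,
        throughput_mean=float(np.mean(thr)),
        throughput_range=(int(min(thr)), int(max(thr))),
        dose_wastage_mean=float(np.mean([s.dose_wastage for s in summaries])),
        median_range=(float(min(medians)), float(max(medians))),
    )
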