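"""Scenario orchestration: baselines, what-if sweeps, calibration.

A *scenario* is one fully specified clinic day (site, staffing level,
appointment book, noise/no-show/adverse parameters), simulated for a
number of independent replications (20 by default) whose metrics are
pooled.  On top of baselines sit two stress tests — incrementally raising
the appointment rate with fixed staff, and incrementally removing staff
with fixed appointments — and a calibration search for the largest
appointment load that keeps the pooled median processing time below 60
minutes and every station's utilisation below 0.8.

Randomness is fully determined by the scenario's base seed: replication
``r`` of a scenario variant keyed ``key`` uses
``numpy.random.SeedSequence(base_seed, spawn_key=key + (r,))``, so any
single replication can be re-run in isolation.  Sweep points use
independent streams by default (each scenario is its own experiment);
``common_random_numbers=True`` reuses the baseline streams across points
to reduce comparison variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np

from .arrivals import (
    ArrivalSpec,
    DEFAULT_NOISE,
    build_schedule,
    generate_arrivals,
    generate_dose_demand,
    increment_schedule,
)
from .distributions import ConfigurationError, DistributionSpec
from .metrics import PooledSummary, SimulationSummary, summarize, summarize_reps
from .networks import (
    DEFAULT_WALK_LAG,
    InfeasibleScenarioError,
    NetworkConfig,
    make_gp_network,
    make_hub_network,
    reduce_staff,
)
from .queue_engine import LagSpec, PatientLog, simulate_network

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "SweepPoint",
    "SweepResult",
    "InfeasibleCalibrationError",
    "ARRIVAL_SWEEP_STEP",
    "run_baseline",
    "whatif_arrivals",
    "whatif_staff",
    "calibrate_appointments",
]

#: what-if arrival increment per sweep step: +10/hour for hubs,
#: +1 per 10-minute slot for GP clinics
ARRIVAL_SWEEP_STEP = {"hub": 10, "gp": 1}


class InfeasibleCalibrationError(RuntimeError):
    """Raised when no positive appointment load satisfies the constraints."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated clinic configuration.

    ``bookings_per_slot`` and ``staffing`` override the published presets;
    ``reps`` replications are pooled, each seeded deterministically from
    ``seed``.
    """

    site: str
    level: str = "medium"
    reps: int = 20
    seed: int = 0
    bookings_per_slot: int | None = None
    staffing: dict[str, int] | None = None
    no_show_prob: float = 0.02
    adverse_prob: float = 0.02
    noise: DistributionSpec = DEFAULT_NOISE
    walk_lag: LagSpec | None = field(default=DEFAULT_WALK_LAG)
    #: minutes before its slot that each dose enters preparation; None means
    #: one slot interval (doses drawn up during the preceding block)
    dose_lead: float | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ConfigurationError(f"reps must be >= 1, got {self.reps}")
        if self.site not in ("hub", "gp"):
            raise ConfigurationError(f"unknown site {self.site!r}")

    def network(self) -> NetworkConfig:
        if self.site == "hub":
            net = make_hub_network(self.level, self.adverse_prob, self.walk_lag)
        else:
            net = make_gp_network(self.level, self.adverse_prob)
        if self.staffing:
            net = net.with_staffing(self.staffing)
        return net

    def schedule(self):
        return build_schedule(self.site, self.level, self.bookings_per_slot)

    def arrival_spec(self) -> ArrivalSpec:
        return ArrivalSpec(noise=self.noise, no_show_prob=self.no_show_prob)


@dataclass(frozen=True)
class ScenarioResult:
    """Pooled metrics plus per-replication detail for one scenario."""

    config: ScenarioConfig
    network: NetworkConfig
    pooled: PooledSummary
    replications: list[SimulationSummary]
    logs: list[PatientLog] | None = None
    seed_spawn_keys: list[tuple[int, ...]] = field(default_factory=list)


@dataclass(frozen=True)
class SweepPoint:
    """One grid point of a what-if sweep; infeasible points carry a reason."""

    value: int
    result: ScenarioResult | None
    infeasible_reason: str | None = None

    @property
    def feasible(self) -> bool:
        return self.result is not None


@dataclass(frozen=True)
class SweepResult:
    """Ordered grid of sweep points (value -> pooled summary)."""

    kind: str  # "arrivals" or "staff"
    points: list[SweepPoint]

    def feasible_points(self) -> list[SweepPoint]:
        return [p for p in self.points if p.feasible]


def _rep_rng(base_seed: int, key: tuple[int, ...], r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key + (r,)))


def _run(
    config: ScenarioConfig,
    network: NetworkConfig,
    schedule,
    key: tuple[int, ...] = (),
    keep_logs: bool = False,
) -> ScenarioResult:
    spec = config.arrival_spec()
    summaries: list[SimulationSummary] = []
    logs: list[PatientLog] = []
    keys: list[tuple[int, ...]] = []
    lead = schedule.slot_interval if config.dose_lead is None else config.dose_lead
    dose_releases = generate_dose_demand(schedule, lead_time=lead)
    for r in range(config.reps):
        rng = _rep_rng(config.seed, key, r)
        arrivals = generate_arrivals(schedule, spec, rng)
        log = simulate_network(network, arrivals, dose_releases, rng)
        summaries.append(summarize(log, network, replication=r))
        keys.append(key + (r,))
        if keep_logs:
            logs.append(log)
    return ScenarioResult(
        config=config,
        network=network,
        pooled=summarize_reps(summaries),
        replications=summaries,
        logs=logs if keep_logs else None,
        seed_spawn_keys=keys,
    )


def run_baseline(config: ScenarioConfig, keep_logs: bool = False) -> ScenarioResult:
    """Simulate ``config.reps`` independent clinic days and pool them."""
    return _run(config, config.network(), config.schedule(), key=(), keep_logs=keep_logs)


def whatif_arrivals(
    config: ScenarioConfig,
    n_steps: int,
    step: int | None = None,
    common_random_numbers: bool = False,
) -> SweepResult:
    """Stress test: raise the appointment rate in ``n_steps`` increments.

    The default increment is the site-specific step (+10/hour hub, +1 per
    slot GP); the grid includes the unmodified baseline at increment 0.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    step = ARRIVAL_SWEEP_STEP[config.site] if step is None else int(step)
    network = config.network()
    base_schedule = config.schedule()
    points: list[SweepPoint] = []
    for i in range(n_steps + 1):
        extra = i * step
        schedule = increment_schedule(base_schedule, extra)
        key = () if common_random_numbers else (1, extra)
        res = _run(config, network, schedule, key=key)
        points.append(SweepPoint(value=extra, result=res))
    return SweepResult(kind="arrivals", points=points)


def whatif_staff(
    config: ScenarioConfig,
    max_reduction: int,
    common_random_numbers: bool = False,
) -> SweepResult:
    """Stress test: remove 0..``max_reduction`` staff from the network.

    Reductions that would leave a station unstaffed are reported as
    explicitly infeasible grid points, never silently dropped.
    """
    if max_reduction < 0:
        raise ValueError(f"max_reduction must be >= 0, got {max_reduction}")
    base_network = config.network()
    schedule = config.schedule()
    points: list[SweepPoint] = []
    for k in range(max_reduction + 1):
        try:
            network = reduce_staff(base_network, k)
        except InfeasibleScenarioError as err:
            points.append(SweepPoint(value=k, result=None, infeasible_reason=str(err)))
            continue
        key = () if common_random_numbers else (2, k)
        res = _run(config, network, schedule, key=key)
        points.append(SweepPoint(value=k, result=res))
    return SweepResult(kind="staff", points=points)


def calibrate_appointments(
    site: str,
    level: str,
    median_max: float = 60.0,
    util_max: float = 0.8,
    reps: int = 20,
    seed: int = 0,
    **config_kwargs,
) -> int:
    """Largest bookings-per-slot meeting the queue-performance constraints.

    A booking level is *feasible* when the pooled median processing time is
    strictly below ``median_max`` (minutes) and every station's mean
    utilisation is strictly below ``util_max``.  The search doubles the
    load until it hits an infeasible level, then bisects the integer
    bracket.  Feasibility is assumed monotone in load, which holds for
    these networks.
    """
    if median_max <= 0 or util_max <= 0:
        raise InfeasibleCalibrationError(
            f"constraints must be positive: median_max={median_max}, util_max={util_max}"
        )

    def feasible(b: int) -> bool:
        cfg = ScenarioConfig(
            site=site, level=level, reps=reps, seed=seed,
            bookings_per_slot=b, **config_kwargs,
        )
        res = _run(cfg, cfg.network(), cfg.schedule(), key=(3, b))
        return (
            res.pooled.median_processing < median_max
            and res.pooled.max_utilisation < util_max
        )

    if not feasible(1):
        raise InfeasibleCalibrationError(
            "no positive appointment load satisfies the constraints"
        )
    lo = 1  # largest known-feasible
    hi = 2
    while feasible(hi):
        lo = hi
        hi *= 2
    # invariant: lo feasible, hi infeasible
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
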