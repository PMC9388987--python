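"""FCFS queue assignment, lags, fork/join, and whole-network simulation."""

import numpy as np
import pytest

from vaxflow.arrivals import (
    AppointmentSchedule,
    ArrivalSpec,
    build_schedule,
    generate_arrivals,
    generate_dose_demand,
)
from vaxflow.distributions import ObservationMixtureSpec, shifted_exponential, uniform
from vaxflow.networks import NetworkConfig, StationConfig, make_hub_network
from vaxflow.queue_engine import (
    InsufficientResourceError,
    LagSpec,
    apply_lag,
    fork_join,
    queue_step,
    simulate_network,
)

from oracle import erlang_c_mean_wait, event_driven_queue


class TestQueueStep:
    def test_single_customer(self):
        res = queue_step([0.0], [5.0], 1)
        assert res.start[0] == 0.0 and res.departure[0] == 5.0 and res.wait[0] == 0.0

    def test_two_servers_three_customers(self):
        res = queue_step([0.0, 1.0, 2.0], [10.0, 10.0, 10.0], 2)
        np.testing.assert_array_equal(res.start, [0.0, 1.0, 10.0])
        np.testing.assert_array_equal(res.departure, [10.0, 11.0, 20.0])
        np.testing.assert_array_equal(res.wait, [0.0, 0.0, 8.0])

    def test_no_waits_with_enough_servers(self):
        res = queue_step([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], 3)
        np.testing.assert_array_equal(res.wait, [0.0, 0.0, 0.0])

    def test_tie_break_prefers_lowest_server_index(self):
        res = queue_step([0.0, 0.0, 5.0], [5.0, 5.0, 1.0], 2)
        # both servers free at t=5; the third customer goes to server 0
        assert res.server[2] == 0

    @pytest.mark.parametrize(
        "arrivals,services,c,err",
        [
            ([1.0, 0.0], [1.0, 1.0], 1, "sorted"),
            ([0.0, 1.0], [1.0], 1, "mismatch"),
            ([0.0], [1.0], 0, "n_servers"),
            ([0.0], [-1.0], 1, ">= 0"),
        ],
    )
    def test_contract_violations(self, arrivals, services, c, err):
        with pytest.raises(ValueError, match=err):
            queue_step(arrivals, services, c)

    def test_matches_event_driven_oracle(self):
        """Departure times agree exactly with an independent event-driven
        simulation on 1000 random small instances."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            c = int(rng.integers(1, 6))
            arrivals = np.sort(rng.uniform(0, 30, n))
            if rng.random() < 0.3:  # force simultaneous arrivals sometimes
                arrivals = np.floor(arrivals)
            services = rng.exponential(2.0, n)
            res = queue_step(arrivals, services, c)
            o_start, o_depart = event_driven_queue(arrivals, services, c)
            np.testing.assert_array_equal(res.start, o_start)
            np.testing.assert_array_equal(res.departure, o_depart)

    def test_more_servers_never_delay_anyone(self):
        rng = np.random.default_rng(5)
        arrivals = np.sort(rng.uniform(0, 100, 200))
        services = rng.exponential(3.0, 200)
        starts = [queue_step(arrivals, services, c).start for c in (1, 2, 3, 5, 8)]
        for narrower, wider in zip(starts, starts[1:]):
            assert (wider <= narrower + 1e-12).all()

    @pytest.mark.parametrize(
        "lam,mu,c",
        [(0.8, 1.0, 1), (1.5, 1.0, 2)],
    )
    def test_erlang_c_limit(self, lam, mu, c):
        """Long-run mean wait under Poisson/exponential traffic matches the
        M/M/c closed form."""
        rng = np.random.default_rng(17)
        n = 120_000
        arrivals = np.cumsum(rng.exponential(1.0 / lam, n))
        services = rng.exponential(1.0 / mu, n)
        res = queue_step(arrivals, services, c)
        mean_wait = res.wait[5000:].mean()  # discard warm-up
        assert mean_wait == pytest.approx(erlang_c_mean_wait(lam, mu, c), rel=0.08)


class TestLagAndJoin:
    def test_degenerate_lag_is_identity(self):
        t = np.array([0.0, 3.0, 9.0])
        out = apply_lag(t, LagSpec(uniform(0.0, 0.0)), np.random.default_rng(0))
        np.testing.assert_array_equal(out, t)

    def test_constant_lag_shifts(self):
        t = np.array([0.0, 3.0])
        out = apply_lag(t, LagSpec(uniform(1.5, 1.5)), np.random.default_rng(0))
        np.testing.assert_allclose(out, t + 1.5)

    def test_uniform_lag_mean_shift(self):
        t = np.zeros(100_000)
        out = apply_lag(t, LagSpec(uniform(0.5, 2.0)), np.random.default_rng(1))
        se = out.std() / np.sqrt(out.size)
        assert abs(out.mean() - 1.25) < 3 * se

    def test_join_unconstrained_when_resources_ready(self):
        patients = np.array([3.0, 7.0, 8.0])
        np.testing.assert_array_equal(fork_join(patients, np.zeros(5)), patients)

    def test_join_waits_for_resources(self):
        np.testing.assert_array_equal(
            fork_join(np.array([10.0, 12.0]), np.array([11.0, 11.0])), [11.0, 12.0]
        )

    def test_join_shortfall_raises(self):
        with pytest.raises(InsufficientResourceError, match="short by 1"):
            fork_join(np.array([5.0]), np.array([]))


def _deterministic_gp_network(
    seats: int = 5, reg: int = 1, vacc: int = 2, reg_minutes: float = 4.0
) -> NetworkConfig:
    """GP-shaped network with constant service times for exact checks."""
    obs = ObservationMixtureSpec(
        main=uniform(20.0, 20.0),
        adverse=shifted_exponential(20.0, 0.1),
        adverse_prob=0.0,
    )
    return NetworkConfig(
        site="gp",
        patient_stations=(
            StationConfig("registration", reg, uniform(reg_minutes, reg_minutes)),
            StationConfig("vaccination", vacc, uniform(6.0, 6.0)),
            StationConfig("observation", seats, obs),
        ),
        prep_station=StationConfig("preparation", 1, uniform(1.0, 1.0)),
        walk_lag=None,
    )


class TestSimulateNetwork:
    def test_uncontested_patient_processing_time(self):
        """With ample capacity the processing time is the sum of services."""
        net = _deterministic_gp_network()
        sched = build_schedule("gp", bookings_per_slot=1)
        spec = ArrivalSpec(noise=uniform(0.0, 0.0), no_show_prob=0.0)
        rng = np.random.default_rng(0)
        arr = generate_arrivals(sched, spec, rng)
        log = simulate_network(net, arr, generate_dose_demand(sched), rng)
        np.testing.assert_allclose(log.patients["processing_time"], 4.0 + 6.0 + 20.0)

    def test_two_patients_single_server_chain(self):
        """Two simultaneous arrivals through single-server stations resolve
        to hand-computed timestamps."""
        net = _deterministic_gp_network(seats=1, reg=1, vacc=1)
        sched = AppointmentSchedule(slot_interval=480.0, n_slots=1, bookings_per_slot=2)
        spec = ArrivalSpec(noise=uniform(0.0, 0.0), no_show_prob=0.0)
        rng = np.random.default_rng(0)
        arr = generate_arrivals(sched, spec, rng)
        log = simulate_network(net, arr, generate_dose_demand(sched), rng)
        df = log.patients.sort_values("registration_start")
        # second patient queues behind the first at every station:
        # reg 0-4 / 4-8, vacc 4-10 / 10-16, single seat 10-30 / 30-50
        np.testing.assert_allclose(df["registration_start"], [0.0, 4.0])
        np.testing.assert_allclose(df["vaccination_start"], [4.0, 10.0])
        np.testing.assert_allclose(df["observation_start"], [10.0, 30.0])
        np.testing.assert_allclose(df["processing_time"], [30.0, 50.0])

    def test_timestamps_monotone_and_patients_conserved(self):
        net = make_hub_network("low")
        sched = build_schedule("hub", "low")
        rng = np.random.default_rng(3)
        arr = generate_arrivals(sched, ArrivalSpec(), rng)
        log = simulate_network(net, arr, generate_dose_demand(sched, lead_time=60.0), rng)
        df = log.patients
        assert len(df) == arr.n_attended
        assert set(df["patient_id"]) == set(arr.attended["patient_id"])
        cols = []
        for st in log.stations:
            cols += [f"{st}_arrival", f"{st}_start", f"{st}_departure"]
        times = df[cols].to_numpy()
        assert (np.diff(times, axis=1) >= -1e-9).all()

    def test_doses_limit_vaccination_start(self):
        """Vaccination cannot start before the paired dose is prepared."""
        # registration takes 0.5 min, but each dose is only released at the
        # slot start and takes 1 min to prepare: the dose is binding
        net = _deterministic_gp_network(reg_minutes=0.5)
        sched = build_schedule("gp", bookings_per_slot=1)
        spec = ArrivalSpec(noise=uniform(0.0, 0.0), no_show_prob=0.0)
        rng = np.random.default_rng(0)
        arr = generate_arrivals(sched, spec, rng)
        log = simulate_network(net, arr, generate_dose_demand(sched), rng)
        vacc = log.patients.sort_values("vaccination_arrival")
        np.testing.assert_allclose(
            vacc["vaccination_arrival"], sched.slot_times + 1.0
        )
        dose_ready = np.sort(log.prep.departure)
        assert (vacc["vaccination_arrival"].to_numpy() >= dose_ready - 1e-9).all()

    def test_wastage_counts_no_show_doses(self):
        net = _deterministic_gp_network()
        sched = build_schedule("gp", "medium")
        rng = np.random.default_rng(8)
        arr = generate_arrivals(sched, ArrivalSpec(no_show_prob=0.1), rng)
        log = simulate_network(net, arr, generate_dose_demand(sched), rng)
        assert log.dose_wastage == sched.total_bookings - arr.n_attended
        assert log.dose_wastage == log.n_no_shows
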