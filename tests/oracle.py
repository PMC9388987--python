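"""Independent oracles for the queue engine.

``event_driven_queue`` is a classical discrete-event simulation of an
FCFS multi-server station: an event calendar (heap) of arrivals and
departures, an explicit FIFO waiting line, and a pool of idle servers.
It shares no code or algorithmic structure with the package's
server-free-time assignment, so agreement between the two is meaningful.

``erlang_c_mean_wait`` is the M/M/c closed-form mean queueing delay.
"""

from __future__ import annotations

import heapq
from math import factorial

import numpy as np

ARRIVAL, DEPARTURE = 0, 1


def event_driven_queue(arrival_times, service_times, n_servers):
    """Simulate an FCFS multi-server queue with an event calendar.

    Returns ``(start_times, departure_times)`` aligned with the input
    order, which must be sorted by arrival time.
    """
    arrival_times = list(map(float, arrival_times))
    service_times = list(map(float, service_times))
    n = len(arrival_times)
    start = [0.0] * n
    depart = [0.0] * n
    serving: dict[int, int] = {}  # customer -> server currently serving them

    # Arrivals sort before departures at equal times; the FIFO line plus
    # idle-server pool enforce FCFS with lowest-index server preference.
    events = [(t, ARRIVAL, i, i) for i, t in enumerate(arrival_times)]
    heapq.heapify(events)
    idle = list(range(n_servers))
    heapq.heapify(idle)
    waiting: list[int] = []
    while events:
        t, kind, _, cust = heapq.heappop(events)
        if kind == ARRIVAL:
            waiting.append(cust)
        else:
            heapq.heappush(idle, serving.pop(cust))
        while waiting and idle:
            c = waiting.pop(0)
            srv = heapq.heappop(idle)
            serving[c] = srv
            start[c] = t
            depart[c] = t + service_times[c]
            heapq.heappush(events, (depart[c], DEPARTURE, n + c, c))
    return np.array(start), np.array(depart)


def erlang_c_mean_wait(lam: float, mu: float, c: int) -> float:
    """Mean M/M/c queueing delay (time in queue, excluding service)."""
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError("unstable system")
    p0_inv = sum(a**k / factorial(k) for k in range(c)) + a**c / (
        factorial(c) * (1 - rho)
    )
    prob_wait = (a**c / (factorial(c) * (1 - rho))) / p0_inv
    return prob_wait / (c * mu - lam)
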