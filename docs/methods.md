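# Methods

## The queueing model

A vaccination clinic is modelled as a network of first-come-first-served
(FCFS) multi-server queues traversed in a fixed order. Two layouts are
built in:

* **Mass vaccination hub** — Entrance, Registration, Assessment,
  Vaccination, Observation. A stochastic walking lag (a delay that
  consumes time but no server) separates consecutive stations, reflecting
  the large venues these hubs occupy.
* **GP clinic** — Registration, Vaccination, Observation, with walking
  time treated as negligible.

Stations are resolved one at a time. Within a station, customers are
processed in arrival order and each is assigned to the server that frees
up earliest (ties to the lowest server index — departure times are
invariant to the tie-break; fixing it makes server-occupancy traces
reproducible). Because assignment needs only the current server free
times, a station resolves in a single pass over a heap rather than a full
event calendar; the test suite checks this against an independent
event-driven simulator (exact agreement on 1000 random instances) and
against the M/M/c Erlang-C closed form.

After a lag, patients are re-ranked by their post-lag ready times: FCFS
discipline applies at each station on that station's arrival order, so a
slow walker can be overtaken.

**Observation** is a queue whose "servers" are seats. Patients occupy a
seat for the observed stay and leave; staff supervising the area are not
part of the queueing process and are not counted in staffing totals.

**Dose preparation** runs as a parallel queue driven by the appointment
book: one dose per booking, prepared by dedicated staff, joining the
patient stream at vaccination. The i-th patient to reach the vaccination
queue consumes the i-th completed dose and waits for it if necessary.
Doses are prepared for all bookings, so doses drawn up for no-shows are
reported as wastage (they have no queueing effect). When a dose *enters*
preparation is not pinned down by the published assumptions, so it is a
parameter: by default each dose is released one slot interval ahead of
its appointment — preparation staff work one appointment block ahead —
which keeps the dose join from artificially delaying patients who arrive
early. Releasing doses exactly at the slot start (`dose_lead = 0`) makes
the join binding for most patients and adds roughly 2–6 minutes to every
processing time; both policies are available.

All booked patients are processed to completion even past the 8-hour
horizon, so reported processing times include end-of-day spillover
(overtime) rather than censoring it.

## Service times

Station service times are `shift + X` in minutes: a fixed minimum plus a
parametric draw (exponential, normal, log-normal, gamma or Weibull; a
uniform family exists for walking lags). The built-in assumptions are
shifted exponentials — most patients are quick, a minority much slower:

| station (hub) | spec | station (GP) | spec |
|---|---|---|---|
| preparation | 1 + Exp(3) | preparation | 1 + Exp(3) |
| entrance | 2 + Exp(1) | registration | 3 + Exp(1) |
| registration | 3 + Exp(0.7) | vaccination | 5 + Exp(0.5) |
| assessment | 2 + Exp(1) | | |
| vaccination | 3 + Exp(1) | | |

λ is a *rate*: median(3 + Exp(0.7)) = 3 + ln 2/0.7 ≈ 3.99 minutes.
Observation stays are a two-component mixture: N(20, 0.5) for the
1 − p majority and 20 + Exp(0.1) for the p = 0.02 fraction flagged with an
adverse reaction (each patient's component is an independent Bernoulli
draw; the flag is carried through to the patient log). Normal draws are
resampled if negative — service times cannot be negative — which the
narrow N(20, 0.5) never triggers in practice. σ = 0.5 is used for the
observation normal at both sites.

Closed-form quantiles (`shift + F⁻¹(p)`) reproduce the percentile table
the service assumptions were published with; a handful of that table's
cells differ from the analytic values by up to a few tenths of a minute
(several minutes in the heavy-tailed adverse rows), consistent with those
printed figures being Monte-Carlo estimates. The analytic values are
treated as ground truth.

## Arrivals

An eight-hour clinic runs a fixed appointment book: hubs issue
appointments on the hour (8 slots × 60/120/180 bookings for
low/medium/high capacity), GP clinics every ten minutes (48 slots ×
2/4/6). Each booking independently no-shows with probability 0.02.
Attendees arrive at `slot + noise` with noise ~ N(−10, 5) minutes,
clamped at clinic opening: the median patient is 10 minutes early and
about 2.3% arrive at or after their slot, matching the qualitative
pattern of a booked clinic. The noise distribution is fully
user-configurable; nothing in the published material pins it down beyond
that qualitative description, and congested-regime results are sensitive
to it (see Limitations).

## Metrics

* **Processing time** — per patient, departure from observation minus
  arrival at the first station, in minutes.
* **Staff utilisation** — per station, delivered service minutes divided
  by `n_servers ×` the run horizon, where the horizon spans the first
  arrival anywhere in the network to the last departure (staff are on
  duty for the whole run, so idle ramp-up/wind-down counts). An earlier
  per-station busy-span variant was rejected because it overstates
  utilisation at stations that start late, pushing baseline vaccination
  utilisation above the 0.8 design cap that the appointment levels were
  calibrated to respect.
* **Throughput** — patients completing the network per day.

Scenario estimates pool 20 independent replications (adequate for stable
estimates of these metrics at clinic scale): percentiles are computed on
the concatenated patient-level processing times using the
median-unbiased sample-quantile convention (fixed so that reported
percentiles are well-defined); per-day metrics are reported as mean and
range.

## Scenarios, seeds, calibration

Replication `r` of a scenario variant keyed `key` draws from
`SeedSequence(base_seed, spawn_key=key + (r,))`, so every replication is
independently re-runnable from the manifest. Sweep points use independent
streams by default, matching an independent-scenarios design; a flag
enables common random numbers across points for variance-reduced
comparisons.

The what-if sweeps raise arrivals in site-specific steps (+10/hour hub,
+1 per slot GP) or remove staff one at a time, cycling largest stations
first (ties to the station later on the patient path; the hub low-capacity
network (2, 4, 6, 4, 5) loses registration, vaccination, then assessment
staff for k = 3). Which stations lose staff in a real shortage is
genuinely open; an explicit per-station staffing override is accepted for
testing alternatives, and reductions that would leave a station unstaffed
are flagged infeasible rather than skipped.

Calibration searches the largest integer bookings-per-slot whose pooled
median processing time stays strictly under 60 minutes and whose maximum
station utilisation stays strictly under 0.8 ("remained below" is read as
a strict inequality), by doubling until infeasible and then bisecting —
feasibility is monotone in load for these networks. With the built-in
assumptions this recovers the published appointment densities (≈60/hour
for a low hub, 4 per slot for a medium GP clinic): the binding constraint
is observation-seat and vaccinator utilisation.

## What the generator does and does not emulate

The synthetic clinic days capture appointment-driven arrival bunching,
no-shows, heavy-tailed service times, adverse-reaction observation stays,
dose preparation coupling, seat limits, and end-of-day overtime. They do
not model walk-ins, reneging or balking, time-varying no-show or service
rates, staff breaks or rostering, dose expiry clocks, or physical space
constraints. Passing tests therefore validate the queueing arithmetic and
the published-scenario conditions, not the realism of any particular
clinic's parameters — the service and noise distributions are assumptions
to be replaced with measured ones where available.

## Numerical and degenerate-input choices

Times are decimal minutes from clinic opening (clock 0). Empty schedules,
zero-booking clinics and empty logs flow through without special casing
(empty vectors; utilisation is an empty mapping). Exact float equality is
used when comparing the queue engine to the event-driven oracle — both
compute `max` and `+` on the same values, so agreement is bitwise.
Pre-opening arrivals are clamped to the opening time; the first slot's
cohort therefore enters together at opening, a deliberate modelling of
doors-open queueing. Quantile evaluation rejects p outside (0, 1); the
dose join raises a shortfall error naming the deficit rather than
silently recycling doses.

## Known limitations

* Baseline processing-time estimates run ~5–10% above the figures the
  assumptions were published alongside (hub median ≈55 vs 52 minutes; GP
  ≈32 vs 32), within between-replication spread, but congested-regime
  medians are higher (low hub at +30 arrivals/hour: ≈127 vs ≈109
  minutes). In sustained overload the median is governed by the
  cumulative gap between arrivals (≈88/hour attended) and the smallest
  station capacities implied by the published tables (observation
  ≈74/hour, vaccination 75/hour, entrance 80/hour), and is nearly
  invariant to the arrival-noise spread — sensitivity runs with noise
  standard deviations of 5–10 minutes move it by under a minute — so the
  discrepancy reflects the under-determined arrival process and any
  unpublished details of the original experiments, not a tunable setting.
* Utilisation above ~0.8 degrades performance sharply; the calibration
  tooling treats 0.8 as a hard cap rather than exploring the trade-off.
* Single-day horizon: no carry-over between days, no multi-day rostering.
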