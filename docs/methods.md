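# Methods

## The system being modeled

An outpatient hospital pharmacy serving prescription patients through
three stations in series — receiving the prescription, filling it, and
delivering the drugs — in two independent 4-hour shifts.  Arrivals form a
Poisson stream; service times are exponential; each station is a
multi-server FIFO queue; patients traverse the stations in order (a
tandem network).  The cashier step is folded into the filling stage's
service time: the underlying observation study measured waiting "before
referring to the cashier" and never staffed a cashier separately, so a
separate cashier station would have no calibration target.  Rates are
expressed per 30-minute window (the study's observation unit); all
reported durations are minutes.  Over-the-counter customers (10–15% of
arrivals, who skip the prescription pathway) are excluded by default; a
`build_network(..., otc_fraction=f)` flag thins the prescription arrival
stream accordingly, but their separate direct-to-delivery path is not
modeled.

## Shift-level indicators and the reporting policy

Two analytic routes coexist deliberately:

* **Observed-L route** (`indicators_from_observed_L`): the mean number in
  the pharmacy L is an empirical input; L_q = L − r, W_q = 30·L_q/λ,
  W = W_q + 30/µ, W_a = 30/(sµ − λ), ρ = λ/(sµ).  This is the route the
  published indicator table uses, and it is internally Little's-law
  consistent.
* **Erlang-C route** (`erlang_c_indicators`): textbook M/M/s steady
  state.  At the study's utilizations (ρ ≈ 0.27 and 0.22) it predicts
  L_q < 0.1 — wildly below the observed 18.15.  The two routes cannot be
  reconciled; the observed congestion is not an M/M/s steady state at the
  measured rates.  Both are exposed; the observed-L route is the default
  for reproducing the study table, the Erlang-C route is the oracle for
  validating the simulator.

**Truncation, not rounding.**  The published table is reproduced
bit-exactly only if values are truncated: 12.5/11.5 = 1.0869 → 1.08,
30/45 = 0.6667 → 0.66, 12.5/57.5 = 0.2174 → 0.21, 35.198 → 35.19.
`ReportingPolicy(mode="truncate", decimals=2)` is therefore the default;
rounding is available.  Truncation pre-rounds at 9 decimals so that a
value that is exactly on a decimal boundary in real arithmetic (e.g.
30·(14.66 − 1.08)/12.5 = 32.592) is not pushed below it by binary
floating point.

**Per-shift W_q precision.**  The published chain prints W_q at one
decimal for the morning (36.6) and two for the evening (32.59), and
computes W from the *printed* W_q: 36.6 + 30/14 = 38.742 → 38.74, and
32.59 + 30/11.5 = 35.198 → 35.19.  No single decimal count reproduces
both columns, so the printed precision is a per-call option
(`wq_decimals`), defaulting to the policy's two decimals.

**One non-reproducible figure.**  Morning ρ = 14.87/56 = 0.26553 prints
as 0.26 truncated and 0.27 rounded; the study prints 0.25.  The package
computes 0.26 and documents the discrepancy rather than special-casing
it.

**Sample size.**  n = ((z·δ)/d)² with z = 1.96, δ = 5.12 min, d = 1 min
gives 100.705 per shift; the value is returned unrounded.

## The discrete-event engine

A heap-ordered event-list simulation, not a process framework.  Design
choices that matter for reproducibility and for variance reduction:

* **Event ordering.**  Ties at equal timestamps are broken
  deterministically: departures before arrivals, then lower patient id.
  A patient leaving station i is injected into station i+1 at the same
  timestamp as an arrival event, so simultaneous departures elsewhere are
  settled first and replay is exact.
* **Random streams.**  One substream for the arrival process plus one per
  station, all spawned from `(seed, replication)`.  Station k's service
  draws are consumed in service-start order from its own stream, so
  changing another station's staffing — or this station's server count —
  does not perturb the draw sequence.  This gives common random numbers
  across scenario variants for free; measured on the add-a-filler
  scenario, the paired before/after correlation is ≈ 0.7 and the delta
  variance ratio ≈ 0.93 versus independent streams (most delta variance
  comes from the heavily loaded baseline alone, which pairing cannot
  remove).
* **Warm-up.**  Default 0 with an empty start, because the studied shifts
  begin empty and the scenario statistics deliberately cover the whole
  transient shift.  Steady-state validation runs instead use explicit
  long horizons with a warm-up cut (statistics collected on
  [warm-up, horizon]).
* **Statistics.**  Per station: mean wait (queue-entry to service-start,
  for patients entering after warm-up), time-average waiting-queue
  length (integrated occupancy), the fraction of arrivals finding an
  empty queue, and the arrival-found queue-length distribution (PASTA
  makes these estimate the stationary law).  Queue-length report bins
  default to [0,5), [5,10), [10,15), [15,20), [20,∞): the published bins
  overlap at their endpoints, so the half-open reading is used and
  values beyond the last edge are clipped into the last bin to keep the
  fractions a partition.  System level: completed patients, mean time in
  network, conservation (arrivals = completions + in-system at horizon).
* **Replications.**  `replicate(cfg, n)` uses substreams 0..n−1, so one
  replication is identical to a plain `simulate` call.  Across-replication
  summaries use normal-approximation confidence intervals (mean ±
  z·sd/√n).

Validation (all in the test suite): bit-identical replay; FIFO order;
patient conservation; agreement of L_q and W_q with Erlang-C within 99%
confidence intervals on a utilization grid ρ ∈ {0.3, 0.6, 0.9} with 1 and
3 servers (200 replications × 12 000 simulated minutes per cell — the
replication count is chosen so that the normal-approximation interval is
trustworthy for the right-skewed per-replication queue lengths at low
utilization); station 2 of a tandem behaving as an independent M/M/1
(Burke's theorem); Little's law per station; the geometric
arrival-found queue-length law at ρ = 0.5.

## Calibrating the pharmacy baseline

The study published per-station observed waits but not station service
rates.  `calibrate_baseline` recovers each station's exponential service
mean by inverting the closed-form M/M/s mean delay at the shift arrival
rate: analytically for single-server stations (the positive root of
µ² − λµ − λ/W_q = 0), numerically (Brent bracketing on the monotone
W_q(µ)) for multi-server ones.  Departures of a stable exponential
multi-server queue are Poisson at the arrival rate, so each tandem stage
sees a Poisson stream at λ and the per-station inversion is exact in
steady state.  Round-trip accuracy is < 1e-6 minutes at every station.

Calibration targets (minutes): morning 46 s / 24 min 24 s / 1 min 33 s,
evening 50 s / 20 min 2 s / 1 min 26 s for receiving / filling /
delivery.  The study's evening narrative attributes the 50-second wait to
the delivery station while its own scenario table puts 1 min 26 s there;
the tables are taken as authoritative and the 50 s is read as the
receiving station.  (A morning queue length reported as "48%people" is
read as 0.48 persons by analogy with the evening's 0.52; it is not used
as a calibration target.)

The calibrated morning filling station has ρ = 0.9287 (service mean
1.874 min).  Its stationary probability that an arrival finds 10 or more
patients waiting is ρ¹¹ = 0.443, and long-run simulation reproduces that
value — notably *below* the study's observed 61.7%.  This is the same
structural tension as the observed-L vs Erlang-C gap above: the observed
congestion exceeds what any M/M/1 calibrated to the observed mean wait
can produce in steady state.  The package reports what the model
computes.

## Scenarios

Four built-in staffing scenarios: morning receivers 2→1 (S1), morning
fillers 1→2 (S2), evening delivery 2→1 (S3), evening fillers 1→2 (S4);
baselines (2, 1, 1) morning and (2, 1, 2) evening.  An added filler is
modeled as one FIFO queue feeding two servers (M/M/2), not two separate
queues — the study's routing is ambiguous and the single-queue reading
matches its "one-lined, multi-server" description.  Scenario runs use the
240-minute shift horizon with an empty start and whole-shift statistics,
mimicking the observation design rather than steady state; consequently
the *magnitudes* of the study's before/after tables (produced by an
unpublished commercial-simulator model) are not reproducible, and only
the direction of each change plus the printed tables' internal
arithmetic are asserted.  Staff reductions S1 and S3 push the modified
station past ρ = 1; that is flagged in the result (transient shift
statistics remain well defined) rather than raised.  Deltas are stored
signed (after − before); durations render in the study's
"M min + S sec" style.

## The synthetic observation study

`generate_log` runs the service network per shift and emits the
observation-form log (one row per patient: arrival, per-stage start/end
timestamps, the cashier referral instant, minutes from shift start at
3 decimals in CSV).  Two designs are provided:

* `pharmacy_study_design()` — the full three-station emulation at the
  study's rates with calibrated service means; defaults are the study's
  conditions (λ = 14.87 and 12.5 per window, two 4-hour shifts, 30-minute
  windows, systematic sample of ~220 patients taken as every k-th
  arrival).
* `consolidated_study_design()` — one consolidated service stage per
  shift with mean 30/µ and s servers.  This is the design under which the
  shift-level µ is exactly specified (per-patient total service time is
  exponential with rate µ), and is therefore what estimator-recovery and
  test-calibration studies use.

What the generator does *not* emulate: within-shift arrival-rate peaks
(the study reports them; rates here are constant per shift, matching its
model), the OTC sub-population's separate pathway, and any human
measurement error in the timestamps.  Passing tests therefore validate
the estimators and tests under the stated stochastic model, not against
field-data idiosyncrasies.

**Rate estimation.**  λ̂ is the mean arrival count over all windows of
the shift (empty trailing windows included), with model-based standard
error √(λ̂/n_windows).  µ̂ is the censored-exponential maximum-likelihood
rate: completions over total observed service exposure, converted to
per-window units, with the standard (e−1) small-sample numerator when
e ≥ 2 completions are available.  Patients still mid-service at shift
close contribute their elapsed service as censored exposure; dropping
them would discard exactly the longest services and bias µ̂ upward by
about +3% under the study conditions — enough to fail a 2-standard-error
recovery check, which is why the censoring-aware estimator is the
default and only route.

**Goodness of fit.**  Arrivals: chi-square of window counts against
Poisson(λ̂), cells pooled so each expected count is ≥ 5 where achievable.
Service: KS distance of per-patient total service times to an
exponential with the estimated mean.  Both default to parametric
bootstrap p-values (re-estimating the parameter in every bootstrap
sample), because with 8–16 windows the pooled chi-square keeps at most
2–3 cells (df ≤ 1, sometimes 0) and the classical KS p-value is well
known to be conservative once the mean is estimated from the data.
Asymptotic p-values remain available (`method="asymptotic"`; the
chi-square uses df = cells − 2 and refuses to run below 3 cells).
Measured calibration over 500 simulated null studies (16 windows at
λ = 14.87, 300 bootstrap samples): rejection rates 5.4% (arrivals) and
5.2% (service) at the 5% level; constant (fixed-interval) window counts
are rejected with power ≈ 1.

## Numerical choices and degenerate inputs

* Erlang-C is evaluated through the Erlang-B recurrence (no factorials,
  stable for large s); the test suite cross-checks it against a direct
  series summation.
* Calibration brackets µ in (λ/s, ∞) and doubles the upper end until the
  target is bracketed; W_q(µ) is strictly decreasing there, so the root
  is unique.  A non-positive target wait raises a calibration error
  naming the station.
* λ ≥ sµ raises an instability error wherever a steady-state quantity is
  requested; simulation accepts such configurations (finite-horizon
  transients are well defined) and scenario results flag the stations.
* Observed L below r raises an inconsistent-observation error.
* An empty log, a single window, or fewer than 5 service times raise
  errors naming the offending estimate or test.

## Problem sizes used in validation

Oracle-equivalence grids use 200 replications of 12 000 simulated minutes
per cell; calibration round-trip simulations 24 × 40 000 minutes;
scenario sign checks 100 shift replications; estimator recovery 100
synthetic studies; goodness-of-fit calibration 500 studies × 300
bootstrap samples.  These sizes keep every stochastic check's Monte Carlo
error well inside the asserted tolerance while the full suite runs in
about a minute and a half.

## Known limitations

* Constant within-shift arrival rates; no balking, reneging, priorities,
  breakdowns, or non-tandem routing.
* Steady-state calibration from shift-average observations understates
  the congestion the study actually observed (see above); the
  published scenario tables' absolute values are out of reach by
  construction.
* Confidence intervals are normal-approximation across replications;
  at small replication counts with highly skewed statistics they
  undercover (hence the validation sizes above).
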