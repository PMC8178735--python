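# Methods

## Model and assumptions

The urgent care center is modeled as an open queueing network of four
FIFO multi-server stations — triage nurses, doctors, an
examination/treatment nurse, a discharge administrator — visited in the
order triage → doctor → {exam → (doctor | discharge) | discharge}.
Arrivals form a homogeneous Poisson process on the opening window
[0, 240) minutes; every service duration is exponential with a
stage-specific mean (15, 20, 15, 5 minutes at baseline). Routing after
the doctor (to exam with probability `p_exam`) and after exam (back to
a doctor with probability `p_return`) is Bernoulli, independent of
everything else. There is no balking, reneging, prioritisation,
appointment stream or capacity limit on the waiting room, and staffing
is constant within the window.

The digital history-taking app is represented purely as a reduction of
the *mean* of the triage and consultation service distributions
(effective mean = mean − saving); the draw remains exponential, so the
patient-to-patient variability of the saving is inherited from the
service-time variability rather than modeled separately. The
consultation saving applies to every doctor visit, including return
visits after examination/treatment, since the app's report is equally
available in both encounters.

The simulation starts empty, stops arrivals strictly before the
horizon and halts the clock at the horizon: services still in progress
are truncated in all busy-time accounting and patients not yet
discharged are recorded as in-system-at-close. A flushed-past-horizon
variant was deliberately not implemented; the published summaries this
package reproduces are consistent with hard truncation (their queue and
wait values violate Little's law with the nominal rate, exactly as
truncation predicts).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `arrival_rate` | 0.2 | patients/min | Poisson intensity; 0.2 ≈ one patient per 5 min, deliberately crowding-inducing (triage offered load ρ = 1.5) |
| `mean_triage`, `mean_doctor`, `mean_exam`, `mean_admin` | 15, 20, 15, 5 | min | exponential service means |
| `n_triage`, `n_doctor`, `n_exam`, `n_admin` | 2, 2, 1, 1 | servers | staffing |
| `triage_saving`, `consult_saving` | 0, 0 | min | app effect; study grids 2.5–5 and 1.5–3.5 |
| `p_exam`, `p_return` | 0.4, 0.2 | — | routing probabilities (see below) |
| `horizon` | 240 | min | opening window |
| `n_reps` | 5000 | — | replications per scenario |
| `base_seed` | 20210521 | — | stream root |

`p_exam` and `p_return` have no authoritative published value; 0.4 and
0.2 were fixed once as plausible UCC referral/return rates. Their exact
values are immaterial for every triage-stage result: the per-purpose
stream design (below) makes all triage timestamps bit-identical under
any change to downstream parameters, and the test suite asserts this
exactly. Doctor-stage summaries do depend on them and are therefore
validated only structurally (conservation, FIFO, work conservation),
never against published numbers.

## Randomness and reproducibility

Each replication draws from six independent PCG64 streams — arrivals,
one per service stage, routing — seeded by
`SeedSequence([base_seed, rep_index, purpose])`. Consequences: (i)
replications are mutually independent and a run is a pure function of
`(config, base_seed, rep_index)`; (ii) triage-stage statistics are
invariant to downstream parameters; (iii) sharing `base_seed` across
scenarios yields common-random-number couplings for paired monotonicity
comparisons (the sweep seeds scenarios independently by default, with a
CRN option). Service times are drawn at service start; because service
order within a stage is FIFO, this choice is distributionally
irrelevant but fixes the replay.

The event calendar is a binary heap ordered by (time, event-class,
insertion sequence), with completions processed before arrivals at
equal times, so floating-point ties replay deterministically. A
non-monotone clock raises instead of being silently reordered.

## Outcome measures and the two queue estimators

Per replication: time-averaged queue length (number waiting, excluding
patients in service) per role; utilization = busy server-minutes /
(capacity × horizon); idle time = its complement; crowding = fraction
of the window with more than 5 patients waiting for triage; waiting
time for triage = triage start − arrival. Across replications: mean
with normal 95% CI (n = 5000 makes the normal approximation safe),
utilization as median with IQR, quantiles by linear interpolation.

Two conventions need calling out, both chosen to match how
process-oriented DES monitors in this literature summarise, and both
validated against the published table across four independent
scenarios:

- **Waiting-time censoring.** The default population is patients whose
  triage consultation *completed* within the window — the set a
  per-resource activity monitor reports. Alternatives (`started`,
  `include` with horizon-censored waits) are available for sensitivity.
  Under overload the choice matters: at baseline the completed-censored
  mean is ~35 min while the uncensored expected wait of an average
  arrival is ~67 min.
- **Queue summary.** `queue_*` is the exact time-weighted average of
  the queue step function — the estimator with an analytic counterpart,
  which the transient oracle checks to Monte-Carlo resolution.
  `queue_sampled_*` is the unweighted mean of the queue column over the
  role's state-change records (one record per seize attempt or service
  completion). The unweighted form oversamples busy periods and
  reproduces the published queue-size means (it is the natural summary
  of a monitor's event log without time weights); the time-weighted
  form is the package's primary scientific measure. Both are reported
  side by side in every sweep table.

## The analytic oracle

The triage stage in isolation is an M/M/c queue started empty: a
birth–death chain with birth rate λ and death rate min(n, c)/mean. The
oracle solves its Kolmogorov forward equations on states 0..N via the
action of the generator's matrix exponential (Krylov-based
`expm_multiply`, machine-precision within the retained states). N
defaults to max(50, ⌈λT + 10√(λT)⌉) and auto-doubles until the top
state's probability stays below 1e−6; the uniform time grid is refined
until halving the step moves the time-averaged queue by < 1e−4.
Expected queue length is E[max(N(t)−c, 0)]; the expected virtual wait
of an arrival at t is E[max(N(t)−c+1, 0)]·mean/c (the Erlang sum of the
completions ahead of it), and by PASTA its time average equals the
arrival-averaged expected wait, giving the engine-side comparison
quantity computed by transforming the simulated state trajectory.
Erlang-C (via the Erlang-B recursion) supplies the ρ < 1 steady-state
limit used in long-horizon checks.

## What the tests do and do not show

The simulator *is* the data generator — no external data exist for
this design — so the suite establishes internal correctness, not
external validity: exact agreement of the triage stage with transient
M/M/c theory, Erlang-C and Little's-law closure in the stable regime,
structural invariants (patient conservation, FIFO, work conservation,
bit-exact replay) on every run, and reproduction of the published
triage-stage summaries under the estimator conventions above. Passing
says nothing about whether real UCC arrivals are Poisson, service times
exponential, or app savings homogeneous — the known simplifications of
this model family.

Problem sizes: verification runs use 5000 replications per scenario for
the study reproduction (matching the published plan), 80 × 100,000-min
runs for the steady-state limits, and smaller replication counts for
structural property checks.

## Known limitations

- Doctor-stage results inherit the uncertainty of `p_exam`/`p_return`;
  published doctor-stage and idle-time values are additionally not
  reconcilable with a single idle-time definition and are not used as
  numeric references anywhere.
- The published waiting-time reduction quoted in one summary (26.17%)
  disagrees with the value derived from the table itself (25.28%); the
  derived value is treated as authoritative.
- No time-varying arrival intensity, priority classes, staff breaks or
  device-availability queue for the app itself.
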