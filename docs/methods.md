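# Methods

## Model

The community is a bipartite population of seekers and helpers sharing one
stigmergic environment: a table of per-helper trail levels τ_h. The
routing state is deliberately the per-helper *aggregate* — selection only
ever consumes the total trail toward a helper, so storing per-edge
(seeker, helper) weights would add state the algorithm never reads.

Dynamics per interaction: the seeker's rating R ∈ {1..5} deposits
Δτ = R − 3 on the helper immediately at interaction completion.
Evaporation τ ← (1 − ρ)τ runs on a fixed hourly grid (Δt = 1 h),
decoupled from interaction timing, with ρ = 1 − 0.5^(1/T½). Selection
weight is max(τ_h, 0)^α + τ_min over the currently available helpers.

Two conventions deserve note because the bare formulas leave them open:

* **Negative trails in the selection rule.** With α = 1 a trail below
  −τ_min would make the literal weight τ_h^α + τ_min negative. We clamp
  the trail term at zero, so a negatively rated helper sits exactly on the
  exploration floor τ_min: suppressed, never excluded, and never a source
  of negative probabilities. The stored trail stays negative; recovery
  requires either positive ratings or evaporation.
* **Evaporation of negative trails.** Decay is multiplicative for all
  entries, so bad reputations fade toward zero at the same half-life as
  good ones — evaporation is a forgetting mechanism, not a reward.

No tie-breaking rule is needed anywhere: selection is probabilistic and
equal weights simply yield equal probabilities.

## Simulated community

Defaults (the study conditions): N = 1000 agents, 20% seekers / 80%
helpers, horizon 720 h (30 virtual days), hourly evaporation, α = 1,
τ_min = 0.1, T½ = 48 h.

* **Latent helpfulness.** Each helper draws H ~ Beta(2, 5) once (mean
  2/7): a right-skewed population with many moderately helpful members
  and few excellent ones.
* **Ratings.** A helper's latent score sets the mean rating through the
  affine map μ = 1 + 4H onto the 1–5 scale (preserving the Beta's skew);
  the observed rating is round(μ + ε) clamped to [1, 5], ε ~ N(0, σ) with
  σ = 0.7. At σ = 0.7 a helper with μ = 4 delivers a rating ≥ 4 about 76%
  of the time — "helpful most of the time" — while the population-average
  probability that a *random* helper's response is rated ≥ 4 is ≈ 0.075.
* **Arrivals.** Each seeker generates requests as an independent Poisson
  process, default 1 request/seeker/day, exposed for calibration.
* **Interactions.** Service times are exponential (memoryless minimal
  model), default mean 30 min, independent of outcome; a helper serves one
  interaction at a time. All agents are always online, so availability
  reduces to "not currently in an interaction".
* **Retries.** A response rated ≤ 3 returns the request to the routing
  queue immediately (zero re-think delay). Without retries the time to a
  *helpful* response could never span more than one interaction; with
  them, TTHR accumulates across attempts, which is the phenomenon of
  interest. When no helper is free, requests wait in a FIFO queue drained
  oldest-first (a fresh probabilistic draw per request) on every helper
  release — the simplest starvation-free policy.
* **Event ordering and randomness.** The discrete-event loop processes
  simultaneous events as: evaporation, then completions, then arrivals,
  then insertion order. One seeded generator serves the whole run and is
  consumed strictly in event order (population draw, arrival gaps, then
  per-event draws), so runs are bit-reproducible from the seed. Event
  times are real-valued minutes; evaporation sits on the hourly grid.

## Metrics

* **TTHR** — minutes from request creation to the first response the
  seeker rates ≥ 4, averaged over resolved requests. Requests unresolved
  at the horizon are excluded from the mean and reported as a count, so
  the censoring is visible rather than silently absorbed.
* **Load** — the number of requests a helper *resolved*. A request that
  bounced off an unhelpful helper was answered but not handled; counting
  raw responses instead would make loads uniform by construction under
  random routing (every helper is equally likely to be tried) and blind
  the metric to the super-helper effect. Both bases are computable
  (`helper_loads(..., basis="attempts")`); "resolved" is the default and
  is what the headline Gini, Lorenz, and top-quintile figures use. All
  helpers, including zero-load ones, enter the load vector — excluding
  them would understate inequality.
* **Gini** — mean-absolute-difference form G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄),
  computed by the equivalent sorted-cumulative formula and cross-checked
  in tests against the O(n²) definition. An all-zero load vector reports
  G = 0 with a warning (a vacuous run). The Lorenz curve satisfies
  G = 1 − 2·(trapezoidal area) to O(1/n), which is tested as an identity.

## Calibration and experiments

The arrival rate, service-time mean, and rating-noise level are
behavioural unknowns; absolute TTHR levels depend on them. Experiments
therefore anchor the *control* condition: bisection on one knob until
random routing's mean TTHR over ≥ 5 seeds hits a target (default
tolerance ± 5 min). The adaptive condition is then run on the identical
calibrated configuration, so its efficiency and equity numbers are
emergent, not fitted.

The default knob is the interaction-duration mean, not the arrival rate.
Under random routing a request needs on average 1/p̄ ≈ 13.3 attempts
(p̄ ≈ 0.075 as above), so the control TTHR has a zero-contention floor of
≈ 13.3 × (service mean) — about 400 min at the 30-min default. Raising
the arrival rate only adds queueing delay on top of that floor; it can
never pull TTHR *down* to targets below it. Duration bisects cleanly
through any target (an 84-min target calibrates to ≈ 7-min interactions,
plausible for short supportive chat exchanges). The arrival-rate knob
remains available and reports bracket exhaustion honestly when the target
is below the floor.

Replication is 10 seeds per cell (mean ± sd reported); the sensitivity
sweep is a full factorial over half-lives {6, 12, 24, 48, 72} h with a
shared seed list. The Pareto rule for choosing an operating half-life:
among grid points not dominated under (minimise TTHR, minimise Gini),
take the minimal-TTHR point, ties broken by lower Gini.

## What the generator does and does not emulate

The generator reproduces participation inequality (20/80 roles), skewed
helper quality, noisy subjective ratings, capacity contention, and
retry-driven waiting. It deliberately omits login/logout schedules, role
switching, helper fatigue or burnout feedback, topic content, and any
drift in helper quality — the population is *static* over the horizon.

Two consequences of that static regime, both computed by this package's
own tests and acceptance study, are worth stating plainly:

* **Adaptive routing concentrates resolved load here.** Only ≈ 10% of a
  Beta(2, 5) population has a positive expected deposit (μ > 3), so
  trails single out a small elite and the resolved-load Gini *rises*
  under adaptive routing (≈ 0.99 vs ≈ 0.73 for the random control in the
  calibrated study). The exploration floor guarantees everyone some
  traffic, but it cannot make weak helpers resolve requests. Claims that
  trail-based routing equalises load implicitly require mechanisms this
  generator omits (e.g. capacity saturation of top helpers, quality
  drift, or fatigue) — under the stated assumptions the efficiency gain
  and the equity gain do not co-occur.
* **No interior optimum in the half-life.** With nothing to forget
  (static helpers), longer memory is monotonically better for
  efficiency: TTHR decreases in T½ across the grid and the Pareto rule
  lands on the longest half-life. The textbook argument for an interior
  half-life rests on environmental change, which this generator excludes
  by design.

Passing tests therefore validate the algorithm's mechanics, determinism,
and the efficiency claim under helper scarcity; they do not show that the
algorithm balances load in real communities.

## Numerical choices

* Selection draws use one uniform variate against the cumulative weight
  vector (no per-draw normalisation), keeping the stream layout fixed.
* Trail snapshots and CSV logs print floats with `%.17g`, which
  round-trips IEEE doubles exactly; JSONL round-trips via native JSON
  floats.
* ρ is always derived from T½ at use time (never stored), so the identity
  ρ = 1 − 0.5^(1/T½) holds by construction.
* Bisection uses a [0.5, 120] min bracket, ≤ 30 iterations, and a
  fixed-point shortcut (an already-on-target configuration is returned
  unchanged). With a stochastic objective, tolerance 0 correctly fails.
* Problem sizes in the test suite are scaled to the statistics they
  check: oracle comparisons use 10⁴–10⁵ draws; full-size (1000-agent,
  30-day, 10-seed) runs are reserved for the acceptance study, which
  completes in about two minutes.

## Known limitations

Beyond the generator gaps above: trails are content-agnostic (no topic
matching); the moderator operations are library calls with an audit
trail, not a governance UI; and the simulator is single-colony,
single-process — no concurrent deposits or distributed trail storage.
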