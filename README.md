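# trailmap

Stigmergic (ant-colony-style) adaptive peer matching for online support
communities: the routing algorithm, a discrete-event agent-based simulator
of a peer support community, efficiency and equity metrics, and an
experiment harness for calibration and sensitivity analysis.

Online peer support platforms typically match help-seekers to helpers at
random or by queue order. That is slow for seekers (many unhelpful
interactions before a good one) and is entangled with the "super-helper"
problem: a small fraction of members carries most of the support load and
burns out. This package implements and studies a biomimetic alternative in
which the community's own feedback steers routing, the way ant colonies
steer foraging with pheromone trails. It is aimed at researchers in
digital mental-health systems, computational social science, and
swarm-intelligence routing who want a reproducible, fully seeded testbed
for this class of matching policies.

## The algorithm

Each helper *h* carries a trail level τ<sub>h</sub> (a "digital
pheromone"). Three rules drive the dynamics:

* **Deposition.** After an interaction the seeker rates its helpfulness
  *R* on a 1–5 Likert scale and the helper's trail changes by
  Δτ = *R* − 3. Ratings above neutral reinforce a helper; ratings below
  neutral deposit *negative* pheromone that actively suppresses one.
  τ<sub>h</sub> is the running sum of all deposits.
* **Evaporation.** Every hour each trail decays,
  τ ← (1 − ρ)τ, with ρ = 1 − 0.5<sup>1/T½</sup> parameterised by the
  half-life T½ (hours for an untouched trail to halve). Evaporation is the
  forgetting mechanism: both good and bad reputations fade.
* **Probabilistic selection.** A request is routed to an available helper
  with probability
  P(h) = (max(τ<sub>h</sub>, 0)<sup>α</sup> + τ<sub>min</sub>) / Σ<sub>k</sub>(max(τ<sub>k</sub>, 0)<sup>α</sup> + τ<sub>min</sub>).
  The floor τ<sub>min</sub> > 0 guarantees every available helper — new,
  unrated, or negatively rated — keeps a nonzero chance of selection
  (enforced exploration); α = 0 degenerates to uniform random routing.
  Defaults: α = 1, τ<sub>min</sub> = 0.1, T½ = 48 h.

The simulator embeds this rule in a community of 1000 agents (20%
seekers, 80% helpers) over 30 virtual days. Helpers carry a latent
helpfulness H ~ Beta(2, 5); ratings are drawn by mapping H onto the
rating scale (μ = 1 + 4H), adding Gaussian perception noise, rounding and
clamping. A rating ≥ 4 resolves the request; lower ratings send it back
to the queue, so the **time to helpful response (TTHR)** accumulates
across attempts. Equity is measured by the **Gini coefficient** and
Lorenz curve of resolved requests per helper.

## Worked example

`examples/03_compare_conditions.py` runs adaptive routing against the
random control on five shared seeds in a 100-agent community:

```
           mean_tthr_min    tthr_sd      gini  mean_rating
condition
random         89.404821  30.247906  0.719996     2.197784
trailmap       19.414852  12.874997  0.955716     3.218463

TTHR reduction: 78.3%
```

Under random routing a seeker waits ~89 minutes (on average ~13 attempts)
for a response they rate helpful; adaptive routing learns who the
effective helpers are and cuts this to ~19 minutes, raising the mean
delivered rating from 2.2 to 3.2. The Gini row shows the cost: resolved
requests concentrate on the helpers with strong trails (0.96 vs 0.72), a
finding discussed in `docs/methods.md`. The other example scripts cover
trail mechanics (`01`), a single instrumented run (`02`), and the
half-life sensitivity sweep with Pareto selection (`04`).

The same studies are available from the shell:

```sh
trailmap simulate --condition trailmap --half-life 48 --days 30 --seed 1 --out run/
trailmap metrics run/events.jsonl --out m.json --lorenz lorenz.csv
trailmap compare --seeds 1:10 --out cmp/
trailmap sweep --half-lives 6,12,24,48,72 --seeds 1:10 --out sweep/
trailmap calibrate --target-tthr 84 --tol 5 --out calibrated.yaml
```

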