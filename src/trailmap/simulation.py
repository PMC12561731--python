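"""Discrete-event agent-based simulation of a peer support community.

The simulated community has ``N`` agents split into a fixed proportion of
help-seekers and helpers (default 1000 agents, 20% / 80%, mirroring the
participation inequality of real support platforms).  Each helper carries a
latent helpfulness score drawn from a right-skewed Beta(2, 5): many
moderately helpful members, a few exceptionally effective ones.

Seekers generate support requests as independent Poisson processes.  A
request is routed to one *available* helper (not currently in an
interaction; everyone is modelled as always online), the interaction
occupies the helper for an exponentially distributed duration, and on
completion the seeker emits a 1-5 rating drawn from the helper's latent
score plus Gaussian perception noise.  A rating >= 4 resolves the request;
anything lower sends it straight back to the routing queue, so the time to
a *helpful* response accumulates across attempts.  Under the ``trailmap``
condition every rating is deposited into the shared trail table and routing
follows the pheromone selection rule; under the ``random`` control,
ratings are logged but routing stays uniform.

Trails evaporate on a fixed hourly grid for the whole horizon (default 720
hours = 30 virtual days).  All randomness flows from one seeded generator
consumed in event order, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from trailmap.pheromone import (
    RoutingParams,
    TrailTable,
    rating_to_delta,
    weights_from_tau,
)

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "HelperAgent",
    "SeekerAgent",
    "SupportRequest",
    "EventLog",
    "build_population",
    "sample_rating",
    "schedule_requests",
    "available_helpers",
    "route_request",
    "run_simulation",
]

CONDITIONS = ("trailmap", "random")

#: Minimum rating that counts as a helpful (request-resolving) response.
HELPFUL_THRESHOLD = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulation run.

    The population, horizon, and rating model defaults are the study
    conditions (1000 agents, 20/80 split, Beta(2, 5) latent helpfulness,
    720 h horizon, hourly evaporation); arrival rate, interaction duration,
    and rating noise are behavioural parameters exposed for calibration.
    """

    n_agents: int = 1000
    seeker_proportion: float = 0.2
    helper_proportion: float = 0.8
    latent_beta_a: float = 2.0
    latent_beta_b: float = 5.0
    duration_hours: float = 720.0
    evaporation_interval_hours: float = 1.0
    condition: str = "trailmap"
    routing: RoutingParams = field(default_factory=RoutingParams)
    request_rate_per_seeker_per_day: float = 1.0
    interaction_duration_mean_min: float = 30.0
    rating_noise_sd: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` on any constraint violation, before any work."""
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if abs(self.seeker_proportion + self.helper_proportion - 1.0) > 1e-9:
            raise ValueError(
                "seeker_proportion + helper_proportion must equal 1, got "
                f"{self.seeker_proportion} + {self.helper_proportion}"
            )
        n_seek = self.n_agents * self.seeker_proportion
        if abs(n_seek - round(n_seek)) > 1e-9:
            raise ValueError(
                f"n_agents * seeker_proportion = {n_seek} is not an integer"
            )
        for name in (
            "latent_beta_a",
            "latent_beta_b",
            "duration_hours",
            "evaporation_interval_hours",
            "request_rate_per_seeker_per_day",
            "interaction_duration_mean_min",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        steps = self.duration_hours / self.evaporation_interval_hours
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError(
                "duration_hours must be a positive multiple of "
                "evaporation_interval_hours"
            )

    @property
    def n_seekers(self) -> int:
        return int(round(self.n_agents * self.seeker_proportion))

    @property
    def n_helpers(self) -> int:
        return self.n_agents - self.n_seekers

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SeekerAgent:
    """A help-seeking community member."""

    id: int
    pending_requests: list = field(default_factory=list)


@dataclass
class HelperAgent:
    """A help-providing community member.

    ``h_latent`` is the intrinsic helpfulness in (0, 1) that parameterises
    the seeker's rating distribution; ``busy_until`` is the minute at which
    the helper's current interaction ends (0 when free).
    """

    id: int
    h_latent: float
    busy_until: float = 0.0


@dataclass
class SupportRequest:
    """One support request and its resolution bookkeeping."""

    id: int
    seeker_id: int
    t_created: float
    attempts: int = 0
    t_first_helpful: Optional[float] = None
    status: str = "open"  # open | in_interaction | resolved


class EventLog:
    """Time-ordered record of everything that happened in a run.

    Records are plain dicts with a fixed schema: ``event`` (one of
    ``request_created | routed | interaction_completed | trail_evaporated``),
    ``t_min``, and where applicable ``request_id``, ``seeker_id``,
    ``helper_id``, ``rating``, ``tau_after`` (``None`` where inapplicable;
    for evaporation records ``tau_after`` is the total trail mass).
    ``helper_ids`` carries the full helper registry so that zero-load
    helpers are part of every load metric.
    """

    FIELDS = (
        "event",
        "t_min",
        "request_id",
        "seeker_id",
        "helper_id",
        "rating",
        "tau_after",
    )

    def __init__(
        self,
        records: Optional[List[dict]] = None,
        helper_ids: Optional[Sequence[int]] = None,
    ) -> None:
        self.records: List[dict] = records if records is not None else []
        self.helper_ids: Optional[Tuple[int, ...]] = (
            tuple(helper_ids) if helper_ids is not None else None
        )

    def append(self, event: str, t_min: float, **fields) -> None:
        rec = {
            "event": event,
            "t_min": float(t_min),
            "request_id": None,
            "seeker_id": None,
            "helper_id": None,
            "rating": None,
            "tau_after": None,
        }
        rec.update(fields)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.records == other.records

    def counts(self) -> dict:
        out: dict = {}
        for r in self.records:
            out[r["event"]] = out.get(r["event"], 0) + 1
        return out


def build_population(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[List[SeekerAgent], List[HelperAgent], TrailTable]:
    """Instantiate seekers, helpers (with latent helpfulness), and trails.

    Seekers get ids ``0 .. n_seekers-1`` and helpers
    ``n_seekers .. n_agents-1`` (disjoint by construction).  Each helper's
    latent helpfulness is an i.i.d. Beta(a, b) draw; the trail table starts
    at 0 for every helper.
    """
    config.validate()
    n_s, n_h = config.n_seekers, config.n_helpers
    seekers = [SeekerAgent(id=i) for i in range(n_s)]
    h_latent = rng.beta(config.latent_beta_a, config.latent_beta_b, size=n_h)
    helpers = [
        HelperAgent(id=n_s + j, h_latent=float(h_latent[j])) for j in range(n_h)
    ]
    table = TrailTable(h.id for h in helpers)
    return seekers, helpers, table


def sample_rating(
    h_latent: float, sigma: float, rng: np.random.Generator
) -> int:
    """Draw a 1-5 helpfulness rating for a helper with latent score ``h``.

    The latent score in (0, 1) is mapped affinely onto the rating scale,
    ``mu = 1 + 4 h`` (preserving the Beta's right skew), Gaussian
    perception noise is added, and the result is rounded to the nearest
    integer and clamped to [1, 5].
    """
    if not (0.0 < h_latent < 1.0):
        raise ValueError(f"h_latent must be in (0, 1), got {h_latent!r}")
    mu = 1.0 + 4.0 * h_latent
    raw = mu + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return int(min(5, max(1, round(raw))))


def schedule_requests(
    seekers: Sequence[SeekerAgent],
    rate_per_day: float,
    horizon_min: float,
    rng: np.random.Generator,
) -> List[Tuple[int, float]]:
    """Homogeneous Poisson request arrivals per seeker, merged and sorted.

    Each seeker generates arrivals with exponential inter-arrival gaps at
    ``rate_per_day`` over ``[0, horizon_min)``; seekers are processed in id
    order so the stream is reproducible from the generator state.  Ties are
    broken by seeker order, and the merged stream is sorted by time.
    """
    if not (rate_per_day > 0):
        raise ValueError(f"rate_per_day must be > 0, got {rate_per_day!r}")
    rate_per_min = rate_per_day / (24.0 * 60.0)
    out: List[Tuple[int, float]] = []
    for s in seekers:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_per_min)
            if t >= horizon_min:
                break
            out.append((s.id, t))
    out.sort(key=lambda p: (p[1], p[0]))
    return out


def available_helpers(
    helpers: Sequence[HelperAgent], t: float
) -> List[int]:
    """Ids of helpers free at minute ``t`` (``busy_until <= t``).

    Every helper is modelled as always logged in, so availability reduces
    to "not currently in an active interaction".
    """
    return [h.id for h in helpers if h.busy_until <= t]


def route_request(
    table: TrailTable,
    available: Sequence[int],
    condition: str,
    params: RoutingParams,
    rng: np.random.Generator,
) -> int:
    """Choose one helper from the available set for the given condition.

    ``trailmap`` draws from the pheromone selection distribution
    (weights ``max(tau, 0)**alpha + tau_min``); ``random`` draws uniformly.
    Raises ``ValueError`` on an empty availability set — the caller queues
    the request instead.
    """
    if len(available) == 0:
        raise ValueError("no available helpers: queue the request")
    if condition == "random":
        return available[int(rng.integers(len(available)))]
    if condition != "trailmap":
        raise ValueError(f"unknown condition {condition!r}")
    idx = np.fromiter(
        (table.index_of(h) for h in available), dtype=int, count=len(available)
    )
    w = weights_from_tau(table.values[idx], params.alpha, params.tau_min)
    cdf = np.cumsum(w)
    i = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    return available[min(i, len(available) - 1)]


# Event-type priorities for simultaneous events: evaporation happens on the
# hour boundary before any routing at that instant; completions free helpers
# before new arrivals are routed.
_PRIO_EVAPORATE = 0
_PRIO_COMPLETE = 1
_PRIO_ARRIVAL = 2


def run_simulation(config: SimulationConfig):
    """Run one full community simulation; returns ``(EventLog, MetricsResult)``.

    Discrete-event loop over the horizon: request arrivals, interaction
    completions, and hourly evaporation boundaries are processed in time
    order (ties: evaporation, then completions, then arrivals, then
    insertion order).  Interactions still in flight at the horizon remain
    incomplete; their requests count as unresolved.  For a fixed seed the
    event log is byte-identical across runs.
    """
    from trailmap.metrics import compute_metrics  # cycle-free late import

    config.validate()
    rng = np.random.default_rng(config.seed)
    seekers, helpers, table = build_population(config, rng)
    horizon_min = config.duration_hours * 60.0
    arrivals = schedule_requests(
        seekers, config.request_rate_per_seeker_per_day, horizon_min, rng
    )
    rho = config.routing.evaporation_rate
    n_helpers = len(helpers)
    helper_offset = config.n_seekers
    busy_until = np.zeros(n_helpers, dtype=float)
    tau = table._tau  # dense trail vector, shared with the table
    h_latent = np.array([h.h_latent for h in helpers])
    is_trailmap = config.condition == "trailmap"
    alpha, tau_min = config.routing.alpha, config.routing.tau_min

    log = EventLog(helper_ids=[h.id for h in helpers])
    requests: List[SupportRequest] = []
    queue: deque[int] = deque()

    heap: list = []
    seq = 0
    for sid, t in arrivals:
        heapq.heappush(heap, (t, _PRIO_ARRIVAL, seq, sid))
        seq += 1
    n_steps = int(round(config.duration_hours / config.evaporation_interval_hours))
    for k in range(1, n_steps + 1):
        heapq.heappush(
            heap,
            (k * config.evaporation_interval_hours * 60.0, _PRIO_EVAPORATE, seq, k),
        )
        seq += 1

    def start_interaction(req: SupportRequest, t: float) -> bool:
        """Route and start an interaction; False if nobody is available."""
        nonlocal seq
        free = np.flatnonzero(busy_until <= t)
        if free.size == 0:
            return False
        if is_trailmap:
            w = weights_from_tau(tau[free], alpha, tau_min)
            cdf = np.cumsum(w)
            j = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
            hidx = int(free[min(j, free.size - 1)])
        else:
            hidx = int(free[int(rng.integers(free.size))])
        duration = rng.exponential(config.interaction_duration_mean_min)
        t_end = t + duration
        busy_until[hidx] = t_end
        helpers[hidx].busy_until = t_end
        req.status = "in_interaction"
        log.append(
            "routed",
            t,
            request_id=req.id,
            seeker_id=req.seeker_id,
            helper_id=helper_offset + hidx,
            tau_after=float(tau[hidx]),
        )
        heapq.heappush(heap, (t_end, _PRIO_COMPLETE, seq, (req.id, hidx, t)))
        seq += 1
        return True

    def drain_queue(t: float) -> None:
        while queue and np.any(busy_until <= t):
            req = requests[queue[0]]
            if start_interaction(req, t):
                queue.popleft()
            else:  # pragma: no cover - guarded by the loop condition
                break

    while heap:
        t, prio, _, payload = heapq.heappop(heap)
        if t > horizon_min:
            break
        if prio == _PRIO_EVAPORATE:
            tau *= 1.0 - rho
            table.last_evaporation_hour = payload
            log.append("trail_evaporated", t, tau_after=float(tau.sum()))
            # helpers freed exactly on the boundary can pick up queued work
            drain_queue(t)
        elif prio == _PRIO_ARRIVAL:
            req = SupportRequest(
                id=len(requests), seeker_id=payload, t_created=t
            )
            requests.append(req)
            seekers[payload].pending_requests.append(req.id)
            log.append(
                "request_created", t, request_id=req.id, seeker_id=payload
            )
            queue.append(req.id)
            drain_queue(t)
        else:  # completion
            req_id, hidx, t_start = payload
            req = requests[req_id]
            rating = sample_rating(
                float(h_latent[hidx]), config.rating_noise_sd, rng
            )
            req.attempts += 1
            if is_trailmap:
                tau[hidx] += rating_to_delta(rating)
            log.append(
                "interaction_completed",
                t,
                request_id=req_id,
                seeker_id=req.seeker_id,
                helper_id=helper_offset + hidx,
                rating=rating,
                tau_after=float(tau[hidx]),
            )
            if rating >= HELPFUL_THRESHOLD and req.t_first_helpful is None:
                req.t_first_helpful = t
                req.status = "resolved"
                seekers[req.seeker_id].pending_requests.remove(req_id)
            else:
                req.status = "open"
                queue.append(req_id)
            drain_queue(t)

    metrics = compute_metrics(log, helper_ids=log.helper_ids)
    return log, metrics
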