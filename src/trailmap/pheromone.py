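"""The TrailMap trail algorithm: deposition, evaporation, and selection.

A community's routing state is a *trail table*: one dimensionless pheromone
level ``tau_h`` per registered helper.  Three mechanisms act on it:

* **Deposition** — after a rated interaction the helper's trail changes by
  ``R - 3`` where ``R`` is a 1-5 Likert helpfulness rating, so ratings above
  neutral reinforce a helper and ratings below neutral actively suppress one.
* **Evaporation** — at a fixed interval (one hour by convention) every trail
  is multiplied by ``1 - rho``.  The rate ``rho`` is parameterised by the
  more intuitive half-life ``T_half`` via ``rho = 1 - 0.5 ** (1 / T_half)``,
  the hours for an untouched trail to halve.
* **Probabilistic selection** — a request is routed to an available helper
  with probability proportional to ``max(tau_h, 0) ** alpha + tau_min``.
  ``tau_min > 0`` is the exploration floor: helpers with zero or negative
  trails keep a nonzero chance of being chosen, which onboards newcomers and
  prevents lock-in on a small elite.  ``alpha = 0`` degenerates to uniform
  random choice.

Negative trails are clamped to zero *inside the selection weight only*; the
stored trail remains negative so that a poorly rated helper must either be
re-rated positively or wait for evaporation to forget the record.

Moderator governance operations (:func:`prune_trail`, :func:`explain_match`)
support human-in-the-loop oversight: trails can be reset with an audit
record, and matches can be explained with a plain-language template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, Mapping

import numpy as np

__all__ = [
    "HelperId",
    "RatingEvent",
    "RoutingParams",
    "TrailTable",
    "rating_to_delta",
    "deposit",
    "halflife_to_rate",
    "evaporate",
    "selection_weights",
    "selection_probabilities",
    "select_helper",
    "prune_trail",
    "explain_match",
    "weights_from_tau",
]

HelperId = Hashable

#: Likert anchor around which deposition is centred: a rating of 3 is neutral.
NEUTRAL_RATING = 3

VALID_RATINGS = frozenset({1, 2, 3, 4, 5})


def rating_to_delta(rating: int) -> int:
    """Pheromone increment deposited by a helpfulness rating.

    The deposition rule is ``delta = R - 3``: ratings of 4-5 deposit
    positive pheromone, 3 deposits nothing, 1-2 deposit negative pheromone
    so the community can suppress unhelpful or harmful actors.

    Parameters
    ----------
    rating : int
        Likert rating in {1, 2, 3, 4, 5}.

    Returns
    -------
    int
        ``rating - 3``, one of {-2, -1, 0, 1, 2}.

    Raises
    ------
    ValueError
        If ``rating`` is not an integer in 1..5 (corrupt feedback).
    """
    if isinstance(rating, bool) or not isinstance(rating, (int, np.integer)):
        raise ValueError(f"rating must be an integer 1-5, got {rating!r}")
    if rating not in VALID_RATINGS:
        raise ValueError(f"rating must be in 1..5, got {rating}")
    return int(rating) - NEUTRAL_RATING


def halflife_to_rate(half_life_hours: float) -> float:
    """Per-interval evaporation rate for a given trail half-life.

    ``rho = 1 - 0.5 ** (1 / T_half)``: applying ``tau <- (1 - rho) * tau``
    once per hour for ``T_half`` hours halves any trail.  ``rho`` is
    strictly decreasing in the half-life and tends to 0 as it grows.

    Raises
    ------
    ValueError
        If ``half_life_hours`` is not strictly positive.
    """
    if not (half_life_hours > 0):
        raise ValueError(f"half-life must be > 0 hours, got {half_life_hours!r}")
    return 1.0 - 0.5 ** (1.0 / float(half_life_hours))


@dataclass(frozen=True)
class RoutingParams:
    """Parameters of the probabilistic routing rule and trail decay.

    Attributes
    ----------
    alpha : float
        Heuristic-importance exponent (>= 0).  Higher values make selection
        greedier; 0 yields purely random selection.  Default 1.
    tau_min : float
        Exploration floor (> 0) added to every selection weight.
        Default 0.1.
    half_life_hours : float
        Trail half-life ``T_half`` in hours (> 0).  Default 48.
    delta_t_hours : float
        Evaporation interval in hours.  Default 1.
    """

    alpha: float = 1.0
    tau_min: float = 0.1
    half_life_hours: float = 48.0
    delta_t_hours: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha >= 0):
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not (self.tau_min > 0):
            raise ValueError(f"tau_min must be > 0, got {self.tau_min}")
        if not (self.half_life_hours > 0):
            raise ValueError(
                f"half_life_hours must be > 0, got {self.half_life_hours}"
            )
        if not (self.delta_t_hours > 0):
            raise ValueError(
                f"delta_t_hours must be > 0, got {self.delta_t_hours}"
            )

    @property
    def evaporation_rate(self) -> float:
        """Per-interval decay fraction, ``1 - 0.5 ** (1 / T_half)``."""
        return halflife_to_rate(self.half_life_hours)


@dataclass(frozen=True)
class RatingEvent:
    """One rated seeker-helper interaction."""

    seeker_id: Hashable
    helper_id: HelperId
    rating: int
    time_min: float = 0.0

    def __post_init__(self) -> None:
        rating_to_delta(self.rating)  # validates


class TrailTable:
    """Per-helper pheromone levels: the stigmergic shared environment.

    Every registered helper has exactly one entry, initialised to 0.
    Entries are stored in a dense float array (with an id -> index map) so
    that the simulator can form selection weights over hundreds of helpers
    per routed request without Python-level loops.

    Attributes
    ----------
    last_evaporation_hour : int
        Bookkeeping for trail decay: number of evaporation intervals applied
        so far, in units of the caller's ``delta_t``.
    audit : list of dict
        Append-only audit records emitted by moderator operations
        (:func:`prune_trail`).
    """

    def __init__(self, helper_ids: Iterable[HelperId] = ()) -> None:
        self._index: Dict[HelperId, int] = {}
        self._ids: list[HelperId] = []
        self._tau = np.zeros(0, dtype=float)
        self.last_evaporation_hour: int = 0
        self.audit: list[dict] = []
        for hid in helper_ids:
            self.register(hid)

    # -- registry -----------------------------------------------------

    def register(self, helper_id: HelperId) -> None:
        """Add a helper with trail 0; re-registration is an error."""
        if helper_id in self._index:
            raise ValueError(f"helper {helper_id!r} already registered")
        self._index[helper_id] = len(self._ids)
        self._ids.append(helper_id)
        self._tau = np.append(self._tau, 0.0)

    def __contains__(self, helper_id: HelperId) -> bool:
        return helper_id in self._index

    def __len__(self) -> int:
        return len(self._ids)

    @property
    def helper_ids(self) -> tuple:
        return tuple(self._ids)

    def index_of(self, helper_id: HelperId) -> int:
        try:
            return self._index[helper_id]
        except KeyError:
            raise KeyError(
                f"helper {helper_id!r} is not registered in the trail table "
                "(registry/trail desynchronisation)"
            ) from None

    # -- values -------------------------------------------------------

    def tau(self, helper_id: HelperId) -> float:
        """Current trail level of one helper."""
        return float(self._tau[self.index_of(helper_id)])

    @property
    def values(self) -> np.ndarray:
        """Dense trail vector in registration order (read-only view)."""
        v = self._tau.view()
        v.flags.writeable = False
        return v

    def as_dict(self) -> Dict[HelperId, float]:
        return {hid: float(self._tau[i]) for hid, i in self._index.items()}

    def _set(self, helper_id: HelperId, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"trail value must be finite, got {value!r}")
        self._tau[self.index_of(helper_id)] = value

    def copy(self) -> "TrailTable":
        out = TrailTable()
        out._index = dict(self._index)
        out._ids = list(self._ids)
        out._tau = self._tau.copy()
        out.last_evaporation_hour = self.last_evaporation_hour
        out.audit = list(self.audit)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TrailTable(n={len(self)}, "
            f"last_evaporation_hour={self.last_evaporation_hour})"
        )


def deposit(table: TrailTable, event: RatingEvent) -> TrailTable:
    """Apply one rating's pheromone deposit to the helper's trail.

    The helper's aggregate trail is the running sum of all deposits (less
    evaporation); no other entry is touched.  Returns the same table for
    chaining.

    Raises
    ------
    KeyError
        If the helper is not registered.
    """
    i = table.index_of(event.helper_id)
    table._tau[i] += rating_to_delta(event.rating)
    return table


def evaporate(table: TrailTable, rho: float, n_steps: int = 1) -> TrailTable:
    """Apply ``n_steps`` evaporation intervals: ``tau <- (1 - rho)**n * tau``.

    Decay is multiplicative and applies to negative entries as well, so bad
    reputations also fade toward zero — evaporation is the community's
    forgetting mechanism, not a reward.  ``last_evaporation_hour`` advances
    by ``n_steps`` intervals.

    Raises
    ------
    ValueError
        If ``rho`` is outside (0, 1) or ``n_steps`` is negative.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"evaporation rate must be in (0, 1), got {rho!r}")
    if not isinstance(n_steps, (int, np.integer)) or isinstance(n_steps, bool):
        raise ValueError(f"n_steps must be an integer >= 0, got {n_steps!r}")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0: time cannot run backward")
    table._tau *= (1.0 - rho) ** int(n_steps)
    table.last_evaporation_hour += int(n_steps)
    return table


def weights_from_tau(tau: np.ndarray, alpha: float, tau_min: float) -> np.ndarray:
    """Selection weights ``max(tau, 0) ** alpha + tau_min`` (vectorised).

    The clamp keeps the routing rule well defined for negative trails: a
    negatively rated helper falls to the exploration floor ``tau_min`` but
    never below, preserving the guarantee that every available helper has a
    nonzero selection probability.  With ``alpha = 0`` every weight is
    ``1 + tau_min`` (uniform selection).
    """
    return np.clip(np.asarray(tau, dtype=float), 0.0, None) ** alpha + tau_min


def selection_weights(
    table: TrailTable,
    available: Iterable[HelperId],
    params: RoutingParams,
) -> Dict[HelperId, float]:
    """Unnormalised routing weights for the available helpers.

    Raises
    ------
    ValueError
        If the availability set is empty (the caller must queue the request
        instead of routing it).
    KeyError
        If an available helper is not registered.
    """
    avail = list(available)
    if not avail:
        raise ValueError("availability set is empty: queue the request instead")
    idx = np.array([table.index_of(h) for h in avail], dtype=int)
    w = weights_from_tau(table._tau[idx], params.alpha, params.tau_min)
    return dict(zip(avail, w.tolist()))


def selection_probabilities(
    weights: Mapping[HelperId, float],
) -> Dict[HelperId, float]:
    """Normalise positive weights to a categorical distribution.

    Probabilities sum to 1, are strictly positive, and are monotone in the
    weights.

    Raises
    ------
    ValueError
        If any weight is non-positive (violates the exploration guarantee).
    """
    if not weights:
        raise ValueError("weights mapping is empty")
    w = np.fromiter(weights.values(), dtype=float, count=len(weights))
    if np.any(w <= 0):
        raise ValueError("all selection weights must be > 0")
    p = w / w.sum()
    return dict(zip(weights.keys(), p.tolist()))


def select_helper(
    probabilities: Mapping[HelperId, float],
    rng: np.random.Generator,
) -> HelperId:
    """Draw one helper from a categorical routing distribution.

    The draw uses a single uniform variate against the cumulative weights in
    mapping order, so a run's random stream is consumed in a fixed,
    reproducible order.
    """
    ids = list(probabilities.keys())
    p = np.fromiter(probabilities.values(), dtype=float, count=len(ids))
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be non-negative and sum to 1")
    cdf = np.cumsum(p)
    i = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    return ids[min(i, len(ids) - 1)]


def prune_trail(
    table: TrailTable,
    helper_id: HelperId,
    new_value: float = 0.0,
    actor: str = "moderator",
    time_hour: float | None = None,
) -> TrailTable:
    """Moderator override: set a helper's trail to ``new_value`` (default 0).

    Supports human-in-the-loop governance — e.g. resetting the trail of a
    user found to be spreading misinformation, removing them from the
    trusted pool.  An audit record (time, helper, old/new value, actor) is
    appended to ``table.audit``.

    Raises
    ------
    KeyError
        If the helper is not registered.
    """
    i = table.index_of(helper_id)
    old = float(table._tau[i])
    table._set(helper_id, float(new_value))
    table.audit.append(
        {
            "time_hour": (
                float(time_hour)
                if time_hour is not None
                else float(table.last_evaporation_hour)
            ),
            "helper_id": helper_id,
            "old_value": old,
            "new_value": float(new_value),
            "actor": actor,
        }
    )
    return table


_HELPFUL_TEMPLATE = (
    "You were connected with {helper} because they have been rated as very "
    "helpful by others recently."
)
_EXPLORE_TEMPLATE = (
    "You were connected with {helper} to give a newer member of the "
    "community a chance to help."
)


def explain_match(
    helper_id: HelperId,
    trail_value: float,
    threshold: float,
) -> str:
    """Plain-language explanation of a match, for transparency.

    Helpers whose trail is at or above ``threshold`` get the
    reputation-based template; below it, the exploration-phrased template.
    Deterministic for fixed inputs.
    """
    template = _HELPFUL_TEMPLATE if trail_value >= threshold else _EXPLORE_TEMPLATE
    return template.format(helper=helper_id)
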