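"""Efficiency and equity statistics over a simulation event log.

Two families of measures:

* **Efficiency** — mean time to helpful response (TTHR): minutes from a
  request's creation to its first response rated >= 4, averaged over
  resolved requests.  Requests never resolved by the horizon are excluded
  from the mean and reported as a count, so the censoring is visible.
* **Equity** — the dispersion of the per-helper load: Gini coefficient,
  Lorenz curve, and the share of load carried by the top quantile of
  helpers.  The load of a helper is the number of requests they *resolved*
  (delivered the response rated >= 4); a request bounced off an unhelpful
  helper was answered but not handled.  Zero-load helpers are included, as
  excluding them would understate inequality.  Attempt counts (responses
  served, helpful or not) are available as an alternative basis.

The Gini here is the standard mean-absolute-difference form
``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))``, computed via the equivalent
sorted-cumulative formula; it is scale-invariant, permutation-invariant,
and reaches its maximum (n-1)/n when a single helper carries everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MetricsResult",
    "mean_tthr",
    "gini",
    "lorenz",
    "top_share",
    "helper_loads",
    "compute_metrics",
]

HELPFUL_THRESHOLD = 4


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given log (e.g. no
    resolved requests)."""


@dataclass(frozen=True)
class MetricsResult:
    """Summary statistics of one simulation run."""

    mean_tthr_min: float
    n_resolved: int
    n_unresolved: int
    gini: float
    lorenz_points: Tuple[Tuple[float, float], ...]
    top20_share: float
    mean_rating: float = float("nan")
    n_interactions: int = 0
    attempts_gini: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "mean_tthr_min": self.mean_tthr_min,
            "n_resolved": self.n_resolved,
            "n_unresolved": self.n_unresolved,
            "gini": self.gini,
            "top20_share": self.top20_share,
            "mean_rating": self.mean_rating,
            "n_interactions": self.n_interactions,
            "attempts_gini": self.attempts_gini,
            "lorenz_points": [list(p) for p in self.lorenz_points],
        }


def _validate_loads(loads) -> np.ndarray:
    x = np.asarray(loads, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("loads must be a 1-D vector of length >= 2")
    if np.any(x < 0):
        raise ValueError("loads must be non-negative")
    if not np.all(np.isfinite(x)):
        raise ValueError("loads must be finite")
    return x


def gini(loads) -> float:
    """Gini coefficient of a non-negative load vector.

    ``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))``: 0 for perfectly equal
    loads, (n-1)/n when one helper carries everything.  An all-zero vector
    returns 0 with a warning (a vacuous run, not perfect equality in any
    meaningful sense).
    """
    x = np.sort(_validate_loads(loads))
    n = x.size
    total = x.sum()
    if total == 0:
        warnings.warn(
            "all loads are zero; Gini reported as 0 for a vacuous run",
            stacklevel=2,
        )
        return 0.0
    # sorted-cumulative equivalent of the pairwise-difference formula
    cum = np.cumsum(x)
    return float((n + 1 - 2.0 * (cum / total).sum()) / n)


def lorenz(loads) -> List[Tuple[float, float]]:
    """Lorenz curve of the load distribution.

    Helpers are sorted by ascending load; the curve gives (cumulative
    helper fraction, cumulative load fraction), starting at (0, 0) and
    ending at (1, 1).  The area identity ``G = 1 - 2 * area_under_curve``
    (trapezoidal) recovers the Gini to within O(1/n).
    """
    x = np.sort(_validate_loads(loads))
    n = x.size
    total = x.sum()
    if total == 0:
        warnings.warn(
            "all loads are zero; Lorenz curve reported as the diagonal",
            stacklevel=2,
        )
        frac = np.arange(n + 1) / n
        return list(zip(frac.tolist(), frac.tolist()))
    cum = np.concatenate([[0.0], np.cumsum(x) / total])
    frac = np.arange(n + 1) / n
    return list(zip(frac.tolist(), cum.tolist()))


def top_share(loads, fraction: float) -> float:
    """Fraction of total load carried by the top ``fraction`` of helpers.

    The top ``ceil(fraction * n)`` helpers by load are summed and divided
    by the total load.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction!r}")
    x = np.sort(_validate_loads(loads))[::-1]
    total = x.sum()
    if total == 0:
        warnings.warn("all loads are zero; top share reported as 0", stacklevel=2)
        return 0.0
    k = int(np.ceil(fraction * x.size))
    return float(x[:k].sum() / total)


def mean_tthr(log) -> Tuple[float, int, int]:
    """Mean time to helpful response over a full event log.

    Returns ``(mean_minutes, n_resolved, n_unresolved)``.  A request's TTHR
    is the time from its creation to the first completed interaction rated
    >= 4; requests without such a response by the end of the log are
    excluded from the mean and counted as unresolved.

    Raises
    ------
    UndefinedMetricError
        If the log contains no resolved request.
    """
    created: dict = {}
    first_helpful: dict = {}
    for rec in log:
        ev = rec["event"]
        if ev == "request_created":
            created[rec["request_id"]] = rec["t_min"]
        elif (
            ev == "interaction_completed"
            and rec["rating"] is not None
            and rec["rating"] >= HELPFUL_THRESHOLD
        ):
            rid = rec["request_id"]
            if rid not in first_helpful or rec["t_min"] < first_helpful[rid]:
                first_helpful[rid] = rec["t_min"]
    waits = [
        first_helpful[rid] - t0 for rid, t0 in created.items() if rid in first_helpful
    ]
    n_res = len(waits)
    n_unres = len(created) - n_res
    if n_res == 0:
        raise UndefinedMetricError(
            "mean TTHR is undefined: the log contains no resolved request"
        )
    return float(np.mean(waits)), n_res, n_unres


def helper_loads(
    log,
    helper_ids: Optional[Sequence[int]] = None,
    basis: str = "resolved",
) -> np.ndarray:
    """Per-helper load vector from an event log.

    ``basis="resolved"`` counts requests the helper resolved (first
    response rated >= 4); ``basis="attempts"`` counts every response the
    helper delivered.  ``helper_ids`` fixes the helper universe so that
    zero-load helpers are included; when omitted it is taken from the log's
    own registry, or (with a warning) from the helpers that appear in it.
    """
    if basis not in ("resolved", "attempts"):
        raise ValueError(f"basis must be 'resolved' or 'attempts', got {basis!r}")
    if helper_ids is None:
        helper_ids = getattr(log, "helper_ids", None)
    if helper_ids is None:
        seen = sorted(
            {
                r["helper_id"]
                for r in log
                if r["event"] in ("routed", "interaction_completed")
                and r["helper_id"] is not None
            }
        )
        warnings.warn(
            "no helper registry supplied; zero-load helpers are invisible and "
            "inequality will be understated",
            stacklevel=2,
        )
        helper_ids = seen
    index = {h: i for i, h in enumerate(helper_ids)}
    loads = np.zeros(len(index), dtype=float)
    resolved_requests: set = set()
    for rec in log:
        if rec["event"] != "interaction_completed":
            continue
        h = rec["helper_id"]
        if h not in index:
            continue
        if basis == "attempts":
            loads[index[h]] += 1
        else:
            rid = rec["request_id"]
            if rec["rating"] is not None and rec["rating"] >= HELPFUL_THRESHOLD:
                if rid not in resolved_requests:
                    resolved_requests.add(rid)
                    loads[index[h]] += 1
    return loads


def compute_metrics(
    log,
    helper_ids: Optional[Sequence[int]] = None,
    load_basis: str = "resolved",
) -> MetricsResult:
    """All summary metrics for one run's event log.

    If no request resolved, the TTHR is reported as NaN (with counts) rather
    than raising, so that degenerate runs still produce a result object.
    """
    try:
        tthr, n_res, n_unres = mean_tthr(log)
    except UndefinedMetricError:
        tthr = float("nan")
        n_res = 0
        n_unres = sum(1 for r in log if r["event"] == "request_created")
    loads = helper_loads(log, helper_ids=helper_ids, basis=load_basis)
    attempts = helper_loads(log, helper_ids=helper_ids, basis="attempts")
    ratings = [
        r["rating"]
        for r in log
        if r["event"] == "interaction_completed" and r["rating"] is not None
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # vacuous-run warnings on empty logs
        g = gini(loads) if loads.size >= 2 else 0.0
        pts = tuple(tuple(p) for p in lorenz(loads)) if loads.size >= 2 else ()
        t20 = top_share(loads, 0.2) if loads.size >= 2 else 0.0
        ag = gini(attempts) if attempts.size >= 2 else float("nan")
    return MetricsResult(
        mean_tthr_min=tthr,
        n_resolved=n_res,
        n_unresolved=n_unres,
        gini=g,
        lorenz_points=pts,
        top20_share=t20,
        mean_rating=float(np.mean(ratings)) if ratings else float("nan"),
        n_interactions=len(ratings),
        attempts_gini=ag,
    )
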