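"""Per-mouse running distance from cage wheel counters and sampled video.

Enriched cages hold three mice sharing three wheels with a single daily spin
total per cage.  The first 3 minutes of every video-recorded hour are scored
for how many seconds each mouse ran.  For a cage-day, mouse ``i``'s observed
seconds ``t_i`` divided by the total time ``T`` during which at least one
mouse ran gives its activity proportion ``p_i = t_i / T``; since mice can
run simultaneously the proportions may sum above one, so the day's spins are
allocated by the renormalized shares ``p_i / sum_j p_j`` — equivalently
``t_i / sum_j t_j`` — which conserves the counted spins exactly.  Spins are
converted to distance with the wheel circumference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from dgquant.core import ActivityLog

__all__ = ["DistanceEstimate", "UnattributableActivityError",
           "allocate_spins", "total_distance", "estimate_distances"]


@dataclass
class DistanceEstimate:
    animal_id: str
    distance_km: float
    per_day_breakdown: pd.DataFrame


class UnattributableActivityError(ValueError):
    """Spins were counted on a day with no observed running."""


def allocate_spins(log: ActivityLog,
                   split_equally_if_unobserved: bool = False) -> np.ndarray:
    """Allocate one cage-day's spin total to its mice.

    Fractional spins are returned (no rounding) so that the allocation sums
    to ``total_spins`` exactly.  A day with counted spins but no observed
    running is unattributable and raises, unless
    ``split_equally_if_unobserved`` permits an even split.
    """
    seconds = np.array([w[1] for w in log.windows], dtype=float)
    if seconds.size and (np.any(seconds < 0)
                         or np.any(seconds > 180.0 + 1e-9)):
        raise ValueError("per-window seconds must lie in [0, 180]")
    t = seconds.sum(axis=0) if seconds.size else np.zeros(len(log.mouse_ids))
    # union running time per window is unobservable from per-mouse totals;
    # the lower bound max_i(s_i) is used — it cancels from the shares anyway
    T = float(np.minimum(seconds.max(axis=1), 180.0).sum()) if seconds.size \
        else 0.0
    if t.sum() == 0.0 or T == 0.0:
        if log.total_spins == 0:
            return np.zeros(len(log.mouse_ids))
        if split_equally_if_unobserved:
            return np.full(len(log.mouse_ids),
                           log.total_spins / len(log.mouse_ids))
        raise UnattributableActivityError(
            f"cage {log.cage_id} day {log.day}: {log.total_spins} spins "
            "counted but no mouse was observed running")
    p = t / T
    return log.total_spins * p / p.sum()


def total_distance(spins_by_day: Iterable[float],
                   circumference_m: float) -> float:
    """Distance in km from per-day spin counts and wheel circumference."""
    if circumference_m <= 0:
        raise ValueError("circumference_m must be positive")
    return float(np.sum(np.fromiter(spins_by_day, dtype=float))
                 * circumference_m / 1000.0)


def estimate_distances(logs: Iterable[ActivityLog], circumference_m: float,
                       split_equally_if_unobserved: bool = False,
                       ) -> pd.DataFrame:
    """Per-mouse total distance over all cage-days.

    Returns a tidy table (``animal_id, distance_km, n_days``); mice absent
    from every log get no row.
    """
    per_day: dict[str, list[float]] = {}
    for log in logs:
        spins = allocate_spins(log, split_equally_if_unobserved)
        for mouse, s in zip(log.mouse_ids, spins):
            per_day.setdefault(mouse, []).append(float(s))
    rows = [{"animal_id": m,
             "distance_km": total_distance(days, circumference_m),
             "n_days": len(days)}
            for m, days in sorted(per_day.items())]
    return pd.DataFrame(rows)
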