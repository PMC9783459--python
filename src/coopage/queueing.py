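"""Reproductive queues: age-rank weighting of succession candidates.

When a breeder dies, the vacancy is filled from a queue of non-breeding
females (floaters in the solitary scenarios, helpers in the cooperative
ones).  Candidates are ranked from old to young and the i-th candidate
(1-based) gets weight ``w_i = q**(i-1)``:

* ``q = 0`` — strictly age-dependent queueing: the oldest always wins
  (with the convention ``0**0 == 1``).
* ``0 < q < 1`` — weakly age-dependent queueing: older candidates are
  favoured geometrically.
* ``q = 1`` — age-independent waiting: a uniform lottery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["QueueDiscipline", "queue_weights", "select_breeder", "age_sorted_order"]


@dataclass(frozen=True)
class QueueDiscipline:
    """Age-dependency parameter ``q`` of the reproductive queue."""

    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"queue parameter q={self.q} outside [0, 1]")


def queue_weights(n: int, q: float) -> np.ndarray:
    """Weights ``q**(i-1)`` for ``i = 1..n`` age-ranked candidates.

    ``n`` counts candidates already sorted oldest-first; ``q = 0`` yields
    ``[1, 0, ..., 0]`` so the oldest candidate always wins.
    """
    if n < 1:
        raise ValueError("queue_weights needs at least one candidate")
    if q == 0.0:
        w = np.zeros(n)
        w[0] = 1.0
        return w
    return q ** np.arange(n, dtype=float)


def weighted_rank_choice(n: int, q: float, rng: np.random.Generator) -> int:
    """Sample one rank (0-based, oldest first) with probability w_i / sum(w)."""
    if n == 1 or q == 0.0:
        return 0
    if q == 1.0:
        return int(rng.integers(n))
    cw = np.cumsum(queue_weights(n, q))
    return int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))


def select_breeder(candidates: Sequence, q: float, rng: np.random.Generator):
    """Pick the next breeder from an age-sorted (oldest-first) queue.

    Sampling probability of the i-th candidate is proportional to
    ``q**(i-1)``.  Removal of the winner from the queue is the caller's
    responsibility.
    """
    n = len(candidates)
    if n == 0:
        raise ValueError("cannot select a breeder from an empty queue")
    return candidates[weighted_rank_choice(n, q, rng)]


def age_sorted_order(ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices sorting ``ages`` old→young, ties broken by a random shuffle.

    A uniform random permutation is applied before a stable sort, so
    equal-aged candidates are ranked in uniformly random order rather than
    by arrival order.
    """
    ages = np.asarray(ages)
    perm = rng.permutation(ages.size)
    return perm[np.argsort(-ages[perm], kind="stable")]
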