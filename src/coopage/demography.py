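"""Agents, territories and the population container.

The population holds a fixed number ``N`` of breeding territories, each
with at most one breeding female and — in the cooperative scenarios — a
local queue of helpers; the solitary queueing scenarios instead keep a
single global pool of floaters.  Males are not persistent agents: they die
after one time step, so only the genome of a female's mate is stored (on
the female, at mating).

Internally the population is a slot-based struct-of-arrays: every female
occupies one row across a set of parallel numpy arrays, dead rows are
recycled for newborns, and no per-step compaction is needed.  ``Female``
and ``Territory`` are read-only views materialised on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .genome import MutationParams, NeutralMarker, SurvivalGenome

__all__ = [
    "BREEDER",
    "HELPER",
    "FLOATER",
    "ROLE_NAMES",
    "SimulationConfig",
    "Female",
    "Territory",
    "Population",
    "Census",
    "initialize",
    "census",
    "scenario_default_q",
]

# role codes
BREEDER, HELPER, FLOATER = 0, 1, 2
ROLE_NAMES = {BREEDER: "breeder", HELPER: "helper", FLOATER: "floater"}

#: scenarios with a global floater pool (solitary queueing/waiting)
FLOATER_SCENARIOS = frozenset({2, 3, 4})
#: scenarios with local helper queues (cooperative breeding)
COOPERATIVE_SCENARIOS = frozenset({5, 6, 7})

_SCENARIO_Q = {1: 1.0, 2: 1.0, 3: 0.8, 4: 0.0, 5: 1.0, 6: 0.8, 7: 0.0}

_SCENARIO_LABELS = {
    1: "solitary",
    2: "solitary, age-independent waiting",
    3: "solitary, weakly age-dependent queueing",
    4: "solitary, strictly age-dependent queueing",
    5: "cooperative, age-independent waiting",
    6: "cooperative, weakly age-dependent queueing",
    7: "cooperative, strictly age-dependent queueing",
}


def scenario_default_q(scenario: int) -> float:
    """Default queue age-dependency for a breeding-system scenario."""
    return _SCENARIO_Q[scenario]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulation run.

    Parameters
    ----------
    scenario : int
        Breeding system, 1–7.  1 = solitary (failed settlers die);
        2/3/4 = solitary with a global floater queue (q = 1 / 0.8 / 0);
        5/6/7 = cooperative with local helper queues (q = 1 / 0.8 / 0).
    N : int
        Number of breeding territories (the maximum breeder count).
    t_end : int
        Number of time steps to simulate.
    d : float
        Dispersal probability of newborn helpers (cooperative scenarios):
        probability of joining a random non-natal territory.
    c : int
        Maximum age; the genome carries one survival locus per age
        ``0 .. c-1`` and death is certain on reaching ``c``.
    m, mu, sigma : float
        Genome-wide mutation rate per birth, mutation bias (mean effect,
        negative) and mutational effect size (SD).
    g : float
        Initial value of every survival gene.
    q : float or None
        Age-dependency of waiting/queueing; ``None`` selects the
        scenario's default.
    a, b : float
        Fecundity function ``R = a F / (1 + b F)``: ``a`` is the maximum
        productivity (ceiling ``a/b``), ``b`` the diminishing-return rate.
    f_max : int
        Hard cap on queue length (global floater pool, or helpers per
        territory); youngest members beyond the cap are culled.
    seed : int
        RNG seed; fully determines a replicate.
    """

    scenario: int = 1
    N: int = 1000
    t_end: int = 80_000
    d: float = 1.0
    c: int = 20
    m: float = 0.02
    mu: float = -0.009
    sigma: float = 0.018
    g: float = 0.8
    q: Optional[float] = None
    a: float = 2.5
    b: float = 0.5
    f_max: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in range(1, 8):
            raise ValueError(f"scenario={self.scenario} must be one of 1..7")
        if self.N < 1:
            raise ValueError(f"N={self.N} must be >= 1")
        if self.t_end < 0:
            raise ValueError(f"t_end={self.t_end} must be >= 0")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"d={self.d} outside [0, 1]")
        if self.c < 1:
            raise ValueError(f"c={self.c} must be >= 1")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m={self.m} outside [0, 1]")
        if self.sigma < 0.0:
            raise ValueError(f"sigma={self.sigma} must be >= 0")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError(f"g={self.g} outside [0, 1]")
        if self.q is not None and not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q={self.q} outside [0, 1]")
        if self.a <= 0.0:
            raise ValueError(f"a={self.a} must be > 0")
        if self.b <= 0.0:
            raise ValueError(f"b={self.b} must be > 0")
        if self.f_max < 1:
            raise ValueError(f"f_max={self.f_max} must be >= 1")
        if self.seed < 0:
            raise ValueError(f"seed={self.seed} must be >= 0")

    @property
    def queue_q(self) -> float:
        """The effective queue parameter (scenario default if q is None)."""
        return scenario_default_q(self.scenario) if self.q is None else self.q

    @property
    def cooperative(self) -> bool:
        return self.scenario in COOPERATIVE_SCENARIOS

    @property
    def has_floaters(self) -> bool:
        return self.scenario in FLOATER_SCENARIOS

    @property
    def scenario_label(self) -> str:
        return _SCENARIO_LABELS[self.scenario]

    @property
    def mutation(self) -> MutationParams:
        return MutationParams(self.m, self.mu, self.sigma)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with replaced fields."""
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class Female:
    """Read-only view of one female agent (materialised from the arrays)."""

    id: int
    age: int
    role: str
    territory: Optional[int]
    survival_genome: SurvivalGenome
    neutral_marker: NeutralMarker
    mate_survival_genome: SurvivalGenome
    mate_neutral_marker: NeutralMarker
    age_first_reproduction: Optional[int]


@dataclass
class Territory:
    """Read-only view of one territory: breeder slot + ordered helpers."""

    id: int
    breeder: Optional[int]
    helpers: list[int]


class Population:
    """Slot-based population state: parallel arrays over female slots.

    Rows with ``alive == False`` are free slots reused for newborns.  All
    mutating operations live in :mod:`coopage.lifecycle`; this class only
    manages storage, views and bookkeeping.
    """

    GROWTH = 2.0

    def __init__(self, n_territories: int, c: int, capacity: int):
        self.n_territories = int(n_territories)
        self.c = int(c)
        self.t = 0
        cap = max(int(capacity), 4)
        self.alive = np.zeros(cap, dtype=bool)
        self.age = np.zeros(cap, dtype=np.int32)
        self.role = np.zeros(cap, dtype=np.int8)
        self.terr = np.full(cap, -1, dtype=np.int32)
        self.newborn = np.zeros(cap, dtype=bool)
        self.afr = np.full(cap, -1, dtype=np.int32)
        self.sur_m = np.empty((cap, c), dtype=float)
        self.sur_p = np.empty((cap, c), dtype=float)
        self.mate_m = np.empty((cap, c), dtype=float)
        self.mate_p = np.empty((cap, c), dtype=float)
        self.neut = np.empty((cap, 2), dtype=float)
        self.mate_neut = np.empty((cap, 2), dtype=float)
        # first-reproduction event log: (step, age) pairs
        self._afr_event_t: list[np.ndarray] = []
        self._afr_event_age: list[np.ndarray] = []

    # -- storage ------------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.alive.size

    @property
    def size(self) -> int:
        """Number of living females."""
        return int(self.alive.sum())

    def live_rows(self) -> np.ndarray:
        """Ascending slot indices of living females (deterministic order)."""
        return np.nonzero(self.alive)[0]

    def _grow(self, need: int) -> None:
        new_cap = max(int(self.capacity * self.GROWTH), self.capacity + need)
        for name in ("alive", "age", "role", "terr", "newborn", "afr",
                     "sur_m", "sur_p", "mate_m", "mate_p", "neut", "mate_neut"):
            old = getattr(self, name)
            shape = (new_cap,) + old.shape[1:]
            if name == "terr" or name == "afr":
                new = np.full(shape, -1, dtype=old.dtype)
            elif old.dtype == bool or old.dtype == np.int32 or old.dtype == np.int8:
                new = np.zeros(shape, dtype=old.dtype)
            else:
                new = np.empty(shape, dtype=old.dtype)
            new[: old.shape[0]] = old
            setattr(self, name, new)

    def claim_slots(self, k: int) -> np.ndarray:
        """Return ``k`` free slot indices (ascending), growing if needed."""
        free = np.nonzero(~self.alive)[0]
        if free.size < k:
            self._grow(k - free.size)
            free = np.nonzero(~self.alive)[0]
        return free[:k]

    def record_first_reproduction(self, rows: np.ndarray) -> None:
        """Log first-reproduction events (current step, breeder ages)."""
        self.afr[rows] = self.age[rows]
        self._afr_event_t.append(np.full(rows.size, self.t, dtype=np.int32))
        self._afr_event_age.append(self.age[rows].copy())

    def first_reproduction_events(self) -> tuple[np.ndarray, np.ndarray]:
        """All logged (step, age) first-reproduction events."""
        if not self._afr_event_t:
            return np.empty(0, np.int32), np.empty(0, np.int32)
        return np.concatenate(self._afr_event_t), np.concatenate(self._afr_event_age)

    # -- views --------------------------------------------------------------

    def breeder_of_territory(self) -> np.ndarray:
        """Row index of each territory's breeder, or -1 if vacant."""
        rows = self.live_rows()
        b = rows[self.role[rows] == BREEDER]
        out = np.full(self.n_territories, -1, dtype=np.int64)
        out[self.terr[b]] = b
        return out

    def helper_counts(self) -> np.ndarray:
        """Number of helpers per territory."""
        rows = self.live_rows()
        h = rows[self.role[rows] == HELPER]
        return np.bincount(self.terr[h], minlength=self.n_territories)

    def female(self, row: int) -> Female:
        if not self.alive[row]:
            raise ValueError(f"slot {row} holds no living female")
        terr = int(self.terr[row])
        return Female(
            id=int(row),
            age=int(self.age[row]),
            role=ROLE_NAMES[int(self.role[row])],
            territory=terr if terr >= 0 else None,
            survival_genome=SurvivalGenome(self.sur_m[row].copy(), self.sur_p[row].copy()),
            neutral_marker=NeutralMarker(*self.neut[row]),
            mate_survival_genome=SurvivalGenome(self.mate_m[row].copy(), self.mate_p[row].copy()),
            mate_neutral_marker=NeutralMarker(*self.mate_neut[row]),
            age_first_reproduction=int(self.afr[row]) if self.afr[row] >= 0 else None,
        )

    def territory(self, tid: int) -> Territory:
        rows = self.live_rows()
        here = rows[self.terr[rows] == tid]
        breeders = here[self.role[here] == BREEDER]
        helpers = here[self.role[here] == HELPER]
        if breeders.size > 1:
            raise RuntimeError(f"territory {tid} has {breeders.size} breeders")
        return Territory(
            id=int(tid),
            breeder=int(breeders[0]) if breeders.size else None,
            helpers=[int(h) for h in helpers],
        )

    def check_consistency(self) -> None:
        """Raise if the one-role / one-territory bookkeeping is violated."""
        rows = self.live_rows()
        roles = self.role[rows]
        terr = self.terr[rows]
        if np.any((roles == FLOATER) & (terr >= 0)):
            raise RuntimeError("floater with a territory reference")
        if np.any((roles != FLOATER) & (terr < 0)):
            raise RuntimeError("breeder/helper without a territory reference")
        b_terr = terr[roles == BREEDER]
        if np.unique(b_terr).size != b_terr.size:
            raise RuntimeError("territory with more than one breeder")
        if np.any(self.age[rows] >= self.c):
            raise RuntimeError("living female at or beyond the maximum age")


@dataclass
class Census:
    """Role tallies and age histogram of the living population."""

    breeders: int
    helpers: int
    floaters: int
    age_histogram: np.ndarray  # counts per age 0 .. c-1

    @property
    def total(self) -> int:
        return self.breeders + self.helpers + self.floaters


def initialize(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Found the population: one age-0 breeder per territory.

    Every survival gene value starts at ``g``; the stored mate genome of a
    founder is likewise all-``g`` (a neutral start, identical to her own
    trait values).  Neutral marker homologs are independent standard-normal
    draws so the relatedness correlation is defined from the first
    generation on.
    """
    N, c = config.N, config.c
    pop = Population(N, c, capacity=max(2 * N, 64))
    rows = np.arange(N)
    pop.alive[rows] = True
    pop.age[rows] = 0
    pop.role[rows] = BREEDER
    pop.terr[rows] = rows
    pop.newborn[rows] = False
    pop.sur_m[rows] = config.g
    pop.sur_p[rows] = config.g
    pop.mate_m[rows] = config.g
    pop.mate_p[rows] = config.g
    pop.neut[rows] = rng.standard_normal((N, 2))
    pop.mate_neut[rows] = rng.standard_normal((N, 2))
    return pop


def census(pop: Population) -> Census:
    """Role and age tallies over the living population."""
    rows = pop.live_rows()
    roles = pop.role[rows]
    hist = np.bincount(pop.age[rows], minlength=pop.c) if rows.size else np.zeros(pop.c, int)
    return Census(
        breeders=int((roles == BREEDER).sum()),
        helpers=int((roles == HELPER).sum()),
        floaters=int((roles == FLOATER).sum()),
        age_histogram=hist,
    )
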