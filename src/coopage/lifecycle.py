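"""The per-time-step update rule of the simulation.

Each step runs a fixed phase order:

A. mortality — every female survives with her genetic age-specific
   survival probability;
B. reproduction — each territory with a surviving breeder produces
   ``R = a F / (1 + b F)`` expected offspring (``F`` = females in the
   territory: breeder plus surviving helpers in the cooperative
   scenarios, 1 in the solitary ones), stochastically rounded; the
   breeder's age of first reproduction is recorded at her first non-empty
   litter;
C. offspring formation — fair coin sex ratio; one recombined gamete from
   the breeder and one from her stored mate genome; each newborn genome
   then mutates with genome-wide probability ``m`` (biased on survival
   loci, unbiased on the neutral marker);
D. mating — every newborn female stores the genome of one uniformly
   random newborn male of this step; males are then discarded (they live
   a single step and do not express survival genes);
E. recruitment/dispersal — scenario 1: vacancies are filled by random
   newborns and unsettled newborns die; scenarios 2–4: newborns join the
   global floater pool; scenarios 5–7: newborns become helpers in a
   random non-natal territory with probability ``d``, else at home;
F. succession — vacant territories draw a new breeder from the floater
   pool (2–4) or the local helper queue (5–7, with a uniform draw from
   all other territories' helpers if the local queue is empty), with
   age-rank weights ``q**(i-1)``;
G. queue cap — queues beyond ``f_max`` lose their youngest members;
H. ageing — survivors age by one step; females reaching the maximum age
   ``c`` die.  Newborns stay at age 0 through their birth step, first
   face mortality at age 0, and age to 1 at the end of that first full
   step.

Dead breeders do not reproduce in the step they die, and newly promoted
breeders first reproduce in the following step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import statistics as stats
from .demography import (
    BREEDER,
    FLOATER,
    HELPER,
    Population,
    SimulationConfig,
    initialize,
)
from .genome import mutate_genomes_batch, recombine_batch
from .queueing import age_sorted_order, weighted_rank_choice

__all__ = ["StepReport", "step", "expected_offspring", "stochastic_round", "run_replicate"]


@dataclass
class StepReport:
    """Per-step bookkeeping counts."""

    deaths: int = 0
    births_female: int = 0
    births_male: int = 0
    vacancies_filled: int = 0
    scenario1_failed_settlers: int = 0
    unmated_females: int = 0


def expected_offspring(F, a: float, b: float):
    """Diminishing-returns fecundity ``R = a F / (1 + b F)``.

    Monotone increasing in the female group size ``F`` and bounded above
    by the maximum productivity ceiling ``a / b``.  Accepts scalars or
    arrays.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("female count F must be >= 0")
    if a <= 0 or b <= 0:
        raise ValueError("fecundity parameters a and b must be > 0")
    R = a * F / (1.0 + b * F)
    return float(R) if R.ndim == 0 else R


def stochastic_round(x, rng: np.random.Generator):
    """Round to an integer preserving the expectation.

    ``floor(x)`` plus a Bernoulli draw on the fractional part, so
    ``E[stochastic_round(x)] == x``.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("stochastic_round requires non-negative input")
    lo = np.floor(x)
    out = (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------


def step(pop: Population, config: SimulationConfig, rng: np.random.Generator) -> StepReport:
    """Advance the population by one time step (in place).

    Returns a :class:`StepReport` with the step's tallies.  The phase
    order is documented in the module docstring.
    """
    report = StepReport()
    N, c = config.N, config.c

    # --- A: mortality -----------------------------------------------------
    rows = pop.live_rows()
    if rows.size:
        ages = pop.age[rows]
        s = 0.5 * (pop.sur_m[rows, ages] + pop.sur_p[rows, ages])
        dead = rows[rng.random(rows.size) >= s]
        pop.alive[dead] = False
        report.deaths += dead.size

    # --- B: reproduction --------------------------------------------------
    breeder_of = pop.breeder_of_territory()
    occ = np.nonzero(breeder_of >= 0)[0]
    litter = np.zeros(occ.size, dtype=np.int64)
    if occ.size:
        if config.cooperative:
            F = 1.0 + pop.helper_counts()[occ]
        else:
            F = np.ones(occ.size)
        R = expected_offspring(F, config.a, config.b)
        litter = stochastic_round(R, rng)
        fertile = breeder_of[occ[litter > 0]]
        first = fertile[pop.afr[fertile] < 0]
        if first.size:
            pop.record_first_reproduction(first)

    # --- C: offspring formation -------------------------------------------
    moms = np.repeat(breeder_of[occ], litter)
    natal = np.repeat(occ, litter).astype(np.int64)
    K = moms.size
    if K:
        child_m = recombine_batch(pop.sur_m[moms], pop.sur_p[moms], rng)
        child_p = recombine_batch(pop.mate_m[moms], pop.mate_p[moms], rng)
        neut_m = np.where(rng.random(K) < 0.5, pop.neut[moms, 0], pop.neut[moms, 1])
        neut_p = np.where(rng.random(K) < 0.5, pop.mate_neut[moms, 0], pop.mate_neut[moms, 1])
        child_neut = np.column_stack((neut_m, neut_p))
        mutate_genomes_batch(child_m, child_p, child_neut, config.mutation, rng)
        neut_m, neut_p = child_neut[:, 0], child_neut[:, 1]
        is_female = rng.random(K) < 0.5
    else:
        is_female = np.zeros(0, dtype=bool)

    girls = np.nonzero(is_female)[0]
    boys = np.nonzero(~is_female)[0]
    report.births_female = girls.size
    report.births_male = boys.size

    # --- D: mating --------------------------------------------------------
    if girls.size and boys.size == 0:
        # no males this step: these females can never reproduce
        report.unmated_females = girls.size
        girls = np.zeros(0, dtype=np.int64)

    # --- E: recruitment / dispersal ----------------------------------------
    vacant = np.nonzero(breeder_of < 0)[0]
    if girls.size:
        mates = boys[rng.integers(0, boys.size, girls.size)]
        if config.scenario == 1:
            n_settle = min(vacant.size, girls.size)
            pick = rng.permutation(girls.size)[:n_settle]
            report.scenario1_failed_settlers = girls.size - n_settle
            girls, mates = girls[pick], mates[pick]
            role_new = np.full(n_settle, BREEDER, dtype=np.int8)
            terr_new = vacant[:n_settle].astype(np.int32)
            report.vacancies_filled += n_settle
        elif config.has_floaters:
            role_new = np.full(girls.size, FLOATER, dtype=np.int8)
            terr_new = np.full(girls.size, -1, dtype=np.int32)
        else:  # cooperative: helper at home or, with probability d, elsewhere
            terr_new = natal[girls].astype(np.int32)
            if N > 1 and config.d > 0:
                disp = np.nonzero(rng.random(girls.size) < config.d)[0]
                if disp.size:
                    r = rng.integers(0, N - 1, disp.size).astype(np.int32)
                    terr_new[disp] = r + (r >= terr_new[disp])
            role_new = np.full(girls.size, HELPER, dtype=np.int8)

        slots = pop.claim_slots(girls.size)
        pop.alive[slots] = True
        pop.age[slots] = 0
        pop.newborn[slots] = True
        pop.afr[slots] = -1
        pop.role[slots] = role_new
        pop.terr[slots] = terr_new
        pop.sur_m[slots] = child_m[girls]
        pop.sur_p[slots] = child_p[girls]
        pop.neut[slots, 0] = neut_m[girls]
        pop.neut[slots, 1] = neut_p[girls]
        pop.mate_m[slots] = child_m[mates]
        pop.mate_p[slots] = child_p[mates]
        pop.mate_neut[slots, 0] = neut_m[mates]
        pop.mate_neut[slots, 1] = neut_p[mates]

    # --- F: succession ----------------------------------------------------
    if vacant.size:
        if config.has_floaters:
            report.vacancies_filled += _succeed_from_floaters(pop, config, vacant, rng)
        elif config.cooperative:
            report.vacancies_filled += _succeed_from_helpers(pop, config, vacant, rng)

    # --- G: queue cap -----------------------------------------------------
    report.deaths += _enforce_queue_cap(pop, config, rng)

    # --- H: ageing --------------------------------------------------------
    rows = pop.live_rows()
    grown = rows[~pop.newborn[rows]]
    pop.age[grown] += 1
    ceiling = grown[pop.age[grown] >= c]
    if ceiling.size:
        pop.alive[ceiling] = False
        report.deaths += ceiling.size
    pop.newborn[rows] = False

    pop.t += 1
    return report


def _succeed_from_floaters(
    pop: Population, config: SimulationConfig, vacant: np.ndarray, rng: np.random.Generator
) -> int:
    """Fill vacancies (ascending id) from the global age-sorted floater pool."""
    rows = pop.live_rows()
    pool = rows[pop.role[rows] == FLOATER]
    if pool.size == 0:
        return 0
    q = config.queue_q
    n_fill = min(vacant.size, pool.size)
    if q == 1.0:
        chosen = pool[rng.choice(pool.size, size=n_fill, replace=False)]
    else:
        order = pool[age_sorted_order(pop.age[pool], rng)]
        if q == 0.0:
            chosen = order[:n_fill]
        else:
            picks = []
            for _ in range(n_fill):
                i = weighted_rank_choice(order.size, q, rng)
                picks.append(order[i])
                order = np.delete(order, i)
            chosen = np.asarray(picks)
    pop.role[chosen] = BREEDER
    pop.terr[chosen] = vacant[:n_fill].astype(np.int32)
    return n_fill


def _succeed_from_helpers(
    pop: Population, config: SimulationConfig, vacant: np.ndarray, rng: np.random.Generator
) -> int:
    """Fill vacancies from local helper queues, ascending territory id.

    The territory's own helpers take precedence (age-rank weighted); a
    territory with an empty queue recruits one uniformly random helper
    from the rest of the population, if any exists.
    """
    rows = pop.live_rows()
    h_rows = rows[pop.role[rows] == HELPER]
    if h_rows.size == 0:
        return 0
    # group helpers by territory once; each local queue is then a slice
    grouping = np.argsort(pop.terr[h_rows], kind="stable")
    h_rows = h_rows[grouping]
    h_terr = pop.terr[h_rows]
    h_age = pop.age[h_rows]
    counts = np.bincount(h_terr, minlength=pop.n_territories)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    active = np.ones(h_rows.size, dtype=bool)
    q = config.queue_q
    filled = 0
    for v in vacant:
        lo = starts[v]
        hi = lo + counts[v]
        local = lo + np.nonzero(active[lo:hi])[0]
        if local.size:
            ages = h_age[local]
            if q == 1.0:
                pick = local[rng.integers(local.size)]
            elif q == 0.0:
                oldest = np.nonzero(ages == ages.max())[0]
                pick = local[oldest[rng.integers(oldest.size)]]
            else:
                order = local[age_sorted_order(ages, rng)]
                pick = order[weighted_rank_choice(local.size, q, rng)]
        else:
            elsewhere = np.nonzero(active)[0]
            elsewhere = elsewhere[(elsewhere < lo) | (elsewhere >= hi)]
            if elsewhere.size == 0:
                continue
            pick = elsewhere[rng.integers(elsewhere.size)]
        r = h_rows[pick]
        pop.role[r] = BREEDER
        pop.terr[r] = v
        active[pick] = False
        filled += 1
    return filled


def _enforce_queue_cap(
    pop: Population, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Remove the youngest queue members beyond ``f_max``; returns removals."""
    removed = 0
    f_max = config.f_max
    if config.has_floaters:
        rows = pop.live_rows()
        pool = rows[pop.role[rows] == FLOATER]
        if pool.size > f_max:
            order = pool[age_sorted_order(pop.age[pool], rng)]
            cut = order[f_max:]
            pop.alive[cut] = False
            removed += cut.size
    elif config.cooperative:
        counts = pop.helper_counts()
        over = np.nonzero(counts > f_max)[0]
        if over.size:
            rows = pop.live_rows()
            h_rows = rows[pop.role[rows] == HELPER]
            for v in over:
                local = h_rows[pop.terr[h_rows] == v]
                order = local[age_sorted_order(pop.age[local], rng)]
                cut = order[f_max:]
                pop.alive[cut] = False
                removed += cut.size
    return removed


# ---------------------------------------------------------------------------


def run_replicate(
    config: SimulationConfig,
    record_every: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> "stats.ReplicateSummary":
    """Run one seeded replicate for ``t_end`` steps and summarise it.

    A fixed ``config.seed`` fully determines the outcome.  If the
    population goes extinct the run stops early and the summary carries
    the ``extinct`` flag.  With ``record_every`` set, a thinned time
    series of light summaries (every that many steps, plus the final
    state) is attached to the summary's ``history``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize(config, rng)
    history: Optional[list[dict]] = [] if record_every else None
    extinct = False
    for t in range(config.t_end):
        if history is not None and t % record_every == 0:
            history.append(stats.light_summary(pop, config))
        step(pop, config, rng)
        if pop.size == 0:
            extinct = True
            break
    if history is not None:
        history.append(stats.light_summary(pop, config))
    summary = stats.summarize(pop, config, rng, extinct=extinct)
    summary.history = history
    return summary
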