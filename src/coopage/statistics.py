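"""End-state summaries of a replicate.

The headline statistic is the *evolved life expectancy*: for each living
female, the sum over ages of the cumulative product of her genetic
age-specific survival probabilities, averaged over the population.  Other
summaries are the mean age of first reproduction (over first-litter
events logged in a trailing census window), the mean group size of
occupied territories, the per-age population survival schedule with its
survivorship curve, and breeder–helper relatedness, estimated as the
Pearson correlation across territories between the breeder's mean
neutral-marker value and that of one uniformly random helper.

Statistics that are undefined for a state (no AFR events, too few
territories with helpers, zero marker variance) are reported as NaN and
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .demography import HELPER, Population, SimulationConfig, census
from .genome import life_expectancy_batch

__all__ = [
    "ReplicateSummary",
    "mean_life_expectancy",
    "mean_age_first_reproduction",
    "survivorship",
    "relatedness",
    "mean_group_size",
    "age_survival_schedule",
    "summarize",
]

#: trailing window (time steps) over which first-reproduction events are averaged
AFR_WINDOW = 1000


@dataclass
class ReplicateSummary:
    """End-of-run population summaries of one replicate."""

    mean_life_expectancy: float
    mean_age_first_reproduction: float
    mean_group_size: float
    relatedness: float
    age_survival_schedule: np.ndarray  # c values in [0, 1]
    survivorship_curve: np.ndarray     # c+1 values, non-increasing from 1
    t_final: int
    extinct: bool
    population_size: int
    n_breeders: int
    n_helpers: int
    n_floaters: int
    history: Optional[list[dict]] = field(default=None, repr=False)


def mean_life_expectancy(pop: Population) -> float:
    """Population mean of per-female genetic life expectancy.

    NaN for an empty population.
    """
    rows = pop.live_rows()
    if rows.size == 0:
        return float("nan")
    return float(life_expectancy_batch(pop.sur_m[rows], pop.sur_p[rows]).mean())


def mean_age_first_reproduction(pop: Population, window: int = AFR_WINDOW) -> float:
    """Mean breeder age at first non-empty litter, over a trailing window.

    Averages all first-reproduction events logged during the final
    ``window`` steps (a quasi-equilibrium snapshot); NaN if no female
    first reproduced in that window.
    """
    ev_t, ev_age = pop.first_reproduction_events()
    if ev_t.size == 0:
        return float("nan")
    recent = ev_age[ev_t >= pop.t - window]
    if recent.size == 0:
        return float("nan")
    return float(recent.mean())


def survivorship(schedule: np.ndarray) -> np.ndarray:
    """Survivorship curve from an age-specific survival schedule.

    ``l(0) = 1`` and ``l(x) = prod_{k<x} s_k`` for ``x = 1..c``; always
    non-increasing.
    """
    schedule = np.asarray(schedule, dtype=float)
    return np.concatenate(([1.0], np.cumprod(schedule)))


def age_survival_schedule(pop: Population) -> np.ndarray:
    """Per-age mean survival probability over living females (length c)."""
    rows = pop.live_rows()
    if rows.size == 0:
        return np.full(pop.c, np.nan)
    return 0.5 * (pop.sur_m[rows] + pop.sur_p[rows]).mean(axis=0)


def relatedness(pop: Population, rng: np.random.Generator) -> float:
    """Breeder–helper relatedness from the neutral marker.

    For every territory holding both a breeder and at least one helper,
    pair the breeder's mean marker value with that of one uniformly
    random helper; return the Pearson correlation of the pairs across
    territories.  NaN when fewer than two territories qualify or either
    coordinate has zero variance.
    """
    breeder_of = pop.breeder_of_territory()
    rows = pop.live_rows()
    h_rows = rows[pop.role[rows] == HELPER]
    if h_rows.size == 0:
        return float("nan")
    h_terr = pop.terr[h_rows]
    order = np.argsort(h_terr, kind="stable")
    h_sorted = h_rows[order]
    counts = np.bincount(h_terr, minlength=pop.n_territories)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    qualify = np.nonzero((counts > 0) & (breeder_of >= 0))[0]
    if qualify.size < 2:
        return float("nan")
    # one uniformly random helper per qualifying territory
    offs = np.floor(rng.random(qualify.size) * counts[qualify]).astype(np.int64)
    helpers = h_sorted[starts[qualify] + offs]
    x = pop.neut[breeder_of[qualify]].mean(axis=1)
    y = pop.neut[helpers].mean(axis=1)
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mean_group_size(pop: Population) -> float:
    """Mean number of females (breeder + helpers) per occupied territory."""
    breeder_of = pop.breeder_of_territory()
    occ = breeder_of >= 0
    if not occ.any():
        return float("nan")
    return float(1.0 + pop.helper_counts()[occ].mean())


def light_summary(pop: Population, config: SimulationConfig) -> dict:
    """Cheap per-step record for thinned time series."""
    cen = census(pop)
    return {
        "t": pop.t,
        "population_size": cen.total,
        "n_breeders": cen.breeders,
        "n_helpers": cen.helpers,
        "n_floaters": cen.floaters,
        "mean_life_expectancy": mean_life_expectancy(pop),
    }


def summarize(
    pop: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    extinct: bool = False,
) -> ReplicateSummary:
    """Full end-state summary of a replicate."""
    cen = census(pop)
    schedule = age_survival_schedule(pop)
    return ReplicateSummary(
        mean_life_expectancy=mean_life_expectancy(pop),
        mean_age_first_reproduction=mean_age_first_reproduction(pop),
        mean_group_size=mean_group_size(pop) if config.cooperative else (
            1.0 if cen.breeders else float("nan")
        ),
        relatedness=relatedness(pop, rng) if config.cooperative else float("nan"),
        age_survival_schedule=schedule,
        survivorship_curve=survivorship(schedule),
        t_final=pop.t,
        extinct=extinct,
        population_size=cen.total,
        n_breeders=cen.breeders,
        n_helpers=cen.helpers,
        n_floaters=cen.floaters,
    )
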