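# Methods

## The model

`coopage` is a forward-time, individual-based simulation of the evolution
of ageing under mutation accumulation, in populations whose access to
reproduction is limited by a fixed number of breeding territories `N`.

**Genetics.** Each female is diploid and carries one pair of homologous
survival gene values (bounded to [0, 1]) for every age class
`0 … c−1`, i.e. `2c` genes in total. The mean of the two homologous
values at age `x` is her survival probability `s_x` through that age;
on reaching the maximum age `c` she dies regardless. Transmission is by
free recombination: each locus of a gamete is copied from the maternal or
paternal haplotype with probability 1/2, independently across loci (no
linkage map is assumed). Mutation acts at the emergence of an offspring
with one genome-wide Bernoulli(`m`) trial; an event picks the maternally
or the paternally inherited haplotype by fair coin and perturbs *every*
survival locus of that haplotype by an independent draw from
`Normal(mu, sigma)` with `mu < 0` (deleterious bias), clamped back into
[0, 1]. This genome-wide granularity (expected `m` events per birth, not
`m` per haplotype) is what reproduces the reference full-scale
equilibrium life expectancies; doubling the input visibly depresses
them. A second, selectively neutral pair of gene values rides along:
the neutral value linked to the mutated haplotype receives an unbiased
`Normal(0, sigma)` draw in the same event, without bounds — clamping
would distort the correlation-based relatedness estimator, so the
marker is left free.

**Breeding systems.** Seven scenarios share the same genetics and differ
only in what happens to newborn females:

1. *Solitary*: newborns compete for vacant territories; those that fail
   to settle die.
2–4. *Solitary with a global queue*: newborns become floaters waiting for
   vacancies, with age-independent (q=1), weakly age-dependent (q=0.8) or
   strictly age-dependent (q=0) queueing.
5–7. *Cooperative*: newborns become helpers in a territory (their natal
   one, or with probability `d` a uniformly random other one) and queue
   locally, again with q = 1 / 0.8 / 0.

Queue candidates are ranked old→young (ties broken by a uniform random
shuffle) and the i-th candidate has selection weight `q**(i−1)`, with
`0**0 = 1`. In the cooperative scenarios a territory whose own queue is
empty recruits one uniformly random helper from the rest of the
population; the local queue always takes precedence.

**Reproduction.** A surviving breeder produces an expected
`R = a F / (1 + b F)` offspring, where `F` is the number of females in
her territory after the mortality phase (breeder plus surviving helpers;
`F = 1` in the solitary scenarios). `R` is stochastically rounded
(floor plus Bernoulli on the fraction, preserving the mean). Sexes are
assigned by fair coin. Males are not persistent agents: they do not
express survival genes, mate uniformly at random with the newborn female
cohort of the same step, and die; each female stores her mate's genome at
mating and uses it for all her future offspring.

## Step phase order

Within a time step: mortality → reproduction → offspring formation
(recombination + mutation) → mating → recruitment/dispersal →
succession → queue cap → ageing. Consequences of this order, chosen
deliberately:

- a breeder that dies in step `t` does not reproduce in step `t`, so
  vacancies open before recruitment and can be refilled the same step;
- newly recruited floaters/helpers (including newborns) are immediately
  eligible for succession in their first step, but a newly promoted
  breeder first reproduces in the following step;
- newborns are created at age 0, are not aged in their birth step, first
  face mortality at age 0 in the next step, and age 0→1 at the end of
  that first full step — so the age-0 survival locus is under selection;
- a female aged `c−1` survives her last step with `s_{c−1}` and may
  breed once more before dying at the age ceiling, so the terminal locus
  retains (weak) selection. Because ceiling deaths happen at the end of
  the step, a perfectly synchronised cohort hitting the ceiling leaves
  vacancies that are only refillable one step later; with stochastic
  mortality this never matters, but a fully deterministic population
  (all `s = 1`, all founders the same age, `c` small) collapses when all
  breeders die simultaneously — visible in unit tests, harmless in any
  stochastic run;
- when several vacancies open in one step they are filled in ascending
  territory id, sampling candidates sequentially without replacement
  (the queue is re-ranked after each removal).

Degenerate inputs: a step that produces newborn females but zero males
discards those females (they could never mate); the event is counted in
the step report and is vanishingly rare at realistic fecundities.
Extinction stops a replicate early and flags its summary.

## Initialisation

Each territory is founded by one age-0 breeder with all survival genes at
`g` and a stored mate genome likewise all-`g` (a neutral start identical
to her own trait). Founder neutral markers are independent standard
normal draws per homolog — a constant start would leave the relatedness
correlation undefined for many generations.

## Summary statistics

- **Evolved life expectancy**: per female,
  `sum_{x=1}^{c} prod_{k=0}^{x-1} s_k`, averaged over the living
  population. For a constant schedule this is the geometric sum
  `sum s^x`, used as an exact oracle in the tests.
- **Age of first reproduction (AFR)**: the breeder's age in the first
  step her territory realises ≥1 offspring, averaged over all such
  first-litter events logged in the final 1,000 steps of a run (a
  quasi-equilibrium snapshot; breeders only, which is why mean AFR can
  exceed mean life expectancy in strongly age-dependent queues).
- **Survivorship**: `l(0)=1`, `l(x) = prod_{k<x} s_k` from the
  population-mean survival schedule.
- **Group size**: breeder plus helper count, averaged over occupied
  territories.
- **Relatedness**: across all territories with a breeder and ≥1 helper,
  the Pearson correlation between the breeder's mean neutral-marker value
  and that of one uniformly random helper per territory (re-drawn per
  measurement). Undefined statistics are reported as NaN, never as 0.

## Parameters and defaults

| name | default | meaning |
|------|---------|---------|
| `N` | 1000 | breeding territories (maximum breeder count) |
| `t_end` | 80000 | time steps; long enough for mutation–selection quasi-equilibrium |
| `d` | 1.0 | helper dispersal probability (fully outbred queues) |
| `c` | 20 | maximum age = survival loci per haplotype |
| `m` | 0.02 | genome-wide mutation probability per birth |
| `mu` | −0.009 | mutation bias (mean effect on a gene value) |
| `sigma` | 0.018 | mutational effect size (SD) |
| `g` | 0.8 | initial survival gene value |
| `q` | scenario preset | queue age-dependency (1 / 0.8 / 0) |
| `a` | 2.5 | maximum productivity (offspring ceiling `a/b` = 5) |
| `b` | 0.5 | diminishing-return rate of fecundity |
| `f_max` | 50000 | queue-length cap (computational guard; never binds) |

## Scales, run time and what the tests show

A full default run (N=1000, t_end=80000, 20 replicates per condition) is
the reference experiment; a single solitary-scenario replicate at that
scale takes a few minutes, a cooperative one substantially longer because
equilibrium group sizes of 15–25 females multiply the population size.
Two presets are therefore used throughout:

- `full`: N=1000, t_end=80000, n=20 — the reference design;
- `desk`: N=200, t_end=20000, n=5 — the test-scale configuration.

At desk scale the mutation–selection balance is *not* fully equilibrated
(mean life expectancies are still rising at t=20000) and genetic drift at
N=200 lowers the equilibrium survival values slightly. Desk-scale runs
therefore reproduce the *ordering* and *relative* effects — solitary
without queueing ≪ age-independent waiting < age-dependent queueing;
solitary ≈ cooperative at equal q; relatedness falling with dispersal —
but sit systematically below the full-scale equilibrium means. The
quantitative checks that need quasi-equilibrium are placed accordingly:
survivorship up to the mean AFR and the comparison against the
equilibrium mean use a full-scale solitary strict-queueing replicate
(cheap, because solitary populations stay small); the productivity
insensitivity of lifespan is checked at N=100 once the
between-discipline gap has emerged (t=40000); the lifespan response to
dispersal — an equilibrium kin-selection shift of under one
life-expectancy unit — uses N=200, t=60000 runs. Ordering assertions use
margins of ~1 life-expectancy unit where the transient gaps are that
large, plain ordering where they are smaller, and "approximately equal"
means a difference in scenario means below 2 (10% of the age ceiling) —
all small against the 4–7-unit between-discipline effects and large
against replicate noise (SD ≈ 0.3–0.6 at these scales).

The synthetic populations the simulator generates are the study system
itself (there is no external data); what passing tests show is therefore
internal: that the implemented update rule has the stated invariants and
reproduces the model's reference equilibrium behaviour at the stated
scales — not that any particular biological population behaves this way.

## Numerical and design choices

- One RNG stream (`numpy.random.default_rng`) per replicate, seeded as
  master seed + row index within an experiment, so replicate tables are
  bit-reproducible and order-independent.
- Mutation granularity: one Bernoulli(`m`) trial per newborn genome; a
  hit perturbs all `c` loci of one coin-picked haplotype plus its linked
  neutral value. The per-haplotype kernels remain available as
  primitives in the genome module.
- The population is stored slot-based (struct-of-arrays); vacated rows
  are recycled, avoiding per-step compaction. All genome kernels are
  batched; the per-genome API delegates to them.
- Weighted queue sampling uses cumulative sums with fast paths for q=0
  (oldest wins, ties uniform) and q=1 (uniform lottery).
- Per-age survival schedules are population means of per-female locus
  means; survivorship is derived from that mean schedule.

## Known limitations

- Males are memoryless vectors of genes; no male life history or
  overlapping male generations.
- Helper effects act only on fecundity, not on breeder survival.
- No territory quality variation, immigration, or condition-dependent
  dispersal.
- AFR averages over breeders' first litters only; individuals that never
  breed contribute nothing to the statistic.
- Desk-scale equilibria sit below full-scale ones (drift + finite
  horizon); see above.
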