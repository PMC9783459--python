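"""Diploid genetic architecture for age-specific survival.

Each female carries two homologous haplotypes of ``c`` gene values, one
value per age class ``0 .. c-1``.  The two homologous values at an age are
averaged to give the age-specific survival probability, so a genome is a
heritable life table.  Mutation happens at the emergence of a new
individual — one genome-wide Bernoulli(``m``) event that perturbs all loci
of one inherited haplotype — and is biased downwards (mean effect
``mu < 0``): without selection, survival genes erode — Medawar's
mutation-accumulation picture of senescence.  A second, selectively neutral pair of gene values serves as
a marker for estimating relatedness; it mutates without bias and without
bounds.

All kernels are written batch-first (``(n, c)`` haplotype stacks) so the
simulation engine and the per-genome convenience API share one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalGenome",
    "NeutralMarker",
    "MutationParams",
    "survival_probability",
    "life_expectancy",
    "make_gamete",
    "mutate_haplotype",
    "mutate_neutral",
    "recombine_batch",
    "mutate_haplotypes_batch",
    "mutate_neutral_batch",
    "mutate_genomes_batch",
    "life_expectancy_batch",
]


@dataclass
class SurvivalGenome:
    """Two homologous haplotypes of ``c`` survival gene values in [0, 1]."""

    maternal: np.ndarray
    paternal: np.ndarray

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=float)
        self.paternal = np.asarray(self.paternal, dtype=float)
        if self.maternal.ndim != 1 or self.maternal.shape != self.paternal.shape:
            raise ValueError("haplotypes must be 1-D and of equal length")
        for name, h in (("maternal", self.maternal), ("paternal", self.paternal)):
            if h.size == 0:
                raise ValueError(f"{name} haplotype is empty")
            if np.any(h < 0.0) or np.any(h > 1.0):
                raise ValueError(f"{name} haplotype has gene values outside [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.maternal.size

    @classmethod
    def constant(cls, c: int, g: float) -> "SurvivalGenome":
        """Genome with every gene value equal to ``g`` (the initial state)."""
        return cls(np.full(c, float(g)), np.full(c, float(g)))


@dataclass
class NeutralMarker:
    """Two homologous, unbounded neutral gene values (relatedness marker)."""

    maternal: float
    paternal: float

    @property
    def mean(self) -> float:
        return 0.5 * (self.maternal + self.paternal)


@dataclass(frozen=True)
class MutationParams:
    """Mutation kernel: genome-wide rate ``m``, effect ``Normal(mu, sigma)``.

    ``m`` is the probability that a newborn picks up a mutation event at
    emergence; an event perturbs every locus of one inherited haplotype by
    independent normal draws (see :func:`mutate_genomes_batch`).  ``mu`` is
    the mutation bias (negative: deleterious on average) and ``sigma`` the
    mutational effect size.
    """

    m: float = 0.02
    mu: float = -0.009
    sigma: float = 0.018

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"mutation rate m={self.m} outside [0, 1]")
        if self.sigma < 0.0:
            raise ValueError(f"mutational effect size sigma={self.sigma} < 0")


# ---------------------------------------------------------------------------
# per-genome API


def survival_probability(genome: SurvivalGenome, age: int) -> float:
    """Age-specific survival: the mean of the two homologous gene values.

    Ages at or beyond the number of loci return 0.0 — death is certain at
    the maximum age.
    """
    if age < 0:
        raise ValueError(f"negative age {age}")
    if age >= genome.n_loci:
        return 0.0
    return 0.5 * (genome.maternal[age] + genome.paternal[age])


def life_expectancy(genome: SurvivalGenome) -> float:
    """Expected lifespan: sum over ages of cumulative survival products.

    Returns ``sum_{x=1}^{c} prod_{k=0}^{x-1} s_k`` where ``s_k`` is the
    age-specific survival probability; lies in ``[0, c]``.
    """
    s = 0.5 * (genome.maternal + genome.paternal)
    return float(np.cumprod(s).sum())


def make_gamete(genome: SurvivalGenome, rng: np.random.Generator) -> np.ndarray:
    """Form a gamete under free recombination.

    Each locus value is copied from the maternal or paternal haplotype with
    probability 1/2, independently across loci.
    """
    return recombine_batch(genome.maternal[None, :], genome.paternal[None, :], rng)[0]


def mutate_haplotype(
    haplotype: np.ndarray, params: MutationParams, rng: np.random.Generator
) -> np.ndarray:
    """Mutate one inherited survival haplotype.

    With probability ``params.m`` a mutation event occurs and every locus
    receives an independent ``Normal(mu, sigma)`` perturbation, clamped back
    into [0, 1]; otherwise the haplotype is returned unchanged.  Always
    returns a copy.
    """
    out = np.array(haplotype, dtype=float, copy=True)[None, :]
    mutate_haplotypes_batch(out, params, rng)
    return out[0]


def mutate_neutral(
    value: float, params: MutationParams, rng: np.random.Generator
) -> float:
    """Mutate one inherited neutral gene value: unbiased, unbounded.

    With probability ``params.m`` adds a ``Normal(0, sigma)`` draw; no
    clamping, so the marker stays an unbiased pedigree tracer.
    """
    out = np.array([value], dtype=float)
    mutate_neutral_batch(out, params, rng)
    return float(out[0])


# ---------------------------------------------------------------------------
# batched kernels (shared with the simulation engine)


def recombine_batch(
    maternal: np.ndarray, paternal: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Free recombination for a stack of genomes: per-locus fair coin flips.

    ``maternal`` and ``paternal`` are ``(n, c)``; returns ``(n, c)`` gametes.
    """
    take_mat = rng.random(maternal.shape) < 0.5
    return np.where(take_mat, maternal, paternal)


def mutate_haplotypes_batch(
    haplotypes: np.ndarray, params: MutationParams, rng: np.random.Generator
) -> np.ndarray:
    """In-place biased mutation of an ``(n, c)`` stack of survival haplotypes.

    One Bernoulli(m) trial per haplotype (row); hit rows get independent
    Normal(mu, sigma) perturbations at every locus, then are clamped to
    [0, 1].
    """
    n, c = haplotypes.shape
    if n == 0 or params.m == 0.0:
        return haplotypes
    hit = rng.random(n) < params.m
    k = int(hit.sum())
    if k:
        rows = haplotypes[hit]
        rows += rng.normal(params.mu, params.sigma, size=(k, c))
        np.clip(rows, 0.0, 1.0, out=rows)
        haplotypes[hit] = rows
    return haplotypes


def mutate_neutral_batch(
    values: np.ndarray, params: MutationParams, rng: np.random.Generator
) -> np.ndarray:
    """In-place unbiased mutation of an ``(n,)`` stack of neutral values."""
    n = values.shape[0]
    if n == 0 or params.m == 0.0 or params.sigma == 0.0:
        return values
    hit = rng.random(n) < params.m
    k = int(hit.sum())
    if k:
        values[hit] += rng.normal(0.0, params.sigma, size=k)
    return values


def mutate_genomes_batch(
    maternal: np.ndarray,
    paternal: np.ndarray,
    neutral: np.ndarray,
    params: MutationParams,
    rng: np.random.Generator,
) -> None:
    """In-place mutation of whole newborn genomes at genome-wide rate ``m``.

    For each of the ``n`` offspring, one Bernoulli(``m``) trial decides
    whether a mutation event occurs at emergence; when it does, a fair
    coin picks the maternally or the paternally inherited haplotype, and
    every survival locus of that haplotype receives an independent
    ``Normal(mu, sigma)`` perturbation (clamped to [0, 1]) while its
    linked neutral gene value receives an unbiased, unclamped
    ``Normal(0, sigma)`` draw.

    ``maternal`` and ``paternal`` are ``(n, c)`` survival haplotypes and
    ``neutral`` is ``(n, 2)`` with the maternally inherited value in
    column 0.
    """
    n, c = maternal.shape
    if n == 0 or params.m == 0.0:
        return
    hit = rng.random(n) < params.m
    take_mat = rng.random(n) < 0.5
    for which, hap, col in ((take_mat, maternal, 0), (~take_mat, paternal, 1)):
        rows = np.nonzero(hit & which)[0]
        if rows.size:
            sub = hap[rows]
            sub += rng.normal(params.mu, params.sigma, size=(rows.size, c))
            np.clip(sub, 0.0, 1.0, out=sub)
            hap[rows] = sub
            if params.sigma > 0.0:
                neutral[rows, col] += rng.normal(0.0, params.sigma, size=rows.size)


def life_expectancy_batch(maternal: np.ndarray, paternal: np.ndarray) -> np.ndarray:
    """Life expectancy for an ``(n, c)`` stack of genomes (vectorised)."""
    s = 0.5 * (maternal + paternal)
    return np.cumprod(s, axis=1).sum(axis=1)
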