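import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from coopage.genome import (
    MutationParams,
    SurvivalGenome,
    life_expectancy,
    make_gamete,
    mutate_haplotype,
    mutate_neutral,
    recombine_batch,
    survival_probability,
)

C = 20

haplotype_strategy = arrays(
    float, C, elements=st.floats(0.0, 1.0, allow_nan=False, width=32)
)


def geometric_life_expectancy(s, c):
    """Independent oracle: brute-force loop over the life table."""
    total = 0.0
    surv = 1.0
    for _ in range(c):
        surv *= s
        total += surv
    return total


class TestSurvivalProbability:
    def test_mean_of_homologs(self):
        g = SurvivalGenome.constant(C, 0.5)
        g.maternal[3], g.paternal[3] = 0.9, 0.7
        assert survival_probability(g, 3) == pytest.approx(0.8)

    def test_constant_genome(self):
        g = SurvivalGenome.constant(C, 0.8)
        for age in (0, 7, C - 1):
            assert survival_probability(g, age) == pytest.approx(0.8)

    def test_death_certain_at_maximum_age(self):
        g = SurvivalGenome.constant(C, 1.0)
        assert survival_probability(g, C) == 0.0
        assert survival_probability(g, C + 5) == 0.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(SurvivalGenome.constant(C, 0.5), -1)

    def test_gene_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SurvivalGenome(np.full(C, 1.2), np.full(C, 0.5))


class TestLifeExpectancy:
    def test_certain_survival_reaches_age_ceiling(self):
        assert life_expectancy(SurvivalGenome.constant(C, 1.0)) == pytest.approx(C)

    def test_certain_death(self):
        assert life_expectancy(SurvivalGenome.constant(C, 0.0)) == 0.0

    def test_constant_survival_matches_geometric_series(self):
        got = life_expectancy(SurvivalGenome.constant(C, 0.8))
        assert got == pytest.approx(geometric_life_expectancy(0.8, C), abs=1e-9)
        assert got == pytest.approx(3.9539, abs=5e-5)

    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_matches_closed_form_for_any_constant_s(self, s):
        got = life_expectancy(SurvivalGenome.constant(C, s))
        assert got == pytest.approx(geometric_life_expectancy(s, C), abs=1e-9)

    @given(haplotype_strategy, st.integers(0, C - 1))
    def test_monotone_in_every_locus(self, h, locus):
        base = SurvivalGenome(h.copy(), h.copy())
        raised = SurvivalGenome(h.copy(), h.copy())
        raised.maternal[locus] = 1.0
        assert life_expectancy(raised) >= life_expectancy(base) - 1e-12


class TestMakeGamete:
    def test_homozygous_parent_transmits_exactly(self, rng):
        h = np.linspace(0.0, 1.0, C)
        gamete = make_gamete(SurvivalGenome(h.copy(), h.copy()), rng)
        np.testing.assert_array_equal(gamete, h)

    def test_gamete_length(self, rng):
        g = SurvivalGenome(np.full(7, 0.3), np.full(7, 0.9))
        assert make_gamete(g, rng).shape == (7,)

    @given(haplotype_strategy, haplotype_strategy)
    def test_loci_come_from_one_of_the_parental_haplotypes(self, mat, pat):
        rng = np.random.default_rng(0)
        gamete = make_gamete(SurvivalGenome(mat, pat), rng)
        for k in range(C):
            assert gamete[k] in (mat[k], pat[k])

    def test_free_recombination_is_a_fair_coin(self, rng):
        n = 10_000
        mat = np.ones((n, 1))
        pat = np.zeros((n, 1))
        draws = recombine_batch(mat, pat, rng)[:, 0]
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= draws.sum() <= hi


class TestMutation:
    def test_zero_rate_leaves_haplotype_unchanged(self, rng):
        h = np.linspace(0.0, 1.0, C)
        out = mutate_haplotype(h, MutationParams(m=0.0), rng)
        np.testing.assert_array_equal(out, h)

    def test_clamped_at_lower_limit(self, rng):
        h = np.full(C, 0.005)
        out = mutate_haplotype(h, MutationParams(m=1.0, mu=-0.010, sigma=0.0), rng)
        np.testing.assert_allclose(out, 0.0)

    def test_degenerate_normal_shifts_every_locus(self, rng):
        h = np.full(C, 0.5)
        out = mutate_haplotype(h, MutationParams(m=1.0, mu=-0.009, sigma=0.0), rng)
        np.testing.assert_allclose(out, 0.5 - 0.009)

    @given(haplotype_strategy)
    def test_values_stay_in_unit_interval(self, h):
        rng = np.random.default_rng(7)
        params = MutationParams(m=1.0, mu=-0.5, sigma=0.8)
        out = h.copy()
        for _ in range(5):
            out = mutate_haplotype(out, params, rng)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            MutationParams(m=-0.1)
        with pytest.raises(ValueError):
            MutationParams(sigma=-1.0)


class TestGenomeWideMutation:
    """One Bernoulli(m) event per newborn, hitting one inherited haplotype."""

    def _genomes(self, n, value=0.5):
        mat = np.full((n, C), value)
        pat = np.full((n, C), value)
        neut = np.zeros((n, 2))
        return mat, pat, neut

    def test_zero_rate_changes_nothing(self, rng):
        from coopage.genome import mutate_genomes_batch

        mat, pat, neut = self._genomes(100)
        mutate_genomes_batch(mat, pat, neut, MutationParams(m=0.0), rng)
        assert np.all(mat == 0.5) and np.all(pat == 0.5) and np.all(neut == 0.0)

    def test_event_hits_exactly_one_haplotype(self, rng):
        from coopage.genome import mutate_genomes_batch

        n = 2000
        mat, pat, neut = self._genomes(n)
        params = MutationParams(m=1.0, mu=-0.009, sigma=0.0)
        mutate_genomes_batch(mat, pat, neut, params, rng)
        mat_hit = np.all(mat == 0.5 - 0.009, axis=1)
        pat_hit = np.all(pat == 0.5 - 0.009, axis=1)
        assert np.all(mat_hit ^ pat_hit)  # one and only one per newborn
        # the coin is fair
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= mat_hit.sum() <= hi

    def test_expected_event_count_matches_the_rate(self, rng):
        from coopage.genome import mutate_genomes_batch

        n, m = 20_000, 0.02
        mat, pat, neut = self._genomes(n)
        mutate_genomes_batch(mat, pat, neut, MutationParams(m=m, sigma=0.0), rng)
        hits = (np.any(mat != 0.5, axis=1) | np.any(pat != 0.5, axis=1)).sum()
        lo, hi = sps.binom.ppf([0.005, 0.995], n, m)
        assert lo <= hits <= hi

    def test_neutral_value_mutates_with_the_hit_haplotype(self, rng):
        from coopage.genome import mutate_genomes_batch

        mat, pat, neut = self._genomes(500)
        params = MutationParams(m=1.0, mu=-0.009, sigma=0.018)
        mutate_genomes_batch(mat, pat, neut, params, rng)
        mat_hit = np.all(mat != 0.5, axis=1)
        assert np.all((neut[:, 0] != 0.0) == mat_hit)
        assert np.all((neut[:, 1] != 0.0) == ~mat_hit)

    def test_survival_values_clamped_but_neutral_unbounded(self, rng):
        from coopage.genome import mutate_genomes_batch

        mat, pat, neut = self._genomes(500, value=0.001)
        params = MutationParams(m=1.0, mu=-1.0, sigma=0.001)
        for _ in range(3):
            mutate_genomes_batch(mat, pat, neut, params, rng)
        assert np.all(mat >= 0.0) and np.all(pat >= 0.0)
        assert np.all(mat <= 1.0) and np.all(pat <= 1.0)


class TestNeutralMutation:
    def test_zero_rate_unchanged(self, rng):
        assert mutate_neutral(1.5, MutationParams(m=0.0), rng) == 1.5

    def test_zero_sigma_unchanged(self, rng):
        assert mutate_neutral(1.5, MutationParams(m=1.0, sigma=0.0), rng) == 1.5

    def test_unbiased_mean_change(self, rng):
        from coopage.genome import mutate_neutral_batch

        n = 100_000
        sigma = 0.018
        values = np.zeros(n)
        mutate_neutral_batch(values, MutationParams(m=1.0, sigma=sigma), rng)
        half_width = 2.576 * sigma / np.sqrt(n)
        assert abs(values.mean()) < half_width
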