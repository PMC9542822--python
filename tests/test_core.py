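"""Fitness schemes and exact recombination machinery."""

import itertools

import numpy as np
import pytest

from riflow import (
    FitnessScheme,
    GeneticArchitecture,
    HaplotypeDistribution,
    Locus,
    PairInteraction,
    UnknownEnvironmentError,
    divergent_locus,
    genotype_fitness,
    recombination_distribution,
)
from riflow.core import recombine_cross, recombine_population


def three_neutral(r1=0.1, r2=0.2):
    return GeneticArchitecture(
        [Locus("a"), Locus("b"), Locus("c")], [r1, r2]
    )


def brute_force_offspring(adjacent_r, p1, p2, L):
    """Enumerate crossover indicator vectors and both leading parents."""
    probs = np.zeros(1 << L)
    for cs in itertools.product([0, 1], repeat=L - 1):
        w = 1.0
        for c, r in zip(cs, adjacent_r):
            w *= r if c else 1.0 - r
        for lead in (0, 1):
            src = lead
            hap = 0
            parents = (p1, p2)
            for i in range(L):
                if i > 0:
                    src ^= cs[i - 1]
                hap |= ((parents[src] >> i) & 1) << i
            probs[hap] += 0.5 * w
    return probs


class TestGenotypeFitness:
    def test_resident_baseline_is_one(self):
        arch = GeneticArchitecture(
            [divergent_locus("s1", 0.1), divergent_locus("s2", 0.3), Locus("n")],
            [0.1, 0.5],
        )
        scheme = FitnessScheme(arch)
        assert genotype_fitness(scheme, 0b000, "recipient") == 1.0
        assert genotype_fitness(scheme, 0b011, "source") == 1.0  # resident at home

    def test_multiplicative_product_over_loci(self):
        arch = GeneticArchitecture(
            [divergent_locus("s1", 0.1), divergent_locus("s2", 0.1), Locus("n")],
            [0.5, 0.5],
        )
        scheme = FitnessScheme(arch)
        assert genotype_fitness(scheme, 0b011, "recipient") == pytest.approx(0.81)
        # multiplicativity over disjoint foreign-allele sets
        w = scheme.fitness_vector("recipient")
        assert w[0b011] == pytest.approx(w[0b001] * w[0b010])

    def test_all_s_zero_gives_unit_fitness_everywhere(self):
        arch = GeneticArchitecture(
            [divergent_locus("s1", 0.0), Locus("n")], [0.2]
        )
        w = FitnessScheme(arch).fitness_vector("recipient")
        assert np.all(w == 1.0)

    def test_dmi_lethal_incompatibility(self):
        arch = GeneticArchitecture(
            [
                Locus("A", "selected", s={"recipient": 0.0}),
                Locus("B", "selected", s={"recipient": 0.0}),
            ],
            [0.5],
        )
        scheme = FitnessScheme(arch, "dmi", [PairInteraction("A", "B", 1.0)])
        assert genotype_fitness(scheme, 0b11, "recipient") == 0.0
        assert genotype_fitness(scheme, 0b01, "recipient") == 1.0

    def test_pairwise_epistasis_joint_term(self):
        arch = GeneticArchitecture(
            [divergent_locus("A", 0.1), divergent_locus("B", 0.1)], [0.3]
        )
        scheme = FitnessScheme(
            arch, "pairwise_epistasis", [PairInteraction("A", "B", 0.3)]
        )
        w = scheme.fitness_vector("recipient")
        assert w[0b01] == pytest.approx(0.9)
        assert w[0b10] == pytest.approx(0.9)
        assert w[0b11] == pytest.approx(0.7)  # 1 - s12, not (1-s1)(1-s2)

    def test_unknown_environment_raises(self):
        arch = GeneticArchitecture([divergent_locus("s1", 0.1), Locus("n")], [0.1])
        scheme = FitnessScheme(arch)
        with pytest.raises(UnknownEnvironmentError):
            genotype_fitness(scheme, 0, "nowhere")

    def test_negative_fitness_rejected(self):
        arch = GeneticArchitecture(
            [Locus("A", "selected", s={"e": 1.5})], []
        )
        with pytest.raises(ValueError, match="negative fitness"):
            FitnessScheme(arch).fitness_vector("e")


class TestRecombination:
    def test_identical_parents_point_mass(self):
        arch = three_neutral()
        d = recombination_distribution(arch, 0b101, 0b101)
        assert d[0b101] == pytest.approx(1.0)

    def test_free_recombination_two_loci_uniform(self):
        arch = GeneticArchitecture([Locus("a"), Locus("b")], [0.5])
        d = recombination_distribution(arch, 0b00, 0b11)
        assert np.allclose(d, 0.25)

    @pytest.mark.parametrize("p1,p2", [(0b000, 0b111), (0b010, 0b101), (0b110, 0b001)])
    def test_matches_brute_force_crossover_enumeration(self, p1, p2):
        arch = three_neutral()
        d = recombination_distribution(arch, p1, p2)
        expected = brute_force_offspring(arch.adjacent_r, p1, p2, 3)
        assert np.allclose(d, expected)
        assert d.sum() == pytest.approx(1.0)

    def test_symmetric_in_parents(self):
        arch = three_neutral(0.05, 0.4)
        assert np.allclose(
            recombination_distribution(arch, 0b001, 0b110),
            recombination_distribution(arch, 0b110, 0b001),
        )

    def test_population_recombination_preserves_allele_frequencies(self):
        arch = three_neutral()
        rng = np.random.default_rng(42)
        for _ in range(5):
            f = rng.dirichlet(np.ones(8))
            off = recombine_population(f, arch)
            assert off.sum() == pytest.approx(1.0)
            assert np.allclose(
                arch.marginal_allele_frequencies(off),
                arch.marginal_allele_frequencies(f),
            )
            assert np.all(off >= 0)

    def test_cross_recombination_mean_of_parent_alleles(self):
        arch = three_neutral()
        rng = np.random.default_rng(1)
        f1 = rng.dirichlet(np.ones(8))
        f2 = rng.dirichlet(np.ones(8))
        off = recombine_cross(f1, f2, arch)
        expect = 0.5 * (
            arch.marginal_allele_frequencies(f1) + arch.marginal_allele_frequencies(f2)
        )
        assert np.allclose(arch.marginal_allele_frequencies(off), expect)

    def test_zero_recombination_gives_parental_mixture(self):
        arch = three_neutral(0.0, 0.0)
        d = recombination_distribution(arch, 0b010, 0b101)
        assert d[0b010] == pytest.approx(0.5)
        assert d[0b101] == pytest.approx(0.5)


class TestRecombinationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        r1=st.floats(0.0, 0.5),
        r2=st.floats(0.0, 0.5),
        p1=st.integers(0, 7),
        p2=st.integers(0, 7),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_offspring_allele_content_is_parental_mean(self, r1, r2, p1, p2):
        arch = three_neutral(r1, r2)
        d = recombination_distribution(arch, p1, p2)
        assert d.sum() == pytest.approx(1.0)
        assert np.all(d >= 0)
        expect = 0.5 * np.array(
            [((p1 >> i) & 1) + ((p2 >> i) & 1) for i in range(3)], dtype=float
        )
        assert np.allclose(arch.marginal_allele_frequencies(d), expect)

    @given(
        r1=st.floats(0.0, 0.5),
        r2=st.floats(0.0, 0.5),
        p1=st.integers(0, 7),
        p2=st.integers(0, 7),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_brute_force_everywhere(self, r1, r2, p1, p2):
        arch = three_neutral(r1, r2)
        d = recombination_distribution(arch, p1, p2)
        assert np.allclose(d, brute_force_offspring(arch.adjacent_r, p1, p2, 3))


class TestArchitecture:
    def test_compound_r_capped_at_half(self):
        arch = GeneticArchitecture(
            [Locus(c) for c in "abcd"], [0.4, 0.4, 0.4]
        )
        assert arch.compound_r(0, 3) <= 0.5
        assert arch.compound_r(0, 1) == pytest.approx(0.4)
        # two intervals: r = (1 - (1-2r1)(1-2r2))/2
        assert arch.compound_r(0, 2) == pytest.approx(0.5 * (1 - 0.2 * 0.2))

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            GeneticArchitecture([Locus("a")], [0.1])  # wrong r count
        with pytest.raises(ValueError):
            GeneticArchitecture([Locus("a"), Locus("b")], [0.7])  # r > 0.5
        with pytest.raises(ValueError):
            Locus("x", "selected", s={"e": -1.0})  # s <= -1
        with pytest.raises(ValueError):
            Locus("x", "neutral", s={"e": 0.1})  # neutral with s

    def test_haplotype_distribution_invariants(self):
        arch = three_neutral()
        with pytest.raises(ValueError):
            HaplotypeDistribution(arch, np.full(8, 0.2))  # sums to 1.6
        d = HaplotypeDistribution.point_mass(arch, 0b110)
        assert d.allele_frequency("a") == 0.0
        assert d.allele_frequency("b") == 1.0
        assert d.allele_frequency(2) == 1.0
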