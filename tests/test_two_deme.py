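"""Two-deme effective migration, RI formulas and the pool construction."""

import warnings

import numpy as np
import pytest

from riflow import (
    FitnessScheme,
    GeneticArchitecture,
    Locus,
    PairInteraction,
    TwoDemeConfig,
    UndefinedEstimateError,
    divergent_locus,
    effective_migration_rate,
    expected_class_fitnesses,
    pool_matrix_me,
    recombination_distribution,
    ri_from_fitness_product,
    ri_single_linked_locus,
    ri_two_deme,
    ri_two_flanking_loci,
    simulate_two_deme,
)
from riflow.two_deme import TwoDemeTrajectory


def linked_pair(s, r):
    return GeneticArchitecture([divergent_locus("sel", s), Locus("neu")], [r])


class TestClosedForms:
    def test_single_locus_limits(self):
        assert ri_single_linked_locus(0.0, 0.1) == 1.0
        assert ri_single_linked_locus(0.1, 0.0) == 0.0
        assert ri_single_linked_locus(0.5, 0.1) == pytest.approx(1.0 / 6.0)
        with pytest.raises(ValueError):
            ri_single_linked_locus(0.0, 0.0)

    def test_single_locus_monotonicities(self):
        rs = np.linspace(0.01, 0.5, 20)
        ri_r = [ri_single_linked_locus(r, 0.1) for r in rs]
        assert np.all(np.diff(ri_r) < 0)
        ss = np.linspace(0.01, 0.5, 20)
        ri_s = [ri_single_linked_locus(0.1, s) for s in ss]
        assert np.all(np.diff(ri_s) > 0)

    def test_two_flanking_no_epistasis_is_product_of_single_factors(self):
        r1, s1, r2, s2 = 0.1, 0.1, 0.1, 0.1
        ri = ri_two_flanking_loci(r1, s1, r2, s2, s1 + s2)
        prod = (1 - ri_single_linked_locus(r1, s1)) * (1 - ri_single_linked_locus(r2, s2))
        assert ri == pytest.approx(1 - prod)
        assert ri == pytest.approx(0.75)

    def test_two_flanking_limits(self):
        assert ri_two_flanking_loci(0.1, 0.0, 0.1, 0.0, 0.0) == pytest.approx(0.0)
        assert ri_two_flanking_loci(1e-9, 0.1, 0.1, 0.1, 0.2) == pytest.approx(1.0, abs=1e-6)

    def test_ri_two_deme_identities(self):
        assert ri_two_deme(0.01, 0.01).ri == 0.0
        assert ri_two_deme(0.0, 0.01).ri == 1.0
        assert ri_two_deme(0.012, 0.01).ri == pytest.approx(-0.2)
        with pytest.raises(ValueError):
            ri_two_deme(0.01, 0.0)


class TestFitnessProduct:
    def test_trivial_cases(self):
        assert ri_from_fitness_product([1.0, 1.0, 1.0]) == 0.0
        assert ri_from_fitness_product([0.0, 1.0, 1.0]) == 1.0

    def test_geometric_halving_worked_example(self):
        ws = [0.5] + [0.64 ** (2.0 ** (1 - k)) for k in range(1, 60)]
        assert ri_from_fitness_product(ws) == pytest.approx(0.7952, abs=1e-4)

    def test_truncated_form(self):
        ws = [0.5, 0.8, 0.9, 0.99]
        assert ri_from_fitness_product(ws, truncation=2) == pytest.approx(
            1 - 0.5 * 0.8 * 0.9**2
        )
        with pytest.raises(ValueError):
            ri_from_fitness_product([0.5, 0.8], truncation=2)
        with pytest.raises(ValueError):
            ri_from_fitness_product([0.5, -0.1])


class TestSimulation:
    def test_no_barrier_identity(self):
        arch = GeneticArchitecture([Locus("neu")], [])
        traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=0.01))
        me = effective_migration_rate(traj, "neu")
        assert me == pytest.approx(0.01, abs=1e-10)
        assert ri_two_deme(me, 0.01).ri == pytest.approx(0.0, abs=1e-8)
        assert np.all(np.isclose(traj.me_inst["neu"], 0.01))

    def test_unlinked_single_locus_near_closed_form(self):
        # the discrete-generation barrier for r=0.5, s=0.1 sits within 0.02
        # of the diffusion-limit value m_e/m = 5/6
        arch = linked_pair(0.1, 0.5)
        traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=1e-4))
        me = effective_migration_rate(traj, "neu")
        assert me / 1e-4 == pytest.approx(5.0 / 6.0, abs=0.02)

    def test_linked_locus_matches_closed_form(self):
        arch = linked_pair(0.1, 0.1)
        traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=1e-4))
        ri = ri_two_deme(effective_migration_rate(traj, "neu"), 1e-4).ri
        assert ri == pytest.approx(0.5, abs=0.05)

    def test_simulated_monotonicity_in_r_and_s(self):
        ris = []
        for r in (0.01, 0.1, 0.5):
            arch = linked_pair(0.1, r)
            traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=1e-4))
            ris.append(ri_two_deme(effective_migration_rate(traj, "neu"), 1e-4).ri)
        assert ris[0] > ris[1] > ris[2]
        ris = []
        for s in (0.01, 0.05, 0.2):
            arch = linked_pair(s, 0.1)
            traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=1e-4))
            ris.append(ri_two_deme(effective_migration_rate(traj, "neu"), 1e-4).ri)
        assert ris[0] < ris[1] < ris[2]

    def test_frequencies_stay_in_unit_interval(self):
        arch = linked_pair(0.2, 0.05)
        traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=0.05))
        for mk in traj.markers:
            assert np.all(traj.p_recipient[mk] >= 0) and np.all(traj.p_recipient[mk] <= 1)

    def test_me_inst_constant_after_equilibration(self):
        arch = linked_pair(0.1, 0.2)
        traj = simulate_two_deme(arch, FitnessScheme(arch), TwoDemeConfig(m=1e-4))
        g0 = traj.equilibrated_generation
        tail = traj.me_inst["neu"][traj.generation >= g0]
        tail = tail[np.isfinite(tail)]
        assert np.ptp(tail) < 1e-8 * np.mean(tail) + 1e-14

    def test_heterosis_raises_me_above_m(self):
        # haplotypes carrying a single foreign allele are fitter than both
        # parental types: early-generation m_e exceeds m, RI is negative
        arch = GeneticArchitecture(
            [divergent_locus("A", -0.2), divergent_locus("B", -0.2), Locus("neu")],
            [0.5, 0.5],
        )
        scheme = FitnessScheme(arch, "pairwise_epistasis", [PairInteraction("A", "B", 0.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = simulate_two_deme(
                arch, scheme, TwoDemeConfig(m=1e-3, max_generations=100)
            )
        early = traj.me_inst["neu"][1:20]
        assert np.all(early > 1e-3)
        assert ri_two_deme(np.nanmax(early), 1e-3).ri < 0


class TestEffectiveMigrationRate:
    def test_exact_line_through_origin(self):
        g = np.arange(1, 51)
        Dp = 0.9**g
        traj = TwoDemeTrajectory(
            m=0.01,
            markers=["neu"],
            generation=g,
            p_source={"neu": np.ones(50)},
            p_recipient={"neu": 1 - Dp},
            delta_p={"neu": 0.003 * Dp},
            Delta_p={"neu": Dp},
            me_inst={"neu": np.full(50, 0.003)},
            equilibrated_generation=1,
            converged=True,
        )
        assert effective_migration_rate(traj, "neu") == pytest.approx(0.003)

    def test_homogenized_populations_undefined(self):
        g = np.arange(1, 11)
        z = np.zeros(10)
        traj = TwoDemeTrajectory(
            m=0.01, markers=["neu"], generation=g,
            p_source={"neu": np.ones(10)}, p_recipient={"neu": np.ones(10)},
            delta_p={"neu": z}, Delta_p={"neu": z}, me_inst={"neu": np.full(10, np.nan)},
            equilibrated_generation=1, converged=True,
        )
        with pytest.raises(UndefinedEstimateError):
            effective_migration_rate(traj, "neu")


class TestClassFitnesses:
    def test_no_selection_all_unity(self):
        arch = GeneticArchitecture([divergent_locus("A", 0.0), Locus("neu")], [0.5])
        cf = expected_class_fitnesses(arch, FitnessScheme(arch), n_classes=5)
        assert np.allclose(cf.values, 1.0)

    def test_migrant_class_fitness_two_unlinked_loci(self):
        arch = GeneticArchitecture(
            [divergent_locus("A", 0.1), divergent_locus("B", 0.1), Locus("neu")],
            [0.5, 0.5],
        )
        scheme = FitnessScheme(arch)
        cf = expected_class_fitnesses(arch, scheme, n_classes=10)
        assert cf.values[0] == pytest.approx(0.81)
        # F1 class against brute-force genotype enumeration: offspring of
        # migrant x resident, fitness averaged over the exact distribution
        w = scheme.fitness_vector("recipient")
        f1 = recombination_distribution(arch, arch.n_haplotypes - 1, 0)
        assert cf.values[1] == pytest.approx(float(f1 @ w))
        # naive chain ignores selection: strictly below the propagated one
        # from the second backcross on (selection purges deleterious alleles)
        assert np.all(cf.values[2:] >= cf.naive[2:])

    def test_product_matches_simulation_at_low_m(self):
        arch = GeneticArchitecture(
            [divergent_locus("A", 0.1), divergent_locus("B", 0.1), Locus("neu")],
            [0.5, 0.5],
        )
        scheme = FitnessScheme(arch)
        ri_prod = ri_from_fitness_product(
            expected_class_fitnesses(arch, scheme, n_classes=40)
        )
        traj = simulate_two_deme(arch, scheme, TwoDemeConfig(m=1e-5))
        ri_sim = ri_two_deme(effective_migration_rate(traj, "neu"), 1e-5).ri
        assert ri_prod == pytest.approx(ri_sim, abs=0.02)

    def test_n_classes_validation(self):
        arch = GeneticArchitecture([divergent_locus("A", 0.1), Locus("neu")], [0.5])
        with pytest.raises(ValueError):
            expected_class_fitnesses(arch, FitnessScheme(arch), n_classes=0)


class TestPoolMatrix:
    def test_no_selection_returns_migration_matrix(self):
        arch = GeneticArchitecture([Locus("neu")], [])
        M = np.array([[0.999, 0.001], [0.001, 0.999]])
        res = pool_matrix_me(arch, FitnessScheme(arch), ["a", "b"], M)
        assert res.me[0, 1] == pytest.approx(0.001, rel=1e-9)
        assert res.me[1, 0] == pytest.approx(0.001, rel=1e-9)

    def test_matches_two_deme_simulation(self):
        m = 1e-4
        arch = linked_pair(0.1, 0.1)
        scheme = FitnessScheme(arch)
        M = np.array([[1 - m, m], [m, 1 - m]])
        res = pool_matrix_me(arch, scheme, ["source", "recipient"], M)
        traj = simulate_two_deme(
            arch, scheme, TwoDemeConfig(m=m, mode="bidirectional")
        )
        me_sim = effective_migration_rate(traj, "neu")
        assert res.me[0, 1] == pytest.approx(me_sim, rel=0.05)

    def test_middle_deme_filters_flow_in_a_chain(self):
        m = 1e-4
        arch = GeneticArchitecture(
            [
                Locus("A", "selected", s={"d1": 0.3, "d2": 0.3, "d3": 0.3},
                      disfavoured={"d1": 0, "d2": 1, "d3": 1}),
                Locus("B", "selected", s={"d1": 0.3, "d2": 0.3, "d3": 0.3},
                      disfavoured={"d1": 1, "d2": 1, "d3": 0}),
                Locus("neu"),
            ],
            [0.5, 0.5],
        )
        M = np.array([[1 - m, m, 0], [m, 1 - 2 * m, m], [0, m, 1 - m]])
        res = pool_matrix_me(arch, FitnessScheme(arch), ["d1", "d2", "d3"], M)
        assert res.me[0, 2] < res.me[0, 1] * res.me[1, 2] / m
        assert res.me[0, 1] < m  # each hop is itself filtered
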