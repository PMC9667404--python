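import numpy as np
import pytest

from haplodem.coalsim import (
    SimulationConfig,
    compile_program,
    expected_branch_sfs,
    expected_sfs_with_se,
    island_model,
    mc_standard_error,
    sample_observed_sfs,
    simulate_expected_sfs,
)
from haplodem.models import (
    Divergence,
    MigrationWindow,
    ModelSpec,
    Population,
)

HARMONIC = lambda n: sum(1.0 / i for i in range(1, n))


def single_pop(ne=1000.0, n=8, mu=2e-7, length=100):
    return ModelSpec(
        populations=[Population("P", ne, n)], mutation_rate=mu, locus_length=length
    )


class TestSinglePopulationTheory:
    def test_expected_sfs_proportional_to_one_over_i(self):
        spec = single_pop()
        sfs = simulate_expected_sfs(spec, n_sims=200_000, seed=5)
        w = 1.0 / np.arange(1, 8)
        w /= w.sum()
        assert np.abs(sfs.counts[1:8] / w - 1).max() < 0.03

    def test_total_tree_length(self):
        spec = single_pop()
        raw, _ = expected_branch_sfs(spec, 200_000, seed=6)
        expected = 2 * 1000.0 * HARMONIC(8)
        assert raw.total_mass() == pytest.approx(expected, rel=0.02)

    def test_deterministic_given_seed(self):
        spec = single_pop()
        a = simulate_expected_sfs(spec, n_sims=2000, seed=3)
        b = simulate_expected_sfs(spec, n_sims=2000, seed=3)
        c = simulate_expected_sfs(spec, n_sims=2000, seed=4)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)


class TestStructure:
    def test_ancient_split_kills_shared_polymorphism(self):
        ne = 500.0
        spec = ModelSpec(
            populations=[
                Population("A", ne, 4), Population("B", ne, 4),
                Population("ANC", ne, 0),
            ],
            divergences=[
                Divergence(100 * ne, "A", "ANC"), Divergence(100 * ne, "B", "ANC"),
            ],
        )
        sfs = simulate_expected_sfs(spec, n_sims=20_000, seed=1)
        shared = sfs.counts[1:, 1:].sum()  # derived allele present in both
        assert shared < 0.01

    def test_symmetric_demes_give_symmetric_sfs(self):
        spec = island_model(2, ne=800.0, nem=2.0, samples_per_deme=4)
        sfs = simulate_expected_sfs(spec, n_sims=150_000, seed=2)
        assert np.abs(sfs.counts - sfs.counts.T).max() < 0.005

    def test_migration_direction_convention(self):
        """Forward source->dest means backward lineage movement dest->source.

        With strictly forward A->B flow, sampled B lineages trace back into
        A (small Ne, fast coalescence): the mean tree length of a pure-B
        sample is far below the no-migration expectation 2*Ne_B*H(n).
        Under the reverse arrow the B sample must coalesce within B.
        """
        def two_pop(src, dst):
            return ModelSpec(
                populations=[
                    Population("A", 100.0, 0), Population("B", 50_000.0, 6),
                    Population("ANC", 100.0, 0),
                ],
                divergences=[
                    Divergence(5e6, "A", "ANC"), Divergence(5e6, "B", "ANC"),
                ],
                migrations=[MigrationWindow(src, dst, 5e-3, 0.0, 5e6)],
            )

        raw_fwd, _ = expected_branch_sfs(two_pop("A", "B"), 4000, seed=9)
        raw_rev, _ = expected_branch_sfs(two_pop("B", "A"), 4000, seed=9)
        no_mig = 2 * 50_000.0 * HARMONIC(6)
        assert raw_fwd.total_mass() < 0.2 * no_mig
        assert raw_rev.total_mass() > 0.5 * no_mig

    def test_compile_program_backward_rates(self):
        spec = ModelSpec(
            populations=[
                Population("A", 100.0, 2), Population("B", 100.0, 2),
                Population("ANC", 100.0, 0),
            ],
            divergences=[Divergence(1000, "A", "ANC"), Divergence(1000, "B", "ANC")],
            migrations=[MigrationWindow("A", "B", 1e-3, 0.0, 1000.0)],
        )
        prog = compile_program(spec)
        a, b = 0, 1
        # forward A->B stored as backward B->A in epoch 0
        assert prog.mig[0, b, a] == pytest.approx(1e-3)
        assert prog.mig[0, a, b] == 0.0


class TestCrossSimulatorOracle:
    def test_three_population_model_matches_msprime(self):
        """Expected SFS of a 3-population split + windowed-migration model
        agrees with msprime's branch-mode allele frequency spectrum."""
        import msprime

        t1, t2 = 2000.0, 6000.0
        spec = ModelSpec(
            populations=[
                Population("A", 1000.0, 4), Population("B", 800.0, 4),
                Population("C", 1200.0, 4), Population("BC", 900.0, 0),
                Population("ROOT", 1000.0, 0),
            ],
            divergences=[
                Divergence(t1, "B", "BC"), Divergence(t1, "C", "BC"),
                Divergence(t2, "BC", "ROOT"), Divergence(t2, "A", "ROOT"),
            ],
            migrations=[MigrationWindow("B", "C", 1e-3, 0.0, t1)],
        )
        mine, mine_se = expected_sfs_with_se(spec, 150_000, seed=3, n_batches=30)

        dem = msprime.Demography()
        for name, size in (
            ("A", 1000), ("B", 800), ("C", 1200), ("BC", 900), ("ROOT", 1000)
        ):
            dem.add_population(name=name, initial_size=size)
        # forward B->C is backward C->B
        dem.set_migration_rate(source="C", dest="B", rate=1e-3)
        dem.add_population_split(time=t1, derived=["B", "C"], ancestral="BC")
        dem.add_population_split(time=t2, derived=["BC", "A"], ancestral="ROOT")

        n_batches, reps_per = 20, 1000
        batches = np.zeros((n_batches, 5, 5, 5))
        reps = msprime.sim_ancestry(
            samples={"A": 4, "B": 4, "C": 4}, demography=dem, ploidy=1,
            num_replicates=n_batches * reps_per, random_seed=11,
        )
        for r, ts in enumerate(reps):
            ss = [ts.samples(population=i) for i in range(3)]
            batches[r // reps_per] += ts.allele_frequency_spectrum(
                ss, mode="branch", polarised=True, span_normalise=True
            )
        theirs_se = mc_standard_error(
            batches.reshape(n_batches, -1), (5, 5, 5)
        )
        total = batches.sum(axis=0)
        mask = np.ones((5, 5, 5), bool)
        mask[0, 0, 0] = mask[4, 4, 4] = False
        theirs = np.where(mask, total / total[mask].sum(), 0.0)

        tol = 3 * np.sqrt(mine_se**2 + theirs_se**2) + 1e-4
        assert (np.abs(mine.counts - theirs) < tol).all()


class TestSampledSfs:
    def test_zero_mutation_rate_empty(self):
        spec = single_pop(mu=0.0)
        sfs = sample_observed_sfs(spec, SimulationConfig(n_loci=200, seed=1))
        assert sfs.total_mass() == 0.0

    def test_watterson_expectation(self):
        ne, n, mu, length = 1000.0, 8, 2e-7, 100
        spec = single_pop(ne=ne, n=n, mu=mu, length=length)
        n_loci = 4000
        sfs = sample_observed_sfs(spec, SimulationConfig(n_loci=n_loci, seed=2))
        theta_locus = 2 * ne * mu * length
        expected = n_loci * theta_locus * HARMONIC(n)
        got = sfs.total_mass(polymorphic_only=True)
        assert got == pytest.approx(expected, rel=0.06)

    def test_mean_sampled_matches_expected_proportions(self):
        spec = single_pop()
        sampled = sample_observed_sfs(spec, SimulationConfig(n_loci=20_000, seed=4))
        expected = simulate_expected_sfs(spec, n_sims=100_000, seed=5)
        got = sampled.normalized()
        assert np.abs(got.counts - expected.counts).max() < 0.01


class TestMcStandardError:
    def test_se_scaling_with_n_sims(self):
        spec = single_pop()
        _, se1 = expected_sfs_with_se(spec, 20_000, seed=7, n_batches=40)
        _, se2 = expected_sfs_with_se(spec, 80_000, seed=7, n_batches=40)
        cells = slice(1, 8)
        ratio = np.median(se1[cells] / se2[cells])
        assert 1.5 < ratio < 2.7  # ~2 expected for a 4x budget

    def test_structural_zero_cell_has_zero_se(self):
        spec = single_pop(n=4)
        sfs, se = expected_sfs_with_se(spec, 5000, seed=8, n_batches=20)
        assert sfs.counts[0] == 0.0 and se[0] == 0.0

    def test_envelope_covers_long_run_value(self):
        spec = single_pop(n=6)
        w = 1.0 / np.arange(1, 6)
        truth = w / w.sum()
        hits = total = 0
        for seed in range(15):
            sfs, se = expected_sfs_with_se(spec, 15_000, seed=100 + seed,
                                           n_batches=30)
            covered = np.abs(sfs.counts[1:6] - truth) <= 2 * se[1:6]
            hits += covered.sum()
            total += covered.size
        assert hits / total >= 0.85


class TestIslandModel:
    def test_structure(self):
        spec = island_model(3, ne=500.0, nem=1.0, samples_per_deme=2)
        assert len(spec.migrations) == 6
        assert spec.migrations[0].rate == pytest.approx(1.0 / (500.0 * 3))

    def test_needs_two_demes(self):
        with pytest.raises(ValueError):
            island_model(1, 100.0, 1.0, 2)
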