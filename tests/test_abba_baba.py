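import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodem.abba_baba import (
    block_jackknife,
    compute_trio,
    d_statistic,
    f4_ratio,
    orient_trio,
    site_pattern_sums,
)
from haplodem.models import (
    AdmixturePulse,
    Divergence,
    ModelSpec,
    Population,
)
from haplodem.synthetic import SyntheticTruth, generate_dataset


class TestPatternSums:
    def test_pure_abba(self):
        bbaa, abba, baba = site_pattern_sums(np.array([[0, 1, 1, 0.0]]))
        assert (bbaa, abba, baba) == (0.0, 1.0, 0.0)

    def test_pure_baba(self):
        bbaa, abba, baba = site_pattern_sums(np.array([[1, 0, 1, 0.0]]))
        assert (bbaa, abba, baba) == (0.0, 0.0, 1.0)

    def test_binary_fixture_matches_enumeration(self):
        rng = np.random.default_rng(0)
        freqs = rng.integers(0, 2, size=(50, 4)).astype(float)
        bbaa, abba, baba = site_pattern_sums(freqs)
        counts = {"bbaa": 0, "abba": 0, "baba": 0}
        for p1, p2, p3, p4 in freqs:
            pattern = (p1, p2, p3, p4)
            if pattern == (1, 1, 0, 0):
                counts["bbaa"] += 1
            elif pattern == (0, 1, 1, 0):
                counts["abba"] += 1
            elif pattern == (1, 0, 1, 0):
                counts["baba"] += 1
        assert (bbaa, abba, baba) == (
            counts["bbaa"], counts["abba"], counts["baba"]
        )


class TestDStatistic:
    def test_equal_counts_zero(self):
        assert d_statistic(5.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert d_statistic(10.0, 5.0) == pytest.approx(1 / 3)

    def test_undefined_flagged(self):
        assert np.isnan(d_statistic(0.0, 0.0))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_p1_p2_swap(self, seed):
        rng = np.random.default_rng(seed)
        freqs = rng.random((30, 4))
        _, abba, baba = site_pattern_sums(freqs)
        swapped = freqs[:, [1, 0, 2, 3]]
        _, abba_s, baba_s = site_pattern_sums(swapped)
        assert d_statistic(abba, baba) == pytest.approx(
            -d_statistic(abba_s, baba_s)
        )


class TestF4Ratio:
    def test_p2_equals_p3_gives_one(self):
        rng = np.random.default_rng(1)
        f = rng.random((20, 4))
        f[:, 1] = f[:, 2]
        assert f4_ratio(f) == pytest.approx(1.0)

    def test_p2_equals_p1_gives_zero(self):
        rng = np.random.default_rng(2)
        f = rng.random((20, 4))
        f[:, 1] = f[:, 0]
        assert f4_ratio(f) == pytest.approx(0.0)

    def test_zero_denominator_flagged(self):
        f = np.zeros((5, 4))
        assert np.isnan(f4_ratio(f))


class TestBlockJackknife:
    def test_identical_blocks_flagged(self):
        abba = np.ones(40)
        baba = np.full(40, 0.5)
        z, p = block_jackknife(abba, baba, n_blocks=4)
        assert np.isnan(z) and np.isnan(p)

    def test_zero_d_gives_z_zero_p_one(self):
        # D = 0 overall but block contributions vary -> SE > 0
        abba = np.array([5.0, 0.0, 1.0, 3.0, 2.0, 2.0, 0.0, 4.0, 3.0, 0.0])
        baba = abba[::-1].copy()
        assert abba.sum() == baba.sum()
        z, p = block_jackknife(abba, baba, n_blocks=5)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_needs_two_blocks(self):
        with pytest.raises(ValueError):
            block_jackknife(np.ones(5), np.ones(5), n_blocks=1)


def _admixture_spec(
    alpha: float, n_per_pop: int = 16, ne: float = 1000.0
) -> ModelSpec:
    pulses = [AdmixturePulse(500.0, "P3", "P2", alpha)] if alpha > 0 else []
    return ModelSpec(
        populations=[
            Population("P1", ne, n_per_pop),
            Population("P2", ne, n_per_pop),
            Population("P3", ne, n_per_pop),
            Population("OUT", ne, 4),
            Population("P12", ne, 0),
            Population("P123", ne, 0),
            Population("ROOT", ne, 0),
        ],
        divergences=[
            Divergence(4000, "P1", "P12"),
            Divergence(4000, "P2", "P12"),
            Divergence(8000, "P12", "P123"),
            Divergence(8000, "P3", "P123"),
            Divergence(20000, "P123", "ROOT"),
            Divergence(20000, "OUT", "ROOT"),
        ],
        pulses=pulses,
        mutation_rate=2e-7,
        locus_length=100,
    )


def _trio_dataset(alpha: float, seed: int, n_loci: int = 1200):
    truth = SyntheticTruth(
        spec=_admixture_spec(alpha), seed=seed, n_loci=n_loci, locus_length=100
    )
    matrix, pmap, _ = generate_dataset(truth)
    return matrix, pmap


class TestTrioOnSimulatedData:
    def test_jackknife_se_within_2x_of_replicate_sd(self):
        """Block-jackknife SE should approximate the true sampling SD of D.

        The deeper coalescent (Ne = 2000 against splits at 4000/8000) keeps
        incomplete lineage sorting common enough that ABBA/BABA counts are
        dense; at very sparse counts the delete-one-block ratio becomes
        heavy-tailed and the jackknife is conservative.
        """
        spec = _admixture_spec(0.15, n_per_pop=8, ne=2000.0)
        ds = []
        ses = []
        for seed in range(40):
            truth = SyntheticTruth(spec=spec, seed=1000 + seed, n_loci=1500,
                                   locus_length=100)
            matrix, pmap, _ = generate_dataset(truth)
            res = compute_trio(matrix, pmap, "P1", "P2", "P3", "OUT")
            ds.append(res.d)
            if np.isfinite(res.z) and res.z != 0:
                ses.append(res.d / res.z if res.z else np.nan)
        empirical_sd = np.std(ds, ddof=1)
        mean_se = np.nanmean(np.abs(ses))
        assert 0.5 < mean_se / empirical_sd < 2.0

    def test_outgroup_ancestral_option_matches_when_outgroup_monomorphic(self):
        matrix, pmap = _trio_dataset(0.1, seed=77)
        # restrict to sites where the outgroup is monomorphic ancestral
        out_idx = matrix.sample_indices(pmap.samples_for("OUT"))
        mono = (matrix.calls[out_idx] == 0).all(axis=0)
        sub = matrix.subset_sites(mono)
        a = compute_trio(sub, pmap, "P1", "P2", "P3", "OUT")
        b = compute_trio(sub, pmap, "P1", "P2", "P3", "OUT",
                         outgroup_ancestral=True)
        assert a.d == pytest.approx(b.d)
        assert a.abba_sum == pytest.approx(b.abba_sum)

    def test_f4_monotone_in_alpha(self):
        est = []
        for i, alpha in enumerate((0.0, 0.05, 0.1, 0.5)):
            matrix, pmap = _trio_dataset(alpha, seed=300 + i, n_loci=1500)
            res = compute_trio(matrix, pmap, "P1", "P2", "P3", "OUT")
            est.append(res.f4_ratio)
        assert est == sorted(est)


class TestOrientTrio:
    def test_oriented_input_unchanged(self):
        rng = np.random.default_rng(3)
        # make P1,P2 clearly share derived alleles and D >= 0
        f = rng.random((100, 4)) * 0.2
        f[:, 0] += 0.6
        f[:, 1] += 0.7
        f[:30, 2] += 0.3  # some abba excess
        _, names = orient_trio(f, ("A", "B", "C"))
        bbaa, abba, baba = site_pattern_sums(f)
        assert bbaa > max(abba, baba) and abba >= baba
        assert names == ("A", "B", "C")

    def test_negative_d_swaps_p1_p2(self):
        rng = np.random.default_rng(4)
        f = rng.random((100, 4)) * 0.2
        f[:, 0] += 0.6
        f[:, 1] += 0.7
        f[:30, 0] += 0.2
        f[:30, 2] += 0.3  # baba excess -> D < 0
        _, abba, baba = site_pattern_sums(f)
        assert d_statistic(abba, baba) < 0
        oriented, names = orient_trio(f, ("A", "B", "C"))
        assert names == ("B", "A", "C")
        _, abba2, baba2 = site_pattern_sums(oriented)
        assert d_statistic(abba2, baba2) >= 0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_exhaustive_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random((40, 4))
        oriented, names = orient_trio(f, ("A", "B", "C"))
        bbaa, abba, baba = site_pattern_sums(oriented)
        assert bbaa == pytest.approx(max(
            site_pattern_sums(f[:, list(rot) + [3]])[0]
            for rot in ((0, 1, 2), (1, 2, 0), (2, 0, 1))
        ))
        assert d_statistic(abba, baba) >= 0 or np.isnan(d_statistic(abba, baba))
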