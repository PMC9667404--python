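import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodem.genotype_io import MISSING
from haplodem.popgen_stats import (
    compare_groups,
    dxy,
    fst,
    jackknife,
    migrants_per_generation,
    nucleotide_diversity,
    site_classes,
    wright_island_nem,
)

from conftest import make_matrix


def naive_pair_mean(calls, pairs, invariant):
    """Independent plain-Python oracle for mean pairwise differences."""
    vals = []
    for i, j in pairs:
        diffs = comp = 0
        for a, b in zip(calls[i], calls[j]):
            if a != MISSING and b != MISSING:
                comp += 1
                diffs += a != b
        vals.append(diffs / (comp + invariant))
    return sum(vals) / len(vals)


class TestPi:
    def test_one_diff_in_hundred_sites(self):
        m = make_matrix(np.array([[0], [1]], dtype=np.int8))
        assert nucleotide_diversity(m, total_sites=100) == pytest.approx(0.01)

    def test_identical_sequences(self):
        m = make_matrix(np.zeros((3, 5), dtype=np.int8))
        assert nucleotide_diversity(m) == 0.0

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(1)
        calls = rng.choice(
            np.array([0, 1, MISSING], dtype=np.int8), size=(5, 30), p=[0.5, 0.4, 0.1]
        )
        m = make_matrix(calls)
        pairs = list(itertools.combinations(range(5), 2))
        assert len(pairs) == 10
        expected = naive_pair_mean(calls, pairs, invariant=70)
        assert nucleotide_diversity(m, total_sites=100) == pytest.approx(expected)

    def test_needs_two_samples(self):
        m = make_matrix(np.zeros((1, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            nucleotide_diversity(m)


class TestDxyFst:
    def test_dxy_identical_groups_zero(self):
        m = make_matrix(np.zeros((4, 5), dtype=np.int8))
        assert dxy(m, ["S0", "S1"], ["S2", "S3"]) == 0.0

    def test_dxy_fixed_difference_fraction(self):
        calls = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        m = make_matrix(calls)
        assert dxy(m, ["S0", "S1"], ["S2", "S3"], total_sites=10) == pytest.approx(
            2 / 10
        )

    def test_dxy_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        calls = rng.choice(
            np.array([0, 1, MISSING], dtype=np.int8), size=(6, 25), p=[0.5, 0.4, 0.1]
        )
        m = make_matrix(calls)
        pairs = [(i, j) for i in range(3) for j in range(3, 6)]
        expected = naive_pair_mean(calls, pairs, invariant=0)
        got = dxy(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert got == pytest.approx(expected)

    def test_fst_one_for_fixed_groups(self):
        calls = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        m = make_matrix(calls)
        assert fst(m, ["S0", "S1"], ["S2", "S3"]) == pytest.approx(1.0)

    def test_fst_near_zero_panmictic(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.2, 0.8, 300)
        calls = (rng.random((12, 300)) < freqs).astype(np.int8)
        m = make_matrix(calls)
        a = [f"S{i}" for i in range(6)]
        b = [f"S{i}" for i in range(6, 12)]
        assert abs(fst(m, a, b)) < 0.05

    def test_fst_symmetric(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, (8, 50)).astype(np.int8)
        m = make_matrix(calls)
        a = [f"S{i}" for i in range(4)]
        b = [f"S{i}" for i in range(4, 8)]
        assert fst(m, a, b) == pytest.approx(fst(m, b, a))
        assert dxy(m, a, b) == pytest.approx(dxy(m, b, a))


class TestSiteClasses:
    def test_examples(self):
        calls = np.array(
            # fixed_diff, shared_poly, monomorphic, private_poly
            [[0, 0, 1, 0],
             [0, 1, 1, 1],
             [1, 0, 1, 0],
             [1, 1, 1, 0]],
            dtype=np.int8,
        )
        m = make_matrix(calls)
        out = site_classes(m, ["S0", "S1"], ["S2", "S3"])
        assert out["fixed_difference"] == 1
        assert out["shared_polymorphic"] == 1
        assert out["monomorphic"] == 1
        assert out["private_polymorphic"] == 1
        assert out["n_sites_used"] == 4

    def test_matches_per_site_bruteforce(self):
        rng = np.random.default_rng(5)
        calls = rng.choice(
            np.array([0, 1, MISSING], dtype=np.int8), size=(6, 80), p=[0.45, 0.45, 0.1]
        )
        m = make_matrix(calls)
        a_idx, b_idx = [0, 1, 2], [3, 4, 5]
        expected = dict.fromkeys(
            ["monomorphic", "fixed_difference", "shared_polymorphic",
             "private_polymorphic"], 0
        )
        used = 0
        for j in range(80):
            a = {c for c in calls[a_idx, j] if c != MISSING}
            b = {c for c in calls[b_idx, j] if c != MISSING}
            if not a or not b:
                continue
            used += 1
            if len(a) == 2 and len(b) == 2:
                expected["shared_polymorphic"] += 1
            elif len(a) == 2 or len(b) == 2:
                expected["private_polymorphic"] += 1
            elif a == b:
                expected["monomorphic"] += 1
            else:
                expected["fixed_difference"] += 1
        got = site_classes(m, [f"S{i}" for i in a_idx], [f"S{i}" for i in b_idx])
        assert {k: got[k] for k in expected} == expected
        assert got["n_sites_used"] == used
        assert sum(expected.values()) == used

    def test_sample_order_invariant(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 2, (6, 40)).astype(np.int8)
        m = make_matrix(calls)
        a = ["S0", "S1", "S2"]
        b = ["S3", "S4", "S5"]
        assert site_classes(m, a, b) == site_classes(m, a[::-1], b[::-1])

    def test_disjoint_required(self):
        m = make_matrix(np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            site_classes(m, ["S0", "S1"], ["S1", "S2"])


class TestJackknife:
    def test_constant_estimator_sd_zero(self, tiny_matrix):
        jk = jackknife(lambda m, s: 1.23, tiny_matrix, tiny_matrix.samples)
        assert jk.sd == 0.0
        assert len(jk.pseudovalues) == tiny_matrix.n_samples

    def test_matches_hand_formula(self, tiny_matrix):
        # leave-one-out estimates: [2, 2, 2, 6]; mean 3
        vals = iter([0.0, 2.0, 2.0, 2.0, 6.0])  # first call = point estimate

        def stat(m, s):
            return next(vals)

        jk = jackknife(stat, tiny_matrix, tiny_matrix.samples)
        # sd = sqrt((n-1)/n * sum((x - xbar)^2)) = sqrt(3/4 * (1+1+1+9))
        assert jk.sd == pytest.approx(np.sqrt(0.75 * 12))

    def test_pi_jackknife_shrinks_with_n(self):
        from haplodem.models import ModelSpec, Population
        from haplodem.synthetic import SyntheticTruth, generate_dataset

        def sd_at(n, seed):
            spec = ModelSpec(
                populations=[Population("P", 2000.0, n)],
                mutation_rate=2e-7, locus_length=100,
            )
            truth = SyntheticTruth(spec=spec, seed=seed, n_loci=400, locus_length=100)
            matrix, _, _ = generate_dataset(truth)
            jk = jackknife(
                lambda m, s: nucleotide_diversity(m, s), matrix, matrix.samples
            )
            return jk.sd

        small = [sd_at(6, s) for s in (1, 2, 3)]
        large = [sd_at(12, s) for s in (1, 2, 3)]
        assert all(s > 0 for s in small)
        assert np.mean(large) < np.mean(small)


class TestCompareGroups:
    def test_identical_groups(self):
        g = np.array([1.0, 1.1, 0.9, 1.05])
        out = compare_groups({"a": g, "b": g.copy(), "c": g.copy()})
        assert out.anova_f == pytest.approx(0.0, abs=1e-12)
        assert (out.pairwise["p_bonferroni"] == 1.0).all()

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        out = compare_groups({"a": a, "b": b})
        assert out.anova_p < 0.05
        assert (out.pairwise["p_bonferroni"] < 0.05).all()

    def test_bonferroni_is_raw_times_three_capped(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(0, 1, 8) for k in "abc"}
        out = compare_groups(groups)
        expect = np.minimum(1.0, out.pairwise["p_raw"] * 3)
        assert np.allclose(out.pairwise["p_bonferroni"], expect)


class TestIslandModelConversion:
    def test_fst_point_one_gives_four_point_five(self):
        assert wright_island_nem(0.1) == pytest.approx(4.5)

    def test_fst_half(self):
        assert wright_island_nem(0.5) == pytest.approx(0.5)

    def test_limit_fst_to_one(self):
        assert wright_island_nem(1 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            wright_island_nem(bad)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.001, 0.998),
        st.floats(1e-4, 0.001),
    )
    def test_strictly_decreasing(self, f, eps):
        assert wright_island_nem(f) > wright_island_nem(f + eps)

    def test_migrants_per_generation(self):
        assert migrants_per_generation(452, 1.13e-4) == pytest.approx(0.051, abs=5e-4)
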