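"""Diversity and differentiation statistics for haploid SNP matrices.

Nucleotide diversity (pi) and Dxy follow the average-pairwise-difference
definition: the mean over sample pairs of (pairwise differences / pairwise
comparable sites).  When the total alignment length (including invariant
sites) is supplied, the per-pair denominator is
``total_sites - n_variant + comparable_variant_sites`` so statistics are
per-site over the whole alignment; otherwise they are per-variant-site and
flagged as such.  Pairwise comparisons skip sites missing in either member
of a pair (pairwise-complete normalization).

Fst is Hudson's sequence-based estimator ``1 - mean(pi_within) / pi_between``
with ``pi_within`` the unweighted mean of the two groups and ``pi_between``
equal to Dxy.  It may be <= 0 for undifferentiated groups and is reported
unclipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from haplodem.genotype_io import MISSING, HaploidGenotypeMatrix


@dataclass
class JackknifeEstimate:
    """Delete-one jackknife summary of a statistic over samples."""

    point: float
    pseudovalues: np.ndarray
    sd: float


@dataclass
class GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_bonferroni


def _pair_stat(
    calls: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    invariant_sites: int,
) -> float:
    """Mean over pairs of differences / comparable sites."""
    vals = []
    for i, j in pairs:
        a, b = calls[i], calls[j]
        comparable = (a != MISSING) & (b != MISSING)
        n_comp = int(comparable.sum()) + invariant_sites
        if n_comp == 0:
            continue
        diffs = int(((a != b) & comparable).sum())
        vals.append(diffs / n_comp)
    if not vals:
        raise ValueError("no comparable pairs")
    return float(np.mean(vals))


def _resolve(matrix: HaploidGenotypeMatrix, samples) -> np.ndarray:
    if samples is None:
        return np.arange(matrix.n_samples)
    return matrix.sample_indices(list(samples))


def _invariant(matrix: HaploidGenotypeMatrix, total_sites: int | None) -> int:
    if total_sites is None:
        return 0
    if total_sites < matrix.n_sites:
        raise ValueError("total_sites smaller than number of variant sites")
    return total_sites - matrix.n_sites


def nucleotide_diversity(
    matrix: HaploidGenotypeMatrix,
    samples: Sequence[str] | None = None,
    total_sites: int | None = None,
) -> float:
    """Per-site pi: mean pairwise differences within ``samples``."""
    idx = _resolve(matrix, samples)
    if len(idx) < 2:
        raise ValueError("nucleotide diversity needs >= 2 samples")
    pairs = list(itertools.combinations(idx, 2))
    return _pair_stat(matrix.calls, pairs, _invariant(matrix, total_sites))


def dxy(
    matrix: HaploidGenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    total_sites: int | None = None,
) -> float:
    """Per-site Dxy: mean pairwise differences between the two groups."""
    ia, ib = _resolve(matrix, group_a), _resolve(matrix, group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    pairs = [(i, j) for i in ia for j in ib]
    return _pair_stat(matrix.calls, pairs, _invariant(matrix, total_sites))


def fst(
    matrix: HaploidGenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    total_sites: int | None = None,
) -> float:
    """Hudson-style Fst: ``1 - mean(pi_a, pi_b) / dxy``.

    Returns NaN when ``dxy`` is zero (undefined).  Values are unclipped and
    may be negative for undifferentiated groups.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("fst needs >= 2 samples per group")
    pi_a = nucleotide_diversity(matrix, group_a, total_sites)
    pi_b = nucleotide_diversity(matrix, group_b, total_sites)
    pi_between = dxy(matrix, group_a, group_b, total_sites)
    if pi_between == 0:
        return float("nan")
    return 1.0 - 0.5 * (pi_a + pi_b) / pi_between


def site_classes(
    matrix: HaploidGenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> dict[str, int]:
    """Classify each jointly-called site for two disjoint groups.

    A site with at least one call in each group is exactly one of:
    ``monomorphic`` (same single allele in both), ``fixed_difference`` (each
    group fixed for different alleles), ``shared_polymorphic`` (both groups
    polymorphic) or ``private_polymorphic`` (exactly one polymorphic).
    """
    ia, ib = _resolve(matrix, group_a), _resolve(matrix, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    ca, cb = matrix.calls[ia], matrix.calls[ib]
    a0 = (ca == 0).sum(axis=0)
    a1 = (ca == 1).sum(axis=0)
    b0 = (cb == 0).sum(axis=0)
    b1 = (cb == 1).sum(axis=0)
    called = (a0 + a1 > 0) & (b0 + b1 > 0)
    poly_a = (a0 > 0) & (a1 > 0)
    poly_b = (b0 > 0) & (b1 > 0)
    fixed_diff = called & ~poly_a & ~poly_b & (
        ((a1 > 0) & (b0 > 0) & (a0 == 0) & (b1 == 0))
        | ((a0 > 0) & (b1 > 0) & (a1 == 0) & (b0 == 0))
    )
    mono = called & ~poly_a & ~poly_b & ~fixed_diff
    shared = called & poly_a & poly_b
    private = called & (poly_a ^ poly_b)
    return {
        "monomorphic": int(mono.sum()),
        "fixed_difference": int(fixed_diff.sum()),
        "shared_polymorphic": int(shared.sum()),
        "private_polymorphic": int(private.sum()),
        "n_sites_used": int(called.sum()),
    }


def jackknife(
    stat: Callable[[HaploidGenotypeMatrix, Sequence[str]], float],
    matrix: HaploidGenotypeMatrix,
    samples: Sequence[str],
) -> JackknifeEstimate:
    """Delete-one jackknife of ``stat`` over ``samples``.

    ``sd = sqrt((n-1)/n * sum((theta_(i) - theta_bar)^2))`` with
    ``theta_(i)`` the leave-one-out estimates.
    """
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError("jackknife needs >= 3 samples")
    point = stat(matrix, samples)
    pseudo = []
    for i in range(n):
        subset = samples[:i] + samples[i + 1:]
        try:
            pseudo.append(stat(matrix, subset))
        except Exception as exc:  # pragma: no cover - propagation path
            raise RuntimeError(
                f"estimator failed on delete-{samples[i]!r} subsample"
            ) from exc
    pseudo = np.array(pseudo)
    sd = float(np.sqrt((n - 1) / n * np.sum((pseudo - pseudo.mean()) ** 2)))
    return JackknifeEstimate(point=float(point), pseudovalues=pseudo, sd=sd)


def compare_groups(estimates: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA and Bonferroni-adjusted pairwise Student's t-tests.

    ``estimates`` maps group label -> array of leave-one-out estimates
    (jackknife pseudovalue sets).  The Bonferroni adjustment is
    ``min(1, p * n_comparisons)``.
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in estimates.items()}
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has < 2 values")
    if all(np.ptp(v) == 0 for v in groups.values()):
        f_val, p_val = float("nan"), float("nan")
    else:
        f_val, p_val = sps.f_oneway(*groups.values())
    labels = list(groups)
    n_comp = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        t, p = sps.ttest_ind(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * n_comp),
            }
        )
    return GroupComparison(
        anova_f=float(f_val), anova_p=float(p_val), pairwise=pd.DataFrame(rows)
    )


def diversity_table(
    matrix: HaploidGenotypeMatrix,
    groups: dict[str, Sequence[str]],
    total_sites: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-group pi and pairwise Fst/Dxy/site-class tables."""
    within = pd.DataFrame(
        [
            {
                "population": name,
                "n": len(samples),
                "pi": nucleotide_diversity(matrix, samples, total_sites),
            }
            for name, samples in groups.items()
        ]
    )
    rows = []
    for a, b in itertools.combinations(groups, 2):
        classes = site_classes(matrix, groups[a], groups[b])
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "fst": fst(matrix, groups[a], groups[b], total_sites),
                "dxy": dxy(matrix, groups[a], groups[b], total_sites),
                **classes,
            }
        )
    return within, pd.DataFrame(rows)


def wright_island_nem(fst_value: float) -> float:
    """Migrants per generation under Wright's haploid island model.

    ``Nem = 0.5 * (1/Fst - 1)``; an equilibrium Fst of 0.1 corresponds to
    4.5 migrants per generation.  Strictly decreasing in Fst on (0, 1).
    """
    if not 0 < fst_value < 1:
        raise ValueError(f"Fst must be in (0, 1), got {fst_value}")
    return 0.5 * (1.0 / fst_value - 1.0)


def migrants_per_generation(ne: float, m: float) -> float:
    """Nem: effective population size times per-generation migration rate."""
    if ne <= 0 or m < 0:
        raise ValueError("need ne > 0 and m >= 0")
    return ne * m
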