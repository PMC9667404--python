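"""Frequency-based ABBA/BABA site-pattern statistics.

For an ordered trio plus outgroup (P1, P2, P3, O) with per-site derived
allele frequencies ``p1..p4``, the site-pattern sums are

* ``ABBA = sum (1-p1) * p2 * p3 * (1-p4)``
* ``BABA = sum p1 * (1-p2) * p3 * (1-p4)``
* ``BBAA = sum p1 * p2 * (1-p3) * (1-p4)``

Patterson's D is ``(ABBA - BABA) / (ABBA + BABA)``; its significance comes
from a delete-one-block jackknife over contiguous site blocks (loci are
effectively unlinked in RAD data, so contiguous blocks are conservative).
The f4-ratio admixture fraction uses the P3-substitution denominator
``f4(P1,P2;P3,O) / f4(P1,P3;P3,O)`` — an approximation (no P3 subpopulation
is available) flagged in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from haplodem.genotype_io import MISSING, HaploidGenotypeMatrix, PopulationMap


@dataclass
class TrioResult:
    """ABBA/BABA statistics for one (P1, P2, P3, outgroup) arrangement."""

    trio: tuple[str, str, str, str]
    bbaa_sum: float
    abba_sum: float
    baba_sum: float
    d: float
    z: float
    p: float
    f4_ratio: float
    n_blocks: int
    n_sites: int
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        p1, p2, p3, out = self.trio
        return {
            "P1": p1, "P2": p2, "P3": p3, "outgroup": out,
            "D": self.d, "Z": self.z, "p": self.p, "f4_ratio": self.f4_ratio,
            "BBAA": self.bbaa_sum, "ABBA": self.abba_sum, "BABA": self.baba_sum,
            "n_blocks": self.n_blocks, "n_sites": self.n_sites,
        }


def population_frequencies(
    matrix: HaploidGenotypeMatrix,
    pmap: PopulationMap,
    pops: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and call count for each population.

    Sites where any population has zero non-missing calls are dropped.
    Returns ``(freqs, counts)`` arrays of shape (n_kept_sites, len(pops)).
    """
    freqs, counts = [], []
    for pop in pops:
        samples = [s for s in pmap.samples_for(pop) if s in matrix.samples]
        if not samples:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
        calls = matrix.calls[matrix.sample_indices(samples)]
        n = (calls != MISSING).sum(axis=0).astype(float)
        d = (calls == 1).sum(axis=0).astype(float)
        counts.append(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(n > 0, d / np.maximum(n, 1), np.nan))
    freqs = np.stack(freqs, axis=1)
    counts = np.stack(counts, axis=1)
    keep = (counts > 0).all(axis=1)
    return freqs[keep], counts[keep]


def site_pattern_sums(freqs: np.ndarray) -> tuple[float, float, float]:
    """(BBAA, ABBA, BABA) sums from per-site (p1, p2, p3, p4) frequencies."""
    p1, p2, p3, p4 = freqs.T
    abba = float(np.sum((1 - p1) * p2 * p3 * (1 - p4)))
    baba = float(np.sum(p1 * (1 - p2) * p3 * (1 - p4)))
    bbaa = float(np.sum(p1 * p2 * (1 - p3) * (1 - p4)))
    return bbaa, abba, baba


def d_statistic(abba: float, baba: float) -> float:
    """Patterson's D = (ABBA - BABA) / (ABBA + BABA); NaN if undefined."""
    tot = abba + baba
    if tot <= 0:
        return float("nan")
    return (abba - baba) / tot


def f4_ratio(freqs: np.ndarray, counts: np.ndarray | None = None) -> float:
    """Admixture-fraction estimate via the P3-substitution f4-ratio.

    ``alpha_hat = sum (p1-p2)(p3-p4) / sum (p1-p3)(p3-p4)``.  The denominator
    contains ``p3^2``; with per-site call counts supplied, the unbiased
    sample estimate ``p3 (n3 p3 - 1) / (n3 - 1)`` replaces the plug-in
    ``p3^2`` (the plug-in is biased by Het(p3)/n3).  Returns NaN when the
    denominator is ~0.
    """
    p1, p2, p3, p4 = freqs.T
    num = float(np.sum((p1 - p2) * (p3 - p4)))
    if counts is not None:
        n3 = counts[:, 2]
        p3_sq = np.where(n3 > 1, p3 * (n3 * p3 - 1) / np.maximum(n3 - 1, 1), p3**2)
    else:
        p3_sq = p3**2
    # (p1 - p3)(p3 - p4) = p1 p3 - p1 p4 - p3^2 + p3 p4
    den = float(np.sum(p1 * p3 - p1 * p4 - p3_sq + p3 * p4))
    if abs(den) < 1e-12:
        return float("nan")
    return num / den


def block_jackknife(
    abba_site: np.ndarray, baba_site: np.ndarray, n_blocks: int = 20
) -> tuple[float, float]:
    """Delete-one-block jackknife Z and two-tailed p for D.

    Sites are assigned to ``n_blocks`` contiguous near-equal blocks in input
    order.  Returns ``(Z, p)``; ``(nan, nan)`` when the jackknife SE is zero.
    """
    if n_blocks < 2:
        raise ValueError("need >= 2 blocks")
    abba_site = np.asarray(abba_site, dtype=float)
    baba_site = np.asarray(baba_site, dtype=float)
    if abba_site.shape != baba_site.shape:
        raise ValueError("per-site contribution arrays must have equal length")
    n_blocks = min(n_blocks, len(abba_site))
    blocks = np.array_split(np.arange(len(abba_site)), n_blocks)
    abba_tot, baba_tot = abba_site.sum(), baba_site.sum()
    d_point = d_statistic(abba_tot, baba_tot)
    loo = []
    for blk in blocks:
        a = abba_tot - abba_site[blk].sum()
        b = baba_tot - baba_site[blk].sum()
        loo.append(d_statistic(a, b))
    loo = np.array(loo)
    g = len(loo)
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
    if se == 0 or np.isnan(se):
        return float("nan"), float("nan")
    z = d_point / se
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


def orient_trio(
    freqs: np.ndarray, pops: Sequence[str]
) -> tuple[np.ndarray, tuple[str, str, str]]:
    """Reorder the three ingroup populations so BBAA is maximal and D >= 0.

    Tries the three rotations of (P1, P2, P3), keeps the one whose BBAA sum
    is the largest pattern sum, then swaps P1 and P2 if D < 0 (D is
    antisymmetric under that swap).  The outgroup column stays last.
    """
    best = None
    for rot in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        cols = list(rot) + [3]
        f = freqs[:, cols]
        bbaa, abba, baba = site_pattern_sums(f)
        if best is None or bbaa > best[0]:
            best = (bbaa, abba, baba, rot)
    _, abba, baba, rot = best
    order = list(rot)
    if d_statistic(abba, baba) < 0:
        order = [order[1], order[0], order[2]]
    names = tuple(pops[i] for i in order)
    return freqs[:, order + [3]], names


def compute_trio(
    matrix: HaploidGenotypeMatrix,
    pmap: PopulationMap,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    n_blocks: int = 20,
    orient: bool = False,
    outgroup_ancestral: bool = False,
) -> TrioResult:
    """Full ABBA/BABA analysis for one trio.

    ``orient=True`` lets the data choose the P1/P2/P3 roles (BBAA maximal,
    D >= 0); the default fixed-trio mode reproduces hypothesis-driven
    arrangements.  ``outgroup_ancestral=True`` sets the outgroup frequency to
    0 (valid for polarized data; identical results when the outgroup is
    monomorphic ancestral).
    """
    pops = [p1, p2, p3, outgroup]
    freqs, counts = population_frequencies(matrix, pmap, pops)
    if outgroup_ancestral:
        freqs = freqs.copy()
        freqs[:, 3] = 0.0
    names = (p1, p2, p3)
    if orient:
        reordered, names = orient_trio(freqs, (p1, p2, p3))
        perm = [(p1, p2, p3).index(n) for n in names] + [3]
        counts = counts[:, perm]
        freqs = reordered
    q1, q2, q3, q4 = freqs.T
    abba_site = (1 - q1) * q2 * q3 * (1 - q4)
    baba_site = q1 * (1 - q2) * q3 * (1 - q4)
    bbaa, abba, baba = site_pattern_sums(freqs)
    z, pval = block_jackknife(abba_site, baba_site, n_blocks)
    return TrioResult(
        trio=(*names, outgroup),
        bbaa_sum=bbaa,
        abba_sum=abba,
        baba_sum=baba,
        d=d_statistic(abba, baba),
        z=z,
        p=pval,
        f4_ratio=f4_ratio(freqs, counts),
        n_blocks=min(n_blocks, freqs.shape[0]),
        n_sites=freqs.shape[0],
        meta={
            "f4_denominator": "P3-substitution (f-hom approximation)",
            "oriented": orient,
        },
    )
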