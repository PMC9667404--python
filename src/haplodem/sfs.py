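"""Unfolded joint site-frequency spectra with hypergeometric projection.

An observed joint SFS is a d-dimensional table indexed by derived-allele
counts per population.  Missing data are handled by projecting each site
down to a fixed per-population sample size: the contribution of a site with
``n_obs`` non-missing calls and ``d_obs`` derived alleles to projection size
``n_proj`` is the hypergeometric distribution of derived alleles in a draw
of ``n_proj`` alleles without replacement.  The default is the fractional
(expected-value) projection, which is deterministic and uses all data; a
seeded per-site random-draw mode is available for exact emulation of
single-subsample pipelines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from haplodem.genotype_io import (
    MISSING,
    HaploidGenotypeMatrix,
    PopulationMap,
    one_snp_per_locus,
)


@dataclass
class JointSFS:
    """Joint site-frequency spectrum over ``len(pop_labels)`` populations.

    ``counts[i1, ..., id]`` is the (possibly fractional) number of sites with
    ``ik`` derived alleles in population ``k`` (observed SFS), or the
    expected proportion of polymorphic sites in that cell (expected SFS,
    ``is_expected=True``).
    """

    pop_labels: tuple[str, ...]
    sample_sizes: tuple[int, ...]
    counts: np.ndarray
    is_expected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pop_labels = tuple(self.pop_labels)
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        expected_shape = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expected_shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != {expected_shape} implied "
                f"by sample sizes {self.sample_sizes}"
            )
        if (self.counts < 0).any():
            raise ValueError("SFS entries must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.pop_labels)

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask excluding the all-ancestral and all-derived corners."""
        mask = np.ones(self.counts.shape, dtype=bool)
        mask[(0,) * self.ndim] = False
        mask[tuple(n for n in self.sample_sizes)] = False
        return mask

    def total_mass(self, polymorphic_only: bool = False) -> float:
        if polymorphic_only:
            return float(self.counts[self.polymorphic_mask()].sum())
        return float(self.counts.sum())

    def transposed(self, labels: tuple[str, ...]) -> "JointSFS":
        """Reorder the population axes to ``labels`` (a permutation)."""
        if set(labels) != set(self.pop_labels) or len(labels) != self.ndim:
            raise ValueError(
                f"{labels} is not a permutation of {self.pop_labels}"
            )
        perm = [self.pop_labels.index(lab) for lab in labels]
        return JointSFS(
            tuple(labels),
            tuple(self.sample_sizes[i] for i in perm),
            np.transpose(self.counts, perm),
            is_expected=self.is_expected,
            meta=dict(self.meta),
        )

    def normalized(self) -> "JointSFS":
        """Expected-proportion SFS over polymorphic cells (corners zeroed)."""
        mask = self.polymorphic_mask()
        total = self.counts[mask].sum()
        if total <= 0:
            raise ValueError("no polymorphic mass to normalize")
        counts = np.where(mask, self.counts / total, 0.0)
        return JointSFS(
            self.pop_labels, self.sample_sizes, counts, is_expected=True,
            meta=dict(self.meta),
        )

    # -- plain-text round trip ------------------------------------------
    # line 1..: '# key=value' comments (provenance)
    # first non-comment line: 'LABEL=size LABEL=size ...' (+ 'expected' flag)
    # then flattened counts, row-major (last axis fastest), whitespace-split.

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            head = " ".join(
                f"{lab}={n}" for lab, n in zip(self.pop_labels, self.sample_sizes)
            )
            if self.is_expected:
                head += " expected"
            fh.write(head + "\n")
            flat = self.counts.ravel(order="C")
            fh.write(" ".join(repr(float(x)) for x in flat) + "\n")

    @classmethod
    def load(cls, path) -> "JointSFS":
        meta: dict = {}
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        body = []
        for ln in lines:
            if ln.startswith("#"):
                kv = ln[1:].strip()
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if ln.strip():
                body.append(ln)
        header, *rest = body
        toks = header.split()
        is_expected = "expected" in toks
        toks = [t for t in toks if t != "expected"]
        labels = tuple(t.split("=")[0] for t in toks)
        sizes = tuple(int(t.split("=")[1]) for t in toks)
        flat = np.array(" ".join(rest).split(), dtype=float)
        shape = tuple(n + 1 for n in sizes)
        return cls(labels, sizes, flat.reshape(shape), is_expected, meta)


def project_site(n_obs: int, d_obs: int, n_proj: int) -> np.ndarray:
    """Hypergeometric projection of one site.

    Returns the probability of observing ``k = 0..n_proj`` derived alleles in
    a draw of ``n_proj`` alleles without replacement from ``n_obs`` observed
    alleles of which ``d_obs`` are derived.

    Raises
    ------
    ValueError
        If ``n_proj > n_obs`` (the site is not projectable) or the counts are
        inconsistent.
    """
    if not 0 <= d_obs <= n_obs:
        raise ValueError(f"need 0 <= d_obs <= n_obs, got {d_obs}, {n_obs}")
    if n_proj > n_obs:
        raise ValueError(f"site not projectable: n_proj {n_proj} > n_obs {n_obs}")
    if n_proj < 1:
        raise ValueError("n_proj must be >= 1")
    k = np.arange(n_proj + 1)
    return hypergeom.pmf(k, n_obs, d_obs, n_proj)


def build_joint_sfs(
    matrix: HaploidGenotypeMatrix,
    pmap: PopulationMap,
    projections: dict[str, int],
    mode: str = "all_snps",
    seed: int = 0,
    method: str = "expected",
) -> JointSFS:
    """Build the unfolded joint SFS of ``projections.keys()`` populations.

    Each usable site (every population has at least ``projections[pop]``
    non-missing calls) adds its product-of-hypergeometrics mass to the table
    (``method='expected'``), or a single random draw per population
    (``method='draw'``, seeded).  Unusable sites are skipped and counted in
    ``meta['n_sites_skipped']``.

    ``mode='one_per_locus'`` first thins the matrix to one SNP per locus
    (uniformly, with ``seed``); ``mode='all_snps'`` uses every site.
    """
    if mode not in ("all_snps", "one_per_locus"):
        raise ValueError(f"unknown mode {mode!r}")
    if method not in ("expected", "draw"):
        raise ValueError(f"unknown method {method!r}")
    pops = list(projections)
    for pop in pops:
        if pop not in pmap.populations:
            raise KeyError(f"population {pop!r} not in population map")
    if mode == "one_per_locus":
        matrix = one_snp_per_locus(matrix, seed)

    pop_idx = [
        matrix.sample_indices([s for s in pmap.samples_for(p) if s in matrix.samples])
        for p in pops
    ]
    sizes = [int(projections[p]) for p in pops]
    for p, idx, n in zip(pops, pop_idx, sizes):
        if n < 1:
            raise ValueError(f"projection for {p!r} must be >= 1")
        if n > len(idx):
            raise ValueError(
                f"projection {n} exceeds {len(idx)} samples in population {p!r}"
            )

    shape = tuple(n + 1 for n in sizes)
    counts = np.zeros(shape)
    rng = np.random.default_rng(seed)
    pmf_cache: dict[tuple[int, int, int], np.ndarray] = {}

    # per-site per-pop observed allele counts, vectorized
    n_obs = np.stack([(matrix.calls[idx] != MISSING).sum(axis=0) for idx in pop_idx])
    d_obs = np.stack([(matrix.calls[idx] == 1).sum(axis=0) for idx in pop_idx])
    usable = np.all(n_obs >= np.array(sizes)[:, None], axis=0)
    n_skipped = int((~usable).sum())

    for j in np.flatnonzero(usable):
        if method == "expected":
            vecs = []
            for k in range(len(pops)):
                key = (int(n_obs[k, j]), int(d_obs[k, j]), sizes[k])
                pmf = pmf_cache.get(key)
                if pmf is None:
                    pmf = project_site(*key)
                    pmf_cache[key] = pmf
                vecs.append(pmf)
            mass = vecs[0]
            for v in vecs[1:]:
                mass = np.multiply.outer(mass, v)
            counts += mass
        else:
            cell = tuple(
                int(
                    rng.hypergeometric(
                        d_obs[k, j], n_obs[k, j] - d_obs[k, j], sizes[k]
                    )
                )
                for k in range(len(pops))
            )
            counts[cell] += 1

    return JointSFS(
        tuple(pops),
        tuple(sizes),
        counts,
        is_expected=False,
        meta={
            "mode": mode,
            "method": method,
            "n_loci": len(matrix.locus_ids),
            "n_sites_used": int(usable.sum()),
            "n_sites_skipped": n_skipped,
        },
    )


def marginal_sfs(sfs: JointSFS, pop: str) -> JointSFS:
    """Marginal 1-D SFS of ``pop``: sum over all other axes."""
    if pop not in sfs.pop_labels:
        raise KeyError(f"unknown population {pop!r}")
    axis = sfs.pop_labels.index(pop)
    other = tuple(i for i in range(sfs.ndim) if i != axis)
    counts = sfs.counts.sum(axis=other) if other else sfs.counts.copy()
    return JointSFS(
        (pop,),
        (sfs.sample_sizes[axis],),
        counts,
        is_expected=sfs.is_expected,
        meta=dict(sfs.meta),
    )


def enumerate_cells(sfs: JointSFS):
    """Iterate ``(index_tuple, value)`` over all cells (testing helper)."""
    for idx in itertools.product(*(range(n + 1) for n in sfs.sample_sizes)):
        yield idx, sfs.counts[idx]
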