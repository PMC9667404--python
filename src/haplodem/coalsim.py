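"""Structured-coalescent simulation of joint site-frequency spectra.

Continuous-time implementation of the structured coalescent: within a deme
holding ``k`` lineages of haploid size ``Ne``, pairs coalesce at total rate
``k (k-1) / (2 Ne)``; each lineage migrates backward in time according to the
reversed migration arrows of the :class:`~haplodem.models.ModelSpec`
(forward ``source -> dest`` becomes backward ``dest -> source``); at
divergence events all lineages of the child deme relocate to the parent, and
pulse admixture moves each dest-deme lineage to the source with the pulse
probability.

The expected SFS of a model is the table of mean branch lengths indexed by
the branch's descendant counts per sampled population, normalized over
polymorphic cells (the quantity a simulation-based composite-likelihood
method compares the observed SNP spectrum against).  Sampled spectra place
Poisson(mu * L * total branch length) infinite-sites mutations on one
genealogy per unlinked locus.

Reproducibility: replicate ``r`` of a run with seed ``s`` uses the
deterministic substream ``mix(s, r)``, so results are independent of
chunking and identical across repeat runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from haplodem.models import MigrationWindow, ModelSpec, Population
from haplodem.sfs import JointSFS


@dataclass
class SimulationConfig:
    """Settings for one simulation run.

    ``mode`` is ``'expected_sfs'`` (branch-length SFS over ``n_sims``
    genealogies) or ``'sampled_sfs'`` (mutation counts over ``n_loci``
    unlinked loci).
    """

    n_sims: int = 50_000
    seed: int = 0
    mode: str = "expected_sfs"
    n_loci: int = 1000

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.mode not in ("expected_sfs", "sampled_sfs"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# program compilation: ModelSpec -> flat arrays for the jitted kernel
# ---------------------------------------------------------------------------


@dataclass
class _Program:
    breaks: np.ndarray      # epoch start times, breaks[0] == 0
    coal: np.ndarray        # (n_epochs, n_demes) per-pair coalescence rate
    mig: np.ndarray         # (n_epochs, n_demes, n_demes) backward rates
    ev_break: np.ndarray    # boundary index at which each instantaneous event fires
    ev_from: np.ndarray
    ev_to: np.ndarray
    ev_prob: np.ndarray
    init_deme: np.ndarray   # per sampled lineage
    init_axis: np.ndarray   # sampled-population axis per lineage
    pop_labels: tuple[str, ...]
    axis_sizes: tuple[int, ...]
    strides: np.ndarray
    n_cells: int


def compile_program(spec: ModelSpec) -> _Program:
    names = spec.pop_names()
    idx = {n: i for i, n in enumerate(names)}
    sampled = spec.sampled_pops()
    if not sampled:
        raise ValueError("model has no sampled populations")
    sizes = [spec.pop(p).sample_size for p in sampled]

    times = set()
    for d in spec.divergences:
        if d.time <= 0:
            raise ValueError(f"divergence time must be > 0: {d}")
        times.add(float(d.time))
    for s in spec.size_changes:
        times.add(float(s.time))
    for m in spec.migrations:
        if m.start > 0:
            times.add(float(m.start))
        if math.isfinite(m.end):
            times.add(float(m.end))
    for p in spec.pulses:
        if p.time <= 0:
            raise ValueError(f"pulse time must be > 0: {p}")
        times.add(float(p.time))
    breaks = np.array([0.0] + sorted(t for t in times if t > 0))
    n_epochs = len(breaks)
    n_demes = len(names)

    ne = np.empty((n_epochs, n_demes))
    for j, p in enumerate(spec.populations):
        ne[:, j] = p.ne
    for sc in sorted(spec.size_changes, key=lambda s: s.time):
        j = idx[sc.population]
        ne[breaks >= sc.time - 1e-12, j] = sc.ne
    coal = 1.0 / ne

    mig = np.zeros((n_epochs, n_demes, n_demes))
    for m in spec.migrations:
        si, di = idx[m.source], idx[m.dest]
        for e in range(n_epochs):
            e_start = breaks[e]
            e_end = breaks[e + 1] if e + 1 < n_epochs else math.inf
            if e_start >= m.start - 1e-12 and e_end <= m.end + 1e-12:
                # backward in time, lineages in dest trace back to source
                mig[e, di, si] += m.rate

    # instantaneous events, pulses before divergences at equal times
    events = []
    for p in spec.pulses:
        b = int(np.searchsorted(breaks, p.time))
        if not math.isclose(breaks[min(b, n_epochs - 1)], p.time):
            b = int(np.argmin(np.abs(breaks - p.time)))
        events.append((b, 0, idx[p.dest], idx[p.source], float(p.proportion)))
    for d in spec.divergences:
        b = int(np.searchsorted(breaks, d.time))
        if not math.isclose(breaks[min(b, n_epochs - 1)], d.time):
            b = int(np.argmin(np.abs(breaks - d.time)))
        events.append((b, 1, idx[d.child], idx[d.parent], 1.0))
    events.sort(key=lambda t: (t[0], t[1]))
    if events:
        ev_break = np.array([e[0] for e in events], dtype=np.int64)
        ev_from = np.array([e[2] for e in events], dtype=np.int64)
        ev_to = np.array([e[3] for e in events], dtype=np.int64)
        ev_prob = np.array([e[4] for e in events])
    else:
        ev_break = np.zeros(0, dtype=np.int64)
        ev_from = np.zeros(0, dtype=np.int64)
        ev_to = np.zeros(0, dtype=np.int64)
        ev_prob = np.zeros(0)

    init_deme, init_axis = [], []
    for a, pop in enumerate(sampled):
        for _ in range(spec.pop(pop).sample_size):
            init_deme.append(idx[pop])
            init_axis.append(a)
    shape = tuple(n + 1 for n in sizes)
    strides = np.empty(len(shape), dtype=np.int64)
    acc = 1
    for a in range(len(shape) - 1, -1, -1):
        strides[a] = acc
        acc *= shape[a]
    return _Program(
        breaks=breaks,
        coal=coal,
        mig=mig,
        ev_break=ev_break,
        ev_from=ev_from,
        ev_to=ev_to,
        ev_prob=ev_prob,
        init_deme=np.array(init_deme, dtype=np.int64),
        init_axis=np.array(init_axis, dtype=np.int64),
        pop_labels=tuple(sampled),
        axis_sizes=tuple(sizes),
        strides=strides,
        n_cells=int(acc),
    )


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mix_seed(seed, r):
    x = (np.int64(seed) ^ (np.int64(r) * np.int64(2654435761))) & np.int64(0x7FFFFFFF)
    return np.int64(1) if x == 0 else x


@njit(cache=True)
def _run_genealogy(
    breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
    init_deme, init_axis, strides,
    deme, counts, birth, mask, nd,
    br_cell, br_len, br_mask,
):
    """One structured-coalescent genealogy.

    Fills branch records (SFS cell, length, descendant bitmask) for every
    lineage that coalesces; the root branch is never recorded.  Working
    buffers are caller-allocated and reused across replicates.  Returns the
    number of branches written.
    """
    n = init_deme.shape[0]
    n_axes = strides.shape[0]
    n_epochs = breaks.shape[0]
    n_demes = coal.shape[1]
    for i in range(n):
        deme[i] = init_deme[i]
        for a in range(n_axes):
            counts[i, a] = 0
        counts[i, init_axis[i]] = 1
        birth[i] = 0.0
        mask[i] = np.uint64(1) << np.uint64(i & 63)
    k = n
    t = 0.0
    e = 0
    nb = 0
    while k > 1:
        for d in range(n_demes):
            nd[d] = 0
        for i in range(k):
            nd[deme[i]] += 1
        coal_tot = 0.0
        for d in range(n_demes):
            if nd[d] > 1:
                coal_tot += coal[e, d] * nd[d] * (nd[d] - 1) * 0.5
        mig_tot = 0.0
        for d in range(n_demes):
            if nd[d] > 0:
                s = 0.0
                for j in range(n_demes):
                    s += mig[e, d, j]
                mig_tot += nd[d] * s
        total = coal_tot + mig_tot
        t_next = breaks[e + 1] if e + 1 < n_epochs else np.inf
        if total > 0.0:
            adv = t - math.log(np.random.random()) / total
        else:
            adv = t_next
        if adv >= t_next:
            t = t_next
            b = e + 1
            for ievt in range(ev_break.shape[0]):
                if ev_break[ievt] == b:
                    fr = ev_from[ievt]
                    to = ev_to[ievt]
                    pr = ev_prob[ievt]
                    for i in range(k):
                        if deme[i] == fr:
                            if pr >= 1.0 or np.random.random() < pr:
                                deme[i] = to
            e += 1
            continue
        t = adv
        u = np.random.random() * total
        if u < coal_tot:
            acc = 0.0
            cd = -1
            for d in range(n_demes):
                if nd[d] > 1:
                    acc += coal[e, d] * nd[d] * (nd[d] - 1) * 0.5
                    if u < acc:
                        cd = d
                        break
            if cd < 0:
                for d in range(n_demes - 1, -1, -1):
                    if nd[d] > 1:
                        cd = d
                        break
            # pick two distinct lineages in deme cd
            r1 = int(np.random.random() * nd[cd])
            r2 = int(np.random.random() * (nd[cd] - 1))
            if r2 >= r1:
                r2 += 1
            ii = -1
            jj = -1
            seen = 0
            for i in range(k):
                if deme[i] == cd:
                    if seen == r1:
                        ii = i
                    if seen == r2:
                        jj = i
                    seen += 1
            # record both child branches
            for child in (ii, jj):
                cell = 0
                for a in range(n_axes):
                    cell += counts[child, a] * strides[a]
                br_cell[nb] = cell
                br_len[nb] = t - birth[child]
                br_mask[nb] = mask[child]
                nb += 1
            # merge jj into ii
            for a in range(n_axes):
                counts[ii, a] += counts[jj, a]
            mask[ii] = mask[ii] | mask[jj]
            birth[ii] = t
            k -= 1
            if jj != k:
                deme[jj] = deme[k]
                birth[jj] = birth[k]
                mask[jj] = mask[k]
                for a in range(n_axes):
                    counts[jj, a] = counts[k, a]
        else:
            u -= coal_tot
            acc = 0.0
            md = -1
            dest = -1
            for d in range(n_demes):
                if nd[d] > 0:
                    for j in range(n_demes):
                        acc += nd[d] * mig[e, d, j]
                        if u < acc:
                            md = d
                            dest = j
                            break
                    if md >= 0:
                        break
            if md < 0:
                continue
            r1 = int(np.random.random() * nd[md])
            seen = 0
            for i in range(k):
                if deme[i] == md:
                    if seen == r1:
                        deme[i] = dest
                        break
                    seen += 1
    return nb


@njit(cache=True)
def _expected_kernel(
    n_reps, seed, n_batches,
    breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
    init_deme, init_axis, strides, n_cells,
):
    n = init_deme.shape[0]
    n_axes = strides.shape[0]
    n_demes = coal.shape[1]
    deme = np.zeros(n, dtype=np.int64)
    counts = np.zeros((n, n_axes), dtype=np.int64)
    birth = np.zeros(n)
    mask = np.zeros(n, dtype=np.uint64)
    nd = np.zeros(n_demes, dtype=np.int64)
    br_cell = np.zeros(2 * n, dtype=np.int64)
    br_len = np.zeros(2 * n)
    br_mask = np.zeros(2 * n, dtype=np.uint64)
    out = np.zeros((n_batches, n_cells))
    for r in range(n_reps):
        np.random.seed(_mix_seed(seed, r))
        nb = _run_genealogy(
            breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
            init_deme, init_axis, strides,
            deme, counts, birth, mask, nd, br_cell, br_len, br_mask,
        )
        bi = r * n_batches // n_reps
        for b in range(nb):
            out[bi, br_cell[b]] += br_len[b]
    return out


@njit(cache=True)
def _sampled_kernel(
    n_loci, seed, mu_len,
    breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
    init_deme, init_axis, strides, n_cells,
):
    n = init_deme.shape[0]
    n_axes = strides.shape[0]
    n_demes = coal.shape[1]
    deme = np.zeros(n, dtype=np.int64)
    counts = np.zeros((n, n_axes), dtype=np.int64)
    birth = np.zeros(n)
    mask = np.zeros(n, dtype=np.uint64)
    nd = np.zeros(n_demes, dtype=np.int64)
    br_cell = np.zeros(2 * n, dtype=np.int64)
    br_len = np.zeros(2 * n)
    br_mask = np.zeros(2 * n, dtype=np.uint64)
    out = np.zeros(n_cells)
    for r in range(n_loci):
        np.random.seed(_mix_seed(seed, r))
        nb = _run_genealogy(
            breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
            init_deme, init_axis, strides,
            deme, counts, birth, mask, nd, br_cell, br_len, br_mask,
        )
        tot = 0.0
        for b in range(nb):
            tot += br_len[b]
        if tot <= 0.0 or mu_len <= 0.0:
            continue
        nmut = np.random.poisson(mu_len * tot)
        for _ in range(nmut):
            u = np.random.random() * tot
            acc = 0.0
            for b in range(nb):
                acc += br_len[b]
                if u < acc:
                    out[br_cell[b]] += 1.0
                    break
    return out


@njit(cache=True)
def _genotype_kernel(
    n_loci, seed, mu_len, cap,
    breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
    init_deme, init_axis, strides,
):
    n = init_deme.shape[0]
    n_axes = strides.shape[0]
    n_demes = coal.shape[1]
    deme = np.zeros(n, dtype=np.int64)
    counts = np.zeros((n, n_axes), dtype=np.int64)
    birth = np.zeros(n)
    mask = np.zeros(n, dtype=np.uint64)
    nd = np.zeros(n_demes, dtype=np.int64)
    br_cell = np.zeros(2 * n, dtype=np.int64)
    br_len = np.zeros(2 * n)
    br_mask = np.zeros(2 * n, dtype=np.uint64)
    site_mask = np.zeros(cap, dtype=np.uint64)
    site_locus = np.zeros(cap, dtype=np.int64)
    total = 0
    for r in range(n_loci):
        np.random.seed(_mix_seed(seed, r))
        nb = _run_genealogy(
            breaks, coal, mig, ev_break, ev_from, ev_to, ev_prob,
            init_deme, init_axis, strides,
            deme, counts, birth, mask, nd, br_cell, br_len, br_mask,
        )
        tot = 0.0
        for b in range(nb):
            tot += br_len[b]
        if tot <= 0.0 or mu_len <= 0.0:
            continue
        nmut = np.random.poisson(mu_len * tot)
        for _ in range(nmut):
            u = np.random.random() * tot
            acc = 0.0
            for b in range(nb):
                acc += br_len[b]
                if u < acc:
                    if total < cap:
                        site_mask[total] = br_mask[b]
                        site_locus[total] = r
                    total += 1
                    break
    return site_mask, site_locus, total


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _kernel_args(prog: _Program):
    return (
        prog.breaks, prog.coal, prog.mig,
        prog.ev_break, prog.ev_from, prog.ev_to, prog.ev_prob,
        prog.init_deme, prog.init_axis, prog.strides,
    )


def expected_branch_sfs(
    spec: ModelSpec, n_sims: int, seed: int, n_batches: int = 1
) -> tuple[JointSFS, np.ndarray]:
    """Unnormalized mean branch-length SFS and the per-batch accumulators.

    ``counts[cell]`` is the mean, over ``n_sims`` genealogies, of the total
    branch length subtending that joint derived-allele configuration; its
    grand total is the mean total tree length (root branch excluded).
    """
    prog = compile_program(spec)
    batches = _expected_kernel(
        int(n_sims), int(seed), int(n_batches), *_kernel_args(prog), prog.n_cells
    )
    shape = tuple(n + 1 for n in prog.axis_sizes)
    mean = batches.sum(axis=0).reshape(shape) / n_sims
    sfs = JointSFS(
        prog.pop_labels, prog.axis_sizes, mean, is_expected=False,
        meta={"n_sims": int(n_sims), "seed": int(seed), "kind": "mean_branch_length"},
    )
    return sfs, batches


def simulate_expected_sfs(
    spec: ModelSpec, cfg: SimulationConfig | None = None, **kwargs
) -> JointSFS:
    """Expected-proportion SFS over polymorphic cells (sums to 1).

    Deterministic given ``cfg.seed``.  ``meta`` records the simulation count
    (used downstream as the composite-likelihood floor) and the mean total
    branch length.
    """
    cfg = cfg or SimulationConfig(**kwargs)
    raw, _ = expected_branch_sfs(spec, cfg.n_sims, cfg.seed)
    total_len = raw.total_mass()
    out = raw.normalized()
    out.meta.update(
        n_sims=cfg.n_sims, seed=cfg.seed, mean_total_branch_length=total_len
    )
    return out


def expected_sfs_with_se(
    spec: ModelSpec, n_sims: int, seed: int, n_batches: int = 50
) -> tuple[JointSFS, np.ndarray]:
    """Expected SFS plus per-cell Monte Carlo standard errors."""
    raw, batches = expected_branch_sfs(spec, n_sims, seed, n_batches=n_batches)
    out = raw.normalized()
    out.meta.update(n_sims=n_sims, seed=seed)
    se = mc_standard_error(batches, tuple(n + 1 for n in raw.sample_sizes))
    return out, se


def mc_standard_error(batches: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Per-cell SE of the expected-proportion estimate from batch sums.

    Each batch is normalized over polymorphic cells; the SE of the mean
    proportion is the between-batch standard deviation over sqrt(B).
    """
    if batches.shape[0] < 2:
        raise ValueError("need >= 2 batches for a standard error")
    b = batches.shape[0]
    props = np.zeros_like(batches)
    mask = np.ones(shape, dtype=bool)
    mask[(0,) * len(shape)] = False
    mask[tuple(n - 1 for n in shape)] = False
    flat_mask = mask.ravel()
    for i in range(b):
        tot = batches[i, flat_mask].sum()
        if tot > 0:
            props[i] = np.where(flat_mask, batches[i] / tot, 0.0)
    se = props.std(axis=0, ddof=1) / math.sqrt(b)
    return se.reshape(shape)


def sample_observed_sfs(
    spec: ModelSpec, cfg: SimulationConfig | None = None, **kwargs
) -> JointSFS:
    """Integer-count SFS: one genealogy per unlinked locus, Poisson mutations.

    The per-locus mutation intensity is ``mutation_rate * locus_length *
    total branch length``; every mutation is an infinite-sites SNP whose SFS
    cell is its branch's joint descendant configuration.
    """
    cfg = cfg or SimulationConfig(**kwargs)
    prog = compile_program(spec)
    mu_len = spec.mutation_rate * spec.locus_length
    flat = _sampled_kernel(
        int(cfg.n_loci), int(cfg.seed), float(mu_len),
        *_kernel_args(prog), prog.n_cells,
    )
    shape = tuple(n + 1 for n in prog.axis_sizes)
    return JointSFS(
        prog.pop_labels, prog.axis_sizes, flat.reshape(shape), is_expected=False,
        meta={
            "n_loci": int(cfg.n_loci), "seed": int(cfg.seed),
            "mutation_rate": spec.mutation_rate,
            "locus_length": spec.locus_length,
        },
    )


def simulate_genotype_masks(
    spec: ModelSpec, n_loci: int, seed: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP descendant bitmasks for ``n_loci`` unlinked loci.

    Returns ``(masks, locus_index, sample_pops)`` where bit ``i`` of a mask
    marks sample ``i`` as carrying the derived allele and ``sample_pops[i]``
    is that sample's population.  Requires <= 64 sampled haploids.
    """
    prog = compile_program(spec)
    n = prog.init_deme.shape[0]
    if n > 64:
        raise ValueError("genotype simulation supports at most 64 sampled haploids")
    mu_len = spec.mutation_rate * spec.locus_length
    cap = max(1024, int(4 * mu_len * 4 * sum(spec.pop(p).ne for p in prog.pop_labels)))
    while True:
        site_mask, site_locus, total = _genotype_kernel(
            int(n_loci), int(seed), float(mu_len), int(cap), *_kernel_args(prog)
        )
        if total <= cap:
            break
        cap = int(total * 1.2) + 64
    sample_pops = [
        prog.pop_labels[a] for a in prog.init_axis
    ]
    return site_mask[:total], site_locus[:total], sample_pops


def island_model(
    n_demes: int,
    ne: float,
    nem: float,
    samples_per_deme: int,
    mutation_rate: float = 2.8e-8,
    locus_length: int = 90,
) -> ModelSpec:
    """Symmetric d-deme island model calibrated to Wright's equilibrium.

    The per-pair migration rate is ``nem / (ne * d)``, i.e. a finite-deme
    correction ``(d-1)/d`` on the total emigration rate, so the equilibrium
    Hudson Fst matches Wright's haploid island-model value
    ``1 / (1 + 2 Nem)`` for any number of demes (with the naive
    ``m = nem/ne`` a 2-deme model would equilibrate at ``1/(1+4 Nem)``).
    """
    if n_demes < 2:
        raise ValueError("island model needs >= 2 demes")
    pops = [
        Population(f"D{i}", ne, samples_per_deme) for i in range(n_demes)
    ]
    m_pair = nem / (ne * n_demes)
    migs = [
        MigrationWindow(f"D{i}", f"D{j}", m_pair)
        for i in range(n_demes)
        for j in range(n_demes)
        if i != j
    ]
    return ModelSpec(
        populations=pops,
        migrations=migs,
        mutation_rate=mutation_rate,
        locus_length=locus_length,
    )
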