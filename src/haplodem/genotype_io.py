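"""Read, write, polarize, filter and subset haploid SNP matrices.

The central container is :class:`HaploidGenotypeMatrix`: a samples x sites
matrix of polarized haploid calls, ``0`` = ancestral allele, ``1`` = derived
allele, ``-1`` = missing.  Sites carry a locus identifier (RAD locus), a
1-based position within the locus and the ancestral/derived bases.

Polarization convention: the ancestral state is the allele matching the
outgroup-aligned reference (``AA`` INFO tag when present, otherwise REF).
Sites whose annotated ancestral allele matches neither observed allele are
dropped rather than folded, preserving the validity of the unfolded SFS.
Multi-allelic sites are dropped as well; both drop counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing haploid call.  Never contributes to allele counts.
MISSING: int = -1

SITE_COLUMNS = ["locus_id", "pos", "anc", "der"]


class MatrixFormatError(ValueError):
    """Raised for malformed genotype-matrix input."""


@dataclass
class HaploidGenotypeMatrix:
    """Polarized haploid SNP matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``calls``).
    sites
        DataFrame with columns ``locus_id`` (str), ``pos`` (int, 1-based
        within locus, strictly increasing), ``anc`` and ``der`` (bases).
    calls
        int8 array of shape ``(n_samples, n_sites)`` with values in
        ``{0, 1, MISSING}``.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise MatrixFormatError("calls must be 2-D (samples x sites)")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise MatrixFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise MatrixFormatError("calls must be 0, 1 or MISSING (-1)")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise MatrixFormatError(f"sites missing columns {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)
        # positions strictly increasing within each locus
        for locus, grp in self.sites.groupby("locus_id", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise MatrixFormatError(
                    f"positions within locus {locus!r} not strictly increasing"
                )

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def locus_ids(self) -> list[str]:
        """Locus identifiers in order of first appearance."""
        return list(dict.fromkeys(self.sites["locus_id"]))

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def subset_samples(self, ids: list[str]) -> "HaploidGenotypeMatrix":
        idx = self.sample_indices(ids)
        return HaploidGenotypeMatrix(list(ids), self.sites.copy(), self.calls[idx])

    def subset_sites(self, index: np.ndarray) -> "HaploidGenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaploidGenotypeMatrix(
            list(self.samples),
            self.sites.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )

    def locus_presence(self) -> pd.Series:
        """Fraction of samples with >=1 non-missing call per locus."""
        present = self.calls != MISSING  # samples x sites
        out = {}
        for locus, grp in self.sites.groupby("locus_id", sort=False):
            cols = grp.index.to_numpy()
            out[locus] = float(present[:, cols].any(axis=1).mean())
        return pd.Series(out, name="presence")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaploidGenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites.equals(other.sites)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with an ordered label list."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            self.populations = list(dict.fromkeys(self.assignments.values()))
        extra = set(self.assignments.values()) - set(self.populations)
        if extra:
            raise ValueError(f"assignments use unlisted populations {sorted(extra)}")
        for pop in self.populations:
            if not any(v == pop for v in self.assignments.values()):
                raise ValueError(f"population {pop!r} has no samples")

    def samples_for(self, pop: str) -> list[str]:
        if pop not in self.populations:
            raise KeyError(f"unknown population {pop!r}")
        return [s for s, p in self.assignments.items() if p == pop]

    def check_covers(self, matrix: HaploidGenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population label: {missing}")


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------
# Header:  locus_id  pos  anc  der  <sample1>  <sample2> ...
# Rows:    one per site; calls are 0, 1 or '.' for missing.


def write_matrix(matrix: HaploidGenotypeMatrix, path, format: str = "tabular") -> None:
    """Write a matrix in the tabular dialect or as haploid VCF."""
    if format == "tabular":
        _write_tabular(matrix, path)
    elif format == "vcf-haploid":
        _write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_tabular(matrix: HaploidGenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS + matrix.samples) + "\n")
        for j in range(matrix.n_sites):
            rec = matrix.sites.iloc[j]
            calls = [
                "." if c == MISSING else str(int(c)) for c in matrix.calls[:, j]
            ]
            fh.write(
                f"{rec.locus_id}\t{int(rec.pos)}\t{rec.anc}\t{rec.der}\t"
                + "\t".join(calls)
                + "\n"
            )


def _write_vcf(matrix: HaploidGenotypeMatrix, path) -> None:
    """Haploid VCF: one contig per locus, REF=ancestral, ALT=derived, AA tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in matrix.locus_ids:
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            rec = matrix.sites.iloc[j]
            gts = ["." if c == MISSING else str(int(c)) for c in matrix.calls[:, j]]
            fh.write(
                f"{rec.locus_id}\t{int(rec.pos)}\t.\t{rec.anc}\t{rec.der}\t.\t.\t"
                f"AA={rec.anc}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_matrix(path, format: str = "tabular") -> HaploidGenotypeMatrix:
    """Read a haploid SNP matrix.

    ``format='tabular'`` reads the package's documented TSV dialect;
    ``format='vcf-haploid'`` reads a VCF with haploid single-allele GT calls,
    polarizing on the AA INFO tag (falling back to REF).  Sites that cannot
    be polarized or are multi-allelic are dropped with a logged count.
    """
    if format == "tabular":
        return _read_tabular(path)
    if format == "vcf-haploid":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tabular(path) -> HaploidGenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[: len(SITE_COLUMNS)] != SITE_COLUMNS:
            raise MatrixFormatError(
                f"{path}: line 1: header must start with {SITE_COLUMNS}"
            )
        samples = cols[len(SITE_COLUMNS):]
        rows, calls = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise MatrixFormatError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(parts)}"
                )
            locus, pos, anc, der = parts[:4]
            try:
                pos_i = int(pos)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: bad position {pos!r}"
                ) from None
            row_calls = []
            for tok in parts[4:]:
                if tok == ".":
                    row_calls.append(MISSING)
                elif tok in ("0", "1"):
                    row_calls.append(int(tok))
                else:
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: bad call {tok!r}"
                    )
            rows.append((locus, pos_i, anc, der))
            calls.append(row_calls)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    arr = (
        np.array(calls, dtype=np.int8).T
        if calls
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return HaploidGenotypeMatrix(samples, sites, arr)


def _read_vcf(path) -> HaploidGenotypeMatrix:
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, calls = [], []
    n_unpolarized = 0
    n_multiallelic = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        try:
            aa = rec.info.get("AA", ref)
        except ValueError:  # AA tag absent from the header entirely
            aa = ref
        if isinstance(aa, (tuple, list)):
            aa = aa[0]
        aa = str(aa).upper()
        if aa == ref.upper():
            anc, der, flip = ref, alt, False
        elif aa == alt.upper():
            anc, der, flip = alt, ref, True
        else:
            n_unpolarized += 1
            continue
        row = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                row.append(MISSING)
                continue
            alleles = [a for a in gt if a is not None]
            if len(alleles) != 1:
                raise MatrixFormatError(
                    f"{path}: {rec.chrom}:{rec.pos}: diploid genotype for "
                    f"sample {s!r}; haploid calls required"
                )
            a = alleles[0]
            row.append((1 - a) if flip else a)
        rows.append((rec.chrom, rec.pos, anc, der))
        calls.append(row)
    if n_unpolarized:
        logger.info(
            "%s: dropped %d site(s) whose ancestral allele matched neither "
            "observed allele", path, n_unpolarized,
        )
    if n_multiallelic:
        logger.info("%s: dropped %d multi-allelic site(s)", path, n_multiallelic)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    arr = (
        np.array(calls, dtype=np.int8).T
        if calls
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return HaploidGenotypeMatrix(samples, sites, arr)


def read_popmap(path) -> PopulationMap:
    """Two-column TSV: sample, population."""
    assignments: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            sample, pop = parts
            assignments[sample] = pop
            if pop not in order:
                order.append(pop)
    return PopulationMap(assignments, order)


def write_popmap(pmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_locus_presence(
    matrix: HaploidGenotypeMatrix, min_fraction: float
) -> HaploidGenotypeMatrix:
    """Discard loci present in fewer than ``min_fraction`` of the samples.

    Locus presence is the fraction of samples with at least one non-missing
    call at the locus.  ``min_fraction=0`` keeps every locus with at least
    one call.  Sample and site order are preserved.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    presence = matrix.locus_presence()
    if min_fraction == 0:
        keep = set(presence.index[presence > 0])
    else:
        keep = set(presence.index[presence >= min_fraction])
    mask = matrix.sites["locus_id"].isin(keep).to_numpy()
    return matrix.subset_sites(mask)


def one_snp_per_locus(matrix: HaploidGenotypeMatrix, seed: int) -> HaploidGenotypeMatrix:
    """Keep exactly one SNP per locus, chosen uniformly with ``seed``."""
    rng = np.random.default_rng(seed)
    chosen = []
    for _, grp in matrix.sites.groupby("locus_id", sort=False):
        idx = grp.index.to_numpy()
        chosen.append(idx[rng.integers(len(idx))])
    chosen = np.sort(np.array(chosen, dtype=np.intp))
    return matrix.subset_sites(chosen)
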