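"""RAD-like synthetic haploid SNP datasets with known demographic truth.

Each locus receives one genealogy from the structured-coalescent machinery;
Poisson(mu * L * total branch length) infinite-sites mutations define the
derived-allele carriers, so polarization is exact (ancestral = 0).  Missing
data are whole-locus dropouts per sample — the allele-dropout pattern the
80% locus-presence filter targets in real RAD assemblies — not per-site
holes.  An outgroup population simulated as a deep-diverged lineage gives
ABBA/BABA tests a genuine P4.

Features of real RAD data deliberately not emulated: sequencing error,
paralog collapse, reference bias and read-depth variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from haplodem.coalsim import simulate_genotype_masks
from haplodem.genotype_io import (
    MISSING,
    HaploidGenotypeMatrix,
    PopulationMap,
    write_matrix,
    write_popmap,
)
from haplodem.models import (
    Divergence,
    MigrationWindow,
    ModelSpec,
    Population,
    validate_model,
)


@dataclass
class SyntheticTruth:
    """The stated world of one synthetic dataset; fully reproducible."""

    spec: ModelSpec
    seed: int
    n_loci: int
    locus_length: int = 90
    missingness: float = 0.0
    sample_layout: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if not self.sample_layout:
            self.sample_layout = self.spec.sample_sizes()
        issues = validate_model(self.spec)
        if issues:
            raise ValueError(f"invalid generating model: {issues}")

    def to_json(self, path=None) -> str:
        payload = {
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "n_loci": self.n_loci,
            "locus_length": self.locus_length,
            "missingness": self.missingness,
            "sample_layout": self.sample_layout,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        try:
            with open(source) as fh:
                data = json.load(fh)
        except (OSError, TypeError):
            data = json.loads(source)
        return cls(
            spec=ModelSpec.from_dict(data["spec"]),
            seed=data["seed"],
            n_loci=data["n_loci"],
            locus_length=data["locus_length"],
            missingness=data["missingness"],
            sample_layout=data["sample_layout"],
        )


def generate_dataset(
    truth: SyntheticTruth, out_dir: str | Path | None = None
) -> tuple[HaploidGenotypeMatrix, PopulationMap, SyntheticTruth]:
    """Generate one dataset; (truth, seed) regenerates it identically.

    Returns the polarized SNP matrix (loci ``L000000...``; every segregating
    mutation is one biallelic site with ancestral allele 'A', derived 'T'),
    the population map, and the truth record.  ``out_dir`` additionally
    writes ``matrix.tsv``, ``popmap.tsv`` and ``truth.json``.
    """
    spec = truth.spec
    if spec.locus_length != truth.locus_length:
        raise ValueError("truth.locus_length must match spec.locus_length")
    masks, locus_of, sample_pops = simulate_genotype_masks(
        spec, truth.n_loci, truth.seed
    )
    n_samples = len(sample_pops)
    rng = np.random.default_rng([truth.seed & 0x7FFFFFFF, 0xDA7A])

    # sample names grouped by population, matching the simulator's order
    counters: dict[str, int] = {}
    samples = []
    for pop in sample_pops:
        counters[pop] = counters.get(pop, 0) + 1
        samples.append(f"{pop}_{counters[pop]:02d}")
    pmap = PopulationMap({s: p for s, p in zip(samples, sample_pops)})

    # assign within-locus positions (infinite sites ~ distinct positions)
    width = len(str(max(truth.n_loci - 1, 1)))
    rows = []
    keep = []
    pos_used: dict[int, set[int]] = {}
    for j in range(len(masks)):
        loc = int(locus_of[j])
        used = pos_used.setdefault(loc, set())
        if len(used) >= truth.locus_length:
            continue  # more mutations than sites; drop the overflow
        while True:
            pos = int(rng.integers(1, truth.locus_length + 1))
            if pos not in used:
                used.add(pos)
                break
        rows.append((f"L{loc:0{width}d}", pos, "A", "T"))
        keep.append(j)
    masks = masks[keep]

    sites = pd.DataFrame(rows, columns=["locus_id", "pos", "anc", "der"])
    order = sites.sort_values(["locus_id", "pos"], kind="stable").index.to_numpy()
    sites = sites.iloc[order].reset_index(drop=True)
    masks = masks[order]

    bits = (masks[None, :] >> np.arange(n_samples, dtype=np.uint64)[:, None]) & np.uint64(1)
    calls = bits.astype(np.int8)

    if truth.missingness > 0:
        drop = rng.random((n_samples, truth.n_loci)) < truth.missingness
        locus_index = {f"L{i:0{width}d}": i for i in range(truth.n_loci)}
        site_locus = sites["locus_id"].map(locus_index).to_numpy()
        calls[drop[:, site_locus]] = MISSING

    matrix = HaploidGenotypeMatrix(samples, sites, calls)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(matrix, out / "matrix.tsv")
        write_popmap(pmap, out / "popmap.tsv")
        truth.to_json(out / "truth.json")
    return matrix, pmap, truth


def preset_rad_shape(
    seed: int,
    n_loci: int = 1000,
    missingness: float = 0.10,
    sample_layout: dict[str, int] | None = None,
) -> SyntheticTruth:
    """Three focal populations plus an outgroup, RAD-like shape.

    The stated world: a (REC, (ENA, EUR)) species tree with a deep-diverged
    outgroup OUT for polarization/ABBA-BABA, secondary-contact gene flow from
    REC into the FLEX ancestor plus two current-population flows (the
    three-event family), ~10^3 loci of 90 bp and 10% whole-locus dropout.
    Sizes follow the intended diversity ordering (REC largest, EUR smallest);
    the mutation rate is the 2.8e-8 per-site per-generation default.
    """
    layout = sample_layout or {"REC": 8, "ENA": 16, "EUR": 11, "OUT": 4}
    t_flex, t_spec, t_out = 2_000.0, 8_000.0, 40_000.0
    t_contact = 5_000.0  # secondary contact: flow on [t_flex, t_contact)
    spec = ModelSpec(
        populations=[
            Population("REC", 6_000.0, layout.get("REC", 8)),
            Population("ENA", 3_000.0, layout.get("ENA", 16)),
            Population("EUR", 1_000.0, layout.get("EUR", 11)),
            Population("FLEX", 1_500.0, 0),
            Population("ANC", 6_000.0, 0),
            Population("OUT", 5_000.0, layout.get("OUT", 4)),
            Population("ROOT", 6_000.0, 0),
        ],
        divergences=[
            Divergence(t_flex, "ENA", "FLEX"),
            Divergence(t_flex, "EUR", "FLEX"),
            Divergence(t_spec, "FLEX", "ANC"),
            Divergence(t_spec, "REC", "ANC"),
            Divergence(t_out, "ANC", "ROOT"),
            Divergence(t_out, "OUT", "ROOT"),
        ],
        migrations=[
            MigrationWindow("ENA", "EUR", 1e-3, 0.0, t_flex),
            MigrationWindow("ENA", "REC", 1.13e-4, 0.0, t_flex),
            MigrationWindow("REC", "FLEX", 1e-3, t_flex, t_contact),
        ],
        mutation_rate=2.8e-8,
        locus_length=90,
    )
    return SyntheticTruth(
        spec=spec,
        seed=seed,
        n_loci=n_loci,
        locus_length=90,
        missingness=missingness,
        sample_layout=layout,
    )
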