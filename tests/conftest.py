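import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from haplodem.genotype_io import MISSING, HaploidGenotypeMatrix, PopulationMap

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(calls, loci=None, samples=None):
    """Matrix from a (samples x sites) int list; loci assigns locus ids."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = samples or [f"S{i}" for i in range(n_samples)]
    loci = loci or ["L0"] * n_sites
    pos, seen = [], {}
    for lid in loci:
        seen[lid] = seen.get(lid, 0) + 1
        pos.append(seen[lid])
    sites = pd.DataFrame(
        {"locus_id": loci, "pos": pos, "anc": "A", "der": "T"}
    )
    return HaploidGenotypeMatrix(samples, sites, calls)


@pytest.fixture
def tiny_matrix():
    # 4 samples, 2 loci x 3 sites, with missing calls
    calls = [
        [0, 1, 0, 1, 1, 0],
        [0, 1, 1, MISSING, 1, 0],
        [1, 0, 1, 0, MISSING, 1],
        [1, MISSING, 1, 0, 0, 1],
    ]
    return make_matrix(calls, loci=["L0"] * 3 + ["L1"] * 3)


@pytest.fixture
def tiny_popmap(tiny_matrix):
    return PopulationMap(
        {"S0": "P1", "S1": "P1", "S2": "P2", "S3": "P2"}, ["P1", "P2"]
    )
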