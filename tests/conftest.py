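import numpy as np
import pytest

from cochise.sfs import GenotypeMatrix, SiteRecord


def make_gm(calls, pops, ref_alt=None):
    """GenotypeMatrix from a dense call array and per-individual labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_ind = calls.shape
    if ref_alt is None:
        ref_alt = [("A", "T")] * n_sites
    sites = [
        SiteRecord(f"chr{s}", s + 1, f"L{s:04d}", ref_alt[s][0], ref_alt[s][1])
        for s in range(n_sites)
    ]
    individuals = [f"ind{i}" for i in range(n_ind)]
    pop_of = {f"ind{i}": pops[i] for i in range(n_ind)}
    return GenotypeMatrix(sites, calls, individuals, pop_of)


@pytest.fixture
def tiny_gm():
    # 3 populations x 2 individuals each + 1 outgroup individual
    calls = [
        [0, 1, 2, 2, 0, 1, 0],
        [2, 2, 1, 0, 0, 0, 2],
        [0, 0, 0, 1, 1, 2, 1],  # heterozygous outgroup -> dropped on polarization
    ]
    pops = ["SON", "SON", "CHI", "CHI", "CAR", "CAR", "OUTGROUP"]
    return make_gm(calls, pops)
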