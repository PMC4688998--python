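import numpy as np
import pytest

from orchardgs import simdata
from orchardgs.pedkin import Pedigree


@pytest.fixture(scope="session")
def single_family():
    """One full-sib family with HD parents: genotypes for imputation tests.

    5 chromosomes x 300 markers, 100 cM each; 60 offspring; truth haplotypes
    retained.
    """
    gmap = simdata.make_genetic_map(5, 300, 100.0)
    ped = Pedigree()
    ped.add("S")
    ped.add("D")
    kids = [f"K{j:02d}" for j in range(60)]
    for k in kids:
        ped.add(k, "S", "D")
    rng = np.random.default_rng(1)
    freqs = rng.uniform(0.1, 0.9, gmap.n_snps)
    geno = simdata.gene_drop(ped, gmap, freqs, seed=2)
    return {"map": gmap, "ped": ped, "kids": kids, "geno": geno}


@pytest.fixture(scope="session")
def small_population():
    """Small multi-family population shared across analysis-stage tests."""
    cfg = simdata.small_preset()
    return cfg, simdata.simulate_population(cfg)
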