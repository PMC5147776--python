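"""Shared fixtures: small seeded cohorts reused across test modules."""

import numpy as np
import pytest

import sexgwas as sg
from sexgwas.simulate import ArchitectureSpec, CausalSet, null_spec


@pytest.fixture(scope="session")
def small_null_spec():
    return null_spec(n_auto=200, n_x=20, seed=11)


@pytest.fixture(scope="session")
def null_trios(small_null_spec):
    """400 null-architecture trios, 30% female probands, two batches."""
    return sg.simulate_trios(small_null_spec, 400, 0.3, batches=("B1", "B2"))


@pytest.fixture(scope="session")
def null_population(small_null_spec):
    """800 unascertained individuals, half labelled cases at random."""
    pop = sg.simulate_population(small_null_spec, 800)
    rng = np.random.default_rng(17)
    case = rng.permutation(pop.n) < pop.n // 2
    pop.meta.loc[case, "role"] = "case"
    pop.meta.loc[case, "affection"] = 2
    return pop


@pytest.fixture(scope="session")
def polygenic_spec():
    """50 shared-effect autosomal causal SNPs, liability h2 = 0.5."""
    idx = tuple(range(0, 200, 4))
    beta = tuple(1.0 for _ in idx)
    return ArchitectureSpec(
        n_snps_by_chrom={str(c): 10 for c in range(1, 21)},
        causal_sets=(CausalSet(idx, beta, beta),),
        h2_liability=0.5,
        threshold_male=1.0,
        threshold_female=1.0,
        seed=23,
    )
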