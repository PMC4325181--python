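import numpy as np
import pytest

import replitype as rt


@pytest.fixture(scope="session")
def small_pool():
    """Six 60-bp alleles, pairwise distance >= 3, no insertions."""
    return rt.make_allele_pool(6, 60, 3, 0, seed=101)


@pytest.fixture(scope="session")
def paper_pool():
    """Design-scale pool: 22 alleles, 240 bp, two with a 3-nt insertion."""
    return rt.make_allele_pool(22, 240, 2, 2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_amplicon_clusters(read_counts: dict[str, int], sample_id: str,
                           replicate: int, amplicon_id: str | None = None):
    """Build step-1-classified clusters from a {sequence: count} spec."""
    reads = [s for s, c in read_counts.items() for _ in range(c)]
    ac = rt.cluster_reads(reads,
                          amplicon_id=amplicon_id or f"{sample_id}_r{replicate}",
                          sample_id=sample_id, replicate=replicate)
    return rt.classify_step1(ac)
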