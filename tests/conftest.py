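import numpy as np
import pandas as pd
import pytest

from gbsforge.enzymes import get_enzyme
from gbsforge.genome import Genome
from gbsforge.genome_sim import GenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def pstI():
    return get_enzyme("PstI")


@pytest.fixture(scope="session")
def sbfI():
    return get_enzyme("SbfI")


@pytest.fixture(scope="session")
def random_1mb_genome():
    return simulate_genome(GenomeSpec([1_000_000], ["large"], gc=0.5), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


@pytest.fixture(scope="session")
def tiny_variants():
    """A small variant table on one chromosome for pedigree tests."""
    rows = [("c1", p, "A", "C", "tt_fixed", 0.5) for p in range(100, 2100, 100)]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "origin", "alt_freq"]
    )
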