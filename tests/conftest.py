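import numpy as np
import pytest

from sigdyn import generate_genome, signature_reference
from sigdyn.genome import SyntheticGenome


@pytest.fixture(scope="session")
def genome():
    """Mid-size genome shared by sampling-heavy tests."""
    return generate_genome(n_chroms=1, chrom_length=400_000, gc_fraction=0.4,
                           dyad_spacing=197, seed=7)


@pytest.fixture(scope="session")
def sbs_ref():
    return signature_reference("sbs96")


@pytest.fixture(scope="session")
def id_ref():
    return signature_reference("id83")


@pytest.fixture()
def toy_genome():
    """Tiny handcrafted genome for exact classification checks."""
    seq = "ACGTACGTTTACGCACACACATAGTAGGACGTTCATTTGGCCAATTGGACGT" * 4
    return SyntheticGenome(sequences={"chrT": seq},
                           dyads={"chrT": np.array([100], dtype=np.int64)})
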