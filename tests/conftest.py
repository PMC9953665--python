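import numpy as np
import pytest

from isoscope.synthetic_data import LocusSpec, simulate_locus


@pytest.fixture(scope="session")
def bundle():
    """The standard toy locus, seed 1."""
    return simulate_locus(LocusSpec(), seed=1)


@pytest.fixture(scope="session")
def spec():
    return LocusSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def isoform_family():
    """Five isoforms sharing a 200-nt block, each with a unique 800-nt core.

    Used for EM parameter-recovery tests; proportions follow the standard
    (0.50, 0.25, 0.15, 0.07, 0.03) simplex.
    """
    r = np.random.default_rng(2024)
    shared = random_seq(r, 200)
    seqs = {f"T{i}": random_seq(r, 800) + shared for i in range(5)}
    props = dict(zip(sorted(seqs), (0.50, 0.25, 0.15, 0.07, 0.03)))
    return seqs, props
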