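import numpy as np
import pytest

from punctless.simulate import default_program, reference_arrangement_a


@pytest.fixture(scope="session")
def reference():
    """The synthetic arrangement-A reference genome and annotation."""
    genome, feats = reference_arrangement_a()
    return genome, list(feats)


@pytest.fixture(scope="session")
def program_a():
    """Ground-truth transcription program for arrangement A."""
    program, genome, feats = default_program("A")
    return program, genome, list(feats)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_toy_genome(rng, length=600, forbid_polya_at=()):
    """Random toy circular genome; positions in ``forbid_polya_at`` (1-based)
    are forced to a non-A base so constructed transcript ends are canonical."""
    from punctless.genome import CircularGenome

    seq = rng.choice(list("ACGT"), size=length)
    for p in forbid_polya_at:
        seq[(p - 1) % length] = "C"
    return CircularGenome(id="toy", sequence="".join(seq))
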