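import numpy as np
import pytest

from cdr3comp import CDR3Peptide, AntigenFragment

SCORING_ALPHABET = "KRHDEGA"  # charged + neutral letters used in random scoring tests


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length, alphabet=SCORING_ALPHABET):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def make_cdr3():
    def _make(sequence, case_id="case1", chain="TRB"):
        return CDR3Peptide(case_id, chain, sequence)
    return _make


@pytest.fixture
def make_fragment():
    def _make(sequence, name="AG", index=1):
        return AntigenFragment(name, index, sequence)
    return _make
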