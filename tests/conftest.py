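import numpy as np
import pytest

from dinuprof import builtin_beta_globin
from dinuprof.sequence_io import DnaSequence


@pytest.fixture(scope="session")
def beta_globin():
    return builtin_beta_globin()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int, label: str = "rnd") -> DnaSequence:
    residues = "".join(rng.choice(list("ACGT"), size=n))
    return DnaSequence(id=label, residues=residues)
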