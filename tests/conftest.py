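import numpy as np
import pytest

import acpmine as am
from acpmine._tables import data_path
from acpmine.features import ACP, NON_ACP, featurize_set

AMALGAM = "AAEKEFIKYPYPTPLQYQQLATRLKVEKKLVRRW"
CORE_30MER = "EFIKYPYPTPLQYQQLATRLKVEKKLVRRW"


@pytest.fixture(scope="session")
def amalgam():
    return AMALGAM


@pytest.fixture(scope="session")
def core_30mer():
    return CORE_30MER


@pytest.fixture(scope="session")
def amalgam_fasta_path():
    return data_path("amalgam_34mer.fasta")


@pytest.fixture(scope="session")
def training_table():
    """200+200 synthetic ACP/background peptides, featurized (fixed seeds)."""
    acp = am.default_profile("acp")
    bg = am.default_profile("background")
    a = am.sample_peptides(acp, 200, seed=1)
    b = am.sample_peptides(bg, 200, seed=2)
    return featurize_set([r.sequence for r in a] + [r.sequence for r in b],
                         [ACP] * 200 + [NON_ACP] * 200,
                         [r.id for r in a] + [r.id for r in b])


@pytest.fixture(scope="session")
def trained_model(training_table):
    return am.train(training_table, am.TrainConfig(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_peptides(rng, n, min_len=5, max_len=50):
    from acpmine.seqio import PROTEIN_ALPHABET
    alpha = np.array(list(PROTEIN_ALPHABET))
    return ["".join(alpha[rng.integers(0, 20, size=rng.integers(min_len, max_len + 1))])
            for _ in range(n)]
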