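import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import promobot as pb
from promobot.synth import promoter_study_spec

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_dataset():
    """A tiny hand-sized dataset (2 promoters / 2 non-promoters)."""
    return pb.LabeledDataset(
        promoters=[
            pb.Sequence("p1", "ACGTACGTACGTAAATTT"),
            pb.Sequence("p2", "TTTAAACCCGGGACGTAC"),
        ],
        nonpromoters=[
            pb.Sequence("n1", "GGGGGGCCCCCCGGGCCC"),
            pb.Sequence("n2", "CCCCGGGGCCCCGGGGCC"),
        ],
    )


@pytest.fixture(scope="session")
def study_dataset():
    """The reference synthetic study: planted motifs + gapped RTP, 100/class."""
    return pb.generate(promoter_study_spec(seed=7), k_folds=5)


@pytest.fixture(scope="session")
def null_dataset():
    """No-signal synthetic data at the same scale."""
    return pb.generate(pb.SynthSpec(n_per_class=100, length=251, seed=7), k_folds=5)


def _random_sequences(rng, n, length, prefix="s"):
    bases = np.array(list("ACGT"))
    return [
        pb.Sequence(f"{prefix}{i}", "".join(rng.choice(bases, size=length)))
        for i in range(n)
    ]


@pytest.fixture
def random_sequences():
    """Factory: random_sequences(rng, n, length, prefix)."""
    return _random_sequences
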