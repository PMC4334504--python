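import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from ecmforest.profile_encoders import DomainVocabulary, EncoderConfig, encode_dataset
from ecmforest.synth import PLANTED_DOMAINS, SynthConfig, generate_records


@pytest.fixture(scope="session")
def full_config():
    """Full 315-feature configuration with the 17-entry planted vocabulary."""
    return EncoderConfig(vocabulary=DomainVocabulary(PLANTED_DOMAINS))


@pytest.fixture(scope="session")
def small_dataset():
    """12 + 12 synthetic proteins with strong class signal."""
    return generate_records(SynthConfig(n_pos=12, n_neg=12, signal=1.0, seed=3))


@pytest.fixture(scope="session")
def small_matrix(small_dataset, full_config):
    records, profiles, labels = small_dataset
    return encode_dataset(records, profiles, full_config, labels=labels)
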