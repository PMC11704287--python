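import numpy as np
import pytest

from molprompt.synthetic_fixtures import FixtureSpec, generate_molecules, generate_labels
from molprompt.pretrain import PretrainConfig, PretrainData, run_pretraining


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic molecules: fast enough for per-module tests."""
    return generate_molecules(FixtureSpec(n_molecules=60, seed=0))


@pytest.fixture(scope="session")
def small_labels(small_corpus):
    return generate_labels(small_corpus, FixtureSpec(n_molecules=60, seed=0))


@pytest.fixture(scope="session")
def pretrained(small_corpus):
    """A short pre-training run shared by fine-tune and contract tests."""
    cfg = PretrainConfig(epochs=5, seed=0)
    data = PretrainData.prepare(small_corpus, cfg)
    ckpt = run_pretraining(small_corpus, cfg, data=data)
    return ckpt, data
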