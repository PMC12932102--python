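import numpy as np
import pytest

from cardiofm import CSFM, EncoderConfig, GeneratorConfig, generate_corpus
from cardiofm.signals import preprocess_signal, segment_signal
from cardiofm.text import encode_text, fit_vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_cfg():
    """Deliberately small architecture for fast unit tests."""
    return EncoderConfig(preset="tiny", depth=2, d=32, heads=2, dec_depth=1,
                         dec_d=32, dec_heads=2, n_l=16, vocab_size=64,
                         n_s_max=120)


@pytest.fixture(scope="session")
def micro_model(micro_cfg):
    return CSFM(micro_cfg, seed=7)


@pytest.fixture(scope="session")
def small_corpus():
    """Two-channel (lead II + PPG) corpus with reports."""
    return generate_corpus(GeneratorConfig(
        n_records=12, duration=3.0, channels=("II", "PPG"), seed=42))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return fit_vocabulary([tr.report for tr in small_corpus.truths], size=64)


@pytest.fixture(scope="session")
def tokenized_items(small_corpus, small_vocab, micro_model):
    items = []
    for rec, tr in zip(small_corpus.records, small_corpus.truths):
        patches = segment_signal(preprocess_signal(rec),
                                 micro_model.cfg.patch_seconds)
        text = encode_text(tr.report, small_vocab, micro_model.cfg.n_l)
        items.append((patches, text))
    return items
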