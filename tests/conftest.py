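import numpy as np
import pytest

from pcgpipe import SynthConfig, synth_generate
from pcgpipe.spectrogram import recording_to_image
from pcgpipe.synthetic import synth_corpus


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """A tiny on-disk synthetic corpus (3 normal + 2 abnormal WAVs + manifest)."""
    out = tmp_path_factory.mktemp("corpus")
    cfg = SynthConfig(n_normal=3, n_abnormal=2, seed=3)
    manifest = synth_generate(cfg, out)
    return out, manifest


@pytest.fixture(scope="session")
def curated_corpus():
    """Curated-quality corpus (SNR ~ N(6,2)): 30 normal + 30 abnormal recordings
    with their rendered spectrogram images, shared across expensive tests."""
    cfg = SynthConfig(
        n_normal=30,
        n_abnormal=30,
        seed=42,
        snr_normal_db=(6.0, 2.0),
        snr_abnormal_db=(6.0, 2.0),
    )
    recs = synth_corpus(cfg)
    images = {r.id: recording_to_image(r).pixels for r in recs}
    labels = {r.id: r.label for r in recs}
    return recs, images, labels


@pytest.fixture(scope="session")
def default_small_corpus():
    """Twelve recordings under the default study conditions (SNR ~ N(0,5))."""
    cfg = SynthConfig(n_normal=6, n_abnormal=6, seed=7)
    return synth_corpus(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
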