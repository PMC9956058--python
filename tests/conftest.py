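import numpy as np
import pytest

from distilharvest.synthcarrot import CorpusSpec, build_corpus


@pytest.fixture(scope="session")
def tiny_spec():
    """Small deterministic corpus: 20/class at 96 px, quota 4+3 per class."""
    return CorpusSpec(per_class_count=20, image_side=96,
                      degrade_per_class=(4, 3), seed=11)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    return build_corpus(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
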