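import numpy as np
import pytest

from icdaug.corpus import label_populations
from icdaug.selection import SelectionConfig, select
from icdaug.synthetic_data import (
    CodeSpaceConfig,
    CorpusConfig,
    make_code_space,
    sample_corpus,
)

SMALL_CORPUS_CFG = CorpusConfig(n_train=400, n_dev=60, n_test=120, seed=2)


@pytest.fixture(scope="session")
def code_space():
    return make_code_space(CodeSpaceConfig(seed=1))


@pytest.fixture(scope="session")
def small_corpus(code_space):
    corpus, manifest = sample_corpus(code_space, SMALL_CORPUS_CFG)
    return corpus, manifest


@pytest.fixture(scope="session")
def small_selection(small_corpus):
    corpus, _ = small_corpus
    pop = label_populations(corpus)
    cfg = SelectionConfig(seed=3)
    return select(pop, cfg, np.random.default_rng(cfg.seed)), pop
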