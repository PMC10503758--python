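import numpy as np
import pytest

from phenotyper import synthetic_ehr as se


@pytest.fixture(scope="session")
def small_dataset():
    """Modest two-cohort dataset shared by read-only tests."""
    cfg = se.default_config(
        n_opioid_encounters=120, n_background_encounters=120,
        doc_length_mean=40.0, seed=101,
    )
    return se.generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_corpus():
    """Planted 3-topic corpus for sampler unit tests (no filtering)."""
    cfg = se.default_config(
        n_opioid_encounters=200, n_background_encounters=0,
        n_true_topics=3, n_true_clusters=3, vocab_size=60,
        doc_length_mean=60.0, seed=202,
    )
    ds = se.generate_dataset(cfg)
    corpus = se.token_corpus(ds)
    phi_true = np.asarray(ds.truth["phi"])
    return ds, corpus, phi_true
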