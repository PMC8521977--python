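import numpy as np
import pytest

import epivec as ev


@pytest.fixture
def toy_word_table():
    """Two dim-2 word vectors with known min/max/mean aggregation."""
    return ev.EmbeddingTable(
        entries={"a": np.array([1.0, 2.0]), "b": np.array([3.0, 0.0])},
        dim=2, level="word", provider_id="toy")


@pytest.fixture
def small_world():
    return ev.make_world(6, 4, 20, 2, 3, 2, seed=1)


@pytest.fixture
def small_table(small_world):
    return ev.sample_incidence(small_world, noise_sd=0.05, zero_rate=0.0, seed=2)


@pytest.fixture
def providers(small_world):
    from epivec.embeddings import EntityProvider
    d = EntityProvider(table=ev.derive_embeddings(small_world, "disease", 6, 1.0, seed=3))
    c = EntityProvider(table=ev.derive_embeddings(small_world, "country", 6, 1.0, seed=4))
    return d, c
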