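import numpy as np
import pytest

from protfuse import GeneratorSpec, embed_synthetic, generate_corpus


def labels_of(records):
    return np.array([1 if r.label == "positive" else 0 for r in records])


@pytest.fixture(scope="session")
def small_corpus():
    """60 records/class, 10% near-duplicates, motif-bearing positives."""
    spec = GeneratorSpec(
        n_per_class=60, length_range=(100, 200), seed=7, near_duplicate_rate=0.1
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def separable_embeddings(small_corpus):
    """Strongly separable embeddings (class shift = 5 x noise sd) over the
    small corpus, with matching 0/1 labels."""
    records, _ = small_corpus
    eset = embed_synthetic(records, num_feature=36, class_shift=5.0, noise_sd=1.0, seed=8)
    return eset, labels_of(records)
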