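import numpy as np
import pytest

from biodtm.corpus_io import CorpusMatrix


def random_matrix(rng, V=None, T=None, max_docs_per_slice=4) -> CorpusMatrix:
    """A small random valid CorpusMatrix for property tests."""
    V = V if V is not None else int(rng.integers(2, 10))
    T = T if T is not None else int(rng.integers(1, 4))
    docs_by_slice = []
    for _ in range(T):
        n_docs = int(rng.integers(1, max_docs_per_slice + 1))
        docs = []
        for _ in range(n_docs):
            n_words = int(rng.integers(1, V + 1))
            idxs = sorted(rng.choice(V, size=n_words, replace=False).tolist())
            docs.append(tuple((int(i), int(rng.integers(1, 5))) for i in idxs))
        docs_by_slice.append(docs)
    vocab = [f"w{v:04d}" for v in range(V)]
    return CorpusMatrix(vocabulary=vocab, docs_by_slice=docs_by_slice)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix() -> CorpusMatrix:
    """2 slices, 3 documents, V=4."""
    return CorpusMatrix(
        vocabulary=["attack", "failur", "heart", "stress"],
        docs_by_slice=[
            [((0, 1), (2, 2)), ((1, 1), (3, 2))],
            [((0, 2), (1, 1), (2, 1))],
        ],
    )
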