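"""Tokeniser, matrix construction and the two vocabulary filters.

The filters are checked against an independent brute-force oracle that
recomputes totals, document frequencies and tf-idf scores by direct
enumeration over (document, word) pairs, sharing no code with the
pipeline implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodtm.biodict import BioDictionary, build_dictionary
from biodtm.corpus_io import CorpusMatrix, Document
from biodtm.preprocess import (
    PreprocessError,
    TokenPipelineConfig,
    build_matrix,
    filter_tfidf,
    filter_total_frequency,
    tokenize,
)
from conftest import random_matrix


# ---------------------------------------------------------------- oracle

def oracle_total_frequency(matrix: CorpusMatrix, min_total: int) -> set[str]:
    """Surviving words, recomputed by enumeration."""
    totals: dict[str, int] = {}
    for docs in matrix.docs_by_slice:
        for doc in docs:
            for i, c in doc:
                w = matrix.vocabulary[i]
                totals[w] = totals.get(w, 0) + c
    return {w for w, tot in totals.items() if tot >= min_total}


def oracle_tfidf(matrix: CorpusMatrix, quantile: float, margin: float = 0.0) -> set[str]:
    """Surviving words under the tf-idf cut, recomputed by enumeration."""
    if not matrix.vocabulary:
        return set()
    tf: dict[str, int] = {}
    df: dict[str, int] = {}
    D = 0
    for docs in matrix.docs_by_slice:
        for doc in docs:
            D += 1
            for i, c in doc:
                w = matrix.vocabulary[i]
                tf[w] = tf.get(w, 0) + c
                df[w] = df.get(w, 0) + 1
    scores = {
        w: tf.get(w, 0) * (math.log(D / df[w]) if w in df else 0.0)
        for w in matrix.vocabulary
    }
    threshold = float(
        np.quantile(np.array([scores[w] for w in matrix.vocabulary]), quantile)
    ) + margin
    return {w for w in matrix.vocabulary if scores[w] > threshold}


def word_counts(matrix: CorpusMatrix) -> list[tuple[int, dict[str, int]]]:
    """(slice, {word: count}) per document, for index-free comparison."""
    out = []
    for t, docs in enumerate(matrix.docs_by_slice):
        for doc in docs:
            out.append((t, {matrix.vocabulary[i]: c for i, c in doc}))
    return out


# -------------------------------------------------------------- tokenize

class TestTokenize:
    def test_punctuation_and_hyphen_splitting(self):
        assert tokenize("Ginseng's anti-cancer effects.", stopwords=set()) == [
            "ginseng", "anti", "cancer", "effects",
        ]

    def test_alphanumeric_tokens_kept(self):
        assert tokenize("p38 and NF-kappaB", stopwords={"and"}) == [
            "p38", "nf", "kappab",
        ]

    def test_empty_input(self):
        assert tokenize("") == []

    def test_numeric_tokens_dropped(self):
        assert tokenize("12 mg 34 dose", stopwords=set()) == ["mg", "dose"]

    def test_default_stopwords_applied(self):
        assert tokenize("the heart and the lung") == ["heart", "lung"]


# ---------------------------------------------------------- build_matrix

def _doc(i, text, slice_index=1):
    return Document(record_id=str(i), title="", abstract=text, year=2000,
                    slice_index=slice_index)


NO_FILTERS = TokenPipelineConfig(stopwords=frozenset(), min_total_freq=1,
                                 tfidf_quantile=None)


class TestBuildMatrix:
    def test_counting(self):
        d = BioDictionary(frozenset({"heart", "attack"}), {})
        matrix, report = build_matrix([_doc(1, "heart heart attack")], d, NO_FILTERS)
        assert matrix.vocabulary == ["attack", "heart"]
        assert matrix.docs_by_slice == [[((0, 1), (1, 2))]]
        assert report.n_documents_out == 1

    def test_dictionary_restriction(self):
        d = BioDictionary(frozenset({"heart"}), {})
        matrix, _ = build_matrix([_doc(1, "heart heart attack")], d, NO_FILTERS)
        assert matrix.vocabulary == ["heart"]

    def test_title_and_abstract_both_count(self):
        d = BioDictionary(frozenset({"heart"}), {})
        doc = Document(record_id="1", title="heart", abstract="heart attack",
                       year=2000, slice_index=1)
        matrix, _ = build_matrix([doc], d, NO_FILTERS)
        assert matrix.docs_by_slice == [[((0, 2),)]]

    def test_tokens_are_stemmed_before_lookup(self):
        d = BioDictionary(frozenset({"memori"}), {})
        matrix, _ = build_matrix([_doc(1, "memory memories")], d, NO_FILTERS)
        assert matrix.vocabulary == ["memori"]
        # "memories" stems to "memori" as well
        assert matrix.docs_by_slice == [[((0, 2),)]]

    def test_empty_documents_dropped_and_reported(self):
        d = BioDictionary(frozenset({"heart"}), {})
        docs = [_doc(1, "heart"), _doc(2, "unrelated words only")]
        matrix, report = build_matrix(docs, d, NO_FILTERS)
        assert matrix.n_documents == 1
        assert report.empty_after_dictionary == 1
        assert report.n_documents_out == 1

    def test_empty_slice_raises_naming_slice(self):
        d = BioDictionary(frozenset({"heart"}), {})
        docs = [_doc(1, "heart", slice_index=1), _doc(2, "nothing", slice_index=2)]
        with pytest.raises(PreprocessError, match="slice 2"):
            build_matrix(docs, d, NO_FILTERS)

    def test_missing_slice_index_raises(self):
        d = BioDictionary(frozenset({"heart"}), {})
        doc = Document(record_id="1", title="", abstract="heart", year=2000)
        with pytest.raises(PreprocessError):
            build_matrix([doc], d, NO_FILTERS)

    def test_document_order_within_slice_is_input_order(self):
        d = BioDictionary(frozenset({"heart", "attack"}), {})
        docs = [_doc(1, "heart"), _doc(2, "attack")]
        matrix, _ = build_matrix(docs, d, NO_FILTERS)
        assert matrix.docs_by_slice[0] == [((1, 1),), ((0, 1),)]

    def test_pipeline_matches_oracle_on_toy_corpus(self):
        # six documents, both filters active
        d = build_dictionary(
            [("x", ["alpha beta gamma delta epsilon zeta eta"])], stopwords=set()
        )
        texts = [
            "alpha alpha beta",
            "alpha gamma",
            "beta beta delta",
            "alpha beta gamma delta",
            "epsilon epsilon epsilon",
            "alpha zeta",
        ]
        docs = [_doc(i, t, slice_index=1 + i % 2) for i, t in enumerate(texts)]
        cfg = TokenPipelineConfig(stopwords=frozenset(), min_total_freq=2,
                                  tfidf_quantile=0.25)
        matrix, _ = build_matrix(docs, d, cfg)

        # oracle: dictionary-restricted unfiltered matrix, then both cuts
        base, _ = build_matrix(docs, d, NO_FILTERS)
        survive1 = oracle_total_frequency(base, 2)
        inter = filter_total_frequency(base, 2)
        assert set(inter.vocabulary) == survive1
        survive2 = oracle_tfidf(inter, 0.25)
        assert set(matrix.vocabulary) == survive2


# -------------------------------------------------------------- filters

class TestTotalFrequencyFilter:
    def test_total_one_removed(self):
        m = CorpusMatrix(vocabulary=["a", "b"],
                         docs_by_slice=[[((0, 1), (1, 3))]])
        out = filter_total_frequency(m, 2)
        assert out.vocabulary == ["b"]
        assert out.docs_by_slice == [[((0, 3),)]]

    def test_all_totals_sufficient_is_identity(self, tiny_matrix):
        out = filter_total_frequency(tiny_matrix, 2)
        assert out == tiny_matrix

    def test_min_total_one_is_noop(self, tiny_matrix):
        assert filter_total_frequency(tiny_matrix, 1) == tiny_matrix

    def test_totals_summed_across_slices(self):
        # word 0 occurs once in each of two slices: total 2, survives
        m = CorpusMatrix(vocabulary=["a"],
                         docs_by_slice=[[((0, 1),)], [((0, 1),)]])
        assert filter_total_frequency(m, 2).vocabulary == ["a"]


class TestTfidfFilter:
    def test_word_in_every_document_removed(self):
        m = CorpusMatrix(
            vocabulary=["everywhere", "rare"],
            docs_by_slice=[[((0, 1), (1, 5)), ((0, 2),), ((0, 1),)]],
        )
        out = filter_tfidf(m, 0.0)
        assert "everywhere" not in out.vocabulary

    def test_quantile_zero_removes_only_minimum(self):
        # distinct positive scores: only the smallest is not > min
        m = CorpusMatrix(
            vocabulary=["a", "b", "c"],
            docs_by_slice=[[((0, 1), (1, 2)), ((1, 1), (2, 4)), ((2, 3),)]],
        )
        out = filter_tfidf(m, 0.0)
        scores = {}
        D = 3
        for w, tf, df in [("a", 1, 1), ("b", 3, 2), ("c", 7, 2)]:
            scores[w] = tf * math.log(D / df)
        assert len(set(scores.values())) == 3 and min(scores.values()) > 0
        expected = {w for w in scores if scores[w] > min(scores.values())}
        assert set(out.vocabulary) == expected

    def test_brute_force_oracle_on_handmade_corpus(self):
        m = CorpusMatrix(
            vocabulary=["a", "b", "c", "d"],
            docs_by_slice=[
                [((0, 3), (1, 1)), ((0, 1), (2, 2))],
                [((0, 2), (3, 1)), ((1, 2), (2, 1)), ((3, 4),)],
            ],
        )
        out = filter_tfidf(m, 0.25)
        assert set(out.vocabulary) == oracle_tfidf(m, 0.25)

    def test_bad_quantile_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            filter_tfidf(tiny_matrix, 1.0)


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10**6), min_total=st.integers(1, 4),
       quantile=st.floats(0.0, 0.9))
def test_filters_match_oracle_on_random_corpora(seed, min_total, quantile):
    m = random_matrix(np.random.default_rng(seed), max_docs_per_slice=3)
    out1 = filter_total_frequency(m, min_total)
    assert set(out1.vocabulary) == oracle_total_frequency(m, min_total)
    out2 = filter_tfidf(out1, quantile)
    assert set(out2.vocabulary) == oracle_tfidf(out1, quantile)
    # filters only shrink
    assert out2.V <= out1.V <= m.V
    assert out2.total_tokens() <= out1.total_tokens() <= m.total_tokens()
    # surviving documents keep their non-filtered words with counts intact
    for (t1, c1), (t2, c2) in zip(word_counts(m), word_counts(out2)):
        assert t1 == t2
        kept = set(out2.vocabulary)
        assert c2 == {w: c for w, c in c1.items() if w in kept}
    # every surviving word appears in >= 1 document
    seen = {w for _, counts in word_counts(out2) for w in counts}
    assert seen == set(out2.vocabulary)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_filter_output_invariant_to_doc_shuffling(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, max_docs_per_slice=4)
    shuffled = CorpusMatrix(
        vocabulary=list(m.vocabulary),
        docs_by_slice=[
            [docs[i] for i in rng.permutation(len(docs))] for docs in m.docs_by_slice
        ],
    )
    a = filter_tfidf(filter_total_frequency(m, 2), 0.25)
    b = filter_tfidf(filter_total_frequency(shuffled, 2), 0.25)
    assert set(a.vocabulary) == set(b.vocabulary)
    canon_a = sorted((t, tuple(sorted(c.items()))) for t, c in word_counts(a))
    canon_b = sorted((t, tuple(sorted(c.items()))) for t, c in word_counts(b))
    assert canon_a == canon_b
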