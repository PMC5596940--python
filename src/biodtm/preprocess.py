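"""Tokenisation, stemming and corpus-matrix construction with pruning filters.

The pipeline is: tokenize title+abstract, stem, keep only stems present
in the bio-dictionary, aggregate counts per document, then prune the
vocabulary by (1) a corpus-total frequency floor and (2) a tf-idf
quantile cut.  Documents emptied along the way are dropped and reported;
slices are never dropped (an empty slice is an error).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._stopwords import DEFAULT_STOPWORDS
from .biodict import BioDictionary
from .corpus_io import CorpusMatrix, Document
from .stemming import stem

__all__ = [
    "TokenPipelineConfig",
    "DropReport",
    "PreprocessError",
    "tokenize",
    "stem",
    "build_matrix",
    "filter_total_frequency",
    "filter_tfidf",
]

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


class PreprocessError(ValueError):
    """Raised when preprocessing produces an unusable corpus (e.g. empty slice)."""


@dataclass
class TokenPipelineConfig:
    """Knobs of the token pipeline and vocabulary filters.

    ``tfidf_quantile=None`` disables the tf-idf filter; ``min_total_freq=1``
    makes the frequency filter a no-op.  ``tfidf_margin`` is added to the
    quantile threshold ("a bit more than" the quartile); the default keeps
    the cut at exactly the quantile with a strict comparison.
    """

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    min_total_freq: int = 2
    tfidf_quantile: float | None = 0.25
    tfidf_margin: float = 0.0
    min_token_len: int = 2
    drop_numeric: bool = True

    def __post_init__(self) -> None:
        if self.min_total_freq < 1:
            raise ValueError("min_total_freq must be >= 1")
        if self.tfidf_quantile is not None and not 0.0 <= self.tfidf_quantile < 1.0:
            raise ValueError("tfidf_quantile must lie in [0, 1)")


@dataclass
class DropReport:
    """Documents dropped at each stage of build_matrix."""

    n_documents_in: int = 0
    empty_after_dictionary: int = 0
    empty_after_filters: int = 0
    n_documents_out: int = 0
    docs_per_slice: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def tokenize(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    min_token_len: int = 2,
    drop_numeric: bool = True,
) -> list[str]:
    """Lowercase and split on non-alphanumerics; drop stop words, purely
    numeric tokens and tokens shorter than ``min_token_len``."""
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    out = []
    for token in _TOKEN_RE.split(text.lower()):
        if len(token) < min_token_len:
            continue
        if drop_numeric and token.isdigit():
            continue
        if token in stopwords:
            continue
        out.append(token)
    return out


def _reindex(matrix: CorpusMatrix, keep: np.ndarray) -> CorpusMatrix:
    """New matrix containing only words where ``keep`` is True (dense reindex)."""
    old_to_new = -np.ones(matrix.V, dtype=int)
    old_to_new[keep] = np.arange(int(keep.sum()))
    vocabulary = [w for w, k in zip(matrix.vocabulary, keep) if k]
    docs_by_slice = []
    for docs in matrix.docs_by_slice:
        new_docs = []
        for doc in docs:
            new_doc = tuple(
                (int(old_to_new[i]), c) for i, c in doc if keep[i]
            )
            new_docs.append(new_doc)
        docs_by_slice.append(new_docs)
    return CorpusMatrix(vocabulary=vocabulary, docs_by_slice=docs_by_slice)


def _word_totals(matrix: CorpusMatrix) -> np.ndarray:
    totals = np.zeros(matrix.V, dtype=float)
    for _, doc in matrix.iter_documents():
        for i, c in doc:
            totals[i] += c
    return totals


def filter_total_frequency(matrix: CorpusMatrix, min_total: int) -> CorpusMatrix:
    """Remove words whose summed count over the whole corpus is < min_total."""
    totals = _word_totals(matrix)
    return _reindex(matrix, totals >= min_total)


def filter_tfidf(
    matrix: CorpusMatrix, quantile: float, margin: float = 0.0
) -> CorpusMatrix:
    """Keep words with tf-idf score strictly above the given quantile.

    score(w) = tf(w) * ln(D / df(w)) with tf the corpus-total count, df
    the number of documents containing w and D the total document count.
    The threshold is the linear-interpolation quantile of all scores,
    plus ``margin``.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    if matrix.V == 0:
        return matrix
    tf = np.zeros(matrix.V, dtype=float)
    df = np.zeros(matrix.V, dtype=float)
    D = 0
    for _, doc in matrix.iter_documents():
        D += 1
        for i, c in doc:
            tf[i] += c
            df[i] += 1
    if D == 0:
        return matrix
    with np.errstate(divide="ignore"):
        idf = np.where(df > 0, np.log(D / np.maximum(df, 1)), 0.0)
    scores = tf * idf
    threshold = float(np.quantile(scores, quantile)) + margin
    return _reindex(matrix, scores > threshold)


def build_matrix(
    docs: Sequence[Document],
    dictionary: BioDictionary,
    cfg: TokenPipelineConfig | None = None,
    n_slices: int | None = None,
) -> tuple[CorpusMatrix, DropReport]:
    """Turn sliced documents into a filtered, dictionary-restricted matrix.

    Every document must carry a 1-based ``slice_index``.  ``n_slices``
    defaults to the largest slice index present.
    """
    if cfg is None:
        cfg = TokenPipelineConfig()
    if not docs:
        raise PreprocessError("no documents to process")
    for doc in docs:
        if doc.slice_index is None:
            raise PreprocessError(f"document {doc.record_id} has no slice index")
    T = n_slices if n_slices is not None else max(d.slice_index for d in docs)

    report = DropReport(n_documents_in=len(docs))

    # dictionary-restricted per-document stem counts
    doc_counters: list[tuple[int, Counter]] = []
    for doc in docs:
        tokens = tokenize(
            doc.title + " " + doc.abstract,
            stopwords=cfg.stopwords,
            min_token_len=cfg.min_token_len,
            drop_numeric=cfg.drop_numeric,
        )
        counts = Counter(
            s for s in (stem(tok) for tok in tokens) if dictionary.contains(s)
        )
        if not counts:
            report.empty_after_dictionary += 1
        doc_counters.append((doc.slice_index, counts))

    vocabulary = sorted({w for _, c in doc_counters for w in c})
    if not vocabulary:
        raise PreprocessError("no document token qualifies in the dictionary")
    index = {w: i for i, w in enumerate(vocabulary)}

    docs_by_slice: list[list[tuple[tuple[int, int], ...]]] = [[] for _ in range(T)]
    for slice_index, counts in doc_counters:
        pairs = tuple(sorted((index[w], c) for w, c in counts.items()))
        docs_by_slice[slice_index - 1].append(pairs)
    matrix = CorpusMatrix(vocabulary=vocabulary, docs_by_slice=docs_by_slice)

    # vocabulary pruning: frequency floor first, then tf-idf.  Documents are
    # retained (possibly empty) throughout, so df and D keep their values
    # from the dictionary-restricted matrix.
    matrix = filter_total_frequency(matrix, cfg.min_total_freq)
    if cfg.tfidf_quantile is not None:
        matrix = filter_tfidf(matrix, cfg.tfidf_quantile, cfg.tfidf_margin)

    # drop emptied documents
    pruned: list[list[tuple[tuple[int, int], ...]]] = []
    n_out = 0
    n_empty_total = 0
    for docs_t in matrix.docs_by_slice:
        kept = [d for d in docs_t if d]
        n_empty_total += len(docs_t) - len(kept)
        n_out += len(kept)
        pruned.append(kept)
    report.empty_after_filters = n_empty_total - report.empty_after_dictionary
    report.n_documents_out = n_out
    matrix = CorpusMatrix(vocabulary=matrix.vocabulary, docs_by_slice=pruned)
    report.docs_per_slice = matrix.slice_sizes()

    for t, docs_t in enumerate(matrix.docs_by_slice, start=1):
        if not docs_t:
            raise PreprocessError(f"slice {t} has no surviving documents")
    matrix.validate()
    return matrix, report
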