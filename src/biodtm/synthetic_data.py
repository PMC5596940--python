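"""Synthetic corpora drawn from the exact generative process the model fits.

Ground truth is a set of K natural-parameter chains random-walking over
T slices; documents are LDA draws against the slice's topic-word
distributions.  Corpora can be emitted as pseudo-MEDLINE text plus a
matching term-list file so the whole ingestion pipeline (parsing,
dictionary restriction, matrix construction) can be exercised and
round-tripped without any external data.

Pseudo-words are ``w0000``-style tokens (letter + digits): Porter
stemming is the identity on them, so pipeline round-trips are isolated
from stemmer behaviour.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import CorpusMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticCorpus",
    "sample_ground_truth",
    "sample_corpus",
    "emit_pseudo_medline",
    "default_slice_years",
]


@dataclass(frozen=True)
class SyntheticSpec:
    K: int = 3
    V: int = 50
    T: int = 5
    docs_per_slice: int = 40
    mean_doc_length: float = 80.0
    drift_sd: float = 0.2
    alpha: float = 0.1
    init_sd: float = 1.0  # sd of the initial-slice noise around the base
    seed: int = 0
    slice_years: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if min(self.K, self.V, self.T, self.docs_per_slice) < 1:
            raise ValueError("K, V, T and docs_per_slice must be positive")
        if self.mean_doc_length <= 0:
            raise ValueError("mean_doc_length must be positive")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if self.slice_years is not None and len(self.slice_years) != self.T:
            raise ValueError("slice_years must provide one range per slice")


def default_slice_years(T: int, start: int = 1990, span: int = 2) -> tuple[tuple[int, int], ...]:
    """Contiguous ``span``-year ranges, one per slice, starting at ``start``."""
    return tuple(
        (start + t * span, start + (t + 1) * span - 1) for t in range(T)
    )


@dataclass
class GroundTruth:
    b: np.ndarray  # (K, T, V), mean-centred
    phi: np.ndarray  # (K, T, V)


@dataclass
class SyntheticCorpus:
    matrix: CorpusMatrix
    thetas: np.ndarray  # (D, K) true document mixtures
    doc_slices: np.ndarray  # (D,) 0-based
    token_words: list[np.ndarray]  # per doc, word index of each token in order
    token_topics: list[np.ndarray]  # per doc, topic of each token in order


def vocabulary_words(V: int) -> list[str]:
    return [f"w{v:04d}" for v in range(V)]


def distractor_words(V: int, fraction: float = 0.2) -> list[str]:
    n = int(np.ceil(V * fraction))
    return [f"xx{i:04d}" for i in range(n)]


def sample_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Seed-deterministic drifting chains: a shared centred log-frequency
    base, per-topic initial noise, then a Gaussian walk of sd ``drift_sd``."""
    rng = np.random.default_rng([spec.seed, 0])
    base_freq = rng.dirichlet(np.ones(spec.V))
    base = np.log(base_freq + 1.0 / spec.V)
    base -= base.mean()
    b = np.empty((spec.K, spec.T, spec.V))
    for k in range(spec.K):
        chain = base + rng.normal(0.0, spec.init_sd, size=spec.V)
        chain -= chain.mean()
        b[k, 0] = chain
        for t in range(1, spec.T):
            chain = chain + rng.normal(0.0, spec.drift_sd, size=spec.V)
            chain -= chain.mean()
            b[k, t] = chain
    z = b - b.max(axis=2, keepdims=True)
    phi = np.exp(z)
    phi /= phi.sum(axis=2, keepdims=True)
    return GroundTruth(b=b, phi=phi)


def sample_corpus(spec: SyntheticSpec, truth: GroundTruth) -> SyntheticCorpus:
    """Draw the documents: Poisson length (truncated >= 1), Dirichlet
    mixture, topic-then-word token sampling."""
    if truth.phi.shape != (spec.K, spec.T, spec.V):
        raise ValueError("ground truth does not match the spec dimensions")
    rng = np.random.default_rng([spec.seed, 1])
    thetas = []
    doc_slices = []
    token_words: list[np.ndarray] = []
    token_topics: list[np.ndarray] = []
    docs_by_slice: list[list[tuple[tuple[int, int], ...]]] = []
    for t in range(spec.T):
        slice_docs = []
        for _ in range(spec.docs_per_slice):
            length = max(1, int(rng.poisson(spec.mean_doc_length)))
            theta = rng.dirichlet(np.full(spec.K, spec.alpha))
            z = rng.choice(spec.K, size=length, p=theta)
            w = np.empty(length, dtype=np.int64)
            for k in range(spec.K):
                mask = z == k
                if mask.any():
                    w[mask] = rng.choice(spec.V, size=int(mask.sum()), p=truth.phi[k, t])
            thetas.append(theta)
            doc_slices.append(t)
            token_words.append(w)
            token_topics.append(z)
            counts = Counter(int(x) for x in w)
            slice_docs.append(tuple(sorted(counts.items())))
        docs_by_slice.append(slice_docs)
    matrix = CorpusMatrix(
        vocabulary=vocabulary_words(spec.V), docs_by_slice=docs_by_slice
    )
    matrix.validate()
    return SyntheticCorpus(
        matrix=matrix,
        thetas=np.asarray(thetas),
        doc_slices=np.asarray(doc_slices, dtype=np.int64),
        token_words=token_words,
        token_topics=token_topics,
    )


def _wrap_field(tag: str, text: str, width: int = 78) -> list[str]:
    """MEDLINE-style field emission with 6-space continuation lines,
    wrapping on token boundaries only."""
    lines = []
    current = f"{tag:<4}- "
    for token in text.split():
        candidate = token if current.endswith("- ") else " " + token
        if len(current) + len(candidate) > width and not current.endswith("- "):
            lines.append(current)
            current = "      " + token
        else:
            current += candidate
    lines.append(current)
    return lines


def emit_pseudo_medline(
    spec: SyntheticSpec,
    corpus: SyntheticCorpus,
    medline_path: str | Path,
    terms_path: str | Path,
) -> tuple[Path, Path]:
    """Write the corpus as MEDLINE records plus a term-list dictionary file.

    Each document's tokens are split between TI (the first few tokens,
    at most 5, always leaving the abstract non-empty) and AB (the rest),
    so title+abstract together carry every token exactly once and the
    ingestion pipeline with filters disabled reproduces the matrix.
    The term list holds the full vocabulary plus 20% distractor words
    that occur in no document.
    """
    if spec.slice_years is None:
        raise ValueError("spec.slice_years is required for text emission")
    medline_path = Path(medline_path)
    terms_path = Path(terms_path)
    vocab = corpus.matrix.vocabulary
    lines: list[str] = []
    pmid = 0
    for d, t in enumerate(corpus.doc_slices):
        pmid += 1
        tokens = [vocab[i] for i in corpus.token_words[d]]
        n_title = min(5, len(tokens) - 1)
        title_tokens = tokens[:n_title] if n_title > 0 else ["untitled", "record"]
        ab_tokens = tokens[n_title:]
        start, end = spec.slice_years[int(t)]
        year = start + (pmid % (end - start + 1))
        lines.extend(_wrap_field("PMID", str(pmid)))
        lines.extend(_wrap_field("TI", " ".join(title_tokens) + "."))
        lines.extend(_wrap_field("AB", " ".join(ab_tokens) + "."))
        lines.extend(_wrap_field("DP", f"{year} Jan"))
        lines.append("")
    medline_path.write_text("\n".join(lines), encoding="utf-8")
    with terms_path.open("w", encoding="utf-8") as fh:
        for w in vocab:
            fh.write(w + "\n")
        for w in distractor_words(len(vocab)):
            fh.write(w + "\n")
    return medline_path, terms_path
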