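"""Biomedical dictionary construction from pluggable term-list files.

The dictionary is a flat set of stemmed unigrams.  Multi-word terms are
split into individual words (the model is bag-of-single-words), each
unigram is lowercased, stripped of punctuation, stop-filtered, stemmed
and deduplicated across sources.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._stopwords import DEFAULT_STOPWORDS
from .stemming import stem

__all__ = [
    "BioDictionary",
    "EmptyDictionaryError",
    "build_dictionary",
    "load_term_file",
    "save_dictionary",
    "load_dictionary",
]

_SPLIT_RE = re.compile(r"[^0-9a-z]+")


class EmptyDictionaryError(ValueError):
    """Raised when no stem survives — an empty vocabulary is meaningless."""


@dataclass(frozen=True)
class BioDictionary:
    stems: frozenset[str]
    source_counts: dict[str, int]

    def contains(self, word_stem: str) -> bool:
        """True iff ``word_stem`` (already stemmed) is in the dictionary."""
        return word_stem in self.stems

    def __contains__(self, word_stem: str) -> bool:
        return word_stem in self.stems

    def __len__(self) -> int:
        return len(self.stems)


def _term_unigrams(term: str, stopwords: frozenset[str] | set[str]) -> Iterable[str]:
    for token in _SPLIT_RE.split(term.lower()):
        if len(token) < 2:  # single letters are noise from gene symbols
            continue
        if token.isdigit():
            continue
        if token in stopwords:
            continue
        s = stem(token)
        # keep the invariant that no stem is itself a stop word
        if s in stopwords or len(s) < 2 or s.isdigit():
            continue
        yield s


def build_dictionary(
    term_lists: Sequence[tuple[str, Sequence[str]]],
    stopwords: frozenset[str] | set[str] | None = None,
) -> BioDictionary:
    """Union the stemmed unigrams of all sources into one dictionary.

    Parameters
    ----------
    term_lists:
        ``(source_name, terms)`` pairs; terms may be multi-word phrases.
    stopwords:
        Words excluded before stemming (defaults to the bundled English
        list; pass an empty set to disable).
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    stems: set[str] = set()
    source_counts: dict[str, int] = {}
    for name, terms in term_lists:
        count = 0
        for term in terms:
            if not term.strip():
                continue
            count += 1
            stems.update(_term_unigrams(term, stopwords))
        source_counts[name] = source_counts.get(name, 0) + count
    if not stems:
        raise EmptyDictionaryError("no stems survive: dictionary would be empty")
    return BioDictionary(stems=frozenset(stems), source_counts=source_counts)


def load_term_file(path: str | Path) -> tuple[str, list[str]]:
    """Read a one-term-per-line UTF-8 file; source name is the file stem."""
    p = Path(path)
    terms = [line.rstrip("\n") for line in p.open(encoding="utf-8")]
    return p.stem, [t for t in terms if t.strip()]


def save_dictionary(dictionary: BioDictionary, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.dict`` (one stem per line, sorted) and a JSON sidecar."""
    stems_path = Path(str(path_prefix) + ".dict")
    meta_path = Path(str(path_prefix) + ".dict.json")
    with stems_path.open("w", encoding="utf-8") as fh:
        for s in sorted(dictionary.stems):
            fh.write(s + "\n")
    with meta_path.open("w", encoding="utf-8") as fh:
        json.dump(
            {"n_stems": len(dictionary), "source_counts": dictionary.source_counts},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return stems_path, meta_path


def load_dictionary(path: str | Path) -> BioDictionary:
    """Read a stems file written by :func:`save_dictionary` (sidecar optional)."""
    stems_path = Path(path)
    stems = frozenset(
        line.strip() for line in stems_path.open(encoding="utf-8") if line.strip()
    )
    if not stems:
        raise EmptyDictionaryError(f"{stems_path}: empty dictionary file")
    meta_path = Path(str(stems_path) + ".json")
    source_counts: dict[str, int] = {}
    if meta_path.exists():
        with meta_path.open(encoding="utf-8") as fh:
            source_counts = json.load(fh).get("source_counts", {})
    return BioDictionary(stems=stems, source_counts=source_counts)
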