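"""MEDLINE record parsing, time-slice assignment and the sparse corpus format.

The corpus exchange format is the LDA-C style triplet:

* ``<prefix>-mult.dat`` — one document per line, ``U idx1:cnt1 ... idxU:cntU``
  where ``U`` is the number of unique words in the document and word
  indices are 0-based;
* ``<prefix>-seq.dat`` — first line the number of slices ``T``, then one
  line per slice with its document count (documents in the mult file are
  slice-major, in slice order);
* ``<prefix>-vocab.dat`` — one word per line, in index order.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "Document",
    "SliceConfig",
    "CorpusMatrix",
    "ParseReport",
    "MedlineParseError",
    "CorpusFormatError",
    "DEFAULT_SLICE_CONFIG",
    "parse_medline",
    "assign_slices",
    "write_corpus",
    "read_corpus",
]


class MedlineParseError(ValueError):
    """Raised for a line that is neither a tag line nor a continuation."""


class CorpusFormatError(ValueError):
    """Raised when the corpus triplet files are mutually inconsistent."""


@dataclass
class Document:
    """One parsed literature record."""

    record_id: str
    title: str
    abstract: str
    year: int
    slice_index: int | None = None  # 1-based, set by assign_slices


@dataclass(frozen=True)
class SliceConfig:
    """Ordered, non-overlapping inclusive year ranges defining time slices."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.ranges) < 2:
            raise ValueError("at least two slices are required")
        prev_end = None
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"bad slice range ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError("slice ranges must be strictly ascending and disjoint")
            prev_end = end

    @property
    def T(self) -> int:
        return len(self.ranges)

    def slice_for_year(self, year: int) -> int | None:
        """1-based slice index containing ``year``, or None if outside all ranges."""
        for i, (start, end) in enumerate(self.ranges, start=1):
            if start <= year <= end:
                return i
        return None

    def labels(self) -> list[str]:
        return [f"{s}-{e}" if s != e else str(s) for s, e in self.ranges]


#: Four multi-year slices (1975-1995, 1996-2000, 2001-2003, 2004-2005)
#: followed by single-year slices 2006..2017 — sixteen in total.
DEFAULT_SLICE_CONFIG = SliceConfig(
    ((1975, 1995), (1996, 2000), (2001, 2003), (2004, 2005))
    + tuple((y, y) for y in range(2006, 2018))
)


@dataclass
class CorpusMatrix:
    """Per-slice sparse bag-of-words counts over an indexed vocabulary.

    ``docs_by_slice[t]`` holds the documents of slice ``t`` (0-based
    internally; public APIs that take a slice index are 1-based).  Each
    document is a sorted tuple of ``(word_index, count)`` pairs.
    """

    vocabulary: list[str]
    docs_by_slice: list[list[tuple[tuple[int, int], ...]]]

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def T(self) -> int:
        return len(self.docs_by_slice)

    @property
    def n_documents(self) -> int:
        return sum(len(docs) for docs in self.docs_by_slice)

    def slice_sizes(self) -> list[int]:
        return [len(docs) for docs in self.docs_by_slice]

    def total_tokens(self) -> int:
        return sum(
            c for docs in self.docs_by_slice for doc in docs for _, c in doc
        )

    def iter_documents(self) -> Iterator[tuple[int, tuple[tuple[int, int], ...]]]:
        """Yield ``(slice_index_0based, doc)`` in slice-major order."""
        for t, docs in enumerate(self.docs_by_slice):
            for doc in docs:
                yield t, doc

    def validate(self) -> None:
        V = self.V
        for t, docs in enumerate(self.docs_by_slice):
            for doc in docs:
                seen = set()
                for idx, cnt in doc:
                    if not 0 <= idx < V:
                        raise ValueError(f"word index {idx} out of range in slice {t + 1}")
                    if cnt < 1:
                        raise ValueError(f"count {cnt} < 1 in slice {t + 1}")
                    if idx in seen:
                        raise ValueError(f"duplicate word index {idx} in slice {t + 1}")
                    seen.add(idx)


@dataclass
class ParseReport:
    """Bookkeeping for parse_medline: every record is parsed or skipped."""

    n_records: int = 0
    n_documents: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())

    def _skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s{0,2}- (.*)$")
_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _finish_record(
    fields: dict[str, list[str]], report: ParseReport
) -> Document | None:
    report.n_records += 1
    pmid = fields.get("PMID")
    title = fields.get("TI")
    abstract = fields.get("AB")
    dp = fields.get("DP")
    if abstract is None:
        report._skip("no_abstract")
        return None
    if title is None:
        report._skip("no_title")
        return None
    if pmid is None:
        report._skip("no_pmid")
        return None
    year = None
    if dp is not None:
        m = _YEAR_RE.search(" ".join(dp))
        if m:
            year = int(m.group(1))
    if year is None:
        report._skip("no_year")
        return None
    report.n_documents += 1
    return Document(
        record_id=" ".join(pmid),
        title=" ".join(title),
        abstract=" ".join(abstract),
        year=year,
    )


def parse_medline(stream: Iterable[str] | IO[str]) -> tuple[list[Document], ParseReport]:
    """Parse a PubMed MEDLINE-format export into documents.

    ``stream`` is any iterable of lines.  A record starts at a ``PMID``
    tag line; continuation lines (leading whitespace) are folded into the
    preceding field with a single space.  Records lacking an abstract, a
    title, a PMID or a parseable 4-digit year are skipped and counted.
    """
    report = ParseReport()
    docs: list[Document] = []
    fields: dict[str, list[str]] | None = None
    current_tag: str | None = None

    def flush() -> None:
        nonlocal fields, current_tag
        if fields is not None:
            doc = _finish_record(fields, report)
            if doc is not None:
                docs.append(doc)
        fields = None
        current_tag = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            flush()
            continue
        if line[0].isspace():
            # continuation of the previous field
            if fields is None or current_tag is None:
                raise MedlineParseError(
                    f"line {lineno}: continuation line outside any record"
                )
            fields[current_tag][-1] += " " + line.strip()
            continue
        m = _TAG_RE.match(line)
        if m is None:
            raise MedlineParseError(f"line {lineno}: malformed tag line: {line!r}")
        tag, value = m.group(1), m.group(2)
        if tag == "PMID":
            flush()
            fields = {}
        elif fields is None:
            raise MedlineParseError(
                f"line {lineno}: tag line {tag!r} outside any record"
            )
        fields.setdefault(tag, []).append(value.strip())
        current_tag = tag
    flush()
    return docs, report


def assign_slices(
    docs: Sequence[Document], cfg: SliceConfig
) -> tuple[list[Document], int]:
    """Attach slice indices; documents outside every range are dropped.

    Returns the retained documents (copies, with ``slice_index`` set)
    and the number of dropped documents.
    """
    kept: list[Document] = []
    dropped = 0
    for doc in docs:
        idx = cfg.slice_for_year(doc.year)
        if idx is None:
            dropped += 1
            continue
        kept.append(dataclasses.replace(doc, slice_index=idx))
    return kept, dropped


def _paths(path_prefix: str | Path) -> tuple[Path, Path, Path]:
    prefix = str(path_prefix)
    return (
        Path(prefix + "-mult.dat"),
        Path(prefix + "-seq.dat"),
        Path(prefix + "-vocab.dat"),
    )


def write_corpus(matrix: CorpusMatrix, path_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write the corpus triplet; returns the three paths written."""
    matrix.validate()
    mult_path, seq_path, vocab_path = _paths(path_prefix)
    with open(mult_path, "w") as fh:
        for _, doc in matrix.iter_documents():
            parts = [str(len(doc))] + [f"{i}:{c}" for i, c in doc]
            fh.write(" ".join(parts) + "\n")
    with open(seq_path, "w") as fh:
        fh.write(f"{matrix.T}\n")
        for n in matrix.slice_sizes():
            fh.write(f"{n}\n")
    with open(vocab_path, "w") as fh:
        for word in matrix.vocabulary:
            fh.write(word + "\n")
    return mult_path, seq_path, vocab_path


def read_corpus(path_prefix: str | Path) -> CorpusMatrix:
    """Read the corpus triplet written by :func:`write_corpus`."""
    mult_path, seq_path, vocab_path = _paths(path_prefix)
    vocabulary = [line.rstrip("\n") for line in open(vocab_path)]
    seq_lines = [line.strip() for line in open(seq_path) if line.strip()]
    if not seq_lines:
        raise CorpusFormatError(f"{seq_path}: empty sequence file")
    T = int(seq_lines[0])
    slice_sizes = [int(x) for x in seq_lines[1:]]
    if len(slice_sizes) != T:
        raise CorpusFormatError(
            f"{seq_path}: header says {T} slices but {len(slice_sizes)} counts follow"
        )
    docs: list[tuple[tuple[int, int], ...]] = []
    with open(mult_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            u = int(parts[0])
            pairs = []
            for token in parts[1:]:
                idx_s, cnt_s = token.split(":")
                pairs.append((int(idx_s), int(cnt_s)))
            if len(pairs) != u:
                raise CorpusFormatError(
                    f"{mult_path}:{lineno}: declared {u} words but found {len(pairs)}"
                )
            docs.append(tuple(pairs))
    if sum(slice_sizes) != len(docs):
        raise CorpusFormatError(
            f"sequence file totals {sum(slice_sizes)} documents "
            f"but {mult_path} has {len(docs)} lines"
        )
    docs_by_slice: list[list[tuple[tuple[int, int], ...]]] = []
    pos = 0
    for n in slice_sizes:
        docs_by_slice.append(docs[pos : pos + n])
        pos += n
    matrix = CorpusMatrix(vocabulary=vocabulary, docs_by_slice=docs_by_slice)
    matrix.validate()
    return matrix
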