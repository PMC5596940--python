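"""Top-word extraction and per-slice topic strengths.

Topic strength at a slice is the token-weighted expected topic share:
the expected fraction of the slice's tokens assigned to the topic under
the fitted posteriors.  Strengths therefore sum to one within each slice,
which is what makes the downstream river layout mass-conserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import CorpusMatrix
from .dtm_core import DocPosterior, DTMModel

__all__ = [
    "TopicStrengthMatrix",
    "top_words",
    "overall_top_words",
    "topic_strength",
    "export_topic_table",
    "write_strengths",
    "read_strengths",
]


@dataclass
class TopicStrengthMatrix:
    """s[k, t]: strength of topic k at slice t; columns sum to 1."""

    s: np.ndarray  # (K, T)

    @property
    def K(self) -> int:
        return self.s.shape[0]

    @property
    def T(self) -> int:
        return self.s.shape[1]

    def validate(self) -> None:
        if np.any(self.s < 0):
            raise ValueError("strengths must be non-negative")
        col = self.s.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-10):
            raise ValueError("strengths must sum to 1 within each slice")


def _ranked_indices(scores: np.ndarray) -> list[int]:
    # descending score, ties broken by ascending word index
    return sorted(range(len(scores)), key=lambda v: (-scores[v], v))


def top_words(model: DTMModel, k: int, t: int, n: int) -> list[str]:
    """The ``n`` highest-probability words of topic ``k`` at slice ``t``
    (both 1-based), descending; ties broken by ascending word index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= k <= model.K:
        raise IndexError(f"topic index {k} outside [1, {model.K}]")
    if not 1 <= t <= model.T:
        raise IndexError(f"slice index {t} outside [1, {model.T}]")
    if model.vocabulary is None:
        raise ValueError("model carries no vocabulary")
    phi = np.exp(model.log_phi()[k - 1, t - 1])
    order = _ranked_indices(phi)[:n]
    return [model.vocabulary[i] for i in order]


def overall_top_words(model: DTMModel, k: int, n: int) -> list[str]:
    """Whole-period summary: words ranked by the mean of phi over slices."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= k <= model.K:
        raise IndexError(f"topic index {k} outside [1, {model.K}]")
    if model.vocabulary is None:
        raise ValueError("model carries no vocabulary")
    mean_phi = np.exp(model.log_phi()[k - 1]).mean(axis=0)
    order = _ranked_indices(mean_phi)[:n]
    return [model.vocabulary[i] for i in order]


def topic_strength(
    model: DTMModel, posterior: DocPosterior, matrix: CorpusMatrix
) -> TopicStrengthMatrix:
    """Expected token share of each topic within each slice."""
    K, T = model.K, model.T
    mass = np.zeros((K, T))
    tokens = np.zeros(T)
    for d, t in enumerate(posterior.doc_slices):
        c = posterior.doc_counts[d]
        r = posterior.resp[d]
        mass[:, t] += c @ r
        tokens[t] += c.sum()
    if np.any(tokens == 0):
        empty = int(np.argwhere(tokens == 0).ravel()[0]) + 1
        raise ValueError(f"slice {empty} has no tokens")
    s = mass / tokens[None, :]
    ts = TopicStrengthMatrix(s=s)
    ts.validate()
    return ts


def export_topic_table(
    model: DTMModel, n: int, path_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>-topics.csv`` (one row per topic, overall top-n
    words) and ``<prefix>-topic-slices.csv`` (long format: topic, slice,
    rank, word, probability)."""
    prefix = str(path_prefix)
    summary_path = Path(prefix + "-topics.csv")
    long_path = Path(prefix + "-topic-slices.csv")
    if model.vocabulary is None:
        raise ValueError("model carries no vocabulary")

    rows = [
        {"topic": k, "top_words": ", ".join(overall_top_words(model, k, n))}
        for k in range(1, model.K + 1)
    ]
    pd.DataFrame(rows).to_csv(summary_path, index=False)

    phi = np.exp(model.log_phi())
    long_rows = []
    for k in range(1, model.K + 1):
        for t in range(1, model.T + 1):
            probs = phi[k - 1, t - 1]
            order = _ranked_indices(probs)[: min(n, model.V)]
            for rank, v in enumerate(order, start=1):
                long_rows.append(
                    {
                        "topic": k,
                        "slice": t,
                        "rank": rank,
                        "word": model.vocabulary[v],
                        "probability": probs[v],
                    }
                )
    pd.DataFrame(long_rows).to_csv(
        long_path, index=False, float_format="%.10g"
    )
    return summary_path, long_path


def write_strengths(
    strengths: TopicStrengthMatrix,
    path: str | Path,
    slice_labels: list[str] | None = None,
) -> None:
    """T x K CSV, one row per slice, columns topic_1..topic_K."""
    labels = slice_labels if slice_labels is not None else [
        str(t) for t in range(1, strengths.T + 1)
    ]
    df = pd.DataFrame(
        strengths.s.T,
        index=pd.Index(labels, name="slice"),
        columns=[f"topic_{k}" for k in range(1, strengths.K + 1)],
    )
    df.to_csv(path, float_format="%.10g")


def read_strengths(path: str | Path) -> tuple[TopicStrengthMatrix, list[str]]:
    df = pd.read_csv(path, index_col=0)
    ts = TopicStrengthMatrix(s=df.to_numpy().T)
    ts.validate()
    return ts, [str(x) for x in df.index]
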