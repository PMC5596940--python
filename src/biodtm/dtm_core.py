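"""Dynamic topic model: drifting topic-word distributions over time slices.

Model
-----
Each topic ``k`` is a chain of natural-parameter vectors ``b[k][t]`` of
length ``V``; the topic-word distribution at slice ``t`` is
``phi[k][t] = softmax(b[k][t])``.  Adjacent slices are tied by a
Gaussian random walk with variance ``sigma2`` (variance ``sigma0_2`` on
the initial slice), so topics at one slice evolve smoothly from the
previous slice.  Documents are standard LDA: a Dirichlet(alpha) topic
mixture and per-token topic assignments.

Inference
---------
Variational EM.  The E-step is exact LDA mean-field per document
(responsibilities ``r`` and Dirichlet parameters ``gamma``), using the
current slice's ``phi``.  The M-step maximises, per topic, the expected
word log-likelihood minus the Gaussian chain penalties over the whole
chain ``b[k]`` by proximal gradient ascent with a backtracking line
search: the smooth multinomial term is linearised while the quadratic
chain penalty is handled exactly by a banded solve, which keeps the
update stable even for very stiff chains (tiny ``sigma2``).  Natural
parameters are mean-centred after every accepted step (softmax is
shift-invariant; centring pins the gauge and never decreases the
objective).

The tracked objective is the variational bound: the document terms of
the LDA bound (excluding the word likelihood) plus the per-topic chain
objectives ``J_k`` (which contain the word likelihood and penalties).
It is non-decreasing across EM iterations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, log_softmax, logsumexp, xlogy

from .corpus_io import CorpusMatrix

__all__ = [
    "FitConfig",
    "DTMModel",
    "DocPosterior",
    "SuffStats",
    "FitResult",
    "init_model",
    "e_step",
    "m_step",
    "fit",
    "log_topic_distribution",
    "matched_mean_tv",
    "total_variation",
    "save_model",
    "load_model",
]


@dataclass
class FitConfig:
    K: int = 20
    alpha: float = 0.1
    sigma2: float = 0.005
    sigma0_2: float = 1.0
    max_iter: int = 100
    conv_tol: float = 1e-4
    e_tol: float = 1e-4
    e_max_inner: int = 100
    m_tol: float = 1e-3
    m_max_inner: int = 200
    init_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.sigma2 <= 0 or self.sigma0_2 <= 0:
            raise ValueError("variances must be positive")
        if min(self.conv_tol, self.e_tol, self.m_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DTMModel:
    """Natural-parameter chains; ``b`` has shape (K, T, V), mean-centred."""

    b: np.ndarray
    alpha: float
    sigma2: float
    sigma0_2: float
    vocabulary: list[str] | None = None
    _log_phi: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def K(self) -> int:
        return self.b.shape[0]

    @property
    def T(self) -> int:
        return self.b.shape[1]

    @property
    def V(self) -> int:
        return self.b.shape[2]

    def log_phi(self) -> np.ndarray:
        """(K, T, V) log topic-word distributions; cached."""
        if self._log_phi is None:
            self._log_phi = log_softmax(self.b, axis=2)
        return self._log_phi

    def phi(self) -> np.ndarray:
        return np.exp(self.log_phi())


@dataclass
class DocPosterior:
    """Variational posteriors, documents in slice-major corpus order."""

    gamma: np.ndarray  # (D, K)
    resp: list[np.ndarray]  # per doc (U_d, K), rows sum to 1
    doc_slices: np.ndarray  # (D,) 0-based slice of each doc
    doc_words: list[np.ndarray]  # per doc unique word indices (U_d,)
    doc_counts: list[np.ndarray]  # per doc counts aligned with doc_words


@dataclass
class SuffStats:
    """n[k, t, v] = expected count of word v assigned to topic k in slice t."""

    n: np.ndarray  # (K, T, V)

    @property
    def N(self) -> np.ndarray:
        """(K, T) per-topic per-slice expected token totals."""
        return self.n.sum(axis=2)


@dataclass
class FitResult:
    model: DTMModel
    posterior: DocPosterior
    trace: list[float]


def _doc_arrays(
    matrix: CorpusMatrix,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    slices, words, counts = [], [], []
    for t, doc in matrix.iter_documents():
        slices.append(t)
        words.append(np.fromiter((i for i, _ in doc), dtype=np.int64, count=len(doc)))
        counts.append(np.fromiter((c for _, c in doc), dtype=np.float64, count=len(doc)))
    return np.asarray(slices, dtype=np.int64), words, counts


def init_model(matrix: CorpusMatrix, cfg: FitConfig) -> DTMModel:
    """Seed-deterministic init: centred log corpus frequencies plus
    per-topic Gaussian noise, constant across slices."""
    matrix.validate()
    V, T = matrix.V, matrix.T
    totals = np.zeros(V)
    for _, doc in matrix.iter_documents():
        for i, c in doc:
            totals[i] += c
    total_tokens = totals.sum()
    if cfg.K > total_tokens:
        raise ValueError(f"K={cfg.K} exceeds the total token count {int(total_tokens)}")
    freq = totals / total_tokens
    base = np.log(freq + 1.0 / V)
    base -= base.mean()
    rng = np.random.default_rng(cfg.seed)
    b = np.empty((cfg.K, T, V))
    for k in range(cfg.K):
        noise = (
            rng.normal(0.0, cfg.init_noise_sd, size=V)
            if cfg.init_noise_sd > 0 and cfg.K > 1
            else np.zeros(V)
        )
        chain = base + noise
        chain -= chain.mean()
        b[k, :, :] = chain[None, :]
    return DTMModel(b=b, alpha=cfg.alpha, sigma2=cfg.sigma2, sigma0_2=cfg.sigma0_2,
                    vocabulary=list(matrix.vocabulary))


def e_step(
    model: DTMModel,
    matrix: CorpusMatrix,
    cfg: FitConfig | None = None,
    _docs: tuple | None = None,
    warm_gamma: np.ndarray | None = None,
) -> tuple[DocPosterior, SuffStats, float]:
    """LDA mean-field coordinate ascent per document.

    Returns posteriors, expected-count sufficient statistics, and the
    document terms of the variational bound (everything except the word
    log-likelihood, which lives in the M-step objective).

    ``warm_gamma`` (from the previous EM iteration) seeds the per-document
    loop; warm starts make the EM surrogate objective exactly monotone
    rather than monotone only up to inner-loop truncation error.
    """
    if cfg is None:
        cfg = FitConfig(K=model.K, alpha=model.alpha,
                        sigma2=model.sigma2, sigma0_2=model.sigma0_2)
    K = model.K
    alpha = model.alpha
    log_phi = model.log_phi()
    doc_slices, doc_words, doc_counts = (
        _docs if _docs is not None else _doc_arrays(matrix)
    )
    D = len(doc_slices)
    gamma_all = np.empty((D, K))
    resp: list[np.ndarray] = []
    n = np.zeros((K, model.T, model.V))
    e_obj = 0.0
    const_theta = gammaln(K * alpha) - K * gammaln(alpha)
    for d in range(D):
        t = int(doc_slices[d])
        w = doc_words[d]
        c = doc_counts[d]
        lp = log_phi[:, t, :][:, w].T  # (U, K)
        total = c.sum()
        gamma = (
            warm_gamma[d].copy()
            if warm_gamma is not None
            else np.full(K, alpha + total / K)
        )
        r = np.full((len(w), K), 1.0 / K)
        for _ in range(cfg.e_max_inner):
            log_r = lp + digamma(gamma)[None, :]
            log_r -= logsumexp(log_r, axis=1, keepdims=True)
            r = np.exp(log_r)
            gamma_new = alpha + c @ r
            delta = np.abs(gamma_new - gamma).max()
            gamma = gamma_new
            if delta < cfg.e_tol:
                break
        gamma_all[d] = gamma
        resp.append(r)
        n[:, t, :][:, w] += (c[:, None] * r).T
        # bound terms (excluding E[log p(w|z)])
        psi = digamma(gamma) - digamma(gamma.sum())
        e_obj += (
            const_theta
            + float((alpha - gamma) @ psi)
            + float(gammaln(gamma).sum() - gammaln(gamma.sum()))
            + float(c @ (r @ psi))
            - float((c[:, None] * xlogy(r, r)).sum())
        )
    posterior = DocPosterior(
        gamma=gamma_all, resp=resp, doc_slices=doc_slices,
        doc_words=doc_words, doc_counts=doc_counts,
    )
    return posterior, SuffStats(n=n), e_obj


def _chain_penalty_matrix(T: int, sigma2: float, sigma0_2: float) -> np.ndarray:
    """T x T matrix Q with penalty = 0.5 * sum_v b[:,v]^T Q b[:,v]."""
    Q = np.zeros((T, T))
    for t in range(1, T):
        Q[t, t] += 1.0 / sigma2
        Q[t - 1, t - 1] += 1.0 / sigma2
        Q[t, t - 1] -= 1.0 / sigma2
        Q[t - 1, t] -= 1.0 / sigma2
    Q[0, 0] += 1.0 / sigma0_2
    return Q


def _chain_objective(b: np.ndarray, n: np.ndarray, Q: np.ndarray) -> float:
    """J_k = sum_t n_t . log softmax(b_t) - 0.5 * tr(b^T Q b)."""
    log_phi = log_softmax(b, axis=1)
    ll = float((n * log_phi).sum())
    pen = 0.5 * float(np.einsum("tv,ts,sv->", b, Q, b))
    return ll - pen


def chain_objective_total(model: DTMModel, stats: SuffStats) -> float:
    """Sum of J_k over topics for the current model parameters."""
    Q = _chain_penalty_matrix(model.T, model.sigma2, model.sigma0_2)
    return sum(
        _chain_objective(model.b[k], stats.n[k], Q) for k in range(model.K)
    )


def _maximize_chain(
    b0: np.ndarray, n: np.ndarray, Q: np.ndarray, tol: float, max_inner: int
) -> tuple[np.ndarray, float]:
    """Proximal gradient ascent on one topic chain (T, V)."""
    T = b0.shape[0]
    b = b0 - b0.mean(axis=1, keepdims=True)
    N = n.sum(axis=1)  # (T,)
    eta = 1.0 / (N.max() + 1.0)
    factors: dict[float, tuple] = {}

    def f_and_grad(bb):
        log_phi = log_softmax(bb, axis=1)
        f = float((n * log_phi).sum())
        grad = n - N[:, None] * np.exp(log_phi)
        return f, grad

    f, grad_f = f_and_grad(b)
    for _ in range(max_inner):
        grad_J = grad_f - Q @ b
        if np.abs(grad_J).max() < tol:
            break
        accepted = False
        for _ in range(60):
            if eta not in factors:
                factors[eta] = cho_factor(Q + np.eye(T) / eta)
            b_new = cho_solve(factors[eta], b / eta + grad_f)
            b_new -= b_new.mean(axis=1, keepdims=True)
            step = b_new - b
            f_new, grad_new = f_and_grad(b_new)
            # sufficient increase of the smooth part guarantees ascent of J
            if f_new >= f + float((grad_f * step).sum()) - float((step * step).sum()) / (2 * eta) - 1e-12:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            break
        b, f, grad_f = b_new, f_new, grad_new
        eta *= 2.0
    J = float((n * log_softmax(b, axis=1)).sum()) - 0.5 * float(
        np.einsum("tv,ts,sv->", b, Q, b)
    )
    return b, J


def m_step(
    model: DTMModel, stats: SuffStats, cfg: FitConfig | None = None
) -> tuple[DTMModel, float]:
    """MAP update of every topic chain; returns the new model and sum_k J_k."""
    if cfg is None:
        cfg = FitConfig(K=model.K, alpha=model.alpha,
                        sigma2=model.sigma2, sigma0_2=model.sigma0_2)
    Q = _chain_penalty_matrix(model.T, model.sigma2, model.sigma0_2)
    b_new = np.empty_like(model.b)
    total_J = 0.0
    for k in range(model.K):
        bk, Jk = _maximize_chain(model.b[k], stats.n[k], Q, cfg.m_tol, cfg.m_max_inner)
        if not np.isfinite(Jk) or not np.all(np.isfinite(bk)):
            bad_t = int(np.argwhere(~np.isfinite(bk).all(axis=1)).ravel()[0]) + 1 \
                if not np.all(np.isfinite(bk)) else 0
            raise FloatingPointError(
                f"non-finite M-step objective for topic {k + 1}, slice {bad_t}"
            )
        b_new[k] = bk
        total_J += Jk
    updated = DTMModel(
        b=b_new, alpha=model.alpha, sigma2=model.sigma2,
        sigma0_2=model.sigma0_2, vocabulary=model.vocabulary,
    )
    return updated, total_J


def fit(matrix: CorpusMatrix, cfg: FitConfig) -> FitResult:
    """Alternate E and M steps until the bound's relative change is below
    ``cfg.conv_tol`` or ``cfg.max_iter`` iterations."""
    matrix.validate()
    model = init_model(matrix, cfg)
    docs = _doc_arrays(matrix)
    trace: list[float] = []
    posterior = None
    prev = None
    warm = None
    for _ in range(cfg.max_iter):
        posterior, stats, e_obj = e_step(model, matrix, cfg, _docs=docs,
                                         warm_gamma=warm)
        warm = posterior.gamma
        obj = e_obj + chain_objective_total(model, stats)
        trace.append(obj)
        if prev is not None and abs(obj - prev) <= cfg.conv_tol * abs(prev):
            break
        prev = obj
        model, _ = m_step(model, stats, cfg)
    else:
        posterior, stats, e_obj = e_step(model, matrix, cfg, _docs=docs,
                                         warm_gamma=warm)
        trace.append(e_obj + chain_objective_total(model, stats))
    return FitResult(model=model, posterior=posterior, trace=trace)


def log_topic_distribution(model: DTMModel, k: int, t: int) -> np.ndarray:
    """phi[k][t] as a probability vector; ``k`` in [1, K], ``t`` in [1, T]."""
    if not 1 <= k <= model.K:
        raise IndexError(f"topic index {k} outside [1, {model.K}]")
    if not 1 <= t <= model.T:
        raise IndexError(f"slice index {t} outside [1, {model.T}]")
    return np.exp(model.log_phi()[k - 1, t - 1])


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance, half the L1 difference, along the last axis."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def matched_mean_tv(phi_true: np.ndarray, phi_est: np.ndarray) -> float:
    """Hungarian-matched mean TV distance between two (K, T, V) phi arrays."""
    phi_true = np.asarray(phi_true)
    phi_est = np.asarray(phi_est)
    K = phi_true.shape[0]
    cost = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = 0.5 * np.abs(phi_true[i] - phi_est[j]).sum(axis=1).mean()
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def save_model(
    result: FitResult, path_prefix: str | Path, cfg: FitConfig | None = None,
    extra_manifest: dict | None = None,
) -> None:
    """Write phi/b arrays (npz), a JSON manifest and the gamma table (CSV)."""
    prefix = str(path_prefix)
    model = result.model
    np.savez_compressed(prefix + "-model.npz", b=model.b, phi=model.phi())
    manifest = {
        "K": model.K,
        "T": model.T,
        "V": model.V,
        "alpha": model.alpha,
        "sigma2": model.sigma2,
        "sigma0_2": model.sigma0_2,
        "objective_trace": result.trace,
        "vocabulary_file": prefix + "-vocab.dat",
    }
    if cfg is not None:
        manifest["config"] = cfg.to_dict()
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(prefix + "-model.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if model.vocabulary is not None:
        with open(prefix + "-vocab.dat", "w") as fh:
            for w in model.vocabulary:
                fh.write(w + "\n")
    header = ",".join(f"topic_{k + 1}" for k in range(model.K))
    np.savetxt(
        prefix + "-gamma.csv", result.posterior.gamma,
        delimiter=",", header=header, comments="", fmt="%.8g",
    )


def load_model(path_prefix: str | Path) -> DTMModel:
    prefix = str(path_prefix)
    with np.load(prefix + "-model.npz") as data:
        b = data["b"]
    with open(prefix + "-model.json") as fh:
        manifest = json.load(fh)
    vocab = None
    vocab_path = Path(prefix + "-vocab.dat")
    if vocab_path.exists():
        vocab = [line.rstrip("\n") for line in vocab_path.open()]
    return DTMModel(
        b=b, alpha=manifest["alpha"], sigma2=manifest["sigma2"],
        sigma0_2=manifest["sigma0_2"], vocabulary=vocab,
    )
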