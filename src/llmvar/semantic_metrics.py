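"""Embedding-based consistency: the semantic scores.

Each run's (stopword-filtered) text is mapped to a d-dimensional vector by
a pluggable embedding backend. Semantic repeatability is the mean pairwise
cosine similarity across the R run embeddings of a RunSet, rescaled from
[−1, 1] to [0, 1] via (S̄ + 1)/2. Semantic reproducibility averages each
prompt's R embeddings into a prompt-mean vector first, then takes the mean
pairwise cosine across the P prompt means, rescaled the same way.

The framework is agnostic to the embedding model. Shipped backends:

* ``"mock-vmf"`` — deterministic seeded von Mises–Fisher draws, for
  simulation and testing without any model download;
* ``"lookup"`` — a fixed text → vector map, for fixtures;
* ``"sentence-transformer"`` — optional adapter for sentence-embedding
  checkpoints (requires the ``embeddings`` extra; never needed by tests).

All backends cache by exact input text, so scores are independent of how
often the backend is called and identical texts embed identically.
"""

from __future__ import annotations

import abc
import hashlib
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from ._sphere import sample_vmf
from .run_store import PromptFamily, RunSet, StopwordConfig, filter_stopwords_text

__all__ = [
    "EmbeddingVector",
    "SemanticScore",
    "EmbeddingBackend",
    "LookupBackend",
    "MockVMFBackend",
    "SentenceTransformerBackend",
    "register_backend",
    "get_backend",
    "ZeroNormError",
    "EmptyTextError",
    "InsufficientRunsError",
    "cosine",
    "mean_pairwise_cosine",
    "semantic_repeatability",
    "prompt_mean_embedding",
    "semantic_reproducibility",
]

EmbeddingVector = np.ndarray


class ZeroNormError(ValueError):
    """Cosine similarity requested for a zero-norm vector."""


class EmptyTextError(ValueError):
    """A run's text is empty after stopword filtering."""


class InsufficientRunsError(ValueError):
    """Pairwise similarity is undefined for fewer than two items."""


@dataclass(frozen=True)
class SemanticScore:
    """``raw`` is the mean pairwise cosine S̄ in [−1, 1]; ``score`` is the
    rescaled (raw + 1)/2 in [0, 1], computed exactly."""

    raw: float
    score: float
    n_items: int

    @classmethod
    def from_raw(cls, raw: float, n_items: int) -> "SemanticScore":
        return cls(raw=raw, score=(raw + 1.0) / 2.0, n_items=n_items)


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class EmbeddingBackend(abc.ABC):
    """Maps text to a d-dimensional vector, deterministically within a
    session (results are cached by exact input text)."""

    name: str
    dimension: int

    def __init__(self) -> None:
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, text: str) -> EmbeddingVector:
        vec = self._cache.get(text)
        if vec is None:
            vec = np.asarray(self._embed(text), dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"backend {self.name!r} returned shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"backend {self.name!r} returned non-finite values")
            self._cache[text] = vec
        return vec

    @abc.abstractmethod
    def _embed(self, text: str) -> EmbeddingVector: ...


class LookupBackend(EmbeddingBackend):
    """Fixed text → vector map; unknown text is an error. For fixtures."""

    name = "lookup"

    def __init__(self, mapping: Mapping[str, Sequence[float]]):
        super().__init__()
        self._map = {k: np.asarray(v, dtype=float) for k, v in mapping.items()}
        if not self._map:
            raise ValueError("lookup backend needs a non-empty mapping")
        dims = {v.shape for v in self._map.values()}
        if len(dims) != 1:
            raise ValueError("lookup backend vectors must share one dimension")
        self.dimension = next(iter(dims))[0]

    def _embed(self, text: str) -> EmbeddingVector:
        try:
            return self._map[text]
        except KeyError:
            raise KeyError(f"lookup backend has no vector for text {text!r}") from None


_TAG_RE = re.compile(r"\bptag\d+\b")


class MockVMFBackend(EmbeddingBackend):
    """Deterministic vMF embedding simulator.

    Each text is embedded as one von Mises–Fisher draw of concentration
    ``kappa`` around a mean direction. The draw is seeded from a SHA-256
    hash of (backend name, seed, text), so the same text always yields the
    same vector while distinct texts give independent draws — an embedding
    cloud of known angular dispersion. The mean direction is resolved by
    scanning the text for a tag word present in ``directions`` (the
    synthetic generator plants ``ptagNN`` header tokens for this), falling
    back to ``default_direction`` (the first canonical axis).
    """

    name = "mock-vmf"

    def __init__(
        self,
        dimension: int = 8,
        kappa: float = 50.0,
        directions: Mapping[str, np.ndarray] | None = None,
        default_direction: np.ndarray | None = None,
        seed: int = 0,
    ):
        super().__init__()
        self.dimension = int(dimension)
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.kappa = float(kappa)
        self.seed = int(seed)
        if default_direction is None:
            default_direction = np.zeros(self.dimension)
            default_direction[0] = 1.0
        self.default_direction = np.asarray(default_direction, dtype=float)
        self.directions = {
            k: np.asarray(v, dtype=float) for k, v in (directions or {}).items()
        }
        for key, mu in list(self.directions.items()) + [("default", self.default_direction)]:
            if mu.shape != (self.dimension,) or abs(np.linalg.norm(mu) - 1.0) > 1e-8:
                raise ValueError(f"direction {key!r} must be a unit vector of dim {dimension}")

    def _mean_direction(self, text: str) -> np.ndarray:
        if self.directions:
            for word in _TAG_RE.findall(text):
                mu = self.directions.get(word)
                if mu is not None:
                    return mu
        return self.default_direction

    def _embed(self, text: str) -> EmbeddingVector:
        digest = hashlib.sha256(
            f"{self.name}|{self.seed}|{text}".encode("utf-8")
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return sample_vmf(self._mean_direction(text), self.kappa, rng)


class SentenceTransformerBackend(EmbeddingBackend):
    """Adapter for sentence-embedding checkpoints (e.g. clinical-text
    models). Optional: requires the ``embeddings`` extra."""

    name = "sentence-transformer"

    def __init__(self, model_name: str):
        super().__init__()
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "the 'sentence-transformer' backend requires the optional "
                "'embeddings' extra (pip install llmvar[embeddings])"
            ) from exc
        self._model = SentenceTransformer(model_name)  # pragma: no cover
        self.dimension = int(self._model.get_sentence_embedding_dimension())  # pragma: no cover

    def _embed(self, text: str) -> EmbeddingVector:  # pragma: no cover
        return np.asarray(self._model.encode([text])[0], dtype=float)


_BACKENDS: dict[str, Callable[..., EmbeddingBackend]] = {
    "mock-vmf": MockVMFBackend,
    "lookup": LookupBackend,
    "sentence-transformer": SentenceTransformerBackend,
}


def register_backend(name: str, factory: Callable[..., EmbeddingBackend]) -> None:
    _BACKENDS[name] = factory


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Resolve a registered backend name to a configured instance."""
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown embedding backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# Cosine machinery
# ---------------------------------------------------------------------------

def cosine(a: np.ndarray, b: np.ndarray, *, context: str = "") -> float:
    """Cosine similarity dot(a, b)/(‖a‖‖b‖), clamped to [−1, 1].

    Identical inputs return exactly 1.0 (float rounding in sqrt/divide can
    otherwise land 1 ulp below 1 for a vector compared with itself).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    where = f" ({context})" if context else ""
    if na == 0.0 or nb == 0.0:
        raise ZeroNormError(f"zero-norm embedding vector{where}")
    if a is b or np.array_equal(a, b):
        return 1.0
    val = float(np.dot(a, b) / (na * nb))
    return min(1.0, max(-1.0, val))


def mean_pairwise_cosine(vectors: Sequence[np.ndarray]) -> float:
    """Mean cosine similarity over all unordered pairs,
    S̄ = 2/(n(n−1)) Σ_{r<s} cos(e_r, e_s)."""
    n = len(vectors)
    if n < 2:
        raise InsufficientRunsError(
            f"pairwise similarity needs >= 2 vectors, got {n}"
        )
    total = 0.0
    for r in range(n):
        for s in range(r + 1, n):
            total += cosine(vectors[r], vectors[s], context=f"items {r},{s}")
    return total / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _filtered_texts(runset: RunSet, stopwords: StopwordConfig | None) -> list[str]:
    if stopwords is not None and stopwords.filter_semantic:
        texts = [filter_stopwords_text(r.text, stopwords.words) for r in runset.runs]
    else:
        texts = [r.text for r in runset.runs]
    empty = [r.run_id for r, t in zip(runset.runs, texts) if not t.strip()]
    if empty:
        raise EmptyTextError(
            "empty text after stopword filtering for runs: "
            + ", ".join(repr(r) for r in empty)
        )
    return texts


def semantic_repeatability(
    runset: RunSet,
    backend: EmbeddingBackend,
    stopwords: StopwordConfig | None = None,
) -> SemanticScore:
    """Semantic repeatability of a RunSet: S̄_Rpt is the mean pairwise
    cosine over the R run embeddings; score = (S̄_Rpt + 1)/2."""
    if runset.n_runs < 2:
        raise InsufficientRunsError(
            f"repeatability is undefined for R={runset.n_runs} "
            f"(case={runset.case_id!r}, prompt={runset.prompt_id!r})"
        )
    texts = _filtered_texts(runset, stopwords)
    vectors = [backend.embed(t) for t in texts]
    raw = mean_pairwise_cosine(vectors)
    return SemanticScore.from_raw(raw, n_items=runset.n_runs)


def prompt_mean_embedding(
    runset: RunSet,
    backend: EmbeddingBackend,
    stopwords: StopwordConfig | None = None,
    *,
    l2_normalize_before_mean: bool = False,
) -> EmbeddingVector:
    """Coordinate-wise mean embedding of a prompt's runs,
    ē^(p) = (1/R) Σ_r e_r^(p).

    Raw vectors are averaged by default, following the score's definition
    literally; ``l2_normalize_before_mean`` switches to direction-only
    averaging for backends with heterogeneous norms.
    """
    if runset.n_runs < 1:
        raise InsufficientRunsError("prompt mean embedding needs >= 1 run")
    texts = _filtered_texts(runset, stopwords)
    vectors = np.asarray([backend.embed(t) for t in texts], dtype=float)
    if l2_normalize_before_mean:
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(norms == 0.0):
            raise ZeroNormError(
                f"zero-norm embedding in prompt {runset.prompt_id!r}"
            )
        vectors = vectors / norms[:, None]
    return vectors.mean(axis=0)


def semantic_reproducibility(
    family: PromptFamily,
    backend: EmbeddingBackend,
    stopwords: StopwordConfig | None = None,
    *,
    l2_normalize_before_mean: bool = False,
) -> SemanticScore:
    """Semantic reproducibility of a PromptFamily: S̄_Rpd is the mean
    pairwise cosine over the P prompt-mean embeddings; score = (S̄_Rpd+1)/2.

    A zero-norm prompt mean (antipodal cancellation) is a domain error
    naming the prompt.
    """
    if family.n_prompts < 2:
        raise InsufficientRunsError(
            f"reproducibility needs P >= 2 prompts, got {family.n_prompts} "
            f"(case={family.case_id!r}, model={family.model_id!r})"
        )
    means: list[np.ndarray] = []
    for prompt_id, rs in family.runsets.items():
        mu = prompt_mean_embedding(
            rs, backend, stopwords, l2_normalize_before_mean=l2_normalize_before_mean
        )
        if np.linalg.norm(mu) == 0.0:
            raise ZeroNormError(
                f"prompt {prompt_id!r} has a zero-norm mean embedding"
            )
        means.append(mu)
    raw = mean_pairwise_cosine(means)
    return SemanticScore.from_raw(raw, n_items=family.n_prompts)
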