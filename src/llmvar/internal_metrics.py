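"""Token-level distribution math and the internal (entropy) scores.

At every output position a language model holds a probability distribution
over candidate tokens. Its Shannon entropy (base 2, so the range is
[0, log2 k] after top-k truncation) measures how spread out the sampling
process is at that position. Averaging over positions, runs, and — for
reproducibility — prompt pairs, and rescaling by log2 k, yields:

* internal repeatability  = 1 − H̄_Rpt / log2 k, where H̄_Rpt is the mean
  per-run entropy over R runs under identical conditions;
* internal reproducibility = 1 − H̄_Rpd / log2 k, where H̄_Rpd is the mean
  absolute difference of per-prompt mean entropies over all prompt pairs.

Both scores live in [0, 1]; larger means a more stable token-generating
process. Base 2 is the only logarithm base under which a uniform top-k
distribution scores exactly 0 and a deterministic one exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .run_store import (
    PromptFamily,
    RunRecord,
    RunSet,
    StopwordConfig,
    stopword_position_mask,
)

__all__ = [
    "TopKDistribution",
    "EntropySummary",
    "InternalScore",
    "EmptyRunError",
    "InsufficientPromptsError",
    "temperature_softmax",
    "topk_renormalize",
    "position_entropy",
    "run_entropy",
    "internal_repeatability",
    "internal_reproducibility",
]

_CLAMP_WARN = 1e-6


class EmptyRunError(ValueError):
    """A run has zero usable positions after exclusions."""


class InsufficientPromptsError(ValueError):
    """Reproducibility requested for a family with fewer than two prompts."""


@dataclass(frozen=True)
class TopKDistribution:
    """Renormalized probabilities over the retained top-k tokens."""

    probs: np.ndarray
    k_effective: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if self.k_effective < 1:
            raise ValueError("k_effective must be >= 1")
        if p.ndim != 1 or len(p) != self.k_effective:
            raise ValueError("probs length must equal k_effective")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be nonnegative and sum to 1 within 1e-9")


@dataclass(frozen=True)
class EntropySummary:
    """Per-position entropies (bits) and their mean for one run."""

    per_position: np.ndarray
    run_mean: float
    positions_used: int


@dataclass(frozen=True)
class InternalScore:
    """An internal score: ``raw`` on the entropy scale (bits), ``score`` in
    [0, 1] after the 1 − raw/log2(k) rescaling."""

    raw: float
    score: float
    k: int
    n_items: int


def temperature_softmax(logits: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature-scaled softmax, π(v) = exp(z_v/T) / Σ_u exp(z_u/T).

    Computed with max subtraction for stability, hence invariant to adding
    a constant to all logits. T must be strictly positive; the T→0 argmax
    limit is not taken implicitly.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    x = z / temperature
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def topk_renormalize(probs: np.ndarray, k: int) -> TopKDistribution:
    """Keep the k largest probabilities and renormalize to sum 1.

    Ties are broken by original candidate order (stable selection), so the
    result is deterministic across platforms. With k at or above the
    support size the distribution is unchanged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a valid probability vector")
    if k >= len(p):
        return TopKDistribution(probs=p, k_effective=len(p))
    keep = np.sort(np.argsort(-p, kind="stable")[:k])
    top = p[keep]
    return TopKDistribution(probs=top / top.sum(), k_effective=k)


def position_entropy(dist: TopKDistribution) -> float:
    """Shannon entropy in bits, with 0·log 0 = 0; lies in
    [0, log2(k_effective)]."""
    p = dist.probs[dist.probs > 0]
    return float(-(p * np.log2(p)).sum())


def _position_distribution(
    candidate_logprobs: np.ndarray,
    k: int,
    temperature: float,
    logprobs_are_post_temperature: bool,
) -> TopKDistribution:
    """Logged values → TopKDistribution.

    API logs usually carry provider-normalized log-probabilities with any
    temperature already applied; then only exponentiation (renormalized
    over the logged candidates, since the tail is truncated away) and
    top-k selection are needed. Raw-logit logs (the simulator's
    ``logprobs_are_post_temperature=False`` path) run the full
    temperature-softmax first — applying temperature twice would silently
    corrupt the entropies.
    """
    if logprobs_are_post_temperature:
        lp = np.asarray(candidate_logprobs, dtype=float)
        e = np.exp(lp - lp.max())
        p = e / e.sum()
    else:
        p = temperature_softmax(candidate_logprobs, temperature)
    return topk_renormalize(p, k)


def run_entropy(
    run: RunRecord,
    k: int,
    mask: np.ndarray | None = None,
    *,
    logprobs_are_post_temperature: bool = True,
) -> EntropySummary:
    """Per-position entropies of one run and their mean, H_r.

    Positions where ``mask`` is True (e.g. stopword tokens) and positions
    whose sampled token fell outside the logged top-k are excluded; a
    truncated distribution that is missing its own sample would bias the
    entropy, so such positions never enter the average.
    """
    if mask is not None and len(mask) != run.length:
        raise ValueError(
            f"mask length {len(mask)} != run length {run.length} for run {run.run_id!r}"
        )
    ents: list[float] = []
    for i, pos in enumerate(run.positions):
        if mask is not None and mask[i]:
            continue
        if pos.sampled_index is None:
            continue
        dist = _position_distribution(
            pos.candidate_logprobs, k, run.params.temperature,
            logprobs_are_post_temperature,
        )
        ents.append(position_entropy(dist))
    if not ents:
        raise EmptyRunError(f"run {run.run_id!r} has zero usable positions")
    arr = np.asarray(ents)
    return EntropySummary(
        per_position=arr, run_mean=float(arr.mean()), positions_used=len(arr)
    )


def _score_from_raw(raw: float, k: int, n_items: int) -> InternalScore:
    if k == 1:
        # log2(1) = 0: a single-candidate process is perfectly deterministic.
        return InternalScore(raw=raw, score=1.0, k=k, n_items=n_items)
    score = 1.0 - raw / math.log2(k)
    if score < -_CLAMP_WARN or score > 1.0 + _CLAMP_WARN:
        warnings.warn(
            f"internal score {score:.6g} clamped to [0, 1] by more than {_CLAMP_WARN}; "
            "check k against the logged candidate counts",
            stacklevel=3,
        )
    return InternalScore(
        raw=raw, score=float(min(1.0, max(0.0, score))), k=k, n_items=n_items
    )


def _run_means(
    runset: RunSet,
    k: int,
    stopwords: StopwordConfig | None,
    logprobs_are_post_temperature: bool,
) -> np.ndarray:
    if runset.n_runs == 0:
        raise EmptyRunError(
            f"RunSet (case={runset.case_id!r}, prompt={runset.prompt_id!r}) has no runs"
        )
    means = []
    empty: list[str] = []
    for run in runset.runs:
        mask = None
        if stopwords is not None and stopwords.mask_internal:
            mask = stopword_position_mask(run, stopwords.words)
        try:
            means.append(
                run_entropy(
                    run, k, mask,
                    logprobs_are_post_temperature=logprobs_are_post_temperature,
                ).run_mean
            )
        except EmptyRunError:
            empty.append(run.run_id)
    if empty:
        raise EmptyRunError(
            f"runs with zero usable positions: {', '.join(repr(r) for r in empty)}"
        )
    return np.asarray(means)


def internal_repeatability(
    runset: RunSet,
    k: int,
    *,
    stopwords: StopwordConfig | None = None,
    logprobs_are_post_temperature: bool = True,
) -> InternalScore:
    """Internal repeatability of a RunSet.

    raw = H̄_Rpt, the mean over runs of the per-run mean entropy (bits);
    score = 1 − raw/log2(k), clamped to [0, 1]. Uniform top-k
    distributions everywhere give 0; deterministic ones give 1.
    """
    means = _run_means(runset, k, stopwords, logprobs_are_post_temperature)
    return _score_from_raw(float(means.mean()), k, n_items=len(means))


def internal_reproducibility(
    family: PromptFamily,
    k: int,
    *,
    stopwords: StopwordConfig | None = None,
    logprobs_are_post_temperature: bool = True,
) -> InternalScore:
    """Internal reproducibility of a PromptFamily.

    Per prompt p, H̄^(p) is the mean per-run entropy; raw = H̄_Rpd, the
    mean |H̄^(p) − H̄^(q)| over all P(P−1)/2 prompt pairs; score =
    1 − raw/log2(k). Prompts with identical mean entropy score exactly 1.
    """
    if family.n_prompts < 2:
        raise InsufficientPromptsError(
            f"family (case={family.case_id!r}, model={family.model_id!r}) has "
            f"{family.n_prompts} prompt(s); reproducibility needs P >= 2"
        )
    prompt_means = np.asarray(
        [
            _run_means(rs, k, stopwords, logprobs_are_post_temperature).mean()
            for rs in family.runsets.values()
        ]
    )
    diffs = np.abs(prompt_means[:, None] - prompt_means[None, :])
    p = len(prompt_means)
    raw = float(diffs[np.triu_indices(p, k=1)].mean())
    return _score_from_raw(raw, k, n_items=p)
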