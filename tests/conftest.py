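"""Shared builders for runs with hand-specified token distributions."""

from __future__ import annotations

import math

import numpy as np
import pytest

from llmvar.run_store import (
    GenerationParams,
    PositionLogprobs,
    RunRecord,
    RunSet,
)

DEFAULT_PARAMS = GenerationParams(temperature=0.5, top_k=30)


def make_position(probs, sampled_index: int | None = 0) -> PositionLogprobs:
    """Position whose logged logprobs are ln(p) of the given distribution
    (the post-temperature API dialect), candidates sorted descending."""
    p = np.asarray(probs, dtype=float)
    order = [int(i) for i in np.argsort(-p, kind="stable") if p[i] > 0]
    if sampled_index is not None:
        sampled_index = order.index(sampled_index)
    return PositionLogprobs(
        candidate_tokens=[f" tok{i:02d}" for i in order],
        candidate_logprobs=np.log(p[order]),
        sampled_index=sampled_index,
    )


def make_run(
    run_id: str,
    positions: list[PositionLogprobs],
    *,
    tokens: list[str] | None = None,
    case_id: str = "case0",
    prompt_id: str = "prompt0",
    model_id: str = "model0",
    params: GenerationParams = DEFAULT_PARAMS,
    text: str | None = None,
) -> RunRecord:
    if tokens is None:
        tokens = [
            p.candidate_tokens[p.sampled_index if p.sampled_index is not None else 0]
            for p in positions
        ]
    if text is None:
        text = "".join(tokens)
    return RunRecord(
        run_id=run_id,
        case_id=case_id,
        prompt_id=prompt_id,
        model_id=model_id,
        text=text,
        tokens=tokens,
        positions=positions,
        params=params,
    )


def make_runset(runs: list[RunRecord]) -> RunSet:
    r0 = runs[0]
    return RunSet(
        case_id=r0.case_id,
        prompt_id=r0.prompt_id,
        model_id=r0.model_id,
        params=r0.params,
        runs=runs,
    )


def entropy_bits_direct(probs) -> float:
    """Independent entropy oracle: direct summation of −p·log2 p."""
    total = 0.0
    for p in probs:
        if p > 0:
            total -= p * math.log2(p)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
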