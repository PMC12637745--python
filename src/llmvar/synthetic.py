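"""Seeded generator of synthetic run logs with known ground-truth variability.

No language model is involved: token-level distributions at each position
are drawn from a symmetric Dirichlet(α) over a small synthetic vocabulary
(α is the entropy knob — small α gives peaked, low-entropy positions;
large α approaches uniform, the maximum-entropy limit), and embeddings are
von Mises–Fisher draws of concentration κ around prompt-specific mean
directions (κ is the semantic-dispersion knob). Every metric is therefore
testable by parameter recovery: internal repeatability must fall as α
rises, semantic repeatability must rise with κ, and zeroing the per-prompt
entropy shifts / direction separation must drive the reproducibility
scores to their ceiling.

Determinism: one master seed spawns an independent substream per
(case, prompt, run) by counter-based seed spawning, so the same config is
byte-identical across program runs and adding cases never perturbs
earlier cases' draws.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ._sphere import sample_vmf
from .internal_metrics import run_entropy
from .run_store import (
    DEFAULT_STOPWORDS,
    GenerationParams,
    PositionLogprobs,
    RunRecord,
    RunSet,
)
from .semantic_metrics import MockVMFBackend

__all__ = [
    "SyntheticConfig",
    "build_vocab",
    "prompt_directions",
    "sample_position_distribution",
    "sample_vmf",
    "generate_experiment",
    "mock_backend_for",
]

_PROB_FLOOR = 1e-300  # guards log() against Dirichlet underflow at tiny alpha


class SyntheticConfig(BaseModel):
    """Generator configuration.

    Defaults mirror the evaluation conditions the scores are designed for:
    temperature 0.5, top-k 30 over a 30-token vocabulary, 5 prompts, and a
    recovery-study scale of 50 runs per prompt and 20 cases.
    """

    vocab_size: int = Field(default=30, ge=2)
    run_length: int = Field(default=40, ge=1)
    n_runs: int = Field(default=50, ge=1)
    n_prompts: int = Field(default=5, ge=1)
    n_cases: int = Field(default=20, ge=1)
    dirichlet_alpha: float = Field(default=1.0, gt=0)
    entropy_shift_per_prompt: list[float] | None = None
    vmf_kappa: float = Field(default=50.0, ge=0)
    vmf_dim: int = Field(default=8, ge=2)
    prompt_direction_separation: float = Field(default=0.0, ge=0.0, le=math.pi)
    stopword_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    temperature: float = Field(default=0.5, gt=0)
    top_k: int = Field(default=30, ge=1)
    model_id: str = "synthetic-llm"
    dataset_label: str = "synthetic"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.entropy_shift_per_prompt is not None and len(
            self.entropy_shift_per_prompt
        ) != self.n_prompts:
            raise ValueError(
                "entropy_shift_per_prompt must have n_prompts entries"
            )
        if self.top_k > self.vocab_size:
            raise ValueError("top_k cannot exceed vocab_size")
        return self

    def prompt_alphas(self) -> np.ndarray:
        """Per-prompt Dirichlet concentration.

        The per-prompt entropy shift (bits) is applied multiplicatively on
        α (one doubling of α per bit), a monotone knob rather than an
        exact entropy inversion; realized entropies are recorded
        empirically in the sidecar.
        """
        shifts = self.entropy_shift_per_prompt or [0.0] * self.n_prompts
        return self.dirichlet_alpha * np.exp2(np.asarray(shifts, dtype=float))


def build_vocab(cfg: SyntheticConfig) -> list[str]:
    """Synthetic token strings: a configurable fraction are real stopwords
    (so stopword masking is exercised end-to-end), the rest "tokNNNN";
    all carry a leading space like real tokenizer pieces."""
    n_stop = int(round(cfg.stopword_fraction * cfg.vocab_size))
    stop = sorted(DEFAULT_STOPWORDS)[:n_stop]
    rest = [f"tok{i:04d}" for i in range(cfg.vocab_size - n_stop)]
    return [f" {w}" for w in stop + rest]


def _prompt_tag(p: int) -> str:
    return f"ptag{p:02d}"


def prompt_directions(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """vMF mean direction per prompt tag, every pair separated by the
    configured angle.

    separation 0 gives identical directions. For P = 2 the angle is laid
    out directly; for P > 2 each direction is tilted from a shared base
    axis along its own orthogonal axis by t = arccos(√cos θ), which makes
    every pairwise cosine exactly cos θ (only possible for θ ≤ 90°; more
    than two mutually obtuse directions at a fixed angle do not exist in
    general).
    """
    theta = cfg.prompt_direction_separation
    d, p_count = cfg.vmf_dim, cfg.n_prompts
    base = np.zeros(d)
    base[0] = 1.0
    if theta == 0.0 or p_count == 1:
        return {_prompt_tag(p): base.copy() for p in range(p_count)}
    if p_count == 2:
        other = np.zeros(d)
        other[0], other[1] = math.cos(theta), math.sin(theta)
        return {_prompt_tag(0): base, _prompt_tag(1): other}
    if math.cos(theta) < 0:
        raise ValueError(
            "pairwise separation > 90 degrees is not realizable for more "
            "than two prompt directions"
        )
    if d < p_count + 1:
        raise ValueError(
            f"vmf_dim must be >= n_prompts + 1 (= {p_count + 1}) for "
            "nonzero direction separation"
        )
    t = math.acos(math.sqrt(math.cos(theta)))
    out = {}
    for p in range(p_count):
        mu = np.zeros(d)
        mu[0] = math.cos(t)
        mu[1 + p] = math.sin(t)
        out[_prompt_tag(p)] = mu
    return out


def sample_position_distribution(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> PositionLogprobs:
    """One position: Dirichlet(α) probabilities over the vocabulary,
    sorted descending, truncated to top_k, natural-log probabilities
    logged; the sampled index is drawn from the truncated renormalized
    distribution."""
    vocab = build_vocab(cfg)
    a = cfg.dirichlet_alpha if alpha is None else alpha
    p = rng.dirichlet(np.full(cfg.vocab_size, a))
    p = np.clip(p, _PROB_FLOOR, None)
    p = p / p.sum()
    order = np.argsort(-p, kind="stable")[: cfg.top_k]
    top = p[order]
    q = top / top.sum()
    u = rng.random()
    j = int(np.searchsorted(np.cumsum(q), u, side="right"))
    j = min(j, len(order) - 1)
    return PositionLogprobs(
        candidate_tokens=[vocab[i] for i in order],
        candidate_logprobs=np.log(top),
        sampled_index=j,
    )


def _sample_run(
    cfg: SyntheticConfig,
    vocab: list[str],
    alpha: float,
    rng: np.random.Generator,
) -> tuple[list[PositionLogprobs], list[str]]:
    """All positions of one run in a single vectorized block (same
    per-position law as :func:`sample_position_distribution`)."""
    length = cfg.run_length
    p = rng.dirichlet(np.full(cfg.vocab_size, alpha), size=length)
    p = np.clip(p, _PROB_FLOOR, None)
    p = p / p.sum(axis=1, keepdims=True)
    order = np.argsort(-p, axis=1, kind="stable")[:, : cfg.top_k]
    top = np.take_along_axis(p, order, axis=1)
    logps = np.log(top)
    q = top / top.sum(axis=1, keepdims=True)
    cum = np.cumsum(q, axis=1)
    u = rng.random(length)
    j = np.minimum(
        (u[:, None] > cum).sum(axis=1), order.shape[1] - 1
    )
    positions = []
    tokens = []
    for i in range(length):
        cand = [vocab[v] for v in order[i]]
        positions.append(
            PositionLogprobs(
                candidate_tokens=cand,
                candidate_logprobs=logps[i],
                sampled_index=int(j[i]),
            )
        )
        tokens.append(cand[int(j[i])])
    return positions, tokens


def _header_position(tag_token: str) -> PositionLogprobs:
    # deterministic one-hot prompt tag: contributes exactly zero entropy
    return PositionLogprobs(
        candidate_tokens=[tag_token],
        candidate_logprobs=np.zeros(1),
        sampled_index=0,
    )


def generate_experiment(
    cfg: SyntheticConfig,
) -> tuple[list[RunSet], dict]:
    """Simulate the full case × prompt × run grid.

    Returns the RunSets (one per case × prompt) and a ground-truth sidecar
    recording the true α and κ, per-prompt α values and empirically
    realized mean entropies (bits, over the first few cases), the prompt
    mean directions, and the mock-vmf backend parameters needed to score
    the log.
    """
    vocab = build_vocab(cfg)
    alphas = cfg.prompt_alphas()
    directions = prompt_directions(cfg)
    params = GenerationParams(
        temperature=cfg.temperature,
        top_k=cfg.top_k,
        extra={"dataset_label": cfg.dataset_label, "source": "synthetic"},
    )
    runsets: list[RunSet] = []
    for c in range(cfg.n_cases):
        case_id = f"case{c:03d}"
        for p in range(cfg.n_prompts):
            prompt_id = f"prompt{p:02d}"
            tag = f" {_prompt_tag(p)}"
            runs: list[RunRecord] = []
            for r in range(cfg.n_runs):
                rng = np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(c, p, r))
                )
                positions, tokens = _sample_run(cfg, vocab, float(alphas[p]), rng)
                positions = [_header_position(tag)] + positions
                tokens = [tag] + tokens
                runs.append(
                    RunRecord(
                        run_id=f"{case_id}:{prompt_id}:r{r:03d}",
                        case_id=case_id,
                        prompt_id=prompt_id,
                        model_id=cfg.model_id,
                        text="".join(tokens),
                        tokens=tokens,
                        positions=positions,
                        params=params,
                    )
                )
            runsets.append(
                RunSet(
                    case_id=case_id,
                    prompt_id=prompt_id,
                    model_id=cfg.model_id,
                    params=params,
                    runs=runs,
                )
            )

    # empirically realized per-prompt mean entropy, over a few cases
    n_check = min(3, cfg.n_cases)
    realized = []
    for p in range(cfg.n_prompts):
        vals = []
        for c in range(n_check):
            rs = runsets[c * cfg.n_prompts + p]
            vals.extend(
                run_entropy(run, cfg.top_k).run_mean for run in rs.runs
            )
        realized.append(float(np.mean(vals)))

    sidecar = {
        "config": cfg.model_dump(),
        "truth": {
            "dirichlet_alpha": cfg.dirichlet_alpha,
            "per_prompt_alpha": [float(a) for a in alphas],
            "realized_mean_entropy_bits": realized,
            "entropy_check_cases": n_check,
            "vmf_kappa": cfg.vmf_kappa,
            "prompt_directions": {
                tag: mu.tolist() for tag, mu in directions.items()
            },
        },
        "backend": {
            "name": "mock-vmf",
            "dimension": cfg.vmf_dim,
            "kappa": cfg.vmf_kappa,
            "seed": cfg.seed,
            "directions": {tag: mu.tolist() for tag, mu in directions.items()},
        },
    }
    return runsets, sidecar


def mock_backend_for(cfg_or_sidecar: SyntheticConfig | dict) -> MockVMFBackend:
    """The mock-vmf backend matching a config or a ground-truth sidecar."""
    if isinstance(cfg_or_sidecar, SyntheticConfig):
        cfg = cfg_or_sidecar
        return MockVMFBackend(
            dimension=cfg.vmf_dim,
            kappa=cfg.vmf_kappa,
            directions=prompt_directions(cfg),
            seed=cfg.seed,
        )
    b = cfg_or_sidecar["backend"]
    return MockVMFBackend(
        dimension=int(b["dimension"]),
        kappa=float(b["kappa"]),
        directions={k: np.asarray(v) for k, v in b["directions"].items()},
        seed=int(b["seed"]),
    )
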