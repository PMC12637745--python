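"""Run-log data model, validation, stopword preprocessing, and JSONL I/O.

A *run* is one stochastic generation from a language model: the emitted
text, its token sequence, and — at every position — the top-k candidate
tokens with their log-probabilities, as returned by commercial completion
APIs. Runs sharing (case, prompt, model, sampling parameters) form a
:class:`RunSet`, the unit over which repeatability is measured; the RunSets
of one case/model across several prompts form a :class:`PromptFamily`, the
unit over which reproducibility is measured.

Containers are lightweight dataclasses; invariants are enforced explicitly
at the I/O boundary (:func:`read_runs`) and by :func:`validate_run_record`,
so that bulk simulation can construct millions of positions cheaply.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TokenCandidate",
    "PositionLogprobs",
    "GenerationParams",
    "RunRecord",
    "RunSet",
    "PromptFamily",
    "StopwordConfig",
    "RunLogError",
    "RunLogParseError",
    "RunValidationError",
    "DEFAULT_STOPWORDS",
    "load_stopwords",
    "normalize_word",
    "filter_stopwords_text",
    "stopword_position_mask",
    "read_runs",
    "write_runs",
    "group_into_runsets",
    "group_into_families",
    "validate_run_record",
]


class RunLogError(ValueError):
    """Base class for run-log errors."""


class RunLogParseError(RunLogError):
    """A line of a run-log file is not valid JSON or lacks required keys."""


class RunValidationError(RunLogError):
    """A run record violates a structural invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class TokenCandidate:
    """One candidate token at one position with its natural-log probability."""

    token: str
    logprob: float


@dataclass(slots=True)
class PositionLogprobs:
    """Top-k candidates at one output position.

    ``candidate_logprobs`` is ordered non-increasing (the API dialect);
    ``sampled_index`` is the index of the token actually generated, or
    ``None`` when the sampled token fell outside the logged top-k (possible
    with some providers). Candidates are stored columnar (token list +
    float array) so large simulated logs stay cheap; the ``candidates``
    property presents them as :class:`TokenCandidate` objects.
    """

    candidate_tokens: list[str]
    candidate_logprobs: np.ndarray
    sampled_index: int | None

    @classmethod
    def from_candidates(
        cls, candidates: Sequence[TokenCandidate], sampled_index: int | None
    ) -> "PositionLogprobs":
        return cls(
            candidate_tokens=[c.token for c in candidates],
            candidate_logprobs=np.asarray([c.logprob for c in candidates], dtype=float),
            sampled_index=sampled_index,
        )

    @property
    def candidates(self) -> list[TokenCandidate]:
        return [
            TokenCandidate(t, float(lp))
            for t, lp in zip(self.candidate_tokens, self.candidate_logprobs)
        ]

    def __len__(self) -> int:
        return len(self.candidate_tokens)


@dataclass(frozen=True)
class GenerationParams:
    """Sampling parameters of a run. Grouping compares only ``temperature``
    and ``top_k``; ``extra`` carries free-form provenance (dataset label,
    API deployment, ...) and never affects equality of groups."""

    temperature: float
    top_k: int
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise RunValidationError(f"temperature must be > 0, got {self.temperature}")
        if self.top_k < 1:
            raise RunValidationError(f"top_k must be >= 1, got {self.top_k}")

    @property
    def sampling_key(self) -> tuple[float, int]:
        return (float(self.temperature), int(self.top_k))


@dataclass(slots=True)
class RunRecord:
    """One logged generation run."""

    run_id: str
    case_id: str
    prompt_id: str
    model_id: str
    text: str
    tokens: list[str]
    positions: list[PositionLogprobs]
    params: GenerationParams

    @property
    def length(self) -> int:
        """Number of generated positions (output length of the run)."""
        return len(self.tokens)


@dataclass(slots=True)
class RunSet:
    """All runs for one (case, prompt, model, params) combination."""

    case_id: str
    prompt_id: str
    model_id: str
    params: GenerationParams
    runs: list[RunRecord]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def validate(self) -> None:
        seen: set[str] = set()
        for run in self.runs:
            key = (run.case_id, run.prompt_id, run.model_id, run.params.sampling_key)
            own = (self.case_id, self.prompt_id, self.model_id, self.params.sampling_key)
            if key != own:
                raise RunValidationError(
                    f"run {run.run_id!r} does not belong to RunSet {own}: {key}"
                )
            if run.run_id in seen:
                raise RunValidationError(f"duplicate run_id {run.run_id!r} in RunSet")
            seen.add(run.run_id)


@dataclass(slots=True)
class PromptFamily:
    """RunSets of one (case, model, params) across prompts.

    Reproducibility is only defined for families with at least two distinct
    prompts; single-prompt families are valid containers but are flagged
    ineligible (scoring functions refuse them explicitly).
    """

    case_id: str
    model_id: str
    params: GenerationParams
    runsets: dict[str, RunSet]

    @property
    def n_prompts(self) -> int:
        return len(self.runsets)

    @property
    def eligible_for_reproducibility(self) -> bool:
        return self.n_prompts >= 2

    def validate(self) -> None:
        for prompt_id, rs in self.runsets.items():
            if rs.prompt_id != prompt_id:
                raise RunValidationError(
                    f"runset keyed {prompt_id!r} has prompt_id {rs.prompt_id!r}"
                )
            if (rs.case_id, rs.model_id, rs.params.sampling_key) != (
                self.case_id,
                self.model_id,
                self.params.sampling_key,
            ):
                raise RunValidationError(
                    f"runset for prompt {prompt_id!r} does not share the family key"
                )


# ---------------------------------------------------------------------------
# Stopword preprocessing
# ---------------------------------------------------------------------------

def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stopword list: one lowercase word per line, blanks ignored.

    With ``path=None`` the vendored 179-word English list is returned, so
    results do not drift with any external package's list version.
    """
    if path is None:
        text = (
            resources.files("llmvar").joinpath("data/stopwords_en.txt").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


DEFAULT_STOPWORDS: frozenset[str] = load_stopwords()

_STRIP_CHARS = string.punctuation + string.whitespace


def normalize_word(word: str) -> str:
    """Lowercased form with leading/trailing whitespace and punctuation
    stripped — the canonical form matched against the stopword list."""
    return word.strip(_STRIP_CHARS).lower()


@dataclass(frozen=True)
class StopwordConfig:
    """Where stopword removal applies.

    ``filter_semantic`` removes stopwords from the text before embedding;
    ``mask_internal`` excludes stopword positions from entropy averaging.
    Both default on: filler tokens are exactly the noise the metrics are
    meant to ignore, and the two switches are independent so either scope
    can be studied alone.
    """

    filter_semantic: bool = True
    mask_internal: bool = True
    words: frozenset[str] = DEFAULT_STOPWORDS


def filter_stopwords_text(text: str, stopword_set: Iterable[str]) -> str:
    """Remove whitespace-delimited words whose normalized form is a stopword.

    Word order is preserved and only words present in the input are
    returned (joined by single spaces). Idempotent. An all-stopword input
    yields the empty string; callers decide how to handle that.
    """
    stopwords = set(stopword_set)
    kept = [w for w in text.split() if normalize_word(w) not in stopwords]
    return " ".join(kept)


def stopword_position_mask(run: RunRecord, stopword_set: Iterable[str]) -> np.ndarray:
    """Boolean mask over positions: True where the generated token is a stopword.

    Matching uses the detokenized piece stripped of surrounding whitespace
    and punctuation, lowercased; a sub-word piece matching a stopword is
    masked even when the tokenizer split a longer word oddly.
    """
    stopwords = set(stopword_set)
    return np.array([normalize_word(tok) in stopwords for tok in run.tokens], dtype=bool)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _squash_ws(s: str) -> str:
    return "".join(s.split())


def validate_run_record(run: RunRecord, k_config: int | None = None) -> None:
    """Check all structural invariants of one run; raise
    :class:`RunValidationError` naming the run and offending field."""
    rid = run.run_id
    if len(run.tokens) != len(run.positions):
        raise RunValidationError(
            f"run {rid!r}: field 'positions' has length {len(run.positions)} "
            f"but 'tokens' has length {len(run.tokens)}"
        )
    if _squash_ws(run.text) != _squash_ws("".join(run.tokens)):
        raise RunValidationError(
            f"run {rid!r}: field 'text' does not match the concatenated tokens "
            "(whitespace-insensitive comparison)"
        )
    k_cap = k_config if k_config is not None else run.params.top_k
    for i, pos in enumerate(run.positions):
        ncand = len(pos.candidate_tokens)
        if ncand < 1 or ncand > k_cap:
            raise RunValidationError(
                f"run {rid!r}: field 'logprobs[{i}]' has {ncand} candidates, "
                f"expected 1..{k_cap}"
            )
        lp = pos.candidate_logprobs
        if len(lp) != ncand:
            raise RunValidationError(
                f"run {rid!r}: field 'logprobs[{i}]' token/logprob length mismatch"
            )
        if not np.all(np.isfinite(lp)):
            raise RunValidationError(
                f"run {rid!r}: field 'logprobs[{i}]' contains non-finite logprob"
            )
        if any(t == "" for t in pos.candidate_tokens):
            raise RunValidationError(
                f"run {rid!r}: field 'logprobs[{i}]' contains an empty token"
            )
        # non-increasing, with tiny slack for float round-trips
        if np.any(np.diff(lp) > 1e-9):
            raise RunValidationError(
                f"run {rid!r}: field 'logprobs[{i}]' candidates not sorted "
                "non-increasing by logprob"
            )
        si = pos.sampled_index
        if si is not None and not (0 <= si < ncand):
            raise RunValidationError(
                f"run {rid!r}: field 'sampled_index[{i}]' = {si} out of range 0..{ncand - 1}"
            )


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------

def _record_to_json(run: RunRecord) -> dict:
    return {
        "run_id": run.run_id,
        "case_id": run.case_id,
        "prompt_id": run.prompt_id,
        "model_id": run.model_id,
        "params": {
            "temperature": run.params.temperature,
            "top_k": run.params.top_k,
            "extra": dict(run.params.extra),
        },
        "text": run.text,
        "tokens": run.tokens,
        "logprobs": [
            [
                {"token": t, "logprob": float(lp)}
                for t, lp in zip(p.candidate_tokens, p.candidate_logprobs)
            ]
            for p in run.positions
        ],
        "sampled_index": [p.sampled_index for p in run.positions],
    }


def _record_from_json(obj: dict) -> RunRecord:
    params_obj = obj["params"]
    params = GenerationParams(
        temperature=float(params_obj["temperature"]),
        top_k=int(params_obj["top_k"]),
        extra=dict(params_obj.get("extra", {})),
    )
    sampled = obj.get("sampled_index")
    logprobs = obj["logprobs"]
    if sampled is None:
        sampled = [None] * len(logprobs)
    positions = [
        PositionLogprobs(
            candidate_tokens=[c["token"] for c in cands],
            candidate_logprobs=np.array([c["logprob"] for c in cands], dtype=float),
            sampled_index=(None if si is None else int(si)),
        )
        for cands, si in zip(logprobs, sampled)
    ]
    return RunRecord(
        run_id=str(obj["run_id"]),
        case_id=str(obj["case_id"]),
        prompt_id=str(obj["prompt_id"]),
        model_id=str(obj["model_id"]),
        text=obj["text"],
        tokens=list(obj["tokens"]),
        positions=positions,
        params=params,
    )


def group_into_runsets(runs: Iterable[RunRecord]) -> list[RunSet]:
    """Group runs by (case_id, prompt_id, model_id, sampling params),
    preserving first-appearance order of both groups and members."""
    groups: dict[tuple, RunSet] = {}
    for run in runs:
        key = (run.case_id, run.prompt_id, run.model_id, run.params.sampling_key)
        rs = groups.get(key)
        if rs is None:
            rs = RunSet(
                case_id=run.case_id,
                prompt_id=run.prompt_id,
                model_id=run.model_id,
                params=run.params,
                runs=[],
            )
            groups[key] = rs
        rs.runs.append(run)
    out = list(groups.values())
    for rs in out:
        rs.validate()
    return out


def read_runs(path: str | Path) -> list[RunSet]:
    """Read a JSONL run log and group records into validated RunSets.

    Raises :class:`RunLogParseError` (naming the line number) for malformed
    JSON, :class:`RunValidationError` (naming run_id and field) for
    invariant violations.
    """
    path = Path(path)
    runs: list[RunRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RunLogParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                run = _record_from_json(obj)
            except (KeyError, TypeError, ValueError) as exc:
                raise RunLogParseError(
                    f"{path}:{lineno}: record missing or malformed field: {exc}"
                ) from exc
            validate_run_record(run)
            runs.append(run)
    return group_into_runsets(runs)


def write_runs(runsets: Iterable[RunSet], path: str | Path) -> None:
    """Write RunSets to a JSONL run log (one run per line, full float
    precision so that read_runs round-trips exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rs in runsets:
            for run in rs.runs:
                fh.write(json.dumps(_record_to_json(run), ensure_ascii=False))
                fh.write("\n")


def group_into_families(runsets: Iterable[RunSet]) -> list[PromptFamily]:
    """Partition RunSets by (case_id, model_id, params) into PromptFamilies.

    Families with a single prompt are returned with
    ``eligible_for_reproducibility == False`` rather than dropped.
    """
    fams: dict[tuple, PromptFamily] = {}
    for rs in runsets:
        key = (rs.case_id, rs.model_id, rs.params.sampling_key)
        fam = fams.get(key)
        if fam is None:
            fam = PromptFamily(
                case_id=rs.case_id, model_id=rs.model_id, params=rs.params, runsets={}
            )
            fams[key] = fam
        if rs.prompt_id in fam.runsets:
            raise RunValidationError(
                f"duplicate RunSet for prompt {rs.prompt_id!r} in family "
                f"(case={rs.case_id!r}, model={rs.model_id!r})"
            )
        fam.runsets[rs.prompt_id] = rs
    out = list(fams.values())
    for fam in out:
        fam.validate()
    return out
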