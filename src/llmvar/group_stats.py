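"""Between-group comparison of bivariate (semantic, internal) score points.

The comparison is a multivariate extension of the Kruskal–Wallis test:
each dimension is midrank-transformed over the pooled sample, and the
rank-MANOVA quadratic form

    W = Σ_g n_g (R̄_g − R̄)' S⁻¹ (R̄_g − R̄)

is computed, where R̄_g is group g's mean rank vector, R̄ the grand mean
rank vector, and S the pooled covariance of the rank vectors. W is
invariant to strictly monotone per-dimension transforms and valid under
ties. Significance comes from a seeded permutation null by default (exact
enumeration available at small n), which is two-sided by construction; an
asymptotic chi-square p-value (d·(groups−1) df) is reported for reference.

Key efficiency fact: pooled midranks and S are invariant under label
permutation, so only group mean ranks are recomputed per permutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ScoreRecord",
    "GroupTestResult",
    "midranks",
    "mkw_statistic",
    "mkw_permutation_test",
    "compare_labelled_groups",
    "holm_adjust",
]


@dataclass(frozen=True)
class ScoreRecord:
    """Per-case score point: the bivariate (semantic, internal) position of
    one clinical case, plus grouping metadata and an optional binary label
    (e.g. diagnosed correctly / incorrectly)."""

    case_id: str
    model_id: str
    semantic: float
    internal: float
    metric_kind: str  # "repeatability" | "reproducibility"
    prompt_id: str | None = None
    dataset_label: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("semantic", "internal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1] for case {self.case_id!r}")
        if self.metric_kind not in ("repeatability", "reproducibility"):
            raise ValueError(f"unknown metric_kind {self.metric_kind!r}")
        if self.metric_kind == "reproducibility" and self.prompt_id is not None:
            raise ValueError(
                "reproducibility scores aggregate over prompts; prompt_id must be None"
            )


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    p_value_asymptotic: float
    n_groups: int
    n_per_group: tuple[int, ...]
    n_permutations: int
    seed: int
    exhaustive: bool = False
    group_medians: Mapping[str, tuple[float, float]] | None = None
    group_names: tuple[str, ...] | None = None


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied observations receiving the mean of the ranks
    they span."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("midranks needs at least one value")
    return sps.rankdata(v, method="average")


def _prepare(groups: Sequence[Sequence[Sequence[float]]]):
    arrays = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    dim = arrays[0].shape[1]
    for a in arrays:
        if a.shape[1] != dim:
            raise ValueError("all points must share one dimension")
        if a.shape[0] < 1:
            raise ValueError("each group needs at least one point")
    pooled = np.vstack(arrays)
    n = pooled.shape[0]
    if n < max(2, len(arrays)):
        raise ValueError(
            "need at least 2 points in total and at least one per group"
        )
    sizes = np.array([a.shape[0] for a in arrays])
    ranks = np.column_stack([midranks(pooled[:, j]) for j in range(dim)])
    grand = ranks.mean(axis=0)
    centered = ranks - grand
    cov = centered.T @ centered / (n - 1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = None
    if cov_inv is None or np.linalg.cond(cov) > 1e12:
        warnings.warn(
            "singular pooled rank covariance (constant or perfectly dependent "
            "dimension); using pseudo-inverse",
            stacklevel=3,
        )
        cov_inv = np.linalg.pinv(cov)
    return ranks, grand, cov_inv, sizes


def _stat_for_index_batches(
    ranks: np.ndarray,
    grand: np.ndarray,
    cov_inv: np.ndarray,
    sizes: np.ndarray,
    index_batches: np.ndarray,
) -> np.ndarray:
    """W for each row of ``index_batches`` (a (B, n) matrix whose row is a
    permutation of 0..n−1; consecutive blocks of each row form the groups)."""
    stats_out = np.zeros(index_batches.shape[0])
    start = 0
    for n_g in sizes:
        idx = index_batches[:, start : start + n_g]
        means = ranks[idx].mean(axis=1)  # (B, dim)
        dev = means - grand
        stats_out += n_g * np.einsum("bi,ij,bj->b", dev, cov_inv, dev)
        start += n_g
    return stats_out


def mkw_statistic(groups: Sequence[Sequence[Sequence[float]]]) -> float:
    """The rank-MANOVA quadratic form W for a list of groups of d-dim
    points; ≥ 0, invariant to strictly monotone per-dimension transforms."""
    ranks, grand, cov_inv, sizes = _prepare(groups)
    idx = np.arange(ranks.shape[0])[None, :]
    return float(_stat_for_index_batches(ranks, grand, cov_inv, sizes, idx)[0])


def _exhaustive_indices(sizes: np.ndarray) -> np.ndarray:
    """All distinct assignments of the pooled indices to groups of the
    given sizes, each as a row of indices grouped in consecutive blocks."""
    n = int(sizes.sum())
    labels = np.repeat(np.arange(len(sizes)), sizes)
    seen = sorted(set(itertools.permutations(labels.tolist())))
    rows = []
    for lab in seen:
        lab = np.asarray(lab)
        rows.append(np.concatenate([np.flatnonzero(lab == g) for g in range(len(sizes))]))
    return np.asarray(rows)


def mkw_permutation_test(
    groups: Sequence[Sequence[Sequence[float]]],
    n_permutations: int = 9999,
    seed: int = 0,
    *,
    exhaustive: bool = False,
) -> GroupTestResult:
    """Permutation p-value for the multivariate rank statistic.

    Monte-Carlo: p = (1 + #{W_perm ≥ W_obs}) / (1 + n_permutations) with
    group labels permuted uniformly under the given seed — deterministic
    for a fixed seed and never smaller than 1/(n_permutations + 1).
    ``exhaustive=True`` enumerates every distinct label assignment instead
    (feasible for small n); the identity assignment is included, so p is
    again bounded away from 0.
    """
    ranks, grand, cov_inv, sizes = _prepare(groups)
    n = ranks.shape[0]
    idx0 = np.arange(n)[None, :]
    observed = float(_stat_for_index_batches(ranks, grand, cov_inv, sizes, idx0)[0])
    tol = 1e-9 * max(1.0, abs(observed))

    if exhaustive:
        batches = _exhaustive_indices(sizes)
        perm_stats = _stat_for_index_batches(ranks, grand, cov_inv, sizes, batches)
        p = float(np.mean(perm_stats >= observed - tol))
        n_perm = batches.shape[0]
    else:
        if n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        rng = np.random.default_rng(seed)
        batches = rng.permuted(
            np.tile(np.arange(n), (n_permutations, 1)), axis=1
        )
        perm_stats = _stat_for_index_batches(ranks, grand, cov_inv, sizes, batches)
        p = (1.0 + int(np.sum(perm_stats >= observed - tol))) / (1.0 + n_permutations)
        n_perm = n_permutations

    dim = ranks.shape[1]
    df = dim * (len(sizes) - 1)
    p_asym = float(sps.chi2.sf(observed, df))
    return GroupTestResult(
        statistic=observed,
        p_value=float(p),
        p_value_asymptotic=p_asym,
        n_groups=len(sizes),
        n_per_group=tuple(int(s) for s in sizes),
        n_permutations=int(n_perm),
        seed=int(seed),
        exhaustive=exhaustive,
    )


def compare_labelled_groups(
    records: Sequence[ScoreRecord],
    label_field: str = "label",
    n_permutations: int = 9999,
    seed: int = 0,
) -> GroupTestResult:
    """Compare (semantic, internal) score points between the two levels of
    a binary label (e.g. correctly vs incorrectly diagnosed cases).

    Exactly two label levels must be present with ≥ 2 records each;
    records with a missing label raise an error listing their case_ids.
    The result carries per-group medians of each dimension.
    """
    missing = [r.case_id for r in records if getattr(r, label_field) is None]
    if missing:
        raise ValueError(
            f"records missing {label_field!r} for cases: "
            + ", ".join(repr(c) for c in missing)
        )
    by_label: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        by_label.setdefault(str(getattr(r, label_field)), []).append(
            (r.semantic, r.internal)
        )
    if len(by_label) != 2:
        raise ValueError(
            f"need exactly 2 label levels, got {sorted(by_label)}"
        )
    names = tuple(sorted(by_label))
    groups = [by_label[name] for name in names]
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"label level {name!r} has fewer than 2 records")
    result = mkw_permutation_test(groups, n_permutations=n_permutations, seed=seed)
    medians = {
        name: (
            float(np.median([p[0] for p in g])),
            float(np.median([p[1] for p in g])),
        )
        for name, g in zip(names, groups)
    }
    return GroupTestResult(
        statistic=result.statistic,
        p_value=result.p_value,
        p_value_asymptotic=result.p_value_asymptotic,
        n_groups=result.n_groups,
        n_per_group=result.n_per_group,
        n_permutations=result.n_permutations,
        seed=result.seed,
        exhaustive=result.exhaustive,
        group_medians=medians,
        group_names=names,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment for a batch of per-comparison p-values.
    Off by default in the CLI; per-comparison p-values are the primary
    output."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
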