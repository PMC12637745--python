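# Methods

## The four scores

`llmvar` quantifies the output variability of a sampling-based language
model along two axes (repeatability vs reproducibility) and two dimensions
(semantic vs internal), following the metrology convention that
*repeatability* is agreement under identical conditions and
*reproducibility* is agreement under different, pre-specified conditions —
here, different reasoning prompts for the same case, model, and sampling
parameters.

Let `R` runs be generated per (case, prompt, model, parameter) cell, with
run `r` producing tokens `Y_{r,1:L_r}` and, at each position `i`, a logged
top-k candidate distribution.

**Semantic repeatability.** An embedding function `E` maps each run's
(stopword-filtered) text to a vector `e_r ∈ R^d`. The raw score is the mean
pairwise cosine similarity

    S̄_Rpt = 2/(R(R−1)) Σ_{r<s} cos(e_r, e_s),   S̃_Rpt = (S̄_Rpt + 1)/2.

**Internal repeatability.** At position `i` the model's distribution over
candidates, after temperature scaling and top-k truncation/renormalization
`π̃_{r,i}`, has Shannon entropy `H_{r,i} = −Σ_v π̃ log2 π̃` (bits). Averaging
over positions gives `H_r`, over runs gives `H̄_Rpt`, and

    H̃_Rpt = 1 − H̄_Rpt / log2 k ∈ [0, 1].

Base-2 logarithms are used throughout: `log2 k` is the entropy of the
uniform distribution over k tokens, so a uniform process scores exactly 0
and a deterministic one exactly 1 — the only base for which the stated
range is tight. For `k = 1` the score is defined as 1 by continuity.

**Semantic reproducibility.** With `P ≥ 2` prompts, each prompt's runs are
averaged into a prompt-mean embedding `ē^(p) = (1/R) Σ_r e_r^(p)` (raw
vectors, per the definition; an `l2_normalize_before_mean` flag switches to
direction-only averaging), and

    S̄_Rpd = 2/(P(P−1)) Σ_{p<q} cos(ē^(p), ē^(q)),   S̃_Rpd = (S̄_Rpd + 1)/2.

**Internal reproducibility.** With `H̄^(p)` the mean entropy under prompt
`p`,

    H̄_Rpd = 2/(P(P−1)) Σ_{p<q} |H̄^(p) − H̄^(q)|,   H̃_Rpd = 1 − H̄_Rpd / log2 k.

## Interpreting logged log-probabilities

Commercial completion APIs return per-position top-k *log-probabilities*
with any temperature already applied by the provider; raw logits are not
available. The `logprobs_are_post_temperature` flag (default `true`)
controls the pipeline:

* `true` — logged values are exponentiated, renormalized over the logged
  candidates (the truncated tail carries no mass), and top-k truncated;
  applying the temperature softmax again would corrupt every entropy.
* `false` — logged values are treated as raw logits and the full
  temperature-scaled softmax (with max-subtraction for numerical
  stability) runs first. This is the path the simulator's contract and any
  local-model logit dump use.

## Stopword handling

Filler words ("the", "an", …) carry little meaning but can dominate both
text similarity and token-level entropy. A fixed 179-word English stopword
list is vendored into the package (overridable by a one-word-per-line
file) so scores never drift with an external package's list version. Two
independent switches, both on by default:

* `filter_semantic` — stopwords are removed from the text before
  embedding (whitespace-delimited words whose lowercased,
  punctuation-stripped form is in the list);
* `mask_internal` — positions whose *generated* token normalizes to a
  stopword are excluded from entropy averaging, as are positions whose
  sampled token fell outside the logged top-k (a truncated distribution
  missing its own sample would bias `H`).

Sub-word pieces are matched per-piece after stripping surrounding
whitespace/punctuation; exact tokenizer reconstruction is out of scope.

## The group comparison

Score distributions across prompts, models, datasets, or accuracy labels
are compared with a multivariate extension of the Kruskal–Wallis test:
midrank-transform each dimension over the pooled sample, then form the
rank-MANOVA quadratic form `W = Σ_g n_g (R̄_g − R̄)' S⁻¹ (R̄_g − R̄)` with `S`
the pooled rank covariance. `W` is invariant to strictly monotone
per-dimension transforms and handles ties through midranks. There is no
single canonical "multivariate Kruskal–Wallis"; this construction was
chosen because it is distribution-free under permutation and does not lean
on an asymptotic reference at small group sizes. The default p-value is a
seeded permutation p, `p = (1 + #{W_perm ≥ W_obs})/(1 + B)` with B = 9,999
by default (exact enumeration of all label assignments is available for
small samples); a chi-square p at `d·(groups−1)` degrees of freedom is
reported alongside for reference. A singular pooled rank covariance
(constant or perfectly dependent dimension) falls back to the
pseudo-inverse with a warning. Per-comparison p-values are primary, as
users typically read each comparison on its own; a Holm adjustment helper
is provided for batches.

Permutations are vectorised by exploiting that pooled ranks and `S` do not
change when labels are permuted — only group mean ranks are recomputed —
which makes thousand-replicate calibration studies cheap (the suite's
calibration check, 1,000 null replicates × 999 permutations at n = 30 per
group, runs in a few seconds and lands inside [0.03, 0.07] at the 0.05
level).

## The synthetic-run generator

The simulator emulates the logged-run dialect end-to-end with known ground
truth, so every score is testable by parameter recovery without any model
access:

* **Token distributions** at each position are symmetric Dirichlet(α)
  draws over a `vocab_size`-token synthetic vocabulary, sorted, truncated
  to `top_k`, and logged as natural-log probabilities; the sampled token is
  drawn from the truncated renormalized distribution. α is the entropy
  knob: α → 0 gives near-one-hot positions (internal repeatability → 1),
  α → ∞ near-uniform ones (score → 0 with k = vocabulary size). Per-prompt
  entropy shifts (bits) act multiplicatively on α (one doubling per bit) —
  a monotone knob rather than an exact entropy inversion, which would add a
  brittle root-finding step; realized per-prompt mean entropies are
  recorded empirically in the ground-truth sidecar instead.
* **Embeddings** come from the deterministic `mock-vmf` backend: each
  distinct text is one von Mises–Fisher draw (rejection sampling of the
  mean-direction cosine, Householder rotation) of concentration κ around a
  prompt-specific mean direction, seeded by a hash of the text so caching
  and determinism hold exactly. κ is the semantic-dispersion knob: κ = 0
  gives uniform directions (mean pairwise cosine ≈ 0, score ≈ 0.5 in
  moderate dimension), large κ drives the score to 1. Prompt mean
  directions are separated pairwise by a configurable angle (exact for
  separations ≤ 90°; more than two mutually obtuse directions at one fixed
  angle do not exist in general); zero separation means all prompts share
  one semantic target.
* **Prompt tagging.** Each run opens with a deterministic one-hot header
  token `ptagNN` so the backend can resolve the prompt's mean direction
  from the text alone. The header contributes exactly zero entropy and
  dilutes each run's mean entropy by the constant factor `L/(L+1)`,
  identically across all conditions, so monotone-recovery comparisons and
  equal-entropy checks are unaffected; it also guarantees the filtered
  text is never empty.
* **Vocabulary.** A configurable fraction (default 0.2) of the synthetic
  vocabulary are real stopwords from the shipped list, so stopword masking
  is exercised end-to-end; the rest are `tokNNNN` strings with leading
  spaces, like real tokenizer pieces.
* **Seeding.** One master seed spawns an independent substream per
  (case, prompt, run) via `SeedSequence` spawn keys, so identical configs
  are byte-identical and adding cases never perturbs earlier cases.

### Default conditions and what they show

Defaults: `temperature 0.5`, `top_k 30` over a 30-token vocabulary (so
top-k truncation is exercised by configs with larger vocabularies, while
the default keeps `log2 k` the exact entropy ceiling), `P = 5` prompts,
`R = 50` runs, `20` cases, `run_length 40`, `α = 1`, `κ = 50`, `vmf_dim 8`.
Embedding dimension 8 keeps the κ-recovery curve well separated at its
low-κ end (in very high dimension the κ = 1 mean cosine `A_d(κ)² ≈ (κ/d)²`
collapses into the κ = 0 noise floor); run length 40 gives each run enough
positions that per-run mean entropies concentrate. These sizes make the
recovery checks decisive while a full default experiment (5,000 runs)
generates and scores in seconds.

The generator emulates the *statistical structure* of logged runs — known
entropy and known embedding dispersion — not natural language: synthetic
texts are token strings, embeddings ignore meaning, and no claim about any
particular LLM's scores follows from these tests. What passing recovery
shows is that the estimators order known ground truth correctly, hit their
closed-form endpoints, and are numerically stable; applying the tool to
real run logs inherits those properties but not any particular score
level.

## Numerical choices

* Entropy uses `0·log 0 = 0`; top-k selection breaks probability ties by
  the logged candidate order (stable), for cross-platform determinism.
* Scores are clamped to [0, 1] after float arithmetic; a clamp larger
  than 1e-6 warns, to separate rounding from logic errors (e.g. a wrong
  `k`).
* `cosine(a, b)` returns exactly 1.0 when the inputs are element-wise
  identical; the general formula can land 1 ulp below 1 for a vector
  paired with itself, which would make "identical texts score exactly 1"
  false by rounding.
* Repeatability at `R = 1` and reproducibility at `P = 1` are refused with
  explicit errors rather than returning a conventional value: the
  estimands are pairwise and undefined there. Single-prompt families are
  carried through grouping but flagged ineligible, and the scoring CLI
  lists them in a skip report rather than dropping them silently.
* CSV floats are fixed at 10 significant digits and every output embeds
  the full run configuration plus package version, making
  simulate → score → compare byte-stable across reruns.

## Known limitations

* Stopword matching is per-token-piece; a stopword split across two
  pieces by the tokenizer is not recognized.
* The post-temperature interpretation of API logprobs is an assumption
  about the provider; if a provider logged pre-temperature values, the
  flag must be set accordingly — the package cannot detect this.
* Prompt-mean embedding of raw vectors weights runs by embedding norm;
  use `l2_normalize_before_mean` for norm-heterogeneous backends.
* The asymptotic chi-square p-value is a reference only; at small n the
  permutation p is authoritative.
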