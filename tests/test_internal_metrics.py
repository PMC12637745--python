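"""Entropy machinery and the internal repeatability/reproducibility scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from llmvar.internal_metrics import (
    EmptyRunError,
    InsufficientPromptsError,
    TopKDistribution,
    internal_repeatability,
    internal_reproducibility,
    position_entropy,
    run_entropy,
    temperature_softmax,
    topk_renormalize,
)
from llmvar.run_store import PromptFamily, StopwordConfig

from conftest import entropy_bits_direct, make_position, make_run, make_runset

finite_logits = hnp.arrays(
    np.float64,
    st.integers(2, 8),
    elements=st.floats(-30, 30, allow_nan=False),
)


class TestTemperatureSoftmax:
    def test_equal_logits_give_uniform(self):
        np.testing.assert_allclose(
            temperature_softmax([3.3, 3.3, 3.3], 0.7), [1 / 3] * 3
        )

    def test_closed_form_at_unit_temperature(self):
        np.testing.assert_allclose(
            temperature_softmax([math.log(2), 0.0, 0.0], 1.0), [0.5, 0.25, 0.25]
        )

    def test_two_logit_closed_form_with_temperature(self):
        # oracle: direct evaluation of exp(z/T)/sum at high precision
        e2 = math.exp(2.0)
        expected = [e2 / (e2 + 1.0), 1.0 / (e2 + 1.0)]
        got = temperature_softmax([1.0, 0.0], 0.5)
        np.testing.assert_allclose(got, expected, rtol=1e-13)
        np.testing.assert_allclose(got, [0.8808, 0.1192], atol=5e-5)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            temperature_softmax([1.0, 0.0], 0.0)
        with pytest.raises(ValueError):
            temperature_softmax([1.0, 0.0], -1.0)

    @settings(deadline=None, derandomize=True)
    @given(finite_logits, st.floats(0.05, 2.0), st.floats(-50, 50))
    def test_shift_invariance(self, logits, temp, shift):
        base = temperature_softmax(logits, temp)
        shifted = temperature_softmax(logits + shift, temp)
        np.testing.assert_allclose(base, shifted, atol=1e-12)
        assert abs(base.sum() - 1.0) < 1e-12

    @settings(deadline=None, derandomize=True)
    @given(finite_logits)
    def test_entropy_nondecreasing_in_temperature(self, logits):
        temps = [0.1, 0.25, 0.5, 1.0, 2.0, 5.0]
        ents = [
            position_entropy(topk_renormalize(temperature_softmax(logits, t), len(logits)))
            for t in temps
        ]
        assert all(b >= a - 1e-9 for a, b in zip(ents, ents[1:]))


class TestTopKRenormalize:
    def test_k_at_support_size_is_identity(self):
        d = topk_renormalize([0.5, 0.3, 0.2], 3)
        np.testing.assert_allclose(d.probs, [0.5, 0.3, 0.2])
        assert d.k_effective == 3

    def test_truncation_renormalizes(self):
        d = topk_renormalize([0.5, 0.3, 0.2], 2)
        np.testing.assert_allclose(d.probs, [0.625, 0.375])

    def test_uniform_over_ten_truncates_to_uniform_over_four(self):
        d = topk_renormalize(np.full(10, 0.1), 4)
        np.testing.assert_allclose(d.probs, [0.25] * 4)

    def test_ties_broken_by_original_order(self):
        d = topk_renormalize([0.25, 0.25, 0.25, 0.25], 2)
        assert d.k_effective == 2
        np.testing.assert_allclose(d.probs, [0.5, 0.5])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            topk_renormalize([0.5, 0.5], 0)


class TestPositionEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([1.0, 0.0, 0.0], 0.0),
            (np.full(30, 1 / 30), math.log2(30)),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_closed_forms(self, probs, expected):
        dist = TopKDistribution(np.asarray(probs, dtype=float), len(probs))
        assert position_entropy(dist) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, st.integers(1, 5), elements=st.floats(0.01, 1.0))
    )
    def test_matches_direct_summation_oracle_on_small_supports(self, raw):
        probs = raw / raw.sum()
        dist = topk_renormalize(probs, len(probs))
        assert position_entropy(dist) == pytest.approx(
            entropy_bits_direct(dist.probs), abs=1e-12
        )


class TestRunEntropy:
    def test_all_one_hot_gives_zero(self):
        run = make_run("r1", [make_position([1.0, 0.0]) for _ in range(4)])
        assert run_entropy(run, k=30).run_mean == 0.0

    def test_mean_of_position_entropies(self):
        # entropies 1.0 and 2.0 bits
        run = make_run(
            "r1", [make_position([0.5, 0.5]), make_position([0.25] * 4)]
        )
        summary = run_entropy(run, k=30)
        assert summary.run_mean == pytest.approx(1.5, abs=1e-12)
        assert summary.positions_used == 2

    def test_mask_excludes_positions(self):
        run = make_run(
            "r1", [make_position([0.5, 0.5]), make_position([0.25] * 4)]
        )
        summary = run_entropy(run, k=30, mask=np.array([False, True]))
        assert summary.run_mean == pytest.approx(1.0, abs=1e-12)
        assert summary.positions_used == 1

    def test_sample_absent_positions_excluded(self):
        pos = make_position([0.25] * 4)
        pos.sampled_index = None
        run = make_run("r1", [make_position([0.5, 0.5]), pos],
                       tokens=[" tok00", " tok01"])
        assert run_entropy(run, k=30).positions_used == 1

    def test_zero_usable_positions_is_an_error(self):
        run = make_run("r1", [make_position([0.5, 0.5])])
        with pytest.raises(EmptyRunError, match="r1"):
            run_entropy(run, k=30, mask=np.array([True]))

    def test_raw_logit_path_applies_temperature(self):
        # logits [1, 0] at T=0.5 give probs [e^2, 1]/(e^2+1)
        pos = make_position([0.9, 0.1])  # placeholder probabilities
        pos.candidate_logprobs = np.array([1.0, 0.0])
        run = make_run("r1", [pos], tokens=[" tok00"])
        got = run_entropy(run, k=2, logprobs_are_post_temperature=False).run_mean
        e2 = math.exp(2.0)
        p = np.array([e2 / (e2 + 1), 1 / (e2 + 1)])
        assert got == pytest.approx(entropy_bits_direct(p), abs=1e-12)


class TestInternalRepeatability:
    def test_uniform_distributions_score_zero(self):
        runs = [
            make_run(f"r{i}", [make_position(np.full(30, 1 / 30)) for _ in range(3)])
            for i in range(3)
        ]
        score = internal_repeatability(make_runset(runs), k=30)
        assert score.score == pytest.approx(0.0, abs=1e-12)
        assert score.raw == pytest.approx(math.log2(30), abs=1e-12)

    def test_one_hot_distributions_score_one(self):
        runs = [
            make_run(f"r{i}", [make_position([1.0, 0.0, 0.0]) for _ in range(3)])
            for i in range(3)
        ]
        score = internal_repeatability(make_runset(runs), k=30)
        assert score.score == 1.0
        assert score.raw == 0.0

    def test_closed_form_mixture(self):
        # run entropies 1.0 and 2.0 bits, k=4: raw 1.5, score 0.25
        r1 = make_run("r1", [make_position([0.5, 0.5])])
        r2 = make_run("r2", [make_position([0.25] * 4)])
        score = internal_repeatability(make_runset([r1, r2]), k=4)
        assert score.raw == pytest.approx(1.5, abs=1e-12)
        assert score.score == pytest.approx(0.25, abs=1e-12)

    def test_run_order_invariance(self):
        r1 = make_run("r1", [make_position([0.7, 0.3])])
        r2 = make_run("r2", [make_position([0.25] * 4)])
        a = internal_repeatability(make_runset([r1, r2]), k=8)
        b = internal_repeatability(make_runset([r2, r1]), k=8)
        assert a.score == b.score

    def test_single_candidate_k1_scores_one_by_continuity(self):
        runs = [make_run("r1", [make_position([1.0])])]
        assert internal_repeatability(make_runset(runs), k=1).score == 1.0

    def test_empty_runset_rejected(self):
        with pytest.raises(EmptyRunError):
            internal_repeatability(
                make_runset([make_run("r1", [make_position([1.0])])]).__class__(
                    case_id="c", prompt_id="p", model_id="m",
                    params=make_run("rx", [make_position([1.0])]).params, runs=[],
                ),
                k=4,
            )

    def test_stopword_masking_changes_the_score(self):
        noisy = make_position([0.5, 0.5])
        run = make_run("r1", [noisy, make_position([1.0, 0.0])],
                       tokens=[" the", " fever"])
        rs = make_runset([run])
        cfg = StopwordConfig(mask_internal=True)
        masked = internal_repeatability(rs, k=2, stopwords=cfg)
        unmasked = internal_repeatability(rs, k=2)
        assert masked.score == 1.0  # the 1-bit position sits under " the"
        assert unmasked.score == pytest.approx(0.5, abs=1e-12)


class TestInternalReproducibility:
    def _family(self, runsets):
        r0 = runsets[0]
        return PromptFamily(
            case_id=r0.case_id, model_id=r0.model_id, params=r0.params,
            runsets={rs.prompt_id: rs for rs in runsets},
        )

    def test_equal_prompt_entropies_score_exactly_one(self):
        runsets = [
            make_runset([make_run(f"r{p}", [make_position([0.25] * 4)],
                                  prompt_id=f"p{p}")])
            for p in range(3)
        ]
        score = internal_reproducibility(self._family(runsets), k=4)
        assert score.raw == 0.0
        assert score.score == 1.0

    def test_two_prompt_closed_form(self):
        # prompt means 1.0 and 2.0 bits, k=4: raw 1.0, score 0.5
        rs1 = make_runset([make_run("r1", [make_position([0.5, 0.5])], prompt_id="p1")])
        rs2 = make_runset([make_run("r2", [make_position([0.25] * 4)], prompt_id="p2")])
        score = internal_reproducibility(self._family([rs1, rs2]), k=4)
        assert score.raw == pytest.approx(1.0, abs=1e-12)
        assert score.score == pytest.approx(0.5, abs=1e-12)

    def test_three_prompt_pair_enumeration(self):
        # prompt means [0, 0, log2 k]; pairs: |0-0|, |0-log2k| twice
        # -> raw = (2/3) log2 k, score = 1/3
        k = 4
        one_hot = make_position([1.0, 0.0, 0.0, 0.0])
        uniform = make_position([0.25] * 4)
        runsets = [
            make_runset([make_run("r1", [one_hot], prompt_id="p1")]),
            make_runset([make_run("r2", [one_hot], prompt_id="p2")]),
            make_runset([make_run("r3", [uniform], prompt_id="p3")]),
        ]
        score = internal_reproducibility(self._family(runsets), k=k)
        pairs = [abs(0 - 0), abs(0 - math.log2(k)), abs(0 - math.log2(k))]
        assert score.raw == pytest.approx(sum(pairs) / 3, abs=1e-12)
        assert score.score == pytest.approx(1 / 3, abs=1e-12)

    def test_prompt_order_invariance(self):
        rs1 = make_runset([make_run("r1", [make_position([0.6, 0.4])], prompt_id="p1")])
        rs2 = make_runset([make_run("r2", [make_position([0.25] * 4)], prompt_id="p2")])
        a = internal_reproducibility(self._family([rs1, rs2]), k=8)
        b = internal_reproducibility(self._family([rs2, rs1]), k=8)
        assert a.score == b.score

    def test_single_prompt_rejected(self):
        rs = make_runset([make_run("r1", [make_position([1.0])])])
        with pytest.raises(InsufficientPromptsError):
            internal_reproducibility(self._family([rs]), k=4)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    hnp.arrays(
        np.float64, st.tuples(st.integers(2, 4), st.integers(1, 4), st.integers(2, 6)),
        elements=st.floats(-20, 20),
    )
)
def test_scores_always_in_unit_interval(tensor):
    """Random logit tensors (runs x positions x candidates) always map to
    scores in [0, 1]."""
    runs = []
    for r in range(tensor.shape[0]):
        positions = []
        for i in range(tensor.shape[1]):
            probs = temperature_softmax(tensor[r, i], 1.0)
            positions.append(make_position(probs))
        runs.append(make_run(f"r{r}", positions))
    score = internal_repeatability(make_runset(runs), k=tensor.shape[2])
    assert 0.0 <= score.score <= 1.0
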