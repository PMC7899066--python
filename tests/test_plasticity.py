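import numpy as np
import pytest

from wordrep.environment import TrialConfig
from wordrep.inference import InferenceSettings, run_trial
from wordrep.model import build_word_repetition_model, normalize_counts
from wordrep.plasticity import (
    LESION_A,
    LESION_B,
    LesionSpec,
    accumulate_dirichlet,
    consolidate_transitions,
    lesion,
    make_nonspurious,
    transition_pair_increment,
)


def _one_record(model, seed=0):
    return run_trial(model, TrialConfig(), InferenceSettings(), np.random.default_rng(seed))


class TestAccumulateDirichlet:
    def test_counts_never_decrease(self, spurious_model):
        m = spurious_model.copy()
        before = [a.copy() for a in m.a] + [b.copy() for b in m.b]
        accumulate_dirichlet(m, _one_record(m))
        after = m.a + m.b
        for x, y in zip(before, after):
            assert np.all(y >= x - 1e-12)

    def test_delta_posterior_unit_increment(self, spurious_model):
        m = spurious_model.copy()
        record = _one_record(m)
        # force a delta joint belief at every time point
        for f in range(3):
            record.beliefs[-1].bma[f][:] = 0.0
            record.beliefs[-1].bma[f][:, 0] = 1.0
        before = m.a[0].copy()
        accumulate_dirichlet(m, record)
        delta = m.a[0] - before
        assert delta.sum() == pytest.approx(3.0)  # one unit per epoch
        assert np.count_nonzero(delta) <= 3

    def test_fractional_outer_product(self, spurious_model):
        m = spurious_model.copy()
        record = _one_record(m)
        for f, w in zip(range(3), ([1.0, 0, 0], [0.6, 0.4, 0, 0], [1.0, 0, 0, 0, 0])):
            record.beliefs[-1].bma[f][:] = np.array(w)
        before = m.a[0].copy()
        accumulate_dirichlet(m, record)
        # "still" is observed at epochs 1 and 3, so that cell accumulates twice
        delta = (m.a[0] - before)[record.outcomes[0].proprioception]
        assert delta[0, 0, 0] == pytest.approx(2 * 0.6)
        assert delta[0, 1, 0] == pytest.approx(2 * 0.4)

    def test_repeated_pairing_probability_increases(self, spurious_model):
        """The more often a pairing is seen, the higher its learned probability."""
        m = spurious_model.copy()
        record = _one_record(m)
        probs = []
        o = record.outcomes[0]
        for _ in range(5):
            accumulate_dirichlet(m, record)
            col = normalize_counts(m.a[1], axis=0)
            j = np.unravel_index(np.argmax(m.a[1][o.audition]), m.a[1][o.audition].shape)
            probs.append(col[(o.audition,) + j])
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_likelihood_learning_commutes(self, spurious_model):
        m1 = spurious_model.copy()
        m2 = spurious_model.copy()
        r1 = _one_record(spurious_model, seed=1)
        r2 = _one_record(spurious_model, seed=2)
        for m, order in ((m1, (r1, r2)), (m2, (r2, r1))):
            m.learn_b = False
            for r in order:
                accumulate_dirichlet(m, r)
        for a, b in zip(m1.a, m2.a):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rate_must_be_positive(self, spurious_model):
        with pytest.raises(ValueError):
            accumulate_dirichlet(spurious_model.copy(), _one_record(spurious_model), 0.0)


class TestMakeNonspurious:
    def test_audition_read_columns_uniform(self, small_learned_model):
        m = make_nonspurious(small_learned_model)
        aud = m.modality_index("audition")
        read = m.factors[2].level_labels.index("read")
        cols = normalize_counts(m.a[aud], axis=0)[:, :, :, read]
        np.testing.assert_allclose(cols, 0.25, atol=1e-12)
        assert np.all(m.a[aud][:, :, :, read] == 10.0)

    def test_other_columns_untouched(self, small_learned_model):
        m = make_nonspurious(small_learned_model)
        read = m.factors[2].level_labels.index("read")
        keep = [i for i in range(5) if i != read]
        for mi in range(3):
            np.testing.assert_array_equal(
                m.a[mi][..., keep], small_learned_model.a[mi][..., keep]
            )

    def test_idempotent(self, small_learned_model):
        once = make_nonspurious(small_learned_model)
        twice = make_nonspurious(once)
        for a, b in zip(once.a, twice.a):
            np.testing.assert_array_equal(a, b)

    def test_missing_read_level_rejected(self, small_learned_model):
        m = small_learned_model.copy()
        m.factors[2] = type(m.factors[2])("repeated_word", ("a", "b", "c", "d", "e"), True)
        with pytest.raises(ValueError):
            make_nonspurious(m)


class TestLesion:
    def test_half_exponent_example(self):
        m = build_word_repetition_model(True)
        col = np.array([0.9, 0.1])
        p = col**0.5
        np.testing.assert_allclose(p / p.sum(), [0.75, 0.25], atol=1e-10)

    def test_exponent_one_is_noop(self, small_learned_model):
        m = lesion(small_learned_model, LesionSpec("likelihood", "evaluation", 1.0))
        for a, b in zip(m.a, small_learned_model.a):
            np.testing.assert_array_equal(a, b)

    def test_extrinsic_lesion_targets_evaluation(self, small_learned_model):
        m = lesion(small_learned_model, LESION_A)
        ev = m.modality_index("evaluation")
        for i in range(3):
            if i == ev:
                assert not np.allclose(m.a[i], small_learned_model.a[i])
            else:
                np.testing.assert_array_equal(m.a[i], small_learned_model.a[i])

    def test_intrinsic_lesion_preserves_column_totals(self, small_learned_model):
        m = lesion(small_learned_model, LESION_B)
        f = m.factor_index("target_word")
        np.testing.assert_allclose(
            m.b[f].sum(axis=1), small_learned_model.b[f].sum(axis=1), atol=1e-9
        )

    def test_largest_shrinks_smallest_grows(self, small_learned_model):
        m = lesion(small_learned_model, LESION_B)
        f = m.factor_index("target_word")
        before = normalize_counts(small_learned_model.b[f], axis=1)
        after = normalize_counts(m.b[f], axis=1)
        for u in range(before.shape[0]):
            for j in range(before.shape[2]):
                col_b, col_a = before[u, :, j], after[u, :, j]
                if np.ptp(col_b) < 1e-9:
                    np.testing.assert_allclose(col_a, col_b, atol=1e-9)
                else:
                    assert col_a.max() < col_b.max()
                    assert col_a.min() > col_b.min()

    @pytest.mark.parametrize("eta", [0.8, 0.5, 0.3])
    def test_negentropy_strictly_decreases(self, small_learned_model, eta):
        m = lesion(small_learned_model, LesionSpec("likelihood", "evaluation", eta))
        ev = m.modality_index("evaluation")
        before = normalize_counts(small_learned_model.a[ev], axis=0)
        after = normalize_counts(m.a[ev], axis=0)
        h = lambda p: -(p * np.log(np.maximum(p, 1e-16))).sum(axis=0)
        gain = h(after) - h(before)
        nonuniform = np.ptp(before, axis=0) > 1e-9
        assert np.all(gain[nonuniform] > 0)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec("likelihood", "evaluation", 0.0)
        with pytest.raises(ValueError):
            LesionSpec("connection", "evaluation", 0.5)

    def test_unknown_target_rejected(self, small_learned_model):
        with pytest.raises(KeyError):
            lesion(small_learned_model, LesionSpec("transition", "nope", 0.5))


def test_consolidation_adds_pending_counts(spurious_model):
    m = spurious_model.copy()
    record = _one_record(m)
    pending = transition_pair_increment(m, record, 1)
    before = m.b[1].copy()
    consolidate_transitions(m, pending, 1)
    added = m.b[1] - before
    assert added.sum() > 0
    assert np.all(added >= -1e-12)
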