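import numpy as np
import pytest

from wordrep.environment import EVALUATION, TrialConfig
from wordrep.inference import (
    InferenceSettings,
    _likelihood_fields,
    _policy_free_energy,
    _Precomputed,
    infer_states,
    policy_posterior,
    run_trial,
    select_action,
    update_precision,
)
from wordrep.model import FactorSpec, GenerativeModel, ModalitySpec


def make_simple_model(likelihood, prior, scale=1e8):
    """Single-factor, single-time-point model with near-exact probabilities.

    ``likelihood`` is (n_outcomes, n_levels); large count scaling makes the
    Dirichlet expected-log coincide with the log probability.
    """
    likelihood = np.maximum(np.asarray(likelihood, dtype=float), 1e-12)
    n_out, n_lev = likelihood.shape
    factors = [FactorSpec("s", tuple(f"s{i}" for i in range(n_lev)))]
    modalities = [ModalitySpec("o", tuple(f"o{i}" for i in range(n_out)))]
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        a=[likelihood * scale],
        b=[np.maximum(np.eye(n_lev), 1e-12)[None, :, :] * scale],
        c=[np.zeros((n_out, 1))],
        d=[np.asarray(prior, dtype=float) * scale],
        policies=np.zeros((1, 0, 1), dtype=int),
        n_timesteps=1,
    )


class _Obs:
    def __init__(self, idx):
        self.idx = idx

    def as_tuple(self):
        return (self.idx,)


class TestExactBayes:
    def test_two_level_example(self):
        model = make_simple_model([[0.9, 0.2], [0.1, 0.8]], [0.5, 0.5])
        qs, F, _ = infer_states(model, [_Obs(0)], model.policies[0])
        np.testing.assert_allclose(qs[0][0], [0.45 / 0.55, 0.10 / 0.55], atol=1e-3)

    def test_fixed_point_at_delta(self):
        model = make_simple_model([[1.0, 1e-9], [1e-9, 1.0]], [1.0, 1e-7], scale=1e9)
        qs, _, _ = infer_states(model, [_Obs(0)], model.policies[0])
        assert qs[0][0, 0] > 1 - 1e-6

    def test_random_instances_match_analytic_posterior(self, rng):
        for _ in range(100):
            n_lev = int(rng.integers(2, 6))
            n_out = int(rng.integers(2, 6))
            lik = rng.dirichlet(np.ones(n_out), size=n_lev).T  # P(o | s) columns
            prior = rng.dirichlet(np.ones(n_lev))
            obs = int(rng.integers(n_out))
            model = make_simple_model(lik, prior)
            qs, _, _ = infer_states(model, [_Obs(obs)], model.policies[0])
            exact = prior * lik[obs]
            exact = exact / exact.sum()
            np.testing.assert_allclose(qs[0][0], exact, atol=1e-6)


def test_free_energy_nonincreasing_over_sweeps(spurious_model, rng):
    """F is monotone under exact coordinate ascent, for every epoch."""
    settings = InferenceSettings(store_traces=True, convergence_tol=0.0)
    record = run_trial(spurious_model, TrialConfig(), settings, rng)
    pre = _Precomputed(spurious_model)
    for t, belief in enumerate(record.beliefs):
        fields = _likelihood_fields(pre, record.outcomes[: t + 1])
        for p, trace in enumerate(belief.iteration_trace):
            if trace is None:
                continue
            fs = [
                _policy_free_energy(pre, snap, spurious_model.policies[p], fields)
                for snap in trace
            ]
            assert all(b - a <= 1e-6 for a, b in zip(fs, fs[1:]))


def test_target_belief_propagates_after_first_epoch(small_learned_model, rng):
    """Hearing the target concentrates beliefs at all three time points."""
    m = small_learned_model.copy()
    m.learn_a = m.learn_b = False
    record = run_trial(m, TrialConfig(forced_target=2), InferenceSettings(), rng)
    q_target = record.beliefs[0].bma[1]
    assert np.all(np.argmax(q_target, axis=1) == 2)
    assert q_target[0, 2] > 0.5


class TestPolicyPosterior:
    def test_symmetric(self):
        pi = policy_posterior(np.zeros(5), np.zeros(5), 1.0)
        np.testing.assert_allclose(pi, 0.2)

    def test_logistic_pair(self):
        pi = policy_posterior(np.array([0.0, 1.0]), np.zeros(2), 1.0)
        np.testing.assert_allclose(pi, [0.73105858, 0.26894142], atol=1e-8)

    def test_shift_invariance(self, rng):
        F = rng.normal(size=5)
        G = rng.normal(size=5)
        np.testing.assert_allclose(
            policy_posterior(F, G, 2.0), policy_posterior(F + 7.0, G, 2.0), atol=1e-12
        )

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(2), np.zeros(2), 0.0)


class TestPrecision:
    def test_fixed_point_unchanged(self):
        G = np.array([1.0, 2.0])
        pi_G = np.exp(-G) / np.exp(-G).sum()
        gamma, beta = update_precision(1.0, G, pi_G)
        np.testing.assert_allclose(beta, 1.0, atol=1e-6)
        np.testing.assert_allclose(gamma, 1.0, atol=1e-6)

    def test_confident_low_G_policies_raise_gamma(self):
        G = np.array([0.0, 1.0])
        pi = np.array([0.95, 0.05])  # more concentrated on low G than softmax(-G)
        gamma, beta = update_precision(1.0, G, pi)
        assert beta < 1.0 and gamma > 1.0

    def test_equal_G_degenerate(self):
        gamma, beta = update_precision(2.0, np.ones(4), np.full(4, 0.25))
        np.testing.assert_allclose(beta, 2.0, atol=1e-9)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            update_precision(0.0, np.zeros(2), np.ones(2))


class TestSelectAction:
    def test_uniform_marginals_sample_uniformly(self, spurious_model, rng):
        pi = np.full(5, 0.2)
        draws = [
            select_action(pi, spurious_model.policies, 0, 16.0, rng)[2] for _ in range(10_000)
        ]
        freqs = np.bincount(draws, minlength=5) / len(draws)
        np.testing.assert_allclose(freqs, 0.2, atol=0.02)

    def test_high_alpha_is_argmax(self, spurious_model, rng):
        pi = np.array([0.7, 0.3, 0.0, 0.0, 0.0])
        draws = {select_action(pi, spurious_model.policies, 0, 16.0, rng)[2] for _ in range(1000)}
        assert draws == {0}

    def test_uncontrollable_factors_get_action_zero(self, spurious_model, rng):
        u = select_action(np.full(5, 0.2), spurious_model.policies, 0, 16.0, rng)
        assert u[0] == 0 and u[1] == 0

    def test_alpha_must_be_positive(self, spurious_model, rng):
        with pytest.raises(ValueError):
            select_action(np.full(5, 0.2), spurious_model.policies, 0, 0.0, rng)


class TestRunTrial:
    def test_record_shapes_and_simplexes(self, spurious_model, rng):
        record = run_trial(spurious_model, TrialConfig(), InferenceSettings(), rng)
        assert len(record.outcomes) == 3 and len(record.actions) == 2
        for belief in record.beliefs:
            for q in belief.bma:
                np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)
                assert np.all(q >= 0)
        for pi_info in record.policy_inference:
            np.testing.assert_allclose(pi_info.policy_posterior.sum(), 1.0, atol=1e-9)

    def test_forced_negative_evaluation_recorded(self, spurious_model, rng):
        neg = EVALUATION.index("negative")
        record = run_trial(
            spurious_model, TrialConfig(forced_evaluation=neg), InferenceSettings(), rng
        )
        assert record.outcomes[-1].evaluation == neg

    def test_post_learning_control_repeats_target(self, small_learned_model):
        m = small_learned_model.copy()
        m.learn_a = m.learn_b = False
        correct = 0
        rng = np.random.default_rng(7)
        for _ in range(40):
            record = run_trial(m, TrialConfig(), InferenceSettings(), rng)
            correct += record.outcomes[-1].evaluation == EVALUATION.index("positive")
        assert correct / 40 >= 0.45
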