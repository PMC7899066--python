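"""The per-trial active-inference loop.

State inference is mean-field coordinate ascent on the policy-conditioned
variational free energy: each hidden factor holds a categorical belief for
every time point of the trial (past, present and future), and coordinates
are updated in turn from three messages — the Dirichlet expected-log
likelihood of outcomes observed so far, the forward transition message
from the previous time point, and the backward message from the next.
Exact coordinate updates guarantee that F never increases across sweeps.

Policies (word choices) are scored by their free energy F and expected
free energy G over the remaining time points (risk relative to the
log-preference distribution plus likelihood ambiguity); the policy
posterior is a precision-weighted softmax, the precision gamma is updated
by its usual fixed point, and actions are sampled from the precision-alpha
softmax of the policy-marginal action probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import TrialConfig, TrueState, apply_action, emit_outcome, init_trial
from .measures import FreeEnergyComponents, free_energy_components
from .model import (
    LOG_FLOOR,
    GenerativeModel,
    expected_log_probability,
    normalize_counts,
)

__all__ = [
    "InferenceSettings",
    "PolicyInference",
    "BeliefState",
    "TrialRecord",
    "infer_states",
    "expected_free_energy",
    "policy_posterior",
    "update_precision",
    "select_action",
    "run_trial",
]


@dataclass(frozen=True)
class InferenceSettings:
    """Numerical settings of the variational scheme.

    iterations_per_epoch
        Maximum coordinate-ascent sweeps per epoch (default 16).
    step_size
        Fractional update toward the coordinate optimum (1 = full update).
    convergence_tol
        Early stop when the free-energy decrease per sweep falls below
        this (nats; default 1/128).
    precision_iters
        Fixed-point iterations of the joint policy/precision update.
    store_traces
        Retain per-sweep belief snapshots (needed for simulated LFPs).
    """

    iterations_per_epoch: int = 16
    step_size: float = 1.0
    log_floor: float = LOG_FLOOR
    convergence_tol: float = 1.0 / 128.0
    precision_iters: int = 8
    store_traces: bool = False
    #: Risk formulation in the expected free energy: "kl" is the KL
    #: divergence of predicted outcomes from the preference distribution
    #: (its prediction-entropy term rewards resolving state uncertainty);
    #: "utility" drops that term and scores only the expected
    #: log-preference.  The default "auto" uses "kl" while the model is
    #: learning (epistemic, exploratory regime) and "utility" once
    #: learning is frozen (exploitative regime): with weak preferences the
    #: entropy bonus would otherwise make flattened or lesioned mappings
    #: behaviorally attractive.
    risk: str = "auto"

    def __post_init__(self) -> None:
        if self.iterations_per_epoch < 1:
            raise ValueError("iterations_per_epoch must be >= 1")
        if not 0.0 < self.step_size <= 1.0:
            raise ValueError("step_size must lie in (0, 1]")
        if self.risk not in ("utility", "kl", "auto"):
            raise ValueError("risk must be 'utility', 'kl' or 'auto'")


@dataclass
class PolicyInference:
    """Policy-level quantities for one epoch."""

    F_per_policy: np.ndarray
    G_per_policy: np.ndarray
    policy_posterior: np.ndarray
    gamma: float
    beta: float


@dataclass
class BeliefState:
    """Posterior expectations for one epoch.

    ``per_policy[p][f]`` is an array ``(n_timesteps, n_levels_f)``;
    ``bma[f]`` is the Bayesian model average over policies.
    ``iteration_trace[p]`` is the list of per-sweep snapshots for policy p
    (present only when traces are stored).
    """

    per_policy: list[list[np.ndarray]]
    bma: list[np.ndarray]
    iteration_trace: list[list[list[np.ndarray]]] | None = None


@dataclass
class TrialRecord:
    """Everything observed and inferred during one trial."""

    config: TrialConfig
    true_states: list[TrueState] = field(default_factory=list)
    outcomes: list = field(default_factory=list)
    actions: list[np.ndarray] = field(default_factory=list)
    beliefs: list[BeliefState] = field(default_factory=list)
    policy_inference: list[PolicyInference] = field(default_factory=list)
    components: list[list[FreeEnergyComponents]] = field(default_factory=list)
    #: Same bundles with degeneracy scored on the present time point only.
    components_present: list[list[FreeEnergyComponents]] = field(default_factory=list)
    priors: list[list[np.ndarray]] = field(default_factory=list)
    n_timesteps: int = 3


class _Precomputed:
    """Per-trial cache of log-parameters derived from the count arrays."""

    def __init__(self, model: GenerativeModel, floor: float = LOG_FLOOR):
        self.model = model
        self.floor = floor
        self.lnA = [expected_log_probability(a, axis=0) for a in model.a]
        self.A_norm = [normalize_counts(a, axis=0) for a in model.a]
        # Transitions, like likelihoods, enter the messages as Dirichlet
        # expected logs: at small counts digamma amplifies the plausible/
        # implausible contrast (e.g. a 1-vs-0.5 column behaves like a
        # 0.57-persistence rather than 0.4-persistence mapping), which is
        # what lets trajectory beliefs persist well enough for learning to
        # bootstrap.
        self.lnB = [expected_log_probability(b, axis=1) for b in model.b]
        self.lnA_norm = [np.log(np.maximum(p, floor)) for p in self.A_norm]
        self.B_norm = [normalize_counts(b, axis=1) for b in model.b]
        self.D_norm = [normalize_counts(d) for d in model.d]
        self.lnD = [np.log(np.maximum(p, floor)) for p in self.D_norm]
        # Per-modality conditional entropy of the likelihood (for ambiguity).
        self.H = [
            -np.sum(p * lnp, axis=0) for p, lnp in zip(self.A_norm, self.lnA_norm)
        ]
        # Preference distributions per modality and time point.
        self.C_dist = []
        for c in model.c:
            e = np.exp(c - c.max(axis=0, keepdims=True))
            self.C_dist.append(e / e.sum(axis=0, keepdims=True))
        self.lnC = [np.log(np.maximum(p, floor)) for p in self.C_dist]
        # Expected information gain about likelihood parameters (novelty):
        # per modality, the predicted count-curvature 0.5 (1/a - 1/colsum),
        # averaged under the predicted outcome.  Zero when not learning a.
        if model.learn_a:
            self.novelty = [
                np.sum(p * 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True)), axis=0)
                for p, a in zip(self.A_norm, model.a)
            ]
        else:
            self.novelty = None
        # Equivalent curiosity bonus for transition counts that are being
        # learned: expected information gain about b under the predicted
        # transition, per factor/action, as a function of the previous
        # state.  Drives sampling of untried actions, which preference
        # terms alone cannot.
        if model.learn_b:
            self.novelty_b = []
            for f, b in enumerate(model.b):
                if model.learn_b_factors is not None and not model.learn_b_factors[f]:
                    self.novelty_b.append(None)
                    continue
                W = 0.5 * (1.0 / b - 1.0 / b.sum(axis=1, keepdims=True))
                self.novelty_b.append(np.sum(self.B_norm[f] * W, axis=1))
        else:
            self.novelty_b = None


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _contract_except(tensor: np.ndarray, qs: list[np.ndarray], keep: int) -> np.ndarray:
    """Contract every state axis of ``tensor`` with its belief except ``keep``."""
    out = tensor
    for g in range(len(qs) - 1, -1, -1):
        if g == keep:
            continue
        out = np.tensordot(out, qs[g], axes=([g if g < keep else g, ], [0]))
    return out


def _contract_all(tensor: np.ndarray, qs: list[np.ndarray]) -> float:
    out = tensor
    for g in range(len(qs) - 1, -1, -1):
        out = np.tensordot(out, qs[g], axes=([g], [0]))
    return float(out)


def _likelihood_fields(pre: _Precomputed, outcomes: list) -> list[np.ndarray]:
    """Per observed time point, the summed expected-log likelihood tensor."""
    fields = []
    for o in outcomes:
        idx = o.as_tuple() if hasattr(o, "as_tuple") else tuple(o)
        L = np.zeros(pre.model.state_dims)
        for m, lnA in enumerate(pre.lnA):
            L = L + lnA[idx[m]]
        fields.append(L)
    return fields


def _policy_free_energy(
    pre: _Precomputed, qs: list[np.ndarray], policy: np.ndarray, fields: list[np.ndarray]
) -> float:
    """Mean-field variational free energy of one policy's beliefs."""
    T = pre.model.n_timesteps
    floor = pre.floor
    F = 0.0
    for f in range(len(qs)):
        q = qs[f]
        F += float(np.sum(q * np.log(np.maximum(q, floor))))
        F -= float(q[0] @ pre.lnD[f])
        for tau in range(1, T):
            msg = pre.lnB[f][policy[tau - 1, f]] @ q[tau - 1]
            F -= float(q[tau] @ msg)
    for tau, L in enumerate(fields):
        qs_tau = [qs[f][tau] for f in range(len(qs))]
        F -= _contract_all(L, qs_tau)
    return F


def infer_states(
    model: GenerativeModel,
    outcomes: list,
    policy: np.ndarray,
    settings: InferenceSettings = InferenceSettings(),
    init: list[np.ndarray] | None = None,
    _pre: _Precomputed | None = None,
    _fields: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], float, list[list[np.ndarray]]]:
    """Variational state inference under one policy.

    Parameters
    ----------
    outcomes
        Outcome tuples observed so far (time points ``0..t``).
    policy
        ``(n_transitions, n_factors)`` action matrix.
    init
        Optional warm start (e.g. the previous epoch's posterior).

    Returns
    -------
    qs, F, trace
        Beliefs ``qs[f]`` of shape ``(n_timesteps, n_levels_f)``, the
        converged free energy (nats), and — if traces are stored — one
        belief snapshot per sweep.
    """
    pre = _pre if _pre is not None else _Precomputed(model, settings.log_floor)
    fields = _fields if _fields is not None else _likelihood_fields(pre, outcomes)
    T = model.n_timesteps
    n_factors = len(model.factors)
    if len(fields) > T:
        raise ValueError("more outcomes than time points")
    if init is None:
        qs = [np.full((T, f.n_levels), 1.0 / f.n_levels) for f in model.factors]
    else:
        qs = [q.copy() for q in init]
    trace: list[list[np.ndarray]] = []
    F_prev = np.inf
    F = np.inf
    for _ in range(settings.iterations_per_epoch):
        for tau in range(T):
            qs_tau = [qs[f][tau] for f in range(n_factors)]
            for f in range(n_factors):
                msg = np.zeros(model.factors[f].n_levels)
                if tau < len(fields):
                    msg += _contract_except(fields[tau], qs_tau, f)
                if tau == 0:
                    msg += pre.lnD[f]
                else:
                    msg += pre.lnB[f][policy[tau - 1, f]] @ qs[f][tau - 1]
                if tau < T - 1:
                    msg += pre.lnB[f][policy[tau, f]].T @ qs[f][tau + 1]
                new_q = _softmax(msg)
                if settings.step_size < 1.0:
                    old = np.log(np.maximum(qs[f][tau], settings.log_floor))
                    new_q = _softmax(old + settings.step_size * (msg - old))
                qs[f][tau] = new_q
                qs_tau[f] = new_q
        F = _policy_free_energy(pre, qs, policy, fields)
        if settings.store_traces:
            trace.append([q.copy() for q in qs])
        if F_prev - F < settings.convergence_tol:
            break
        F_prev = F
    if settings.store_traces:
        while len(trace) < settings.iterations_per_epoch:
            trace.append([q.copy() for q in qs])
    return qs, F, trace


def expected_free_energy(
    model: GenerativeModel,
    qs: list[np.ndarray],
    policy: np.ndarray,
    current_t: int,
    risk: str = "kl",
    _pre: _Precomputed | None = None,
) -> float:
    """Expected free energy G (risk + ambiguity) over remaining time points.

    Risk is the KL divergence of each modality's predicted outcome
    distribution from the preference distribution (softmax of the
    log-preferences); ambiguity is the expected conditional entropy of the
    likelihood.  While likelihood learning is enabled, the expected
    information gain about the Dirichlet parameters (novelty) is
    subtracted, so poorly sampled state-outcome pairings attract behavior;
    without it, an early mislearned evaluation mapping is never retested
    and learning can lock into a wrong model.
    """
    pre = _pre if _pre is not None else _Precomputed(model)
    T = model.n_timesteps
    G = 0.0
    for tau in range(current_t + 1, T):
        qs_tau = [qs[f][tau] for f in range(len(qs))]
        for m in range(len(model.modalities)):
            o_pred = pre.A_norm[m]
            for g in range(len(qs_tau) - 1, -1, -1):
                o_pred = np.tensordot(o_pred, qs_tau[g], axes=([g + 1], [0]))
            o_pred = np.clip(o_pred, 0.0, None)
            if risk == "kl":
                ln_o = np.log(np.maximum(o_pred, pre.floor))
                G += float(o_pred @ (ln_o - pre.lnC[m][:, tau]))
            else:
                G -= float(o_pred @ pre.lnC[m][:, tau])
            G += _contract_all(pre.H[m], qs_tau)
            if pre.novelty is not None:
                G -= _contract_all(pre.novelty[m], qs_tau)
        if pre.novelty_b is not None:
            for f in range(len(qs)):
                nb = pre.novelty_b[f]
                if nb is None:
                    continue
                G -= float(nb[policy[tau - 1, f]] @ qs[f][tau - 1])
    return G


def policy_posterior(
    F_per_policy: np.ndarray, G_per_policy: np.ndarray, gamma: float
) -> np.ndarray:
    """Softmax policy posterior, pi = sigma(-F - gamma * G)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return _softmax(-np.asarray(F_per_policy) - gamma * np.asarray(G_per_policy))


def update_precision(
    beta_prior: float,
    G_per_policy: np.ndarray,
    pi: np.ndarray,
    n_iter: int = 16,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Fixed-point update of the policy precision gamma = 1 / beta.

    Solves ``beta = beta_prior + (pi - pi_G) . G`` with
    ``pi_G = softmax(-gamma G)``; beta is floored at a small positive value
    if the update would drive it nonpositive.
    """
    if beta_prior <= 0:
        raise ValueError("beta_prior must be positive")
    G = np.asarray(G_per_policy, dtype=float)
    beta = beta_prior
    for _ in range(n_iter):
        pi_G = _softmax(-G / beta)
        beta_new = beta_prior + float((pi - pi_G) @ G)
        if beta_new <= 0:
            beta_new = 1e-6
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    return 1.0 / beta, beta


def select_action(
    pi: np.ndarray,
    policies: np.ndarray,
    transition: int,
    alpha: float,
    rng: np.random.Generator,
    n_actions_per_factor: list[int] | None = None,
) -> np.ndarray:
    """Sample one action per factor from the precision-weighted marginals.

    The marginal probability of action u for a factor is the summed
    posterior mass of policies prescribing u at this transition; the
    realized action is sampled from ``softmax(alpha * ln marginal)``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_policies, n_transitions, n_factors = policies.shape
    if not 0 <= transition < n_transitions:
        raise ValueError("transition index out of range")
    if n_actions_per_factor is None:
        n_actions_per_factor = [int(policies[:, :, f].max()) + 1 for f in range(n_factors)]
    actions = np.zeros(n_factors, dtype=int)
    for f in range(n_factors):
        n_u = n_actions_per_factor[f]
        if n_u == 1:
            continue
        marginal = np.zeros(n_u)
        for p in range(n_policies):
            marginal[policies[p, transition, f]] += pi[p]
        if marginal.sum() <= 0:
            raise ValueError("all action marginals are zero")
        marginal = marginal / marginal.sum()
        weights = _softmax(alpha * np.log(np.maximum(marginal, LOG_FLOOR)))
        actions[f] = int(rng.choice(n_u, p=weights))
    return actions


def _bma(per_policy: list[list[np.ndarray]], pi: np.ndarray) -> list[np.ndarray]:
    n_factors = len(per_policy[0])
    out = []
    for f in range(n_factors):
        acc = np.zeros_like(per_policy[0][f])
        for p, qs in enumerate(per_policy):
            acc += pi[p] * qs[f]
        out.append(acc)
    return out


def _prior_trajectories(pre: _Precomputed, model: GenerativeModel) -> list[list[np.ndarray]]:
    """Per-policy predictive prior over the trajectory before any outcome."""
    T = model.n_timesteps
    out = []
    for p in range(model.n_policies):
        qs = []
        for f in range(len(model.factors)):
            traj = np.zeros((T, model.factors[f].n_levels))
            traj[0] = pre.D_norm[f]
            for tau in range(1, T):
                traj[tau] = pre.B_norm[f][model.policies[p, tau - 1, f]] @ traj[tau - 1]
            qs.append(traj)
        out.append(qs)
    return out


def run_trial(
    model: GenerativeModel,
    config: TrialConfig = TrialConfig(),
    settings: InferenceSettings = InferenceSettings(),
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Run one three-epoch trial of perception, planning and action.

    Each epoch the agent observes an outcome, re-infers its beliefs under
    every policy, scores policies by F and G, updates the policy precision,
    and (before the final epoch) samples a word to say.  Per-epoch
    free-energy components are computed per hidden factor from the
    Bayesian-model-average posterior against the pre-update predictive
    prior; the accuracy term is shared equally across factors so the
    decomposition identities hold factor-wise.
    """
    if rng is None:
        rng = np.random.default_rng()
    if settings.risk == "auto":
        effective_risk = "kl" if model.learn_a else "utility"
    else:
        effective_risk = settings.risk
    pre = _Precomputed(model, settings.log_floor)
    n_factors = len(model.factors)
    n_actions = [model.b[f].shape[0] for f in range(n_factors)]
    T = model.n_timesteps
    record = TrialRecord(config=config, n_timesteps=T)

    state = init_trial(rng, config)
    per_policy = _prior_trajectories(pre, model)
    pi = np.full(model.n_policies, 1.0 / model.n_policies)
    prior_bma = _bma(per_policy, pi)
    outcomes_so_far: list = []

    for t in range(T):
        record.true_states.append(state)
        o = emit_outcome(state, config)
        record.outcomes.append(o)
        outcomes_so_far.append(o)
        fields = _likelihood_fields(pre, outcomes_so_far)

        # The agent knows which actions it has taken: only policies
        # consistent with them remain in play.
        allowed = [
            p
            for p in range(model.n_policies)
            if all(
                np.array_equal(model.policies[p, tp], record.actions[tp])
                for tp in range(len(record.actions))
            )
        ]
        F = np.zeros(model.n_policies)
        G = np.zeros(model.n_policies)
        traces: list[list[list[np.ndarray]] | None] = [None] * model.n_policies
        for p in allowed:
            qs, F_p, trace = infer_states(
                model,
                outcomes_so_far,
                model.policies[p],
                settings,
                init=per_policy[p],
                _pre=pre,
                _fields=fields,
            )
            per_policy[p] = qs
            F[p] = F_p
            G[p] = expected_free_energy(
                model, qs, model.policies[p], t, risk=effective_risk, _pre=pre
            )
            traces[p] = trace

        beta = model.beta_prior
        gamma = 1.0 / beta
        F_a, G_a = F[allowed], G[allowed]
        pi_a = np.full(len(allowed), 1.0 / len(allowed))
        for _ in range(settings.precision_iters):
            pi_a = policy_posterior(F_a, G_a, gamma)
            gamma_new, beta = update_precision(model.beta_prior, G_a, pi_a)
            if abs(gamma_new - gamma) < 1e-6:
                gamma = gamma_new
                break
            gamma = gamma_new
        pi_a = policy_posterior(F_a, G_a, gamma)
        pi = np.zeros(model.n_policies)
        pi[allowed] = pi_a

        bma = _bma([per_policy[p] for p in allowed], pi_a)
        record.beliefs.append(
            BeliefState(
                per_policy=per_policy,
                bma=bma,
                iteration_trace=traces if settings.store_traces else None,
            )
        )
        record.policy_inference.append(
            PolicyInference(
                F_per_policy=F, G_per_policy=G, policy_posterior=pi, gamma=gamma, beta=beta
            )
        )
        record.priors.append([q.copy() for q in prior_bma])

        # Accuracy of the observed outcome under the BMA present-time belief.
        qs_t = [bma[f][t] for f in range(n_factors)]
        idx = o.as_tuple()
        accuracy = 0.0
        for m in range(len(model.modalities)):
            accuracy += _contract_all(pre.lnA_norm[m][idx[m]], qs_t)
        comps = []
        comps_present = []
        for f in range(n_factors):
            comp = free_energy_components(bma[f], prior_bma[f], accuracy / n_factors)
            comps.append(comp)
            q_now = bma[f][t]
            h_now = float(-np.sum(q_now * np.log(np.maximum(q_now, settings.log_floor))))
            comps_present.append(
                FreeEnergyComponents(
                    F=comp.F,
                    accuracy=comp.accuracy,
                    complexity=comp.complexity,
                    entropy=h_now,
                    cost=comp.complexity + h_now,
                    energy=comp.F + h_now,
                )
            )
        record.components.append(comps)
        record.components_present.append(comps_present)

        if t < T - 1:
            u = select_action(pi, model.policies, t, model.alpha, rng, n_actions)
            record.actions.append(u)
            state = apply_action(state, int(u[model.factor_index("repeated_word")]))
        prior_bma = [q.copy() for q in bma]

    return record
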