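"""Generative-model data structures for discrete-state active inference.

A generative model here is a discrete (POMDP-style) joint distribution over
hidden states and outcomes, parameterized by Dirichlet concentration arrays:

* ``a`` — likelihood counts, one array per outcome modality with shape
  ``(n_outcomes, *state_dims)``; normalizing each conditioning column gives
  ``P(o | s)``.
* ``b`` — transition counts, one array per hidden factor with shape
  ``(n_actions, n_levels, n_levels)`` mapping previous level (last axis) to
  next level; uncontrollable factors carry a single action.
* ``c`` — log-preferences over outcomes per time step (nats).
* ``d`` — initial-state counts per factor.

Concentration parameters act as pseudocounts: they encode connection
strengths and are incremented by experience (see :mod:`wordrep.plasticity`).

The module also builds the word-repetition model used throughout the
package: three hidden factors (epoch, target word, repeated word), three
outcome modalities (proprioception, audition, evaluation), five one-word
policies, and the deliberately spurious repeated-word level "read" that is
heard as "red".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma

__all__ = [
    "FactorSpec",
    "ModalitySpec",
    "GenerativeModel",
    "LOG_FLOOR",
    "build_word_repetition_model",
    "normalize_counts",
    "expected_log_probability",
    "validate_model",
    "model_to_json",
    "model_from_json",
]

#: Small positive floor used inside every logarithm and for "zero" counts.
LOG_FLOOR = float(np.exp(-16.0))

PLAUSIBLE = 1.0
IMPLAUSIBLE = 0.5

EPOCHS = ["listen", "repeat", "feedback"]
TARGETS = ["red", "blue", "triangle", "square"]
REPEATS = ["red", "read", "triangle", "square", "blue"]
AUDITION = ["red", "blue", "triangle", "square"]
PROPRIOCEPTION = ["still", "moving"]
EVALUATION = ["neutral", "positive", "negative"]

#: Auditory word produced when speaking each repeated-word level
#: ("read" is pronounced like "red").
SPOKEN_TO_AUDITION = {
    "red": "red",
    "read": "red",
    "triangle": "triangle",
    "square": "square",
    "blue": "blue",
}


@dataclass(frozen=True)
class FactorSpec:
    """One hidden-state factor: a name, its ordered levels, controllability."""

    name: str
    level_labels: tuple[str, ...]
    controllable: bool = False

    def __post_init__(self) -> None:
        if len(self.level_labels) < 2:
            raise ValueError(f"factor {self.name!r} needs at least 2 levels")
        if len(set(self.level_labels)) != len(self.level_labels):
            raise ValueError(f"factor {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)


@dataclass(frozen=True)
class ModalitySpec:
    """One outcome modality: a name and its ordered outcome labels."""

    name: str
    level_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.level_labels) < 2:
            raise ValueError(f"modality {self.name!r} needs at least 2 levels")
        if len(set(self.level_labels)) != len(self.level_labels):
            raise ValueError(f"modality {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)


@dataclass
class GenerativeModel:
    """Dirichlet-parameterized discrete generative model.

    Attributes
    ----------
    factors, modalities
        Structural specifications of hidden states and outcomes.
    a
        Likelihood concentration arrays, ``a[m]`` with shape
        ``(modalities[m].n_levels, *state_dims)``.
    b
        Transition concentration arrays, ``b[f]`` with shape
        ``(n_actions_f, n_levels_f, n_levels_f)``; ``b[f][u][next, prev]``.
    c
        Log-preferences in nats, ``c[m]`` with shape
        ``(modalities[m].n_levels, n_timesteps)``.
    d
        Initial-state counts, ``d[f]`` with shape ``(n_levels_f,)``.
    policies
        Integer array ``(n_policies, n_transitions, n_factors)`` of action
        indices per factor (0 for uncontrollable factors).
    alpha
        Action-selection precision.
    beta_prior
        Prior rate of the policy precision gamma (gamma = 1 / beta).
    learn_a, learn_b, learn_d
        Which concentration arrays accumulate experience.
    """

    factors: list[FactorSpec]
    modalities: list[ModalitySpec]
    a: list[np.ndarray]
    b: list[np.ndarray]
    c: list[np.ndarray]
    d: list[np.ndarray]
    policies: np.ndarray
    alpha: float = 16.0
    beta_prior: float = 1.0
    learn_a: bool = True
    learn_b: bool = True
    learn_d: bool = False
    #: Per-factor override for transition learning (None = all factors when
    #: ``learn_b``).  Transitions of an uncontrollable context factor whose
    #: level is never directly observed (the target word) are task structure
    #: the subject brings to the experiment; learning them from diffuse
    #: beliefs is unidentifiable and degenerates.
    learn_b_factors: tuple[bool, ...] | None = None
    n_timesteps: int = 3

    @property
    def state_dims(self) -> tuple[int, ...]:
        return tuple(f.n_levels for f in self.factors)

    @property
    def n_policies(self) -> int:
        return int(self.policies.shape[0])

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise KeyError(f"unknown factor {name!r}")

    def modality_index(self, name: str) -> int:
        for i, m in enumerate(self.modalities):
            if m.name == name:
                return i
        raise KeyError(f"unknown modality {name!r}")

    def copy(self) -> "GenerativeModel":
        return replace(
            self,
            a=[x.copy() for x in self.a],
            b=[x.copy() for x in self.b],
            c=[x.copy() for x in self.c],
            d=[x.copy() for x in self.d],
            policies=self.policies.copy(),
        )


def normalize_counts(counts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Normalize concentration counts to conditional probability vectors.

    Each conditioning column (along ``axis``) is divided by its sum.

    Raises
    ------
    ValueError
        If any entry is negative or any column sums to zero.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("concentration counts must be nonnegative")
    total = counts.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("degenerate input: conditioning column with zero sum")
    return counts / total


def expected_log_probability(counts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Dirichlet expected log-probability, digamma(n) - digamma(sum n).

    This is the quantity the variational updates use in place of
    ``ln P``; for large counts it converges to ``ln(normalize_counts)``
    from below.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("expected_log_probability requires strictly positive counts")
    return digamma(counts) - digamma(counts.sum(axis=axis, keepdims=True))


def _plausible(shape: tuple[int, ...], mask: np.ndarray) -> np.ndarray:
    arr = np.full(shape, IMPLAUSIBLE)
    arr[mask] = PLAUSIBLE
    return arr


def build_word_repetition_model(spurious: bool = True) -> GenerativeModel:
    """Construct the word-repetition generative model.

    Three hidden factors — epoch (3 levels, a fixed chain), target word
    (4 levels, identity transitions) and repeated word (5 levels including
    the spurious "read", fully controllable) — generate proprioceptive,
    auditory and evaluative outcomes.  Plausible mappings receive
    concentration 1, implausible ones 0.5.  Preferences put +0.5 nats on a
    positive evaluation at the third epoch.  Five deep policies, one per
    sayable word, each repeat their word-action at both transitions.

    ``spurious=False`` applies the structure-learning flattening of all
    likelihood columns conditioned on repeated word "read" (concentration
    10, i.e. uniform predictions) to the freshly built model; in the
    experiments the flattening is instead applied to post-learning counts
    via :func:`wordrep.plasticity.make_nonspurious`.
    """
    factors = [
        FactorSpec("epoch", tuple(EPOCHS), controllable=False),
        FactorSpec("target_word", tuple(TARGETS), controllable=False),
        FactorSpec("repeated_word", tuple(REPEATS), controllable=True),
    ]
    modalities = [
        ModalitySpec("proprioception", tuple(PROPRIOCEPTION)),
        ModalitySpec("audition", tuple(AUDITION)),
        ModalitySpec("evaluation", tuple(EVALUATION)),
    ]
    nE, nT, nR = len(EPOCHS), len(TARGETS), len(REPEATS)
    aud_of_target = np.array([AUDITION.index(w) for w in TARGETS])
    aud_of_spoken = np.array([AUDITION.index(SPOKEN_TO_AUDITION[w]) for w in REPEATS])

    # Proprioception depends on epoch only: "moving" iff epoch 2.
    mask = np.zeros((2, nE, nT, nR), dtype=bool)
    for e in range(nE):
        mask[1 if e == 1 else 0, e, :, :] = True
    a_prop = _plausible(mask.shape, mask)

    # Audition: target word at epoch 1; spoken word (read -> red) at epochs 2-3.
    mask = np.zeros((len(AUDITION), nE, nT, nR), dtype=bool)
    for t in range(nT):
        mask[aud_of_target[t], 0, t, :] = True
    for r in range(nR):
        mask[aud_of_spoken[r], 1, :, r] = True
        mask[aud_of_spoken[r], 2, :, r] = True
    a_aud = _plausible(mask.shape, mask)

    # Evaluation: neutral at epochs 1-2; at epoch 3 positive iff the spoken
    # word sounds like the target (so "read" counts as matching "red").
    mask = np.zeros((len(EVALUATION), nE, nT, nR), dtype=bool)
    mask[0, 0, :, :] = True
    mask[0, 1, :, :] = True
    for t in range(nT):
        for r in range(nR):
            correct = aud_of_spoken[r] == aud_of_target[t]
            mask[1 if correct else 2, 2, t, r] = True
    a_eval = _plausible(mask.shape, mask)

    # Transitions.  Epoch: fixed chain 1 -> 2 -> 3 with 3 absorbing.
    mask = np.zeros((1, nE, nE), dtype=bool)
    for prev in range(nE):
        mask[0, min(prev + 1, nE - 1), prev] = True
    b_epoch = _plausible(mask.shape, mask)

    # Target word: identity.
    mask = np.eye(nT, dtype=bool)[None, :, :]
    b_target = _plausible(mask.shape, mask)

    # Repeated word: action k sends every previous level to level k.
    mask = np.zeros((nR, nR, nR), dtype=bool)
    for k in range(nR):
        mask[k, k, :] = True
    b_repeat = _plausible(mask.shape, mask)

    # Log-preferences: +0.5 nats for a positive evaluation at epoch 3.
    c = [np.zeros((m.n_levels, nE)) for m in modalities]
    c[2][EVALUATION.index("positive"), 2] = 0.5

    # Initial-state counts: 10 on every target/repeated level; epoch counts
    # 10 on level 1 and a small floor elsewhere (a literal zero would make
    # ln P undefined).
    d = [
        np.array([10.0] + [10.0 * LOG_FLOOR] * (nE - 1)),
        np.full(nT, 10.0),
        np.full(nR, 10.0),
    ]

    # Five deep policies, policy k = (action k, action k) on the repeated
    # word; uncontrollable factors always take action 0.
    policies = np.zeros((nR, nE - 1, len(factors)), dtype=int)
    for k in range(nR):
        policies[k, :, 2] = k

    model = GenerativeModel(
        factors=factors,
        modalities=modalities,
        a=[a_prop, a_aud, a_eval],
        b=[b_epoch, b_target, b_repeat],
        c=c,
        d=d,
        policies=policies,
        alpha=16.0,
        beta_prior=1.0,
        learn_b_factors=(True, False, True),
        n_timesteps=nE,
    )
    if not spurious:
        from .plasticity import make_nonspurious

        model = make_nonspurious(model)
    problems = validate_model(model)
    if problems:  # pragma: no cover - constructor must validate
        raise AssertionError("invalid built model: " + "; ".join(problems))
    return model


def validate_model(model: GenerativeModel) -> list[str]:
    """Return a human-readable diagnostic per violated invariant (empty if valid)."""
    problems: list[str] = []
    dims = model.state_dims
    for m, spec in enumerate(model.modalities):
        arr = model.a[m]
        expected = (spec.n_levels,) + dims
        if arr.shape != expected:
            problems.append(
                f"likelihood for modality {spec.name!r} has shape {arr.shape}, expected {expected}"
            )
            continue
        if np.any(arr < 0):
            problems.append(f"likelihood for modality {spec.name!r} has negative counts")
        colsums = arr.sum(axis=0)
        if np.any(colsums <= 0):
            bad = np.argwhere(colsums <= 0)[0]
            problems.append(
                f"likelihood for modality {spec.name!r} has zero-sum column at state {tuple(bad)}"
            )
    for f, spec in enumerate(model.factors):
        arr = model.b[f]
        if arr.ndim != 3 or arr.shape[1:] != (spec.n_levels, spec.n_levels):
            problems.append(f"transition array for factor {spec.name!r} has shape {arr.shape}")
            continue
        if np.any(arr < 0):
            problems.append(f"transition array for factor {spec.name!r} has negative counts")
        if np.any(arr.sum(axis=1) <= 0):
            problems.append(f"transition array for factor {spec.name!r} has zero-sum column")
        if np.any(model.d[f] < 0) or model.d[f].sum() <= 0:
            problems.append(f"initial counts for factor {spec.name!r} are degenerate")
    if model.policies.ndim != 3 or model.policies.shape[2] != len(model.factors):
        problems.append("policy array must be (n_policies, n_transitions, n_factors)")
    else:
        if model.policies.shape[1] != model.n_timesteps - 1:
            problems.append(
                f"policies must have length {model.n_timesteps - 1}, got {model.policies.shape[1]}"
            )
        for f, spec in enumerate(model.factors):
            n_actions = model.b[f].shape[0]
            if np.any(model.policies[:, :, f] >= n_actions):
                problems.append(f"policy action out of range for factor {spec.name!r}")
    if {f.name for f in model.factors} == {"epoch", "target_word", "repeated_word"}:
        if model.n_policies != 5:
            problems.append(
                f"word-repetition model requires 5 policies, got {model.n_policies}"
            )
    if model.alpha <= 0:
        problems.append("action precision alpha must be positive")
    if model.beta_prior <= 0:
        problems.append("precision prior beta must be positive")
    return problems


# ---------------------------------------------------------------------------
# Serialization (JSON-compatible; count arrays round-trip bit-stable)


def model_to_json(model: GenerativeModel) -> str:
    payload = {
        "factors": [
            {"name": f.name, "levels": list(f.level_labels), "controllable": f.controllable}
            for f in model.factors
        ],
        "modalities": [
            {"name": m.name, "levels": list(m.level_labels)} for m in model.modalities
        ],
        "a": [x.tolist() for x in model.a],
        "b": [x.tolist() for x in model.b],
        "c": [x.tolist() for x in model.c],
        "d": [x.tolist() for x in model.d],
        "policies": model.policies.tolist(),
        "alpha": model.alpha,
        "beta_prior": model.beta_prior,
        "learn_a": model.learn_a,
        "learn_b": model.learn_b,
        "learn_d": model.learn_d,
        "learn_b_factors": list(model.learn_b_factors)
        if model.learn_b_factors is not None
        else None,
        "n_timesteps": model.n_timesteps,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> GenerativeModel:
    payload = json.loads(text)
    return GenerativeModel(
        factors=[
            FactorSpec(f["name"], tuple(f["levels"]), f["controllable"])
            for f in payload["factors"]
        ],
        modalities=[ModalitySpec(m["name"], tuple(m["levels"])) for m in payload["modalities"]],
        a=[np.asarray(x, dtype=float) for x in payload["a"]],
        b=[np.asarray(x, dtype=float) for x in payload["b"]],
        c=[np.asarray(x, dtype=float) for x in payload["c"]],
        d=[np.asarray(x, dtype=float) for x in payload["d"]],
        policies=np.asarray(payload["policies"], dtype=int),
        alpha=float(payload["alpha"]),
        beta_prior=float(payload["beta_prior"]),
        learn_a=bool(payload["learn_a"]),
        learn_b=bool(payload["learn_b"]),
        learn_d=bool(payload["learn_d"]),
        learn_b_factors=tuple(payload["learn_b_factors"])
        if payload.get("learn_b_factors") is not None
        else None,
        n_timesteps=int(payload["n_timesteps"]),
    )
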