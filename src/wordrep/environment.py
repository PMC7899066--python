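"""The word-repetition experiment as a deterministic generative process.

The environment plays the experimenter: it draws a target word, presents it
auditorily in the first epoch, registers the agent's spoken word in the
second, and delivers an evaluation in the third (positive iff the spoken
word *sounds like* the target, so speaking "read" for target "red" counts
as correct).  For the violation (oddball) paradigm the third-epoch
evaluation can be forced to any level regardless of correctness.

Outcomes are a pure deterministic function of the true state; the only
randomness is the draw of the target word.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AUDITION,
    EVALUATION,
    PROPRIOCEPTION,
    REPEATS,
    SPOKEN_TO_AUDITION,
    TARGETS,
)

__all__ = ["TrueState", "OutcomeTuple", "TrialConfig", "init_trial", "emit_outcome", "apply_action"]

N_EPOCHS = 3
_AUD_OF_TARGET = [AUDITION.index(w) for w in TARGETS]
_AUD_OF_SPOKEN = [AUDITION.index(SPOKEN_TO_AUDITION[w]) for w in REPEATS]
_NEUTRAL = EVALUATION.index("neutral")
_POSITIVE = EVALUATION.index("positive")
_NEGATIVE = EVALUATION.index("negative")


@dataclass(frozen=True)
class TrueState:
    """Realized hidden state of one epoch (all indices 0-based)."""

    epoch: int
    target_word: int
    repeated_word: int

    def __post_init__(self) -> None:
        if not 0 <= self.epoch < N_EPOCHS:
            raise ValueError(f"epoch index {self.epoch} out of range")
        if not 0 <= self.target_word < len(TARGETS):
            raise ValueError(f"target word index {self.target_word} out of range")
        if not 0 <= self.repeated_word < len(REPEATS):
            raise ValueError(f"repeated word index {self.repeated_word} out of range")


@dataclass(frozen=True)
class OutcomeTuple:
    """Observed outcome indices: (proprioception, audition, evaluation)."""

    proprioception: int
    audition: int
    evaluation: int

    def __post_init__(self) -> None:
        if not 0 <= self.proprioception < len(PROPRIOCEPTION):
            raise ValueError("proprioception outcome out of range")
        if not 0 <= self.audition < len(AUDITION):
            raise ValueError("audition outcome out of range")
        if not 0 <= self.evaluation < len(EVALUATION):
            raise ValueError("evaluation outcome out of range")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.proprioception, self.audition, self.evaluation)


@dataclass(frozen=True)
class TrialConfig:
    """Per-trial experimental configuration.

    ``forced_target`` pins the target word (used in the violation paradigm,
    where it is always "red"); ``forced_evaluation`` overrides the computed
    third-epoch evaluation to produce standards/deviants.
    """

    forced_target: int | None = None
    forced_evaluation: int | None = None
    n_epochs: int = N_EPOCHS

    def __post_init__(self) -> None:
        if self.n_epochs != N_EPOCHS:
            raise ValueError("the word-repetition paradigm has exactly 3 epochs")
        if self.forced_target is not None and not 0 <= self.forced_target < len(TARGETS):
            raise ValueError(f"forced_target {self.forced_target} out of range")
        if self.forced_evaluation is not None and not 0 <= self.forced_evaluation < len(EVALUATION):
            raise ValueError(f"forced_evaluation {self.forced_evaluation} out of range")


def init_trial(rng: np.random.Generator, config: TrialConfig = TrialConfig()) -> TrueState:
    """Start a trial: epoch 1, target drawn uniformly unless forced.

    Nothing has been spoken yet, so the true repeated-word level is fixed to
    level 0; it affects no epoch-1 outcome.
    """
    if config.forced_target is not None:
        target = config.forced_target
    else:
        target = int(rng.integers(len(TARGETS)))
    return TrueState(epoch=0, target_word=target, repeated_word=0)


def emit_outcome(state: TrueState, config: TrialConfig = TrialConfig()) -> OutcomeTuple:
    """Generate the outcome tuple for the current true state (deterministic)."""
    moving = 1 if state.epoch == 1 else 0
    if state.epoch == 0:
        audition = _AUD_OF_TARGET[state.target_word]
    else:
        audition = _AUD_OF_SPOKEN[state.repeated_word]
    if state.epoch < 2:
        evaluation = _NEUTRAL
    else:
        correct = _AUD_OF_SPOKEN[state.repeated_word] == _AUD_OF_TARGET[state.target_word]
        evaluation = _POSITIVE if correct else _NEGATIVE
        if config.forced_evaluation is not None:
            evaluation = config.forced_evaluation
    return OutcomeTuple(proprioception=moving, audition=audition, evaluation=evaluation)


def apply_action(state: TrueState, action: int) -> TrueState:
    """Advance the world by one epoch: the agent speaks the action's word.

    The epoch chain is 1 -> 2 -> 3 with 3 absorbing; the target word never
    changes; the repeated word becomes the chosen word.
    """
    if not 0 <= action < len(REPEATS):
        raise ValueError(f"action {action} out of range")
    return TrueState(
        epoch=min(state.epoch + 1, N_EPOCHS - 1),
        target_word=state.target_word,
        repeated_word=action,
    )
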