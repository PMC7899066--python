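"""Free-energy decompositions: accuracy/complexity and energy/entropy.

Variational free energy of a posterior Q against a prior P and observed
outcomes decomposes two ways::

    F = complexity - accuracy = energy - entropy

with ``complexity = KL[Q || P]`` (the belief-updating cost, here read as
*redundancy*), ``accuracy = E_Q[ln P(o|s)]``, ``entropy = E_Q[-ln Q]``
(posterior uncertainty, here read as *degeneracy*) and
``energy = E_Q[-ln P(s, o)]``.  A companion identity relates the two
readings: ``redundancy = cost - degeneracy`` with
``cost = E_Q[-ln P(s)]`` the cross-entropy of the posterior on the prior.

All quantities are in nats.  This module computes the decomposition for
arbitrary categorical beliefs, aggregates per-epoch/per-factor bundles to
trial and group level, and scores behavioral accuracy (percent correct
repetitions) — which is distinct from statistical accuracy above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import LOG_FLOOR

__all__ = [
    "FreeEnergyComponents",
    "AggregationSpec",
    "GroupResult",
    "free_energy_components",
    "redundancy_decomposition",
    "trial_measures",
    "behavioral_accuracy",
    "group_summary",
]

_IDENTITY_TOL = 1e-8


@dataclass
class FreeEnergyComponents:
    """The F = complexity − accuracy = energy − entropy bundle (nats).

    ``redundancy`` is an alias for complexity and ``degeneracy`` for
    entropy, following the operational definitions used throughout the
    package.
    """

    F: float = 0.0
    accuracy: float = 0.0
    complexity: float = 0.0
    entropy: float = 0.0
    cost: float = 0.0
    energy: float = 0.0

    @property
    def redundancy(self) -> float:
        return self.complexity

    @property
    def degeneracy(self) -> float:
        return self.entropy

    def verify(self, tol: float = _IDENTITY_TOL) -> None:
        """Re-check the decomposition identities; raise on violation."""
        if abs(self.F - (self.complexity - self.accuracy)) > tol:
            raise AssertionError("identity violated: F != complexity - accuracy")
        if abs(self.F - (self.energy - self.entropy)) > tol:
            raise AssertionError("identity violated: F != energy - entropy")
        if abs(self.complexity - (self.cost - self.entropy)) > tol:
            raise AssertionError("identity violated: complexity != cost - entropy")

    def __add__(self, other: "FreeEnergyComponents") -> "FreeEnergyComponents":
        return FreeEnergyComponents(
            F=self.F + other.F,
            accuracy=self.accuracy + other.accuracy,
            complexity=self.complexity + other.complexity,
            entropy=self.entropy + other.entropy,
            cost=self.cost + other.cost,
            energy=self.energy + other.energy,
        )

    def scaled(self, factor: float) -> "FreeEnergyComponents":
        return FreeEnergyComponents(
            F=self.F * factor,
            accuracy=self.accuracy * factor,
            complexity=self.complexity * factor,
            entropy=self.entropy * factor,
            cost=self.cost * factor,
            energy=self.energy * factor,
        )

    @staticmethod
    def mean(items: list["FreeEnergyComponents"]) -> "FreeEnergyComponents":
        if not items:
            raise ValueError("cannot average an empty component list")
        total = FreeEnergyComponents()
        for item in items:
            total = total + item
        return total.scaled(1.0 / len(items))


def _check_simplex(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-9):
        raise ValueError(f"{name} has negative entries")
    sums = x.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"{name} rows must sum to 1")
    return np.clip(x, 0.0, None)


def free_energy_components(
    Q: np.ndarray, P: np.ndarray, loglik_at_outcome: float
) -> FreeEnergyComponents:
    """Assemble the free-energy bundle from posterior, prior and likelihood.

    Parameters
    ----------
    Q, P
        Posterior and prior categorical beliefs; arrays whose last axis is
        the probability simplex.  Leading axes (e.g. time points) are summed.
    loglik_at_outcome
        Expected log-likelihood of the observed outcomes under Q (the
        accuracy term), supplied by the inference engine.
    """
    Q = _check_simplex(Q, "posterior Q")
    P = _check_simplex(P, "prior P")
    if Q.shape != P.shape:
        raise ValueError("posterior and prior must have matching shapes")
    lnQ = np.log(np.maximum(Q, LOG_FLOOR))
    lnP = np.log(np.maximum(P, LOG_FLOOR))
    complexity = float(np.sum(Q * (lnQ - lnP)))
    entropy = float(-np.sum(Q * lnQ))
    cost = float(-np.sum(Q * lnP))
    accuracy = float(loglik_at_outcome)
    F = complexity - accuracy
    out = FreeEnergyComponents(
        F=F,
        accuracy=accuracy,
        complexity=complexity,
        entropy=entropy,
        cost=cost,
        energy=F + entropy,
    )
    out.verify()
    return out


def redundancy_decomposition(Q: np.ndarray, P: np.ndarray) -> tuple[float, float, float]:
    """Return ``(cost, degeneracy, redundancy)`` for posterior Q and prior P."""
    comp = free_energy_components(Q, P, loglik_at_outcome=0.0)
    return comp.cost, comp.entropy, comp.complexity


@dataclass(frozen=True)
class AggregationSpec:
    """How per-epoch, per-factor components reduce to one trial scalar.

    ``factor_op`` and ``epoch_op`` are ``"sum"`` or ``"mean"`` over hidden
    factors and epochs; ``time_op`` rescales the within-epoch sum over the
    three posterior time points (``"sum"`` keeps it, ``"mean"`` divides by
    the trial length).  ``entropy_scope`` selects whether degeneracy is the
    entropy of the whole posterior trajectory (``"trajectory"``) or only of
    the beliefs about the present, just-observed time point (``"present"``);
    complexity always scores the full trajectory shift and cost is defined
    as complexity + entropy, so the identities hold either way.  The
    package default was fixed once against the reference control-condition
    magnitudes.
    """

    time_op: str = "sum"
    factor_op: str = "sum"
    epoch_op: str = "mean"
    entropy_scope: str = "present"

    def __post_init__(self) -> None:
        for name in ("time_op", "factor_op", "epoch_op"):
            if getattr(self, name) not in ("sum", "mean"):
                raise ValueError(f"{name} must be 'sum' or 'mean'")
        if self.entropy_scope not in ("trajectory", "present"):
            raise ValueError("entropy_scope must be 'trajectory' or 'present'")


DEFAULT_AGGREGATION = AggregationSpec()


def trial_measures(record, agg: AggregationSpec = DEFAULT_AGGREGATION) -> FreeEnergyComponents:
    """Reduce a trial's per-epoch, per-factor components to one bundle."""
    source = (
        record.components
        if agg.entropy_scope == "trajectory"
        else getattr(record, "components_present", None)
    )
    if not source:
        raise ValueError("trial record carries no per-epoch components")
    per_epoch: list[FreeEnergyComponents] = []
    for epoch_comps in source:
        total = FreeEnergyComponents()
        for comp in epoch_comps:
            total = total + comp
        if agg.factor_op == "mean":
            total = total.scaled(1.0 / len(epoch_comps))
        per_epoch.append(total)
    out = FreeEnergyComponents()
    for item in per_epoch:
        out = out + item
    if agg.epoch_op == "mean":
        out = out.scaled(1.0 / len(per_epoch))
    if agg.time_op == "mean":
        out = out.scaled(1.0 / record.n_timesteps)
    out.verify(1e-7)
    return out


def behavioral_accuracy(records) -> float:
    """Percent of unforced trials whose final evaluation was positive."""
    from .model import EVALUATION

    positive = EVALUATION.index("positive")
    scored = [r for r in records if r.config.forced_evaluation is None]
    if not scored:
        raise ValueError("no unforced trials to score")
    n_correct = sum(1 for r in scored if r.outcomes[-1].evaluation == positive)
    return 100.0 * n_correct / len(scored)


@dataclass
class GroupResult:
    """One group-level summary row (means over trials and subjects)."""

    label: str
    spurious: bool
    trials_per_agent: int
    free_energy: float
    redundancy: float
    degeneracy: float
    cost: float
    energy: float
    accuracy: float
    behavioral_accuracy: float = float("nan")

    def verify(self, tol: float = 1e-6) -> None:
        comp = FreeEnergyComponents(
            F=self.free_energy,
            accuracy=self.accuracy,
            complexity=self.redundancy,
            entropy=self.degeneracy,
            cost=self.cost,
            energy=self.energy,
        )
        comp.verify(tol)


def group_summary(
    trial_components: list[FreeEnergyComponents],
    behavioral_percent: float,
    label: str,
    spurious: bool,
    trials_per_agent: int,
) -> GroupResult:
    """Average per-trial bundles into one results-table row."""
    if not trial_components:
        raise ValueError("group summary requires at least one trial")
    mean = FreeEnergyComponents.mean(trial_components)
    result = GroupResult(
        label=label,
        spurious=spurious,
        trials_per_agent=trials_per_agent,
        free_energy=mean.F,
        redundancy=mean.complexity,
        degeneracy=mean.entropy,
        cost=mean.cost,
        energy=mean.energy,
        accuracy=mean.accuracy,
        behavioral_accuracy=behavioral_percent,
    )
    result.verify()
    return result
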