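"""Simulated local-field potentials from belief-updating dynamics.

The variational sweeps within each epoch are read as a neuronally
plausible gradient flow: the firing rate of a population encoding one
expectation follows the iteration trace, and the simulated depolarization
(LFP) is its first temporal derivative.  Each epoch is mapped onto a
configurable span of peristimulus time (default 250 ms), and mismatch
(difference) waves are deviant-minus-standard subtractions on a shared
time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import TrialRecord
from .model import GenerativeModel

__all__ = [
    "ErpTrace",
    "PopulationSelector",
    "simulate_population_response",
    "mmn_difference",
    "average_traces",
]


@dataclass
class ErpTrace:
    """A peristimulus time series (seconds, arbitrary amplitude units)."""

    time: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.shape != self.amplitude.shape:
            raise ValueError("time and amplitude grids must match")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class PopulationSelector:
    """Which expectation a simulated population encodes.

    ``kind="state"`` selects the belief ``Q(factor = level)`` at the given
    represented time point.  ``kind="outcome"`` selects the predicted
    probability of an outcome (modality level) at that time point — the
    default population responds to the "positive" evaluation expected at
    the third epoch.
    """

    kind: str = "outcome"
    label: str = "evaluation"
    level: str = "positive"
    timepoint: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("state", "outcome"):
            raise ValueError("selector kind must be 'state' or 'outcome'")


DEFAULT_SELECTOR = PopulationSelector()


def _selector_value(
    selector: PopulationSelector, model: GenerativeModel, qs: list[np.ndarray]
) -> float:
    tau = selector.timepoint
    if selector.kind == "state":
        f = model.factor_index(selector.label)
        level = model.factors[f].level_labels.index(selector.level)
        return float(qs[f][tau][level])
    m = model.modality_index(selector.label)
    level = model.modalities[m].level_labels.index(selector.level)
    pred = model.a[m] / model.a[m].sum(axis=0, keepdims=True)
    for g in range(len(qs) - 1, -1, -1):
        pred = np.tensordot(pred, qs[g][tau], axes=([g + 1], [0]))
    return float(pred[level])


def simulate_population_response(
    record: TrialRecord,
    model: GenerativeModel,
    selector: PopulationSelector = DEFAULT_SELECTOR,
    bins_per_iteration: int = 4,
    epoch_duration: float = 0.25,
) -> ErpTrace:
    """Turn a trial's iteration traces into a simulated LFP.

    The selected expectation is evaluated at every variational sweep of
    every epoch (Bayesian-model-averaged over policies with that epoch's
    policy posterior), linearly interpolated onto a finer peristimulus
    grid, and differentiated in time.  A constant expectation yields an
    identically zero trace.
    """
    if not record.beliefs or record.beliefs[0].iteration_trace is None:
        raise ValueError("trial record retains no iteration traces")
    snap_t: list[float] = []
    snap_v: list[float] = []
    for t, belief in enumerate(record.beliefs):
        traces = belief.iteration_trace
        pi = record.policy_inference[t].policy_posterior
        live = [p for p, tr in enumerate(traces) if tr is not None]
        n_iter = len(traces[live[0]])
        for i in range(n_iter):
            qs_bma = []
            for f in range(len(model.factors)):
                acc = np.zeros_like(traces[live[0]][i][f])
                for p in live:
                    acc += pi[p] * traces[p][i][f]
                qs_bma.append(acc)
            snap_t.append(epoch_duration * (t + (i + 0.5) / n_iter))
            snap_v.append(_selector_value(selector, model, qs_bma))
    snap_t_arr = np.array(snap_t)
    snap_v_arr = np.array(snap_v)
    fine_t = np.linspace(
        snap_t_arr[0], snap_t_arr[-1], bins_per_iteration * len(snap_t_arr)
    )
    fine_v = np.interp(fine_t, snap_t_arr, snap_v_arr)
    amplitude = np.gradient(fine_v, fine_t)
    return ErpTrace(time=fine_t, amplitude=amplitude)


def mmn_difference(standard: ErpTrace, deviant: ErpTrace) -> ErpTrace:
    """Pointwise deviant-minus-standard difference wave."""
    if standard.time.shape != deviant.time.shape or not np.allclose(
        standard.time, deviant.time
    ):
        raise ValueError("traces must share a time grid")
    return ErpTrace(time=standard.time.copy(), amplitude=deviant.amplitude - standard.amplitude)


def average_traces(traces: list[ErpTrace]) -> ErpTrace:
    """Subject-mean trace (traces must share a time grid)."""
    if not traces:
        raise ValueError("no traces to average")
    base = traces[0]
    for tr in traces[1:]:
        if not np.allclose(tr.time, base.time):
            raise ValueError("traces must share a time grid")
    amp = np.mean([tr.amplitude for tr in traces], axis=0)
    return ErpTrace(time=base.time.copy(), amplitude=amp)
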