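"""Experience-dependent plasticity and structural interventions.

Three ways the concentration arrays change:

* **Dirichlet accumulation** — Hebbian-like pseudocount increments from a
  trial's posterior beliefs and observed outcomes/actions.
* **Structure learning** — offline flattening of every likelihood column
  conditioned on the spurious repeated-word level "read" (concentration 10,
  i.e. uniform predictions), disconnecting that state from the sensorium.
* **Lesions** — precision reductions of a likelihood or transition array:
  each conditional column p is replaced by ``normalize(p ** eta)`` with the
  column total preserved, so the strongest connections weaken and the
  weakest strengthen.  ``eta = 1`` is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenerativeModel, normalize_counts

__all__ = ["LesionSpec", "accumulate_dirichlet", "make_nonspurious", "lesion"]


@dataclass(frozen=True)
class LesionSpec:
    """A precision lesion: which array, and how strongly.

    ``target_kind`` is ``"likelihood"`` (label = a modality, the extrinsic
    lesion) or ``"transition"`` (label = a factor, the intrinsic lesion);
    ``exponent`` is the precision hyperparameter in (0, 1].
    """

    target_kind: str
    target_label: str
    exponent: float

    def __post_init__(self) -> None:
        if self.target_kind not in ("likelihood", "transition"):
            raise ValueError("target_kind must be 'likelihood' or 'transition'")
        if not 0.0 < self.exponent <= 1.0:
            raise ValueError("lesion exponent must lie in (0, 1]")


#: The two lesions studied in the experiments: the extrinsic lesion reduces
#: the precision of the evaluation likelihood (1 -> 0.4); the intrinsic
#: lesion reduces the precision of the target-word transitions (1 -> 0.5).
LESION_A = LesionSpec("likelihood", "evaluation", 0.4)
LESION_B = LesionSpec("transition", "target_word", 0.5)


def accumulate_dirichlet(
    model: GenerativeModel, record, learning_rate: float = 1.0
) -> GenerativeModel:
    """Accumulate pseudocounts from one trial (in place; model returned).

    Likelihood counts at each observed outcome grow by the outer product of
    the posterior state expectations; transition counts under each taken
    action grow by the outer product of consecutive posterior expectations.
    Counts never decrease.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    final = record.beliefs[-1].bma
    T = model.n_timesteps
    if len(final) != len(model.factors):
        raise ValueError("record and model disagree on the number of factors")
    for f, q in enumerate(final):
        if q.shape != (T, model.factors[f].n_levels):
            raise ValueError(f"belief shape mismatch for factor {model.factors[f].name!r}")
    if model.learn_a:
        for tau in range(T):
            qs_tau = [final[f][tau] for f in range(len(model.factors))]
            joint = qs_tau[0]
            for q in qs_tau[1:]:
                joint = np.multiply.outer(joint, q)
            idx = record.outcomes[tau].as_tuple()
            for m in range(len(model.modalities)):
                model.a[m][idx[m]] += learning_rate * joint
    if model.learn_b:
        # Two-slice (pair) marginals, not products of marginals.  The pair
        # belief xi(s', s) = B(s'|s) q(s) * [q(s') / (B q)(s')] corrects the
        # forward prediction by the actual posterior, exactly as in
        # forward-backward smoothing for a chain.  A plain outer product of
        # diffuse marginals loses the within-trial correlation that
        # identifies persistent states and accumulates a rank-one
        # "everything maps to the average" matrix; the uncorrected
        # B-weighted product instead amplifies whatever the current
        # transition model believes.
        for tau in range(1, T):
            u = record.actions[tau - 1]
            for f in range(len(model.factors)):
                if model.learn_b_factors is not None and not model.learn_b_factors[f]:
                    continue
                B = model.b[f][int(u[f])]
                B = B / B.sum(axis=0, keepdims=True)
                q_prev = final[f][tau - 1]
                q_next = final[f][tau]
                pred = B @ q_prev
                w = np.where(pred > 1e-12, q_next / np.maximum(pred, 1e-12), 0.0)
                xi = (w[:, None] * B) * q_prev[None, :]
                total = xi.sum()
                if total <= 0:
                    continue
                xi = xi / total
                # Precision-weighted plasticity: the increment is scaled by
                # the confidence (negentropy) of the beliefs at *both* ends
                # of the pairing, so nothing is written unless pre- and
                # post-synaptic states are individually well resolved.  A
                # confident successor paired with a diffuse predecessor
                # would otherwise deposit an "all states lead here" stripe,
                # and during the noisy early phase of learning that drift
                # feeds back through inference until every word maps to the
                # same successor.
                n = len(q_prev)
                conf_prev = max(
                    0.0, 1.0 + float(np.sum(q_prev * np.log(np.maximum(q_prev, 1e-12)))) / np.log(n)
                )
                conf_next = max(
                    0.0, 1.0 + float(np.sum(q_next * np.log(np.maximum(q_next, 1e-12)))) / np.log(n)
                )
                model.b[f][int(u[f])] += learning_rate * conf_prev * conf_next * xi

    if model.learn_d:
        for f in range(len(model.factors)):
            model.d[f] += learning_rate * final[f][0]
    return model


def transition_pair_increment(
    model: GenerativeModel, record, factor: int
) -> dict[int, np.ndarray]:
    """Two-slice transition counts for one factor of one trial, per action.

    Used for offline consolidation of factors whose transition learning is
    deferred (see :func:`consolidate_transitions`): the pair marginals are
    computed against the model's *current* (structural) transition prior,
    and scaled by the confidence of both marginals, exactly as in
    :func:`accumulate_dirichlet`.
    """
    final = record.beliefs[-1].bma
    T = model.n_timesteps
    out: dict[int, np.ndarray] = {}
    for tau in range(1, T):
        u = int(record.actions[tau - 1][factor])
        B = model.b[factor][u]
        B = B / B.sum(axis=0, keepdims=True)
        q_prev = final[factor][tau - 1]
        q_next = final[factor][tau]
        pred = B @ q_prev
        w = np.where(pred > 1e-12, q_next / np.maximum(pred, 1e-12), 0.0)
        xi = (w[:, None] * B) * q_prev[None, :]
        total = xi.sum()
        if total <= 0:
            continue
        xi = xi / total
        n = len(q_prev)
        conf_prev = max(
            0.0, 1.0 + float(np.sum(q_prev * np.log(np.maximum(q_prev, 1e-12)))) / np.log(n)
        )
        conf_next = max(
            0.0, 1.0 + float(np.sum(q_next * np.log(np.maximum(q_next, 1e-12)))) / np.log(n)
        )
        inc = conf_prev * conf_next * xi
        out[u] = out.get(u, 0.0) + inc
    return out


def consolidate_transitions(
    model: GenerativeModel, pending: dict[int, np.ndarray], factor: int
) -> GenerativeModel:
    """Add deferred (offline) transition counts for one factor, in place.

    Transition learning for a hidden context that is observed only once
    per trial (the target word) is circular when performed online: beliefs
    about later time points derive from the very transition prior being
    learned, so early sampling noise feeds back through inference until
    every level maps to the same successor.  Deferring the accumulated
    pair counts to a single end-of-phase (offline, sleep-like) update
    breaks that loop while preserving the experience-dependent counts.
    """
    for u, inc in pending.items():
        model.b[factor][int(u)] += inc
    return model


def make_nonspurious(
    model: GenerativeModel,
    flatten_value: float = 10.0,
    flatten_modalities: tuple[str, ...] = ("audition",),
) -> GenerativeModel:
    """Remove the spurious state by flattening its likelihood mappings.

    Every likelihood concentration of the named modalities whose
    conditioning context has repeated word "read" is set to
    ``flatten_value``, making the normalized columns uniform and
    disconnecting the spurious state from the outcomes it generates.  By
    default only the audition mapping — the outcome that speaking "read"
    actually produces — is flattened; flattening the evaluation mapping as
    well would make the disconnected state's predictions *agreeable* under
    weak preferences and turn it into an attractor for behavior rather
    than a redundant alternative.  Idempotent; returns a new model.
    """
    out = model.copy()
    f_rep = out.factor_index("repeated_word")
    spec = out.factors[f_rep]
    if "read" not in spec.level_labels:
        raise ValueError("model has no spurious 'read' level to remove")
    read = spec.level_labels.index("read")
    for name in flatten_modalities:
        m = out.modality_index(name)
        sl = [slice(None)] * out.a[m].ndim
        sl[1 + f_rep] = read
        out.a[m][tuple(sl)] = flatten_value
    return out


def _power_columns(counts: np.ndarray, exponent: float, axis: int) -> np.ndarray:
    """Temperature transform of each conditional column, totals preserved."""
    totals = counts.sum(axis=axis, keepdims=True)
    p = normalize_counts(counts, axis=axis)
    q = p**exponent
    q = q / q.sum(axis=axis, keepdims=True)
    return q * totals


def lesion(model: GenerativeModel, spec: LesionSpec) -> GenerativeModel:
    """Apply a precision lesion to the named array; returns a new model."""
    out = model.copy()
    if spec.exponent == 1.0:
        return out
    if spec.target_kind == "likelihood":
        m = out.modality_index(spec.target_label)
        out.a[m] = _power_columns(out.a[m], spec.exponent, axis=0)
    else:
        f = out.factor_index(spec.target_label)
        out.b[f] = _power_columns(out.b[f], spec.exponent, axis=1)
    return out
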