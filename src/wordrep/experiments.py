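"""Orchestration of the four experiment families.

1. **Learning** — 50 subjects acquire the task over 500 trials with
   Dirichlet learning on (spurious model), yielding learning curves of
   free energy, redundancy and degeneracy.
2. **Structure learning** — the spurious "read" likelihood of each
   post-learning model is flattened and the task re-run (learning off) to
   compare spurious vs nonspurious groups.
3. **Lesion groups** — precision lesions to the evaluation likelihood
   (extrinsic, "A"), the target-word transitions (intrinsic, "B"), or
   both, crossed with spuriousness: the eight-row results table.
4. **Violation paradigm** — standard/deviant evaluation at the final
   epoch, with belief-update traces retained for simulated evoked
   responses.

All randomness derives from a base seed; subject s uses seed
``base_seed + s`` for learning and a documented offset per evaluation
context, so identical seeds reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import TrialConfig
from .inference import InferenceSettings, TrialRecord, run_trial
from .measures import (
    DEFAULT_AGGREGATION,
    AggregationSpec,
    FreeEnergyComponents,
    GroupResult,
    behavioral_accuracy,
    group_summary,
    trial_measures,
)
from .model import EVALUATION, TARGETS, GenerativeModel, build_word_repetition_model
from .plasticity import (
    LESION_A,
    LESION_B,
    LesionSpec,
    accumulate_dirichlet,
    consolidate_transitions,
    lesion,
    make_nonspurious,
    transition_pair_increment,
)

__all__ = [
    "GroupSpec",
    "LearningCurves",
    "LearningPhaseResult",
    "run_learning_phase",
    "run_group",
    "run_all_groups",
    "run_violation_paradigm",
    "PAPER_GROUPS",
]

_POSITIVE = EVALUATION.index("positive")
_NEGATIVE = EVALUATION.index("negative")

# Seed offsets keeping the rng streams of the experiment stages disjoint.
_EVAL_SEED_OFFSET = 700_001
_ERP_SEED_OFFSET = 900_001


@dataclass(frozen=True)
class GroupSpec:
    """One row of the group-comparison design."""

    label: str
    spurious: bool
    lesions: tuple[LesionSpec, ...] = ()
    n_subjects: int = 50
    n_trials: int = 10
    learning_enabled: bool = False
    base_seed: int = 0


#: The eight groups of the results table: {Control, B, A, A-and-B} x {Y, N}.
PAPER_GROUPS: tuple[tuple[str, bool, tuple[LesionSpec, ...]], ...] = (
    ("Control", True, ()),
    ("Control", False, ()),
    ("B", True, (LESION_B,)),
    ("B", False, (LESION_B,)),
    ("A", True, (LESION_A,)),
    ("A", False, (LESION_A,)),
    ("A and B", True, (LESION_A, LESION_B)),
    ("A and B", False, (LESION_A, LESION_B)),
)


@dataclass
class LearningCurves:
    """Trial-indexed means over subjects of F, redundancy and degeneracy."""

    free_energy: np.ndarray
    redundancy: np.ndarray
    degeneracy: np.ndarray

    def __len__(self) -> int:
        return len(self.free_energy)


@dataclass
class LearningPhaseResult:
    curves: LearningCurves
    models: list[GenerativeModel]
    #: ``trial_components[s][i]`` — aggregated bundle of subject s, trial i.
    trial_components: list[list[FreeEnergyComponents]]
    #: ``correct[s][i]`` — whether trial i ended with a positive evaluation.
    correct: list[list[bool]]

    def mean_components(self) -> FreeEnergyComponents:
        flat = [c for subj in self.trial_components for c in subj]
        return FreeEnergyComponents.mean(flat)

    def last_trials_accuracy(self, n: int = 10) -> float:
        """Mean percent correct over each subject's last ``n`` trials."""
        per_subject = [100.0 * np.mean(c[-n:]) for c in self.correct]
        return float(np.mean(per_subject))


def run_learning_phase(
    n_subjects: int = 50,
    n_trials: int = 500,
    settings: InferenceSettings = InferenceSettings(),
    base_seed: int = 0,
    agg: AggregationSpec = DEFAULT_AGGREGATION,
    progress: bool = False,
) -> LearningPhaseResult:
    """Simulate task acquisition: per-subject Dirichlet learning from scratch."""
    all_components: list[list[FreeEnergyComponents]] = []
    all_correct: list[list[bool]] = []
    models: list[GenerativeModel] = []
    for s in range(n_subjects):
        model = build_word_repetition_model(spurious=True)
        rng = np.random.default_rng(base_seed + s)
        comps: list[FreeEnergyComponents] = []
        correct: list[bool] = []
        # Target-word transition counts are consolidated offline at the end
        # of the phase (see plasticity.consolidate_transitions).
        f_target = model.factor_index("target_word")
        pending: dict[int, np.ndarray] = {}
        for _ in range(n_trials):
            record = run_trial(model, TrialConfig(), settings, rng)
            accumulate_dirichlet(model, record)
            for u, inc in transition_pair_increment(model, record, f_target).items():
                pending[u] = pending.get(u, 0.0) + inc
            comps.append(trial_measures(record, agg))
            correct.append(record.outcomes[-1].evaluation == _POSITIVE)
        consolidate_transitions(model, pending, f_target)
        models.append(model)
        all_components.append(comps)
        all_correct.append(correct)
        if progress:
            print(f"  subject {s + 1}/{n_subjects} done", flush=True)
    curves = LearningCurves(
        free_energy=np.array(
            [np.mean([all_components[s][i].F for s in range(n_subjects)]) for i in range(n_trials)]
        ),
        redundancy=np.array(
            [
                np.mean([all_components[s][i].complexity for s in range(n_subjects)])
                for i in range(n_trials)
            ]
        ),
        degeneracy=np.array(
            [
                np.mean([all_components[s][i].entropy for s in range(n_subjects)])
                for i in range(n_trials)
            ]
        ),
    )
    return LearningPhaseResult(curves, models, all_components, all_correct)


def _prepare_model(base: GenerativeModel, spurious: bool, lesions: tuple[LesionSpec, ...]):
    model = base.copy() if spurious else make_nonspurious(base)
    for spec in lesions:
        model = lesion(model, spec)
    model.learn_a = False
    model.learn_b = False
    model.learn_d = False
    return model


def run_group(
    spec: GroupSpec,
    models: list[GenerativeModel],
    settings: InferenceSettings = InferenceSettings(),
    agg: AggregationSpec = DEFAULT_AGGREGATION,
) -> GroupResult:
    """Evaluate one group on the post-learning models (learning off)."""
    if len(models) < spec.n_subjects:
        raise ValueError("not enough post-learning models for the group")
    comps: list[FreeEnergyComponents] = []
    records: list[TrialRecord] = []
    for s in range(spec.n_subjects):
        model = _prepare_model(models[s], spec.spurious, spec.lesions)
        rng = np.random.default_rng(spec.base_seed + _EVAL_SEED_OFFSET + s)
        for _ in range(spec.n_trials):
            record = run_trial(model, TrialConfig(), settings, rng)
            comps.append(trial_measures(record, agg))
            records.append(record)
    return group_summary(
        comps,
        behavioral_accuracy(records),
        label=spec.label,
        spurious=spec.spurious,
        trials_per_agent=spec.n_trials,
    )


@dataclass
class ExperimentResults:
    """The learning phase plus the eight-row group table."""

    learning: LearningPhaseResult
    table: list[GroupResult]


def run_all_groups(
    settings: InferenceSettings = InferenceSettings(),
    base_seed: int = 0,
    n_subjects: int = 50,
    n_trials_learn: int = 500,
    n_trials_eval: int = 10,
    agg: AggregationSpec = DEFAULT_AGGREGATION,
    learning: LearningPhaseResult | None = None,
    progress: bool = False,
) -> ExperimentResults:
    """Produce the full results table, sharing one learning phase.

    The spurious control row summarizes the learning trials themselves
    (behavioral accuracy from the last 10 trials); every other row re-runs
    the task on the frozen post-learning models.
    """
    if learning is None:
        learning = run_learning_phase(
            n_subjects, n_trials_learn, settings, base_seed, agg, progress=progress
        )
    mean = learning.mean_components()
    table: list[GroupResult] = [
        GroupResult(
            label="Control",
            spurious=True,
            trials_per_agent=n_trials_learn,
            free_energy=mean.F,
            redundancy=mean.complexity,
            degeneracy=mean.entropy,
            cost=mean.cost,
            energy=mean.energy,
            accuracy=mean.accuracy,
            behavioral_accuracy=learning.last_trials_accuracy(min(10, n_trials_learn)),
        )
    ]
    for i, (label, spurious, lesions) in enumerate(PAPER_GROUPS[1:], start=1):
        spec = GroupSpec(
            label=label,
            spurious=spurious,
            lesions=lesions,
            n_subjects=n_subjects,
            n_trials=n_trials_eval,
            base_seed=base_seed + 10_000 * i,
        )
        table.append(run_group(spec, learning.models, settings, agg))
        if progress:
            print(f"  group {label}/{'Y' if spurious else 'N'} done", flush=True)
    return ExperimentResults(learning=learning, table=table)


def run_violation_paradigm(
    models: list[GenerativeModel],
    settings: InferenceSettings | None = None,
    base_seed: int = 0,
    n_subjects: int | None = None,
) -> dict[str, dict]:
    """Standard vs deviant evaluation trials for the four lesion groups.

    Uses the nonspurious specification with the target fixed to "red"; the
    standard trial forces a positive evaluation and the deviant a negative
    one, so the two trials of a subject differ only in the final-epoch
    evaluation.  Belief-iteration traces are retained for LFP simulation.
    """
    if settings is None:
        settings = InferenceSettings(store_traces=True)
    elif not settings.store_traces:
        raise ValueError("violation paradigm requires store_traces=True")
    if n_subjects is None:
        n_subjects = len(models)
    red = TARGETS.index("red")
    groups = {
        "Control": (),
        "B": (LESION_B,),
        "A": (LESION_A,),
        "A and B": (LESION_A, LESION_B),
    }
    out: dict[str, dict] = {}
    for label, lesions in groups.items():
        pairs = []
        group_models = []
        for s in range(n_subjects):
            model = _prepare_model(models[s], spurious=False, lesions=lesions)
            standard_cfg = TrialConfig(forced_target=red, forced_evaluation=_POSITIVE)
            deviant_cfg = TrialConfig(forced_target=red, forced_evaluation=_NEGATIVE)
            seed = base_seed + _ERP_SEED_OFFSET + s
            standard = run_trial(model, standard_cfg, settings, np.random.default_rng(seed))
            deviant = run_trial(model, deviant_cfg, settings, np.random.default_rng(seed))
            pairs.append((standard, deviant))
            group_models.append(model)
        out[label] = {"pairs": pairs, "models": group_models}
    return out
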