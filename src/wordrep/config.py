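"""Run configuration and tabular output.

Configurations are YAML (JSON-compatible) mappings with documented
defaults; outputs are plain CSV so results tables, learning curves and
ERP traces are diffable across runs.  Identical config + seed reproduces
identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import InferenceSettings
from .measures import AggregationSpec, GroupResult
from .plasticity import LesionSpec

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_results_table",
    "write_curves",
    "write_erp",
]

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Validated top-level run configuration with defaults filled in."""

    seed: int = 0
    n_subjects: int = 50
    n_trials_learn: int = 500
    n_trials_eval: int = 10
    out_dir: str = "results"
    verbose: bool = False
    settings: InferenceSettings = field(default_factory=InferenceSettings)
    aggregation: AggregationSpec = field(default_factory=AggregationSpec)
    #: Extra lesion groups beyond the standard eight-row design, each a
    #: mapping {label, spurious, lesions: [{target_kind, target_label, exponent}]}.
    extra_groups: list[dict] = field(default_factory=list)


_KNOWN_KEYS = {
    "seed",
    "n_subjects",
    "n_trials_learn",
    "n_trials_eval",
    "out_dir",
    "verbose",
    "settings",
    "aggregation",
    "extra_groups",
}


def _parse_lesion(raw: dict) -> LesionSpec:
    try:
        return LesionSpec(
            target_kind=raw["target_kind"],
            target_label=raw["target_label"],
            exponent=float(raw["exponent"]),
        )
    except KeyError as exc:
        raise ValueError(f"lesion spec missing field {exc.args[0]!r}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the all-defaults configuration.  Unknown keys and
    invalid values raise ``ValueError`` naming the offending field.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key in ("seed", "n_subjects", "n_trials_learn", "n_trials_eval"):
        if key in raw:
            value = int(raw[key])
            if value < 0 or (key != "seed" and value < 1):
                raise ValueError(f"configuration field {key!r} must be positive")
            setattr(cfg, key, value)
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    if "verbose" in raw:
        cfg.verbose = bool(raw["verbose"])
    if "settings" in raw:
        try:
            cfg.settings = InferenceSettings(**raw["settings"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid inference settings: {exc}") from exc
    if "aggregation" in raw:
        try:
            cfg.aggregation = AggregationSpec(**raw["aggregation"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid aggregation spec: {exc}") from exc
    if "extra_groups" in raw:
        for g in raw["extra_groups"]:
            for lraw in g.get("lesions", []):
                _parse_lesion(lraw)  # validate eagerly, error names the field
        cfg.extra_groups = list(raw["extra_groups"])
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    payload = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_trials_learn": cfg.n_trials_learn,
        "n_trials_eval": cfg.n_trials_eval,
        "out_dir": cfg.out_dir,
        "verbose": cfg.verbose,
        "settings": dataclasses.asdict(cfg.settings),
        "aggregation": dataclasses.asdict(cfg.aggregation),
        "extra_groups": cfg.extra_groups,
    }
    Path(path).write_text(yaml.safe_dump(payload))


def write_results_table(results: list[GroupResult], path: str | Path) -> None:
    """Write GroupResults as CSV in the results-table column order."""
    if not results:
        raise ValueError("no results to write")
    rows = [
        {
            "group": r.label,
            "spurious": "Y" if r.spurious else "N",
            "trials_per_agent": r.trials_per_agent,
            "free_energy": r.free_energy,
            "redundancy": r.redundancy,
            "degeneracy": r.degeneracy,
            "cost": r.cost,
            "energy": r.energy,
            "accuracy": r.accuracy,
            "behavioral_accuracy": r.behavioral_accuracy,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_curves(curves, path: str | Path) -> None:
    """Write learning curves (trial index, F, redundancy, degeneracy) as CSV."""
    if len(curves) == 0:
        raise ValueError("no curves to write")
    df = pd.DataFrame(
        {
            "trial": np.arange(1, len(curves) + 1),
            "free_energy": curves.free_energy,
            "redundancy": curves.redundancy,
            "degeneracy": curves.degeneracy,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_erp(dataset: dict[str, dict[str, object]], path: str | Path) -> None:
    """Write ERP traces in long format (group, condition, time_s, amplitude)."""
    if not dataset:
        raise ValueError("no ERP traces to write")
    rows = []
    for group, conditions in dataset.items():
        for condition, trace in conditions.items():
            for t, amp in zip(trace.time, trace.amplitude):
                rows.append(
                    {"group": group, "condition": condition, "time_s": t, "amplitude": amp}
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
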