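"""Readers and writers for ratings data, trial tables, and model parameters.

Formats
-------
Aggregated ratings: long CSV with header ``stimulus_id,attribute,rating,count``
(missing cells are zero).  Per-trial tables: long CSV with header
``participant,phase,stimulus_id,attribute,rating``.  Model parameters: JSON
with ``spec`` / ``stimuli`` / ``ideal`` / ``criteria`` blocks, schema
versioned; liking criteria are serialized on both the distance scale and the
squared-distance scale (they are bijective; the distance scale is canonical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    HEDONIC_ATTRIBUTE,
    CriteriaSet,
    GrtUnfoldingModel,
    IdealDistribution,
    ModelSpec,
    RatingDataset,
    StimulusDistribution,
)
from .simulate import TRIAL_COLUMNS

SCHEMA_VERSION = 1

RATINGS_COLUMNS = ("stimulus_id", "attribute", "rating", "count")


class DataValidationError(ValueError):
    """A data file failed validation; the message names the offending rows."""


# ---------------------------------------------------------------------------
# Aggregated ratings CSV
# ---------------------------------------------------------------------------


def read_ratings(path: str | Path, spec: ModelSpec) -> RatingDataset:
    """Read an aggregated long-format ratings CSV into a RatingDataset.

    Cells absent from the file are treated as zero counts.  Unknown stimuli
    or attributes, out-of-scale ratings, and negative or non-integer counts
    are reported with their row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataValidationError(f"{path}: no rating rows found")
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    attrs = list(spec.attributes)
    problems = []
    for idx, row in df.iterrows():
        line = idx + 1
        if row["stimulus_id"] not in spec.stimulus_ids:
            problems.append(f"row {line}: unknown stimulus {row['stimulus_id']!r}")
        if row["attribute"] not in attrs:
            problems.append(f"row {line}: unknown attribute {row['attribute']!r}")
        if not (1 <= int(row["rating"]) <= spec.n_ratings):
            problems.append(
                f"row {line}: rating {row['rating']} outside 1..{spec.n_ratings}"
            )
        count = row["count"]
        if count < 0 or float(count) != int(count):
            problems.append(f"row {line}: count {count!r} must be a nonnegative integer")
    if problems:
        raise DataValidationError(f"{path}: " + "; ".join(problems))
    counts = np.zeros((spec.n_stimuli, spec.n_dims + 1, spec.n_ratings), dtype=int)
    sid_index = {s: i for i, s in enumerate(spec.stimulus_ids)}
    attr_index = {a: k for k, a in enumerate(attrs)}
    for _, row in df.iterrows():
        counts[sid_index[row["stimulus_id"]], attr_index[row["attribute"]], int(row["rating"]) - 1] += int(row["count"])
    return RatingDataset(spec=spec, counts=counts)


def write_ratings(dataset: RatingDataset, path: str | Path) -> None:
    """Write a RatingDataset as a long-format CSV (all cells, zeros included)."""
    spec = dataset.spec
    rows = []
    for i, sid in enumerate(spec.stimulus_ids):
        for a, attr in enumerate(spec.attributes):
            for j in range(spec.n_ratings):
                rows.append((sid, attr, j + 1, int(dataset.counts[i, a, j])))
    pd.DataFrame(rows, columns=list(RATINGS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trial tables and engagement filtering
# ---------------------------------------------------------------------------


def read_trials(path: str | Path, spec: ModelSpec) -> pd.DataFrame:
    """Read and validate a per-trial long table."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    return validate_trials(df, spec)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def validate_trials(trials: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    attrs = set(spec.attributes)
    bad_attr = ~trials["attribute"].isin(attrs)
    bad_rating = ~trials["rating"].between(1, spec.n_ratings)
    bad_stim = ~trials["stimulus_id"].isin(spec.stimulus_ids)
    problems = []
    for mask, what in [(bad_attr, "attribute"), (bad_rating, "rating"), (bad_stim, "stimulus_id")]:
        if mask.any():
            rows = (trials.index[mask] + 1).tolist()[:5]
            problems.append(f"invalid {what} in rows {rows}")
    if problems:
        raise DataValidationError("; ".join(problems))
    return trials


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of the engagement filter: what was dropped and why."""

    excluded_hedonic_phases: int
    excluded_sensory_phases: int
    retained_hedonic_phases: int
    retained_sensory_phases: int
    reasons: tuple[str, ...]

    @property
    def total_hedonic_phases(self) -> int:
        return self.excluded_hedonic_phases + self.retained_hedonic_phases

    @property
    def total_sensory_phases(self) -> int:
        return self.excluded_sensory_phases + self.retained_sensory_phases


def filter_disengaged_phases(
    trials: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participant-phases showing disengaged (repetitive) responding.

    A hedonic participant-phase is excluded when it contains 3 or fewer
    distinct liking ratings across stimuli.  A sensory participant-phase is
    excluded entirely when any single dimension received the same rating for
    every stimulus in that phase.  The filtering unit is the
    (participant, phase) pair; a phase's hedonic and sensory portions are
    filtered independently under their own rules.
    """
    validate_trials(trials, spec)
    is_hed = trials["attribute"] == HEDONIC_ATTRIBUTE
    hed = trials[is_hed]
    sens = trials[~is_hed]
    reasons: list[str] = []

    hed_excluded_keys = set()
    hed_groups = hed.groupby(["participant", "phase"], sort=False)
    for key, grp in hed_groups:
        if grp["rating"].nunique() <= 3:
            hed_excluded_keys.add(key)
            reasons.append(
                f"hedonic phase {key}: only {grp['rating'].nunique()} distinct rating(s)"
            )
    n_hed_phases = len(hed_groups)

    sens_excluded_keys = set()
    sens_groups = sens.groupby(["participant", "phase"], sort=False)
    for key, grp in sens_groups:
        flat = grp.groupby("attribute")["rating"].nunique()
        offenders = flat[flat == 1].index.tolist()
        if offenders:
            sens_excluded_keys.add(key)
            reasons.append(
                f"sensory phase {key}: constant rating on dimension(s) {offenders}"
            )
    n_sens_phases = len(sens_groups)

    def keep(df: pd.DataFrame, excluded: set) -> pd.DataFrame:
        keys = list(zip(df["participant"], df["phase"]))
        mask = [k not in excluded for k in keys]
        return df[mask]

    filtered = pd.concat([keep(sens, sens_excluded_keys), keep(hed, hed_excluded_keys)])
    filtered = filtered.sort_index()
    report = ExclusionReport(
        excluded_hedonic_phases=len(hed_excluded_keys),
        excluded_sensory_phases=len(sens_excluded_keys),
        retained_hedonic_phases=n_hed_phases - len(hed_excluded_keys),
        retained_sensory_phases=n_sens_phases - len(sens_excluded_keys),
        reasons=tuple(reasons),
    )
    return filtered, report


def aggregate_trials(trials: pd.DataFrame, spec: ModelSpec) -> RatingDataset:
    """Aggregate a (filtered) trial table into a rating-frequency array."""
    validate_trials(trials, spec)
    counts = np.zeros((spec.n_stimuli, spec.n_dims + 1, spec.n_ratings), dtype=int)
    sid_index = {s: i for i, s in enumerate(spec.stimulus_ids)}
    attr_index = {a: k for k, a in enumerate(spec.attributes)}
    grouped = trials.groupby(["stimulus_id", "attribute", "rating"]).size()
    for (sid, attr, rating), n in grouped.items():
        counts[sid_index[sid], attr_index[attr], int(rating) - 1] = int(n)
    return RatingDataset(spec=spec, counts=counts)


# ---------------------------------------------------------------------------
# Model parameter JSON
# ---------------------------------------------------------------------------


def write_model(model: GrtUnfoldingModel, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "spec": {
            "n_stimuli": model.spec.n_stimuli,
            "n_dims": model.spec.n_dims,
            "n_ratings": model.spec.n_ratings,
            "dimension_names": list(model.spec.dimension_names),
            "stimulus_ids": list(model.spec.stimulus_ids),
            "reference_stimulus": model.spec.reference_stimulus,
        },
        "stimuli": [
            {"stimulus_id": s.stimulus_id, "mean": s.mean.tolist()}
            for s in model.stimuli
        ],
        "ideal": {
            "mean": model.ideal.mean.tolist(),
            "covariance": model.ideal.covariance.tolist(),
        },
        "criteria": {
            "sensory": model.criteria.sensory.tolist(),
            "liking_distance": model.criteria.liking.tolist(),
            "liking_squared_distance": (model.criteria.liking**2).tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path: str | Path) -> GrtUnfoldingModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DataValidationError(f"{path}: unsupported schema version {version!r}")
    spec = ModelSpec(**payload["spec"])
    stimuli = tuple(
        StimulusDistribution(stimulus_id=s["stimulus_id"], mean=np.array(s["mean"]))
        for s in payload["stimuli"]
    )
    ideal = IdealDistribution(
        mean=np.array(payload["ideal"]["mean"]),
        covariance=np.array(payload["ideal"]["covariance"]),
    )
    criteria = CriteriaSet(
        sensory=np.array(payload["criteria"]["sensory"]),
        liking=np.array(payload["criteria"]["liking_distance"]),
    )
    return GrtUnfoldingModel(spec=spec, stimuli=stimuli, ideal=ideal, criteria=criteria)


def write_fit_report(result, path: str | Path) -> None:
    """Serialize a FitResult's bookkeeping (not the model itself) as JSON."""
    from .model import count_free_parameters

    opts = result.options
    payload = {
        "schema_version": SCHEMA_VERSION,
        "options": {
            "optimizer": opts.optimizer,
            "n_restarts": opts.n_restarts,
            "seed": opts.seed,
            "max_iterations": opts.max_iterations,
            "tolerance": opts.tolerance,
            "eigenvalue_floor": opts.eigenvalue_floor,
            "objective_scale": opts.objective_scale,
            "covariance_structure": opts.covariance_structure,
        },
        "free_parameters": count_free_parameters(
            result.model.spec, opts.covariance_structure
        ),
        "sse": result.sse,
        "r_squared": {
            "overall": result.r_squared_overall,
            "sensory": result.r_squared_sensory,
            "hedonic": result.r_squared_hedonic,
        },
        "converged": result.converged,
        "n_evaluations": result.n_evaluations,
        "restart_scores": list(result.restart_scores),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
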