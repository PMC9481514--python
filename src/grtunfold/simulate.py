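"""Synthetic ratings data from a known GRT-unfolding model.

Emulates the one-rating-per-trial concurrent-ratings design: on every trial a
single attribute of a single stimulus is rated, and every rating request
consumes a fresh percept draw (and, for liking, a fresh imagined-ideal draw) —
re-examining a stimulus yields a new sensory sample, so no within-trial reuse.

Defaults mirror the reference study design: 20 stimuli rated on 6 sensory
dimensions plus liking on 7-point scales, with 56 ratings per sensory cell and
52 per hedonic cell after aggregating across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

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
    delta_squared_moments,
)

TRIAL_COLUMNS = ("participant", "phase", "stimulus_id", "attribute", "rating")


@dataclass(frozen=True)
class SimulationDesign:
    """How much data to generate and how to label it.

    ratings_per_cell
        Aggregated ratings per stimulus x sensory-dimension cell.
    hedonic_ratings_per_cell
        Ratings per stimulus x liking cell; ``None`` means same as sensory.
        The defaults (56 sensory, 52 hedonic) match a two-ratings-per-phase
        design over ~28 retained sensory and 26 retained hedonic phases.
    seed
        Seed for the dataset's random stream.
    emit_trials
        Also return a per-trial long table (participant, phase, stimulus,
        attribute, rating) with round-robin participant/phase labels.
    """

    ratings_per_cell: int = 56
    hedonic_ratings_per_cell: int | None = 52
    seed: int = 0
    emit_trials: bool = False

    def __post_init__(self) -> None:
        if self.ratings_per_cell < 1:
            raise ValueError("ratings_per_cell must be >= 1")
        if self.hedonic_ratings_per_cell is not None and self.hedonic_ratings_per_cell < 1:
            raise ValueError("hedonic_ratings_per_cell must be >= 1")

    @property
    def hedonic_count(self) -> int:
        return (
            self.ratings_per_cell
            if self.hedonic_ratings_per_cell is None
            else self.hedonic_ratings_per_cell
        )


def sample_percept(
    stimulus: StimulusDistribution, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw percepts from N(mu_i, I); one fresh draw per rating request."""
    n = 1 if size is None else size
    draws = stimulus.mean + rng.standard_normal((n, stimulus.n_dims))
    return draws[0] if size is None else draws


def sample_ideal(
    ideal: IdealDistribution, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw imagined ideals from N(mu_Y, Sigma_Y)."""
    n = 1 if size is None else size
    draws = rng.multivariate_normal(ideal.mean, ideal.covariance, size=n, method="eigh")
    return draws[0] if size is None else draws


def assign_sensory_rating(percept_value: float, criteria: np.ndarray) -> int:
    """Map a marginal percept value to a rating 1..r.

    Intervals are lower-exclusive / upper-inclusive: a value exactly at
    criterion X_{d,j} receives rating j.
    """
    criteria = np.asarray(criteria, dtype=float)
    return int(np.searchsorted(criteria, percept_value, side="left")) + 1


def assign_liking_rating(distance: float, liking_criteria: np.ndarray) -> int:
    """Map an ideal-to-percept distance to a liking rating 1..r.

    Criteria are decreasing; rating j is given iff X_{I,j} < d <= X_{I,j-1},
    so smaller distances earn larger ratings and distance 0 earns rating r.
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    lik = np.asarray(liking_criteria, dtype=float)
    return int(np.sum(lik >= distance)) + 1


def _sensory_ratings_batch(
    mean: np.ndarray, criteria: np.ndarray, dim: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    values = mean[dim] + rng.standard_normal(n)
    return np.searchsorted(criteria[dim], values, side="left") + 1


def _liking_ratings_batch(
    model: GrtUnfoldingModel, stim: StimulusDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    y = sample_ideal(model.ideal, rng, size=n)
    x = sample_percept(stim, rng, size=n)
    w = y - x
    sol = np.linalg.solve(model.ideal.covariance, w.T).T
    dist = np.sqrt(np.einsum("ij,ij->i", w, sol))
    lik = model.criteria.liking
    return (lik[np.newaxis, :] >= dist[:, np.newaxis]).sum(axis=1) + 1


def simulate_dataset(
    model: GrtUnfoldingModel, design: SimulationDesign
) -> RatingDataset | tuple[RatingDataset, pd.DataFrame]:
    """Generate an aggregated rating-frequency dataset (and optional trials).

    Every stimulus x attribute cell receives its designed number of rating
    trials; each trial draws a fresh percept (and ideal, for liking trials).
    With ``emit_trials`` the per-trial table is returned too, with
    participant and phase labels assigned round-robin over a template of
    two ratings per attribute per participant (the ratings a participant
    contributes across their retained phases).
    """
    spec = model.spec
    rng = np.random.default_rng(design.seed)
    n, d, r = spec.n_stimuli, spec.n_dims, spec.n_ratings
    counts = np.zeros((n, d + 1, r), dtype=int)
    trial_rows: list[tuple] = []
    for i, stim in enumerate(model.stimuli):
        for a in range(d + 1):
            n_cell = design.hedonic_count if a == d else design.ratings_per_cell
            if a < d:
                ratings = _sensory_ratings_batch(
                    stim.mean, model.criteria.sensory, a, n_cell, rng
                )
            else:
                ratings = _liking_ratings_batch(model, stim, n_cell, rng)
            counts[i, a, :] = np.bincount(ratings - 1, minlength=r)
            if design.emit_trials:
                attribute = spec.attributes[a]
                for k, rating in enumerate(ratings):
                    # two ratings per attribute per participant-phase pair,
                    # mirroring the two rating phases per attribute type
                    participant = f"P{k // 2 + 1}"
                    phase = 2 + (k % 2) * 2 + (1 if a == d else 0)
                    trial_rows.append(
                        (participant, phase, spec.stimulus_ids[i], attribute, int(rating))
                    )
    dataset = RatingDataset(spec=spec, counts=counts)
    if design.emit_trials:
        trials = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))
        return dataset, trials
    return dataset


def example_model(
    n_stimuli: int = 20,
    n_dims: int = 6,
    n_ratings: int = 7,
    seed: int = 0,
    mean_spread: float = 2.0,
) -> GrtUnfoldingModel:
    """A fully specified model emulating the reference study's conditions.

    Stimulus means are drawn around the origin with SD ``mean_spread``
    (in perceptual-noise units) and the reference stimulus pinned at the
    origin.  Ideal variances are log-spaced so that dimensions differ in
    importance, with a moderate negative correlation between the two most
    important dimensions.  Sensory criteria sit at equally spaced quantile
    positions over the stimulus range; liking criteria are spaced to cover
    the typical range of ideal-to-percept distances implied by the model.
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec.create(n_stimuli, n_dims, n_ratings)
    means = rng.normal(0.0, mean_spread, size=(n_stimuli, n_dims))
    means[-1] = 0.0  # reference stimulus at the origin
    stimuli = tuple(
        StimulusDistribution(stimulus_id=sid, mean=means[i])
        for i, sid in enumerate(spec.stimulus_ids)
    )

    variances = np.geomspace(2.0, 40.0, n_dims)
    cov = np.diag(variances)
    if n_dims >= 2:
        # negative coupling between the two most important (smallest-variance) dims
        rho = -0.45
        cov[0, 1] = cov[1, 0] = rho * np.sqrt(variances[0] * variances[1])
    ideal_mean = rng.normal(0.0, mean_spread / 2.0, size=n_dims)
    ideal = IdealDistribution(mean=ideal_mean, covariance=cov)

    # criteria at equal-probability positions of the percept mixture per dim
    qs = np.linspace(0.0, 1.0, n_ratings + 1)[1:-1]
    lo = means.min(axis=0) - 1.5
    hi = means.max(axis=0) + 1.5
    sensory = lo[:, None] + qs[None, :] * (hi - lo)[:, None]

    # liking criteria spanning the central range of Delta across stimuli
    mom = [delta_squared_moments(ideal, s) for s in stimuli]
    d2_lo = min(m.mean - np.sqrt(m.variance) for m in mom)
    d2_hi = max(m.mean + np.sqrt(m.variance) for m in mom)
    d2_lo = max(d2_lo, 0.05 * d2_hi)
    liking = np.sqrt(np.linspace(d2_hi, d2_lo, n_ratings - 1))

    criteria = CriteriaSet(sensory=sensory, liking=liking)
    return GrtUnfoldingModel(spec=spec, stimuli=stimuli, ideal=ideal, criteria=criteria)


def recovery_study_model(
    n_stimuli: int = 8,
    n_ratings: int = 5,
    seed: int = 11,
) -> GrtUnfoldingModel:
    """Two-dimensional generating model for parameter-recovery studies.

    The regime is chosen so every parameter is informative at feasible sample
    sizes: stimulus means spread uniformly over +/- 2.5 perceptual-noise units
    with the reference at the origin; the ideal mean inside the stimulus
    cloud; ideal variances (1.5, 4.0) of the same order as the stimulus
    spread, with a negative correlation (-0.45); criteria covering the
    observed ranges so no rating category starves.
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec.create(n_stimuli, 2, n_ratings)
    means = rng.uniform(-2.5, 2.5, size=(n_stimuli, 2))
    means[-1] = 0.0
    stimuli = tuple(
        StimulusDistribution(stimulus_id=sid, mean=means[i])
        for i, sid in enumerate(spec.stimulus_ids)
    )
    cov = np.array([[1.5, -1.1], [-1.1, 4.0]])
    ideal = IdealDistribution(mean=np.array([0.8, -0.6]), covariance=cov)
    sensory = np.stack(
        [
            np.linspace(means[:, d].min() - 0.5, means[:, d].max() + 0.5, n_ratings - 1)
            for d in range(2)
        ]
    )
    mom = [delta_squared_moments(ideal, s) for s in stimuli]
    lo = max(min(m.mean - np.sqrt(m.variance) for m in mom), 0.5)
    hi = max(m.mean + np.sqrt(m.variance) for m in mom)
    liking = np.sqrt(np.linspace(hi, lo, n_ratings - 1))
    criteria = CriteriaSet(sensory=sensory, liking=liking)
    return GrtUnfoldingModel(spec=spec, stimuli=stimuli, ideal=ideal, criteria=criteria)
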