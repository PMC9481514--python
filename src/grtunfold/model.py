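"""Domain types and forward probability computations of the GRT-unfolding model.

Model summary
-------------
A stimulus ``i`` elicits a percept ``x_i ~ N(mu_i, I)`` on ``D`` sensory
dimensions (unit, uncorrelated noise fixes the measurement scale).  A sensory
rating on dimension ``d`` is produced by cutting the marginal percept with
``r - 1`` ordered criteria.  For a hedonic (liking) rating the participant
imagines an ideal stimulus ``y ~ N(mu_Y, Sigma_Y)`` and computes the
Mahalanobis distance

    Delta = sqrt((y - x_i)' Sigma_Y^{-1} (y - x_i)),

so dimensions on which the ideal is consistent (small variance) weigh more.
Liking criteria are ordered *decreasing* positive distances: small distances
map to high liking.  The squared distance is a weighted sum of D noncentral
chi-square variables; its first two moments have closed forms, which support a
fast normal approximation to the liking-rating probabilities, with an exact
path (Monte Carlo or characteristic-function inversion) retained as oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate
from scipy.special import ndtr  # standard normal CDF, vectorized
from scipy.stats import chi2, ncx2

#: Smallest admissible eigenvalue of the ideal covariance.  The squared
#: Mahalanobis distance involves Sigma_Y^{-1}; eigenvalues below this floor
#: are treated as a conditioning failure.
EIGENVALUE_FLOOR = 1e-4

HEDONIC_ATTRIBUTE = "hedonic"


class CriteriaOrderError(ValueError):
    """Response criteria violate their required strict ordering."""


class ConditioningError(ValueError):
    """The ideal covariance is singular or below the eigenvalue floor."""


class DimensionMismatchError(ValueError):
    """Inputs disagree on the number of sensory dimensions."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Experimental design: stimulus inventory, dimensions, rating scale.

    ``reference_stimulus`` names the stimulus whose perceptual mean is fixed
    at the origin during fitting (an identifiability constraint: absolute
    location on each dimension is arbitrary).
    """

    n_stimuli: int
    n_dims: int
    n_ratings: int
    dimension_names: tuple[str, ...]
    stimulus_ids: tuple[str, ...]
    reference_stimulus: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimension_names", tuple(self.dimension_names))
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))
        if self.n_stimuli < 1 or self.n_dims < 1:
            raise ValueError("n_stimuli and n_dims must be positive")
        if self.n_ratings < 2:
            raise ValueError("rating scale needs at least 2 points")
        if len(self.dimension_names) != self.n_dims:
            raise ValueError("dimension_names length must equal n_dims")
        if len(self.stimulus_ids) != self.n_stimuli:
            raise ValueError("stimulus_ids length must equal n_stimuli")
        if len(set(self.dimension_names)) != self.n_dims:
            raise ValueError("dimension_names must be unique")
        if len(set(self.stimulus_ids)) != self.n_stimuli:
            raise ValueError("stimulus_ids must be unique")
        if HEDONIC_ATTRIBUTE in self.dimension_names:
            raise ValueError(f"{HEDONIC_ATTRIBUTE!r} is reserved for the liking attribute")
        if self.reference_stimulus not in self.stimulus_ids:
            raise ValueError("reference_stimulus must be one of stimulus_ids")

    @classmethod
    def create(
        cls,
        n_stimuli: int,
        n_dims: int,
        n_ratings: int,
        dimension_names: Sequence[str] | None = None,
        stimulus_ids: Sequence[str] | None = None,
        reference_stimulus: str | None = None,
    ) -> "ModelSpec":
        """Build a spec with generated labels where none are given."""
        if dimension_names is None:
            dimension_names = tuple(f"dim{d + 1}" for d in range(n_dims))
        if stimulus_ids is None:
            stimulus_ids = tuple(f"S{i + 1}" for i in range(n_stimuli))
        if reference_stimulus is None:
            reference_stimulus = tuple(stimulus_ids)[-1]
        return cls(
            n_stimuli=n_stimuli,
            n_dims=n_dims,
            n_ratings=n_ratings,
            dimension_names=tuple(dimension_names),
            stimulus_ids=tuple(stimulus_ids),
            reference_stimulus=reference_stimulus,
        )

    @property
    def attributes(self) -> tuple[str, ...]:
        """Rated attributes: the sensory dimensions plus the liking attribute."""
        return self.dimension_names + (HEDONIC_ATTRIBUTE,)


@dataclass(frozen=True)
class StimulusDistribution:
    """Perceptual distribution of one stimulus: N(mean, I), unit noise SD."""

    stimulus_id: str
    mean: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        if mean.ndim != 1:
            raise ValueError("stimulus mean must be a vector")
        if not np.all(np.isfinite(mean)):
            raise ValueError("stimulus mean must be finite")
        object.__setattr__(self, "mean", mean)

    @property
    def n_dims(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class IdealDistribution:
    """Trial-to-trial distribution of the imagined ideal: N(mean, covariance).

    The per-dimension variance is inversely related to that dimension's
    importance for liking; covariances encode how imagined ideal values
    co-vary across dimensions.
    """

    mean: np.ndarray
    covariance: np.ndarray
    eigenvalue_floor: float = EIGENVALUE_FLOOR

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.ndim != 1:
            raise ValueError("ideal mean must be a vector")
        d = mean.shape[0]
        if cov.shape != (d, d):
            raise DimensionMismatchError(
                f"covariance shape {cov.shape} incompatible with mean length {d}"
            )
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("ideal covariance must be symmetric")
        cov = 0.5 * (cov + cov.T)
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < self.eigenvalue_floor:
            raise ConditioningError(
                f"ideal covariance eigenvalue {eigvals.min():.3e} is below the "
                f"floor {self.eigenvalue_floor:.3e}"
            )
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def n_dims(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class CriteriaSet:
    """Response criteria: sensory cut-points per dimension, liking cut-points.

    Sensory criteria on dimension ``d`` are strictly increasing; rating ``j``
    is given iff ``X_{d,j-1} < x_d <= X_{d,j}`` with ``X_{d,0} = -inf`` and
    ``X_{d,r} = +inf``.  Liking criteria live on the (nonnegative) distance
    scale and are strictly *decreasing*: liking rating ``j`` is given iff
    ``X_{I,j} < Delta <= X_{I,j-1}`` with ``X_{I,0} = +inf`` and
    ``X_{I,r} = 0``, so the smallest distances earn the top rating.
    """

    sensory: np.ndarray  # (D, r-1), rows strictly increasing
    liking: np.ndarray  # (r-1,), strictly decreasing, positive

    def __post_init__(self) -> None:
        sens = np.atleast_2d(np.asarray(self.sensory, dtype=float))
        lik = np.asarray(self.liking, dtype=float)
        if np.any(np.diff(sens, axis=1) <= 0):
            raise CriteriaOrderError("sensory criteria must be strictly increasing")
        if lik.ndim != 1:
            raise ValueError("liking criteria must be a vector")
        if np.any(np.diff(lik) >= 0):
            raise CriteriaOrderError("liking criteria must be strictly decreasing")
        if np.any(lik <= 0):
            raise CriteriaOrderError("liking criteria must be strictly positive")
        object.__setattr__(self, "sensory", sens)
        object.__setattr__(self, "liking", lik)

    @property
    def n_ratings(self) -> int:
        return self.sensory.shape[1] + 1


@dataclass(frozen=True)
class GrtUnfoldingModel:
    """Complete parameterization: spec, stimulus means, ideal, criteria."""

    spec: ModelSpec
    stimuli: tuple[StimulusDistribution, ...]
    ideal: IdealDistribution
    criteria: CriteriaSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        ids = [s.stimulus_id for s in self.stimuli]
        if ids != list(self.spec.stimulus_ids):
            raise ValueError("stimuli must appear once each, in spec order")
        d = self.spec.n_dims
        for s in self.stimuli:
            if s.n_dims != d:
                raise DimensionMismatchError(
                    f"stimulus {s.stimulus_id} has {s.n_dims} dims, spec has {d}"
                )
        if self.ideal.n_dims != d:
            raise DimensionMismatchError("ideal dimensionality disagrees with spec")
        if self.criteria.sensory.shape != (d, self.spec.n_ratings - 1):
            raise ValueError("sensory criteria shape must be (D, r-1)")
        if self.criteria.liking.shape != (self.spec.n_ratings - 1,):
            raise ValueError("liking criteria length must be r-1")

    def stimulus(self, stimulus_id: str) -> StimulusDistribution:
        return self.stimuli[self.spec.stimulus_ids.index(stimulus_id)]

    @property
    def stimulus_means(self) -> np.ndarray:
        """(N, D) array of perceptual means in spec order."""
        return np.stack([s.mean for s in self.stimuli])


@dataclass(frozen=True)
class DifferenceDistribution:
    """Distribution of w = y - x_i: N(mean, covariance) with cov = Sigma_Y + I."""

    mean: np.ndarray
    covariance: np.ndarray


@dataclass(frozen=True)
class DeltaSquaredMoments:
    """Mean and variance of the squared ideal-to-percept Mahalanobis distance."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.variance)):
            raise ValueError("moments must be finite")
        if self.mean <= 0 or self.variance <= 0:
            raise ValueError("moments must be positive")


@dataclass(frozen=True)
class QuadFormDecomposition:
    """Squared distance as sum_d weight_d * chi2_1(noncentrality_d).

    Weights are (lambda_d + 1) / lambda_d for eigenvalues lambda_d of
    Sigma_Y (always > 1); noncentralities are (q_d' mu_W)^2 / (lambda_d + 1).
    """

    weights: np.ndarray
    noncentralities: np.ndarray

    @property
    def implied_mean(self) -> float:
        return float(np.sum(self.weights * (1.0 + self.noncentralities)))

    @property
    def implied_variance(self) -> float:
        return float(np.sum(2.0 * self.weights**2 * (1.0 + 2.0 * self.noncentralities)))


@dataclass(frozen=True)
class RatingDataset:
    """Aggregated rating frequencies: counts[stimulus, attribute, rating].

    The attribute axis holds the D sensory dimensions followed by the hedonic
    attribute (index D).  ``trial_totals[i, a]`` is the number of rating
    trials behind row (i, a); every row of counts sums to its total.
    Counts are nonnegative; readers of observed data additionally require
    them to be integers.
    """

    spec: ModelSpec
    counts: np.ndarray  # (N, D+1, r)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        n, d, r = self.spec.n_stimuli, self.spec.n_dims, self.spec.n_ratings
        if counts.shape != (n, d + 1, r):
            raise ValueError(
                f"counts shape {counts.shape} != expected {(n, d + 1, r)}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def trial_totals(self) -> np.ndarray:
        """(N, D+1) row sums: rating trials per stimulus x attribute."""
        return self.counts.sum(axis=2)


# ---------------------------------------------------------------------------
# Forward probability computations
# ---------------------------------------------------------------------------


def sensory_rating_probabilities(mean: float, criteria: np.ndarray) -> np.ndarray:
    """Probability of each rating 1..r for one stimulus on one dimension.

    The marginal percept is N(mean, 1); rating ``j`` is the mass between
    consecutive criteria, so entry ``j-1`` is
    ``Phi(X_j - mean) - Phi(X_{j-1} - mean)`` with the outer boundaries at
    plus/minus infinity.
    """
    criteria = np.asarray(criteria, dtype=float)
    if np.any(np.diff(criteria) <= 0):
        raise CriteriaOrderError("sensory criteria must be strictly increasing")
    upper = np.concatenate([ndtr(criteria - mean), [1.0]])
    lower = np.concatenate([[0.0], ndtr(criteria - mean)])
    return upper - lower


def predicted_sensory_array(model: GrtUnfoldingModel) -> np.ndarray:
    """(N, D, r) sensory rating probabilities for every stimulus x dimension."""
    means = model.stimulus_means  # (N, D)
    crit = model.criteria.sensory  # (D, r-1)
    z = ndtr(crit[np.newaxis, :, :] - means[:, :, np.newaxis])  # (N, D, r-1)
    pad_lo = np.zeros(z.shape[:2] + (1,))
    pad_hi = np.ones(z.shape[:2] + (1,))
    cum = np.concatenate([pad_lo, z, pad_hi], axis=2)
    return np.diff(cum, axis=2)


def difference_distribution(
    ideal: IdealDistribution, stimulus: StimulusDistribution
) -> DifferenceDistribution:
    """Distribution of w = y - x_i.

    Since ideal and percept are independent normals, w is normal with mean
    mu_Y - mu_i and covariance Sigma_Y + I.
    """
    if ideal.n_dims != stimulus.n_dims:
        raise DimensionMismatchError(
            f"ideal has {ideal.n_dims} dims, stimulus has {stimulus.n_dims}"
        )
    return DifferenceDistribution(
        mean=ideal.mean - stimulus.mean,
        covariance=ideal.covariance + np.eye(ideal.n_dims),
    )


def _checked_eigh(ideal: IdealDistribution) -> tuple[np.ndarray, np.ndarray]:
    eigvals, eigvecs = np.linalg.eigh(ideal.covariance)
    if eigvals.min() < ideal.eigenvalue_floor:
        raise ConditioningError(
            f"ideal covariance eigenvalue {eigvals.min():.3e} is below the "
            f"floor {ideal.eigenvalue_floor:.3e}"
        )
    return eigvals, eigvecs


def delta_squared_moments(
    ideal: IdealDistribution, stimulus: StimulusDistribution
) -> DeltaSquaredMoments:
    """Closed-form mean and variance of the squared Mahalanobis distance.

    With mu_W = mu_Y - mu_i and S = Sigma_Y^{-1}:

        mean     = D + trace(S) + mu_W' S mu_W
        variance = 2D + 4 trace(S) + 2 trace(S^2) + 4 mu_W' S (I + S) mu_W
    """
    if ideal.n_dims != stimulus.n_dims:
        raise DimensionMismatchError(
            f"ideal has {ideal.n_dims} dims, stimulus has {stimulus.n_dims}"
        )
    d = ideal.n_dims
    eigvals, eigvecs = _checked_eigh(ideal)
    mu_w = ideal.mean - stimulus.mean
    m = eigvecs.T @ mu_w  # mu_W in the eigenbasis
    inv = 1.0 / eigvals
    mean = d + inv.sum() + np.sum(m**2 * inv)
    variance = (
        2.0 * d
        + 4.0 * inv.sum()
        + 2.0 * np.sum(inv**2)
        + 4.0 * np.sum(m**2 * inv * (1.0 + inv))
    )
    return DeltaSquaredMoments(mean=float(mean), variance=float(variance))


def quadform_decomposition(
    ideal: IdealDistribution, stimulus: StimulusDistribution
) -> QuadFormDecomposition:
    """Decompose the squared distance into weighted noncentral chi-squares.

    Eigendecompose Sigma_Y = Q Lambda Q'.  In the eigenbasis each coordinate
    of w contributes independently:

        Delta^2 = sum_d omega_d * chi2_1(delta_d),
        omega_d = (lambda_d + 1) / lambda_d,
        delta_d = (q_d' mu_W)^2 / (lambda_d + 1).
    """
    if ideal.n_dims != stimulus.n_dims:
        raise DimensionMismatchError(
            f"ideal has {ideal.n_dims} dims, stimulus has {stimulus.n_dims}"
        )
    eigvals, eigvecs = _checked_eigh(ideal)
    mu_w = ideal.mean - stimulus.mean
    m = eigvecs.T @ mu_w
    weights = (eigvals + 1.0) / eigvals
    noncentralities = m**2 / (eigvals + 1.0)
    return QuadFormDecomposition(weights=weights, noncentralities=noncentralities)


def _squared_liking_bounds(liking_criteria: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-rating (lower, upper) bounds on the squared-distance scale.

    Rating j occupies (X_{I,j}^2, X_{I,j-1}^2]; the top rating's lower bound
    is 0 (the distance is nonnegative).
    """
    lik = np.asarray(liking_criteria, dtype=float)
    if np.any(np.diff(lik) >= 0) or np.any(lik <= 0):
        raise CriteriaOrderError("liking criteria must be strictly decreasing and positive")
    if lik.shape[0] != r - 1:
        raise ValueError(f"expected {r - 1} liking criteria, got {lik.shape[0]}")
    sq = lik**2
    upper = np.concatenate([[np.inf], sq])  # X_{I,0} = +inf
    lower = np.concatenate([sq, [0.0]])  # X_{I,r} = 0
    return lower, upper


def liking_rating_probabilities_approx(
    ideal: IdealDistribution,
    stimulus: StimulusDistribution,
    liking_criteria: np.ndarray,
) -> np.ndarray:
    """Liking rating probabilities under the normal approximation.

    The squared distance is approximated by a normal with the closed-form
    moments; rating j's probability is the normal mass between the squared
    criteria bounding it.  The approximating normal assigns some mass below
    zero; that mass is folded into the top rating (its lower integration
    bound is taken as -inf) so the vector sums to exactly one.
    """
    r = np.asarray(liking_criteria).shape[0] + 1
    lower, upper = _squared_liking_bounds(liking_criteria, r)
    lower = lower.copy()
    lower[-1] = -np.inf  # fold sub-zero mass of the approximation into rating r
    mom = delta_squared_moments(ideal, stimulus)
    sd = np.sqrt(mom.variance)
    hi = np.where(np.isinf(upper), 1.0, ndtr((upper - mom.mean) / sd))
    lo = np.where(np.isinf(lower), 0.0, ndtr((lower - mom.mean) / sd))
    return hi - lo


def _imhof_cdf(x: float, weights: np.ndarray, noncentralities: np.ndarray) -> float:
    """P(sum_d w_d chi2_1(delta_d) <= x) by characteristic-function inversion.

    Imhof's formula with one degree of freedom per term:
        P(Q > x) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du.
    """

    w = weights
    d = noncentralities

    def integrand(u: np.ndarray) -> np.ndarray:
        wu = np.multiply.outer(u, w)  # (..., D)
        theta = 0.5 * (
            np.arctan(wu) + d * wu / (1.0 + wu**2)
        ).sum(axis=-1) - 0.5 * x * u
        rho = np.prod((1.0 + wu**2) ** 0.25, axis=-1) * np.exp(
            0.5 * (d * wu**2 / (1.0 + wu**2)).sum(axis=-1)
        )
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        # the integrand's slowly decaying oscillatory tail triggers a
        # subdivision warning long after the requested accuracy is reached
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, 0.0, np.inf, limit=2000, epsabs=1e-12, epsrel=1e-11
        )
    upper_tail = 0.5 + val / np.pi
    return float(np.clip(1.0 - upper_tail, 0.0, 1.0))


def liking_rating_probabilities_exact(
    ideal: IdealDistribution,
    stimulus: StimulusDistribution,
    liking_criteria: np.ndarray,
    method: Literal["montecarlo", "inversion"] = "inversion",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Liking rating probabilities under the exact squared-distance law.

    The exact distribution is the weighted noncentral chi-square sum from
    :func:`quadform_decomposition`, evaluated either by Monte Carlo over the
    D independent noncentral chi-square terms or by Imhof-type
    characteristic-function inversion of the CDF at the squared criteria.
    """
    r = np.asarray(liking_criteria).shape[0] + 1
    lower, upper = _squared_liking_bounds(liking_criteria, r)
    dec = quadform_decomposition(ideal, stimulus)
    if method == "montecarlo":
        if n_draws < 10_000:
            raise ValueError("montecarlo requires n_draws >= 10000")
        rng = np.random.default_rng(seed)
        draws = np.zeros(n_draws)
        for w_d, nc_d in zip(dec.weights, dec.noncentralities):
            draws += w_d * rng.noncentral_chisquare(1.0, nc_d, size=n_draws)
        # rating j iff X_j^2 < Delta^2 <= X_{j-1}^2; counts via the CDF at bounds
        cdf_at = np.array(
            [np.mean(draws <= b) if np.isfinite(b) else 1.0 for b in upper]
        )
        cdf_lo = np.concatenate([cdf_at[1:], [0.0]])
        probs = cdf_at - cdf_lo
    elif method == "inversion":
        if dec.weights.shape[0] == 1:
            # one dimension: a single scaled noncentral chi-square, closed form
            def cdf_one(b: float) -> float:
                return float(ncx2.cdf(b / dec.weights[0], 1.0, dec.noncentralities[0]))

            cdf_vals = np.array([1.0 if np.isinf(b) else cdf_one(b) for b in upper])
        else:
            cdf_vals = np.array(
                [
                    1.0 if np.isinf(b) else _imhof_cdf(b, dec.weights, dec.noncentralities)
                    for b in upper
                ]
            )
        cdf_lo = np.concatenate([cdf_vals[1:], [0.0]])
        probs = cdf_vals - cdf_lo
    else:
        raise ValueError(f"unknown method {method!r}; use 'montecarlo' or 'inversion'")
    probs = np.clip(probs, 0.0, 1.0)
    return probs / probs.sum()


def predicted_probability_array(
    model: GrtUnfoldingModel,
    hedonic_method: Literal["approx", "montecarlo", "inversion"] = "approx",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """(N, D+1, r) predicted rating probabilities for all attributes.

    Sensory rows come from the normal-criteria model; the hedonic row uses the
    normal approximation by default, or an exact path on request.
    """
    n, d, r = model.spec.n_stimuli, model.spec.n_dims, model.spec.n_ratings
    out = np.empty((n, d + 1, r))
    out[:, :d, :] = predicted_sensory_array(model)
    for i, stim in enumerate(model.stimuli):
        if hedonic_method == "approx":
            out[i, d, :] = liking_rating_probabilities_approx(
                model.ideal, stim, model.criteria.liking
            )
        else:
            out[i, d, :] = liking_rating_probabilities_exact(
                model.ideal,
                stim,
                model.criteria.liking,
                method=hedonic_method,
                n_draws=n_draws,
                seed=seed,
            )
    return out


def predicted_frequency_array(
    model: GrtUnfoldingModel,
    trial_totals: np.ndarray | float,
    hedonic_method: Literal["approx", "montecarlo", "inversion"] = "approx",
) -> np.ndarray:
    """(N, D+1, r) expected rating counts: probabilities times row totals.

    ``trial_totals`` broadcasts against shape (N, D+1), so a scalar, a
    per-attribute row, or a full table are all accepted.
    """
    n, d = model.spec.n_stimuli, model.spec.n_dims
    totals = np.broadcast_to(np.asarray(trial_totals, dtype=float), (n, d + 1))
    if np.any(totals < 0):
        raise ValueError("trial totals must be nonnegative")
    probs = predicted_probability_array(model, hedonic_method=hedonic_method)
    return probs * totals[:, :, np.newaxis]


def luce_choice_probability(v_a: float, v_b: float) -> float:
    """Luce choice rule: P(A chosen over B) = v_A / (v_A + v_B)."""
    if v_a < 0 or v_b < 0:
        raise ValueError("choice values must be nonnegative")
    if v_a + v_b == 0:
        raise ValueError("at least one choice value must be positive")
    return v_a / (v_a + v_b)


def count_free_parameters(
    spec: ModelSpec,
    covariance_structure: Literal["full", "diagonal"] = "full",
) -> dict[str, int]:
    """Itemized free-parameter counts for a given design.

    With the reference stimulus fixed at the origin and unit sensory noise:
    (N-1)*D stimulus means, D*(r-1) sensory criteria, D ideal means,
    D(D+1)/2 (full) or D (diagonal) ideal covariance entries, and r-1 liking
    criteria.
    """
    n, d, r = spec.n_stimuli, spec.n_dims, spec.n_ratings
    if covariance_structure == "full":
        cov = d * (d + 1) // 2
    elif covariance_structure == "diagonal":
        cov = d
    else:
        raise ValueError(f"unknown covariance structure {covariance_structure!r}")
    items = {
        "stimulus_means": (n - 1) * d,
        "sensory_criteria": d * (r - 1),
        "ideal_mean": d,
        "ideal_covariance": cov,
        "liking_criteria": r - 1,
    }
    items["total"] = sum(items.values())
    return items


def chi2_equal_covariance_liking_probabilities(
    liking_criteria: np.ndarray, n_dims: int
) -> np.ndarray:
    """Closed-form liking probabilities when Sigma_Y = I and mu_Y = mu_i.

    In that limit Delta^2 = 2 * chi2_D, so rating probabilities are chi2_D
    CDF differences at half the squared criteria.  Used as an independent
    oracle for the exact path.
    """
    r = np.asarray(liking_criteria).shape[0] + 1
    lower, upper = _squared_liking_bounds(liking_criteria, r)
    hi = np.where(np.isinf(upper), 1.0, chi2.cdf(upper / 2.0, n_dims))
    lo = chi2.cdf(lower / 2.0, n_dims)
    return hi - lo
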