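"""Parameter estimation for the GRT-unfolding model.

All free parameters are estimated by minimizing the sum of squared errors
between predicted and observed rating frequencies, with the identifiability
constraints built in: the reference stimulus's perceptual mean is fixed at the
origin and every perceptual covariance is the identity.

Two optimizer routes are provided.  The default reparameterizes the model so
every constraint (ordered criteria, positive-definite ideal covariance,
positive decreasing liking criteria) holds by construction and runs a smooth
unconstrained quasi-Newton search; a COBYLA route on the raw parameter vector
with a finite constraint penalty is kept for parity with derivative-free
constrained fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtr, ndtri

from .model import (
    EIGENVALUE_FLOOR,
    CriteriaSet,
    GrtUnfoldingModel,
    IdealDistribution,
    ModelSpec,
    RatingDataset,
    StimulusDistribution,
    count_free_parameters,
)

PARAMETER_LAYOUT_VERSION = 1

#: Finite value returned by the objective when raw parameters violate a
#: constraint, scaled by the violation size so derivative-free search can
#: climb back into the feasible region instead of crashing.
CONSTRAINT_PENALTY = 1e10

_LOG_CLIP = 30.0  # bound on log-scale parameters to keep exp() finite


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the fitting procedure.

    ``hedonic_method`` selects how the objective predicts liking-rating
    probabilities: ``"approx"`` is the fast normal approximation to the
    squared-distance distribution (the default fitting path); ``"exact"``
    evaluates the weighted noncentral chi-square law by quadrature
    (one eigendimension handled analytically, the rest by fixed
    Gauss-Hermite / frozen-normal nodes).  The exact path matters at low
    dimensionality, where the squared distance is markedly skewed and the
    normal approximation biases the ideal-distribution estimates.
    """

    optimizer: Literal["transformed-unconstrained", "cobyla-style"] = (
        "transformed-unconstrained"
    )
    n_restarts: int = 3
    seed: int = 0
    max_iterations: int = 1000
    tolerance: float = 1e-9
    eigenvalue_floor: float = EIGENVALUE_FLOOR
    objective_scale: Literal["frequencies", "proportions"] = "frequencies"
    covariance_structure: Literal["full", "diagonal"] = "full"
    hedonic_method: Literal["approx", "exact"] = "approx"
    n_quad_nodes: int = 64
    restart_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tolerance <= 0 or self.eigenvalue_floor <= 0:
            raise ValueError("tolerance and eigenvalue_floor must be positive")


@dataclass(frozen=True)
class FitResult:
    """Best model over restarts plus goodness-of-fit bookkeeping."""

    model: GrtUnfoldingModel
    sse: float
    r_squared_overall: float
    r_squared_sensory: float
    r_squared_hedonic: float
    converged: bool
    n_evaluations: int
    restart_scores: tuple[float, ...]
    options: FitOptions


# ---------------------------------------------------------------------------
# Parameter vector layout (version 1)
# ---------------------------------------------------------------------------
# [ stimulus means, (N-1) x D, spec order skipping the reference stimulus |
#   sensory criteria, D x (r-1) row-major                                 |
#   ideal mean, D                                                          |
#   ideal covariance: lower triangle row-major (full) or diagonal          |
#   liking criteria, r-1, decreasing ]


class _Layout:
    def __init__(self, spec: ModelSpec, covariance_structure: str) -> None:
        n, d, r = spec.n_stimuli, spec.n_dims, spec.n_ratings
        self.spec = spec
        self.structure = covariance_structure
        self.ref_index = spec.stimulus_ids.index(spec.reference_stimulus)
        self.free_indices = [i for i in range(n) if i != self.ref_index]
        n_cov = d * (d + 1) // 2 if covariance_structure == "full" else d
        sizes = [(n - 1) * d, d * (r - 1), d, n_cov, r - 1]
        bounds = np.cumsum([0] + sizes)
        self.slices = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        self.total = int(bounds[-1])
        self.tril = np.tril_indices(d)

    def split(self, vector: np.ndarray):
        n, d, r = self.spec.n_stimuli, self.spec.n_dims, self.spec.n_ratings
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.total,):
            raise ValueError(f"expected parameter vector of length {self.total}, got {v.shape}")
        means_free = v[self.slices[0]].reshape(n - 1, d)
        sens = v[self.slices[1]].reshape(d, r - 1)
        mu_y = v[self.slices[2]]
        cov_part = v[self.slices[3]]
        liking = v[self.slices[4]]
        return means_free, sens, mu_y, cov_part, liking

    def full_means(self, means_free: np.ndarray) -> np.ndarray:
        n, d = self.spec.n_stimuli, self.spec.n_dims
        means = np.zeros((n, d))
        means[self.free_indices] = means_free
        return means

    def covariance(self, cov_part: np.ndarray) -> np.ndarray:
        d = self.spec.n_dims
        if self.structure == "diagonal":
            return np.diag(cov_part)
        cov = np.zeros((d, d))
        cov[self.tril] = cov_part
        cov = cov + np.tril(cov, -1).T
        return cov


def pack_parameters(
    model: GrtUnfoldingModel,
    covariance_structure: Literal["full", "diagonal"] = "full",
) -> np.ndarray:
    """Flatten a model into the documented raw parameter vector.

    The reference stimulus's mean is excluded (fixed at the origin); the
    vector length equals the free-parameter total for the design.
    """
    layout = _Layout(model.spec, covariance_structure)
    means = model.stimulus_means
    if not np.allclose(means[layout.ref_index], 0.0):
        raise ValueError("reference stimulus mean must be the zero vector")
    parts = [
        means[layout.free_indices].ravel(),
        model.criteria.sensory.ravel(),
        model.ideal.mean,
    ]
    if covariance_structure == "diagonal":
        cov = model.ideal.covariance
        off = cov - np.diag(np.diag(cov))
        if not np.allclose(off, 0.0):
            raise ValueError("model has a non-diagonal ideal covariance")
        parts.append(np.diag(cov))
    else:
        parts.append(model.ideal.covariance[layout.tril])
    parts.append(model.criteria.liking)
    return np.concatenate(parts)


def unpack_parameters(
    vector: np.ndarray,
    spec: ModelSpec,
    covariance_structure: Literal["full", "diagonal"] = "full",
    eigenvalue_floor: float = EIGENVALUE_FLOOR,
) -> GrtUnfoldingModel:
    """Rebuild a model from a raw parameter vector (validating constraints)."""
    layout = _Layout(spec, covariance_structure)
    means_free, sens, mu_y, cov_part, liking = layout.split(vector)
    means = layout.full_means(means_free)
    stimuli = tuple(
        StimulusDistribution(stimulus_id=sid, mean=means[i])
        for i, sid in enumerate(spec.stimulus_ids)
    )
    ideal = IdealDistribution(
        mean=mu_y, covariance=layout.covariance(cov_part), eigenvalue_floor=eigenvalue_floor
    )
    criteria = CriteriaSet(sensory=sens, liking=liking)
    return GrtUnfoldingModel(spec=spec, stimuli=stimuli, ideal=ideal, criteria=criteria)


# ---------------------------------------------------------------------------
# Unconstrained reparameterization
# ---------------------------------------------------------------------------
# criteria rows    -> first cut-point + log-increments
# ideal covariance -> Cholesky factor with log-diagonal (full) or
#                     log-variances (diagonal)
# liking criteria  -> log of the smallest criterion + log-decrements upward


def _ordered_to_log(row: np.ndarray) -> np.ndarray:
    return np.concatenate([[row[0]], np.log(np.diff(row))])


def _log_to_ordered(t: np.ndarray) -> np.ndarray:
    return t[0] + np.concatenate([[0.0], np.cumsum(np.exp(np.clip(t[1:], -_LOG_CLIP, _LOG_CLIP)))])


def raw_to_unconstrained(vector: np.ndarray, layout: _Layout) -> np.ndarray:
    means_free, sens, mu_y, cov_part, liking = layout.split(vector)
    d = layout.spec.n_dims
    sens_t = np.stack([_ordered_to_log(row) for row in sens])
    if layout.structure == "diagonal":
        cov_t = np.log(cov_part)
    else:
        chol = np.linalg.cholesky(layout.covariance(cov_part))
        chol[np.diag_indices(d)] = np.log(np.diag(chol))
        cov_t = chol[layout.tril]
    asc = liking[::-1]  # ascending positive
    lik_t = np.concatenate([[np.log(asc[0])], np.log(np.diff(asc))])
    return np.concatenate([means_free.ravel(), sens_t.ravel(), mu_y, cov_t, lik_t])


def unconstrained_to_raw(t_vector: np.ndarray, layout: _Layout) -> np.ndarray:
    means_free, sens_t, mu_y, cov_t, lik_t = layout.split(t_vector)
    d = layout.spec.n_dims
    sens = np.stack([_log_to_ordered(row) for row in sens_t])
    if layout.structure == "diagonal":
        cov_part = np.exp(np.clip(cov_t, -_LOG_CLIP, _LOG_CLIP))
    else:
        chol = np.zeros((d, d))
        chol[layout.tril] = cov_t
        chol[np.diag_indices(d)] = np.exp(
            np.clip(np.diag(chol), -_LOG_CLIP, _LOG_CLIP)
        )
        cov = chol @ chol.T
        cov_part = cov[layout.tril]
    asc = np.exp(np.clip(lik_t[0], -_LOG_CLIP, _LOG_CLIP)) + np.concatenate(
        [[0.0], np.cumsum(np.exp(np.clip(lik_t[1:], -_LOG_CLIP, _LOG_CLIP)))]
    )
    liking = asc[::-1]
    return np.concatenate([means_free.ravel(), sens.ravel(), mu_y, cov_part, liking])


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def _quadrature_nodes(n_nodes: int, n_cond_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for integrating out all but one eigendimension.

    One conditioning dimension uses Gauss-Hermite nodes (exact for smooth
    integrands); higher-dimensional conditioning uses a frozen stream of
    standard-normal nodes with equal weights, which keeps the objective
    deterministic and smooth in the parameters (common random numbers).
    """
    if n_cond_dims == 1:
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        return (np.sqrt(2.0) * t)[:, np.newaxis], w / np.sqrt(np.pi)
    rng = np.random.default_rng(123456789)
    z = rng.standard_normal((max(n_nodes, 512), n_cond_dims))
    return z, np.full(z.shape[0], 1.0 / z.shape[0])


def _exact_hedonic_cdf(
    weights: np.ndarray,
    noncentralities: np.ndarray,  # (N, D)
    bounds: np.ndarray,  # finite squared criteria, descending, (r-1,)
    n_nodes: int,
) -> np.ndarray:
    """(N, r-1) CDF of the weighted noncentral chi-square sum at each bound.

    Conditions on all eigendimensions but the last: given node values z for
    those dimensions, the remainder is a scaled noncentral chi-square with one
    degree of freedom, whose CDF is a pair of normal CDFs.
    """
    d = weights.shape[0]
    if d == 1:
        # single dimension: fully analytic
        y = bounds[np.newaxis, :] / weights[0]
        root = np.sqrt(np.maximum(y, 0.0))
        s = np.sqrt(noncentralities[:, 0])[:, np.newaxis]
        return ndtr(root - s) - ndtr(-root - s)
    if d == 2:
        # Condition on dimension 1 over its feasible interval |t| <= a and
        # substitute t = a sin(theta): the sqrt singularities at the interval
        # ends become cos(theta) factors and the integrand is smooth, so
        # Gauss-Legendre converges fast.
        theta, w = np.polynomial.legendre.leggauss(n_nodes)
        theta = 0.5 * np.pi * theta  # map [-1, 1] -> [-pi/2, pi/2]
        w = 0.5 * np.pi * w
        a = np.sqrt(bounds / weights[0])[np.newaxis, :, np.newaxis]  # (1, r-1, K)
        s1 = np.sqrt(noncentralities[:, 0])[:, np.newaxis, np.newaxis]
        s2 = np.sqrt(noncentralities[:, 1])[:, np.newaxis, np.newaxis]
        sin_t = np.sin(theta)[np.newaxis, np.newaxis, :]
        cos_t = np.cos(theta)[np.newaxis, np.newaxis, :]
        b = a * np.sqrt(weights[0] / weights[1]) * cos_t
        density = np.exp(-0.5 * (a * sin_t - s1) ** 2) / np.sqrt(2.0 * np.pi)
        inner = ndtr(b - s2) - ndtr(-b - s2)
        return np.einsum("k,njk->nj", w, density * inner * a[..., :] * cos_t)
    z, w = _quadrature_nodes(n_nodes, d - 1)  # (K, D-1), (K,)
    shifts = np.sqrt(noncentralities[:, : d - 1])  # (N, D-1)
    # consumed mass per node per stimulus: sum_d w_d (z_d + sqrt(delta_d))^2
    consumed = np.einsum(
        "d,nkd->nk",
        weights[: d - 1],
        (z[np.newaxis, :, :] + shifts[:, np.newaxis, :]) ** 2,
    )  # (N, K)
    rem = (bounds[np.newaxis, np.newaxis, :] - consumed[:, :, np.newaxis]) / weights[-1]
    root = np.sqrt(np.maximum(rem, 0.0))
    s_last = np.sqrt(noncentralities[:, -1])[:, np.newaxis, np.newaxis]
    cdf_cond = ndtr(root - s_last) - ndtr(-root - s_last)  # zero where rem <= 0
    return np.einsum("k,nkj->nj", w, cdf_cond)


def _predicted_counts_raw(
    vector: np.ndarray,
    layout: _Layout,
    totals: np.ndarray,
    eigenvalue_floor: float,
    hedonic_method: str = "approx",
    n_quad_nodes: int = 64,
) -> np.ndarray:
    """(N, D+1, r) expected counts from a raw vector, no dataclass overhead.

    Ideal-covariance eigenvalues are clipped at the floor so the objective
    stays finite and smooth near the boundary of the feasible region.
    """
    spec = layout.spec
    n, d, r = spec.n_stimuli, spec.n_dims, spec.n_ratings
    means_free, sens, mu_y, cov_part, liking = layout.split(vector)
    means = layout.full_means(means_free)

    z = ndtr(sens[np.newaxis, :, :] - means[:, :, np.newaxis])
    cum = np.concatenate(
        [np.zeros((n, d, 1)), z, np.ones((n, d, 1))], axis=2
    )
    sens_p = np.diff(cum, axis=2)

    cov = layout.covariance(cov_part)
    lam, q = np.linalg.eigh(cov)
    lam = np.maximum(lam, eigenvalue_floor)
    m = (mu_y[np.newaxis, :] - means) @ q  # (N, D) in the eigenbasis
    sq = liking**2  # descending squared criteria

    if hedonic_method == "exact":
        omega = (lam + 1.0) / lam
        delta = m**2 / (lam + 1.0)[np.newaxis, :]
        cdf = _exact_hedonic_cdf(omega, delta, sq, n_quad_nodes)  # (N, r-1)
        hi = np.concatenate([np.ones((n, 1)), cdf], axis=1)
        lo = np.concatenate([cdf, np.zeros((n, 1))], axis=1)
        hed_p = hi - lo
    else:
        inv = 1.0 / lam
        mean_d2 = d + inv.sum() + (m**2 * inv).sum(axis=1)
        var_d2 = (
            2.0 * d
            + 4.0 * inv.sum()
            + 2.0 * np.sum(inv**2)
            + 4.0 * (m**2 * (inv * (1.0 + inv))[np.newaxis, :]).sum(axis=1)
        )
        sd = np.sqrt(var_d2)
        upper = np.concatenate([[np.inf], sq])
        lower = np.concatenate([sq, [-np.inf]])  # -inf folds sub-zero mass into rating r
        hi = np.where(
            np.isinf(upper)[np.newaxis, :],
            1.0,
            ndtr((upper[np.newaxis, :] - mean_d2[:, np.newaxis]) / sd[:, np.newaxis]),
        )
        lo = np.where(
            np.isinf(lower)[np.newaxis, :],
            0.0,
            ndtr((lower[np.newaxis, :] - mean_d2[:, np.newaxis]) / sd[:, np.newaxis]),
        )
        hed_p = hi - lo

    probs = np.concatenate([sens_p, hed_p[:, np.newaxis, :]], axis=1)
    return probs * totals[:, :, np.newaxis]


def _constraint_violation(vector: np.ndarray, layout: _Layout, floor: float) -> float:
    """Total constraint slack violated by a raw vector (0 when feasible)."""
    _, sens, _, cov_part, liking = layout.split(vector)
    v = 0.0
    v += float(np.sum(np.maximum(0.0, -np.diff(sens, axis=1))))
    v += float(np.sum(np.maximum(0.0, np.diff(liking))))  # must be decreasing
    v += float(np.sum(np.maximum(0.0, -liking)))
    lam = np.linalg.eigvalsh(layout.covariance(cov_part))
    v += float(np.sum(np.maximum(0.0, floor - lam)))
    return v


def sse_objective(
    parameter_vector: np.ndarray,
    dataset: RatingDataset,
    options: FitOptions | None = None,
) -> float:
    """Sum of squared errors between observed and predicted frequencies.

    Operates on the raw parameter vector.  Infeasible vectors return a large
    finite penalty (scaled by the violation) rather than raising, so
    derivative-free search can recover.
    """
    options = options or FitOptions()
    layout = _Layout(dataset.spec, options.covariance_structure)
    violation = _constraint_violation(parameter_vector, layout, options.eigenvalue_floor)
    if violation > 0.0:
        return CONSTRAINT_PENALTY * (1.0 + violation)
    totals = dataset.trial_totals
    predicted = _predicted_counts_raw(
        parameter_vector,
        layout,
        totals,
        options.eigenvalue_floor,
        options.hedonic_method,
        options.n_quad_nodes,
    )
    observed = dataset.counts
    if options.objective_scale == "proportions":
        safe = np.where(totals > 0, totals, 1.0)[:, :, np.newaxis]
        return float(np.sum(((observed - predicted) / safe) ** 2))
    return float(np.sum((observed - predicted) ** 2))


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _initial_raw_vector(dataset: RatingDataset, options: FitOptions) -> np.ndarray:
    """Data-driven starting point.

    Sensory criteria start at inverse-normal transforms of pooled cumulative
    rating proportions; stimulus means at the average z-shift needed to match
    each stimulus's own cumulative proportions, re-centered so the reference
    stimulus sits at the origin; the ideal mean at the liking-weighted
    centroid of the stimulus means; the ideal covariance at 10*I; liking
    criteria at quantile positions of the initial squared-distance normal
    approximation.
    """
    spec = dataset.spec
    n, d, r = spec.n_stimuli, spec.n_dims, spec.n_ratings
    layout = _Layout(spec, options.covariance_structure)
    counts = dataset.counts
    eps = 1e-3

    # pooled criteria per dimension
    sens_counts = counts[:, :d, :]
    pooled = sens_counts.sum(axis=0)  # (D, r)
    pooled_prop = pooled / np.maximum(pooled.sum(axis=1, keepdims=True), 1.0)
    cum = np.clip(np.cumsum(pooled_prop, axis=1)[:, :-1], eps, 1 - eps)
    crit = ndtri(cum)  # (D, r-1)
    crit = np.sort(crit, axis=1)
    crit += np.arange(r - 1) * 1e-6  # break exact ties from empty ratings

    # per-stimulus means: average z-gap between pooled criteria and own quantiles
    stim_prop = sens_counts / np.maximum(
        sens_counts.sum(axis=2, keepdims=True), 1.0
    )
    stim_cum = np.clip(np.cumsum(stim_prop, axis=2)[:, :, :-1], eps, 1 - eps)
    means = np.mean(crit[np.newaxis, :, :] - ndtri(stim_cum), axis=2)  # (N, D)

    # identifiability: shift means and criteria so the reference is at 0
    ref_shift = means[layout.ref_index].copy()
    means -= ref_shift[np.newaxis, :]
    crit -= ref_shift[:, np.newaxis]

    # ideal mean: liking-weighted centroid of stimulus means
    hed = counts[:, d, :]
    ratings = np.arange(1, r + 1)
    mean_liking = (hed * ratings).sum(axis=1) / np.maximum(hed.sum(axis=1), 1.0)
    w = mean_liking - mean_liking.min() + 0.1
    mu_y = (w[:, np.newaxis] * means).sum(axis=0) / w.sum()

    cov0 = 10.0 * np.eye(d)
    cov_part = np.diag(cov0) if options.covariance_structure == "diagonal" else cov0[layout.tril]

    # liking criteria from the pooled hedonic cumulative proportions under the
    # initial normal approximation of the squared distance
    inv = np.full(d, 0.1)
    mu_w = mu_y[np.newaxis, :] - means
    mean_d2 = d + inv.sum() + (mu_w**2 * inv[np.newaxis, :]).sum(axis=1)
    var_d2 = (
        2.0 * d
        + 4.0 * inv.sum()
        + 2.0 * np.sum(inv**2)
        + 4.0 * (mu_w**2 * (inv * (1.0 + inv))[np.newaxis, :]).sum(axis=1)
    )
    mbar, sbar = float(mean_d2.mean()), float(np.sqrt(var_d2).mean())
    hed_pool = hed.sum(axis=0)
    hed_cum = np.clip(
        np.cumsum(hed_pool / max(hed_pool.sum(), 1.0))[:-1], eps, 1 - eps
    )
    sq = mbar + sbar * ndtri(1.0 - hed_cum)  # descending in j
    # enforce strictly decreasing positive squared criteria
    sq[-1] = max(sq[-1], 0.05 * mbar)
    for j in range(r - 3, -1, -1):
        sq[j] = max(sq[j], sq[j + 1] * 1.05 + 1e-3)
    liking = np.sqrt(sq)

    return np.concatenate(
        [means[layout.free_indices].ravel(), crit.ravel(), mu_y, cov_part, liking]
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _repair_raw(vector: np.ndarray, layout: _Layout, floor: float) -> np.ndarray:
    """Project a raw vector onto the feasible region (used on final output)."""
    means_free, sens, mu_y, cov_part, liking = layout.split(vector)
    sens = np.sort(sens, axis=1)
    for row in sens:
        for j in range(1, row.shape[0]):
            if row[j] <= row[j - 1]:
                row[j] = row[j - 1] + 1e-8
    cov = layout.covariance(cov_part)
    lam, q = np.linalg.eigh(cov)
    if lam.min() < floor:
        cov = (q * np.maximum(lam, floor)) @ q.T
    cov_part = (
        np.diag(cov) if layout.structure == "diagonal" else cov[layout.tril]
    )
    liking = np.sort(liking)[::-1]
    liking = np.maximum(liking, 1e-8)
    for j in range(liking.shape[0] - 2, -1, -1):
        if liking[j] <= liking[j + 1]:
            liking[j] = liking[j + 1] * (1 + 1e-8) + 1e-10
    return np.concatenate([means_free.ravel(), sens.ravel(), mu_y, cov_part, liking])


def fit_model(dataset: RatingDataset, options: FitOptions | None = None) -> FitResult:
    """Estimate all free parameters from a rating-frequency dataset.

    Runs ``n_restarts`` seeded optimizations (a data-driven start plus
    Gaussian jitters of it) and returns the best; the returned model always
    satisfies the constraints, and the run is deterministic given the seed.
    """
    options = options or FitOptions()
    if np.all(dataset.counts == 0):
        raise ValueError("dataset has no ratings")
    spec = dataset.spec
    layout = _Layout(spec, options.covariance_structure)
    x0_raw = _initial_raw_vector(dataset, options)
    rng = np.random.default_rng(options.seed)
    n_eval = 0
    restart_scores: list[float] = []
    best_raw: np.ndarray | None = None
    best_score = np.inf
    any_converged = False

    if options.optimizer == "transformed-unconstrained":
        t0 = raw_to_unconstrained(x0_raw, layout)

        def fun(t: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            return sse_objective(unconstrained_to_raw(t, layout), dataset, options)

        for k in range(options.n_restarts):
            start = t0 if k == 0 else t0 + rng.normal(0.0, options.restart_jitter_sd, t0.shape)
            res = optimize.minimize(
                fun,
                start,
                method="L-BFGS-B",
                tol=options.tolerance,
                options={"maxiter": options.max_iterations, "maxfun": 10**7},
            )
            restart_scores.append(float(res.fun))
            any_converged = any_converged or bool(res.success)
            if res.fun < best_score:
                best_score = float(res.fun)
                best_raw = unconstrained_to_raw(res.x, layout)
    elif options.optimizer == "cobyla-style":

        def fun_raw(x: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            return sse_objective(x, dataset, options)

        for k in range(options.n_restarts):
            start = (
                x0_raw
                if k == 0
                else x0_raw + rng.normal(0.0, options.restart_jitter_sd, x0_raw.shape)
            )
            res = optimize.minimize(
                fun_raw,
                start,
                method="COBYLA",
                options={"maxiter": max(options.max_iterations, 10 * layout.total)},
            )
            restart_scores.append(float(res.fun))
            any_converged = any_converged or bool(res.success)
            if res.fun < best_score:
                best_score = float(res.fun)
                best_raw = np.asarray(res.x, dtype=float)
    else:
        raise ValueError(f"unknown optimizer {options.optimizer!r}")

    assert best_raw is not None
    best_raw = _repair_raw(best_raw, layout, options.eigenvalue_floor)
    model = unpack_parameters(
        best_raw,
        spec,
        options.covariance_structure,
        eigenvalue_floor=options.eigenvalue_floor,
    )
    sse = sse_objective(best_raw, dataset, options)

    from .assess import variance_accounted  # local import avoids a cycle

    predicted = _predicted_counts_raw(
        best_raw,
        layout,
        dataset.trial_totals,
        options.eigenvalue_floor,
        options.hedonic_method,
        options.n_quad_nodes,
    )
    d = spec.n_dims
    r2_all = variance_accounted(predicted, dataset.counts)
    r2_sens = variance_accounted(predicted[:, :d], dataset.counts[:, :d])
    r2_hed = variance_accounted(predicted[:, d:], dataset.counts[:, d:])
    return FitResult(
        model=model,
        sse=float(sse),
        r_squared_overall=r2_all,
        r_squared_sensory=r2_sens,
        r_squared_hedonic=r2_hed,
        converged=any_converged,
        n_evaluations=n_eval,
        restart_scores=tuple(restart_scores),
        options=options,
    )


# ---------------------------------------------------------------------------
# Luce choice values from paired comparisons
# ---------------------------------------------------------------------------


def full_design_pair_count(n_stimuli: int) -> int:
    """Distinct stimulus pairs in a complete paired-comparison design."""
    if n_stimuli < 2:
        raise ValueError("a paired-comparison design needs at least 2 stimuli")
    return n_stimuli * (n_stimuli - 1) // 2


def fit_luce_values(
    pairwise_counts: np.ndarray,
    fixed_index: int = 0,
    max_iterations: int = 20_000,
    tolerance: float = 1e-12,
) -> np.ndarray:
    """Maximum-likelihood Bradley-Terry/Luce values from preference counts.

    ``pairwise_counts[i, j]`` is the number of trials on which stimulus i was
    preferred over stimulus j (zero diagonal).  Values are estimated by the
    standard minorization-maximization iteration and normalized so the value
    at ``fixed_index`` equals 1 (only ratios are identified).
    """
    w = np.asarray(pairwise_counts, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("pairwise_counts must be a square matrix")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal of pairwise_counts must be zero")
    if np.any(w < 0):
        raise ValueError("counts must be nonnegative")
    n = w.shape[0]
    comparisons = w + w.T
    n_comp, _ = connected_components(comparisons > 0, directed=False)
    if n_comp > 1:
        raise ValueError(
            "comparison graph is disconnected; relative values are not identifiable"
        )
    wins = w.sum(axis=1)
    v = np.ones(n)
    for _ in range(max_iterations):
        denom = (comparisons / (v[:, np.newaxis] + v[np.newaxis, :] + np.eye(n))).sum(axis=1)
        v_new = np.where(denom > 0, wins / np.maximum(denom, 1e-300), 0.0)
        # geometric-mean normalization stabilizes the iteration
        pos = v_new[v_new > 0]
        if pos.size:
            v_new = v_new / np.exp(np.mean(np.log(pos)))
        if np.max(np.abs(v_new - v)) < tolerance * max(1.0, np.max(np.abs(v))):
            v = v_new
            break
        v = v_new
    if v[fixed_index] <= 0:
        raise ValueError("fixed stimulus has an estimated value of zero")
    return v / v[fixed_index]
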