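"""Model assessment and interpretation.

Covers variance accounted for (two definitions, since "r^2" can mean either
the squared observed-predicted correlation or 1 - SSE/SST), degrees-of-freedom
bookkeeping, the binomial standard error of estimated rating proportions,
dimension-importance ranking from the ideal covariance, and equal-likelihood
contour ellipses of the ideal distribution projected onto dimension pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import chi2

from .model import GrtUnfoldingModel, IdealDistribution, ModelSpec, count_free_parameters


@dataclass(frozen=True)
class DfReport:
    """Degrees-of-freedom accounting for a design.

    The data contribute N*(D+1)*(r-1) free cell proportions (each of the
    N*(D+1) rows loses one df to its sum constraint); the residual df is what
    remains after parameter estimation.
    """

    data_df: int
    free_parameters: int
    residual_df: int

    def __post_init__(self) -> None:
        if self.residual_df != self.data_df - self.free_parameters:
            raise ValueError("residual_df must equal data_df - free_parameters")


def variance_accounted(
    predicted: np.ndarray,
    observed: np.ndarray,
    definition: Literal["squared_correlation", "one_minus_sse_over_sst"] = (
        "squared_correlation"
    ),
) -> float:
    """Proportion of variance in observed frequencies accounted for.

    ``squared_correlation`` is the squared Pearson correlation between the
    flattened observed and predicted arrays (the default report);
    ``one_minus_sse_over_sst`` compares squared error against squared
    deviations of the observed values from their grand mean and can be
    negative for a bad model.  Subsets (sensory-only, hedonic-only) are
    selected by slicing the arrays before the call.
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have the same shape")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values have zero variance")
    if definition == "one_minus_sse_over_sst":
        return 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    if definition == "squared_correlation":
        # a (numerically) constant predictor carries no variance information
        if np.std(pred) <= 1e-12 * max(1.0, float(np.abs(pred).max())):
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    raise ValueError(f"unknown definition {definition!r}")


def degrees_of_freedom(
    spec: ModelSpec,
    covariance_structure: Literal["full", "diagonal"] = "full",
) -> DfReport:
    """Data, parameter, and residual degrees of freedom for a design."""
    data_df = spec.n_stimuli * (spec.n_dims + 1) * (spec.n_ratings - 1)
    free = count_free_parameters(spec, covariance_structure)["total"]
    return DfReport(data_df=data_df, free_parameters=free, residual_df=data_df - free)


def rating_proportion_standard_error(p: float, n: int) -> float:
    """Standard error sqrt(p(1-p)/n) of an estimated rating proportion.

    The count of a given rating is binomial(n, p) under the multinomial
    sampling model, so the proportion's standard error shrinks as 1/sqrt(n);
    this quantifies whether a sample size supports accurate estimation of
    the true rating probabilities.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be a positive integer")
    return float(np.sqrt(p * (1.0 - p) / n))


def importance_ranking(
    ideal: IdealDistribution, dimension_names: Sequence[str] | None = None
) -> list[str]:
    """Dimensions ordered from most to least important for liking.

    Importance is inversely related to the ideal variance on a dimension:
    a consistently imagined value marks a dimension the ideal cares about.
    Ties keep input order (stable sort).
    """
    variances = np.diag(ideal.covariance)
    if dimension_names is None:
        dimension_names = [f"dim{i + 1}" for i in range(ideal.n_dims)]
    if len(dimension_names) != ideal.n_dims:
        raise ValueError("dimension_names length must match dimensionality")
    order = np.argsort(variances, kind="stable")
    return [dimension_names[i] for i in order]


def ideal_contour_projection(
    ideal: IdealDistribution,
    dim_pair: tuple[int, int],
    coverage_levels: Sequence[float] = (0.5, 0.9),
) -> dict:
    """Equal-likelihood contour ellipses of the ideal on a dimension pair.

    Projects onto the 2x2 marginal covariance block.  Each coverage level c
    maps to the ellipse containing probability c, whose semi-axis lengths are
    sqrt(eigenvalue * chi2_2 quantile at c) along the eigenvectors.  The
    orientation is the angle of the major axis in radians; a negative
    covariance between the pair yields a negatively sloped major axis.
    """
    i, j = dim_pair
    if i == j:
        raise ValueError("dim_pair must name two distinct dimensions")
    block = ideal.covariance[np.ix_([i, j], [i, j])]
    center = ideal.mean[[i, j]]
    eigvals, eigvecs = np.linalg.eigh(block)  # ascending
    major = eigvecs[:, 1]
    orientation = float(np.arctan2(major[1], major[0]))
    levels = {}
    for c in coverage_levels:
        if not 0.0 < c < 1.0:
            raise ValueError("coverage levels must lie in (0, 1)")
        scale = chi2.ppf(c, df=2)
        levels[c] = {
            "semi_axes": tuple(np.sqrt(eigvals[::-1] * scale)),  # major, minor
        }
    return {
        "center": tuple(center),
        "eigenvalues": (float(eigvals[1]), float(eigvals[0])),  # major, minor
        "orientation": orientation,
        "major_axis_slope": float(major[1] / major[0]) if major[0] != 0 else np.inf,
        "levels": levels,
    }


def plot_ideal_contours(
    model: GrtUnfoldingModel,
    dim_pair: tuple[int, int],
    coverage_levels: Sequence[float] = (0.5, 0.9),
    path: str | None = None,
):
    """Plot ideal contour ellipses with stimulus means (presentation helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    proj = ideal_contour_projection(model.ideal, dim_pair, coverage_levels)
    fig, ax = plt.subplots()
    for c, lvl in proj["levels"].items():
        a, b = lvl["semi_axes"]
        ax.add_patch(
            Ellipse(
                proj["center"],
                width=2 * a,
                height=2 * b,
                angle=np.degrees(proj["orientation"]),
                fill=False,
                label=f"{c:.0%} contour",
            )
        )
    means = model.stimulus_means
    ax.scatter(means[:, dim_pair[0]], means[:, dim_pair[1]], marker="x")
    names = model.spec.dimension_names
    ax.set_xlabel(names[dim_pair[0]])
    ax.set_ylabel(names[dim_pair[1]])
    ax.legend()
    ax.set_aspect("equal", adjustable="datalim")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
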