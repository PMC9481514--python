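# Methods

## The model

`grtunfold` implements a joint multidimensional signal-detection and
ideal-point ("unfolding") account of concurrent sensory and hedonic ratings.
An experiment presents N stimuli; on each trial a participant rates one
stimulus on one of D sensory attributes or on liking, using an r-point scale.

**Sensory side.** Stimulus *i* elicits a percept
`x_i ~ N(mu_i, I)` on the D rated dimensions. Unit, uncorrelated perceptual
noise is an identifiability device, not an empirical claim: with one rating
per trial no information about perceptual covariances is available, and the
unit variance fixes the measurement scale of each dimension. A rating on
dimension d cuts the marginal percept with r − 1 strictly increasing criteria
`X_{d,1} < ... < X_{d,r-1}`; the response is j iff
`X_{d,j-1} < x_d <= X_{d,j}` (with the outer bounds at ±infinity). Intervals
are lower-exclusive/upper-inclusive; a value exactly at a criterion — a
measure-zero event — takes the lower interval's upper rating.

**Hedonic side.** On a liking trial the participant imagines an ideal
stimulus `y ~ N(mu_Y, Sigma_Y)`; the imagined ideal varies across trials and
participants. The per-dimension variance of the ideal is inversely related to
that dimension's importance: an attribute the participant cares about is
imagined consistently. The response is driven by the Mahalanobis distance

    Delta = sqrt((y - x_i)' Sigma_Y^{-1} (y - x_i)),

i.e. Euclidean distance with each direction weighted by the ideal's inverse
covariance, and is cut by r − 1 strictly decreasing positive liking criteria
on the distance scale: rating j iff `X_{I,j} < Delta <= X_{I,j-1}` with
`X_{I,0} = +inf`, `X_{I,r} = 0`, so small distances earn high liking.
Criteria are stored on the distance scale and squared internally where the
squared-distance scale is needed; serialized parameter files carry both
scales (they are bijective).

**Distance distribution.** With `w = y - x_i ~ N(mu_W, Sigma_Y + I)`,
`mu_W = mu_Y - mu_i`, the squared distance `Delta^2 = w' Sigma_Y^{-1} w` is a
weighted sum of D independent noncentral chi-square variables with one degree
of freedom each: eigendecomposing `Sigma_Y = Q Lambda Q'`,

    Delta^2 = sum_d omega_d chi2_1(delta_d),
    omega_d = (lambda_d + 1) / lambda_d,
    delta_d = (q_d' mu_W)^2 / (lambda_d + 1),

with closed-form moments (S = Sigma_Y^{-1})

    E[Delta^2]   = D + tr(S) + mu_W' S mu_W
    Var[Delta^2] = 2D + 4 tr(S) + 2 tr(S^2) + 4 mu_W' S (I + S) mu_W.

Both identities are verified against each other (algebraically, to 1e-8
relative error over random models) and against Monte Carlo in the tests.

**Hedonic rating probabilities.** Three evaluation paths:

- *Normal approximation* (default): `Delta^2` is treated as normal with the
  moments above; the probability of rating j is the normal mass between the
  squared criteria. The approximating normal puts some mass below zero; that
  mass is folded into the top rating (its lower integration bound is −inf),
  which preserves exact normalization. The approximation is good at larger D
  and is what makes the model cheap to fit.
- *Inversion*: Imhof-type characteristic-function inversion of the weighted
  noncentral chi-square CDF (adaptive quadrature, absolute accuracy ~1e-7).
  Used as the oracle path.
- *Monte Carlo*: direct simulation of the D noncentral chi-square terms.

In the limit `Sigma_Y = I`, `mu_Y = mu_i`, the squared distance is exactly
`2 chi2_D`, giving a closed form used to validate the exact paths.

## Simulation

The generator reproduces the one-rating-per-trial design: every rating
request consumes a fresh percept draw, and every liking trial additionally a
fresh imagined-ideal draw — re-examining a stimulus yields a new sensory
sample, so nothing is reused within a trial. Defaults mirror the reference
design: 20 stimuli, 6 sensory dimensions, 7-point scales, 56 ratings per
sensory cell and 52 per hedonic cell (the cell counts left after engagement
filtering in a 5-phase, two-ratings-per-attribute group design). Per-trial
tables carry participant and phase labels assigned round-robin (sensory
trials in phases 2/4, hedonic in 3/5) so the engagement filters can be
exercised on synthetic data. All trials are generated from a single shared
parameter set: aggregation across participants is modeled as if participants
were exchangeable, which is an explicit simplification — real groups are
heterogeneous, so passing recovery tests here demonstrate correctness of the
machinery, not robustness to individual differences.

## Fitting

All free parameters are estimated by minimizing the summed squared error
between predicted and observed rating frequencies (an SSE objective on
frequencies; a per-row proportions option exists because sensory and hedonic
rows can have different trial totals). Identifiability constraints: the
reference stimulus's mean is fixed at the origin and all perceptual
covariances at I. For the flagship design this leaves
114 + 36 + 6 + 21 + 6 = 183 free parameters against 840 data degrees of
freedom (N(D+1)(r−1)), 657 residual.

The default optimizer reparameterizes the model so that all constraints hold
by construction — criteria as a first cut-point plus log-increments, the
ideal covariance through its Cholesky factor with log-diagonal, liking
criteria as a log smallest criterion plus log-decrements — and runs L-BFGS-B
with finite-difference gradients from a data-driven start plus seeded
Gaussian jitters (SD 0.5 in the transformed space) for restarts. A
COBYLA-style route on the raw parameter vector is retained; there,
constraint violations return a large finite penalty scaled by the violation
so the derivative-free search can recover. The returned model is always
feasible (eigenvalues of Sigma_Y floored at 1e-4, orderings repaired before
the final validation) and the whole procedure is deterministic given the
seed.

Initialization: sensory criteria at inverse-normal transforms of pooled
cumulative rating proportions; stimulus means at the mean z-shift matching
each stimulus's own cumulative proportions, re-centered so the reference
stimulus is at the origin; ideal mean at the liking-weighted centroid of the
stimulus means; `Sigma_Y = 10 I`; liking criteria at quantile positions of
the initial squared-distance approximation.

### The normal approximation biases ideal estimates at low D

The package's own analysis (reproduced by the tests) is that fitting the
normal-approximation path to data generated by the exact process gives
strongly biased ideal-distribution estimates when D is small. At D = 2 the
squared distance has skewness of order one in any realistic regime, giving
per-cell probability errors around 0.05–0.1; the ideal's location and scale
are identified only through comparatively weak curvature terms, so this
error dominates and the SSE minimum can sit several units away from the
generating ideal even with noise-free data. For this reason `FitOptions`
exposes `hedonic_method="exact"`, which evaluates the exact weighted
noncentral chi-square law inside the objective: one eigendimension is
handled analytically (a noncentral chi2_1 CDF is a pair of normal CDFs) and
the remaining ones integrated out — at D = 2 by Gauss–Legendre after a
trigonometric substitution that removes the square-root endpoint
singularities (accuracy ~1e-5 with 64 nodes), at D > 2 by a frozen stream of
standard-normal nodes (common random numbers, so the objective stays smooth
and deterministic). Recovery studies use this exact path; the default
remains the approximation, which is accurate and fast at the D = 6 scale the
model is designed for (per-cell error ≤ 0.10 even in the central chi-square
limit, and far smaller off-center).

### Recovery study conditions

The parameter-recovery study (tests and `scripts/acceptance.py`) fits data
simulated from `recovery_study_model()`: 8 stimuli on 2 dimensions with
5-point scales, stimulus means uniform on ±2.5 perceptual-noise units
(reference at the origin), ideal mean (0.8, −0.6) inside the stimulus cloud,
ideal covariance [[1.5, −1.1], [−1.1, 4.0]], criteria covering the observed
ranges, 5000 ratings per cell, five optimizer restarts. These conditions
were chosen once as an informative regime — every rating category populated
and liking sensitive to both dimensions. Under them the fit recovers
stimulus means with RMSE ≈ 0.03–0.06, the ideal mean to within ≈0.1 per
dimension, and the sign (and approximate size) of the ideal covariance, in
under a minute of CPU.

## Luce choice values

For paired-comparison data the Bradley–Terry/Luce values are estimated by
the standard minorization-maximization iteration on the win counts, with a
connectivity check on the comparison graph (relative values are not
identifiable across disconnected components) and the value of a designated
stimulus fixed at 1 (only ratios are identified). A complete design over N
stimuli has N(N−1)/2 distinct pairs — 190 for N = 20.

## Assessment

- Variance accounted for is reported under both common definitions — squared
  observed-predicted correlation (the default report) and 1 − SSE/SST —
  because "r²" is ambiguous between them; they can differ materially when
  predictions are biased.
- Degrees of freedom: each stimulus × attribute row of the frequency array
  loses one df to its sum constraint, so the data carry N(D+1)(r−1) df.
- The binomial standard error `sqrt(p(1-p)/n)` of an estimated rating
  proportion quantifies design adequacy; under a uniform 7-point null
  (p = 1/7) a cell with 48 ratings has SE ≈ 0.05.
- Importance ranking orders dimensions by ascending ideal variance.
- Equal-likelihood contours of the ideal on a dimension pair are ellipses of
  the 2×2 marginal covariance block; a coverage level c maps to semi-axes
  `sqrt(eigenvalue * chi2_2.ppf(c))` along the eigenvectors. Negative
  covariance yields a negatively sloped major axis.

## Engagement filtering

Raw trial tables are filtered per (participant, phase): a hedonic phase with
3 or fewer distinct liking ratings is excluded; a sensory phase in which any
single dimension received the same rating for every stimulus is excluded
entirely (the whole-phase reading — the offending dimension indicts the
phase, since disengagement is a property of the participant's state, not of
one attribute). The exclusion report satisfies the accounting identity
retained + excluded = total on both phase types.

## Numerical choices and limitations

- Eigenvalue floor 1e-4 on `Sigma_Y` (the model needs `Sigma_Y^{-1}`);
  violations raise a conditioning error naming the offending eigenvalue.
- Probability vectors from the approximation sum to 1 exactly by the −inf
  lower-bound convention; exact-path vectors are clipped to [0, 1] and
  renormalized (deviations are at the integrator's tolerance).
- SSE is a least-squares, not a likelihood, objective: no standard errors or
  information criteria are produced, matching the estimation target.
- The simulator's exchangeable-participant assumption and the absence of
  participant-level parameters mean that real-data aggregation effects
  (criterion drift, heterogeneity of ideals) are outside what the tests
  validate.
- L-BFGS-B restarts can land in distinct local minima on small/noisy
  datasets; the reported fit is the best restart and `restart_scores`
  exposes the spread.
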