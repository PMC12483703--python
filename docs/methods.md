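# Methods

This note documents the statistical machinery in `ordmap`: the model, the
estimation algorithm and its numerical choices, the synthetic-data generator
behind the simulation harnesses, and known limitations.

## Model

Each of R ordinal responses follows a cumulative-logit model,
`P(y_ir <= c) = Lambda(tau_rc - theta_ir)`, equivalent to a latent logistic
variable `z_ir = theta_ir + e_ir` cut at the thresholds. Thresholds are free
per response (category-specific); the structural part is variable-specific,
which is exactly the proportional-odds assumption applied jointly across
responses. Responses are conditionally independent given the S-dimensional
representation.

Dominance (monotone) items use inner products, `theta = u_i'v_r`; proximity
(single-peaked) items use negated Euclidean distances,
`theta = -d(u_i, v_r)`, which are nonpositive by construction — their
thresholds therefore typically sit below zero. With person predictors the
row scores are constrained to `U = XB` (reduced-rank regression /
restricted unfolding). Category coding matters for the distance models:
reversing an item's coding changes the fit, whereas for inner-product models
it only flips signs.

## Estimation: the EMM loop

Each outer iteration performs three monotone steps.

1. **E-step.** The complete-data term `-log f(z - theta)` (f the logistic
   density) has score `1 - 2 Lambda(z - theta)` and curvature
   `2 f(z - theta) <= 1/2`. Conditioning on the observed category truncates
   `x = z - theta` to `(a, b) = (tau_{c-1} - theta, tau_c - theta)`; since
   `int Lambda * lambda = Lambda^2/2`, the conditional expected score is
   `g = 1 - Lambda(a) - Lambda(b)` in closed form (validated against
   adaptive quadrature to 1e-8 in the tests).
2. **M-step by majorization.** The curvature bound 1/2 yields a quadratic
   majorizer whose minimizer targets the *working responses*
   `ztilde = theta - 2g`, so the structural update is least squares:
   - CLPCA: rank-S truncated SVD of `ztilde` (Eckart–Young), symmetric
     singular-value split so `U'U = V'V = diag(phi)`;
   - CLRRR: generalized SVD in the `X'X` metric via the thin QR of X;
   - CLMDU/CLRMDU: one SMACOF (Guttman-type) sweep on the working
     dissimilarities `delta = -ztilde`. Negative dissimilarities are handled
     by the sign-split device: a cell with `delta < 0` gets adjusted
     dissimilarity 0 and weight `1 + |delta|/max(d, eps)` (from
     `2|delta| d <= |delta|(d^2 + d0^2)/d0`), so the weighted stress remains
     a valid majorizer; both matrices are rebuilt every iteration. The
     restricted sweep replaces the row update by a weighted regression onto
     the predictors, `B = (X'D_w X)^{-1} X' D_w U_guttman`, then sets
     `U = XB` before the item update.
3. **Thresholds.** Per response, damped Newton on the cut-points with the
   structural column as a fixed offset (exact tridiagonal Hessian,
   step-halving until the likelihood does not deteriorate and the order is
   preserved). Inside the outer loop two warm-started Newton steps per
   iteration are used; at a fixed point this coincides with full ML.

Convergence is declared when the relative deviance change drops below `tol`
(default 1e-6; maximum 5000 outer iterations). Dominance models use a
deterministic start (SVD of the working responses at `theta = 0`).
Proximity models run a deterministic correspondence-analysis-flavoured start
(SVD of the standardized residuals of the coded table, coordinates scaled
to unit RMS) plus 9 random Gaussian starts by default, keeping the best
deviance; both counts are user-settable.

### Numerical choices

- Probabilities are floored at 1e-12 inside logarithms; the logistic CDF is
  evaluated with `scipy.special.expit` (stable for |arguments| up to ~700).
- `eps = 1e-8` in the SMACOF weight redefinition; halving it moves converged
  configurations by < 1e-4 on test fixtures.
- Equal singular values are broken by the decomposition order with a
  deterministic sign convention (largest-magnitude element of each right
  singular vector positive).
- Thresholds of empty categories drift to +-infinity; they are capped at
  +-30 on the latent scale with a warning so study loops survive sparse
  replicates.
- Zero distances in the Guttman transform contribute zero (standard SMACOF
  convention); singular weight totals fall back to a ridge-guarded solve.

## Parameter counts and model selection

AIC = D + 2k and BIC = D + log(N) k, with k the thresholds
(`sum_r (C_r - 1)`) plus the structural count net of indeterminacies:
`S(N+R) - S^2` (CLPCA), `S(P+R) - S^2` (CLRRR; e.g. S=2, P=R=10,
three-category responses gives 20 + 36 = 56 versus 10 x 12 = 120 for
separate proportional-odds fits), `S(N+R) - S(S+1)/2` (CLMDU: joint
translation and rotation leave distances unchanged), and
`S(P+R) - S(S-1)/2` (CLRMDU: rotation only, since without an intercept in X
a translation is not reachable through B). These are the usual naive
counts; for reduced-rank models they are known to be only approximate,
which shows up in practice: the deletion likelihood-ratio for a truly null
predictor fluctuates at the same scale as the 2S AIC penalty, so backward
elimination is more stable under BIC (the stepwise helper accepts either
criterion; dimensionality first, then predictor groups).

## Biplots and triplots

Dominance: each response is an axis through the origin with direction `v_r`;
the marker for threshold `tau_rc` sits at `(tau_rc/v_r'v_r) v_r`, labelled
`c|c+1`, with decision lines orthogonal to the axis — any point projecting
past the marker is predicted above c. Proximity: each response is a point
with circles of radius `-tau_rc`; inside a circle `P(y > c) > 1/2`, and
non-positive radii are suppressed (that category boundary is never reached
in the plane). Markers for empty on-axis regions are still drawn, since the
thresholds always exist. Triplots add, per numeric predictor, an axis along
the corresponding row of B with a solid segment over the observed
(standardized) range — an effect-size cue — dotted continuation to the plot
edge, and back-transformed value markers; categorical predictors appear as
one point per non-reference category, the reference sitting at the origin.
Interpolation of a predictor profile is vector addition, `x'B`. Variable
labels sit at the positive axis ends. Region assignment from the drawn
geometry agrees exactly with the latent-rule prediction (verified on dense
grids for both families).

## Synthetic data and the study harnesses

The generator mirrors a survey-style restricted design: P = 5 predictors
with a fixed correlation matrix (two correlated attitude scores plus
demographics-like variables), a 5 x 2 population coefficient matrix, four
item locations (eight by appending their 45-degree rotation), and
per-family population thresholds for 3- and 5-category responses (dominance
thresholds roughly symmetric around zero; proximity thresholds negative,
matching nonpositive structural values). These population values are a
synthetic fixture chosen for survey-like magnitudes — categories reasonably
balanced, recovery neither trivial nor hopeless — not estimates from any
external data set. Predictors are multivariate normal, moment-matched
uniform (Gaussian copula), or 5-point Likert discretizations, all
standardized. Ordinal draws are multinomial through the cumulative-logistic
probabilities; every replicate derives from an independent substream of a
master seed, so condition order never affects draws.

Recovery is summarised by `Q = sqrt(sum(theta_hat - theta_true)^2 /
sum(theta_true^2))`, a Stress-1-type relative discrepancy on the structural
matrix, hence invariant to rotation/reflection indeterminacies. The recovery
harness fits the matching restricted model per replicate (proximity fits
start from the population configuration, optionally plus random starts); the
dimension-selection harness generates two-dimensional data, fits S = 1..3
and records the AIC- and BIC-chosen dimensionality. The shipped study sizes
are scaled down (20 replicates per condition, N in {250, 1000}, fit caps of
500–1500 iterations at tolerances 1e-6/1e-7) — sizes chosen so the full
suite runs comfortably on one CPU while the qualitative findings (Q falls
with N, R and C; BIC finds the true rank at N = 1000, AIC never picks fewer
dimensions than BIC) are stable across seeds.

What passing these harnesses does *not* show: the generator draws exactly
from the fitted model family (no proportional-odds violations, no response
styles, no missingness, no dependence between items beyond the latent
structure), so the studies validate the estimation machinery, not
robustness to real-data misspecification.

## Known limitations

- **Unrestricted joint ML is degenerate.** With free row scores the
  joint-ML objective of CLPCA/CLMDU has, for small item sets, no interior
  minimum: one item's loadings and thresholds can grow together toward a
  step-function fit (ties at the cut-points cost only 2 log 2 per tied
  cell), so estimates drift along a boundary and different starts can reach
  different limiting deviances. The EMM still decreases the deviance
  monotonically and stops at the tolerance, but reported CLPCA/CLMDU
  solutions on small R should be read as regularized-by-early-stopping
  rather than as proper maxima — the same pathology that motivates marginal
  ML or priors in item response theory. The restricted models (CLRRR,
  CLRMDU) tie row scores to predictors and do not suffer from this.
- Missing response cells are not supported; rows must be complete.
- No standard errors; information criteria and the bootstrap (external to
  this package) are the intended inference tools.
- Probit or other links, category-specific (non-proportional) effects, and
  a-priori zero constraints on B or V are out of scope.
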