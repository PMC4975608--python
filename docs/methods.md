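# Methods

This note documents the statistical model implemented in `mqreg`, the
estimation algorithm and its numerical choices, the design decisions taken
where more than one reasonable construction exists, and what the
simulation-based tests do and do not establish.

## Model

`mqreg` models the order-q M-quantile of a response given covariates and a
group-specific random intercept:

    MQ_y(q | x_ij, γ_j) = x_ijᵀ β_q + γ_j,     i = 1..n_j, j = 1..d.

An M-quantile generalises the quantile through an influence function: with
the Huber ψ truncated at c, the index q tilts the influence by the factor
2{q I(u>0) + (1−q) I(u≤0)}, and the estimator interpolates between
expectile regression (c → ∞, asymmetric least squares) and quantile
regression (c → 0, not reachable by this fitting method).  Every parameter
— fixed effects β_q and the two variance components σ²_γq (between-group)
and σ²_εq (within-group) — is specific to q: the model is fitted
independently on a grid of q values and read as a family of location
descriptions of the conditional distribution.

Only random intercepts and two-level hierarchies are supported.  Random
slopes, three-level designs, REML-type variants and redescending influence
functions are out of scope.

## Estimating equations

Let V_q = σ²_εq I + σ²_γq ZZᵀ (block diagonal over groups), U_q = diag(V_q)
— a scalar matrix (σ²_εq + σ²_γq) I for a random-intercepts model — and
r_q = U_q^{−1/2}(y − Xβ_q) the marginally standardised residuals.  The
three equations solved are

    (β)    Xᵀ V_q⁻¹ U_q^{1/2} ψ_q(r_q) = 0
    (σ²_γ) ½ ψ_qᵀ U^{1/2} V⁻¹ ZZᵀ V⁻¹ U^{1/2} ψ_q = ½ K_2q tr(V⁻¹ ZZᵀ)
    (σ²_ε) ½ ψ_qᵀ U^{1/2} V⁻¹ V⁻¹ U^{1/2} ψ_q    = ½ K_2q tr(V⁻¹)

With squared loss at q = 0.5 these are exactly the Gaussian ML score
equations of the random-intercepts model (verified against an independent
ML implementation to 1e-3 relative); with Huber loss at q = 0.5 they are
the robust-ML "proposal 2"-type equations; squared loss at q ≠ 0.5 gives
expectile random-effects regression.  ψ_q acts on r_q directly — no
additional MAD scale is estimated in the multilevel fit, since r_q is
already standardised by U_q^{1/2}.

### Calibration constant K_2q

K_2q makes the variance equations unbiased under a Gaussian reference.  We
evaluate it at the reference *centred at its own M-quantile*:

    K_2q = E[ψ_q(Z − m_q)²],   Z ~ N(0,1),   E[ψ_q(Z − m_q)] = 0.

The centring matters.  At the q-th solution the fitted residuals are
balance-shifted (r_q ≈ Z − m_q, m_0.9 ≈ 0.94), and for a bounded ψ the
residual side of the σ²_ε equation is capped at
4c²{q²P(u>0) + (1−q)²P(u≤0)} ≈ 0.65 at (q = 0.9, c = 1.345) — strictly
below the *uncentred* constant E[ψ_q(Z)²] ≈ 1.16.  An uncentred
calibration therefore leaves the variance equation without a root far from
the median and drives the fixed-point iteration to zero; the centred
constant keeps the equations soluble and Fisher-consistent at every q,
and coincides with the uncentred definition at q = 0.5 (0.7102 at
c = 1.345, exactly 1 under squared loss).  Both the shift m_q and K_2q
have closed forms in Φ and φ (truncated normal moments), cross-checked
against adaptive quadrature to 1e-8 in the test suite.

## Algorithm

1. **Start**: β from the single-level M-quantile fit at the same (q, c)
   (iterative weighted least squares, MAD scale re-estimated per
   iteration, OLS start — the monotone ψ with c > 0 makes the solution
   unique so the start only affects speed).  σ²_ε starts from the squared
   within-group MAD of those residuals, σ²_γ from the between-group
   variance of group-mean residuals; both floored at 1e-6.  The robust
   start keeps heavy contamination out of the initial weights.
2. **Outer loop** (≤ 500 iterations): one full damped Newton–Raphson solve
   for β at the current variances — Jacobian Xᵀ V⁻¹ diag(ψ_q′(r_q)) X with
   the a.e. derivative ψ_q′ = 2{q or 1−q} I(|r| ≤ c), step halving
   whenever the score norm would not decrease, ridge retry on a singular
   Jacobian — followed by one multiplicative fixed-point sweep
   σ² ← σ² · (quadratic side)/(calibrated trace side) for both components.
   The multiplicative form preserves positivity and is stationary exactly
   at a root of the corresponding equation.
3. **Convergence**: maximum relative parameter change < 1e-6, after which
   β is re-solved at the final variances.  A fit is flagged `converged`
   only if all three estimating-equation norms are below 1e-6·n.
   Non-convergence is recorded, never silently accepted.  σ²_γ may hit
   the 1e-6 floor (boundary estimate under weak clustering) — clamped
   with a warning.

All linear algebra uses the per-group rank-one structure
V_j = σ²_ε I + σ²_γ 11ᵀ: solves, traces and log-determinants are O(n)
via Sherman–Morrison and group sums, and agree with a dense oracle to
1e-10 in the tests.  A full fit on n = 1259, d = 100 takes ~6 ms.

### Random-effect prediction

γ is predicted from a modified Fellner equation in which the same ψ_q
bounds both the residual and the random-effect terms:

    (1/σ_ε) Σ_i ψ_q((e_ij − γ_j)/σ_ε) − (1/σ_γ) ψ_q(γ_j/σ_γ) = 0.

The system decouples into d monotone scalar equations, solved by
vectorised bisection.  Under squared loss at q = 0.5 the root is the
classical BLUP shrinkage of the group-mean residual (verified to 1e-9);
with Huber loss a single extreme observation cannot drag the group effect
beyond the bound.  Predictions are q-specific and no cross-q ordering is
imposed — combining them across q is an open modelling question, not
something the package should silently resolve.

### Inference

The covariance of β̂_q is a Taylor-linearisation sandwich A⁻¹ B A⁻ᵀ with

* bread A = Xᵀ V⁻¹ diag(ψ_q′(r̂_q)) X, the **observed** score derivative;
* meat  B = d/(d−1) Σ_j g_j g_jᵀ, g_j = X_jᵀ V_j⁻¹ U_j^{1/2} ψ_q(r̂_j),
  the empirical outer product of *cluster-level* score contributions.

The empirical bread is deliberate: at q far from 0.5 the fitted residual
distribution is shifted, so the Gaussian-reference expectation of ψ_q′
(≈ 0.82 for c = 1.345, independent of q) would overstate the curvature by
a factor above 2 at q = 0.9 and halve the standard errors; the observed
bread instead makes the estimated SEs grow toward the tails, matching the
Monte-Carlo SEs within 10% in every scenario/q cell of the evaluation
study.  The cluster-level meat retains within-group score correlation that
any diagonal middle would discard.  Variance-component uncertainty is not
propagated (plug-in): the SEs are first-order in β only.  Confidence
intervals are normal-approximation intervals.

## Synthetic-data generator

The Monte-Carlo module regenerates the evaluation design: d = 100 groups
with sizes drawn once from Uniform{5..20} and repaired by ±1 moves to
total exactly n = 1259, x ~ U[0, 20] drawn once, truth
y = 100 + 2x + γ_j + ε_ij, and four error mechanisms — N(0,3)/N(0,5);
t(3)/t(3) (unscaled, variance 3 each); N(0,3)/Laplace(0, 1.58) (level-1
variance ≈ 5); and a contamination mixture with γ ~ N(0,20) in 10 of the
100 groups and ε ~ 0.9 N(0,5) + 0.1 N(0,150).  Design and replicate
streams are spawned from one master seed, so any replicate is
independently reproducible.  Bias (ARB, %) is measured against the
conditional-quantile convention: slope 2 at every q, intercept
100 + F⁻¹(q) of the level-1 error distribution — the uncontaminated
N(0,5) core in the contamination scenario.  Relative efficiency (EFF) is
the ratio of Monte-Carlo variances against the single-level M-quantile
fit at c = 1.345.

What the generator does *not* emulate: covariate-dependent error scale
(no quantile crossing pressure), informative cluster sizes, missingness,
bounded or discrete responses, and measurement error — all present in
real cohort scores.  Passing the study therefore shows correct
estimating-equation behaviour under clean location-shift truths, not
robustness to every feature of real data.

## Problem sizes and tolerances in the tests

The acceptance tests and `scripts/acceptance.py` run the full prescribed
study — 4 scenarios × q ∈ {0.5, 0.75, 0.9} × R = 500 — in under a minute
each.  Monte-Carlo tolerances follow the sampling noise of R = 500: ~3%
(1 sd) on an empirical-SE cell, ~0.05 (1 sd) on a variance-ratio cell,
wider under contamination where fourth moments are heavy.  The efficiency
ratios are the noisiest quantities reported: their values for a given
master seed can move by ±0.1 around their long-run values, while the
SE-calibration and bias summaries are stable to a few percent.

## Known limitations

* Variance-component estimates inherit the approximation of proposal-2
  style calibration: cross-residual terms E[ψ(r_i)ψ(r_k)] are calibrated
  as if ψ were linear, so σ̂² carries a small bias under heavy clipping.
* σ²_γ boundary estimates (weak clustering) shrink all predicted random
  effects to zero rather than switching to a single-level model.
* The intercept at extreme q estimates the Huber M-quantile of the error
  distribution, which lies between the expectile and the quantile; users
  comparing against true quantiles should expect the documented
  penalisation (≈ −0.35% at q = 0.9 under normal errors at c = 1.345).
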