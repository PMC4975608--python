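# mqreg — M-quantile random-effects regression

`mqreg` fits **M-quantile random-effects (MQRE) regression** for two-level
clustered or longitudinal data: a robust, quantile-like description of how
covariates shift *any* part of a conditional response distribution — not
just its mean — while a group-specific random intercept absorbs the
within-group dependence.  It is aimed at biostatisticians and
epidemiologists analysing repeated-measures cohort data (e.g. bounded,
skewed behavioural or quality-of-life scores measured on children over
several ages), where both outliers and clustering make the classical
Gaussian mixed model fragile.

## The model

For observation *i* in group *j*, the order-*q* M-quantile of the response
is modelled linearly with a group random intercept:

```
MQ_y(q | x_ij, γ_j) = x_ijᵀ β_q + γ_j,          q ∈ (0, 1),
```

with q-specific variance components γ_j ~ (0, σ²_γq) and level-1 errors
(0, σ²_εq).  Estimation solves robustified estimating equations built on
the asymmetric Huber influence

```
ψ_q(u) = 2 ψ(u) { q I(u > 0) + (1 − q) I(u ≤ 0) },    ψ(u) = max(−c, min(u, c)),
```

applied to scaled residuals r_q = U_q^{−1/2}(y − Xβ_q), with
V_q = σ²_εq I + σ²_γq ZZᵀ, U_q = diag(V_q):

* fixed effects:   Xᵀ V_q⁻¹ U_q^{1/2} ψ_q(r_q) = 0   (damped Newton–Raphson),
* variances:       ½ ψ_qᵀ U_q^{1/2} V_q⁻¹ M V_q⁻¹ U_q^{1/2} ψ_q = ½ K_{2q} tr(V_q⁻¹ M),
  with M = ZZᵀ (level 2) and M = I (level 1)   (positivity-preserving
  fixed-point iteration),

where K_{2q} = E[ψ_q(Z − m_q)²] is a standard-normal calibration constant
(m_q the normal's own M-quantile).  The tuning constant *c* trades
robustness for efficiency; c = 1.345 (95% Gaussian efficiency) is the
default.  Special cases recovered exactly: squared loss at q = 0.5 is
Gaussian ML for the random-intercepts model; Huber loss at q = 0.5 is
robust ML ("Huber proposal 2" style); squared loss at q ≠ 0.5 is expectile
random-effects regression.  Random effects are predicted from a modified
Fellner equation (a bounded-influence BLUP analogue); standard errors come
from a cluster-level Taylor/sandwich approximation.

All block-matrix algebra uses the rank-one structure of V_q — nothing
n×n is ever materialised, so fits on thousands of observations take
milliseconds.

## Worked example

Simulate one replicate of the study design (100 groups, n = 1259,
y = 100 + 2x + γ + ε with γ ~ N(0,3), ε ~ N(0,5)) and fit at three orders:

```python
from mqreg import (MQSpec, coefficient_table, draw_replicate,
                   fit_mqre, make_scenario)

scn = make_scenario("NN", 7)
data = draw_replicate(scn, 8)
fits = [fit_mqre(data, MQSpec(q=q, c=1.345)) for q in (0.1, 0.5, 0.9)]
print(coefficient_table(fits, alpha=0.05, names=["(Intercept)", "x"]))
```

```
  q        term  estimate     se    lower    upper
0.1 (Intercept)   97.6047 0.2565  97.1020  98.1073
0.1           x    1.9584 0.0141   1.9307   1.9861
0.5 (Intercept)  100.1131 0.2068  99.7077 100.5185
0.5           x    1.9792 0.0122   1.9554   2.0031
0.9 (Intercept)  102.4411 0.2427 101.9654 102.9167
0.9           x    2.0119 0.0210   1.9708   2.0530
```

The intercept traces the conditional distribution of the response (the
0.1- and 0.9-lines bracket the median line), the slope is stable across
q — as it should be under a location-shift truth — and the standard
errors grow toward the tails.  The q-specific variance components are on
`fits[k].varcomp` (here e.g. σ²_γ ≈ 3.1, σ²_ε ≈ 5.0 at q = 0.5) and the
predicted random effects on `fits[k].gamma`.

The same fit is available from a shell on any long-format CSV:

```sh
mqreg fit --data cohort.csv --response sdq --group child \
          --fixed age,ses --q 0.1,0.25,0.5,0.75,0.9 --c 1.345 --out-dir out/
mqreg simulate --scenario ALL --reps 500 --seed 1 --out-dir sim/
```

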