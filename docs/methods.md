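# Methods

## Model

Let C(t) ∈ ℝⁿ be metabolite concentrations with dynamics dC/dt = N·r(C),
where N is the stoichiometric matrix (metabolites × reactions) and r the
vector of reaction rates. Linearized around a stable steady state, small
biological fluctuations x = C − C* follow the Ornstein–Uhlenbeck process

    dx = J x dt + √(2F) dW,     J = N · (∂r/∂C)|_*,

with diagonal fluctuation intensity F. The stationary covariance C_x solves
the continuous Lyapunov equation J·C_x + C_x·Jᵀ = −2F; stationarity requires
J Hurwitz-stable (all eigenvalue real parts negative).

The inverse problem takes the sample covariance of biological replicates as
an estimate of C_x and recovers J. Raw Jacobians have n² unknowns against
n(n+1)/2 independent covariance equations; identifiability comes from the
network: only the elasticities ∂r_i/∂C_j where metabolite j is a substrate
(or declared modifier) of reaction i are free, and J = N·E maps them to the
Jacobian. Each free elasticity e at position (reaction p, metabolite q)
enters equation (i ≤ j) of the upper-triangular Lyapunov residual linearly
with coefficient N[i,p]·C[q,j] + N[j,p]·C[q,i]; the right-hand side is
−2F[i,j]. The system is solved by least squares, by default with a small
ridge (1e−8) for conditioning; with ridge 0 a rank-deficient system returns
the minimum-norm solution and an "under-determined" warning. A `direct` mode
solves for Jacobian entries on the structural mask instead of elasticities,
for comparison.

Determinacy is not purely combinatorial: even with fewer unknowns than
equations, a sparsity-respecting perturbation D with D·C + C·Dᵀ = 0 can
exist at a particular covariance (the antisymmetric null space W·C⁻¹ of the
Lyapunov operator intersecting the pattern). `system_rank` reports the
design-matrix rank against the unknown count; the random-network test
generator treats full column rank as the definition of "determinate".

## Monte-Carlo ensemble and the fluctuation model

F is unknown for real data. Each of `n_draws` (default 1000) inversions uses
a sampled diagonal F with entries base_i·exp(spread·z), z standard normal —
log-normal, hence always positive definite, with entrywise median equal to
the base. Draw streams are addressed by (seed, draw index), so ensembles are
bit-reproducible and order-independent. The reported reconstruction is the
entrywise median over draws; the entrywise interquartile range is its
uncertainty. With spread 0 every draw is identical and the IQR is the zero
matrix. Defaults: base = 0.1 × diag(sample covariance), spread = 0.2. Draws
whose linear system fails are skipped; at least 90 % must succeed.

Because the recovered elasticities are exactly linear in F at fixed C, a
uniformly mis-scaled base rescales the whole reconstruction without changing
signs or rankings — correlation-based recovery and differential ranking are
insensitive to the overall fluctuation scale. For the same reason, the
**differential** comparison must use one shared fluctuation base for both
conditions: calibrating F from each condition's own covariance diagonal
biases the two reconstructions differently and can bury a genuine
perturbation under calibration artifacts. The pipeline therefore pools the
two conditions' covariance diagonals into a single base. An optional
bootstrap over replicate rows can additionally propagate covariance
uncertainty into the ensemble.

## Differential Jacobian

For masked entry (i,j), with per-condition ensemble medians m_A, m_B and
IQRs q_A, q_B:

    score = |m_B − m_A| / max( ((q_A + q_B)/2)², ε ).

ε defaults to 1e−6 × the largest pooled IQR (absolute floor 1e−12), guarding
the spread-0 degenerate case. The score is symmetric in the two conditions;
signed median differences are exported alongside for interpretation. Ties
are broken deterministically by (row, column) index. Squaring the pooled IQR
strongly favours entries whose ensembles are tight; entries outside the
structural mask are exactly zero and excluded from ranking. An alternative
`per_condition` normalization (each median divided by its own squared IQR
before differencing) is available behind a flag.

## Discriminant statistics

The two-group companion workflow operates on Pareto-scaled data (mean-center,
divide by √SD — the convention for intensity-scaled metabolomics panels):

- **PLS-DA**: NIPALS/PLS1 on the centered 0/1 class response. For a single
  response column the weight per component is w ∝ Xᵀy, giving unit-norm
  weights, scores t = Xw, and deflation of X and y. R²Y is the fitted
  response variance; Q² comes from stratified 7-fold cross-validated PRESS
  (leave-one-out when a class has fewer samples than folds), with scaling
  refit inside each training fold.
- **OPLS-DA**: orthogonal signal correction — components of the x-loading
  orthogonal to the predictive weight direction are deflated from X
  (default 1) — followed by a single predictive PLS component.
- **VIP**: VIP_j = √( p · Σ_a w²_ja·SSY_a / Σ_a SSY_a ) with SSY_a = c_a²·‖t_a‖²
  the response variance captured by component a. Σ_j VIP²_j = p by
  construction, so the mean squared VIP is one and VIP > 1 marks
  above-average contributors.
- **Permutation validation** (default n = 200): the model is refit on
  label-permuted data; the original R²Y/Q² are compared with the permuted
  distributions, and intercepts of the regression of permuted R²/Q² on the
  |correlation| between permuted and original labels (including the original
  model at correlation 1) must fall below the original values.
- **Selection**: discriminant metabolites satisfy VIP > 1.0 (strict) and
  two-tailed t-test p < 0.05 (strict). Welch's unequal-variance t-test is
  the default — the safer choice for 3–6 replicates per group — with the
  pooled-variance variant behind a flag. No multiple-testing correction is
  applied in the rule itself (Benjamini–Hochberg can be added downstream);
  under the null the compound rule's false-selection rate is necessarily
  below α.
- **Fold change**: log_base of the ratio of class mean intensities, second
  class over first in label order.

## Synthetic ground truth

`build_serine_network` encodes D-serine de novo synthesis:
PHGDH (3PG + NAD → 3PHP + NADH), PSAT1 (3PHP + Glu → PSer + KGA),
PSPH (PSer → LSer), SRR (LSer → DSer). The four-reaction chain alone cannot
be Hurwitz-stable — NAD+NADH and Glu+KGA are conserved, and terminal D-serine
has no outflow, each forcing a zero eigenvalue — so the system is closed with
respiration-like turnover: NADHOX (NADH → NAD), NADT (NAD →, breaking the
couple's conservation), KGDH (KGA + NAD → NADH, the TCA-side step that makes
the Jacobian's NADH row depend on α-ketoglutarate), GLUT (Glu →) and DSDEG
(DSer →). That yields 9 metabolites, 9 reactions, 12 free elasticities
against 45 covariance equations — comfortably over-determined. KGA is
α-ketoglutarate (also written KEG in some sources). A 40-metabolite panel
variant pads this core with independent first-order-turnover bystanders to
emulate a targeted screen in which most measured metabolites are uninvolved.

Ground truths sample elasticities uniformly on scale × [0.5, 1.5] on the
pattern (resampling until Hurwitz-stable, bounded retries) and fluctuation
intensities on 0.1 × [0.8, 1.2]; the analytic covariance comes from the
forward Lyapunov solve. Knockout-like conditions scale one elasticity by a
factor (the bundled example: KGDH's KGA elasticity × 0.3, i.e. a weakened
NADH–α-ketoglutarate coupling) and recompute J and C.

Simulation uses Euler–Maruyama with noise amplitude √(2·dt·F) — the
convention matching the −2F right-hand side, stated here explicitly to avoid
factor-of-two drift. dt defaults to 0.05/ρ(J) and is hard-limited by
dt·ρ(J) < 0.1; burn-in covers ten relaxation times of the slowest mode and
thinning about two, so emitted samples are nearly independent. Steady-state
offsets put each metabolite's mean at 10× its stationary SD (positivity
without touching the covariance); optional i.i.d. Gaussian measurement noise
can be added. Identical (config, seed) gives identical profiles.

What the generator does *not* emulate: nonlinear (Michaelis–Menten)
saturation, heteroscedastic MS measurement error, missing values, batch or
drift effects, and non-steady-state dynamics. Passing tests therefore
demonstrate correctness of the inference machinery under its own model
assumptions, not robustness to everything real data can do.

## Problem sizes and numerical choices

The validation suite and the acceptance script use: 100 random stable
systems (n ≤ 6) for solver–oracle agreement (≤ 1e−10); 50 random determinate
networks (n ≤ 8) for exact round trips (≤ 1e−8 relative Frobenius error);
1000 thinned OU samples and 1000 Monte-Carlo draws for finite-sample
recovery (Pearson r ≥ 0.9 against true elasticities, all signs correct);
10 simulation seeds for perturbation detection (top-3 rank of the perturbed
entry); 200 simulated 40-metabolite panels (n = 6/6 per condition, three
2-SD effects for power, none for null calibration) for the discriminant
rule; 200 label permutations on groups of 20 for the permutation check; and
10⁵ Euler–Maruyama steps for the scalar OU variance (within 5 % of D/θ —
the discretization bias at dt·θ = 0.05 is ≈ 2.5 %, and the effective sample
size of the autocorrelated chain bounds the attainable precision, which is
why dt is not taken smaller).

Replicate-group defaults mirror a real targeted study (6 per condition);
the reconstruction validations use the 1000-sample regime in which the
covariance estimate is accurate enough for quantitative recovery. With
6 replicates and 40 metabolites the sample covariance has rank 5 and
reconstruction is qualitative at best — the package runs, with the ridge
carrying the rank deficiency, but recovery guarantees apply only to the
large-sample regime.

Other numerical conventions: unbiased (n−1) covariance; covariance for
reconstruction is computed on raw mean-centered intensities (Pareto scaling
belongs to the multivariate workflow; both transforms are available and
configurable); symmetrization of solver output against round-off; PCA signs
fixed by making each loading's largest-magnitude coordinate positive;
permutation p-values use the add-one convention, bounded below by
1/(n_perm + 1).

## Known limitations

- First-order (linearized) inference only; strong nonlinearity near the
  steady state violates the OU premise.
- The fluctuation matrix is modeled as diagonal; correlated noise sources
  would require the full-matrix extension.
- Elasticity-sparsity patterns for real panels must be supplied by the user;
  results are conditional on that structural prior.
- Two-class discriminant models only; multi-class designs are out of scope.
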