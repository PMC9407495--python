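# Methods

## The inference chain

The pipeline treats peel color as the terminus of a linear causal chain:
altitude sets the local climate; the ten annual climate factors (mean,
mean-maximum and mean-minimum temperature; relative humidity;
precipitation; mean, maximum and extreme wind speed; sunshine duration and
sunshine percentage) shape flavonoid and anthocyanin accumulation in the
peel; and the pigments, together with residual direct climate effects,
determine the CIELAB color coordinates. All relationships are modelled as
linear with additive Gaussian noise — the assumption underlying every
stage from Pearson screening to the normal-theory SEM likelihood.

## Correlation screening

Pearson correlations are computed on pairwise-complete observations (so a
table missing its climate block can still be screened against color), with
two-sided p-values from the exact t transform t = r√((n−2)/(1−r²)) on
n−2 degrees of freedom rather than a normal approximation: the design
sizes here are ~26 samples. Significance stars follow the conventional
raw-per-pair convention (`**` p < 0.01, `*` p < 0.05, strict at the
boundary) with no multiplicity correction, matching how such matrices are
reported in this literature; a corrected variant is a caller-side
post-processing of the returned p matrix. Constant columns yield
undefined correlations reported as missing, never as zero.

## Chemotyping

**PCA** operates on the column-standardized (z-scored, ddof = 1) matrix
via SVD. Unit-variance scaling is the default because the analytes span
two orders of magnitude (0.26 to 45 mg/g) and covariance-scale PCA would
be dominated by quercitrin and hyperoside alone; center-only scaling is
available. Component signs are fixed so each loading vector's
largest-magnitude entry is positive, making scores BLAS-independent. On
the bundled 26 × 15 content table this PCA puts 48.58% of variance on PC1
against a reference value of 48.36%; PC2 comes out at 13.76% against a
reference of 14.59%, and no alternative pre-processing we tried
(covariance-scale, pareto, log + unit variance, uncentered, Q-mode)
reproduces the latter. The likeliest explanation is that the reference
was computed on the underlying analytical replicates (3 per provenance)
or with additional pre-processing that was never stated; only provenance
means are available here, so the PC1 agreement is the reproducible part
and the PC2 gap is documented rather than papered over.

**Hierarchical clustering** z-scores each analyte, then applies
scipy's agglomerative linkage (default euclidean/complete; ward, average
and single provided) with its deterministic smallest-index tie-break. The
dendrogram exports as an ultrametric newick string (node depth = merge
height / 2). The defaults reproduce the expected biogeography on the
bundled table — the six high-altitude group-A provenances form a single
clade — but because the reference analysis never stated its metric or
linkage this cohesion is asserted only under the package defaults.

**OPLS-DA** codes the two classes ±1 (centered) and, per orthogonal
component, removes from X the part of its loading orthogonal to the
class-correlated weight w ∝ Xᵀy before fitting one predictive component
on the deflated matrix. Orthogonal scores are exactly uncorrelated with
the class vector by construction (wᵀw_orth = 0). R²X/R²Y are
explained-variance fractions; Q² uses stratified 7-fold cross-validation
(a conventional fold count for cohorts of a few dozen samples), seeded,
with the orthogonal filter re-estimated inside every fold. With
`n_orth = 0` the procedure reduces to single-component PLS-DA and is
cross-checked against scikit-learn's PLS in the tests. Default class
labels split the cohort into the high-altitude groups (A, B) versus the
rest.

## Path analysis

Stepwise screening is forward selection with backward checks. The entry
statistic is the partial-F p-value of the best remaining candidate, but
the entry *decision* uses its Šidák adjustment 1 − (1 − p_min)^m over the
m candidates screened in that step, so the familywise false-entry rate
per step equals `p_enter` (default 0.05) under the null. The raw
smallest-p rule would admit a spurious factor in roughly 1 − 0.95^10 ≈ 40%
of pure-noise datasets with ten candidates — unacceptable for a screen
whose output feeds a causal decomposition. Removal compares each included
variable's raw coefficient p-value against `p_remove` (default 0.10);
`p_enter ≤ p_remove` is enforced to prevent enter/remove cycling, and ties
break by candidate order.

Given the screened predictors, the direct path coefficients are the
standardized regression coefficients P = R_xx⁻¹ r_xy; predictor i's
indirect effect via j is r_ij P_j, and the identity
r_i = P_i + Σ_{j≠i} r_ij P_j holds algebraically to machine precision
(property-tested on random positive-definite instances). The decision
coefficient D_i = 2 P_i r_i − P_i² summarizes each factor's net
contribution; it equals r² for a single predictor and goes negative when a
factor's direct and mediated roles conflict. `path_decompose` accepts
either raw data or correlation-level inputs (r_xy, R_xx) so published
coefficient blocks can be checked when no raw data exist. Direct
coefficients of magnitude > 1 are allowed (they arise under strong
collinearity) but trigger a warning naming the offenders.

## Color regression

Contents regress on a\* and b\* in raw CIELAB units (no standardization,
so coefficients apply directly to colorimeter output); L\* is available as
an optional third predictor but the reference equations use a\*, b\* only.
R² is the coefficient of determination and F = (R²/k)/((1−R²)/(n−k−1)).
Note for users comparing against the published seven-row regression
table: its F column swapped two row pairs in typesetting
(`flavopath.published.F_ROW_SWAPS`) — each printed F lies inside the
3-d.p. rounding interval implied by the *other* row's R² and far outside
its own. Predictions are not clipped; negative contents warn.

## Structural equation models

Models are observed-variable recursive path models: directed edges among
measured variables, free variances/covariances for exogenous variables,
free residual variances for endogenous ones. The latent "climate" and
"flavonoid" blocks of the conceptual diagram are treated as grouping
labels, not measurement models (latent SEM is out of scope). With A the
edge-coefficient matrix and Ψ the exogenous/residual covariance,
Σ(θ) = (I−A)⁻¹ Ψ (I−A)⁻ᵀ, and θ minimizes
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p. χ² = (n−1)·F_min (the Wishart
convention), df = p(p+1)/2 − #free; RMSEA = √(max(χ²−df,0)/(df(n−1)));
GFI = 1 − tr[(Σ⁻¹(S−Σ))²]/tr[(Σ⁻¹S)²] and
AGFI = 1 − [p(p+1)/(2df)](1−GFI).

Numerics: optimization runs on the correlation scale (F is invariant to
diagonal rescaling of the observed variables), where raw variances
ranging from ~1 to ~1600 no longer ill-condition the finite differences;
estimates map back through per-parameter scale factors. Start values are
the per-equation least-squares coefficients read off S — for recursive
models with all exogenous covariances free these are already the ML
solution, so the optimizer mostly polishes. Convergence is declared on
L-BFGS-B success with max-gradient < 1e-4 (the noise floor of 2-point
numeric gradients at this scale) or F < 1e-9 (F ≥ 0 with equality only at
a perfect fit); up to five jittered restarts run otherwise, and a
non-converged best effort is returned flagged rather than raised.
Standard errors come from the inverse numeric Hessian of ((n−1)/2)F on
the correlation scale, mapped back; Wald z-tests drive the `**`/`*`/`ns`
annotations.

Standardization multiplies each coefficient by sd(source)/sd(target)
under the *implied* covariance. Total effects factor as (I−B)⁻¹Γ;
indirect = total − direct, and per-mediator contributions are enumerated
path-by-path over the acyclic graph (each product attributed to the
path's first intermediate node), with the matrix form used as an internal
cross-check. Model selection applies CMIN/DF < 1, RMSEA < 0.08,
AGFI > 0.9 with strict inequalities; just-identified models (df = 0) have
undefined CMIN/DF and RMSEA and therefore never pass selection, by
design — the thresholds presuppose a testable model.

## Synthetic cohorts

The generator realizes the chain the SEM assumes. Six groups occupy
contiguous altitude bands spanning 201–2188 m (group A highest), with
(5, 5, 4, 4, 4, 4) samples by default — 26 in all, matching the reference
design. Each climate factor is intercept + slope·z(altitude) + noise in
its natural units, with temperatures and humidity declining and wind
speeds rising with altitude (e.g. annual mean temperature 12 °C at mean
altitude, −4 °C per altitude SD, noise SD 2 °C). Flavonoids are linear in
the *standardized* climate factors plus Gaussian noise; color axes
receive both direct climate terms and flavonoid loadings. The structural
coefficients of the color chains default to the fitted reference values
(−0.50 and 0.41 into cyanidin 3-O-glucoside with 0.88 onward to a\*;
0.45 and 0.75 along the peonidin-3-O-glucoside → L\* chain; −0.77 from
quercitrin to b\*); the remaining loadings follow the signs of the
reference correlation screen (most analytes cooled and wind-favored;
catechin pure noise; rutin and hesperetin weakly temperature-favored).
Raw contents place each analyte near its measured mean with scale =
location/8, keeping draws positive by a > 5σ margin without clipping
(clipping would break the noiseless-linearity contract).

The ground truth (`SyntheticTruth`) is derived analytically: the implied
covariance of the full linear system gives every standardized path, and
two-edge products give the implied mediated effects. Note the
standardized truths are *derived*, not copied from the input
coefficients: the reference's printed standardized coefficients are
mutually inconsistent with unit variances once the strong negative
temperature–wind correlation is imposed (the systematic variance of a\*
would exceed 1), so inputs are specified on the standardized-parent scale
and the truth re-standardizes under the model's own implied variances.

What the generator does **not** emulate: spatially structured climate
(sites are exchangeable within an altitude band), non-Gaussian or
nonlinear responses, within-sample analytical replicates (the measured
table's n = 3), measurement error in the colorimeter, and group-level
random effects (groups are altitude bins, nothing more). Passing
recovery tests on these cohorts therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to the ways
real provenance data violate them.

## Test problem sizes

Estimator-recovery tests use cohorts of n = 500 with 200 seeded
replicates (SEM bias < 0.03, RMSE < 0.08 per standardized path;
Monte-Carlo correlation error < 0.02), stepwise simulations use n = 100
with 100 replicates, and the Monte-Carlo oracle for the implied
covariance uses a single 10⁶-draw simulation — sizes at which the
binomial/sampling error of each check is several times smaller than its
acceptance margin while the whole suite stays fast on one CPU.

## Known limitations

* Latent-variable measurement models, robust estimators (GLS, WLSMV),
  FIML for missing data and bootstrap CIs for indirect effects are not
  implemented.
* The decision coefficient is a ranking heuristic, not an inferential
  statistic; no sampling distribution is attached to it.
* OPLS-DA reports no VIP scores or permutation tests.
* The reference PC2/cumulative variance share is not reproducible from
  the shipped provenance means (see Chemotyping above); PC1 is.
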