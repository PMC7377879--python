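# Methods

## Model

`trajmix` clusters subjects by the shape of their longitudinal trajectories
across several correlated outcome measures (in the motivating application,
regional brain-atrophy measures). For subject *i*, region *j* and visit
*l* the observed (standardized) measurement is modelled as

    Y_ijl = x_i' β_j + z_ijl' b_ij + ε_ijl ,   ε_ijl ~ N(0, φ_j)

with `z_ijl = (1, t_ijl)` and `t` in **years** from the subject's first
visit, so each subject carries a random intercept (level at baseline) and
random slope (annual change) per region. The per-region blocks are
collected into one joint vector `b_i` of length `q = 2J`, and the mixture
acts on the random effects (hierarchical centering):

    b_i | U_i = k ~ N(μ_k, D_k) ,   P(U_i = k) = w_k ,   Σ_k w_k = 1.

* `μ_k` encodes component *k*'s trajectory pattern — per-region baseline
  severity (intercepts) and progression rate (slopes).
* `D_k` is a positive-definite `q×q` covariance; its off-diagonal blocks
  carry the cross-region dependence of the outcomes. Structures:
  `full` (default), `block_by_region` (independent 2×2 intercept/slope
  blocks) and `diagonal` as scalability fallbacks.
* `β_j`, `φ_j` are population parameters shared by all components:
  covariate (confounder) adjustment happens *inside* the clustering
  rather than by pre-residualizing the data. Only time-constant
  covariates are supported; covariates are mean-centered by default
  because uncentered covariates trade off against the hierarchically
  centered intercepts, slowing mixing without changing the fit.

Conditional on `U_i = k`, the random effects integrate out in closed form:

    y_i | U_i = k ~ N( X_i β + Z_i μ_k ,  Z_i D_k Z_i' + Φ_i ) ,

which gives the per-subject mixture log-likelihood, the deviance
`−2 Σ_i log Σ_k w_k f_ik(y_i)`, and the allocation probabilities used both
inside the sampler and for classification. A unit test validates the
closed form against brute-force Monte-Carlo integration over `b_i`.

## Standardization

Patient values are expressed as z-scores against the control group at the
matching region and *scheduled* visit: `z = (x − m̂_jt) / s_jt` with the
sample (n−1) SD. Standardizing per visit removes both the normal-ageing
level and the normal-ageing change, so a flat patient z-trajectory means
"ageing like a control". Actual acquisition times are mapped to the
nominal 0/12/24-month waves with a ±3-month window (configurable);
continuous-time normative smoothing is a documented alternative, not the
default. Norms are fitted before any patient filtering, never on fewer
than two controls per cell, and exported as CSV for audit. Whether the
reference SD is sample or population, and the window width, are exposed in
configuration because field practice varies.

The minimum-visit filter drops subjects with fewer than two distinct visit
times (applied to controls and patients alike). A stricter variant
requiring a gap-free prefix of the scheduled waves is available via the
`schedule` argument; the default counts distinct visits only, since a
subject observed at 0 and 24 months still identifies an intercept and
slope.

## Priors and sampler

Weakly-informative conjugate defaults (all configuration-exposed):
Dirichlet concentration δ = 1; `μ_k ~ N(0, 100 I)` on the standardized
scale; `D_k^{-1} ~ Wishart(q+1, I)` per covariance block (block dim + 1
degrees of freedom for non-full structures); `β ~ N(0, 10^4 I)` — the
fitted posterior SD of β should be, and in our runs is, far smaller than
this prior scale; `φ_j ~ InvGamma(0.01, 0.01)`.

One sweep of the systematic-scan Gibbs sampler draws, in order:
allocations `U_i` from the *random-effects-integrated* likelihood
(a blocked update that mixes far better than conditioning on the current
`b_i`), weights from their Dirichlet conditional, `b_i`, `μ_k`, `D_k^{-1}`
(per block), `β_j` and `φ_j` from their Gaussian / Wishart /
inverse-gamma conditionals. Empty components are legal during sampling;
components empty at classification time are simply reported. Subjects
sharing a visit pattern share `Z_i` and the component covariance, so the
expensive steps are batched per pattern (two patterns in the default
design: with and without the 24-month visit). A single `numpy` Generator
seeded from the chain configuration makes runs bit-reproducible; parallel
chains get distinct declared seeds.

Label switching is corrected by pivot relabeling: the retained draw with
the highest mixture likelihood is the pivot, and each draw's components
are permuted by optimal assignment on the overlap of allocation-probability
matrices. This is cheap and adequate for separated components; for heavily
overlapping components a pivot can be ambiguous, which is a known
limitation of the method.

Desk-scale defaults are 20 000 iterations, 5 000 burn-in, thinning 15
(1 000 retained draws). A production-scale setting such as 750 000
iterations with 250 000 burn-in and thinning 500 (also 1 000 retained) is
reachable through the same configuration.

## Classification and uncertainty

`p̂_ik` is by default the across-draw mean of the per-draw allocation
probabilities (the across-draw frequency of sampled hard allocations is
available as an alternative estimator; the two agree closely on mixing
chains). Hard labels use the maximum-probability rule with ties broken
toward the lowest index (logged). Two exclusion layers follow, in a fixed
order: members of components with fewer than `min_size` (default 3)
max-probability members are flagged as outlier-cluster members first; HPD
uncertainty is evaluated on the remaining subjects. A subject is
HPD-uncertain when the shortest 95% interval (arviz `hdi`) of its top
component's probability overlaps another component's interval — the
operational reading of "cannot be classified to any cluster with high
certainty". An alternative rule (top component's HPD lower bound below a
threshold) is selectable; the overlap rule is the default because it makes
no assumption about an absolute probability scale.

## Model selection

Candidates (different K and/or initializations) are compared on three
criteria: posterior mean deviance; worst absolute lag-1 autocorrelation
among monitored scalar traces (deviance plus mixture weights — scalar and
label-robust after relabeling), replacing visual trace inspection with a
quantitative proxy; and mean classification certainty `mean_i max_k p̂_ik`.
Each is min-max scaled to [0, 1] across candidates with 1 = best, and
combined by an equal-weight mean (weights configurable). A criterion that
is constant across candidates contributes 1 to all (logged); ties break
toward smaller K. Deviance is summarized by the posterior mean of the
trace rather than the deviance at posterior means, which is robust to
label switching. Information criteria (DIC/WAIC) are deliberately not
implemented — the three-part score is the selection instrument here.

Initialization matters in practice: on default-sized synthetic cohorts a
single k-means start can lock the chain into a merged local mode, while
hierarchical or random starts reach the better mode, and the deviance
criterion reliably prefers the latter. The intended workflow (and what
`scripts/acceptance.py` does) is therefore a small grid over K and
initialization strategies, ranked by the hybrid score.

## Visualization

Classical (Torgerson) metric MDS — double-centering of the squared
Euclidean distance matrix between subjects' probability rows, then an
eigendecomposition — is implemented directly because scikit-learn's MDS is
the SMACOF stress optimizer, not the classical variant. Classical MDS is
deterministic and reproduces the input distances exactly once the
dimension reaches the configuration's intrinsic rank, which the tests
verify on a known spectrum.

Fitted-value maps evaluate `x'β_j + μ_k,int(j) + μ_k,slope(j)·t` per
retained draw at a user-supplied covariate profile and report the
across-draw median with quartiles; with default thresholding only cells at
least 2 control SDs *below* the control mean are displayed (a median
exactly at the threshold is masked; masking is a lossless flag, the values
are retained). The quartile basis is ambiguous between posterior-draw and
within-cluster-subject dispersion; both are implemented
(`fitted_maps` / `subject_quartile_maps`), posterior-draw is the default,
and the basis is recorded in the output metadata. Outputs are CSV tables
per (cluster, time, region); anatomical surface rendering is out of scope.

## Synthetic cohorts

The generator emulates the study structure the model assumes: controls on
a complete 0/12/24-month schedule following a linear normal-ageing raw
trajectory plus Gaussian measurement noise; patients with mandatory
baseline and 12-month visits and 57/72 expected attendance at 24 months;
cluster-specific random intercept/slope means in control-SD units;
region-correlated random effects (cross-region correlation 0.3,
within-region intercept–slope correlation −0.2); Gaussian residuals
(default 0.5 SD); and covariate effects (age, sex, education) identical
across clusters, injected relative to the design's reference profile so
that ground-truth `μ_k` and fitted `μ_k` are directly comparable. Default
sizes are 72 patients / 31 controls with three patterns (diffuse,
minimal-atrophy, hippocampal-sparing) weighted 0.50/0.35/0.15. A
model-violation mode with cluster-specific covariate effects exists for
robustness experiments only.

What the generator does **not** emulate: measurement-pipeline error
structure (scanner/segmentation effects), non-Gaussian or heavy-tailed
residuals, visit-time jitter around the nominal schedule, informative
dropout (attendance is independent of severity), and missingness in
covariates. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to real-data violations of them.

## Numerical choices and test scales

Cholesky factorizations get one jitter-and-retry (`1e-8`-scaled) before
raising; marginal-covariance failures report the condition number.
Degenerate (zero-variance) random-effect designs are allowed in the
generator via an eigen-based PSD factor. HPD intervals require at least 10
retained draws; autocorrelation scores at least 20.

Test problem sizes were chosen to exercise every code path at desk scale:
the recovery benchmark uses K = 3, J = 4, 120 patients, 500 controls
(so that reference-norm sampling noise, of order `1/√n_controls` SD, stays
below the posterior SD of `μ_k` and the benchmark isolates the sampler),
20 000 iterations per seed, ten seeds. Per-seed adjusted Rand index is
required to reach 0.9 and pooled 95% credible-interval coverage of `μ_k`
to reach 0.80 — nominal coverage is 0.95, and the acknowledged degradation
comes from the multiplicative and additive noise the estimated norms
inject into the z-scores. With the default 31-control design that noise is
roughly `1/√31 ≈ 0.18` SD per cell, which visibly lowers coverage and can
cost a few subjects' assignments; this is a property of small normative
samples, not of the sampler.

## Known limitations

* Gaussian outcomes only; the `family` hook exists but no other link is
  implemented.
* K is fixed per chain; selection across K replaces transdimensional
  sampling.
* Pivot relabeling can be unstable when components overlap heavily.
* Covariates must be time-constant and complete for modelled subjects
  (no imputation, by design).
* The certainty criterion rewards confident chains even when confidently
  wrong; it is one of three criteria precisely for that reason.
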