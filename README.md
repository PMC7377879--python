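# trajmix

Bayesian clustering of multi-region longitudinal trajectories: a finite
mixture of multivariate linear mixed models, fit by Gibbs sampling, for
finding subgroups of subjects that share a pattern of baseline severity
*and* progression across several correlated outcome measures.

The motivating use case is disease-subtype discovery from longitudinal
regional brain measures (cortical thickness, subcortical volume): patients
are followed over irregular visits, measurements are referenced to a
healthy control group, confounders must be held fixed without
pre-residualizing the data, and any clustering claim needs an explicit
uncertainty statement. `trajmix` does all of this in one model:

* **Control-referenced z-scores** per region and scheduled visit remove
  both the normal-ageing level and the normal-ageing change.
* **The mixture model.** For subject *i*, region *j*, visit *l* (time *t*
  in years from baseline):

  ```
  Y_ijl = x_i' β_j + b_ij,0 + b_ij,1 t_ijl + ε_ijl ,    ε_ijl ~ N(0, φ_j)
  b_i | U_i = k ~ N(μ_k, D_k) ,                         P(U_i = k) = w_k
  ```

  Random intercepts/slopes per region form one joint vector `b_i`
  (hierarchical centering); cluster-specific `(μ_k, D_k)` define the
  trajectory patterns, with cross-region dependence in the off-diagonal
  blocks of `D_k`; fixed effects `β_j` (age, sex, education, intracranial
  volume, ...) are shared by all clusters, so confounders are adjusted
  inside the clustering. Irregular visit schedules are handled natively —
  every available measurement contributes.
* **Soft clustering with uncertainty.** Each subject gets posterior
  component probabilities `p̂_ik` averaged over MCMC draws; hard labels use
  the maximum-probability rule; tiny "outlier" components and subjects
  whose highest-posterior-density probability intervals overlap across
  components are flagged rather than silently assigned.
* **Hybrid model selection** across K and initializations by deviance
  (−2·log-likelihood), MCMC lag-1 autocorrelation and classification
  certainty, each min-max scaled to [0, 1].
* **Interpretable outputs**: classical MDS embedding of the probability
  matrix, and per-cluster fitted-value maps at a chosen covariate profile
  with quartile dispersion and a "below −2 control SDs" display mask.

A synthetic-cohort generator with known ground truth
(`trajmix.simulate`) makes the whole pipeline testable end to end without
any restricted data.

## Worked example

```python
import numpy as np
from trajmix import (SimulationDesign, generate_cohort, fit_reference, to_zscores,
                     ModelSpec, Priors, ChainConfig, run_chain, relabel, classify,
                     truth_recovery_report, fitted_maps, apply_display_mask)

design = SimulationDesign(n_patients=120, n_controls=500)
cohort, truth = generate_cohort(design, seed=7)

norms = fit_reference(cohort)                      # control means/SDs per (region, visit)
z = to_zscores(cohort, norms).patients             # patients in control-SD units

spec = ModelSpec(K=3, panel=cohort.panel,
                 fixed_covariates=("age", "sex_female", "education_years"))
chain = run_chain(z, spec, Priors(),
                  ChainConfig(n_iter=20_000, burn_in=5_000, thin=15,
                              seed=11, init_strategy="kmeans_baseline"))
chain = relabel(chain)                             # undo label switching
result = classify(chain)                           # soft probabilities + HPD flags

report = truth_recovery_report(truth, result)
print(f"retained draws: {chain.n_draws}")
print(f"cluster sizes (assigned): {result.cluster_sizes().tolist()}")
print(f"flags: {dict(zip(*np.unique(result.flags, return_counts=True)))}")
print(f"ARI vs ground truth: {report.ari:.3f}")

maps = apply_display_mask(fitted_maps(chain, design.reference_profile()))
print(maps.table[~maps.table.masked].head(6).to_string(index=False))
```

Output (about a minute on a laptop core):

```
retained draws: 1000
cluster sizes (assigned): [58, 44, 17]
flags: {'assigned': np.int64(119), 'hpd_uncertain': np.int64(1)}
ARI vs ground truth: 1.000
 cluster  time_months            region    median        q1        q3  masked
       1          0.0        entorhinal -2.104419 -2.157417 -2.051226   False
       1          0.0         precuneus -2.296185 -2.352347 -2.240051   False
       1         12.0       hippocampus -2.495384 -2.547728 -2.446520   False
       1         12.0        entorhinal -2.628808 -2.672844 -2.586704   False
       1         12.0 inferior_temporal -2.573896 -2.618077 -2.530380   False
       1         12.0         precuneus -2.610099 -2.662030 -2.561835   False
```

Reading this: the sampler kept 1000 post-burn-in draws; the three
generated trajectory patterns were recovered exactly (ARI 1.0) with one
subject flagged as HPD-uncertain rather than force-assigned; the fitted
map rows show cluster 1's median z-values — e.g. entorhinal cortex 2.1 SD
below the control mean at baseline, 2.6 SD below at 12 months — with
across-draw quartiles; rows above the −2 SD display threshold are masked.

## Command line

```bash
trajmix simulate --seed 7 --out cohort/
trajmix run --config run.yaml        # standardize → chain grid → classify → select → visualize
trajmix fit --config run.yaml --k 3 --init kmeans_baseline --seed 11
```

A run directory contains `norms.csv`, per-chain draw archives and traces,
`scorecard.csv` (the hybrid ranking), `classification.csv`,
`embedding.csv`, `fitted_maps.csv` and a `manifest.json` tying every
artifact to the configuration hash and seeds.

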