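# sourcesig

Unsupervised discovery of latent clinical disease sources and their
signatures from multi-modal EHR data, with patient-specific causal
attribution of a supervised disease prediction.

A patient record is the confluence of several simultaneous conditions that
share a vocabulary of labs, billing codes and medications. `sourcesig`
models each condition as an unobserved root cause in the causal graph of the
observed variables and disentangles them by probabilistic independence: the
standardized cross-section matrix is decomposed as

    X = A S        (A: n_vars × m signatures, S: m × t source expressions)

by PCA whitening followed by fixed-point ICA, exploiting the non-Gaussianity
and mutual independence of source expressions. Because the recovered sources
are independent root nodes, a classifier on `S` is a *causal* model of an
outcome, and per-sample Shapley values of that classifier read as
patient-specific causal effects — in contrast to the associational baseline
trained on the raw entangled `X`. The package is aimed at researchers in
EHR phenotype discovery and clinical causal inference.

It provides:

* a canonical data model and delimited-text I/O for multi-modal EHR event
  streams (`ehr_data`), with index-date truncation and an outcome-labeling
  rule with an exclusion window;
* per-mode transformations from sparse irregular events to dense
  longitudinal curves (`longitudinal_curves`);
* random cross-section sampling and per-variable standardization
  (`cross_sections`);
* PCA + fixed-point ICA decomposition with sign/scale conventions,
  signature pruning and original-unit back-transformation
  (`signature_discovery`);
* supervised models, a permutation Shapley estimator and polarity-specific
  effect aggregation (`causal_attribution`);
* completeness/decomposition/evidence scoring against a reference etiology
  list and Hungarian-matching recovery scores against synthetic ground
  truth (`evaluation_metrics`);
* a synthetic-EHR generator with known latent structure (`synthetic_ehr`)
  and fixed benchmarks (`benchmarks`);
* a resumable pipeline and `sourcesig` CLI (`pipeline`, `cli`).

## Worked example

Simulate a cohort from known ground truth, recover the sources, and check
the recovery:

```python
import numpy as np
import sourcesig as sg
from sourcesig import signature_discovery as sd, evaluation_metrics as em

gt = sg.sample_ground_truth(n_vars=60, m_sources=8, sparsity=0.3, seed=1)
X, S_true = sg.sample_cross_sections(gt, 20_000, noise_sd=0.1,
                                     rng=np.random.default_rng(2))
std = sg.fit_standardizer(X)
model = sd.fastica_fit(std.apply(X), m=8, seed=3, standardizer=std)
raw = model.raw_expressions(std.apply(X))
model, raw = sd.orient_signs(model, raw)
S_est = sd.scale_expressions(model, raw)

report = em.recovery_score(S_true, S_est)
print(round(report.mean_abs_r, 4), round(report.min_abs_r, 4))
```

This prints `0.9897 0.9863`: after optimally matching estimated to true
sources by absolute correlation (which absorbs ICA's permutation and sign
indeterminacies), the mean matched |r| is 0.99 — the decomposition recovers
every planted source almost exactly despite the observation noise.

Scoring a reference etiology list against discovered signatures:

```python
ref = em.load_bundled_reference()
print(round(100 * em.completeness(ref, "malignant")),
      round(100 * em.completeness(ref, "benign")))
print(em.display_decomposition(em.decomposition(ref, "malignant", "group")),
      em.display_decomposition(em.decomposition(ref, "benign")))
```

prints `92 30` (per-cent of malignant/benign etiologies matched by at least
one signature) and `5.5 4.1` (average number of signatures per matched
cause — distinct sources found for one listed condition, typically
stratified by disease course or treatment).

The full pipeline runs from a YAML config:

```bash
sourcesig simulate --out store --n-records 2000 --seed 1
sourcesig run --config run.yaml
```

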