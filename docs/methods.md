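# Methods

`sourcesig` implements an unsupervised pipeline for discovering latent
clinical disease *sources* and their observable *signatures* from
longitudinal, multi-modal EHR data, and for attributing a supervised disease
prediction back to those sources per patient. This note records the model,
its assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Model

Each observed EHR variable `X_i` is treated as a function of its observed
parents and an unobserved root cause `S_i` in the causal graph of the
record. Under two identifying assumptions — the map from sources to
variables is **linear**, and source expressions are **non-Gaussian and
mutually independent** — the cross-sectional data matrix admits the
decomposition

    X = A S,    A ∈ R^(n×m),  S ∈ R^(m×t),

where column `A_{*j}` is source j's signature (the change each standardized
variable undergoes per unit expression of the source) and `S_{ji}` is the
level at which cross-section i expresses source j. Independent component
analysis recovers `A` and `S` up to permutation, sign and scale. Because the
recovered sources are (approximately) independent root nodes, a classifier
`Y = H_c(S)` is a *causal* model of the outcome given the sources, whereas
the baseline `Y = H_s(X)` on the raw entangled variables is merely
associational.

Remaining assumptions inherited from causal inference: no directed cycles,
no unobserved single-cause confounding, and enough observed variables that
multi-source confounding is negligible.

## Pipeline stages

**Curves.** Point events become dense per-variable curves so that a
cross-section is defined at any time:

* *Labs*: shape-preserving piecewise-cubic (PCHIP) interpolation through the
  observations — smooth, exact at observations, no overshoot, non-stationary
  — with constant extrapolation outside the observed range, and a constant
  population median if a test was never observed. Same-day duplicates are
  averaged.
* *Billing codes*: a Gaussian-kernel estimate of the event rate
  (events/year) with reflection at both record boundaries so the rate
  integrates back to the event count, floored and stored as
  `log(rate + floor)`. The log scale makes signature weights back-transform
  into multiplicative rate factors.
* *Medications*: 0/1 presence on the union of fixed persistence windows
  after each mention.
* *Demographics*: constant 0/1 level indicators; age is linear in record
  time.

Defaults: kernel bandwidth 180 days (clinical processes evolving over
months), floor rate 0.01/year (one spurious code per century, keeps the log
finite), persistence 90 days (a typical prescription refill horizon). All
are exposed in configuration; none is identified by the data model itself.

**Cross-sections.** Each record is sampled at uniformly random times at a
mean density of 1 sample per 3 record-years (Poisson count, so records may
contribute zero or many columns, long records more). Variables are then
standardized per variable to zero mean and unit variance across samples;
zero-variance variables keep scale 1 and are flagged. Standardization is
per *variable* (matrix rows): that is the only reading that puts variables
on a common scale for the decomposition. Evaluation-set cross-sections are
taken exactly at each record's index day, one per record, since prediction
may use only information available then.

**Discovery.** PCA reduces and whitens the standardized matrix to `m`
components (re-centering defensively), then symmetric fixed-point ICA with
the logcosh contrast finds the orthonormal rotation maximizing
non-Gaussianity. Tolerance 1e-4 on the rotation change, max 500 iterations,
seeded initialization; non-convergence returns the partial result with a
warning. The mixing matrix is composed back through the PCA basis, and the
unmixing matrix is its exact left inverse through the subspace (`U A = I_m`
to 1e-6), which is how the non-square "A⁻¹" is interpreted for inference.

Conventions applied after fitting, in this order: (1) *sign orientation* —
each signature is flipped so its dominant (largest |weight|) element is a
positive change, ties broken by lowest variable index; (2) *expression
scaling* — each source's discovery-set expressions are affinely mapped to
mean 0, SD 0.5, and the affine is frozen for all later inference (the scale
is not identifiable, so a convention is fixed once). Orientation precedes
scaling so the stored affine signs match the displayed signatures. For
Gaussian expressions SD 0.5 puts ≈95% of expressions in [−1, 1]; for the
heavy-tailed expressions the pipeline actually recovers this is only
descriptive, and is not asserted.

Signature displays prune to the smallest top-k subset carrying ≥97.5% of
the column's L2 norm; for n equal-magnitude weights this gives
k = ⌈0.975² n⌉. Original-unit effects are additive (weight × scale) for
labs/meds/demographics and multiplicative (`exp(weight × scale)`) for code
intensities.

**Attribution.** Three architectures (random forest, gradient-boosted
trees, elastic-net logistic) × two input spaces (source expressions,
raw variables) give six configurations; hyperparameters are selected by
cross-validation per configuration, then training repeats across seeds on a
fixed held-out split (default 10 seeds at desk scale). Per-sample Shapley
values are estimated by Monte-Carlo permutation sampling with **marginal
(interventional) expectations** over a fixed background subsample (default
size 256 in the pipeline; smaller in the benchmarks): along each sampled
feature ordering, features switch one at a time from background to sample
values, crediting each feature the increase in the background-averaged
prediction. The telescoping sum makes the efficiency identity
`base + Σφ = f(x)` hold exactly on every sample, and for additive models the
estimator is exact with a single permutation. Per-source causal effects are
polarity-specific: the malignant-direction effect is the mean over strictly
positive per-sample attributions (a positive attribution means the source
pushed this record's predicted malignancy up), the benign-direction effect
the mean over strictly negative ones; sources with no qualifying values get
0, and ranks order |effect| within each polarity with ties broken by source
id.

## Synthetic generator

The generator emulates what the pipeline assumes plus the observation
noise it must survive: a sparse unit-column mixing matrix (expected column
density 0.3, pairwise |cosine| < 0.95), per-record expressions that are
zero with probability 0.5 and Laplace(0, 1) otherwise (super-Gaussian, as
ICA requires), a latent profile `x* = A s` constant within a record, and
per-mode observation processes — noisy lab draws at 4/variable-year, code
events from a Poisson process with log-rate shifted by `x*`, medication
presence with logit shifted by `x*`, exponential record spans (mean 5
years), and two dedicated sources driving sex and race so demographic
signatures exist. Outcomes are Bernoulli under a logistic model on the
designated causal sources with weight 3.0 each, which makes labels nearly
deterministic given the causal expressions so that benchmark failures
implicate the method rather than label noise.

What the generator does **not** emulate: informative (visit-driven)
observation timing, within-record expression dynamics, inter-source causal
edges, coding-practice artifacts, or terminology drift. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions — not robustness to the ways real EHR data violate them.

## Benchmarks and problem sizes

Two standard conditions are fixed in `sourcesig.benchmarks`:

* *Decomposition recovery*: 8 sources, 60 variables, 20,000 cross-sections,
  noise SD 0.1. Recovery is scored by Hungarian-matched absolute
  correlation between true and estimated expressions — invariant to ICA's
  permutation/sign/scale indeterminacies. Typical result: mean |r| ≈ 0.99.
* *Causal ranking*: the same latent structure with 3 causal sources of 8,
  5,000 records, random forests retrained over 10 seeds on a fixed 80/20
  split; Shapley attributions on 300 held-out records against a 64-row
  background with 8 permutations. Checks that every causal source ranks in
  the top 6 by malignant-polarity mean effect and that the source-input
  model reaches held-out AUC ≥ 0.85.

These sizes make both benchmarks informative in a few minutes on one CPU;
they are the package's chosen study conditions, stated here so results are
comparable across runs.

## Numerical choices and degenerate inputs

* PCA rank checks name the achievable rank when `m` is too large; whitening
  divides by per-component SDs of the fitting data.
* ICA symmetric decorrelation uses the eigendecomposition of `W Wᵀ`;
  Gaussian-only input cannot be separated and yields an arbitrary (still
  orthonormal) rotation — documented behavior, tested only for
  orthonormality.
* Constant expression rows are excluded from recovery matching with a
  warning; zero-variance sources make expression scaling fail loudly.
* Labeling: records with a malignancy code *before* the outcome window
  (days 4–1095 after the index event, both ends inclusive) are *excluded*
  rather than labeled negative — the cohort definition requires no prior
  cancer history, and same-day diagnoses are not prediction targets.
* Medication presence windows are closed at both ends (`nextafter` on the
  closing breakpoint).
* Decomposition display rounds toward zero at one decimal (50/9 → 5.5,
  29/7 → 4.1); full precision is always retained programmatically.
* The pipeline derives independent per-stage seeds from one global seed via
  SHA-256, so stage caching never aliases randomness across stages.

## Known limitations

* The curve transformations are swappable concretions chosen for their
  stated properties (shape preservation, mass conservation, boundedness),
  not identified by any data.
* `m` must be chosen by the user; the package does not select the number of
  sources.
* The causal reading of source-input models rests on the untestable
  assumptions above; the package validates machinery on synthetic ground
  truth, not the causal claims on any real cohort.
* The bundled reference tables are transcriptions of published worked
  examples used as evaluation inputs; the institutional cohort behind them
  is not available, so real-data headline numbers are out of scope.
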