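# Methods

## The model

`mspgm` fits latent Gaussian factor models to multi-subject brain-activity
matrices recorded while every subject views the same stimuli. For subject
*i* (of *J*), stimulus *n* evokes the response

    b_{i,n} = P_i c_n + mu_i + eps_i,      eps_i ~ N(0, rho_i^2 I),

where the **shared features** `c_n ~ N(0, Sigma_c)` (dimension `d_com`) are
common to all subjects and `P_i` (d_i x d_com) has orthonormal columns. The
orthonormality constraint makes each `P_i` a rigid embedding of the shared
latent space into that subject's voxel space: subjects differ in where the
common response lives, not in what it is. Stacking subjects gives the
marginal `b_n ~ N(mu, P Sigma_c P^T + Psi)` with block-diagonal isotropic
noise `Psi = diag(rho_1^2 I, ..., rho_J^2 I)`.

The **individual features** `h_{i,n} ~ N(0, Sigma'_{h_i})` (dimension
`d_ind`) follow the identical model fitted to one subject alone — no
parameter is pooled across subjects. `mspgm.individual` is therefore a thin
wrapper over the shared implementation at J=1, which keeps the two from
drifting apart; the equivalence is asserted bit-for-bit in the tests.

### EM fitting

Both models are fitted by expectation-maximization on the marginal
likelihood:

* **E-step.** The posterior of the latent given the stacked data is Gaussian
  with mean `(P Sigma_c)^T (P Sigma_c P^T + Psi)^{-1} (b_n - mu)` and an
  n-independent covariance `Sigma_c - Sigma_c P^T (...)^{-1} P Sigma_c`.
  Both are computed through a Woodbury-form solve (below).
* **M-step.** `P_i` is updated to the polar factor `A_i (A_i^T A_i)^{-1/2}`
  of `A_i = 1/2 sum_n (b_{i,n}-mu_i) E[c_n]^T` — the orthogonal-Procrustes
  maximizer of the expected complete log-likelihood under the orthonormality
  constraint (the 1/2 is immaterial: the polar factor is invariant to
  positive scaling, which the tests assert). The noise variance and
  `Sigma_c` follow in closed form; `rho_i^2` uses the *new* `P_i`
  (a conditional-maximization ordering), so every step is an exact ascent
  step and the log-likelihood trace is non-decreasing. Means are the data
  row means, computed once.

Initialization is a seeded neutral start: `P_i` the polar factor of a random
Gaussian matrix, `rho_i^2 = 1`, `Sigma_c = I`. The iteration budget defaults
to 10 (the method's reference setting); an optional relative-change early
stop can be enabled and is recorded in `fit_info` together with the full
log-likelihood trace and seed. A decrease beyond
`1e-8 * max(1, |loglik|)` raises `EMMonotonicityError` — a broken update is
a bug, not a warning.

### Feature extraction

Train- and test-phase features are extracted with the Moore–Penrose
pseudo-inverse of the fitted loading: `c_n = P^+ (b_n - mu)` for the stacked
data (which, with orthonormal blocks, is the average of per-subject
projections `P_i^T (b_{i,n} - mu_i)`), and `c_{i,n} = P_i^T (b_{i,n} - mu_i)`
per subject. At test time only the subject's own data are needed. The
posterior mean is a second extractor (`mode="posterior"`); the pseudo-inverse
is the default because it is the test-phase rule and is exact for orthonormal
loadings. Individual features extract identically through `P'_i`.

The individual model is fitted on the raw (mean-centered) data, not on
residuals after removing the shared fit — the two models are independent
views of the same data, and the decoder is what arbitrates between them.

## The visual decoder

Per subject, visual features `V` (d_v x N, e.g. PCA-reduced CNN activations)
are regressed on both feature blocks:

    min  ||V - (P_com C + P_ind H)||_F^2
         + lambda_com ||P_com||_F^2 + lambda_ind ||P_ind||_F^2.

The problem is jointly convex (strictly for positive penalties), and the
blockwise minimizers are closed-form ridge solutions, so the fit alternates

    P_com <- (V - P_ind H) C^T (C C^T + lambda_com I)^{-1}
    P_ind <- (V - P_com C) H^T (H H^T + lambda_ind I)^{-1}

from `P_ind = 0`. Gram matrices are factorized once. **Stopping** is on the
relative change of the projection matrices (default `1e-10`, at most 500
sweeps), not on the objective: near the optimum the objective flattens
quadratically in the parameter error, so an objective-change rule stops while
the projections are still ~1e-4 away from the joint minimizer, which would
break the documented guarantee that the alternation lands on the unique
joint optimum (asserted against the stacked closed form in the tests). The
objective is still recorded after every half-update and must descend
monotonically. Prediction is `v_est = P_com c_test + P_ind h_test`; either
block may be empty, which is how the shared-only and individual-only
ablations are expressed. `V` is not centered and the decoder has no
intercept, matching the objective as stated; callers can center `V`
themselves if wanted.

Penalties are searched on a validation split over `{0.1, 1, 10}` per block
(the reference grid), maximizing the validation mean confidence score —
identification is the quantity of interest, so it is also the selection
criterion. The search lives in the pipeline, not in `fit_decoder`.

## Identification metric

Visual features are first PCA-reduced to the smallest dimension whose
cumulative explained-variance ratio reaches 0.8 (default), the transform
fitted on training samples only and reused on validation/test/candidates.
Candidates are per-category means of image features. An estimate is scored
by Pearson correlation against all `M` candidates; the ground-truth
category's 1-based position `G` in descending order gives the confidence
category score `S = (M - G)/(M - 1)`. Under the null `G` is uniform and
`E[S] = 0.5`. Pearson is the correlation convention of the identification
literature; exact ties give the ground truth its **worst** rank in the tied
block (the conservative choice; `best` and `mean` are available).

## The synthetic benchmark

`gen_multisubject` forward-samples the model equations exactly (shared
latents through per-subject orthonormal loadings, individual latents through
loadings orthogonal to the shared span within each subject, isotropic
noise). The within-subject orthogonality of the two spans is a generator
convenience that makes "shared vs individual" identifiable in recovery
tests; the fitted models never assume it.

`gen_decoding_benchmark` builds the end-to-end desk-scale study
(defaults: J=3 subjects, d_i=60 voxels, d_com=d_ind=8, 50 categories x 8
images = 400 samples, d_v=60 visual dimensions):

* Category *m* has a shared latent prototype and, per subject, an individual
  latent prototype (both N(0, 1) per dimension); a sample's latents scatter
  around its category's prototypes with s.d. 0.4. Individual features thus
  carry stimulus information in subject-specific coordinates — the premise
  that makes them useful for decoding.
* Visual features are linear in the shared latents plus the *first*
  subject's individual latents (one feature matrix exists per stimulus set,
  so one subject's individual view is designated as contributing), plus
  per-image **distractor** latents (40 dimensions at scale 0.4): image
  content that no brain latent encodes, emulating the large non-decodable
  variance of CNN features. The distractor spectrum sits below the category
  signal, so the pipeline's PCA step discards distractor variance rather
  than decodable structure — the regime the real 4096-dimensional features
  put it in. Without distractors, a cumulative-ratio cut necessarily
  removes flat-spectrum signal and caps identification well below its
  information-theoretic ceiling even in noiseless runs.
* Candidates are per-category means of a *separate* image pool (5–10 images
  per category) drawn through the same visual model.
* Noise defaults: voxel noise variance 0.2 (per-voxel signal variance is
  ~16/60 ≈ 0.27, i.e. voxel-level SNR just above 1 — deliberately low, as
  in fMRI), visual noise variance 0.1.

The pipeline holds out a fixed stratified validation split (50 samples, one
image per category) for penalty selection and runs 7-fold stratified
cross-validation over the remaining 350 (one image per category per fold:
300 train / 50 test per fold). This mirrors the reference design of a fixed
validation set with k-fold rotation of the test set at 1/3 scale; the exact
fold arithmetic (8 images per category; 50-sample folds) was chosen so the
stratification is exact. The stratifier is hand-rolled because proportional
stratified splitters reject categories with fewer members than folds, which
this regime requires.

**What the generator does not emulate:** hemodynamic temporal
autocorrelation, voxel spatial structure, inter-subject differences in
voxel count or SNR, nonlinearity between latents and CNN features, and the
10,000-category scale of real candidate sets (50 categories here). Passing
benchmarks therefore demonstrate correctness and the qualitative
shared+individual > single-block ordering under the model's own assumptions,
not performance on real recordings.

## Numerical choices

* `(A^T A)^{-1/2}` via thin SVD (`U V^T`); singular values with
  `(s/s_max)^2 <= 1e-12` are rank deficiency and raise — the M-step formula
  assumes full rank, so nothing is silently regularized.
* All solves against `P Sigma_c P^T + Psi` go through the Woodbury identity
  using a PSD factor of `Sigma_c` (eigendecomposition, nonnegative
  eigenvalues kept), costing O(d_com^3) instead of O(d_all^3) and handling
  singular — even zero — latent covariance exactly. Genuinely indefinite
  covariances raise with a message to add jitter explicitly. A dense path
  is kept behind a flag for oracle testing. Log-determinants use the matrix
  determinant lemma.
* Covariances are symmetrized `(X + X^T)/2` before factorization;
  `Sigma_c` updates are eigenvalue-floored at 0 to absorb floating-point
  negativity.
* Degenerate N=1 data are rejected (mean subtraction would zero them).
* PCA dimension selection uses `searchsorted(cumsum(ratios), ratio - 1e-12)`
  so that `cum_ratio=1` returns the numerical rank.
* Penalty-grid ties during selection resolve to the first grid entry in a
  fixed order; every random draw flows from explicit seeds, so pipeline
  reports reproduce bit-for-bit.

## Problem sizes

Unit and property tests run on instances up to d_all=50, latent dimension 5,
N=500; oracle comparisons use brute-force dense conditioning and the stacked
closed-form ridge. The end-to-end benchmark runs the default configuration
above over several seeds; recovery experiments use J=3, d_i=30, d_com=4,
N=500 at 1% relative noise. These sizes exercise every code path at a scale
a laptop handles in a couple of minutes; the reference configuration for
real data (d_com=d_ind=100, ~4500 voxels) is the `PipelineConfig` default
and runs unchanged, just longer.

## Known limitations

* The EM ascends but is a local method; very low SNR or adversarial
  initialization can park it at poor optima (seeded restarts are the
  caller's tool).
* Shared and individual models are fitted independently; nothing prevents
  their fitted subspaces from overlapping, and on raw data they partially
  do. The decoder's penalties are what manage the resulting redundancy.
* The identification score assumes candidates with non-constant features
  and fails loudly otherwise.
* No missing-data handling: all subjects must see all stimuli.
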