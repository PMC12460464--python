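# Methods

This note documents the models implemented in `fcadapt`, the choices made
where the design was genuinely open, what the synthetic cohorts do and do not
emulate, and the problem sizes used by the test suite and the acceptance
script.

## Feature extraction

A subject's functional connectivity is the Pearson correlation matrix of its
T×R regional time-series matrix.  Because FC is non-directional, the model
input is the strict upper triangle, flattened row-major over 0-based pairs
(i, j), i < j, with flat index `i·R − i(i+1)/2 + (j−i−1)`.  The ordering is
fixed bit-exactly so that importance scores map back to ROI pairs
unambiguously; 200 regions give 19,900 features.  Raw correlations (not
Fisher-z values) are fed to the classifiers; the Fisher transform
z = arctanh(r) exists in the package for the simulator and for harmonizing in
a space where additive/multiplicative site effects are exactly affine.
Constant time-series columns are a hard error by default (a configurable
policy zeroes that region's correlations with a warning instead).

## The semi-supervised VAE with MMD domain confusion

**Generative model.**  z₂ ~ N(0, I), y ~ uniform over the three classes,
z₁ ~ p_θ(z₁|z₂,y), x ~ p_θ(x|z₁,d).  Both conditional densities are diagonal
Gaussians whose means come from one-hidden-layer ReLU networks (the
"decoders") and whose log-variances are learned global vectors.  A global
output variance was chosen over a per-sample variance head because FC inputs
are bounded and approximately homoscedastic, and it removes a common source of
training instability (variance collapse).

**Inference model.**  q_ϕ(z₁|x,d) and q_ϕ(z₂|z₁,y) are diagonal Gaussians
parameterized by the two encoding layers (widths 2,000 and 1,000 at full
scale); q_ϕ(y|z₁) is a linear softmax head on z₁.  The domain variable d
enters the encoder and decoder as a one-hot concatenated to their inputs.
Latent dimensions default to a quarter of the corresponding encoder width and
are fully configurable.

**Objective.**  For a labeled subject, the single-sample reparameterized
negative ELBO is

    L_s = −log p(x|z₁,d) − log p(z₁|z₂,y) − log p(z₂) − log p(y)
          + log q(z₁|x,d) + log q(z₂|z₁,y),

with z₁, z₂ drawn once per forward pass (recorded ε, so seeds reproduce runs
exactly).  For an unlabeled subject the class is marginalized exactly:

    L_T = Σ_y q(y|z₁)·L_s(x,d,y) − H(q(y|z₁)),

with an independent ε for each of the three class branches.  Because q(y|z₁)
otherwise receives gradient only through unlabeled data, an α-weighted
cross-entropy on labeled subjects is added.  Finally every non-target domain
S contributes β·MMD²(Z₁⁽ˢ⁾, Z₁⁽ᵗᵃʳᵍᵉᵗ⁾) on the z₁ posterior means of the
current minibatches.  All four pieces are combined under a single
minimization convention, (−ELBO) + α·CE + β·MMD²: the penalty formulation is
the only internally consistent reading of a bound that is maximized while
penalties are added.

**MMD estimator.**  The biased V-statistic
mean k(a,a′) + mean k(b,b′) − 2·mean k(a,b) with an RBF kernel
k(u,v) = exp(−‖u−v‖²/2σ²).  σ defaults to the median heuristic (2σ² = median
pairwise squared distance of the pooled samples, recomputed per batch and
treated as a constant in the gradient); a fixed numeric bandwidth can be set
instead.  The V-statistic is non-negative by construction, which keeps the
penalty interpretable as a distance.

**Training.**  Joint end-to-end training of both stages (the stacked
construction also admits a two-phase schedule; joint training was chosen
because the loss decomposition is reported as a single objective and it avoids
a pretraining schedule hyperparameter).  Adam at learning rate 1e-4, 50
epochs, and 20 minibatches per epoch per domain — so cohorts of different
sizes are trained simultaneously with equal batch counts, which is how
auxiliary control-only cohorts (transfer learning) are folded in.  "Number of
batches" is interpreted as batches-per-epoch; an explicit `batch_size`
override derives the count instead.  Class order is fixed as (control, autism,
asperger); prediction is the arg-max of q(y|z₁) at the posterior mean, ties
resolving to the lowest class index.  Unlabeled subjects are represented by
the literal diagnosis token `"unknown"`, so a labeled path can never read a
hidden label by construction.  Non-finite losses abort with the loss
breakdown as diagnostics.

**α and β defaults.**  Both weights trade classification against generative
fidelity and domain confusion and are meant to be tuned on validation data.
The shipped defaults (α = 500, β = 1) were chosen so the classification
gradient is commensurate with the reconstruction term at the few-hundred-
feature scale of the bundled experiments; at other input dimensions α should
scale roughly with the reconstruction magnitude.

**Autodiff.**  No deep-learning framework is used: the package ships a ~300
line tape-based reverse-mode autodiff engine over numpy float64 arrays
(broadcasting arithmetic, matmul, ReLU/exp/log/tanh, reductions, concat,
slicing) with an Adam optimizer.  Every primitive is gradient-checked against
central finite differences in the test suite.  Everything runs on one CPU.

## ComBat harmonization

The standard parametric empirical-Bayes location/scale model: features are
standardized by the batch-size-weighted grand location, preserved-covariate
effects (OLS) and pooled residual scale; per-batch additive (γ̂) and
multiplicative (δ̂²) effects are estimated in standardized space and shrunk —
normal prior on γ, inverse-gamma on δ² with across-feature moment-matched
hyperparameters — by the usual conditional fixed point, iterated to 1e-6 or
100 iterations.  `parametric=False` uses the raw per-batch moments instead.
Covariates worth preserving (diagnosis one-hots, age) are centered, regressed
jointly with batch, and re-added after correction, so harmonization does not
scrub the class signal; whether diagnosis is preserved is a caller decision
and both modes run.  Fit-on-train/apply-to-test is the supported discipline
(the transformer refuses unseen batches rather than extrapolating).
Zero-variance features are excluded from fitting and passed through with a
warning; a single batch is an error unless `allow_single_batch=True` requests
the degenerate identity model.  The implementation agrees with the
Bioconductor reference implementation to ~1e-7 on a two-batch example (tested
via Rscript).

Two properties discovered while validating are worth recording.  First,
EB shrinkage leaves a residual batch offset of order 0.1/√n per feature under
the null — the across-feature variance of γ̂ *is* its sampling variance, so
the shrinkage factor approaches ½ rather than 1 — hence "harmonizing twice"
only agrees to 1e-3 RMS once batches reach ~3·10⁴ subjects.  Second, probing
for residual site information on data harmonized in-sample yields
*below-chance* held-out accuracy (each subject's residual is anti-correlated
with its sitemates' fold mean); the site-probe experiment therefore fits
ComBat inside each cross-validation training fold, which is also the
leakage-free protocol the package recommends.

## Baselines

Polynomial-kernel SVM at C = 100 (degree 3, the conventional default, as the
degree is otherwise unspecified; one-vs-rest for three classes) and an MLP
with 200- and 500-unit ReLU hidden layers trained with Adam — thin
configurations of scikit-learn estimators.  They are trained on labeled
source data only and have no mechanism to absorb domain shift, which the test
suite verifies directionally (cross-domain accuracy below in-domain accuracy
on site-shifted cohorts).

## Evaluation

Accuracy is correct/total.  Per-class F1 = 2PR/(P+R) with F1 = 0 flagged on
zero division; the headline F1 is the macro (unweighted) average — robust to
class imbalance — with micro also emitted.  Latent domain divergence is
KL(N_a‖N_b) between diagonal Gaussians moment-fitted (MLE) to two latent
sample sets: deterministic, closed-form, asymmetric, with a 1e-8 variance
floor on degenerate dimensions.  A sample-based KL estimator (e.g. k-NN) was
rejected for determinism.  t-SNE (Barnes–Hut, PCA init, fixed seed) is
export-only: coordinates plus group/domain labels to TSV.

## Feature importance

The score of input feature j is the mean over per-epoch checkpoints of the
mean absolute first-encoding-layer weight leaving j (an L2 aggregate is
available; the mean-absolute form matches the "one scalar per feature"
reading of a weight-based importance).  The null distribution retrains the
model n_perm times on globally column-shuffled inputs — one permutation per
run applied to all subjects, the only reading that keeps a coherent feature
at each input position — and the per-feature p-value is the percent of null
scores strictly greater than the observed score.  The strict-greater count
can hit exactly 0%; an add-one smoothed policy ((count+1)/(n+1)) is offered
and flagged in output metadata.  Benjamini–Hochberg step-up at q = 0.05
selects survivors, which map back to ROI pairs via the fixed upper-triangle
ordering.  The full-scale protocol is 1,000 permutations; the bundled
experiments use a documented 100-permutation, reduced-dimension setting
(retraining 1,000 times at full scale is a cluster-sized job).

## Synthetic cohorts

The generator composes, in Fisher-z space: a per-feature baseline drawn
N(0, 0.3²); class mean shifts on a designated affected-feature subset
(autism +e, Asperger's +e/2 — intermediate between control and autism, as the
clinical literature describes — control 0); per-site per-feature additive
offsets γ ~ N(0, 0.3²) and multiplicative factors δ ~ U(0.7, 1.4); and
subject noise N(0, 0.25²).  The composed z-values map through tanh, so
features lie strictly in (−1, 1) and the site effect is *exactly* the
location/scale model ComBat assumes — giving the harmonizer a recoverable
ground truth.  Site-effect magnitudes were set comparable to the class effect,
the regime in which multi-site pooling is genuinely harmful.  Time-series
mode instead draws each subject's T×R series from a zero-mean multivariate
normal whose correlation matrix is the subject's ground-truth FC matrix
(eigenvalue-clipping repair at 1e-8 with renormalization when a random target
is not positive definite, logged), so extraction recovers the truth to
~1/√T.

What the simulator does **not** emulate: hemodynamics, motion and scanner
physics, heavy-tailed or spatially structured noise, site-by-class
interactions, age/sex confounding, and realistic FC covariance structure
(features are independent in z-space given class and site).  Passing tests
therefore demonstrate that the machinery is correct and behaves as designed
under the assumed effect structure — not that any particular accuracy will
be attained on real multi-site fMRI data.

## Problem sizes and experiment design

The bundled experiments are scaled to a desk machine, as the package's own
choice of test conditions:

- **Strong-signal accuracy**: 30 ROIs (435 features), 3 sites/domain,
  20 subjects/class/site (60/class/domain), class effect 0.6 z-units, no site
  effects; encoders 128/64, latents 32/16, α = 500, β = 1, 50 epochs.  Target
  test accuracy on 60 held-out unlabeled-domain subjects exceeds 0.90.
- **Domain-confusion effect**: same cohort geometry with class effect 0.3 and
  the default site effects; β ∈ {0, 1, 10}, 20 epochs, 5 seeds; residual
  source↔target latent KL decreases in β (mean over seeds).
- **ComBat recovery**: 3 sites × 1,000 controls, null classes, zero baseline;
  recovered γ*, δ* within 10% relative RMS of the (identifiability-centered)
  truth.  The comparison centers γ by the batch-size-weighted mean and scales
  δ by the pooled sigma because ComBat's parameters are only identified
  relative to those references.
- **Importance recovery**: 15 ROIs (105 features), 120 subjects, 10 affected
  features, tiny network (32/16, latents 8/4), learning rate 3e-3 for 30
  epochs so the trained signal dominates the random initialization in the
  weight magnitudes; precision@k ≥ 0.7 of the score ranking against the
  affected set, and a 100-permutation null for FDR selection.

The whole test suite runs in a few minutes on one CPU;
`scripts/acceptance.py` re-runs all of the above from scratch with seeds
derived from `--seed`.

## Known limitations

- The sampled-ELBO gradient is single-draw; loss curves are noisy at small
  batch sizes.
- The median-heuristic bandwidth is recomputed per minibatch from means, so
  the MMD penalty's scale drifts slowly during training.
- ComBat here is the classic linear-covariate model: no ComBat-GAM, no
  reference-batch variant.
- The importance score is a first-layer weight heuristic, not a saliency
  method; it inherits the identifiability caveats of weight-based
  interpretation.
- Five-fold cross-validation utilities follow scikit-learn conventions;
  fold-level variability on small cohorts is substantial and reported as
  mean±sd, not significance-tested.
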