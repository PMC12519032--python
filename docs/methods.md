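# Methods

`fedsynth` is a self-contained simulation benchmark for one question: what
does horizontal federated training do to the fidelity and privacy of
synthetic tabular data generators, relative to training the same generator
centrally?  This note records the models, the synthetic study table, the
metrics, and the numerical and design choices a maintainer would want to
know.

## The study table

The pipeline is exercised on a generated stand-in for a mixed-type adult AML
(acute myeloid leukemia) clinical table of 1540 records and 12 features.
Access-controlled real data cannot ship with a test suite, so
`fixtures.build_aml_schema()` defines an explicit emulation: five continuous
columns (age — the non-IID conditioning variable — plus white-cell count,
hemoglobin, platelets and marrow blast percentage, the blood counts
log-normal as they are in practice) and seven label-encoded categoricals
with 2–5 levels (sex, ECOG performance status, cytogenetic risk, WHO class,
secondary disease, transplant, remission status).  Columns are coupled
through a Gaussian copula with a fixed rank-correlation target encoding
plausible clinical structure (age–risk, age–transplant, WBC–blasts,
Hb–platelets, risk–remission, …; the full matrix is in the source).  The
copula gives a simple oracle: the latent correlation ρ between two coupled
continuous columns induces Spearman correlation (6/π)·asin(ρ/2), which the
tests verify at n = 20 000.

What the emulation does *not* reproduce: the real table's variable
identities and marginals, missing-data artifacts, and any deterministic
clinical relations.  Passing tests therefore demonstrate that the machinery
behaves correctly on realistic mixed-type data of this shape — not that any
particular clinical finding transfers.

## Encoding

Both generators train on a continuous representation produced by a single
encoder fitted on the **full** table before partitioning and shared by every
federated client, so all nodes use one layout and unseen labels cannot
occur.  Continuous columns get mode-specific normalization: a univariate
Gaussian mixture is fitted per column (EM, model order 1…10 chosen by BIC,
components under weight 0.005 pruned; a constant column degenerates to one
mode with scale floor 1e-6), a mode k\* is drawn per cell with probability
proportional to responsibility, and the cell becomes α = (v − μ\_k\*)/(4 σ\_k\*)
clipped to [−1, 1] next to a one-hot mode indicator.  Categoricals are plain
one-hots.  Decoding is the exact algebraic inverse (argmax of the indicator
blocks, ties to the lowest index); round-trips are exact wherever α was not
clipped.  BIC-based order selection was chosen after both plain EM at fixed
order and a Dirichlet-process variational mixture failed the obvious sanity
oracle (a single Gaussian should keep one mode; a well-separated bimodal
sample, two).

## Generators

Both models are small MLPs trained with Adam on an in-repo reverse-mode
autodiff engine (`autodiff.py`) whose backward rules are themselves
differentiable — the Wasserstein gradient penalty needs gradients of an
input-gradient norm.  The engine is validated against finite differences,
including the second-order path.

**Conditional tabular GAN.**  Generator: 128-dim noise plus a conditional
vector, two residual blocks (Linear 256 + batch-norm + ReLU, output
concatenated onto the block input), linear head; tanh on the normalized
scalars, gumbel-softmax (τ = 0.2) on every one-hot block.  Critic: inputs
grouped in pacs of 10, two 256-unit layers with LeakyReLU(0.2) and dropout
0.5, Wasserstein loss with gradient penalty (λ = 10, per-pac-group
interpolates).  The conditional vector is drawn by training-by-sampling:
pick a categorical column uniformly, a level by log-frequency, and a real
row carrying that level; the generator pays a cross-entropy penalty when its
generated block contradicts the condition.  Hyperparameters follow the study
configuration: hidden 256×2 on both networks, lr 2e-4 with weight decay
1e-6, Adam betas (0.5, 0.9), batch 500, embedding 128, pac 10; one critic
and one generator update per step; reference budget 500 epochs.  Batch
normalization always uses current-batch statistics, so sampling is a pure
function of (weights, seed, batch).

**Tabular diffusion model.**  A standard continuous-space DDPM over the
encoded table (one-hot blocks treated as continuous and re-argmaxed at
decode): linear β schedule from 1e-4 to 0.02 over T = 500 steps (T = 100 in
the desk profile), an MLP denoiser (512, 512) with a 16-dim sinusoidal time
embedding regressing the injected noise under MSE, lr 1e-4 (constant by
default, with an optional per-epoch linear decay), ancestral sampling.

Both training loops consume one explicit RNG stored on the model state, and
encoding inside training uses a fixed seed, so R single-epoch calls are
bit-identical to one R-epoch call.  That property is what the federation
keystone test leans on.

## Federation

`run_federation` simulates FedAvg with full participation: per round the
server broadcasts the global weight vector, each client trains one local
epoch on its partition (optimizer moments and RNG persist client-side), and
the server takes the sample-count-weighted average.  Counts are normalized
before averaging so the single-client average is bitwise its own weights;
with one node holding all data, federated training is therefore *exactly*
centralized training — every downstream federated-vs-centralized difference
is attributable to the data split and the averaging, not the harness.  The
reference budget of 500 centralized epochs maps to 500 rounds × 1 local
epoch so total local passes match.

Partition scenarios: **B** — uniform split into near-equal nodes; **IB** —
N−1 minority nodes of round(0.05·n) random rows each, the rest to the last
node; **IB_non_iid** — rows binned into age quantiles, each bin spread over
nodes by a Dirichlet(α = 10) draw (largest-remainder integer allocation,
empty nodes repaired from the largest).  Quantile-bin Dirichlet allocation
is the standard label-skew recipe generalized to a continuous covariate; the
study describes only "age-dependent Dirichlet sampling", so the stratum
construction is this package's choice.

## Metrics

* **φk correlation**: both variables binned (equal-frequency, 10 bins for
  continuous; native levels for categorical), Pearson χ² with the
  (r−1)(c−1) noise pedestal subtracted, then inverted to the ρ of a binned
  bivariate normal whose bin edges match the observed marginals (rectangle
  probabilities by Gauss–Legendre quadrature, 24 nodes; monotone root-find,
  tolerance 1e-6).  A constant column scores 0 against everything.
* **Correlation-matrix cosine similarity**: 1 − d_cos between the two φk
  matrices' strict upper triangles (the unit diagonal would only inflate
  similarity; a `full_matrix` flag restores it).
* **Vendi Score**: exp of the Shannon entropy of the eigenvalues of K/n,
  K the cosine-similarity kernel of the numeric columns, z-scored by
  default so no column's scale dominates; eigenvalues below −1e-8 are an
  error, small negatives are clipped.
* **Hellinger**: √(1 − Σ√(p q)) per column (label union for categoricals,
  20 equal-width bins over the pooled range for continuous), averaged.
* **DD-plot R²**: Mahalanobis depth 1/(1+d²) (ridge 1e-6) of every pooled
  point w.r.t. the real and the synthetic sample; R² of the scatter against
  the identity line (not a fitted line), floored at 0.
* **DLA**: six classifier families (logistic, tree, random forest,
  histogram gradient boosting, kNN, Gaussian naive Bayes) trained to tell
  real rows (label 0) from synthetic (label 1) on one-hot + z-scored
  features, stratified 70/30 split; the classifier with the best F1 — the
  most restrictive case — is reported.  A fixed roster rather than an
  auto-ML sweep keeps folds deterministic.

## Privacy attacks

All four attacks report success, a naive baseline, and the normalized excess
risk max(0, (success − baseline)/(1 − baseline)).  Record similarity is the
Gower distance with numeric ranges taken from the reference table.

* **Membership inference**: claim membership when the nearest synthetic
  neighbour is within Gower 0.05; baseline = claim rate on an equal-size
  control sample drawn from the same population generator but unseen by the
  model.
* **Attribute inference**: each column in turn is the secret, predicted
  from the nearest synthetic neighbour over the remaining columns; numeric
  success within 0.05·range, categorical exact; baseline predicts by
  drawing from the synthetic marginal; the overall rate is the column mean.
* **Linkability**: two disjoint column views (default first/second half of
  the schema) matched to their k = 1 nearest synthetic neighbours; success
  when the neighbour sets intersect; baseline is the exact probability two
  random k-subsets intersect.  Note that an all-categorical view can
  collide across records, which dilutes the attack — a real property, not
  an artifact.
* **Singling out (multivariate)**: 500 predicates, each conjoining
  conditions on *all* attributes of a sampled synthetic record (categorical
  equality, numeric within ±0.05·range); success = matching exactly one
  real record; baseline predicates are built identically from an
  independent draw of the same schema.

## Experimental protocol and statistics

A cell is (model, scenario, node count).  Per cell one model is trained,
then 10 synthetic tables of the real table's size are sampled with fold
seeds that are a pure blake2-hash function of (base seed, cell, fold) — any
cell reruns bit-identically in isolation.  Every fold is scored with the
full battery; cells report mean and SD.  Comparisons use the pooled-variance
Student t-test (df = n₁+n₂−2 = 18 at 10 folds), two-sided, significance
0.05, no multiple-testing correction by default (a Benjamini–Hochberg flag
exists).  Cells with zero spread in both groups skip the test with an
explicit flag.  A failing cell is logged and skipped without aborting the
grid.

## Desk-scale profile and what it shows

The reference configuration (500 epochs / 500 rounds, T = 500) is available
but slow on one CPU; tests and the acceptance script run a desk profile:
100 epochs / 100 rounds, T = 100, fixture n = 1540, with 10 folds for the
statistical protocol and 3 folds inside the heaviest directional check.
At this scale the centralized GAN reproduces marginals well (mean Hellinger
≈ 0.07, detection AUC ≈ 0.8–0.9) but captures only part of the
cross-column dependence structure; the directional federated-vs-centralized
comparison is correspondingly noisy, which the acceptance suite measures
rather than hides.

## Known limitations

* The autodiff engine is deliberately minimal (float64, 2-D tensors, the op
  set the models need); it is not a general-purpose framework.
* Dependence learning by the GAN at desk scale is weak; conclusions about
  correlation fidelity at the reference scale require the full budget.
* The linkability and singling-out baselines are this package's
  constructions; published attack tools may calibrate differently.
* Vertical federation, client dropout, secure aggregation and differential
  privacy are out of scope.
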