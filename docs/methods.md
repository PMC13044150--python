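# Methods

## The model

`atlasfuse` classifies subjects as case or control from resting-state
functional-connectivity (FC) networks observed under several brain
parcellations (atlases) at once. The pipeline per subject:

1. **Connectome.** For each atlas with ROI time series
   `X ∈ R^{T×N}` (T timepoints, N ROIs), the FC matrix is the Pearson
   correlation `R_ij = corr(X_:,i, X_:,j)`. Correlations are used raw — no
   Fisher z-transform — for both edges and features.
2. **Graph.** The dense FC matrix is sparsified by K-nearest neighbors:
   each ROI keeps its K most similar neighbors, where similarity is the
   *signed* correlation by default (`metric="absolute"` is available).
   Directed selections are symmetrized by union, so every node retains
   degree ≥ K and no node is isolated. Ties at the K-th rank break toward
   the lower ROI index, making construction deterministic. Edge weights
   are the correlation values; node features are the FC row profiles
   (feature of ROI i = row i of R, so the feature dimension equals N).
3. **Structure-aware transformer (SAT) encoder, per atlas.** Each layer
   computes dense multi-head self-attention over ROIs, but queries and
   keys are projections of *structural* node embeddings: for every node, a
   small message-passing GNN (sum aggregation, ReLU, edge weights as
   multiplicative message coefficients) is run on the node's k-hop induced
   subgraph and read out at the root. Values are projections of the raw
   node states. Scaled dot-product attention, residual + LayerNorm, and a
   ReLU feed-forward block with dropout complete the layer. A mean readout
   over nodes gives the per-atlas graph embedding. With `k_hops = 0` the
   structural branch sees only each node's own feature and the encoder is
   exactly a plain transformer — the test suite exploits this limit.
4. **Lightweight attentional feature fusion (LAFF).** Per-atlas embeddings
   are projected to a shared fusion dimension; one shared affine map scores
   each projected embedding to a scalar, and a softmax over atlases yields
   nonnegative weights summing to 1. The fused representation is the
   weighted sum — cost linear in the number of atlases, in contrast to the
   quadratic cost of pairwise query-key-value attention. The weights are
   computed per subject from that subject's embeddings, so averaging them
   over a cohort gives an interpretable "which atlas mattered" score.
5. **Classifier.** One hidden ReLU layer with dropout, a 2-unit softmax
   output. Ties in the argmax decision break toward the control class.

### Training protocol

AdamW with decoupled weight decay (0.01), cosine-annealed learning rate
from `learning_rate` at step 0 to `min_lr` (default 0) at the final step,
label-smoothed cross-entropy (target `(1−ε, ε)`, ε = 0.1 by default),
batch size 8. The shipped defaults are lr 0.001, 200 epochs, dropout 0.3,
three SAT layers — a conventional operating point for connectome
classifiers at the 100–250-ROI scale.

Multi-branch models are prone to *branch starvation*: if the fusion
scorer locks onto the most informative atlas early, the other atlas
encoders receive gradients scaled by their (small) fusion weight and stop
improving — which degrades their attention maps even when classification
is perfect. `TrainConfig.fusion_warmup_frac` therefore trains with
uniform fusion weights for the first fraction of epochs (scorer frozen),
then lets the scorer specialize; the toy-scale experiments use 0.5. With
warm-up disabled (the default) behavior is the plain end-to-end model.

Evaluation uses nested stratified cross-validation: outer folds (10 for
large cohorts, 5 for small) estimate generalization; on each outer
training set an inner 3-fold grid search selects hyperparameters by mean
inner AUC; the winner is retrained on the whole outer training set and
scored once on the held-out fold. A leakage guard asserts on every run
that outer-test subjects are disjoint from everything used for selection
and training. With a single-configuration grid the inner loop is skipped
(selection is trivial). Metrics: ACC, SEN (case recall), SPE (control
recall), and AUC computed per fold by rank-based pair counting with
half-credit for ties, then aggregated as mean ± sd over folds (never
pooled).

### Interpretability

* **ROI attention**: the attention mass each ROI *receives* inside the
  SAT layers — column means of the row-normalized attention matrices —
  averaged over heads, layers, and subjects of the training set. The exact
  aggregation convention is an open choice in this family of models; it is
  isolated in `interpret.subject_roi_attention` so it can be swapped. The
  top-10 ROIs per atlas (ties toward lower index) are the reported
  discriminative regions. Under cross-validation the recovery experiment
  reports the *consensus* ranking — attention averaged over the outer-fold
  models before taking the top-10 — because single-model attention maps
  are noisy across training runs while their consensus is stable; this is
  the usual stability-selection logic for CV-derived biomarkers. Per-fold
  recalls are kept alongside so the variability stays visible.
* **Cross-atlas overlap**: top-ROI lists are matched across atlases by
  centroid proximity (≤ 10 mm) when centroids exist, else by label, and
  grouped into three-atlas, two-atlas, and singleton buckets; unmapped
  labels are reported, never dropped.
* **Discriminative edges**: Welch (unequal-variance) two-sample t-tests on
  every FC edge among the top-10 ROIs, Benjamini–Hochberg corrected within
  each atlas's 45-pair family, significant at q < 0.05. Welch is preferred
  over the pooled-variance test because case/control groups are rarely the
  same size. Edges constant in both groups get p = 1 and a degeneracy flag.

## Synthetic cohorts

The generator emulates the *multi-atlas* structure of a two-group
resting-state study: `n_latent` Gaussian sources with a compound-symmetric
baseline correlation (0.2) are the shared brain signal; every ROI of every
atlas maps to exactly one source and observes it through additive Gaussian
noise (`noise_sd`, default 0.5). Cases differ only in the coupling of
designated source pairs, shifted by `effect_delta` (default −0.4,
hypo-connectivity) and repaired to the nearest valid correlation matrix
(alternating projections via statsmodels). Consequences used throughout
the tests:

* expected ROI-level FC is `C[s,t] / (1 + σ²)` for ROIs on sources s ≠ t
  and `1 / (1 + σ²)` for two ROIs on one source — at the defaults the
  planted group difference is −0.4/1.25 = −0.32 on exactly the ROI pairs
  bridging the affected sources, and nowhere else;
* the planted ROI sets per atlas are recorded as ground truth, and the
  ROI→source assignment is deterministically shuffled so ROI index order
  carries no information (a ranking that breaks ties toward low indices
  must not look spuriously good at recovery);
* with 195 timepoints the sampling sd of a single correlation is ≈ 0.07,
  so the planted effect is strong (d ≈ 4 per edge) — the recovery scenario
  tests the pipeline's correctness, not its statistical power.

What the generator does **not** emulate: band-limited (0.01–0.1 Hz) BOLD
temporal autocorrelation, site/scanner effects, head-motion artifacts,
inter-subject anatomical variability, or overlapping/weighted
ROI-to-network memberships. Passing the recovery experiments therefore
shows the pipeline is implemented correctly and can recover planted
signal under idealized noise; it says nothing about effect sizes or
accuracies attainable on real cohorts.

### Shipped scenarios

The default "toy" scenario uses three parcellations of 20/34/42 ROIs over
12 sources, 60 cases vs 60 controls, 195 timepoints. The 42-ROI atlas
maps five ROIs to each affected source (25 planted bridge pairs) versus
2+2 and 3+3 for the smaller atlases, so it carries the strongest planted
signal — the fusion weights should find this. `full_scale_atlases`
provides 116/200/246-ROI versions of the same construction for slower,
optional runs.

## Problem sizes and numerical choices

The neural network runs on a small reverse-mode autodiff engine written
on NumPy (`autodiff.py`); gradients are verified against central finite
differences in the test suite. All randomness (init, shuffling, dropout,
simulation) flows through seeded `numpy.random.Generator`s; evaluation
mode disables dropout and is bit-reproducible.

The shipped toy-scale experiments use a deliberately small encoder —
2 SAT layers, hidden 16, 2 heads, `k_hops = 1`, 1-layer subgraph GNN,
KNN K = 8 on the 20–42-node graphs — trained with lr 3e-3 (cosine to 0)
for 12–30 epochs. With ~100 training subjects and batch 8 this is a few
hundred optimizer steps; the full-scale defaults (lr 1e-3, 200 epochs)
are appropriate for the larger parcellations but would add nothing but
wall-clock at toy scale. A full nested-CV recovery run completes in
minutes on one CPU.

Other numerical details:

* probabilities are clamped at 1e-12 before the log in the loss (logged);
* the nearest-correlation repair tolerance is 1e-8, and a planted effect
  whose repair moves any entry by more than 0.01 is rejected with advice
  to shrink `effect_delta`;
* LayerNorm uses ε = 1e-5; attention uses per-head √d scaling;
* parameter init is symmetric uniform fan-in; max readout routes the
  subgradient through the argmax entries;
* all ranking operations (KNN neighbors, top-k ROIs) break ties toward
  the lower index for cross-platform determinism.

## Known limitations

* Temporal whiteness of the synthetic signal means empirical correlations
  have the textbook sampling variance; real BOLD autocorrelation would
  inflate it.
* The subgraph extractor recomputes structural embeddings from current
  node states at every layer; for `k_hops ≥ 2` on dense KNN graphs most
  k-hop neighborhoods cover the whole graph, so structure and plain
  attention converge — small `k_hops` with moderate K is where the
  structural bias matters.
* The LAFF scorer is a single shared affine map; richer gated scorers
  would change the atlas-weight semantics.
* Training on one CPU is practical for tens of ROIs; the 246-ROI
  full-scale configuration works but is slow (minutes per epoch).
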