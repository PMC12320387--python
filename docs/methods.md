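# Methods

## Problem and model

The package classifies emotional state from multichannel EEG by treating
the electrode array as a graph: each electrode is a node whose feature
vector is its differential entropy (DE) in a handful of frequency bands,
and the edges carry learned inter-channel weights. The classifier is a
graph attention network whose adjacency is *dynamic*: instead of relying
on a fixed, distance-derived electrode graph, a persistent buffer of edge
weights is pulled toward freshly computed attention scores during
training, so the connectivity structure itself is learned.

### Differential entropy features

EEG windows a few seconds long are well approximated as Gaussian, for
which differential entropy has the closed form

    DE = 1/2 log(2 pi e sigma^2)   [nats],

i.e. a log-variance feature. The pipeline: optional anti-aliased
polyphase resampling; zero-phase order-4 Butterworth band decomposition
(presets: the five-band delta/theta/alpha/beta/gamma split used with
62-channel caps, and the four-band theta/alpha/beta/gamma split used with
32-channel caps); then DE per non-overlapping 4-s Hann-tapered window,
channel, and band. Two estimators are available:

* `variance` (default): the closed form on the tapered window's
  time-domain variance, divided by the taper's mean square so stationary
  noise is estimated without bias;
* `psd`: the closed form on band power recovered by integrating the
  periodogram over the band.

Both agree for band-limited Gaussian signals (tested). The ML (ddof=0)
variance estimator is used, matching the Gaussian fit whose entropy the
closed form evaluates. Constant windows are floored at variance 1e-12 so
downstream training stays finite. A 62-channel recording over five bands
yields 310 features per window.

### Graph construction

Electrode coordinates come from the standard 10-20/10-10 template (the
two cerebellar leads of the 62-channel cap, absent from the template,
take the nearest standard inferior-occipital positions), centered and
projected to the unit sphere. Distances are 3-D chord distances —
monotone in geodesic distance, so threshold graphs are identical. The
initial adjacency is the Gaussian kernel

    w0_ij = exp(-dist(i,j)^2 / (2 theta^2))  for dist <= tau, else 0,

with theta defaulting to the mean inter-electrode distance and tau to
infinity (fully connected). The dynamic model is meant to supersede a
hand-chosen sparsity radius, so the default keeps every edge available;
both parameters are configurable for the static baseline.

### Attention layers

A static attention head projects node features through `W` (F'xF) and
scores ordered pairs with `e_ij = LeakyReLU(a^T [Wh_i || Wh_j])` (slope
0.2), row-softmaxes the scores over each node's neighborhood, and
aggregates `h'_i = ELU(sum_j alpha_ij W h_j)`; K heads are concatenated.
The dynamic layer keeps the buffer `w` (initialized at `w0`) and on each
training forward pass blends, per head,

    d = beta * w + (1 - beta) * e,      alpha = softmax_rows(d),

then absorbs the head- and batch-averaged scores into the buffer with the
same momentum rule, `w <- beta*w + (1-beta)*mean(e)`. The momentum
parameter defaults to beta = 0.5. Limits: beta = 0 is exactly the static
attention layer; beta = 1 with a frozen buffer is input-independent
attention with logits `w0` (the "static adjacency" ablation arm). The
buffer is shared across heads by default (heads share the structural
prior and differ in their feature projections; `per_head_adjacency`
switches to per-head buffers), is updated once per training forward pass,
is frozen during evaluation, and is not symmetrized (attention is
directed). Masked pairs receive a -1e9 additive sentinel before the
softmax so gradients stay finite.

Everything is implemented in NumPy with hand-derived analytic gradients
(verified against central finite differences to 1e-4 relative error in
the test suite); no deep-learning framework is used. Three notational
choices the source material leaves open were resolved as follows: the
softmax normalizes the *updated* (momentum-blended) weights, each head
blends its own scores with the shared buffer, and buffer updates happen
once per training forward pass.

### Classifier and training

Node outputs of the (by default single) attention layer are flattened and
passed through one fully connected ReLU layer (dimensionality reduction)
and a linear softmax classifier. The loss is mean cross-entropy plus
`l2_lambda * sum ||params||^2` (default 1e-4) optimized with Adam
(learning rate 1e-3, batch size 64). Features are z-scored per
(channel, band) with training-split statistics; the statistics travel
with the fitted results. Training runs up to 300 epochs with early
stopping after 30 epochs without a 1e-4 improvement in training loss —
with batch size 64 and the ~100-window training splits used here an
epoch is only about two gradient updates, so the large epoch count is
modest in wall-clock terms. All randomness (initialization, shuffling,
dropout) derives from a single seed; a full run is bit-reproducible.
Dropout on inputs and attention coefficients is available but defaults to
0: only L2 is used as regularization, and at these sample sizes dropout
measurably prevents convergence.

Depth defaults to one attention layer. Two stacked layers overfit the
desk-scale synthetic tasks (test accuracy drops from 1.0 to ~0.7 with no
training-accuracy gain); depth, widths, and head counts are per-layer
configurable.

## Evaluation protocols

* **Subject-dependent**: 5-fold cross-validation within each subject,
  with folds formed at *trial* granularity — every analysis window of a
  trial shares a fold — to keep near-duplicate windows from leaking
  between train and test. A window-level mode exists for comparison with
  pipelines that split windows independently. Reported: pooled accuracy,
  confusion counts, and mean +/- std of per-subject accuracies.
* **Subject-independent (LOSO)**: each subject held out in turn, the
  model trained on the pooled remainder.
* **Ablation**: dynamic model vs a static-adjacency arm (beta = 1,
  buffer frozen at the Gaussian-kernel initialization) with identical
  seeds, folds and hyperparameters.
* **Head sweep**: the subject-dependent protocol re-run per head count.

Accuracy is correct predictions over total; for every report
`accuracy = trace(confusion) / sum(confusion)` by construction.

## Synthetic data

The generator emulates the statistical skeleton of multi-subject emotion
datasets (several subjects, several trials per class, band-limited
multichannel signals) without attempting physiological realism — no 1/f
background, no artifacts. Class is encoded two ways, deliberately kept
distinct:

* **connectivity**: per class, channel-wise band-limited unit-variance
  Gaussian noise is mixed through `I + c * B_class`, where `B_class`
  joins two designated channel groups (class k couples groups k and k+1
  of four contiguous groups; coupling strength c = 0.6 by default);
* **band power**: per class, one designated (band, group) pair receives
  a 1.5x amplitude gain (band_effect = 0.5).

Per-subject log-normal per-channel gain jitter (sd 0.1) and white sensor
noise (sd 0.5, against unit-variance sources) are added. Filtered
Gaussian noise keeps every band consistent with the Gaussianity
assumption behind the closed-form DE. The seed fans out through
`SeedSequence` substreams per subject and trial, so generation is
reproducible and order-independent. Effect sizes were chosen so that the
planted band-power contrast is overwhelmingly detectable in single-window
DE features (two-sample t-test p << 1e-6 at default trial counts), which
is what makes the recovery benchmarks below meaningful.

Passing results on this generator demonstrate that the implementation
can exploit planted spectral and coupling structure under Gaussian
assumptions; they do not certify performance on real EEG, which is
nonstationary, artifact-laden, and has inter-subject variability far
beyond a scalar gain.

## Benchmarks computed by `scripts/acceptance.py`

On the 16-channel, 3-class, 10-subject, 20-trials-per-class synthetic
benchmark with default effect sizes: subject-dependent 5-fold accuracy
(dynamic and static-adjacency arms, matched seeds), LOSO accuracy, a
chance-level control with all class effects zeroed (expected to sit
within binomial bounds of 1/3), and the connectivity-recovery statistic
(Spearman correlation of class-conditional mean attention against the
planted coupling, with a 1000-shuffle permutation null).

## Known limitations

* **Attention-based connectivity recovery is sign-unstable.** The
  attention logits are additive in source and destination features
  (`e_ij = a_src.Wh_i + a_dst.Wh_j`), so the layer can express
  per-channel salience but not genuinely pairwise dependence; and because
  the classification task is solvable through the fully connected readout
  regardless of how attention is oriented, the polarity of the learned
  salience is an unidentified symmetry broken by initialization. On the
  synthetic benchmark the class-conditional attention does localize on
  the active channel groups, but whether it correlates positively or
  negatively with the planted coupling varies with the model seed (3 of
  10 seeds give all-classes-positive Spearman). The corresponding
  recovery test in the acceptance suite documents this honestly rather
  than selecting a favorable seed. Interpretation outputs should
  therefore be read as "which channels the model weights unusually",
  not as signed coupling estimates.
* Ocular-artifact removal (ICA) is out of scope; inputs are assumed
  pre-cleaned or synthetic.
* The momentum buffer converges toward the running mean of attention
  scores; with beta close to 0 it effectively tracks the last batch and
  training can become noisy.
* EDF support covers reading (and a minimal 16-bit writer for export);
  original distribution layouts of licensed datasets are not parsed —
  users convert externally.
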