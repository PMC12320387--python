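# dgat-eeg

Dynamic graph-attention networks for EEG emotion recognition.

EEG emotion classifiers increasingly treat the electrode array as a
graph: each electrode is a node carrying per-frequency-band features, and
a graph neural network aggregates information along inter-channel edges.
Most such models fix the edge structure up front from electrode geometry.
This package implements the *dynamic* alternative: the adjacency starts
from a Gaussian kernel of inter-electrode distance,

    w0_ij = exp(-dist(i,j)^2 / (2 theta^2)),   dist(i,j) <= tau,

but is then maintained as a trainable buffer that a momentum rule pulls
toward freshly computed attention scores on every training step,

    e_ij   = LeakyReLU(a^T [W h_i || W h_j])          (per head)
    w_ij  <- beta * w_ij + (1 - beta) * e_ij          (momentum, beta = 0.5)
    alpha  = softmax_rows(beta * w + (1 - beta) * e)
    h'_i   = ELU(sum_j alpha_ij W h_j),               K heads concatenated,

so the connectivity is learned jointly with the classifier. Node features
are differential entropies `DE = 1/2 log(2 pi e sigma^2)` per band and
4-s window. The package is aimed at researchers who want a tested,
framework-free (pure NumPy, analytic gradients) reference implementation
of this model family, complete with the field's evaluation protocols and
a synthetic benchmark with planted ground truth — the licensed emotion
datasets it mirrors are deliberately not required.

What's included:

- montage handling (62- and 32-channel 10-20 layouts, custom CSV,
  synthetic layouts), EDF and HDF5 recording/feature I/O;
- signal conditioning (polyphase resampling, zero-phase Butterworth
  band decomposition) and DE feature extraction (variance and
  PSD-integral estimators);
- static and dynamic graph-attention layers with hand-derived,
  finite-difference-verified gradients;
- the classifier with Adam training, subject-dependent 5-fold and
  leave-one-subject-out protocols, the static-adjacency ablation and
  attention-head sweep;
- a synthetic multi-subject generator with planted class-dependent
  coupling and band power;
- post-hoc interpretation: class-conditional connectivity and scalp
  attention topographies.

## Worked example

Simulate a small 2-subject, 3-class dataset, extract DE features, fit a
classifier on one subject, then run the subject-dependent protocol:

```python
from dgat import SyntheticConfig, generate_dataset, ModelConfig, DGATClassifier
from dgat.synthetic import de_features_for_dataset
from dgat.protocols import subject_dependent_cv

syn = SyntheticConfig(n_subjects=2, n_trials_per_class=10, n_classes=3,
                      montage="synth16", seed=42)
features = de_features_for_dataset(generate_dataset(syn))
print("windows x channels x bands:", features[0].values.shape)

results = DGATClassifier(features[0], ModelConfig(n_classes=3, seed=0)).fit()
print(results.summary())

report = subject_dependent_cv(features, ModelConfig(n_classes=3, seed=0), k=5)
print(report.summary())
```

Output:

```
windows x channels x bands: (60, 16, 4)
Dynamic graph attention classifier
===================================
nodes (channels):    16
node features:       4 bands (DE, nats)
layers:              1 (F'=(8,), heads=(3,))
classes:             3
adjacency momentum:  beta=0.5
optimizer:           Adam lr=0.001, batch=64, l2=0.0001
training:            300 epochs, final loss 0.0123, final accuracy 1.0000
accuracy: 1.0000 +/- 0.0000
confusion (rows = true):
      40      0      0
       0     40      0
       0      0     40
  s00: 1.0000
  s01: 1.0000
```

Each subject contributes 30 trials of 8 s at 128 Hz, i.e. 60 four-second
windows of 16-channel, 4-band DE features. `results.summary()` describes
the fitted model (one dynamic attention layer, 3 heads, momentum 0.5)
and its training trajectory; the cross-validation report shows pooled
confusion counts over held-out trials and per-subject accuracies — here
the planted class effects are strong enough that held-out trials are
classified perfectly. `results.adjacency()` returns the learned edge
buffer and `dgat.interpret.class_connectivity` the class-conditional
attention maps.

The same workflow is available from the shell:

```bash
dgat simulate --config sim.yaml --out raw/
dgat extract-features --input raw/ --output feats/ --bands deap4
dgat train --features feats/ --protocol subject-dependent
dgat ablate --features feats/
dgat sweep-heads --features feats/ --ks 1,2,3
```

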