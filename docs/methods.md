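# Methods

## Overview

`moldescpred` trains a reaction-yield regressor in three phases: (1) label
every molecule in a corpus with a low-dimensional summary of its 2D
molecular descriptors (PCA scores), (2) pre-train a graph isomorphism
network (GIN) encoder to predict those pseudo-labels, (3) initialize the
encoder of a yield-prediction model with the pre-trained weights and
fine-tune on reactions with measured yields. The premise is that a GNN
that can predict descriptor structure from the graph alone has already
learned chemistry-relevant representations, which transfer to the
data-poor yield task.

## Molecular graphs

Molecules are heavy-atom graphs; hydrogens appear only as an adjacent-H
count on their neighbour. Eleven atom properties and four bond properties
are encoded; categorical properties are one-hot with an overflow bucket,
the rest are binary flags. Each bond is stored as two directed edge rows
carrying identical features, so message aggregation is a plain segment sum
over incoming edges. The encoding is fixed by a JSON-serializable
`FeatureSchema`; featurizing a canonical SMILES twice is bit-identical,
and two SMILES of the same molecule give graphs equal up to node
permutation.

Vocabulary choices (the element list including catalytic metals Pd, Fe,
Sn, Cu, Zn and alkali counterions; ring-size flags 3–8; degree/valence/
H-count categories 0–6 with overflow) are design decisions targeting
Pd-catalyzed cross-coupling chemistry, where reactant sets include
ligands, bases and additives containing these elements. Donor/acceptor
flags use the simple lone-pair/attached-H rule for N and O rather than a
full pharmacophore perception; this is deliberate — the flag needs to be
deterministic and cheap, not exhaustive.

## Descriptor pipeline

Descriptors are RDKit's registered 2D descriptor set (210 descriptors in
the pinned RDKit version); no 3D geometry is used or assumed.
Non-computable or non-finite entries are marked missing, never zero.
Cleaning runs in a fixed order:

1. drop descriptors with **more than 10 missing values** (an absolute row
   count — the threshold is a parameter, since its natural value depends
   on corpus size);
2. drop descriptors whose finite values are all identical (exact
   equality);
3. exclude molecules with any residual missing entry;
4. standardize each column to mean 0, SD 1 (population SD, divide by n —
   the sample/population distinction is immaterial at corpus scale but
   must be fixed for bit-reproducibility).

The fitted `DescriptorFilterReport` (dropped names, means, SDs) replays
the exact transformation on held-out molecules; applying it never refits.

## PCA pseudo-labels

PCA is computed via SVD of the centered matrix (numerically stabler than
forming the covariance explicitly); eigenvalues are singular values
squared over n, i.e. eigenvalues of the population covariance. The test
suite verifies equivalence with a dense covariance eigendecomposition to
1e-8. Determinism choices:

- **Sign convention:** each component is flipped so its largest-magnitude
  loading is positive (PCA signs are otherwise arbitrary).
- **q selection:** smallest q whose cumulative explained variance reaches
  the target (default 0.70); an explicit `q_override` is accepted. The
  70% default follows the observation that performance is insensitive to
  the exact explained-variance level in this neighbourhood.
- **Clipping:** scores are clipped at ±10 × the empirical SD of the
  fitting-set scores on that dimension (the empirical SD is numerically
  ≈ √λ; we use the empirical value), then re-standardized with post-clip
  statistics computed on the fitting set and persisted.

## Encoder

A three-layer GIN with edge features, all widths as in the full-scale
recipe: node/edge embedders to 300 units (node ReLU, edge linear),
two-layer 300→300→300 node-update networks ψ⁽ˡ⁾ (ReLU hidden; ReLU output
except linear at the last layer), average-pooling readout, and a 1024-unit
PReLU projection. Edge embeddings are computed once and shared across
layers.

**The message form.** The layer update as usually printed sums
ReLU(h_center + h_edge), which would make messages independent of the
neighbours and propagate no information. The edge-featured GIN lineage
this architecture follows uses the *neighbour's* embedding in the message,
and that is the default here; the literal centre-node form is available
via `GINConfig(literal_messages=True)` for comparison. This is the one
genuinely consequential ambiguity in the architecture description, and the
neighbour reading is the only one under which the locality property
(features of a node more than L hops away cannot affect a node's
embedding, which the tests verify) is meaningful.

**Dropout placement** (needed for MC dropout): on each node-update hidden
layer and on the final representation, rate 0.1 by default. The placement
and rate are design decisions; nothing downstream depends on them beyond
dropout being present somewhere in the fine-tuned model.

**Initialization:** uniform fan-in scaling U(−1/√fan_in, 1/√fan_in) for
weights and biases, from a seeded generator; PReLU slope starts at 0.25.
No batch normalization.

All forward/backward computation runs on a small tape-based reverse-mode
autodiff over NumPy arrays written for this package (affine maps,
ReLU/PReLU, gather, segment sums, concatenation, elementwise arithmetic);
gradients are verified against central finite differences in the test
suite. The optimizer is Adam with coupled L2 weight decay.

## Pre-training

The encoder plus a one-layer head (1024 → q) minimize the
eigenvalue-weighted squared error (1/q) Σ_j λ_j (z_j − ẑ_j)², equivalent
to an unweighted MSE after scaling both vectors by √λ (a tested identity).
Eigenvalues enter raw; a normalized option (λ/Σλ) exists but is off by
default. Defaults: 10 epochs, batch 128, lr 5e-4, weight decay 1e-5, no
validation split, no early stopping, no gradient clipping or warmup.
Batches are reshuffled each epoch from the run seed; two runs with the
same seed produce bit-identical checkpoints. The auxiliary head is not
part of the transferable artifact.

## Yield model

Each molecule in a reaction is encoded with the shared GIN; reactant
representations are **sum-pooled** (the reactant list is a set — the tests
quantify permutation invariance at 1e-6), concatenated with the product
representation, and passed through a two-layer head (hidden width equal to
the representation width, PReLU, dropout) emitting (μ̂, log σ̂²). Variance
positivity comes from the log-parameterization. The head architecture
beyond these constraints is a documented stand-in: set-invariant pooling
is forced, depth/width are conventional choices.

The loss mixes homoscedastic and heteroscedastic terms with weight α.
α is not pinned by the upstream recipe; the default is **α = 0.1**, and
every loss test parameterizes over α. Yields are standardized on the
training split before loss computation (stabilizes log σ̂²) and inverted
for reporting; σ̂² is scaled back by the squared SD. A raw-percent mode
exists.

Fine-tuning: Adam, batch 128, weight decay 1e-5, 500 epochs with lr 5e-4
dropping to 5e-5 at epoch 400 and 5e-6 at epoch 450. A non-finite batch
loss aborts with the epoch and batch index.

**MC dropout:** T = 30 stochastic passes; the point prediction is the
arithmetic mean of per-pass means, which are retained for inspection. The
reported variance is the mean per-pass σ̂² — an extension beyond the
mean-averaging procedure, flagged as such in the docstring.

## Synthetic data

The generator stands in for both the large pre-training corpus and the HTE
benchmark datasets, so everything is testable offline. Molecules come from
a fragment grammar (aromatic and aliphatic cores, alkyl chains, halides,
amines, ethers, nitriles, boronic-acid-like groups); every emitted SMILES
passes the same sanitization gate as real input. Reactions sample m
reactants (default 2–4; configurable up to the benchmark range) and a
product; the yield is

    g = 100 · sigmoid(0.35·(n_P−10)/5 + 1.2·arom_P − 1.5·het_R − 0.8·het_P
                      + 0.15·(n_R−8)/4)

with n the heavy-atom count, arom the aromatic-atom fraction, het the
heteroatom fraction (P product, R reactant mean), plus Gaussian noise
(default SD 3 yield points) clamped to [0, 100]. With the heteroscedastic
flag the noise SD scales with mean participant size, exercising the
variance head. Because g's inputs are themselves standard descriptors,
descriptor pseudo-labels provably carry signal for the synthetic task —
that is the point of the construction.

What the generator does **not** emulate: real reaction-yield chemistry
(catalysis, inhibition, additive effects), the combinatorial plate
structure of HTE datasets, heavy-tailed yield distributions near 0/100, or
molecules beyond ~24 heavy atoms. Passing transfer tests on synthetic data
therefore demonstrate that the machinery works and that the method's
mechanism (descriptor-informative pre-training helps a small-data
regressor) operates as designed — not that benchmark-level accuracy is
reproduced.

## Problem sizes for the shipped experiments

The architecture defaults are the full-scale widths (300/1024), exercised
by the unit tests. The integration and transfer experiments use a
width-reduced encoder (hidden 64, representation 128 via
`experiments.small_gin_config`) and reduced epochs (pre-train 10–15,
fine-tune 15–60), chosen so a complete pre-train → fine-tune → evaluate
comparison over 5 seeds runs in about a minute on one CPU. The transfer
experiment compares pre-trained against from-scratch initialization at 100
training reactions with identical budgets; only the encoder initialization
differs. The comparison is directional (mean over seeds) and the effect
size (mean RMSE decrease / SD of per-seed differences) is reported rather
than a significance claim.

## Known limitations

- The descriptor engine is RDKit's 2D set (210 descriptors). Corpus-scale
  descriptor sets from other engines are larger; the filtering, PCA and
  loss machinery is engine-agnostic, but absolute descriptor counts and
  retained-column counts depend on the engine.
- Training is single-threaded NumPy: correct and reproducible, but not
  suited to corpora beyond ~10⁴ molecules at full widths.
- Out-of-sample benchmark splits require the published split files; the
  package consumes them as plain index lists but does not ship them.
- Operating conditions (temperature, concentrations) are not modelled;
  the benchmark datasets do not report them.
- MC-dropout variance aggregation across passes is a pragmatic extension;
  calibration of σ̂² is not analysed.
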