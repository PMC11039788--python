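# Methods

This note documents the modelling choices behind `braingat`: what each stage
computes, the defaults and why, the numerical conventions that pin down
reproducibility, and what the synthetic benchmark does and does not show.

## Node features

Each ROI's BOLD signal (length T ≥ 64) is decomposed with a 6-level discrete
wavelet transform using the Daubechies-1 (Haar) basis, giving seven
coefficient arrays ordered `[cA6, cD6, cD5, cD4, cD3, cD2, cD1]`. The node
feature vector is

```
[ raw_mean, raw_var,
  mean(cA6), mean(cD6), ..., mean(cD1),
  var(cA6),  var(cD6),  ..., var(cD1) ]        (16 features)
```

Conventions that matter for reproducibility:

- **Variance divisor is N** (population variance), for both the raw signal
  and every coefficient array.
- **Boundary handling** for T not divisible by 2⁶ is symmetric (half-sample)
  extension, the common multilevel default. At power-of-two lengths the
  transform is exactly orthonormal: total energy is conserved across the
  coefficient arrays (tested to 1e−8).
- **Sign convention** is fixed by the orthonormal Haar analysis filters:
  level-1 details of `[1..8]` are −1/√2, pinned by a regression test.
- The minimum length 64 = 2⁶ is enforced with an explicit error; a shorter
  signal cannot support a 6-level dyadic decomposition.
- Feature ordering within the 16-vector is a package convention (the model
  learns weights per column, so any fixed order is equivalent); it is
  exported as `FEATURE_NAMES`.

No per-feature standardisation is applied at this stage; normalisation is a
training-time concern handled by the head's batch norm.

## Connectivity and graph assembly

Per-subject FC is the Pearson correlation of ROI time courses (zero-variance
columns are rejected with the offending ROI index; values are clipped to
[−1, 1] against rounding). Class-wise averages are computed element-wise,
and thresholding zeroes entries strictly below the threshold — the boundary
value is kept, and negative correlations are always removed (signed rule,
not absolute value). The default threshold is 0.4. Thresholding is
idempotent, and raising the threshold can only shrink the edge set.

**Adjacency sharing.** Averaging FC per class leaves open which average a
given subject's graph should use; giving each subject its own class's
average would inject the label into test-time inputs. The default is
therefore the element-wise mean of the two class averages, computed from
training subjects only and shared by all graphs; `adjacency_mode="group"`
(CLI `--group-adjacency`) reproduces the literal two-matrix variant for
comparison. Cross-validation always rebuilds the adjacency inside each fold
from that fold's training subjects.

**Edges.** The surviving entry pattern defines an undirected edge set shared
by every subject; self-loops are added after thresholding (default on) so
every node's attention neighbourhood is non-empty and isolated nodes still
propagate their own features. The GAT layer consumes only the edge *set*;
surviving correlation values are stored for inspection but carry no weight
in attention, whose score function has no edge-weight term.

ROI indices are 0-based internally; reports are 1-based to match the
numbering conventions of published parcellation tables.

## The classifier

Two GAT + pooling blocks followed by a dense head:

- **Attention** (per head k): score(i ← j) = a_kᵀ [W_k h_i ∥ W_k h_j],
  exponentiated and normalised over j ∈ N(i). By default no leaky rectifier
  is applied to the score (a `leaky_attention` flag restores the common
  convention). Coefficients are averaged over the 4 heads.
- **Aggregation**: h_i′ = ReLU(Σ_j α_ij W h_j) with a single shared W per
  layer — the heads parameterise only the attention. The conventional
  `concat` and `average` multi-head variants are available through
  `multihead_output` for comparison.
- **Pooling score.** A normalised attention row always sums to 1, so ranking
  nodes by their own row is degenerate. Node i is instead scored by the total
  attention mass on directed pairs incident to it — its row (constant 1)
  plus the attention it receives from neighbours; each self-loop is one pair,
  counted once. Under uniform attention this reduces to degree centrality
  (a star's hub outscores its leaves), and a connected node always outscores
  an isolated one. The all-node total is exposed only as a normalisation
  diagnostic. Pooling keeps ⌈ratio·N⌉ nodes (minimum 1; ratio 0.2), breaking
  ties by ascending index, and induces the subgraph on the survivors with
  original indices carried through for reporting.
- **Readout**: Z = GMP(H) ∥ GAP(H) (per-feature max and mean over nodes),
  taken from each block's *pooled* node set (a `readout_prepool` flag flips
  to the pre-pooling output). Both GAT widths are 32, so Z₁ and Z₂ have
  length 64 and the multi-scale sum Z₃ = Z₁ + Z₂ is well-defined; this is
  asserted at run time.
- **Head**: BatchNorm(64) → Linear(64→32) → ReLU → Dropout(0.5) →
  Linear(32→1) → sigmoid. A minimal two-layer head consistent with batch
  normalisation and dropout placed before the final sigmoid unit.

Defaults: d_in 16, hidden width 32 per GAT layer, 4 heads, pool ratio 0.2,
dropout 0.5.

## Training and evaluation

Binary cross-entropy on the sigmoid output (computed stably from logits),
minimised by Adam at learning rate 1e−3. L2 regularisation is applied as
optimizer weight decay **scoped to the GAT-layer parameters only** (W_k,
a_k, W); the head is not decayed. Presets: single-site (30 epochs, decay
1e−4, 5 folds) and multi-site (100 epochs, decay 1e−3, 10 folds).

Batch size defaults to 16. With epochs in the tens, full-batch training
would perform only as many optimizer steps as epochs, far too few for Adam
at this learning rate to move a freshly initialised network; minibatching
restores a useful step count while keeping batch-norm statistics stable.
Batches with fewer than two graphs are skipped for the same reason.

Folds are stratified (small cohorts need both classes in every fold) and
seeded; per-fold training seeds derive from the CV seed via
`SeedSequence`. The decision threshold on the sigmoid output is 0.5.
Aggregate metrics are computed from confusion counts pooled across folds
(per-fold metrics and their mean are also reported): pooling is what makes
single reported ratios such as 20/27 well-defined. A metric whose
denominator is zero is reported as NaN and flagged, never silently zeroed.

Everything is float64 numpy, single-threaded and counter-seeded, so a given
seed reproduces cohorts, fold splits, parameters and metrics bit for bit.

**ROI importance** counts, over every test-subject evaluation in every fold,
which original ROI indices the *first* pooling layer retained (pool 1 sees
all N ROIs; pool 2 sees a remapped subset, so its selections are mapped back
through pool 1's indices but not tallied). The report ranks ROIs by
selection frequency, ties by ascending index, 1-based.

## The synthetic cohort generator

The generator emulates the *shape* of a multi-site pediatric resting-state
cohort and plants a controllable group difference:

- every ROI starts as i.i.d. Gaussian noise (sd `noise_sd`, default 0.5);
- in group 1 only, the planted ROIs share λ × a latent AR(1) signal
  (lag-1 coefficient 0.3, unit marginal variance — the mild temporal
  autocorrelation keeps the wavelet levels from being uniformly white) plus
  a sinusoid of amplitude a and fixed period (default 32 samples) with a
  random per-subject phase.

With unit-variance latent, the planted-pair population correlation is
(λ² + a²/2)/(λ² + a²/2 + σ²). The defaults — λ = 0.9, a = 1.0, σ = 0.5 —
put it near 0.84, so after averaging with the null class the shared
adjacency retains the planted clique at the 0.4 threshold: the defaults are
chosen so that *both* discriminative channels the pipeline consumes (edge
structure and band-specific node features) actually carry signal. A noise
floor of σ = 1 at the same effect sizes would push the averaged planted
entries (≈ 0.28) below threshold and silently reduce the benchmark to a
feature-only problem. The oscillation period of 32 concentrates energy in a
single detail band, making feature discriminability level-specific and
testable.

Per-subject random substreams are spawned from the cohort seed by
(group, index), so generation is order-independent and bit-reproducible.
Cohorts carry rotating site tags to mirror multi-site structure, but no site
batch effects are simulated.

**What passing the benchmark shows — and what it does not.** The canonical
benchmark (100 subjects, 200 ROIs, T = 128, five planted ROIs) verifies that
the pipeline can learn a planted joint correlation/spectral difference to
high accuracy, stays at chance on the matched null, and that the pooling
layer's selections recover the planted ROIs. It does not show performance on
real BOLD data: the generator has no hemodynamic response, scanner physics,
motion artefacts, site batch effects or spatial autocorrelation, and real
group differences are far subtler than the planted ones.

## Implementation note on the autodiff engine

No deep-learning framework is a dependency; the model's forward and backward
passes run on a package-internal reverse-mode tape over numpy arrays
(`braingat.autodiff`) providing exactly the primitives the model needs
(dense ops, gather/segment-sum message passing, axis reductions, stable
BCE-with-logits, Adam). Gradients of every primitive and of the full model
are verified against central finite differences in the test suite.

## Known limitations

- The attention mechanism ignores surviving edge weights; only the edge set
  matters. This is faithful to the score function used but discards
  information a weighted variant could exploit.
- Pooling ties (common when many nodes are isolated with only self-loops)
  are resolved by ascending index — deterministic but arbitrary; importance
  frequencies of tied isolated nodes reflect that convention, not evidence.
- Batch-norm statistics make single-graph training batches ill-defined;
  such batches are skipped.
- The per-site threshold for single-site analyses is not separately
  configurable beyond the global `threshold` parameter; only the multi-site
  value 0.4 has a published precedent.
- `cross_validate` consumes per-subject features and FC matrices rather than
  prebuilt graphs, because leakage-free evaluation requires rebuilding the
  adjacency inside each fold.
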