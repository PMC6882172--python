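# Methods

## Problem

Given a dimer — a receptor chain and a ligand chain — the task is to rank
all cross-chain residue pairs by their probability of being *interface*
pairs (pairs whose mutual contact area in the complex is nonzero).
Because a dimer with chains of length ~300 has ~10^5 candidate pairs of
which only a few hundred are interface pairs, the problem is treated as a
ranking problem: the headline metric is the rank of the first positive
prediction (RFPP), normalized by the total pair count (the *accuracy
order*, reported in per-mille).

## Model

### Peephole LSTM layer

Each layer is a standard peephole LSTM with one memory cell per hidden
unit and full connectivity.  Per timestep *t* (vectors over cells, `⊙`
elementwise):

    a_ι = W_xι x_t + W_hι b_{t-1} + w_cι ⊙ s_{t-1}        (input gate)
    a_φ = W_xφ x_t + W_hφ b_{t-1} + w_cφ ⊙ s_{t-1}        (forget gate)
    a_c = W_xc x_t + W_hc b_{t-1}                          (cell input)
    s_t = f(a_φ) ⊙ s_{t-1} + f(a_ι) ⊙ g(a_c)              (state)
    a_ω = W_xω x_t + W_hω b_{t-1} + w_cω ⊙ s_t             (output gate)
    b_t = f(a_ω) ⊙ h(s_t)                                  (cell output)

with `f` logistic and `g = h = tanh` by default (configurable).  Biases
are supported but default to zero, so the defaults compute the bias-free
textbook equations literally.

**Output-gate peephole convention.**  The output gate peeks at the
*current* state `s_t` (Graves convention).  A published variant of these
equations lets it peek at `s_{t-1}`, but the corresponding backward
equations (the `w_cω δ_ω^t` term in the state error) are only consistent
with the current-state dependence, so current-state is the default here;
`output_gate_peeks_current_state=False` switches both passes to the
previous-state variant consistently (the backward then carries
`w_cω δ_ω^{t+1}` instead).

### Backward pass

All gradients are derived by hand (no autodiff anywhere).  Running
t = T..1 with all t+1 quantities zero beyond T:

    ε_c^t = upstream_t + Σ_gates W_h·ᵀ δ_·^{t+1}                    (cell-output error)
    δ_ω^t = ε_c^t ⊙ h(s_t) ⊙ f'(a_ω^t)
    ε_s^t = ε_c^t ⊙ b_ω^t ⊙ h'(s_t) + b_φ^{t+1} ⊙ ε_s^{t+1}
            + w_cι ⊙ δ_ι^{t+1} + w_cφ ⊙ δ_φ^{t+1} + w_cω ⊙ δ_ω^t
    δ_c^t = ε_s^t ⊙ b_ι^t ⊙ g'(a_c^t)
    δ_φ^t = ε_s^t ⊙ s_{t-1} ⊙ f'(a_φ^t)
    δ_ι^t = ε_s^t ⊙ g(a_c^t) ⊙ f'(a_ι^t)

Weight gradients accumulate `δ · (presynaptic activation)` over t.  The
plain-RNN backward is the standard BPTT form
`δ_h^t = θ'(a_h^t)(Σ_k δ_k^t w_hk + Σ_{h'} w_hh' δ_{h'}^{t+1})`.

### Residual big block

Two stacked LSTM layers with a shortcut that adds the lower layer's cell
outputs into the upper layer's: `out_t = (b_t)^l + (b_t)^{l+2}`.  During
backpropagation the error at the sum reaches the lower layer with the
factor `1 + ∂(b^{l+2})/∂(b^l)`; if the through-layer Jacobian vanishes
(the deep-stack failure mode), the lower layer still receives the full
upstream error.  This is what permits stacks of 30+ layers: measured on
identically parameterized 30-layer stacks (U(−0.1, 0.1) init, 10 seeds),
the median first-layer gradient norm is ~10^44 times larger with the
shortcut than without.

A network of `m` layers is arranged as `m // 2` big blocks; an odd final
layer stands alone without a shortcut.  Widths must match across a block
(no projection shortcut).

### Attention, head, loss

The source work motivates attention as weight reallocation over the
sequence but gives no equations; the formulation here is additive
self-attention after the last block: `e_t = v · tanh(A h_t)`, weights
`w = softmax(e)`, outputs rescaled as `y_t = T · w_t · h_t` so that a
uniform weighting is the identity and per-position outputs are preserved
for per-pair classification.  A dense layer (units → 2) with a
shift-invariant softmax gives per-pair class probabilities; the loss is
categorical cross-entropy `H(p, q) = −Σ p log q` (natural log, estimate
floored at 1e-12 inside the log).

### Dropout

Inverted dropout, so evaluation mode applies no rescaling: rate 0.15 on
the input features, 0.6 on every non-recurrent layer-to-layer feed.
Recurrent connections and the residual shortcut are never masked.  Both
rates follow the source configuration and are configurable.

### Training

The source work does not state its optimizer; the default here is Adam
(lr 0.01, β = 0.9/0.999) with plain SGD available, one dimer = one
sequence = one update, seeded shuffling per epoch, optional global-norm
gradient clipping (off by default).  Two additional choices the source is
silent on:

* **Feature standardization.**  The 9 physicochemical features span very
  different magnitudes (areas of tens of Å², ratios in [0,1], pKa units);
  raw values saturate the gates under small-scale weight initialization.
  `train_model` therefore fits a per-feature z-score scaler on the
  training set and stores it with the parameters (applied automatically
  at inference; disable with `standardize=False`).
* **Class weighting.**  Interface pairs are a few percent of even the
  reduced pair lists, so the cross-entropy is weighted by inverse class
  frequency by default (`class_weight="balanced"`); the unweighted loss
  is available with `class_weight=None`.

The checkpoint with the best validation mean accuracy order is retained
alongside the final parameters.

## Pair pipeline

* **Pairing**: all |receptor| × |ligand| cross-chain pairs; the 18-feature
  vector is receptor features (slots 1–9) then ligand features (10–18);
  distance is the Euclidean distance of the representative atoms (the
  loader accepts whatever coordinate the table provides; Cα recommended).
* **Labelling**: label 1 iff the pair's contact area is strictly
  positive; pairs absent from the contact table are negatives.
* **Negative reduction**: the k smallest-distance pairs are anchors;
  "3 residues around" an anchor is read as a length-3 window centred on
  the anchor residue in each chain (truncated, not wrapped, at termini),
  giving up to 3×3 = 9 pairs per anchor, de-duplicated.  The anchor
  count is a parameter; the default is twice the number of labelled
  positives — interface pairs are the closest pairs, so this retains
  every positive plus a comparable negative neighborhood.  Order:
  anchors by ascending distance, row-major within an anchor — the
  sequential structure the recurrent model consumes.
* **Split**: seeded dimer-level 6:2:2 split with largest-remainder
  apportionment (54 dimers → 32/11/11).
* Residues with any missing feature value are dropped on load (with a
  warning), so their pairs never exist — mirroring how incomplete source
  data is handled upstream.

## Evaluation metrics

* `rank_pairs`: stable descending sort (ties keep original pair order —
  the source is silent on ties); RFPP is the 1-based rank of the first
  true positive; a dimer with no positive gets the sentinel TNRP + 1 and
  an explicit flag.
* `accuracy_order = 1000 · RFPP / TNRP` per-mille, rounded to 3 decimals
  for reporting.
* `ncpd(values, m)`: count of dimers with accuracy order ≤ m per-mille.
* `rfpp_percentile`: ascending sort, 1-based index round-half-down(p·n)
  clamped to [1, n].  This convention was calibrated once against the
  published quantile row of the reference model (it reproduces all five
  printed entries 4/31/33/113/194 from the published per-dimer RFPPs)
  and is documented as such.

## Random baseline

Draw 1000 distinct pairs uniformly from N candidates of which M are
interface pairs; X is the position of the first interface pair, with 1000
assigned when none is drawn.  The first-success law for ordered sampling
without replacement is

    P(X = i) = [Π_{j=0}^{i-2} (N−M−j)/(N−j)] · M/(N−i+1)

computed in log space (no underflow up to N ~ 10^6).  A published pmf for
this experiment contains a combinatorial slip in its hypergeometric-style
numerator; the ordered-draw law above is the distribution that the
experiment's own Monte-Carlo procedure realizes, and is what this package
implements.  The truncated expectation is computed two independent ways
(pmf-weighted sum and survival-function sum) that agree to 1e-9 and serve
as mutual checks; the Monte-Carlo estimator simulates the sequential
draws directly (success probability M/(N−j+1) at draw j given no earlier
success), vectorized over replicates.  10^6 replicates give a standard
error of ~0.3 on expectations of ~400, sufficient for integer-level
agreement; larger replicate counts buy nothing at that precision.

## Synthetic data

The generator emulates the *relational* structure of the real inputs, not
their physics: a contiguous interface patch per chain placed inside a
contact ball (all cross-patch distances < d_contact = 8 Å, every other
cross-chain distance ≥ ~15 Å by construction), contact areas positive for
exactly the within-threshold pairs (so the generator and the labeller
agree by definition), and Gaussian class-conditional features whose
baseline means/SDs are loosely modelled on real surface-residue values,
with interface residues shifted by `effect_size` pooled SDs (default 2.0
— strongly but not trivially separable; 0 makes the classes statistically
identical, verified by a label-permutation test).  Default geometry:
chains of 20/25 residues, 3×3 patch → 9 positives among 500 candidate
pairs (1.8% positive rate, echoing the real imbalance at desk scale).

What passing on this generator does and does not show: it validates the
pipeline's mechanics, the optimization, and that the model can exploit a
feature signal of the stated effect size under the stated imbalance; it
says nothing about real dimers, where feature-class separation is far
weaker, geometry is not two well-separated blobs, and labels are noisy.

## Numerical verification

Gradient checks use central differences with ε = 1e-5 in double
precision.  The comparison statistic is the global L2 norm ratio
`||a − n|| / max(||a||, ||n||)` over the concatenated gradient — the
standard gradient-check statistic.  A per-array variant exists as a
stricter diagnostic but is only meaningful when every array's gradient is
large enough for central differences not to be roundoff-limited: with
small-scale initialization, deep-layer recurrent weights can have true
gradients ~1e-12 whose finite differences are pure floating-point noise.
The oracle refuses non-deterministic losses (dropout must be off).

## Problem sizes

Tests and the acceptance script run at desk scale as the package's own
default experiment sizes: networks of ≤ 6 layers and ≤ 8 units for
gradient checks (20+ seeded configurations), 30-layer stacks for the
gradient-flow comparison (10 seeds), 10^6 Monte-Carlo replicates for the
baseline, and 9 synthetic dimers / 60 epochs for the recovery run.  The
60-layer, 8-unit configuration of the reference model is constructible
through the same API but is not exercised in the test suite.

## Known limitations

* No GPU path and no autodiff; everything is numpy at double precision.
* No projection shortcut: residual blocks require equal widths.
* The attention equations and the optimizer are this package's own
  choices where the source work is silent (documented above).
* The feature computation itself (contact areas, solvent accessibility,
  hydropathy, pKa) is out of scope; features arrive precomputed in the
  documented table schema.
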