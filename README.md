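# ppilstm

Protein–protein interface residue-pair prediction with an
attention-enhanced residual LSTM — implemented from scratch, including the
hand-derived backpropagation-through-time equations.

## What this is for

Predicting which cross-chain residue pairs of a dimer form the
binding interface is a needle-in-a-haystack ranking problem: a complex
with ~300-residue chains has ~10⁵ candidate pairs, of which a few hundred
are interface pairs.  This package provides, for researchers working on
that problem (or on deep recurrent architectures generally):

* **`ppilstm.recurrent`** — peephole LSTM forward/backward passes written
  out by hand in numpy (no autodiff), plus the *residual big block*: two
  stacked LSTM layers with a shortcut summing the lower layer's cell
  outputs `(b_c^t)^l` into the upper layer's `(b_c^t)^{l+2}`.  The
  backward pass realizes the factor `1 + ∂(b^{l+2})/∂(b^l)`, so the error
  signal survives even when the through-layer Jacobian vanishes — the
  failure mode that normally caps LSTM stacks at a few layers.
* **`ppilstm.network`** — stacked big blocks with additive self-attention
  (`e_t = v·tanh(A h_t)`, softmax over the sequence), dropout (0.15 on
  inputs, 0.6 on non-recurrent feeds), a per-pair softmax head with
  cross-entropy loss, Adam/SGD training and a coarse-then-neighborhood
  grid search over depth and width.
* **`ppilstm.pairs`** — the residue-pair pipeline: cross-chain pairing of
  per-residue feature tables (9 physicochemical/geometric features per
  residue → 18 per pair), contact-area interface labelling, distance-based
  negative reduction (anchor pairs + 3×3 windows), and seeded 6:2:2
  dimer splits.
* **`ppilstm.metrics`** — rank-based evaluation: RFPP (rank of the first
  positive prediction), accuracy order (RFPP/TNRP, per-mille), NCPD, RFPP
  quantiles, and sweep summary tables.
* **`ppilstm.baseline`** — the random-rank null model: exact pmf and
  truncated expectation of the first interface pair among 1000 random
  draws, plus a vectorized Monte-Carlo estimator.
* **`ppilstm.synth`** — synthetic dimers with the same relational
  structure (contact geometry, positive contact areas, class-conditional
  features, extreme label imbalance), so the whole stack runs with no
  external data.
* **`ppilstm.gradcheck`** — the central finite-difference oracle every
  backward pass is verified against.

## Worked example

`examples/synthetic_training.py` runs the whole pipeline end to end:

```text
9 dimers, split 5/2/2; per dimer: L = 50 reduced pairs of TNRP = 500 candidates, 9 positives
training: loss 0.692 -> 0.034 over 60 epochs

held-out dimers:
  SYN0000: RFPP = 1, accuracy order = 2.0 per-mille, balanced accuracy = 1.000
  SYN0001: RFPP = 1, accuracy order = 2.0 per-mille, balanced accuracy = 1.000
mean balanced accuracy: 1.000
```

RFPP = 1 means the model's top-ranked pair is a true interface pair;
accuracy order 2.0‰ says that first hit sits within the top 0.2% of the
dimer's 500 candidate pairs.  The other examples are equally short:
`gradient_check.py` (analytic vs numerical gradients, error ~1e-10),
`residual_gradient_flow.py` (first-layer gradient norms of 30-layer
stacks: the shortcut preserves ~10⁴⁴× more signal than the plain stack),
`random_baseline.py` (closed form 412.74 vs Monte Carlo 412.4 ± 0.3 for
N = 321,630, M = 687), and `ranking_metrics.py` (sweep means, NCPD and
RFPP quantiles recomputed from published per-dimer results).

There is also a thin CLI:

```bash
ppilstm simulate --n-dimers 9 --seed 0 --out runs/sim
ppilstm prepare  --data runs/sim --out runs/prep
ppilstm train    --data runs/prep --layers 4 --units 8 --epochs 60 --out runs/model
ppilstm evaluate --data runs/prep --model runs/model/checkpoint.npz --out runs/report
ppilstm baseline --N 321630 --M 687 --exact
ppilstm gradcheck --layers 4 --units 2
```

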