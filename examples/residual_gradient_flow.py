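"""Why the residual big block exists: gradient survival in deep stacks.

Builds 30-layer LSTM stacks with small-scale initialization and measures
the norm of the loss gradient at the first layer, with the layer-pair
shortcut active (residual big blocks) and without it (plain stack), using
identical parameters.  The plain stack's gradient collapses by tens of
orders of magnitude; the shortcut keeps a usable signal, which is what
makes 30-block-deep training possible at all.
"""

import numpy as np

import ppilstm as pl

cmp = pl.gradient_flow_comparison(depth=30, units=4, T=10, input_size=4,
                                  scale=0.1, n_seeds=10, seed=0)

print("first-layer gradient norm, 30-layer stacks, 10 seeds")
print(f"  residual big blocks (median): {cmp.median_residual:.3e}")
print(f"  plain stack         (median): {cmp.median_plain:.3e}")
print(f"  median ratio residual/plain:  {cmp.median_ratio:.3e}")
print("(a ratio >> 1 means the shortcut preserves gradient signal that the"
      " plain stack loses to vanishing)")
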