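"""Verify the hand-derived backward passes against finite differences.

Builds a small residual attention network on random data, computes every
weight gradient analytically, and compares against the central-difference
oracle.  The printed number is the global relative error
||analytic - numeric|| / max(norms): values around 1e-8 or below mean the
two independent derivative computations agree to numerical precision.
"""

import numpy as np

import ppilstm as pl

rng = np.random.default_rng(0)
config = pl.NetworkConfig(layers=4, units=3, input_size=6,
                          dropout_in=0.0, dropout_mid=0.0,
                          init_scale=0.5, seed=0)
params = pl.init_network(config)
X = rng.uniform(-1, 1, size=(8, config.input_size))
y = rng.integers(0, 2, size=8)


def loss():
    return pl.sequence_loss(pl.model_forward(params, X), y)[0]


probs, cache = pl.model_forward(params, X, return_cache=True)
_, dlogits = pl.sequence_loss(probs, y)
analytic = pl.model_backward(params, cache, dlogits)
numeric = pl.numerical_gradient_oracle(loss, params.named_arrays())
err = pl.max_relative_error(analytic, numeric)

print(f"network: {config.layers} LSTM layers as residual big blocks, "
      f"{config.units} units, attention + softmax head")
print(f"parameters checked: {sum(a.size for a in params.named_arrays().values())}")
print(f"max relative error vs central finite differences: {err:.2e}")
print("(<= 1e-6 means the analytic BPTT equations are correct)")
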