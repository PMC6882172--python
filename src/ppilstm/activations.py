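"""Named elementwise activations with derivatives.

Derivatives are expressed as functions of the *preactivation*, which is what
the hand-derived backward passes cache.  Gate activations must map into
(0, 1); the registry records that so parameter containers can validate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class Activation:
    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]  # derivative at preactivation a
    gate_like: bool = False  # True if range is (0, 1)

    def __call__(self, a: np.ndarray) -> np.ndarray:
        return self.fn(a)


def _logistic_deriv(a):
    s = expit(a)
    return s * (1.0 - s)


def _tanh_deriv(a):
    return 1.0 - np.tanh(a) ** 2


LOGISTIC = Activation("logistic", expit, _logistic_deriv, gate_like=True)
TANH = Activation("tanh", np.tanh, _tanh_deriv)
IDENTITY = Activation("identity", lambda a: a, lambda a: np.ones_like(a))

REGISTRY: dict[str, Activation] = {
    act.name: act for act in (LOGISTIC, TANH, IDENTITY)
}


def get_activation(name_or_act: "str | Activation") -> Activation:
    if isinstance(name_or_act, Activation):
        return name_or_act
    try:
        return REGISTRY[name_or_act]
    except KeyError:
        raise KeyError(
            f"unknown activation {name_or_act!r}; known: {sorted(REGISTRY)}"
        ) from None
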