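"""Central finite-difference gradient oracle.

Used only for verification: an independent numerical estimate of every
weight gradient, compared against the hand-derived backward passes.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .exceptions import ValidationError

__all__ = ["numerical_gradient_oracle", "max_relative_error"]


def numerical_gradient_oracle(loss_fn: Callable[[], float],
                              arrays: Mapping[str, np.ndarray],
                              eps: float = 1e-5) -> dict[str, np.ndarray]:
    """Estimate dL/dw for every entry of every array by central differences.

    ``loss_fn`` takes no arguments and must close over ``arrays``; each
    weight is perturbed in place to +/- eps and restored, so the estimate is
    (L(w+eps) - L(w-eps)) / (2 eps) per weight.  ``loss_fn`` must be
    deterministic (stochastic regularizers such as dropout must be disabled);
    this is checked by evaluating it twice up front.
    """
    if not (1e-7 <= eps <= 1e-3):
        raise ValidationError(f"eps={eps} outside the supported range [1e-7, 1e-3]")
    l1, l2 = float(loss_fn()), float(loss_fn())
    if l1 != l2:
        raise ValidationError(
            "loss_fn is not deterministic (two evaluations differ); "
            "disable dropout or other stochastic components before gradient checking")
    out: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        grad = np.empty_like(arr, dtype=float)
        flat = arr.reshape(-1)
        gflat = grad.reshape(-1)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            lp = float(loss_fn())
            flat[k] = orig - eps
            lm = float(loss_fn())
            flat[k] = orig
            gflat[k] = (lp - lm) / (2.0 * eps)
        out[name] = grad
    return out


def max_relative_error(analytic: Mapping[str, np.ndarray],
                       numeric: Mapping[str, np.ndarray],
                       aggregate: str = "global",
                       zero_tol: float = 1e-10) -> float:
    """Relative disagreement between two gradient sets.

    With ``aggregate='global'`` (the standard gradient-check statistic) the
    whole gradient is treated as one vector and the error is
    ``||a - n|| / max(||a||, ||n||)``.  With ``aggregate='per_array'`` the
    same L2-norm ratio is computed per parameter array and the maximum is
    returned — a stricter diagnostic that is only meaningful when every
    array's gradient is large enough for central differences not to be
    roundoff-limited.  Gradients whose both norms fall below ``zero_tol``
    count as exact agreement.
    """
    if set(analytic) != set(numeric):
        raise ValidationError("gradient sets cover different parameter arrays")
    for name in analytic:
        if np.shape(analytic[name]) != np.shape(numeric[name]):
            raise ValidationError(f"shape mismatch for {name}")
    if aggregate == "global":
        a = np.concatenate([np.ravel(analytic[k]) for k in sorted(analytic)])
        n = np.concatenate([np.ravel(numeric[k]) for k in sorted(numeric)])
        denom = max(np.linalg.norm(a), np.linalg.norm(n))
        return 0.0 if denom < zero_tol else float(np.linalg.norm(a - n) / denom)
    if aggregate != "per_array":
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    worst = 0.0
    for name in analytic:
        a = np.asarray(analytic[name], dtype=float)
        n = np.asarray(numeric[name], dtype=float)
        denom = max(np.linalg.norm(a), np.linalg.norm(n))
        if denom < zero_tol:
            continue
        worst = max(worst, np.linalg.norm(a - n) / denom)
    return worst
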