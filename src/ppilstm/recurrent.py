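"""Hand-derived recurrent layers: plain RNN, peephole LSTM, residual big block.

Everything here is explicit numpy — the forward recursions and the
backpropagation-through-time (BPTT) equations are written out by hand and
verified in the test suite against a central finite-difference oracle.  No
automatic differentiation is used anywhere in the package.

Conventions
-----------
* Sequences are ``(T, width)`` arrays; timestep 0 is the first element.
* One memory cell per hidden unit (full connection), so the cell count ``C``
  equals the hidden width.
* The peephole from the cell state into the *output* gate reads the current
  state ``s_c^t`` (the Graves convention).  Setting
  ``output_gate_peeks_current_state=False`` on a layer switches both passes
  to the previous state ``s_c^{t-1}`` consistently.
* Biases exist but default to zero, so with the defaults the layer computes
  the textbook bias-free peephole equations literally.

The "big block" is the residual unit: two stacked LSTM layers with a
shortcut that adds the lower layer's cell outputs ``(b_c^t)^l`` into the
upper layer's cell outputs ``(b_c^t)^{l+2}``.  During backpropagation the
error at the residual sum reaches the lower layer through both the shortcut
and the through-layer path, i.e. with the factor
``1 + d(b_c^t)^{l+2} / d(b_c^t)^l``; even when the through-path Jacobian
vanishes the lower layer still receives the full upstream error, which is
what lets gradients survive deep stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .activations import Activation, IDENTITY, LOGISTIC, TANH, get_activation
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "RnnLayerParams",
    "RnnTrace",
    "RnnBackwardResult",
    "rnn_forward",
    "rnn_backward",
    "LstmLayerParams",
    "LstmForwardTrace",
    "LstmBackwardResult",
    "lstm_layer_forward",
    "lstm_layer_backward",
    "BigBlockParams",
    "BigBlockTrace",
    "BigBlockBackwardResult",
    "big_block_forward",
    "big_block_backward",
    "init_lstm_layer",
    "init_rnn_layer",
    "stack_forward",
    "stack_backward",
    "StackTrace",
]


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


def _as_sequence(x, width: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"{what} must be a (T, {width}) matrix, got shape {x.shape}")
    if x.shape[0] < 1:
        raise ValidationError(f"{what} must have T >= 1 timesteps")
    if x.shape[1] != width:
        raise ValidationError(
            f"{what} width {x.shape[1]} does not match expected width {width}"
        )
    _check_finite(what, x)
    return x


# ---------------------------------------------------------------------------
# Plain recurrent layer
# ---------------------------------------------------------------------------

@dataclass
class RnnLayerParams:
    """One standard recurrent layer with a linear readout.

    ``w_xh`` maps inputs to hidden preactivations (I x H), ``w_hh`` is the
    recurrent matrix (H x H) applied to the previous hidden output, and
    ``w_hk`` the readout (H x K).  Hidden activation defaults to tanh.
    """

    w_xh: np.ndarray
    w_hh: np.ndarray
    w_hk: np.ndarray
    activation: Activation = TANH

    def __post_init__(self):
        self.w_xh = np.asarray(self.w_xh, dtype=float)
        self.w_hh = np.asarray(self.w_hh, dtype=float)
        self.w_hk = np.asarray(self.w_hk, dtype=float)
        self.activation = get_activation(self.activation)
        I, H = self.w_xh.shape
        if self.w_hh.shape != (H, H):
            raise ConfigurationError(
                f"recurrent matrix shape {self.w_hh.shape} inconsistent with H={H}"
            )
        if self.w_hk.shape[0] != H:
            raise ConfigurationError(
                f"readout shape {self.w_hk.shape} inconsistent with H={H}"
            )
        for name in ("w_xh", "w_hh", "w_hk"):
            _check_finite(name, getattr(self, name))

    @property
    def input_size(self) -> int:
        return self.w_xh.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w_xh.shape[1]

    @property
    def output_size(self) -> int:
        return self.w_hk.shape[1]

    def named_arrays(self) -> dict[str, np.ndarray]:
        return {"w_xh": self.w_xh, "w_hh": self.w_hh, "w_hk": self.w_hk}


@dataclass
class RnnTrace:
    inputs: np.ndarray      # (T, I)
    a_h: np.ndarray         # (T, H) hidden preactivations
    b_h: np.ndarray         # (T, H) hidden outputs
    a_k: np.ndarray         # (T, K) output-layer preactivations


def rnn_forward(params: RnnLayerParams, inputs) -> RnnTrace:
    """Unroll the recurrence a_h^t = W_xh x^t + W_hh b^{t-1}, b^t = theta(a^t),
    a_k^t = W_hk b^t, with b^0 = 0."""
    X = _as_sequence(inputs, params.input_size, "inputs")
    T, H = X.shape[0], params.hidden_size
    a_h = np.empty((T, H))
    b_h = np.empty((T, H))
    prev_b = np.zeros(H)
    for t in range(T):
        a_h[t] = X[t] @ params.w_xh + prev_b @ params.w_hh
        b_h[t] = params.activation(a_h[t])
        prev_b = b_h[t]
    a_k = b_h @ params.w_hk
    return RnnTrace(inputs=X, a_h=a_h, b_h=b_h, a_k=a_k)


@dataclass
class RnnBackwardResult:
    gradients: dict[str, np.ndarray]
    hidden_deltas: np.ndarray   # (T, H) dL/da_h
    input_deltas: np.ndarray    # (T, I) dL/dx


def rnn_backward(trace: RnnTrace, output_deltas, params: RnnLayerParams) -> RnnBackwardResult:
    """BPTT for the plain layer.

    ``output_deltas`` holds dL/da_k per timestep.  The hidden delta combines
    the readout path and the next-timestep recurrent path,
    delta_h^t = theta'(a_h^t) (W_hk delta_k^t + W_hh delta_h^{t+1}),
    with deltas beyond T treated as zero; weight gradients accumulate
    delta times the presynaptic activation over t.
    """
    T, H = trace.b_h.shape
    if trace.inputs.shape[1] != params.input_size or H != params.hidden_size:
        raise ValidationError("trace does not match the supplied parameters")
    D = _as_sequence(output_deltas, params.output_size, "output_deltas")
    if D.shape[0] != T:
        raise ValidationError("output_deltas length does not match the trace")

    g = {name: np.zeros_like(arr) for name, arr in params.named_arrays().items()}
    hidden_deltas = np.empty((T, H))
    input_deltas = np.empty_like(trace.inputs)
    next_delta = np.zeros(H)
    for t in range(T - 1, -1, -1):
        upstream = D[t] @ params.w_hk.T + next_delta @ params.w_hh.T
        delta_h = params.activation.deriv(trace.a_h[t]) * upstream
        hidden_deltas[t] = delta_h
        prev_b = trace.b_h[t - 1] if t > 0 else np.zeros(H)
        g["w_hk"] += np.outer(trace.b_h[t], D[t])
        g["w_xh"] += np.outer(trace.inputs[t], delta_h)
        g["w_hh"] += np.outer(prev_b, delta_h)
        input_deltas[t] = delta_h @ params.w_xh.T
        next_delta = delta_h
    return RnnBackwardResult(gradients=g, hidden_deltas=hidden_deltas,
                             input_deltas=input_deltas)


# ---------------------------------------------------------------------------
# Peephole LSTM layer
# ---------------------------------------------------------------------------

_GATES = ("i", "f", "o")


@dataclass
class LstmLayerParams:
    """All weights of one peephole LSTM layer.

    Per gate (input ``i``, forget ``f``, output ``o``): an input matrix
    ``w_x*`` (I x C), a recurrent matrix ``w_h*`` (C x C) applied to the
    previous cell outputs, and a peephole vector ``w_c*`` (length C, one
    scalar per cell) reading the cell state.  The cell input has ``w_xc``
    and ``w_hc`` only.  Gate activation ``gate_act`` must map into (0, 1).
    """

    w_xi: np.ndarray
    w_hi: np.ndarray
    w_ci: np.ndarray
    w_xf: np.ndarray
    w_hf: np.ndarray
    w_cf: np.ndarray
    w_xc: np.ndarray
    w_hc: np.ndarray
    w_xo: np.ndarray
    w_ho: np.ndarray
    w_co: np.ndarray
    b_i: Optional[np.ndarray] = None
    b_f: Optional[np.ndarray] = None
    b_c: Optional[np.ndarray] = None
    b_o: Optional[np.ndarray] = None
    gate_act: Activation = LOGISTIC
    cell_in_act: Activation = TANH
    cell_out_act: Activation = TANH
    output_gate_peeks_current_state: bool = True

    def __post_init__(self):
        for name in ("w_xi", "w_hi", "w_ci", "w_xf", "w_hf", "w_cf",
                     "w_xc", "w_hc", "w_xo", "w_ho", "w_co"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.gate_act = get_activation(self.gate_act)
        self.cell_in_act = get_activation(self.cell_in_act)
        self.cell_out_act = get_activation(self.cell_out_act)
        if not self.gate_act.gate_like:
            raise ConfigurationError(
                f"gate activation {self.gate_act.name!r} does not map into (0, 1)"
            )
        I, C = self.w_xi.shape
        for name in ("w_xf", "w_xc", "w_xo"):
            if getattr(self, name).shape != (I, C):
                raise ConfigurationError(f"{name} shape inconsistent with (I={I}, C={C})")
        for name in ("w_hi", "w_hf", "w_hc", "w_ho"):
            if getattr(self, name).shape != (C, C):
                raise ConfigurationError(f"{name} must be ({C}, {C})")
        for name in ("w_ci", "w_cf", "w_co"):
            if getattr(self, name).shape != (C,):
                raise ConfigurationError(f"peephole {name} must have length C={C}")
        for bname in ("b_i", "b_f", "b_c", "b_o"):
            b = getattr(self, bname)
            b = np.zeros(C) if b is None else np.asarray(b, dtype=float)
            if b.shape != (C,):
                raise ConfigurationError(f"bias {bname} must have length C={C}")
            setattr(self, bname, b)
        for name, arr in self.named_arrays().items():
            _check_finite(name, arr)

    @property
    def input_size(self) -> int:
        return self.w_xi.shape[0]

    @property
    def cell_count(self) -> int:
        return self.w_xi.shape[1]

    def named_arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in (
            "w_xi", "w_hi", "w_ci", "w_xf", "w_hf", "w_cf",
            "w_xc", "w_hc", "w_xo", "w_ho", "w_co",
            "b_i", "b_f", "b_c", "b_o")}


@dataclass
class LstmForwardTrace:
    """Per-timestep activations cached for the backward pass.

    All sequence arrays are (T, C); ``s0``/``b0`` hold the initial state and
    initial cell outputs (zeros by default).  The stored states satisfy the
    recursion s^t = b_f^t * s^{t-1} + b_i^t * g(a_c^t) exactly.
    """

    inputs: np.ndarray
    a_i: np.ndarray
    a_f: np.ndarray
    a_c: np.ndarray
    a_o: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    s: np.ndarray
    b: np.ndarray
    s0: np.ndarray
    b0: np.ndarray

    @property
    def T(self) -> int:
        return self.inputs.shape[0]

    def prev_s(self, t: int) -> np.ndarray:
        return self.s[t - 1] if t > 0 else self.s0

    def prev_b(self, t: int) -> np.ndarray:
        return self.b[t - 1] if t > 0 else self.b0


def lstm_layer_forward(params: LstmLayerParams, inputs,
                       initial_state: Optional[tuple[np.ndarray, np.ndarray]] = None
                       ) -> LstmForwardTrace:
    """Forward pass of one peephole LSTM layer.

    Gate preactivations read the layer input, the previous cell outputs and
    (via the peepholes) the cell state: the input and forget gates peek at
    s^{t-1}; the output gate peeks at the current s^t unless the layer is
    configured for the previous-state variant.
    """
    X = _as_sequence(inputs, params.input_size, "inputs")
    T, C = X.shape[0], params.cell_count
    if initial_state is None:
        s0, b0 = np.zeros(C), np.zeros(C)
    else:
        s0 = np.asarray(initial_state[0], dtype=float)
        b0 = np.asarray(initial_state[1], dtype=float)
        if s0.shape != (C,) or b0.shape != (C,):
            raise ValidationError(f"initial state must be two length-{C} vectors")
        _check_finite("initial_state", np.concatenate([s0, b0]))

    f, g, h = params.gate_act, params.cell_in_act, params.cell_out_act
    out = {k: np.empty((T, C)) for k in
           ("a_i", "a_f", "a_c", "a_o", "b_i", "b_f", "b_o", "s", "b")}
    prev_s, prev_b = s0, b0
    for t in range(T):
        a_i = X[t] @ params.w_xi + prev_b @ params.w_hi + params.w_ci * prev_s + params.b_i
        a_f = X[t] @ params.w_xf + prev_b @ params.w_hf + params.w_cf * prev_s + params.b_f
        b_i = f(a_i)
        b_f = f(a_f)
        a_c = X[t] @ params.w_xc + prev_b @ params.w_hc + params.b_c
        s = b_f * prev_s + b_i * g(a_c)
        s_peek = s if params.output_gate_peeks_current_state else prev_s
        a_o = X[t] @ params.w_xo + prev_b @ params.w_ho + params.w_co * s_peek + params.b_o
        b_o = f(a_o)
        b = b_o * h(s)
        for k, v in (("a_i", a_i), ("a_f", a_f), ("a_c", a_c), ("a_o", a_o),
                     ("b_i", b_i), ("b_f", b_f), ("b_o", b_o), ("s", s), ("b", b)):
            out[k][t] = v
        prev_s, prev_b = s, b
    return LstmForwardTrace(inputs=X, s0=s0, b0=b0, **out)


@dataclass
class LstmBackwardResult:
    """Gradients plus the intermediate error signals of one BPTT sweep.

    ``gradients`` has one entry per weight array of the owning layer;
    ``input_deltas`` is dL/dx for stacking.  The per-timestep deltas
    (``d_i``, ``d_f``, ``d_o`` = dL/da_gate, ``d_c`` = dL/da_c) and errors
    (``eps_c`` = dL/db, ``eps_s`` = dL/ds) are retained for inspection.
    """

    gradients: dict[str, np.ndarray]
    input_deltas: np.ndarray
    eps_c: np.ndarray
    eps_s: np.ndarray
    d_i: np.ndarray
    d_f: np.ndarray
    d_o: np.ndarray
    d_c: np.ndarray


def lstm_layer_backward(trace: LstmForwardTrace, upstream_cell_output_errors,
                        params: LstmLayerParams) -> LstmBackwardResult:
    """BPTT through one peephole LSTM layer.

    ``upstream_cell_output_errors`` is the caller-supplied dL/db_c^t (from
    the layer above, a residual sum, attention or the loss head); the
    recurrent contributions through the next timestep's gates are added
    internally.  Per timestep, running t = T..1:

    * cell-output error: eps_c^t = upstream^t + sum over next-step gate and
      cell deltas routed back through the recurrent matrices;
    * output gate: d_o^t = eps_c^t * h(s^t) * f'(a_o^t);
    * state error: eps_s^t = b_o^t h'(s^t) eps_c^t + b_f^{t+1} eps_s^{t+1}
      + w_ci d_i^{t+1} + w_cf d_f^{t+1} + w_co d_o^t
      (the final peephole term uses d_o^{t+1} instead when the output gate
      peeks at the previous state);
    * cell: d_c^t = eps_s^t b_i^t g'(a_c^t); forget: d_f^t = eps_s^t s^{t-1}
      f'(a_f^t); input: d_i^t = eps_s^t g(a_c^t) f'(a_i^t).

    Weight gradients accumulate delta times presynaptic activation over t.
    """
    T, C = trace.s.shape
    if C != params.cell_count or trace.inputs.shape[1] != params.input_size:
        raise ValidationError("trace does not match the supplied parameters")
    U = _as_sequence(upstream_cell_output_errors, C, "upstream errors")
    if U.shape[0] != T:
        raise ValidationError(
            f"upstream errors have T={U.shape[0]} but the trace has T={T}")

    f, g, h = params.gate_act, params.cell_in_act, params.cell_out_act
    grads = {name: np.zeros_like(arr) for name, arr in params.named_arrays().items()}
    res = {k: np.empty((T, C)) for k in ("eps_c", "eps_s", "d_i", "d_f", "d_o", "d_c")}
    input_deltas = np.empty_like(trace.inputs)

    nd_i = nd_f = nd_c = nd_o = np.zeros(C)   # next-timestep deltas
    n_eps_s = np.zeros(C)
    n_b_f = np.zeros(C)
    for t in range(T - 1, -1, -1):
        eps_c = (U[t]
                 + nd_i @ params.w_hi.T + nd_f @ params.w_hf.T
                 + nd_c @ params.w_hc.T + nd_o @ params.w_ho.T)
        d_o = eps_c * h(trace.s[t]) * f.deriv(trace.a_o[t])
        eps_s = (eps_c * trace.b_o[t] * h.deriv(trace.s[t])
                 + n_b_f * n_eps_s
                 + params.w_ci * nd_i + params.w_cf * nd_f)
        if params.output_gate_peeks_current_state:
            eps_s = eps_s + params.w_co * d_o
        else:
            eps_s = eps_s + params.w_co * nd_o
        d_c = eps_s * trace.b_i[t] * g.deriv(trace.a_c[t])
        d_f = eps_s * trace.prev_s(t) * f.deriv(trace.a_f[t])
        d_i = eps_s * g(trace.a_c[t]) * f.deriv(trace.a_i[t])

        x, pb, ps = trace.inputs[t], trace.prev_b(t), trace.prev_s(t)
        grads["w_xi"] += np.outer(x, d_i)
        grads["w_hi"] += np.outer(pb, d_i)
        grads["w_ci"] += ps * d_i
        grads["w_xf"] += np.outer(x, d_f)
        grads["w_hf"] += np.outer(pb, d_f)
        grads["w_cf"] += ps * d_f
        grads["w_xc"] += np.outer(x, d_c)
        grads["w_hc"] += np.outer(pb, d_c)
        grads["w_xo"] += np.outer(x, d_o)
        grads["w_ho"] += np.outer(pb, d_o)
        grads["w_co"] += (trace.s[t] if params.output_gate_peeks_current_state else ps) * d_o
        grads["b_i"] += d_i
        grads["b_f"] += d_f
        grads["b_c"] += d_c
        grads["b_o"] += d_o
        input_deltas[t] = (d_i @ params.w_xi.T + d_f @ params.w_xf.T
                           + d_c @ params.w_xc.T + d_o @ params.w_xo.T)

        for k, v in (("eps_c", eps_c), ("eps_s", eps_s), ("d_i", d_i),
                     ("d_f", d_f), ("d_o", d_o), ("d_c", d_c)):
            res[k][t] = v
        nd_i, nd_f, nd_c, nd_o = d_i, d_f, d_c, d_o
        n_eps_s = eps_s
        n_b_f = trace.b_f[t]
    return LstmBackwardResult(gradients=grads, input_deltas=input_deltas, **res)


# ---------------------------------------------------------------------------
# Residual big block
# ---------------------------------------------------------------------------

@dataclass
class BigBlockParams:
    """Two stacked LSTM layers with a shortcut summing the lower layer's
    outputs into the upper layer's outputs.  The shortcut requires matching
    widths; there is no projection variant."""

    lower: LstmLayerParams
    upper: LstmLayerParams
    residual: bool = True

    def __post_init__(self):
        if self.lower.cell_count != self.upper.cell_count:
            raise ConfigurationError(
                "residual sum requires equal unit counts: "
                f"lower C={self.lower.cell_count}, upper C={self.upper.cell_count}")
        if self.upper.input_size != self.lower.cell_count:
            raise ConfigurationError(
                "upper layer input width must equal lower layer unit count")

    def named_arrays(self) -> dict[str, np.ndarray]:
        out = {f"lower.{k}": v for k, v in self.lower.named_arrays().items()}
        out.update({f"upper.{k}": v for k, v in self.upper.named_arrays().items()})
        return out


@dataclass
class BigBlockTrace:
    lower: LstmForwardTrace
    upper: LstmForwardTrace
    inner_mask: Optional[np.ndarray]     # dropout mask on the lower->upper feed
    residual_output: np.ndarray          # (T, C)


def big_block_forward(block: BigBlockParams, inputs,
                      inner_mask: Optional[np.ndarray] = None) -> BigBlockTrace:
    """Run both layers and form the residual sum (b_c^t)^l + (b_c^t)^{l+2}.

    ``inner_mask``, if given, multiplies the lower layer's outputs on the
    non-recurrent feed into the upper layer only — the shortcut itself is
    never masked.
    """
    lower_trace = lstm_layer_forward(block.lower, inputs)
    feed = lower_trace.b if inner_mask is None else lower_trace.b * inner_mask
    upper_trace = lstm_layer_forward(block.upper, feed)
    out = upper_trace.b + lower_trace.b if block.residual else upper_trace.b.copy()
    return BigBlockTrace(lower=lower_trace, upper=upper_trace,
                         inner_mask=inner_mask, residual_output=out)


@dataclass
class BigBlockBackwardResult:
    lower: LstmBackwardResult
    upper: LstmBackwardResult
    input_deltas: np.ndarray

    def named_gradients(self) -> dict[str, np.ndarray]:
        out = {f"lower.{k}": v for k, v in self.lower.gradients.items()}
        out.update({f"upper.{k}": v for k, v in self.upper.gradients.items()})
        return out


def big_block_backward(block: BigBlockParams, trace: BigBlockTrace,
                       upstream_errors) -> BigBlockBackwardResult:
    """Backpropagate through the residual sum.

    The upstream error reaches the lower layer along the shortcut (factor 1)
    and through the upper layer (its input deltas), realizing the factor
    1 + d(b^{l+2})/d(b^l); with a zero through-path Jacobian the lower layer
    still receives the upstream error unchanged.
    """
    U = _as_sequence(upstream_errors, block.upper.cell_count, "upstream errors")
    upper_res = lstm_layer_backward(trace.upper, U, block.upper)
    through = upper_res.input_deltas
    if trace.inner_mask is not None:
        through = through * trace.inner_mask
    lower_upstream = through + U if block.residual else through
    lower_res = lstm_layer_backward(trace.lower, lower_upstream, block.lower)
    return BigBlockBackwardResult(lower=lower_res, upper=upper_res,
                                  input_deltas=lower_res.input_deltas)


# ---------------------------------------------------------------------------
# Stacks of layers (paired into big blocks, or plain)
# ---------------------------------------------------------------------------

@dataclass
class StackTrace:
    items: list          # per block: BigBlockTrace or ("layer", LstmForwardTrace)
    output: np.ndarray   # (T, C) final sequence


def _pair_layers(layers: Sequence[LstmLayerParams], residual: bool):
    """Pair consecutive layers into big blocks; an odd final layer stands
    alone without a shortcut."""
    blocks = []
    n = len(layers)
    for i in range(0, n - 1, 2):
        blocks.append(BigBlockParams(lower=layers[i], upper=layers[i + 1],
                                     residual=residual))
    if n % 2 == 1:
        blocks.append(layers[-1])
    return blocks


def stack_forward(layers: Sequence[LstmLayerParams], inputs, residual: bool = True,
                  masks: Optional[Sequence[Optional[np.ndarray]]] = None) -> StackTrace:
    """Run a stack of LSTM layers, pairing them into residual big blocks
    when ``residual`` is set.  ``masks[i]`` (optional) multiplies the input
    of layer ``i`` — used for non-recurrent dropout; recurrent connections
    are never masked.
    """
    if len(layers) == 0:
        raise ConfigurationError("empty layer stack")
    if masks is not None and len(masks) != len(layers):
        raise ConfigurationError("need one (possibly None) mask per layer")
    x = np.asarray(inputs, dtype=float)
    items = []
    li = 0
    for blk in _pair_layers(layers, residual):
        m_in = masks[li] if masks is not None else None
        feed = x if m_in is None else x * m_in
        if isinstance(blk, BigBlockParams):
            inner = masks[li + 1] if masks is not None else None
            tr = big_block_forward(blk, feed, inner_mask=inner)
            x = tr.residual_output
            li += 2
        else:
            tr = ("layer", lstm_layer_forward(blk, feed))
            x = tr[1].b
            li += 1
        items.append(tr)
    return StackTrace(items=items, output=x)


def stack_backward(layers: Sequence[LstmLayerParams], trace: StackTrace,
                   upstream_errors, residual: bool = True,
                   masks: Optional[Sequence[Optional[np.ndarray]]] = None
                   ) -> tuple[list[dict[str, np.ndarray]], np.ndarray]:
    """Backward through a stack, returning per-layer gradient dicts (in layer
    order) and the deltas with respect to the stack input."""
    blocks = _pair_layers(layers, residual)
    per_layer: list[dict[str, np.ndarray]] = [None] * len(layers)
    U = np.asarray(upstream_errors, dtype=float)
    li = len(layers)
    for blk, tr in zip(reversed(blocks), reversed(trace.items)):
        if isinstance(blk, BigBlockParams):
            res = big_block_backward(blk, tr, U)
            li -= 2
            per_layer[li] = res.lower.gradients
            per_layer[li + 1] = res.upper.gradients
            d_in = res.input_deltas
        else:
            res = lstm_layer_backward(tr[1], U, blk)
            li -= 1
            per_layer[li] = res.gradients
            d_in = res.input_deltas
        if masks is not None and masks[li] is not None:
            d_in = d_in * masks[li]
        U = d_in
    return per_layer, U


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_rnn_layer(input_size: int, hidden_size: int, output_size: int,
                   rng: np.random.Generator, scale: float = 0.1,
                   activation: "str | Activation" = TANH) -> RnnLayerParams:
    """Uniform U(-scale, scale) initialization of a plain recurrent layer."""
    u = lambda *shape: rng.uniform(-scale, scale, size=shape)
    return RnnLayerParams(w_xh=u(input_size, hidden_size),
                          w_hh=u(hidden_size, hidden_size),
                          w_hk=u(hidden_size, output_size),
                          activation=get_activation(activation))


def init_lstm_layer(input_size: int, cells: int, rng: np.random.Generator,
                    scale: float = 0.1, **kwargs) -> LstmLayerParams:
    """Uniform U(-scale, scale) initialization of a peephole LSTM layer.
    Biases start at zero so the printed bias-free equations hold literally."""
    u = lambda *shape: rng.uniform(-scale, scale, size=shape)
    return LstmLayerParams(
        w_xi=u(input_size, cells), w_hi=u(cells, cells), w_ci=u(cells),
        w_xf=u(input_size, cells), w_hf=u(cells, cells), w_cf=u(cells),
        w_xc=u(input_size, cells), w_hc=u(cells, cells),
        w_xo=u(input_size, cells), w_ho=u(cells, cells), w_co=u(cells),
        **kwargs)
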