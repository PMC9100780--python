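"""Active-dendrites network core: neurons, layers, gating, kWTA, parameter accounting.

An *active dendrites neuron* extends the point neuron with a set of dendritic
segments that process a context vector ``c`` alongside the feedforward input
``x``.  The neuron computes

    t_hat = w.T x + b                      (feedforward drive)
    d     = response of the winning segment to c
    y_hat = t_hat * sigmoid(d)             (sigmoidal gating)

Under *max* gating the winning segment maximises ``u_j.T c``; under
*absolute-max* gating (the default) it maximises ``|u_j.T c|`` and the sign is
kept, so a strongly negative segment can actively silence its neuron.  Layers
of such neurons are followed by a k-winner-take-all (kWTA) non-linearity that
keeps the top-k activations of each sample and zeroes the rest, producing
sparse, context-dependent activity patterns.  Feedforward weights carry a fixed
binary sparsity mask chosen at initialisation.

The module is pure NumPy, including the backward pass.  The backward pass
enforces the locality rules that make the architecture resistant to
interference: neurons silenced by kWTA receive exactly zero gradient, and on
each winning neuron only the winning dendritic segment is updated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "NetworkSpec",
    "DendriticLayerParams",
    "ForwardTrace",
    "dendritic_response",
    "gate",
    "kwta",
    "make_sparsity_mask",
    "init_params",
    "forward",
    "backward",
    "count_nonzero_params",
    "save_params",
    "load_params",
    "AdamState",
    "adam_step",
    "softmax_cross_entropy",
]

GATING_MODES = ("absolute_max", "max")


def _round(x: float) -> int:
    """Round half to even, returning a Python int (NumPy's rint convention)."""
    return int(np.rint(x))


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description from which parameter counts are exactly derivable.

    Parameters
    ----------
    input_dim, hidden_dims, output_dim
        Layer sizes.  The output layer is always a plain affine map (single
        head shared across tasks): no gating, no kWTA.
    context_dim
        Dimensionality of the context vector fed to dendritic segments
        (input dimension for prototype contexts, number of tasks for one-hot).
        May be 0 only when no layer is modulated.
    weight_sparsity
        Fraction in [0, 1) of feedforward weights fixed at exactly zero by a
        mask chosen at initialisation.  Biases are never masked.
    activation_density
        Fraction in (0, 1] of units kept by kWTA; ``k = max(1,
        round(density * layer_size))``.
    num_segments
        Dendritic segments per modulated neuron.
    segment_dim
        Weights per segment; must equal ``context_dim``.
    modulated_layers
        Hidden-layer indices whose neurons carry dendritic segments.
        ``None`` means all hidden layers when ``num_segments > 0`` else none.
    gating_mode
        ``"absolute_max"`` (default) or ``"max"``.
    kwta_layers
        Hidden-layer indices with kWTA.  ``None`` means all hidden layers.
        Hidden layers without kWTA use ReLU unless modulated (modulated
        layers without kWTA pass the gated value through unchanged).
    """

    input_dim: int
    hidden_dims: tuple[int, ...]
    output_dim: int
    context_dim: int = 0
    weight_sparsity: float = 0.0
    activation_density: float = 1.0
    num_segments: int = 0
    segment_dim: int | None = None
    modulated_layers: tuple[int, ...] | None = None
    gating_mode: str = "absolute_max"
    kwta_layers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(int(h) for h in self.hidden_dims))
        n_hidden = len(self.hidden_dims)
        if self.modulated_layers is None:
            mod = tuple(range(n_hidden)) if self.num_segments > 0 else ()
        else:
            mod = tuple(sorted(int(i) for i in self.modulated_layers))
        object.__setattr__(self, "modulated_layers", mod)
        if self.kwta_layers is None:
            object.__setattr__(self, "kwta_layers", tuple(range(n_hidden)))
        else:
            object.__setattr__(
                self, "kwta_layers", tuple(sorted(int(i) for i in self.kwta_layers))
            )
        if self.segment_dim is None:
            object.__setattr__(self, "segment_dim", self.context_dim)
        self.validate()

    def validate(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ConfigurationError("input_dim and output_dim must be positive")
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ConfigurationError("hidden_dims must be positive integers")
        if not 0.0 <= self.weight_sparsity < 1.0:
            raise ConfigurationError("weight_sparsity must lie in [0, 1)")
        if not 0.0 < self.activation_density <= 1.0:
            raise ConfigurationError("activation_density must lie in (0, 1]")
        if self.gating_mode not in GATING_MODES:
            raise ConfigurationError(f"gating_mode must be one of {GATING_MODES}")
        n_hidden = len(self.hidden_dims)
        for idx in self.modulated_layers:
            if not 0 <= idx < n_hidden:
                raise ConfigurationError(f"modulated layer index {idx} out of range")
        for idx in self.kwta_layers:
            if not 0 <= idx < n_hidden:
                raise ConfigurationError(f"kWTA layer index {idx} out of range")
        if self.modulated_layers:
            if self.num_segments < 1:
                raise ConfigurationError(
                    "modulated neurons require at least one dendritic segment"
                )
            if self.context_dim < 1:
                raise ConfigurationError("modulated layers require context_dim >= 1")
            if self.segment_dim != self.context_dim:
                raise ConfigurationError(
                    f"segment_dim ({self.segment_dim}) must equal "
                    f"context_dim ({self.context_dim})"
                )
        for idx in self.kwta_layers:
            if self.activation_density * self.hidden_dims[idx] < 1.0:
                raise ConfigurationError(
                    f"kWTA layer {idx}: activation_density * layer_size < 1"
                )

    @property
    def layer_shapes(self) -> list[tuple[int, int]]:
        """(out, in) shape of every weight matrix, hidden layers then output."""
        dims = (self.input_dim, *self.hidden_dims, self.output_dim)
        return [(dims[i + 1], dims[i]) for i in range(len(dims) - 1)]

    def kwta_k(self, layer: int) -> int:
        return max(1, _round(self.activation_density * self.hidden_dims[layer]))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        for key in ("hidden_dims", "modulated_layers", "kwta_layers"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DendriticLayerParams:
    """Parameters of one layer: feedforward weights, bias, mask, dendritic tensor.

    ``W`` is (out, in) and satisfies ``W * (1 - M) == 0`` at all times; the
    binary mask ``M`` is fixed for the life of the layer.  ``U`` is
    (out, num_segments, context_dim) with no bias terms, or ``None`` for
    unmodulated layers (including the output layer).
    """

    W: np.ndarray
    b: np.ndarray
    M: np.ndarray
    U: np.ndarray | None = None

    def apply_mask(self) -> None:
        self.W *= self.M


@dataclass
class ForwardTrace:
    """Per-layer record of one forward pass (also the backward-pass cache)."""

    t_hat: np.ndarray                 # pre-gating activation, (N, out)
    d: np.ndarray | None              # selected dendritic activation, (N, out)
    j_star: np.ndarray | None         # winning segment index, (N, out) int
    y_hat: np.ndarray                 # layer output after gating/activation/kWTA
    k: int | None                     # kWTA winner count, None if no kWTA
    winners: np.ndarray | None        # bool (N, out), True where kept by kWTA
    x_in: np.ndarray = field(repr=False, default=None)  # layer input (cache)
    context: np.ndarray = field(repr=False, default=None)  # context batch (cache)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def dendritic_response(
    U: np.ndarray, c: np.ndarray, mode: str = "absolute_max"
) -> tuple[float, int]:
    """Dendritic activation of a single neuron for context ``c``.

    Returns ``(d, j_star)``.  Under ``"max"`` gating ``d = max_j u_j.c``;
    under ``"absolute_max"`` the response with the largest magnitude is
    selected and its sign kept.  Ties resolve to the lowest segment index.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] == 0:
        raise ConfigurationError("neuron has no dendritic segments")
    c = np.asarray(c, dtype=float)
    if c.shape != (U.shape[1],):
        raise InvalidInputError(
            f"context length {c.shape} incompatible with segment_dim {U.shape[1]}"
        )
    if mode not in GATING_MODES:
        raise InvalidInputError(f"unknown gating mode {mode!r}")
    responses = U @ c
    if mode == "max":
        j = int(np.argmax(responses))
    else:
        j = int(np.argmax(np.abs(responses)))
    return float(responses[j]), j


def gate(t_hat, d):
    """Sigmoidal gating ``t_hat * sigmoid(d)``; total, elementwise on arrays."""
    return np.asarray(t_hat, dtype=float) * expit(np.asarray(d, dtype=float))


def kwta(values: np.ndarray, k: int) -> np.ndarray:
    """Keep the ``k`` largest entries verbatim, zero the rest.

    Ties at the threshold are broken toward the lowest index so the result is
    deterministic.  Requires ``1 <= k <= len(values)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise InvalidInputError("kwta expects a 1-D activation vector")
    if not 1 <= k <= v.shape[0]:
        raise InvalidInputError(f"k={k} out of range for {v.shape[0]} values")
    return _kwta_batch(v[None, :], k)[0][0]


def _kwta_batch(y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise kWTA; returns (sparse output, boolean winner mask)."""
    n, m = y.shape
    if k >= m:
        return y.copy(), np.ones_like(y, dtype=bool)
    # stable argsort of -y: among ties the lowest index ranks first
    order = np.argsort(-y, axis=1, kind="stable")[:, :k]
    mask = np.zeros_like(y, dtype=bool)
    np.put_along_axis(mask, order, True, axis=1)
    return np.where(mask, y, 0.0), mask


def make_sparsity_mask(
    shape: tuple[int, ...], weight_sparsity: float, seed: int
) -> np.ndarray:
    """Fixed binary mask with exactly ``n - round((1-s)*n)`` zeros, uniform at random."""
    if not 0.0 <= weight_sparsity < 1.0:
        raise InvalidInputError("weight_sparsity must lie in [0, 1)")
    n = int(np.prod(shape))
    n_keep = _round((1.0 - weight_sparsity) * n)
    mask = np.zeros(n, dtype=np.float64)
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=n_keep, replace=False)
    mask[keep] = 1.0
    return mask.reshape(shape)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def init_params(
    spec: NetworkSpec, seed: int, dtype=np.float32
) -> list[DendriticLayerParams]:
    """Initialise all layers (hidden layers then the output head).

    Feedforward weights and biases: uniform on (-1/sqrt(fan_in),
    1/sqrt(fan_in)), weights drawn before masking with masked entries then
    zeroed.  Dendritic weights: zero-mean uniform with scale
    1/sqrt(segment_dim), giving scattered positive, negative and near-zero
    initial segment responses.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(spec.layer_shapes))
    params: list[DendriticLayerParams] = []
    n_hidden = len(spec.hidden_dims)
    for li, (out, fan_in) in enumerate(spec.layer_shapes):
        child = children[li]
        rng = np.random.default_rng(child)
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(out, fan_in)).astype(dtype)
        mask_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        M = make_sparsity_mask((out, fan_in), spec.weight_sparsity, mask_seed).astype(dtype)
        W *= M
        b = rng.uniform(-bound, bound, size=out).astype(dtype)
        U = None
        if li < n_hidden and li in spec.modulated_layers:
            ubound = 1.0 / np.sqrt(spec.segment_dim)
            U = rng.uniform(
                -ubound, ubound, size=(out, spec.num_segments, spec.segment_dim)
            ).astype(dtype)
        params.append(DendriticLayerParams(W=W, b=b, M=M, U=U))
    return params


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _segment_responses(U: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Responses r[n, o, s] = u_{o,s} . c_n, computed over unique context rows.

    Context batches are typically highly redundant (one prototype per task),
    so responses are evaluated once per distinct context row.
    """
    n = c.shape[0]
    out, S, C = U.shape
    uniq, inv = np.unique(c, axis=0, return_inverse=True)
    r_uniq = uniq @ U.reshape(out * S, C).T           # (n_uniq, out*S)
    return r_uniq.reshape(-1, out, S)[inv]


def forward(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    x: np.ndarray,
    c: np.ndarray | None = None,
) -> tuple[np.ndarray, list[ForwardTrace]]:
    """Batched forward pass.

    ``x`` is (N, input_dim); ``c`` is (N, context_dim) and is required whenever
    any layer is modulated.  Returns the output logits (N, output_dim) and one
    :class:`ForwardTrace` per layer (the output head's trace has no dendritic
    fields).  Modulated layers gate per neuron then apply kWTA per sample;
    unmodulated hidden layers apply kWTA or ReLU on the affine activation.
    """
    x = np.atleast_2d(np.asarray(x))
    if x.shape[1] != spec.input_dim:
        raise InvalidInputError(
            f"input has {x.shape[1]} columns, expected {spec.input_dim}"
        )
    if spec.modulated_layers:
        if c is None:
            raise InvalidInputError("context batch required: network has modulated layers")
        c = np.atleast_2d(np.asarray(c))
        if c.shape[1] != spec.context_dim:
            raise InvalidInputError(
                f"context has {c.shape[1]} columns, expected {spec.context_dim}"
            )
        if c.shape[0] != x.shape[0]:
            raise InvalidInputError("context batch size must match input batch size")

    traces: list[ForwardTrace] = []
    h = x
    n_hidden = len(spec.hidden_dims)
    for li in range(n_hidden):
        p = params[li]
        t_hat = h @ p.W.T + p.b
        d = j_star = None
        if li in spec.modulated_layers:
            r = _segment_responses(p.U, c)
            if spec.gating_mode == "max":
                j_star = np.argmax(r, axis=2)
            else:
                j_star = np.argmax(np.abs(r), axis=2)
            d = np.take_along_axis(r, j_star[:, :, None], axis=2)[:, :, 0]
            y = t_hat * expit(d)
        else:
            y = t_hat
        if li in spec.kwta_layers:
            k = spec.kwta_k(li)
            out, winners = _kwta_batch(y, k)
        elif li not in spec.modulated_layers:
            k, winners = None, None
            out = np.maximum(y, 0.0)      # ReLU for plain hidden layers
        else:
            k, winners = None, None
            out = y                       # modulated, dense-activation variant
        traces.append(
            ForwardTrace(t_hat=t_hat, d=d, j_star=j_star, y_hat=out, k=k,
                         winners=winners, x_in=h,
                         context=c if li in spec.modulated_layers else None)
        )
        h = out
    p = params[n_hidden]
    logits = h @ p.W.T + p.b
    traces.append(
        ForwardTrace(t_hat=logits, d=None, j_star=None, y_hat=logits, k=None,
                     winners=None, x_in=h)
    )
    return logits, traces


def backward(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    traces: Sequence[ForwardTrace],
    dlogits: np.ndarray,
) -> list[dict]:
    """Exact gradients for one batch, honouring the locality rules.

    Neurons zeroed by kWTA contribute zero gradient to their feedforward row
    and bias; the max / absolute-max selection routes each neuron's dendritic
    gradient exclusively to its winning segment ``j*`` (subgradient of max).
    Masked weight entries receive zero gradient.  Returns one dict per layer
    with keys ``W``, ``b`` and (for modulated layers) ``U``.
    """
    n_hidden = len(spec.hidden_dims)
    grads: list[dict] = [None] * len(params)

    # output head
    tr = traces[n_hidden]
    p = params[n_hidden]
    grads[n_hidden] = {
        "W": (dlogits.T @ tr.x_in) * p.M,
        "b": dlogits.sum(axis=0),
    }
    dh = dlogits @ p.W

    for li in range(n_hidden - 1, -1, -1):
        tr = traces[li]
        p = params[li]
        dy = dh
        if tr.winners is not None:                 # kWTA: losers get zero
            dy = np.where(tr.winners, dy, 0.0)
        elif li not in spec.modulated_layers:      # ReLU
            dy = np.where(tr.t_hat > 0.0, dy, 0.0)
        g = {}
        if li in spec.modulated_layers:
            sig = expit(tr.d)
            dt = dy * sig
            dd = dy * tr.t_hat * sig * (1.0 - sig)
            # scatter dd onto winning segments only
            out, S, C = p.U.shape
            gU = np.zeros_like(p.U, dtype=np.float64)
            c = tr.context
            if c is None:
                raise InvalidInputError("trace is missing its context batch")
            for s in range(S):
                sel = (tr.j_star == s)             # (N, out) bool
                if sel.any():
                    gU[:, s, :] = (dd * sel).T @ c
            g["U"] = gU
        else:
            dt = dy
        g["W"] = (dt.T @ tr.x_in) * p.M
        g["b"] = dt.sum(axis=0)
        grads[li] = g
        dh = dt @ p.W
    return grads


def forward_backward(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    x: np.ndarray,
    y: np.ndarray,
    c: np.ndarray | None = None,
) -> tuple[float, list[dict], np.ndarray]:
    """Forward pass, softmax cross-entropy loss, and full gradient set.

    Returns ``(loss, grads, logits)`` for integer labels ``y``.
    """
    logits, traces = forward(spec, params, x, c)
    loss, dlogits = softmax_cross_entropy(logits, y)
    grads = backward(spec, params, traces, dlogits)
    return loss, grads, logits


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    labels = np.asarray(labels, dtype=int)
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(logp[np.arange(n), labels].mean())
    probs = np.exp(logp)
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits


# ---------------------------------------------------------------------------
# Optimiser (Adam)
# ---------------------------------------------------------------------------


@dataclass
class AdamState:
    """First/second-moment accumulators for every parameter tensor."""

    m: list[dict]
    v: list[dict]
    t: int = 0

    @classmethod
    def for_params(cls, params: Sequence[DendriticLayerParams]) -> "AdamState":
        m, v = [], []
        for p in params:
            keys = {"W": p.W, "b": p.b}
            if p.U is not None:
                keys["U"] = p.U
            m.append({k: np.zeros_like(a, dtype=np.float64) for k, a in keys.items()})
            v.append({k: np.zeros_like(a, dtype=np.float64) for k, a in keys.items()})
        return cls(m=m, v=v)


def adam_step(
    params: Sequence[DendriticLayerParams],
    grads: Sequence[dict],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """One Adam update in place; re-applies the sparsity mask afterwards."""
    state.t += 1
    t = state.t
    for p, g, m, v in zip(params, grads, state.m, state.v):
        for key, grad in g.items():
            m[key] = beta1 * m[key] + (1 - beta1) * grad
            v[key] = beta2 * v[key] + (1 - beta2) * grad * grad
            mhat = m[key] / (1 - beta1**t)
            vhat = v[key] / (1 - beta2**t)
            arr = getattr(p, key)
            arr -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(arr.dtype)
        p.apply_mask()


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------


def count_nonzero_params(spec: NetworkSpec) -> dict:
    """Exact non-zero parameter counts implied by the architecture.

    Feedforward: ``round((1 - sparsity) * in * out)`` per weight matrix
    (output head included) plus all biases, which are never masked.
    Dendritic: ``units * num_segments * segment_dim`` per modulated layer
    (segments carry no biases).
    """
    spec.validate()
    ff = 0
    for out, fan_in in spec.layer_shapes:
        ff += _round((1.0 - spec.weight_sparsity) * out * fan_in)
        ff += out
    dend = sum(
        spec.hidden_dims[li] * spec.num_segments * spec.segment_dim
        for li in spec.modulated_layers
    )
    return {
        "feedforward_count": int(ff),
        "dendritic_count": int(dend),
        "total": int(ff + dend),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_params(path, spec: NetworkSpec, params: Sequence[DendriticLayerParams]) -> None:
    """Write all layer tensors plus the spec (as JSON metadata) to an NPZ file."""
    arrays = {"spec_json": np.frombuffer(spec.to_json().encode(), dtype=np.uint8)}
    for i, p in enumerate(params):
        arrays[f"W{i}"] = p.W
        arrays[f"b{i}"] = p.b
        arrays[f"M{i}"] = p.M
        if p.U is not None:
            arrays[f"U{i}"] = p.U
    np.savez_compressed(path, **arrays)


def load_params(path) -> tuple[NetworkSpec, list[DendriticLayerParams]]:
    with np.load(path) as data:
        spec = NetworkSpec.from_json(bytes(data["spec_json"]).decode())
        params = []
        for i in range(len(spec.layer_shapes)):
            params.append(
                DendriticLayerParams(
                    W=data[f"W{i}"],
                    b=data[f"b{i}"],
                    M=data[f"M{i}"],
                    U=data[f"U{i}"] if f"U{i}" in data else None,
                )
            )
    return spec, params
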