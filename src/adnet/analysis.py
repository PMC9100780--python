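"""Emergent-subnetwork analysis.

After sequential training, each task should drive a distinct sparse subset of
hidden neurons (its *subnetwork*).  This module measures that: per-task
activation frequencies after kWTA, raw dendritic segment responses to each
task's context vector, and Jaccard overlap between thresholded task
subnetworks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .context import nearest_prototype_batch, one_hot_context
from .exceptions import InvalidInputError
from .network import DendriticLayerParams, NetworkSpec, forward
from .streams import TaskStream

__all__ = [
    "activation_frequency",
    "subnetwork_overlap",
    "dendrite_responses",
    "mean_pairwise_overlap",
    "context_routing_overlap",
    "plot_activation_frequency",
    "plot_dendrite_responses",
]


def activation_frequency(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    stream: TaskStream,
    store=None,
    layer: int = -1,
    n_samples: int = 1000,
    context_mode: str = "prototype_given",
    seed: int = 0,
) -> np.ndarray:
    """Fraction of each task's samples for which each neuron survives kWTA.

    Returns a (tasks, neurons) matrix for the chosen hidden layer.  Samples
    are drawn from each task's test set (all of it if smaller than
    ``n_samples``).  For a kWTA layer every row's mean is exactly
    ``k / layer_size`` since each sample activates exactly k units.
    """
    if n_samples < 1:
        raise InvalidInputError("n_samples must be at least 1")
    li = layer % len(spec.hidden_dims)
    rows = []
    for tau, task in enumerate(stream.tasks):
        x = task.test_x
        if x.shape[0] > n_samples:
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tau,)))
            x = x[rng.choice(x.shape[0], size=n_samples, replace=False)]
        c = None
        if spec.modulated_layers:
            if context_mode == "onehot":
                c = np.broadcast_to(
                    one_hot_context(tau, stream.T), (x.shape[0], stream.T)
                )
            else:
                idx = nearest_prototype_batch(x, store)
                c = store.prototype_matrix()[idx]
        _logits, traces = forward(spec, params, x, c)
        tr = traces[li]
        active = tr.winners if tr.winners is not None else (tr.y_hat != 0.0)
        rows.append(active.mean(axis=0))
    return np.array(rows)


def subnetwork_overlap(freq: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Pairwise Jaccard overlap of thresholded task subnetworks.

    ``S_t`` is the set of neurons with frequency >= threshold for task t;
    entry (a, b) is ``|S_a ∩ S_b| / |S_a ∪ S_b|``.  Entries whose union is
    empty are NaN; the diagonal is 1 whenever ``S_t`` is non-empty.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    member = np.asarray(freq) >= threshold          # (T, n) bool
    inter = member.astype(int) @ member.astype(int).T
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return overlap


def context_routing_overlap(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    probe_x: np.ndarray,
    contexts: np.ndarray,
    layer: int = -1,
    threshold: float = 0.1,
) -> float:
    """Winner-set overlap of one fixed probe batch under each task's context.

    Isolates the routing effect of the dendrites: the feedforward input is
    held constant and only the context varies, so any difference between the
    winner sets is due to context gating.  Returns the mean pairwise Jaccard
    overlap of the thresholded winner-frequency sets (one per context row).
    A network whose gates ignore context scores near 1; a network that routes
    each context to its own subnetwork scores near 0.
    """
    li = layer % len(spec.hidden_dims)
    probe_x = np.atleast_2d(probe_x)
    rows = []
    for cvec in np.atleast_2d(contexts):
        c = np.broadcast_to(cvec, (probe_x.shape[0], cvec.shape[0]))
        _logits, traces = forward(spec, params, probe_x, c)
        tr = traces[li]
        active = tr.winners if tr.winners is not None else (tr.y_hat != 0.0)
        rows.append(active.mean(axis=0))
    return mean_pairwise_overlap(np.array(rows), threshold)


def mean_pairwise_overlap(freq: np.ndarray, threshold: float = 0.1) -> float:
    """Mean of the off-diagonal Jaccard overlaps (NaN entries excluded)."""
    ov = subnetwork_overlap(freq, threshold)
    T = ov.shape[0]
    off = ov[~np.eye(T, dtype=bool)]
    return float(np.nanmean(off))


def dendrite_responses(
    params_or_U, contexts: np.ndarray, layer: int = -1
) -> np.ndarray:
    """Raw segment responses ``u_j . c`` per neuron, segment and context.

    ``contexts`` holds one context vector per task (rows).  Accepts either a
    parameter list (the dendritic tensor of ``layer`` is used) or a raw
    (neurons, segments, context_dim) tensor.  No gating is applied; responses
    are linear in the context.  Returns (neurons, segments, tasks).
    """
    if isinstance(params_or_U, np.ndarray):
        U = params_or_U
    else:
        modulated = [p for p in params_or_U if p.U is not None]
        if not modulated:
            raise InvalidInputError("no modulated layer in params")
        U = modulated[layer % len(modulated)].U
    contexts = np.atleast_2d(np.asarray(contexts, dtype=float))
    if contexts.shape[1] != U.shape[2]:
        raise InvalidInputError(
            f"context dim {contexts.shape[1]} != segment_dim {U.shape[2]}"
        )
    return np.einsum("osc,tc->ost", U, contexts)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def _axes(ax):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 4))
    return ax


def plot_activation_frequency(freq: np.ndarray, max_neurons: int = 64, ax=None):
    """Task-by-neuron activation-frequency heatmap (first 64 neurons by index)."""
    ax = _axes(ax)
    im = ax.imshow(freq[:, :max_neurons], aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=min(1.0, float(freq.max()) or 1.0))
    ax.set_xlabel("hidden unit")
    ax.set_ylabel("task")
    ax.figure.colorbar(im, ax=ax, label="activation frequency")
    return ax


def plot_dendrite_responses(responses: np.ndarray, neuron: int = 0, ax=None):
    """Segment-by-task response heatmap for one neuron (signed, diverging scale)."""
    ax = _axes(ax)
    r = responses[neuron]
    lim = float(np.abs(r).max()) or 1.0
    im = ax.imshow(r, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("task context")
    ax.set_ylabel("dendritic segment")
    ax.figure.colorbar(im, ax=ax, label="segment response")
    return ax
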