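"""Sequential-task training and evaluation (the Model / Results layer).

:class:`ContinualClassifier` is the front door of the package: it binds a
:class:`~adnet.streams.TaskStream` to a :class:`~adnet.network.NetworkSpec`
and a :class:`TrainConfig`, and ``fit()`` runs the tasks strictly in order —
while training on task tau the model never sees a sample from any other task
— returning a :class:`ContinualResults` with trained parameters, the context
store, per-task accuracies and analysis helpers.

Three context regimes are supported:

``onehot``
    The true task ID as a one-hot vector, supplied during training *and*
    evaluation (the weaker, task-aware protocol used in multi-task RL).
``prototype_given``
    Task identity is available during training only: every sample of task tau
    is assigned the task prototype p_tau (the element-wise mean of the task's
    training inputs, computed in a full pass at task start).  At test time the
    context is the nearest stored prototype — no labels consulted.
``prototype_inferred``
    Task-free: each training batch is routed through the online clustering
    t-test (:func:`adnet.context.assign_batch`) and uses its matched or newly
    created cluster's prototype.  Test time is identical to
    ``prototype_given``.

Optimisation is softmax cross-entropy under Adam; gradients obey the
winner-only locality rules of :mod:`adnet.network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .context import (
    ContextStore,
    assign_batch,
    nearest_prototype_batch,
    one_hot_context,
)
from .exceptions import ConfigurationError, InvalidInputError, StateError
from .network import (
    AdamState,
    DendriticLayerParams,
    NetworkSpec,
    adam_step,
    count_nonzero_params,
    forward,
    forward_backward,
    init_params,
)
from .streams import Task, TaskStream

__all__ = [
    "TrainConfig",
    "EvalReport",
    "ContinualClassifier",
    "ContinualResults",
    "train_continual",
    "evaluate_all_tasks",
    "run_sweep",
    "matched_mlp_spec",
    "default_hyperparams",
]

log = logging.getLogger("adnet.train")

CONTEXT_MODES = ("onehot", "prototype_given", "prototype_inferred")

# Per-task-count training hyperparameters for the permuted-image benchmark,
# keyed by (number of tasks, task-aware?) -> (learning rate, epochs per task).
_CL_HYPERPARAMS = {
    (2, True): (5e-4, 1), (2, False): (1e-3, 5),
    (5, True): (5e-4, 1), (5, False): (1e-3, 5),
    (10, True): (5e-4, 3), (10, False): (1e-3, 3),
    (25, True): (3e-4, 5), (25, False): (3e-4, 1),
    (50, True): (3e-4, 3), (50, False): (1e-4, 3),
    (100, True): (1e-4, 3), (100, False): (1e-4, 3),
}


def default_hyperparams(T: int, context_mode: str = "prototype_given"):
    """(learning_rate, epochs_per_task) defaults for a T-task run.

    Exact table rows exist for T in {2, 5, 10, 25, 50, 100}; any other T
    falls back to the T=10 row.
    """
    aware = context_mode != "prototype_inferred"
    return _CL_HYPERPARAMS.get((T, aware), _CL_HYPERPARAMS[(10, aware)])


@dataclass
class TrainConfig:
    """Continual-training configuration.

    ``batch_size`` must be at least 2: the task-free clustering mode performs
    a two-sample test on every batch.
    """

    epochs_per_task: int = 3
    learning_rate: float = 5e-4
    batch_size: int = 256
    context_mode: str = "prototype_given"
    seed: int = 0
    alpha: float = 1e-4
    max_stored_per_cluster: int = 2048
    diag_cov: bool = False
    eval_every_task: bool = False

    def __post_init__(self):
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be at least 2")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs_per_task < 1:
            raise ConfigurationError("epochs_per_task must be at least 1")
        if self.context_mode not in CONTEXT_MODES:
            raise ConfigurationError(
                f"context_mode must be one of {CONTEXT_MODES}"
            )


@dataclass
class EvalReport:
    """Per-task and pooled accuracies from one all-task evaluation."""

    per_task_accuracy: np.ndarray
    test_sizes: np.ndarray
    context_assignment_accuracy: float | None = None
    history: list = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        """Pooled accuracy: the per-task average weighted by test-set sizes."""
        w = self.test_sizes / self.test_sizes.sum()
        return float((self.per_task_accuracy * w).sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task": np.arange(len(self.per_task_accuracy)),
                "accuracy": self.per_task_accuracy,
                "n_test": self.test_sizes,
            }
        )

    def to_dict(self) -> dict:
        return {
            "per_task_accuracy": [float(a) for a in self.per_task_accuracy],
            "mean_accuracy": self.mean_accuracy,
            "context_assignment_accuracy": self.context_assignment_accuracy,
        }


def _check_dims(spec: NetworkSpec, stream: TaskStream, config: TrainConfig) -> None:
    if not spec.modulated_layers:
        return
    if config.context_mode == "onehot":
        if spec.context_dim != stream.T:
            raise ConfigurationError(
                f"one-hot context needs context_dim == T ({stream.T}), "
                f"got {spec.context_dim}"
            )
    elif spec.context_dim != stream.dim:
        raise ConfigurationError(
            f"prototype context needs context_dim == input dim ({stream.dim}), "
            f"got {spec.context_dim}"
        )


def _task_batches(
    task: Task, batch_size: int, rng: np.random.Generator
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Shuffled minibatches drawn from a single task only."""
    n = task.train_x.shape[0]
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        yield task.train_x[idx], task.train_y[idx]


def _eval_forward(spec, params, x, c, chunk: int = 2048) -> np.ndarray:
    preds = []
    for start in range(0, x.shape[0], chunk):
        logits, _ = forward(
            spec, params, x[start : start + chunk],
            None if c is None else c[start : start + chunk],
        )
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def train_continual(
    spec: NetworkSpec,
    stream: TaskStream,
    config: TrainConfig,
    store: ContextStore | None = None,
) -> tuple[list[DendriticLayerParams], ContextStore | None, EvalReport]:
    """Train on the stream's tasks strictly in sequence; evaluate on all tasks.

    Returns ``(params, store, report)``.  With ``config.eval_every_task`` the
    report's ``history`` holds one all-task :class:`EvalReport` per completed
    task (evaluation never feeds back into training).
    """
    _check_dims(spec, stream, config)
    uses_context = bool(spec.modulated_layers)
    prototype_mode = uses_context and config.context_mode != "onehot"
    inferred = config.context_mode == "prototype_inferred"

    ss = np.random.SeedSequence(config.seed)
    init_seed = int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
    params = init_params(spec, init_seed)
    adam = AdamState.for_params(params)

    if prototype_mode and store is None:
        store = ContextStore(
            dim=stream.dim,
            alpha=config.alpha,
            max_stored_per_cluster=config.max_stored_per_cluster,
            diag_cov=config.diag_cov,
        )
    task_to_cluster: dict[int, int] = {}
    cluster_votes: dict[int, dict[int, int]] = {}
    history: list[EvalReport] = []

    for tau, task in enumerate(stream.tasks):
        cvec = None
        if uses_context:
            if config.context_mode == "onehot":
                cvec = one_hot_context(tau, stream.T)
            elif config.context_mode == "prototype_given":
                j = store.add_task_prototype(task.train_x)
                task_to_cluster[tau] = j
                cvec = store.prototypes[j]
        for epoch in range(config.epochs_per_task):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, tau, epoch))
            )
            epoch_loss = epoch_correct = epoch_n = 0
            for xb, yb in _task_batches(task, config.batch_size, rng):
                if uses_context:
                    if inferred:
                        j, _created = assign_batch(xb, store)
                        cluster_votes.setdefault(j, {}).setdefault(tau, 0)
                        cluster_votes[j][tau] += 1
                        cvec = store.prototypes[j]
                    c = np.broadcast_to(cvec, (xb.shape[0], cvec.shape[0]))
                else:
                    c = None
                loss, grads, logits = forward_backward(spec, params, xb, yb, c)
                adam_step(params, grads, adam, config.learning_rate)
                epoch_loss += loss * xb.shape[0]
                epoch_correct += int((np.argmax(logits, axis=1) == yb).sum())
                epoch_n += xb.shape[0]
            log.info(
                "task %d epoch %d: loss %.4f train_acc %.4f",
                tau, epoch, epoch_loss / epoch_n, epoch_correct / epoch_n,
            )
        if config.eval_every_task:
            history.append(
                evaluate_all_tasks(
                    spec, params, stream, store, config.context_mode,
                    task_to_cluster=_resolve_mapping(
                        stream.T, task_to_cluster, cluster_votes, inferred
                    ),
                )
            )

    mapping = _resolve_mapping(stream.T, task_to_cluster, cluster_votes, inferred)
    report = evaluate_all_tasks(
        spec, params, stream, store, config.context_mode, task_to_cluster=mapping
    )
    report.history = history
    return params, store, report


def _resolve_mapping(T, task_to_cluster, cluster_votes, inferred):
    """Task -> cluster map; for inferred mode, the cluster a task's batches
    were most often assigned to."""
    if not inferred:
        return dict(task_to_cluster) or {t: t for t in range(T)}
    mapping = {}
    for j, votes in cluster_votes.items():
        for tau, n in votes.items():
            best = mapping.get(tau)
            if best is None or n > best[1]:
                mapping[tau] = (j, n)
    return {tau: jn[0] for tau, jn in mapping.items()}


def evaluate_all_tasks(
    spec: NetworkSpec,
    params: Sequence[DendriticLayerParams],
    stream: TaskStream,
    store: ContextStore | None,
    context_mode: str = "prototype_given",
    task_to_cluster: dict[int, int] | None = None,
) -> EvalReport:
    """Accuracy on every task's test set.

    In the prototype modes each test example's context is the nearest stored
    prototype — task labels are never consulted at evaluation time.  In
    one-hot mode the true task ID is supplied (the weaker protocol).
    ``context_assignment_accuracy`` is the fraction of test samples routed to
    the prototype of their true task, when a task-to-cluster map is defined.
    """
    uses_context = bool(spec.modulated_layers)
    if uses_context and context_mode != "onehot":
        if store is None or store.M == 0:
            raise StateError("prototype evaluation requires a non-empty context store")
    accs, sizes = [], []
    routed_correct = routed_total = 0
    for tau, task in enumerate(stream.tasks):
        c = None
        if uses_context:
            if context_mode == "onehot":
                c = np.broadcast_to(
                    one_hot_context(tau, stream.T), (task.test_x.shape[0], stream.T)
                )
            else:
                idx = nearest_prototype_batch(task.test_x, store)
                c = store.prototype_matrix()[idx]
                if task_to_cluster and tau in task_to_cluster:
                    routed_correct += int((idx == task_to_cluster[tau]).sum())
                    routed_total += idx.shape[0]
        preds = _eval_forward(spec, params, task.test_x, c)
        accs.append(float((preds == task.test_y).mean()))
        sizes.append(task.test_y.shape[0])
    assignment = routed_correct / routed_total if routed_total else None
    return EvalReport(
        per_task_accuracy=np.array(accs),
        test_sizes=np.array(sizes),
        context_assignment_accuracy=assignment,
    )


def matched_mlp_spec(spec: NetworkSpec) -> NetworkSpec:
    """Dense ReLU MLP whose non-zero parameter count matches ``spec``'s total.

    Keeps the number of hidden layers and solves for a common hidden width so
    the dense network has at least as many non-zero parameters as the
    dendritic network (never fewer, to keep the comparison conservative).
    """
    target = count_nonzero_params(spec)["total"]
    n_hidden = len(spec.hidden_dims)
    lo, hi = 1, max(spec.hidden_dims) * 8

    def total(h: int) -> int:
        dense = NetworkSpec(
            input_dim=spec.input_dim,
            hidden_dims=(h,) * n_hidden,
            output_dim=spec.output_dim,
            weight_sparsity=0.0,
            num_segments=0,
            modulated_layers=(),
            kwta_layers=(),
        )
        return count_nonzero_params(dense)["total"]

    while total(hi) < target:
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        if total(mid) < target:
            lo = mid + 1
        else:
            hi = mid
    return NetworkSpec(
        input_dim=spec.input_dim,
        hidden_dims=(lo,) * n_hidden,
        output_dim=spec.output_dim,
        weight_sparsity=0.0,
        num_segments=0,
        modulated_layers=(),
        kwta_layers=(),
    )


def run_sweep(
    spec: NetworkSpec,
    stream: TaskStream,
    base_config: TrainConfig,
    axis: str,
    values: Sequence,
) -> pd.DataFrame:
    """Independent seeded runs varying ``num_segments`` or ``activation_density``.

    Returns a table with one row per swept value (mean and per-task
    accuracies); the full :class:`EvalReport` objects are attached under
    ``df.attrs['reports']``.
    """
    if axis not in ("num_segments", "activation_density"):
        raise InvalidInputError("axis must be 'num_segments' or 'activation_density'")
    if len(values) == 0:
        raise InvalidInputError("values must be non-empty")
    rows, reports = [], []
    for i, value in enumerate(values):
        run_spec = replace(spec, **{axis: value})
        seed = int(
            np.random.SeedSequence(base_config.seed, spawn_key=(2, i)).generate_state(
                1, dtype=np.uint32
            )[0]
        ) % (2**31)
        run_config = replace(base_config, seed=seed)
        _params, _store, report = train_continual(run_spec, stream, run_config)
        row = {axis: value, "mean_accuracy": report.mean_accuracy}
        for tau, acc in enumerate(report.per_task_accuracy):
            row[f"task_{tau}_accuracy"] = acc
        rows.append(row)
        reports.append(report)
    df = pd.DataFrame(rows)
    df.attrs["reports"] = reports
    return df


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class ContinualClassifier:
    """Continual-learning classifier bound to a task stream.

    Parameters
    ----------
    stream
        The ordered task stream to learn.
    spec
        Network architecture.  ``None`` builds a default dendritic network
        for the stream: two hidden layers, kWTA, one segment per task,
        prototype-sized context.
    config
        Training configuration; ``None`` uses the per-T defaults of
        :func:`default_hyperparams` with the prototype-given regime.

    Examples
    --------
    >>> stream = generate_synthetic_stream(T=5, seed=0)        # doctest: +SKIP
    >>> res = ContinualClassifier(stream).fit()                # doctest: +SKIP
    >>> print(res.summary())                                   # doctest: +SKIP
    """

    def __init__(
        self,
        stream: TaskStream,
        spec: NetworkSpec | None = None,
        config: TrainConfig | None = None,
    ):
        self.stream = stream
        if spec is None:
            spec = NetworkSpec(
                input_dim=stream.dim,
                hidden_dims=(256, 256),
                output_dim=stream.n_classes,
                context_dim=stream.dim,
                weight_sparsity=0.5,
                activation_density=0.05,
                num_segments=stream.T,
            )
        if config is None:
            lr, epochs = default_hyperparams(stream.T)
            config = TrainConfig(epochs_per_task=epochs, learning_rate=lr)
        self.spec = spec
        self.config = config

    def fit(self, store: ContextStore | None = None) -> "ContinualResults":
        params, store, report = train_continual(
            self.spec, self.stream, self.config, store=store
        )
        return ContinualResults(self, params, store, report)

    def count_params(self) -> dict:
        return count_nonzero_params(self.spec)


class ContinualResults:
    """Fitted continual-learning model: trained parameters, store, accuracies."""

    def __init__(self, model: ContinualClassifier, params, store, report: EvalReport):
        self.model = model
        self.params = params
        self.store = store
        self.report = report

    @property
    def per_task_accuracy(self) -> np.ndarray:
        return self.report.per_task_accuracy

    @property
    def mean_accuracy(self) -> float:
        return self.report.mean_accuracy

    @property
    def context_assignment_accuracy(self):
        return self.report.context_assignment_accuracy

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class predictions with dynamically selected (nearest-prototype) context."""
        spec = self.model.spec
        c = None
        if spec.modulated_layers:
            if self.model.config.context_mode == "onehot":
                raise StateError(
                    "one-hot models need task IDs; use evaluate_all_tasks instead"
                )
            idx = nearest_prototype_batch(x, self.store)
            c = self.store.prototype_matrix()[idx]
        return _eval_forward(spec, self.params, np.atleast_2d(x), c)

    def activation_frequency(self, layer: int = -1, n_samples: int = 1000):
        from .analysis import activation_frequency

        return activation_frequency(
            self.model.spec, self.params, self.stream_or_raise(),
            self.store, layer=layer, n_samples=n_samples,
            context_mode=self.model.config.context_mode,
        )

    def stream_or_raise(self) -> TaskStream:
        if self.model.stream is None:
            raise StateError("results are detached from their stream")
        return self.model.stream

    def summary(self) -> str:
        spec, cfg = self.model.spec, self.model.config
        counts = count_nonzero_params(spec)
        lines = [
            "        Continual Learning Results        ",
            "=" * 46,
            f"Tasks:                 {len(self.per_task_accuracy)}",
            f"Hidden layers:         {list(spec.hidden_dims)}",
            f"Dendritic segments:    {spec.num_segments}"
            + (" (unmodulated)" if not spec.modulated_layers else ""),
            f"Weight sparsity:       {spec.weight_sparsity:.0%}",
            f"Activation density:    {spec.activation_density:.0%}"
            + ("" if spec.kwta_layers else " (no kWTA)"),
            f"Context regime:        {cfg.context_mode}",
            f"Non-zero parameters:   {counts['total']:,}",
            "-" * 46,
        ]
        for tau, acc in enumerate(self.per_task_accuracy):
            lines.append(f"  task {tau:>3d} accuracy:    {acc:.4f}")
        lines.append("-" * 46)
        lines.append(f"Mean accuracy:         {self.mean_accuracy:.4f}")
        if self.context_assignment_accuracy is not None:
            lines.append(
                f"Context routing acc.:  {self.context_assignment_accuracy:.4f}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ContinualResults: T={len(self.per_task_accuracy)}, "
            f"mean_accuracy={self.mean_accuracy:.4f}>"
        )
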