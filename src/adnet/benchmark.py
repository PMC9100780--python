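"""Desk-scale continual-learning benchmark.

Runs the bundled synthetic 5-task stream through a dendritic network and a
parameter-matched dense ReLU MLP under identical training budgets, measuring

* final mean accuracy over all tasks for both models,
* task-1 accuracy immediately after task 1 versus after the final task
  (the catastrophic-forgetting probe),
* inter-task subnetwork overlap before and after training,
* task-free cluster recovery (number of clusters found and batch routing).

The default conditions are deliberately small — 5 tasks of 5,000 training
samples in 128 dimensions, hidden layers of 256 with 5 segments per neuron —
a ~1/12-scale analogue of the 10-task permuted-image benchmark, sized to run
in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (
    activation_frequency,
    context_routing_overlap,
    mean_pairwise_overlap,
)
from .context import ContextStore, assign_batch
from .model import TrainConfig, matched_mlp_spec, train_continual, _task_batches
from .network import NetworkSpec, init_params
from .streams import TaskStream, generate_synthetic_stream

__all__ = [
    "BenchmarkResult",
    "run_continual_benchmark",
    "run_cluster_recovery",
    "chance_accuracy",
]


def benchmark_spec(dim: int = 128, T: int = 5, n_classes: int = 10) -> NetworkSpec:
    """The dendritic architecture used by the benchmark (2x256, 5% density)."""
    return NetworkSpec(
        input_dim=dim,
        hidden_dims=(256, 256),
        output_dim=n_classes,
        context_dim=dim,
        weight_sparsity=0.5,
        activation_density=0.05,
        num_segments=T,
    )


@dataclass
class BenchmarkResult:
    """Seed-averaged outcomes of the dendritic-vs-dense comparison."""

    adn_mean_accuracy: float
    mlp_mean_accuracy: float
    adn_task1_drop: float
    mlp_task1_drop: float
    overlap_untrained: float
    overlap_trained: float
    routing_overlap_untrained: float
    routing_overlap_trained: float
    per_seed: list

    @property
    def accuracy_gap(self) -> float:
        return self.adn_mean_accuracy - self.mlp_mean_accuracy


def run_continual_benchmark(
    seeds=(0, 1, 2),
    dim: int = 128,
    T: int = 5,
    learning_rate: float = 7e-4,
    epochs_per_task: int = 20,
    include_mlp: bool = True,
    include_overlap: bool = True,
) -> BenchmarkResult:
    """Train dendritic and dense models on the synthetic stream, one run per seed."""
    spec = benchmark_spec(dim=dim, T=T)
    mlp = matched_mlp_spec(spec) if include_mlp else None
    per_seed = []
    for seed in seeds:
        stream = generate_synthetic_stream(dim=dim, T=T, seed=seed)
        cfg = TrainConfig(
            epochs_per_task=epochs_per_task,
            learning_rate=learning_rate,
            seed=seed,
            eval_every_task=True,
        )
        params, store, rep = train_continual(spec, stream, cfg)
        entry = {
            "seed": seed,
            "adn_mean": rep.mean_accuracy,
            "adn_task1_after_task1": float(rep.history[0].per_task_accuracy[0]),
            "adn_task1_final": float(rep.per_task_accuracy[0]),
            "context_assignment_accuracy": rep.context_assignment_accuracy,
        }
        if include_overlap:
            # same init seed the trainer derives, so "untrained" is the true
            # starting point of this very run
            init_seed = int(
                np.random.SeedSequence(seed).generate_state(1, dtype=np.uint32)[0]
            ) % (2**31)
            virgin = init_params(spec, init_seed)
            freq0 = activation_frequency(spec, virgin, stream, store, layer=1,
                                         n_samples=500, seed=seed)
            freq1 = activation_frequency(spec, params, stream, store, layer=1,
                                         n_samples=500, seed=seed)
            entry["overlap_untrained"] = mean_pairwise_overlap(freq0)
            entry["overlap_trained"] = mean_pairwise_overlap(freq1)
            probe = stream[0].test_x[:500]
            contexts = store.prototype_matrix()
            entry["routing_overlap_untrained"] = context_routing_overlap(
                spec, virgin, probe, contexts, layer=1
            )
            entry["routing_overlap_trained"] = context_routing_overlap(
                spec, params, probe, contexts, layer=1
            )
        if include_mlp:
            _p, _s, mrep = train_continual(mlp, stream, cfg)
            entry["mlp_mean"] = mrep.mean_accuracy
            entry["mlp_task1_after_task1"] = float(mrep.history[0].per_task_accuracy[0])
            entry["mlp_task1_final"] = float(mrep.per_task_accuracy[0])
        per_seed.append(entry)

    def avg(key):
        vals = [e[key] for e in per_seed if key in e]
        return float(np.mean(vals)) if vals else float("nan")

    return BenchmarkResult(
        adn_mean_accuracy=avg("adn_mean"),
        mlp_mean_accuracy=avg("mlp_mean"),
        adn_task1_drop=avg("adn_task1_after_task1") - avg("adn_task1_final"),
        mlp_task1_drop=avg("mlp_task1_after_task1") - avg("mlp_task1_final"),
        overlap_untrained=avg("overlap_untrained"),
        overlap_trained=avg("overlap_trained"),
        routing_overlap_untrained=avg("routing_overlap_untrained"),
        routing_overlap_trained=avg("routing_overlap_trained"),
        per_seed=per_seed,
    )


def chance_accuracy(
    seed: int = 0,
    n_blocks: int = 25,
    n_test_per_block: int = 400,
) -> dict:
    """Accuracy of untrained single-head networks on balanced 10-class data.

    An individual untrained network routes whole regions of input space to
    fixed output units, so with one network the 10 class-to-unit assignments
    dominate the variance of the measured accuracy and a binomial error bar
    would be too small.  The measurement therefore averages over ``n_blocks``
    independent draws of (untrained network, class means), each evaluated on
    ``n_test_per_block`` balanced samples with nearest-prototype contexts —
    the same chance-level quantity, estimated with sample-level error bars.

    Returns ``{"accuracy_pct", "n", "sem_pct", "block_accuracies"}``.
    """
    from .config import preset_spec

    spec = preset_spec("cl-permuted", n_tasks=10)
    block_acc = []
    correct = total = 0
    for b in range(n_blocks):
        block_seed = int(
            np.random.SeedSequence(seed, spawn_key=(4, b)).generate_state(
                1, dtype=np.uint32
            )[0]
        ) % (2**31)
        stream = generate_synthetic_stream(
            n_classes=10,
            dim=spec.input_dim,
            T=1,
            n_train=1000,
            n_test=n_test_per_block,
            seed=block_seed,
        )
        params = init_params(spec, block_seed + 1)
        store = ContextStore(dim=spec.input_dim)
        store.add_task_prototype(stream[0].train_x)
        from .model import evaluate_all_tasks

        report = evaluate_all_tasks(spec, params, stream, store)
        block_acc.append(report.mean_accuracy)
        correct += int(round(report.mean_accuracy * n_test_per_block))
        total += n_test_per_block
    acc = correct / total
    sem = float(np.std(block_acc, ddof=1) / np.sqrt(n_blocks))
    return {
        "accuracy_pct": 100.0 * acc,
        "n": total,
        "sem_pct": 100.0 * sem,
        "block_accuracies": block_acc,
    }


def run_cluster_recovery(
    stream: TaskStream | None = None,
    batch_size: int = 256,
    epochs_per_task: int = 1,
    alpha: float = 1e-4,
    seed: int = 0,
) -> tuple[ContextStore, dict]:
    """Feed the stream's batches through the online clustering t-test.

    Returns the final store and a summary dict with the number of clusters
    found, the cluster each task's batches were routed to, and the fraction
    of batches routed to their task's own cluster.
    """
    if stream is None:
        stream = generate_synthetic_stream(seed=seed)
    store = ContextStore(dim=stream.dim, alpha=alpha)
    assignments: list[tuple[int, int, bool]] = []
    for tau, task in enumerate(stream.tasks):
        for epoch in range(epochs_per_task):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(3, tau, epoch))
            )
            for xb, _yb in _task_batches(task, batch_size, rng):
                j, created = assign_batch(xb, store)
                assignments.append((tau, j, created))
    task_cluster = {tau: j for tau, j, created in assignments if created}
    n_correct = sum(
        1 for tau, j, _c in assignments if j == task_cluster.get(tau, -1)
    )
    summary = {
        "n_clusters": store.M,
        "task_cluster": task_cluster,
        "batch_routing_accuracy": n_correct / len(assignments),
    }
    return store, summary
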