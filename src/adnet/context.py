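"""Context vectors: prototypes, nearest-prototype selection, and task-free clustering.

A *prototype* is the element-wise mean of a task's training inputs and serves
as that task's context vector.  When task identity is unavailable, batches are
clustered online: each incoming batch X is compared with every existing
cluster's stored samples using an unpaired multivariate t-test (Hotelling's
t-squared, transformed to an F statistic).  The first cluster whose test does
not reject absorbs X and its prototype is updated; if every test rejects, a
new cluster is created with prototype mean(X).  At inference the context for a
test example is the nearest prototype under Euclidean distance — no task label
is ever consulted.

The statistic for batches X and Y with means x̄, ȳ and pooled sample
covariance Σ is

    t² = (|X||Y| / (|X|+|Y|)) (x̄−ȳ)ᵀ Σ⁻¹ (x̄−ȳ)
    f  = (|X|+|Y|−d−1) / (d (|X|+|Y|−2)) · t²  ~  F(d, |X|+|Y|−d−1)

with Σ⁻¹ computed as a Moore–Penrose pseudo-inverse, so rank-deficient pooled
covariances (common when d approaches the pooled sample count) do not abort
the test.  The null ("same generating process") is rejected when the upper
tail probability of f falls below ``alpha``.

The default ``alpha`` is 1e-4: a continual-learning run performs hundreds of
batch-vs-cluster tests, and a per-test level this small keeps the expected
number of spuriously created clusters well below one per run (Bonferroni-style
control) while batches from genuinely different tasks reject with p-values
many orders of magnitude smaller.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDimensionError,
    InvalidInputError,
    StateError,
)

__all__ = [
    "TTestResult",
    "ClusterStats",
    "ContextStore",
    "compute_prototype",
    "nearest_prototype",
    "hotellings_t2",
    "hotelling_test",
    "t2_to_f",
    "assign_batch",
    "one_hot_context",
]


def compute_prototype(samples: np.ndarray) -> np.ndarray:
    """Element-wise mean of a set of samples (rows)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[None, :]
    if samples.shape[0] == 0:
        raise InvalidInputError("cannot compute a prototype from zero samples")
    return samples.mean(axis=0)


def nearest_prototype(x_prime: np.ndarray, store: "ContextStore | np.ndarray") -> int:
    """Index of the prototype closest to ``x_prime`` in Euclidean distance.

    Exact ties resolve to the lowest index.  Accepts either a
    :class:`ContextStore` or a (M, d) array of prototype rows.
    """
    protos = store.prototype_matrix() if isinstance(store, ContextStore) else np.asarray(store, dtype=float)
    if protos.ndim != 2 or protos.shape[0] == 0:
        raise StateError("no prototypes stored")
    x_prime = np.asarray(x_prime, dtype=float)
    dists = np.linalg.norm(protos - x_prime[None, :], axis=1)
    return int(np.argmin(dists))


def nearest_prototype_batch(X: np.ndarray, store: "ContextStore | np.ndarray") -> np.ndarray:
    """Vectorised :func:`nearest_prototype` over the rows of ``X``."""
    protos = store.prototype_matrix() if isinstance(store, ContextStore) else np.asarray(store, dtype=float)
    if protos.ndim != 2 or protos.shape[0] == 0:
        raise StateError("no prototypes stored")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def one_hot_context(task_id: int, n_tasks: int) -> np.ndarray:
    """One-hot task-identity context vector (the RL-style context)."""
    if not 0 <= task_id < n_tasks:
        raise InvalidInputError(f"task_id {task_id} out of range for {n_tasks} tasks")
    c = np.zeros(n_tasks)
    c[task_id] = 1.0
    return c


# ---------------------------------------------------------------------------
# Hotelling's t-squared
# ---------------------------------------------------------------------------


@dataclass
class TTestResult:
    """Outcome of one unpaired multivariate t-test."""

    t2: float
    f: float
    p_value: float
    pooled_cov: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    reject: bool
    df: tuple[int, int] = (0, 0)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def hotellings_t2(X, Y) -> TTestResult:
    """Hotelling's t² for two independent sample batches (rows = samples).

    Uses the pooled sample covariance and its Moore–Penrose pseudo-inverse.
    Only the ``t2`` / mean / covariance fields are populated; use
    :func:`t2_to_f` (or :meth:`ContextStore.test_batch`) for the F transform
    and p-value.  Requires at least two samples per batch.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    if X.shape[1] != Y.shape[1]:
        raise InvalidInputError("X and Y must share dimensionality")
    nx, ny = X.shape[0], Y.shape[0]
    if nx < 2 or ny < 2:
        raise InvalidInputError("both batches need at least 2 samples")
    mean_x, mean_y = X.mean(axis=0), Y.mean(axis=0)
    Sx = np.cov(X, rowvar=False, ddof=1)
    Sy = np.cov(Y, rowvar=False, ddof=1)
    pooled = ((nx - 1) * np.atleast_2d(Sx) + (ny - 1) * np.atleast_2d(Sy)) / (nx + ny - 2)
    delta = mean_x - mean_y
    t2 = float(nx * ny / (nx + ny) * delta @ np.linalg.pinv(pooled) @ delta)
    t2 = max(t2, 0.0)  # guard tiny negative round-off
    return TTestResult(
        t2=t2, f=np.nan, p_value=np.nan, pooled_cov=pooled,
        mean_x=mean_x, mean_y=mean_y, reject=False,
    )


def t2_to_f(t2: float, n_x: int, n_y: int, d: int) -> float:
    """Transform t² to its F-distributed statistic.

    ``f = (n_x+n_y−d−1) / (d (n_x+n_y−2)) · t²`` with reference distribution
    F(d, n_x+n_y−d−1).  Requires ``n_x+n_y−d−1 > 0``; otherwise the test is
    degenerate and the caller should reduce dimensionality or pool more
    samples.
    """
    dof2 = n_x + n_y - d - 1
    if dof2 <= 0:
        raise DegenerateDimensionError(
            f"n_x+n_y-d-1 = {dof2} <= 0: too few samples for dimension {d}"
        )
    return float((dof2 / (d * (n_x + n_y - 2))) * t2)


def hotelling_test(X, Y, alpha: float = 1e-4) -> TTestResult:
    """Full two-sample test: t², F transform, p-value and reject decision."""
    res = hotellings_t2(X, Y)
    d = _as_matrix(X).shape[1]
    nx, ny = _as_matrix(X).shape[0], _as_matrix(Y).shape[0]
    f = t2_to_f(res.t2, nx, ny, d)
    dof2 = nx + ny - d - 1
    p = float(stats.f.sf(f, d, dof2))
    res.f, res.p_value, res.reject, res.df = f, p, p < alpha, (d, dof2)
    return res


# ---------------------------------------------------------------------------
# Context store (prototypes + online clustering state)
# ---------------------------------------------------------------------------


@dataclass
class ClusterStats:
    """Streaming sufficient statistics of one cluster plus a capped exemplar store.

    Count, mean and scatter (sum of squared deviations, Welford-style) are
    accumulated over *all* absorbed samples, so the t-test's pooled covariance
    never degrades however many exemplars the FIFO cap discards.
    """

    dim: int
    max_stored: int = 2048
    count: int = 0
    mean: np.ndarray = None
    scatter: np.ndarray = None
    samples: deque = field(default_factory=deque)

    def __post_init__(self):
        if self.mean is None:
            self.mean = np.zeros(self.dim)
        if self.scatter is None:
            self.scatter = np.zeros((self.dim, self.dim))

    def update(self, X: np.ndarray) -> None:
        """Merge a batch into the streaming statistics (Chan et al. pooling)."""
        X = _as_matrix(X)
        nb = X.shape[0]
        mb = X.mean(axis=0)
        dev = X - mb
        sb = dev.T @ dev
        if self.count == 0:
            self.count, self.mean, self.scatter = nb, mb, sb
        else:
            delta = mb - self.mean
            tot = self.count + nb
            self.scatter = self.scatter + sb + np.outer(delta, delta) * (self.count * nb / tot)
            self.mean = self.mean + delta * (nb / tot)
            self.count = tot
        for row in X:
            if len(self.samples) >= self.max_stored:
                self.samples.popleft()
            self.samples.append(np.array(row))

    @property
    def covariance(self) -> np.ndarray:
        if self.count < 2:
            raise StateError("cluster needs at least 2 samples for a covariance")
        return self.scatter / (self.count - 1)

    def sample_array(self) -> np.ndarray:
        return np.array(self.samples)


@dataclass
class ContextStore:
    """Prototype memory with optional task-free clustering state.

    ``prototypes[j]`` is always the element-wise mean of every sample absorbed
    by cluster j.  ``alpha`` is the per-test significance level of the
    batch-vs-cluster F-test; ``diag_cov=True`` replaces the full pooled
    covariance with its diagonal (a speed option for very high dimensions).
    """

    dim: int
    alpha: float = 1e-4
    max_stored_per_cluster: int = 2048
    diag_cov: bool = False
    prototypes: list = field(default_factory=list)
    clusters: list = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.prototypes)

    def __len__(self) -> int:
        return self.M

    def prototype_matrix(self) -> np.ndarray:
        if not self.prototypes:
            raise StateError("context store is empty")
        return np.array(self.prototypes)

    def add_task_prototype(self, samples: np.ndarray) -> int:
        """Task-aware path: create one cluster per task from its full training set."""
        X = _as_matrix(samples)
        cluster = ClusterStats(dim=self.dim, max_stored=self.max_stored_per_cluster)
        cluster.update(X)
        self.clusters.append(cluster)
        self.prototypes.append(cluster.mean.copy())
        return self.M - 1

    def test_batch(self, X: np.ndarray, j: int) -> TTestResult:
        """Unpaired multivariate t-test of batch X against cluster j.

        Works from the cluster's streaming statistics (count, mean, scatter),
        so the comparison covers every sample the cluster has absorbed.
        """
        X = _as_matrix(X)
        cl = self.clusters[j]
        nx, ny = X.shape[0], cl.count
        if nx < 2 or ny < 2:
            raise InvalidInputError("both batches need at least 2 samples")
        d = X.shape[1]
        mean_x = X.mean(axis=0)
        dev = X - mean_x
        pooled = (dev.T @ dev + cl.scatter) / (nx + ny - 2)
        delta = mean_x - cl.mean
        if self.diag_cov:
            var = np.diag(pooled).copy()
            inv_delta = np.where(var > 0, delta / np.where(var > 0, var, 1.0), 0.0)
            t2 = float(nx * ny / (nx + ny) * delta @ inv_delta)
        else:
            t2 = float(nx * ny / (nx + ny) * delta @ np.linalg.pinv(pooled) @ delta)
        t2 = max(t2, 0.0)
        f = t2_to_f(t2, nx, ny, d)
        dof2 = nx + ny - d - 1
        p = float(stats.f.sf(f, d, dof2))
        return TTestResult(
            t2=t2, f=f, p_value=p, pooled_cov=pooled, mean_x=mean_x,
            mean_y=cl.mean.copy(), reject=p < self.alpha, df=(d, dof2),
        )

    def save(self, path) -> None:
        arrays = {
            "meta": np.array([self.dim, self.M, self.max_stored_per_cluster]),
            "alpha": np.array([self.alpha]),
            "diag_cov": np.array([int(self.diag_cov)]),
        }
        for j, (p, cl) in enumerate(zip(self.prototypes, self.clusters)):
            arrays[f"proto{j}"] = np.asarray(p)
            arrays[f"count{j}"] = np.array([cl.count])
            arrays[f"mean{j}"] = cl.mean
            arrays[f"scatter{j}"] = cl.scatter
            arrays[f"samples{j}"] = cl.sample_array()
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "ContextStore":
        with np.load(path) as data:
            dim, M, cap = (int(v) for v in data["meta"])
            store = cls(
                dim=dim,
                alpha=float(data["alpha"][0]),
                max_stored_per_cluster=cap,
                diag_cov=bool(data["diag_cov"][0]),
            )
            for j in range(M):
                cl = ClusterStats(dim=dim, max_stored=cap)
                cl.count = int(data[f"count{j}"][0])
                cl.mean = data[f"mean{j}"]
                cl.scatter = data[f"scatter{j}"]
                cl.samples = deque(np.array(data[f"samples{j}"]))
                store.clusters.append(cl)
                store.prototypes.append(data[f"proto{j}"])
        return store


def assign_batch(X: np.ndarray, store: ContextStore) -> tuple[int, bool]:
    """Assign a batch to the first matching cluster, or create a new one.

    Clusters are scanned greedily in creation order; the first whose t-test
    fails to reject absorbs X (its prototype is then recomputed over the
    enlarged sample set).  If every test rejects — or no clusters exist — a
    new cluster is created with prototype mean(X).  Assumes the batch is drawn
    from a single task.  Returns ``(cluster_index, created)``.
    """
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise InvalidInputError("cannot assign an empty batch")
    for j in range(store.M):
        if not store.test_batch(X, j).reject:
            store.clusters[j].update(X)
            store.prototypes[j] = store.clusters[j].mean.copy()
            return j, False
    cluster = ClusterStats(dim=store.dim, max_stored=store.max_stored_per_cluster)
    cluster.update(X)
    store.clusters.append(cluster)
    store.prototypes.append(cluster.mean.copy())
    return store.M - 1, True
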