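"""Permuted-task continual-learning streams.

A stream is an ordered list of tasks related by pixel-wise permutation: task 1
is the base data under the identity permutation, and every later task applies
one fixed random permutation to all of the base images (train and test alike),
preserving labels.  Because networks are not permutation-invariant, each task
presents a distinct input distribution while sharing the same class structure,
which is what makes sequential training forget.

Two constructors are provided: :func:`build_permuted_tasks` wraps user-supplied
MNIST IDX files (or any flattened image array scaled to [0, 1]) into a
permuted stream, and :func:`generate_synthetic_stream` draws a Gaussian
task family with the same statistical structure — balanced classes, a shared
non-constant base pattern so tasks are separable by input mean, and class
means separated by a configurable multiple of the noise scale — so the whole
package builds and tests without downloading anything.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError, InvalidInputError

__all__ = [
    "Task",
    "TaskStream",
    "build_permuted_tasks",
    "generate_synthetic_stream",
    "read_idx",
    "write_idx",
    "load_mnist_stream",
]


@dataclass
class Task:
    task_id: int
    permutation: np.ndarray           # length-d index vector; task 0 is identity
    train_x: np.ndarray
    train_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray


@dataclass
class TaskStream:
    tasks: list[Task] = field(default_factory=list)
    seed: int = 0

    @property
    def T(self) -> int:
        return len(self.tasks)

    @property
    def dim(self) -> int:
        return self.tasks[0].train_x.shape[1]

    @property
    def n_classes(self) -> int:
        return int(max(t.train_y.max() for t in self.tasks)) + 1

    def __iter__(self):
        return iter(self.tasks)

    def __getitem__(self, i) -> Task:
        return self.tasks[i]

    def save(self, path) -> None:
        arrays = {"seed": np.array([self.seed]), "T": np.array([self.T])}
        for t in self.tasks:
            i = t.task_id
            arrays[f"perm{i}"] = t.permutation
            arrays[f"train_x{i}"] = t.train_x
            arrays[f"train_y{i}"] = t.train_y
            arrays[f"test_x{i}"] = t.test_x
            arrays[f"test_y{i}"] = t.test_y
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "TaskStream":
        with np.load(path) as data:
            stream = cls(seed=int(data["seed"][0]))
            for i in range(int(data["T"][0])):
                stream.tasks.append(
                    Task(
                        task_id=i,
                        permutation=data[f"perm{i}"],
                        train_x=data[f"train_x{i}"],
                        train_y=data[f"train_y{i}"],
                        test_x=data[f"test_x{i}"],
                        test_y=data[f"test_y{i}"],
                    )
                )
        return stream


def _task_permutations(dim: int, T: int, seed: int) -> list[np.ndarray]:
    """Identity for task 0, then fresh seeded Fisher-Yates permutations.

    Per-task sub-seeds derive from the master seed by fixed spawn offsets, so
    extending a stream never changes earlier tasks.
    """
    perms = [np.arange(dim)]
    for tau in range(1, T):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tau,)))
        perms.append(rng.permutation(dim))
    return perms


def build_permuted_tasks(
    images: np.ndarray,
    labels: np.ndarray,
    T: int,
    seed: int,
    test_images: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    holdout: int = 0,
) -> TaskStream:
    """Build a T-task permuted stream from flattened base images in [0, 1].

    Each task applies one permutation to both its train and test images; task
    1 (index 0) is the identity.  If no separate test set is given, the last
    ``holdout`` base images are split off for testing (e.g. 10,000 for a
    50k/10k split of the 60k MNIST training set).
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if T < 1:
        raise InvalidInputError("T must be at least 1")
    if images.ndim != 2:
        raise InvalidInputError("images must be flattened to (n, d)")
    if images.shape[0] != labels.shape[0]:
        raise InvalidInputError("images and labels length mismatch")
    if test_images is None:
        if holdout > 0:
            test_images, test_labels = images[-holdout:], labels[-holdout:]
            images, labels = images[:-holdout], labels[:-holdout]
        else:
            test_images, test_labels = images, labels
    else:
        test_images = np.asarray(test_images)
        test_labels = np.asarray(test_labels)
        if test_images.shape[0] != test_labels.shape[0]:
            raise InvalidInputError("test images and labels length mismatch")

    dim = images.shape[1]
    stream = TaskStream(seed=seed)
    for tau, perm in enumerate(_task_permutations(dim, T, seed)):
        stream.tasks.append(
            Task(
                task_id=tau,
                permutation=perm,
                train_x=images[:, perm],
                train_y=labels.copy(),
                test_x=test_images[:, perm],
                test_y=test_labels.copy(),
            )
        )
    return stream


def generate_synthetic_stream(
    n_classes: int = 10,
    dim: int = 128,
    T: int = 5,
    class_separation: float = 5.0,
    noise_sd: float = 1.0,
    n_train: int = 5000,
    n_test: int = 1000,
    seed: int = 0,
) -> TaskStream:
    """Gaussian task family mirroring the structure of permuted image streams.

    The base task draws each class from an isotropic Gaussian
    N(g + delta_c, noise_sd² I) with sep = class_separation·noise_sd:

    * ``g`` is a shared *sparse* base pattern — a random eighth of the
      coordinates is "bright", uniform on (sep, 2·sep), the rest zero — the
      analogue of the bright-foreground/dark-background structure all digit
      images share.  Permuting a sparse pattern moves its support, so
      distinct tasks have well-separated, weakly correlated input means
      (as permuted digit tasks do), which is what nearest-prototype routing
      and dendritic context discrimination both rely on.
    * ``delta_c`` is supported on a random quarter of the coordinates per
      class (class information is localised, as digit strokes are) with
      Gaussian amplitude sep/2, rescaled up if needed so the minimum
      pairwise class-mean distance is at least sep.

    Classes are exactly balanced; tasks tau > 1 permute the base samples
    coordinate-wise, exactly as a permuted image stream would.
    """
    if dim < n_classes:
        raise InvalidInputError("dim must be at least n_classes")
    if n_train < n_classes or n_test < n_classes or T < 1:
        raise InvalidInputError("invalid counts")
    if n_train % n_classes or n_test % n_classes:
        raise InvalidInputError("n_train and n_test must be multiples of n_classes")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    sep = class_separation * noise_sd
    n_bright = max(1, dim // 8)
    base_pattern = np.zeros(dim)
    bright = rng.choice(dim, size=n_bright, replace=False)
    base_pattern[bright] = rng.uniform(sep, 2.0 * sep, size=n_bright)
    n_support = max(1, dim // 4)
    offsets = np.zeros((n_classes, dim))
    for cls in range(n_classes):
        support = rng.choice(dim, size=n_support, replace=False)
        offsets[cls, support] = rng.normal(0.0, sep / 2.0, size=n_support)
    dmat = np.linalg.norm(offsets[:, None, :] - offsets[None, :, :], axis=2)
    min_dist = dmat[np.triu_indices(n_classes, k=1)].min()
    if min_dist < sep:
        offsets *= sep / min_dist
    class_means = base_pattern[None, :] + offsets

    def draw(n_per_class: int, sub: int) -> tuple[np.ndarray, np.ndarray]:
        r = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, sub)))
        xs, ys = [], []
        for cls in range(n_classes):
            xs.append(r.normal(class_means[cls], noise_sd, size=(n_per_class, dim)))
            ys.append(np.full(n_per_class, cls, dtype=np.int64))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        order = r.permutation(x.shape[0])
        return x[order], y[order]

    train_x, train_y = draw(n_train // n_classes, 1)
    test_x, test_y = draw(n_test // n_classes, 2)

    stream = TaskStream(seed=seed)
    for tau, perm in enumerate(_task_permutations(dim, T, seed)):
        stream.tasks.append(
            Task(
                task_id=tau,
                permutation=perm,
                train_x=train_x[:, perm],
                train_y=train_y.copy(),
                test_x=test_x[:, perm],
                test_y=test_y.copy(),
            )
        )
    return stream


# ---------------------------------------------------------------------------
# IDX (MNIST distribution format)
# ---------------------------------------------------------------------------

_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def read_idx(path) -> np.ndarray:
    """Read an IDX binary file (big-endian magic, dims, then the payload)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise FormatError("IDX file shorter than its 4-byte magic")
    zero1, zero2, dcode, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or dcode not in _IDX_DTYPES:
        raise FormatError(f"bad IDX magic bytes {raw[:4]!r}")
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise FormatError("IDX header truncated")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    dtype = _IDX_DTYPES[dcode]
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = raw[header_len:]
    if len(payload) != expected:
        raise FormatError(
            f"IDX payload has {len(payload)} bytes, expected {expected}"
        )
    arr = np.frombuffer(payload, dtype=dtype).reshape(dims)
    return arr.astype(dtype.newbyteorder("="))


def write_idx(path, array: np.ndarray) -> None:
    """Write an array in IDX format (inverse of :func:`read_idx`)."""
    array = np.asarray(array)
    code = {
        ("u", 1): 0x08, ("i", 1): 0x09, ("i", 2): 0x0B,
        ("i", 4): 0x0C, ("f", 4): 0x0D, ("f", 8): 0x0E,
    }.get((array.dtype.kind, array.dtype.itemsize))
    if code is None:
        raise FormatError(f"dtype {array.dtype} not representable in IDX")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, array.ndim))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.astype(_IDX_DTYPES[code]).tobytes())


def load_mnist_stream(
    train_images_path,
    train_labels_path,
    T: int,
    seed: int,
    test_images_path=None,
    test_labels_path=None,
    holdout: int = 10000,
) -> TaskStream:
    """Build a permuted stream from MNIST-style IDX files.

    Pixels are flattened and scaled to [0, 1] (no mean-centering, so that
    prototypes live in the input domain).  If the standard test files are not
    supplied, the last ``holdout`` training images form the test split.
    """
    images = read_idx(train_images_path)
    labels = read_idx(train_labels_path).astype(np.int64)
    images = images.reshape(images.shape[0], -1).astype(np.float64) / 255.0
    test_images = test_labels = None
    hold = holdout
    if test_images_path is not None:
        test_images = read_idx(test_images_path)
        test_images = test_images.reshape(test_images.shape[0], -1).astype(np.float64) / 255.0
        test_labels = read_idx(test_labels_path).astype(np.int64)
        hold = 0
    return build_permuted_tasks(
        images, labels, T, seed,
        test_images=test_images, test_labels=test_labels, holdout=hold,
    )
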