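"""Self-organizing feature map (Kohonen SOM) on a rectangular lattice.

Implements the map from scratch as a scikit-learn style estimator:
random or data-sampled initialization, best-matching-unit (BMU) search
under the Euclidean metric, Gaussian or bubble neighborhood kernel, batch
and sequential training with a linearly decaying neighborhood radius, and
the quantization error as the goodness-of-fit measure.

Training follows the classical two-phase recipe: a rough phase in which the
radius shrinks linearly from ``radius_initial`` to ``radius_final``, then a
fine phase at the final radius.  The batch update sets each codebook vector
to the neighborhood-weighted mean of the data,

    w_j  <-  sum_i h(j, bmu(x_i)) x_i  /  sum_i h(j, bmu(x_i)),

where ``h`` is the kernel evaluated on the lattice distance between neuron
``j`` and the sample's BMU; neurons receiving zero total neighborhood mass
keep their previous weights.  The sequential rule is the online update
``w_j += alpha h (x - w_j)`` with a linearly decaying learning rate and a
seeded random presentation order per epoch.  Ties in the BMU search break
to the lowest row-major neuron index, so runs are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

Kernel = Literal["gaussian", "bubble"]
Mode = Literal["batch", "sequential"]


@dataclass(frozen=True)
class RadiusSchedule:
    """Linear neighborhood-radius decay from ``initial`` to ``final`` over
    ``n_epochs`` epochs (endpoints included)."""

    initial: float
    final: float
    n_epochs: int

    def __post_init__(self) -> None:
        if not (self.initial >= self.final > 0):
            raise ValueError("radii must satisfy initial >= final > 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    def radius_at(self, epoch: int) -> float:
        if self.n_epochs == 1:
            return self.final
        t = epoch / (self.n_epochs - 1)
        return self.initial + (self.final - self.initial) * t

    def radii(self) -> np.ndarray:
        return np.array([self.radius_at(e) for e in range(self.n_epochs)])


@dataclass(frozen=True)
class LearningRateSchedule:
    """Linear learning-rate decay (sequential mode only)."""

    initial: float = 0.5
    final: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.final <= 1 and 0 < self.initial <= 1):
            raise ValueError("learning rates must lie in (0, 1]")

    def rate_at(self, step: int, total_steps: int) -> float:
        if total_steps <= 1:
            return self.final
        t = step / (total_steps - 1)
        return self.initial + (self.final - self.initial) * t


def _grid_coordinates(n_rows: int, n_cols: int) -> np.ndarray:
    """Integer (row, col) coordinates of each neuron in row-major order."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


def _grid_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean lattice distances between neurons."""
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def kernel_weights(grid_dist: np.ndarray, radius: float,
                   kernel: Kernel = "gaussian") -> np.ndarray:
    """Neighborhood weight h in [0, 1] for each lattice distance.

    Gaussian: exp(-d^2 / (2 radius^2)); bubble: 1 if d <= radius else 0.
    """
    if radius <= 0:
        raise ValueError("neighborhood radius must be > 0")
    if kernel == "gaussian":
        return np.exp(-(grid_dist ** 2) / (2.0 * radius ** 2))
    if kernel == "bubble":
        return (grid_dist <= radius).astype(float)
    raise ValueError(f"unknown kernel {kernel!r}")


class SelfOrganizingMap(BaseEstimator):
    """Batch/sequential SOM on an ``n_rows`` x ``n_cols`` rectangular lattice.

    Parameters
    ----------
    n_rows, n_cols
        Output-map dimensions (e.g. 12 x 10 for the study-scale map).
    radius_initial, radius_final
        Endpoints of the linear neighborhood-radius schedule (default 4 -> 1).
    n_epochs_rough, n_epochs_fine
        Epoch counts of the shrinking-radius and constant-radius phases.
    kernel
        ``gaussian`` (default) or ``bubble`` neighborhood kernel.
    mode
        ``batch`` (default; ignores the learning rate) or ``sequential``.
    lr_initial, lr_final
        Learning-rate schedule for sequential mode.
    init
        ``sample`` draws initial codebook vectors from the data (with
        replacement); ``uniform_random`` draws uniformly on the per-feature
        data range.
    dtype
        Floating dtype of the codebook (float32 is ample for binary images).
    random_state
        Seed for initialization and sample presentation order.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_rows * n_cols, n_features)
        Trained weight vectors, row-major neuron order.
    quantization_errors_ : list of float
        Quantization error logged after every training epoch.
    """

    def __init__(self, n_rows: int = 12, n_cols: int = 10, *,
                 radius_initial: float = 4.0, radius_final: float = 1.0,
                 n_epochs_rough: int = 10, n_epochs_fine: int = 40,
                 kernel: Kernel = "gaussian", mode: Mode = "batch",
                 lr_initial: float = 0.5, lr_final: float = 0.01,
                 init: Literal["sample", "uniform_random"] = "sample",
                 dtype: type = np.float32,
                 random_state: int | None = None) -> None:
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.radius_initial = radius_initial
        self.radius_final = radius_final
        self.n_epochs_rough = n_epochs_rough
        self.n_epochs_fine = n_epochs_fine
        self.kernel = kernel
        self.mode = mode
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.init = init
        self.dtype = dtype
        self.random_state = random_state

    # -- lattice helpers ---------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return self.n_rows * self.n_cols

    def grid_coordinates(self) -> np.ndarray:
        return _grid_coordinates(self.n_rows, self.n_cols)

    def grid_distances(self) -> np.ndarray:
        return _grid_distances(self.grid_coordinates())

    def neighborhood_weights(self, bmu: int, radius: float) -> np.ndarray:
        """Kernel weight of every neuron relative to one BMU."""
        d = self.grid_distances()[bmu]
        return kernel_weights(d, radius, self.kernel)

    def schedules(self) -> list[RadiusSchedule]:
        """The two-phase radius schedule implied by the parameters."""
        out = []
        if self.n_epochs_rough > 0:
            out.append(RadiusSchedule(self.radius_initial, self.radius_final,
                                      self.n_epochs_rough))
        if self.n_epochs_fine > 0:
            out.append(RadiusSchedule(self.radius_final, self.radius_final,
                                      self.n_epochs_fine))
        if not out:
            raise ValueError("at least one training epoch is required")
        return out

    # -- core --------------------------------------------------------------

    def _init_codebook(self, X: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        if self.init == "sample":
            idx = rng.integers(0, X.shape[0], size=self.n_neurons)
            return X[idx].astype(self.dtype).copy()
        if self.init == "uniform_random":
            lo, hi = X.min(axis=0), X.max(axis=0)
            return rng.uniform(lo, hi, size=(self.n_neurons, X.shape[1])
                               ).astype(self.dtype)
        raise ValueError(f"unknown init {self.init!r}")

    @staticmethod
    def _bmu_indices(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Row-wise BMU of each sample (ties -> lowest row-major index)."""
        # squared distances via |x|^2 - 2 x.w + |w|^2; argmin is tie-stable
        d2 = (np.einsum("ij,ij->i", codebook, codebook)[None, :]
              - 2.0 * X @ codebook.T)
        return np.argmin(d2, axis=1)

    def fit(self, X, y=None) -> "SelfOrganizingMap":
        X = check_array(X, dtype=self.dtype)
        if X.shape[0] < 1:
            raise ValueError("training data must contain at least one vector")
        rng = np.random.default_rng(self.random_state)
        codebook = self._init_codebook(X, rng)
        self.initial_codebook_ = codebook.copy()
        grid_d = self.grid_distances()

        log: list[float] = []
        if self.mode == "batch":
            for sched in self.schedules():
                for e in range(sched.n_epochs):
                    codebook = self._batch_epoch(
                        codebook, X, grid_d, sched.radius_at(e))
                    log.append(_quantization_error(codebook, X))
        elif self.mode == "sequential":
            lr = LearningRateSchedule(self.lr_initial, self.lr_final)
            total = sum(s.n_epochs for s in self.schedules()) * X.shape[0]
            step = 0
            for sched in self.schedules():
                for e in range(sched.n_epochs):
                    radius = sched.radius_at(e)
                    order = rng.permutation(X.shape[0])
                    for i in order:
                        bmu = int(self._bmu_indices(codebook, X[i:i + 1])[0])
                        h = kernel_weights(grid_d[bmu], radius, self.kernel)
                        alpha = lr.rate_at(step, total)
                        codebook += (alpha * h)[:, None] * (X[i] - codebook)
                        step += 1
                    log.append(_quantization_error(codebook, X))
        else:
            raise ValueError(f"unknown training mode {self.mode!r}")

        self.codebook_ = codebook
        self.quantization_errors_ = log
        self.n_features_in_ = X.shape[1]
        self.labels_ = self._bmu_indices(codebook, X)
        self.trained_ = True
        return self

    def _batch_epoch(self, codebook: np.ndarray, X: np.ndarray,
                     grid_d: np.ndarray, radius: float) -> np.ndarray:
        bmu = self._bmu_indices(codebook, X)
        K = kernel_weights(grid_d, radius, self.kernel).astype(codebook.dtype)
        H = K[:, bmu]                       # (n_neurons, n_samples)
        mass = H.sum(axis=1)
        num = H @ X
        new = codebook.copy()
        nz = mass > 0
        new[nz] = num[nz] / mass[nz, None]
        return new

    # -- fitted API --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Best-matching-unit (row-major neuron index) of each sample."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=self.codebook_.dtype)
        if X.shape[1] != self.codebook_.shape[1]:
            raise ValueError(
                f"dimension mismatch: data has {X.shape[1]} features, "
                f"codebook has {self.codebook_.shape[1]}")
        return self._bmu_indices(self.codebook_, X)

    def transform(self, X) -> np.ndarray:
        """Euclidean distance of each sample to every codebook vector."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=self.codebook_.dtype)
        d2 = ((X ** 2).sum(1)[:, None] - 2.0 * X @ self.codebook_.T
              + (self.codebook_ ** 2).sum(1)[None, :])
        return np.sqrt(np.maximum(d2, 0.0))

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of samples to their BMU."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=self.codebook_.dtype)
        if X.shape[0] == 0:
            raise ValueError("quantization error is undefined on empty data")
        return _quantization_error(self.codebook_, X)

    @property
    def trained(self) -> bool:
        """True once :meth:`fit` has run (an initialized-only codebook,
        e.g. from :func:`init_model`, does not count as trained)."""
        return getattr(self, "trained_", False)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize the fitted map: a JSON header (grid dims + schedule)
        and the codebook, round-trip exact."""
        check_is_fitted(self, "codebook_")
        path = Path(path)
        header = json.dumps({"params": {k: (v if not isinstance(v, type)
                                            else np.dtype(v).name)
                                        for k, v in self.get_params().items()},
                             "qe_log": self.quantization_errors_})
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 codebook=self.codebook_)
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "SelfOrganizingMap":
        with np.load(Path(path)) as npz:
            header = json.loads(npz["header"].tobytes().decode())
            codebook = npz["codebook"]
        params = header["params"]
        params["dtype"] = np.dtype(params["dtype"]).type
        model = cls(**params)
        model.codebook_ = codebook
        model.quantization_errors_ = list(header["qe_log"])
        model.n_features_in_ = codebook.shape[1]
        model.trained_ = True
        return model


def _quantization_error(codebook: np.ndarray, X: np.ndarray) -> float:
    d2 = ((X ** 2).sum(1)[:, None] - 2.0 * X @ codebook.T
          + (codebook ** 2).sum(1)[None, :])
    return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0)).mean())


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def init_model(rows: int, cols: int, dim: int, *,
               mode: Literal["sample", "uniform_random"] = "uniform_random",
               data: np.ndarray | None = None,
               seed: int | None = None) -> SelfOrganizingMap:
    """Build an initialized (untrained) map with a seeded codebook."""
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    model = SelfOrganizingMap(rows, cols, init=mode, random_state=seed,
                              dtype=np.float64)
    rng = np.random.default_rng(seed)
    if mode == "sample":
        if data is None:
            raise ValueError("init mode 'sample' requires a dataset")
        data = np.asarray(data, dtype=float)
        if data.shape[1] != dim:
            raise ValueError(
                f"data dimension {data.shape[1]} does not match dim={dim}")
        model.codebook_ = model._init_codebook(data, rng)
    else:
        model.codebook_ = rng.uniform(0, 1, size=(rows * cols, dim))
    model.n_features_in_ = dim
    model.quantization_errors_ = []
    return model


def find_bmu(model: SelfOrganizingMap, x: np.ndarray) -> int:
    """Index of the codebook vector nearest to ``x`` (ties -> lowest index)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.codebook_.shape[1]:
        raise ValueError("dimension mismatch between x and codebook")
    return int(model._bmu_indices(model.codebook_, x[None, :])[0])


def neighborhood_weights(model: SelfOrganizingMap, bmu: int,
                         radius: float) -> np.ndarray:
    return model.neighborhood_weights(bmu, radius)


def train(model: SelfOrganizingMap, data: np.ndarray,
          radius_schedule: RadiusSchedule | Sequence[RadiusSchedule] | None = None,
          mode: Mode | None = None,
          lr_schedule: LearningRateSchedule | None = None,
          seed: int | None = None) -> SelfOrganizingMap:
    """Train a (fresh clone of the) model on data; returns the fitted clone."""
    params = model.get_params()
    if radius_schedule is not None:
        scheds = ([radius_schedule] if isinstance(radius_schedule, RadiusSchedule)
                  else list(radius_schedule))
        params["radius_initial"] = scheds[0].initial
        params["radius_final"] = scheds[-1].final
        params["n_epochs_rough"] = scheds[0].n_epochs
        params["n_epochs_fine"] = sum(s.n_epochs for s in scheds[1:])
    if mode is not None:
        params["mode"] = mode
    if lr_schedule is not None:
        params["lr_initial"] = lr_schedule.initial
        params["lr_final"] = lr_schedule.final
    if seed is not None:
        params["random_state"] = seed
    return SelfOrganizingMap(**params).fit(np.asarray(data, dtype=float))


def quantization_error(model: SelfOrganizingMap, data: np.ndarray) -> float:
    return model.quantization_error(np.asarray(data, dtype=float))
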