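"""U-matrix computation and cluster delineation on the SOM lattice.

The u-matrix assigns each neuron the mean Euclidean distance between its
codebook vector and those of its lattice-adjacent neurons (4-neighborhood;
corners average over 2 neighbors, edges over 3).  Low "valleys" are regions
of similar codebook vectors — clusters — while high "ridges" separate them.

Cluster delineation is automated here (it is commonly done by eye on the
color-coded u-matrix): either a quantile threshold, where neurons at or
below the ``q``-quantile of u-values seed 4-connected cluster regions and
the remaining neurons stay unlabeled ridge, or a watershed flood from the
u-matrix minima, which labels every neuron.  Held-out components are
assigned to the cluster of their best-matching unit; a BMU on a ridge falls
back to the nearest labeled neuron by lattice distance (ties to the lower
cluster id).  No codebook learning occurs at assignment time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import h_minima, local_minima
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClusterMixin

from .som import SelfOrganizingMap


# ---------------------------------------------------------------------------
# U-matrix
# ---------------------------------------------------------------------------

def umatrix(model: SelfOrganizingMap) -> np.ndarray:
    """Per-neuron mean codebook distance to 4-neighbors, as an
    (n_rows, n_cols) grid."""
    if not model.trained:
        warnings.warn("computing a u-matrix on an untrained map",
                      stacklevel=2)
    rows, cols = model.n_rows, model.n_cols
    W = model.codebook_.reshape(rows, cols, -1).astype(np.float64)
    total = np.zeros((rows, cols))
    count = np.zeros((rows, cols))
    # vertical and horizontal neighbor distances
    dv = np.linalg.norm(W[1:, :] - W[:-1, :], axis=-1)
    dh = np.linalg.norm(W[:, 1:] - W[:, :-1], axis=-1)
    total[1:, :] += dv
    total[:-1, :] += dv
    count[1:, :] += 1
    count[:-1, :] += 1
    total[:, 1:] += dh
    total[:, :-1] += dh
    count[:, 1:] += 1
    count[:, :-1] += 1
    count[count == 0] = 1  # degenerate 1x1 map
    return total / count


@dataclass(frozen=True)
class ClusterMap:
    """Neuron -> cluster labeling of the lattice.

    ``labels`` is an (n_rows, n_cols) integer grid; cluster ids run
    contiguously from 1 and 0 marks unlabeled ridge neurons.  Every cluster
    is a 4-connected region; ids are ordered by each region's minimum
    row-major neuron index, so the labeling is stable across runs.
    """

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        present = np.unique(lab[lab > 0])
        if len(present) != self.n_clusters or (
                len(present) and present[-1] != self.n_clusters):
            raise ValueError("cluster ids must be contiguous from 1")

    def cluster_of(self, neuron_index: int) -> int:
        return int(self.labels.ravel()[neuron_index])

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.labels.shape
        rr, cc = np.meshgrid(range(rows), range(cols), indexing="ij")
        return pd.DataFrame({"neuron_row": rr.ravel(), "neuron_col": cc.ravel(),
                             "cluster_id": self.labels.ravel()})


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _relabel_stable(raw: np.ndarray) -> ClusterMap:
    """Relabel regions contiguously from 1, ordered by min row-major index."""
    ids = [i for i in np.unique(raw) if i > 0]
    order = sorted(ids, key=lambda i: int(np.flatnonzero(raw.ravel() == i)[0]))
    labels = np.zeros_like(raw, dtype=int)
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return ClusterMap(labels=labels, n_clusters=len(order))


def delineate_clusters(u: np.ndarray,
                       method: Literal["threshold", "watershed"] = "threshold",
                       q: float = 0.5,
                       merge_tolerance: float = 0.0) -> ClusterMap:
    """Extract a ClusterMap from a u-matrix.

    ``threshold``: neurons with u <= quantile(u, q) seed 4-connected
    components; ridge neurons stay unlabeled.  ``watershed``: flood from the
    local minima of the u-matrix (after suppressing minima shallower than
    ``merge_tolerance``), labeling every neuron.  Both are deterministic.
    """
    u = np.asarray(u, dtype=float)
    if method == "threshold":
        if not (0.0 < q <= 1.0):
            raise ValueError("quantile q must lie in (0, 1]")
        cut = np.quantile(u, q)
        seeds = u <= cut
        raw, _ = ndimage.label(seeds, structure=_FOUR_CONN)
        return _relabel_stable(raw)
    if method == "watershed":
        if merge_tolerance > 0:
            basins = u + 0.0
            suppressed = h_minima(basins, merge_tolerance,
                                  footprint=_FOUR_CONN)
            markers, _ = ndimage.label(suppressed, structure=_FOUR_CONN)
        else:
            markers, _ = ndimage.label(
                local_minima(u, footprint=_FOUR_CONN, allow_borders=True),
                structure=_FOUR_CONN)
        raw = watershed(u, markers=markers, connectivity=_FOUR_CONN)
        return _relabel_stable(raw)
    raise ValueError(f"unknown delineation method {method!r}")


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_cluster(model: SelfOrganizingMap, clustermap: ClusterMap,
                   x: np.ndarray) -> int:
    """Cluster id of one component: its BMU's cluster, or — for a ridge
    BMU — the id of the nearest labeled neuron by lattice distance
    (ties -> lower cluster id)."""
    return int(assign_clusters(model, clustermap, np.atleast_2d(x))[0])


def assign_clusters(model: SelfOrganizingMap, clustermap: ClusterMap,
                    X: np.ndarray) -> np.ndarray:
    bmus = model.predict(X)
    flat = clustermap.labels.ravel()
    out = np.empty(len(bmus), dtype=int)
    labeled = np.flatnonzero(flat > 0)
    if labeled.size == 0:
        raise ValueError("cluster map contains no labeled neurons")
    coords = model.grid_coordinates()
    for i, b in enumerate(bmus):
        if flat[b] > 0:
            out[i] = flat[b]
        else:
            d = np.linalg.norm(coords[labeled] - coords[b], axis=1)
            nearest = labeled[d == d.min()]
            out[i] = int(flat[nearest].min())
    return out


def composition_table(assignments: Sequence[int],
                      metadata: pd.DataFrame,
                      retrieved_sources: tuple[str, ...] = ("revision",
                                                            "postmortem")
                      ) -> pd.DataFrame:
    """Cluster-by-source counts plus the fraction of retrieved components
    (revision + postmortem) that landed in each cluster."""
    sources = metadata["source"].to_numpy()
    known = set(retrieved_sources) | {"simulator"}
    unknown = set(sources) - known
    if unknown:
        raise ValueError(f"unknown source label(s): {sorted(unknown)}")
    df = pd.DataFrame({"cluster": list(assignments), "source": sources})
    counts = (df.groupby(["cluster", "source"]).size()
              .unstack(fill_value=0))
    for s in sorted(known):
        if s not in counts.columns:
            counts[s] = 0
    counts = counts[sorted(counts.columns)]
    n_retrieved = int(np.isin(sources, retrieved_sources).sum())
    retr = counts[list(retrieved_sources)].sum(axis=1)
    counts["retrieved_fraction"] = retr / max(n_retrieved, 1)
    counts["total"] = counts[sorted(known)].sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class SOMClusterer(BaseEstimator, ClusterMixin):
    """SOM training + u-matrix delineation as one sklearn clusterer.

    ``fit(X)`` trains a :class:`SelfOrganizingMap` on X and delineates
    clusters on its u-matrix; ``predict(X)`` assigns (held-out) samples to
    the existing clusters without further learning — the reference-cohort /
    held-out design of retrieval studies.
    """

    def __init__(self, *, n_rows: int = 12, n_cols: int = 10,
                 radius_initial: float = 4.0, radius_final: float = 1.0,
                 n_epochs_rough: int = 10, n_epochs_fine: int = 40,
                 kernel: str = "gaussian", mode: str = "batch",
                 method: str = "threshold", q: float = 0.5,
                 merge_tolerance: float = 0.0,
                 random_state: int | None = None) -> None:
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.radius_initial = radius_initial
        self.radius_final = radius_final
        self.n_epochs_rough = n_epochs_rough
        self.n_epochs_fine = n_epochs_fine
        self.kernel = kernel
        self.mode = mode
        self.method = method
        self.q = q
        self.merge_tolerance = merge_tolerance
        self.random_state = random_state

    def fit(self, X, y=None) -> "SOMClusterer":
        self.som_ = SelfOrganizingMap(
            self.n_rows, self.n_cols,
            radius_initial=self.radius_initial,
            radius_final=self.radius_final,
            n_epochs_rough=self.n_epochs_rough,
            n_epochs_fine=self.n_epochs_fine,
            kernel=self.kernel, mode=self.mode,
            random_state=self.random_state,
        ).fit(X)
        self.umatrix_ = umatrix(self.som_)
        self.clustermap_ = delineate_clusters(
            self.umatrix_, self.method, q=self.q,
            merge_tolerance=self.merge_tolerance)
        self.labels_ = assign_clusters(self.som_, self.clustermap_, X)
        return self

    def predict(self, X) -> np.ndarray:
        return assign_clusters(self.som_, self.clustermap_, X)
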