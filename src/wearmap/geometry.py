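"""Geometric wear-scar descriptors and post-hoc statistics.

Descriptors are computed per compartment (medial = right canvas half of a
right-normalized image, lateral = left half) from the worn-pixel set:

* area (mm^2): worn-pixel count times pixel area;
* perimeter (mm): Crofton-formula estimate (4 projection directions) of
  the worn/unworn boundary length, the standard raster perimeter whose
  estimate converges to the true length for smooth blobs;
* centroid (mm): worn-pixel mean position relative to the compartment
  center, anterior positive along AP, medial-edge positive along ML;
* ML / AP stretch (mm): bounding-box extents along each axis;
* second area moments I_ap, I_ml (mm^4) about the centroid axes;
* shape factors: circularity 4 pi A / P^2 (1 for a disk), aspect ratio of
  the stretches, and solidity (area / bounding-box area);
* a whole-component symmetry index in [0, 1] combining medial/lateral area
  balance with the AP alignment of the two centroids.

The statistics mirror a retrieval-study workflow: one-way ANOVA of each
descriptor across clusters (singleton clusters excluded), per-cluster OLS
regression of descriptors on the covariates time-in-host and
age-at-surgery restricted to clusters with more than three components with
known covariate, flagged when p < 0.05 and R^2 > 0.4, and an exact
binomial tail probability for cluster enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skimage import measure

from .images import WearScarImage

#: regression flagging rule: significant and meaningful
P_FLAG = 0.05
R2_FLAG = 0.4
#: per-cluster covariate inclusion rule: more than three known values
MIN_COVARIATE_N = 4


@dataclass(frozen=True)
class CompartmentDescriptors:
    """Geometric parameters of one compartment's scar."""

    area_mm2: float
    perimeter_mm: float
    centroid_ml_mm: float
    centroid_ap_mm: float
    bbox_ml_min_mm: float
    bbox_ml_max_mm: float
    bbox_ap_min_mm: float
    bbox_ap_max_mm: float
    ml_stretch_mm: float
    ap_stretch_mm: float
    i_ap_mm4: float
    i_ml_mm4: float
    shape_factor: float
    aspect_ratio: float
    solidity: float
    empty: bool


@dataclass(frozen=True)
class ShapeDescriptors:
    """Both compartments plus the whole-component symmetry index."""

    medial: CompartmentDescriptors
    lateral: CompartmentDescriptors
    symmetry_index: float

    def to_row(self) -> dict:
        row = {}
        for comp in ("medial", "lateral"):
            for k, v in asdict(getattr(self, comp)).items():
                row[f"{comp}_{k}"] = v
        row["symmetry_index"] = self.symmetry_index
        return row


_EMPTY = CompartmentDescriptors(*([0.0] * 15), empty=True)


def _boundary_length_px(worn: np.ndarray) -> float:
    """Boundary length (pixel units) of a binary blob set by the Crofton
    formula with 4 projection directions; unbiased in the smooth-blob
    limit and symmetric under mirroring and 90-degree rotation."""
    return float(measure.perimeter_crofton(np.pad(worn, 1), directions=4))


def _compartment_descriptors(worn: np.ndarray, mm_ml: float, mm_ap: float,
                             center_row: float, center_col: float
                             ) -> CompartmentDescriptors:
    rows, cols = np.nonzero(worn)
    if rows.size == 0:
        return _EMPTY
    px_area = mm_ml * mm_ap
    area = rows.size * px_area
    # mm coordinates: anterior positive AP, increasing column positive ML
    ml = (cols - center_col) * mm_ml
    ap = (center_row - rows) * mm_ap
    c_ml, c_ap = float(ml.mean()), float(ap.mean())
    # bounding box extents include the full pixel footprint
    ml_min, ml_max = float(ml.min() - mm_ml / 2), float(ml.max() + mm_ml / 2)
    ap_min, ap_max = float(ap.min() - mm_ap / 2), float(ap.max() + mm_ap / 2)
    ml_stretch = ml_max - ml_min
    ap_stretch = ap_max - ap_min
    i_ap = float(((ml - c_ml) ** 2).sum() * px_area)
    i_ml = float(((ap - c_ap) ** 2).sum() * px_area)
    # perimeter is isotropic only under square pixels; use the mean scale
    perim = _boundary_length_px(worn) * math.sqrt(mm_ml * mm_ap)
    shape_factor = 4 * math.pi * area / perim ** 2 if perim > 0 else 0.0
    aspect = ml_stretch / ap_stretch if ap_stretch > 0 else 0.0
    bbox_area = ml_stretch * ap_stretch
    solidity = area / bbox_area if bbox_area > 0 else 0.0
    return CompartmentDescriptors(
        area_mm2=area, perimeter_mm=perim,
        centroid_ml_mm=c_ml, centroid_ap_mm=c_ap,
        bbox_ml_min_mm=ml_min, bbox_ml_max_mm=ml_max,
        bbox_ap_min_mm=ap_min, bbox_ap_max_mm=ap_max,
        ml_stretch_mm=ml_stretch, ap_stretch_mm=ap_stretch,
        i_ap_mm4=i_ap, i_ml_mm4=i_ml,
        shape_factor=shape_factor, aspect_ratio=aspect, solidity=solidity,
        empty=False,
    )


def compute_descriptors(image: WearScarImage) -> ShapeDescriptors:
    """Geometric parameters of both compartments of a (right-normalized)
    standardized image.  An empty compartment yields zeroed descriptors
    with the ``empty`` flag set, not an error."""
    px = image.pixels
    rows, cols = px.shape
    half = cols // 2
    worn = px == 0
    results = {}
    for name, sl in (("lateral", slice(0, half)), ("medial", slice(half, cols))):
        sub = worn[:, sl]
        c_row = (rows - 1) / 2.0
        c_col = (sl.stop - sl.start - 1) / 2.0
        results[name] = _compartment_descriptors(
            sub, image.mm_per_px_ml, image.mm_per_px_ap, c_row, c_col)
    med, lat = results["medial"], results["lateral"]
    if med.empty or lat.empty:
        sym = 0.0
    else:
        area_balance = 1.0 - (abs(med.area_mm2 - lat.area_mm2)
                              / (med.area_mm2 + lat.area_mm2))
        canvas_ap_mm = rows * image.mm_per_px_ap
        ap_align = 1.0 - abs(med.centroid_ap_mm - lat.centroid_ap_mm) / canvas_ap_mm
        sym = float(area_balance * ap_align)
    return ShapeDescriptors(medial=med, lateral=lat, symmetry_index=sym)


def descriptor_table(images: Sequence[WearScarImage]) -> pd.DataFrame:
    """One descriptor row per component, keyed by ``component_id``."""
    rows = []
    for img in images:
        row = {"component_id": img.component_id}
        row.update(compute_descriptors(img).to_row())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def anova_by_cluster(table: pd.DataFrame, descriptor: str,
                     cluster_col: str = "cluster") -> tuple[float, float]:
    """One-way ANOVA of a descriptor across clusters.

    Clusters of size 1 have no within-group variance and are excluded
    (their means still appear in the descriptor summary table).
    Returns (F, p).
    """
    groups = [g[descriptor].dropna().to_numpy()
              for _, g in table.groupby(cluster_col) if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two clusters with >= 2 members")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # no variance anywhere: F = 0/0, resolved as 0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def cluster_summary(table: pd.DataFrame, descriptors: Sequence[str],
                    cluster_col: str = "cluster") -> pd.DataFrame:
    """Per-cluster mean (SD) of each descriptor; SD is NaN for singleton
    clusters."""
    agg = table.groupby(cluster_col)[list(descriptors)].agg(["mean", "std", "count"])
    agg.columns = [f"{d}_{s}" for d, s in agg.columns]
    return agg


def covariate_regression(table: pd.DataFrame, descriptor: str,
                         covariate: str,
                         cluster_col: str = "cluster") -> pd.DataFrame:
    """Per-cluster OLS of a descriptor on a covariate.

    Clusters with fewer than four components with a known covariate are
    excluded.  Each row carries slope, p (slope t-test), R^2 and the
    ``flagged`` indicator (p < 0.05 and R^2 > 0.4).
    """
    rows = []
    for cid, g in table.groupby(cluster_col):
        sub = g[[descriptor, covariate]].dropna()
        if len(sub) < MIN_COVARIATE_N:
            continue
        X = sm.add_constant(sub[covariate].to_numpy())
        fit = sm.OLS(sub[descriptor].to_numpy(), X).fit()
        slope = float(fit.params[1])
        p = float(fit.pvalues[1]) if np.isfinite(fit.pvalues[1]) else 0.0
        r2 = float(fit.rsquared)
        rows.append({
            "cluster": cid, "descriptor": descriptor, "covariate": covariate,
            "n": len(sub), "slope": slope, "intercept": float(fit.params[0]),
            "p": p, "r2": r2,
            "flagged": bool(p < P_FLAG and r2 > R2_FLAG),
        })
    return pd.DataFrame(rows)


def binomial_enrichment(n_trials: int, k_successes: int,
                        p_success: float) -> float:
    """Exact upper-tail binomial probability P(X >= k) by direct summation.

    Used for cluster enrichment: the chance that ``k`` of ``n`` held-out
    components land in one cluster when each lands there independently
    with probability ``p`` (estimated from the reference composition).
    """
    if not (0 <= k_successes <= n_trials):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 <= p_success <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if k_successes == 0:
        return 1.0  # P(X >= 0) is identically 1
    return float(sum(
        math.comb(n_trials, j) * p_success ** j
        * (1.0 - p_success) ** (n_trials - j)
        for j in range(k_successes, n_trials + 1)))
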