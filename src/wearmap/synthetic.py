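"""Synthetic wear-scar cohort generator.

The study cohort this package targets — retrieval and simulator-tested
tibial inserts — has no public image deposit, so a parametric generator
stands in for it.  Each component carries two scar blobs (medial and
lateral compartments) rendered as perturbed superellipses: the family spans
ellipses to rounded rectangles and reproduces the blob-like contours of
digitized wear scars.  Population presets encode the qualitative structure
of a retrieval repository:

* ``postmortem-like`` — well-functioning components, moderate variability
  in scar position and size (the training / reference cohort);
* ``revision-like`` — failed components, larger variability;
* ``simulator-like`` — machine-worn components: more anteriorly located
  and far more reproducible scars (all parameter spreads at most a quarter
  of the postmortem spreads), implanted side fixed to left, in-host time
  fixed at 60 months (5 million cycles at 1 million cycles per 12 months
  of level walking).

All randomness flows from a master seed through ``numpy.random.SeedSequence``
spawning, so a cohort is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .images import (DEFAULT_MM_PER_PX, STANDARD_SHAPE, Side, WearScarImage)

Compartment = Literal["medial", "lateral"]

#: months of in-vivo level walking represented by one million simulator cycles
MONTHS_PER_MEGACYCLE: float = 12.0


def megacycles_to_months(megacycles: float,
                         months_per_megacycle: float = MONTHS_PER_MEGACYCLE
                         ) -> float:
    """Convert simulator test duration (million cycles) to equivalent months
    of level walking (1 Mc = 12 months)."""
    if megacycles < 0:
        raise ValueError("cycle count must be non-negative")
    return megacycles * months_per_megacycle


# ---------------------------------------------------------------------------
# Shape parameters and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScarShapeParams:
    """Geometry of one scar blob within its compartment frame (mm / degrees).

    ``center_ap``/``center_ml`` offset the blob from the compartment center
    (anterior positive, medial-edge positive).  ``squareness`` is the
    superellipse exponent (2 = ellipse, larger = boxier).
    ``boundary_roughness`` is the relative amplitude of a low-order random
    Fourier perturbation of the boundary radius.
    """

    center_ap: float = 0.0
    center_ml: float = 0.0
    semi_axis_ap: float = 10.0
    semi_axis_ml: float = 10.0
    rotation: float = 0.0
    squareness: float = 2.0
    boundary_roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_ap <= 0:
            raise ValueError("semi_axis_ap must be > 0")
        if self.semi_axis_ml <= 0:
            raise ValueError("semi_axis_ml must be > 0")
        if self.squareness < 1:
            raise ValueError("squareness (superellipse exponent) must be >= 1")
        if not (0 <= self.boundary_roughness < 0.5):
            raise ValueError("boundary_roughness must lie in [0, 0.5)")

    @property
    def analytic_area(self) -> float:
        """Area (mm^2) of the unperturbed superellipse:
        4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)."""
        p = self.squareness
        return (4.0 * self.semi_axis_ap * self.semi_axis_ml
                * _gamma(1 + 1 / p) ** 2 / _gamma(1 + 2 / p))


@dataclass(frozen=True)
class Canvas:
    """Canvas geometry: pixel dimensions plus mm-per-pixel calibration."""

    shape: tuple[int, int] = STANDARD_SHAPE  # (rows=AP, cols=ML)
    mm_per_px_ml: float = DEFAULT_MM_PER_PX
    mm_per_px_ap: float = DEFAULT_MM_PER_PX

    def compartment_bounds(self, compartment: Compartment
                           ) -> tuple[int, int]:
        """Column range [lo, hi) of a compartment on a right-side canvas:
        medial = right half, lateral = left half."""
        _, cols = self.shape
        half = cols // 2
        return (half, cols) if compartment == "medial" else (0, half)

    def compartment_center_px(self, compartment: Compartment
                              ) -> tuple[float, float]:
        lo, hi = self.compartment_bounds(compartment)
        rows, _ = self.shape
        return (rows - 1) / 2.0, (lo + hi - 1) / 2.0


def _fourier_perturbation(rng: np.random.Generator,
                          n_harmonics: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Random coefficients of a zero-mean, unit-max low-order Fourier series."""
    a = rng.standard_normal(n_harmonics)
    b = rng.standard_normal(n_harmonics)
    # normalize so |f| <= 1 everywhere (bound by the L1 coefficient norm)
    norm = np.abs(a).sum() + np.abs(b).sum()
    if norm == 0:
        return a, b
    return a / norm, b / norm


def make_scar_mask(params: ScarShapeParams,
                   compartment: Compartment,
                   canvas: Canvas = Canvas(),
                   seed: int = 0) -> np.ndarray:
    """Rasterize one scar blob into a full-canvas binary mask.

    Returns an array of the canvas shape with 0 = worn (inside the blob)
    and 1 = unworn, the study's encoding convention.  Deterministic for a
    fixed seed (the seed drives only the boundary-roughness perturbation).

    Raises ``ValueError`` naming the offending parameter if the blob cannot
    fit inside its compartment.
    """
    rows, cols = canvas.shape
    c_row, c_col = canvas.compartment_center_px(compartment)
    lo, hi = canvas.compartment_bounds(compartment)

    # conservative containment check: maximal radial extent
    max_r = max(params.semi_axis_ap, params.semi_axis_ml) * (
        1.0 + params.boundary_roughness)
    half_ml = (hi - lo) / 2.0 * canvas.mm_per_px_ml
    half_ap = rows / 2.0 * canvas.mm_per_px_ap
    if abs(params.center_ml) + max_r > half_ml:
        raise ValueError(
            f"scar exceeds compartment ML bounds: |center_ml|={abs(params.center_ml):.2f}"
            f" + extent {max_r:.2f} > {half_ml:.2f} mm (check center_ml / semi_axis_ml)")
    if abs(params.center_ap) + max_r > half_ap:
        raise ValueError(
            f"scar exceeds compartment AP bounds: |center_ap|={abs(params.center_ap):.2f}"
            f" + extent {max_r:.2f} > {half_ap:.2f} mm (check center_ap / semi_axis_ap)")

    rr, cc = np.meshgrid(np.arange(rows), np.arange(lo, hi), indexing="ij")
    # mm coordinates relative to blob center; anterior (row 0) positive AP,
    # increasing column positive ML
    y_ap = (c_row - rr) * canvas.mm_per_px_ap - params.center_ap
    x_ml = (cc - c_col) * canvas.mm_per_px_ml - params.center_ml

    theta = math.radians(params.rotation)
    u = x_ml * math.cos(theta) + y_ap * math.sin(theta)
    v = -x_ml * math.sin(theta) + y_ap * math.cos(theta)

    r = np.hypot(u, v)
    phi = np.arctan2(v, u)
    p = params.squareness
    a, b = params.semi_axis_ml, params.semi_axis_ap
    with np.errstate(divide="ignore"):
        r_boundary = (np.abs(np.cos(phi) / a) ** p
                      + np.abs(np.sin(phi) / b) ** p) ** (-1.0 / p)

    if params.boundary_roughness > 0:
        rng = np.random.default_rng(seed)
        ca, cb = _fourier_perturbation(rng)
        k = np.arange(2, 2 + len(ca))
        f = (np.cos(np.multiply.outer(phi, k)) @ ca
             + np.sin(np.multiply.outer(phi, k)) @ cb)
        r_boundary = r_boundary * (1.0 + params.boundary_roughness * f)

    inside = r <= r_boundary
    mask = np.ones((rows, cols), dtype=np.uint8)
    mask[:, lo:hi][inside] = 0
    return mask


# ---------------------------------------------------------------------------
# Population specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Normal distribution (mean, spread >= 0) for one shape parameter."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("spread must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mean, self.sd)) if self.sd else self.mean


@dataclass(frozen=True)
class CompartmentModel:
    """Per-compartment distributions over every ScarShapeParams field."""

    center_ap: ParamDist = ParamDist(0.0)
    center_ml: ParamDist = ParamDist(0.0)
    semi_axis_ap: ParamDist = ParamDist(10.0)
    semi_axis_ml: ParamDist = ParamDist(10.0)
    rotation: ParamDist = ParamDist(0.0)
    squareness: ParamDist = ParamDist(2.0)
    boundary_roughness: ParamDist = ParamDist(0.0)

    def draw(self, rng: np.random.Generator) -> ScarShapeParams:
        raw = {f.name: getattr(self, f.name).draw(rng)
               for f in fields(ScarShapeParams)}
        raw["semi_axis_ap"] = max(raw["semi_axis_ap"], 2.0)
        raw["semi_axis_ml"] = max(raw["semi_axis_ml"], 2.0)
        raw["squareness"] = max(raw["squareness"], 1.0)
        raw["boundary_roughness"] = float(
            np.clip(raw["boundary_roughness"], 0.0, 0.45))
        return ScarShapeParams(**raw)


@dataclass(frozen=True)
class CovariateModel:
    """Linear link from time-in-host (months) to total analytic scar area
    (mm^2): area = intercept + slope * time + N(0, noise_sd)."""

    slope: float
    intercept: float
    noise_sd: float = 0.0


@dataclass(frozen=True)
class PopulationSpec:
    """One component population: shape distributions plus covariates."""

    name: str
    source: str  # postmortem | revision | simulator
    medial: CompartmentModel
    lateral: CompartmentModel
    side_probability_left: float = 0.5
    time_in_host: ParamDist = ParamDist(60.0, 0.0)  # months
    age_at_surgery: ParamDist = ParamDist(70.0, 0.0)  # years
    covariate_model: Optional[CovariateModel] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.side_probability_left <= 1.0):
            raise ValueError("side_probability_left must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort: (population, count) pairs plus canvas and master seed."""

    populations: tuple[tuple[PopulationSpec, int], ...]
    canvas: Canvas = Canvas()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("cohort spec must list at least one population")
        for pop, n in self.populations:
            if n < 1:
                raise ValueError(f"population {pop.name!r} must have n >= 1")


# Presets.  All presets carry a systematic medial/lateral asymmetry (the
# medial compartment bears the larger, the lateral a smaller and slightly
# posterior scar) — the compartment signature that makes implantation side
# recoverable from the image alone.  The simulator-like preset encodes
# machine-worn scars: anterior mean centers and parameter spreads at most
# a quarter of the postmortem spreads (more reproducible placement/shape).
def postmortem_like() -> PopulationSpec:
    medial = CompartmentModel(
        center_ap=ParamDist(2.0, 3.0),
        center_ml=ParamDist(2.0, 2.0),
        semi_axis_ap=ParamDist(11.5, 2.0),
        semi_axis_ml=ParamDist(11.0, 1.5),
        rotation=ParamDist(0.0, 8.0),
        squareness=ParamDist(2.2, 0.3),
        boundary_roughness=ParamDist(0.10, 0.04),
    )
    lateral = CompartmentModel(
        center_ap=ParamDist(-5.0, 3.0),
        center_ml=ParamDist(2.0, 2.0),
        semi_axis_ap=ParamDist(9.5, 2.0),
        semi_axis_ml=ParamDist(8.5, 1.5),
        rotation=ParamDist(0.0, 8.0),
        squareness=ParamDist(2.2, 0.3),
        boundary_roughness=ParamDist(0.10, 0.04),
    )
    return PopulationSpec(
        name="postmortem-like", source="postmortem",
        medial=medial, lateral=lateral,
        side_probability_left=0.5,
        time_in_host=ParamDist(79.0, 30.0),
        age_at_surgery=ParamDist(72.0, 9.0),
    )


def revision_like() -> PopulationSpec:
    medial = CompartmentModel(
        center_ap=ParamDist(1.0, 4.0),
        center_ml=ParamDist(2.0, 2.5),
        semi_axis_ap=ParamDist(10.5, 2.5),
        semi_axis_ml=ParamDist(10.0, 2.0),
        rotation=ParamDist(0.0, 12.0),
        squareness=ParamDist(2.2, 0.4),
        boundary_roughness=ParamDist(0.15, 0.06),
    )
    lateral = CompartmentModel(
        center_ap=ParamDist(-7.0, 4.0),
        center_ml=ParamDist(2.0, 2.5),
        semi_axis_ap=ParamDist(9.0, 2.5),
        semi_axis_ml=ParamDist(8.0, 2.0),
        rotation=ParamDist(0.0, 12.0),
        squareness=ParamDist(2.2, 0.4),
        boundary_roughness=ParamDist(0.15, 0.06),
    )
    return PopulationSpec(
        name="revision-like", source="revision",
        medial=medial, lateral=lateral,
        side_probability_left=0.5,
        time_in_host=ParamDist(26.0, 20.0),
        age_at_surgery=ParamDist(66.0, 10.0),
    )


def simulator_like() -> PopulationSpec:
    medial = CompartmentModel(
        center_ap=ParamDist(8.0, 0.6),
        center_ml=ParamDist(2.0, 0.4),
        semi_axis_ap=ParamDist(10.0, 0.4),
        semi_axis_ml=ParamDist(11.0, 0.3),
        rotation=ParamDist(0.0, 1.5),
        squareness=ParamDist(2.0, 0.05),
        boundary_roughness=ParamDist(0.03, 0.01),
    )
    lateral = CompartmentModel(
        center_ap=ParamDist(5.0, 0.6),
        center_ml=ParamDist(2.0, 0.4),
        semi_axis_ap=ParamDist(9.5, 0.4),
        semi_axis_ml=ParamDist(8.5, 0.3),
        rotation=ParamDist(0.0, 1.5),
        squareness=ParamDist(2.0, 0.05),
        boundary_roughness=ParamDist(0.03, 0.01),
    )
    return PopulationSpec(
        name="simulator-like", source="simulator",
        medial=medial, lateral=lateral,
        side_probability_left=1.0,  # simulator components all mounted left
        time_in_host=ParamDist(megacycles_to_months(5.0), 0.0),
        age_at_surgery=ParamDist(math.nan, 0.0),
    )


PRESETS = {
    "postmortem-like": postmortem_like,
    "revision-like": revision_like,
    "simulator-like": simulator_like,
}


def planted_triplet_spec(n_per_population: int = 15,
                         master_seed: int = 0) -> CohortSpec:
    """Three well-separated populations with distinct scar centers and
    sizes and tight spreads — planted ground truth for cluster-recovery
    checks (each population should occupy its own map region)."""
    def _cm(center_ap, center_ml, a_ap, a_ml):
        return CompartmentModel(
            center_ap=ParamDist(center_ap, 1.0),
            center_ml=ParamDist(center_ml, 1.0),
            semi_axis_ap=ParamDist(a_ap, 0.8),
            semi_axis_ml=ParamDist(a_ml, 0.8),
            squareness=ParamDist(2.2, 0.1),
            boundary_roughness=ParamDist(0.05, 0.02),
        )

    anterior_large = PopulationSpec(
        name="anterior-large", source="postmortem",
        medial=_cm(6.0, 0.0, 12.0, 11.0), lateral=_cm(4.0, 0.0, 10.0, 9.0),
        side_probability_left=0.0)
    posterior_medium = PopulationSpec(
        name="posterior-medium", source="revision",
        medial=_cm(-8.0, 2.0, 9.0, 9.0), lateral=_cm(-9.0, 2.0, 8.0, 8.0),
        side_probability_left=0.0)
    central_small = PopulationSpec(
        name="central-small", source="simulator",
        medial=_cm(0.0, 5.0, 6.0, 6.0), lateral=_cm(0.0, 5.0, 5.0, 5.0),
        side_probability_left=0.0)
    return CohortSpec(
        populations=((anterior_large, n_per_population),
                     (posterior_medium, n_per_population),
                     (central_small, n_per_population)),
        master_seed=master_seed,
    )


def default_cohort_spec(master_seed: int = 0,
                        n_postmortem: int = 21,
                        n_revision: int = 54,
                        n_simulator: int = 6) -> CohortSpec:
    """Default study-sized cohort: 21 postmortem-like + 54 revision-like +
    6 simulator-like components.  Populations with a zero count are omitted."""
    pops = [(postmortem_like(), n_postmortem),
            (revision_like(), n_revision),
            (simulator_like(), n_simulator)]
    return CohortSpec(
        populations=tuple((p, n) for p, n in pops if n > 0),
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _fit_within_bounds(params: ScarShapeParams, compartment: Compartment,
                       canvas: Canvas) -> ScarShapeParams:
    """Clamp a drawn shape so it is guaranteed to fit its compartment."""
    rows, cols = canvas.shape
    lo, hi = canvas.compartment_bounds(compartment)
    half_ml = (hi - lo) / 2.0 * canvas.mm_per_px_ml
    half_ap = rows / 2.0 * canvas.mm_per_px_ap
    margin = 1.0 + params.boundary_roughness
    changes = {}
    max_r = max(params.semi_axis_ap, params.semi_axis_ml) * margin
    # first pull the center in, then shrink the axes if still too large
    c_ml = float(np.clip(params.center_ml, -(half_ml - 2.5), half_ml - 2.5))
    c_ap = float(np.clip(params.center_ap, -(half_ap - 2.5), half_ap - 2.5))
    if c_ml != params.center_ml:
        changes["center_ml"] = c_ml
    if c_ap != params.center_ap:
        changes["center_ap"] = c_ap
    room = min(half_ml - abs(c_ml), half_ap - abs(c_ap))
    if max_r > room:
        scale = max(room / max_r, 1e-3) * 0.999
        changes["semi_axis_ap"] = max(params.semi_axis_ap * scale, 1.0)
        changes["semi_axis_ml"] = max(params.semi_axis_ml * scale, 1.0)
    return replace(params, **changes) if changes else params


def _scale_to_area(med: ScarShapeParams, lat: ScarShapeParams,
                   target_total: float
                   ) -> tuple[ScarShapeParams, ScarShapeParams]:
    current = med.analytic_area + lat.analytic_area
    s = math.sqrt(max(target_total, 1e-6) / current)
    return (replace(med, semi_axis_ap=med.semi_axis_ap * s,
                    semi_axis_ml=med.semi_axis_ml * s),
            replace(lat, semi_axis_ap=lat.semi_axis_ap * s,
                    semi_axis_ml=lat.semi_axis_ml * s))


def sample_component(pop: PopulationSpec,
                     canvas: Canvas = Canvas(),
                     seed: int | np.random.SeedSequence = 0,
                     component_id: str = "") -> WearScarImage:
    """Draw one component: two scar blobs, side, covariates.

    A left-side draw is the mirror rendering of the right-side canvas.
    When the population carries a covariate model, total analytic scar area
    follows the stated linear link in time-in-host (plus noise); the
    realized analytic area is recorded in the metadata table by
    :func:`sample_cohort`.
    """
    rng = np.random.default_rng(seed)
    time_in_host = pop.time_in_host.draw(rng)
    age = pop.age_at_surgery.draw(rng)

    med = pop.medial.draw(rng)
    lat = pop.lateral.draw(rng)
    if pop.covariate_model is not None:
        cm = pop.covariate_model
        target = cm.intercept + cm.slope * time_in_host
        if cm.noise_sd:
            target += rng.normal(0.0, cm.noise_sd)
        med, lat = _scale_to_area(med, lat, target)
    med = _fit_within_bounds(med, "medial", canvas)
    lat = _fit_within_bounds(lat, "lateral", canvas)

    seed_med, seed_lat = rng.integers(0, 2**31 - 1, size=2)
    mask = (make_scar_mask(med, "medial", canvas, int(seed_med))
            & make_scar_mask(lat, "lateral", canvas, int(seed_lat)))

    side: Side = "left" if rng.random() < pop.side_probability_left else "right"
    if side == "left":
        mask = mask[:, ::-1].copy()

    img = WearScarImage(
        pixels=mask,
        mm_per_px_ml=canvas.mm_per_px_ml,
        mm_per_px_ap=canvas.mm_per_px_ap,
        side=side,
        source=pop.source,  # type: ignore[arg-type]
        component_id=component_id,
        time_in_host=time_in_host,
        age_at_surgery=age,
        population=pop.name,
    )
    # stash realized analytic areas for the cohort table
    img._analytic_area = med.analytic_area + lat.analytic_area  # type: ignore[attr-defined]
    return img


def sample_cohort(spec: CohortSpec
                  ) -> tuple[list[WearScarImage], pd.DataFrame]:
    """Generate a full cohort plus its metadata table.

    Per-component seeds are spawned deterministically from the master seed,
    so a fixed ``CohortSpec`` yields a byte-identical cohort.  The table
    carries the ground-truth population label for recovery tests.
    """
    root = np.random.SeedSequence(spec.master_seed)
    total = sum(n for _, n in spec.populations)
    children = root.spawn(total)

    images: list[WearScarImage] = []
    rows = []
    k = 0
    for pop, n in spec.populations:
        for i in range(n):
            cid = f"{pop.source}-{i:03d}"
            img = sample_component(pop, spec.canvas, children[k], cid)
            k += 1
            images.append(img)
            rows.append({
                "component_id": cid,
                "source": img.source,
                "population": pop.name,
                "side": img.side,
                "time_in_host": img.time_in_host,
                "age_at_surgery": img.age_at_surgery,
                "area_mm2": img._analytic_area,  # type: ignore[attr-defined]
            })
    return images, pd.DataFrame(rows)
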