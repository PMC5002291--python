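"""Wear-scar bitmap containers, I/O, side normalization and vector encoding.

A wear-scar image is a binary canvas covering the articulating surface of a
tibial polyethylene insert: black pixels (value 0) mark worn material, white
pixels (value 1) unworn material.  The standardized canvas is 220 columns
(medial-lateral axis) by 170 rows (anterior-posterior axis, anterior at the
top row); flattened row-major it yields a 37,400-entry binary vector, the
input representation for the self-organizing map.

Conventions (fixed so that trained models are portable):

* rows = AP axis, anterior at row 0; columns = ML axis.
* On a right-side (or right-normalized) image the medial compartment is the
  right half of the canvas, the lateral compartment the left half.
* Left-side components are mirrored about the vertical axis to obtain the
  right-normalized form.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: standardized canvas: (rows, cols) = (AP, ML)
STANDARD_SHAPE: tuple[int, int] = (170, 220)
#: length of the encoded vector for a standardized image
ENCODED_LENGTH: int = STANDARD_SHAPE[0] * STANDARD_SHAPE[1]
#: default isotropic calibration, mm per pixel
DEFAULT_MM_PER_PX: float = 0.35

Side = Literal["left", "right", "unknown"]
Source = Literal["postmortem", "revision", "simulator", "unknown"]


@dataclass
class WearScarImage:
    """A binary wear-scar bitmap plus calibration and component metadata.

    ``pixels`` holds 0 for worn (black) and 1 for unworn (white) material.
    """

    pixels: np.ndarray
    mm_per_px_ml: float = DEFAULT_MM_PER_PX
    mm_per_px_ap: float = DEFAULT_MM_PER_PX
    side: Side = "unknown"
    source: Source = "unknown"
    component_id: str = ""
    time_in_host: float = math.nan  # months
    age_at_surgery: float = math.nan  # years
    population: str = ""  # generator ground-truth label, empty for real data

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        uniq = np.unique(px)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("pixels must be binary (0 = worn, 1 = unworn)")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_standard(self) -> bool:
        return self.pixels.shape == STANDARD_SHAPE

    @property
    def worn_count(self) -> int:
        return int(self.pixels.size - self.pixels.sum())

    def replace(self, **changes) -> "WearScarImage":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> WearScarImage:
    """Read a binary mask from PBM (P1/P4) or PNG (any gray/color input is
    thresholded at mid-intensity).

    Metadata fields are left unset; use :func:`attach_metadata` with a
    sidecar table to populate them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"empty (0-byte) image file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise ValueError(f"could not read image {path}: {exc}") from exc
    pixels = (arr >= 128).astype(np.uint8)
    return WearScarImage(pixels=pixels, component_id=path.stem)


def write_mask(image: WearScarImage, path: str | Path,
               format: str | None = None) -> Path:
    """Write a mask as PBM (``p1`` ASCII or ``p4`` binary) or PNG.

    The round trip ``read_mask(write_mask(img))`` is bit-exact.  The format
    is inferred from the suffix when not given (``.pbm`` -> P4).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("png",):
        Image.fromarray((image.pixels * 255).astype(np.uint8)).convert("1").save(
            path, format="PNG")
    elif fmt in ("p4", "pbm"):
        # PBM convention: 1 = black = worn, i.e. the inverse of our values
        Image.fromarray((image.pixels * 255).astype(np.uint8)).convert("1").save(
            path, format="PPM")
    elif fmt == "p1":
        rows, cols = image.pixels.shape
        lines = [f"P1", f"{cols} {rows}"]
        inverted = 1 - image.pixels  # PBM: 1 = black
        lines += [" ".join(map(str, row)) for row in inverted]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r} (use p1, p4/pbm, png)")
    return path


def attach_metadata(images: Iterable[WearScarImage],
                    table: pd.DataFrame) -> list[WearScarImage]:
    """Join sidecar metadata (keyed by ``component_id``) onto images."""
    idx = table.set_index("component_id")
    out = []
    for img in images:
        if img.component_id in idx.index:
            row = idx.loc[img.component_id]
            img = img.replace(
                side=row.get("side", img.side),
                source=row.get("source", img.source),
                time_in_host=float(row.get("time_in_host", math.nan)),
                age_at_surgery=float(row.get("age_at_surgery", math.nan)),
            )
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def mirror(image: WearScarImage) -> WearScarImage:
    """Flip the canvas about the vertical (AP) axis, swapping left/right."""
    flipped = image.pixels[:, ::-1].copy()
    new_side: Side = {"left": "right", "right": "left",
                      "unknown": "unknown"}[image.side]
    return image.replace(pixels=flipped, side=new_side)


def to_right_side(image: WearScarImage) -> WearScarImage:
    """Normalize a component to right implantation side.

    Left images are mirrored about the vertical axis and relabeled right;
    right images pass through unchanged.
    """
    if image.side == "right":
        return image
    if image.side == "left":
        return image.replace(pixels=image.pixels[:, ::-1].copy(), side="right")
    raise ValueError(
        "implantation side is unknown; determine it first with infer_side()")


def infer_side(image: WearScarImage,
               reference: Sequence[WearScarImage]) -> Side:
    """Infer the implantation side by mirror-distance to a reference cohort.

    Compares the encoded image as-is and mirrored against a set of
    right-normalized references; the orientation with the smaller mean
    Euclidean distance wins (tie -> ``right``).  This is a deterministic
    stand-in for side classification: a left component resembles the
    reference cohort only after mirroring.
    """
    if len(reference) == 0:
        raise ValueError("infer_side requires a non-empty reference set")
    ref = np.stack([r.pixels.astype(np.float64).ravel() for r in reference])
    as_is = image.pixels.astype(np.float64).ravel()
    mirrored = image.pixels[:, ::-1].astype(np.float64).ravel()
    d_right = np.linalg.norm(ref - as_is, axis=1).mean()
    d_left = np.linalg.norm(ref - mirrored, axis=1).mean()
    return "left" if d_left < d_right else "right"


def standardize(image: WearScarImage,
                target_shape: tuple[int, int] = STANDARD_SHAPE) -> WearScarImage:
    """Nearest-neighbor resample to the standard canvas, rescaling calibration.

    Nearest-neighbor (not interpolating) resampling preserves binarity.
    """
    rows, cols = target_shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"target dimensions must be positive, got {target_shape}")
    src_r, src_c = image.pixels.shape
    if (src_r, src_c) == (rows, cols):
        return image
    r_idx = np.minimum((np.arange(rows) + 0.5) * src_r / rows, src_r - 1).astype(int)
    c_idx = np.minimum((np.arange(cols) + 0.5) * src_c / cols, src_c - 1).astype(int)
    resampled = image.pixels[np.ix_(r_idx, c_idx)]
    return image.replace(
        pixels=resampled,
        mm_per_px_ml=image.mm_per_px_ml * src_c / cols,
        mm_per_px_ap=image.mm_per_px_ap * src_r / rows,
    )


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode(image: WearScarImage) -> np.ndarray:
    """Row-major flatten a standardized image to a {0,1} vector of length 37,400."""
    if not image.is_standard:
        raise ValueError(
            f"image has shape {image.shape}; standardize() to "
            f"{STANDARD_SHAPE} before encoding")
    return image.pixels.ravel(order="C").copy()


def decode(vector: np.ndarray,
           template: WearScarImage | None = None) -> WearScarImage:
    """Inverse of :func:`encode`: reshape a 37,400-vector back to a canvas."""
    vec = np.asarray(vector)
    if vec.size != ENCODED_LENGTH:
        raise ValueError(f"expected length {ENCODED_LENGTH}, got {vec.size}")
    pixels = vec.reshape(STANDARD_SHAPE).astype(np.uint8)
    if template is not None:
        return template.replace(pixels=pixels)
    return WearScarImage(pixels=pixels)


def encode_cohort(images: Sequence[WearScarImage]) -> np.ndarray:
    """Stack encoded vectors into an (n_components, 37,400) design matrix."""
    return np.stack([encode(img) for img in images])
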