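"""Colour/trash feature extraction from cotton-lint images.

The pipeline turns one RGB image of a lint sample into a 12-dimensional
feature record:

1. crop away the unevenly lit border of the frame;
2. detect dark trash specks by grayscale conversion followed by balanced
   histogram thresholding, and report their pixel percentage;
3. convert RGB -> CIE XYZ -> Hunter Lab and average L, a, b over the crop;
4. split the crop into a tile grid and compute the mean and standard
   deviation across tiles of the per-tile trash percentage and per-tile
   mean Hunter L, a, b (intra-sample variation).

Whole-image values (4) plus tile mean/std pairs (8) give 12 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor

__all__ = [
    "CropSpec",
    "RIG_CROP",
    "FULL_FRAME",
    "HunterColour",
    "FeatureRecord",
    "FEATURE_NAMES",
    "ILLUMINANTS",
    "crop_uniform_region",
    "to_grayscale",
    "histogram_256",
    "balanced_histogram_threshold",
    "trash_mask",
    "trash_percentage",
    "rgb_to_xyz",
    "xyz_to_hunter",
    "segment_grid",
    "extract_features",
    "records_to_frame",
    "frame_to_records",
]

#: Column order of the 12 features, also the CSV column order.
FEATURE_NAMES = [
    "trash_pct",
    "hunter_L",
    "hunter_a",
    "hunter_b",
    "tile_trash_mean",
    "tile_trash_std",
    "tile_L_mean",
    "tile_L_std",
    "tile_a_mean",
    "tile_a_std",
    "tile_b_mean",
    "tile_b_std",
]

#: Hunter Lab constants per illuminant: (Ka, Kb, (Xn, Yn, Zn)).
#: D65 suits daylight-balanced camera images; C is the classic Hunter choice.
ILLUMINANTS = {
    "D65": (172.30, 67.20, (95.047, 100.0, 108.883)),
    "C": (175.0, 70.0, (98.074, 100.0, 118.232)),
}


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropSpec:
    """Centred crop along one axis.

    Either ``target`` (final length of the cropped axis) or ``margin``
    (pixels removed from each end) is given. ``axis=None`` selects the
    longer axis (columns on a tie), matching a rig whose light falls off
    along the long side of the frame.
    """

    target: int | None = None
    margin: int = 0
    axis: int | None = None

    def resolve(self, shape: tuple[int, ...]) -> tuple[int, int, int]:
        """Return (axis, start, stop) for an image of the given shape."""
        axis = self.axis
        if axis is None:
            axis = 0 if shape[0] > shape[1] else 1
        length = shape[axis]
        if self.target is not None:
            if self.target > length or self.target < 1:
                raise ValueError(
                    f"crop target {self.target} invalid for axis length {length}"
                )
            trim = length - self.target
            start = trim // 2
            return axis, start, start + self.target
        if 2 * self.margin >= length:
            raise ValueError(f"margin {self.margin} too large for axis length {length}")
        return axis, self.margin, length - self.margin


#: Preset matching the grading rig: 3264-px long axis cropped to 2965.
RIG_CROP = CropSpec(target=2965)

#: Identity crop.
FULL_FRAME = CropSpec(margin=0)


def crop_uniform_region(image: np.ndarray, spec: CropSpec = RIG_CROP) -> np.ndarray:
    """Crop the unevenly illuminated border from an image.

    The default preset trims the long axis from 3264 to 2965 pixels,
    keeping the crop centred.
    """
    if image.ndim < 2:
        raise ValueError("expected a 2-D or 3-D image")
    axis, start, stop = spec.resolve(image.shape[:2])
    sl = [slice(None)] * image.ndim
    sl[axis] = slice(start, stop)
    return image[tuple(sl)]


# ---------------------------------------------------------------------------
# grayscale + balanced histogram thresholding
# ---------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale (0.2989 R + 0.5870 G + 0.1140 B), float in [0, 255]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return image[..., 0] * 0.2989 + image[..., 1] * 0.5870 + image[..., 2] * 0.1140


def histogram_256(gray: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit-range grayscale raster."""
    if gray.size == 0:
        raise ValueError("empty raster")
    levels = np.clip(np.rint(gray), 0, 255).astype(np.int64)
    return np.bincount(levels.ravel(), minlength=256)


def balanced_histogram_threshold(hist: Sequence[int] | np.ndarray) -> int:
    """Balance point of a grayscale histogram, used as a binarisation level.

    Two edge pointers start at the outermost occupied bins. Each step the
    mass left of centre (centre bin included) is weighed against the mass
    right of it; the outermost bin of the heavier side is trimmed and the
    centre recomputed. Trimming stops when the two sides balance or the
    edges meet; the final centre is returned.

    The returned level always lies within [first occupied bin, last
    occupied bin].
    """
    h = np.asarray(hist, dtype=np.int64)
    if h.ndim != 1 or h.size == 0 or h.sum() <= 0:
        raise ValueError("histogram must be 1-D with positive total count")
    occupied = np.flatnonzero(h)
    left, right = int(occupied[0]), int(occupied[-1])
    centre = (left + right) // 2
    w_left = int(h[left : centre + 1].sum())
    w_right = int(h[centre + 1 : right + 1].sum())
    while left < right:
        if w_left == w_right:
            break
        if w_left > w_right:
            w_left -= int(h[left])
            left += 1
        else:
            w_right -= int(h[right])
            right -= 1
        new_centre = (left + right) // 2
        # re-centre: move bins between old and new centre across the scale
        while centre < new_centre:
            centre += 1
            w_left += int(h[centre])
            w_right -= int(h[centre])
        while centre > new_centre:
            w_left -= int(h[centre])
            w_right += int(h[centre])
            centre -= 1
    return centre


def trash_mask(gray: np.ndarray, threshold: int | None = None) -> np.ndarray:
    """Boolean mask of trash pixels: strictly darker than the threshold.

    With ``threshold=None`` the balanced-histogram level of ``gray`` is
    used. A uniform image therefore yields an all-False mask.
    """
    if threshold is None:
        threshold = balanced_histogram_threshold(histogram_256(gray))
    return np.rint(gray) < threshold


def trash_percentage(mask: np.ndarray) -> float:
    """Percentage of True pixels in a binary raster."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty raster")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


# ---------------------------------------------------------------------------
# colour conversion
# ---------------------------------------------------------------------------

def rgb_to_xyz(image: np.ndarray) -> np.ndarray:
    """sRGB (0-255) to CIE XYZ with a D65 white of Y = 100.

    Applies the sRGB inverse gamma then the D65 sRGB->XYZ matrix; the
    white point (255, 255, 255) maps to approximately (95.047, 100,
    108.883).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return _skcolor.rgb2xyz(arr / 255.0) * 100.0


@dataclass(frozen=True)
class HunterColour:
    """A Hunter Lab colour: L lightness (0-100 for physical reflectances),
    a the green(-)/red(+) axis, b the blue(-)/yellow(+) axis."""

    L: float
    a: float
    b: float


def xyz_to_hunter(
    xyz: np.ndarray | Sequence[float], illuminant: str = "D65"
) -> np.ndarray:
    """CIE XYZ (white Y = 100) to Hunter Lab.

    L = 100 sqrt(Y/Yn);  a = Ka (X/Xn - Y/Yn) / sqrt(Y/Yn);
    b = Kb (Y/Yn - Z/Zn) / sqrt(Y/Yn).  At Y = 0 the chromatic terms are
    undefined and (0, 0, 0) is returned by convention.

    Accepts a single triplet or an (..., 3) array; returns the same shape.
    """
    ka, kb, (xn, yn, zn) = ILLUMINANTS[illuminant]
    arr = np.asarray(xyz, dtype=np.float64)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError("expected (..., 3) XYZ input")
    x, y, z = arr[..., 0] / xn, arr[..., 1] / yn, arr[..., 2] / zn
    if np.any(y < -1e-12):
        raise ValueError("negative Y is non-physical")
    y = np.clip(y, 0.0, None)
    root = np.sqrt(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = 100.0 * root
        a = np.where(root > 0, ka * (x - y) / np.where(root > 0, root, 1.0), 0.0)
        b = np.where(root > 0, kb * (y - z) / np.where(root > 0, root, 1.0), 0.0)
    out = np.stack([L, a, b], axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# tiling and the full record
# ---------------------------------------------------------------------------

def segment_grid(image: np.ndarray, rows: int, cols: int) -> list[np.ndarray]:
    """Partition an image into ``rows x cols`` contiguous tiles.

    Tiles are near-equal; remainder pixels go to the last row/column of
    tiles. The tiles cover the image exactly once.
    """
    h, w = image.shape[:2]
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    if rows > h or cols > w:
        raise ValueError(f"grid {rows}x{cols} exceeds image {h}x{w}")
    rb = [i * (h // rows) for i in range(rows)] + [h]
    cb = [j * (w // cols) for j in range(cols)] + [w]
    return [
        image[rb[i] : rb[i + 1], cb[j] : cb[j + 1]]
        for i in range(rows)
        for j in range(cols)
    ]


@dataclass
class FeatureRecord:
    """One sample's 12 image features plus identity metadata.

    ``grade`` is the expert grade as a 0-based index (grade I -> 0) when
    known, else None. ``values`` follows :data:`FEATURE_NAMES`.
    """

    cultivar: str
    grade: int | None
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (12,):
            raise ValueError("a feature record has exactly 12 values")

    def as_dict(self) -> dict:
        d = {"cultivar": self.cultivar, "grade": self.grade}
        d.update(zip(FEATURE_NAMES, self.values))
        return d


def extract_features(
    image: np.ndarray,
    grid: tuple[int, int] = (4, 4),
    crop: CropSpec | None = None,
    illuminant: str = "D65",
    cultivar: str = "",
    grade: int | None = None,
) -> FeatureRecord:
    """Run the full feature pipeline on one RGB image.

    The trash threshold is computed once on the whole cropped image and
    reused for every tile, so trash-free tiles are not forced to contain
    "trash". Tile statistics use the population standard deviation.
    """
    if crop is not None:
        image = crop_uniform_region(image, crop)
    gray = to_grayscale(image)
    threshold = balanced_histogram_threshold(histogram_256(gray))
    whole_trash = trash_percentage(trash_mask(gray, threshold))
    hunter = xyz_to_hunter(rgb_to_xyz(image), illuminant)
    whole_lab = hunter.reshape(-1, 3).mean(axis=0)

    tiles = segment_grid(image, *grid)
    tile_trash = np.empty(len(tiles))
    tile_lab = np.empty((len(tiles), 3))
    for i, tile in enumerate(tiles):
        tgray = to_grayscale(tile)
        tile_trash[i] = trash_percentage(trash_mask(tgray, threshold))
        tile_lab[i] = xyz_to_hunter(rgb_to_xyz(tile), illuminant).reshape(-1, 3).mean(axis=0)

    values = np.concatenate(
        [
            [whole_trash],
            whole_lab,
            [tile_trash.mean(), tile_trash.std()],
            np.stack([tile_lab.mean(axis=0), tile_lab.std(axis=0)], axis=1).ravel(),
        ]
    )
    return FeatureRecord(cultivar=cultivar, grade=grade, values=values)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    """Feature records as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame([r.as_dict() for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[FeatureRecord]:
    """Inverse of :func:`records_to_frame`; NaN grades become None."""
    records = []
    for _, row in frame.iterrows():
        grade = row.get("grade")
        grade = None if pd.isna(grade) else int(grade)
        records.append(
            FeatureRecord(
                cultivar=str(row.get("cultivar", "")),
                grade=grade,
                values=row[FEATURE_NAMES].to_numpy(dtype=np.float64),
            )
        )
    return records
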