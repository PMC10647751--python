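"""Synthetic cotton-lint data with the structure the grading analysis assumes.

Egyptian lint grades run from I (fully good) to IX (fully fair). Better
grades are brighter and less yellow with almost no visible trash; worse
grades are duller, yellower and carry more dark specks of leaf, seed coat
and dust. Real graded image sets are not openly distributed, so this
module generates:

* a :class:`GradeModel` — per-grade Hunter Lab colour means and trash
  coverage, linear in grade index, with a single ``separation`` knob that
  scales between-grade mean distances relative to within-grade spread
  (small separation reproduces the heavily overlapping clusters real
  grade data show);
* rendered lint images (fibre-textured background + dark elliptical
  trash blobs) that the feature-extraction pipeline can process
  end-to-end;
* a fast path that samples 12-feature records directly, bypassing
  rendering;
* a :class:`SimulatedOracle` standing in for the human expert grader:
  it returns true grades (optionally perturbed by ±1 grade to emulate
  fatigue-induced mislabelling) and charges a fixed time per query,
  30 s by default — the speed of both a human expert and an HVI
  fibre-testing instrument.

Per-cultivar grade counts for the three Giza cultivars ship as presets
(:data:`CULTIVAR_COUNTS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._seeds import rng_for
from .image_features import ILLUMINANTS, FeatureRecord
from skimage import color as _skcolor

__all__ = [
    "CULTIVAR_COUNTS",
    "GradeModel",
    "LintImage",
    "OracleAccount",
    "SimulatedOracle",
    "make_grade_model",
    "synthesize_image",
    "synthesize_feature_table",
    "oracle_label",
    "save_image",
]

#: Per-grade sample counts (grades I..IX) for each cultivar in the study's
#: 2020 harvest; totals 845, 703 and 713 (2261 overall).
CULTIVAR_COUNTS = {
    "Giza 86": [115, 118, 113, 119, 150, 115, 115, 0, 0],
    "Giza 90": [0, 100, 131, 116, 124, 131, 101, 0, 0],
    "Giza 96": [103, 0, 109, 118, 97, 102, 120, 0, 64],
}

#: Seconds a human expert or an HVI instrument needs to grade one sample.
SECONDS_PER_LABEL = 30.0


# ---------------------------------------------------------------------------
# grade-appearance model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeModel:
    """Per-grade appearance statistics.

    Grade index 0 is the best grade (brightest, cleanest). Colour means
    are Hunter Lab units; ``trash_cover`` is the fraction of image pixels
    occupied by trash specks. ``noise_rate`` is the probability that the
    simulated expert returns a label shifted by one grade.
    """

    n_grades: int
    L_mean: np.ndarray
    a_mean: np.ndarray
    b_mean: np.ndarray
    trash_cover: np.ndarray
    colour_std: float
    trash_std: float
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_grades <= 9):
            raise ValueError("n_grades must be in [2, 9]")
        for arr in (self.L_mean, self.a_mean, self.b_mean, self.trash_cover):
            if len(arr) != self.n_grades:
                raise ValueError("per-grade arrays must have n_grades entries")
        if np.any(self.trash_cover < 0) or np.any(self.trash_cover > 1):
            raise ValueError("trash coverage must lie in [0, 1]")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must lie in [0, 1)")


def make_grade_model(
    n_grades: int = 7,
    separation: float = 1.8,
    noise_rate: float = 0.0,
    seed: int = 0,
    colour_std: float = 2.0,
    trash_std: float = 0.01,
) -> GradeModel:
    """Build a grade-appearance model.

    ``separation`` is the Euclidean distance, in within-grade standard
    deviations, between adjacent grade means in the (L, b) colour plane;
    trash coverage likewise steps by ``separation * trash_std`` per
    grade. Zero separation collapses all grades onto identical means (a
    pure-overlap null). Lightness decreases and yellowness and trash
    increase with grade index, matching the visual ordering of the grade
    scale. A small seeded jitter on the red-green axis (scaled by
    separation) keeps grades off a perfect line.
    """
    if not (2 <= n_grades <= 9):
        raise ValueError("n_grades must be in [2, 9]")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    g = np.arange(n_grades, dtype=np.float64)
    step = separation * colour_std
    # split the step between L (down) and b (up): 0.8^2 + 0.6^2 = 1
    L = 85.0 - 0.8 * step * g
    b = 8.0 + 0.6 * step * g
    rng = rng_for(seed, "grade-model")
    a = 2.5 + 0.15 * separation * colour_std * rng.standard_normal(n_grades)
    cover = np.clip(0.004 + separation * trash_std * g, 0.0, 1.0)
    return GradeModel(
        n_grades=n_grades,
        L_mean=L,
        a_mean=a,
        b_mean=b,
        trash_cover=cover,
        colour_std=colour_std,
        trash_std=trash_std,
        noise_rate=noise_rate,
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class LintImage:
    """An RGB lint image with its provenance.

    ``trash_pixels`` is the exact number of pixels painted as trash by
    the renderer — a ledger the feature-extraction tests check against.
    """

    pixels: np.ndarray
    cultivar: str
    true_grade: int | None = None
    trash_pixels: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        self.pixels = p


def _hunter_to_rgb(L: float, a: float, b: float, illuminant: str = "D65") -> np.ndarray:
    """Invert Hunter Lab -> XYZ -> sRGB for rendering target colours."""
    ka, kb, (xn, yn, zn) = ILLUMINANTS[illuminant]
    y = (L / 100.0) ** 2
    root = np.sqrt(y)
    x = (a * root / ka + y) * xn / 100.0
    z = (y - b * root / kb) * zn / 100.0
    rgb = _skcolor.xyz2rgb(np.array([[[x, y * yn / 100.0, z]]]))[0, 0]
    return np.clip(rgb, 0.0, 1.0) * 255.0


def synthesize_image(
    model: GradeModel,
    grade: int,
    dims: tuple[int, int] = (512, 512),
    seed: int = 0,
    cultivar: str = "synthetic",
) -> LintImage:
    """Render one synthetic lint image for a grade.

    The background is the grade's target colour modulated by an
    anisotropically smoothed lightness field (a fibre-streak texture).
    Trash is painted as dark ellipses until exactly
    ``round(coverage * n_pixels)`` pixels are covered (the final ellipse
    is clipped), so rendered coverage matches the model by construction;
    the painted count is recorded on the returned image.
    """
    h, w = dims
    if h < 64 or w < 64:
        raise ValueError("dims must be at least 64 x 64")
    if not (0 <= grade < model.n_grades):
        raise ValueError(f"unknown grade {grade}")
    rng = rng_for(seed, "image", grade)

    base = _hunter_to_rgb(model.L_mean[grade], model.a_mean[grade], model.b_mean[grade])
    # fibre texture: elongated low-pass noise modulating lightness by a few %
    streaks = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=(1.0, 8.0))
    streaks /= max(streaks.std(), 1e-12)
    gain = 1.0 + 0.035 * streaks
    img = np.clip(base[None, None, :] * gain[:, :, None], 0, 255)

    target = int(round(model.trash_cover[grade] * h * w))
    mask = np.zeros((h, w), dtype=bool)
    painted = 0
    while painted < target:
        cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        ry, rx = rng.uniform(2, 6), rng.uniform(2, 6)
        theta = rng.uniform(0, np.pi)
        r = int(np.ceil(max(ry, rx)))
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        blob = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        new = blob & ~mask[y0:y1, x0:x1]
        excess = painted + int(new.sum()) - target
        if excess > 0:
            idx = np.flatnonzero(new.ravel())
            trimmed = np.zeros(new.size, dtype=bool)
            trimmed[idx[: len(idx) - excess]] = True
            new = trimmed.reshape(new.shape)
        mask[y0:y1, x0:x1] |= new
        painted += int(new.sum())
    dark = rng.uniform(15, 45)
    img[mask] = dark
    return LintImage(
        pixels=np.rint(img).astype(np.uint8),
        cultivar=cultivar,
        true_grade=grade,
        trash_pixels=painted,
    )


def save_image(image: LintImage, path: str) -> None:
    """Write a lint image to PNG (lossless) or JPEG by file extension."""
    from PIL import Image

    Image.fromarray(image.pixels).save(path)


# ---------------------------------------------------------------------------
# feature-table fast path
# ---------------------------------------------------------------------------

def synthesize_feature_table(
    model: GradeModel,
    counts_per_grade: list[int],
    seed: int = 0,
    cultivar: str = "synthetic",
) -> list[FeatureRecord]:
    """Sample 12-feature records directly from the grade model.

    Whole-image colour is drawn from the grade's Gaussian; trash
    percentage from the grade's coverage Gaussian (clipped to [0, 100]).
    Tile statistics emulate intra-sample variation: tile means sit near
    the whole-image value and tile standard deviations are small
    positive half-normals. Per-grade feature means converge to the model
    means as counts grow.
    """
    if len(counts_per_grade) != model.n_grades:
        raise ValueError("counts_per_grade must have one entry per grade")
    counts = np.asarray(counts_per_grade, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("at least one grade needs a positive count")

    records: list[FeatureRecord] = []
    for grade, n in enumerate(counts):
        rng = rng_for(seed, "table", cultivar, grade)
        for _ in range(int(n)):
            L = rng.normal(model.L_mean[grade], model.colour_std)
            a = rng.normal(model.a_mean[grade], model.colour_std)
            b = rng.normal(model.b_mean[grade], model.colour_std)
            trash = 100.0 * np.clip(
                rng.normal(model.trash_cover[grade], model.trash_std), 0.0, 1.0
            )
            tile_sigma = 0.3 * model.colour_std
            vals = np.array(
                [
                    trash,
                    L,
                    a,
                    b,
                    trash + rng.normal(0, 0.1 * model.trash_std * 100),
                    abs(rng.normal(0, 0.5 * model.trash_std * 100)),
                    L + rng.normal(0, 0.2 * tile_sigma),
                    abs(rng.normal(tile_sigma, 0.3 * tile_sigma)),
                    a + rng.normal(0, 0.2 * tile_sigma),
                    abs(rng.normal(tile_sigma, 0.3 * tile_sigma)),
                    b + rng.normal(0, 0.2 * tile_sigma),
                    abs(rng.normal(tile_sigma, 0.3 * tile_sigma)),
                ]
            )
            records.append(FeatureRecord(cultivar=cultivar, grade=grade, values=vals))
    return records


# ---------------------------------------------------------------------------
# simulated expert oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleAccount:
    """Running ledger of oracle queries and the labelling time they cost."""

    queries: int = 0
    seconds_per_label: float = SECONDS_PER_LABEL

    @property
    def total_minutes(self) -> float:
        return self.queries * self.seconds_per_label / 60.0


@dataclass
class SimulatedOracle:
    """Stand-in for the human expert grader.

    Returns an item's hidden true grade, shifted by ±1 grade with
    probability ``noise_rate`` (clamped to the valid range — adjacent-
    grade confusions are how tired human graders actually err), and
    charges ``seconds_per_label`` per query to its account.
    """

    n_grades: int
    noise_rate: float = 0.0
    seed: int = 0
    seconds_per_label: float = SECONDS_PER_LABEL
    account: OracleAccount = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.account is None:
            self.account = OracleAccount(seconds_per_label=self.seconds_per_label)
        self._rng = rng_for(self.seed, "oracle")

    def label(self, item: FeatureRecord | LintImage | int) -> int:
        """Grade one item (a record, an image, or a bare true grade)."""
        if isinstance(item, FeatureRecord):
            truth = item.grade
        elif isinstance(item, LintImage):
            truth = item.true_grade
        else:
            truth = int(item)
        if truth is None:
            raise ValueError("oracle asked to label an item without a hidden grade")
        self.account.queries += 1
        if self.noise_rate > 0 and self._rng.random() < self.noise_rate:
            shift = 1 if self._rng.random() < 0.5 else -1
            truth = int(np.clip(truth + shift, 0, self.n_grades - 1))
        return int(truth)


def oracle_label(
    item: FeatureRecord | LintImage | int, oracle: SimulatedOracle
) -> int:
    """Query the simulated expert for one label (functional surface)."""
    return oracle.label(item)
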