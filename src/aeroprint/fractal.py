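"""Rasterisation and sub-regional box-counting fractal features.

A fingerprint is rasterised onto a binary square image (the unit disc mapped
to the full image square, row 0 at top).  The image is divided into a 6x6
grid and the box-counting fractal dimension D_B is computed independently on
each cell, giving a 36-dimensional feature vector per sample; the four
corner cells lie entirely outside the deposition radius, so their features
are constant (zero) over any dataset and are removed by zero-variance
pruning, leaving the 32 features used for classification.

D_B is the ordinary least-squares slope of ln N_eps versus ln(1/eps), where
N_eps counts the boxes of a fixed-origin eps-grid that contain at least one
set pixel.  D_B is 0 for a point, 1 for a line and 2 for a filled region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .synth import AerosolFingerprint, Dataset

__all__ = [
    "RasterImage",
    "GridSpec",
    "BoxCountResult",
    "FeatureVector",
    "rasterize",
    "box_count_fd",
    "box_counts",
    "subregional_features",
    "fd_ratio",
    "remove_zero_variance",
    "extract_feature_table",
    "default_ladder",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [f"f{i:02d}" for i in range(1, 37)]


@dataclass
class RasterImage:
    """Binary occupancy raster of a fingerprint (W = H, row 0 at top)."""

    pixels: np.ndarray
    width_px: int
    empty: bool = False

    def save_png(self, path) -> None:
        Image.fromarray((self.pixels.astype(np.uint8)) * 255, mode="L").save(path)

    @classmethod
    def from_png(cls, path) -> "RasterImage":
        arr = np.asarray(Image.open(path).convert("L")) > 0
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("raster images must be square")
        return cls(pixels=arr, width_px=arr.shape[0], empty=not arr.any())


@dataclass(frozen=True)
class GridSpec:
    """Sub-regional analysis grid: row-major, 1-based, top-left first."""

    rows: int = 6
    cols: int = 6

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def corner_indices(self) -> tuple[int, int, int, int]:
        """0-based flat indices of the four corner cells."""
        return (
            0,
            self.cols - 1,
            (self.rows - 1) * self.cols,
            self.rows * self.cols - 1,
        )


@dataclass
class BoxCountResult:
    """Box-size ladder, occupied-box counts and the fitted slope."""

    epsilons: np.ndarray
    counts: np.ndarray
    d_b: float
    r_squared: float | None  # None when the fit is undefined (empty/constant)

    def __post_init__(self):
        self.epsilons = np.asarray(self.epsilons, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class FeatureVector:
    """36 per-cell fractal dimensions (row-major) with labels."""

    values: np.ndarray
    sample_id: str = "S1"
    labels: dict = field(default_factory=dict)
    retained_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def rasterize(afp: AerosolFingerprint, width_px: int = 512) -> RasterImage:
    """Map the unit disc onto a ``width_px`` square binary image.

    A pixel is set when at least one particle lands in it.  An empty
    fingerprint yields an all-zero image with the ``empty`` flag set.
    """
    if width_px < 64:
        raise ValueError("width_px must be >= 64")
    img = np.zeros((width_px, width_px), dtype=bool)
    pos = afp.positions
    if len(pos) == 0:
        return RasterImage(pixels=img, width_px=width_px, empty=True)
    col = np.clip(((pos[:, 0] + 1.0) / 2.0 * width_px).astype(int), 0, width_px - 1)
    row = np.clip(((1.0 - pos[:, 1]) / 2.0 * width_px).astype(int), 0, width_px - 1)
    img[row, col] = True
    return RasterImage(pixels=img, width_px=width_px, empty=False)


def default_ladder(size: int) -> np.ndarray:
    """Powers of 2 from 2 px up to size // 2."""
    if size < 4:
        raise ValueError("region too small for a box ladder")
    eps = []
    e = 2
    while e <= size // 2:
        eps.append(e)
        e *= 2
    return np.array(eps, dtype=int)


def box_counts(region: np.ndarray, epsilons) -> np.ndarray:
    """Occupied-box counts N_eps on a fixed-origin grid anchored at the
    region's top-left corner; partial boxes at the far edges count."""
    region = np.asarray(region).astype(bool)
    h, w = region.shape
    out = []
    for eps in np.asarray(epsilons, dtype=int):
        if eps > min(h, w):
            raise ValueError(f"box size {eps} exceeds region extent {min(h, w)}")
        rb = np.arange(0, h, eps)
        cb = np.arange(0, w, eps)
        occ = np.add.reduceat(np.add.reduceat(region, rb, axis=0), cb, axis=1)
        out.append(int((occ > 0).sum()))
    return np.array(out, dtype=int)


def box_count_fd(
    image: RasterImage | np.ndarray,
    region: tuple[int, int, int, int] | None = None,
    epsilons=None,
) -> BoxCountResult:
    """Box-counting fractal dimension of an image or sub-rectangle.

    ``region`` is (row0, col0, height, width).  D_B is the OLS slope of
    ln N_eps against ln(1/eps), all ladder points weighted equally.  An
    empty region returns D_B = 0 with r_squared = None by convention.
    """
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    arr = arr.astype(bool)
    if region is not None:
        r0, c0, h, w = region
        if h <= 0 or w <= 0:
            raise ValueError("degenerate region")
        arr = arr[r0 : r0 + h, c0 : c0 + w]
    h, w = arr.shape
    if epsilons is None:
        epsilons = default_ladder(min(h, w))
    epsilons = np.asarray(epsilons, dtype=int)
    if len(epsilons) < 3:
        raise ValueError("ladder must have at least 3 box sizes")
    counts = box_counts(arr, epsilons)
    order = np.argsort(epsilons)
    if np.any(np.diff(counts[order]) > 0):  # refinement can only add boxes
        raise AssertionError("box counts must be non-increasing in box size")
    if counts.max() == 0:
        return BoxCountResult(epsilons, counts, d_b=0.0, r_squared=None)
    x = np.log(1.0 / epsilons)
    y = np.log(counts)
    if np.allclose(y, y[0]):
        return BoxCountResult(epsilons, counts, d_b=0.0, r_squared=None)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return BoxCountResult(epsilons, counts, d_b=float(slope), r_squared=r2)


def _pad_to_grid(arr: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape
    ph = (-h) % grid.rows
    pw = (-w) % grid.cols
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)))
    return arr, (ph, pw)


def subregional_features(
    image: RasterImage | np.ndarray,
    grid: GridSpec = GridSpec(),
    epsilons=None,
    sample_id: str = "S1",
    labels: dict | None = None,
) -> FeatureVector:
    """Per-cell box-counting dimensions on the analysis grid, row-major.

    The image is padded with empty pixels at the bottom/right when its width
    is not divisible by the grid; each cell is analysed independently with
    ``box_count_fd``.
    """
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    arr, _padding = _pad_to_grid(arr.astype(bool), grid)
    ch = arr.shape[0] // grid.rows
    cw = arr.shape[1] // grid.cols
    eps = default_ladder(min(ch, cw)) if epsilons is None else epsilons
    values = np.empty(grid.n_cells)
    for r in range(grid.rows):
        for c in range(grid.cols):
            cell = arr[r * ch : (r + 1) * ch, c * cw : (c + 1) * cw]
            values[r * grid.cols + c] = box_count_fd(cell, epsilons=eps).d_b
    return FeatureVector(values=values, sample_id=sample_id, labels=labels or {})


def fd_ratio(
    fv: FeatureVector | np.ndarray, reference: FeatureVector | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise fractal-dimension ratio alpha(i) = FD_i / FD_ref,i.

    Cells where both are zero get ratio 1; cells where only the reference is
    zero are flagged undefined (NaN in the ratio, True in the mask).
    """
    a = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    b = (
        reference.values
        if isinstance(reference, FeatureVector)
        else np.asarray(reference, dtype=float)
    )
    if a.shape != b.shape:
        raise ValueError("feature vectors must have equal length")
    ratios = np.empty_like(a)
    undefined = np.zeros(a.shape, dtype=bool)
    both_zero = (a == 0) & (b == 0)
    ref_zero = (b == 0) & ~both_zero
    ok = ~both_zero & ~ref_zero
    ratios[ok] = a[ok] / b[ok]
    ratios[both_zero] = 1.0
    ratios[ref_zero] = np.nan
    undefined[ref_zero] = True
    return ratios, undefined


def remove_zero_variance(features) -> tuple[np.ndarray, np.ndarray]:
    """Drop feature columns whose values are exactly constant across samples.

    Returns the reduced matrix and the boolean retained mask (for
    round-tripping back to the full 36-column layout).  Raises when every
    column is constant.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    retained = X.max(axis=0) != X.min(axis=0)  # variance exactly zero <=> max == min
    if not retained.any():
        raise ValueError("degenerate dataset: every feature column is constant")
    return X[:, retained], retained


def extract_feature_table(
    dataset: Dataset,
    width_px: int = 512,
    grid: GridSpec = GridSpec(),
    epsilons=None,
) -> pd.DataFrame:
    """Rasterise every sample and tabulate the 36 per-cell fractal features.

    Returns a DataFrame with columns sample_id, D, Q_lpm, dp_um, ua_variant,
    f01..f36 (row-major cell order).
    """
    rows = []
    for fp, (_, meta) in zip(dataset.fingerprints, dataset.manifest.iterrows()):
        img = rasterize(fp, width_px=width_px)
        fv = subregional_features(img, grid=grid, epsilons=epsilons)
        row = {
            "sample_id": meta["sample_id"],
            "D": meta["D"],
            "Q_lpm": meta["Q_lpm"],
            "dp_um": meta["dp_um"],
            "ua_variant": meta["ua_variant"],
        }
        row.update({FEATURE_COLUMNS[i]: fv.values[i] for i in range(grid.n_cells)})
        rows.append(row)
    return pd.DataFrame(rows)
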