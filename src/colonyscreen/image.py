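"""Quantification of colony sizes from plate photographs.

The stages mirror a grid-based colony analyzer: pick the colour channel
with the highest contrast, straighten the plate so colony rows run
horizontal, crop away the plastic plate edge to keep the agar area, fit
an equally spaced grid to the intensity profiles, and count the
foreground pixels assigned to every grid node.

Colonies are assumed brighter than the agar by default (reflective
scans); ``dark_colonies=True`` inverts the polarity.  Foreground
segmentation uses a global Otsu threshold on the selected channel.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import signal
from skimage import filters as _skfilters
from skimage import measure as _skmeasure
from skimage import transform as _sktransform

from .core import PlateFormat, PlateMeasurements

__all__ = [
    "PlateImage",
    "GridFit",
    "GridFitError",
    "select_channel",
    "estimate_rotation",
    "crop_plate",
    "fit_grid",
    "quantify_colonies",
    "analyze_image",
]

#: Minimum resolution (dots per inch) below which results degrade.
MIN_DPI = 160.0


class GridFitError(RuntimeError):
    """Raised when too few colony rows or columns can be located."""


@dataclass
class PlateImage:
    """Pixel raster of a photographed plate (grayscale or RGB, 0-255)."""

    pixels: np.ndarray
    dpi: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ValueError("expected a 2-D raster with 1 or 3 channels")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, index: int) -> np.ndarray:
        return self.pixels[:, :, index]


@dataclass
class GridFit:
    """Equally spaced colony grid in image coordinates (pixels)."""

    row_centers: np.ndarray  # y of each colony row, top to bottom
    col_centers: np.ndarray  # x of each colony column, left to right
    spacing_y: float
    spacing_x: float
    rotation_applied: float = 0.0


def select_channel(image: PlateImage) -> int:
    """Index of the channel with the highest contrast (intensity std).

    Grayscale images return 0; exact ties break toward the lower index.
    """
    stds = [float(np.std(image.channel(i))) for i in range(image.n_channels)]
    return int(np.argmax(stds))


def _foreground(channel: np.ndarray, dark_colonies: bool = False) -> np.ndarray:
    values = channel if not dark_colonies else -channel
    if np.ptp(values) == 0:
        return np.zeros(channel.shape, dtype=bool)
    thr = _skfilters.threshold_otsu(values)
    return values > thr


def estimate_rotation(image: PlateImage, max_angle: float = 5.0, step: float = 0.1,
                      dark_colonies: bool = False) -> float:
    """Correction angle (degrees) that makes colony rows horizontal.

    Candidate angles on a ``step``-degree lattice in [-max_angle,
    +max_angle] are scored by the variance of the horizontal (row-sum)
    projection profile of the rotated foreground: aligned rows produce
    sharp peaks and maximal variance.  Only the foreground pixel
    coordinates are rotated, so the search is cheap.  An empty
    foreground returns 0 with a warning.
    """
    channel = image.channel(select_channel(image))
    mask = _foreground(channel, dark_colonies)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        warnings.warn("no foreground pixels; rotation estimate skipped", stacklevel=2)
        return 0.0
    cy, cx = (np.array(mask.shape) - 1) / 2.0
    y = ys - cy
    x = xs - cx
    n_rows_px = mask.shape[0]
    angles = np.arange(-max_angle, max_angle + step / 2, step)
    best_angle, best_score = 0.0, -np.inf
    for a in angles:
        rad = np.deg2rad(a)
        # y-coordinate after applying a correction of `a` degrees
        # (matching skimage.transform.rotate's direction)
        y_rot = -x * np.sin(rad) + y * np.cos(rad)
        prof = np.bincount(
            np.clip(np.round(y_rot + cy).astype(int), 0, n_rows_px - 1),
            minlength=n_rows_px)
        score = float(np.var(prof))
        if score > best_score or (score == best_score and abs(a) < abs(best_angle)):
            best_score, best_angle = score, a
    return float(best_angle)


def _apply_rotation(image: PlateImage, angle: float) -> PlateImage:
    if angle == 0.0:
        return image
    rotated = np.stack([
        _sktransform.rotate(image.channel(i), angle, preserve_range=True,
                            mode="edge", order=1)
        for i in range(image.n_channels)
    ], axis=2)
    return PlateImage(rotated, image.dpi)


def crop_plate(image: PlateImage, method: str = "auto", margin: float = 0.05,
               dark_colonies: bool = False) -> tuple[PlateImage, tuple[int, int]]:
    """Remove the plate edge, keeping the agar area.

    ``auto`` separates the dark plastic rim from the agar with a
    three-class Otsu split and crops to the bounding box of the largest
    connected non-rim region (which must cover at least half the image,
    else the method falls back to ``fixed_margin`` with a warning);
    ``fixed_margin`` trims ``margin`` of each edge; ``none`` is the
    identity.  The returned (row, col) offset maps cropped coordinates
    back to the original raster.
    """
    if method == "none":
        return image, (0, 0)
    h, w = image.pixels.shape[:2]
    if method == "fixed_margin":
        dy, dx = int(h * margin), int(w * margin)
        return PlateImage(image.pixels[dy:h - dy, dx:w - dx], image.dpi), (dy, dx)
    if method != "auto":
        raise ValueError(f"unknown cropping method {method!r}")

    channel = image.channel(select_channel(image))
    try:
        if np.ptp(channel) == 0:
            raise ValueError("uniform image")
        try:
            thresholds = _skfilters.threshold_multiotsu(channel, classes=3)
            rim_cut = thresholds[0] if not dark_colonies else thresholds[-1]
        except ValueError:
            # effectively bimodal (agar + colonies, no rim): everything is interior
            rim_cut = channel.min() - 1 if not dark_colonies else channel.max() + 1
        interior = channel > rim_cut if not dark_colonies else channel < rim_cut
        labels = _skmeasure.label(interior)
        if labels.max() == 0:
            raise ValueError("no interior region")
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        ys, xs = np.nonzero(labels == largest)
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        if (y1 - y0) * (x1 - x0) < 0.5 * h * w:
            raise ValueError("largest agar-like region below half the image")
    except ValueError as exc:
        warnings.warn(f"automatic cropping failed ({exc}); "
                      "falling back to fixed margins", stacklevel=2)
        return crop_plate(image, "fixed_margin", margin, dark_colonies)
    return PlateImage(image.pixels[y0:y1, x0:x1], image.dpi), (y0, x0)


def _fit_axis(profile: np.ndarray, n_expected: int, axis_name: str
              ) -> tuple[np.ndarray, float]:
    """Locate ``n_expected`` equally spaced peaks along one axis.

    Detected peak positions are least-squares fitted to ``a + k * s``
    with integer node indices ``k``; missing peaks are tolerated down to
    half the expected count, and the grid is shifted to the index offset
    that covers the most profile mass.
    """
    approx_spacing = len(profile) / (n_expected + 1)
    peaks, _ = signal.find_peaks(
        profile, distance=max(2, int(0.6 * approx_spacing)),
        height=0.1 * profile.max() if profile.max() > 0 else None)
    if len(peaks) < 0.5 * n_expected:
        raise GridFitError(
            f"only {len(peaks)} of {n_expected} colony {axis_name}s located")
    diffs = np.diff(peaks)
    s0 = float(np.median(diffs))
    multiples = np.maximum(1, np.round(diffs / s0))
    s0 = float(np.median(diffs / multiples))
    idx = np.concatenate([[0], np.cumsum(multiples)]).astype(int)
    if idx[-1] > n_expected - 1 + max(2, n_expected // 8):
        raise GridFitError(f"detected {axis_name} peaks span more than the grid")
    idx = np.minimum(idx, idx[-1])
    A = np.vstack([np.ones_like(idx), idx]).T
    (a, s), *_ = np.linalg.lstsq(A.astype(float), peaks.astype(float), rcond=None)
    # choose the integer shift aligning the n_expected nodes with the mass
    span = idx[-1]
    best_shift, best_mass = 0, -np.inf
    for shift in range(span - n_expected + 1, 1):
        centers = a + (np.arange(n_expected) + shift) * s
        cols = np.round(centers).astype(int)
        inside = (cols >= 0) & (cols < len(profile))
        if inside.sum() < n_expected:
            continue
        mass = float(profile[cols].sum())
        if mass > best_mass:
            best_mass, best_shift = mass, shift
    centers = a + (np.arange(n_expected) + best_shift) * s
    return centers, float(s)


def fit_grid(image: PlateImage, fmt: PlateFormat,
             dark_colonies: bool = False) -> GridFit:
    """Fit the colony grid to the foreground intensity profiles.

    Peaks of the column-sum and row-sum foreground profiles are
    detected and an equally spaced grid with exactly the format's
    physical node count is least-squares fitted; at least half the
    expected peaks must be found on each axis.
    """
    channel = image.channel(select_channel(image))
    mask = _foreground(channel, dark_colonies)
    n_rows, n_cols = fmt.physical_shape
    row_centers, sy = _fit_axis(mask.sum(axis=1).astype(float), n_rows, "row")
    col_centers, sx = _fit_axis(mask.sum(axis=0).astype(float), n_cols, "column")
    return GridFit(row_centers, col_centers, sy, sx)


def quantify_colonies(image: PlateImage, grid: GridFit, fmt: PlateFormat,
                      dark_colonies: bool = False) -> PlateMeasurements:
    """Count foreground pixels at every grid node.

    Each foreground pixel is assigned to the nearest node provided it
    lies within half the grid spacing along both axes (no pixel is
    counted twice).  Colony size is the assigned pixel count;
    circularity is 4*pi*A/P^2 of the largest connected component of the
    assigned blob, clamped to [0, 1] and undefined for empty nodes.
    """
    channel = image.channel(select_channel(image))
    mask = _foreground(channel, dark_colonies)
    ys, xs = np.nonzero(mask)
    n_rows, n_cols = fmt.physical_shape
    ri = np.round((ys - grid.row_centers[0]) / grid.spacing_y).astype(int)
    cj = np.round((xs - grid.col_centers[0]) / grid.spacing_x).astype(int)
    valid = (ri >= 0) & (ri < n_rows) & (cj >= 0) & (cj < n_cols)
    ri_v, cj_v, ys_v, xs_v = ri[valid], cj[valid], ys[valid], xs[valid]
    near = (np.abs(ys_v - grid.row_centers[ri_v]) <= grid.spacing_y / 2.0) & \
           (np.abs(xs_v - grid.col_centers[cj_v]) <= grid.spacing_x / 2.0)
    ri_v, cj_v, ys_v, xs_v = ri_v[near], cj_v[near], ys_v[near], xs_v[near]

    occupied = fmt.occupied_mask()
    node = ri_v * n_cols + cj_v
    counts = np.bincount(node, minlength=n_rows * n_cols).reshape(n_rows, n_cols)
    sizes = np.where(occupied, counts, np.nan)
    circ = np.full((n_rows, n_cols), np.nan)

    order = np.argsort(node, kind="stable")
    node_sorted = node[order]
    ys_s, xs_s = ys_v[order], xs_v[order]
    boundaries = np.searchsorted(node_sorted, np.arange(n_rows * n_cols + 1))
    for flat in np.unique(node_sorted):
        i, j = divmod(int(flat), n_cols)
        if not occupied[i, j]:
            continue
        lo, hi = boundaries[flat], boundaries[flat + 1]
        circ[i, j] = _blob_circularity(ys_s[lo:hi], xs_s[lo:hi])
    return PlateMeasurements("", fmt, sizes, circ)


def _blob_circularity(ys: np.ndarray, xs: np.ndarray) -> float:
    """Circularity 4*pi*A/P^2 of the largest connected component."""
    if ys.size == 1:
        return 1.0
    y0, x0 = ys.min(), xs.min()
    blob = np.zeros((ys.max() - y0 + 1, xs.max() - x0 + 1), dtype=bool)
    blob[ys - y0, xs - x0] = True
    labels = _skmeasure.label(blob, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    component = labels == largest
    area = float(component.sum())
    if area <= 1:
        return 1.0
    perimeter = float(_skmeasure.perimeter(component, neighborhood=4))
    if perimeter <= 0:
        return 1.0
    return float(np.clip(4.0 * np.pi * area / perimeter ** 2, 0.0, 1.0))


def read_plate_image(path: str) -> PlateImage:
    """Load a PNG/JPEG/TIFF plate photograph, keeping any dpi metadata."""
    with Image.open(path) as img:
        dpi_info = img.info.get("dpi")
        dpi = float(dpi_info[0]) if dpi_info else None
        arr = np.asarray(img.convert("RGB") if img.mode not in ("L", "I;16") else img,
                         dtype=float)
    return PlateImage(arr, dpi)


def analyze_image(path: str, fmt: PlateFormat, crop: str = "auto",
                  dark_colonies: bool = False, max_rotation: float = 5.0,
                  out_dir: str | None = None) -> PlateMeasurements:
    """Full image stage: load, straighten, crop, fit grid, quantify.

    Writes the per-plate tab-delimited ``.dat`` colony file when
    ``out_dir`` is given.  Stage failures propagate with the stage name
    prepended.
    """
    from .io import write_colony_file

    image = read_plate_image(path)
    if image.dpi is not None and image.dpi < MIN_DPI:
        warnings.warn(f"{path}: resolution {image.dpi:.0f} dpi is below the "
                      f"recommended {MIN_DPI:.0f} dpi", stacklevel=2)
    stage = "rotation"
    try:
        angle = estimate_rotation(image, max_rotation, dark_colonies=dark_colonies)
        image = _apply_rotation(image, angle)
        stage = "cropping"
        image, _offset = crop_plate(image, crop, dark_colonies=dark_colonies)
        stage = "grid fitting"
        grid = fit_grid(image, fmt, dark_colonies)
        grid.rotation_applied = angle
        stage = "quantification"
        plate = quantify_colonies(image, grid, fmt, dark_colonies)
    except Exception as exc:
        raise type(exc)(f"{stage} failed for {path}: {exc}") from exc
    base = os.path.splitext(os.path.basename(path))[0]
    plate.plate_id = base + ".dat"
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_colony_file(plate, os.path.join(out_dir, plate.plate_id))
    return plate
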