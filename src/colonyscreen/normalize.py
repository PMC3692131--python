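"""Correction of systematic biases in raw colony sizes.

Three multiplicative biases are removed, in order:

1. **Plate effect** — plates differ in average colony size (incubation
   time, agar batch, imaging); every plate is rescaled so its median
   colony size matches a common target.  This assumes most colonies
   have wild-type fitness, i.e. effects of the perturbation are rare.
2. **Row/column effect** — colonies on the outer rows and columns have
   more access to nutrients and grow larger; each row and column is
   rescaled by its median relative to the plate median.
3. **Spatial effect** — uneven agar thickness produces smooth regional
   trends; a running 2-D median surface is estimated and divided out.

All corrections are ratios of medians, so they are robust to the rare
true interactions and equivariant under rescaling of the input.
Zero-size (dead) colonies and pre-flagged colonies are excluded from
every median estimate but are transformed like any other colony
(0 stays 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import PlateFormat, PlateMeasurements

__all__ = [
    "NormalizationConfig",
    "NormalizedPlate",
    "DegeneratePlateError",
    "plate_normalize",
    "rowcol_normalize",
    "spatial_normalize",
    "normalize_plate",
    "normalize_plates",
]


class DegeneratePlateError(ValueError):
    """Raised when a plate's median colony size is zero or undefined."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Parameters of the three bias corrections.

    ``target_median`` is the common plate scale: a positive number, or
    the string ``"batch"`` to use the median of the plate medians of the
    submitted set (keeping control and experiment plates on one scale).
    ``spatial_window`` is the side of the square running-median window
    in grid cells (odd, at least 3).
    """

    target_median: Union[float, str] = "batch"
    plate_enabled: bool = True
    rowcol_enabled: bool = True
    spatial_enabled: bool = True
    spatial_window: int = 7
    rowcol_floor: float = 0.1
    spatial_floor_frac: float = 0.1

    def __post_init__(self) -> None:
        if isinstance(self.target_median, str):
            if self.target_median != "batch":
                raise ValueError("target_median must be a positive number or 'batch'")
        elif self.target_median <= 0:
            raise ValueError("target_median must be positive")
        if self.spatial_window < 3 or self.spatial_window % 2 == 0:
            raise ValueError("spatial_window must be an odd integer >= 3")


@dataclass
class NormalizedPlate:
    """Bias-corrected colony sizes plus per-colony status flags.

    ``sizes`` holds the transformed value for every position (flagged
    colonies are transformed too); :meth:`masked` returns a copy with
    flagged positions set to NaN, which is what scoring consumes.
    """

    plate_id: str
    format: PlateFormat
    sizes: np.ndarray
    raw_sizes: np.ndarray
    flags: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add_flag(self, row: int, col: int, status: str) -> None:
        statuses = self.flags.setdefault((row, col), [])
        if status not in statuses:
            statuses.append(status)

    def flag_mask(self) -> np.ndarray:
        mask = np.zeros(self.format.physical_shape, dtype=bool)
        for (row, col) in self.flags:
            mask[row - 1, col - 1] = True
        return mask

    def masked(self) -> np.ndarray:
        return np.where(self.flag_mask(), np.nan, self.sizes)


def _estimation_values(sizes: np.ndarray, flag_mask: Optional[np.ndarray]) -> np.ndarray:
    """Sizes usable for median estimation: finite, positive, unflagged."""
    est = np.where(np.isfinite(sizes) & (sizes > 0), sizes, np.nan)
    if flag_mask is not None:
        est = np.where(flag_mask, np.nan, est)
    return est


def _nanmedian(values: np.ndarray, **kw) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmedian(values, **kw)


def plate_normalize(sizes: np.ndarray, target_median: float,
                    flag_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Rescale a plate so its median (nonzero, unflagged) size equals the target."""
    est = _estimation_values(sizes, flag_mask)
    nonzero_frac = np.count_nonzero(np.isfinite(est)) / max(
        1, np.count_nonzero(np.isfinite(sizes)))
    if nonzero_frac < 0.5:
        warnings.warn("fewer than half the colonies grew; plate-median scaling "
                      "may not reflect wild-type fitness", stacklevel=2)
    med = float(_nanmedian(est))
    if not np.isfinite(med) or med <= 0:
        raise DegeneratePlateError("plate median colony size is zero or undefined")
    return sizes * (target_median / med)


def rowcol_normalize(sizes: np.ndarray, flag_mask: Optional[np.ndarray] = None,
                     floor: float = 0.1) -> np.ndarray:
    """Divide out multiplicative row and column effects.

    The effect of row i is median(row i)/median(plate) (columns
    analogously); effects are floored at ``floor`` so sparse rows cannot
    blow up the correction.  Rows or columns with no usable colony get
    effect 1 with a warning.
    """
    est = _estimation_values(sizes, flag_mask)
    plate_med = float(_nanmedian(est))
    if not np.isfinite(plate_med) or plate_med <= 0:
        raise DegeneratePlateError("plate median colony size is zero or undefined")
    row_med = _nanmedian(est, axis=1)
    col_med = _nanmedian(est, axis=0)
    if np.isnan(row_med).any() or np.isnan(col_med).any():
        warnings.warn("row/column without usable colonies; effect set to 1", stacklevel=2)
    r = np.where(np.isnan(row_med), 1.0, row_med / plate_med)
    c = np.where(np.isnan(col_med), 1.0, col_med / plate_med)
    r = np.maximum(r, floor)
    c = np.maximum(c, floor)
    return sizes / np.outer(r, c)


def spatial_normalize(sizes: np.ndarray, window: int = 7,
                      flag_mask: Optional[np.ndarray] = None,
                      floor_frac: float = 0.1) -> np.ndarray:
    """Divide out a smooth spatial trend estimated by a running 2-D median.

    The local surface L[i, j] is the NaN-ignoring median of the
    ``window`` x ``window`` neighbourhood (reflected across the plate
    edges, which keeps the correction idempotent at the borders); the
    output is ``sizes * median(plate) / L`` with L floored at
    ``floor_frac * median(plate)``.
    """
    nr, nc = sizes.shape
    if window % 2 == 0 or window < 3 or window > min(nr, nc):
        raise ValueError(f"window must be odd, >=3 and <= {min(nr, nc)}")
    est = _estimation_values(sizes, flag_mask)
    plate_med = float(_nanmedian(est))
    if not np.isfinite(plate_med) or plate_med <= 0:
        raise DegeneratePlateError("plate median colony size is zero or undefined")
    half = window // 2
    padded = np.pad(est, half, mode="reflect")
    windows = sliding_window_view(padded, (window, window))
    local = _nanmedian(windows.reshape(nr, nc, -1), axis=2)
    local = np.where(np.isnan(local), plate_med, local)
    local = np.maximum(local, floor_frac * plate_med)
    return sizes * (plate_med / local)


def normalize_plate(plate: PlateMeasurements,
                    config: NormalizationConfig = NormalizationConfig(),
                    flags: Optional[dict[tuple[int, int], list[str]]] = None,
                    target_median: Optional[float] = None) -> NormalizedPlate:
    """Run the full three-stage correction on one plate.

    ``flags`` carries pre-normalization filter results (e.g. suspected
    contamination); flagged colonies are excluded from every median
    estimate but still transformed.  ``target_median`` overrides the
    config's plate-scale target (used by :func:`normalize_plates` to
    impose the batch median); when the config says ``"batch"`` and no
    override is given, the plate's own median is used, i.e. the plate
    stage leaves the scale unchanged.
    """
    flags = dict(flags) if flags else {}
    sizes = plate.sizes.astype(float).copy()
    flag_mask = np.zeros(sizes.shape, dtype=bool)
    for (row, col) in flags:
        flag_mask[row - 1, col - 1] = True
    provenance: dict = {"stages": []}

    if config.plate_enabled:
        if target_median is not None:
            target = float(target_median)
        elif config.target_median == "batch":
            target = float(_nanmedian(_estimation_values(sizes, flag_mask)))
        else:
            target = float(config.target_median)
        sizes = plate_normalize(sizes, target, flag_mask)
        provenance["stages"].append(("plate", {"target_median": target}))
    if config.rowcol_enabled:
        sizes = rowcol_normalize(sizes, flag_mask, config.rowcol_floor)
        provenance["stages"].append(("rowcol", {"floor": config.rowcol_floor}))
    if config.spatial_enabled:
        sizes = spatial_normalize(sizes, config.spatial_window, flag_mask,
                                  config.spatial_floor_frac)
        provenance["stages"].append(
            ("spatial", {"window": config.spatial_window,
                         "floor_frac": config.spatial_floor_frac}))

    out = NormalizedPlate(plate.plate_id, plate.format, sizes,
                          plate.sizes.copy(), flags, provenance)
    return out


def normalize_plates(plates: list[PlateMeasurements],
                     config: NormalizationConfig = NormalizationConfig(),
                     flags: Optional[list[dict[tuple[int, int], list[str]]]] = None,
                     ) -> list[NormalizedPlate]:
    """Normalize a set of plates onto a common scale.

    With ``target_median="batch"`` the common target is the median of
    the per-plate medians (nonzero, unflagged colonies), so control and
    experiment plates land on the same scale.
    """
    if flags is None:
        flags = [{} for _ in plates]
    target: Optional[float] = None
    if config.plate_enabled and config.target_median == "batch":
        medians = []
        for plate, fl in zip(plates, flags):
            mask = np.zeros(plate.sizes.shape, dtype=bool)
            for (row, col) in fl:
                mask[row - 1, col - 1] = True
            medians.append(float(_nanmedian(_estimation_values(plate.sizes, mask))))
        target = float(np.median(medians))
    return [normalize_plate(p, config, f, target) for p, f in zip(plates, flags)]
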