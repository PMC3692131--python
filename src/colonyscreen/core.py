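"""Core domain types for array-based colony screens.

A screen consists of agar plates on which an ordered array of mutant
strains is pinned as colonies.  The package works with four pinning
densities (96, 384, 768 and 1536 colonies per plate); the 768 format is
two 384-density arrays interleaved on a 32 x 48 physical grid.  Plates
are linked to their experimental role (control vs. query screen) through
a five-field underscore-delimited filename convention.

All plate coordinates are 1-based, row 1 at the top, column 1 at the
left.  Grids are stored dense and row-major.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "PlateFormat",
    "FORMATS",
    "PlateMetadata",
    "ColonyMeasurement",
    "PlateMeasurements",
    "ArrayEntry",
    "ArrayDefinition",
    "ReplicateLayout",
    "ScoreRecord",
    "MalformedNameError",
    "PairingError",
    "parse_plate_filename",
    "render_plate_filename",
    "pair_plates",
]


class MalformedNameError(ValueError):
    """Raised when a plate filename does not follow the naming convention."""


class PairingError(ValueError):
    """Raised when an experiment plate has several candidate control plates."""


@dataclass(frozen=True)
class PlateFormat:
    """Pinning density of a plate.

    ``n_rows``/``n_cols`` describe the logical array; for the interleaved
    768 format two 16 x 24 arrays share a 32 x 48 physical grid, each
    occupying one parity class of the checkerboard (sub-array A at
    odd/odd positions, sub-array B at even/even).
    """

    n_rows: int
    n_cols: int
    interleaved: bool = False

    def __post_init__(self) -> None:
        if (self.n_rows, self.n_cols) not in {(8, 12), (16, 24), (32, 48)}:
            raise ValueError(f"unsupported plate format {self.n_rows}x{self.n_cols}")
        if self.interleaved and (self.n_rows, self.n_cols) != (16, 24):
            raise ValueError("only the 384 layout can be interleaved (768 format)")

    @property
    def physical_shape(self) -> tuple[int, int]:
        """(rows, cols) of the physical pin grid."""
        if self.interleaved:
            return (2 * self.n_rows, 2 * self.n_cols)
        return (self.n_rows, self.n_cols)

    @property
    def n_colonies(self) -> int:
        if self.interleaved:
            return 2 * self.n_rows * self.n_cols
        return self.n_rows * self.n_cols

    def occupied_mask(self) -> np.ndarray:
        """Boolean grid over the physical shape: True where a colony is pinned."""
        nr, nc = self.physical_shape
        if not self.interleaved:
            return np.ones((nr, nc), dtype=bool)
        r = np.arange(1, nr + 1)[:, None]
        c = np.arange(1, nc + 1)[None, :]
        return (r % 2) == (c % 2)

    def positions(self) -> Iterator[tuple[int, int]]:
        """Yield 1-based (row, col) of every occupied physical position."""
        mask = self.occupied_mask()
        for i, j in zip(*np.nonzero(mask)):
            yield (int(i) + 1, int(j) + 1)

    def subarray(self, row: int, col: int) -> Optional[str]:
        """Sub-array label for interleaved plates ('A'/'B'), else None."""
        if not self.interleaved:
            return None
        if row % 2 == 1 and col % 2 == 1:
            return "A"
        if row % 2 == 0 and col % 2 == 0:
            return "B"
        return None


#: Registry of the supported pinning densities, keyed by colony count.
FORMATS: dict[int, PlateFormat] = {
    96: PlateFormat(8, 12),
    384: PlateFormat(16, 24),
    768: PlateFormat(16, 24, interleaved=True),
    1536: PlateFormat(32, 48),
}

_CONTROL_TOKENS = {"ctrl", "wt"}


@dataclass(frozen=True)
class PlateMetadata:
    """Screen role of a plate, parsed from its filename."""

    prefix: str
    plate_type: str  # "control" | "experiment"
    query: str
    plate_number: int
    suffix: str

    @property
    def is_control(self) -> bool:
        return self.plate_type == "control"


def parse_plate_filename(name: str) -> PlateMetadata:
    """Parse a plate filename into :class:`PlateMetadata`.

    The base name must split on ``_`` into at least five fields:
    prefix, plate type, query strain, plate number and suffix.  A plate
    is a control iff its type field is ``ctrl`` or ``wt``
    (case-insensitive); ``dm`` or any other token marks an experiment
    plate.  Extra underscores are absorbed into the prefix, so the four
    trailing fields are taken from the end.

    >>> parse_plate_filename("2013-05-12_ctrl_YML032C_2_rep3.jpg").query
    'YML032C'
    """
    base = os.path.basename(name)
    root, ext = os.path.splitext(base)
    if not re.fullmatch(r"\.[A-Za-z0-9]{1,5}", ext):
        root = base  # no recognisable extension; treat whole name as fields
    fields = root.split("_")
    if len(fields) < 5:
        raise MalformedNameError(
            f"{name!r}: expected at least five underscore-delimited fields, got {len(fields)}"
        )
    prefix = "_".join(fields[:-4])
    type_token, query, number_token, suffix = fields[-4], fields[-3], fields[-2], fields[-1]
    try:
        plate_number = int(number_token)
    except ValueError as exc:
        raise MalformedNameError(
            f"{name!r}: plate number field {number_token!r} is not an integer"
        ) from exc
    if plate_number < 1:
        raise MalformedNameError(f"{name!r}: plate number must be positive")
    plate_type = "control" if type_token.lower() in _CONTROL_TOKENS else "experiment"
    return PlateMetadata(prefix, plate_type, query, plate_number, suffix)


def render_plate_filename(meta: PlateMetadata, ext: str = "") -> str:
    """Inverse of :func:`parse_plate_filename` on canonical type tokens."""
    token = "ctrl" if meta.is_control else "dm"
    name = "_".join([meta.prefix, token, meta.query, str(meta.plate_number), meta.suffix])
    return name + ext


def pair_plates(
    plates: list[PlateMetadata],
) -> tuple[list[tuple[PlateMetadata, PlateMetadata]], list[PlateMetadata]]:
    """Link every experiment plate to its control plate.

    A control matches an experiment plate when it shares the plate
    number; when several controls share the number, the query strain
    must also match and must single out exactly one.

    Returns ``(pairs, unpaired)`` where ``unpaired`` lists experiment
    plates without any matching control (excluded from scoring).

    Raises
    ------
    PairingError
        If an experiment plate has more than one candidate control.
    """
    controls = [p for p in plates if p.is_control]
    experiments = [p for p in plates if not p.is_control]
    pairs: list[tuple[PlateMetadata, PlateMetadata]] = []
    unpaired: list[PlateMetadata] = []
    for exp in experiments:
        candidates = [c for c in controls if c.plate_number == exp.plate_number]
        if len(candidates) > 1:
            candidates = [c for c in candidates if c.query == exp.query] or candidates
        if len(candidates) == 1:
            pairs.append((exp, candidates[0]))
        elif not candidates:
            unpaired.append(exp)
        else:
            names = ", ".join(f"{c.prefix}/{c.query}/p{c.plate_number}" for c in candidates)
            raise PairingError(
                f"experiment plate {exp.query}/p{exp.plate_number} has several "
                f"candidate controls: {names}"
            )
    return pairs, unpaired


@dataclass
class ColonyMeasurement:
    """Raw quantification of one colony: foreground pixel count and shape."""

    row: int
    col: int
    size: int
    circularity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("colony size must be non-negative")
        if self.size == 0:
            self.circularity = None


class PlateMeasurements:
    """Dense grid of raw colony sizes for one plate.

    ``sizes`` and ``circularity`` are arrays over the physical grid;
    unoccupied nodes of the interleaved 768 format hold NaN.
    """

    def __init__(self, plate_id: str, fmt: PlateFormat, sizes: np.ndarray,
                 circularity: Optional[np.ndarray] = None):
        shape = fmt.physical_shape
        sizes = np.asarray(sizes, dtype=float)
        if sizes.shape != shape:
            raise ValueError(f"sizes shape {sizes.shape} != physical grid {shape}")
        occ = fmt.occupied_mask()
        if np.isnan(sizes[occ]).any():
            raise ValueError("missing measurement at an occupied grid position")
        if (sizes[occ] < 0).any():
            raise ValueError("negative colony size")
        self.plate_id = plate_id
        self.format = fmt
        self.sizes = np.where(occ, sizes, np.nan)
        if circularity is None:
            circularity = np.full(shape, np.nan)
        self.circularity = np.asarray(circularity, dtype=float)

    @classmethod
    def from_measurements(cls, plate_id: str, fmt: PlateFormat,
                          measurements: list[ColonyMeasurement]) -> "PlateMeasurements":
        shape = fmt.physical_shape
        sizes = np.full(shape, np.nan)
        circ = np.full(shape, np.nan)
        occ = fmt.occupied_mask()
        seen: set[tuple[int, int]] = set()
        for m in measurements:
            if not (1 <= m.row <= shape[0] and 1 <= m.col <= shape[1]):
                raise ValueError(f"position ({m.row},{m.col}) outside the {shape} grid")
            if not occ[m.row - 1, m.col - 1]:
                raise ValueError(f"position ({m.row},{m.col}) is not pinned in this format")
            if (m.row, m.col) in seen:
                raise ValueError(f"duplicate position ({m.row},{m.col})")
            seen.add((m.row, m.col))
            sizes[m.row - 1, m.col - 1] = m.size
            if m.circularity is not None:
                circ[m.row - 1, m.col - 1] = m.circularity
        if len(seen) != fmt.n_colonies:
            raise ValueError(
                f"incomplete plate: {len(seen)} of {fmt.n_colonies} positions present"
            )
        return cls(plate_id, fmt, sizes, circ)

    def measurements(self) -> Iterator[ColonyMeasurement]:
        for row, col in self.format.positions():
            size = int(round(self.sizes[row - 1, col - 1]))
            c = self.circularity[row - 1, col - 1]
            yield ColonyMeasurement(row, col, size, None if np.isnan(c) else float(c))

    def __len__(self) -> int:
        return self.format.n_colonies


@dataclass(frozen=True)
class ArrayEntry:
    """One position of an array definition: gene and chromosomal locus."""

    gene: str
    chromosome: Optional[str] = None
    position_kb: Optional[float] = None

    @property
    def is_blank(self) -> bool:
        return self.gene.upper() == "BLANK"

    @property
    def has_locus(self) -> bool:
        return self.chromosome is not None and self.position_kb is not None


class ArrayDefinition:
    """Map from (plate number, row, col) to the array strain at that position."""

    def __init__(self, entries: dict[tuple[int, int, int], ArrayEntry]):
        self.entries = dict(entries)

    def get(self, plate_number: int, row: int, col: int) -> Optional[ArrayEntry]:
        return self.entries.get((plate_number, row, col))

    def gene_at(self, plate_number: int, row: int, col: int) -> Optional[str]:
        e = self.get(plate_number, row, col)
        return e.gene if e is not None else None

    def locus_of_gene(self, gene: str) -> Optional[tuple[str, float]]:
        """Locus of the first array entry carrying this gene name, if known."""
        for e in self.entries.values():
            if e.gene == gene and e.has_locus:
                return (e.chromosome, e.position_kb)  # type: ignore[return-value]
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReplicateLayout:
    """Technical-replicate structure of a plate.

    ``single`` maps each position to itself; ``quad`` groups disjoint
    2 x 2 blocks of the physical grid (the same strain pinned four
    times).
    """

    kind: str = "single"

    def __post_init__(self) -> None:
        if self.kind not in ("single", "quad"):
            raise ValueError("layout kind must be 'single' or 'quad'")

    def group_key(self, row: int, col: int) -> tuple[int, int]:
        if self.kind == "single":
            return (row, col)
        return ((row - 1) // 2 + 1, (col - 1) // 2 + 1)

    def groups(self, fmt: PlateFormat) -> dict[tuple[int, int], list[tuple[int, int]]]:
        out: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for row, col in fmt.positions():
            out.setdefault(self.group_key(row, col), []).append((row, col))
        return out


@dataclass
class ScoreRecord:
    """One row of the nine-column score table.

    ``normalized_size`` and ``score`` are ``None`` (serialized as
    ``NA``) when the colony failed a filter or carries no score;
    ``kvp`` holds free-form key=value annotations such as the filter
    status.
    """

    row: int
    col: int
    raw_size: int
    plate_id: str
    query: str
    array_gene: str
    normalized_size: Optional[float] = None
    score: Optional[float] = None
    kvp: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalized_size is None and self.score is not None:
            raise ValueError("a colony without a normalized size cannot carry a score")
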