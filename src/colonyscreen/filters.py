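"""Per-colony quality filters.

Four independent rules flag colonies whose sizes cannot be trusted:

* **jackknife (JK)** — a technical replicate so different from its
  siblings that removing it collapses the group's spread;
* **linkage (LK)** — array genes within a user-set chromosomal distance
  of the query gene: forming the double mutant then requires a rare
  meiotic crossover, so small colonies reflect crossover frequency, not
  fitness;
* **big colony (BG)** — colonies much larger than the plate median,
  indicating contamination or escaped diploids;
* **competition (CF)** — colonies with a positive interaction score
  adjacent to strongly negative neighbours: extra nutrients left by the
  small neighbours can inflate the colony, a potential false positive.

Filters only annotate; they never alter a surviving colony's size.
BG and JK run before normalization (oversized or discordant colonies
corrupt the median estimates); LK runs before scoring and CF on the
finished score grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ArrayDefinition, ReplicateLayout

__all__ = [
    "FilterConfig",
    "jackknife_filter",
    "linkage_filter",
    "big_colony_filter",
    "competition_flag",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the four colony filters.

    ``jackknife_fraction`` is the minimum fractional collapse of the
    replicate spread that marks an outlier; ``linkage_threshold_kb`` the
    chromosomal distance below which array genes are linked to the
    query; ``big_colony_multiplier`` the plate-median multiple above
    which a colony is suspect; the competition thresholds bound the
    positive score band to treat with caution (0.1 to 0.3) and the
    negative neighbour level that triggers the flag.
    """

    jackknife_enabled: bool = True
    jackknife_fraction: float = 0.9
    linkage_enabled: bool = True
    linkage_threshold_kb: float = 200.0
    big_colony_enabled: bool = True
    big_colony_multiplier: float = 1.5
    competition_enabled: bool = True
    competition_pos_threshold: float = 0.1
    competition_neg_threshold: float = -0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.jackknife_fraction < 1.0):
            raise ValueError("jackknife_fraction must lie in (0, 1)")
        if self.linkage_threshold_kb <= 0:
            raise ValueError("linkage_threshold_kb must be positive")
        if self.big_colony_multiplier <= 1.0:
            raise ValueError("big_colony_multiplier must exceed 1")
        if not (self.competition_pos_threshold > 0 > self.competition_neg_threshold):
            raise ValueError("competition thresholds must straddle zero")


def jackknife_filter(replicate_sizes, fraction: float = 0.9) -> set[int]:
    """Flag at most one replicate whose removal collapses the group spread.

    Replicate ``k`` is an outlier when the standard deviation of the
    group without it is below ``(1 - fraction)`` times the full-group
    standard deviation.  With several candidates the one causing the
    largest collapse is flagged (ties broken toward the lower index);
    groups of fewer than three replicates are left untouched.  Returned
    indices are 0-based.
    """
    values = np.asarray(replicate_sizes, dtype=float)
    n = len(values)
    if n < 3 or not np.isfinite(values).all():
        return set()
    full_std = float(np.std(values))
    if full_std == 0.0:
        return set()
    loo_std = np.array([np.std(np.delete(values, k)) for k in range(n)])
    candidates = np.nonzero(loo_std < (1.0 - fraction) * full_std)[0]
    if candidates.size == 0:
        return set()
    best = int(candidates[np.argmin(loo_std[candidates])])
    return {best}


def linkage_filter(query_locus: Optional[tuple[str, float]],
                   array_def: ArrayDefinition,
                   plate_number: int,
                   threshold_kb: float = 200.0) -> set[tuple[int, int]]:
    """Flag positions whose array gene is chromosomally linked to the query.

    A position is linked when its gene lies on the query's chromosome
    within ``threshold_kb`` kilobases (inclusive).  Entries without a
    locus are never flagged; an unknown query locus skips the filter
    with a warning.
    """
    if query_locus is None:
        warnings.warn("query locus unknown; linkage filter skipped", stacklevel=2)
        return set()
    q_chrom, q_pos = query_locus
    flagged: set[tuple[int, int]] = set()
    for (pnum, row, col), entry in array_def.entries.items():
        if pnum != plate_number or not entry.has_locus:
            continue
        if entry.chromosome == q_chrom and abs(entry.position_kb - q_pos) <= threshold_kb:
            flagged.add((row, col))
    return flagged


def big_colony_filter(sizes: np.ndarray, multiplier: float = 1.5) -> set[tuple[int, int]]:
    """Flag colonies strictly larger than ``multiplier`` times the plate median.

    The median is taken over nonzero colonies (dead positions say
    nothing about the typical size).  Returned positions are 1-based.
    """
    values = np.asarray(sizes, dtype=float)
    usable = values[np.isfinite(values) & (values > 0)]
    if usable.size == 0:
        raise ValueError("plate median undefined: no nonzero colony")
    med = float(np.median(usable))
    flagged = set()
    for i, j in zip(*np.nonzero(np.isfinite(values) & (values > multiplier * med))):
        flagged.add((int(i) + 1, int(j) + 1))
    return flagged


def competition_flag(scores: np.ndarray,
                     layout: ReplicateLayout = ReplicateLayout("single"),
                     pos_threshold: float = 0.1,
                     neg_threshold: float = -0.1) -> set[tuple[int, int]]:
    """Flag potential false-positive scores caused by nutrient competition.

    A position is flagged when its score exceeds ``pos_threshold`` and
    at least one of its 8-neighbours scores below ``neg_threshold``.
    Under a quad layout the 2 x 2 technical-replicate blocks are
    collapsed (NaN-ignoring mean) before the adjacency test, and a
    flagged block flags all its members.  NaN scores never trigger or
    receive the flag.  Returned positions are 1-based on the input grid.
    """
    scores = np.asarray(scores, dtype=float)
    if layout.kind == "quad":
        nr, nc = scores.shape
        blocks = scores.reshape(nr // 2, 2, nc // 2, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            grid = np.nanmean(blocks, axis=(1, 3))
    else:
        grid = scores
    flagged_groups = _competition_on_grid(grid, pos_threshold, neg_threshold)
    if layout.kind != "quad":
        return {(i + 1, j + 1) for i, j in flagged_groups}
    out: set[tuple[int, int]] = set()
    for gi, gj in flagged_groups:
        for di in range(2):
            for dj in range(2):
                if np.isfinite(scores[2 * gi + di, 2 * gj + dj]):
                    out.add((2 * gi + di + 1, 2 * gj + dj + 1))
    return out


def _competition_on_grid(grid: np.ndarray, pos_thr: float, neg_thr: float
                         ) -> set[tuple[int, int]]:
    nr, nc = grid.shape
    flagged = set()
    for i in range(nr):
        for j in range(nc):
            if not (np.isfinite(grid[i, j]) and grid[i, j] > pos_thr):
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nr and 0 <= nj < nc \
                            and np.isfinite(grid[ni, nj]) and grid[ni, nj] < neg_thr:
                        flagged.add((i, j))
                        break
                else:
                    continue
                break
    return flagged
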