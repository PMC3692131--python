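"""Multiplicative genetic-interaction scoring against a control screen.

Colony fitness is the normalized colony size divided by the reference
scale C (the median unflagged colony size of the matched control
plate), so wild-type fitness sits near 1.  For a double mutant at one
array position the score is

    score = W_ij - W_i * W_j

where W_ij is the observed fitness on the experiment plate, W_i the
query-strain fitness (the plate-wide median fitness of the experiment,
which under the rare-effects assumption isolates the query's own
defect) and W_j the array-strain fitness (median over its technical
replicates on the control plate).  Negative scores mean the double
mutant is sicker than the product of the single mutants predicts
(aggravating; the extreme is synthetic lethality at W_ij = 0), positive
scores mean it is healthier (alleviating / suppression).

Calibration bands from yeast screens of this design: scores below -0.3
are strong effects visible by eye on the plate image; |score| < 0.1 is
unlikely to reproduce; positive scores in 0.1-0.3 warrant caution
because of the competition effect.  These bands are documentation, not
computed statistics.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np

from .core import ArrayDefinition, ReplicateLayout, ScoreRecord
from .filters import FilterConfig, competition_flag, linkage_filter
from .normalize import NormalizedPlate

__all__ = [
    "ScoringError",
    "reference_scale",
    "strain_fitness",
    "query_fitness",
    "multiplicative_score",
    "score_screen",
    "average_replicates",
]


class ScoringError(ValueError):
    """Raised when a plate pair cannot be scored (e.g. empty control)."""


def _nanmedian(values: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmedian(values))


def reference_scale(control: NormalizedPlate) -> float:
    """Reference scale C: median unflagged normalized size on the control.

    Dividing colony sizes by C expresses them as fitness with wild type
    near 1.
    """
    c = _nanmedian(control.masked())
    if not np.isfinite(c) or c <= 0:
        raise ScoringError(
            f"control plate {control.plate_id}: no usable colony to set the fitness scale")
    return c


def strain_fitness(control: NormalizedPlate, layout: ReplicateLayout,
                   C: float) -> dict[tuple[int, int], float]:
    """Array-strain fitness W_j per replicate group of the control plate.

    W_j is the median of the strain's unflagged replicate sizes divided
    by C; NaN when no replicate survives filtering.
    """
    masked = control.masked()
    out: dict[tuple[int, int], float] = {}
    for key, members in layout.groups(control.format).items():
        vals = np.array([masked[r - 1, c - 1] for r, c in members])
        out[key] = _nanmedian(vals) / C
    return out


def query_fitness(experiment: NormalizedPlate, C: float) -> float:
    """Query fitness W_i: plate-wide median fitness of the experiment.

    Because interaction effects are rare, the median double-mutant
    fitness reflects the query single mutant's own growth defect
    relative to the control.  Note that this is only identifiable when
    the plate-scale normalization has not forced the experiment plate
    onto the control's median (see the normalization docs).
    """
    return _nanmedian(experiment.masked()) / C


def multiplicative_score(w_ij: float, w_i: float, w_j: float) -> float:
    """Deviation of the observed fitness from the multiplicative expectation."""
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in (w_ij, w_i, w_j)):
        return float("nan")
    return w_ij - w_i * w_j


def score_screen(experiment: NormalizedPlate, control: NormalizedPlate,
                 layout: ReplicateLayout = ReplicateLayout("single"),
                 array_def: Optional[ArrayDefinition] = None,
                 filters: FilterConfig = FilterConfig(),
                 query: str = "query",
                 plate_number: int = 1,
                 control_genes: frozenset[str] = frozenset({"BLANK"}),
                 ) -> list[ScoreRecord]:
    """Score one experiment plate against its matched control.

    Both plates must be normalized onto a common scale.  The linkage
    filter (when an array definition with loci is supplied) masks
    positions chromosomally linked to the query before scoring; BLANK
    and control-gene positions keep their normalized size but receive no
    score; the competition flag annotates suspect positives on the
    finished score grid without removing them.
    """
    if experiment.format.physical_shape != control.format.physical_shape:
        raise ScoringError("experiment and control plate formats differ")
    fmt = experiment.format

    if filters.linkage_enabled and array_def is not None:
        locus = array_def.locus_of_gene(query)
        for (row, col) in linkage_filter(locus, array_def, plate_number,
                                         filters.linkage_threshold_kb):
            experiment.add_flag(row, col, "LK")

    C = reference_scale(control)
    w_j = strain_fitness(control, layout, C)
    w_i = query_fitness(experiment, C)

    exp_masked = experiment.masked()
    nr, nc = fmt.physical_shape
    score_grid = np.full((nr, nc), np.nan)
    records: list[ScoreRecord] = []
    index = 0
    for row, col in fmt.positions():
        index += 1
        gene = None
        if array_def is not None:
            gene = array_def.gene_at(plate_number, row, col)
        if gene is None:
            gene = str(index)
        flagged = (row, col) in experiment.flags
        nsize = exp_masked[row - 1, col - 1]
        w_ij = nsize / C if np.isfinite(nsize) else float("nan")
        scoreable = (not flagged and np.isfinite(nsize)
                     and gene.upper() not in control_genes and gene != query)
        score = multiplicative_score(w_ij, w_i, w_j[layout.group_key(row, col)]) \
            if scoreable else float("nan")
        if np.isfinite(score):
            score_grid[row - 1, col - 1] = score
        kvp: dict[str, str] = {}
        statuses = experiment.flags.get((row, col), [])
        if statuses:
            kvp["status"] = ",".join(statuses)
        sub = fmt.subarray(row, col)
        if sub is not None:
            kvp["subarray"] = sub
        raw = experiment.raw_sizes[row - 1, col - 1]
        records.append(ScoreRecord(
            row=row, col=col, raw_size=int(raw) if np.isfinite(raw) else 0,
            plate_id=experiment.plate_id, query=query, array_gene=gene,
            normalized_size=None if not np.isfinite(nsize) else float(nsize),
            score=None if not np.isfinite(score) else float(score),
            kvp=kvp,
        ))

    if filters.competition_enabled:
        suspects = competition_flag(score_grid, layout,
                                    filters.competition_pos_threshold,
                                    filters.competition_neg_threshold)
        by_pos = {(r.row, r.col): r for r in records}
        for pos in suspects:
            rec = by_pos.get(pos)
            if rec is not None:
                statuses = rec.kvp.get("status")
                rec.kvp["status"] = f"{statuses},CF" if statuses else "CF"
    return records


def average_replicates(records: list[ScoreRecord],
                       layout: ReplicateLayout = ReplicateLayout("single"),
                       ) -> list[ScoreRecord]:
    """Collapse technical (and biological) replicates per (query, gene).

    Normalized sizes and scores are averaged over the non-NA members of
    each group; a group with no surviving member stays NA.  The combined
    record sits at the group's top-left position and reports the number
    of averaged replicates as ``n=`` in the kvp column.
    """
    groups: dict[tuple[str, str], list[ScoreRecord]] = {}
    for rec in records:
        groups.setdefault((rec.query, rec.array_gene), []).append(rec)
    combined: list[ScoreRecord] = []
    for (query, gene), members in groups.items():
        members = sorted(members, key=lambda r: (r.plate_id, r.row, r.col))
        nsizes = [m.normalized_size for m in members if m.normalized_size is not None]
        scores = [m.score for m in members if m.score is not None]
        lead = members[0]
        kvp = {"n": str(len(scores) if scores else 0)}
        combined.append(ScoreRecord(
            row=lead.row, col=lead.col, raw_size=lead.raw_size,
            plate_id=lead.plate_id, query=query, array_gene=gene,
            normalized_size=float(np.mean(nsizes)) if nsizes else None,
            score=float(np.mean(scores)) if scores and nsizes else None,
            kvp=kvp,
        ))
    return combined
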