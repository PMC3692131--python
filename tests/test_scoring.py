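"""Fitness conversion and the multiplicative interaction score."""

import math

import numpy as np
import pytest

from colonyscreen import (
    FORMATS,
    ArrayDefinition,
    ArrayEntry,
    FilterConfig,
    NormalizationConfig,
    NormalizedPlate,
    ReplicateLayout,
    ScoringError,
    SyntheticScreenConfig,
    average_replicates,
    multiplicative_score,
    normalize_plates,
    query_fitness,
    reference_scale,
    score_screen,
    simulate_screen,
    strain_fitness,
)
from colonyscreen.core import ScoreRecord

NO_FLAG_FILTERS = FilterConfig(competition_enabled=False, linkage_enabled=False)


def _normalized(sizes, fmt=None, plate_id="p", flags=None):
    fmt = fmt or FORMATS[96]
    sizes = np.asarray(sizes, dtype=float)
    return NormalizedPlate(plate_id, fmt, sizes, sizes.copy(), flags or {})


class TestReferenceScale:
    def test_uniform_control_sets_scale(self):
        plate = _normalized(np.full((8, 12), 500.0))
        assert reference_scale(plate) == 500.0

    def test_scale_is_the_median(self):
        sizes = np.full((8, 12), 500.0)
        sizes[0, :6] = 400.0
        sizes[0, 6:] = 600.0
        assert reference_scale(_normalized(sizes)) == 500.0

    def test_fully_flagged_control_aborts(self):
        flags = {(r, c): ["BG"] for r, c in FORMATS[96].positions()}
        with pytest.raises(ScoringError):
            reference_scale(_normalized(np.full((8, 12), 500.0), flags=flags))


class TestStrainAndQueryFitness:
    def test_quad_strain_fitness_is_replicate_median_over_scale(self):
        sizes = np.full((8, 12), 500.0)
        sizes[0:2, 0:2] = [[480, 500], [520, 500]]
        w = strain_fitness(_normalized(sizes), ReplicateLayout("quad"), 500.0)
        assert w[(1, 1)] == pytest.approx(1.0)

    def test_dead_strain_has_zero_fitness(self):
        sizes = np.full((8, 12), 500.0)
        sizes[0:2, 0:2] = 0.0
        w = strain_fitness(_normalized(sizes), ReplicateLayout("quad"), 500.0)
        assert w[(1, 1)] == 0.0

    def test_fully_flagged_strain_is_na(self):
        flags = {(1, 1): ["BG"], (1, 2): ["BG"], (2, 1): ["JK"], (2, 2): ["BG"]}
        w = strain_fitness(_normalized(np.full((8, 12), 500.0), flags=flags),
                           ReplicateLayout("quad"), 500.0)
        assert math.isnan(w[(1, 1)])

    def test_query_fitness_is_relative_plate_median(self):
        assert query_fitness(_normalized(np.full((8, 12), 400.0)), 500.0) == \
            pytest.approx(0.8)

    def test_identical_plates_give_unit_query_fitness(self):
        plate = _normalized(np.full((8, 12), 500.0))
        assert query_fitness(plate, reference_scale(plate)) == 1.0

    def test_injected_query_defect_recovered_without_plate_stage(self):
        """A whole-plate query fitness defect survives only when the
        plate-scale stage is anchored to the control (here: disabled),
        since an overall 0.7x cannot be told apart from a plate effect."""
        cfg = SyntheticScreenConfig(format=FORMATS[1536], seed=21,
                                    query_fitness=0.7,
                                    plate_scale_range=(1.0, 1.0))
        _, control, experiment = simulate_screen(cfg)
        ncfg = NormalizationConfig(plate_enabled=False)
        nc, ne = normalize_plates([control, experiment], ncfg)
        w_i = query_fitness(ne, reference_scale(nc))
        assert w_i == pytest.approx(0.7, abs=0.05)


class TestMultiplicativeScore:
    @pytest.mark.parametrize("triple,expected", [
        ((1.0, 1.0, 1.0), 0.0),        # null model
        ((0.0, 1.0, 1.0), -1.0),       # synthetic lethality
        ((0.9, 1.0, 0.8), 0.1),        # mild suppression
    ])
    def test_score_arithmetic(self, triple, expected):
        assert multiplicative_score(*triple) == pytest.approx(expected)

    def test_na_propagates(self):
        assert math.isnan(multiplicative_score(float("nan"), 1.0, 1.0))

    def test_unit_slope_in_observed_fitness(self):
        base = multiplicative_score(0.9, 1.0, 0.8)
        for delta in (0.05, 0.2, -0.3):
            assert multiplicative_score(0.9 + delta, 1.0, 0.8) - base == \
                pytest.approx(delta)


class TestScoreScreen:
    def test_screen_against_itself_scores_zero(self, screen_96):
        _, control, _ = screen_96
        n1, n2 = normalize_plates([control, control])
        records = score_screen(n2, n1, filters=NO_FLAG_FILTERS)
        scores = [r.score for r in records if r.score is not None]
        assert scores and max(abs(s) for s in scores) < 1e-9

    def test_blank_positions_get_na_score(self, screen_96):
        _, control, experiment = screen_96
        entries = {(1, r, c): ArrayEntry(f"g{r}_{c}") for r, c in FORMATS[96].positions()}
        entries[(1, 1, 1)] = ArrayEntry("BLANK")
        nc, ne = normalize_plates([control, experiment])
        records = score_screen(ne, nc, array_def=ArrayDefinition(entries),
                               filters=NO_FLAG_FILTERS)
        by_pos = {(r.row, r.col): r for r in records}
        assert by_pos[(1, 1)].score is None
        assert by_pos[(1, 1)].normalized_size is not None
        assert by_pos[(1, 2)].score is not None

    def test_mismatched_formats_rejected(self):
        a = _normalized(np.full((8, 12), 500.0), FORMATS[96])
        b = _normalized(np.full((16, 24), 500.0), FORMATS[384])
        with pytest.raises(ScoringError):
            score_screen(a, b)

    def test_linked_genes_masked_before_scoring(self, screen_96):
        _, control, experiment = screen_96
        entries = {(1, r, c): ArrayEntry(f"g{r}_{c}", "chrII", 100.0 * c)
                   for r, c in FORMATS[96].positions()}
        entries[(1, 3, 3)] = ArrayEntry("QGENE", "chrV", 500.0)
        entries[(1, 3, 4)] = ArrayEntry("NEAR", "chrV", 450.0)
        nc, ne = normalize_plates([control, experiment])
        records = score_screen(ne, nc, array_def=ArrayDefinition(entries),
                               filters=FilterConfig(competition_enabled=False),
                               query="QGENE")
        by_pos = {(r.row, r.col): r for r in records}
        assert by_pos[(3, 4)].score is None
        assert by_pos[(3, 4)].kvp.get("status") == "LK"

    def test_injected_effects_recovered(self):
        """Median recovered score for epsilon = -0.4 interactions lands
        within 0.1 of the injected effect on one default screen."""
        cfg = SyntheticScreenConfig(seed=77)
        truth, control, experiment = simulate_screen(cfg)
        nc, ne = normalize_plates([control, experiment])
        records = score_screen(ne, nc, filters=NO_FLAG_FILTERS)
        smap = {(r.row, r.col): r.score for r in records}
        hits = [smap[(i + 1, j + 1)]
                for i, j in zip(*np.nonzero(truth.interaction_effects == -0.4))
                if smap.get((i + 1, j + 1)) is not None]
        assert np.median(hits) == pytest.approx(-0.4, abs=0.1)

    def test_interleaved_records_carry_subarray_annotation(self):
        fmt = FORMATS[768]
        cfg = SyntheticScreenConfig(format=fmt, seed=5)
        _, control, experiment = simulate_screen(cfg)
        nc, ne = normalize_plates([control, experiment])
        records = score_screen(ne, nc, filters=NO_FLAG_FILTERS)
        assert len(records) == 768
        labels = {r.kvp.get("subarray") for r in records}
        assert labels == {"A", "B"}


class TestAverageReplicates:
    def _rec(self, row, col, score, gene="g"):
        return ScoreRecord(row, col, 100, "p", "q", gene,
                           normalized_size=500.0 if score is not None else None,
                           score=score)

    def test_full_quad_averages(self):
        recs = [self._rec(1, 1, 0.2), self._rec(1, 2, 0.2),
                self._rec(2, 1, 0.2), self._rec(2, 2, 0.2)]
        out = average_replicates(recs, ReplicateLayout("quad"))
        assert len(out) == 1
        assert out[0].score == pytest.approx(0.2)
        assert out[0].kvp["n"] == "4"

    def test_na_ignoring_mean(self):
        recs = [self._rec(1, 1, 0.3), self._rec(1, 2, None),
                self._rec(2, 1, 0.1), self._rec(2, 2, None)]
        out = average_replicates(recs, ReplicateLayout("quad"))
        assert out[0].score == pytest.approx(0.2)
        assert out[0].kvp["n"] == "2"

    def test_all_na_group_stays_na(self):
        recs = [self._rec(1, 1, None), self._rec(1, 2, None)]
        out = average_replicates(recs, ReplicateLayout("quad"))
        assert out[0].score is None
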