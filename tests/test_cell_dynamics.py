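"""Cell behaviour: lifespans, clocks, differentiation, movement, mitosis."""

import math
import random

import numpy as np
import pytest

from cryptsim.cell_dynamics import (
    LIFESPAN_RANGE,
    LIFESPAN_RANGE_TUMORAL,
    MitosisSchedule,
    age_and_check_death,
    attempt_scheduled_mitosis,
    differentiate,
    gap_fill,
    move,
    sample_lifespan,
    sample_mitosis_clock,
)
from cryptsim.crypt_world import BetaCateninField
from cryptsim.genome import Genotype, Typology

from conftest import Harness

TA = Typology.TRANSIT_AMPLIFYING
DIFF = Typology.DIFFERENTIATED


def neoplastic_genotype(kras=(0, 1), tp53=(0, 0)):
    return Genotype.from_driver_pairs(apc=(1, 1), kras=kras, tp53=tp53)


class TestSampling:
    def test_lifespan_ranges_and_mean(self, rng):
        phys = [sample_lifespan(TA, rng) for _ in range(10_000)]
        tum = [sample_lifespan(Typology.TUMORAL, rng) for _ in range(10_000)]
        assert min(phys) >= LIFESPAN_RANGE[0] and max(phys) <= LIFESPAN_RANGE[1]
        assert min(tum) >= LIFESPAN_RANGE_TUMORAL[0] and max(tum) <= LIFESPAN_RANGE_TUMORAL[1]
        # uniform-range expectation 108 for the physiological lifespan
        se = (LIFESPAN_RANGE[1] - LIFESPAN_RANGE[0]) / math.sqrt(12 * len(phys))
        assert abs(np.mean(phys) - 108) < 3 * se

    @pytest.mark.parametrize(
        "typology,genotype,expected_mean",
        [
            (TA, Genotype.wildtype(), 24),
            (DIFF, Genotype.from_driver_pairs(kras=(1, 0)), 12),
            (Typology.ADENOMA, neoplastic_genotype(), 12),
            (Typology.TUMORAL, neoplastic_genotype(tp53=(1, 1)), 10),
        ],
    )
    def test_mitosis_clock_means(self, typology, genotype, expected_mean, rng):
        h = Harness()
        cell = h.add(2, 2, typology=typology, genotype=genotype)
        draws = [sample_mitosis_clock(cell, MitosisSchedule(), rng) for _ in range(5000)]
        assert min(draws) >= 1
        assert abs(np.mean(draws) - expected_mean) < 3 / math.sqrt(len(draws))


class TestDifferentiate:
    def test_above_threshold_stays_ta(self):
        h = Harness(n_layers=100)
        cell = h.add(0, 0, typology=TA)
        assert differentiate(cell, BetaCateninField(100), 0.75) == TA

    def test_apc_het_differentiates_normally(self):
        h = Harness(n_layers=100)
        cell = h.add(50, 0, typology=TA, genotype=Genotype.from_driver_pairs(apc=(0, 1)))
        assert differentiate(cell, BetaCateninField(100), 0.75) == DIFF

    def test_apc_null_never_differentiates(self):
        h = Harness(n_layers=100)
        cell = h.add(50, 0, typology=TA, genotype=Genotype.from_driver_pairs(apc=(1, 1)))
        assert differentiate(cell, BetaCateninField(100), 0.75) == TA


class TestMove:
    def test_physiological_advances_into_empty_spot(self, harness):
        cell = harness.add(2, 2, typology=DIFF)
        assert move(cell, harness.grid, harness.rng) == "moved"
        assert cell.pos == (3, 2)

    def test_physiological_blocked_by_occupant(self, harness):
        cell = harness.add(2, 2, typology=DIFF)
        harness.add(3, 2, typology=DIFF)
        assert move(cell, harness.grid, harness.rng) == "blocked"
        assert cell.pos == (2, 2)

    def test_top_layer_move_is_exit(self, harness):
        cell = harness.add(harness.grid.top_layer, 1, typology=DIFF)
        assert move(cell, harness.grid, harness.rng) == "exited"

    def test_tumoral_never_moves(self, harness):
        cell = harness.add(2, 2, typology=Typology.TUMORAL,
                           genotype=neoplastic_genotype(tp53=(1, 1)))
        for _ in range(50):
            assert move(cell, harness.grid, harness.rng) == "stayed"
        assert cell.pos == (2, 2)

    def test_adenoma_diagonal_symmetry_and_stacking(self):
        """Diagonal drift is left/right symmetric and ignores occupancy."""
        h = Harness(n_layers=40, n_cols=9, seed=3)
        rng = random.Random(17)
        lefts = rights = stays = 0
        n = 10_000
        for _ in range(n):
            cell = h.add(5, 4, typology=Typology.ADENOMA, genotype=neoplastic_genotype())
            blocker = h.add(6, 4, typology=Typology.ADENOMA, genotype=neoplastic_genotype())
            out = move(cell, h.grid, rng, p_slow=0.25)
            if out == "stayed":
                stays += 1
            elif cell.col == 3:
                lefts += 1
            else:
                rights += 1
            h.grid.remove(cell, cell.pos)
            h.grid.remove(blocker, blocker.pos)
        moved = lefts + rights
        assert abs(stays / n - 0.25) < 3 * math.sqrt(0.25 * 0.75 / n)
        assert abs(lefts / moved - 0.5) < 3 * math.sqrt(0.25 / moved)


class TestScheduledMitosis:
    def test_daughter_placed_in_empty_lateral_spot(self, harness):
        parent = harness.add(2, 2, typology=DIFF, mitosis_count=2)
        harness.add(2, 1, typology=DIFF)  # left occupied, right free
        out = attempt_scheduled_mitosis(parent, harness.ctx)
        assert out == "divided"
        assert parent.mitosis_count == 3
        (_, daughter, kind), = harness.births
        assert kind == "scheduled"
        assert daughter.pos == (2, 3)
        assert daughter.age == 0 and daughter.mitosis_count == 0

    def test_blocked_divider_kills_least_fit_neighbor(self, harness):
        parent = harness.add(2, 2, typology=DIFF, mitosis_count=5)
        veteran = harness.add(2, 1, typology=DIFF, mitosis_count=3, age=50)
        rookie = harness.add(2, 3, typology=DIFF, mitosis_count=1, age=40)
        out = attempt_scheduled_mitosis(parent, harness.ctx)
        assert out == "divided_by_kill"
        assert harness.killed == [(rookie, "physiological")]
        (_, daughter, _), = harness.births
        assert daughter.pos == (2, 3)
        assert veteran.id in harness.cells

    def test_kill_tie_broken_by_greater_age(self, harness):
        parent = harness.add(2, 2, typology=DIFF)
        younger = harness.add(2, 1, typology=DIFF, mitosis_count=1, age=30)
        older = harness.add(2, 3, typology=DIFF, mitosis_count=1, age=90)
        attempt_scheduled_mitosis(parent, harness.ctx)
        assert harness.killed == [(older, "physiological")]
        assert younger.id in harness.cells

    def test_tumoral_daughter_may_stack_any_direction(self):
        """A fully surrounded tumoral divider stacks into an occupied spot."""
        h = Harness(n_layers=6, n_cols=5, seed=1)
        geno = neoplastic_genotype(tp53=(1, 1))
        parent = h.add(2, 2, typology=Typology.TUMORAL, genotype=geno)
        for pos in h.grid.neighbors((2, 2), ("left", "right", "up", "down",
                                             "up_left", "up_right", "down_left", "down_right")):
            h.add(*pos, typology=DIFF)
        seen = set()
        for _ in range(200):
            attempt_scheduled_mitosis(parent, h.ctx)
            seen.add(h.births[-1][1].pos)
        assert h.killed == []  # neoplastic dividers never eliminate neighbours
        assert len(seen) == 8  # daughters appeared in every direction incl. downward

    def test_tp53_null_parent_counts_hypermutable_mitoses(self, harness):
        geno = neoplastic_genotype(kras=(1, 0), tp53=(1, 1))
        parent = harness.add(2, 2, typology=Typology.TUMORAL, genotype=geno)
        assert parent.tp53_null_mitoses == 0
        attempt_scheduled_mitosis(parent, harness.ctx)
        attempt_scheduled_mitosis(parent, harness.ctx)
        assert parent.tp53_null_mitoses == 2


class TestGapFill:
    def test_single_gap_filled_by_one_lateral_division(self):
        h = Harness(n_layers=4, n_cols=5)
        left = h.add(1, 1, typology=DIFF)
        right = h.add(1, 3, typology=DIFF)
        h.add(1, 0, typology=DIFF)
        h.add(1, 4, typology=DIFF)
        gap_fill(h.ctx)  # (1, 2) is the only gap with lateral neighbours
        assert len(h.births) == 1
        parent, daughter, kind = h.births[0]
        assert kind == "gap_fill"
        assert daughter.pos == (1, 2)
        assert parent in (left, right)
        assert parent.mitosis_count == 1

    def test_empty_row_segments_stay_empty(self):
        """Gaps with no lateral physiological occupant cannot be filled."""
        h = Harness(n_layers=4, n_cols=5)
        gap_fill(h.ctx)  # whole lattice empty: no eligible parents anywhere
        assert h.births == []
        geno = neoplastic_genotype(tp53=(1, 1))
        h.add(1, 1, typology=Typology.TUMORAL, genotype=geno)
        gap_fill(h.ctx)  # a lone neoplastic neighbour does not gap-fill
        assert h.births == []

    def test_full_row_is_noop(self):
        h = Harness(n_layers=2, n_cols=4)
        for col in range(4):
            h.add(0, col, typology=DIFF)
            h.add(1, col, typology=DIFF)
        gap_fill(h.ctx)
        assert h.births == []

    def test_adjacent_gaps_heal_in_one_tick(self):
        """A run of empty spots is healed by cascading single fills."""
        h = Harness(n_layers=2, n_cols=6)
        h.add(0, 0, typology=DIFF)
        for col in range(6):
            h.add(1, col, typology=DIFF)
        gap_fill(h.ctx)  # row 0 columns 1..5 empty, only col 0 occupied
        assert len(h.births) == 5
        assert all(h.grid.spot_count((0, c)) == 1 for c in range(6))


class TestAgeAndDeath:
    def test_dies_tick_after_reaching_lifespan(self, harness):
        cell = harness.add(1, 1, typology=TA, lifespan=120, age=119)
        assert age_and_check_death(cell, harness.model) is None  # age 120 == lifespan
        assert age_and_check_death(cell, harness.model) == "physiological"

    def test_tumoral_death_cause(self, harness):
        cell = harness.add(1, 1, typology=Typology.TUMORAL,
                           genotype=neoplastic_genotype(tp53=(1, 1)),
                           lifespan=150, age=150)
        assert age_and_check_death(cell, harness.model) == "tumoral"

    def test_gatekeeper_burden_kills_tp53_wildtype(self):
        h = Harness(base_prob=1e-9)
        reg = np.ones((50, 2), dtype=np.uint8)
        doomed = h.add(1, 1, typology=DIFF, lifespan=120,
                       genotype=Genotype.from_driver_pairs(regulation=reg))
        escaped = h.add(1, 2, typology=DIFF, lifespan=120,
                        genotype=Genotype.from_driver_pairs(tp53=(0, 1), regulation=reg))
        assert age_and_check_death(doomed, h.model) == "physiological"
        assert age_and_check_death(escaped, h.model) is None
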