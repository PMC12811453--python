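"""Baseline loci preselection: MMS, ESS, mFTP, HRS and metric evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from microprog import (
    FtpRanking,
    Metric,
    SensitivityField,
    circle_polygon,
    evaluate,
    freeze_selections,
    rank_ftp,
    select_ess,
    select_hrs,
    select_mftp,
    select_mms,
)

from conftest import make_field
from oracles import ess_oracle, ftp_proportions_oracle, hrs_oracle, mftp_oracle, random_field


def _ranking(pairs):
    """FtpRanking from (locus_id, proportion) pairs (4 neighbours each)."""
    return FtpRanking(
        pd.DataFrame(
            [
                {
                    "locus_id": i,
                    "baseline_db": 10,
                    "n_neighbors": 4,
                    "n_drops": int(round(p * 4)),
                    "proportion": p,
                }
                for i, p in pairs
            ]
        )
    )


class TestMms:
    def test_selects_all_68_loci(self, grid, field_factory):
        sel = select_mms(field_factory(default=5), grid)
        assert len(sel.locus_ids) == 68 and sel.trend_ids == sel.locus_ids

    def test_all_zero_field_has_no_event_loci(self, grid, field_factory):
        sel = select_mms(field_factory(default=0), grid)
        assert sel.event_ids == frozenset()

    def test_event_loci_are_exactly_the_8db_plus_loci(self, grid, rng):
        vals = random_field(rng, grid.locus_ids)
        sel = select_mms(SensitivityField(values=vals), grid)
        assert sel.event_ids == frozenset(i for i, v in vals.items() if v >= 8)


class TestEss:
    def test_no_scotoma_gives_empty_flagged_selection(self, grid, field_factory):
        sel = select_ess(field_factory(default=10), grid)
        assert sel.locus_ids == frozenset() and "no_scotoma" in sel.flags

    def test_single_interior_scotoma_selects_its_8_neighbors(self, grid, field_factory):
        lid = grid.locus_at(1, 1).id
        sel = select_ess(field_factory(default=10, overrides={(1, 1): -1}), grid)
        assert sel.locus_ids == grid.neighbors(lid)
        assert len(sel.locus_ids) == 8

    def test_all_scotomatous_field_gives_empty_selection(self, grid, field_factory):
        sel = select_ess(field_factory(default=-1), grid)
        assert sel.locus_ids == frozenset()

    def test_every_ess_locus_is_seeing_with_scotomatous_neighbor(self, grid, rng):
        for _ in range(20):
            f = SensitivityField(values=random_field(rng, grid.locus_ids))
            sel = select_ess(f, grid)
            for i in sel.locus_ids:
                assert f[i] != -1
                assert any(f[j] == -1 for j in grid.neighbors(i))


class TestRankFtp:
    def test_uniform_field_has_zero_proportions(self, grid, field_factory):
        t = rank_ftp(field_factory(default=20), grid).table
        assert len(t) == 68 and (t["proportion"] == 0).all()

    def test_half_of_orthogonal_neighbors_dropping(self, field_factory):
        from microprog import build_grid

        g4 = build_grid(adjacency_scheme="orthogonal4")
        # neighbours of (1,1) are (1,3), (3,1), (1,-1), (-1,1)
        f = make_field(
            g4,
            default=20,
            overrides={(1, 1): 10, (1, 3): 2, (3, 1): 3, (1, -1): 15, (-1, 1): 20},
        )
        t = rank_ftp(f, g4).table.set_index("locus_id")
        lid = g4.locus_at(1, 1).id
        assert t.loc[lid, "proportion"] == 0.5  # drops of 8 and 7 dB

    def test_locus_below_8db_absent_from_ranking(self, grid, field_factory):
        f = field_factory(default=20, overrides={(1, 1): 7})
        t = rank_ftp(f, grid).table
        assert grid.locus_at(1, 1).id not in set(t["locus_id"])

    def test_floor_neighbors_count_arithmetically(self, grid, field_factory):
        # 8 - (-1) = 9 >= 7: every neighbour of the 8 dB locus is a drop
        f = field_factory(default=-1, overrides={(1, 1): 8})
        t = rank_ftp(f, grid).table.set_index("locus_id")
        assert t.loc[grid.locus_at(1, 1).id, "proportion"] == 1.0

    def test_raising_drop_threshold_never_raises_proportions(self, grid, rng):
        for _ in range(10):
            f = SensitivityField(values=random_field(rng, grid.locus_ids))
            p7 = rank_ftp(f, grid, drop_db=7).table.set_index("locus_id")["proportion"]
            p8 = rank_ftp(f, grid, drop_db=8).table.set_index("locus_id")["proportion"]
            assert (p8 <= p7 + 1e-12).all()

    def test_peripheral_only_restricts_neighborhood(self, grid, field_factory):
        f = field_factory(default=20)
        t = rank_ftp(f, grid, peripheral_only=True).table
        full = rank_ftp(f, grid).table
        assert (
            t.set_index("locus_id")["n_neighbors"]
            <= full.set_index("locus_id")["n_neighbors"].reindex(t["locus_id"])
        ).all()
        # the most eccentric loci have no more-eccentric neighbours
        assert len(t) < len(full)


class TestSelectMftp:
    def test_enough_full_proportion_loci_no_expansion(self, field_factory):
        r = _ranking([(i, 1.0) for i in range(1, 7)] + [(10, 0.5), (11, 0.25)])
        sel = select_mftp(r, field_factory(default=20))
        assert sel.locus_ids == frozenset(range(1, 7))

    def test_expansion_takes_whole_tied_tier(self, field_factory):
        r = _ranking(
            [(1, 1.0), (2, 1.0), (3, 1.0)]
            + [(i, 0.5) for i in (4, 5, 6, 7)]
            + [(8, 0.25), (9, 0.0)]
        )
        sel = select_mftp(r, field_factory(default=20))
        assert sel.locus_ids == frozenset(range(1, 8))  # 3 + whole 0.5 tier

    def test_zero_proportions_never_selected(self, field_factory):
        r = _ranking([(i, 0.0) for i in range(1, 10)])
        sel = select_mftp(r, field_factory(default=20))
        assert sel.locus_ids == frozenset()
        assert "ineligible_for_event" in sel.flags

    def test_fewer_than_5_positive_loci_flagged(self, field_factory):
        r = _ranking([(1, 1.0), (2, 0.5), (3, 0.0)])
        sel = select_mftp(r, field_factory(default=20))
        assert sel.locus_ids == frozenset({1, 2})
        assert "ineligible_for_event" in sel.flags

    def test_at_least_5_whenever_5_positive_exist(self, grid, rng):
        for _ in range(30):
            f = SensitivityField(values=random_field(rng, grid.locus_ids))
            ranking = rank_ftp(f, grid)
            n_positive = int((ranking.table["proportion"] > 0).sum())
            sel = select_mftp(ranking, f)
            if n_positive >= 5:
                assert len(sel.locus_ids) >= 5


class TestSelectHrs:
    def test_matches_corner_distance_oracle_for_circle(self, grid, field_factory):
        ring = circle_polygon(3.0)
        sel = select_hrs(field_factory(default=10), grid, ring)
        # a circle about the origin transects a square iff the corner
        # distances straddle the radius
        expected = set()
        for l in grid.loci:
            corners = [
                math.hypot(l.x + dx, l.y + dy) for dx in (-1, 1) for dy in (-1, 1)
            ]
            if min(corners) <= 3.0 <= max(corners):
                expected.add(l.id)
        assert sel.locus_ids == frozenset(expected)

    def test_ring_inside_central_square_selects_one_locus(self, grid, field_factory):
        ring = circle_polygon(0.3, center=(1.0, 1.0))
        sel = select_hrs(field_factory(default=10), grid, ring)
        assert sel.locus_ids == frozenset({grid.locus_at(1, 1).id})

    def test_ring_beyond_grid_is_empty_and_flagged(self, grid, field_factory):
        sel = select_hrs(field_factory(default=10), grid, circle_polygon(30.0))
        assert sel.locus_ids == frozenset() and "no_hrs_loci" in sel.flags

    def test_baseline_floor_loci_excluded_from_trend(self, grid, field_factory):
        ring = circle_polygon(3.0)
        f = field_factory(default=10, overrides={(3, 1): -1})
        sel = select_hrs(f, grid, ring)
        lid = grid.locus_at(3, 1).id
        assert lid in sel.locus_ids and lid not in sel.trend_ids
        assert "excluded_from_trend" in sel.provenance[lid]


class TestOracleEquivalenceAndDeterminism:
    def test_selections_match_brute_force_on_random_fields(self, grid, rng):
        ring = circle_polygon(4.0, center=(0.5, -0.5))
        for _ in range(40):
            vals = random_field(rng, grid.locus_ids)
            f = SensitivityField(values=vals)
            assert select_ess(f, grid).locus_ids == frozenset(
                ess_oracle(vals, grid.adjacency)
            )
            props = ftp_proportions_oracle(vals, grid.adjacency)
            assert select_mftp(rank_ftp(f, grid), f).locus_ids == frozenset(
                mftp_oracle(props)
            )
            assert select_hrs(f, grid, ring).locus_ids == frozenset(
                hrs_oracle(grid.squares, ring.vertices)
            )

    def test_freezing_is_deterministic(self, grid, rng):
        vals = random_field(rng, grid.locus_ids)
        f = SensitivityField(values=vals)
        ring = circle_polygon(5.0)
        a = freeze_selections(f, grid, ring)
        b = freeze_selections(f, grid, ring)
        for m in Metric:
            assert a[m].locus_ids == b[m].locus_ids
            assert a[m].event_ids == b[m].event_ids


class TestEvaluate:
    def test_uniform_field_mean(self, grid, field_factory):
        sel = select_mms(field_factory(default=12), grid)
        assert evaluate(sel, field_factory(default=12)) == 12.0

    def test_floor_values_enter_arithmetically(self, grid, field_factory):
        f = field_factory(default=0, overrides={(1, 1): -1})
        sel = select_mms(f, grid)
        assert evaluate(sel, f) == pytest.approx(-1 / 68)

    def test_hrs_excludes_baseline_floor_loci_from_mean(self, grid, field_factory):
        ring = circle_polygon(2.0)  # transects the central squares
        base = field_factory(default=10, overrides={(1, 1): -1})
        sel = select_hrs(base, grid, ring)
        assert grid.locus_at(1, 1).id in sel.locus_ids
        assert evaluate(sel, base) == 10.0  # mean over the seeing loci only

    def test_empty_selection_yields_nan(self, grid, field_factory):
        sel = select_ess(field_factory(default=10), grid)
        assert math.isnan(evaluate(sel, field_factory(default=10)))
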