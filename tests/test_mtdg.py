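import math

import numpy as np
import pytest

from membranome.mtdg import (
    MTDGTable,
    consistency_percentages,
    identify_mtdg,
    overlap_matrix,
    overlap_significance,
)
from membranome.sam import DeregulatedGeneLists
from oracles import hypergeom_tail_enum


def make_table(tissue, universe_size=1000, cl_up=(), cl_down=(), t_up=(), t_down=()):
    universe = frozenset(f"g{i}" for i in range(universe_size))
    return MTDGTable(
        tissue=tissue,
        cl_up=set(cl_up),
        cl_down=set(cl_down),
        t_up=set(t_up),
        t_down=set(t_down),
        universe=universe,
    )


def ids(lo, hi):
    return {f"g{i}" for i in range(lo, hi)}


class TestIdentifyMtdg:
    def test_empty_lists_give_empty_table(self):
        t = identify_mtdg(
            DeregulatedGeneLists(set(), set()),
            DeregulatedGeneLists(set(), set()),
            universe={"g1", "g2"},
            tissue="brain",
        )
        assert not (t.cl_up | t.cl_down | t.t_up | t.t_down)

    def test_hand_enumerated_fixture(self):
        tumor = DeregulatedGeneLists(up=ids(0, 4), down=ids(4, 7))
        cl = DeregulatedGeneLists(up=ids(2, 5) - ids(4, 5) | {"g9"}, down=ids(5, 8))
        t = identify_mtdg(tumor, cl, universe=ids(0, 10), tissue="x")
        rep = consistency_percentages(t)
        assert rep.counts["inter_up"] == 2  # g2, g3
        assert rep.counts["inter_down"] == 2  # g5, g6
        assert rep.pct_up == pytest.approx(100 * 2 / 4)
        assert rep.pct_down == pytest.approx(100 * 2 / 3)

    def test_published_scale_counts_accepted(self):
        """Brain-column cardinalities (353/528/363/277) build cleanly."""
        t = make_table(
            "brain",
            universe_size=1701,
            cl_up=ids(0, 353),
            cl_down=ids(353, 881),
            t_up=ids(0, 199) | ids(881, 1045),
            t_down=ids(400, 617) | ids(1045, 1105),
        )
        rep = consistency_percentages(t)
        assert rep.counts["cl_up"] == 353 and rep.counts["cl_down"] == 528
        assert rep.counts["t_up"] == 363 and rep.counts["t_down"] == 277

    def test_gene_outside_universe_named(self):
        tumor = DeregulatedGeneLists(up={"alien"}, down=set())
        with pytest.raises(ValueError, match="alien"):
            identify_mtdg(
                tumor, DeregulatedGeneLists(set(), set()), universe={"g1"}
            )

    def test_mismatched_fdr_targets_error(self):
        a = DeregulatedGeneLists(set(), set(), fdr_target=0.01)
        b = DeregulatedGeneLists(set(), set(), fdr_target=0.05)
        with pytest.raises(ValueError, match="FDR"):
            identify_mtdg(a, b, universe=set())


class TestConsistencyPercentages:
    def test_published_brain_arithmetic(self):
        """199/363 -> 55%, 217/277 -> 78%, 416/640 -> 65% after rounding."""
        t = make_table(
            "brain",
            universe_size=1701,
            t_up=ids(0, 363),
            cl_up=ids(0, 199) | ids(400, 554),
            t_down=ids(600, 877),
            cl_down=ids(600, 817) | ids(900, 1211),
        )
        rep = consistency_percentages(t)
        assert rep.counts["inter_up"] == 199
        assert rep.counts["inter_down"] == 217
        assert rep.rounded() == {"pct_up": 55, "pct_down": 78, "pct_combined": 65}

    def test_full_agreement_is_100(self):
        t = make_table("x", t_up=ids(0, 5), cl_up=ids(0, 5),
                       t_down=ids(5, 9), cl_down=ids(5, 9))
        rep = consistency_percentages(t)
        assert (rep.pct_up, rep.pct_down, rep.pct_combined) == (100.0, 100.0, 100.0)

    def test_empty_tumor_side_is_nan(self):
        rep = consistency_percentages(make_table("x", cl_up=ids(0, 3)))
        assert math.isnan(rep.pct_up) and math.isnan(rep.pct_combined)

    @pytest.mark.parametrize("seed", range(5))
    def test_combined_is_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(60)]
        t_up = set(rng.choice(pool[:30], size=rng.integers(2, 20), replace=False))
        t_down = set(rng.choice(pool[30:], size=rng.integers(2, 20), replace=False))
        cl_up = set(rng.choice(pool[:30], size=10, replace=False))
        cl_down = set(rng.choice(pool[30:], size=10, replace=False))
        t = make_table("x", 100, cl_up=cl_up, cl_down=cl_down,
                       t_up=t_up, t_down=t_down)
        rep = consistency_percentages(t)
        w_up, w_down = len(t_up), len(t_down)
        expected = (rep.pct_up * w_up + rep.pct_down * w_down) / (w_up + w_down)
        assert rep.pct_combined == pytest.approx(expected, rel=1e-12)


class TestOverlapSignificance:
    def test_exhaustive_enumeration_example(self):
        """Universe 10, |a|=5, |b|=4, overlap 4 -> p = 5/210."""
        universe = ids(0, 10)
        a, b = ids(0, 5), ids(0, 4)
        p, neglog = overlap_significance(a, b, universe)
        assert p == pytest.approx(5 / 210, rel=1e-12)
        assert p == pytest.approx(hypergeom_tail_enum(4, 10, 5, 4), rel=1e-12)

    @pytest.mark.parametrize(
        "N, K, n, k",
        [(8, 3, 4, 2), (10, 6, 5, 3), (12, 5, 7, 1), (12, 4, 4, 4), (9, 9, 3, 3)],
    )
    def test_matches_enumeration_grid(self, N, K, n, k):
        universe = ids(0, N)
        a = ids(0, K)
        b = ids(K - k, K - k + n)
        p, _ = overlap_significance(a, b, universe)
        assert p == pytest.approx(hypergeom_tail_enum(len(a & b), N, K, n), rel=1e-9)

    def test_zero_overlap_near_one(self):
        p, neglog = overlap_significance(ids(0, 3), ids(3, 6), ids(0, 20))
        assert p > 0.5 and neglog < 0.5

    def test_forced_overlap_is_one(self):
        u = ids(0, 6)
        p, neglog = overlap_significance(u, u, u)
        assert p == pytest.approx(1.0)
        assert neglog == 0.0

    def test_symmetry(self):
        u = ids(0, 40)
        a, b = ids(0, 12), ids(6, 21)
        assert overlap_significance(a, b, u) == pytest.approx(
            overlap_significance(b, a, u)
        )

    def test_monotone_in_overlap(self):
        u = ids(0, 50)
        neglogs = []
        for k in range(0, 11):
            a = ids(0, 10)
            b = ids(10 - k, 20 - k)
            _, nl = overlap_significance(a, b, u)
            neglogs.append(nl)
        assert neglogs == sorted(neglogs)

    def test_log_space_survives_tiny_p(self):
        u = ids(0, 5000)
        a = b = ids(0, 1500)
        p, neglog = overlap_significance(a, b, u)
        assert p == 0.0  # underflows in linear space
        assert np.isfinite(neglog) and neglog > 300

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_significance(set(), set(), set())


class TestOverlapMatrix:
    def test_identical_tables_symmetric(self):
        tables = [
            make_table("a", 200, cl_up=ids(0, 20), cl_down=ids(20, 40),
                       t_up=ids(0, 20), t_down=ids(20, 40)),
            make_table("b", 200, cl_up=ids(50, 70), cl_down=ids(70, 90),
                       t_up=ids(50, 70), t_down=ids(70, 90)),
        ]
        om = overlap_matrix(tables)
        m = om.neg_log10_p
        assert m.loc["a", "b"] == pytest.approx(m.loc["b", "a"])
        assert all(om.diagonal_is_column_max.values())

    def test_disjoint_sets_score_zero_ish(self):
        tables = [
            make_table("a", 100, cl_up=ids(0, 30), t_up=ids(0, 30)),
            make_table("b", 100, cl_up=ids(30, 60), t_up=ids(30, 60)),
        ]
        om = overlap_matrix(tables)
        assert om.neg_log10_p.loc["a", "b"] < 0.05

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_matrix([make_table("a", 100), make_table("b", 101)])

    def test_direction_blind_variant_counts_any_overlap(self):
        # up in the cell line, down in the tumor: invisible to the
        # direction-aware count, visible to the blind one
        t = make_table("a", 50, cl_up=ids(0, 10), t_down=ids(0, 10), t_up=ids(20, 25))
        aware = overlap_matrix([t], direction_aware=True)
        blind = overlap_matrix([t], direction_aware=False)
        assert aware.neg_log10_p.loc["a", "a"] < blind.neg_log10_p.loc["a", "a"]


def test_directional_sets_must_be_disjoint():
    with pytest.raises(ValueError, match="overlap"):
        make_table("x", t_up=ids(0, 3), t_down=ids(2, 5))
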