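"""Differential expression: NB exact test, ANOVA fold-change selection,
top-10% rules and the RP/PP set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from translatome.diffexpr import (
    anova_fc_select,
    fit_nb,
    hypergeom_overlap,
    log2_fold_change,
    nb_test,
    opposite_direction_groups,
    select_top_fraction,
    set_algebra,
    size_factors,
)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert size_factors(c).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_column_ratio_two(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        s = size_factors(c)
        assert s["b"] / s["a"] == pytest.approx(2.0)

    def test_single_sample_factor_one(self):
        c = pd.DataFrame({"a": [4, 9, 1]})
        assert size_factors(c)["a"] == pytest.approx(1.0)

    def test_no_common_nonzero_gene_rejected(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(c)


def _nb_null(seed, n=1000, reps=4, disp=10.0):
    rng = np.random.default_rng(seed)
    mu = 2.0 ** rng.normal(6, 2, n)
    draw = lambda: pd.DataFrame(
        {f"r{j}": rng.negative_binomial(disp, disp / (disp + mu)) for j in range(reps)}
    )
    return draw(), draw()


class TestNBTest:
    def test_identical_count_vectors_give_p_near_one(self):
        a, b = _nb_null(0)
        a.iloc[0] = b.iloc[0] = [50, 50, 50, 50]
        fit = fit_nb(pd.concat([a, b], axis=1), np.array(["a"] * 4 + ["b"] * 4))
        p = nb_test(a, b, fit)
        assert p.iloc[0] >= 0.99

    def test_zero_total_gene_p_one(self):
        a, b = _nb_null(1)
        a.iloc[0] = b.iloc[0] = 0
        p = nb_test(a, b)
        assert p.iloc[0] == 1.0

    def test_power_monotone_in_fold_change(self):
        # planted subset on a null background: normalization must not
        # absorb the signal, and power should rise with fold change
        rng = np.random.default_rng(2)
        n, n_de, disp = 1000, 50, 10.0
        base = 2.0 ** rng.normal(6, 2, n)
        rejections = []
        for fc in (2, 4, 8):
            mu_m = base.copy()
            mu_m[:n_de] = base[:n_de] * fc
            draw = lambda m: pd.DataFrame(
                {f"r{j}": rng.negative_binomial(disp, disp / (disp + m)) for j in range(4)}
            )
            p = nb_test(draw(mu_m), draw(base))
            rejections.append((p.iloc[:n_de] < 0.01).mean())
        assert rejections[0] < rejections[1] <= rejections[2]
        assert rejections[2] >= 0.9

    def test_fewer_than_two_replicates_rejected(self):
        a, b = _nb_null(3)
        with pytest.raises(ValueError):
            nb_test(a.iloc[:, :1], b)


class TestTopFraction:
    def test_exact_selection_count(self):
        rng = np.random.default_rng(0)
        p = pd.Series(rng.uniform(size=100), index=[f"g{i}" for i in range(100)])
        lfc = pd.Series(rng.normal(size=100), index=p.index)
        assert len(select_top_fraction(p, lfc).selected) == 10

    def test_universe_of_20727_selects_2072(self):
        n = 20727
        rng = np.random.default_rng(1)
        p = pd.Series(rng.uniform(size=n), index=[f"g{i}" for i in range(n)])
        lfc = pd.Series(rng.normal(size=n), index=p.index)
        assert len(select_top_fraction(p, lfc).selected) == 2072

    def test_tied_pvalues_break_by_fold_change_then_id(self):
        idx = ["g0", "g1", "g2", "g3"]
        p = pd.Series([0.5] * 4, index=idx)
        lfc = pd.Series([0.1, 3.0, -2.0, 0.1], index=idx)
        sel = select_top_fraction(p, lfc, frac=0.5)
        assert sel.selected == {"g1", "g2"}
        # id breaks the remaining tie deterministically
        lfc2 = pd.Series([1.0, 1.0, 1.0, 1.0], index=idx)
        assert select_top_fraction(p, lfc2, frac=0.5).selected == {"g0", "g1"}

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = pd.Series(rng.uniform(size=50))
        sel = select_top_fraction(p, pd.Series(np.zeros(50)))
        tab = sel.table.sort_values("p")
        assert (np.diff(tab["q"]) >= -1e-12).all()


class TestAnovaSelect:
    def test_identical_triplicates_not_selected(self):
        m = pd.DataFrame({"m1": [20.0], "m2": [20.0], "m3": [20.0]})
        g = m.rename(columns={"m1": "g1", "m2": "g2", "m3": "g3"})
        sel = anova_fc_select(m, g)
        assert sel.selected == set()
        assert sel.table["p"].iloc[0] == 1.0

    def test_f_statistic_equals_squared_t(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(22, 1, (40, 3)))
        g = pd.DataFrame(rng.normal(22, 1, (40, 3)))
        sel = anova_fc_select(m, g)
        t = stats.ttest_ind(m.to_numpy(), g.to_numpy(), axis=1)
        assert sel.table["statistic"].to_numpy() == pytest.approx(t.statistic**2)

    def test_planted_large_fold_changes_recovered(self):
        rng = np.random.default_rng(8)
        n = 400
        base = rng.normal(24, 1.5, n)
        lfc = np.zeros(n)
        planted = rng.choice(n, 40, replace=False)
        lfc[planted] = rng.choice([-3.0, 3.0], 40)
        m = pd.DataFrame(
            {f"m{j}": base + lfc + rng.normal(0, 0.5, n) for j in range(3)}
        )
        g = pd.DataFrame({f"g{j}": base + rng.normal(0, 0.5, n) for j in range(3)})
        sel = anova_fc_select(m, g)
        assert len(sel.selected & set(planted)) / len(planted) >= 0.95


class TestSetAlgebra:
    def test_basic_partition(self):
        gs = set_algebra({"a", "b", "c"}, {"b", "d"})
        assert gs.rp_only == {"a", "c"}
        assert gs.pp_only == {"d"}
        assert gs.both == {"b"}
        assert gs.union == {"a", "b", "c", "d"}

    def test_partition_invariants_on_random_sets(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(50)]
        for _ in range(20):
            a = set(rng.choice(universe, 20, replace=False))
            b = set(rng.choice(universe, 15, replace=False))
            gs = set_algebra(a, b)
            assert gs.both | gs.rp_only == gs.rp_de
            assert not (gs.rp_only & gs.pp_only)
            assert not (gs.rp_only & gs.both) and not (gs.pp_only & gs.both)
            assert gs.rp_only | gs.pp_only | gs.both == gs.union


class TestHypergeomOverlap:
    def test_complete_overlap_closed_form(self):
        u = set(range(10))
        a = set(range(5))
        assert hypergeom_overlap(a, a, u) == pytest.approx(1 / 252)

    def test_matches_exhaustive_enumeration_small_universe(self):
        # P(X >= k) by enumerating every |B|-subset of the universe
        rng = np.random.default_rng(6)
        universe = set(range(10))
        for _ in range(5):
            a = set(rng.choice(10, 4, replace=False))
            b = set(rng.choice(10, 5, replace=False))
            k = len(a & b)
            total = hits = 0
            for comb in itertools.combinations(universe, len(b)):
                total += 1
                hits += len(a & set(comb)) >= k
            assert hypergeom_overlap(a, b, universe) == pytest.approx(hits / total)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap({"x"}, {"a"}, {"a", "b"})


class TestOppositeDirection:
    def test_sign_pattern_routing(self):
        fc_rp = pd.Series({"g1": 1.2, "g2": 1.2, "g3": -0.5})
        fc_pp = pd.Series({"g1": -0.8, "g2": 0.8, "g3": 0.3})
        a, b = opposite_direction_groups(fc_rp, fc_pp)
        assert a == {"g1"} and b == {"g3"}

    def test_independent_signs_give_balanced_groups(self):
        rng = np.random.default_rng(9)
        idx = [f"g{i}" for i in range(2000)]
        a, b = opposite_direction_groups(
            pd.Series(rng.normal(size=2000), index=idx),
            pd.Series(rng.normal(size=2000), index=idx),
        )
        n = len(a) + len(b)
        ci = stats.binom.interval(0.999, n, 0.5)
        assert ci[0] <= len(a) <= ci[1]
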