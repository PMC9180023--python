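"""Mann-Kendall test: pair counts, tie-corrected variance, continuity-corrected
Z, exact small-n null as oracle, rank-statistic invariances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import equipanel as ep
from equipanel.errors import EquipanelError, SeriesTooShortError


class TestS:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1, 2, 3, 4], 6),        # all pairs concordant
            ([4, 3, 2, 1], -6),
            ([2, 2, 2], 0),
            ([1, 2, 2, 3], 5),        # one tied pair contributes 0
        ],
    )
    def test_pair_enumeration(self, series, expected):
        assert ep.mk_s(series) == expected

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            ep.mk_s([1.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force(self, xs):
        brute = sum(
            np.sign(xs[j] - xs[i])
            for i in range(len(xs))
            for j in range(i + 1, len(xs))
        )
        assert ep.mk_s(xs) == brute
        assert abs(ep.mk_s(xs)) <= len(xs) * (len(xs) - 1) // 2


class TestVariance:
    def test_no_ties_closed_form(self):
        assert ep.mk_variance([1, 2, 3, 4]) == pytest.approx(4 * 3 * 13 / 18)

    def test_one_tie_group(self):
        assert ep.mk_variance([1, 2, 2, 3]) == pytest.approx((156 - 2 * 1 * 9) / 18)

    def test_constant_series_has_zero_variance(self):
        assert ep.mk_variance([5.0] * 6) == pytest.approx(0)


class TestZ:
    def test_small_monotone_series(self):
        r = ep.mk_test([1, 2, 3, 4])
        assert r.Z == pytest.approx(5 / math.sqrt(26 / 3), abs=1e-12)
        assert r.Z == pytest.approx(1.6984, abs=1e-4)
        assert r.p_two_sided == pytest.approx(0.0894, abs=5e-4)
        assert r.stars == "*"
        assert r.direction == "increasing"

    def test_18_point_monotone_ceiling(self):
        r = ep.mk_test(np.arange(1, 19))
        assert r.S == 153
        assert r.var_s == pytest.approx(697.0)
        assert r.Z == pytest.approx(152 / math.sqrt(697.0), abs=1e-12)
        assert round(r.Z, 3) == 5.757
        assert r.stars == "***" and r.cell == "5.757 *** (+)"

    def test_zero_s_gives_zero_z(self):
        r = ep.mk_test([1.0, 1.0, 1.0])
        assert r.S == 0 and r.Z == 0.0
        assert r.direction == "none" and r.stars == ""
        assert r.cell == "0.000 (0)"

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=15, unique=True))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_under_reversal_and_negation(self, xs):
        z = ep.mk_test(xs).Z
        assert ep.mk_test(xs[::-1]).Z == pytest.approx(-z, abs=1e-12)
        assert ep.mk_test([-v for v in xs]).Z == pytest.approx(-z, abs=1e-12)

    @given(st.lists(st.floats(0.1, 50), min_size=3, max_size=15))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, xs):
        base = ep.mk_test(xs)
        for f in (np.log, np.sqrt, lambda v: 3 * np.asarray(v) + 7):
            t = ep.mk_test(f(xs))
            assert t.S == base.S
            assert t.var_s == pytest.approx(base.var_s)
            assert t.Z == pytest.approx(base.Z, abs=1e-12)

    def test_star_ladder(self):
        # p thresholds 0.01 / 0.05 / 0.1 map to *** / ** / *
        assert ep.mk_test(np.arange(18)).stars == "***"
        assert ep.mk_test([1, 2, 3, 4]).stars == "*"   # p ~ 0.089
        assert ep.mk_test([1, 2, 3, 4, 6, 5]).stars == "**"  # p ~ 0.024
        assert ep.mk_test([2, 1, 3]).stars == ""

    def test_one_sided_option_halves_p(self):
        two = ep.mk_test([1, 2, 3, 4])
        one = ep.mk_test([1, 2, 3, 4], one_sided=True)
        assert one.Z == two.Z
        # one-sided flagging is stricter in p but same ladder
        assert one.stars in {"**", "*"}


class TestExactNull:
    def test_n3_distribution_by_hand(self):
        dist = ep.exact_null(3)
        assert dist == pytest.approx(
            {3: 1 / 6, 1: 2 / 6, -1: 2 / 6, -3: 1 / 6}
        )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_brute_force_enumeration(self, n):
        counts: dict[int, int] = {}
        for perm in itertools.permutations(range(n)):
            s = ep.mk_s(list(perm))
            counts[s] = counts.get(s, 0) + 1
        total = math.factorial(n)
        brute = {s: c / total for s, c in counts.items()}
        assert ep.exact_null(n) == pytest.approx(brute)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_variance_matches_no_tie_formula(self, n):
        dist = ep.exact_null(n)
        var = sum(p * s**2 for s, p in dist.items())
        assert var == pytest.approx(n * (n - 1) * (2 * n + 5) / 18, abs=1e-9)
        # symmetry about zero
        for s, p in dist.items():
            assert dist[-s] == pytest.approx(p)

    @pytest.mark.parametrize("n", range(4, 9))
    def test_normal_approximation_tail_agreement(self, n):
        """Continuity-corrected normal tails track the exact null within
        0.03 absolute over the rejection regions."""
        from scipy import stats

        dist = ep.exact_null(n)
        var = n * (n - 1) * (2 * n + 5) / 18
        # S has fixed parity, so compare at attainable values only
        for s0 in sorted(s for s in dist if s > 0):
            exact_tail = sum(p for s, p in dist.items() if s >= s0)
            approx_tail = stats.norm.sf((s0 - 1) / math.sqrt(var))
            if exact_tail <= 0.05:  # one-sided tails of the alpha ladder
                assert abs(exact_tail - approx_tail) <= 0.03

    def test_out_of_range(self):
        with pytest.raises(EquipanelError):
            ep.exact_null(1)
        with pytest.raises(EquipanelError):
            ep.exact_null(11)


class TestTrendTable:
    def test_bundle_shape_and_cells(self):
        bundle = {
            "up": np.arange(18.0),
            "down": -np.arange(18.0),
            "flat": np.ones(18),
        }
        table = ep.trend_table(bundle)
        assert list(table["series"]) == ["up", "down", "flat"]
        up = table[table.series == "up"].iloc[0]
        assert up.cell == "5.757 *** (+)"
        down = table[table.series == "down"].iloc[0]
        assert down.z_3dp == -5.757 and down["sign"] == "(−)"
        flat = table[table.series == "flat"].iloc[0]
        assert flat.cell == "0.000 (0)" and flat.stars == ""
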