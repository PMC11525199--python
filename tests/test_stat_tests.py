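import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonefate.stat_tests import (
    art_anova_two_factor,
    binomial_two_tailed,
    ks2d_statistic,
    mann_whitney_two_tailed,
    peacock_ks2d,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_ks2d(sample1, sample2):
    """Enumerate every quadrant origin and open/closed orientation directly."""
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    xs = np.unique(np.concatenate([a[:, 0], b[:, 0]]))
    ys = np.unique(np.concatenate([a[:, 1], b[:, 1]]))
    rels = [np.less_equal, np.greater, np.less, np.greater_equal]
    d = 0.0
    for ox in xs:
        for oy in ys:
            for rx in rels:
                for ry in rels:
                    fa = np.mean(rx(a[:, 0], ox) & ry(a[:, 1], oy))
                    fb = np.mean(rx(b[:, 0], ox) & ry(b[:, 1], oy))
                    d = max(d, abs(fa - fb))
    return d


def exact_binomial_oracle(k, n, p0_frac):
    """Minimum-likelihood two-tailed binomial p via exact rational arithmetic."""
    pmfs = [Fraction(math.comb(n, x)) * p0_frac ** x * (1 - p0_frac) ** (n - x)
            for x in range(n + 1)]
    ref = pmfs[k]
    tol = ref + ref / 10**7
    return float(sum(p for p in pmfs if p <= tol))


# ---------------------------------------------------------------------------
# Peacock 2D KS
# ---------------------------------------------------------------------------


class TestPeacockKs2d:
    def test_identical_samples(self):
        pts = [(0, 0), (1, 2), (3, 1)]
        res = peacock_ks2d(pts, pts, n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_quadrants(self):
        res = peacock_ks2d([(0, 0)], [(5, 5)], n_perm=99, seed=0)
        assert res.statistic == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 6, size=(20, 2))
        b = rng.integers(0, 7, size=(20, 2))
        assert ks2d_statistic(a, b) == pytest.approx(brute_force_ks2d(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_varied(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=(12, 2))
        b = rng.integers(1, 6, size=(15, 2))
        assert ks2d_statistic(a, b) == pytest.approx(brute_force_ks2d(a, b), abs=1e-12)

    def test_ff_variant_le_peacock(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 8, size=(15, 2))
        b = rng.integers(0, 8, size=(15, 2))
        assert ks2d_statistic(a, b, "ff") <= ks2d_statistic(a, b, "peacock") + 1e-12

    def test_rank_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 9, size=(18, 2)).astype(float)
        b = rng.integers(0, 9, size=(18, 2)).astype(float)
        f = lambda v: (v + 1.0) ** 3  # strictly increasing
        a2 = np.column_stack([f(a[:, 0]), np.exp(a[:, 1])])
        b2 = np.column_stack([f(b[:, 0]), np.exp(b[:, 1])])
        assert ks2d_statistic(a, b) == pytest.approx(ks2d_statistic(a2, b2), abs=1e-12)

    def test_permutation_p_reproducible_and_positive(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, size=(10, 2))
        b = rng.integers(0, 5, size=(10, 2))
        r1 = peacock_ks2d(a, b, n_perm=199, seed=7)
        r2 = peacock_ks2d(a, b, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value > 0.0

    def test_rejects_small_n_perm(self):
        with pytest.raises(ValueError, match="n_perm"):
            peacock_ks2d([(0, 0)], [(1, 1)], n_perm=50)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            peacock_ks2d([], [(1, 1)], n_perm=99)

    def test_d_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.integers(0, 10, size=(rng.integers(2, 12), 2))
            b = rng.integers(0, 10, size=(rng.integers(2, 12), 2))
            assert 0.0 <= ks2d_statistic(a, b) <= 1.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_two_tailed([1, 2], [1, 2])
        assert res.p_value == 1.0

    def test_fully_separated(self):
        res = mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_all_equal_flags_ties(self):
        res = mann_whitney_two_tailed([2, 2, 2], [2, 2])
        assert res.p_value == 1.0
        assert res.ties_present

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])

    def test_normal_approx_close_to_exact(self, monkeypatch):
        # agreement within 0.02 at the top of the exact range (untied data);
        # heavily tied tiny samples are exactly why enumeration is used there
        import clonefate.stat_tests as st_mod
        rng = np.random.default_rng(12)
        for _ in range(40):
            x = rng.normal(size=rng.integers(7, 9))
            y = rng.normal(size=rng.integers(7, 9))
            exact = mann_whitney_two_tailed(x, y).p_value
            monkeypatch.setattr(st_mod, "_EXACT_LIMIT", 0)
            approx = mann_whitney_two_tailed(x, y).p_value
            monkeypatch.setattr(st_mod, "_EXACT_LIMIT", 8)
            assert approx == pytest.approx(exact, abs=0.02)

    def test_scipy_cross_check_no_ties(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(3)
        x = rng.permutation(20)[:6].astype(float)
        y = (rng.permutation(20)[:7] + 30).astype(float) / 1.7
        res = mann_whitney_two_tailed(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# binomial
# ---------------------------------------------------------------------------


class TestBinomialTwoTailed:
    def test_modal_outcome(self):
        assert binomial_two_tailed(1, 2, 0.5) == 1.0

    def test_symmetric_extreme(self):
        assert binomial_two_tailed(2, 2, 0.5) == pytest.approx(0.5)

    def test_matches_rational_oracle_small(self):
        for k, n in [(0, 5), (3, 5), (5, 5), (2, 10), (9, 10)]:
            got = binomial_two_tailed(k, n, 0.25)
            ref = exact_binomial_oracle(k, n, Fraction(1, 4))
            assert got == pytest.approx(ref, rel=1e-9)

    def test_paper_regime_matches_oracle(self):
        got = binomial_two_tailed(37, 57, 0.02)
        ref = exact_binomial_oracle(37, 57, Fraction(1, 50))
        assert math.log10(got) == pytest.approx(math.log10(ref), abs=1e-9)
        assert 1e-50 < got < 1e-45  # same astronomically small regime

    def test_depletion_side_matches_oracle(self):
        # under the minimum-likelihood convention P(X=1) > P(X=0) here, so the
        # two-tailed p is 1 - P(X=1) ~ 0.63: not significant, and exactly
        # what the rational oracle gives
        got = binomial_two_tailed(0, 57, 0.02)
        ref = exact_binomial_oracle(0, 57, Fraction(1, 50))
        assert got == pytest.approx(ref, rel=1e-9)
        assert got > 0.5

    def test_monotone_away_from_mode(self):
        p0 = 0.3
        n = 40
        mode = int((n + 1) * p0)
        ps_up = [binomial_two_tailed(k, n, p0) for k in range(mode, n + 1)]
        ps_down = [binomial_two_tailed(k, n, p0) for k in range(mode, -1, -1)]
        assert all(b <= a + 1e-12 for a, b in zip(ps_up, ps_up[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ps_down, ps_down[1:]))

    @given(st.integers(0, 30), st.integers(1, 30),
           st.floats(0.05, 0.95))
    @settings(max_examples=100)
    def test_in_unit_interval(self, k, n, p0):
        if k > n:
            k = n
        p = binomial_two_tailed(k, n, p0)
        assert 0.0 < p <= 1.0

    def test_scipy_cross_check(self):
        from scipy.stats import binomtest
        for k, n, p0 in [(7, 37, 0.19), (3, 20, 0.3), (14, 20, 0.5)]:
            assert binomial_two_tailed(k, n, p0) == pytest.approx(
                binomtest(k, n, p0).pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# ART ANOVA
# ---------------------------------------------------------------------------


def statsmodels_art_oracle(y, a, b):
    """Independent route: explicit alignment, ranks, statsmodels type-III ANOVA."""
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy.stats import rankdata

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    cell = df.groupby(["a", "b"])["y"].transform("mean")
    cm = df.groupby(["a", "b"])["y"].mean().unstack()
    ma = cm.mean(axis=1)
    mb = cm.mean(axis=0)
    grand = cm.values.mean()
    resid = df["y"] - cell
    est = {
        "A": df["a"].map(ma) - grand,
        "B": df["b"].map(mb) - grand,
        "A:B": cell - df["a"].map(ma) - df["b"].map(mb) + grand,
    }
    eff_term = {"A": "C(a, Sum)", "B": "C(b, Sum)", "A:B": "C(a, Sum):C(b, Sum)"}
    out = {}
    for effect in ("A", "B", "A:B"):
        df["rank"] = rankdata(resid + est[effect])
        model = smf.ols("rank ~ C(a, Sum) * C(b, Sum)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=3)
        out[effect] = float(table.loc[eff_term[effect], "F"])
    return out


class TestArtAnova:
    def test_additive_noiseless_interaction_zero(self):
        a = ["x", "x", "y", "y"] * 2
        b = ["u", "v", "u", "v"] * 2
        y = [1.0, 2.0, 3.0, 4.0] * 2  # purely additive, no interaction
        rows = {r["effect"]: r for r in art_anova_two_factor(y, a, b)}
        assert rows["A:B"]["F"] == 0.0
        assert rows["A:B"]["ties"]

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(9)
        a = np.repeat(["x", "y"], 8)
        b = np.tile(np.repeat(["u", "v"], 4), 2)
        y = rng.normal(size=16) + (a == "y") * 1.0 + (b == "v") * 0.5 \
            + ((a == "y") & (b == "v")) * 0.7
        got = {r["effect"]: r["F"] for r in art_anova_two_factor(y, a, b)}
        ref = statsmodels_art_oracle(y, a, b)
        for effect in ("A", "B", "A:B"):
            assert got[effect] == pytest.approx(ref[effect], rel=1e-8)

    def test_matches_statsmodels_oracle_three_levels_unbalanced(self):
        rng = np.random.default_rng(13)
        a = np.array(list("xxyyzzz" * 4))
        b = np.array(list("uvuvuvu" * 4))
        y = rng.normal(size=a.size) + (a == "z") * 0.8
        got = {r["effect"]: r["F"] for r in art_anova_two_factor(y, a, b)}
        ref = statsmodels_art_oracle(y, a, b)
        for effect in ("A", "B", "A:B"):
            assert got[effect] == pytest.approx(ref[effect], rel=1e-6)

    def test_empty_cell_raises(self):
        a = ["x", "x", "y"]
        b = ["u", "v", "u"]
        with pytest.raises(ValueError, match="empty design cell"):
            art_anova_two_factor([1.0, 2.0, 3.0], a, b)

    def test_single_level_raises(self):
        with pytest.raises(ValueError, match="levels"):
            art_anova_two_factor([1.0, 2.0], ["x", "x"], ["u", "v"])

    def test_detects_strong_interaction(self):
        rng = np.random.default_rng(21)
        a = np.repeat(["x", "y"], 20)
        b = np.tile(np.repeat(["u", "v"], 10), 2)
        y = rng.normal(scale=0.3, size=40) + ((a == "y") & (b == "v")) * 3.0
        rows = {r["effect"]: r for r in art_anova_two_factor(y, a, b)}
        assert rows["A:B"]["p"] < 1e-4
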