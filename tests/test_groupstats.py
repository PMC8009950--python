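"""Group-comparison toolchain: omnibus tests, Duncan/LSD/T3, letter soundness."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from feedeval.groupstats import (
    DegenerateDataError,
    compare_groups,
    duncan_critical_q,
    duncan_letters,
    letters_from_pairwise,
    levene,
    lsd_pairwise,
    one_way_anova,
    shapiro_wilk,
    welch_anova,
    welch_dunnett_t3,
)
from feedeval.panels import sd_from_half_width

from .conftest import replicates_with


import functools


@functools.lru_cache(maxsize=None)
def _q_range(quantile: float, span: int, df: int) -> float:
    # cached because scipy's studentized-range ppf is expensive per call
    return float(stats.studentized_range.ppf(quantile, span, df))


def duncan_pair_oracle(groups, alpha=0.05):
    """Independent exhaustive-range oracle for Duncan decisions.

    A pair differs iff every ordered range containing it exceeds its own
    least significant range (protection rule applied directly, no step-down
    bookkeeping shared with the implementation).
    """
    names = sorted(groups, key=lambda k: np.mean(groups[k]))
    arrays = [np.asarray(groups[n], float) for n in names]
    k = len(arrays)
    df = sum(a.size for a in arrays) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    n_h = k / sum(1 / a.size for a in arrays)
    means = [a.mean() for a in arrays]
    decisions = {}
    for i, j in itertools.combinations(range(k), 2):
        sig = True
        for a, b in itertools.combinations(range(k), 2):
            if a <= i and b >= j:
                span = b - a + 1
                alpha_p = 1 - (1 - alpha) ** (span - 1)
                q = _q_range(1 - alpha_p, span, df)
                if means[b] - means[a] <= q * math.sqrt(mse / n_h):
                    sig = False
                    break
        decisions[(names[i], names[j])] = sig
    return decisions


class TestOmnibus:
    def test_levene_identical_groups_statistic_zero(self):
        stat, p = levene({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_levene_hand_computed(self):
        # textbook formula on (1,2,3) vs (10,20,30): W = 4*54/(202/3) = 648/202
        stat, _ = levene({"a": [1, 2, 3], "b": [10, 20, 30]})
        assert stat == pytest.approx(648 / 202, rel=1e-12)

    def test_levene_type_i_rate(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {f"g{i}": rng.normal(0, 1, 30) for i in range(3)}
            rej += levene(groups)[1] < 0.05
        assert abs(rej / n_sim - 0.05) <= 0.02

    def test_levene_degenerate(self):
        with pytest.raises(DegenerateDataError):
            levene({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_anova_identical_constants(self):
        res = one_way_anova({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.F == 0.0 and res.p == 1.0

    def test_anova_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 12)
        res = one_way_anova({"x": x, "y": y})
        t, p = stats.ttest_ind(x, y)
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_anova_df_convention_three_substrates(self):
        res = one_way_anova({"iso": [1, 2, 3], "krill": [2, 3, 4], "fish": [9, 9, 8]})
        assert res.df_between == 2
        assert res.df_within == 6

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i, 1, 7) for i in range(4)}
        res = one_way_anova(groups)
        F, p = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(F, rel=1e-12)

    def test_welch_anova_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(1, 4, 8),
                  "c": rng.normal(0.5, 2, 6)}
        F, df1, df2, p = welch_anova(groups)
        df = pd.DataFrame(
            [(k, v) for k, vals in groups.items() for v in vals],
            columns=["group", "value"])
        ref = pg.welch_anova(df, dv="value", between="group").iloc[0]
        assert F == pytest.approx(ref["F"], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"], rel=1e-9)

    def test_shapiro_wilk_behaviour(self):
        rng = np.random.default_rng(2)
        _, p_norm = shapiro_wilk(rng.normal(0, 1, 30))
        assert p_norm > 0.05
        _, p_exp = shapiro_wilk(rng.exponential(1.0, 100))
        assert p_exp < 0.05
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestDuncan:
    def test_far_apart_groups_all_distinct(self):
        groups = {g: replicates_with(m, 1.0, 3) for g, m in
                  zip("abc", (0.0, 100.0, 200.0))}
        res = duncan_letters(groups)
        assert res.letters == {"a": "a", "b": "b", "c": "c"}

    def test_cys_row_reconstruction(self):
        # means/sds rebuilt from the printed Cys row CIs give the a/b/b pattern
        sds = [sd_from_half_width(h, 3) for h in (0.07, 0.05, 0.05)]
        groups = {
            "isopod": replicates_with(0.09, sds[0]),
            "krill": replicates_with(1.34, sds[1]),
            "fish": replicates_with(1.37, sds[2]),
        }
        res = duncan_letters(groups)
        assert res.letters == {"isopod": "a", "krill": "b", "fish": "b"}

    def test_identical_groups_share_one_letter(self):
        groups = {g: replicates_with(5.0, 1.0) for g in "abc"}
        res = duncan_letters(groups)
        assert set(res.letters.values()) == {"a"}

    def test_letters_match_brute_force_oracle_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = rng.integers(3, 6)
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), rng.uniform(0.2, 1.5), 4)
                for i in range(k)
            }
            res = duncan_letters(groups)
            oracle = duncan_pair_oracle(groups)
            for (g1, g2), sig in oracle.items():
                assert res.share_letter(g1, g2) == (not sig), (groups, res.letters)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(i * 0.8, 1.0, 5) for i in range(4)}
        base = duncan_letters(groups)
        shifted = {g: np.asarray(v) + 137.0 for g, v in groups.items()}
        scaled = {g: np.asarray(v) * 3.5 for g, v in groups.items()}
        assert duncan_letters(shifted).letters == base.letters
        assert duncan_letters(scaled).letters == base.letters

    def test_unbalanced_uses_harmonic_mean_with_warning(self):
        groups = {"a": [0, 0.1, -0.1], "b": [5, 5.1, 4.9, 5.0], "c": [10, 10.1, 9.9]}
        with pytest.warns(UserWarning, match="harmonic"):
            res = duncan_letters(groups)
        assert "harmonic_mean_n" in res.flags

    def test_letter_orientation(self):
        groups = {g: replicates_with(m, 0.01) for g, m in zip("xyz", (1.0, 5.0, 9.0))}
        asc = duncan_letters(groups, orientation="asc")
        desc = duncan_letters(groups, orientation="desc")
        assert asc.letters["x"] == "a" and desc.letters["z"] == "a"


class TestLSD:
    def test_identical_groups_not_significant(self):
        res = lsd_pairwise({"c": [1, 2, 3], "o": [1, 2, 3]}, control="c")
        assert not res[0].significant

    def test_hand_computed_critical_value(self):
        groups = {"c": replicates_with(0.0, 1.0), "o": replicates_with(3.0, 1.0)}
        res = lsd_pairwise(groups, control="c")
        mse = 1.0  # both groups have sd exactly 1
        lsd = stats.t.ppf(0.975, 4) * math.sqrt(mse * (1 / 3 + 1 / 3))
        assert res[0].critical == pytest.approx(lsd, rel=1e-9)
        assert res[0].significant == (3.0 > lsd)

    def test_control_vs_two_others_table_shape(self):
        groups = {"iso": [1, 2, 3], "krill": [4, 5, 6], "fish": [7, 8, 9]}
        res = lsd_pairwise(groups, control="iso")
        assert {(c.group1, c.group2) for c in res} == {("iso", "krill"), ("iso", "fish")}

    def test_unknown_control(self):
        with pytest.raises(KeyError):
            lsd_pairwise({"a": [1, 2], "b": [3, 4]}, control="nope")


class TestDunnettT3:
    def test_identical_groups_single_letter(self):
        groups = {g: replicates_with(2.0, 0.5) for g in "abc"}
        res = welch_dunnett_t3(groups)
        assert set(res.letters.values()) == {"a"}

    def test_agrees_with_duncan_on_well_separated_equal_variance(self):
        groups = {g: replicates_with(m, 0.3, 6) for g, m in
                  zip("abc", (0.0, 10.0, 20.0))}
        assert welch_dunnett_t3(groups).letters == duncan_letters(groups).letters

    def test_zero_variance_pair_limit_rule(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [2.0, 2.1, 1.9]}
        res = welch_dunnett_t3(groups)
        pair = {(c.group1, c.group2): c for c in res.pairwise}[("a", "b")]
        assert not pair.significant and "limit rule" in pair.note
        assert any("zero_variance_pair" in f for f in res.flags)

    def test_familywise_type_i_under_unequal_variances(self):
        rng = np.random.default_rng(77)
        n_sim, fw = 1000, 0
        for _ in range(n_sim):
            groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(0, 3, 6),
                      "c": rng.normal(0, 9, 8)}
            res = welch_dunnett_t3(groups)
            fw += any(c.significant for c in res.pairwise)
        assert fw / n_sim <= 0.05 + 0.02


class TestPipelineAndLetters:
    def test_gate_routes_on_levene(self):
        rng = np.random.default_rng(10)
        homo = {f"g{i}": rng.normal(i, 1, 6) for i in range(3)}
        hetero = {"a": rng.normal(0, 0.1, 6), "b": rng.normal(0, 0.1, 6),
                  "c": rng.normal(0, 30, 6)}
        assert compare_groups(homo).method == "anova+duncan"
        assert compare_groups(hetero).method == "welch+dunnettT3"

    def test_force_override(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4]}
        assert compare_groups(groups, force="dunnettT3").method == "welch+dunnettT3"

    def test_letters_from_pairwise_is_sound_by_construction(self):
        means = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        sig = {("a", "b"): False, ("a", "c"): True, ("a", "d"): True,
               ("b", "c"): False, ("b", "d"): True, ("c", "d"): False}
        letters = letters_from_pairwise(means, sig)
        for (g1, g2), s in sig.items():
            assert bool(set(letters[g1]) & set(letters[g2])) == (not s)

    def test_duncan_critical_q_protection_level(self):
        # p=2 reduces to the plain studentized-range (= sqrt(2) t) quantile
        q = duncan_critical_q(2, 6, 0.05)
        assert q == pytest.approx(stats.studentized_range.ppf(0.95, 2, 6), rel=1e-12)
        assert q == pytest.approx(math.sqrt(2) * stats.t.ppf(0.975, 6), rel=1e-6)
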