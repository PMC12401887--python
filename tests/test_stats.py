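"""Type III ANOVA, Tukey–Kramer contrasts, percentile bootstrap."""

import numpy as np
import pytest
from scipy import stats as sps

from thermoreg import bootstrap_mean_ci, pairwise_contrasts, two_way_anova


def _dataset(seed=0, n_per_cell=(4, 7, 5, 6, 8, 3)):
    """Random unbalanced 2×3 dataset with real effects."""
    rng = np.random.default_rng(seed)
    y, trt, biome = [], [], []
    cells = [(t, b) for t in ("benign", "high") for b in ("alpine", "desert", "temperate")]
    means = {c: m for c, m in zip(cells, [0.0, 1.0, -0.5, 2.0, 0.5, 1.5])}
    for (t, b), n in zip(cells, n_per_cell):
        y.extend(rng.normal(means[(t, b)], 1.0, n))
        trt.extend([t] * n)
        biome.extend([b] * n)
    return np.array(y), np.array(trt), np.array(biome)


class TestTwoWayAnova:
    def test_equal_cell_means_give_zero_f(self):
        # Same values in every cell → every effect SS is exactly 0.
        block = [-1.0, 0.0, 1.0]
        y, trt, biome = [], [], []
        for t in ("benign", "high"):
            for b in ("alpine", "desert", "temperate"):
                y.extend(block)
                trt.extend([t] * 3)
                biome.extend([b] * 3)
        tab = two_way_anova(y, trt, biome)
        for term in tab.terms:
            assert tab.ss[term] == pytest.approx(0.0, abs=1e-18)
            assert tab.f[term] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        y = np.concatenate([a, b])
        labels = np.array(["x"] * 10 + ["y"] * 10)
        tab = two_way_anova(y, labels, None)
        t_stat, p = sps.ttest_ind(a, b)
        assert tab.f["treatment"] == pytest.approx(t_stat**2, rel=1e-12)
        assert tab.p["treatment"] == pytest.approx(p, rel=1e-10)

    def test_matches_statsmodels_type3_oracle(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        import pandas as pd

        y, trt, biome = _dataset(seed=3)
        tab = two_way_anova(y, trt, biome)
        df = pd.DataFrame({"y": y, "t": trt, "b": biome})
        fit = smf.ols("y ~ C(t, Sum) * C(b, Sum)", data=df).fit()
        ref = anova_lm(fit, typ=3)
        pairs = {
            "treatment": "C(t, Sum)",
            "biome": "C(b, Sum)",
            "treatment:biome": "C(t, Sum):C(b, Sum)",
        }
        for term, sm_term in pairs.items():
            assert tab.f[term] == pytest.approx(ref.loc[sm_term, "F"], abs=1e-6)
            assert tab.p[term] == pytest.approx(ref.loc[sm_term, "PR(>F)"], abs=1e-6)

    def test_shift_and_scale_invariance(self):
        y, trt, biome = _dataset(seed=5)
        base = two_way_anova(y, trt, biome)
        shifted = two_way_anova(y + 100.0, trt, biome)
        scaled = two_way_anova(y * -3.5, trt, biome)
        for term in base.terms:
            assert shifted.f[term] == pytest.approx(base.f[term], rel=1e-9)
            assert scaled.f[term] == pytest.approx(base.f[term], rel=1e-9)

    def test_balanced_type3_equals_sequential_type1(self):
        rng = np.random.default_rng(8)
        y, trt, biome = _dataset(seed=8, n_per_cell=(5, 5, 5, 5, 5, 5))
        tab = two_way_anova(y, trt, biome)
        # Independent sequential (Type I) sums of squares via incremental fits.
        import pandas as pd

        df = pd.get_dummies(pd.DataFrame({"t": trt, "b": biome}), dtype=float)

        def rss(X):
            X = np.column_stack([np.ones(len(y)), X]) if X is not None else np.ones((len(y), 1))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        Xt = df.filter(like="t_").to_numpy()
        Xb = df.filter(like="b_").to_numpy()
        Xi = np.column_stack([Xt[:, [i]] * Xb for i in range(Xt.shape[1])])
        ss1_t = rss(None) - rss(Xt)
        ss1_b = rss(Xt) - rss(np.column_stack([Xt, Xb]))
        ss1_i = rss(np.column_stack([Xt, Xb])) - rss(np.column_stack([Xt, Xb, Xi]))
        assert tab.ss["treatment"] == pytest.approx(ss1_t, rel=1e-9)
        assert tab.ss["biome"] == pytest.approx(ss1_b, rel=1e-9)
        assert tab.ss["treatment:biome"] == pytest.approx(ss1_i, rel=1e-9, abs=1e-9)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0], ["a", "a"], ["x", "y"])


class TestPairwiseContrasts:
    def test_two_groups_equal_unadjusted_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 12)
        out = pairwise_contrasts(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 12)
        _, p_t = sps.ttest_ind(a, b)
        assert len(out) == 1
        assert out[0].p_adj == pytest.approx(p_t, abs=1e-10)

    def test_identical_groups_have_p_near_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 10)
        y = np.concatenate([base, base, base])
        g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        for c in pairwise_contrasts(y, g):
            assert c.p_adj > 0.999

    def test_matches_statsmodels_tukey_oracle(self):
        pairwise_tukeyhsd = pytest.importorskip(
            "statsmodels.stats.multicomp"
        ).pairwise_tukeyhsd
        y, trt, biome = _dataset(seed=6)
        groups = np.char.add(np.char.add(biome.astype(str), ":"), trt.astype(str))
        ours = {(c.group_a, c.group_b): c for c in pairwise_contrasts(y, groups)}
        ref = pairwise_tukeyhsd(y, groups)
        names = [str(g) for g in ref.groupsunique]
        for (i, j), p_ref, diff_ref in zip(
            [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))],
            ref.pvalues,
            ref.meandiffs,
        ):
            c = ours[(names[i], names[j])]
            assert c.p_adj == pytest.approx(p_ref, abs=1e-6)
            assert c.diff == pytest.approx(-diff_ref, abs=1e-10)

    def test_singleton_group_excluded_with_warning(self):
        y = [1.0, 2.0, 3.0, 4.0, 10.0]
        g = ["a", "a", "b", "b", "solo"]
        with pytest.warns(UserWarning, match="solo"):
            out = pairwise_contrasts(y, g)
        assert len(out) == 1

    def test_holm_alternative(self):
        y, trt, biome = _dataset(seed=9)
        groups = np.char.add(biome.astype(str), trt.astype(str))
        out = pairwise_contrasts(y, groups, method="holm")
        assert all(0.0 <= c.p_adj <= 1.0 for c in out)


class TestBootstrap:
    def test_constant_vector_degenerates(self):
        assert bootstrap_mean_ci([3.0] * 10, seed=0) == (3.0, 3.0, 3.0)

    def test_same_seed_bit_identical(self):
        y = np.random.default_rng(1).normal(size=40)
        assert bootstrap_mean_ci(y, seed=123) == bootstrap_mean_ci(y, seed=123)

    def test_interval_brackets_mean_sanely(self):
        y = np.random.default_rng(2).normal(5.0, 1.0, 100)
        mean, lo, hi = bootstrap_mean_ci(y, seed=0)
        assert lo < mean < hi
        assert hi - lo < 1.0  # ~4 standard errors at n=100

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bootstrap_mean_ci([1.0])
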