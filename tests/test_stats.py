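"""Repeated-measures ANOVA, post-hoc tests, nonparametric tests and the
stimulus-feature regression, each against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from erdvoice.stats import (feature_regression, posthoc, rm_anova, spearman,
                            wilcoxon_paired)


def long_table(X, factors):
    """n_subj x cells array -> long-format frame (C-order over factors)."""
    levels = [list(v) for v in factors.values()]
    rows = []
    for s in range(X.shape[0]):
        for j, combo in enumerate(itertools.product(*levels)):
            rows.append((f"s{s}", *combo, X[s, j]))
    return pd.DataFrame(rows, columns=["subj", *factors.keys(), "y"])


def brute_force_ss(X, k1, k2):
    """Textbook sums-of-squares decomposition for a 2-factor within design."""
    n = X.shape[0]
    cells = X.reshape(n, k1, k2)
    gm = cells.mean()
    a_m = cells.mean(axis=(0, 2))
    b_m = cells.mean(axis=(0, 1))
    ab_m = cells.mean(axis=0)
    s_m = cells.mean(axis=(1, 2))
    sa_m = cells.mean(axis=2)
    sb_m = cells.mean(axis=1)
    ss = {}
    ss["A"] = n * k2 * np.sum((a_m - gm) ** 2)
    ss["B"] = n * k1 * np.sum((b_m - gm) ** 2)
    ss["AB"] = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + gm) ** 2)
    ss["AS"] = k2 * np.sum(
        (sa_m - a_m[None, :] - s_m[:, None] + gm) ** 2
    )
    ss["BS"] = k1 * np.sum(
        (sb_m - b_m[None, :] - s_m[:, None] + gm) ** 2
    )
    resid = (
        cells - ab_m[None] - sa_m[:, :, None] - sb_m[:, None, :]
        + a_m[None, :, None] + b_m[None, None, :] + s_m[:, None, None] - gm
    )
    ss["ABS"] = np.sum(resid**2)
    return ss


class TestRmAnova:
    def test_equal_cells_give_zero_f(self):
        X = np.full((8, 6), 3.7)
        df = long_table(X, {"A": "ab", "B": "xyz"})
        res = rm_anova(df, "y", "subj", ["A", "B"])
        for e in res.effects.values():
            assert e.F == pytest.approx(0.0, abs=1e-12)

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(0)
        df = long_table(rng.normal(size=(10, 2)), {"A": "ab"})
        e = rm_anova(df, "y", "subj", ["A"])["A"]
        assert e.gg_epsilon == 1.0
        assert e.p_gg == e.p

    def test_matches_brute_force_ss_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 4)) + [[0, 0.5, 1.0, 0.2]]
        df = long_table(X, {"A": "ab", "B": "xy"})
        res = rm_anova(df, "y", "subj", ["A", "B"])
        ss = brute_force_ss(X, 2, 2)
        assert res["A"].ss_effect == pytest.approx(ss["A"], abs=1e-8)
        assert res["B"].ss_effect == pytest.approx(ss["B"], abs=1e-8)
        assert res["A*B"].ss_effect == pytest.approx(ss["AB"], abs=1e-8)
        assert res["A"].ss_error == pytest.approx(ss["AS"], abs=1e-8)
        assert res["B"].ss_error == pytest.approx(ss["BS"], abs=1e-8)
        assert res["A*B"].ss_error == pytest.approx(ss["ABS"], abs=1e-8)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6)) + np.linspace(0, 1, 6)
        df = long_table(X, {"A": "ab", "B": "xyz"})
        res = rm_anova(df, "y", "subj", ["A", "B"])
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subj", data=df)
        for src, name in (("A", "A"), ("B", "B"), ("A * B", "A*B")):
            row = ref[ref.Source == src].iloc[0]
            assert res[name].F == pytest.approx(row.F, rel=1e-6)
            assert res[name].p == pytest.approx(row.p_unc, rel=1e-6)
            assert res[name].gg_epsilon == pytest.approx(row.eps, rel=1e-6)

    def test_three_way_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 12))
        df = long_table(X, {"A": "ab", "B": "xy", "G": "pqr"})
        res = rm_anova(df, "y", "subj", ["A", "B", "G"])
        ref = AnovaRM(df, "y", "subj", within=["A", "B", "G"]).fit().anova_table
        mapping = {"A": "A", "B": "B", "G": "G", "A:B": "A*B",
                   "A:G": "A*G", "B:G": "B*G", "A:B:G": "A*B*G"}
        for src, name in mapping.items():
            assert res[name].F == pytest.approx(ref.loc[src, "F Value"], rel=1e-6)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(4)
        df = long_table(rng.normal(size=(6, 4)), {"A": "ab", "B": "xy"})
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, "y", "subj", ["A", "B"])


class TestPosthoc:
    def _anova(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 6)) * 0.5
        X[:, 2] += shift
        df = long_table(X, {"A": "ab", "B": "xyz"})
        return rm_anova(df, "y", "subj", ["A", "B"])

    def test_identical_means_give_p_near_one(self):
        res = self._anova(0.0)
        ph = posthoc(res, "A*B", "tukey_hsd")
        assert (ph.p > 0.2).all()

    def test_lsd_no_larger_than_hsd(self):
        res = self._anova(1.0)
        hsd = posthoc(res, "A*B", "tukey_hsd")
        lsd = posthoc(res, "A*B", "fisher_lsd")
        assert (lsd.p <= hsd.p + 1e-12).all()

    def test_shifted_cell_dominates_smallest_p(self):
        res = self._anova(3.0, seed=1)
        ph = posthoc(res, "A*B", "tukey_hsd")
        shifted = ("a", "z")  # cell index 2 in C order over (A, B=xyz)
        best = ph.loc[ph.p.idxmin()]
        assert shifted in (best.cell_a, best.cell_b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            posthoc(self._anova(), "A*B", "bonferroni")


class TestWilcoxon:
    def test_identical_pairs_no_effect(self):
        x = np.arange(10.0)
        W, p = wilcoxon_paired(x, x)
        assert p == 1.0

    def test_uniform_shift_gives_smallest_exact_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        W, p = wilcoxon_paired(x, x + 100.0)
        assert W == 0.0
        assert p == pytest.approx(2.0 / 2**12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.3, 0.5, 10)
        W, p = wilcoxon_paired(x, y)
        d = x - y
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        total = ranks.sum()
        null = np.array([
            sum(c)
            for k in range(len(ranks) + 1)
            for c in itertools.combinations(sorted(ranks), k)
        ])
        W_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        p_enum = np.mean(np.minimum(null, total - null) <= W_obs)
        assert p == pytest.approx(p_enum, abs=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [2, 3])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_matches_rank_formula_at_study_size(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(7)
        x = rng.normal(size=18)
        y = 0.6 * x + rng.normal(size=18)
        res = spearman(x, y, rng_seed=1)
        d = rankdata(x) - rankdata(y)
        rho_formula = 1 - 6 * np.sum(d**2) / (18 * (18**2 - 1))
        assert res.rho == pytest.approx(rho_formula, abs=1e-12)
        assert 0 < res.p <= 1

    def test_permutation_p_is_seeded(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 15))
        a = spearman(x, y, rng_seed=5)
        b = spearman(x, y, rng_seed=5)
        assert a.p == b.p

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))


class TestFeatureRegression:
    def _descriptors(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "jitter": rng.uniform(0.1, 0.5, n),
            "shimmer": rng.uniform(0.5, 2.0, n),
            "f0_variation": rng.uniform(3, 15, n),
            "median_duration": rng.uniform(0.6, 0.9, n),
        })

    def test_exact_linear_combo_gives_r2_one(self):
        d = self._descriptors(40)
        y = 2.0 * d.jitter - 0.5 * d.shimmer + 0.1 * d.f0_variation + 3.0
        out = feature_regression(d, y)
        assert out["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_null_r2_matches_k_over_n_minus_1(self):
        # with response independent of k predictors, E[R^2] = k / (n - 1)
        rng = np.random.default_rng(1)
        n, reps = 40, 300
        r2s = []
        for i in range(reps):
            d = self._descriptors(n, seed=i)
            y = rng.normal(size=n)
            r2s.append(feature_regression(d, y)["r2"])
        expected = 4 / (n - 1)
        assert np.mean(r2s) == pytest.approx(expected, rel=0.15)

    def test_too_few_stimuli_rejected(self):
        with pytest.raises(ValueError):
            feature_regression(self._descriptors(5), np.zeros(5))
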