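"""Chi-squared tests, GLM scans, Type III ANOVA and Tukey HSD."""

import numpy as np
import pandas as pd
import pytest

from otoshape.groupstats import (ContingencyTable, anova_type3,
                                 descriptor_glm_scan, linear_model_terms,
                                 proportion_chisq, sum_contrasts,
                                 term_columns, tukey_hsd)


# --------------------------------------------------------------------------
# chi-squared

class TestChisq:
    def test_identical_proportions_give_zero(self):
        t = pd.DataFrame([[10, 20, 30], [20, 40, 60]])
        stat, df, p = proportion_chisq(ContingencyTable(t))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_matches_hand_computed_2x3(self):
        obs = np.array([[10.0, 20.0, 30.0], [25.0, 15.0, 20.0]])
        t = ContingencyTable(pd.DataFrame(obs))
        stat, df, p = proportion_chisq(t)
        # independent arithmetic: sum (O-E)^2 / E with E from the margins
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)
        assert df == 2

    def test_df_formula_3x4(self, rng):
        t = ContingencyTable(pd.DataFrame(rng.integers(5, 40, (3, 4))))
        _, df, _ = proportion_chisq(t)
        assert df == 6

    def test_transpose_invariance(self, rng):
        obs = pd.DataFrame(rng.integers(5, 40, (3, 4)))
        s1, _, _ = proportion_chisq(ContingencyTable(obs))
        s2, _, _ = proportion_chisq(ContingencyTable(obs.T))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_column_dropped_with_warning(self):
        t = pd.DataFrame([[5, 0, 9], [7, 0, 3]])
        with pytest.warns(UserWarning, match="empty"):
            stat, df, _ = proportion_chisq(ContingencyTable(t))
        assert df == 1


# --------------------------------------------------------------------------
# Type III ANOVA

def toy_unbalanced(seed=3, n=30):
    rng = np.random.default_rng(seed)
    a = rng.choice(["a1", "a2"], n, p=[0.6, 0.4])
    b = rng.choice(["b1", "b2", "b3"], n)
    y = (0.8 * (a == "a2") + np.array([{"b1": 0, "b2": 0.5, "b3": -0.3}[x]
                                       for x in b])
         + rng.normal(0, 0.7, n))
    return pd.DataFrame({"y": y, "a": a, "b": b})


class TestAnovaType3:
    def test_unbalanced_toy_matches_statsmodels_rss_oracle(self):
        """Each term's Type III SS equals the full-vs-reduced RSS difference
        computed by an independent least-squares route: the sum-coded design
        is built explicitly with pandas/numpy (not the package's encoder) and
        fitted with statsmodels OLS, removing each term's columns in turn."""
        import statsmodels.api as sm
        data = toy_unbalanced()
        # independent sum-to-zero coding via pandas dummies
        def sum_code(series):
            d = pd.get_dummies(series).astype(float)
            d = d.sort_index(axis=1)
            last = d.columns[-1]
            out = d.iloc[:, :-1].copy()
            out.loc[d[last] == 1.0, :] = -1.0
            return out.to_numpy()

        A = sum_code(data["a"])
        B = sum_code(data["b"])
        AB = np.einsum("ni,nj->nij", A, B).reshape(len(data), -1)
        one = np.ones((len(data), 1))
        y = data["y"].to_numpy()

        def rss(*parts):
            X = np.hstack((one,) + parts)
            return float(sm.OLS(y, X).fit().ssr)

        rss_full = rss(A, B, AB)
        oracle = {"a": rss(B, AB) - rss_full,
                  "b": rss(A, AB) - rss_full,
                  "a:b": rss(A, B) - rss_full}
        res = anova_type3(data, response="y", factors=["a", "b"],
                          two_way_interactions=True)
        for term, ss in oracle.items():
            assert res.table.loc[term, "SS"] == pytest.approx(ss, rel=1e-8), term

    def test_balanced_design_type3_equals_type1(self):
        rng = np.random.default_rng(5)
        levels = [(a, b, c) for a in "xy" for b in "pq" for c in "uv"]
        rows = []
        for a, b, c in levels:
            for _ in range(4):
                rows.append((a, b, c, rng.normal()))
        data = pd.DataFrame(rows, columns=["a", "b", "c", "y"])
        res = anova_type3(data, response="y", factors=["a", "b", "c"])
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        fit = smf.ols("y ~ (C(a, Sum) + C(b, Sum) + C(c, Sum)) ** 2", data).fit()
        t1 = anova_lm(fit, typ=1)
        mapping = {"a": "C(a, Sum)", "b": "C(b, Sum)", "c": "C(c, Sum)",
                   "a:b": "C(a, Sum):C(b, Sum)", "a:c": "C(a, Sum):C(c, Sum)",
                   "b:c": "C(b, Sum):C(c, Sum)"}
        for term, smterm in mapping.items():
            assert res.table.loc[term, "SS"] == pytest.approx(
                t1.loc[smterm, "sum_sq"], rel=1e-8), term

    def test_relabeling_and_row_order_invariance(self):
        data = toy_unbalanced(seed=11)
        res1 = anova_type3(data, response="y", factors=["a", "b"])
        relabeled = data.replace({"a": {"a1": "zz", "a2": "aa"},
                                  "b": {"b1": "m", "b2": "a", "b3": "z"}})
        shuffled = relabeled.sample(frac=1.0, random_state=0)
        res2 = anova_type3(shuffled, response="y", factors=["a", "b"])
        np.testing.assert_allclose(res1.table["SS"].to_numpy(float),
                                   res2.table["SS"].to_numpy(float), rtol=1e-8)

    def test_single_level_factor_rejected(self):
        data = toy_unbalanced()
        data["a"] = "only"
        with pytest.raises(ValueError, match="levels"):
            anova_type3(data, response="y", factors=["a", "b"])

    def test_growth_variance_dominated_by_location_and_cohort(self):
        """Simulated G with location and cohort effects but essentially no
        genotype effect: the three-way Type III ANOVA must find location and
        cohort significant and genotype not, in >= 90% of seeded replicates."""
        from otoshape.growth import fit_vbgf, growth_index
        from otoshape.synthetic import SimConfig, generate_population
        ok = 0
        reps = 10
        for seed in range(reps):
            cfg = SimConfig(n_fish=826, seed=3000 + seed)
            fish = generate_population(cfg)
            fit = fit_vbgf(fish["age"], fish["length"])
            fish = fish.assign(G=growth_index(fit, fish).G)
            res = anova_type3(fish)
            t = res.table
            ok += (t.loc["genotype", "p"] > 0.05
                   and t.loc["location", "p"] < 0.05
                   and t.loc["cohort", "p"] < 0.05)
        assert ok >= 0.9 * reps

    def test_saturated_design_rejected(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                             "a": ["x", "x", "y", "y"],
                             "b": ["p", "q", "p", "q"]})
        with pytest.raises(ValueError, match="satur"):
            anova_type3(data, response="y", factors=["a", "b"])


# --------------------------------------------------------------------------
# GLM scans

class TestGlmScan:
    def test_planted_G_effect_count(self):
        rng = np.random.default_rng(8)
        n, n_desc, n_hit = 400, 45, 20
        data = pd.DataFrame({
            "G": rng.normal(0, 5, n),
            "location": rng.choice(["A", "B", "C"], n),
            "cohort": rng.choice([1950, 1960, 1970, 1980], n),
            "genotype": rng.choice(["AA", "AB", "BB"], n),
        })
        Y = rng.normal(0, 1, (n, n_desc))
        Y[:, :n_hit] += np.outer(data["G"], rng.uniform(0.08, 0.15, n_hit))
        desc = pd.DataFrame(Y, columns=[f"F{j + 1:02d}" for j in range(n_desc)])
        res = descriptor_glm_scan(desc, data)
        count = res.significant_counts["G"]
        assert 18 <= count <= 25

    def test_null_type_one_error_calibrated(self):
        rates = []
        for seed in range(50):
            rng = np.random.default_rng(7000 + seed)
            n = 120
            data = pd.DataFrame({"G": rng.normal(0, 5, n),
                                 "location": rng.choice(["A", "B"], n)})
            desc = pd.DataFrame(rng.normal(size=(n, 40)))
            res = descriptor_glm_scan(desc, data, terms=["G", "location"],
                                      categorical={"location"})
            rates.append(res.significant_counts["G"] / 40.0)
        assert 0.02 < np.mean(rates) < 0.09

    def test_constant_term_flagged_aliased(self, rng):
        n = 60
        data = pd.DataFrame({"G": rng.normal(size=n),
                             "location": ["A"] * n})
        desc = pd.DataFrame(rng.normal(size=(n, 5)))
        with pytest.warns(UserWarning, match="aliased"):
            res = descriptor_glm_scan(desc, data, terms=["G", "location"],
                                      categorical={"location"})
        assert "location" in res.aliased
        assert res.significant_counts["location"] == 0


# --------------------------------------------------------------------------
# Tukey HSD

class TestTukey:
    def test_identical_means_no_significant_pairs(self, rng):
        y = rng.normal(0, 1, 300)
        g = np.repeat(["a", "b", "c"], 100)
        res = tukey_hsd(y, g)
        assert not res.comparisons["significant"].any()
        assert res.letters.nunique() == 1

    def test_matches_statsmodels_oracle_on_small_dataset(self):
        y = np.array([1.1, 0.9, 1.3, 1.0, 1.2,
                      1.0, 1.2, 0.8, 1.1, 0.9,
                      2.4, 2.6, 2.2, 2.5, 2.8])
        g = np.repeat(["a", "b", "c"], 5)
        res = tukey_hsd(y, g)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        sm = pairwise_tukeyhsd(y, g)
        np.testing.assert_allclose(res.comparisons["p_adj"].to_numpy(),
                                   sm.pvalues, atol=1e-6)

    def test_letters_contract(self):
        y = np.concatenate([np.zeros(20), np.zeros(20) + 0.05,
                            np.full(20, 3.0)]) + \
            np.random.default_rng(1).normal(0, 0.3, 60)
        g = np.repeat(["a", "b", "c"], 20)
        res = tukey_hsd(y, g)
        letters = res.letters
        for _, row in res.comparisons.iterrows():
            shared = set(letters[row["group1"]]) & set(letters[row["group2"]])
            assert bool(shared) == (not row["significant"])

    def test_singleton_group_excluded(self, rng):
        y = np.concatenate([rng.normal(size=10), rng.normal(size=10), [99.0]])
        g = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
        with pytest.warns(UserWarning, match="size 1"):
            res = tukey_hsd(y, g)
        assert set(res.letters.index) == {"a", "b"}


def test_sum_contrast_columns_have_zero_level_sums():
    rows = sum_contrasts(["x", "y", "z"])
    total = sum(np.asarray(v) for v in rows.values())
    np.testing.assert_allclose(total, 0.0)
    data = pd.DataFrame({"f": ["x", "y", "z", "z", "y"]})
    cols = term_columns(data, "f", {"f"})
    assert cols.shape == (5, 2)
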