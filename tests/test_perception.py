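"""ANOVA, SNK, correlations, category frequencies and the preference map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timbrefuse import (
    attribute_correlations,
    category_frequencies,
    mdpref_map,
    normality_pp,
    one_way_anova,
    snk_groups,
    two_way_anova,
)


class TestCategoryFrequencies:
    def test_single_category_group(self):
        vals = pd.Series([5.0] * 10)
        groups = pd.Series(["S+S"] * 10)
        out = category_frequencies(vals, groups)
        c5 = out[(out["category"] == "C5")]
        assert c5["percent"].iloc[0] == 100.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.uniform(1, 9, 100))
        groups = pd.Series(rng.choice(["S+S", "S+N"], 100))
        out = category_frequencies(vals, groups)
        for g, sub in out.groupby("group"):
            assert sub["count"].sum() == (groups == g).sum()
            assert sub["percent"].sum() == pytest.approx(100.0)

    def test_high_fusion_class_modal_in_upper_categories(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(6.5, 1.0, 200))
        out = category_frequencies(vals, pd.Series(["S+S"] * 200))
        modal = out.loc[out["count"].idxmax(), "category"]
        assert modal in {"C6", "C7", "C8"}

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            category_frequencies(pd.Series([5.0]), pd.Series(["X"]),
                                 known_groups=("S+S",))


class TestNormalityPP:
    def test_normal_sample_hugs_identity(self):
        rng = np.random.default_rng(2)
        emp, mod = normality_pp(rng.normal(10, 3, 500))
        assert np.max(np.abs(emp - mod)) < 0.05

    def test_sequences_nondecreasing_in_unit_interval(self):
        rng = np.random.default_rng(3)
        emp, mod = normality_pp(rng.exponential(1, 200))
        for seq in (emp, mod):
            assert np.all(np.diff(seq) >= 0)
            assert seq.min() >= 0 and seq.max() <= 1

    def test_heavier_tails_deviate_more(self):
        rng = np.random.default_rng(4)
        n = 400
        emp_n, mod_n = normality_pp(rng.normal(0, 1, n))
        emp_t, mod_t = normality_pp(rng.standard_cauchy(n))
        assert (np.max(np.abs(emp_t - mod_t))
                > np.max(np.abs(emp_n - mod_n)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normality_pp(np.full(10, 2.0))


def oracle_one_way_f(groups):
    """Direct sums-of-squares computation for the F statistic."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestOneWayAnova:
    def test_matches_sums_of_squares_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 4, 5]),
                  np.array([7.0, 8, 6])]
        vals = pd.Series(np.concatenate(groups))
        fac = pd.Series(np.repeat(["a", "b", "c"], 3))
        res = one_way_anova(vals, fac)
        assert res.f("factor") == pytest.approx(oracle_one_way_f(groups),
                                                abs=1e-9)
        # cross-check against scipy
        f_sp, p_sp = stats.f_oneway(*groups)
        assert res.f("factor") == pytest.approx(f_sp, abs=1e-9)
        assert res.p("factor") == pytest.approx(p_sp, abs=1e-12)

    def test_sums_of_squares_conserved(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(rng.normal(0, 1, 60))
        fac = pd.Series(rng.choice(["a", "b", "c"], 60))
        res = one_way_anova(vals, fac)
        ss_total = ((vals - vals.mean()) ** 2).sum()
        assert (res.terms["sum_sq"].sum() + res.residual_ss
                == pytest.approx(ss_total, rel=1e-9))

    def test_f_invariant_to_affine_response_rescale(self):
        rng = np.random.default_rng(6)
        vals = pd.Series(rng.normal(0, 1, 45))
        fac = pd.Series(np.repeat(["a", "b", "c"], 15))
        f1 = one_way_anova(vals, fac).f("factor")
        f2 = one_way_anova(vals * 7 - 3, fac).f("factor")
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_null_structure_small_f(self):
        vals = pd.Series([1.0, 2, 3, 1, 2, 3])
        fac = pd.Series(["a"] * 3 + ["b"] * 3)
        res = one_way_anova(vals, fac)
        assert res.p("factor") > 0.05

    def test_null_rejection_rate_calibrated(self):
        """Seeded Monte Carlo: rejection rate at alpha = 0.05 over 2000
        null datasets stays within 0.05 ± 0.01."""
        rej = 0
        fac = pd.Series(np.repeat(["a", "b", "c"], 20))
        for i in range(2000):
            rng = np.random.default_rng(20_000 + i)
            vals = pd.Series(rng.normal(0, 1, 60))
            rej += one_way_anova(vals, fac).p("factor") < 0.05
        assert rej / 2000 == pytest.approx(0.05, abs=0.01)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova(pd.Series([1.0, 2]), pd.Series(["a", "a"]))


class TestTwoWayAnova:
    def _make(self, seed, interaction=0.0, n_per_cell=30):
        rng = np.random.default_rng(seed)
        rows = []
        for e, mu_e in [("S+S", 6.0), ("S+N", 4.0), ("N+N", 5.5)]:
            for c in ("Chinese", "Western"):
                inter = interaction if (e == "S+S" and c == "Chinese") else 0
                y = mu_e + inter + rng.normal(0, 1, n_per_cell)
                rows += [(yy, e, c) for yy in y]
        df = pd.DataFrame(rows, columns=["y", "env", "cul"])
        return df

    def test_additive_effects_interaction_dropped_and_refit(self):
        df = self._make(0)
        full, refit = two_way_anova(df["y"], df["env"], df["cul"])
        assert full.p("envelope:culture") > 0.05
        assert refit is not None
        assert refit.p("envelope") < 0.001

    def test_null_culture_effect_calibrated(self):
        rej = 0
        n = 400
        for i in range(n):
            df = self._make(1000 + i)
            full, refit = two_way_anova(df["y"], df["env"], df["cul"])
            res = refit if refit is not None else full
            rej += res.p("culture") < 0.05
        assert rej / n == pytest.approx(0.05, abs=0.035)

    def test_balanced_design_type3_equals_direct_decomposition(self):
        """In a balanced design Type III SS coincide with the textbook
        factor sums of squares."""
        df = self._make(2, n_per_cell=20)
        full, _ = two_way_anova(df["y"], df["env"], df["cul"])
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_env = sum((df[df["env"] == e]["y"].mean() - grand) ** 2
                     * (df["env"] == e).sum() for e in df["env"].unique())
        assert full.terms.loc["envelope", "sum_sq"] == pytest.approx(
            ss_env, rel=1e-9)

    def test_empty_cell_rejected(self):
        df = self._make(3).query("~(env == 'S+S' and cul == 'Chinese')")
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(df["y"], df["env"], df["cul"])


class TestSNK:
    def test_identical_groups_one_subset(self):
        vals = pd.Series([1.0, 2, 3] * 3)
        fac = pd.Series(np.repeat(["a", "b", "c"], 3))
        assert snk_groups(vals, fac) == [["a", "b", "c"]]

    def test_extreme_separation_all_singletons(self):
        rng = np.random.default_rng(7)
        vals, fac = [], []
        for i, mu in enumerate([0.0, 10.0, 20.0]):
            vals += list(mu + rng.normal(0, 1, 20))
            fac += [f"g{i}"] * 20
        subsets = snk_groups(pd.Series(vals), pd.Series(fac))
        assert subsets == [["g0"], ["g1"], ["g2"]]

    def test_planted_western_fusion_pattern(self):
        """S+S ≈ N+N ≫ S+N produces subsets {S+N} and {N+N, S+S}."""
        rng = np.random.default_rng(8)
        vals, fac = [], []
        for cls, mu, n in [("S+S", 5.95, 113), ("N+N", 5.85, 32),
                           ("S+N", 3.94, 114)]:
            vals += list(mu + rng.normal(0, 1.0, n))
            fac += [cls] * n
        subsets = snk_groups(pd.Series(vals), pd.Series(fac))
        assert subsets == [["S+N"], ["N+N", "S+S"]]

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(9)
        fac = pd.Series(np.repeat(["a", "b", "c", "d"], 15))
        vals = pd.Series(rng.normal(0, 1, 60)
                         + fac.map({"a": 0, "b": 0.5, "c": 1.0, "d": 5.0}))
        subsets = snk_groups(vals, fac)
        flat = [g for s in subsets for g in s]
        assert sorted(flat) == ["a", "b", "c", "d"]
        assert len(flat) == len(set(flat))

    def test_tiny_group_rejected(self):
        vals = pd.Series([1.0, 2, 3])
        fac = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="< 2 observations"):
            snk_groups(vals, fac)


class TestAttributeCorrelations:
    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"fusion": x, "segregation": -x,
                           "roughness": rng.normal(0, 1, 50),
                           "pleasantness": rng.normal(0, 1, 50)})
        corr, pvals = attribute_correlations(df)
        assert corr.loc["fusion", "segregation"] == pytest.approx(-1.0)
        assert pvals.loc["fusion", "segregation"] < 1e-10

    def test_independent_attributes_near_zero(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(0, 1, (500, 4)),
                          columns=["fusion", "segregation", "roughness",
                                   "pleasantness"])
        corr, _ = attribute_correlations(df)
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_matrix_symmetric_unit_diagonal_psd(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(0, 1, (60, 4)),
                          columns=["fusion", "segregation", "roughness",
                                   "pleasantness"])
        corr, _ = attribute_correlations(df)
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert np.min(np.linalg.eigvalsh(arr)) > -1e-10

    def test_zero_variance_signaled(self):
        df = pd.DataFrame({"fusion": [1.0, 1, 1], "segregation": [1.0, 2, 3],
                           "roughness": [2.0, 1, 3], "pleasantness": [1.0, 3, 2]})
        with pytest.raises(ValueError, match="zero-variance"):
            attribute_correlations(df)


class TestMdprefMap:
    def _planted(self, seed=13, n=150):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        eps = 0.05
        return pd.DataFrame({
            "fusion": f1,
            "segregation": -f1 + eps * rng.normal(0, 1, n),
            "roughness": f2 + eps * rng.normal(0, 1, n),
            "pleasantness": -f2 + eps * rng.normal(0, 1, n),
        }, index=[f"s{i}" for i in range(n)])

    def test_anticorrelated_pair_loads_with_opposite_signs(self):
        pm = mdpref_map(self._planted())
        assert pm.loadings.loc["fusion", "dim1"] > 0  # orientation contract
        assert (np.sign(pm.loadings.loc["fusion", "dim1"])
                == -np.sign(pm.loadings.loc["segregation", "dim1"]))

    def test_loadings_bounded_and_variance_ordered(self):
        pm = mdpref_map(self._planted(14))
        assert (pm.loadings.abs() <= 1 + 1e-9).all().all()
        assert pm.variance_explained[0] >= pm.variance_explained[1]

    def test_two_planted_factors_explain_most_variance(self):
        pm = mdpref_map(self._planted(15))
        assert pm.variance_explained.sum() >= 0.95

    def test_invariant_to_stimulus_reordering(self):
        df = self._planted(16)
        pm1 = mdpref_map(df)
        shuffled = df.sample(frac=1.0, random_state=0)
        pm2 = mdpref_map(shuffled)
        assert np.allclose(pm1.loadings.to_numpy(),
                           pm2.loadings.to_numpy(), atol=1e-6)

    def test_rank_deficient_rejected(self):
        df = pd.DataFrame({"fusion": [1.0, 2, 3, 4],
                           "segregation": [2.0, 4, 6, 8],
                           "roughness": [1.5, 3, 4.5, 6],
                           "pleasantness": [-1.0, -2, -3, -4]})
        with pytest.raises(ValueError, match="rank"):
            mdpref_map(df)
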