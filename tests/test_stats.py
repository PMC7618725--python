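"""GLM fitting and Freedman-Lane permutation inference."""

from itertools import permutations as all_perms

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gaspread as g
from conftest import make_clinical


def design_for(n_als, n_hc, seed=0):
    return g.build_design(make_clinical(n_hc, n_als, seed), "group")


class TestFitGlm:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        tbl = make_clinical(10, 12, seed=1)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=22)
        beta, t, df = g.fit_glm(y, d)
        fit = sm.OLS(y, d.X).fit()
        np.testing.assert_allclose(beta, fit.params, rtol=1e-10)
        assert t == pytest.approx(fit.tvalues[1], rel=1e-10)
        assert df == int(fit.df_resid)

    def test_perfect_separation_capped(self):
        tbl = make_clinical(6, 6, seed=2)
        d = g.build_design(tbl, "group")
        y = (tbl.group == "ALS").to_numpy(float)  # y == indicator exactly
        _, t, _ = g.fit_glm(y, d)
        assert t >= 1e10  # capped, not infinite

    def test_location_invariance_of_group_t(self, rng):
        tbl = make_clinical(8, 9, seed=3)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=17)
        b0, t0, _ = g.fit_glm(y, d)
        b1, t1, _ = g.fit_glm(y + 100.0, d)
        assert t1 == pytest.approx(t0, rel=1e-9)
        assert b1[0] == pytest.approx(b0[0] + 100.0)
        np.testing.assert_allclose(b1[1:], b0[1:], atol=1e-9)

    def test_null_t_is_student_distributed(self):
        """Over repeated null draws, the group t follows Student-t(df)."""
        tbl = make_clinical(12, 13, seed=4)
        d = g.build_design(tbl, "group")
        r = np.random.default_rng(99)
        ts = np.array([g.fit_glm(r.standard_normal(25), d)[1]
                       for _ in range(1000)])
        _, p = sps.kstest(ts, "t", args=(25 - 5,))
        assert p > 0.01

    def test_rank_deficiency_rejected(self):
        X = np.ones((6, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            g.DesignMatrix(X=X, columns=("a", "b"),
                           contrast=np.array([0.0, 1.0]))

    def test_constant_confound_dropped(self):
        tbl = make_clinical(5, 5, seed=5)
        tbl["missing_mri"] = 0  # nobody missing -> uninformative
        d = g.build_design(tbl, "group")
        assert "missing_mri" not in d.columns


def brute_force_fl_pvalue(y, design):
    """Independent exhaustive Freedman-Lane oracle via per-permutation
    statsmodels OLS fits."""
    import statsmodels.api as sm

    X = design.X
    j = design.tested_column
    Z = np.delete(X, j, axis=1)
    hz = Z @ np.linalg.pinv(Z)
    fit_z, resid_z = hz @ y, y - hz @ y
    t_obs = sm.OLS(y, X).fit().tvalues[j]
    hits = total = 0
    for perm in all_perms(range(len(y))):
        y_star = fit_z + resid_z[list(perm)]
        t_star = sm.OLS(y_star, X).fit().tvalues[j]
        hits += abs(t_star) >= abs(t_obs) - 1e-12
        total += 1
    return hits / total


class TestPermutationTest:
    def test_exhaustive_matches_independent_oracle(self, rng):
        tbl = make_clinical(3, 3, seed=6)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=6) + 1.2 * (tbl.group == "ALS").to_numpy()
        res = g.permutation_test(y, d, n_perm=100, seed=0)
        assert res.exhaustive and res.n_perm == 720
        p_oracle = brute_force_fl_pvalue(y, d)
        assert res.p_uncorrected[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_sampled_p_within_mc_error_of_exhaustive(self, rng):
        tbl = make_clinical(3, 4, seed=7)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=7) + 1.0 * (tbl.group == "ALS").to_numpy()
        exact = g.permutation_test(y, d, n_perm=100, seed=0,
                                   exhaustive=True).p_uncorrected[0]
        sampled = g.permutation_test(y, d, n_perm=2000, seed=1,
                                     exhaustive=False).p_uncorrected[0]
        mc_se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(sampled - exact) <= 2 * mc_se + 1e-3

    def test_constant_outcome_gives_p_one(self):
        tbl = make_clinical(5, 5, seed=8)
        d = g.build_design(tbl, "group")
        res = g.permutation_test(np.full(10, 3.3), d, n_perm=200, seed=0)
        assert res.p_uncorrected[0] == 1.0
        assert res.t[0] == 0.0

    def test_affine_rescaling_leaves_p_unchanged(self, rng):
        tbl = make_clinical(6, 7, seed=9)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=13)
        p0 = g.permutation_test(y, d, n_perm=300, seed=5).p_uncorrected
        p1 = g.permutation_test(5.0 * y - 3.0, d, n_perm=300,
                                seed=5).p_uncorrected
        np.testing.assert_allclose(p0, p1)

    def test_fwe_dominates_uncorrected_and_floor(self, rng):
        tbl = make_clinical(10, 10, seed=10)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=(20, 30))
        res = g.permutation_test(y, d, n_perm=300, seed=0)
        assert np.all(res.p_fwe >= res.p_uncorrected)
        assert np.all(res.p_uncorrected >= 1.0 / (1 + res.n_perm) - 1e-12)
        assert np.all(res.p_fwe <= 1.0)

    def test_seeded_reproducibility(self, rng):
        tbl = make_clinical(8, 8, seed=11)
        d = g.build_design(tbl, "group")
        y = rng.normal(size=(16, 5))
        a = g.permutation_test(y, d, n_perm=400, seed=7)
        b = g.permutation_test(y, d, n_perm=400, seed=7)
        np.testing.assert_array_equal(a.p_uncorrected, b.p_uncorrected)
        np.testing.assert_array_equal(a.p_fwe, b.p_fwe)

    def test_multi_coefficient_contrast_rejected(self):
        tbl = make_clinical(5, 5, seed=12)
        d = g.build_design(tbl, "group")
        d.contrast = np.array([0, 1, 1, 0, 0], dtype=float)
        with pytest.raises(ValueError, match="exactly one"):
            g.permutation_test(np.zeros(10), d, n_perm=200)


class TestGroupContrast:
    @staticmethod
    def make_spreads(tbl, rng, effect=0.0, window=(1.0, 3.0)):
        edges = -1.0 + 0.1 * np.arange(61)
        centers = 0.5 * (edges[:-1] + edges[1:])
        spreads = []
        for _, row in tbl.iterrows():
            act = rng.normal(5, 1, (2, 60))
            if row.group == "ALS":
                act[0, (centers >= window[0]) & (centers <= window[1])] += effect
            spreads.append(g.SpreadSeries(
                activated_count=np.clip(act, 0, None),
                deactivated_count=rng.normal(2, 0.5, (2, 60)).clip(0),
                band_names=("gamma", "high_gamma"), bin_edges=edges,
                participant_id=row.participant_id, group=row.group))
        return spreads

    def test_planted_window_effect_recovered_in_window(self, rng):
        tbl = make_clinical(12, 12, seed=13)
        spreads = self.make_spreads(tbl, rng, effect=4.0)
        res = g.group_contrast_spread(spreads, tbl, n_perm=400, seed=0)
        sig = [lab for lab, p in zip(res.labels, res.p_fwe) if p < 0.05]
        assert sig, "planted effect not detected"
        in_window = [lab for lab in sig if lab.startswith("activated:gamma")
                     or lab == "gas:gamma"]
        assert len(in_window) / len(sig) >= 0.9
        for lab in sig:
            if lab.startswith("activated:gamma:"):
                t_mid = float(lab.split(":")[2][:-1])
                assert 0.9 <= t_mid <= 3.1

    def test_shuffled_labels_kill_the_effect(self, rng):
        tbl = make_clinical(10, 10, seed=14)
        spreads = self.make_spreads(tbl, rng, effect=4.0)
        shuffled = tbl.copy()
        shuffled["group"] = np.random.default_rng(0).permutation(tbl.group)
        for s, grp in zip(spreads, shuffled.group):
            s.group = grp
        res = g.group_contrast_spread(spreads, shuffled, n_perm=400, seed=0)
        assert (res.p_fwe < 0.05).mean() < 0.05

    def test_planted_deactivation_deficit_detected_with_negative_t(self, rng):
        tbl = make_clinical(12, 12, seed=15)
        spreads = self.make_spreads(tbl, rng, effect=0.0)
        edges = spreads[0].bin_edges
        centers = 0.5 * (edges[:-1] + edges[1:])
        sel = (centers >= 1) & (centers <= 3)
        for s in spreads:
            if s.group == "ALS":
                s.deactivated_count[0, sel] = np.clip(
                    s.deactivated_count[0, sel] - 1.8, 0, None)
        res = g.group_contrast_spread(spreads, tbl, n_perm=400, seed=0)
        sig_deact = [(lab, t) for lab, t, p in zip(res.labels, res.t, res.p_fwe)
                     if p < 0.05 and lab.startswith("deactivated:gamma")]
        assert sig_deact
        assert all(t < 0 for _, t in sig_deact)


class TestClinicalAssociation:
    def test_null_p_uniform_over_seeds(self):
        """Planted slope 0: permutation p for the GAS coefficient is
        uniform across simulation seeds (KS test)."""
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            tbl = make_clinical(0, 25, seed=seed)
            gas = r.normal(12, 4, 25)
            tbl["progression_rate"] = r.normal(0.4, 0.2, 25).clip(0.01)
            res = g.clinical_association(gas, tbl, "progression_rate",
                                         n_perm=200, seed=seed)
            ps.append(res.p_uncorrected[0])
        _, pks = sps.kstest(ps, "uniform")
        assert pks > 0.01

    def test_planted_positive_slope_recovered_with_power(self):
        """Strong planted GAS->progression slope at n=42: positive beta and
        p < 0.05 in >= 80% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            tbl = make_clinical(0, 42, seed=seed)
            gas = r.normal(12, 4, 42)
            z = (gas - gas.mean()) / gas.std()
            tbl["progression_rate"] = (0.4 + 0.15 * z
                                       + r.normal(0, 0.2, 42)).clip(0.01)
            res = g.clinical_association(gas, tbl, "progression_rate",
                                         n_perm=300, seed=seed)
            hits += (res.beta[0] > 0) and (res.p_uncorrected[0] < 0.05)
        assert hits / n_seeds >= 0.80

    def test_constant_gas_rejected(self):
        tbl = make_clinical(0, 15, seed=16)
        tbl["progression_rate"] = np.random.default_rng(0).normal(0.4, 0.1, 15)
        with pytest.raises(ValueError, match="constant"):
            g.clinical_association(np.full(15, 9.0), tbl, "progression_rate",
                                   n_perm=200)

    def test_unknown_outcome_rejected(self):
        tbl = make_clinical(0, 15, seed=17)
        with pytest.raises(ValueError, match="outcome"):
            g.clinical_association(np.arange(15.0), tbl, "weight", n_perm=200)
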