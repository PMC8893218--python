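"""Three-level REML model against brute-force oracles.

The oracles here deliberately avoid the package's block-structured
shortcuts: the restricted likelihood is evaluated with dense matrices,
log-determinants and explicit solves, and the variance components are
found by 2-D grid search over that dense likelihood.
"""

import numpy as np
import pytest
from scipy import stats

from conftest import make_gv_dataset
from metamem import (AnalysisConfig, fit_three_level, interaction_test,
                     lrt_variance_component, moderator_omnibus_test, reml_loglik,
                     subgroup_fits, wald_inference)
from metamem.model import RankDeficiencyError
from metamem.simulate import ModeratorSpec, SimulationSpec, simulate_dataset


def dense_reml_loglik(tau2_b, tau2_w, y, v, clusters, X):
    """Independent dense-matrix restricted likelihood (no block shortcuts)."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    k, p = X.shape
    clusters = np.asarray(clusters)
    Z = (clusters[:, None] == np.unique(clusters)[None, :]).astype(float)
    M = np.diag(np.asarray(v, float) + tau2_w) + tau2_b * (Z @ Z.T)
    Minv = np.linalg.inv(M)
    XtMX = X.T @ Minv @ X
    beta = np.linalg.solve(XtMX, X.T @ Minv @ y)
    r = y - X @ beta
    _, ld_m = np.linalg.slogdet(M)
    _, ld_x = np.linalg.slogdet(XtMX)
    return -0.5 * ((k - p) * np.log(2 * np.pi) + ld_m + ld_x + r @ Minv @ r)


def grid_search_reml(y, v, clusters, X, hi_b, hi_w, step=1e-3):
    grid_b = np.arange(0.0, hi_b + step, step)
    grid_w = np.arange(0.0, hi_w + step, step)
    best = (-np.inf, 0.0, 0.0)
    for tb in grid_b:
        for tw in grid_w:
            ll = dense_reml_loglik(tb, tw, y, v, clusters, X)
            if ll > best[0]:
                best = (ll, tb, tw)
    return best


def _yvcX(ds):
    y = np.array([r.g for r in ds.records])
    v = np.array([r.v for r in ds.records])
    cl = np.array([r.report_id for r in ds.records])
    return y, v, cl, np.ones((y.size, 1))


class TestRemlLoglik:
    def test_matches_dense_oracle_on_toy(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0.3, 0.3, 6)
        v = rng.uniform(0.02, 0.1, 6)
        cl = np.array(["a", "a", "b", "b", "b", "c"])
        X = np.ones((6, 1))
        for tb, tw in [(0.0, 0.0), (0.05, 0.02), (0.3, 0.0), (0.0, 0.17)]:
            assert reml_loglik(tb, tw, y, v, cl, X) == pytest.approx(
                dense_reml_loglik(tb, tw, y, v, cl, X), abs=1e-9)

    def test_collapses_to_fixed_effect_restricted_likelihood(self):
        # tau2 = 0, one effect per cluster: the weighted fixed-effect value
        y = np.array([0.1, 0.4, 0.2])
        v = np.array([0.04, 0.02, 0.05])
        cl = np.array(["a", "b", "c"])
        X = np.ones((3, 1))
        w = 1 / v
        mu = (w * y).sum() / w.sum()
        expected = -0.5 * (2 * np.log(2 * np.pi) + np.sum(np.log(v))
                           + np.log(w.sum()) + np.sum(w * (y - mu) ** 2))
        assert reml_loglik(0.0, 0.0, y, v, cl, X) == pytest.approx(expected)

    def test_invariant_to_within_cluster_permutation(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=7)
        v = rng.uniform(0.02, 0.2, 7)
        cl = np.array(["a", "a", "a", "b", "b", "c", "c"])
        X = np.ones((7, 1))
        base = reml_loglik(0.07, 0.03, y, v, cl, X)
        perm = np.array([2, 0, 1, 4, 3, 6, 5])
        assert reml_loglik(0.07, 0.03, y[perm], v[perm], cl[perm],
                           X[perm]) == pytest.approx(base)


class TestFit:
    def test_equal_weights_collapse_to_mean(self):
        ds = make_gv_dataset([0.1, 0.2, 0.6, 0.3], [0.05] * 4)
        fit = fit_three_level(ds, None, AnalysisConfig(),
                              fix_tau2_between=0.0, fix_tau2_within=0.0)
        assert fit.estimate == pytest.approx(np.mean([0.1, 0.2, 0.6, 0.3]))

    def test_matches_grid_search_oracle(self, small_sim_dataset):
        fit = fit_three_level(small_sim_dataset)
        y, v, cl, X = _yvcX(small_sim_dataset)
        hi_b = max(2 * fit.tau2_between, 0.05)
        hi_w = max(2 * fit.tau2_within, 0.05)
        _, tb, tw = grid_search_reml(y, v, cl, X, hi_b, hi_w, step=1e-3)
        assert fit.tau2_between == pytest.approx(tb, abs=1.5e-3)
        assert fit.tau2_within == pytest.approx(tw, abs=1.5e-3)

    def test_two_level_special_case_matches_scalar_oracle(self):
        """One effect per cluster, tau2_w fixed 0: an ordinary two-level
        random-effects REML, cross-checked by scalar optimisation of the
        dense likelihood."""
        rng = np.random.default_rng(3)
        k = 20
        v = rng.uniform(0.02, 0.1, k)
        y = rng.normal(0.3, np.sqrt(0.05 + v))
        ds = make_gv_dataset(y, v)
        fit = fit_three_level(ds, None, AnalysisConfig(), fix_tau2_within=0.0)
        from scipy.optimize import minimize_scalar
        cl = np.arange(k).astype(str)
        X = np.ones((k, 1))
        res = minimize_scalar(lambda t: -dense_reml_loglik(t, 0.0, y, v, cl, X),
                              bounds=(0, 1), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.tau2_between == pytest.approx(max(res.x, 0.0), abs=1e-5)
        w = 1 / (v + fit.tau2_between)
        assert fit.estimate == pytest.approx((w * y).sum() / w.sum())

    def test_fixed_effect_collapse_matches_statsmodels(self):
        """tau2 pinned at zero with independent effects is the classic
        inverse-variance fixed-effect pool; statsmodels is the oracle."""
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(14)
        y = rng.normal(0.3, 0.2, 12)
        v = rng.uniform(0.01, 0.1, 12)
        ds = make_gv_dataset(y, v)
        fit = fit_three_level(ds, None, AnalysisConfig(),
                              fix_tau2_between=0.0, fix_tau2_within=0.0)
        sm = combine_effects(y, v)
        assert fit.estimate == pytest.approx(sm.mean_effect_fe, rel=1e-9)
        assert fit.se[0] == pytest.approx(sm.sd_eff_w_fe, rel=1e-6)

    def test_collinear_moderator_raises(self):
        ds = make_gv_dataset([0.1, 0.2, 0.3, 0.4], [0.04] * 4,
                             moderators=[{"recovery_sleep": "yes"}] * 4)
        with pytest.raises(RankDeficiencyError):
            fit_three_level(ds, "~ recovery_sleep")


class TestWald:
    def test_printed_style_interval(self):
        # se 0.050 around 0.277 gives the [0.179, 0.375] normal interval
        ds = make_gv_dataset([0.277, 0.277], [0.005, 0.005])
        fit = fit_three_level(ds, None, AnalysisConfig(),
                              fix_tau2_between=0.0, fix_tau2_within=0.0)
        assert fit.se[0] == pytest.approx(0.05)
        inf = wald_inference(fit)
        assert inf.ci_low[0] == pytest.approx(0.277 - 1.959964 * 0.05, abs=1e-4)
        assert inf.ci_high[0] == pytest.approx(0.277 + 1.959964 * 0.05, abs=1e-4)

    def test_ci_width_linear_in_se(self, small_sim_dataset):
        fit = fit_three_level(small_sim_dataset)
        inf = wald_inference(fit)
        width = inf.ci_high - inf.ci_low
        assert width == pytest.approx(2 * 1.9599639845 * fit.se, rel=1e-9)

    def test_null_estimate_has_p_one(self):
        ds = make_gv_dataset([0.3, -0.3], [0.04, 0.04])
        fit = fit_three_level(ds, None, AnalysisConfig(),
                              fix_tau2_between=0.0, fix_tau2_within=0.0)
        inf = wald_inference(fit)
        assert inf.p[0] == pytest.approx(1.0)


class TestVarianceLRT:
    def test_nesting_gives_nonnegative_lrt(self, small_sim_dataset):
        for level in ("between", "within"):
            res = lrt_variance_component(small_sim_dataset, level)
            assert res["lrt_stat"] >= 0
            assert res["loglik_full"] >= res["loglik_reduced"] - 1e-8
            assert res["p_onesided"] == pytest.approx(res["p_chi2_1"] / 2)

    def test_boundary_null_concentrates_at_zero(self):
        """With tau2_between = 0 truly, about half the LRT draws are 0."""
        zeros = 0
        reps = 120
        for s in range(reps):
            ds = simulate_dataset(SimulationSpec(
                n_reports=15, effects_per_report=(2, 3), tau2_between=0.0,
                tau2_within=0.02, seed=30_000 + s))
            res = lrt_variance_component(ds, "between")
            zeros += res["lrt_stat"] < 1e-6
        assert 0.35 <= zeros / reps <= 0.85

    def test_power_against_large_component(self):
        rejections = 0
        reps = 40
        for s in range(reps):
            ds = simulate_dataset(SimulationSpec(
                n_reports=40, effects_per_report=(2, 3), tau2_between=0.2,
                seed=31_000 + s))
            res = lrt_variance_component(ds, "between")
            rejections += res["p_onesided"] < 0.05
        assert rejections / reps > 0.8


class TestModeratorTests:
    def test_df1_identity_with_slope_z(self):
        ds = simulate_dataset(SimulationSpec(n_reports=20, seed=77))
        fit = fit_three_level(ds, "~ recovery_sleep")
        omni = moderator_omnibus_test(fit)
        z = fit.beta[1] / fit.se[1]
        assert omni["Q_M"] == pytest.approx(z**2)
        assert omni["df"] == 1

    def test_planted_moderator_shift_recovered(self):
        mods = {"recovery_sleep": ModeratorSpec(("yes", "no"), (0.5, 0.5),
                                                {"no": 0.25})}
        diffs = []
        for s in range(25):
            ds = simulate_dataset(SimulationSpec(
                n_reports=40, moderators=mods, tau2_between=0.02,
                tau2_within=0.01, seed=32_000 + s))
            subs = subgroup_fits(ds, "recovery_sleep")
            diffs.append(subs["no"].estimate - subs["yes"].estimate)
        assert np.mean(diffs) == pytest.approx(0.25, abs=0.06)

    def test_subgroups_partition_dataset(self, paper_scale_dataset):
        subs = subgroup_fits(paper_scale_dataset, "recovery_sleep")
        assert sum(f.k for f in subs.values()) == len(paper_scale_dataset)

    def test_single_level_equals_overall(self):
        ds = make_gv_dataset([0.1, 0.3, 0.5], [0.04, 0.05, 0.06],
                             moderators=[{"recovery_sleep": "yes"}] * 3)
        subs = subgroup_fits(ds, "recovery_sleep")
        overall = fit_three_level(ds)
        assert subs["yes"].estimate == pytest.approx(overall.estimate)

    def test_interaction_requires_full_cells(self):
        mods = [{"recovery_sleep": "yes", "memory_type": "declarative"},
                {"recovery_sleep": "yes", "memory_type": "procedural"},
                {"recovery_sleep": "no", "memory_type": "declarative"},
                {"recovery_sleep": "no", "memory_type": "declarative"}]
        ds = make_gv_dataset([0.1, 0.2, 0.3, 0.4], [0.04] * 4, moderators=mods)
        with pytest.raises(RankDeficiencyError, match="empty design cell"):
            interaction_test(ds, "recovery_sleep", "memory_type")

    def test_planted_interaction_detected(self):
        mods = {
            "recovery_sleep": ModeratorSpec(("yes", "no"), (0.5, 0.5)),
            "memory_type": ModeratorSpec(("declarative", "procedural"), (0.5, 0.5)),
        }
        hits = 0
        for s in range(20):
            ds = simulate_dataset(SimulationSpec(
                n_reports=60, effects_per_report=(2, 3),
                tau2_between=0.01, tau2_within=0.005,
                moderators=mods, seed=33_000 + s))
            # plant a cell-specific shift by editing g directly
            import dataclasses as dc
            recs = []
            for r in ds.records:
                g = r.g
                if (r.moderators["recovery_sleep"] == "no"
                        and r.moderators["memory_type"] == "procedural"):
                    g = g + 0.5
                recs.append(dc.replace(r, g=g, moderators=dict(r.moderators)))
            from metamem import StudyDataset
            ds2 = StudyDataset(recs, "planted")
            if interaction_test(ds2, "recovery_sleep", "memory_type")["p"] < 0.05:
                hits += 1
        assert hits / 20 > 0.8


class TestRecovery:
    def test_paper_scale_point_estimates(self, paper_scale_dataset):
        fit = fit_three_level(paper_scale_dataset)
        truth = paper_scale_dataset.truth
        se_mu = np.sqrt(truth["tau2_between"] / paper_scale_dataset.n_clusters) * 3
        assert abs(fit.estimate - truth["mu"]) < se_mu + 0.05
        assert fit.tau2_between < 4 * truth["tau2_between"] + 0.05
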