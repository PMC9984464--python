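"""Regression, mixed-model and permutation inference: recovery and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from pupilsync import (
    ConfigurationError,
    feature_regression,
    performance_regression,
    permutation_test,
    synchrony_mixed_model,
)
from pupilsync.infer import CrossedREML


def make_story_table(score, beta=0.0, sd_participant=0.5, sd_story=0.5,
                     sd_noise=1.0, n_stories=4, rng=None):
    """Synthetic cohort: story-level synchrony with crossed random intercepts."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n_p = len(score)
    u_p = rng.normal(0, sd_participant, n_p)
    u_s = rng.normal(0, sd_story, n_stories)
    rows = []
    for i in range(n_p):
        for k in range(n_stories):
            y = beta * score[i] + u_p[i] + u_s[k] + rng.normal(0, sd_noise)
            rows.append((i, k, y))
    return pd.DataFrame(rows, columns=["participant", "story", "story_value"])


class TestPerformanceRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = performance_regression(2 * x + 1, x)
        assert res.beta == pytest.approx(1.0, abs=1e-9)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        pvals = [
            performance_regression(rng.normal(size=24), rng.normal(size=24)).p
            for _ in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_shared_driver_gives_positive_beta(self):
        """When one latent gain drives both d' and entrainment, beta > 0."""
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(100):
            gain = rng.uniform(0, 2, size=40)
            dprimes = gain + rng.normal(0, 0.5, 40)
            scores = gain + rng.normal(0, 0.5, 40)
            wins += performance_regression(dprimes, scores).beta > 0
        assert wins >= 95

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ConfigurationError):
            performance_regression(np.arange(5.0), np.ones(5))


class TestFeatureRegression:
    @staticmethod
    def features_frame(rng, n=72):
        return pd.DataFrame(
            {
                "amplitude": rng.normal(size=n),
                "latency": rng.normal(size=n),
                "width": rng.normal(size=n),
            }
        )

    def test_amplitude_effect_recovered(self):
        """Outcome built from amplitude alone: only that coefficient fires."""
        rng = np.random.default_rng(3)
        amp_hits, spurious = 0, 0
        for _ in range(100):
            f = self.features_frame(rng)
            outcome = 0.7 * f["amplitude"] + rng.normal(0, 1.0, len(f))
            res = feature_regression(f, outcome)
            tbl = res.coef_table.set_index("feature")
            amp_hits += tbl.loc["amplitude", "p_fdr"] < 0.05
            spurious += (tbl.loc[["latency", "width"], "p_fdr"] < 0.05).any()
        assert amp_hits >= 90
        assert spurious <= 15

    def test_null_omnibus_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            f = self.features_frame(rng, n=40)
            res = feature_regression(f, rng.normal(size=40))
            pvals.append(res.f_p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_feature_dropped_with_flag(self):
        rng = np.random.default_rng(5)
        f = self.features_frame(rng, n=30)
        f["width"] = 1.0
        res = feature_regression(f, rng.normal(size=30))
        assert any("width" in flag for flag in res.flags)
        assert "width" not in set(res.coef_table["feature"])


class TestSynchronyMixedModel:
    def test_known_effect_recovered(self):
        rng = np.random.default_rng(6)
        betas = []
        for _ in range(30):
            score = rng.normal(size=24)
            tbl = make_story_table(score, beta=0.5, rng=rng)
            betas.append(synchrony_mixed_model(tbl, pd.Series(score)).beta)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.1)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            score = rng.normal(size=24)
            tbl = make_story_table(score, beta=0.0, rng=rng)
            pvals.append(synchrony_mixed_model(tbl, pd.Series(score)).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_story_falls_back_to_story_mean_ols(self):
        rng = np.random.default_rng(8)
        score = rng.normal(size=10)
        tbl = make_story_table(score, n_stories=1, rng=rng)
        res = synchrony_mixed_model(tbl, pd.Series(score))
        assert res.method == "story_mean_ols"
        assert "degenerate_story_variance" in res.flags

    def test_engines_agree(self):
        """The compact REML solver matches statsmodels' MixedLM."""
        rng = np.random.default_rng(9)
        for beta in (0.0, 0.5):
            score = rng.normal(size=16)
            tbl = make_story_table(score, beta=beta, rng=rng)
            sm_fit = synchrony_mixed_model(tbl, pd.Series(score), engine="statsmodels")
            fast = synchrony_mixed_model(tbl, pd.Series(score), engine="reml2")
            assert fast.beta == pytest.approx(sm_fit.beta, abs=1e-6)

    def test_reml_criterion_at_least_as_good_as_statsmodels(self):
        """Our optimizer never lands above statsmodels' REML objective."""
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

        rng = np.random.default_rng(10)
        for trial in range(5):
            n_p, n_s = 12, 4
            score = rng.normal(size=n_p)
            tbl = make_story_table(score, beta=0.3, rng=rng)
            pid = tbl["participant"].to_numpy()
            sid = tbl["story"].to_numpy()
            y = tbl["story_value"].to_numpy()
            X = np.column_stack([np.ones_like(y), score[pid]])
            solver = CrossedREML(pid, sid)
            _, _, gamma, s2, _ = solver.fit(y, X)
            Zp = (pid[:, None] == np.arange(n_p)).astype(float)
            Zs = (sid[:, None] == np.arange(n_s)).astype(float)
            vcs = VCSpec(
                ["p", "s"],
                [[[f"p{i}" for i in range(n_p)]], [[f"s{i}" for i in range(n_s)]]],
                [[Zp], [Zs]],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y, X, groups=np.zeros(len(y), int), exog_vc=vcs).fit(
                    reml=True, method="lbfgs", disp=False
                )
            crit_ours = solver.reml_criterion(gamma[0], gamma[1], y, X)
            g_sm = np.maximum(fit.vcomp / fit.scale, 1e-10)
            crit_sm = solver.reml_criterion(g_sm[0], g_sm[1], y, X)
            assert crit_ours <= crit_sm + 1e-6

    def test_unbalanced_design_dense_path(self):
        """Dropping rows switches to the dense solver; engines still agree."""
        rng = np.random.default_rng(11)
        score = rng.normal(size=12)
        tbl = make_story_table(score, beta=0.4, rng=rng).drop(index=[1, 7, 22])
        fast = synchrony_mixed_model(tbl, pd.Series(score), engine="reml2")
        sm_fit = synchrony_mixed_model(tbl, pd.Series(score), engine="statsmodels")
        assert fast.beta == pytest.approx(sm_fit.beta, abs=0.05)


class TestPermutationTest:
    def test_deterministic_null(self):
        rng = np.random.default_rng(12)
        score = rng.normal(size=12)
        tbl = make_story_table(score, beta=0.3, rng=rng)
        a = permutation_test(tbl, pd.Series(score), n_perm=100, seed=5)
        b = permutation_test(tbl, pd.Series(score), n_perm=100, seed=5)
        assert np.array_equal(a.null_betas, b.null_betas)
        assert a.p_perm == b.p_perm

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(13)
        score = rng.normal(size=12)
        tbl = make_story_table(score, rng=rng)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(tbl, pd.Series(score), n_perm=50, seed=0)

    def test_strong_effect_hits_permutation_floor(self):
        """A clean strong effect at n=63 attains the minimal p of 1/1001."""
        rng = np.random.default_rng(14)
        score = rng.normal(size=63)
        tbl = make_story_table(
            score, beta=0.5, sd_participant=0.1, sd_story=0.1,
            sd_noise=0.2, rng=rng,
        )
        res = permutation_test(tbl, pd.Series(score), n_perm=1000, seed=1)
        assert res.p_perm == pytest.approx(1 / 1001)

    def test_p_perm_floor_enforced(self):
        rng = np.random.default_rng(15)
        score = rng.normal(size=12)
        tbl = make_story_table(score, beta=2.0, sd_noise=0.1, rng=rng)
        res = permutation_test(tbl, pd.Series(score), n_perm=100, seed=0)
        assert res.p_perm >= 1 / 101
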