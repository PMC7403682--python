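"""Sampler and model tests: mixture accuracy, oracles, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from ecotensor.fitmodels import (LOGISTIC_MIX_S, LOGISTIC_MIX_W, CharStateSpec,
                                 MCMCSettings, MeanModelSpec,
                                 conditional_survival_recode,
                                 fit_charstate_model, fit_mean_model,
                                 marginal_probability,
                                 predict_category_probabilities)

FAST = MCMCSettings(iterations=900, burn_in=150, thin=1, seed=3)


def _mean_df(rng, n=3000, eta=None, fam_sd=0.0, blk_sd=0.0):
    hab = rng.choice(["A", "B"], n)
    cat = rng.choice(["X", "Y"], n)
    fam = np.char.add(cat.astype(str), rng.choice(12, n).astype(str))
    blk = np.char.add(hab.astype(str), rng.choice(4, n).astype(str))
    eta = eta or {("A", "X"): -0.8, ("A", "Y"): 0.3, ("B", "X"): 1.1, ("B", "Y"): 0.0}
    fam_eff = {f: rng.normal(0, fam_sd) for f in np.unique(fam)}
    blk_eff = {b: rng.normal(0, blk_sd) for b in np.unique(blk)}
    lat = np.array([eta[(h, c)] + fam_eff[f] + blk_eff[b]
                    for h, c, f, b in zip(hab, cat, fam, blk)])
    y = (rng.logistic(size=n) < lat).astype(int)
    return pd.DataFrame({"habitat": hab, "cross_type": cat, "family": fam,
                         "block": blk, "establishment": y}), eta


class TestLogisticMixture:
    def test_cdf_accuracy(self):
        """The frozen normal mixture reproduces the logistic CDF to < 1e-6."""
        x = np.linspace(-25, 25, 5001)
        cdf = (LOGISTIC_MIX_W[None, :]
               * norm.cdf(x[:, None] / LOGISTIC_MIX_S[None, :])).sum(1)
        assert np.abs(cdf - expit(x)).max() < 1e-6

    def test_variance_matches_logistic(self):
        v = (LOGISTIC_MIX_W * LOGISTIC_MIX_S ** 2).sum()
        assert v == pytest.approx(np.pi ** 2 / 3, rel=1e-4)


class TestMarginalProbability:
    def test_zero_latent_gives_half(self):
        assert marginal_probability(0.0, 0.0)[0] == pytest.approx(0.5)
        assert marginal_probability(0.0, 2.3)[0] == pytest.approx(0.5, abs=1e-10)

    def test_monotone_in_latent(self):
        etas = np.linspace(-3, 3, 25)
        p = marginal_probability(etas, np.full(25, 1.7))
        assert np.all(np.diff(p) > 0)

    def test_matches_monte_carlo_integration(self, rng):
        """Gauss-Hermite marginalization vs brute-force MC at 1e6 points."""
        for eta, var in [(0.7, 1.3), (-1.2, 0.5), (2.0, 2.5)]:
            mc = expit(eta + np.sqrt(var) * rng.standard_normal(10 ** 6)).mean()
            gh = marginal_probability(eta, var)[0]
            assert gh == pytest.approx(mc, abs=0.005)


class TestMeanModel:
    def test_recovers_cell_means(self, rng):
        df, eta = _mean_df(rng, n=6000)
        post = fit_mean_model(df, settings=FAST)
        for i, hc in enumerate(post.cells):
            d = post.cell_draws[:, i]
            assert abs(d.mean() - eta[hc]) < 4 * d.std() + 0.05

    def test_reproducible(self, rng):
        df, _ = _mean_df(rng, n=800)
        a = fit_mean_model(df, settings=FAST)
        b = fit_mean_model(df, settings=FAST)
        assert np.array_equal(a.cell_draws, b.cell_draws)
        assert np.array_equal(a.variance_draws["family"], b.variance_draws["family"])

    def test_empty_cell_error(self, rng):
        df, _ = _mean_df(rng, n=500)
        df = df[~((df.habitat == "A") & (df.cross_type == "X"))]
        with pytest.raises(ValueError, match="empty habitat x category"):
            fit_mean_model(df, settings=FAST)

    def test_non_binary_outcome_error(self, rng):
        df, _ = _mean_df(rng, n=200)
        df.loc[df.index[0], "establishment"] = 2
        with pytest.raises(ValueError, match="not binary"):
            fit_mean_model(df, settings=FAST)

    def test_null_category_contrast_coverage(self):
        """True category effect 0: contrast covers 0 at 95% in >= 9/10 reps."""
        from ecotensor.diagnostics import hpd_interval
        hits = 0
        eta = {("A", "X"): 0.4, ("A", "Y"): 0.4, ("B", "X"): -0.6, ("B", "Y"): -0.6}
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            df, _ = _mean_df(rng, n=2500, eta=eta)
            post = fit_mean_model(df, settings=MCMCSettings(
                iterations=700, burn_in=150, thin=1, seed=rep))
            contrast = (post.cell_draws[:, post.cell_index("A", "X")]
                        - post.cell_draws[:, post.cell_index("A", "Y")])
            lo, hi = hpd_interval(contrast, 0.95)
            hits += lo <= 0.0 <= hi
        assert hits >= 9

    def test_predicted_probability_unknown_cell(self, rng):
        df, _ = _mean_df(rng, n=400)
        post = fit_mean_model(df, settings=FAST)
        with pytest.raises(KeyError, match="unknown habitat/category"):
            predict_category_probabilities(post, "A", "Z")


class TestCharStateModel:
    def test_psd_draws(self, rng, small_pedigree, small_config):
        from ecotensor.synthdata import simulate_field_fitness
        fd = simulate_field_fitness(small_pedigree, small_config)
        post = fit_charstate_model(fd.df, CharStateSpec.for_generation("F4"), FAST)
        eig = np.linalg.eigvalsh(post.draws)
        assert eig.min() > -1e-10
        assert np.abs(post.draws - np.swapaxes(post.draws, 1, 2)).max() < 1e-12

    def test_reproducible(self, rng, small_pedigree, small_config):
        from ecotensor.synthdata import simulate_field_fitness
        fd = simulate_field_fitness(small_pedigree, small_config)
        a = fit_charstate_model(fd.df, CharStateSpec.for_generation("P"), FAST)
        b = fit_charstate_model(fd.df, CharStateSpec.for_generation("P"), FAST)
        assert np.array_equal(a.draws, b.draws)

    def test_degenerate_habitat_flagged(self, rng):
        q = 40
        rows = []
        for j in range(q):
            for h in range(4):
                for k in range(10):
                    y = 1 if h == 0 else int(rng.random() < 0.5)
                    rows.append((f"H{h}", f"H{h}b{k % 2}", "F4", "F4", f"f{j}", y))
        df = pd.DataFrame(rows, columns=["habitat", "block", "generation",
                                         "cross_type", "family", "establishment"])
        post = fit_charstate_model(df, CharStateSpec.for_generation("F4"), FAST)
        assert post.flagged

    def test_null_covariance_shrinks(self):
        """Truth covariance 0: posterior median variances < 10% of prior scale."""
        ok = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            rows = []
            for j in range(120):
                for h in range(4):
                    for k in range(12):
                        y = int(rng.logistic() < 0.0)
                        rows.append((f"H{h}", f"H{h}b{k % 3}", "F4", "F4", f"f{j}", y))
            df = pd.DataFrame(rows, columns=["habitat", "block", "generation",
                                             "cross_type", "family", "establishment"])
            post = fit_charstate_model(
                df, CharStateSpec.for_generation("F4"),
                MCMCSettings(iterations=800, burn_in=200, thin=1, seed=rep))
            med = np.median(np.einsum("shh->sh", post.draws), axis=0)
            ok += med.max() < 0.1 * MCMCSettings().halft_scale
        assert ok >= 9

    def test_gaussian_scaling_equivariance(self, rng):
        """Scaling a Gaussian response by k scales variances by k^2."""
        q, k_rep = 80, 10
        g = rng.normal(0, 0.8, size=(q, 4))
        rows = []
        for j in range(q):
            for h in range(4):
                for r in range(k_rep):
                    y = g[j, h] + rng.normal(0, 1)
                    rows.append((f"H{h}", "b0", "F4", "F4", f"f{j}", y))
        df = pd.DataFrame(rows, columns=["habitat", "block", "generation",
                                         "cross_type", "family", "establishment"])
        post1 = fit_charstate_model(df, CharStateSpec.for_generation("F4"),
                                    FAST, family="gaussian")
        df2 = df.copy()
        df2["establishment"] *= 2.0
        post2 = fit_charstate_model(df2, CharStateSpec.for_generation("F4"),
                                    FAST, family="gaussian")
        v1 = np.einsum("shh->sh", post1.draws).mean(0)
        v2 = np.einsum("shh->sh", post2.draws).mean(0)
        assert np.allclose(v2 / v1, 4.0, rtol=0.25)

    def test_prior_sensitivity(self, rng):
        """Doubling the half-t prior scale leaves well-identified variances
        within overlapping HPDs."""
        from ecotensor.diagnostics import hpd_interval
        q = 100
        g = rng.normal(0, 1.0, size=(q, 4))
        rows = []
        for j in range(q):
            for h in range(4):
                for r in range(12):
                    y = int(rng.logistic() < g[j, h] - 0.3)
                    rows.append((f"H{h}", f"b{r % 3}", "F4", "F4", f"f{j}", y))
        df = pd.DataFrame(rows, columns=["habitat", "block", "generation",
                                         "cross_type", "family", "establishment"])
        posts = [fit_charstate_model(
            df, CharStateSpec.for_generation("F4"),
            MCMCSettings(iterations=900, burn_in=150, thin=1, seed=5,
                         halft_scale=A)) for A in (1.0, 2.0)]
        for h in range(4):
            i1 = hpd_interval(posts[0].draws[:, h, h], 0.95)
            i2 = hpd_interval(posts[1].draws[:, h, h], 0.95)
            assert max(i1[0], i2[0]) < min(i1[1], i2[1])  # intervals overlap


def test_conditional_survival_recode():
    df = pd.DataFrame({"emergence": [1, 1, 0, 1], "establishment": [1, 0, 0, 1],
                       "maturity": [1, 0, 0, 0]})
    out = conditional_survival_recode(df)
    assert out.establishment.isna().tolist() == [False, False, True, False]
    assert out.maturity.isna().tolist() == [False, True, True, False]
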