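"""Weighted linear modeling, variance moderation and FDR control."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from orthomex.de import (
    GeneFits,
    bh_adjust,
    consensus_block_correlation,
    contrast_vector,
    de_contrast,
    design_matrix,
    ebayes_moderate,
    estimate_prior,
    fit_contrast,
    voom_weights,
)
from orthomex.expression import log2_cpm
from orthomex.naive import naive_bh
from orthomex.simulate import CountsConfig, simulate_counts


def frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def two_group_design(n_per=6):
    meta = pd.DataFrame(
        {"grp": ["a"] * n_per + ["b"] * n_per},
        index=[f"s{j}" for j in range(2 * n_per)],
    )
    X = design_matrix(meta, factors=["grp"])
    return meta, X


class TestDesignMatrix:
    def test_interaction_and_numeric_terms(self):
        meta = pd.DataFrame(
            {
                "species": ["h", "h", "c", "c"] * 2,
                "tissue": ["cm", "ht", "cm", "ht"] * 2,
                "RIN": [9.0, 7.0, 8.5, 6.0, 9.5, 6.5, 8.0, 7.5],
            },
            index=list("stuvwxyz"),
        )
        X = design_matrix(
            meta,
            factors=["species", "tissue"],
            numeric=["RIN"],
            interactions=[("species", "tissue")],
        )
        assert list(X.columns) == [
            "Intercept",
            "species_h",
            "tissue_ht",
            "RIN",
            "species_h:tissue_ht",
        ]

    def test_rank_deficiency_rejected(self):
        meta = pd.DataFrame({"a": ["x", "x", "y"], "b": ["u", "u", "v"]},
                            index=list("pqr"))
        with pytest.raises(ValueError, match="rank"):
            design_matrix(meta, factors=["a", "b"])


class TestVoomWeights:
    def test_homoscedastic_input_gives_flat_weights(self):
        rng = np.random.default_rng(3)
        G, n = 800, 12
        mu = 2.0 ** rng.uniform(9, 13, G)
        counts = frame(np.round(mu[:, None] * np.exp(rng.normal(0, 0.5, (G, n)))) + 1)
        _, X = two_group_design()
        w = voom_weights(counts, X)
        rel = w.to_numpy() / np.median(w.to_numpy())
        assert rel.max() < 1.15 and rel.min() > 0.85

    def test_low_counts_get_lower_weights(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        G, n = 800, 12
        mu = 2.0 ** rng.uniform(0.5, 9, G)
        r = 1 / 0.1
        counts = frame(rng.negative_binomial(r, r / (r + mu[:, None]), (G, n)))
        counts = counts.loc[counts.sum(axis=1) > 0]
        _, X = two_group_design()
        w = voom_weights(counts, X)
        mean_w = w.mean(axis=1)
        mean_c = counts.mean(axis=1)
        low = mean_c < mean_c.quantile(0.5)
        assert spearmanr(mean_w[low], mean_c[low]).statistic > 0.9

    def test_weights_strictly_positive(self):
        rng = np.random.default_rng(5)
        counts = frame(rng.integers(0, 50, (200, 12)))
        counts = counts.loc[counts.sum(axis=1) > 0]
        _, X = two_group_design()
        assert (voom_weights(counts, X).to_numpy() > 0).all()


class TestConsensusBlockCorrelation:
    def sim(self, rng, icc, n_blocks=8, reps=2, G=2000):
        blocks = np.repeat([f"b{i}" for i in range(n_blocks)], reps)
        tau, eps = np.sqrt(icc), np.sqrt(1 - icc)
        y = np.empty((G, blocks.size))
        for g in range(G):
            intercepts = rng.normal(0, tau, n_blocks)
            y[g] = np.repeat(intercepts, reps) + rng.normal(0, eps, blocks.size)
        vals = frame(y)
        meta = pd.DataFrame({"ind": blocks}, index=vals.columns)
        X = design_matrix(meta)  # intercept only
        return vals, X, meta["ind"]

    def test_recovers_planted_intraclass_correlation(self, rng):
        vals, X, blocks = self.sim(rng, icc=0.5)
        assert consensus_block_correlation(vals, X, blocks) == pytest.approx(0.5, abs=0.1)

    def test_independent_samples_give_near_zero(self, rng):
        vals, X, blocks = self.sim(rng, icc=0.0)
        assert abs(consensus_block_correlation(vals, X, blocks)) < 0.05

    def test_duplicated_samples_approach_one(self, rng):
        G, B = 500, 10
        half = rng.normal(size=(G, B))
        y = np.repeat(half, 2, axis=1)
        vals = frame(y)
        blocks = pd.Series(np.repeat([f"b{i}" for i in range(B)], 2), index=vals.columns)
        X = design_matrix(pd.DataFrame(index=vals.columns))
        assert consensus_block_correlation(vals, X, blocks) > 0.95

    def test_no_multi_sample_block_warns_and_returns_zero(self, rng):
        vals = frame(rng.normal(size=(100, 4)))
        blocks = pd.Series([f"b{i}" for i in range(4)], index=vals.columns)
        X = design_matrix(pd.DataFrame(index=vals.columns))
        with pytest.warns(UserWarning):
            assert consensus_block_correlation(vals, X, blocks) == 0.0


class TestFitContrast:
    def test_gls_with_identity_covariance_equals_ols(self, rng):
        G, n = 300, 12
        y = frame(rng.normal(size=(G, n)))
        meta, X = two_group_design()
        c = contrast_vector(X, {"grp_b": 1.0})
        ols = fit_contrast(y, X, c)  # fast path
        gls = fit_contrast(
            y, X, c, weights=pd.DataFrame(np.ones((G, n)), index=y.index, columns=y.columns),
            rho=0.0,
        )
        assert np.abs(ols.estimate - gls.estimate).max() < 1e-10
        assert np.abs(ols.s2 - gls.s2).max() < 1e-10

    def test_balanced_contrast_is_mean_difference(self, rng):
        y = frame(rng.normal(size=(50, 12)))
        meta, X = two_group_design()
        c = contrast_vector(X, {"grp_b": 1.0})
        fits = fit_contrast(y, X, c)
        diff = y.iloc[:, 6:].mean(axis=1) - y.iloc[:, :6].mean(axis=1)
        assert np.abs(fits.estimate - diff.to_numpy()).max() < 1e-10

    def test_recovers_planted_effect(self, rng):
        G, n_per = 2000, 6
        meta, X = two_group_design(n_per)
        effect = 1.5
        y = rng.normal(0, 0.5, (G, 2 * n_per))
        y[:, n_per:] += effect
        fits = fit_contrast(frame(y), X, contrast_vector(X, {"grp_b": 1.0}))
        assert fits.estimate.mean() == pytest.approx(effect, abs=0.05)


class TestEbayesModerate:
    def fits_from(self, rng, G=2000, d=10, d0=8.0, s0=0.25):
        sigma2 = s0 * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(d, G) / d
        est = rng.normal(0, 0.1, G)
        return GeneFits(
            estimate=est,
            stdev_unscaled=np.full(G, 0.4),
            s2=s2,
            df_residual=np.full(G, float(d)),
        )

    def test_prior_hyperparameters_recovered(self, rng):
        d0, s0 = estimate_prior(self.fits_from(rng).s2, np.full(2000, 10.0))
        assert d0 == pytest.approx(8.0, rel=0.25)
        assert s0 == pytest.approx(0.25, rel=0.05)

    def test_equal_variances_trigger_pooled_branch(self):
        fits = GeneFits(
            estimate=np.linspace(-1, 1, 200),
            stdev_unscaled=np.full(200, 0.3),
            s2=np.full(200, 0.4),
            df_residual=np.full(200, 10.0),
        )
        tab = ebayes_moderate(fits)
        assert np.isinf(tab["df_total"]).all()
        # all genes share one posterior variance
        assert tab["s2_post"].nunique() == 1

    def test_moderated_t_lies_between_ordinary_and_pooled(self, rng):
        fits = self.fits_from(rng)
        tab = ebayes_moderate(fits)
        t_ord = fits.estimate / (fits.stdev_unscaled * np.sqrt(fits.s2))
        s0 = tab["s0_sq"].iloc[0]
        t_pool = fits.estimate / (fits.stdev_unscaled * np.sqrt(s0))
        lo = np.minimum(np.abs(t_ord), np.abs(t_pool)) - 1e-9
        hi = np.maximum(np.abs(t_ord), np.abs(t_pool)) + 1e-9
        inside = (np.abs(tab["t"]) >= lo) & (np.abs(tab["t"]) <= hi)
        assert inside.all()

    def test_results_invariant_to_gene_order(self, rng):
        fits = self.fits_from(rng, G=500)
        tab = ebayes_moderate(fits)
        perm = rng.permutation(500)
        fits_p = GeneFits(
            estimate=fits.estimate[perm],
            stdev_unscaled=fits.stdev_unscaled[perm],
            s2=fits.s2[perm],
            df_residual=fits.df_residual[perm],
        )
        tab_p = ebayes_moderate(fits_p)
        assert np.allclose(tab["p"].to_numpy()[perm], tab_p["p"].to_numpy())

    def test_too_few_genes_rejected(self):
        fits = GeneFits(
            estimate=np.zeros(10),
            stdev_unscaled=np.ones(10),
            s2=np.ones(10),
            df_residual=np.full(10, 5.0),
        )
        with pytest.raises(ValueError, match="100"):
            ebayes_moderate(fits)


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_propagated_and_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_matches_naive_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDeContrast:
    def test_detection_rate_monotone_in_effect_size(self):
        rates = []
        for k, eff in enumerate((0.25, 0.75, 1.5)):
            cfg = CountsConfig(
                seed=100 + k,
                n_genes=1000,
                groups={"heart": (6, 6)},
                effect_size=eff,
                prop_shared=0.0,
                prop_heart_specific=0.2,
                prop_cm_specific=0.0,
            )
            fx = simulate_counts(cfg)
            X = design_matrix(fx.metadata, factors=["species"], numeric=["RIN"])
            res = de_contrast(
                fx.counts, fx.metadata, X, contrast_vector(X, {"species_human": 1.0})
            )
            truth = fx.truth["effect_heart"] != 0
            rates.append(res.loc[truth, "fdr"].lt(0.05).mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_fdr_bounds_p(self):
        cfg = CountsConfig(seed=42, n_genes=500, groups={"heart": (5, 5)})
        fx = simulate_counts(cfg)
        X = design_matrix(fx.metadata, factors=["species"], numeric=["RIN"])
        res = de_contrast(
            fx.counts, fx.metadata, X, contrast_vector(X, {"species_human": 1.0})
        )
        assert (res["fdr"] >= res["p"] - 1e-12).all()
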