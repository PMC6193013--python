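"""Normalization chain and descriptive comparisons."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from orthomex.expression import (
    correlation_clusters,
    correlation_group_test,
    cyclic_loess,
    filter_expressed,
    log2_cpm,
    log2_rpkm,
    pca_with_association,
    tmm_factors,
)
from orthomex.simulate import simulate_composition_pair


def counts_frame(arr, samples=None):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestLog2Cpm:
    def test_definition_at_prior_zero(self):
        c = counts_frame([[1000], [999000]])
        out = log2_cpm(c, prior_count=0.0)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(1000), abs=1e-9)

    def test_zero_count_with_default_prior(self):
        c = counts_frame([[0], [1000000]])
        out = log2_cpm(c, prior_count=0.25)
        expect = np.log2(0.25 / 1000000.5 * 1e6)
        assert out.values.iloc[0, 0] == pytest.approx(expect, abs=1e-9)
        assert out.values.iloc[0, 0] == pytest.approx(-2.0, abs=1e-3)

    def test_scale_invariance_at_prior_zero(self):
        rng = np.random.default_rng(0)
        c = counts_frame(rng.integers(1, 500, (100, 3)))
        a = log2_cpm(c, prior_count=0.0).values
        b = log2_cpm(2 * c, prior_count=0.0).values
        assert np.allclose(a, b)

    def test_zero_library_raises_with_sample_name(self):
        c = counts_frame([[5, 0], [5, 0]], samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            log2_cpm(c)


class TestFilterExpressed:
    def meta(self):
        return pd.DataFrame(
            {"group": ["cm", "cm", "heart", "heart"]},
            index=["s0", "s1", "s2", "s3"],
        )

    def test_one_group_above_threshold_retains(self):
        vals = counts_frame([[1.9, 1.9, 2.1, 2.1]])
        kept = filter_expressed(vals, self.meta())
        assert list(kept) == ["g0"]

    def test_exactly_two_in_all_groups_drops(self):
        vals = counts_frame([[2.0, 2.0, 2.0, 2.0]])
        assert len(filter_expressed(vals, self.meta())) == 0

    def test_all_low_drops(self):
        vals = counts_frame([[-2.0, -2.0, -2.0, -2.0]])
        assert len(filter_expressed(vals, self.meta())) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = counts_frame(rng.normal(2, 1, (200, 4)))
        meta = self.meta()
        prev = set(filter_expressed(vals, meta, threshold=0.5))
        for thr in (1.0, 2.0, 3.0):
            cur = set(filter_expressed(vals, meta, threshold=thr))
            assert cur <= prev
            prev = cur


class TestTmm:
    def test_identical_to_reference_gives_unit_factor(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 400, 300)
        c = counts_frame(np.column_stack([col, col]))
        assert np.allclose(tmm_factors(c).to_numpy(), 1.0)

    def test_scaled_copy_gives_unit_factor(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 400, 300)
        c = counts_frame(np.column_stack([col, col * 2]))
        assert np.allclose(tmm_factors(c).to_numpy(), 1.0)

    def test_library_scale_invariance(self):
        # near-invariance: M and A are proportion-scale so scaling a library
        # only perturbs the precision weights, not the trimmed log-ratios
        rng = np.random.default_rng(4)
        c = counts_frame(rng.integers(1, 300, (400, 4)))
        f1 = tmm_factors(c)
        c2 = c.copy()
        c2["s1"] = c2["s1"] * 7
        f2 = tmm_factors(c2)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=0.03)

    def test_recovers_planted_composition_shift(self):
        counts, expected = simulate_composition_pair(seed=7)
        f = tmm_factors(counts)
        assert np.all(np.abs(f.to_numpy() / expected.to_numpy() - 1) < 0.05)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Independent cross-check against edgeR::calcNormFactors."""
        rng = np.random.default_rng(12)
        G = 800
        mu = rng.gamma(2, 100, G)
        X = pd.DataFrame(
            {f"s{j}": rng.poisson(mu * rng.uniform(0.5, 2)) for j in range(6)},
            index=[f"g{i}" for i in range(G)],
        )
        X.iloc[:80, 3] = (X.iloc[:80, 3] * 6).astype(int)
        tsv = tmp_path / "counts.tsv"
        X.to_csv(tsv, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(edgeR))
                x <- as.matrix(read.delim('{tsv}', row.names=1))
                f <- calcNormFactors(x, method='TMM')
                cat(sprintf('%.10f', f), sep='\\n')
                """
            )
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(X).to_numpy()
        assert np.allclose(ours, ref, atol=1e-6)


class TestCyclicLoess:
    def base(self, rng, G=800):
        return rng.normal(6, 1.5, G)

    def test_identical_samples_are_untouched(self, rng):
        b = self.base(rng)
        x = counts_frame(np.column_stack([b, b]))
        out = cyclic_loess(x).values
        assert np.abs(out.to_numpy() - x.to_numpy()).max() < 1e-8

    def test_planted_intensity_bias_removed(self, rng):
        b = self.base(rng)
        x = pd.DataFrame(
            {
                "s1": b + rng.normal(0, 0.1, b.size),
                "s2": b + rng.normal(0, 0.1, b.size) + 0.5 * np.sin((b - 2) / 2) + 0.3,
            }
        )
        out = cyclic_loess(x).values
        before = abs((x["s2"] - x["s1"]).mean())
        after = abs((out["s2"] - out["s1"]).mean())
        assert after < 0.1 * before

    @pytest.mark.parametrize("mode", ["pairwise", "reference"])
    def test_no_bias_preserves_ranks(self, rng, mode):
        b = self.base(rng)
        x = pd.DataFrame(
            {f"s{j}": b + rng.normal(0, 0.1, b.size) for j in range(3)}
        )
        out = cyclic_loess(x, mode=mode).values
        for c in x.columns:
            assert spearmanr(x[c], out[c]).statistic > 0.99

    def test_too_few_genes_rejected(self):
        x = counts_frame(np.ones((20, 2)))
        with pytest.raises(ValueError, match="50"):
            cyclic_loess(x)


class TestLog2Rpkm:
    def test_one_kilobase_identity(self):
        c = counts_frame([[1000], [999000]])
        lengths = pd.Series({"g0": 1000, "g1": 1000})
        out = log2_rpkm(c, lengths, prior_count=0.0)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(1000), abs=1e-9)

    def test_doubling_length_subtracts_one(self):
        c = counts_frame([[1000], [999000]])
        a = log2_rpkm(c, pd.Series({"g0": 1000, "g1": 1000}), prior_count=0.0)
        b = log2_rpkm(c, pd.Series({"g0": 2000, "g1": 1000}), prior_count=0.0)
        assert (a.values.iloc[0, 0] - b.values.iloc[0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_species_specific_length_offset(self):
        c = counts_frame([[500], [999500]])
        human = log2_rpkm(c, pd.Series({"g0": 900, "g1": 1000}), prior_count=0.0)
        chimp = log2_rpkm(c, pd.Series({"g0": 1000, "g1": 1000}), prior_count=0.0)
        diff = human.values.iloc[0, 0] - chimp.values.iloc[0, 0]
        assert diff == pytest.approx(np.log2(10 / 9), abs=1e-12)

    def test_missing_gene_length_raises(self):
        c = counts_frame([[10], [20]])
        with pytest.raises(KeyError, match="g1"):
            log2_rpkm(c, pd.Series({"g0": 1000}))


class TestPcaWithAssociation:
    def test_separated_groups_drive_pc1(self, rng):
        G, n = 500, 12
        base = rng.normal(5, 1, G)
        shift = np.zeros(G)
        shift[:100] = 3.0
        cols = {}
        groups = []
        for j in range(n):
            grp = "a" if j < 6 else "b"
            groups.append(grp)
            cols[f"s{j}"] = base + (shift if grp == "b" else 0) + rng.normal(0, 0.2, G)
        vals = pd.DataFrame(cols)
        meta = pd.DataFrame({"group": groups}, index=vals.columns)
        scores, var_frac, pvals = pca_with_association(vals, meta, ["group"])
        assert pvals.loc["PC1", "group"] < 1e-6
        assert var_frac.iloc[0] > 0.5

    def test_variance_fractions_sum_to_one(self, rng):
        vals = pd.DataFrame(rng.normal(size=(300, 8)))
        meta = pd.DataFrame({"x": range(8)}, index=vals.columns)
        _, var_frac, _ = pca_with_association(vals, meta, ["x"])
        assert var_frac.sum() == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_fractions_near_uniform(self, rng):
        n = 8
        vals = pd.DataFrame(rng.normal(size=(20000, n)))
        meta = pd.DataFrame({"x": range(n)}, index=vals.columns)
        _, var_frac, _ = pca_with_association(vals, meta, ["x"])
        nontrivial = var_frac.iloc[: n - 1]
        assert nontrivial.max() / nontrivial.min() < 1.5

    def test_constant_covariate_gives_nan(self, rng):
        vals = pd.DataFrame(rng.normal(size=(100, 5)))
        meta = pd.DataFrame({"c": ["k"] * 5}, index=vals.columns)
        _, _, pvals = pca_with_association(vals, meta, ["c"])
        assert pvals["c"].isna().all()


class TestCorrelationGroupTest:
    def build(self, rng, noise_a=0.1, noise_b=0.6, n_hearts=10):
        G = 400
        base = rng.normal(6, 1.5, G)
        cols, groups = {}, []
        for j in range(n_hearts):
            cols[f"h{j}"] = base + rng.normal(0, 0.3, G)
            groups.append("heart")
        for j in range(5):
            cols[f"a{j}"] = base + rng.normal(0, noise_a, G)
            groups.append("cm27")
        for j in range(5):
            cols[f"b{j}"] = base + rng.normal(0, noise_b, G)
            groups.append("cm15")
        vals = pd.DataFrame(cols)
        meta = pd.DataFrame({"group": groups}, index=vals.columns)
        return vals, meta

    def test_lower_noise_group_correlates_more(self, rng):
        vals, meta = self.build(rng)
        res = correlation_group_test(vals, meta, "heart", ("cm27", "cm15"))
        assert res["mean_difference"] > 0
        assert res["p_value"] < 0.01

    def test_self_correlation_is_one(self, rng):
        vals, meta = self.build(rng)
        assert np.allclose(np.diag(vals.corr()), 1.0)

    def test_identical_noise_levels_are_sign_symmetric(self):
        # with equal noise in both groups the mean-correlation difference
        # has no preferred sign and averages to zero over replicate draws
        diffs = []
        for seed in range(30):
            vals, meta = self.build(np.random.default_rng(seed), noise_a=0.4, noise_b=0.4)
            res = correlation_group_test(vals, meta, "heart", ("cm27", "cm15"))
            diffs.append(res["mean_difference"])
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 0.01
        assert (diffs > 0).any() and (diffs < 0).any()

    def test_singleton_group_rejected(self, rng):
        vals, meta = self.build(rng)
        meta2 = meta.copy()
        meta2.loc["a1":"a4", "group"] = "other"
        with pytest.raises(ValueError, match="fewer than 2"):
            correlation_group_test(vals, meta2, "heart", ("cm27", "cm15"))

    def test_clustering_recovers_planted_groups(self, rng):
        from sklearn.metrics import adjusted_rand_score

        G = 400
        profiles = {g: rng.normal(6, 1.5, G) for g in ("x", "y", "z")}
        cols, labels = {}, []
        for g, prof in profiles.items():
            for j in range(5):
                cols[f"{g}{j}"] = prof + rng.normal(0, 0.2, G)
                labels.append(g)
        vals = pd.DataFrame(cols)
        clusters = correlation_clusters(vals, n_clusters=3)
        assert adjusted_rand_score(labels, clusters.to_numpy()) == 1.0
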