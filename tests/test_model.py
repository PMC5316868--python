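"""NB-GLM TE estimation: normalization, dispersion, fitting, testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_count_table, paired_design
from ribote.model import (
    DeltaTEModel,
    TranslationalEfficiencyModel,
    benjamini_hochberg,
    build_design_matrix,
    classify_delta,
    classify_te,
    estimate_dispersion,
    fit_glm,
    size_factors,
    utr_feature_comparison,
)
from ribote.model import test_vs_median as wald_vs_median
from ribote.simulate import SimDesign, simulate_counts
from ribote.transcripts import TranscriptModel

LN2 = np.log(2.0)


class TestSizeFactors:
    def test_identical_libraries(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(df).to_numpy(), [1.0, 1.0])

    def test_exact_doubling(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(df).to_numpy()
        np.testing.assert_allclose(f[1] / f[0], 2.0)
        np.testing.assert_allclose(np.exp(np.log(f).mean()), 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 500, size=(50, 4)).astype(float)
        mat[rng.integers(0, 50, 5), rng.integers(0, 4, 5)] = 0
        df = pd.DataFrame(mat, columns=list("abcd"))
        # brute-force median-of-ratios with explicit loops
        keep = [g for g in range(50) if all(mat[g] > 0)]
        raw = []
        for j in range(4):
            ratios = []
            for g in keep:
                geo = np.exp(np.mean([np.log(mat[g, k]) for k in range(4)]))
                ratios.append(mat[g, j] / geo)
            raw.append(np.median(ratios))
        raw = np.array(raw)
        expect = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(size_factors(df).to_numpy(), expect)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(1, 300, size=(40, 3)).astype(float)
        df = pd.DataFrame(mat, columns=list("abc"))
        scaled = df.copy()
        scaled["b"] = scaled["b"] * 5
        f0 = size_factors(df)
        f1 = size_factors(scaled)
        np.testing.assert_allclose((f1 / f0)["b"] / (f1 / f0)["a"], 5.0)

    def test_all_zero_reference_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="fallback"):
            size_factors(df)
        f = size_factors(df, fallback_positive=True)
        assert np.all(f > 0)


class TestDispersion:
    def bare_design(self, n_lib):
        X = pd.DataFrame(
            {"Intercept": 1.0, "ribo": [0.0, 1.0] * (n_lib // 2)},
            index=[f"l{i}" for i in range(n_lib)],
        )
        return X

    def test_poisson_limit(self):
        # alpha=0 data with many replicates: per-gene estimates collapse
        rng = np.random.default_rng(0)
        y = rng.poisson(200.0, size=(200, 100)).astype(float)
        df = pd.DataFrame(y, columns=[f"l{i}" for i in range(100)])
        disp = estimate_dispersion(
            df, self.bare_design(100), np.ones(100), mode="per-gene"
        )
        assert np.median(disp) <= 0.01

    def test_alpha_point_one_recovery(self):
        rng = np.random.default_rng(1)
        mu, alpha, n_lib = 300.0, 0.1, 40  # 20 replicates x 2 library types
        lam = rng.gamma(1 / alpha, alpha * mu, size=(500, n_lib))
        y = rng.poisson(lam).astype(float)
        df = pd.DataFrame(y, columns=[f"l{i}" for i in range(n_lib)])
        disp = estimate_dispersion(
            df, self.bare_design(n_lib), np.ones(n_lib), mode="per-gene"
        )
        assert 0.05 <= np.median(disp) <= 0.2

    def test_constant_counts_hit_floor(self):
        # zero sample variance: plain profile ML drives alpha to the floor
        df = pd.DataFrame(np.full((3, 6), 50.0), columns=[f"l{i}" for i in range(6)])
        disp = estimate_dispersion(
            df, self.bare_design(6), np.ones(6), mode="per-gene", cox_reid=False
        )
        np.testing.assert_allclose(disp.to_numpy(), 1e-8)

    def test_trend_recovers_shared_alpha(self):
        d = SimDesign(
            n_genes=400,
            mean_expression=np.full(400, 200.0),
            log2_te=np.zeros(400),
            dispersion=np.full(400, 0.05),
            seed=6,
        )
        ct = simulate_counts(d)
        disp = estimate_dispersion(ct, mode="trend")
        assert 0.03 <= np.median(disp) <= 0.08

    def test_unreplicated_design_rejected(self):
        df = pd.DataFrame([[5.0, 8.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="replic|degrees"):
            estimate_dispersion(df, self.bare_design(2), np.ones(2))


class TestFitGlm:
    def design_matrix(self, n_reps=3):
        ct = make_count_table(
            np.ones((1, 2 * n_reps)), paired_design(n_reps)
        )
        return build_design_matrix(ct.design)

    def test_exact_doubling_gives_log2te_one(self):
        X = self.design_matrix()
        # RNA, Ribo alternating per replicate
        y = np.array([100.0, 200.0, 100.0, 200.0, 100.0, 200.0])
        beta, cov, conv = fit_glm(y, X, np.ones(6), alpha=0.0)
        assert conv
        assert beta[list(X.columns).index("ribo")] / LN2 == pytest.approx(1.0, abs=1e-6)

    def test_all_equal_gives_zero(self):
        X = self.design_matrix()
        beta, _, conv = fit_glm(np.full(6, 50.0), X, np.ones(6), alpha=0.05)
        assert conv
        assert beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels(self):
        """Independent cross-check: statsmodels NB GLM on the same gene."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = self.design_matrix()
        y = rng.poisson([120, 260, 110, 240, 130, 250]).astype(float)
        sf = np.array([1.0, 1.1, 0.9, 1.0, 1.2, 0.8])
        alpha = 0.05
        beta, cov, conv = fit_glm(y, X, sf, alpha)
        ref = sm.GLM(
            y,
            X.to_numpy(),
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(sf),
        ).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov)), ref.bse, rtol=1e-3
        )

    def test_closed_form_balanced_saturated(self):
        # 2x2 balanced design: ribo coefficient equals the log-ratio of
        # normalized means
        X = self.design_matrix(n_reps=2)
        y = np.array([80.0, 320.0, 120.0, 480.0])
        beta, _, conv = fit_glm(y, X, np.ones(4), alpha=0.0)
        ribo_mean = np.sqrt(320.0 * 480.0)
        rna_mean = np.sqrt(80.0 * 120.0)
        assert beta[1] == pytest.approx(np.log(ribo_mean / rna_mean), abs=1e-6)

    def test_swapping_library_labels_negates_te(self):
        rows = paired_design(3)
        swapped = [
            {**r, "library_type": "RNA" if r["library_type"] == "Ribo" else "Ribo"}
            for r in rows
        ]
        rng = np.random.default_rng(8)
        counts = rng.poisson(200.0, size=(20, 6)).astype(float)
        ct1 = make_count_table(counts, rows)
        ct2 = make_count_table(counts, swapped)
        r1 = TranslationalEfficiencyModel(ct1, dispersion=0.05).fit()
        r2 = TranslationalEfficiencyModel(ct2, dispersion=0.05).fit()
        np.testing.assert_allclose(
            r1.table["log2_te"], -r2.table["log2_te"], atol=1e-6
        )


class TestTesting:
    def test_gene_at_median_has_p_one(self):
        log2te = np.array([0.0, 1.0, 2.0])
        se = np.array([0.1, 0.1, 0.1])
        p, fdr, med = wald_vs_median(log2te, se)
        assert med == 1.0
        assert p[1] == pytest.approx(1.0)

    def test_identical_tes_all_p_one(self):
        p, fdr, _ = wald_vs_median(np.full(10, 1.5), np.full(10, 0.2))
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(fdr, 1.0)

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.random(20)
        # independent step-up implementation
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(benjamini_hochberg(p), adj)

    def test_bh_propagates_nan(self):
        p = np.array([0.01, np.nan, 0.5])
        adj = benjamini_hochberg(p)
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


class TestClassification:
    def test_te_class_examples(self):
        med = 0.0
        log2te = np.array([-2.0, -1.0, -3.0])
        fdr = np.array([0.01, 0.01, 0.2])
        cls = classify_te(log2te, fdr, med)
        assert list(cls) == ["TE-low", "none", "none"]

    def test_te_high_symmetric(self):
        cls = classify_te(np.array([2.0]), np.array([0.01]), 0.0)
        assert cls[0] == "TE-high"

    def test_monotone_in_log2te(self):
        med = 0.0
        fdr = np.full(50, 0.01)
        tes = np.linspace(-5, 0, 50)
        cls = classify_te(tes, fdr, med)
        low = [c == "TE-low" for c in cls]
        # once a gene stops being TE-low, no lower-TE gene may be 'none'
        assert low == sorted(low, reverse=True)

    def test_delta_class_examples(self):
        tissues = ("NT", "FL")
        cls = classify_delta(
            np.array([-1.5, -0.9, -3.0, 1.2]),
            np.array([0.1, 0.01, 0.5, 0.19]),
            tissues,
        )
        assert list(cls) == ["NT-higher", "none", "none", "FL-higher"]


class TestDeltaTE:
    def two_tissue_table(self, counts_a, counts_b=None):
        counts_b = counts_a if counts_b is None else counts_b
        rows = paired_design(3, tissues=("NT", "FL"))
        counts = np.concatenate([counts_a, counts_b], axis=1)
        return make_count_table(counts, rows)

    def test_identical_tissues_give_zero_delta(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(300.0, size=(15, 6)).astype(float)
        ct = self.two_tissue_table(counts)
        res = DeltaTEModel(ct, dispersion=0.05).fit()
        np.testing.assert_allclose(res.table["delta_log2_te"], 0.0, atol=1e-6)
        assert (res.table["delta_class"] == "none").all()

    def test_swapping_tissue_labels_negates_delta(self):
        rng = np.random.default_rng(11)
        a = rng.poisson(300.0, size=(15, 6)).astype(float)
        b = rng.poisson(250.0, size=(15, 6)).astype(float)
        rows_ab = paired_design(3, tissues=("NT", "FL"))
        rows_ba = paired_design(3, tissues=("FL", "NT"))
        ct_ab = make_count_table(np.concatenate([a, b], axis=1), rows_ab)
        ct_ba = make_count_table(np.concatenate([b, a], axis=1), rows_ba)
        r_ab = DeltaTEModel(ct_ab, dispersion=0.05).fit()
        r_ba = DeltaTEModel(ct_ba, dispersion=0.05).fit()
        np.testing.assert_allclose(
            r_ab.table["delta_log2_te"], -r_ba.table["delta_log2_te"], atol=1e-6
        )

    def test_single_tissue_rejected(self):
        ct = make_count_table(np.ones((3, 6)), paired_design(3))
        with pytest.raises(ValueError, match="two tissues"):
            DeltaTEModel(ct)


class TestUtrFeatureComparison:
    def transcripts(self, n, extra_for=set()):
        out = {}
        rng = np.random.default_rng(12)
        for i in range(n):
            g = f"g{i}"
            u5 = 150 + (200 if g in extra_for else 0)
            seq = "".join(rng.choice(list("ACGT"), u5)) + "ATG" + "GGC" * 30 + "TAA"
            out[g] = TranscriptModel(g, seq, u5, 96, 0)
        return out

    def test_planted_utr_length_effect(self):
        te_class = pd.Series(
            ["TE-low"] * 10 + ["none"] * 30, index=[f"g{i}" for i in range(40)]
        )
        low = {f"g{i}" for i in range(10)}
        txs = self.transcripts(40, extra_for=low)
        summary, pvals = utr_feature_comparison(te_class, txs)
        assert summary.loc["TE-low", "utr5_len"] - summary.loc["none", "utr5_len"] == 200
        assert pvals["utr5_len"] < 0.01

    def test_null_background(self):
        te_class = pd.Series(
            ["TE-low"] * 20 + ["none"] * 20, index=[f"g{i}" for i in range(40)]
        )
        txs = self.transcripts(40)
        summary, pvals = utr_feature_comparison(te_class, txs)
        assert summary.loc["TE-low", "utr5_len"] == summary.loc["none", "utr5_len"]
        assert pvals["utr5_len"] > 0.9

    def test_mann_whitney_matches_exhaustive_enumeration(self):
        """Exact MW p on a 6-element toy equals enumeration over all
        3-of-6 rank labelings."""
        from itertools import combinations

        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 7.0]
        pooled = a + b

        def u_stat(group_a, group_b):
            return sum(
                1.0 if x > y else 0.5 if x == y else 0.0
                for x in group_a
                for y in group_b
            )

        u_obs = u_stat(a, b)
        mean_u = len(a) * len(b) / 2
        us = []
        for idx in combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            us.append(u_stat(ga, gb))
        p_exact = sum(
            1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u)
        ) / len(us)
        p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p_scipy == pytest.approx(p_exact)


class TestEndToEnd:
    def test_recovery_small_scale(self):
        rng = np.random.default_rng(13)
        n = 300
        log2te = np.zeros(n)
        log2te[:30] = -2.0
        log2te[30:60] = 2.0
        d = SimDesign(
            n_genes=n,
            mean_expression=np.full(n, 200.0),
            log2_te=log2te,
            dispersion=np.full(n, 0.05),
            seed=14,
        )
        res = TranslationalEfficiencyModel(simulate_counts(d)).fit()
        est = res.table["log2_te"].to_numpy()
        assert abs(np.nanmean(est[:30]) + 2.0) < 0.15
        assert abs(np.nanmean(est[60:])) < 0.15
        assert "TE-low" in res.summary()

    def test_all_zero_gene_excluded(self):
        counts = np.full((3, 6), 100.0)
        counts[1, 1::2] = 0.0  # no Ribo counts for gene 1
        ct = make_count_table(counts, paired_design(3))
        res = TranslationalEfficiencyModel(ct, dispersion=0.05).fit()
        assert np.isnan(res.table.loc["g1", "log2_te"])
        assert res.table.loc["g1", "te_class"] == "none"
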