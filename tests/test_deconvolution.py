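import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from oncodecon.cohort import CohortBundle, LesionMatrix
from oncodecon.deconvolution import (
    DesignMatrix,
    GeneLesionDeconvolution,
    adjust_fdr,
    build_design_matrix,
    estimate_prior,
    fit_gene_models,
    moderate_statistics,
    per_gene_variance_explained,
    permutation_null_check,
    run_pca,
)


def make_design(df: pd.DataFrame, lesion_cols: list[str]) -> DesignMatrix:
    groups = {c: ("genetic" if c in lesion_cols else
                  "intercept" if c == "intercept" else "demographic")
              for c in df.columns}
    return DesignMatrix(df, groups)


# ---------------------------------------------------------------------------
# PCA


class TestRunPca:
    def test_rank_one_matrix(self):
        g = np.outer(np.arange(1.0, 5.0), np.array([1.0, 2.0, 3.0]))
        values = pd.DataFrame(g, index=list("abcd"), columns=list("xyz"))
        res = run_pca(values, k=1)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(20, 8)))
        res = run_pca(values, k=3)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("shape", [(4, 3), (10, 7), (50, 30)])
    def test_matches_dense_eigendecomposition(self, shape):
        rng = np.random.default_rng(shape[0])
        values = pd.DataFrame(rng.normal(size=shape))
        k = min(shape) - 1
        res = run_pca(values, k=k)
        # oracle: eigendecomposition of the sample covariance of samples
        data = values.to_numpy().T - values.to_numpy().T.mean(axis=0)
        w, v = np.linalg.eigh(data @ data.T)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = v[:, :k] * np.sqrt(w[:k])
        for j in range(k):  # align oracle to the package's sign convention
            load = data.T @ v[:, j]
            if load[np.argmax(np.abs(load))] < 0:
                scores[:, j] *= -1
        np.testing.assert_allclose(res.scores.to_numpy(), scores, atol=1e-8)

    def test_k_out_of_range(self):
        values = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="out of range"):
            run_pca(values, k=10)


# ---------------------------------------------------------------------------
# design matrix


class TestBuildDesign:
    def test_recurrence_threshold(self, small_bundle):
        design = build_design_matrix(small_bundle, min_recurrence=5)
        counts = small_bundle.lesions.values.sum()
        qualifying = set(counts[counts >= 5].index)
        lesion_cols = set(design.columns) - {"intercept", "disease", "sex", "age"}
        assert lesion_cols == qualifying
        # p = disease + lesions + sex + age non-intercept columns
        assert len(design.columns) == len(qualifying) + 4

    def test_rare_lesion_excluded(self, small_bundle):
        counts = small_bundle.lesions.values.sum()
        rare = counts[counts < 5].index
        design = build_design_matrix(small_bundle, min_recurrence=5)
        assert not set(rare) & set(design.columns)

    def test_no_normals_drops_disease(self, small_bundle):
        patients = [s for s in small_bundle.samples
                    if small_bundle.normal_flag.loc[s] != 1]
        from oncodecon.cohort import subset_bundle
        sub = subset_bundle(small_bundle, patients)
        with pytest.warns(UserWarning, match="disease"):
            design = build_design_matrix(sub)
        assert "disease" not in design.columns

    def test_collinear_columns_reported(self, small_bundle):
        dup = small_bundle.lesions.values.copy()
        dup["copy_of_first"] = dup.iloc[:, 0]
        classes = dict(small_bundle.lesions.classes, copy_of_first="genetic")
        broken = CohortBundle(
            expression=small_bundle.expression,
            lesions=LesionMatrix(dup, classes),
            clinical=small_bundle.clinical,
            demographics=small_bundle.demographics,
            survival=small_bundle.survival,
            normal_flag=small_bundle.normal_flag,
        )
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(broken, min_recurrence=1)


# ---------------------------------------------------------------------------
# per-gene fits


class TestGeneFits:
    def setup_method(self):
        rng = np.random.default_rng(5)
        n = 150
        self.x = (rng.random(n) < 0.3).astype(float)
        df = pd.DataFrame({"intercept": 1.0, "mut": self.x},
                          index=[f"s{i}" for i in range(n)])
        self.design = make_design(df, ["mut"])
        self.rng = rng

    def test_gene_equal_to_design_column(self):
        expr = pd.DataFrame([self.x], index=["g"], columns=self.design.samples)
        fits = fit_gene_models(expr, self.design)
        assert fits.coef.loc["g", "mut"] == pytest.approx(1.0)
        assert fits.sigma_sq["g"] == pytest.approx(0.0, abs=1e-20)

    def test_known_effect_within_3se(self):
        beta = 0.8
        y = 2.0 + beta * self.x + self.rng.normal(0, 0.1, self.x.size)
        expr = pd.DataFrame([y], index=["g"], columns=self.design.samples)
        fits = fit_gene_models(expr, self.design)
        se = np.sqrt(fits.sigma_sq["g"]) * fits.stdev_unscaled.loc["g", "mut"]
        assert abs(fits.coef.loc["g", "mut"] - beta) < 3 * se

    def test_sample_permutation_invariance(self):
        y = self.rng.normal(size=self.x.size)
        expr = pd.DataFrame([y], index=["g"], columns=self.design.samples)
        fits = fit_gene_models(expr, self.design)
        perm = self.rng.permutation(len(self.design.samples))
        ids = [self.design.samples[i] for i in perm]
        design_p = DesignMatrix(self.design.values.loc[ids], self.design.column_groups)
        fits_p = fit_gene_models(expr[ids], design_p)
        np.testing.assert_allclose(fits.coef.to_numpy(), fits_p.coef.to_numpy(),
                                   atol=1e-10)

    def test_additivity_of_predictions(self):
        """Predicted double-mutant expression = baseline + the two single effects."""
        rng = np.random.default_rng(11)
        n = 100
        a = (rng.random(n) < 0.3).astype(float)
        b = (rng.random(n) < 0.3).astype(float)
        df = pd.DataFrame({"intercept": 1.0, "A": a, "B": b},
                          index=[f"s{i}" for i in range(n)])
        design = make_design(df, ["A", "B"])
        y = 1.0 + 0.5 * a - 0.7 * b + rng.normal(0, 0.2, n)
        expr = pd.DataFrame([y], index=["g"], columns=design.samples)
        model = GeneLesionDeconvolution(d0=0.0, s0_sq=1.0).fit(design, expr)
        probe = pd.DataFrame(
            {"intercept": 1.0, "A": [0, 1, 0, 1], "B": [0, 0, 1, 1]},
            index=["wt", "onlyA", "onlyB", "both"])
        pred = model.predict(probe).loc["g"]
        assert pred["both"] - pred["wt"] == pytest.approx(
            (pred["onlyA"] - pred["wt"]) + (pred["onlyB"] - pred["wt"]), abs=1e-10)


# ---------------------------------------------------------------------------
# moderation


class TestModeration:
    def make_fits(self, seed=0, n=40, genes=300, d0=4.0, s0=0.25):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < 0.4).astype(float)
        df = pd.DataFrame({"intercept": 1.0, "mut": x},
                          index=[f"s{i}" for i in range(n)])
        design = make_design(df, ["mut"])
        noise_var = d0 * s0 / rng.chisquare(d0, genes)
        Y = rng.normal(size=(genes, n)) * np.sqrt(noise_var)[:, None]
        expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(genes)],
                            columns=design.samples)
        return fit_gene_models(expr, design)

    def test_d0_zero_recovers_ordinary_t(self):
        fits = self.make_fits()
        mod = moderate_statistics(fits, d0=0.0, s0_sq=1.0)
        ordinary = fits.coef.to_numpy() / (
            fits.stdev_unscaled.to_numpy() * np.sqrt(fits.sigma_sq.to_numpy())[:, None])
        np.testing.assert_allclose(mod["t"].to_numpy(), ordinary, atol=1e-8)

    def test_d0_infinite_gives_prior_variance(self):
        fits = self.make_fits()
        mod = moderate_statistics(fits, d0=np.inf, s0_sq=0.3)
        np.testing.assert_allclose(mod["prior"].s_tilde_sq.to_numpy(), 0.3)

    def test_posterior_between_sample_and_prior(self):
        fits = self.make_fits()
        mod = moderate_statistics(fits)
        prior = mod["prior"]
        lo = np.minimum(fits.sigma_sq.to_numpy(), prior.s0_sq)
        hi = np.maximum(fits.sigma_sq.to_numpy(), prior.s0_sq)
        post = prior.s_tilde_sq.to_numpy()
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_prior_recovery_within_20pct(self):
        fits = self.make_fits(seed=3, n=60, genes=2000, d0=4.0, s0=0.25)
        d0, s0_sq = estimate_prior(fits.sigma_sq.to_numpy(), fits.df_residual)
        assert abs(d0 - 4.0) / 4.0 < 0.2
        assert abs(s0_sq - 0.25) / 0.25 < 0.2

    def test_matches_limma_oracle(self, tmp_path):
        """Bioconductor limma's eBayes is the independent reference for the
        moderated t machinery on a small matrix."""
        fits = self.make_fits(seed=8, n=30, genes=120)
        mod = moderate_statistics(fits)
        ydir = tmp_path / "y.tsv"
        xdir = tmp_path / "x.tsv"
        odir = tmp_path / "out.tsv"
        rng = np.random.default_rng(8)
        x = (rng.random(30) < 0.4).astype(float)
        df = pd.DataFrame({"intercept": 1.0, "mut": x},
                          index=[f"s{i}" for i in range(30)])
        design = make_design(df, ["mut"])
        noise_var = 4.0 * 0.25 / rng.chisquare(4.0, 120)
        Y = rng.normal(size=(120, 30)) * np.sqrt(noise_var)[:, None]
        expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(120)],
                            columns=design.samples)
        fits = fit_gene_models(expr, design)
        mod = moderate_statistics(fits)
        expr.to_csv(ydir, sep="\t")
        design.values.to_csv(xdir, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{ydir}", row.names=1))
            x <- as.matrix(read.delim("{xdir}", row.names=1))
            fit <- eBayes(lmFit(y, x))
            out <- data.frame(t=fit$t[, "mut"], d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{odir}", sep="\t", quote=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(odir, sep="\t")
        np.testing.assert_allclose(mod["t"]["mut"].to_numpy(), ref["t"].to_numpy(),
                                   rtol=1e-6)
        assert mod["prior"].d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert mod["prior"].s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)


# ---------------------------------------------------------------------------
# FDR


class TestAdjustFdr:
    def test_examples(self):
        np.testing.assert_allclose(adjust_fdr(np.ones(5)), np.ones(5))
        np.testing.assert_allclose(adjust_fdr(np.array([0.03])), [0.03])
        np.testing.assert_allclose(
            adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_direct_step_up_and_monotone(self, pvals):
        p = np.asarray(pvals)
        q = adjust_fdr(p)
        m = p.size
        # direct step-up oracle: q_(i) = min_{j >= i} min(1, m p_(j) / j)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        best = 1.0
        for rank in range(m, 0, -1):
            best = min(best, m * p[order[rank - 1]] / rank)
            expected[order[rank - 1]] = best
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        # monotone in p-value order
        qs = q[order]
        assert (np.diff(qs) >= -1e-12).all()


# ---------------------------------------------------------------------------
# explained variance & target sets


class TestVarianceExplained:
    def test_gene_equal_to_lesion_column(self):
        rng = np.random.default_rng(2)
        x = (rng.random(30) < 0.5).astype(float)
        df = pd.DataFrame({"intercept": 1.0, "mut": x},
                          index=[f"s{i}" for i in range(30)])
        design = make_design(df, ["mut"])
        expr = pd.DataFrame([x], index=["g"], columns=design.samples)
        fits = fit_gene_models(expr, design)
        r2 = per_gene_variance_explained(fits)
        assert r2.loc["g", "r2_genomic"] == pytest.approx(1.0)

    def test_hand_computed_six_samples(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        df = pd.DataFrame({"intercept": 1.0, "mut": x},
                          index=[f"s{i}" for i in range(6)])
        design = make_design(df, ["mut"])
        expr = pd.DataFrame([y], index=["g"], columns=design.samples)
        fits = fit_gene_models(expr, design)
        # explicit arithmetic: RSS_full from group means, RSS_reduced = TSS
        rss_full = float(((y[:3] - y[:3].mean()) ** 2).sum()
                         + ((y[3:] - y[3:].mean()) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        expected = (tss - rss_full) / tss
        assert fits.rss["g"] == pytest.approx(rss_full)
        r2 = per_gene_variance_explained(fits)
        assert r2.loc["g", "r2_genomic"] == pytest.approx(expected)

    def test_constant_gene_warns_zero(self):
        x = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        df = pd.DataFrame({"intercept": 1.0, "mut": x},
                          index=[f"s{i}" for i in range(6)])
        design = make_design(df, ["mut"])
        expr = pd.DataFrame([np.full(6, 3.0)], index=["g"], columns=design.samples)
        fits = fit_gene_models(expr, design)
        with pytest.warns(UserWarning, match="constant"):
            r2 = per_gene_variance_explained(fits)
        assert r2.loc["g", "r2_genomic"] == 0.0


class TestTargetSets:
    def test_fdr_zero_empty(self, small_bundle):
        design = build_design_matrix(small_bundle)
        model = GeneLesionDeconvolution().fit(design, small_bundle.expression.values)
        sets = model.target_sets(fdr=0.0)
        assert all(len(t) == 0 for t in sets.values())

    def test_strong_effects_recovered(self, small_cohort):
        bundle, truth = small_cohort
        design = build_design_matrix(bundle, min_recurrence=5)
        model = GeneLesionDeconvolution().fit(design, bundle.expression.values)
        sets = model.target_sets(fdr=0.05)
        # large true effects (|beta| > 1) of well-represented lesions are found
        found_any = 0
        for lesion in design.genomic_columns:
            strong = truth.effect_matrix.loc[lesion]
            strong = set(strong[strong.abs() > 1.0].index)
            if strong:
                found_any += len(strong & set(sets[lesion].index))
        assert found_any > 0


# ---------------------------------------------------------------------------
# permutation calibration


class TestPermutationNull:
    def test_same_seed_same_stream(self, small_bundle):
        design = build_design_matrix(small_bundle)
        expr = small_bundle.expression.values
        a = permutation_null_check(expr, design, n_perm=2, seed=4)
        b = permutation_null_check(expr, design, n_perm=2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_identity_reproduces_observed(self, small_bundle):
        design = build_design_matrix(small_bundle)
        expr = small_bundle.expression.values
        res = permutation_null_check(expr, design, n_perm=1, seed=0,
                                     include_identity=True)
        model = GeneLesionDeconvolution().fit(design, expr)
        assert res["n_discoveries_F"].iloc[0] == int((model.q_f_ < 0.05).sum())

    def test_rejects_bad_nperm(self, small_bundle):
        design = build_design_matrix(small_bundle)
        with pytest.raises(ValueError):
            permutation_null_check(small_bundle.expression.values, design,
                                   n_perm=0, seed=0)
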