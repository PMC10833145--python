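"""Shape PCA, Procrustes ANOVA/RRPP, dispersion, PLS, and Tukey HSD."""

import numpy as np
import pytest
import scipy.stats as sps

import morphosample as ms


class TestShapePca:
    def test_rank_one_data_loads_on_single_axis(self, rng):
        base = ms.to_preshape(rng.standard_normal((8, 2)))
        direction = rng.standard_normal(16)
        shapes = base.ravel() + np.outer(rng.standard_normal(20), direction)
        pca = ms.pca_shape(shapes.reshape(20, 8, 2))
        assert pca.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_svd_oracle_and_orthonormality(self, rng):
        x = rng.standard_normal((15, 12))
        pca = ms.pca_shape(x)
        s = np.linalg.svd(x - x.mean(0), compute_uv=False)
        assert np.allclose(pca.explained_fraction, s**2 / (s**2).sum(), atol=1e-10)
        gram = pca.components @ pca.components.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-9
        assert np.abs(pca.scores.mean(axis=0)).max() < 1e-9
        assert np.all(np.diff(pca.explained_fraction) <= 1e-15)

    def test_mean_projects_to_origin_and_reconstruction_is_exact(self, rng):
        x = rng.standard_normal((10, 6, 2))
        pca = ms.pca_shape(x)
        assert np.abs(pca.transform(x.mean(axis=0).reshape(6, 2))).max() < 1e-9
        recon = pca.center + pca.transform(x) @ pca.components
        assert np.abs(recon - x.reshape(10, -1)).max() < 1e-9

    def test_needs_three_specimens(self, rng):
        with pytest.raises(ValueError):
            ms.pca_shape(rng.standard_normal((2, 6, 2)))


class TestProcAnovaRrpp:
    def test_pure_group_offset_saturates(self, rng):
        base = rng.standard_normal((5, 2))
        g = np.repeat(["a", "b"], 8)
        shapes = np.stack([base + (0.5 if x == "b" else 0.0) * np.eye(5, 2) for x in g])
        res = ms.proc_anova_rrpp(shapes, [("grp", g)], n_perm=100, seed=0)
        assert res.p("grp") == pytest.approx(1 / 100)
        assert res.r_squared("grp") > 0.999

    def test_ss_decomposition_matches_lstsq_oracle(self, rng):
        # independent route: sequential residual sums of squares via lstsq fits
        n = 10
        y = rng.standard_normal((n, 8))
        size = rng.standard_normal(n)
        grp = rng.choice(["a", "b"], n)
        res = ms.proc_anova_rrpp(y, [("size", size), ("grp", grp)], n_perm=50, seed=1)

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return ((y - x @ beta) ** 2).sum()

        one = np.ones((n, 1))
        x1 = np.column_stack([one, size])
        x2 = np.column_stack([x1, (grp == "b").astype(float)])
        t = res.table.set_index("term")
        assert t.loc["size", "SS"] == pytest.approx(rss(one) - rss(x1), abs=1e-8)
        assert t.loc["grp", "SS"] == pytest.approx(rss(x1) - rss(x2), abs=1e-8)
        assert t.loc["Residuals", "SS"] == pytest.approx(rss(x2), abs=1e-8)
        terms = t.drop("Total")
        assert terms.SS.sum() == pytest.approx(t.loc["Total", "SS"], abs=1e-8)
        assert t.loc["size", "R2"] == pytest.approx((rss(one) - rss(x1)) / t.loc["Total", "SS"], abs=1e-10)

    def test_scalar_one_factor_reduces_to_classical_f(self, rng):
        y = rng.standard_normal((30, 1))
        g = np.repeat(["a", "b", "c"], 10)
        res = ms.proc_anova_rrpp(y, [("g", g)], n_perm=100, seed=0)
        f_classic = sps.f_oneway(*[y[g == lev, 0] for lev in "abc"]).statistic
        assert res.table.F[0] == pytest.approx(f_classic, abs=1e-10)

    def test_reproducible_and_seed_sensitive(self, rng):
        y = rng.standard_normal((20, 6))
        g = np.repeat(["a", "b"], 10)
        p1 = ms.proc_anova_rrpp(y, [("g", g)], n_perm=200, seed=7).p("g")
        p2 = ms.proc_anova_rrpp(y, [("g", g)], n_perm=200, seed=7).p("g")
        assert p1 == p2

    def test_collinear_and_constant_inputs_raise(self, rng):
        y = rng.standard_normal((12, 4))
        x = rng.standard_normal(12)
        with pytest.raises(ValueError, match="collinear"):
            ms.proc_anova_rrpp(y, [("a", x), ("b", 2 * x)], n_perm=50)
        with pytest.raises(ValueError, match="constant"):
            ms.proc_anova_rrpp(np.ones((12, 4)), [("a", x)], n_perm=50)


class TestDispersion:
    def test_null_single_run_not_significant(self, rng):
        x = rng.standard_normal((60, 10))
        g = np.repeat(["a", "b"], 30)
        table, _ = ms.dispersion_test(x, g, n_perm=500, seed=3)
        assert table.p[0] > 0.05

    def test_detects_threefold_spread(self, rng):
        a = rng.standard_normal((50, 8))
        b = rng.standard_normal((50, 8)) * 3
        table, _ = ms.dispersion_test(np.vstack([a, b]), np.repeat(["a", "b"], 50), n_perm=500, seed=0)
        assert table.p[0] <= 0.01

    def test_duplicated_group_has_zero_difference(self, rng):
        x = rng.standard_normal((20, 6))
        table, _ = ms.dispersion_test(np.vstack([x, x]), np.repeat(["a", "b"], 20), n_perm=50, seed=0)
        assert table.abs_diff[0] == 0.0

    def test_singleton_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            ms.dispersion_test(rng.standard_normal((5, 4)), np.array(["a"] * 4 + ["b"]), n_perm=50)


class TestTwoBlockPls:
    def test_self_association_is_one(self, rng):
        x = rng.standard_normal((20, 6))
        res = ms.two_block_pls(x, x, n_perm=50, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-12)

    def test_null_single_run_not_significant(self, rng):
        res = ms.two_block_pls(
            rng.standard_normal((100, 8)), rng.standard_normal((100, 5)), n_perm=500, seed=1
        )
        assert res.test.p_value > 0.05

    def test_matches_direct_cross_covariance_oracle(self, rng):
        b1 = rng.standard_normal((10, 4))
        b2 = rng.standard_normal((10, 6))
        res = ms.two_block_pls(b1, b2, n_perm=50, seed=0)
        c1, c2 = b1 - b1.mean(0), b2 - b2.mean(0)
        u, s, vt = np.linalg.svd(c1.T @ c2)
        r = abs(np.corrcoef(c1 @ u[:, 0], c2 @ vt[0])[0, 1])
        assert res.r_pls == pytest.approx(r, abs=1e-10)

    def test_bounds_and_rotation_invariance(self, rng):
        b1 = rng.standard_normal((25, 6))
        b2 = b1 @ rng.standard_normal((6, 4)) + rng.standard_normal((25, 4))
        r0 = ms.two_block_pls(b1, b2, n_perm=50, seed=0).r_pls
        assert 0 <= r0 <= 1
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        r1 = ms.two_block_pls(b1, b2 @ q, n_perm=50, seed=0).r_pls
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ms.two_block_pls(rng.standard_normal((8, 3)), rng.standard_normal((9, 3)))
        with pytest.raises(ValueError, match="zero-variance"):
            ms.two_block_pls(np.ones((8, 3)), rng.standard_normal((8, 3)))


class TestAnovaTukey:
    def test_textbook_fixture_matches_hand_computation(self):
        # 3 balanced groups; F and Tukey p from explicit formulas
        vals = np.array([6.0, 8, 4, 5, 3, 4, 8, 12, 9, 11, 8, 7, 13, 9, 11, 8, 12, 13])
        grp = np.repeat(["a", "b", "c"], 6)
        table, pairs = ms.anova_tukey(vals, grp)
        means = [vals[grp == g].mean() for g in "abc"]
        grand = vals.mean()
        ssb = 6 * sum((m - grand) ** 2 for m in means)
        ssw = sum(((vals[grp == g] - vals[grp == g].mean()) ** 2).sum() for g in "abc")
        f_hand = (ssb / 2) / (ssw / 15)
        assert table.F[0] == pytest.approx(f_hand, abs=1e-6)
        mse = ssw / 15
        q_ab = abs(means[1] - means[0]) / np.sqrt(mse / 6)
        p_ab = sps.studentized_range.sf(q_ab, 3, 15)
        got = pairs[(pairs.group_i == "a") & (pairs.group_j == "b")].p_adj.iloc[0]
        assert got == pytest.approx(p_ab, abs=1e-6)

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 7), rng.normal(0.3, 1, 9)])
        grp = np.array(["a"] * 12 + ["b"] * 7 + ["c"] * 9)
        _, pairs = ms.anova_tukey(vals, grp)
        sm = pairwise_tukeyhsd(vals, grp)
        assert np.allclose(sorted(pairs.p_adj), sorted(sm.pvalues), atol=1e-6)

    def test_two_groups_equals_unadjusted_t_test(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0.5, 1, 14)])
        grp = np.array(["a"] * 10 + ["b"] * 14)
        _, pairs = ms.anova_tukey(vals, grp)
        t = sps.ttest_ind(vals[grp == "a"], vals[grp == "b"])
        assert pairs.p_adj[0] == pytest.approx(t.pvalue, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.warns(UserWarning, match="p = 1"):
            table, _ = ms.anova_tukey(np.ones(9), np.repeat(["a", "b", "c"], 3))
        assert table.p[0] == 1.0
        with pytest.warns(UserWarning, match="p = 0"):
            table, _ = ms.anova_tukey(np.repeat([1.0, 2.0, 3.0], 3), np.repeat(["a", "b", "c"], 3))
        assert table.p[0] == 0.0


class TestDimorphismSuite:
    def test_size_offset_only_gives_ssd_not_sshd(self):
        spec = ms.GeneratorSpec(
            groups=[
                ms.GroupSpec("s", "F", 40, cs_log10_mean=1.54),
                ms.GroupSpec("s", "M", 40, cs_log10_mean=1.46),
            ],
            template=ms.polygon_template(10),
            seed=8,
        )
        ds, _ = ms.generate_dataset(spec)
        res = ms.gpa(ds)
        suite = ms.sexual_dimorphism_suite(
            res.aligned, res.centroid_sizes, ds.classifier_column("sex"), n_perm=200, seed=0
        )
        assert suite["SSD"][0].p[0] <= 0.01
        assert suite["SShD"].r_squared("sex") < 0.05

    def test_sex_shape_r2_monotone_in_offset(self):
        r2 = []
        for offset in (0.0, 0.05, 0.15):
            spec = ms.GeneratorSpec(
                groups=[
                    ms.GroupSpec("s", "F", 30),
                    ms.GroupSpec("s", "M", 30, shape_effect=offset or None),
                ],
                template=ms.polygon_template(10),
                seed=21,  # same seed: same noise and effect direction
            )
            ds, _ = ms.generate_dataset(spec)
            res = ms.gpa(ds)
            suite = ms.sexual_dimorphism_suite(
                res.aligned, res.centroid_sizes, ds.classifier_column("sex"), n_perm=50, seed=0
            )
            r2.append(suite["SShD"].r_squared("sex"))
        assert r2[0] < r2[1] < r2[2]

    def test_balanced_resampling_reported(self, small_dataset):
        ds, _ = small_dataset
        res = ms.gpa(ds, slide=True)
        suite = ms.sexual_dimorphism_suite(
            res.aligned, res.centroid_sizes, ds.classifier_column("sex"),
            n_perm=100, seed=0, balanced_T=5, balanced_n_perm=50,
        )
        assert suite["balanced"]["T"] == 5
        assert 0 <= suite["balanced"]["significant"] <= 5

    def test_single_sex_rejected(self, rng):
        with pytest.raises(ValueError, match="both sexes"):
            ms.sexual_dimorphism_suite(rng.standard_normal((6, 5, 2)), np.ones(6), np.array(["F"] * 6))
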