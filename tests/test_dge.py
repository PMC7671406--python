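"""Filtering, normalisation, model fitting, moderation and classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from intronseq import dge

import oracles


class TestFilterExpressed:
    def test_zero_and_huge_genes(self):
        counts = np.vstack([np.zeros(6), np.full(6, 5000.0),
                            np.full(6, 100.0)])
        keep = dge.filter_expressed(counts, ["a"] * 3 + ["b"] * 3)
        assert not keep[0] and keep[1]

    def test_matches_rule_transcription_on_nb_matrix(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(2, 0.02, size=(500, 6)).astype(float)
        low = rng.random(500) < 0.4
        counts[low] = rng.poisson(1.5, size=(low.sum(), 6))
        groups = ["a"] * 3 + ["b"] * 3
        got = dge.filter_expressed(counts, groups)
        want = oracles.filter_oracle(counts, groups)
        assert (got == want).all()
        assert 0 < got.sum() < 500

    def test_large_group_damping(self):
        # 30 samples in one group: required sample count is 10 + 20·0.7 = 24
        counts = np.ones((3, 30))
        counts[0, :24] = 1000.0
        counts[1, :23] = 1000.0
        counts[2, :] = 5000.0  # anchors the library sizes
        keep = dge.filter_expressed(counts, ["a"] * 30)
        assert keep[0] and not keep[1]


class TestCombinedLibSizes:
    def test_sum_of_both_sets(self):
        it = np.array([[4, 1], [6, 2]])
        ex = np.array([[50, 30], [40, 60]])
        assert dge.combined_library_sizes(it, ex).tolist() == [100, 93]

    def test_equal_matrices_double(self):
        m = np.array([[10, 20], [30, 40]])
        assert dge.combined_library_sizes(m, m).tolist() == [80, 120]

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError):
            dge.combined_library_sizes(np.zeros((2, 1)), np.zeros((2, 1)))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 100).astype(float) + 1
        counts = np.column_stack([col, col])
        f = dge.tmm_factors(counts, counts.sum(axis=0))
        assert np.allclose(f, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(50, 200).astype(float) + 1
        counts = np.column_stack([col, 2 * col])
        lib = counts.sum(axis=0)
        f = dge.tmm_factors(counts, lib)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_formula_transcription(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, size=(50, 4)).astype(float) + 1
        counts[:5, 0] *= 4  # 5 genes 4-fold up in sample 1
        lib = counts.sum(axis=0) + rng.integers(100, 200, 4)
        got = dge.tmm_factors(counts, lib)
        want = oracles.tmm_oracle(counts, lib)
        assert np.allclose(got, want, atol=1e-6)
        assert np.exp(np.mean(np.log(got))) == pytest.approx(1.0)

    def test_single_sample_warns_unit(self):
        with pytest.warns(UserWarning):
            f = dge.tmm_factors(np.ones((10, 1)), np.array([10.0]))
        assert f.tolist() == [1.0]


class TestLogCpmRpkm:
    def test_reference_values(self):
        lib = np.array([1e6])
        assert dge.log_cpm(np.array([[0]]), lib)[0, 0] == pytest.approx(1.0)
        assert dge.log_cpm(np.array([[998]]), lib)[0, 0] == pytest.approx(
            np.log2(1000))

    def test_depth_near_invariance(self):
        counts = np.array([[100.0], [1000.0]])
        a = dge.log_cpm(counts, np.array([1e6]))
        b = dge.log_cpm(2 * counts, np.array([2e6]))
        assert np.allclose(a, b, atol=0.02)

    def test_rpkm_length_adjustment(self):
        lib = np.array([1e6])
        counts = np.array([[998.0]])
        r1 = dge.log_rpkm(counts, lib, np.array([1000.0]))
        assert r1[0, 0] == pytest.approx(np.log2(1000))
        r2 = dge.log_rpkm(counts, lib, np.array([500.0]))
        assert r2[0, 0] == pytest.approx(np.log2(1000) + 1)

    def test_zero_length_region_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = dge.log_rpkm(np.array([[10.0]]), np.array([1e6]), np.array([0.0]))
        assert np.isnan(r[0, 0])

    def test_nonpositive_lib_errors(self):
        with pytest.raises(ValueError):
            dge.log_cpm(np.array([[1]]), np.array([0.0]))


DESIGN_2x3 = np.array([[1, 0]] * 3 + [[0, 1]] * 3, dtype=float)
CONTRAST = np.array([-1.0, 1.0])


class TestVoom:
    def test_deterministic(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, (50, 6)).astype(float)
        lib = counts.sum(axis=0)
        y1, w1 = dge.voom_weights(counts, DESIGN_2x3, lib)
        y2, w2 = dge.voom_weights(counts, DESIGN_2x3, lib)
        assert np.array_equal(w1, w2) and np.array_equal(y1, y2)

    def test_constant_variance_gives_near_constant_weights(self):
        rng = np.random.default_rng(6)
        n = 500
        mu = rng.uniform(8, 14, n)  # log2 abundance, mean-independent noise
        logc = mu[:, None] + rng.normal(0, 0.3, (n, 6))
        counts = np.round(2.0 ** logc)
        lib = np.full(6, 1e6)
        _, w = dge.voom_weights(counts, DESIGN_2x3, lib)
        assert w.max() / w.min() < 2

    def test_nb_counts_weights_increase_with_abundance(self):
        rng = np.random.default_rng(7)
        n = 800
        mean = rng.lognormal(3, 1.5, n)
        counts = rng.negative_binomial(10, 10 / (10 + mean[:, None]),
                                       (n, 6)).astype(float)
        lib = counts.sum(axis=0)
        _, w = dge.voom_weights(counts, DESIGN_2x3, lib)
        rho = sps.spearmanr(w.ravel(), counts.ravel()).statistic
        assert rho > 0

    def test_few_genes_constant_weights_warning(self):
        counts = np.ones((4, 6))
        with pytest.warns(UserWarning):
            _, w = dge.voom_weights(counts, DESIGN_2x3, np.full(6, 100.0))
        assert np.all(w == 1.0)


class TestLinearModels:
    def test_two_group_logfc_is_difference_of_means(self):
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, (10, 6))
        w = np.ones_like(y)
        fit = dge.fit_linear_models(y, w, DESIGN_2x3, CONTRAST)
        want = y[:, 3:].mean(axis=1) - y[:, :3].mean(axis=1)
        assert np.allclose(fit.logFC, want)
        assert np.all(fit.df_resid == 4)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(7), rng.normal(size=7), rng.normal(size=7)])
        c = np.array([0.0, 1.0, -0.5])
        y = rng.normal(size=(5, 7))
        w = rng.uniform(0.2, 3.0, size=(5, 7))
        fit = dge.fit_linear_models(y, w, X, c)
        for g in range(5):
            lfc, s2, df, se = oracles.wls_oracle(y[g], X, w[g], c)
            assert fit.logFC[g] == pytest.approx(lfc)
            assert fit.sigma2[g] == pytest.approx(s2)
            assert fit.stdev_unscaled[g] == pytest.approx(se)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            dge.fit_linear_models(np.ones((3, 6)), np.ones((3, 6)), X,
                                  np.array([1.0, 0.0]))


class TestEmpiricalBayes:
    def test_prior_matches_independent_inversion(self):
        rng = np.random.default_rng(10)
        s2 = 2.0 * 4 / rng.chisquare(4, 300) * rng.chisquare(4, 300) / 4
        d0, s0 = dge.estimate_prior(s2, np.full(300, 4.0))
        d0_o, s0_o = oracles.prior_oracle(s2, 4.0)
        assert d0 == pytest.approx(d0_o, abs=1e-4)
        assert s0 == pytest.approx(s0_o, abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_scaled_inv_chisq_recovery(self, seed):
        rng = np.random.default_rng(seed)
        G, d0_true, s0_true, df = 200, 4.0, 2.0, 4.0
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(df, G) / df
        d0, s0 = dge.estimate_prior(s2, np.full(G, df))
        assert 2.0 <= d0 <= 8.0
        assert 1.4 <= s0 <= 2.8

    def test_posterior_limits(self):
        fit = dge.FitResult(["a", "b"], logFC=np.array([1.0, -1.0]),
                            sigma2=np.array([1.0, 4.0]),
                            df_resid=np.array([4.0, 4.0]),
                            stdev_unscaled=np.array([0.5, 0.5]))
        # d0 = ∞: posterior variance is s0² for every gene
        s2_post_inf = np.full(2, 3.0)
        t_inf = fit.logFC / (fit.stdev_unscaled * np.sqrt(s2_post_inf))
        # d0 = 0: posterior equals each gene's own variance → ordinary t
        d0 = 0.0
        s2_post_0 = (d0 * 3.0 + fit.df_resid * fit.sigma2) / (d0 + fit.df_resid)
        t_0 = fit.logFC / (fit.stdev_unscaled * np.sqrt(s2_post_0))
        assert np.allclose(s2_post_0, fit.sigma2)
        assert np.allclose(t_0, fit.logFC / (fit.stdev_unscaled * np.sqrt(fit.sigma2)))
        assert np.allclose(s2_post_inf, 3.0)
        assert t_inf[0] == pytest.approx(-t_inf[1])

    def test_moderation_attaches_p_values(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, (100, 6))
        fit = dge.fit_linear_models(y, np.ones_like(y), DESIGN_2x3, CONTRAST)
        fit = dge.ebayes_moderate(fit)
        assert np.all((fit.p >= 0) & (fit.p <= 1))
        assert np.all(fit.p_adj >= fit.p - 1e-15)
        assert fit.d0 > 0

    def test_all_zero_variances_error(self):
        fit = dge.FitResult(["a"], np.array([1.0]), np.array([0.0]),
                            np.array([4.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            dge.ebayes_moderate(fit)


class TestBH:
    def test_stepup_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(dge.bh_adjust(p), 0.04)

    def test_single_and_tied(self):
        assert dge.bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        assert np.allclose(dge.bh_adjust(np.array([0.2, 0.2, 0.2])), 0.2)

    def test_nan_passthrough_excluded_from_n(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = dge.bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], oracles.bh_oracle(p[[0, 2]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_oracle(self, ps):
        p = np.array(ps)
        got = dge.bh_adjust(p)
        want = oracles.bh_oracle(p)
        assert np.allclose(got, want, atol=1e-10)
        order = np.argsort(p)
        assert np.all(np.diff(got[order]) >= -1e-12)


def _fit(genes, p_adj, lfc):
    n = len(genes)
    return dge.FitResult(genes, logFC=np.asarray(lfc, float),
                         sigma2=np.ones(n), df_resid=np.full(n, 4.0),
                         stdev_unscaled=np.ones(n), t_mod=np.asarray(lfc, float),
                         p=np.asarray(p_adj, float), p_adj=np.asarray(p_adj, float))


class TestClassify:
    def test_reference_examples(self):
        ex = _fit(["g1", "g2"], [0.001, 0.5], [2.0, 2.0])
        it = _fit(["g1", "g2"], [0.001, 0.001], [1.0, -1.0])
        cats = dge.classify_genes(ex, it)["category"]
        assert cats["g1"] == "+"
        assert cats["g2"] == "intron-"

    def test_exhaustive_truth_table(self):
        rows = []
        for sigE, sigI, upE, upI in itertools.product([True, False], repeat=4):
            ex = _fit(["g"], [0.001 if sigE else 0.5], [1.0 if upE else -1.0])
            it = _fit(["g"], [0.001 if sigI else 0.5], [1.0 if upI else -1.0])
            rows.append(((sigE, sigI, upE, upI),
                         dge.classify_genes(ex, it)["category"]["g"]))
        got = dict(rows)
        assert got[(True, True, True, True)] == "+"
        assert got[(True, True, False, False)] == "-"
        assert got[(True, True, True, False)] == "mixed+-"
        assert got[(True, True, False, True)] == "mixed-+"
        assert got[(True, False, True, True)] == got[(True, False, True, False)] == "exon+"
        assert got[(True, False, False, True)] == "exon-"
        assert got[(False, True, True, True)] == got[(False, True, False, True)] == "intron+"
        assert got[(False, True, True, False)] == "intron-"
        for key, cat in got.items():
            if not key[0] and not key[1]:
                assert cat == "0"
        assert set(got.values()) == set(dge.CATEGORIES)

    def test_gene_order_invariance_and_sign_flip(self):
        genes = ["a", "b", "c", "d"]
        ex = _fit(genes, [0.001, 0.5, 0.001, 0.5], [2, 1, -1, 1])
        it = _fit(genes, [0.001, 0.001, 0.5, 0.5], [1, -2, 1, 1])
        table = dge.classify_genes(ex, it)
        perm = [2, 0, 3, 1]
        exp = _fit([genes[i] for i in perm],
                   [ex.p_adj[i] for i in perm], [ex.logFC[i] for i in perm])
        itp = _fit([genes[i] for i in perm],
                   [it.p_adj[i] for i in perm], [it.logFC[i] for i in perm])
        permuted = dge.classify_genes(exp, itp)
        for g in genes:
            assert table["category"][g] == permuted["category"][g]
        flip = {"+": "-", "-": "+", "exon+": "exon-", "exon-": "exon+",
                "intron+": "intron-", "intron-": "intron+",
                "mixed+-": "mixed-+", "mixed-+": "mixed+-", "0": "0"}
        exf = _fit(genes, ex.p_adj, -ex.logFC)
        itf = _fit(genes, it.p_adj, -it.logFC)
        flipped = dge.classify_genes(exf, itf)
        for g in genes:
            assert flipped["category"][g] == flip[table["category"][g]]

    def test_gene_set_mismatch_errors(self):
        with pytest.raises(ValueError):
            dge.classify_genes(_fit(["a"], [0.5], [1.0]), _fit(["b"], [0.5], [1.0]))


class TestExploratory:
    def test_identical_counts_correlate_perfectly(self):
        df = pd.DataFrame({"s1": [10, 20, 30, 40]}, index=list("abcd"))
        r = dge.correlation_exon_intron(df, df.copy())
        assert r["s1"] == pytest.approx(1.0)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(12)
        ex = pd.DataFrame({"s1": rng.poisson(50, 2000)})
        it = pd.DataFrame({"s1": rng.poisson(50, 2000)}, index=ex.index)
        r = dge.correlation_exon_intron(ex, it)
        assert abs(r["s1"]) < 0.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(13)
        ex = pd.DataFrame({"s1": rng.poisson(30, 50) + 3})
        it = pd.DataFrame({"s1": rng.poisson(20, 50) + 3}, index=ex.index)
        r = dge.correlation_exon_intron(ex, it)
        want = oracles.pearson_oracle(np.log2(ex.s1 + 1), np.log2(it.s1 + 1))
        assert r["s1"] == pytest.approx(want)

    def test_expression_pattern_boundaries(self):
        ex = pd.DataFrame({"s": [3, 3, 2, 2]}, index=list("abcd"))
        it = pd.DataFrame({"s": [3, 2, 3, 2]}, index=list("abcd"))
        labels, pct = dge.expression_pattern(ex, it)
        assert labels["s"].tolist() == ["both", "exon_only", "intron_only",
                                        "unexpressed"]
        row = pct.set_index("sample_id").loc["s"]
        assert row["both"] == pytest.approx(100 / 3)
        # every integer pair maps to exactly one label
        for e in range(5):
            for i in range(5):
                l, _ = dge.expression_pattern(
                    pd.DataFrame({"s": [e]}), pd.DataFrame({"s": [i]}))
                assert l["s"].iloc[0] in {"both", "exon_only", "intron_only",
                                          "unexpressed"}


class TestMDS:
    def test_duplicated_sample_coincides(self):
        rng = np.random.default_rng(14)
        y = rng.normal(5, 1, (600, 4))
        y = np.column_stack([y, y[:, 0]])  # duplicate sample 0
        coords, var = dge.mds_leading_logfc(y, top=100)
        assert np.allclose(coords.iloc[0], coords.iloc[4], atol=1e-8)

    def test_group_separation_on_first_dimension(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(15)
        y = rng.normal(5, 0.3, (2000, 6))
        y[:300, 3:] += 2.0  # 300 genes at logFC 2 between groups
        coords, var = dge.mds_leading_logfc(y, top=500)
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette_score(coords.to_numpy(), labels) > 0.5
        assert var[0] > var[1] >= 0

    def test_fewer_genes_than_top_warns(self):
        rng = np.random.default_rng(16)
        with pytest.warns(UserWarning):
            dge.mds_leading_logfc(rng.normal(size=(50, 4)), top=500)


class TestWorkflowDeterminism:
    def test_same_input_file_gives_byte_identical_tables(self, tmp_path):
        from intronseq import synthetic as syn
        ex, it, truth, groups = syn.simulate_counts(n_genes=400, seed=21)
        ex.to_csv(tmp_path / "ex.tsv", sep="\t")
        it.to_csv(tmp_path / "it.tsv", sep="\t")
        design = dge.design_from_groups(groups, "grp2-grp1")
        outputs = []
        for _ in range(2):
            e = pd.read_csv(tmp_path / "ex.tsv", sep="\t", index_col=0)
            i = pd.read_csv(tmp_path / "it.tsv", sep="\t", index_col=0)
            outputs.append(dge.run_joint_dge(e, i, design).category_table.to_csv())
        assert outputs[0] == outputs[1]
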