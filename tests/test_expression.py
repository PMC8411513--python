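"""PCA, moderated t, BH, template selection, standardization, subsetting."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import lmsubtypes as L
from lmsubtypes.expression import moderated_t_test

from conftest import make_expr


class TestPCA:
    def test_single_divergent_gene_gives_pc1_all_variance(self):
        X = np.full((5, 2), 3.0)
        X[0, 1] = 9.0
        scores, frac = L.pca_scores(make_expr(X), n_top=5)
        assert frac["PC1"] == pytest.approx(1.0)

    def test_duplicated_samples_get_identical_scores(self, rng):
        X = rng.normal(size=(20, 6))
        X2 = np.hstack([X, X])
        samples = [f"s{i}" for i in range(6)] + [f"d{i}" for i in range(6)]
        scores, _ = L.pca_scores(make_expr(X2, samples=samples), n_top=20)
        for i in range(6):
            assert np.allclose(scores.loc[f"s{i}"], scores.loc[f"d{i}"], atol=1e-10)

    def test_matches_brute_force_eigendecomposition(self, rng):
        X = rng.normal(size=(3, 4))
        scores, frac = L.pca_scores(make_expr(X), n_top=3)
        # oracle: eigen-decomposition of the sample covariance of centered data
        C = X.T - X.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(C.T @ C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        flip = np.where(evecs.sum(axis=0) < 0, -1.0, 1.0)
        oracle = C @ (evecs * flip)
        k = scores.shape[1]
        assert np.allclose(scores.to_numpy(), oracle[:, :k], atol=1e-10)
        assert np.allclose(frac.to_numpy(), (evals / evals.sum())[:k], atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            L.pca_scores(make_expr(np.ones((4, 3))))


class TestModeratedT:
    @staticmethod
    def two_group(rng, p=80, n1=4, n2=5):
        X = rng.normal(6, 1, size=(p, n1 + n2))
        X[:10, :n1] += 1.5
        expr = make_expr(X)
        group = pd.Series(["g1"] * n1 + ["g0"] * n2, index=expr.samples)
        return expr, group

    def test_zero_prior_df_recovers_ordinary_pooled_t(self, rng):
        expr, group = self.two_group(rng)
        de = moderated_t_test(expr, group, prior_df=0.0)
        assert np.allclose(de["t_moderated"], de["t_ordinary"], atol=1e-12)

    def test_infinite_prior_df_ranks_by_fold_change(self, rng):
        expr, group = self.two_group(rng)
        de = moderated_t_test(expr, group, prior_df=np.inf)
        by_t = de.table["t_moderated"].abs().rank()
        by_fc = de.table["log2_fc"].abs().rank()
        assert (by_t == by_fc).all()

    def test_q_dominates_p_and_variances_positive(self, rng):
        expr, group = self.two_group(rng)
        de = moderated_t_test(expr, group)
        assert (de["q"] >= de["p"] - 1e-15).all()
        assert (de["s2_posterior"] > 0).all()
        assert de.prior_df >= 0

    def test_empirical_fdr_controlled_in_simulation(self):
        """50 shifted genes of 200, 5v5, sigma=1: FDR among q<=0.05 calls."""
        n_reps = 1000
        false_calls = 0
        total_calls = 0
        for rep in range(n_reps):
            r = np.random.default_rng(10_000 + rep)
            X = r.normal(0, 1, size=(200, 10))
            X[:50, :5] += 2.0
            expr = make_expr(X)
            group = pd.Series(["b"] * 5 + ["a"] * 5, index=expr.samples)
            de = moderated_t_test(expr, group)
            hits = de.table.index[de.table["q"] <= 0.05]
            idx = de.table.index.get_indexer(hits)
            false_calls += int((idx >= 50).sum())
            total_calls += len(idx)
        assert total_calls > 0
        assert false_calls / total_calls <= 0.07

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_reference_empirical_bayes_implementation(self, tmp_path, rng):
        """Independent oracle: the reference linear-model empirical-Bayes fit in R."""
        expr, group = self.two_group(rng, p=60)
        mat = tmp_path / "mat.tsv"
        expr.data.to_csv(mat, sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'X <- as.matrix(read.delim("{mat}", row.names=1))\n'
            "design <- cbind(1, c(rep(1,4), rep(0,5)))\n"
            "fit <- eBayes(lmFit(X, design))\n"
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path / "r.tsv"}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        de = moderated_t_test(expr, group)
        assert de.prior_df == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-6)
        assert de.prior_var == pytest.approx(float(ref["s02"].iloc[0]), rel=1e-6)
        assert np.allclose(de["t_moderated"], ref["t"], atol=1e-10)
        assert np.allclose(de["p"], ref["p"], atol=1e-10)

    def test_empty_group_rejected(self, rng):
        expr, _ = self.two_group(rng)
        group = pd.Series(["a"] * 9, index=expr.samples)
        with pytest.raises(ValueError, match="two groups"):
            moderated_t_test(expr, group)


def bh_oracle(p):
    """Literal step-up definition: q_i = min over j with p_(j) >= p_(i) of m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(min(m * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0)
    return q


class TestBH:
    def test_closed_form_examples(self):
        assert np.allclose(L.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(L.bh_adjust([1.0]), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            L.bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=8)
    )
    def test_exhaustive_oracle_equivalence_small_m(self, p):
        assert np.allclose(L.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_agrees_with_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=50)
            ours = L.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)


class TestTemplateSelection:
    @staticmethod
    def toy(down_gene=False, flat_gene=False):
        rng = np.random.default_rng(3)
        p = 30
        Xt = rng.normal(6, 1, size=(p, 20))
        Xn = rng.normal(6, 0.3, size=(p, 8))
        Xt[:10] += 3.0  # up + variable-ish
        if down_gene:
            Xt[10] -= 4.0
            Xt[10] = Xt[10].mean() + np.linspace(-2, 2, 20)  # high SD but down
        if flat_gene:
            Xt[11] = Xn[11].mean() + 3.0 + rng.normal(0, 0.05, 20)  # up, flat
        genes = [f"G{i:02d}" for i in range(p)]
        return (
            make_expr(Xt, genes=genes, samples=[f"t{i}" for i in range(20)]),
            make_expr(Xn, genes=genes, samples=[f"n{i}" for i in range(8)]),
        )

    def test_downregulated_gene_excluded_regardless_of_sd(self):
        t, n = self.toy(down_gene=True)
        sel = L.select_template_genes(t, n)
        assert "G10" not in sel.upregulated_genes

    def test_low_sd_gene_kept_at_step_one_dropped_at_step_two(self):
        t, n = self.toy(flat_gene=True)
        sel = L.select_template_genes(t, n, sd_min=0.8)
        assert "G11" in sel.upregulated_genes
        assert "G11" not in sel.template_genes

    def test_monotone_in_sd_threshold(self):
        t, n = self.toy()
        loose = set(L.select_template_genes(t, n, sd_min=0.5).template_genes)
        tight = set(L.select_template_genes(t, n, sd_min=0.9).template_genes)
        assert tight <= loose

    def test_planted_up_and_variable_genes_recovered(self):
        """400 planted markers among 5,000 genes at default thresholds."""
        cfg = L.SimulationConfig(
            n_patients=169,
            lesions_per_patient=("truncated_geometric", 1.0, 1),
            n_genes=5000,
            n_template_markers_per_subtype=79,
            mesenchymal_extra_genes=5,
            subtype_prevalences=(0.2,) * 5,
            marker_fold=6.0,
            mesenchymal_fold=8.0,
            n_liver_genes=157,
            seed=21,
        )
        expr, annot, truth = L.generate_expression(cfg)
        expr = L.apply_liver_contamination(expr, truth)
        planted = set(truth.template_genes())
        assert len(planted) == 400
        sel = L.select_template_genes(
            expr.subset_samples(annot.tumor_samples),
            expr.subset_samples(annot.normal_samples),
        )
        got = set(sel.template_genes)
        assert len(got & planted) >= 0.95 * len(planted)
        assert len(got - planted) <= 0.05 * len(got)


class TestStandardize:
    def test_columns_become_zero_mean_unit_sd_and_idempotent(self, rng):
        expr = make_expr(rng.normal(5, 2, size=(40, 6)))
        z = L.standardize_samples(expr)
        assert np.allclose(z.data.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.data.std(axis=0, ddof=1), 1, atol=1e-12)
        zz = L.standardize_samples(z)
        assert np.allclose(z.values, zz.values, atol=1e-12)

    def test_hand_computed_toy(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        z = L.standardize_samples(make_expr(X))
        assert np.allclose(z.values[:, 0], [-1, 0, 1])
        assert np.allclose(z.values[:, 1], [-1, 0, 1])

    def test_zero_sd_sample_named_in_error(self):
        X = np.ones((3, 2))
        X[:, 1] = [1, 2, 3]
        with pytest.raises(ValueError, match="s0"):
            L.standardize_samples(make_expr(X))


class TestOneSamplePerPatient:
    @staticmethod
    def annot3():
        tab = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1"],
                "patient_id": ["A", "A", "A", "B"],
                "tissue": ["tumor"] * 4,
            }
        ).set_index("sample_id")
        return L.CohortAnnotation(tab)

    def test_single_sample_patient_always_chosen(self):
        chosen = L.select_one_sample_per_patient(self.annot3(), seed=0)
        assert "b1" in chosen
        assert len(chosen) == 2

    def test_seed_contract(self):
        a = L.select_one_sample_per_patient(self.annot3(), seed=5)
        b = L.select_one_sample_per_patient(self.annot3(), seed=5)
        assert a == b

    def test_uniform_over_patient_samples(self):
        annot = self.annot3()
        counts = {"a1": 0, "a2": 0, "a3": 0}
        for seed in range(10_000):
            chosen = L.select_one_sample_per_patient(annot, seed=seed)
            counts[[s for s in chosen if s.startswith("a")][0]] += 1
        for v in counts.values():
            assert abs(v / 10_000 - 1 / 3) < 0.02
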