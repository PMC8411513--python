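"""KM/log-rank/Cox, contingency statistics, heterogeneity, branch analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import lmsubtypes as L
from lmsubtypes.datamodel import CohortAnnotation, ContingencyTable

from conftest import make_expr


def annot_from_rows(rows):
    cols = ["sample_id", "patient_id", "lesion_id", "region_id", "tissue", "resection_round"]
    tab = pd.DataFrame(rows, columns=cols).set_index("sample_id")
    return CohortAnnotation(tab)


class TestKMLogrank:
    def test_closed_form_product_limit(self):
        out = L.km_logrank(
            pd.Series([1.0, 2.0, 3.0, 4.0]), pd.Series([1, 1, 1, 1]), pd.Series(["a"] * 4)
        )
        surv = out["km"]["a"].survival_function_["a"]
        assert np.allclose(surv.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])

    def test_identical_groups_null(self):
        t = pd.Series([1.0, 3.0, 5.0, 7.0] * 2)
        e = pd.Series([1, 0, 1, 1] * 2)
        g = pd.Series(["a"] * 4 + ["b"] * 4)
        out = L.km_logrank(t, e, g)
        assert out["pairwise"]["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["pairwise"]["p"].iloc[0] == pytest.approx(1.0)

    def test_time_shift_invariance_of_logrank(self, rng):
        t = pd.Series(rng.exponential(20, size=60))
        e = pd.Series(rng.integers(0, 2, size=60))
        g = pd.Series(["a"] * 30 + ["b"] * 30)
        chi_1 = L.km_logrank(t, e, g, horizon=np.inf)["pairwise"]["chi2"].iloc[0]
        chi_2 = L.km_logrank(t + 5.0, e, g, horizon=np.inf)["pairwise"]["chi2"].iloc[0]
        assert chi_1 == pytest.approx(chi_2, rel=1e-9)

    def test_power_against_planted_hazard_ratio(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            t1 = r.exponential(40.0, 200)
            t2 = r.exponential(20.0, 200)  # HR 2
            t = pd.Series(np.r_[t1, t2])
            e = pd.Series(np.ones(400, dtype=int))
            g = pd.Series(["a"] * 200 + ["b"] * 200)
            out = L.km_logrank(t, e, g)
            rejections += int(out["pairwise"]["p"].iloc[0] < 0.05)
        assert rejections / n_reps >= 0.95

    def test_five_year_truncation_applied(self):
        t = pd.Series([10.0, 80.0])
        e = pd.Series([1, 1])
        tt, ee = L.truncate_survival(t, e)
        assert tt.tolist() == [10.0, 60.0]
        assert ee.tolist() == [1, 0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            L.km_logrank(pd.Series([1.0]), pd.Series([1]), pd.Series([np.nan]))


class TestCox:
    def test_null_on_duplicated_data(self, rng):
        t = pd.Series(np.r_[rng.exponential(30, 50), rng.exponential(30, 50)])
        e = pd.Series(np.ones(100, dtype=int))
        cov = pd.DataFrame({"arm": [0] * 50 + [1] * 50})
        fit = L.cox_fit(t, e, cov, check_ph=False)
        assert abs(np.log(fit["summary"].loc["arm", "hr"])) < 0.5
        assert fit["summary"].loc["arm", "hr_lower"] < 1 < fit["summary"].loc["arm", "hr_upper"]

    def test_bivariable_recovery_of_independent_effects(self):
        r = np.random.default_rng(0)
        n = 2000
        x1 = r.integers(0, 2, n)
        x2 = r.integers(0, 2, n)
        lam = 0.02 * np.exp(np.log(2.2) * x1 + np.log(1.6) * x2)
        t = pd.Series(r.exponential(1 / lam))
        e = pd.Series(np.ones(n, dtype=int))
        fit = L.cox_fit(t, e, pd.DataFrame({"a": x1, "b": x2}), check_ph=False, horizon=np.inf)
        s = fit["summary"]
        assert s.loc["a", "hr_lower"] < 2.2 < s.loc["a", "hr_upper"]
        assert s.loc["b", "hr_lower"] < 1.6 < s.loc["b", "hr_upper"]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            L.cox_fit(pd.Series([1.0, 2.0]), pd.Series([1, 1]), pd.DataFrame({"c": [1, 1]}))


class TestContingency:
    def test_independence_gives_zero_chi2(self):
        tab = ContingencyTable(pd.DataFrame([[10, 10], [10, 10]]))
        out = L.contingency_stats(tab)
        assert out["statistic"] == pytest.approx(0.0)

    def test_chi2_equals_brute_force_sum(self, rng):
        counts = rng.integers(1, 30, size=(5, 4))
        tab = ContingencyTable(pd.DataFrame(counts))
        out = L.contingency_stats(tab)
        total = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / total
        oracle = ((counts - expected) ** 2 / expected).sum()
        assert out["statistic"] == pytest.approx(oracle, rel=1e-12)
        assert out["df"] == 12

    def test_fisher_matches_hypergeometric_enumeration(self):
        a, b, c, d = 12, 5, 3, 20
        tab = ContingencyTable(pd.DataFrame([[a, b], [c, d]]))
        out = L.contingency_stats(tab, test="fisher2x2")
        # enumerate all tables with the same margins; two-sided p sums the
        # probabilities of tables at most as likely as the observed one
        n, K, N = a + b + c + d, a + b, a + c
        support = range(max(0, K + N - n), min(K, N) + 1)
        probs = {x: hypergeom.pmf(x, n, K, N) for x in support}
        p_oracle = sum(pr for pr in probs.values() if pr <= probs[a] * (1 + 1e-9))
        assert out["p"] == pytest.approx(p_oracle, rel=1e-9)
        assert out["odds_ratio"] > 1

    def test_zero_marginal_rejected(self):
        tab = ContingencyTable(pd.DataFrame([[0, 0], [3, 4]]))
        with pytest.raises(ValueError, match="marginal"):
            L.contingency_stats(tab)


class TestHeterogeneity:
    def test_homogeneous_patients_give_zero_fraction(self):
        annot = annot_from_rows(
            [
                ("p1a", "P1", "L1", "R1", "tumor", 1),
                ("p1b", "P1", "L2", "R1", "tumor", 1),
                ("p2a", "P2", "L1", "R1", "tumor", 1),
                ("p2b", "P2", "L2", "R1", "tumor", 1),
            ]
        )
        labels = pd.Series("LMS3", index=annot.samples)
        rep = L.heterogeneity_report(labels, annot)
        assert rep.headline_fraction == 0.0
        assert rep.n_headline_patients == 2

    def test_mixed_patient_counts_in_both_subtype_fractions(self):
        annot = annot_from_rows(
            [
                ("p1a", "P1", "L1", "R1", "tumor", 1),
                ("p1b", "P1", "L2", "R1", "tumor", 1),
            ]
        )
        labels = pd.Series({"p1a": "LMS1", "p1b": "LMS3"})
        rep = L.heterogeneity_report(labels, annot)
        assert rep.headline_fraction == 1.0
        assert rep.per_subtype["LMS1"] == 1.0
        assert rep.per_subtype["LMS3"] == 1.0
        assert rep.per_patient.loc["P1", "heterogeneous"]

    def test_cross_resection_only_patients_excluded_from_headline(self):
        annot = annot_from_rows(
            [
                ("p1a", "P1", "L1", "R1", "tumor", 1),
                ("p1b", "P1", "L2", "R1", "tumor", 2),  # re-resection
                ("p2a", "P2", "L1", "R1", "tumor", 1),
                ("p2b", "P2", "L2", "R1", "tumor", 1),
            ]
        )
        labels = pd.Series({"p1a": "LMS1", "p1b": "LMS2", "p2a": "LMS4", "p2b": "LMS4"})
        rep = L.heterogeneity_report(labels, annot)
        assert rep.excluded_patients == ["P1"]
        assert rep.n_headline_patients == 1
        assert rep.headline_fraction == 0.0

    def test_multiregion_lesion_flagged(self):
        annot = annot_from_rows(
            [
                ("p1a", "P1", "L1", "R1", "tumor", 1),
                ("p1b", "P1", "L1", "R2", "tumor", 1),
                ("p1c", "P1", "L2", "R1", "tumor", 1),
            ]
        )
        labels = pd.Series({"p1a": "LMS1", "p1b": "LMS2", "p1c": "LMS1"})
        rep = L.heterogeneity_report(labels, annot)
        assert rep.per_lesion.loc[("P1", "L1"), "multiregion_heterogeneous"]

    def test_planted_switch_rate_recovered(self):
        cfg = L.SimulationConfig(
            n_patients=700,
            n_genes=20,
            n_template_markers_per_subtype=2,
            n_liver_genes=5,
            mesenchymal_extra_genes=1,
            n_normal_liver=2,
            contamination_alpha=None,
            noise_sd=0.0,
            heterogeneity_prob=0.5,
            seed=7,
        )
        expr, annot, truth = L.generate_expression(cfg)
        labels = truth.subtype_per_sample.map(lambda k: f"LMS{k}")
        rep = L.heterogeneity_report(labels, annot)
        assert rep.n_headline_patients >= 200
        # expected fraction: 1 - 0.5^(L-1) mixed over the lesion-count law
        # (~0.58 for the default truncated-geometric lesion counts)
        assert 0.4 <= rep.headline_fraction <= 0.6


class TestBranchAnalysis:
    def test_duplicate_columns_always_adjacent(self, rng):
        X = rng.normal(5, 2, size=(50, 8))
        X[:, 1] = X[:, 0]  # P1's two samples are identical
        expr = make_expr(X)
        rows = [(f"s{i}", f"P{i}", "L1", "R1", "tumor", 1) for i in range(8)]
        rows[1] = ("s1", "P0", "L2", "R1", "tumor", 1)
        annot = annot_from_rows(rows)
        out = L.dendrogram_branch_analysis(expr, annot, n_branches=3)
        assert out.loc["P0", "category"] == "adjacent"

    def test_split_fraction_monotone_in_heterogeneity(self):
        fractions = []
        for het in (0.0, 0.3, 0.6):
            cfg = L.SimulationConfig(
                n_patients=40,
                lesions_per_patient=("truncated_geometric", 0.35, 6),
                n_genes=500,
                n_template_markers_per_subtype=30,
                mesenchymal_extra_genes=4,
                n_liver_genes=30,
                n_normal_liver=3,
                heterogeneity_prob=het,
                noise_sd=0.2,
                contamination_alpha=None,
                seed=13,
            )
            expr, annot, truth = L.generate_expression(cfg)
            multi = annot.table[annot.table["tissue"] == "tumor"].groupby("patient_id")["lesion_id"].nunique()
            keep = annot.table[
                (annot.table["tissue"] == "tumor")
                & annot.table["patient_id"].isin(multi[multi >= 2].index)
            ]
            out = L.dendrogram_branch_analysis(expr.subset_samples(keep.index.tolist()), annot)
            fractions.append((out["category"] == "split").mean())
        assert fractions[0] < fractions[1] < fractions[2] or (
            fractions[0] <= fractions[1] <= fractions[2] and fractions[2] - fractions[0] > 0.2
        )

    def test_branch_count_bounded_by_samples(self, rng):
        expr = make_expr(rng.normal(size=(30, 4)))
        annot = annot_from_rows([(f"s{i}", f"P{i}", "L1", "R1", "tumor", 1) for i in range(4)])
        with pytest.raises(ValueError, match="branches"):
            L.dendrogram_branch_analysis(expr, annot, n_branches=10)


class TestSwitchSensitivity:
    @staticmethod
    def cohort(het, hr, seed=3):
        cfg = L.SimulationConfig(
            n_patients=300,
            lesions_per_patient=("truncated_geometric", 0.5, 6),
            n_genes=20,
            n_template_markers_per_subtype=2,
            n_liver_genes=5,
            mesenchymal_extra_genes=1,
            n_normal_liver=2,
            contamination_alpha=None,
            noise_sd=0.0,
            heterogeneity_prob=het,
            hr_lms1=hr,
            seed=seed,
        )
        expr, annot, truth = L.generate_expression(cfg)
        annot = L.generate_clinical(truth, cfg, annot)
        labels = truth.subtype_per_sample.map(lambda k: f"LMS{k}")
        pat = annot.table[annot.table["tissue"] == "tumor"].drop_duplicates("patient_id").set_index("patient_id")
        disc = pd.Series(
            {p: f"LMS{truth.subtype_per_lesion[p + ':L1']}" for p in pat.index}
        )
        return labels, annot, pat, disc

    def test_no_heterogeneity_gives_identical_fits(self):
        labels, annot, pat, disc = self.cohort(het=0.0, hr=2.2)
        out = L.lms1_switch_sensitivity(
            labels, annot, pat["os_time_months"], pat["os_event"].astype(int), disc
        )
        assert out["n_heterogeneous"] == 0
        assert out["hr_abs_difference"] == pytest.approx(0.0)
        assert "identical" in out["note"]

    def test_hazard_signal_robust_to_switching(self):
        labels, annot, pat, disc = self.cohort(het=0.4, hr=2.5)
        out = L.lms1_switch_sensitivity(
            labels, annot, pat["os_time_months"], pat["os_event"].astype(int), disc
        )
        assert out["n_heterogeneous"] > 0
        assert out["hr_as_lms1"] > 1.0
        assert out["hr_as_rest"] > 1.0

    def test_null_cohort_stays_null(self):
        labels, annot, pat, disc = self.cohort(het=0.4, hr=1.0, seed=9)
        out = L.lms1_switch_sensitivity(
            labels, annot, pat["os_time_months"], pat["os_event"].astype(int), disc
        )
        for key in ("hr_as_lms1", "hr_as_rest"):
            assert 0.5 < out[key] < 2.0
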