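"""Heterogeneity quantification, dendrogram branch analysis, survival and
contingency statistics.

Survival conventions: time runs from treatment initiation; subjects without
an event in the first 60 months are censored at 60 months before any
estimate or test (5-year endpoints). Kaplan-Meier estimation, log-rank
testing, Cox partial likelihood (Efron ties) and the scaled-Schoenfeld
proportional-hazards diagnostic are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test, proportional_hazard_test
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .datamodel import CohortAnnotation, ContingencyTable, ExpressionMatrix
from .expression import bh_adjust

__all__ = [
    "HeterogeneityReport",
    "truncate_survival",
    "dendrogram_branch_analysis",
    "heterogeneity_report",
    "km_logrank",
    "cox_fit",
    "contingency_stats",
    "lms1_switch_sensitivity",
]

FIVE_YEARS = 60.0  # months


@dataclass
class HeterogeneityReport:
    per_patient: pd.DataFrame      # n_lesions, n_samples, calls, heterogeneous, headline_eligible
    per_lesion: pd.DataFrame       # multiregion lesions: heterogeneous flag
    per_subtype: pd.Series         # patient-wise heterogeneity fraction per subtype
    headline_fraction: float       # heterogeneous / multi-lesion same-resection patients
    n_headline_patients: int
    excluded_patients: list[str]   # multi-lesion only across different resections


def truncate_survival(times: pd.Series, events: pd.Series, horizon: float = FIVE_YEARS):
    """Censor every subject without an event before ``horizon`` at ``horizon``."""
    t = times.astype(float).copy()
    e = events.astype(int).copy()
    late = t > horizon
    t[late] = horizon
    e[late] = 0
    return t, e


def dendrogram_branch_analysis(
    expr: ExpressionMatrix,
    annot: CohortAnnotation,
    n_branches: int = 5,
    n_top: int = 1000,
) -> pd.DataFrame:
    """Categorize multi-sample patients by their position in the cohort tree.

    Agglomeration uses Manhattan distances with the squared-update Ward
    variant. The tree is cut into ``n_branches`` main branches. A patient is
    ``adjacent`` when their samples form an exclusive clade (a subtree
    containing nobody else's samples), ``same_branch_nonadjacent`` when all
    samples share one main branch without forming an exclusive clade, else
    ``split``.
    """
    samples = [s for s in expr.samples if s in annot.table.index and annot.table.loc[s, "tissue"] == "tumor"]
    if n_branches > len(samples):
        raise ValueError("more branches requested than samples available")
    sub = expr.subset_samples(samples)
    sd = sub.data.std(axis=1, ddof=1)
    top = sd.sort_values(ascending=False, kind="stable").index[: min(n_top, sub.n_genes)]
    X = sub.data.loc[top].to_numpy().T
    D = pdist(X, metric="cityblock")
    Z = linkage(D, method="ward")  # Lance-Williams ward update on given distances
    branches = fcluster(Z, t=n_branches, criterion="maxclust")
    branch_of = dict(zip(samples, branches))

    # leaf sets of every internal node, for the exclusive-clade test
    tree = to_tree(Z)
    clades: list[set[int]] = []

    def collect(node):
        if node.is_leaf():
            return {node.id}
        leaves = collect(node.left) | collect(node.right)
        clades.append(leaves)
        return leaves

    collect(tree)
    sample_idx = {s: i for i, s in enumerate(samples)}

    rows = []
    patients = annot.table.loc[samples, "patient_id"]
    for patient in sorted(patients.unique()):
        mine = [s for s in samples if patients[s] == patient]
        if len(mine) < 2:
            continue
        mine_idx = {sample_idx[s] for s in mine}
        exclusive = any(c == mine_idx for c in clades)
        if exclusive:
            cat = "adjacent"
        elif len({branch_of[s] for s in mine}) == 1:
            cat = "same_branch_nonadjacent"
        else:
            cat = "split"
        rows.append({"patient_id": patient, "n_samples": len(mine), "category": cat})
    return pd.DataFrame(rows).set_index("patient_id")


def heterogeneity_report(labels: pd.Series, annot: CohortAnnotation) -> HeterogeneityReport:
    """Intra-patient inter-metastatic and intra-lesion subtype heterogeneity.

    The headline fraction counts patients with >= 2 distinct lesions from the
    same resection whose lesion-level calls disagree. Patients whose multiple
    lesions come only from different resection rounds are excluded from the
    headline and listed separately. Lesion-level calls take the modal call
    across a lesion's regions (ties -> first alphabetically); a lesion with
    disagreeing region calls is flagged in the multiregion report.
    """
    tab = annot.table[annot.table["tissue"] == "tumor"].copy()
    missing = [s for s in tab.index if s not in labels.index or pd.isna(labels.get(s))]
    multi = tab.groupby("patient_id")["lesion_id"].nunique()
    if missing:
        affected = tab.loc[missing, "patient_id"].unique()
        bad = [p for p in affected if multi.get(p, 0) >= 2]
        if bad:
            raise ValueError(f"labels missing for multi-lesion patients {bad[:5]}")
    tab["call"] = labels.reindex(tab.index)
    if "resection_round" in tab.columns:
        rounds = pd.to_numeric(tab["resection_round"], errors="coerce")
    else:
        rounds = pd.Series(np.nan, index=tab.index)
    tab["_round"] = rounds.fillna(1).astype(int)

    lesion_rows = []
    for (patient, lesion), grp in tab.groupby(["patient_id", "lesion_id"]):
        calls = grp["call"].dropna()
        modal = calls.mode().sort_values().iloc[0] if len(calls) else pd.NA
        lesion_rows.append(
            {
                "patient_id": patient,
                "lesion_id": lesion,
                "n_regions": len(grp),
                "resection_round": grp["_round"].iloc[0],
                "call": modal,
                "multiregion_heterogeneous": len(grp) > 1 and calls.nunique() > 1,
            }
        )
    lesions = pd.DataFrame(lesion_rows)

    patient_rows = []
    excluded = []
    for patient, grp in lesions.groupby("patient_id"):
        n_lesions = len(grp)
        calls = set(grp["call"].dropna())
        het = len(calls) > 1
        by_round = grp.groupby("resection_round")["lesion_id"].count()
        same_res = by_round.max() >= 2 if len(by_round) else False
        headline = False
        headline_het = False
        if n_lesions >= 2:
            if same_res:
                headline = True
                best_round = by_round[by_round >= 2].index
                # heterogeneity within any single resection with >= 2 lesions
                headline_het = any(
                    grp.loc[grp["resection_round"] == rr, "call"].dropna().nunique() > 1
                    for rr in best_round
                )
            else:
                excluded.append(patient)
        patient_rows.append(
            {
                "patient_id": patient,
                "n_lesions": n_lesions,
                "n_samples": int((tab["patient_id"] == patient).sum()),
                "calls": tuple(sorted(map(str, calls))),
                "heterogeneous": het,
                "headline_eligible": headline,
                "headline_heterogeneous": headline_het,
            }
        )
    per_patient = pd.DataFrame(patient_rows).set_index("patient_id")

    eligible = per_patient[per_patient["headline_eligible"]]
    frac = float(eligible["headline_heterogeneous"].mean()) if len(eligible) else np.nan

    subtypes = sorted(set(lesions["call"].dropna()))
    per_subtype = {}
    same_res_lesions = lesions.merge(
        eligible.reset_index()[["patient_id"]], on="patient_id", how="inner"
    )
    for sub in subtypes:
        pats = same_res_lesions.loc[same_res_lesions["call"] == sub, "patient_id"].unique()
        if len(pats) == 0:
            per_subtype[sub] = np.nan
            continue
        per_subtype[sub] = float(eligible.loc[pats, "headline_heterogeneous"].mean())
    multiregion = lesions[lesions["n_regions"] > 1].set_index(["patient_id", "lesion_id"])
    return HeterogeneityReport(
        per_patient=per_patient,
        per_lesion=multiregion,
        per_subtype=pd.Series(per_subtype, dtype=float),
        headline_fraction=frac,
        n_headline_patients=int(len(eligible)),
        excluded_patients=excluded,
    )


def km_logrank(
    times: pd.Series,
    events: pd.Series,
    groups: pd.Series,
    horizon: float = FIVE_YEARS,
) -> dict:
    """Kaplan-Meier curves per group plus pairwise BH-adjusted log-rank tests."""
    if (times < 0).any():
        raise ValueError("negative survival times")
    idx = times.index
    groups = groups.reindex(idx)
    t, e = truncate_survival(times, events, horizon)
    levels = sorted(groups.dropna().unique())
    if not levels or any((groups == g).sum() == 0 for g in levels):
        raise ValueError("empty group")
    curves = {}
    for g in levels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(g))
        curves[g] = kmf
    pairwise_rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ma, mb = groups == a, groups == b
            res = logrank_test(t[ma], t[mb], e[ma], e[mb])
            pairwise_rows.append(
                {"group_a": a, "group_b": b, "chi2": float(res.test_statistic), "p": float(res.p_value)}
            )
    pairwise = pd.DataFrame(pairwise_rows)
    if len(pairwise):
        pairwise["q"] = bh_adjust(pairwise["p"]).to_numpy()
    overall = None
    if len(levels) >= 2:
        res = multivariate_logrank_test(t[groups.notna()], groups.dropna(), e[groups.notna()])
        overall = {"chi2": float(res.test_statistic), "df": len(levels) - 1, "p": float(res.p_value)}
    return {"km": curves, "pairwise": pairwise, "overall": overall}


def cox_fit(
    times: pd.Series,
    events: pd.Series,
    covariates: pd.DataFrame,
    check_ph: bool = True,
    horizon: float = FIVE_YEARS,
) -> dict:
    """Cox proportional-hazards fit (Efron tie handling) with Wald CIs and an
    optional scaled-Schoenfeld PH diagnostic."""
    const = [c for c in covariates.columns if covariates[c].nunique(dropna=True) <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    if int(events.sum()) < covariates.shape[1]:
        raise ValueError("fewer events than covariates")
    t, e = truncate_survival(times, events, horizon)
    df = covariates.astype(float).copy()
    df["time"] = t
    df["event"] = e
    separation_flag = False
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        # near-complete separation: refit with a small ridge penalty and flag
        separation_flag = True
        cph = CoxPHFitter(penalizer=0.1)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            raise ConvergenceError(f"Cox fit failed even with ridge penalty: {err}") from err
    summary = cph.summary[["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]].rename(
        columns={
            "coef": "beta",
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lower",
            "exp(coef) upper 95%": "hr_upper",
            "p": "p_wald",
        }
    )
    ph = None
    if check_ph and e.sum() > 0:
        res = proportional_hazard_test(cph, df, time_transform="rank")
        ph = res.summary["p"]
    return {"model": cph, "summary": summary, "ph_test": ph, "separation_flag": separation_flag}


def contingency_stats(table: ContingencyTable, test: str = "chi2") -> dict:
    """Pearson chi-squared (no continuity correction) or, for 2x2 tables,
    Fisher's exact test with the conditional-MLE odds ratio."""
    counts = table.counts.to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    if test == "chi2":
        chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
        return {"statistic": float(chi2), "p": float(p), "df": int(dof)}
    if test == "fisher2x2":
        if counts.shape != (2, 2):
            raise ValueError("Fisher's exact test implemented for 2x2 tables only")
        _, p = sps.fisher_exact(counts)
        or_res = sps.contingency.odds_ratio(counts, kind="conditional")
        return {"statistic": float(or_res.statistic), "p": float(p), "odds_ratio": float(or_res.statistic)}
    raise ValueError(f"unknown test {test!r}")


def lms1_switch_sensitivity(
    labels: pd.Series,
    annot: CohortAnnotation,
    times: pd.Series,
    events: pd.Series,
    discovery_label: pd.Series,
    horizon: float = FIVE_YEARS,
) -> dict:
    """Stability of the subtype-1 hazard ratio under label switching.

    Patients with inter-metastatic LMS1 heterogeneity (some but not all
    lesion calls LMS1) are assigned to the LMS1 arm in fit (a) and to the
    LMS2-5 arm in fit (b); everyone else keeps the patient-level discovery
    label. Returns both fits and the absolute HR difference.
    """
    report = heterogeneity_report(labels, annot)
    tab = annot.table[annot.table["tissue"] == "tumor"]
    het_patients = []
    for patient, row in report.per_patient.iterrows():
        calls = set(row["calls"])
        if "LMS1" in calls and len(calls) > 1:
            het_patients.append(patient)

    base = (discovery_label == "LMS1").astype(int)  # per patient
    fits = {}
    for scenario, as_lms1 in (("heterogeneous_as_lms1", True), ("heterogeneous_as_rest", False)):
        cov = base.copy()
        for p in het_patients:
            if p in cov.index:
                cov[p] = 1 if as_lms1 else 0
        fit = cox_fit(times, events, pd.DataFrame({"lms1": cov}), check_ph=False, horizon=horizon)
        fits[scenario] = fit
    hr_a = float(fits["heterogeneous_as_lms1"]["summary"].loc["lms1", "hr"])
    hr_b = float(fits["heterogeneous_as_rest"]["summary"].loc["lms1", "hr"])
    return {
        "fits": fits,
        "hr_as_lms1": hr_a,
        "hr_as_rest": hr_b,
        "hr_abs_difference": abs(hr_a - hr_b),
        "n_heterogeneous": len(het_patients),
        "note": "no heterogeneous patients; fits identical" if not het_patients else "",
    }
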