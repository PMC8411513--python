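"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator plants a rank-K linear-scale signal S = W_true @ H_true whose
columns are subtype prototypes: each subtype elevates its own marker-gene
block by a configurable fold, and the last subtype additionally carries a
mesenchymal/stromal block so that the epithelial-versus-mesenchymal axis is
the primary source of variation, as in resected liver-metastasis cohorts.
Hepatocyte contamination is modelled as a per-sample convex mixture with a
liver profile on the linear scale, survival as patient-level exponential
hazards with an elevated hazard for subtype-1 patients, and mutation flags
are drawn with subtype-specific odds multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import CohortAnnotation, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_expression",
    "apply_liver_contamination",
    "generate_clinical",
    "generate_genesets",
    "generate_cohort",
]

#: sample-level subtype prevalences of the discovery cohort (30/17/32/50/40 of 169)
DEFAULT_PREVALENCES = (30 / 169, 17 / 169, 32 / 169, 50 / 169, 40 / 169)

#: per-subtype odds multipliers for mutation flags: gene -> (base_prob, {subtype: OR})
DEFAULT_MUTATION_MODEL: dict[str, tuple[float, dict[int, float]]] = {
    "mut_kras": (0.35, {1: 3.9}),
    "mut_nras": (0.05, {}),
    "mut_braf_v600e": (0.04, {}),
    "mut_tp53": (0.75, {5: 0.2}),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the discovery series."""

    n_patients: int = 171
    lesions_per_patient: tuple[str, float, int] = ("truncated_geometric", 0.72, 8)
    n_genes: int = 5000
    n_template_markers_per_subtype: int = 100
    K_true: int = 5
    subtype_prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    noise_sd: float = 0.3
    #: Beta(a, b) parameters of the per-sample liver fraction; None disables mixing
    contamination_alpha: tuple[float, float] | None = (2.0, 5.0)
    heterogeneity_prob: float | tuple[float, ...] = 0.5
    hr_lms1: float = 2.2
    baseline_median_survival_months: float = 45.0
    censor_rate: float = 0.4
    mutation_model: Mapping[str, tuple[float, dict[int, float]]] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_MODEL)
    )
    marker_fold: float = 4.0
    #: fold for the mesenchymal subtype's blocks; larger than marker_fold so
    #: the epithelial-versus-mesenchymal contrast is the primary axis
    mesenchymal_fold: float = 8.0
    #: per-sample admixture of a second subtype's prototype, U(0, admixture_max);
    #: models continuous within-subtype variation / intra-tumor mixtures
    admixture_max: float = 0.3
    n_liver_genes: int = 157
    mesenchymal_extra_genes: int = 14
    n_normal_liver: int = 19
    multiregion_prob: float = 0.08
    neoadjuvant_base_prob: float = 0.65
    neoadjuvant_mesenchymal_or: float = 3.0
    msi_prob: float = 1 / 171
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0 or self.K_true <= 0:
            raise ValueError("counts must be positive")
        prev = np.asarray(self.subtype_prevalences, dtype=float)
        if len(prev) != self.K_true:
            raise ValueError("subtype_prevalences must have K_true entries")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {prev.sum()}")
        if self.n_patients < self.K_true:
            raise ValueError("need at least one patient per planted subtype")
        n_marker = self.n_template_markers_per_subtype * self.K_true + self.mesenchymal_extra_genes
        if n_marker + self.n_liver_genes > self.n_genes:
            raise ValueError("marker + liver blocks exceed n_genes")
        if self.contamination_alpha is not None:
            a, b = self.contamination_alpha
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        het = np.atleast_1d(np.asarray(self.heterogeneity_prob, dtype=float))
        if ((het < 0) | (het > 1)).any():
            raise ValueError("heterogeneity_prob must be in [0, 1]")

    def het_probs(self) -> np.ndarray:
        het = np.atleast_1d(np.asarray(self.heterogeneity_prob, dtype=float))
        if het.size == 1:
            het = np.repeat(het, self.K_true)
        if het.size != self.K_true:
            raise ValueError("heterogeneity_prob must be scalar or length K_true")
        return het


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    subtype_per_lesion: dict[str, int]           # patient_lesion key -> subtype (1-based)
    subtype_per_sample: pd.Series                # tumor sample -> subtype
    alpha_per_sample: pd.Series                  # tumor sample -> liver fraction
    W_true: pd.DataFrame                         # genes x K, linear scale
    H_true: pd.DataFrame                         # K x tumor samples, one-hot
    liver_profile: pd.Series                     # linear-scale hepatocyte profile
    marker_genes: dict[int, list[str]]           # subtype -> marker symbols
    liver_genes: list[str]
    mesenchymal_extra: list[str]

    def template_genes(self) -> list[str]:
        out: list[str] = []
        for k in sorted(self.marker_genes):
            out.extend(self.marker_genes[k])
        out.extend(self.mesenchymal_extra)
        return out


def _draw_lesion_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    kind, p, maxn = cfg.lesions_per_patient
    if kind != "truncated_geometric":
        raise ValueError(f"unknown lesion-count distribution {kind!r}")
    counts = rng.geometric(p, size=cfg.n_patients)
    return np.minimum(counts, maxn)


def _plan_cohort(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign patients, lesions, regions and planted subtypes."""
    lesion_counts = _draw_lesion_counts(cfg, rng)
    prev = np.asarray(cfg.subtype_prevalences, dtype=float)
    het = cfg.het_probs()
    patient_subtype = rng.choice(np.arange(1, cfg.K_true + 1), size=cfg.n_patients, p=prev)
    rows = []
    subtype_per_lesion: dict[str, int] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        base = int(patient_subtype[i])
        for j in range(int(lesion_counts[i])):
            lid = f"L{j + 1}"
            sub = base
            if j > 0 and rng.random() < het[base - 1]:
                others = [k for k in range(1, cfg.K_true + 1) if k != base]
                sub = int(rng.choice(others))
            subtype_per_lesion[f"{pid}:{lid}"] = sub
            n_regions = 1
            if rng.random() < cfg.multiregion_prob:
                n_regions = int(rng.integers(2, 5))
            for r in range(n_regions):
                rows.append((f"{pid}_{lid}_R{r + 1}", pid, lid, f"R{r + 1}", sub))
    samples = pd.DataFrame(rows, columns=["sample_id", "patient_id", "lesion_id", "region_id", "subtype"])
    return samples, subtype_per_lesion


def _build_profiles(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene symbols, planted basis W_true (linear scale), and liver profile."""
    K = cfg.K_true
    m = cfg.n_template_markers_per_subtype
    liver_genes = [f"LIVGENE{i + 1:04d}" for i in range(cfg.n_liver_genes)]
    marker_genes = {k: [f"S{k}MARK{i + 1:04d}" for i in range(m)] for k in range(1, K + 1)}
    mes_extra = [f"MESX{i + 1:03d}" for i in range(cfg.mesenchymal_extra_genes)]
    n_decoy = cfg.n_genes - cfg.n_liver_genes - K * m - len(mes_extra)
    decoys = [f"BG{i + 1:05d}" for i in range(n_decoy)]
    genes = liver_genes + [g for k in range(1, K + 1) for g in marker_genes[k]] + mes_extra + decoys

    base = np.exp2(rng.normal(5.0, 1.0, size=len(genes)))
    gidx = pd.Index(genes)
    W = np.tile(base[:, None], (1, K))
    # liver rows: near-zero tumor signal
    W[: cfg.n_liver_genes, :] = 0.5
    pos = cfg.n_liver_genes
    for k in range(1, K + 1):
        fold = cfg.mesenchymal_fold if k == K else cfg.marker_fold
        W[pos : pos + m, k - 1] *= fold
        pos += m
    # mesenchymal/stromal block on the last subtype
    W[pos : pos + len(mes_extra), K - 1] *= cfg.mesenchymal_fold
    liver = pd.Series(0.25 * base, index=gidx)
    liver.iloc[: cfg.n_liver_genes] = np.exp2(rng.normal(10.0, 0.5, size=cfg.n_liver_genes))
    W_true = pd.DataFrame(W, index=gidx, columns=[f"subtype{k}" for k in range(1, K + 1)])
    return W_true, liver, marker_genes, liver_genes, mes_extra


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CohortAnnotation, SyntheticTruth]:
    """Generate the uncontaminated cohort: expression, annotation skeleton, truth.

    Tumor expression is log2(S + 1) + N(0, noise_sd) with S = W_true @ H_true;
    adjacent normal-liver samples follow the liver profile. Contamination
    fractions are drawn here (stored in the truth) but applied separately by
    :func:`apply_liver_contamination` so the identity alpha=0 case is explicit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples, subtype_per_lesion = _plan_cohort(config, rng)
    W_true, liver, marker_genes, liver_genes, mes_extra = _build_profiles(config, rng)

    sid = samples["sample_id"].tolist()
    sub = samples["subtype"].to_numpy()
    H = np.zeros((config.K_true, len(sid)))
    H[sub - 1, np.arange(len(sid))] = 1.0
    if config.admixture_max > 0 and config.K_true > 1:
        # blend in a second subtype per sample: continuous within-subtype
        # variation, keeping the planted subtype dominant
        mix = rng.uniform(0.0, config.admixture_max, size=len(sid))
        second = (sub - 1 + rng.integers(1, config.K_true, size=len(sid))) % config.K_true
        H[sub - 1, np.arange(len(sid))] = 1.0 - mix
        H[second, np.arange(len(sid))] += mix
    S = W_true.to_numpy() @ H
    X = np.log2(S + 1.0)
    if config.noise_sd > 0:
        X = X + rng.normal(0.0, config.noise_sd, size=X.shape)

    # adjacent normal-liver samples from the first n_normal_liver patients
    n_norm = min(config.n_normal_liver, config.n_patients)
    norm_ids = [f"P{i + 1:03d}_N" for i in range(n_norm)]
    liver_log = np.log2(liver.to_numpy()[:, None] + 1.0)
    N = np.tile(liver_log, (1, n_norm))
    if config.noise_sd > 0:
        N = N + rng.normal(0.0, config.noise_sd, size=N.shape)

    data = pd.DataFrame(
        np.hstack([X, N]), index=W_true.index, columns=sid + norm_ids
    )
    expr = ExpressionMatrix(data, scale="log2")

    if config.contamination_alpha is None:
        alphas = pd.Series(0.0, index=sid)
    else:
        a, b = config.contamination_alpha
        alphas = pd.Series(rng.beta(a, b, size=len(sid)), index=sid)

    annot_rows = samples.drop(columns="subtype").copy()
    annot_rows["tissue"] = "tumor"
    annot_rows["resection_round"] = 1
    norm_rows = pd.DataFrame(
        {
            "sample_id": norm_ids,
            "patient_id": [f"P{i + 1:03d}" for i in range(n_norm)],
            "lesion_id": pd.NA,
            "region_id": pd.NA,
            "tissue": "normal_liver",
            "resection_round": pd.NA,
        }
    )
    annot = pd.concat([annot_rows, norm_rows], ignore_index=True).set_index("sample_id")
    annotation = CohortAnnotation(annot)

    truth = SyntheticTruth(
        subtype_per_lesion=subtype_per_lesion,
        subtype_per_sample=pd.Series(sub, index=sid, name="subtype"),
        alpha_per_sample=alphas,
        W_true=W_true,
        H_true=pd.DataFrame(H, index=W_true.columns, columns=sid),
        liver_profile=liver,
        marker_genes=marker_genes,
        liver_genes=liver_genes,
        mesenchymal_extra=mes_extra,
    )
    return expr, annotation, truth


def apply_liver_contamination(
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    alphas: pd.Series | None = None,
) -> ExpressionMatrix:
    """Mix each tumor sample with the liver profile on the linear scale.

    Per sample s: x' = log2((1 - a_s) * 2^x + a_s * 2^liver). Samples absent
    from ``alphas`` (e.g. normal liver) are left untouched.
    """
    if alphas is None:
        alphas = truth.alpha_per_sample
    if ((alphas < 0) | (alphas > 1)).any():
        raise ValueError("contamination fractions must be in [0, 1]")
    if expr.scale != "log2":
        raise ValueError("expected a log2-scale matrix")
    liver_lin = truth.liver_profile.reindex(expr.data.index)
    if liver_lin.isna().any():
        raise ValueError("liver profile does not cover all matrix genes")
    out = expr.data.copy()
    cols = [s for s in expr.samples if s in alphas.index]
    a = alphas[cols].to_numpy()
    lin = np.exp2(out[cols].to_numpy())
    mixed = (1.0 - a)[None, :] * lin + a[None, :] * liver_lin.to_numpy()[:, None]
    out[cols] = np.log2(mixed)
    return ExpressionMatrix(out, scale="log2")


def _censor_horizon(rate: float, lam: float) -> float:
    """c_max of U(0, c_max) censoring with expected censored fraction = rate."""
    # P(C < T) = (1 - exp(-lam * c)) / (lam * c), decreasing from 1 to 0 in c
    f = lambda c: (1.0 - np.exp(-lam * c)) / (lam * c) - rate
    return brentq(f, 1e-9, 1e7)


def generate_clinical(
    truth: SyntheticTruth,
    config: SimulationConfig,
    annotation: CohortAnnotation,
    rng: np.random.Generator | None = None,
) -> CohortAnnotation:
    """Attach survival, mutation, MSI and treatment fields to the annotation.

    One patient-level survival record (replicated across the patient's
    samples): exponential event time with hazard multiplied by ``hr_lms1``
    when any lesion is subtype 1, independent uniform censoring calibrated to
    ``censor_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tab = annotation.table.copy()
    tumor = tab[tab["tissue"] == "tumor"]
    patients = sorted(tumor["patient_id"].unique())
    has_lms1 = {
        p: any(
            truth.subtype_per_lesion[k] == 1
            for k in truth.subtype_per_lesion
            if k.startswith(p + ":")
        )
        for p in patients
    }
    # dominant subtype of the patient (first lesion) for the mutation model
    first_subtype = {
        p: truth.subtype_per_lesion[min(k for k in truth.subtype_per_lesion if k.startswith(p + ":"))]
        for p in patients
    }
    lam0 = np.log(2.0) / config.baseline_median_survival_months
    all_censored = config.censor_rate >= 1.0
    if not all_censored and config.censor_rate > 0:
        cmax = _censor_horizon(config.censor_rate, lam0)

    records: dict[str, dict] = {}
    for p in patients:
        lam = lam0 * (config.hr_lms1 if has_lms1[p] else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if all_censored:
            time, event = rng.uniform(0.0, 2.0 * config.baseline_median_survival_months), 0
        elif config.censor_rate > 0:
            c = rng.uniform(0.0, cmax)
            time, event = (t_event, 1) if t_event <= c else (c, 0)
        else:
            time, event = t_event, 1
        css_event = event if (event and rng.random() < 0.85) else 0
        k = first_subtype[p]
        muts = {}
        for gene, (base, ors) in config.mutation_model.items():
            odds = base / (1.0 - base) * ors.get(k, 1.0)
            muts[gene] = bool(rng.random() < odds / (1.0 + odds))
        neo_odds = config.neoadjuvant_base_prob / (1.0 - config.neoadjuvant_base_prob)
        if k == config.K_true:
            neo_odds *= config.neoadjuvant_mesenchymal_or
        records[p] = {
            "os_time_months": time,
            "os_event": event,
            "css_time_months": time,
            "css_event": css_event,
            "neoadjuvant": bool(rng.random() < neo_odds / (1.0 + neo_odds)),
            "msi": "MSI" if rng.random() < config.msi_prob else "MSS",
            "resection": rng.choice(["R0", "R1", "R2"], p=[0.42, 0.53, 0.05]),
            "extra_hepatic": bool(rng.random() < 0.23),
            **muts,
        }
    cols = list(next(iter(records.values())))
    for col in cols:
        tab[col] = [
            records[tab.loc[s, "patient_id"]][col] if tab.loc[s, "tissue"] == "tumor" else pd.NA
            for s in tab.index
        ]
    for col in ("os_time_months", "css_time_months"):
        tab[col] = pd.to_numeric(tab[col], errors="coerce")
    for col in ("os_event", "css_event"):
        tab[col] = pd.to_numeric(tab[col], errors="coerce").astype("Int64")
    for col in ("neoadjuvant", "extra_hepatic", "mut_kras", "mut_nras", "mut_braf_v600e", "mut_tp53"):
        if col in tab.columns:
            tab[col] = tab[col].astype("boolean")
    return CohortAnnotation(tab)


def generate_genesets(
    truth: SyntheticTruth,
    n_decoys: int = 10,
    decoy_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Signature stand-ins: the planted liver set, per-subtype marker sets,
    canonical signature aliases (5-subtype cohorts), and random decoy sets."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {"LIVER_ENRICHED": list(truth.liver_genes)}
    desc = {"LIVER_ENRICHED": "planted hepatocyte-enriched genes"}
    for k, genes in truth.marker_genes.items():
        sets[f"SUBTYPE{k}_MARKERS"] = list(genes)
        desc[f"SUBTYPE{k}_MARKERS"] = f"planted subtype-{k} marker block"
    K = max(truth.marker_genes)
    if K == 5:
        sets["SECRETORY_MSI"] = list(truth.marker_genes[1])
        sets["STEM"] = list(truth.marker_genes[2])
        sets["ENTEROCYTE"] = list(truth.marker_genes[4])
        sets["MESENCHYMAL"] = list(truth.marker_genes[5]) + list(truth.mesenchymal_extra)
        sets["EPITHELIAL"] = [g for k in (1, 2, 3, 4) for g in truth.marker_genes[k]]
        desc.update(
            {
                "SECRETORY_MSI": "secretory progenitor / MSI-like signature stand-in",
                "STEM": "LGR5+ stem signature stand-in",
                "ENTEROCYTE": "absorptive enterocyte signature stand-in",
                "MESENCHYMAL": "mesenchymal/stromal signature stand-in",
                "EPITHELIAL": "pooled epithelial marker blocks",
            }
        )
    non_marker = [g for g in truth.W_true.index if g.startswith("BG")]
    for i in range(n_decoys):
        name = f"DECOY{i + 1:02d}"
        sets[name] = list(rng.choice(non_marker, size=min(decoy_size, len(non_marker)), replace=False))
        desc[name] = "random background genes"
    return GeneSetCollection(sets, desc)


def generate_cohort(config: SimulationConfig):
    """Convenience wrapper: expression (with contamination applied), full
    clinical annotation, truth, and the signature collection."""
    expr, annot, truth = generate_expression(config)
    expr = apply_liver_contamination(expr, truth)
    annot = generate_clinical(truth, config, annot)
    sets = generate_genesets(truth, seed=config.seed + 2)
    return expr, annot, truth, sets
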