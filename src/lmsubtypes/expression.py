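"""Sample-level statistics and the template-gene selection chain.

Covers PCA on top-SD genes, the empirical-Bayes moderated t-test with
Benjamini-Hochberg FDR control, the two-step template filter (up in tumors,
then high cross-tumor SD), the single-sample liver score, per-sample
standardization, and the one-random-tumor-per-patient subsetting used to keep
discovery samples independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datamodel import CohortAnnotation, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("lmsubtypes")

__all__ = [
    "DEResult",
    "TemplateSelection",
    "pca_scores",
    "moderated_t_test",
    "bh_adjust",
    "select_template_genes",
    "liver_score",
    "standardize_samples",
    "select_one_sample_per_patient",
]


@dataclass
class DEResult:
    """Per-gene differential-expression statistics (group1 minus group2)."""

    table: pd.DataFrame  # log2_fc, mean_expr, t_ordinary, t_moderated, p, q, df_residual, s2_gene, s2_posterior
    prior_df: float      # d0 from the scaled-F moment fit (may be inf)
    prior_var: float     # s0^2

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class TemplateSelection:
    upregulated_genes: list[str]
    template_genes: list[str]
    fc_min: float
    fdr_max: float
    sd_min: float
    n_input: int

    @property
    def n_upregulated(self) -> int:
        return len(self.upregulated_genes)

    @property
    def n_template(self) -> int:
        return len(self.template_genes)


def pca_scores(expr: ExpressionMatrix, n_top: int = 1000, n_components: int | None = None):
    """PCA of samples on the ``n_top`` highest-SD genes.

    The matrix is gene-centered (not gene-scaled). Each component's loading
    vector is oriented so its entries sum to a non-negative value, which fixes
    the otherwise arbitrary sign. Returns (scores, variance_fractions) with
    scores indexed by sample.
    """
    if expr.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_top > expr.n_genes:
        n_top = expr.n_genes
    sd = expr.data.std(axis=1, ddof=1)
    if float(sd.max()) == 0.0:
        raise ValueError("constant matrix: zero variance in every gene")
    top = sd.sort_values(ascending=False, kind="stable").index[:n_top]
    X = expr.data.loc[top].to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if n_components is None:
        n_components = len(s)
    flip = np.where(vt.sum(axis=1) < 0, -1.0, 1.0)
    scores = (u * s) * flip[None, :]
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(len(s))]
    scores_df = pd.DataFrame(scores[:, :n_components], index=expr.samples, columns=cols[:n_components])
    return scores_df, pd.Series(frac[:n_components], index=cols[:n_components])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match sample variances to a scaled F: s2 ~ s0^2 * F(df, d0).

    Closed-form empirical-Bayes hyperparameter estimator on the log scale
    using digamma/trigamma identities; returns (d0, s0^2), d0 may be inf.
    """
    med = np.median(s2)
    if med > 0:
        s2 = np.maximum(s2, 1e-5 * med)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) if n > 1 else 0.0
    rhs = evar - polygamma(1, df / 2.0)
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(s2.mean())
    return d0, s0_2


def moderated_t_test(
    expr: ExpressionMatrix,
    group: pd.Series,
    prior_df: float | None = None,
) -> DEResult:
    """Unpaired two-group moderated t-test with empirical-Bayes shrinkage.

    ``group`` maps each sample to one of exactly two labels; the contrast is
    (second-level mean) - (first-level mean) with levels sorted, unless the
    labels are booleans, in which case True - False. Per gene the pooled
    variance s2_g (df = n1 + n2 - 2) is shrunk towards the fitted prior:
    s2_post = (d0 * s0^2 + df * s2_g) / (d0 + df); the moderated t has
    d0 + df degrees of freedom. ``prior_df`` overrides the fitted d0
    (0 disables moderation, inf gives pure fold-change ranking).
    """
    group = group.reindex(expr.samples)
    if group.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    lo, hi = levels
    idx_hi = group[group == hi].index.tolist()
    idx_lo = group[group == lo].index.tolist()
    n1, n2 = len(idx_hi), len(idx_lo)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("need at least 3 samples for a pooled-variance test")

    X1 = expr.data[idx_hi].to_numpy()
    X2 = expr.data[idx_lo].to_numpy()
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    lfc = m1 - m2
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if (s2 <= 0).any():
        warnings.warn("genes with zero residual variance; clamping to machine epsilon")
        s2 = np.maximum(s2, np.finfo(float).eps)

    if prior_df is None:
        d0, s0_2 = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_f_dist(s2, df_resid)
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_ord = lfc / (np.sqrt(s2) * se_factor)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = float(expr.n_genes * df_resid)  # pooled-df cap
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        # total df capped at the pooled residual df across genes
        df_total = min(d0 + df_resid, expr.n_genes * df_resid)
    t_mod = lfc / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = bh_adjust(pd.Series(p, index=expr.genes)).to_numpy()
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "mean_expr": (X1.sum(axis=1) + X2.sum(axis=1)) / (n1 + n2),
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p": p,
            "q": q,
            "df_residual": float(df_resid),
            "df_total": float(df_total),
            "s2_gene": s2,
            "s2_posterior": s2_post,
        },
        index=expr.genes,
    )
    return DEResult(table=table, prior_df=d0, prior_var=s0_2)


def bh_adjust(p) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order preserved."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    index = p.index if isinstance(p, pd.Series) else None
    return pd.Series(q, index=index)


def select_template_genes(
    expr_tumor: ExpressionMatrix,
    expr_normal: ExpressionMatrix,
    fc_min: float = 0.0,
    fdr_max: float = 0.05,
    sd_min: float = 0.8,
) -> TemplateSelection:
    """Two-step template filter.

    Step (i): genes upregulated in tumors versus normal liver (unpaired
    moderated t; log2 FC > fc_min and BH q <= fdr_max). Step (ii): among
    those, genes with cross-sample SD over the tumor samples > sd_min. The
    tumor matrix should already be the one-sample-per-patient subset when
    discovery-grade independence is wanted.
    """
    common = [g for g in expr_tumor.genes if g in set(expr_normal.genes)]
    if not common:
        raise ValueError("tumor and normal matrices share no genes")
    tum = expr_tumor.subset_genes(common)
    nor = expr_normal.subset_genes(common)
    merged = ExpressionMatrix(pd.concat([tum.data, nor.data], axis=1), scale="log2")
    group = pd.Series(
        ["tumor"] * tum.n_samples + ["normal"] * nor.n_samples, index=merged.samples
    )
    de = moderated_t_test(merged, group)  # tumor - normal (t > n alphabetically)
    up = de.table[(de.table["log2_fc"] > fc_min) & (de.table["q"] <= fdr_max)].index.tolist()
    if not up:
        raise ValueError("empty selection after step i (upregulation filter)")
    logger.info("template step i: %d of %d genes upregulated", len(up), len(common))
    sd = tum.data.loc[up].std(axis=1, ddof=1)
    template = sd[sd > sd_min].index.tolist()
    if not template:
        raise ValueError("empty selection after step ii (SD filter)")
    logger.info("template step ii: %d genes with SD > %.2f", len(template), sd_min)
    return TemplateSelection(
        upregulated_genes=up,
        template_genes=template,
        fc_min=fc_min,
        fdr_max=fdr_max,
        sd_min=sd_min,
        n_input=len(common),
    )


def liver_score(expr: ExpressionMatrix, liver_set: GeneSetCollection | list[str]) -> pd.Series:
    """Single-sample liver score: the GSVA-style enrichment score of the
    liver-enriched gene set; a proxy for hepatocyte content in [-1, 1]."""
    from .enrichment import gsva_scores  # local import to avoid a cycle

    if isinstance(liver_set, GeneSetCollection):
        genes = liver_set["LIVER_ENRICHED"] if "LIVER_ENRICHED" in liver_set else liver_set[liver_set.names()[0]]
    else:
        genes = list(liver_set)
    collection = GeneSetCollection({"LIVER": genes})
    table = gsva_scores(expr, collection)
    return table["LIVER"]


def standardize_samples(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each sample column by its own mean and SD over genes."""
    X = expr.data
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-SD samples: {zero.index.tolist()[:10]}")
    return ExpressionMatrix((X - mu) / sd, scale=expr.scale)


def select_one_sample_per_patient(annot: CohortAnnotation, seed: int) -> list[str]:
    """One uniformly random tumor sample per patient, deterministic per seed."""
    rng = np.random.default_rng(seed)
    tumor = annot.table[annot.table["tissue"] == "tumor"]
    chosen: list[str] = []
    for patient in sorted(tumor["patient_id"].unique()):
        samples = tumor.index[tumor["patient_id"] == patient].tolist()
        if not samples:
            warnings.warn(f"patient {patient} has no tumor samples; skipped")
            continue
        chosen.append(samples[int(rng.integers(len(samples)))])
    return chosen
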