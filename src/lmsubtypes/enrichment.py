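"""Gene-set machinery: single-sample enrichment scores and the
correlation-adjusted competitive gene-set test.

The single-sample scorer follows the CDF / weighted random-walk
construction used for microarray-scale continuous data: per gene a
cross-sample cumulative-density statistic (mid-rank ECDF by default, with a
Gaussian-kernel smoothed variant available), per sample a ranking of genes by
that relative-expression statistic, and per set a weighted
Kolmogorov-Smirnov-like walk whose signed extrema form the score. The
default keeps the scores exactly invariant under strictly increasing
per-gene transforms of the input.
The competitive test compares the mean moderated statistic of set genes
against the rest, inflating its variance by 1 + (m - 1) * rho_bar where
rho_bar is the estimated inter-gene correlation of the set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import ExpressionMatrix, GeneSetCollection
from .expression import DEResult, bh_adjust, moderated_t_test

__all__ = ["gsva_scores", "camera_style_test", "subtype_enrichment_profile"]


def _kernel_cdf(X: np.ndarray, kcdf: str = "ecdf") -> np.ndarray:
    """Per-gene cumulative-density statistic of each sample's value.

    ``ecdf`` (default): the mid-rank empirical CDF, exactly invariant under
    strictly increasing per-gene transforms. ``gaussian``: the smoothed
    Gaussian-kernel estimate z[i, j] = mean_k Phi((x[i, j] - x[i, k]) / h_i)
    with bandwidth h_i = sd_i / 4; smoother across near-ties but only
    affinely invariant.
    """
    if kcdf == "ecdf":
        Z = np.empty_like(X, dtype=float)
        n = X.shape[1]
        for i in range(X.shape[0]):
            Z[i] = stats.rankdata(X[i], method="average") / n
        return Z
    if kcdf == "gaussian":
        sd = X.std(axis=1, ddof=1)
        h = np.maximum(sd / 4.0, 1e-8)
        Z = np.empty_like(X, dtype=float)
        # gene-wise to bound memory at n_samples^2
        for i in range(X.shape[0]):
            d = (X[i][:, None] - X[i][None, :]) / h[i]
            Z[i] = stats.norm.cdf(d).mean(axis=1)
        return Z
    raise ValueError(f"unknown kcdf {kcdf!r}")


def _walk_scores(positions_in_set: np.ndarray, weights: np.ndarray, tau: float = 1.0) -> float:
    """Signed-extrema score of the weighted KS-like walk for one sample/set.

    ``positions_in_set``: boolean mask over the ranked gene list (rank order);
    ``weights``: rank weights aligned to the same order.
    """
    p = len(positions_in_set)
    m = int(positions_in_set.sum())
    w = np.abs(weights) ** tau
    denom_in = w[positions_in_set].sum()
    step = np.where(positions_in_set, w / max(denom_in, 1e-300), -1.0 / (p - m))
    walk = np.cumsum(step)
    max_pos = max(walk.max(), 0.0)
    max_neg = min(walk.min(), 0.0)
    return float(max_pos + max_neg)


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    kcdf: str = "ecdf",
) -> pd.DataFrame:
    """Single-sample enrichment scores (samples x sets), each in [-1, 1].

    With the default ``kcdf="ecdf"`` the scores are rank-based: any strictly
    increasing per-gene transformation of the expression values leaves them
    unchanged. ``kcdf="gaussian"`` swaps in the kernel-smoothed
    relative-expression statistic.
    """
    if expr.n_samples < 3:
        raise ValueError("single-sample scoring needs at least 3 samples")
    genes = expr.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    memberships = {}
    for name in sets.names():
        present = [g for g in sets[name] if g in gene_pos]
        if not present:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix")
        memberships[name] = np.array([gene_pos[g] for g in present])

    Z = _kernel_cdf(expr.values, kcdf=kcdf)
    p = len(genes)
    # per sample: order genes by decreasing relative expression; weight peaks
    # at both extremes of the ranking
    order = np.argsort(-Z, axis=0, kind="stable")  # genes ranked per sample
    ranks = np.empty_like(order)
    for j in range(Z.shape[1]):
        ranks[order[:, j], j] = np.arange(1, p + 1)
    weights = np.abs(p / 2.0 - ranks + 0.5)

    out = pd.DataFrame(index=expr.samples, columns=sets.names(), dtype=float)
    for name, idx in memberships.items():
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        for j, sample in enumerate(expr.samples):
            ranked_mask = mask[order[:, j]]
            ranked_w = weights[order[:, j], j]
            out.loc[sample, name] = _walk_scores(ranked_mask, ranked_w, tau=tau)
    return out


def camera_style_test(
    gene_stats: DEResult | pd.Series,
    sets: GeneSetCollection,
    expr: ExpressionMatrix,
    group: pd.Series,
    force_rho: float | None = None,
    allow_neg_cor: bool = False,
) -> pd.DataFrame:
    """Competitive gene-set test with a variance-inflation correction.

    Per set: delta = mean z of set genes minus mean z of the rest, where z is
    the normal-quantile transform of the moderated t. The variance of delta
    is inflated by VIF = 1 + (m - 1) * rho_bar, with rho_bar the mean pairwise
    cosine similarity of the group-centered residual vectors of the set
    genes. Negative correlation estimates are reset to zero
    (``allow_neg_cor=True`` keeps them, floored at -1/(m - 1)), so the VIF
    never deflates the variance on null noise. The two-sided p comes from a
    t reference with min(residual df, p - 2) degrees of freedom, which keeps
    the test calibrated at small sample sizes and tends to the normal
    approximation as the cohort grows. ``force_rho`` pins rho_bar (0
    recovers the unadjusted test). Returns a table with BH-adjusted q per
    set.
    """
    if isinstance(gene_stats, DEResult):
        t = gene_stats.table["t_moderated"]
        df_resid = float(gene_stats.table["df_residual"].iloc[0])
        df = float(gene_stats.table["df_total"].iloc[0])
        if df > 1e6:
            z = t.copy()
        else:
            # normal-quantile transform in log space so extreme statistics
            # keep their ordering instead of saturating to +/-inf
            logsf = stats.t.logsf(np.abs(t), df)
            z = pd.Series(np.sign(t) * -special.ndtri_exp(logsf), index=t.index)
    else:
        z = gene_stats.astype(float)
        df_resid = np.inf
    z = z.replace([np.inf, -np.inf], np.nan)
    z = z.fillna(z.mean())

    group = group.reindex(expr.samples)
    levels = sorted(group.dropna().unique())
    rows = []
    for name in sets.names():
        members = [g for g in sets[name] if g in z.index]
        m = len(members)
        if m < 2:
            warnings.warn(f"set {name!r} has < 2 genes after intersection; skipped")
            continue
        in_set = z.loc[members]
        out_set = z.drop(index=members)
        p_total = len(z)
        if len(out_set) == 0:
            # set = whole universe: the competitive contrast is identically 0
            rows.append(
                {
                    "set": name, "n_genes": m, "direction": "up", "delta": 0.0,
                    "rho": 0.0, "vif": 1.0, "z": 0.0, "p": 1.0,
                }
            )
            continue
        delta = float(in_set.mean() - out_set.mean())
        if force_rho is not None:
            rho = force_rho
        else:
            # residual vectors after removing group means; mean pairwise
            # cosine similarity of the unit-normalized residuals (the
            # residuals are already centered by the model fit, so no second
            # centering is applied)
            X = expr.data.loc[members].copy()
            for lev in levels:
                cols = group[group == lev].index
                X[cols] = X[cols].sub(X[cols].mean(axis=1), axis=0)
            R = X.to_numpy()
            norms = np.sqrt((R**2).sum(axis=1))
            ok = norms > 0
            U = R[ok] / norms[ok][:, None]
            m_eff = U.shape[0]
            if m_eff >= 2:
                s = U.sum(axis=0)
                rho = float((s @ s - m_eff) / (m_eff * (m_eff - 1)))
            else:
                rho = 0.0
        rho_used = max(rho, -1.0 / (m - 1)) if allow_neg_cor else max(rho, 0.0)
        vif = 1.0 + (m - 1) * rho_used
        # pooled within-group variance of the z statistics (between-group
        # component removed), as in the published two-sample formulation
        var_all = float(z.var(ddof=1))
        m2 = p_total - m
        sigma2 = ((p_total - 1) * var_all - delta**2 * m * m2 / p_total) / (p_total - 2)
        var_delta = sigma2 * (vif / m + 1.0 / m2)
        zstat = delta / np.sqrt(max(var_delta, 1e-300))
        df_camera = min(df_resid, p_total - 2)
        if np.isinf(df_camera):
            pval = 2.0 * stats.norm.sf(abs(zstat))
        else:
            pval = 2.0 * stats.t.sf(abs(zstat), df_camera)
        rows.append(
            {
                "set": name,
                "n_genes": m,
                "direction": "up" if delta >= 0 else "down",
                "delta": delta,
                "rho": rho,
                "vif": vif,
                "z": zstat,
                "p": pval,
            }
        )
    if not rows:
        raise ValueError("no testable sets (all below minimum size)")
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"])
    return table


def subtype_enrichment_profile(
    expr: ExpressionMatrix,
    labels: pd.Series,
    sets: GeneSetCollection,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Signed significance matrix (subtypes x sets): each subtype versus all
    others, entries sign(delta) * -log10(q).

    The BH adjustment is applied jointly across the whole subtype x set
    matrix, so the profile controls the false discovery rate at the level it
    is read: any cell with |entry| >= -log10(0.05) is a discovery.
    """
    labels = labels.reindex(expr.samples).dropna()
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    p_rows: dict = {}
    sign_rows: dict = {}
    for sub in subtypes:
        n_sub = int((labels == sub).sum())
        if n_sub < min_samples:
            warnings.warn(f"subtype {sub!r} has < {min_samples} samples; skipped")
            continue
        group = (labels == sub).map({True: "this", False: "rest"})
        sub_expr = expr.subset_samples(labels.index.tolist())
        de = moderated_t_test(sub_expr, group)  # this - rest
        res = camera_style_test(de, sets, sub_expr, group)
        p_rows[sub] = res["p"]
        sign_rows[sub] = np.sign(res["delta"])
    p_mat = pd.DataFrame(p_rows).T
    sign_mat = pd.DataFrame(sign_rows).T
    flat = p_mat.to_numpy().ravel()
    ok = ~np.isnan(flat)
    q_flat = np.full_like(flat, np.nan)
    q_flat[ok] = bh_adjust(flat[ok]).to_numpy()
    q_mat = pd.DataFrame(q_flat.reshape(p_mat.shape), index=p_mat.index, columns=p_mat.columns)
    return sign_mat * (-np.log10(np.maximum(q_mat, 1e-300)))
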