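"""Supervised subtype prediction.

A random-forest multi-class model is trained on the discovery samples with a
positive consensus silhouette, with recursive feature elimination (RFE) over
the template genes: inside every resampling split the forest is refit, genes
are re-ranked by importance, and nested candidate subset sizes are scored on
the held-out fold, so feature selection never sees test data. A two-class
9-gene-style mini-classifier targets the clinically relevant subtype-1
versus rest distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .datamodel import ExpressionMatrix
from .expression import moderated_t_test

logger = logging.getLogger("lmsubtypes")

__all__ = [
    "SubtypeModel",
    "MiniClassifier",
    "train_lms_model",
    "predict_subtypes",
    "retrain_for_platform",
    "train_mini_classifier",
    "predict_mini",
    "concordance_report",
    "cohens_kappa",
]

#: nested candidate subset sizes for RFE (log-spaced; "all" appended at fit time)
RFE_SIZE_GRID = (8, 16, 32, 64, 128, 256)
N_TREES = 500


@dataclass
class SubtypeModel:
    classes: list[str]
    selected_genes: list[str]
    importances: pd.Series
    forest: RandomForestClassifier = field(repr=False)
    cv_scheme: str = "3x7-fold repeated CV"
    seed: int = 0
    cv_accuracy: float | None = None
    subset_accuracies: dict[int, float] | None = None


@dataclass
class MiniClassifier:
    gene_list: list[str]
    forest: RandomForestClassifier = field(repr=False)
    positive_class: str = "LMS1"
    seed: int = 0


def _rank_genes(X: np.ndarray, y: np.ndarray, genes: list[str], seed: int) -> list[str]:
    rf = RandomForestClassifier(n_estimators=N_TREES, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return [genes[i] for i in order]


def train_lms_model(
    expr: ExpressionMatrix,
    labels: pd.Series,
    silhouettes: pd.Series | None,
    template_genes: list[str],
    seed: int = 0,
    n_repeats: int = 3,
    n_folds: int = 7,
    size_grid: tuple[int, ...] = RFE_SIZE_GRID,
) -> SubtypeModel:
    """RFE-selected random-forest subtype model.

    Training samples are those with silhouette > 0 (pass ``silhouettes=None``
    to use all labelled samples). Subset sizes are evaluated by repeated
    stratified cross-validated accuracy with in-fold re-ranking; the best
    size is refit on the full training set.
    """
    labels = labels.dropna()
    if silhouettes is not None:
        keep = silhouettes.reindex(labels.index) > 0
        labels = labels[keep]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes in the training set")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"classes with < 2 training samples: {counts[counts < 2].index.tolist()}")
    missing = [g for g in template_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"template genes absent from matrix: {missing[:10]}")

    sub = expr.subset_genes(template_genes).subset_samples(labels.index.tolist())
    X = sub.data.to_numpy().T  # samples x genes
    y = labels.to_numpy()
    genes = list(template_genes)
    p = len(genes)
    sizes = sorted({s for s in size_grid if s < p} | {p})

    n_folds_eff = min(n_folds, int(counts.min()))
    cv = RepeatedStratifiedKFold(n_splits=n_folds_eff, n_repeats=n_repeats, random_state=seed)
    acc = {s: [] for s in sizes}
    for fold_i, (tr, te) in enumerate(cv.split(X, y)):
        ranked = _rank_genes(X[tr], y[tr], genes, seed=seed + 1000 + fold_i)
        col = {g: i for i, g in enumerate(genes)}
        for s in sizes:
            cols = [col[g] for g in ranked[:s]]
            rf = RandomForestClassifier(
                n_estimators=N_TREES, random_state=seed + 2000 + fold_i, n_jobs=1
            )
            rf.fit(X[tr][:, cols], y[tr])
            acc[s].append(float((rf.predict(X[te][:, cols]) == y[te]).mean()))
    mean_acc = {s: float(np.mean(v)) for s, v in acc.items()}
    best_size = max(sizes, key=lambda s: (round(mean_acc[s], 12), -s))
    logger.info("RFE subset accuracies: %s; best=%d", mean_acc, best_size)

    ranked_full = _rank_genes(X, y, genes, seed=seed + 3000)
    selected = ranked_full[:best_size]
    col = {g: i for i, g in enumerate(genes)}
    cols = [col[g] for g in selected]
    final = RandomForestClassifier(n_estimators=N_TREES, random_state=seed, n_jobs=1)
    final.fit(X[:, cols], y)
    imp = pd.Series(final.feature_importances_, index=selected).sort_values(ascending=False)
    return SubtypeModel(
        classes=list(final.classes_),
        selected_genes=selected,
        importances=imp,
        forest=final,
        seed=seed,
        cv_accuracy=mean_acc[best_size],
        subset_accuracies=mean_acc,
    )


def predict_subtypes(model: SubtypeModel, expr: ExpressionMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Apply a trained model; returns (labels, posteriors)."""
    missing = [g for g in model.selected_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"model genes absent from matrix: {missing[:10]}")
    X = expr.data.loc[model.selected_genes].to_numpy().T
    post = model.forest.predict_proba(X)
    posteriors = pd.DataFrame(post, index=expr.samples, columns=model.forest.classes_)
    labels = posteriors.idxmax(axis=1)
    labels.name = "subtype"
    return labels, posteriors


def retrain_for_platform(
    expr_train: ExpressionMatrix,
    labels: pd.Series,
    silhouettes: pd.Series | None,
    template_genes: list[str],
    available_genes: list[str],
    seed: int = 0,
    **kwargs,
) -> SubtypeModel:
    """Re-train on the template genes measured on a target platform.

    The target matrix must be sample-standardized before prediction (see
    :func:`lmsubtypes.expression.standardize_samples`).
    """
    avail = set(available_genes)
    overlap = [g for g in template_genes if g in avail]
    if not overlap:
        raise ValueError("no overlap between template genes and target platform")
    if len(overlap) < 10:
        raise ValueError(f"only {len(overlap)} template genes on target platform; too few")
    if len(overlap) < 0.5 * len(template_genes):
        logger.warning(
            "template overlap is only %d/%d genes", len(overlap), len(template_genes)
        )
    return train_lms_model(expr_train, labels, silhouettes, overlap, seed=seed, **kwargs)


def train_mini_classifier(
    expr: ExpressionMatrix,
    labels: pd.Series,
    seed: int = 0,
    positive_class: str = "LMS1",
    fdr_max: float = 0.05,
    lfc_min: float = 1.6,
    n_folds: int = 7,
) -> MiniClassifier:
    """Two-class mini-classifier (subtype 1 versus the rest).

    Candidate genes are those with BH q <= ``fdr_max`` and log2 fold-change
    >= ``lfc_min`` in the moderated-t comparison of the positive class
    against all other subtypes; the features-per-split parameter is tuned by
    stratified cross-validation.
    """
    labels = labels.dropna()
    is_pos = labels == positive_class
    if is_pos.sum() == 0 or (~is_pos).sum() == 0:
        raise ValueError(f"both {positive_class} and rest must be present")
    sub = expr.subset_samples(labels.index.tolist())
    group = is_pos.map({True: "z_pos", False: "a_rest"})  # z_pos sorts last -> pos minus rest
    de = moderated_t_test(sub, group)
    cand = de.table[(de.table["q"] <= fdr_max) & (de.table["log2_fc"] >= lfc_min)]
    if len(cand) == 0:
        raise ValueError(
            "no genes pass the mini-classifier thresholds; consider relaxing fdr_max/lfc_min"
        )
    genes = cand.sort_values("log2_fc", ascending=False).index.tolist()
    logger.info("mini-classifier candidate genes (n=%d): %s", len(genes), genes[:20])

    X = sub.data.loc[genes].to_numpy().T
    y = is_pos.to_numpy()
    p = len(genes)
    mtry_grid = sorted({max(1, int(np.sqrt(p) / 2)), max(1, int(np.sqrt(p))), min(p, int(2 * np.sqrt(p)) or 1)})
    n_folds_eff = min(n_folds, int(min(is_pos.sum(), (~is_pos).sum())))
    best_mtry, best_acc = mtry_grid[0], -1.0
    if n_folds_eff >= 2 and len(mtry_grid) > 1:
        cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
        for mtry in mtry_grid:
            accs = []
            for tr, te in cv.split(X, y):
                rf = RandomForestClassifier(
                    n_estimators=N_TREES, max_features=mtry, random_state=seed, n_jobs=1
                )
                rf.fit(X[tr], y[tr])
                accs.append(float((rf.predict(X[te]) == y[te]).mean()))
            a = float(np.mean(accs))
            if a > best_acc:
                best_acc, best_mtry = a, mtry
    final = RandomForestClassifier(
        n_estimators=N_TREES, max_features=best_mtry, random_state=seed, n_jobs=1
    )
    final.fit(X, y)
    return MiniClassifier(gene_list=genes, forest=final, positive_class=positive_class, seed=seed)


def predict_mini(mini: MiniClassifier, expr: ExpressionMatrix) -> pd.Series:
    """Binary calls; a single missing signature gene is imputed by its median
    expression across the prediction cohort."""
    present = [g for g in mini.gene_list if g in expr.data.index]
    missing = [g for g in mini.gene_list if g not in expr.data.index]
    if len(missing) >= 2:
        raise ValueError(f"{len(missing)} signature genes missing: {missing}")
    data = expr.data.reindex(mini.gene_list)
    if missing:
        cohort_median = float(np.median(expr.data.loc[present].to_numpy()))
        data.loc[missing[0]] = cohort_median
        logger.info("imputed %s by cohort median %.3f", missing[0], cohort_median)
    X = data.to_numpy().T
    calls = mini.forest.predict(X)
    rest = f"not-{mini.positive_class}"
    out = pd.Series(
        np.where(calls, mini.positive_class, rest), index=expr.samples, name="mini_call"
    )
    return out


def cohens_kappa(labels_a: pd.Series, labels_b: pd.Series) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa with an asymptotic 95% CI (shared sample index)."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("labelings share no samples")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    cats = sorted(set(a) | set(b))
    tab = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0).to_numpy()
    n = tab.sum()
    po = np.trace(tab) / n
    pe = float((tab.sum(axis=1) / n) @ (tab.sum(axis=0) / n))
    if pe == 1.0:
        return 1.0, (1.0, 1.0)
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    return float(kappa), (float(kappa - 1.96 * se), float(kappa + 1.96 * se))


def concordance_report(labels_a: pd.Series, labels_b: pd.Series) -> dict:
    """Confusion matrix (a = reference rows), per-class sensitivity,
    specificity and balanced accuracy, overall accuracy, and Cohen's kappa."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("labelings share no samples")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    cats = sorted(set(a) | set(b))
    conf = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    n = conf.to_numpy().sum()
    per_class = {}
    for c in cats:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        per_class[c] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "balanced_accuracy": float((sens + spec) / 2.0),
        }
    kappa, ci = cohens_kappa(a, b)
    return {
        "confusion": conf,
        "per_class": per_class,
        "accuracy": float((a == b).mean()),
        "balanced_accuracy": float(
            np.nanmean([v["balanced_accuracy"] for v in per_class.values()])
        ),
        "kappa": kappa,
        "kappa_ci": ci,
    }
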