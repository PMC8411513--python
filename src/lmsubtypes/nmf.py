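"""De novo subtype discovery by consensus non-negative matrix factorization.

The factorization minimizes the (generalized) Kullback-Leibler divergence
D(V || WH) with multiplicative updates, starting from random positive
matrices, on the linear-scale (2^x) expression of the template genes. Class
structure is summarized across random restarts by the consensus matrix of
co-clustering frequencies; rank quality is measured by the cophenetic
correlation of the consensus dendrogram and by silhouette widths on the
consensus distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .datamodel import ExpressionMatrix

__all__ = [
    "FactorizationResult",
    "ConsensusResult",
    "nmf_brunet",
    "consensus_cluster",
    "select_rank",
    "assign_subtype_names",
    "epithelial_mesenchymal_split",
]

_EPS = 1e-12


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    K: int
    divergence: float
    n_iter: int
    converged: bool
    run_seed: int
    divergence_trace: np.ndarray | None = None

    def hard_labels(self) -> np.ndarray:
        """Per-sample cluster = argmax metagene coefficient (1-based)."""
        return self.H.argmax(axis=0) + 1


@dataclass
class ConsensusResult:
    K: int
    consensus: pd.DataFrame           # samples x samples co-clustering frequency
    cophenetic: float
    silhouette: pd.Series             # per-sample width on consensus distance
    labels: pd.Series                 # final 1..K assignment
    n_runs: int
    linkage: np.ndarray = field(repr=False, default=None)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    return float(np.sum(V * np.log(np.maximum(V, _EPS) / WH) - V + WH))


def nmf_brunet(
    V: ExpressionMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol_checks: int = 40,
    check_every: int = 10,
    track_divergence: bool = False,
) -> FactorizationResult:
    """KL-divergence NMF with multiplicative updates and connectivity stopping.

    ``V`` must be non-negative (linear-scale expression; callers exponentiate
    log2 data first). Stops when the sample connectivity matrix (argmax of H)
    is unchanged for ``tol_checks`` consecutive checks spaced ``check_every``
    iterations apart, or at ``max_iter``.
    """
    A = V.values if isinstance(V, ExpressionMatrix) else np.asarray(V, dtype=float)
    if (A < 0).any():
        raise ValueError("NMF input must be non-negative (linear scale)")
    n, m = A.shape
    if K >= min(n, m):
        raise ValueError(f"rank K={K} must be < min(n_genes, n_samples)={min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = 2.0 * np.sqrt(max(A.mean(), _EPS) / K)
    W = rng.uniform(_EPS, 1.0, size=(n, K)) * scale
    H = rng.uniform(_EPS, 1.0, size=(K, m)) * scale

    trace = [] if track_divergence else None
    prev_labels = None
    stall = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H
        H *= (W.T @ (A / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= ((A / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if track_divergence:
            trace.append(_kl_divergence(A, W @ H))
        if it % check_every == 0:
            labels = H.argmax(axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stall += 1
                if stall >= tol_checks:
                    converged = True
                    break
            else:
                stall = 0
            prev_labels = labels
    return FactorizationResult(
        W=W,
        H=H,
        K=K,
        divergence=_kl_divergence(A, W @ H),
        n_iter=it,
        converged=converged,
        run_seed=seed,
        divergence_trace=np.asarray(trace) if track_divergence else None,
    )


def consensus_cluster(
    V: ExpressionMatrix,
    K: int,
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
) -> ConsensusResult:
    """Multi-restart NMF consensus clustering at rank K.

    Per restart the hard labels are the argmax over metagene coefficients;
    consensus[i, j] is the fraction of restarts assigning samples i and j to
    the same cluster. Final labels come from average-linkage hierarchical
    clustering of (1 - consensus) cut at K; the cophenetic coefficient is the
    Pearson correlation between consensus distances and the dendrogram's
    cophenetic distances.
    """
    if n_runs < 2:
        raise ValueError("consensus clustering needs at least 2 restarts")
    samples = V.samples
    m = len(samples)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    co = np.zeros((m, m))
    for run_seed in seeds:
        res = nmf_brunet(V, K, seed=int(run_seed), max_iter=max_iter)
        lab = res.hard_labels()
        co += (lab[:, None] == lab[None, :]).astype(float)
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    labels = fcluster(Z, t=K, criterion="maxclust")
    if condensed.std() == 0:  # degenerate: all distances equal
        coph = 1.0
    else:
        coph, _ = cophenet(Z, condensed)
    if len(np.unique(labels)) > 1:
        sil = silhouette_samples(dist, labels, metric="precomputed")
    else:
        sil = np.zeros(m)
    return ConsensusResult(
        K=K,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cophenetic=float(coph),
        silhouette=pd.Series(sil, index=samples),
        labels=pd.Series(labels, index=samples),
        n_runs=n_runs,
        linkage=Z,
    )


def select_rank(results: dict[int, ConsensusResult]) -> dict:
    """Summarize rank-quality metrics and flag candidate ranks.

    Returns a dict with the metric table (cophenetic and mean silhouette per
    K), the global cophenetic maximum, all local cophenetic maxima, and the
    recommended candidates (global maximum plus any local maximum at K >= 4,
    mirroring the convention of keeping both a coarse and a fine level). If
    the maximum sits at the K=2 boundary the result is flagged as showing no
    substructure. No automatic choice is made.
    """
    if len(results) < 2:
        raise ValueError("need at least two candidate ranks")
    ks = sorted(results)
    table = pd.DataFrame(
        {
            "cophenetic": [results[k].cophenetic for k in ks],
            "mean_silhouette": [float(results[k].silhouette.mean()) for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    coph = table["cophenetic"]
    local_maxima = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or coph.iloc[i] >= coph.iloc[i - 1]
        right_ok = i == len(ks) - 1 or coph.iloc[i] >= coph.iloc[i + 1]
        if left_ok and right_ok:
            local_maxima.append(k)
    global_max = int(coph.idxmax())
    candidates = sorted({global_max, *[k for k in local_maxima if k >= 4]})
    return {
        "table": table,
        "global_max": global_max,
        "local_maxima": local_maxima,
        "candidates": candidates,
        "no_substructure": global_max == ks[0],
    }


#: signature columns required to name a 5-cluster solution
_REQUIRED_SIGNATURES = ("MESENCHYMAL", "SECRETORY_MSI", "STEM", "ENTEROCYTE")


def assign_subtype_names(result: ConsensusResult, scores: pd.DataFrame) -> dict[int, str]:
    """Map consensus clusters at K=5 to LMS1..LMS5 by mean signature scores.

    The cluster with the highest mean mesenchymal score becomes LMS5; among
    the rest the highest mean secretory/MSI-like score becomes LMS1; the two
    next clusters are ordered LMS2 (stem), LMS4 (enterocyte); the leftover is
    LMS3. Ties break by larger cluster size, then lower cluster index. At
    K=2 only the epithelial/mesenchymal naming applies.
    """
    labels = result.labels
    clusters = sorted(labels.unique())
    missing = [s for s in ("MESENCHYMAL",) if s not in scores.columns]
    if missing:
        raise ValueError(f"missing required signature scores: {missing}")
    scores = scores.reindex(labels.index)

    def mean_score(sig: str) -> pd.Series:
        return pd.Series(
            {c: float(scores.loc[labels[labels == c].index, sig].mean()) for c in clusters}
        )

    sizes = labels.value_counts()

    def pick(candidates: list[int], sig: str) -> int:
        ms = mean_score(sig)
        best = sorted(
            candidates, key=lambda c: (-round(ms[c], 12), -sizes[c], c)
        )
        return best[0]

    if result.K == 2:
        mes = pick(clusters, "MESENCHYMAL")
        epi = next(c for c in clusters if c != mes)
        return {mes: "mesenchymal", epi: "epithelial"}

    missing = [s for s in _REQUIRED_SIGNATURES if s not in scores.columns]
    if missing:
        raise ValueError(f"missing required signature scores: {missing}")
    remaining = list(clusters)
    lms5 = pick(remaining, "MESENCHYMAL")
    remaining.remove(lms5)
    lms1 = pick(remaining, "SECRETORY_MSI")
    remaining.remove(lms1)
    lms2 = pick(remaining, "STEM")
    remaining.remove(lms2)
    lms4 = pick(remaining, "ENTEROCYTE")
    remaining.remove(lms4)
    (lms3,) = remaining
    return {lms1: "LMS1", lms2: "LMS2", lms3: "LMS3", lms4: "LMS4", lms5: "LMS5"}


def epithelial_mesenchymal_split(
    result_k2: ConsensusResult,
    result_k5: ConsensusResult,
    names_k2: dict[int, str],
    names_k5: dict[int, str],
) -> dict:
    """Concordance of the coarse epithelial/mesenchymal split with the
    5-cluster solution collapsed to LMS1-4 (epithelial) versus LMS5."""
    from .classify import cohens_kappa

    if set(result_k2.labels.index) != set(result_k5.labels.index):
        raise ValueError("the two factorizations cover different samples")
    a = result_k2.labels.map(names_k2)
    b = result_k5.labels.map(names_k5).map(
        lambda x: "mesenchymal" if x == "LMS5" else "epithelial"
    )
    b = b.reindex(a.index)
    agreement = float((a == b).mean())
    kappa, ci = cohens_kappa(a, b)
    return {"agreement": agreement, "kappa": kappa, "kappa_ci": ci}
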