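"""Signature evaluation: ROC/AUC, pre-ranked enrichment, set similarity.

AUC is computed with the rank (Mann-Whitney) formulation with midrank tie
handling, and its 95% confidence interval with the DeLong structural-
component variance estimator (the default of the standard R ROC tooling);
a bootstrap interval is available by flag.  The pre-ranked GSEA enrichment
score is the weighted Kolmogorov-Smirnov running-sum statistic: walking
down the ranked list, hits increment the sum proportionally to
|score|^weight, misses decrement it uniformly, and the ES is the maximal
absolute deviation with its sign retained.  Significance and the
normalized ES come from gene-label permutations (phenotype permutation is
undefined for pre-ranked input) with sign-stratified normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_core import GeneSignature

__all__ = [
    "ROCResult",
    "EnrichmentResult",
    "roc_auc",
    "rank_metric",
    "gsea_es",
    "set_similarity",
    "Dendrogram",
    "cluster_complete_euclidean",
]


@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_negative: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC from placement values."""
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # V10[i]: probability a random negative scores below positive i (ties half)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> ROCResult:
    """AUC with confidence interval and the full ROC curve.

    ``labels`` are boolean (or 0/1) with True marking the positive class;
    higher scores are taken to indicate the positive class.  AUC uses the
    midrank Mann-Whitney estimator; the CI is DeLong by default, bootstrap
    (stratified resampling) by flag; both are clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = _midrank(scores)
    auc = (ranks[labels].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)

    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if ci_method == "delong":
        var = _delong_variance(pos, neg, auc)
        half = z * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(pos.size, size=pos.size)]
            bn = neg[rng.integers(neg.size, size=neg.size)]
            r = _midrank(np.concatenate([bp, bn]))
            boot[b] = (r[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
                pos.size * neg.size
            )
        lo, hi = np.quantile(boot, [(1 - confidence) / 2, 0.5 + confidence / 2])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
    return ROCResult(
        auc=float(auc),
        ci=ci,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def rank_metric(contrast, metric: str = "wald") -> pd.Series:
    """Gene ranking scores from a contrast table, strongest first.

    ``wald`` ranks by the signed test statistic; ``logp_lfc`` by
    -log10(p) * log2FC.  Zero p-values are floored at the smallest positive
    representable float (flagged with a warning).  Ties are broken
    alphabetically by gene symbol, so the order is stable across runs.
    """
    table = contrast.table if hasattr(contrast, "table") else contrast
    if metric == "wald":
        score = table["stat"].astype(float)
    elif metric == "logp_lfc":
        p = table["p"].astype(float).to_numpy().copy()
        if (p == 0).any():
            import warnings

            tiny = np.finfo(float).tiny
            warnings.warn(f"{int((p == 0).sum())} zero p-value(s) floored at {tiny:g}")
            p[p == 0] = tiny
        score = pd.Series(-np.log10(p) * table["log2fc"].to_numpy(), index=table.index)
    else:
        raise ValueError(f"unknown rank metric {metric!r}")
    frame = pd.DataFrame(
        {"score": np.asarray(score), "symbol": np.asarray(score.index, dtype=object)}
    )
    frame = frame.sort_values(["score", "symbol"], ascending=[False, True])
    return pd.Series(frame["score"].to_numpy(), index=pd.Index(frame["symbol"]))


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    leading_edge: tuple[str, ...]
    n_permutations: int


def _running_sum_es(in_set: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """ES (max |deviation|, sign kept) and its position for one labelling."""
    nh = int(in_set.sum())
    n = in_set.size
    hit_w = np.where(in_set, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set).astype(float) / (n - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_es(
    ranked_scores: pd.Series,
    signature: GeneSignature,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Pre-ranked GSEA enrichment score with permutation significance.

    ``ranked_scores`` is the output of :func:`rank_metric` (genes in
    descending score order).  Hits step the running sum up by
    |score|^weight (normalized over hits), misses step it down uniformly;
    the ES is the extremal deviation.  The null permutes which positions
    are hits; NES divides ES by the mean same-sign permutation ES, and the
    p-value is the exceedance fraction within the matching sign stratum.
    The leading edge collects the hit genes at or before (after, for
    negative ES) the extremum.
    """
    genes = np.asarray(ranked_scores.index)
    in_set = np.isin(genes, np.asarray(signature.genes))
    nh = int(in_set.sum())
    if nh == 0:
        raise ValueError(f"signature {signature.name!r} does not intersect the ranked list")
    if nh == genes.size:
        raise ValueError("signature covers the entire ranked list; ES is degenerate")

    weights = np.abs(ranked_scores.to_numpy(dtype=float)) ** weight
    es, pos = _running_sum_es(in_set, weights)
    if es >= 0:
        leading = tuple(genes[: pos + 1][in_set[: pos + 1]])
    else:
        leading = tuple(genes[pos:][in_set[pos:]])

    if seed is None:
        raise ValueError("seed must be set for the permutation null")
    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_permutations)
    for b in range(n_permutations):
        idx = rng.choice(genes.size, size=nh, replace=False)
        perm = np.zeros(genes.size, dtype=bool)
        perm[idx] = True
        perm_es[b], _ = _running_sum_es(perm, weights)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    stratum = perm_es[same_sign]
    if stratum.size == 0:
        nes = np.sign(es) * np.inf if es != 0 else 0.0
        p = 1.0 / n_permutations
    else:
        denom = np.abs(stratum).mean()
        nes = es / denom if denom > 0 else 0.0
        p = float((np.abs(stratum) >= abs(es)).sum() / stratum.size)
    return EnrichmentResult(
        es=es, nes=float(nes), p=p, leading_edge=leading, n_permutations=n_permutations
    )


def set_similarity(signatures: list[GeneSignature], measure: str = "jaccard") -> pd.DataFrame:
    """Symmetric pairwise similarity matrix of gene sets.

    ``jaccard`` = |A n B| / |A u B|; ``overlap`` = |A n B| / min(|A|, |B|).
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    sets = {}
    for sig in signatures:
        if len(sig.genes) == 0:
            raise ValueError(f"signature {sig.name!r} is empty")
        sets[sig.name] = set(sig.genes)
    names = [s.name for s in signatures]
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(sets[a] & sets[b])
            if measure == "jaccard":
                sim = inter / len(sets[a] | sets[b])
            elif measure == "overlap":
                sim = inter / min(len(sets[a]), len(sets[b]))
            else:
                raise ValueError(f"unknown measure {measure!r}")
            out.loc[a, b] = out.loc[b, a] = sim
    return out


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labelled items."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: tuple[str, ...]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        return str(tree)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_complete_euclidean(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering under Euclidean distance.

    Rows are the items; items are pre-sorted lexicographically by label so
    that merge order under distance ties is deterministic regardless of
    input row order.  NaNs are rejected.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix contains NaN")
    ordered = matrix.sort_index()
    dist = pdist(ordered.to_numpy(dtype=float), metric="euclidean")
    z = linkage(dist, method="complete")
    return Dendrogram(linkage=z, labels=tuple(ordered.index))
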