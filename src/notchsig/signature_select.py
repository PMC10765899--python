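"""Coherence score, its empirical null, and signature-size optimization.

The coherence score (CS) of an n-gene signature in a cohort is the mean of
the Pearson correlations over all unordered pairs of signature genes,
computed on the cohort's analysis scale (log2(CPM+1) for counts, log2
intensities as-is for microarrays).  It ranges from 1 (all genes share one
profile) down to -1/(n-1), the algebraic minimum for an average of
correlations among n variables.

Significance is empirical: CS is compared against the coherence scores of
N randomly chosen gene sets from the same gene universe.  The default null
pools random sizes uniform on [3, 100] (the convention the score was
introduced with); a size-matched null is available because the pooled null
mixes sampling variances across sizes.  The empirical p is the plain count
fraction k/N with no smoothing; when no null draw reaches the observed
score the result carries the explicit bound "< 1/N".

Signature size is chosen on a coherence curve (CS and empirical p of each
top-k prefix of a ranked candidate list): within a size window, candidates
are filtered to the minimal empirical p, then the maximal CS, then the
smallest size wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ExpressionCohort, GeneSignature, warn_dropped
from .scoring import analysis_matrix

__all__ = [
    "CoherenceResult",
    "CoherenceCurve",
    "CoherenceNull",
    "correlation_matrix",
    "coherence_score",
    "empirical_p_from_null",
    "empirical_null",
    "coherence_curve",
    "optimize_signature_size",
    "retain_candidates",
    "plot_coherence_curve",
]

#: Size range of the pooled random-set null.
DEFAULT_NULL_SIZES = (3, 100)

#: Reference significance levels drawn on coherence-curve plots.
REFERENCE_P_LEVELS = (0.5, 0.05, 0.0001)


@dataclass
class CoherenceResult:
    """Coherence score with its empirical-null summary."""

    name: str
    size: int
    score: float
    empirical_p: float | None = None
    p_is_bound: bool = False  # True when p is reported as the bound < 1/N
    null_size: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None

    def p_display(self) -> str:
        if self.empirical_p is None:
            return "NA"
        if self.p_is_bound:
            return f"< {1.0 / self.null_size:g}"
        return f"{self.empirical_p:g}"


@dataclass
class CoherenceCurve:
    """CS and empirical p of top-k prefixes of a ranked gene list."""

    name: str
    records: pd.DataFrame  # columns: k, score, empirical_p, p_is_bound
    reference_levels: tuple[float, ...] = REFERENCE_P_LEVELS

    def __post_init__(self) -> None:
        k = self.records["k"].to_numpy()
        if not (np.diff(k) > 0).all():
            raise ValueError("curve sizes must be strictly increasing")


def correlation_matrix(
    cohort: ExpressionCohort, method: str = "pearson", dtype=np.float64
) -> pd.DataFrame:
    """Gene-gene correlation matrix on the cohort's analysis scale.

    Zero-variance genes yield NaN rows/columns (they carry no correlation).
    ``method`` is ``pearson`` (default) or ``spearman``.
    """
    mat = analysis_matrix(cohort).to_numpy(dtype=np.float64)
    if method == "spearman":
        from scipy.stats import rankdata

        mat = rankdata(mat, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr.astype(dtype), index=cohort.genes, columns=cohort.genes)


def _mean_offdiag(corr: np.ndarray) -> float:
    n = corr.shape[0]
    return float((corr.sum() - np.trace(corr)) / (n * (n - 1)))


def coherence_score(
    cohort: ExpressionCohort | pd.DataFrame,
    genes,
    method: str = "pearson",
) -> float:
    """Mean pairwise gene-gene correlation of ``genes`` in the cohort.

    ``cohort`` may be an :class:`ExpressionCohort` or a precomputed
    correlation matrix.  Genes absent from the cohort are dropped with a
    warning, as are zero-variance genes; at least two usable genes are
    required.
    """
    if isinstance(genes, GeneSignature):
        genes = list(genes.genes)
    genes = [g.upper() for g in genes]
    if isinstance(cohort, ExpressionCohort):
        present = [g for g in genes if g in cohort.values.index]
        warn_dropped("coherence_score (absent)", [g for g in genes if g not in set(present)])
        if len(present) < 2:
            raise ValueError("need at least 2 signature genes present in the cohort")
        sub = analysis_matrix(cohort.subset_genes(present)).to_numpy(dtype=np.float64)
        if method == "spearman":
            from scipy.stats import rankdata

            sub = rankdata(sub, axis=1)
        sd = sub.std(axis=1)
        flat = [g for g, s in zip(present, sd) if s == 0]
        warn_dropped("coherence_score (zero variance)", flat)
        usable = sd > 0
        if usable.sum() < 2:
            raise ValueError("fewer than 2 usable (non-constant) signature genes")
        corr = np.corrcoef(sub[usable])
    else:
        present = [g for g in genes if g in cohort.index]
        warn_dropped("coherence_score (absent)", [g for g in genes if g not in set(present)])
        corr = cohort.loc[present, present].to_numpy(dtype=np.float64)
        good = ~np.isnan(corr).all(axis=1)
        flat = [g for g, ok in zip(present, good) if not ok]
        warn_dropped("coherence_score (zero variance)", flat)
        corr = corr[np.ix_(good, good)]
        if corr.shape[0] < 2:
            raise ValueError("fewer than 2 usable signature genes")
    return _mean_offdiag(corr)


def empirical_p_from_null(null_scores: np.ndarray, observed: float) -> tuple[float, bool]:
    """Count fraction of null scores >= observed; flags the k = 0 bound.

    Returns ``(p, is_bound)``: ``p`` is k/N, except when k = 0, where the
    reported value is the bound 1/N with ``is_bound = True`` (the result is
    to be read as "p < 1/N", matching how vanishing empirical p-values are
    printed).
    """
    null_scores = np.asarray(null_scores, dtype=float)
    n = null_scores.size
    if n < 1:
        raise ValueError("null sample is empty")
    k = int((null_scores >= observed).sum())
    if k == 0:
        return 1.0 / n, True
    return k / n, False


class CoherenceNull:
    """Random-gene-set coherence null over a fixed gene universe.

    Precomputes the universe's gene-gene correlation matrix once, then
    draws N random sets (sampling genes without replacement within a set,
    independently across sets) and scores each.  ``size_policy`` is
    ``"pooled"`` (set sizes uniform on ``size_range``, the default
    convention) or ``"matched"`` (all draws of one given size).
    """

    def __init__(self, cohort: ExpressionCohort | pd.DataFrame, method: str = "pearson"):
        if isinstance(cohort, ExpressionCohort):
            corr = correlation_matrix(cohort, method=method, dtype=np.float32)
        else:
            corr = cohort
        keep = ~np.isnan(corr.to_numpy()).all(axis=1)
        self.corr = np.ascontiguousarray(corr.to_numpy(dtype=np.float32)[np.ix_(keep, keep)])
        self.universe = list(np.asarray(corr.index)[keep])

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def draw(
        self,
        n_draws: int,
        size_policy: str = "pooled",
        size: int | None = None,
        size_range: tuple[int, int] = DEFAULT_NULL_SIZES,
        seed: int | None = None,
    ) -> np.ndarray:
        """Coherence scores of ``n_draws`` random gene sets."""
        if seed is None:
            raise ValueError("seed must be set for the random-set null")
        if n_draws < 1:
            raise ValueError("need at least one null draw")
        g = self.universe_size
        if size_policy == "pooled":
            lo, hi = size_range
            hi = min(hi, g - 1)
            if lo >= hi:
                raise ValueError("gene universe too small for the pooled null")
            rng = np.random.default_rng(seed)
            sizes = rng.integers(lo, hi + 1, size=n_draws)
        elif size_policy == "matched":
            if size is None:
                raise ValueError("size must be given for the matched null")
            if size >= g:
                raise ValueError("gene universe too small for the requested size")
            rng = np.random.default_rng(seed)
            sizes = np.full(n_draws, size, dtype=np.int64)
        else:
            raise ValueError(f"unknown size_policy {size_policy!r}")

        out = np.empty(n_draws)
        # batch draws of equal size: one fancy-gather per size keeps the
        # 100,000-draw null tractable on the precomputed matrix
        order = np.argsort(sizes, kind="stable")
        sorted_sizes = sizes[order]
        start = 0
        while start < n_draws:
            k = int(sorted_sizes[start])
            stop = int(np.searchsorted(sorted_sizes, k, side="right"))
            m = stop - start
            idx = np.empty((m, k), dtype=np.int64)
            for i in range(m):
                idx[i] = rng.choice(g, size=k, replace=False)
            sub = self.corr[idx[:, :, None], idx[:, None, :]]
            out[order[start:stop]] = (sub.sum(axis=(1, 2)) - k) / (k * (k - 1))
            start = stop
        return out


def empirical_null(
    cohort: ExpressionCohort | CoherenceNull,
    observed: float,
    n: int,
    n_draws: int = 100_000,
    size_policy: str = "pooled",
    seed: int | None = None,
    name: str = "signature",
) -> CoherenceResult:
    """Empirical p of an observed coherence score against random gene sets.

    Draws ``n_draws`` random gene sets from the cohort's gene universe
    (sizes uniform on [3, 100] under the default pooled policy; all of size
    ``n`` under the matched policy) and reports the count fraction of null
    scores at or above ``observed``; a zero count is reported as the bound
    < 1/N.
    """
    null = cohort if isinstance(cohort, CoherenceNull) else CoherenceNull(cohort)
    null_scores = null.draw(
        n_draws, size_policy=size_policy, size=n, seed=seed
    )
    p, bound = empirical_p_from_null(null_scores, observed)
    return CoherenceResult(
        name=name,
        size=n,
        score=observed,
        empirical_p=p,
        p_is_bound=bound,
        null_size=n_draws,
        null_mean=float(null_scores.mean()),
        null_sd=float(null_scores.std(ddof=1)),
    )


def coherence_curve(
    cohort: ExpressionCohort,
    ranked_genes,
    k_range: tuple[int, int] = (3, 50),
    n_draws: int = 10_000,
    size_policy: str = "pooled",
    seed: int | None = None,
    null: CoherenceNull | None = None,
    name: str | None = None,
) -> CoherenceCurve:
    """CS and empirical p of every top-k prefix of a ranked gene list.

    One shared null (drawn once from the cohort's gene universe) serves all
    prefix sizes under the pooled policy; the matched policy redraws per
    size.  A ``k_range`` upper end beyond the list length is truncated with
    a warning.
    """
    if isinstance(ranked_genes, GeneSignature):
        if name is None:
            name = ranked_genes.name
        ranked_genes = list(ranked_genes.genes)
    ranked_genes = [g.upper() for g in ranked_genes]
    name = name or "candidate"
    lo, hi = k_range
    if hi > len(ranked_genes):
        warnings.warn(
            f"k_range upper end {hi} exceeds ranked list length {len(ranked_genes)}; truncated"
        )
        hi = len(ranked_genes)
    if lo < 2 or lo > hi:
        raise ValueError(f"invalid k_range after truncation: ({lo}, {hi})")

    if null is None:
        null = CoherenceNull(cohort)
    corr = pd.DataFrame(
        null.corr, index=null.universe, columns=null.universe, copy=False
    )
    rows = []
    if size_policy == "pooled":
        null_scores = null.draw(n_draws, size_policy="pooled", seed=seed)
    for j, k in enumerate(range(lo, hi + 1)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = coherence_score(corr, ranked_genes[:k])
        if size_policy == "matched":
            null_scores = null.draw(n_draws, size_policy="matched", size=k, seed=seed + j)
        p, bound = empirical_p_from_null(null_scores, cs)
        rows.append({"k": k, "score": cs, "empirical_p": p, "p_is_bound": bound})
    return CoherenceCurve(name=name, records=pd.DataFrame(rows))


def optimize_signature_size(curve: CoherenceCurve, window: tuple[int, int] = (10, 30)) -> int:
    """Best prefix size within a window, lexicographically.

    Candidates are filtered to the minimal empirical p, then to the maximal
    coherence score, and the smallest surviving size is returned.  A p
    reported as the bound < 1/N ties with any other bound at the same N.
    """
    lo, hi = window
    rec = curve.records
    win = rec[(rec["k"] >= lo) & (rec["k"] <= hi)]
    if win.empty:
        raise ValueError(f"curve does not cover the window [{lo}, {hi}]")
    win = win[win["empirical_p"] == win["empirical_p"].min()]
    win = win[win["score"] == win["score"].max()]
    return int(win["k"].min())


def retain_candidates(results: list[CoherenceResult], cs_min: float = 0.2) -> list[CoherenceResult]:
    """Keep results whose coherence score strictly exceeds ``cs_min``."""
    return [r for r in results if r.score > cs_min]


def plot_coherence_curve(curve: CoherenceCurve, null_scores: np.ndarray | None = None, ax=None):
    """CS vs signature size with the reference significance levels.

    When ``null_scores`` is given, horizontal lines mark the null quantiles
    corresponding to the reference p levels (0.5, 0.05, 0.0001).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rec = curve.records
    ax.plot(rec["k"], rec["score"], marker="o", ms=3, lw=1, label=curve.name)
    if null_scores is not None:
        for level in curve.reference_levels:
            q = float(np.quantile(null_scores, 1.0 - level))
            ax.axhline(q, ls="--", lw=0.8, color="grey")
            ax.annotate(f"p = {level:g}", (rec["k"].iloc[-1], q), fontsize=7, va="bottom")
    ax.set_xlabel("signature size (genes)")
    ax.set_ylabel("coherence score")
    ax.legend(frameon=False, fontsize=8)
    return ax
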