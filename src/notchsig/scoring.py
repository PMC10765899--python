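"""Between-sample normalization and single-sample signature scoring.

RNA-seq counts are normalized with the trimmed mean of M-values (TMM):
for each sample s against a reference r, gene-wise log2 expression ratios

    M_g = log2((x_gs / N_s) / (x_gr / N_r))

and log2 abundances A_g = 0.5 * log2(x_gs x_gr / (N_s N_r)) are computed
over genes expressed in both samples; M is double-trimmed (30% on M, 5% on
A by default), and the normalization factor is 2 to the precision-weighted
mean of the surviving M-values, with inverse binomial variances as weights.
Factors are rescaled to geometric mean 1, and effective library sizes
N_s * f_s replace raw library sizes in CPM computation.

The single-sample signature score is the mean over signature genes of the
gene-wise Z-score of normalized expression: counts are taken to
log2(TMM-CPM + 1) first; microarray log2 intensities are Z-scored as-is.
Relative scores subtract a matched ground-state reference, so a positive
relative score means the treatment raised signature expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionCohort, GeneSignature, warn_dropped

__all__ = [
    "cpm",
    "log2_cpm",
    "tmm_factors",
    "ScoreTable",
    "signature_score",
    "relative_score",
]


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million, optionally on TMM-effective library sizes."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"sample(s) with non-positive library size: {bad}")
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    return counts.div(lib, axis=1) * 1e6


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    return np.log2(cpm(counts, factors) + 1.0)


def analysis_matrix(cohort: ExpressionCohort, factors: pd.Series | None = None) -> pd.DataFrame:
    """The scale all correlation/score computations run on.

    log2(CPM+1) for count platforms (TMM-effective libraries when
    ``factors`` is given), the stored log2 intensities otherwise.
    """
    if cohort.platform == "rnaseq_counts":
        return log2_cpm(cohort.values, factors)
    return cohort.values


def _pick_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper quartile of relative expression is closest to the
    mean upper quartile (deterministic, standard reference choice)."""
    rel = counts.div(counts.sum(axis=0), axis=1)
    uq = rel.apply(lambda col: np.percentile(col.to_numpy(), 75), axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    cohort: ExpressionCohort | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    Genes with zero counts in either the sample or the reference are
    excluded from the trimmed mean.  ``ref`` overrides the automatic
    upper-quartile reference choice.
    """
    if isinstance(cohort, ExpressionCohort):
        if cohort.platform != "rnaseq_counts":
            raise ValueError("TMM is defined for raw-count platforms only")
        counts = cohort.values
    else:
        counts = cohort
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    if ref is None:
        ref = _pick_reference(counts)
    xr = counts[ref].to_numpy(dtype=float)
    nr = lib[ref]

    log_factors = {}
    for sample in counts.columns:
        if sample == ref:
            log_factors[sample] = 0.0
            continue
        xs = counts[sample].to_numpy(dtype=float)
        ns = lib[sample]
        keep = (xs > 0) & (xr > 0)
        if not keep.any():
            raise ValueError(f"sample {sample!r} shares no expressed gene with the reference")
        ps, pr = xs[keep] / ns, xr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # approximate binomial variance of M; weights are its inverse
        w = (ns - xs[keep]) / (ns * xs[keep]) + (nr - xr[keep]) / (nr * xr[keep])

        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        # ranks (average ties) as in the original double-trimming rule
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep2.any():
            keep2 = np.ones_like(keep2, dtype=bool)
        with np.errstate(divide="ignore"):
            inv_w = np.where(w[keep2] > 0, 1.0 / w[keep2], 0.0)
        if inv_w.sum() > 0:
            log_factors[sample] = float(np.sum(m[keep2] * inv_w) / inv_w.sum())
        else:
            log_factors[sample] = float(np.mean(m[keep2]))

    f = pd.Series({s: 2.0 ** lf for s, lf in log_factors.items()}, dtype=float)
    f = f.loc[counts.columns]
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    return f


@dataclass
class ScoreTable:
    """Per-sample signature scores (and optionally relative scores)."""

    scores: pd.DataFrame  # index sample; columns score[, relative_score], n_genes_used
    signature: str
    dropped_genes: tuple[str, ...] = ()

    def write(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="sample")


def signature_score(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    factors: pd.Series | None = None,
    max_dropped_fraction: float = 0.5,
) -> ScoreTable:
    """Mean of gene-wise expression Z-scores over the signature genes.

    Counts are normalized to log2(TMM-CPM + 1) first (``factors`` computed
    on the fly when not supplied); microarray log2 intensities are used
    as-is.  Genes absent from the cohort or with zero variance are dropped
    with a warning; if more than ``max_dropped_fraction`` of the signature
    would be dropped the score is refused.
    """
    if cohort.platform == "rnaseq_counts" and factors is None:
        factors = tmm_factors(cohort)
    mat = analysis_matrix(cohort, factors)

    present = [g for g in signature.genes if g in mat.index]
    absent = [g for g in signature.genes if g not in mat.index]
    sub = mat.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = list(sd.index[(sd == 0) | sd.isna()])
    usable = [g for g in present if g not in flat]
    dropped = absent + flat
    warn_dropped(f"signature_score[{signature.name}]", dropped)
    if not usable:
        raise ValueError(f"no usable gene for signature {signature.name!r}")
    if len(dropped) / len(signature) > max_dropped_fraction:
        raise ValueError(
            f"{len(dropped)}/{len(signature)} signature genes unusable "
            f"(> {max_dropped_fraction:.0%}); refusing to score a partial signature"
        )
    z = sub.loc[usable].sub(sub.loc[usable].mean(axis=1), axis=0).div(sd.loc[usable], axis=0)
    scores = pd.DataFrame(
        {"score": z.mean(axis=0), "n_genes_used": len(usable)},
        index=mat.columns,
    )
    return ScoreTable(scores=scores, signature=signature.name, dropped_genes=tuple(dropped))


def relative_score(
    table: ScoreTable,
    metadata: pd.DataFrame,
    reference: str = "ground",
    condition_col: str = "condition",
    pair_keys: tuple[str, ...] = ("cell_line", "timepoint", "replicate"),
    group_mean_fallback: bool = True,
) -> ScoreTable:
    """Treatment score minus the matched ground-state score.

    Each treated sample is paired to the reference-condition sample sharing
    ``pair_keys``; when no exact partner exists, the mean reference score of
    the group (``pair_keys`` minus ``replicate``) is used if
    ``group_mean_fallback`` allows, otherwise the sample is an error.
    """
    meta = metadata.loc[table.scores.index]
    keys = [k for k in pair_keys if k in meta.columns]
    score = table.scores["score"]
    is_ref = meta[condition_col] == reference

    ref_meta = meta[is_ref]
    out = table.scores.copy()
    rel = pd.Series(np.nan, index=out.index)
    for sample in out.index:
        row = meta.loc[sample]
        match = ref_meta
        for k in keys:
            match = match[match[k] == row[k]]
        if len(match) >= 1:
            rel[sample] = score[sample] - score[match.index].mean()
            continue
        if group_mean_fallback:
            coarse_keys = [k for k in keys if k != "replicate"]
            match = ref_meta
            for k in coarse_keys:
                match = match[match[k] == row[k]]
            if len(match) >= 1:
                rel[sample] = score[sample] - score[match.index].mean()
                continue
        raise ValueError(f"sample {sample!r} has no pairable {reference!r} reference")
    out["relative_score"] = rel
    return ScoreTable(scores=out, signature=table.signature, dropped_genes=table.dropped_genes)
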