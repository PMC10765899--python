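"""Gene-universe filtering and differential-expression screening.

The screening stage reduces a grid of condition/timepoint contrasts to the
few worth deriving a signature from.  Each contrast is tested per gene with
an ordinary linear model on log2(CPM+1) (or log2 intensities) with the
declared covariates; a contrast is retained when its p-value distribution
is left-skewed (an excess of small p-values beyond binomial sampling noise
at p <= 0.05) and it yields at least 100 genes at BH-adjusted p < 0.05.
Each retained contrast contributes two ranked candidate gene lists, one of
up- and one of downregulated genes, ordered by the signed test statistic.

The per-gene OLS stage deliberately stands in for a negative-binomial GLM
with shrinkage: the selection logic downstream consumes only per-gene
(log2FC, p) tables, so any differential-expression backend producing such
tables can be swapped in.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionCohort, GeneSignature
from .scoring import analysis_matrix

__all__ = [
    "DEFAULT_EXCLUSION_PATTERNS",
    "ContrastSpec",
    "ContrastResult",
    "SelectedComparison",
    "filter_gene_universe",
    "run_contrast",
    "enumerate_contrasts",
    "is_left_skewed",
    "select_candidate_comparisons",
]

#: Symbol-pattern exclusion lists applied by :func:`filter_gene_universe`.
#: Keys name the gene class; values are regular expressions matched against
#: the full upper-cased symbol.
DEFAULT_EXCLUSION_PATTERNS: dict[str, str] = {
    "immunoglobulin": r"IG[HKL][VDJC].*",
    "ribosomal": r"(RP[LS]\d.*|MRP[LS]\d.*)",
    "readthrough": r".*-(READTHROUGH|IT\d)",
    "y_linked": r"(RPS4Y\d|DDX3Y|EIF1AY|KDM5D|UTY|USP9Y|NLGN4Y|ZFY|TXLNGY|SRY)",
    "xist": r"XIST",
}


@dataclass(frozen=True)
class ContrastSpec:
    """One comparison of two condition levels.

    ``numerator`` vs ``denominator`` on the metadata column
    ``condition_col``; positive log2FC means higher under the numerator.
    ``timepoint`` restricts to one timepoint or pools all (``"pooled"``);
    ``covariates`` are metadata columns adjusted for as categorical terms.
    """

    numerator: str
    denominator: str
    timepoint: str = "pooled"
    covariates: tuple[str, ...] = ()
    condition_col: str = "condition"

    @property
    def label(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}@{self.timepoint}"


@dataclass
class ContrastResult:
    """Per-gene effects for one contrast.

    ``table`` has columns ``log2fc``, ``stat``, ``p``, ``padj`` indexed by
    gene.
    """

    spec: ContrastSpec
    table: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def n_degs(self, padj_cut: float = 0.05) -> int:
        return int((self.table["padj"] < padj_cut).sum())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def filter_gene_universe(
    cohort: ExpressionCohort,
    mode: str = "counts",
    min_total_count: int = 10,
    min_cpm: float = 1.0,
    exclusion_patterns: dict[str, str] | None = DEFAULT_EXCLUSION_PATTERNS,
) -> ExpressionCohort:
    """Drop lowly expressed genes and excluded symbol classes.

    ``mode="counts"`` removes genes with total count below
    ``min_total_count`` (default: fewer than 10 counts across all samples);
    ``mode="cpm"`` removes genes whose CPM never reaches ``min_cpm`` in any
    sample.  Both modes require a raw-count platform.  Symbol classes in
    ``exclusion_patterns`` (immunoglobulin segments, ribosomal genes,
    readthrough transcripts, Y-linked genes, XIST by default) are removed
    regardless of expression; pass ``None`` to keep them.  The operation is
    idempotent.
    """
    values = cohort.values
    if mode == "counts":
        if cohort.platform != "rnaseq_counts":
            raise ValueError("count filtering requires a raw-count platform")
        keep = values.sum(axis=1) >= min_total_count
    elif mode == "cpm":
        if cohort.platform != "rnaseq_counts":
            raise ValueError("CPM filtering requires a raw-count platform")
        from .scoring import cpm

        keep = (cpm(values) >= min_cpm).any(axis=1)
    elif mode == "none":
        keep = pd.Series(True, index=values.index)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")

    if exclusion_patterns:
        compiled = [re.compile(p) for p in exclusion_patterns.values()]
        excluded = values.index.map(lambda g: any(rx.fullmatch(g) for rx in compiled))
        keep &= ~np.asarray(excluded, dtype=bool)
    return cohort.subset_genes(values.index[keep])


def _design_matrix(meta: pd.DataFrame, spec: ContrastSpec) -> np.ndarray:
    cols = [np.ones(len(meta)), (meta[spec.condition_col] == spec.numerator).astype(float)]
    for cov in spec.covariates:
        levels = sorted(meta[cov].astype(str).unique())
        for lev in levels[1:]:  # first level absorbed by the intercept
            cols.append((meta[cov].astype(str) == lev).astype(float))
    return np.column_stack(cols)


def run_contrast(cohort: ExpressionCohort, spec: ContrastSpec) -> ContrastResult:
    """Per-gene OLS contrast with covariate adjustment.

    Fits, for every gene, ``expression ~ condition + covariates`` on the
    analysis scale over the samples of the two condition levels (restricted
    to ``spec.timepoint`` unless pooled); reports the condition
    coefficient's log2 fold change, t statistic, two-sided p and BH-adjusted
    p.
    """
    meta = cohort.metadata
    levels = set(meta[spec.condition_col])
    for lev in (spec.numerator, spec.denominator):
        if lev not in levels:
            raise ValueError(f"condition level {lev!r} not present in cohort metadata")
    keep = meta[spec.condition_col].isin([spec.numerator, spec.denominator])
    if spec.timepoint != "pooled":
        keep &= meta["timepoint"] == spec.timepoint
    sub = cohort.subset_samples(meta.index[keep])
    counts = sub.metadata[spec.condition_col].value_counts()
    if counts.get(spec.numerator, 0) < 2 or counts.get(spec.denominator, 0) < 2:
        raise ValueError(f"contrast {spec.label}: fewer than 2 samples per condition level")

    y = analysis_matrix(sub).to_numpy(dtype=np.float64)  # genes x samples
    x = _design_matrix(sub.metadata, spec)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError(f"contrast {spec.label}: singular design matrix")
    if n <= p:
        raise ValueError(f"contrast {spec.label}: not enough residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    resid = y - beta @ x.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    log2fc = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "stat": tstat, "p": pvals, "padj": padj},
        index=sub.values.index,
    )
    return ContrastResult(spec=spec, table=table)


def enumerate_contrasts(
    conditions=("notch_on", "ground", "notch_off"),
    timepoints=("8h", "72h", "pooled"),
    covariates: tuple[str, ...] = (),
) -> list[ContrastSpec]:
    """The config-driven grid of condition-pair x timepoint contrasts."""
    return [
        ContrastSpec(a, b, timepoint=tp, covariates=covariates)
        for a, b in itertools.combinations(conditions, 2)
        for tp in timepoints
    ]


def is_left_skewed(
    pvalues, alpha: float = 0.05, k: float = 3.0
) -> tuple[bool, dict]:
    """Excess of small p-values beyond binomial sampling noise.

    True when the fraction of p <= ``alpha`` exceeds
    ``alpha + k * sqrt(alpha (1 - alpha) / m)`` (a one-sided binomial
    excess rule at k standard deviations).  Requires at least 100 p-values.
    Diagnostics carry the observed fraction, the threshold and a 20-bin
    histogram of the p-value distribution.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        raise ValueError(f"need at least 100 p-values, got {p.size}")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    frac = float((p <= alpha).mean())
    threshold = alpha + k * np.sqrt(alpha * (1 - alpha) / p.size)
    hist, edges = np.histogram(p, bins=20, range=(0.0, 1.0))
    diagnostics = {
        "fraction_below_alpha": frac,
        "threshold": float(threshold),
        "alpha": alpha,
        "k": k,
        "histogram_counts": hist.tolist(),
        "histogram_edges": edges.tolist(),
    }
    return frac > threshold, diagnostics


@dataclass
class SelectedComparison:
    """A retained contrast with its two ranked candidate gene lists."""

    result: ContrastResult
    up: GeneSignature
    down: GeneSignature
    diagnostics: dict = field(default_factory=dict)


def select_candidate_comparisons(
    results: list[ContrastResult],
    min_degs: int = 100,
    padj_cut: float = 0.05,
) -> list[SelectedComparison]:
    """Keep contrasts passing the left-skew gate with enough DEGs.

    A contrast survives when :func:`is_left_skewed` holds on its raw
    p-values and at least ``min_degs`` genes reach BH-adjusted p below
    ``padj_cut``.  Each kept contrast yields an up- and a down-regulated
    candidate list ranked by the signed test statistic (strongest first;
    ties broken alphabetically for determinism).
    """
    selected = []
    for res in results:
        skewed, diag = is_left_skewed(res.table["p"].to_numpy())
        n_degs = res.n_degs(padj_cut)
        diag["n_degs"] = n_degs
        if not (skewed and n_degs >= min_degs):
            continue
        tab = res.table.copy()
        tab["gene"] = tab.index
        up = tab[tab["stat"] > 0].sort_values(["stat", "gene"], ascending=[False, True])
        down = tab[tab["stat"] < 0].sort_values(["stat", "gene"], ascending=[True, True])
        label = res.spec.label
        selected.append(
            SelectedComparison(
                result=res,
                up=GeneSignature(f"{label}_up", tuple(up.index), direction="up"),
                down=GeneSignature(f"{label}_down", tuple(down.index), direction="down"),
                diagnostics=diag,
            )
        )
    return selected
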