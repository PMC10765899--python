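"""Composite Notch-alteration scoring and classification.

Per patient, events over the core Notch receptor/ligand genes (NOTCH1-4,
DLL1, DLL3, DLL4, JAG1, JAG2) are summed with -1 for deleterious events
(truncating mutations, missense mutations, homozygous deletions) and +1
for amplifications; structural variants default to 0 (configurable, as
their direction is not defined by the scoring rule).  The sum partitions
patients into three classes: activation (> 0), inactivation (< 0) and
wild-type (= 0).  Patients whose deleterious and amplifying events cancel
land at 0 and are flagged as mixed, because the composite sum cannot
distinguish them from genuinely unaltered patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_core import AlterationTable

__all__ = [
    "DEFAULT_CORE_GENES",
    "DELETERIOUS_CLASSES",
    "composite_score",
    "classify_and_evaluate",
]

DEFAULT_CORE_GENES: tuple[str, ...] = (
    "NOTCH1",
    "NOTCH2",
    "NOTCH3",
    "NOTCH4",
    "DLL1",
    "DLL3",
    "DLL4",
    "JAG1",
    "JAG2",
)

DELETERIOUS_CLASSES = ("truncating", "missense", "homozygous_deletion")

COMPARISONS = ("activation_vs_wt", "wt_vs_inactivation", "activation_vs_inactivation")


def _event_score(alteration_class: str, structural_variant_score: int) -> int:
    if alteration_class in DELETERIOUS_CLASSES:
        return -1
    if alteration_class == "amplification":
        return +1
    if alteration_class == "structural_variant":
        return structural_variant_score
    if alteration_class == "none":
        return 0
    raise ValueError(f"unknown alteration class {alteration_class!r}")


def composite_score(
    table: AlterationTable,
    core_genes: tuple[str, ...] = DEFAULT_CORE_GENES,
    structural_variant_score: int = 0,
) -> pd.DataFrame:
    """Per-patient composite score, class label and per-gene contributions.

    Events on genes outside ``core_genes`` are ignored.  Returns a frame
    indexed by patient with columns ``score`` (integer sum), ``label``
    (activation / inactivation / wild_type), ``mixed`` (True when both
    positive and negative events were present) and ``contributions``
    (per-gene totals as a dict).
    """
    core = {g.upper() for g in core_genes}
    rows = {}
    for pt in table.patients:
        rows[pt] = {"score": 0, "pos": 0, "neg": 0, "contributions": {}}
    for rec in table.calls.itertuples(index=False):
        pt = rec.patient
        if pt not in rows:
            rows[pt] = {"score": 0, "pos": 0, "neg": 0, "contributions": {}}
        if rec.gene not in core:
            continue
        s = _event_score(rec.alteration_class, structural_variant_score)
        rows[pt]["score"] += s
        if s > 0:
            rows[pt]["pos"] += 1
        elif s < 0:
            rows[pt]["neg"] += 1
        rows[pt]["contributions"][rec.gene] = rows[pt]["contributions"].get(rec.gene, 0) + s

    out = []
    for pt, r in rows.items():
        if r["score"] > 0:
            label = "activation"
        elif r["score"] < 0:
            label = "inactivation"
        else:
            label = "wild_type"
        out.append(
            {
                "patient": pt,
                "score": r["score"],
                "label": label,
                "mixed": r["pos"] > 0 and r["neg"] > 0,
                "contributions": r["contributions"],
            }
        )
    return pd.DataFrame(out).set_index("patient")


def classify_and_evaluate(
    scores: pd.Series | pd.DataFrame,
    patient_classes: pd.DataFrame,
    comparison: str,
):
    """ROC of signature scores against a binary alteration-class comparison.

    ``scores`` is a per-patient signature score (a Series, or a ScoreTable
    frame with a ``score`` column); ``patient_classes`` is the output of
    :func:`composite_score`.  ``comparison`` selects which two classes form
    the positive/negative labels; the positive class is the first named.
    Delegates to :func:`notchsig.evaluate.roc_auc`.
    """
    from .evaluate import roc_auc  # local import avoids a module cycle

    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    pos_name, neg_name = {
        "activation_vs_wt": ("activation", "wild_type"),
        "wt_vs_inactivation": ("wild_type", "inactivation"),
        "activation_vs_inactivation": ("activation", "inactivation"),
    }[comparison]

    common = scores.index.intersection(patient_classes.index)
    labels = patient_classes.loc[common, "label"]
    keep = labels.isin([pos_name, neg_name])
    labels = labels[keep]
    vals = scores.loc[labels.index]
    for name in (pos_name, neg_name):
        if (labels == name).sum() == 0:
            raise ValueError(f"comparison {comparison!r}: class {name!r} is empty")
    return roc_auc(vals.to_numpy(), (labels == pos_name).to_numpy())
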