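"""Score samples with a signature and classify the perturbation response.

TMM-normalizes a simulated count experiment, computes the single-sample
signature score (mean of gene-wise Z-scores), forms relative scores against
the matched ground state, and evaluates how well the relative score
separates Notch-on from Notch-off samples by ROC.
"""

import notchsig as ns

cohort = ns.generate_cell_line_experiment(ns.SimulationConfig(seed=3))
signature = ns.GeneSignature(
    "planted20", tuple(cohort.provenance["planted_genes"][:20])
)

factors = ns.tmm_factors(cohort)
print(f"TMM factors: min {factors.min():.3f}, max {factors.max():.3f} "
      f"(geometric mean 1 by construction)")

scores = ns.signature_score(cohort, signature, factors=factors)
rel = ns.relative_score(scores, cohort.metadata)
cond = cohort.metadata["condition"]
for level in ("notch_on", "ground", "notch_off"):
    m = rel.scores.loc[cond == level, "relative_score"].mean()
    print(f"mean relative score [{level:9s}]: {m:+.3f}")

keep = cond != "ground"
roc = ns.roc_auc(rel.scores.loc[keep, "relative_score"],
                 (cond[keep] == "notch_on"))
print(f"\nROC AUC (notch_on vs notch_off): {roc.auc:.3f} "
      f"(95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f}, DeLong)")
print(
    "\nPositive relative scores under activation and negative under"
    "\nblockade show the signature tracks the perturbation; the AUC"
    "\nquantifies how cleanly it classifies the two states."
)
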