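"""Derive a signature size from a coherence curve with an empirical null.

Plants a 20-gene co-expressed module (pairwise correlation 0.3) at the top
of a ranked candidate list in a 500-sample cohort, traces the coherence
score of every top-k prefix, sizes the signature inside the 10-30 window,
and scores its significance against random gene sets.
"""

import notchsig as ns

cfg = ns.SimulationConfig(
    seed=7, n_genes=2020, n_samples=500,
    planted_module_size=20, planted_correlation=0.3,
)
cohort = ns.generate_patient_cohort(cfg)
module = cohort.provenance["planted_module"]
ranked = module + [g for g in cohort.genes if g not in set(module)]

null = ns.CoherenceNull(cohort)
curve = ns.coherence_curve(cohort, ranked, k_range=(3, 50),
                           n_draws=20_000, seed=11, null=null)
k = ns.optimize_signature_size(curve, window=(10, 30))
print(f"chosen signature size: {k} genes (planted module: {len(module)})")

cs = ns.coherence_score(cohort, ranked[:k])
res = ns.empirical_null(null, cs, k, n_draws=100_000, seed=13)
print(f"coherence score of the top-{k} prefix: {cs:.3f}")
print(f"empirical p vs 100,000 random gene sets: {res.p_display()}")
print(f"null mean {res.null_mean:.4f}, null sd {res.null_sd:.4f}")
print(
    "\nThe module's mean pairwise correlation (~0.3) dwarfs every random"
    "\ngene set, so the empirical p is reported as the bound < 1/N."
)
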