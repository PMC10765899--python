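"""Position a signature relative to the Notch transcriptional hub CSL/RBPJ.

Builds a scale-free interaction network that contains the 20-gene Notch
signature, computes each gene's shortest-path distance to the hub, and
tests whether the signature sits closer to the hub than size-matched
random gene sets.
"""

import notchsig as ns

signature = ns.notch_signature()
network = ns.generate_network(
    600, attachment=2, hub_label="RBPJ", seed=21, include=signature.genes
)
print(f"network: {network.n_nodes} nodes, hub = {network.hub}")

result = ns.centrality_empirical_p(network, signature, n_random=1000, seed=22)
print(f"mean distance of {signature.name} to {network.hub}: "
      f"{result.mean_distance:.2f} hops "
      f"(fraction unreachable: {result.fraction_missing:.2f})")
print(f"random gene sets: mean {result.null_mean:.2f} +/- {result.null_sd:.2f}")
print(f"empirical p (random sets strictly closer): {result.empirical_p:.3f}")
print(
    "\nOn this synthetic graph the signature genes occupy random positions,"
    "\nso the p-value is unremarkable; on a curated interaction network a"
    "\nsmall p marks a set wired unusually close to the pathway hub."
)
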