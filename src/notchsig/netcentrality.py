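"""Gene-set centrality relative to a hub on an interaction network.

The centrality score of a gene set is the mean unweighted shortest-path
(hop) distance from its genes to the hub; genes absent from the network or
unreachable from the hub are treated as missing and excluded from the mean.
Significance comes from an empirical null of size-matched random gene sets
drawn uniformly from the network's non-hub nodes: the empirical p-value is
the proportion of random sets with a strictly smaller mean distance, so a
small p says the set sits unusually close to the hub.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_core import GeneSignature, InteractionNetwork

__all__ = ["CentralityResult", "distances_to_hub", "centrality_score", "centrality_empirical_p"]


@dataclass
class CentralityResult:
    """Mean hub distance of a gene set with optional empirical null."""

    signature: str
    distances: dict[str, float]  # NaN marks missing
    mean_distance: float
    fraction_missing: float
    empirical_p: float | None = None
    n_random: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None


def _genes(signature) -> tuple[str, list[str]]:
    if isinstance(signature, GeneSignature):
        return signature.name, list(signature.genes)
    return "gene_set", [g.upper() for g in signature]


def distances_to_hub(network: InteractionNetwork, genes) -> dict[str, float]:
    """BFS shortest-path length from each gene to the hub; NaN if missing.

    Genes absent from the network, isolated, or in a different component
    than the hub are reported as NaN.
    """
    _, gene_list = _genes(genes)
    lengths = nx.single_source_shortest_path_length(network.graph, network.hub)
    return {g: float(lengths[g]) if g in lengths else float("nan") for g in gene_list}


def centrality_score(network: InteractionNetwork, signature) -> CentralityResult:
    """Mean distance to the hub over the reachable signature genes."""
    name, gene_list = _genes(signature)
    dist = distances_to_hub(network, gene_list)
    finite = [d for d in dist.values() if not np.isnan(d)]
    if not finite:
        raise ValueError(f"no gene of {name!r} is reachable from hub {network.hub!r}")
    return CentralityResult(
        signature=name,
        distances=dist,
        mean_distance=float(np.mean(finite)),
        fraction_missing=1.0 - len(finite) / len(gene_list),
    )


def centrality_empirical_p(
    network: InteractionNetwork,
    signature,
    n_random: int = 1000,
    seed: int | None = None,
) -> CentralityResult:
    """Empirical p against size-matched random gene sets from the network.

    Random sets of exactly the signature's size are drawn uniformly without
    replacement from the network nodes (hub excluded); p is the proportion
    with a strictly smaller mean hub distance than the observed set.
    """
    if seed is None:
        raise ValueError("seed must be set for the random-set null")
    result = centrality_score(network, signature)
    _, gene_list = _genes(signature)
    k = len(gene_list)
    pool = np.array([n for n in network.graph.nodes if n != network.hub])
    if len(pool) <= k:
        raise ValueError("network too small for size-matched random sets")
    lengths = nx.single_source_shortest_path_length(network.graph, network.hub)
    dist_arr = np.array([float(lengths.get(n, np.nan)) for n in pool])

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(len(pool), size=k, replace=False)
        d = dist_arr[idx]
        d = d[~np.isnan(d)]
        null_means[i] = d.mean() if d.size else np.nan
    valid = null_means[~np.isnan(null_means)]
    result.empirical_p = float((valid < result.mean_distance).sum() / n_random)
    result.n_random = n_random
    result.null_mean = float(valid.mean())
    result.null_sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return result
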