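"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the pipeline's substrates:

* a cell-line perturbation experiment — six basal-like cell lines, three
  Notch conditions (ligand-activated "notch_on", DMSO "ground", GSI-blocked
  "notch_off"), two timepoints and three replicates, yielding negative-
  binomial counts with a planted set of Notch-responsive genes;
* a patient cohort with subtype labels and a planted co-expressed module of
  tunable pairwise correlation (single shared latent factor with loading
  sqrt(rho), so the expected pairwise Pearson correlation is exactly rho);
* a per-patient alteration table over the core Notch receptor/ligand genes;
* a small scale-free (preferential-attachment) interaction network with a
  designated hub, standing in for a protein-protein interaction graph
  around CSL/RBPJ.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .alterations import DEFAULT_CORE_GENES
from .io_core import (
    ALTERATION_CLASSES,
    AlterationTable,
    ExpressionCohort,
    InteractionNetwork,
)

__all__ = [
    "SimulationConfig",
    "generate_cell_line_experiment",
    "generate_patient_cohort",
    "generate_alteration_table",
    "generate_network",
]

_CELL_LINES = ("BT20", "HCC70", "HCC1187", "HCC1599", "MDAMB436", "MDAMB468")
_CONDITIONS = ("notch_on", "ground", "notch_off")
_TIMEPOINTS = ("8h", "72h")
_SUBTYPES = ("basal", "her2", "luma", "lumb", "normal")


@dataclass
class SimulationConfig:
    """Shared knobs for the synthetic generators.

    The defaults mirror the perturbation design the pipeline was built
    for: 6 cell lines x {notch_on, ground, notch_off} x {8h, 72h} x 3
    replicates (108 samples), a ~5,000-gene universe with 200 planted
    Notch-responsive genes shifted by ``effect_size`` log2 units between
    Notch-on and Notch-off (applied symmetrically, +e/2 and -e/2 around
    the ground state), negative-binomial counts with dispersion 0.1 and
    log-normally distributed gene means; and, for the patient arm, a
    500-sample cohort with a 20-gene module of pairwise correlation 0.3.
    """

    n_genes: int = 5000
    seed: int | None = None
    # cell-line experiment design
    cell_lines: tuple[str, ...] = _CELL_LINES
    conditions: tuple[str, ...] = _CONDITIONS
    timepoints: tuple[str, ...] = _TIMEPOINTS
    replicates: int = 3
    n_responsive: int = 200
    effect_size: float = 2.0
    dispersion: float = 0.1
    mean_log2: float = 6.0
    mean_log2_sd: float = 2.0
    cell_line_sd: float = 0.5
    timepoint_sd: float = 0.2
    library_sd: float = 0.2
    batch_sd: float = 0.0
    n_batches: int = 1
    # patient cohort
    n_samples: int = 500
    planted_module_size: int = 20
    planted_correlation: float = 0.3
    noise_sd: float = 1.0
    module_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0 or self.replicates <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.planted_correlation <= 1.0:
            raise ValueError("planted_correlation must lie in [0, 1]")
        if self.planted_module_size >= self.n_genes:
            raise ValueError("planted_module_size must be smaller than n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("seed must be set for reproducible generation")
        return np.random.default_rng(self.seed)


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cell_line_experiment(config: SimulationConfig) -> ExpressionCohort:
    """Counts for the cell-line perturbation design.

    The first ``n_responsive`` genes are Notch-responsive: their mean is
    shifted by ``effect_size/2`` log2 units upward under ``notch_on`` and
    downward under ``notch_off``, so the ground state sits at the midpoint
    and the on-off contrast equals ``effect_size``.  Gene-wise means are
    log-normal; cell-line and timepoint effects perturb them multiplicatively
    (the dominant variance component is the cell line, as in real panels);
    optional batches add a log-scale offset.  Planted gene identifiers are
    recorded in the cohort provenance.
    """
    if config.n_responsive > config.n_genes:
        raise ValueError("n_responsive cannot exceed n_genes")
    rng = config.rng()
    genes = _gene_names(config.n_genes)
    planted = genes[: config.n_responsive]

    base_log2 = rng.normal(config.mean_log2, config.mean_log2_sd, config.n_genes)
    cl_effect = {
        cl: rng.normal(0.0, config.cell_line_sd, config.n_genes)
        for cl in config.cell_lines
    }
    tp_effect = {
        tp: rng.normal(0.0, config.timepoint_sd, config.n_genes)
        for tp in config.timepoints
    }
    batch_effect = rng.normal(0.0, config.batch_sd, (config.n_batches, config.n_genes))

    cond_shift = {c: 0.0 for c in config.conditions}
    if "notch_on" in cond_shift:
        cond_shift["notch_on"] = +config.effect_size / 2.0
    if "notch_off" in cond_shift:
        cond_shift["notch_off"] = -config.effect_size / 2.0

    columns, meta_rows = [], []
    counts = np.empty(
        (
            config.n_genes,
            len(config.cell_lines)
            * len(config.conditions)
            * len(config.timepoints)
            * config.replicates,
        ),
        dtype=np.int64,
    )
    j = 0
    responsive = np.zeros(config.n_genes)
    responsive[: config.n_responsive] = 1.0
    for cl in config.cell_lines:
        for cond in config.conditions:
            for tp in config.timepoints:
                for rep in range(1, config.replicates + 1):
                    batch = (rep - 1) % config.n_batches
                    log2_mu = (
                        base_log2
                        + cl_effect[cl]
                        + tp_effect[tp]
                        + responsive * cond_shift[cond]
                        + batch_effect[batch]
                    )
                    depth = 2.0 ** rng.normal(0.0, config.library_sd)
                    mu = depth * 2.0 ** log2_mu
                    counts[:, j] = _nb_sample(rng, mu, config.dispersion)
                    name = f"{cl}_{cond}_{tp}_r{rep}"
                    columns.append(name)
                    meta_rows.append(
                        {
                            "sample": name,
                            "cell_line": cl,
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                            "batch": f"b{batch + 1}",
                        }
                    )
                    j += 1

    values = pd.DataFrame(counts, index=genes, columns=columns)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    provenance = {
        "generator": "generate_cell_line_experiment",
        "seed": config.seed,
        "planted_genes": list(planted),
        "effect_size": config.effect_size,
        "dispersion": config.dispersion,
    }
    return ExpressionCohort(values, metadata, "rnaseq_counts", provenance)


def generate_patient_cohort(config: SimulationConfig) -> ExpressionCohort:
    """Log2-intensity patient cohort with one planted co-expressed module.

    Module genes load on a single shared latent factor with loading
    sqrt(rho): x_g = sqrt(rho) * f + sqrt(1 - rho) * eps_g, which makes the
    expected pairwise Pearson correlation exactly ``planted_correlation``.
    Background genes are mutually independent Gaussians.  Per-gene means and
    scales are heterogeneous, mimicking microarray log2 intensities; Pearson
    correlation is invariant to them.  Subtype labels are sampled per sample.
    """
    rng = config.rng()
    m = config.planted_module_size
    genes = _gene_names(config.n_genes)
    if config.module_genes is not None:
        if len(config.module_genes) != m:
            raise ValueError("module_genes length must equal planted_module_size")
        genes = [g.upper() for g in config.module_genes] + genes[: config.n_genes - m]
    module = genes[:m]

    rho = config.planted_correlation
    factor = rng.standard_normal(config.n_samples)
    noise = rng.standard_normal((config.n_genes, config.n_samples))
    latent = np.empty_like(noise)
    latent[:m] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise[:m]
    latent[m:] = noise[m:]

    gene_mean = rng.normal(8.0, 2.0, config.n_genes)
    gene_scale = np.abs(rng.normal(config.noise_sd, 0.25 * config.noise_sd, config.n_genes))
    gene_scale = np.maximum(gene_scale, 1e-3)
    values = gene_mean[:, None] + gene_scale[:, None] * latent

    samples = [f"P{i:04d}" for i in range(1, config.n_samples + 1)]
    subtype = rng.choice(_SUBTYPES, size=config.n_samples, p=(0.2, 0.15, 0.35, 0.2, 0.1))
    metadata = pd.DataFrame({"sample": samples, "subtype": subtype}).set_index("sample")
    provenance = {
        "generator": "generate_patient_cohort",
        "seed": config.seed,
        "planted_module": list(module),
        "planted_correlation": rho,
    }
    return ExpressionCohort(
        pd.DataFrame(values, index=genes, columns=samples),
        metadata,
        "microarray_log2",
        provenance,
    )


def generate_alteration_table(
    n_patients: int,
    rates: dict[str, float] | None = None,
    seed: int | None = None,
    core_genes: tuple[str, ...] = DEFAULT_CORE_GENES,
) -> AlterationTable:
    """Per-patient alteration calls over the core Notch gene set.

    ``rates`` maps event classes to the per-patient probability of carrying
    one event of that class (on a uniformly chosen core gene); the
    probabilities must sum to at most 1 per class-independence reading.
    Patients with no event are retained in the patient universe and appear
    as explicit wild-type rows on disk.
    """
    if seed is None:
        raise ValueError("seed must be set for reproducible generation")
    if rates is None:
        rates = {"amplification": 0.05, "truncating": 0.03, "missense": 0.05}
    event_classes = [c for c in ALTERATION_CLASSES if c != "none"]
    unknown = set(rates) - set(event_classes)
    if unknown:
        raise ValueError(f"unknown alteration class(es): {sorted(unknown)}")
    if sum(rates.values()) > 1.0 + 1e-12:
        raise ValueError("rates must sum to at most 1")

    rng = np.random.default_rng(seed)
    patients = [f"PT{i:05d}" for i in range(1, n_patients + 1)]
    rows = []
    for pt in patients:
        for cls in event_classes:  # fixed order keeps draws reproducible
            r = rates.get(cls, 0.0)
            if r > 0 and rng.random() < r:
                gene = core_genes[rng.integers(len(core_genes))]
                rows.append({"patient": pt, "gene": gene, "alteration_class": cls})
    calls = pd.DataFrame(rows, columns=["patient", "gene", "alteration_class"])
    return AlterationTable(calls=calls, patients=tuple(patients))


def generate_network(
    n_nodes: int,
    attachment: int = 2,
    hub_label: str = "RBPJ",
    seed: int | None = None,
    include: tuple[str, ...] = (),
) -> InteractionNetwork:
    """Connected scale-free interaction network containing ``hub_label``.

    Built by preferential attachment (Barabasi-Albert, ``attachment`` edges
    per new node), which guarantees a single connected component; the
    highest-degree node is relabelled to the hub.  ``include`` symbols (for
    example signature genes) are placed on randomly chosen nodes so that
    gene sets of interest intersect the network.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if seed is None:
        raise ValueError("seed must be set for reproducible generation")
    hub_label = hub_label.upper()
    rng = np.random.default_rng(seed)
    if n_nodes == 2:
        g = nx.Graph([(0, 1)])
    else:
        g = nx.barabasi_albert_graph(n_nodes, min(attachment, n_nodes - 1), seed=int(rng.integers(2**31)))

    names = _gene_names(n_nodes)
    include = tuple(dict.fromkeys(s.upper() for s in include))
    if hub_label in include:
        raise ValueError(f"hub label {hub_label!r} collides with an included gene name")
    if len(include) > n_nodes - 1:
        raise ValueError("more included genes than non-hub nodes")

    degree_order = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))
    hub_node = degree_order[0][0]
    others = [n for n in g.nodes if n != hub_node]
    slots = rng.choice(len(others), size=len(include), replace=False) if include else []
    mapping = {hub_node: hub_label}
    taken = set(include) | {hub_label}
    pool = iter(n for n in names if n not in taken)
    for i, node in enumerate(others):
        mapping[node] = None
    for s, sym in zip(slots, include):
        mapping[others[s]] = sym
    for node in others:
        if mapping[node] is None:
            mapping[node] = next(pool)
    return InteractionNetwork(graph=nx.relabel_nodes(g, mapping), hub=hub_label)
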