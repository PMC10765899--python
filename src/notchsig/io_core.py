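"""Core data containers and text-format I/O.

Everything downstream operates on four objects: an :class:`ExpressionCohort`
(gene x sample matrix with per-sample metadata), a :class:`GeneSignature`
(named, ordered gene list), an :class:`InteractionNetwork` (undirected graph
with a designated hub) and an :class:`AlterationTable` (per-patient genomic
alteration calls). All on-disk formats are plain text: TSV for matrices,
metadata, edge lists and alteration calls; GMT for signature collections.

Gene identity is the upper-cased symbol string; no alias resolution is
attempted.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "ALTERATION_CLASSES",
    "ExpressionCohort",
    "GeneSignature",
    "InteractionNetwork",
    "AlterationTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_alterations",
    "write_alterations",
    "notch_signature",
    "notch_core_signature",
    "packaged_signatures",
]

#: Supported expression platforms.  ``rnaseq_counts`` matrices hold raw
#: non-negative counts; ``microarray_log2`` matrices hold log2 intensities.
PLATFORMS = ("rnaseq_counts", "microarray_log2")

#: Closed vocabulary of alteration calls.
ALTERATION_CLASSES = (
    "truncating",
    "missense",
    "homozygous_deletion",
    "amplification",
    "structural_variant",
    "none",
)


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicated {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionCohort:
    """A gene x sample expression matrix with aligned sample metadata.

    Parameters
    ----------
    values:
        DataFrame indexed by gene symbol with one column per sample.  Raw
        counts for ``rnaseq_counts``, log2 intensities for
        ``microarray_log2``.
    metadata:
        DataFrame indexed by sample identifier; any subset of columns such
        as ``condition``, ``timepoint``, ``cell_line``, ``subtype``,
        ``batch``, ``replicate``.
    platform:
        One of :data:`PLATFORMS`.
    provenance:
        Free-form record of how the cohort was produced (planted genes,
        simulation config, seed, source files).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    platform: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if not self.values.columns.equals(self.metadata.index):
            if set(self.values.columns) == set(self.metadata.index):
                self.metadata = self.metadata.loc[self.values.columns]
            else:
                raise ValueError("metadata index does not match matrix columns")
        if self.platform == "rnaseq_counts":
            vals = self.values.to_numpy()
            if (vals < 0).any():
                raise ValueError("negative values on a raw-count platform")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionCohort":
        genes = [g.upper() for g in genes]
        return dataclasses.replace(self, values=self.values.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionCohort":
        samples = list(samples)
        return dataclasses.replace(
            self,
            values=self.values[samples],
            metadata=self.metadata.loc[samples],
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list with an optional regulation direction."""

    name: str
    genes: tuple[str, ...]
    direction: str = "mixed"
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(g.upper() for g in self.genes))
        if len(self.genes) < 1:
            raise ValueError(f"signature {self.name!r} is empty")
        _check_unique(self.genes, "signature gene")
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def head(self, k: int, name: str | None = None) -> "GeneSignature":
        """Prefix of the first ``k`` genes (used for size optimization)."""
        return GeneSignature(
            name=name or f"{self.name}[:{k}]",
            genes=self.genes[:k],
            direction=self.direction,
        )


@dataclass
class InteractionNetwork:
    """An undirected interaction network with a designated hub node."""

    graph: nx.Graph
    hub: str

    def __post_init__(self) -> None:
        self.hub = self.hub.upper()
        if self.hub not in self.graph:
            raise ValueError(f"hub {self.hub!r} is not a node of the network")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class AlterationTable:
    """Per-patient genomic alteration calls over a declared gene set.

    ``calls`` holds one row per event with columns ``patient``, ``gene`` and
    ``alteration_class``; patients with no event carry a single ``none`` row
    (gene ``"."``).  ``patients`` is the full patient universe, which may be
    larger than the set of patients with event rows.
    """

    calls: pd.DataFrame
    patients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"patient", "gene", "alteration_class"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"alteration table lacks columns: {sorted(missing)}")
        bad = set(self.calls["alteration_class"]) - set(ALTERATION_CLASSES)
        if bad:
            raise ValueError(f"unknown alteration class(es): {sorted(bad)}")
        self.calls = self.calls.copy()
        self.calls["gene"] = self.calls["gene"].astype(str).str.upper()
        if not self.patients:
            self.patients = tuple(dict.fromkeys(self.calls["patient"]))


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    platform: str,
) -> ExpressionCohort:
    """Read a cohort from a matrix TSV (genes x samples) and a metadata TSV.

    The matrix file has a header row of sample identifiers and gene symbols
    in the first column; the metadata file is indexed by sample identifier.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    dup = values.index[values.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene row(s) in {matrix_path}: {dup[0]!r}")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionCohort(values=values, metadata=metadata, platform=platform)


def write_expression(cohort: ExpressionCohort, matrix_path, metadata_path) -> None:
    cohort.values.to_csv(matrix_path, sep="\t", index_label="gene")
    cohort.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GMT signature collections


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file (name, description, genes; tab-separated).

    Gene order is preserved and symbols are upper-cased.  Lines with fewer
    than three fields are rejected.
    """
    signatures: list[GeneSignature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            signatures.append(
                GeneSignature(name=name, genes=tuple(genes), description=description)
            )
    return signatures


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or sig.direction, *sig.genes]))
            fh.write("\n")


def packaged_signatures() -> list[GeneSignature]:
    """All signatures shipped with the package."""
    ref = importlib.resources.files("notchsig").joinpath("data/signatures.gmt")
    with importlib.resources.as_file(ref) as path:
        return read_gmt(path)


def notch_signature() -> GeneSignature:
    """The 20-gene Notch transcriptomic signature, genes in rank order."""
    return next(s for s in packaged_signatures() if s.name == "NOTCH20")


def notch_core_signature() -> GeneSignature:
    """Notch receptors (NOTCH1-4) and canonical ligands (JAG1/2, DLL1/3/4)."""
    return next(s for s in packaged_signatures() if s.name == "NOTCH_CORE")


# ---------------------------------------------------------------------------
# Networks


def read_edge_list(path: str | Path, hub: str) -> InteractionNetwork:
    """Read a 2-column (optionally 3-column weighted) edge-list TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] not in (2, 3):
        raise ValueError(f"edge list must have 2 or 3 columns, got {df.shape[1]}")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]).upper(), str(row[1]).upper()
        if df.shape[1] == 3:
            graph.add_edge(a, b, weight=float(row[2]))
        else:
            graph.add_edge(a, b)
    return InteractionNetwork(graph=graph, hub=hub)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    weighted = any("weight" in d for _, _, d in network.graph.edges(data=True))
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, d in sorted(network.graph.edges(data=True)):
            if weighted:
                fh.write(f"{a}\t{b}\t{d.get('weight', 1.0)}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Alteration tables


def read_alterations(path: str | Path) -> AlterationTable:
    calls = pd.read_csv(path, sep="\t", dtype=str)
    return AlterationTable(calls=calls)


def write_alterations(table: AlterationTable, path: str | Path) -> None:
    calls = table.calls
    covered = set(calls["patient"])
    extra = [p for p in table.patients if p not in covered]
    if extra:
        filler = pd.DataFrame(
            {"patient": extra, "gene": ".", "alteration_class": "none"}
        )
        calls = pd.concat([calls, filler], ignore_index=True)
    calls.to_csv(path, sep="\t", index=False)


def warn_dropped(what: str, dropped: Sequence[str]) -> None:
    """Shared warning for genes excluded from a computation."""
    if dropped:
        warnings.warn(
            f"{what}: dropped {len(dropped)} gene(s): {', '.join(sorted(dropped))}",
            stacklevel=3,
        )
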