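"""TF -> target regulatory network assembly and export.

Candidate transcription factors are those bound to a significant TFBS
whose own coding gene is up-regulated; an edge links a TF to a DUG whose
promoter carries at least one binding site (feature count > 0) for one
of the TF's PWMs. Edges are unweighted binding-presence links; a gene
that is itself a TF appears once with both roles. Networks export as SIF
("tf regulates gene"), GraphML (with node roles, labels, out-degree) and
plain 2-column edge lists; merging is a set union with condition labels
combined when sources disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pwm import PWM
from .scan import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "candidate_tfs",
    "build_network",
    "merge_networks",
    "export_network",
    "import_network",
]


def _normalize_label(label: str) -> str:
    return ";".join(sorted({p for p in label.split(";") if p}))


def _merge_label(a: str, b: str) -> str:
    return _normalize_label(f"{a};{b}")


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Bipartite-style TF -> gene network stored as a directed edge set."""

    edges: frozenset  # of (tf, gene) pairs
    tf_nodes: frozenset
    gene_nodes: frozenset
    gene_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, gene in self.edges:
            if tf not in self.tf_nodes or gene not in self.gene_nodes:
                raise ValueError(f"edge ({tf!r}, {gene!r}) references unknown node")
        object.__setattr__(
            self,
            "gene_labels",
            {g: _normalize_label(l) for g, l in self.gene_labels.items() if l},
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self, tf: str | None = None):
        degrees = {t: 0 for t in self.tf_nodes}
        for t, _ in self.edges:
            degrees[t] += 1
        return degrees if tf is None else degrees[tf]

    @property
    def unlinked_genes(self) -> frozenset:
        """Gene nodes carrying no edge — surfaced, never silently dropped."""
        linked = {g for _, g in self.edges}
        return frozenset(self.gene_nodes - linked)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        degrees = self.out_degree()
        for tf in sorted(self.tf_nodes):
            g.add_node(tf, role="tf", out_degree=degrees[tf])
        for gene in sorted(self.gene_nodes):
            if gene in g:
                g.nodes[gene]["role"] = "tf;gene"
            else:
                g.add_node(gene, role="gene")
            label = self.gene_labels.get(gene, "")
            if label:
                g.nodes[gene]["condition"] = label
        g.add_edges_from(sorted(self.edges))
        return g


def candidate_tfs(
    pwms: Sequence[PWM],
    tf_gene_map: Mapping[str, str],
    upregulated: set[str],
    significant_tfbs: set[str],
) -> set[str]:
    """TFs bound to a significant TFBS whose coding gene is up-regulated.

    TF names missing from ``tf_gene_map`` are dropped with a warning.
    """
    keep: set[str] = set()
    unmapped: set[str] = set()
    for pwm in pwms:
        if pwm.id not in significant_tfbs:
            continue
        for tf in pwm.tf_names:
            gene = tf_gene_map.get(tf)
            if gene is None:
                unmapped.add(tf)
            elif gene in upregulated:
                keep.add(tf)
    if unmapped:
        logger.warning("%d TF name(s) missing from the TF->gene map: %s",
                       len(unmapped), sorted(unmapped))
    return keep


def build_network(
    tfs: set[str],
    dugs: Mapping[str, str] | Iterable[str],
    features: FeatureMatrix,
    pwm_tf_links: Mapping[str, Sequence[str]],
) -> RegulatoryNetwork:
    """Link TFs to DUGs whose promoters carry their binding sites.

    ``dugs`` maps gene -> condition-dependency label (or is a plain
    iterable, in which case labels are empty). Edge (t, g) exists iff
    some PWM associated with t has feature value > 0 for gene g.
    """
    if isinstance(dugs, Mapping):
        labels = dict(dugs)
    else:
        labels = {g: "" for g in dugs}
    missing = set(labels) - set(features.gene_ids)
    if missing:
        raise ValueError(f"DUGs absent from the feature matrix: {sorted(missing)}")
    pwms_of: dict[str, list[str]] = {t: [] for t in tfs}
    for pwm_id, tf_names in pwm_tf_links.items():
        for tf in tf_names:
            if tf in pwms_of:
                pwms_of[tf].append(pwm_id)
    edges = set()
    values = features.values
    for tf in tfs:
        cols = [m for m in pwms_of[tf] if m in values.columns]
        if not cols:
            continue
        present = values.loc[list(labels), cols].sum(axis=1) > 0
        for gene in present.index[present]:
            edges.add((tf, gene))
    net = RegulatoryNetwork(
        frozenset(edges), frozenset(tfs), frozenset(labels), labels
    )
    logger.info("network: %d TFs, %d genes, %d edges (%d unlinked genes)",
                len(net.tf_nodes), len(net.gene_nodes), net.n_edges,
                len(net.unlinked_genes))
    return net


def merge_networks(a: RegulatoryNetwork, b: RegulatoryNetwork) -> RegulatoryNetwork:
    """Node/edge union; disagreeing gene labels are concatenated."""
    labels: dict[str, str] = dict(a.gene_labels)
    for gene, label in b.gene_labels.items():
        labels[gene] = _merge_label(labels.get(gene, ""), label)
    return RegulatoryNetwork(
        a.edges | b.edges,
        a.tf_nodes | b.tf_nodes,
        a.gene_nodes | b.gene_nodes,
        labels,
    )


def export_network(net: RegulatoryNetwork, path: str, fmt: str = "graphml") -> None:
    """Write the network as SIF, GraphML, or a 2-column edge list."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for tf, gene in sorted(net.edges):
                fh.write(f"{tf}\tregulates\t{gene}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif fmt == "edge-list":
        with open(path, "w") as fh:
            for tf, gene in sorted(net.edges):
                fh.write(f"{tf}\t{gene}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path: str, fmt: str = "graphml") -> RegulatoryNetwork:
    """Read a network written by :func:`export_network`."""
    if fmt in ("sif", "edge-list"):
        edges = set()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if fmt == "sif":
                    tf, _, gene = parts[0], parts[1], parts[2]
                else:
                    tf, gene = parts[0], parts[1]
                edges.add((tf, gene))
        tfs = frozenset(t for t, _ in edges)
        genes = frozenset(g for _, g in edges)
        return RegulatoryNetwork(frozenset(edges), tfs, genes, {})
    if fmt == "graphml":
        g = nx.read_graphml(path)
        tfs, genes, labels = set(), set(), {}
        for node, data in g.nodes(data=True):
            roles = data.get("role", "gene").split(";")
            if "tf" in roles:
                tfs.add(node)
            if "gene" in roles:
                genes.add(node)
                if data.get("condition"):
                    labels[node] = data["condition"]
        edges = frozenset((u, v) for u, v in g.edges())
        return RegulatoryNetwork(edges, frozenset(tfs), frozenset(genes), labels)
    raise ValueError(f"unknown network format {fmt!r}")
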