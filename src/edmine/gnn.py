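"""Genome neighborhood network (GNN) over gene-cluster proteomes.

Every protein of every cluster is a node; an edge connects two proteins
whose Smith-Waterman alignment reaches an E-value at or below a threshold
(default 1e-6, the display threshold for the full network).  Connected
components are protein families.  Families containing the E2/E3/R3
subfamilies are re-partitioned at a strict threshold (default 1e-75), which
separates the 9-membered marker E2 from the cassette gene E3 and the
10-membered marker R3 — the resolution needed for ring-size prediction.
Family labels are transferred from reference clusters by majority vote.

All pairs are aligned exactly (no heuristic seeding); a length-ratio
prefilter skips pairs whose lengths differ more than five-fold.  E-values
use the pairwise search-space convention m x n (product of the two
sequence lengths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import EvalueParams, SubstitutionMatrix, align_score, evalue

__all__ = [
    "ORF",
    "GeneCluster",
    "FamilyAssignment",
    "read_genbank_cluster",
    "cluster_from_genome",
    "all_vs_all",
    "build_gnn",
    "detect_families",
    "annotate_families",
    "cluster_profile",
    "cluster_similarity",
    "write_graphml",
    "write_edge_list",
]

DEFAULT_THRESHOLD = 1e-6
DEFAULT_STRICT_THRESHOLD = 1e-75
STRICT_LABELS = ("E2", "E3", "R3")
LENGTH_RATIO_SKIP = 5.0


@dataclass(frozen=True)
class ORF:
    orf_id: str
    start: int
    end: int      # 0-based half-open, plus-strand coordinates
    strand: str
    protein: str
    label: str | None = None  # reference gene label, reference clusters only


@dataclass
class GeneCluster:
    """An ordered set of ORFs from one gene cluster (or annotated genome)."""

    cluster_id: str
    source: str  # "reference" | "hit"
    orfs: list[ORF] = field(default_factory=list)

    def proteins(self) -> dict[str, str]:
        return {o.orf_id: o.protein for o in self.orfs}


def read_genbank_cluster(path, source: str = "hit") -> GeneCluster:
    """Parse a GenBank flat file with CDS features into a GeneCluster.

    The protein comes from the ``translation`` qualifier when present
    (mismatches against the re-translated CDS warn; the qualifier wins),
    else from table-11 translation of the (possibly compound) location.
    Gene labels are kept only for ``source="reference"`` clusters, so hit
    annotation can never leak into family labeling.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: not a single-record GenBank file ({exc})") from exc
    orfs = []
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        extracted = feat.location.extract(record.seq)
        translated = str(extracted.translate(table=11)).rstrip("*")
        qual = feat.qualifiers.get("translation", [None])[0]
        if qual and qual != translated:
            warnings.warn(f"{path.name} CDS {i}: translation qualifier disagrees "
                          "with the sequence; keeping the qualifier")
        protein = qual or translated
        label = None
        if source == "reference":
            label = feat.qualifiers.get("gene", [None])[0]
        orf_id = feat.qualifiers.get("locus_tag", [f"orf{i:03d}"])[0]
        orfs.append(ORF(orf_id, int(feat.location.start), int(feat.location.end),
                        "+" if feat.location.strand != -1 else "-", protein, label))
    if not orfs:
        raise ValueError(f"{path}: no CDS features")
    return GeneCluster(record.id or path.stem, source, orfs)


def cluster_from_genome(genome, source: str = "hit", use_labels: bool = False) -> GeneCluster:
    """Build a GeneCluster from an annotated in-memory genome record."""
    orfs = []
    for i, feat in enumerate(genome.features):
        from .simulate import translate_cds
        protein = translate_cds(genome.gene_dna(feat))
        label = feat.label if use_labels else None
        orfs.append(ORF(f"{genome.genome_id}_{i:03d}", feat.start, feat.end,
                        feat.strand, protein, label))
    if not orfs:
        raise ValueError(f"genome {genome.genome_id} has no annotated genes")
    return GeneCluster(genome.genome_id, source, orfs)


Node = tuple[str, str]  # (cluster_id, orf_id)


def all_vs_all(
    clusters: list[GeneCluster],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    evalue_params: EvalueParams | None = None,
    max_evalue: float | None = 1e-3,
    length_ratio_skip: float = LENGTH_RATIO_SKIP,
) -> pd.DataFrame:
    """Score every unordered protein pair (within and across clusters).

    Returns a frame with cluster/orf ids, the local alignment score and the
    Karlin-Altschul E-value.  Pairs above ``max_evalue`` (the loosest
    threshold anyone will build a network at) are dropped; pairs whose
    lengths differ more than ``length_ratio_skip``-fold are skipped.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    matrix = matrix or SubstitutionMatrix.blosum62()
    params = evalue_params or EvalueParams()
    entries: list[tuple[Node, str]] = []
    for c in clusters:
        for o in c.orfs:
            entries.append(((c.cluster_id, o.orf_id), o.protein))
    rows = []
    for i in range(len(entries)):
        (ca, oa), pa = entries[i]
        for j in range(i + 1, len(entries)):
            (cb, ob), pb = entries[j]
            la, lb = len(pa), len(pb)
            if max(la, lb) > length_ratio_skip * min(la, lb):
                continue
            score = align_score(pa, pb, matrix, gap_open, gap_extend, mode="local")
            e = evalue(score, la, lb, params)
            if max_evalue is None or e <= max_evalue:
                rows.append((ca, oa, cb, ob, score, e))
    return pd.DataFrame(rows, columns=["cluster_a", "orf_a", "cluster_b", "orf_b",
                                       "score", "evalue"])


def build_gnn(
    pairs: pd.DataFrame,
    clusters: list[GeneCluster],
    threshold: float = DEFAULT_THRESHOLD,
) -> nx.Graph:
    """Thresholded homology graph: nodes are all cluster proteins, edges are
    pairs with E <= threshold.  Simple and undirected; the build threshold
    is recorded on the graph."""
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    g = nx.Graph(threshold=threshold)
    for c in clusters:
        for o in c.orfs:
            g.add_node((c.cluster_id, o.orf_id), cluster=c.cluster_id,
                       label=o.label or "", source=c.source, length=len(o.protein))
    for row in pairs.itertuples(index=False):
        if row.evalue <= threshold:
            a, b = (row.cluster_a, row.orf_a), (row.cluster_b, row.orf_b)
            if a != b:
                g.add_edge(a, b, evalue=float(row.evalue), score=float(row.score))
    return g


@dataclass
class FamilyAssignment:
    """Partition of GNN nodes into families, with optional labels."""

    families: dict[Node, int]          # node -> dense family id from 1
    labels: dict[int, str] = field(default_factory=dict)

    def members(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {}
        for node, fid in self.families.items():
            out.setdefault(fid, []).append(node)
        return {fid: sorted(m) for fid, m in out.items()}

    def label_of(self, fid: int) -> str:
        return self.labels.get(fid, "unknown_family")

    def family_of(self, node: Node) -> int:
        return self.families[node]


def detect_families(
    graph: nx.Graph,
    strict_threshold: float | None = DEFAULT_STRICT_THRESHOLD,
    strict_labels: tuple[str, ...] = STRICT_LABELS,
) -> FamilyAssignment:
    """Families = connected components of the thresholded graph.

    Components containing a node whose reference label is one of
    ``strict_labels`` (the E2/E3/R3 superfamily) are re-partitioned using
    only edges with E <= strict_threshold, separating the subfamilies.
    Family ids are dense from 1, ordered by smallest member node.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    final: list[list[Node]] = []
    for comp in comps:
        needs_split = strict_threshold is not None and any(
            graph.nodes[n].get("label") in strict_labels for n in comp
        )
        if needs_split:
            sub = graph.subgraph(comp).copy()
            sub.remove_edges_from([
                (u, v) for u, v, d in sub.edges(data=True)
                if d.get("evalue", 1.0) > strict_threshold
            ])
            final.extend(sorted(c) for c in nx.connected_components(sub))
        else:
            final.append(comp)
    final.sort(key=lambda c: c[0])
    families = {n: fid for fid, comp in enumerate(final, start=1) for n in comp}
    return FamilyAssignment(families)


def annotate_families(
    assignment: FamilyAssignment,
    references: list[GeneCluster],
) -> FamilyAssignment:
    """Label each family by the majority gene label among its reference
    members (lexicographic tie-break); families with no reference member are
    ``unknown_family``; size-1 families are ``singleton``."""
    ref_labels: dict[Node, str] = {}
    for c in references:
        for o in c.orfs:
            if o.label:
                ref_labels[(c.cluster_id, o.orf_id)] = o.label
    labels: dict[int, str] = {}
    for fid, members in assignment.members().items():
        if len(members) == 1:
            labels[fid] = "singleton"
            continue
        votes: dict[str, int] = {}
        for n in members:
            lab = ref_labels.get(n)
            if lab:
                votes[lab] = votes.get(lab, 0) + 1
        if votes:
            labels[fid] = min(votes, key=lambda k: (-votes[k], k))
        else:
            labels[fid] = "unknown_family"
    return FamilyAssignment(dict(assignment.families), labels)


def cluster_profile(assignment: FamilyAssignment, clusters: list[GeneCluster]) -> pd.DataFrame:
    """Integer counts of family members per cluster (clusters x families).

    Row sums equal ORF counts: families partition the node set because the
    graph carries every protein as a node (isolated ones included)."""
    fids = sorted(set(assignment.families.values()))
    cids = [c.cluster_id for c in clusters]
    prof = pd.DataFrame(0, index=cids, columns=fids, dtype=int)
    for (cid, _orf), fid in assignment.families.items():
        if cid in prof.index:
            prof.loc[cid, fid] += 1
    return prof


def cluster_similarity(profile: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-family counts and Jaccard similarity on family presence."""
    presence = (profile > 0).astype(int)
    shared = presence @ presence.T
    counts = presence.sum(axis=1).to_numpy()
    union = counts[:, None] + counts[None, :] - shared.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, shared.to_numpy() / union, 0.0)
    jaccard = pd.DataFrame(jac, index=profile.index, columns=profile.index)
    return shared, jaccard


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export with string node ids ``cluster:orf``."""
    g = nx.relabel_nodes(graph, {n: f"{n[0]}:{n[1]}" for n in graph.nodes})
    nx.write_graphml(g, str(path))


def write_edge_list(graph: nx.Graph, path) -> None:
    """Three-column edge list: node_a, node_b, evalue."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tevalue\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u[0]}:{u[1]}\t{v[0]}:{v[1]}\t{d['evalue']:.3e}\n")
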