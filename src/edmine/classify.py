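"""Structure prediction from GNN family content.

Ring size follows the exclusive-presence rule: a cluster whose proteome
hits the E2 marker subfamily (and not R3) is predicted to encode a
9-membered enediyne; R3 without E2 predicts 10-membered; both markers is
ambiguous; neither is unknown.  Because E2, E3 and R3 are homologous, the
rule operates on the strict-threshold subfamilies, not on the permissive
superfamily.

Peripheral moieties (chromoprotein apoprotein, beta-amino acid, amino
sugar, benzoxazolinate) are predicted from curated reference gene sets: a
moiety is called when the cluster hits at least ``min_hits`` of the set's
gene families.  A novelty report counts families without reference members
and singletons — the "unknown chemistry" signal of a new cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .gnn import FamilyAssignment, GeneCluster, Node
from .simulate import MOIETY_GENE_SETS

__all__ = [
    "RingPrediction",
    "MoietyPrediction",
    "default_moiety_definitions",
    "load_moiety_definitions",
    "predict_ring_size",
    "predict_moieties",
    "novelty_report",
    "prediction_table",
]


@dataclass(frozen=True)
class RingPrediction:
    cluster_id: str
    call: str  # nine | ten | ambiguous | unknown
    evidence: tuple[tuple[str, int, float], ...] = ()  # (marker, family_id, best E)


@dataclass(frozen=True)
class MoietyPrediction:
    cluster_id: str
    moieties: frozenset[str]
    evidence: dict[str, dict[str, int]] = field(default_factory=dict)  # moiety -> label -> family


def default_moiety_definitions() -> dict[str, tuple[tuple[str, ...], int]]:
    """Shipped moiety gene sets with min-hit thresholds: the apoprotein is a
    single gene (min 1); multi-gene pathways require a majority of the set."""
    defs = {}
    for name, labels in MOIETY_GENE_SETS.items():
        min_hits = 1 if len(labels) == 1 else math.ceil(len(labels) / 2)
        defs[name] = (tuple(labels), min_hits)
    return defs


def load_moiety_definitions(path) -> dict[str, tuple[tuple[str, ...], int]]:
    """Parse a plain-text moiety config: ``name: lab1,lab2,...: min_hits``.

    Blank lines and ``#`` comments are ignored; a name outside the four
    canonical moieties is an error.
    """
    defs: dict[str, tuple[tuple[str, ...], int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(":")]
        if len(parts) != 3:
            raise ValueError(f"malformed moiety definition line: {raw!r}")
        name, labels, min_hits = parts
        if name not in MOIETY_GENE_SETS:
            raise ValueError(f"unknown moiety name {name!r}")
        defs[name] = (tuple(x.strip() for x in labels.split(",") if x.strip()), int(min_hits))
    return defs


def _marker_families(assignment: FamilyAssignment, references: list[GeneCluster],
                     label: str) -> set[int]:
    fids = set()
    for c in references:
        for o in c.orfs:
            if o.label == label:
                node = (c.cluster_id, o.orf_id)
                if node in assignment.families:
                    fids.add(assignment.families[node])
    return fids


def _label_families(assignment: FamilyAssignment, references: list[GeneCluster]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for c in references:
        for o in c.orfs:
            if o.label and (c.cluster_id, o.orf_id) in assignment.families:
                out.setdefault(o.label, set()).add(assignment.families[(c.cluster_id, o.orf_id)])
    return out


def _best_evidence(graph: nx.Graph | None, nodes: list[Node]) -> float:
    if graph is None:
        return float("nan")
    best = float("inf")
    for n in nodes:
        for _, _, d in graph.edges(n, data=True):
            best = min(best, d.get("evalue", float("inf")))
    return best if best < float("inf") else float("nan")


def predict_ring_size(
    assignment: FamilyAssignment,
    clusters: list[GeneCluster],
    references: list[GeneCluster],
    graph: nx.Graph | None = None,
) -> list[RingPrediction]:
    """Exclusive-presence ring-size call per (non-reference) cluster."""
    e2_fids = _marker_families(assignment, references, "E2")
    r3_fids = _marker_families(assignment, references, "R3")
    if not e2_fids and not r3_fids:
        raise ValueError("no reference E2 or R3 marker proteins available")
    preds = []
    for c in clusters:
        evidence = []
        for marker, fids in (("E2", e2_fids), ("R3", r3_fids)):
            member_nodes = [(c.cluster_id, o.orf_id) for o in c.orfs
                            if assignment.families.get((c.cluster_id, o.orf_id)) in fids]
            for fid in sorted({assignment.families[n] for n in member_nodes}):
                in_fid = [n for n in member_nodes if assignment.families[n] == fid]
                evidence.append((marker, fid, _best_evidence(graph, in_fid)))
        has_e2 = any(m == "E2" for m, _, _ in evidence)
        has_r3 = any(m == "R3" for m, _, _ in evidence)
        if has_e2 and has_r3:
            call = "ambiguous"
        elif has_e2:
            call = "nine"
        elif has_r3:
            call = "ten"
        else:
            call = "unknown"
        preds.append(RingPrediction(c.cluster_id, call, tuple(evidence)))
    return preds


def predict_moieties(
    assignment: FamilyAssignment,
    clusters: list[GeneCluster],
    references: list[GeneCluster],
    definitions: dict[str, tuple[tuple[str, ...], int]] | None = None,
) -> list[MoietyPrediction]:
    """Call each moiety when the cluster hits >= min_hits of its gene set."""
    definitions = definitions or default_moiety_definitions()
    unknown = set(definitions) - set(MOIETY_GENE_SETS)
    if unknown:
        raise ValueError(f"unknown moiety names {sorted(unknown)}")
    by_label = _label_families(assignment, references)
    preds = []
    for c in clusters:
        cluster_fids = {assignment.families[(c.cluster_id, o.orf_id)] for o in c.orfs
                        if (c.cluster_id, o.orf_id) in assignment.families}
        called = set()
        evidence: dict[str, dict[str, int]] = {}
        for moiety, (labels, min_hits) in definitions.items():
            hits = {}
            for lab in labels:
                shared = by_label.get(lab, set()) & cluster_fids
                if shared:
                    hits[lab] = min(shared)
            if len(hits) >= min_hits:
                called.add(moiety)
                evidence[moiety] = hits
        preds.append(MoietyPrediction(c.cluster_id, frozenset(called), evidence))
    return preds


def novelty_report(
    assignment: FamilyAssignment,
    clusters: list[GeneCluster],
    references: list[GeneCluster],
) -> pd.DataFrame:
    """Per-cluster counts of families lacking any reference member
    ('novel'), unlabeled families, and singletons."""
    ref_nodes = {(c.cluster_id, o.orf_id) for c in references for o in c.orfs}
    members = assignment.members()
    fam_has_ref = {fid: any(n in ref_nodes for n in m) for fid, m in members.items()}
    fam_size = {fid: len(m) for fid, m in members.items()}
    rows = []
    for c in clusters:
        fids = {assignment.families[(c.cluster_id, o.orf_id)] for o in c.orfs
                if (c.cluster_id, o.orf_id) in assignment.families}
        n_unknown = sum(1 for f in fids if assignment.label_of(f) in ("unknown_family", "singleton"))
        n_single = sum(1 for f in fids if fam_size[f] == 1)
        n_novel = sum(1 for f in fids if not fam_has_ref[f])
        rows.append((c.cluster_id, len(fids), n_unknown, n_single, n_novel))
    return pd.DataFrame(rows, columns=[
        "cluster_id", "n_families", "n_unknown_families", "n_singletons", "n_novel_families",
    ])


def prediction_table(
    rings: list[RingPrediction],
    moieties: list[MoietyPrediction],
    novelty: pd.DataFrame,
) -> pd.DataFrame:
    """One row per cluster: ring call, moiety calls, novelty counts."""
    ring_map = {r.cluster_id: r.call for r in rings}
    moiety_map = {m.cluster_id: ",".join(sorted(m.moieties)) for m in moieties}
    out = novelty.copy()
    out.insert(1, "ring_call", [ring_map.get(c, "unknown") for c in out.cluster_id])
    out.insert(2, "moieties", [moiety_map.get(c, "") for c in out.cluster_id])
    return out
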