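"""Dereplication of screening hits by E-fragment identity.

The translated ~1-kb internal fragment of the PKS gene E is the marker for
strain dereplication: a pairwise percent-identity matrix over fragments is
collapsed at an identity cutoff (default 90%) into clades, one medoid
representative is chosen per clade, and a neighbor-joining tree provides the
phylogenetic view of the cohort.

Clade collapsing is single-linkage: strains are clade-mates whenever they
are connected through pairs at or above the cutoff.  Complete linkage is
available for comparison.  Distances for the tree are p-distances
(100 - identity)/100, optionally Poisson-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .align import SubstitutionMatrix, global_align

__all__ = [
    "IdentityMatrix",
    "CladePartition",
    "extract_internal_fragment",
    "identity_matrix",
    "nj_tree",
    "collapse_clades",
    "pick_representatives",
]

DEFAULT_WINDOW_BP = 999
DEFAULT_CUTOFF = 90.0


def extract_internal_fragment(e_gene: str, window_bp: int = DEFAULT_WINDOW_BP) -> str:
    """The centered, frame-preserving internal window of an E-gene CDS.

    The window start is the CDS midpoint offset rounded down to a codon
    boundary; a window length not divisible by 3 is rounded down with a
    warning so the fragment stays in frame.
    """
    if window_bp % 3:
        window_bp -= window_bp % 3
        warnings.warn(f"window rounded down to {window_bp} bp to preserve frame")
    if window_bp <= 0:
        raise ValueError("window must be at least one codon")
    if len(e_gene) < window_bp + 6:
        raise ValueError(
            f"CDS of {len(e_gene)} bp too short for a {window_bp}-bp internal window; "
            "reduce window_bp"
        )
    offset_codons = (len(e_gene) - window_bp) // 2 // 3
    start = 3 * offset_codons
    return e_gene[start:start + window_bp]


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over named fragments."""

    ids: list[str]
    values: np.ndarray  # percent, diagonal 100

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IdentityMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))


def identity_matrix(
    fragments: dict[str, str],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> IdentityMatrix:
    """Global-alignment percent identity for every unordered fragment pair."""
    ids = sorted(fragments)
    if len(ids) < 2:
        raise ValueError("need at least two fragments")
    for sid in ids:
        if not fragments[sid]:
            raise ValueError(f"fragment for {sid!r} is empty")
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(fragments[ids[i]], fragments[ids[j]], matrix, gap_open, gap_extend)
            vals[i, j] = vals[j, i] = res.identity_pct
    return IdentityMatrix(ids, vals)


def nj_tree(matrix: IdentityMatrix, poisson_correction: bool = False) -> TreeNode:
    """Saitou-Nei neighbor joining on fragment distances.

    Distances are (100 - identity)/100 (p-distance), optionally Poisson
    corrected -ln(1 - p).  Negative branch-length estimates are clamped to
    zero with the deficit moved to the sibling edge.  Returns an unrooted
    :class:`skbio.TreeNode` (serializable to Newick).
    """
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = (100.0 - matrix.values) / 100.0
    if poisson_correction:
        d = -np.log(np.clip(1.0 - d, 1e-12, None))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry despite float round-off
    dm = DistanceMatrix(d, ids=matrix.ids)
    return _skbio_nj(dm, neg_as_zero=True)


@dataclass
class CladePartition:
    """Single-linkage collapse of the identity matrix at a cutoff."""

    cutoff: float
    assignment: dict[str, int]  # strain -> dense clade id from 1

    def clades(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, cid in self.assignment.items():
            out.setdefault(cid, []).append(sid)
        return {cid: sorted(members) for cid, members in out.items()}

    def n_clades(self) -> int:
        return len(set(self.assignment.values()))

    def labels(self, order: list[str]) -> list[int]:
        return [self.assignment[s] for s in order]


def collapse_clades(
    matrix: IdentityMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    linkage: str = "single",
) -> CladePartition:
    """Collapse fragments into clades at an identity cutoff.

    Single linkage (default) takes connected components of the graph with
    edges at identity >= cutoff — the operation that collapses a phylogram's
    tight groups into one clade each.  Complete linkage requires every
    within-clade pair to reach the cutoff (greedy agglomeration, for
    comparison only).
    """
    if not 0.0 < cutoff <= 100.0:
        raise ValueError("cutoff must lie in (0, 100]")
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ids, vals = matrix.ids, matrix.values
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if vals[i, j] >= cutoff:
                    g.add_edge(ids[i], ids[j])
        comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    else:
        from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
        from scipy.spatial.distance import squareform
        dist = 100.0 - vals
        np.fill_diagonal(dist, 0.0)
        z = _scipy_linkage(squareform(dist, checks=False), method="complete")
        flat = fcluster(z, t=100.0 - cutoff, criterion="distance")
        groups: dict[int, list[str]] = {}
        for sid, k in zip(ids, flat):
            groups.setdefault(int(k), []).append(sid)
        comps = sorted((sorted(c) for c in groups.values()), key=lambda c: c[0])
    assignment = {sid: k + 1 for k, comp in enumerate(comps) for sid in comp}
    return CladePartition(cutoff, assignment)


def pick_representatives(partition: CladePartition, matrix: IdentityMatrix) -> dict[int, str]:
    """Medoid representative per clade: the member maximizing summed identity
    to its clade-mates; ties broken lexicographically."""
    reps: dict[int, str] = {}
    for cid, members in partition.clades().items():
        if len(members) == 1:
            reps[cid] = members[0]
            continue
        idx = [matrix.ids.index(m) for m in members]
        sub = matrix.values[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        best = min(range(len(members)), key=lambda k: (-sums[k], members[k]))
        reps[cid] = members[best]
    return reps
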