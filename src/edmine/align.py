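"""Pairwise protein alignment and alignment statistics.

This module is the scoring engine shared by every stage of the mining
pipeline: percent identities for clade collapsing are computed with global
(Needleman-Wunsch) alignment, and genome-neighborhood-network edges are
scored with local (Smith-Waterman) alignment converted to Karlin-Altschul
expected-hit counts (E-values).

Alignments are computed with Biopython's :class:`Bio.Align.PairwiseAligner`
(an exact affine-gap dynamic program, not a heuristic seeded search).  A gap
of length ``L`` costs ``gap_open + L * gap_extend``, the BLAST convention.
Percent identity is defined over *all* alignment columns, including gap
columns; this denominator is part of the contract because the 90% clade
cutoff downstream is only reproducible for a fixed definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AlphabetError",
    "DegenerateInputError",
    "SubstitutionMatrix",
    "AlignmentResult",
    "EvalueParams",
    "global_align",
    "local_align",
    "align_score",
    "evalue",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: default affine gap penalties (cost of a length-L gap is open + L * extend)
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


class DegenerateInputError(ValueError):
    """An input sequence is empty or otherwise unusable."""


class AlphabetError(ValueError):
    """A sequence contains a residue absent from the substitution matrix."""


class SubstitutionMatrix:
    """Symmetric residue substitution scores over a fixed alphabet.

    Wraps a :class:`Bio.Align.substitution_matrices.Array`.  Invariants
    checked at construction: symmetry, and every diagonal entry strictly
    above its row minimum (so self-alignment is always favoured).  The
    ambiguity symbol ``X`` scores 0 against everything, including itself.
    """

    def __init__(self, array: substitution_matrices.Array):
        alphabet = str(array.alphabet)
        for a in alphabet:
            row = [array[a, b] for b in alphabet]
            # the ambiguity symbol scores flat zero, so it is exempt from the
            # diagonal-dominance check every real residue must satisfy
            if a != "X" and array[a, a] <= min(s for b, s in zip(alphabet, row) if b != a):
                raise ValueError(f"diagonal score for {a!r} not above row minimum")
            for b in alphabet:
                if array[a, b] != array[b, a]:
                    raise ValueError(f"asymmetric scores for pair ({a!r}, {b!r})")
        self._array = array
        self.alphabet = alphabet

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self._array[pair])

    @property
    def array(self) -> substitution_matrices.Array:
        return self._array

    @classmethod
    def from_dict(cls, alphabet: str, scores: dict[tuple[str, str], float]) -> "SubstitutionMatrix":
        arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
        for (a, b), s in scores.items():
            arr[a, b] = s
            arr[b, a] = s
        return cls(arr)

    @classmethod
    def from_ncbi_file(cls, path) -> "SubstitutionMatrix":
        """Read an NCBI-format substitution matrix text file."""
        return cls(substitution_matrices.read(str(path)))

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return _blosum62()


@lru_cache(maxsize=1)
def _blosum62() -> SubstitutionMatrix:
    """Built-in BLOSUM62 restricted to the 20 amino acids + 'X' (scored 0)."""
    full = substitution_matrices.load("BLOSUM62")
    sub = full.select(PROTEIN_ALPHABET + "X")
    for a in PROTEIN_ALPHABET + "X":
        sub["X", a] = 0.0
        sub[a, "X"] = 0.0
    return SubstitutionMatrix(sub)


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with its score and column-wise identity."""

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_columns: int

    @property
    def identity_pct(self) -> float:
        """100 x identical columns / alignment columns (gap columns count)."""
        if self.n_columns == 0:
            return 0.0
        return 100.0 * self.n_identical / self.n_columns

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters for converting scores to E-values.

    Defaults are the standard gapped-BLOSUM62 statistics (lambda = 0.267
    nats per score unit, K = 0.041).  The search space is the product of
    the two ungapped sequence lengths (pairwise convention: no database
    size enters, and thresholding is monotone-equivalent to any fixed
    database-wide convention).
    """

    lambda_: float = 0.267
    k_: float = 0.041

    def __post_init__(self):
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda_ and k_ must be positive")


def _validate(seq: str, matrix: SubstitutionMatrix, name: str) -> None:
    if not seq:
        raise DegenerateInputError(f"sequence {name!r} is empty")
    extra = set(seq) - set(matrix.alphabet)
    if extra:
        sym = sorted(extra)[0]
        raise AlphabetError(f"residue {sym!r} in sequence {name!r} is not in the matrix alphabet")


def _aligner(matrix: SubstitutionMatrix, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix.array
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _result(aligned_a: str, aligned_b: str, score: float) -> AlignmentResult:
    n_id = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return AlignmentResult(aligned_a, aligned_b, float(score), n_id, len(aligned_a))


def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment under affine gaps.

    Raises :class:`DegenerateInputError` for an empty sequence and
    :class:`AlphabetError` for a residue the matrix does not know.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    _validate(a, matrix, "a")
    _validate(b, matrix, "b")
    aligner = _aligner(matrix, gap_open, gap_extend, "global")
    aln = aligner.align(a, b)[0]
    return _result(str(aln[0]), str(aln[1]), aln.score)


def local_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment under affine gaps.

    When no residue pair scores positively the optimal local alignment is
    empty: the result has score 0 and zero columns.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    _validate(a, matrix, "a")
    _validate(b, matrix, "b")
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult("", "", 0.0, 0, 0)
    aln = aligner.align(a, b)[0]
    return _result(str(aln[0]), str(aln[1]), aln.score)


def align_score(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mode: str = "local",
) -> float:
    """Alignment score only (no traceback); the fast path for bulk scoring."""
    matrix = matrix or SubstitutionMatrix.blosum62()
    _validate(a, matrix, "a")
    _validate(b, matrix, "b")
    score = _aligner(matrix, gap_open, gap_extend, mode).score(a, b)
    if mode == "local":
        score = max(score, 0.0)
    return float(score)


def evalue(score: float, len_a: int, len_b: int, params: EvalueParams | None = None) -> float:
    """Karlin-Altschul expected hit count E = K * m * n * exp(-lambda * S).

    Strictly decreasing in the score and linear in each sequence length.
    """
    params = params or EvalueParams()
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    return params.k_ * len_a * len_b * math.exp(-params.lambda_ * score)
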