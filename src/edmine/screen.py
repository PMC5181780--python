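"""In-silico analog of the high-throughput real-time PCR genome survey.

Two primer pairs target the E5/E and E/E10 junctions of the enediyne PKS
gene cassette; a third pair brackets the 1-kb internal fragment of E used
downstream for dereplication.  A strain producing both junction amplicons
has E5/E/E10 clustered; one amplicon means a split cassette (E5 or E10 away
from E); neither means no cassette.  Predicted amplicon melting temperature
(salt-adjusted GC/length formula) stands in for the melting-curve peak that
identifies specific products on a real instrument.

Coordinates are 0-based, half-open, on the plus strand throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "Primer",
    "PrimerPair",
    "AmpliconHit",
    "ScreenResult",
    "find_primer_sites",
    "amplify",
    "melt_tm",
    "call_architecture",
    "screen_genome",
    "screen_cohort",
    "screen_table",
    "DISTINCT_PEAK_DELTA_C",
]

#: two products count as distinct melting peaks when their Tm differ by this
DISTINCT_PEAK_DELTA_C = 0.5

#: 3'-terminal bases in which no mismatch is tolerated (polymerase clamp)
CLAMP_BASES = 3

DEFAULT_MIN_LEN = 300
DEFAULT_MAX_LEN = 3000


@dataclass(frozen=True)
class Primer:
    """A PCR primer: name, 5'->3' sequence, and mismatch tolerance."""

    name: str
    sequence: str
    max_mismatches: int = 2

    def __post_init__(self):
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"primer {self.name!r} contains non-ACGT symbols {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: Primer
    rev: Primer


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product (plus-strand genome coordinates)."""

    genome_id: str
    pair: str
    start: int
    end: int
    strand: str
    length: int
    tm: float
    seq: str = ""


@dataclass
class ScreenResult:
    """Per-strain screening outcome.

    ``architecture`` is 'clustered' when both junction pairs amplify,
    'split' when exactly one does, 'negative' when neither does.
    """

    strain_id: str
    e5_e: bool
    e_e10: bool
    architecture: str
    hits: list[AmpliconHit] = field(default_factory=list)


def _site_scan(seq: str, probe: str, max_mm: int, clamp_at_start: bool):
    """All start offsets where ``probe`` matches ``seq`` with <= max_mm
    mismatches and zero mismatches in the clamp region."""
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    if p.size > s.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, p.size)
    mism = windows != p
    counts = mism.sum(axis=1)
    clamp = mism[:, :CLAMP_BASES] if clamp_at_start else mism[:, -CLAMP_BASES:]
    ok = np.flatnonzero((counts <= max_mm) & (clamp.sum(axis=1) == 0))
    return [(int(i), int(counts[i])) for i in ok]


def find_primer_sites(genome, primer: Primer) -> list[tuple[int, str, int]]:
    """All binding sites of ``primer`` on both strands of ``genome``.

    Returns ``(position, strand, n_mismatches)`` tuples where ``position``
    is the start of the plus-strand footprint.  A minus-strand site is a
    plus-strand occurrence of the primer's reverse complement; the 3' clamp
    then sits at the footprint's left edge.
    """
    seq = genome.seq if hasattr(genome, "seq") else str(genome)
    if not seq:
        raise ValueError("genome sequence is empty")
    sites = [(pos, "+", mm) for pos, mm in
             _site_scan(seq, primer.sequence, primer.max_mismatches, clamp_at_start=False)]
    rc = str(Seq(primer.sequence).reverse_complement())
    sites += [(pos, "-", mm) for pos, mm in
              _site_scan(seq, rc, primer.max_mismatches, clamp_at_start=True)]
    return sorted(sites)


def melt_tm(amplicon: str, na_molar: float = 0.05) -> float:
    """Salt-adjusted GC/length melting temperature (degrees C).

    Tm = 81.5 + 16.6 log10([Na+]) + 0.41 (%GC) - 675 / length.  Valid for
    products well beyond nearest-neighbor length limits, which is why it is
    the default for 0.3-3 kb amplicons.
    """
    if na_molar <= 0:
        raise ValueError("sodium concentration must be positive")
    if len(amplicon) < 14:
        raise ValueError("amplicon shorter than 14 nt")
    gc_pct = 100.0 * sum(amplicon.count(b) for b in "GC") / len(amplicon)
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_pct - 675.0 / len(amplicon)


def amplify(
    genome,
    fwd: Primer,
    rev: Primer,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    pair_name: str = "",
    na_molar: float = 0.05,
) -> list[AmpliconHit]:
    """Predict PCR products: every plus-strand forward site paired with every
    downstream minus-strand reverse site within the length window.

    The product spans the forward primer's 5' start through the reverse
    primer's 5' start, inclusive of both primer footprints.
    """
    if min_len > max_len:
        raise ValueError("min_len exceeds max_len")
    genome_id = getattr(genome, "genome_id", "")
    seq = genome.seq if hasattr(genome, "seq") else str(genome)
    fwd_sites = [p for p, strand, _ in find_primer_sites(genome, fwd) if strand == "+"]
    rev_sites = [p for p, strand, _ in find_primer_sites(genome, rev) if strand == "-"]
    hits = []
    for p in fwd_sites:
        for q in rev_sites:
            end = q + len(rev)
            length = end - p
            if q >= p and min_len <= length <= max_len:
                product = seq[p:end]
                hits.append(AmpliconHit(
                    genome_id, pair_name or f"{fwd.name}/{rev.name}",
                    p, end, "+", length, melt_tm(product, na_molar), product,
                ))
    return hits


def call_architecture(e5_e: bool, e_e10: bool) -> str:
    """Cassette architecture from the two junction-amplicon flags."""
    if e5_e and e_e10:
        return "clustered"
    if e5_e or e_e10:
        return "split"
    return "negative"


def screen_genome(
    genome,
    pairs: list[PrimerPair],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ScreenResult:
    """Run every primer pair against one genome and call the architecture."""
    hits: list[AmpliconHit] = []
    flags: dict[str, bool] = {}
    for pair in pairs:
        pair_hits = amplify(genome, pair.fwd, pair.rev, min_len, max_len, pair.name)
        flags[pair.name] = bool(pair_hits)
        hits.extend(pair_hits)
    e5_e = flags.get("E5_E", False)
    e_e10 = flags.get("E_E10", False)
    strain_id = getattr(genome, "genome_id", "")
    return ScreenResult(strain_id, e5_e, e_e10, call_architecture(e5_e, e_e10), hits)


def screen_cohort(genomes, pairs, min_len=DEFAULT_MIN_LEN, max_len=DEFAULT_MAX_LEN):
    """Screen a list of genomes; returns one :class:`ScreenResult` each."""
    return [screen_genome(g, pairs, min_len, max_len) for g in genomes]


def screen_table(results: list[ScreenResult]):
    """Flatten screen results into a tidy table (one row per amplicon, plus
    a negative row for strains with no product)."""
    import pandas as pd

    rows = []
    for r in results:
        if not r.hits:
            rows.append((r.strain_id, "", -1, -1, "", 0, float("nan"), r.architecture))
        for h in r.hits:
            rows.append((r.strain_id, h.pair, h.start, h.end, h.strand, h.length, h.tm,
                         r.architecture))
    return pd.DataFrame(
        rows,
        columns=["strain_id", "pair_id", "start", "end", "strand", "length", "tm", "architecture"],
    )
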