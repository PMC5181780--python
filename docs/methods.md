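# Methods

This note documents the models, parameter choices and numerical conventions
behind `edmine`, and what validation on synthetic cohorts does and does not
establish about real data.

## Alignment and statistics

All percent identities come from global Needleman–Wunsch alignment and all
network edges from local Smith–Waterman alignment, both computed exactly
(no heuristic seeding) by Biopython's `PairwiseAligner` under affine gaps.
Defaults are BLOSUM62 with gap open 10 and gap extend 0.5, the de-facto
standard for protein comparison; a gap of length L costs `open + L·extend`.
The built-in matrix is BLOSUM62 restricted to the 20 amino acids plus `X`,
with `X` scored 0 against everything; matrices in NCBI text format can be
substituted.

**Percent identity** is defined as identical columns divided by *all*
alignment columns, gap columns included. The 90% dereplication cutoff is
only meaningful relative to a fixed denominator; this one is the stricter
choice (gaps can only lower identity) and is stated here so results are
reproducible.

**E-values** follow Karlin–Altschul, `E = K·m·n·exp(−λS)`, with the gapped
BLOSUM62 defaults λ = 0.267 nats per score unit and K = 0.041, both
configurable. The search space `m·n` is the product of the two ungapped
sequence lengths (pairwise convention). No database size enters; for
thresholding this is monotone-equivalent to any fixed database-wide
convention, and it keeps each pair's statistic self-contained.

Alignment tracebacks are deterministic (the engine enumerates co-optimal
alignments in a fixed order and the first is taken); scores, which drive
every downstream decision, are unique optima.

## In-silico PCR screen

Primer sites are exhaustive sliding-window Hamming matches on both strands,
with at most `max_mismatches` (default 2) mismatches and none in the three
3'-terminal bases (the polymerase clamp). A product forms when a
plus-strand forward site pairs with a downstream minus-strand reverse site
and the span — forward 5' start through reverse 5' start, both footprints
included — lies within the length window (default 300–3000 bp, bracketing
the expected junction products).

The melting-curve readout is modeled as the amplicon's predicted melting
temperature from the salt-adjusted GC/length formula
`Tm = 81.5 + 16.6·log10([Na+]) + 0.41·(%GC) − 675/len` at 50 mM Na+.
Nearest-neighbor thermodynamics is deliberately not used: it is
parameterized for oligonucleotides, not 0.5–2 kb products. Two products
count as distinct peaks when their Tm differ by ≥ 0.5 °C. The model is
pluggable; only relative peak positions matter to the workflow.

Architecture calls: both junction pairs amplify → `clustered`; exactly one
→ `split`; neither → `negative`. The screen cannot distinguish which gene
moved (E5 vs E10) — that requires sequencing, as in the real workflow.

## Dereplication

The marker is the centered, frame-preserving 999-bp internal window of the
E gene (window start = midpoint rounded down to a codon boundary). In the
pipeline the fragment comes directly from the `E_internal` amplicon, whose
primers are in-frame by construction, so no annotation of the hit genome is
needed.

Clade collapse is single-linkage: connected components of the graph with
edges at identity ≥ cutoff (default 90%). Single linkage matches the visual
operation of collapsing a phylogram's tight groups and is order-independent;
complete linkage is available for comparison. Raising the cutoff always
refines the partition (nested refinement), which the tests verify.

Trees are Saitou–Nei neighbor joining (via scikit-bio) on p-distances
`(100 − identity)/100`, Poisson correction optional. Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling edge.
NJ is consistent on additive matrices, which is the property the test suite
exercises (exact topology recovery for random additive 5–8 taxon matrices).

Clade representatives are medoids — the member maximizing summed identity
to its clade-mates, ties broken lexicographically — a deterministic stand-in
for the expert choice of which hit to sequence.

## Genome neighborhood network

Families are connected components of the thresholded homology graph, not
MCL or community detection: components are deterministic, oracle-checkable,
and match the operational reading of a network "cluster" at a display
threshold (default E ≤ 1e-6). Because E2 (9-membered marker), E3 (cassette
gene) and R3 (10-membered marker) are homologous, their permissive-threshold
component is re-partitioned using only edges with E ≤ 1e-75, which separates
the three subfamilies; ring prediction operates on these subfamilies. Every
protein is a node, so families partition the node set and per-cluster family
counts sum to ORF counts.

A length-ratio prefilter (pairs differing more than five-fold skipped)
avoids pointless alignments; pairs with E > 1e-3 are dropped before graph
construction since no working threshold is looser. Labels transfer from
reference clusters by majority vote among a family's reference members
(lexicographic tie-break); families with no reference member are
`unknown_family`, size-one families are `singleton`.

Ring size uses the exclusive-presence rule: E2 subfamily hit without R3 →
nine; R3 without E2 → ten; both → `ambiguous` (the rule's definition forces
a value for a case the original scheme never meets; an error would make the
classifier partial); neither → `unknown`. Moieties are called when a cluster
hits at least `min_hits` families of a moiety's gene set — 1 for the
single-gene apoprotein, a majority (⌈half⌉) for the multi-gene β-amino
acid, amino sugar and benzoxazolinate sets. The shipped gene sets are
editable placeholders keyed to the four canonical moiety names; real
curated sets can be supplied as a plain-text config.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

- **Master proteome.** Reference proteins for the cassette (E3 300 aa,
  E4 220, E5 180, E 400, E10 200), markers (E2, R3: 300 aa, each generated
  as a ~40%-identity homolog of E3 so that the permissive network joins the
  three and the strict threshold separates them), moiety genes and decoys
  are drawn once from a fixed internal seed, independent of cohort
  configuration, so reference clusters and default primers are stable.
  The synthetic E (400 aa) is shorter than a real enediyne PKS (~1900 aa);
  it is the smallest size that comfortably carries the 999-bp internal
  fragment, and keeps all-vs-all alignment fast.
- **Evolution model.** Substitution-only: evolving at target identity *t*
  substitutes exactly `round((1−t)·len)` positions, each to a different
  residue, positions drawn without replacement. Identity targets are
  therefore exact up to placement randomness, and clade recovery is a
  well-posed target. An optional indel rate exists (default 0).
- **Identity control.** Two sequences independently evolved from a common
  reference at divergences d_i, d_j share expected identity
  `1 − d_i − d_j + (20/19)·d_i·d_j` (substitution sets overlap by chance;
  a doubly-substituted site matches with probability 1/19). Per-clade
  divergences are drawn from the range that maps into the configured
  between-clade band (default 33–69%, edges shrunk 2 points for sampling
  noise), after subtracting the member-level divergence; each member
  evolves from its clade reference at half the within-clade divergence so
  *pairwise* member identity hits the within-clade target (default 93%).
- **Primer anchors.** Seven-codon windows in E5, E and E10 are frozen
  during evolution and pinned to master codons during reverse translation
  (uniform synonymous codons, NCBI table 11, otherwise). The shipped
  primers are exact slices of the master coding sequence at those anchors —
  the in-silico counterpart of primers designed against conserved regions —
  so exact-match screening of planted cassettes is guaranteed by
  construction, and mismatch tolerance can be probed by mutating genomes.
- **Architectures and decor.** Clustered cassettes keep E5/E/E10 contiguous
  with 150–500 bp random spacers; split architectures insert ≥ 10 kb of
  decoy genes between E5 (or E10) and E, putting the junction out of
  amplification range. Each producer clade carries one marker (E2 or R3)
  and its configured moiety gene sets (markers and moiety genes at 85%
  identity to the master, on either strand); decoys are random sequences of
  reference composition with no cassette homology above chance.

**What synthetic validation does not show.** Real screens face degraded
primer sites (the mismatch model is exercised but realized divergence at
primer sites is zero by construction), indels and domain rearrangements in
the marker fragment, fragmented assemblies, contaminating DNA, and
thermodynamic PCR failure modes none of which the generator models. Perfect
sensitivity/specificity on cohorts is a correctness check of the machinery,
not a performance claim about wet-lab screening.

## Problem sizes and determinism

Validation runs use desk-scale cohorts: the 14-strain demonstration cohort,
a 30-producer/8-clade cohort for clade recovery, and a 28-cluster cohort
(one strain per clade, 21 nine / 7 ten) for ring classification; aligner
oracles run on 1,000 random short pairs and NJ on 200 random additive
matrices. All randomness flows from a single seed; identical configuration
and seed reproduce byte-identical outputs (fixed GenBank date stamp, sorted
iteration everywhere), which the manifest's checksums make auditable.

## Known limitations

- Family detection is components-based; a single spurious edge can merge
  two families (no edge-weight community resolution).
- The E-value calibration (λ, K) is the standard gapped-BLOSUM62 pair and
  is not re-estimated per matrix or composition.
- The screen models primer binding combinatorics, not amplification
  efficiency or fluorescence curve shape.
- Moiety gene sets ship as synthetic placeholders; real predictions require
  curated reference sets.
- NJ topology guarantees hold for additive distances; real fragment
  distances are only approximately additive.
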