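"""Ground-truthed synthetic genome cohorts for the enediyne mining pipeline.

The generator emulates the statistical structure the screen and the
downstream analyses assume about a real actinomycete strain collection:

* a subset of strains carries the conserved five-gene enediyne PKS cassette
  (E3, E4, E5, E, E10), either with E5/E/E10 clustered or with E5 or E10
  split >= 10 kb away from E;
* producer cassettes fall into clades: fragments of the E gene within one
  clade share high amino-acid identity (>= ~92% by default) while fragments
  from different clades sit in a configurable 33-69% identity band;
* each producer clade carries exactly one ring-class marker — an E2 homolog
  (9-membered enediynes) or an R3 homolog (10-membered) — plus gene sets for
  peripheral moieties (apoprotein/chromoprotein, beta-amino acid, amino
  sugar, benzoxazolinate);
* non-producers contain only decoy genes with no cassette homology above
  chance.

Evolution is substitution-only by default, so planted identities are exact
up to the random placement of substituted positions, and clade recovery is a
well-posed target.  Primer binding sites are anchored: a handful of codons
in E5, E and E10 are held fixed during evolution and their codons are copied
from the master reference during reverse translation, so the shipped default
primers match every planted cassette exactly — the in-silico analog of
primers designed against conserved cassette regions.

Every source of randomness flows from ``SimulationConfig.seed``; the master
reference proteome is derived from a fixed internal seed so that reference
proteins and default primers are stable across configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .align import PROTEIN_ALPHABET
from .screen import Primer, PrimerPair

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GenomeRecord",
    "GeneFeature",
    "TruthTable",
    "Cohort",
    "evolve_protein",
    "reverse_translate",
    "translate_cds",
    "build_cassette",
    "generate_cohort",
    "default_primers",
    "master_reference_proteins",
    "reference_clusters",
    "MOIETY_GENE_SETS",
    "CASSETTE_GENES",
    "RING_MARKER",
]


class ConfigError(ValueError):
    """A simulation or pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# reference proteome
# ---------------------------------------------------------------------------

CASSETTE_GENES = ("E3", "E4", "E5", "E", "E10")
RING_MARKER = {"nine": "E2", "ten": "R3"}

#: peripheral-moiety gene sets; apoprotein presence predicts a chromoprotein
MOIETY_GENE_SETS: dict[str, tuple[str, ...]] = {
    "apoprotein": ("apo",),
    "beta_amino_acid": ("bAA1", "bAA2", "bAA3", "bAA4"),
    "amino_sugar": ("sug1", "sug2", "sug3", "sug4"),
    "benzoxazolinate": ("boz1", "boz2", "boz3", "boz4"),
}

_GENE_LENGTHS = {
    "E3": 300, "E4": 220, "E5": 180, "E": 400, "E10": 200,
    "E2": 300, "R3": 300, "apo": 140,
    "bAA1": 260, "bAA2": 200, "bAA3": 180, "bAA4": 230,
    "sug1": 240, "sug2": 190, "sug3": 210, "sug4": 170,
    "boz1": 250, "boz2": 220, "boz3": 160, "boz4": 200,
}

# conserved codon windows (primer anchors), per gene: aa positions held fixed
_ANCHOR_CODONS = {
    "E5": [(150, 157)],
    "E": [(33, 40), (40, 47), (359, 366), (380, 387)],
    "E10": [(40, 47)],
}

_MASTER_SEED = 20160314  # fixed: the reference proteome is not configurable
_AA = np.frombuffer(PROTEIN_ALPHABET.encode(), dtype="S1")

_TABLE11 = unambiguous_dna_by_id[11]
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE11.forward_table.items()):
    _BACK_TABLE.setdefault(_aa, []).append(_codon)


def _frozen_positions(label: str) -> frozenset[int]:
    wins = _ANCHOR_CODONS.get(label, [])
    return frozenset(p for a, b in wins for p in range(a, b))


def master_reference_proteins() -> dict[str, str]:
    """The master reference proteome (deterministic, seed-independent).

    E2 and R3 are generated as divergent homologs of E3 (~40% identity), so
    that at a permissive E-value threshold the three form one connected
    family while a strict threshold separates the subfamilies — the basis of
    ring-class prediction.
    """
    rng = np.random.default_rng(_MASTER_SEED)
    refs: dict[str, str] = {}
    for label, length in _GENE_LENGTHS.items():
        if label in ("E2", "R3"):
            continue
        refs[label] = "".join(rng.choice(list(PROTEIN_ALPHABET), size=length))
    refs["E2"] = evolve_protein(refs["E3"], 0.40, int(rng.integers(2**31)))
    refs["R3"] = evolve_protein(refs["E3"], 0.40, int(rng.integers(2**31)))
    return refs


def _master_dna() -> dict[str, str]:
    """Reference coding sequences for the primer-anchored genes."""
    refs = master_reference_proteins()
    rng = np.random.default_rng(_MASTER_SEED + 1)
    return {
        label: reverse_translate(refs[label], int(rng.integers(2**31)))
        for label in ("E5", "E", "E10")
    }


def _anchor_codon_overrides(label: str, dna_by_gene: dict[str, str]) -> dict[int, str]:
    over = {}
    for a, b in _ANCHOR_CODONS.get(label, []):
        for pos in range(a, b):
            over[pos] = dna_by_gene[label][3 * pos: 3 * pos + 3]
    return over


def default_primers() -> list[PrimerPair]:
    """The three shipped primer pairs, matched to the reference cassette.

    E5_E targets the E5 3' region and the E 5' region; E_E10 targets the E
    3' region and the E10 5' region; E_internal brackets the 999-bp internal
    fragment of E used for phylogenetic dereplication.  Anchored codons make
    these exact matches in every planted cassette.
    """
    dna = _master_dna()

    def rc(s: str) -> str:
        return str(Seq(s).reverse_complement())

    return [
        PrimerPair(
            "E5_E",
            fwd=Primer("E5_E_f", dna["E5"][450:471]),
            rev=Primer("E5_E_r", rc(dna["E"][120:141])),
        ),
        PrimerPair(
            "E_E10",
            fwd=Primer("E_E10_f", dna["E"][1140:1161]),
            rev=Primer("E_E10_r", rc(dna["E10"][120:141])),
        ),
        PrimerPair(
            "E_internal",
            fwd=Primer("E_int_f", dna["E"][99:120]),
            rev=Primer("E_int_r", rc(dna["E"][1077:1098])),
        ),
    ]


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def evolve_protein(
    ref: str,
    target_identity: float,
    seed: int,
    frozen: frozenset[int] | tuple[int, ...] = (),
    indel_rate: float = 0.0,
) -> str:
    """Substitute exactly ``round((1 - target_identity) * len(ref))`` residues.

    Positions are drawn without replacement (never from ``frozen``) and each
    substituted residue differs from the original, so the realized ungapped
    identity to ``ref`` is exact.  ``indel_rate`` > 0 additionally applies
    per-position insertions/deletions (off by default: the substitution-only
    model keeps identity targets exact).
    """
    if not ref:
        raise ValueError("reference protein is empty")
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must lie in [0, 1]")
    n_sub = round((1.0 - target_identity) * len(ref))
    free = np.array([i for i in range(len(ref)) if i not in set(frozen)])
    if n_sub > free.size:
        raise ValueError(
            f"cannot place {n_sub} substitutions in {free.size} mutable positions"
        )
    rng = np.random.default_rng(seed)
    out = list(ref)
    if n_sub:
        for pos in rng.choice(free, size=n_sub, replace=False):
            alternatives = [a for a in PROTEIN_ALPHABET if a != ref[pos]]
            out[pos] = alternatives[rng.integers(len(alternatives))]
    if indel_rate > 0.0:
        evolved = []
        for i, aa in enumerate(out):
            r = rng.random()
            if r < indel_rate / 2 and i not in set(frozen):
                continue  # deletion
            evolved.append(aa)
            if indel_rate / 2 <= r < indel_rate:
                evolved.append(PROTEIN_ALPHABET[rng.integers(20)])
        out = evolved or out
    return "".join(out)


def reverse_translate(
    protein: str,
    seed: int,
    codon_overrides: dict[int, str] | None = None,
) -> str:
    """A coding DNA sequence whose table-11 translation is ``protein``.

    Synonymous codons are chosen uniformly under ``seed``; ``codon_overrides``
    pins specific amino-acid positions to given codons (used to plant exact
    primer binding sites).
    """
    rng = np.random.default_rng(seed)
    codon_overrides = codon_overrides or {}
    codons = []
    for i, aa in enumerate(protein):
        if aa not in _BACK_TABLE:
            raise ValueError(f"residue {aa!r} at position {i} is not encodable (stop or unknown)")
        if i in codon_overrides:
            codon = codon_overrides[i]
            if _TABLE11.forward_table.get(codon) != aa:
                raise ValueError(f"override codon {codon!r} does not encode {aa!r}")
            codons.append(codon)
        else:
            options = _BACK_TABLE[aa]
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def translate_cds(dna: str) -> str:
    """Table-11 translation of an in-frame CDS (no stop codon expected)."""
    return str(Seq(dna).translate(table=11))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# cohort data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    label: str
    start: int
    end: int      # 0-based, half-open
    strand: str   # '+' or '-'


@dataclass
class GenomeRecord:
    """A named DNA sequence with optional CDS annotations."""

    genome_id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def gene_dna(self, feat: GeneFeature) -> str:
        s = self.seq[feat.start:feat.end]
        return s if feat.strand == "+" else str(Seq(s).reverse_complement())


@dataclass
class TruthTable:
    """Planted ground truth: one row per strain plus per-gene coordinates."""

    strains: pd.DataFrame  # strain_id, is_producer, clade_id, ring_class, architecture, moieties
    genes: pd.DataFrame    # strain_id, label, start, end, strand

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.strains.to_csv(outdir / "truth_strains.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: Path) -> "TruthTable":
        outdir = Path(outdir)
        strains = pd.read_csv(outdir / "truth_strains.tsv", sep="\t",
                              dtype={"strain_id": str}, keep_default_na=False)
        genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t", dtype={"strain_id": str})
        return cls(strains, genes)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the small demonstration cohort: 14 strains of which 9
    are producers in 3 clades, pairwise within-clade fragment identity ~93%,
    between-clade identities in the 33-69% band, a 2:1 nine/ten ring-class
    ratio, and one of each cassette architecture.
    """

    n_strains: int = 14
    n_producer_clades: int = 3
    strains_per_clade: tuple[int, ...] = (4, 3, 2)
    within_clade_identity: float = 0.93
    between_clade_identity: tuple[float, float] = (0.33, 0.69)
    ring_class_per_clade: tuple[str, ...] | None = None
    architecture_per_clade: tuple[str, ...] | None = None
    moiety_sets_per_clade: tuple[frozenset[str], ...] | None = None
    n_decoy_genes: int = 6
    spacer_range: tuple[int, int] = (150, 500)
    indel_rate: float = 0.0
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Validate and fill per-clade defaults (cycled patterns)."""
        k = self.n_producer_clades
        if self.n_strains <= 0:
            raise ConfigError("n_strains must be positive")
        if len(self.strains_per_clade) != k:
            raise ConfigError("strains_per_clade length must equal n_producer_clades")
        if sum(self.strains_per_clade) > self.n_strains:
            raise ConfigError("strains_per_clade sums to more than n_strains")
        if any(n <= 0 for n in self.strains_per_clade):
            raise ConfigError("each clade needs at least one strain")
        lo, hi = self.between_clade_identity
        if not (0.0 <= lo < hi <= 1.0) or not 0.0 < self.within_clade_identity <= 1.0:
            raise ConfigError("identity targets must lie in [0, 1] with lo < hi")
        if self.within_clade_identity - hi < 0.04:
            raise ConfigError(
                "within/between identity bands closer than 4 points: clade recovery ill-posed"
            )
        rings = self.ring_class_per_clade or tuple(
            ("nine" if i % 3 < 2 else "ten") for i in range(k)
        )
        archs = self.architecture_per_clade or tuple(
            ("clustered", "split_E5", "split_E10")[i % 3] for i in range(k)
        )
        default_moieties = (
            frozenset({"apoprotein", "beta_amino_acid", "benzoxazolinate"}),
            frozenset({"amino_sugar"}),
            frozenset(),
        )
        moieties = self.moiety_sets_per_clade or tuple(default_moieties[i % 3] for i in range(k))
        if len(rings) != k or len(archs) != k or len(moieties) != k:
            raise ConfigError("per-clade settings must have one entry per clade")
        for r in rings:
            if r not in RING_MARKER:
                raise ConfigError(f"unknown ring class {r!r}")
        for a in archs:
            if a not in ("clustered", "split_E5", "split_E10"):
                raise ConfigError(f"unknown architecture {a!r}")
        for ms in moieties:
            unknown = set(ms) - set(MOIETY_GENE_SETS)
            if unknown:
                raise ConfigError(f"unknown moiety names {sorted(unknown)}")
        return SimulationConfig(
            n_strains=self.n_strains,
            n_producer_clades=k,
            strains_per_clade=tuple(self.strains_per_clade),
            within_clade_identity=self.within_clade_identity,
            between_clade_identity=(lo, hi),
            ring_class_per_clade=tuple(rings),
            architecture_per_clade=tuple(archs),
            moiety_sets_per_clade=tuple(frozenset(m) for m in moieties),
            n_decoy_genes=self.n_decoy_genes,
            spacer_range=self.spacer_range,
            indel_rate=self.indel_rate,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# cassette and genome assembly
# ---------------------------------------------------------------------------

def _divergence_band(lo: float, hi: float, member_div: float, margin: float = 0.02) -> tuple[float, float]:
    """Per-clade divergence range so that *strain-level* pairwise identities
    between clades land inside [lo, hi].

    Two sequences independently evolved from a common reference at
    divergences d_i, d_j share expected identity
    1 - d_i - d_j + (20/19) d_i d_j (substitution sets overlap by chance and
    a doubly-substituted position matches with probability 1/19).  Solving
    the homogeneous case for the band edges (shrunk by ``margin``) and
    subtracting the member-level divergence gives the clade-reference range.
    """

    def solve(target: float) -> float:
        c = 20.0 / 19.0
        disc = 4.0 - 4.0 * c * (1.0 - target)
        if disc < 0:
            raise ConfigError(f"identity target {target} unreachable")
        return (2.0 - math.sqrt(disc)) / (2.0 * c)

    d_max = solve(lo + margin) - member_div
    d_min = solve(hi - margin) - member_div
    d_min = max(d_min, 0.01)
    if d_max <= d_min:
        raise ConfigError("between-clade identity band too narrow for the within-clade target")
    return d_min, d_max


@dataclass(frozen=True)
class CassetteGene:
    label: str
    protein: str
    dna: str
    strand: str = "+"


def build_cassette(
    clade_ref_proteins: dict[str, str],
    ring_class: str,
    architecture: str,
    moiety_set: frozenset[str] | set[str],
    seed: int,
    spacer_range: tuple[int, int] = (150, 500),
) -> list[tuple[str, object]]:
    """Assemble one cassette region as an ordered list of elements.

    Returns ``[("gene", CassetteGene), ("spacer", dna), ...]``.  Clustered
    architecture keeps E5/E/E10 contiguous; split architectures move E5
    (resp. E10) >= 10 kb away behind a block of decoy genes.  Ring class
    nine plants an E2 homolog, ten an R3 homolog; moiety gene sets are
    appended after the marker.
    """
    if architecture not in ("clustered", "split_E5", "split_E10"):
        raise ValueError(f"unknown architecture {architecture!r}")
    if ring_class not in RING_MARKER:
        raise ValueError(f"unknown ring class {ring_class!r}")
    for label in CASSETTE_GENES:
        if label not in clade_ref_proteins:
            raise ValueError(f"missing cassette reference protein {label!r}")
    rng = np.random.default_rng(seed)
    master_dna = _master_dna()

    def make_gene(label: str, strand: str = "+") -> CassetteGene:
        protein = clade_ref_proteins[label]
        overrides = None
        if label in _ANCHOR_CODONS:
            overrides = _anchor_codon_overrides(label, master_dna)
        dna = reverse_translate(protein, int(rng.integers(2**31)), overrides)
        return CassetteGene(label, protein, dna, strand)

    def spacer() -> tuple[str, str]:
        return ("spacer", _random_dna(rng, int(rng.integers(spacer_range[0], spacer_range[1] + 1))))

    def far_block() -> list[tuple[str, object]]:
        # >= 10 kb of decoy genes and spacers separating split cassette parts
        block: list[tuple[str, object]] = []
        total = 0
        while total < 10_000:
            dprot = _decoy_protein(rng)
            dna = reverse_translate(dprot, int(rng.integers(2**31)))
            block.append(("gene", CassetteGene("decoy", dprot, dna)))
            sp = spacer()
            block.append(sp)
            total += len(dna) + len(sp[1])
        return block

    marker = RING_MARKER[ring_class]
    tail_labels = [marker]
    for moiety in sorted(moiety_set):
        tail_labels.extend(MOIETY_GENE_SETS[moiety])

    elements: list[tuple[str, object]] = []

    def add_gene(label: str, strand: str = "+") -> None:
        elements.append(("gene", make_gene(label, strand)))
        elements.append(spacer())

    if architecture == "clustered":
        for label in ("E3", "E4", "E5", "E", "E10"):
            add_gene(label)
    elif architecture == "split_E5":
        add_gene("E5")
        elements.extend(far_block())
        for label in ("E3", "E4", "E", "E10"):
            add_gene(label)
    else:  # split_E10
        for label in ("E3", "E4", "E5", "E"):
            add_gene(label)
        elements.extend(far_block())
        add_gene("E10")
    for label in tail_labels:
        # markers/moiety genes may sit on either strand
        strand = "+" if rng.random() < 0.7 else "-"
        add_gene(label, strand)
    return elements


def _decoy_protein(rng: np.random.Generator, composition: str | None = None) -> str:
    length = int(rng.integers(150, 301))
    pool = composition or PROTEIN_ALPHABET
    return "".join(pool[i] for i in rng.integers(len(pool), size=length))


@dataclass
class Cohort:
    """A generated cohort: genomes plus the planted truth."""

    config: SimulationConfig
    genomes: list[GenomeRecord]
    truth: TruthTable

    def producer_ids(self) -> list[str]:
        t = self.truth.strains
        return list(t.loc[t.is_producer, "strain_id"])

    # -- serialization ------------------------------------------------------

    def write(self, outdir: Path) -> None:
        """Write per-genome FASTA, annotated GenBank for producers, truth TSVs."""
        outdir = Path(outdir)
        gdir = outdir / "genomes"
        gbdir = outdir / "clusters"
        gdir.mkdir(parents=True, exist_ok=True)
        gbdir.mkdir(parents=True, exist_ok=True)
        producers = set(self.producer_ids())
        for gr in self.genomes:
            rec = SeqRecord(Seq(gr.seq), id=gr.genome_id, description="synthetic genome")
            SeqIO.write([rec], gdir / f"{gr.genome_id}.fasta", "fasta")
            if gr.genome_id in producers:
                SeqIO.write([_to_genbank(gr)], gbdir / f"{gr.genome_id}.gbk", "genbank")
        self.truth.write(outdir)


def _to_genbank(gr: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(gr.seq), id=gr.genome_id, name=gr.genome_id[:16],
                    description="synthetic enediyne producer")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "linear"
    rec.annotations["date"] = "01-JAN-2016"  # fixed: byte-identical reruns
    for i, feat in enumerate(gr.features):
        loc = FeatureLocation(feat.start, feat.end, strand=1 if feat.strand == "+" else -1)
        protein = translate_cds(gr.gene_dna(feat))
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers={
            "locus_tag": [f"{gr.genome_id}_{i:03d}"],
            "gene": [feat.label],
            "transl_table": ["11"],
            "translation": [protein],
        }))
    return rec


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort from one configuration (deterministic in seed)."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    refs = master_reference_proteins()
    member_div = (1.0 - cfg.within_clade_identity) / 2.0
    d_min, d_max = _divergence_band(*cfg.between_clade_identity, member_div)

    n_producers = sum(cfg.strains_per_clade)
    strain_rows = []
    gene_rows = []
    genomes: list[GenomeRecord] = []

    # clade-level reference proteins
    clade_refs: list[dict[str, str]] = []
    for _ in range(cfg.n_producer_clades):
        d_c = float(rng.uniform(d_min, d_max))
        crefs = {}
        for label in CASSETTE_GENES:
            crefs[label] = evolve_protein(
                refs[label], 1.0 - d_c, int(rng.integers(2**31)),
                frozen=_frozen_positions(label),
            )
        for label in ("E2", "R3", *(g for ms in MOIETY_GENE_SETS.values() for g in ms)):
            crefs[label] = evolve_protein(refs[label], 0.85, int(rng.integers(2**31)))
        clade_refs.append(crefs)

    strain_idx = 0
    for clade in range(cfg.n_producer_clades):
        ring = cfg.ring_class_per_clade[clade]
        arch = cfg.architecture_per_clade[clade]
        moieties = cfg.moiety_sets_per_clade[clade]
        for _ in range(cfg.strains_per_clade[clade]):
            strain_id = f"strain_{strain_idx:03d}"
            strain_idx += 1
            member_refs = {}
            for label, ref in clade_refs[clade].items():
                member_refs[label] = evolve_protein(
                    ref, 1.0 - member_div, int(rng.integers(2**31)),
                    frozen=_frozen_positions(label), indel_rate=cfg.indel_rate,
                )
            elements = build_cassette(
                member_refs, ring, arch, moieties,
                int(rng.integers(2**31)), cfg.spacer_range,
            )
            genome, feats = _assemble_genome(strain_id, elements, cfg, rng)
            genomes.append(genome)
            for f in feats:
                gene_rows.append((strain_id, f.label, f.start, f.end, f.strand))
            strain_rows.append((strain_id, True, clade + 1, ring, arch,
                                ",".join(sorted(moieties))))
    for _ in range(cfg.n_strains - n_producers):
        strain_id = f"strain_{strain_idx:03d}"
        strain_idx += 1
        genome, feats = _assemble_genome(strain_id, [], cfg, rng)
        genomes.append(genome)
        for f in feats:
            gene_rows.append((strain_id, f.label, f.start, f.end, f.strand))
        strain_rows.append((strain_id, False, 0, "", "", ""))

    strains = pd.DataFrame(
        strain_rows,
        columns=["strain_id", "is_producer", "clade_id", "ring_class", "architecture", "moieties"],
    )
    genes = pd.DataFrame(gene_rows, columns=["strain_id", "label", "start", "end", "strand"])
    return Cohort(cfg, genomes, TruthTable(strains, genes))


def reference_clusters() -> list:
    """Two labeled reference gene clusters built from the master proteome.

    ``ref_nine`` mirrors a chromoprotein 9-membered cluster (cassette + E2 +
    apoprotein + beta-amino acid + benzoxazolinate genes); ``ref_ten``
    mirrors an anthraquinone 10-membered cluster (cassette + R3 + amino
    sugar genes).  These are synthetic stand-ins constructed from the
    generator's master reference proteins, labeled for annotation transfer.
    """
    from .gnn import ORF, GeneCluster

    refs = master_reference_proteins()

    def build(cluster_id: str, labels: list[str]) -> GeneCluster:
        orfs = []
        pos = 0
        for i, label in enumerate(labels):
            prot = refs[label]
            end = pos + 3 * len(prot)
            orfs.append(ORF(f"{cluster_id}_{i:03d}", pos, end, "+", prot, label))
            pos = end + 200
        return GeneCluster(cluster_id, "reference", orfs)

    nine_labels = [*CASSETTE_GENES, "E2",
                   *MOIETY_GENE_SETS["apoprotein"],
                   *MOIETY_GENE_SETS["beta_amino_acid"],
                   *MOIETY_GENE_SETS["benzoxazolinate"]]
    ten_labels = [*CASSETTE_GENES, "R3", *MOIETY_GENE_SETS["amino_sugar"]]
    return [build("ref_nine", nine_labels), build("ref_ten", ten_labels)]


def _assemble_genome(
    strain_id: str,
    cassette_elements: list[tuple[str, object]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Concatenate decoys, spacers and the cassette into one linear genome."""
    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0

    def emit(seq: str, label: str | None = None, strand: str = "+") -> None:
        nonlocal pos
        if label is not None:
            feats.append(GeneFeature(label, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)

    def emit_spacer() -> None:
        emit(_random_dna(rng, int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))))

    n_before = int(rng.integers(0, cfg.n_decoy_genes + 1))
    decoy_plan = [n_before, cfg.n_decoy_genes - n_before]

    emit_spacer()
    for n_decoys, cassette in zip(decoy_plan, (cassette_elements, None)):
        for _ in range(n_decoys):
            prot = _decoy_protein(rng)
            emit(reverse_translate(prot, int(rng.integers(2**31))), "decoy")
            emit_spacer()
        if cassette:
            for kind, payload in cassette:
                if kind == "gene":
                    g: CassetteGene = payload  # type: ignore[assignment]
                    dna = g.dna if g.strand == "+" else str(Seq(g.dna).reverse_complement())
                    emit(dna, g.label, g.strand)
                else:
                    emit(payload)  # type: ignore[arg-type]
    return GenomeRecord(strain_id, "".join(parts), feats), feats
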