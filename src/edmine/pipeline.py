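"""End-to-end orchestration: simulate -> screen -> phylo -> gnn -> classify.

Each stage consumes only the artifacts of the previous stage (amplicons,
fragments, clusters), so running the pipeline end to end is equivalent to
running the stages individually with the same parameters.  A run manifest
records the package version, the full effective configuration, SHA-256
checksums of every output and per-stage wall time; identical configuration
and seed reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .classify import (novelty_report, predict_moieties, predict_ring_size,
                       prediction_table)
from .gnn import (all_vs_all, annotate_families, build_gnn, cluster_profile,
                  detect_families, read_genbank_cluster, write_edge_list,
                  write_graphml)
from .phylo import collapse_clades, identity_matrix, nj_tree, pick_representatives
from .screen import Primer, PrimerPair, screen_cohort, screen_table
from .simulate import (Cohort, ConfigError, GenomeRecord, SimulationConfig,
                       default_primers, generate_cohort, reference_clusters,
                       translate_cds)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_primer_tsv",
    "write_primer_tsv",
    "read_genome_fastas",
    "fragments_from_screen",
]


@dataclass
class PipelineConfig:
    """One pipeline run: simulation conditions plus stage parameters."""

    outdir: Path = Path("edmine_run")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_mismatches: int = 2
    min_len: int = 300
    max_len: int = 3000
    cutoff: float = 90.0
    linkage: str = "single"
    window_bp: int = 999
    gnn_threshold: float = 1e-6
    strict_threshold: float = 1e-75
    stages: tuple[str, ...] = ("simulate", "screen", "phylo", "gnn", "classify")

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.cutoff <= 100.0:
            raise ConfigError(f"identity cutoff {self.cutoff} outside (0, 100]")
        if self.linkage not in ("single", "complete"):
            raise ConfigError(f"unknown linkage {self.linkage!r}")
        if self.min_len > self.max_len:
            raise ConfigError("min_len exceeds max_len")
        if self.gnn_threshold <= 0 or self.strict_threshold <= 0:
            raise ConfigError("E-value thresholds must be positive")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be non-negative")
        unknown = set(self.stages) - {"simulate", "screen", "phylo", "gnn", "classify"}
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        self.simulation.resolved()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        if "strains_per_clade" in sim:
            sim["strains_per_clade"] = tuple(sim["strains_per_clade"])
        if "between_clade_identity" in sim:
            sim["between_clade_identity"] = tuple(sim["between_clade_identity"])
        for tup_key in ("ring_class_per_clade", "architecture_per_clade"):
            if sim.get(tup_key) is not None:
                sim[tup_key] = tuple(sim[tup_key])
        if sim.get("moiety_sets_per_clade") is not None:
            sim["moiety_sets_per_clade"] = tuple(frozenset(m) for m in sim["moiety_sets_per_clade"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        try:
            return cls(simulation=SimulationConfig(**sim), **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


# -- primer and genome I/O ---------------------------------------------------

def write_primer_tsv(pairs: list[PrimerPair], path) -> None:
    rows = []
    for p in pairs:
        rows.append((p.fwd.name, p.fwd.sequence, p.name, "fwd"))
        rows.append((p.rev.name, p.rev.sequence, p.name, "rev"))
    pd.DataFrame(rows, columns=["name", "sequence", "pair_id", "orientation"]).to_csv(
        path, sep="\t", index=False)


def read_primer_tsv(path, max_mismatches: int = 2) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        by_orient = {r.orientation: r for r in grp.itertuples(index=False)}
        if set(by_orient) != {"fwd", "rev"}:
            raise ConfigError(f"primer pair {pair_id!r} needs one fwd and one rev primer")
        pairs.append(PrimerPair(
            str(pair_id),
            fwd=Primer(by_orient["fwd"].name, by_orient["fwd"].sequence, max_mismatches),
            rev=Primer(by_orient["rev"].name, by_orient["rev"].sequence, max_mismatches),
        ))
    return pairs


def read_genome_fastas(directory) -> list[GenomeRecord]:
    genomes = []
    for path in sorted(Path(directory).glob("*.fasta")):
        for rec in SeqIO.parse(str(path), "fasta"):
            genomes.append(GenomeRecord(rec.id, str(rec.seq)))
    if not genomes:
        raise ConfigError(f"no FASTA genomes found in {directory}")
    return genomes


def fragments_from_screen(results, window_bp: int = 999) -> dict[str, str]:
    """Translated internal E fragments from the E_internal amplicons.

    The E_internal amplicon is bracketed by in-frame primers, so the product
    is a codon-exact window of the E gene; translating it gives the marker
    fragment without any annotation of the hit genome.
    """
    frags = {}
    for r in results:
        for h in r.hits:
            if h.pair == "E_internal" and h.length % 3 == 0:
                frags[r.strain_id] = translate_cds(h.seq[: window_bp - window_bp % 3])
                break
    return frags


# -- orchestration -----------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Outputs land in ``config.outdir``: cohort files, screen.tsv, identity
    matrix, tree.nwk, clades.tsv, GNN exports, families.tsv, profile.tsv
    and predictions.tsv.
    """
    cfg = config.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "edmine",
        "version": __version__,
        "config": json.loads(json.dumps(asdict(cfg), default=_json_default)),
        "stages": {},
        "outputs": {},
    }

    def finish_stage(name: str, t0: float, outputs: list[Path], info: dict) -> None:
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3), **info}
        for p in outputs:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    # --- simulate ---
    t0 = time.perf_counter()
    if cohort is None and "simulate" in cfg.stages:
        cohort = generate_cohort(cfg.simulation)
    if cohort is None:
        raise ConfigError("no cohort: enable the simulate stage or pass one in")
    cohort.write(outdir / "cohort")
    primers = default_primers()
    primers = [PrimerPair(p.name,
                          Primer(p.fwd.name, p.fwd.sequence, cfg.max_mismatches),
                          Primer(p.rev.name, p.rev.sequence, cfg.max_mismatches))
               for p in primers]
    write_primer_tsv(primers, outdir / "primers.tsv")
    sim_outputs = sorted((outdir / "cohort").rglob("*.*")) + [outdir / "primers.tsv"]
    finish_stage("simulate", t0, sim_outputs,
                 {"n_strains": len(cohort.genomes),
                  "n_producers": len(cohort.producer_ids())})

    # --- screen ---
    t0 = time.perf_counter()
    results = screen_cohort(cohort.genomes, primers, cfg.min_len, cfg.max_len)
    table = screen_table(results)
    table.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    positives = [r for r in results if r.architecture != "negative"]
    finish_stage("screen", t0, [outdir / "screen.tsv"],
                 {"surveyed": len(results), "hits": len(positives)})
    if "phylo" not in cfg.stages:
        return _write_manifest(manifest, outdir)

    # --- phylo ---
    t0 = time.perf_counter()
    frags = fragments_from_screen(positives, cfg.window_bp)
    matrix = identity_matrix(frags)
    matrix.to_frame().to_csv(outdir / "identity_matrix.tsv", sep="\t")
    tree = nj_tree(matrix)
    tree.write(str(outdir / "tree.nwk"))
    partition = collapse_clades(matrix, cfg.cutoff, cfg.linkage)
    reps = pick_representatives(partition, matrix)
    clade_df = pd.DataFrame(
        [(sid, cid, reps[cid] == sid) for sid, cid in sorted(partition.assignment.items())],
        columns=["strain_id", "clade_id", "representative"],
    )
    clade_df.to_csv(outdir / "clades.tsv", sep="\t", index=False)
    finish_stage("phylo", t0,
                 [outdir / "identity_matrix.tsv", outdir / "tree.nwk", outdir / "clades.tsv"],
                 {"n_fragments": len(frags), "n_clades": partition.n_clades(),
                  "cutoff": cfg.cutoff, "linkage": cfg.linkage})
    if "gnn" not in cfg.stages:
        return _write_manifest(manifest, outdir)

    # --- gnn ---
    t0 = time.perf_counter()
    hit_ids = sorted(frags)
    clusters = [read_genbank_cluster(outdir / "cohort" / "clusters" / f"{sid}.gbk", source="hit")
                for sid in hit_ids]
    references = reference_clusters()
    pairs = all_vs_all(clusters + references)
    graph = build_gnn(pairs, clusters + references, cfg.gnn_threshold)
    assignment = annotate_families(
        detect_families(graph, cfg.strict_threshold), references)
    profile = cluster_profile(assignment, clusters + references)
    write_graphml(graph, outdir / "gnn.graphml")
    write_edge_list(graph, outdir / "gnn_edges.tsv")
    fam_rows = [(cid, orf, fid, assignment.label_of(fid))
                for (cid, orf), fid in sorted(assignment.families.items())]
    pd.DataFrame(fam_rows, columns=["cluster_id", "orf_id", "family_id", "label"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False)
    profile.to_csv(outdir / "profile.tsv", sep="\t")
    finish_stage("gnn", t0,
                 [outdir / "gnn.graphml", outdir / "gnn_edges.tsv",
                  outdir / "families.tsv", outdir / "profile.tsv"],
                 {"n_clusters": len(clusters), "n_nodes": graph.number_of_nodes(),
                  "n_edges": graph.number_of_edges(),
                  "n_families": len(set(assignment.families.values()))})
    if "classify" not in cfg.stages:
        return _write_manifest(manifest, outdir)

    # --- classify ---
    t0 = time.perf_counter()
    rings = predict_ring_size(assignment, clusters, references, graph)
    moieties = predict_moieties(assignment, clusters, references)
    novelty = novelty_report(assignment, clusters, references)
    preds = prediction_table(rings, moieties, novelty)
    preds.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    finish_stage("classify", t0, [outdir / "predictions.tsv"],
                 {"n_nine": int((preds.ring_call == "nine").sum()),
                  "n_ten": int((preds.ring_call == "ten").sum())})
    return _write_manifest(manifest, outdir)


def _json_default(obj):
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    return str(obj)


def _write_manifest(manifest: dict, outdir: Path) -> dict:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
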