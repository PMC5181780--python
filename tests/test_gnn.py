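import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from edmine.gnn import (GeneCluster, ORF, all_vs_all, annotate_families,
                        build_gnn, cluster_profile, cluster_similarity,
                        detect_families, read_genbank_cluster)
from edmine.simulate import (evolve_protein, master_reference_proteins,
                             reference_clusters, reverse_translate)


def _write_genbank(tmp_path, features, seq):
    rec = SeqRecord(Seq(seq), id="testrec", name="testrec", description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = features
    path = tmp_path / "rec.gbk"
    SeqIO.write([rec], path, "genbank")
    return path


class TestReadGenbank:
    def test_three_cds_with_minus_strand(self, tmp_path):
        rng = np.random.default_rng(1)
        prots = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40)) for _ in range(3)]
        dnas = [reverse_translate(p, i) for i, p in enumerate(prots)]
        seq = dnas[0] + "ACGTACGT" + str(Seq(dnas[1]).reverse_complement()) + "ACGT" + dnas[2]
        o1 = len(dnas[0]) + 8
        o2 = o1 + len(dnas[1]) + 4
        feats = [
            SeqFeature(FeatureLocation(0, len(dnas[0]), strand=1), type="CDS"),
            SeqFeature(FeatureLocation(o1, o1 + len(dnas[1]), strand=-1), type="CDS"),
            SeqFeature(FeatureLocation(o2, o2 + len(dnas[2]), strand=1), type="CDS"),
        ]
        cluster = read_genbank_cluster(_write_genbank(tmp_path, feats, seq))
        assert [o.protein for o in cluster.orfs] == prots
        assert cluster.orfs[1].strand == "-"

    def test_join_location_concatenated(self, tmp_path):
        prot = "MKTAYIAKQR"
        dna = reverse_translate(prot, 3)
        seq = dna[:15] + "GGGGGG" + dna[15:]
        loc = CompoundLocation([FeatureLocation(0, 15, strand=1),
                                FeatureLocation(21, 21 + len(dna) - 15, strand=1)])
        cluster = read_genbank_cluster(_write_genbank(tmp_path, [SeqFeature(loc, type="CDS")], seq))
        assert cluster.orfs[0].protein == prot

    def test_translation_qualifier_wins_with_warning(self, tmp_path):
        dna = reverse_translate("MKTAYIAKQR", 3)
        feat = SeqFeature(FeatureLocation(0, len(dna), strand=1), type="CDS",
                          qualifiers={"translation": ["MKTAYIAKQW"]})
        with pytest.warns(UserWarning, match="disagrees"):
            cluster = read_genbank_cluster(_write_genbank(tmp_path, [feat], dna))
        assert cluster.orfs[0].protein == "MKTAYIAKQW"

    def test_no_cds_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no CDS"):
            read_genbank_cluster(_write_genbank(tmp_path, [], "ACGT" * 30))

    def test_labels_only_for_reference_source(self, tmp_path):
        dna = reverse_translate("MKTAYIAKQR", 3)
        feat = SeqFeature(FeatureLocation(0, len(dna), strand=1), type="CDS",
                          qualifiers={"gene": ["E5"]})
        path = _write_genbank(tmp_path, [feat], dna)
        assert read_genbank_cluster(path, source="hit").orfs[0].label is None
        assert read_genbank_cluster(path, source="reference").orfs[0].label == "E5"


def _ten_gene_cluster(cluster_id, rng):
    orfs = []
    for i in range(10):
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
        orfs.append(ORF(f"{cluster_id}_{i}", 500 * i, 500 * i + 450, "+", prot))
    return GeneCluster(cluster_id, "hit", orfs)


def _copy_cluster(cluster, new_id):
    return GeneCluster(new_id, "hit", [
        ORF(o.orf_id.replace(cluster.cluster_id, new_id), o.start, o.end, o.strand, o.protein)
        for o in cluster.orfs
    ])


class TestAllVsAll:
    def test_identical_single_orf_clusters(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
        c1 = GeneCluster("c1", "hit", [ORF("a", 0, 159, "+", prot)])
        c2 = GeneCluster("c2", "hit", [ORF("b", 0, 159, "+", prot)])
        pairs = all_vs_all([c1, c2])
        assert len(pairs) == 1
        assert pairs.evalue.iloc[0] < 1e-20

    def test_pair_count_bounded(self):
        rng = np.random.default_rng(0)
        c = _ten_gene_cluster("c1", rng)
        pairs = all_vs_all([c], max_evalue=None)
        assert len(pairs) <= 10 * 9 / 2

    def test_unrelated_proteins_insignificant(self):
        rng = np.random.default_rng(4)
        orfs = [ORF(f"o{i}", 0, 300, "+",
                    "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100)))
                for i in range(8)]
        pairs = all_vs_all([GeneCluster("c", "hit", orfs)], max_evalue=None)
        assert (pairs.evalue > 1e-6).all()


class TestBuildGnnAndFamilies:
    rng = np.random.default_rng(11)
    base = _ten_gene_cluster("dupA", rng)
    dup = _copy_cluster(base, "dupB")

    def test_empty_pairs_isolated_nodes(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["cluster_a", "orf_a", "cluster_b", "orf_b",
                                      "score", "evalue"])
        g = build_gnn(empty, [self.base])
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 0

    def test_nonpositive_threshold_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            build_gnn(pd.DataFrame(), [self.base], threshold=0.0)

    def test_duplicated_cluster_gives_ten_pair_families(self):
        pairs = all_vs_all([self.base, self.dup])
        g = build_gnn(pairs, [self.base, self.dup], 1e-6)
        fams = detect_families(g).members()
        assert len(fams) == 10
        assert all(len(m) == 2 for m in fams.values())
        for members in fams.values():
            assert {c for c, _ in members} == {"dupA", "dupB"}

    def test_stricter_threshold_edges_nested(self):
        pairs = all_vs_all([self.base, self.dup] + reference_clusters())
        loose = build_gnn(pairs, [self.base, self.dup] + reference_clusters(), 1e-6)
        strict = build_gnn(pairs, [self.base, self.dup] + reference_clusters(), 1e-75)
        assert set(strict.edges) <= set(loose.edges)
        # family nesting: every strict family lies inside one loose family
        loose_f = detect_families(loose, strict_threshold=None).families
        strict_f = detect_families(strict, strict_threshold=None).families
        for fid in set(strict_f.values()):
            members = [n for n, f in strict_f.items() if f == fid]
            assert len({loose_f[n] for n in members}) == 1

    def test_marker_subfamilies_separate_at_strict_threshold(self):
        refs = reference_clusters()
        pairs = all_vs_all(refs)
        g = build_gnn(pairs, refs, 1e-6)
        merged = detect_families(g, strict_threshold=None)
        split = detect_families(g, strict_threshold=1e-75)
        label_of = {(c.cluster_id, o.orf_id): o.label for c in refs for o in c.orfs}
        marker_nodes = {n for n, l in label_of.items() if l in ("E2", "E3", "R3")}
        # permissive: E2, E3 and R3 share one family
        assert len({merged.families[n] for n in marker_nodes}) == 1
        # strict pass: one subfamily per marker label
        by_label = {}
        for n in marker_nodes:
            by_label.setdefault(label_of[n], set()).add(split.families[n])
        assert all(len(f) == 1 for f in by_label.values())
        assert (by_label["E2"] != by_label["E3"] != by_label["R3"]
                and by_label["E2"] != by_label["R3"])


class TestAnnotationAndProfiles:
    def test_annotation_and_profile_conservation(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        # every planted cassette family is labeled by its reference gene
        labels = {assignment.label_of(f) for f in assignment.families.values()}
        assert {"E", "E3", "E4", "E5", "E10"} <= labels
        prof = cluster_profile(assignment, clusters + references)
        for c in clusters + references:
            assert prof.loc[c.cluster_id].sum() == len(c.orfs)

    def test_majority_and_unknown_labels(self):
        fams = {("r", "a"): 1, ("r", "b"): 1, ("r", "c"): 1,
                ("h", "x"): 2, ("h", "y"): 2, ("h", "z"): 3}
        from edmine.gnn import FamilyAssignment
        refs = [GeneCluster("r", "reference", [
            ORF("a", 0, 3, "+", "MKT", "E3"), ORF("b", 0, 3, "+", "MKT", "E3"),
            ORF("c", 0, 3, "+", "MKT", "E2")])]
        ann = annotate_families(FamilyAssignment(dict(fams)), refs)
        assert ann.label_of(1) == "E3"       # majority of reference labels
        assert ann.label_of(2) == "unknown_family"
        assert ann.label_of(3) == "singleton"

    def test_cluster_similarity(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        prof = cluster_profile(assignment, clusters + references)
        shared, jaccard = cluster_similarity(prof)
        assert np.allclose(np.diag(jaccard), 1.0)
        assert (jaccard.values == jaccard.values.T).all()
        # same-clade clusters share more families than cross-clade ones
        assert jaccard.loc["strain_000", "strain_001"] > jaccard.loc["strain_000", "strain_007"]

    def test_disjoint_profiles_zero_similarity(self):
        import pandas as pd
        prof = pd.DataFrame([[1, 1, 0, 0], [0, 0, 2, 1]], index=["c1", "c2"],
                            columns=[1, 2, 3, 4])
        shared, jaccard = cluster_similarity(prof)
        assert shared.loc["c1", "c2"] == 0
        assert jaccard.loc["c1", "c2"] == 0.0
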