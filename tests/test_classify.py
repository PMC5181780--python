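import pytest

from edmine.classify import (default_moiety_definitions, load_moiety_definitions,
                             novelty_report, predict_moieties, predict_ring_size,
                             prediction_table)
from edmine.gnn import (GeneCluster, ORF, all_vs_all, annotate_families,
                        build_gnn, detect_families)


class TestRingPrediction:
    def test_calls_match_planted_truth(self, demo_cohort, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        preds = {p.cluster_id: p.call
                 for p in predict_ring_size(assignment, clusters, references, graph)}
        truth = demo_cohort.truth.strains.set_index("strain_id")
        for sid, call in preds.items():
            assert call == truth.loc[sid, "ring_class"]

    def test_exactly_one_call_per_cluster(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        preds = predict_ring_size(assignment, clusters, references, graph)
        assert len(preds) == len(clusters)
        assert all(p.call in ("nine", "ten", "ambiguous", "unknown") for p in preds)

    def test_evidence_recorded_for_calls(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        for p in predict_ring_size(assignment, clusters, references, graph):
            if p.call in ("nine", "ten"):
                markers = {m for m, _, _ in p.evidence}
                assert markers == ({"E2"} if p.call == "nine" else {"R3"})

    def test_removing_e2_references_never_creates_nine(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        no_e2_refs = [GeneCluster(c.cluster_id, c.source, [
            ORF(o.orf_id, o.start, o.end, o.strand, o.protein,
                None if o.label == "E2" else o.label) for o in c.orfs])
            for c in references]
        before = {p.cluster_id: p.call
                  for p in predict_ring_size(assignment, clusters, references, graph)}
        after = {p.cluster_id: p.call
                 for p in predict_ring_size(assignment, clusters, no_e2_refs, graph)}
        for cid, call in after.items():
            assert call != "nine"
            if before[cid] == "ten":
                assert call == "ten"
            if before[cid] == "nine":
                assert call in ("unknown", "ten")

    def test_both_markers_is_ambiguous_neither_is_unknown(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        e2_f = next(f for (c, o), f in assignment.families.items()
                    if c == "ref_nine" and assignment.label_of(f) != "singleton"
                    and any(orf.label == "E2" and orf.orf_id == o
                            for orf in references[0].orfs))
        r3_f = next(f for (c, o), f in assignment.families.items()
                    if any(orf.label == "R3" and orf.orf_id == o
                           for orf in references[1].orfs))
        from edmine.gnn import FamilyAssignment
        both = GeneCluster("both", "hit", [ORF("m1", 0, 3, "+", "MKT"),
                                           ORF("m2", 10, 13, "+", "MKT")])
        neither = GeneCluster("none", "hit", [ORF("n1", 0, 3, "+", "MKT")])
        local = FamilyAssignment(dict(assignment.families), dict(assignment.labels))
        local.families[("both", "m1")] = e2_f
        local.families[("both", "m2")] = r3_f
        local.families[("none", "n1")] = max(local.families.values()) + 1
        preds = {p.cluster_id: p.call
                 for p in predict_ring_size(local, [both, neither], references)}
        assert preds == {"both": "ambiguous", "none": "unknown"}

    def test_no_marker_references_rejected(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        bare = [GeneCluster(c.cluster_id, c.source, [
            ORF(o.orf_id, o.start, o.end, o.strand, o.protein, None) for o in c.orfs])
            for c in references]
        with pytest.raises(ValueError, match="marker"):
            predict_ring_size(assignment, clusters, bare)


class TestMoietyPrediction:
    def test_planted_moiety_sets_recovered(self, demo_cohort, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        preds = {p.cluster_id: p.moieties
                 for p in predict_moieties(assignment, clusters, references)}
        truth = demo_cohort.truth.strains.set_index("strain_id")
        for sid, moieties in preds.items():
            planted = set(filter(None, truth.loc[sid, "moieties"].split(",")))
            assert moieties == planted

    def test_apoprotein_hit_predicts_chromoprotein(self, demo_cohort, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        truth = demo_cohort.truth.strains.set_index("strain_id")
        preds = predict_moieties(assignment, clusters, references)
        apo_strains = {p.cluster_id for p in preds if "apoprotein" in p.moieties}
        expected = {s for s in truth.index
                    if truth.loc[s, "is_producer"] and "apoprotein" in str(truth.loc[s, "moieties"])}
        assert apo_strains == expected

    def test_evidence_per_predicted_moiety(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        for p in predict_moieties(assignment, clusters, references):
            for moiety in p.moieties:
                assert len(p.evidence[moiety]) >= 1

    def test_unknown_moiety_name_rejected(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        with pytest.raises(ValueError, match="unknown moiety"):
            predict_moieties(assignment, clusters, references,
                             {"mystery": (("x",), 1)})

    def test_definition_file_round_trip(self, tmp_path):
        path = tmp_path / "moieties.txt"
        path.write_text(
            "# moiety gene sets\n"
            "apoprotein: apo: 1\n"
            "amino_sugar: sug1,sug2,sug3,sug4: 2\n"
        )
        defs = load_moiety_definitions(path)
        assert defs["apoprotein"] == (("apo",), 1)
        assert defs["amino_sugar"] == (("sug1", "sug2", "sug3", "sug4"), 2)
        bad = tmp_path / "bad.txt"
        bad.write_text("gold_cofactor: g1: 1\n")
        with pytest.raises(ValueError, match="unknown moiety"):
            load_moiety_definitions(bad)

    def test_defaults_require_majority_of_set(self):
        defs = default_moiety_definitions()
        assert defs["apoprotein"][1] == 1
        assert defs["beta_amino_acid"][1] == 2


class TestNoveltyReport:
    def test_reference_against_itself_nothing_unknown(self):
        from edmine.simulate import reference_clusters
        refs = reference_clusters()
        pairs = all_vs_all(refs)
        graph = build_gnn(pairs, refs)
        assignment = annotate_families(detect_families(graph), refs)
        report = novelty_report(assignment, refs, refs).set_index("cluster_id")
        assert (report.n_novel_families == 0).all()

    def test_all_decoy_cluster_entirely_novel(self, demo_gnn):
        import numpy as np
        clusters, references, pairs, graph, assignment = demo_gnn
        rng = np.random.default_rng(8)
        orfs = [ORF(f"d{i}", 0, 300, "+",
                    "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100)))
                for i in range(5)]
        decoy = GeneCluster("alldecoy", "hit", orfs)
        pairs2 = all_vs_all([decoy] + references)
        graph2 = build_gnn(pairs2, [decoy] + references)
        assignment2 = annotate_families(detect_families(graph2), references)
        rep = novelty_report(assignment2, [decoy], references).iloc[0]
        assert rep.n_novel_families == rep.n_families == 5
        assert rep.n_singletons == 5

    def test_prediction_table_shape(self, demo_gnn):
        clusters, references, pairs, graph, assignment = demo_gnn
        table = prediction_table(
            predict_ring_size(assignment, clusters, references, graph),
            predict_moieties(assignment, clusters, references),
            novelty_report(assignment, clusters, references),
        )
        assert list(table.columns[:3]) == ["cluster_id", "ring_call", "moieties"]
        assert len(table) == len(clusters)
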