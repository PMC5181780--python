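import pytest

from edmine.align import SubstitutionMatrix
from edmine.gnn import all_vs_all, annotate_families, build_gnn, detect_families
from edmine.pipeline import fragments_from_screen
from edmine.screen import screen_cohort
from edmine.simulate import (SimulationConfig, default_primers, generate_cohort,
                             reference_clusters)

DNA_ALPHA = "ACGT"


@pytest.fixture(scope="session")
def dna_matrix():
    """Simple +5/-4 matrix over a 4-letter alphabet for oracle comparisons."""
    return SubstitutionMatrix.from_dict(
        DNA_ALPHA, {(a, b): (5.0 if a == b else -4.0) for a in DNA_ALPHA for b in DNA_ALPHA}
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """The default 14-strain demonstration cohort (9 producers, 3 clades)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def demo_screen(demo_cohort):
    return screen_cohort(demo_cohort.genomes, default_primers())


@pytest.fixture(scope="session")
def demo_fragments(demo_screen):
    return fragments_from_screen([r for r in demo_screen if r.architecture != "negative"])


@pytest.fixture(scope="session")
def demo_gnn(demo_cohort, demo_screen):
    """GNN over the demo cohort's producer clusters plus built-in references."""
    from edmine.gnn import cluster_from_genome

    producers = set(demo_cohort.producer_ids())
    clusters = [cluster_from_genome(g) for g in demo_cohort.genomes
                if g.genome_id in producers]
    references = reference_clusters()
    pairs = all_vs_all(clusters + references)
    graph = build_gnn(pairs, clusters + references)
    assignment = annotate_families(detect_families(graph), references)
    return clusters, references, pairs, graph, assignment
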