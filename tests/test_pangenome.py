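import numpy as np
import pytest

from panhgt import pangenome as pg
from oracles import mcl_dense


def test_mcl_matches_dense_oracle():
    # two tight cliques joined by one weak bridge
    nodes = [f"n{i}" for i in range(6)]
    graph = pg.SimilarityGraph(nodes)
    for a, b in [("n0", "n1"), ("n0", "n2"), ("n1", "n2")]:
        graph.add_edge(a, b, 0.9)
    for a, b in [("n3", "n4"), ("n3", "n5"), ("n4", "n5")]:
        graph.add_edge(a, b, 0.8)
    graph.add_edge("n2", "n3", 0.05)
    clusters, converged = pg.mcl_cluster(graph, inflation=2.0)
    oracle = mcl_dense(sorted(nodes), graph.edges, inflation=2.0)
    assert converged
    assert clusters == oracle
    assert clusters == [frozenset({"n0", "n1", "n2"}),
                        frozenset({"n3", "n4", "n5"})]


def test_mcl_isolated_nodes_singletons():
    graph = pg.SimilarityGraph(["a", "b", "c"])
    clusters, converged = pg.mcl_cluster(graph)
    assert converged
    assert clusters == [frozenset({"a"}), frozenset({"b"}), frozenset({"c"})]


def test_similarity_graph_rejects_self_edge_and_big_weight():
    graph = pg.SimilarityGraph(["a", "b"])
    with pytest.raises(ValueError):
        graph.add_edge("a", "a", 0.5)
    with pytest.raises(ValueError):
        graph.add_edge("a", "b", 1.5)


def test_partition_classes_and_sum():
    clusters = [frozenset({"g1.f1", "g2.f1"}),      # core (both genomes)
                frozenset({"g1.f2"}),               # unique
                frozenset({"g1.f3", "g1.f3b"})]     # unique (one genome, 2 copies)
    genome_of = {"g1.f1": "g1", "g2.f1": "g2", "g1.f2": "g1",
                 "g1.f3": "g1", "g1.f3b": "g1"}
    fams = pg.build_families(clusters, genome_of)
    pan = pg.partition_pangenome(fams, ["g1", "g2"], genome_of)
    c = pan.counts()
    assert c["total"] == c["core"] + c["dispensable"] + c["unique"]
    assert c == {"total": 3, "core": 1, "dispensable": 0, "unique": 2}
    assert pan.matrix.loc["g2"].sum() == 1


def test_partition_rejects_unknown_genome():
    fams = pg.build_families([frozenset({"gX.f1"})], {"gX.f1": "gX"})
    with pytest.raises(ValueError):
        pg.partition_pangenome(fams, ["g1"], {"gX.f1": "gX"})


def test_pangenome_recovers_planted_families(small_collection):
    proteins = {c.cds_id: c.aa_seq
                for g in small_collection.genomes for c in g.cds}
    genome_of = {c.cds_id: g.genome_id
                 for g in small_collection.genomes for c in g.cds}
    pan = pg.pangenome_from_proteins(proteins, genome_of)
    inferred = {f.members for f in pan.families}
    truth = {frozenset(m) for m in small_collection.truth.families().values()}
    assert inferred == truth
    c = pan.counts()
    assert c["total"] == c["core"] + c["dispensable"] + c["unique"]


def test_single_copy_core(small_collection):
    proteins = {c.cds_id: c.aa_seq
                for g in small_collection.genomes for c in g.cds}
    genome_of = {c.cds_id: g.genome_id
                 for g in small_collection.genomes for c in g.cds}
    pan = pg.pangenome_from_proteins(proteins, genome_of)
    scc = pg.single_copy_core(pan)
    n_genomes = len(small_collection.genomes)
    fam_by_id = {f.family_id: f for f in pan.families}
    for fam_id in scc:
        prof = fam_by_id[fam_id].copy_profile
        assert len(prof) == n_genomes
        assert all(v == 1 for v in prof.values())


def test_jaccard_matrix_oracle():
    import pandas as pd

    m = pd.DataFrame([[1, 1, 0], [1, 0, 1], [0, 0, 1]],
                     index=["a", "b", "c"], columns=["f1", "f2", "f3"])
    d = pg.jaccard_distance_matrix(m)
    assert d.loc["a", "b"] == pytest.approx(1 - 1 / 3)
    assert d.loc["a", "c"] == pytest.approx(1.0)
    assert d.loc["b", "c"] == pytest.approx(1 - 1 / 2)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert np.allclose(np.diag(d.to_numpy()), 0.0)


def test_presence_absence_dendrogram(small_collection):
    import pandas as pd

    genomes = sorted(g.genome_id for g in small_collection.genomes)
    truth_fams = small_collection.truth.families()
    genome_of_cds = {c.cds_id: g.genome_id
                     for g in small_collection.genomes for c in g.cds}
    data = {fam: [int(any(genome_of_cds[c] == g for c in mem))
                  for g in genomes]
            for fam, mem in truth_fams.items()}
    m = pd.DataFrame(data, index=genomes)
    newick, ordered = pg.cluster_presence_absence(m)
    assert newick.endswith(";")
    assert set(ordered.index) == set(genomes)
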