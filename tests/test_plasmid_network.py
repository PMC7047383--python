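import numpy as np
import pytest

from panhgt import plasmid_network as pn
from oracles import fisher_greater_p


def _toy_proteomes():
    # two plasmid groups with distinct (unrelated) protein repertoires
    rng = np.random.default_rng(61)
    aas = "ARNDCQEGHILKMFPSTWYV"

    def prot(n):
        return "".join(rng.choice(list(aas), n))

    group1 = {f"f{i}": prot(120) for i in range(6)}
    group2 = {f"h{i}": prot(120) for i in range(6)}
    proteomes = {}
    for k in range(3):
        proteomes[f"pA{k}"] = dict(group1)
        proteomes[f"pB{k}"] = dict(group2)
    return proteomes


def test_greedy_cluster_groups_identical_proteins():
    proteins = {"a": "MKTAYIAKQRQISFVKSHFSRQ", "b": "MKTAYIAKQRQISFVKSHFSRQ",
                "c": "WWWWYYYYWWWWYYYYWWWW"}
    fams = pn.greedy_protein_cluster(proteins)
    groups = sorted(sorted(m) for m in fams.values())
    assert groups == [["a", "b"], ["c"]]


def test_greedy_cluster_order_invariance():
    rng = np.random.default_rng(62)
    aas = "ARNDCQEGHILKMFPSTWYV"
    base = "".join(rng.choice(list(aas), 100))
    mut = base[:50] + "".join(rng.choice(list(aas), 4)) + base[54:]
    proteins = {"x1": base, "x2": mut,
                "y1": "".join(rng.choice(list(aas), 100))}
    f1 = pn.greedy_protein_cluster(proteins)
    f2 = pn.greedy_protein_cluster(dict(reversed(list(proteins.items()))))
    assert sorted(map(sorted, f1.values())) == sorted(map(sorted, f2.values()))


def test_bipartite_handshake_invariant():
    net, _ = pn.bipartite_from_proteomes(_toy_proteomes())
    degrees = net.degrees
    assert sum(degrees.values()) == 2 * net.graph.number_of_edges()
    # bipartite: no plasmid-plasmid or family-family edges
    for u, v in net.graph.edges:
        assert {net.graph.nodes[u]["partition"],
                net.graph.nodes[v]["partition"]} == {"plasmid", "family"}


def test_shared_families_on_at_least_two_plasmids():
    net, _ = pn.bipartite_from_proteomes(_toy_proteomes())
    for f in net.shared_families:
        assert net.graph.degree(f) >= 2


def test_cluster_recovery_and_monotone_cut():
    net, _ = pn.bipartite_from_proteomes(_toy_proteomes())
    cl = pn.cluster_plasmids(net, cut=0.15)
    clusters = {frozenset(v) for v in cl.clusters().values()}
    assert clusters == {frozenset({"pA0", "pA1", "pA2"}),
                        frozenset({"pB0", "pB1", "pB2"})}
    n_prev = None
    for cut in (0.02, 0.15, 0.6, 1.01):
        n = len(pn.cluster_plasmids(net, cut=cut).clusters())
        if n_prev is not None:
            assert n <= n_prev  # raising the cut can only merge clusters
        n_prev = n
    assert n_prev == 1


def test_cluster_requires_two_plasmids():
    net = pn.build_bipartite({"p1": {"f1"}})
    with pytest.raises(ValueError):
        pn.cluster_plasmids(net)


def test_cog_enrichment_matches_enumeration_oracle():
    focus = {f"g{i}" for i in range(6)}
    background = {f"b{i}" for i in range(8)}
    categories = {}
    for i in range(6):
        categories[f"g{i}"] = "K" if i < 5 else "T"
    for i in range(8):
        categories[f"b{i}"] = "K" if i < 2 else "T"
    df = pn.cog_enrichment(focus, background, categories)
    row = df[df.category == "K"].iloc[0]
    oracle = fisher_greater_p(int(row.focus_in), int(row.focus_out),
                              int(row.background_in), int(row.background_out))
    assert row.raw_p == pytest.approx(oracle, abs=1e-12)


def test_cog_enrichment_empty_focus_rejected():
    with pytest.raises(ValueError):
        pn.cog_enrichment(set(), {"a"}, {"a": "K"})


def test_gexf_export_roundtrip(tmp_path):
    import networkx as nx

    net, _ = pn.bipartite_from_proteomes(_toy_proteomes())
    cl = pn.cluster_plasmids(net, cut=0.15)
    path = tmp_path / "net.gexf"
    pn.export_gexf(net, cl, path)
    g = nx.read_gexf(path)
    assert g.number_of_nodes() == net.graph.number_of_nodes()
    assert g.nodes["pA0"]["cluster"] == cl.labels["pA0"]


def test_planted_plasmid_clusters_recovered(small_collection):
    proteomes = {}
    for g in small_collection.genomes:
        sym = g.symbiosis_plasmid
        proteomes[sym.replicon_id] = {
            c.cds_id: c.aa_seq for c in g.cds_by_replicon(sym.replicon_id)}
    net, _ = pn.bipartite_from_proteomes(proteomes)
    cl = pn.cluster_plasmids(net, cut=0.15)
    truth_label = {rid: lab
                   for (gid, rid), lab in
                   small_collection.truth.plasmid_clusters.items()
                   if rid in proteomes}
    inferred = {}
    for rid, lab in cl.labels.items():
        inferred.setdefault(lab, set()).add(rid)
    expected = {}
    for rid, lab in truth_label.items():
        expected.setdefault(lab, set()).add(rid)
    assert {frozenset(v) for v in inferred.values()} == \
        {frozenset(v) for v in expected.values()}
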