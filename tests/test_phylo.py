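import dendropy
import numpy as np
import pandas as pd
import pytest

from panhgt import phylo
from oracles import enumerate_tree_loglik, random_additive_tree


def _msa_from_tree(newick, ncols, rng, rate=0.1):
    """Evolve a quick JC alignment down a newick tree (test-local simulator)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    seqs = {}

    def walk(node, seq):
        for child in node.child_nodes():
            p = 0.75 * (1 - np.exp(-4.0 / 3.0 * (child.edge.length or 0.0) * rate))
            mut = rng.random(ncols) < p
            cseq = seq.copy()
            cseq[mut] = rng.integers(0, 4, int(mut.sum()))
            if child.is_leaf():
                seqs[child.taxon.label] = cseq
            else:
                walk(child, cseq)

    walk(tree.seed_node, rng.integers(0, 4, ncols))
    ids = sorted(seqs)
    rows = ["".join("ACGT"[c] for c in seqs[i]) for i in ids]
    return phylo.MSA(ids, rows, "nt")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_nj_recovers_known_quartet():
    # additive matrix for ((A,B),(C,D)) with internal branch 0.3
    labels = ["A", "B", "C", "D"]
    d = pd.DataFrame(
        [[0.0, 0.2, 0.7, 0.8],
         [0.2, 0.0, 0.7, 0.8],
         [0.7, 0.7, 0.0, 0.3],
         [0.8, 0.8, 0.3, 0.0]], index=labels, columns=labels)
    tree = phylo.nj_tree(d)
    ref = dendropy.Tree.get(data="((A:0.1,B:0.1):0.25,(C:0.1,D:0.2):0.25);",
                            schema="newick")
    assert phylo.rf_distance(tree, ref) == 0


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(21)
    for _ in range(20):
        newick, labels, d = random_additive_tree(6, rng)
        dist = pd.DataFrame(d, index=labels, columns=labels)
        tree = phylo.nj_tree(dist)
        ref = dendropy.Tree.get(data=newick, schema="newick")
        assert phylo.rf_distance(tree, ref) == 0
        # NJ on an additive matrix reproduces the tree metric exactly
        pdm = tree.phylogenetic_distance_matrix()
        taxon = {t.label: t for t in tree.taxon_namespace}
        for i in range(6):
            for j in range(i + 1, 6):
                got = pdm.patristic_distance(taxon[labels[i]], taxon[labels[j]])
                assert got == pytest.approx(d[i, j], abs=1e-9)


def test_nj_rejects_asymmetric_matrix():
    d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"],
                     columns=["a", "b"])
    with pytest.raises(ValueError):
        phylo.nj_tree(d)


def test_rf_distance_zero_for_same_topology():
    t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    t2 = dendropy.Tree.get(data="((C:2,D:9):1,(B:1,A:1):3);", schema="newick")
    assert phylo.rf_distance(t1, t2) == 0


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def test_jc_distance_closed_form():
    # 10 differences over 100 sites -> p = 0.1
    a = "A" * 100
    b = "C" * 10 + "A" * 90
    msa = phylo.MSA(["x", "y"], [a, b], "nt")
    d = phylo.jc_distance_matrix(msa)
    expected = -0.75 * np.log(1 - 4 * 0.1 / 3)
    assert d.loc["x", "y"] == pytest.approx(expected, abs=1e-12)


def test_jc_distance_gap_exclusion_and_saturation():
    msa = phylo.MSA(["x", "y"], ["AC-TA", "ACGTA"], "nt")
    assert phylo.jc_distance_matrix(msa).loc["x", "y"] == 0.0
    sat = phylo.MSA(["x", "y"], ["AAAA", "CCCC"], "nt")
    assert phylo.jc_distance_matrix(sat).loc["x", "y"] == 5.0


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def test_align_family_identical_sequences():
    msa = phylo.align_family({"a": "MKTAYI", "b": "MKTAYI", "c": "MKTAYI"})
    assert msa.rows == ["MKTAYI"] * 3


def test_align_family_gaps_placed():
    msa = phylo.align_family({"a": "MKTAYIAK", "b": "MKTAK"})
    assert len(msa.rows[0]) == len(msa.rows[1])
    assert msa.row("a").replace("-", "") == "MKTAYIAK"
    assert msa.row("b").replace("-", "") == "MKTAK"


def test_backtranslate_roundtrip():
    nt = {"a": "ATGAAAACC", "b": "ATGAAA"}
    aa = {"a": "MKT", "b": "MK"}
    msa_nt = phylo.backtranslate(phylo.align_family(aa), nt)
    assert msa_nt.row("a").replace("-", "") == nt["a"]
    assert msa_nt.row("b").replace("-", "") == nt["b"]
    assert msa_nt.n_cols % 3 == 0


def test_backtranslate_rejects_mismatched_nt():
    aa_msa = phylo.MSA(["a"], ["MK"], "aa")
    with pytest.raises(ValueError):
        phylo.backtranslate(aa_msa, {"a": "ATGCCC"})  # MP, not MK


def test_concatenate_partitions():
    m1 = phylo.MSA(["a", "b"], ["AAA", "CCC"], "nt")
    m2 = phylo.MSA(["a", "b"], ["GGGG", "TTTT"], "nt")
    cat, parts = phylo.concatenate([m1, m2], ["a", "b"])
    assert cat.row("a") == "AAAGGGG"
    assert parts == [(0, 3), (3, 7)]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_pattern_loglik_matches_state_enumeration():
    rng = np.random.default_rng(31)
    msa = _msa_from_tree("((A:1,B:1.5):0.5,(C:0.7,D:1.2):0.5);", 120, rng)
    tree = dendropy.Tree.get(data="((A:0.1,B:0.15):0.05,(C:0.07,D:0.12):0.05);",
                             schema="newick")
    fit = phylo.TopologyLikelihood(msa, tree)
    fit.rates = np.array([1.5, 2.5, 0.7, 1.2, 3.1, 1.0])
    fit.alpha = 0.8
    site = fit.site_loglik()
    tip_codes = {sid: np.array([{"A": 0, "C": 1, "G": 2, "T": 3}.get(ch, -1)
                                for ch in row], dtype=np.int8)
                 for sid, row in zip(msa.ids, msa.rows)}
    oracle = enumerate_tree_loglik(fit.tree, tip_codes, fit._q_matrix(),
                                   fit.freqs, fit._category_rates())
    assert np.allclose(site, oracle, atol=1e-9)


def test_optimize_increases_loglik_and_edge_factorization_consistent():
    rng = np.random.default_rng(32)
    msa = _msa_from_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:2):1);",
                         200, rng, rate=0.15)
    tree = phylo.nj_tree(phylo.jc_distance_matrix(msa))
    fit = phylo.TopologyLikelihood(msa, tree)
    before = fit.loglik()
    w, right, left = fit._eigen()
    cr = fit._category_rates()
    for e in fit._edges:
        A, B = fit._edge_arrays(e)
        assert fit._edge_loglik(A, B, e.length, w, right, left, cr) == \
            pytest.approx(before, abs=1e-6)
    after = fit.optimize()
    assert after >= before - 1e-9
    assert fit.loglik() == pytest.approx(after, abs=1e-9)


def test_likelihood_prefers_generating_topology():
    rng = np.random.default_rng(33)
    true_nwk = "((A:1,B:1):2,(C:1,D:1):2);"
    msa = _msa_from_tree(true_nwk, 400, rng, rate=0.2)
    t_true = dendropy.Tree.get(data="((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);",
                               schema="newick")
    t_alt = dendropy.Tree.get(data="((A:0.1,C:0.1):0.2,(B:0.1,D:0.1):0.2);",
                              schema="newick")
    l_true, _ = phylo.site_loglik(msa, t_true)
    l_alt, _ = phylo.site_loglik(msa, t_alt)
    assert l_true.sum() > l_alt.sum()


# ---------------------------------------------------------------------------
# SH test & screen
# ---------------------------------------------------------------------------

def test_sh_test_shortcut_for_identical_topology():
    t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    t2 = dendropy.Tree.get(data="((B:5,A:2):1,(D:1,C:1):1);", schema="newick")
    msa = phylo.MSA(["A", "B", "C", "D"], ["ACGT"] * 4, "nt")
    r = phylo.sh_test(msa, t1, t2)
    assert r.rf_shortcut and r.consistent and r.p_value == 1.0


def test_sh_test_rejects_wrong_topology():
    rng = np.random.default_rng(34)
    msa = _msa_from_tree("((A:1,B:1):3,(C:1,D:1):3);", 600, rng, rate=0.2)
    gene = dendropy.Tree.get(data="((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);",
                             schema="newick")
    wrong = dendropy.Tree.get(data="((A:0.1,C:0.1):0.3,(B:0.1,D:0.1):0.3);",
                              schema="newick")
    r = phylo.sh_test(msa, wrong, gene, n_rell=500, seed=3)
    assert not r.consistent
    assert r.delta_lnl > 0


def test_vertical_screen_consistent_genes(small_collection):
    rng = np.random.default_rng(35)
    nwk = "((A:0.5,B:0.5):1,((C:0.5,D:0.5):0.6,(E:0.5,F:0.5):0.6):0.4);"
    species = dendropy.Tree.get(data=nwk, schema="newick")
    msas = {f"g{i}": _msa_from_tree(nwk, 300, rng, rate=0.2) for i in range(5)}
    out = phylo.vertical_screen(msas, species, n_rell=300, seed=1)
    assert sum(r.consistent for r in out.values()) >= 4
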