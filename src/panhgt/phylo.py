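"""Alignments, trees and the gene-tree/species-tree concordance screen.

The vertical screen asks, per single-copy core family, whether the gene
phylogeny is consistent with the species tree: a gene whose NJ topology
equals the species topology (unrooted Robinson-Foulds distance 0) is
consistent outright; otherwise a Shimodaira-Hasegawa test with RELL
resampling compares the species topology against the gene's own topology
under GTR+Gamma, and the gene is consistent when the test fails to reject
the species topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import align as _align

# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]
    alphabet: str  # "nt" or "aa"

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


# ---------------------------------------------------------------------------
# Progressive protein alignment
# ---------------------------------------------------------------------------

_GAP_OPEN = 10.0
_GAP_EXT = 0.5


def _profile(rows: list[str], submat_size: int) -> np.ndarray:
    prof = np.zeros((len(rows[0]), submat_size))
    n = len(rows)
    for r in rows:
        codes = _align.encode_protein(r)
        for i, ch in enumerate(r):
            if ch != "-":
                prof[i, codes[i]] += 1.0 / n
    return prof


def _merge_alignments(a: dict[str, str], b: dict[str, str],
                      submat: np.ndarray) -> dict[str, str]:
    rows_a, rows_b = list(a.values()), list(b.values())
    pa = _profile(rows_a, submat.shape[0])
    pb = _profile(rows_b, submat.shape[0])
    score = np.ascontiguousarray(pa @ submat @ pb.T)
    ops = _align._nw_profile(score, _GAP_OPEN, _GAP_EXT)
    out: dict[str, list[str]] = {k: [] for k in list(a) + list(b)}
    i = j = 0
    for op in ops:
        if op == 0:
            for k in a:
                out[k].append(a[k][i])
            for k in b:
                out[k].append(b[k][j])
            i += 1
            j += 1
        elif op == 1:
            for k in a:
                out[k].append(a[k][i])
            for k in b:
                out[k].append("-")
            i += 1
        else:
            for k in a:
                out[k].append("-")
            for k in b:
                out[k].append(b[k][j])
            j += 1
    return {k: "".join(v) for k, v in out.items()}


def _kmer_distance(seqs: dict[str, str], k: int = 3) -> pd.DataFrame:
    ids = sorted(seqs)
    sets = {i: {seqs[i][j:j + k] for j in range(max(1, len(seqs[i]) - k + 1))}
            for i in ids}
    d = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sets[ids[i]], sets[ids[j]]
            shared = len(a & b) / max(1, min(len(a), len(b)))
            d[i, j] = d[j, i] = 1.0 - shared
    return pd.DataFrame(d, index=ids, columns=ids)


def align_family(seqs: dict[str, str]) -> MSA:
    """Deterministic progressive alignment of a protein family.

    Guide tree: NJ on fractional shared-3-mer distances, midpoint rooted.
    Profile-profile Needleman-Wunsch with BLOSUM62 (gap open 10, extend 0.5).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    legal = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    for sid, s in seqs.items():
        bad = set(s.upper()) - legal
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(bad)} in {sid}")
    submat = _align.blosum62_matrix()
    ids = sorted(seqs)
    if len(ids) == 2:
        merged = _merge_alignments({ids[0]: seqs[ids[0]]},
                                   {ids[1]: seqs[ids[1]]}, submat)
        return MSA(ids, [merged[i] for i in ids], "aa")
    guide = nj_tree(_kmer_distance(seqs))
    guide.reroot_at_midpoint(update_bipartitions=False)
    aln = _progressive(guide.seed_node, seqs, submat)
    return MSA(ids, [aln[i] for i in ids], "aa")


def _progressive(node, seqs, submat) -> dict[str, str]:
    if node.is_leaf():
        return {node.taxon.label: seqs[node.taxon.label]}
    children = [_progressive(c, seqs, submat) for c in node.child_nodes()]
    acc = children[0]
    for nxt in children[1:]:
        acc = _merge_alignments(acc, nxt, submat)
    if node.taxon is not None:
        # midpoint rooting of a zero-length guide tree can root at a leaf,
        # leaving it with children; merge its own sequence too
        acc = _merge_alignments(
            acc, {node.taxon.label: seqs[node.taxon.label]}, submat)
    return acc


def backtranslate(msa_aa: MSA, nt_seqs: dict[str, str]) -> MSA:
    """Expand each amino-acid column into its codon; aa gap -> '---'."""
    from Bio.Seq import Seq

    rows = []
    for sid, row in zip(msa_aa.ids, msa_aa.rows):
        nt = nt_seqs[sid]
        aa_plain = row.replace("-", "")
        trans = str(Seq(nt).translate())
        if trans.endswith("*"):
            trans = trans[:-1]
        if trans != aa_plain:
            pos = next((i for i, (x, y) in enumerate(zip(trans, aa_plain))
                        if x != y), min(len(trans), len(aa_plain)))
            raise ValueError(
                f"nucleotide sequence of {sid} does not translate to its "
                f"aligned protein (first mismatch at residue {pos})")
        out = []
        k = 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[3 * k:3 * k + 3])
                k += 1
        rows.append("".join(out))
    return MSA(list(msa_aa.ids), rows, "nt")


def concatenate(msas: list[MSA], id_order: list[str]
                ) -> tuple[MSA, list[tuple[int, int]]]:
    """Concatenate alignments in order; returns the supermatrix and the
    half-open column range of each partition."""
    rows = {i: [] for i in id_order}
    partitions = []
    pos = 0
    for m in msas:
        missing = set(id_order) - set(m.ids)
        if missing:
            raise ValueError(f"alignment missing taxa: {sorted(missing)}")
        for i in id_order:
            rows[i].append(m.row(i))
        partitions.append((pos, pos + m.n_cols))
        pos += m.n_cols
    return MSA(list(id_order), ["".join(rows[i]) for i in id_order],
               msas[0].alphabet), partitions


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor joining with deterministic tie-breaks.

    Ties in the Q criterion resolve to the lexicographically smallest pair
    of subtree labels (the smallest leaf label below each node). Negative
    branch lengths are clamped to zero and the deficit moved to the sibling
    branch, preserving the path length through the join.
    """
    labels = list(dist.index)
    n = len(labels)
    tns = dendropy.TaxonNamespace()
    if n == 1:
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node.taxon = tns.new_taxon(label=labels[0])
        return tree
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-9) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=lab)
        nodes.append((lab, node))
    if n == 2:
        tree = dendropy.Tree(taxon_namespace=tns)
        half = d[0, 1] / 2.0
        for _, node in nodes:
            node.edge.length = half
            tree.seed_node.add_child(node)
        tree.is_rooted = False
        return tree

    active = list(range(n))
    dm = d
    min_label = {i: labels[i] for i in range(n)}
    node_of = {i: nodes[i][1] for i in range(n)}
    next_id = n
    dmat = {(i, j): dm[i, j] for i in range(n) for j in range(n) if i < j}

    def dist_of(i, j):
        return dmat[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = {i: sum(dist_of(i, k) for k in active if k != i) for i in active}
        best = None
        m = len(active)
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                q = (m - 2) * dist_of(i, j) - r[i] - r[j]
                key = tuple(sorted((min_label[i], min_label[j])))
                if best is None or q < best[0] - 1e-12 or \
                        (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = dist_of(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(0.0, li)
        parent = dendropy.Node()
        ni, nj = node_of[i], node_of[j]
        ni.edge.length = li
        nj.edge.length = lj
        parent.add_child(ni)
        parent.add_child(nj)
        u = next_id
        next_id += 1
        node_of[u] = parent
        min_label[u] = min(min_label[i], min_label[j])
        for k in active:
            if k in (i, j):
                continue
            dmat[(min(u, k), max(u, k))] = 0.5 * (
                dist_of(i, k) + dist_of(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three nodes around an unrooted central node
    a, b, c = sorted(active, key=lambda k: min_label[k])
    dab, dac, dbc = dist_of(a, b), dist_of(a, c), dist_of(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    lengths = {a: la, b: lb, c: lc}
    # clamp negatives, moving the deficit to the other two branches equally
    for k in (a, b, c):
        if lengths[k] < 0:
            deficit = lengths[k]
            lengths[k] = 0.0
            others = [x for x in (a, b, c) if x != k]
            for o in others:
                lengths[o] = max(0.0, lengths[o] + deficit / 2.0)
    center = dendropy.Node()
    for k in (a, b, c):
        node_of[k].edge.length = lengths[k]
        center.add_child(node_of[k])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (shared taxon namespace enforced)."""
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def jc_distance_matrix(msa_nt: MSA) -> pd.DataFrame:
    """Maximum-likelihood pairwise distances under Jukes-Cantor.

    Gap or ambiguous positions are excluded pairwise; saturated pairs
    (p >= 0.749) are capped at distance 5.
    """
    ids = list(msa_nt.ids)
    arrs = [np.array([_NT_CODE.get(c, -1) for c in row], dtype=np.int8)
            for row in msa_nt.rows]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] >= 0) & (arrs[j] >= 0)
            tot = int(ok.sum())
            if tot == 0:
                dij = 5.0
            else:
                p = float(np.sum(arrs[i][ok] != arrs[j][ok])) / tot
                dij = 5.0 if p >= 0.749 else -0.75 * np.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = max(0.0, dij)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# GTR + Gamma likelihood on a fixed topology
# ---------------------------------------------------------------------------

_RATE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


class TopologyLikelihood:
    """Felsenstein pruning under GTR(+Gamma, 4 categories) on a fixed topology.

    Branch lengths are optimized coordinate-wise (Brent); exchangeability
    rates (GT fixed at 1) and the gamma shape are optimized by L-BFGS-B on
    log-parameters; base frequencies are empirical. Columns with gaps or
    ambiguity codes contribute partial information (uniform tip likelihood at
    those positions).
    """

    def __init__(self, msa_nt: MSA, tree: dendropy.Tree, n_cat: int = 4,
                 equal_rates: bool = False, gamma: bool = True):
        if msa_nt.n_cols == 0:
            raise ValueError("alignment has zero columns")
        self.msa = msa_nt
        self.tree = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                                      schema="newick",
                                      taxon_namespace=dendropy.TaxonNamespace())
        self.tree.is_rooted = True
        # resolve any basal polytomy so every node has <= 2 children
        self.tree.resolve_polytomies()
        self.n_cat = n_cat if gamma else 1
        self.gamma = gamma
        self.equal_rates = equal_rates
        tips = {t.label for t in self.tree.taxon_namespace}
        if tips != set(msa_nt.ids):
            raise ValueError("tree tips and alignment ids differ")

        mat = np.array([[_NT_CODE.get(c, -1) for c in row]
                        for row in msa_nt.rows], dtype=np.int8)
        # pattern compression
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True)
        self._patterns = patterns
        self._inverse = inverse
        self._weights = counts.astype(float)
        self._row_of = {sid: k for k, sid in enumerate(msa_nt.ids)}

        counts4 = np.bincount(mat[mat >= 0].ravel(), minlength=4) + 1.0
        self.freqs = counts4 / counts4.sum()
        self.rates = np.ones(6)
        self.alpha = 1.0

        self._edges = [e for e in self.tree.preorder_edge_iter()
                       if e.head_node.parent_node is not None]
        for e in self._edges:
            if e.length is None or e.length <= 0:
                e.length = 0.05
        self._postorder = list(self.tree.postorder_node_iter())
        # tip partial likelihoods
        self._tip_partials = {}
        npat = patterns.shape[1]
        for sid, k in self._row_of.items():
            p = np.zeros((4, npat))
            codes = patterns[k]
            for s in range(4):
                p[s] = (codes == s) | (codes < 0)
            self._tip_partials[sid] = p

    # -- model matrices ----------------------------------------------------

    def _q_matrix(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _RATE_PAIRS):
            q[i, j] = r * self.freqs[j]
            q[j, i] = r * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(self.freqs, np.diag(q))
        return q / scale

    def _category_rates(self) -> np.ndarray:
        if not self.gamma or self.n_cat == 1:
            return np.ones(1)
        from scipy.stats import gamma as gamma_dist

        quantiles = (2 * np.arange(self.n_cat) + 1) / (2 * self.n_cat)
        r = gamma_dist.ppf(quantiles, a=self.alpha, scale=1.0 / self.alpha)
        return r / r.mean()

    def _eigen(self):
        q = self._q_matrix()
        sq = np.sqrt(self.freqs)
        s = (q * sq[:, None]) / sq[None, :]
        s = (s + s.T) / 2.0
        w, u = np.linalg.eigh(s)
        left = u.T * sq[None, :]
        right = u / sq[:, None]
        return w, right, left

    # -- likelihood --------------------------------------------------------

    def _pmat(self, length: float, w, right, left, cat_rates) -> np.ndarray:
        """Stacked transition matrices, one per rate category: (ncat, 4, 4)."""
        pm = np.einsum("ij,cj,jk->cik", right,
                       np.exp(np.outer(cat_rates, w) * length), left)
        np.clip(pm, 1e-300, None, out=pm)
        return pm

    def _below_partials(self, pmats: dict) -> dict:
        """Postorder conditional likelihoods, stacked over categories:
        node id -> (ncat, 4, npat)."""
        ncat = len(self._category_rates())
        partials = {}
        for node in self._postorder:
            if node.is_leaf():
                tip = self._tip_partials[node.taxon.label]
                partials[id(node)] = np.broadcast_to(
                    tip, (ncat,) + tip.shape)
                continue
            acc = None
            for child in node.child_nodes():
                term = pmats[id(child.edge)] @ partials[id(child)]
                acc = term if acc is None else acc * term
            partials[id(node)] = acc
        return partials

    def _all_pmats(self) -> dict:
        w, right, left = self._eigen()
        cat_rates = self._category_rates()
        return {id(e): self._pmat(e.length, w, right, left, cat_rates)
                for e in self._edges}

    def _pattern_loglik(self) -> np.ndarray:
        partials = self._below_partials(self._all_pmats())
        root = partials[id(self.tree.seed_node)]
        total = np.einsum("i,cip->p", self.freqs, root) / root.shape[0]
        return np.log(np.clip(total, 1e-300, None))

    def loglik(self) -> float:
        return float(np.dot(self._pattern_loglik(), self._weights))

    def site_loglik(self) -> np.ndarray:
        """Per original alignment column log-likelihoods."""
        return self._pattern_loglik()[self._inverse]

    # -- optimization ------------------------------------------------------

    def _edge_arrays(self, edge) -> tuple[np.ndarray, np.ndarray]:
        """Above/below factorization at ``edge``: (A, B), each (ncat,4,npat).

        With P(t) the transition matrices of ``edge``, the per-pattern
        likelihood is mean_c sum_ij A[c,i] P_c(t)[i,j] B[c,j] — everything
        except the edge's own length is frozen into A and B, so branch
        optimization evaluates in O(npat) instead of a full pruning pass.
        """
        pmats = self._all_pmats()
        below = self._below_partials(pmats)
        above: dict = {}
        for node in self.tree.preorder_node_iter():
            children = node.child_nodes()
            if not children:
                continue
            down = {id(c): pmats[id(c.edge)] @ below[id(c)] for c in children}
            if node.parent_node is None:
                base = self.freqs[None, :, None]
            else:
                f = node.edge
                base = np.matmul(pmats[id(f)].transpose(0, 2, 1),
                                 above[id(node)])
            for c in children:
                acc = np.broadcast_to(base, down[id(c)].shape).copy()
                for other in children:
                    if other is not c:
                        acc *= down[id(other)]
                above[id(c)] = acc
        v = edge.head_node
        return above[id(v)], below[id(v)]

    def _edge_loglik(self, A: np.ndarray, B: np.ndarray, length: float,
                     w, right, left, cat_rates) -> float:
        pm = self._pmat(length, w, right, left, cat_rates)
        total = np.einsum("cip,cip->p", A, pm @ B) / A.shape[0]
        return float(np.dot(np.log(np.clip(total, 1e-300, None)),
                            self._weights))

    def _optimize_branches(self, rel_tol: float = 1e-6) -> None:
        from scipy.optimize import minimize_scalar

        w, right, left = self._eigen()
        cat_rates = self._category_rates()
        for e in self._edges:
            A, B = self._edge_arrays(e)

            def neg(x):
                return -self._edge_loglik(A, B, x, w, right, left, cat_rates)

            res = minimize_scalar(neg, bounds=(1e-9, 5.0), method="bounded",
                                  options={"xatol": max(1e-8, rel_tol)})
            e.length = float(res.x)

    def _optimize_model(self) -> None:
        from scipy.optimize import minimize

        names = []
        x0 = []
        if not self.equal_rates:
            names += ["rates"]
            x0 += list(np.log(self.rates[:5]))
        if self.gamma:
            names += ["alpha"]
            x0 += [np.log(self.alpha)]
        if not x0:
            return

        def neg(x):
            k = 0
            if "rates" in names:
                self.rates = np.append(np.exp(x[k:k + 5]), 1.0)
                k += 5
            if "alpha" in names:
                self.alpha = float(np.clip(np.exp(x[k]), 0.02, 100.0))
            return -self.loglik()

        from scipy import optimize as _opt
        res = _opt.minimize(neg, np.array(x0), method="L-BFGS-B",
                            options={"maxiter": 60, "ftol": 1e-8})
        neg(res.x)

    def optimize(self, rounds: int = 2) -> float:
        for _ in range(rounds):
            self._optimize_branches()
            self._optimize_model()
        self._optimize_branches()
        return self.loglik()


def site_loglik(msa_nt: MSA, topology: dendropy.Tree, n_cat: int = 4,
                equal_rates: bool = False, gamma: bool = True,
                rounds: int = 2) -> tuple[np.ndarray, TopologyLikelihood]:
    """Optimize GTR+Gamma on the fixed topology; return per-site lnL."""
    fit = TopologyLikelihood(msa_nt, topology, n_cat=n_cat,
                             equal_rates=equal_rates, gamma=gamma)
    fit.optimize(rounds=rounds)
    return fit.site_loglik(), fit


# ---------------------------------------------------------------------------
# Shimodaira-Hasegawa test
# ---------------------------------------------------------------------------

@dataclass
class SHTestResult:
    family_id: str
    delta_lnl: float
    p_value: float
    consistent: bool
    rf_shortcut: bool = False


def sh_test(msa_nt: MSA, species_topology: dendropy.Tree,
            alternative_topology: dendropy.Tree, n_rell: int = 1000,
            seed: int = 0, alpha: float = 0.05,
            family_id: str = "") -> SHTestResult:
    """SH test of the species topology against one alternative.

    Per-site log-likelihoods are computed for both topologies (each with its
    own optimized branch lengths and model); the statistic is
    delta = lnL_best - lnL_species. RELL resampling of site columns gives the
    null distribution of centered differences; p is the fraction of
    replicates with centered delta* >= delta.
    """
    if rf_distance(species_topology, alternative_topology) == 0:
        return SHTestResult(family_id, 0.0, 1.0, True, rf_shortcut=True)
    ls, _ = site_loglik(msa_nt, species_topology)
    la, _ = site_loglik(msa_nt, alternative_topology)
    lnl_s, lnl_a = float(ls.sum()), float(la.sum())
    delta = max(lnl_s, lnl_a) - lnl_s
    ncols = len(ls)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(ncols, np.full(ncols, 1.0 / ncols), size=n_rell)
    rs = counts @ ls
    ra = counts @ la
    cs = rs - rs.mean()
    ca = ra - ra.mean()
    deltas = np.maximum(cs, ca) - cs
    p = float(np.mean(deltas >= delta - 1e-12))
    return SHTestResult(family_id, float(delta), p, p >= alpha)


def vertical_screen(family_msas: dict[str, MSA],
                    species_tree: dendropy.Tree, alpha: float = 0.05,
                    n_rell: int = 1000, seed: int = 0,
                    ) -> dict[str, SHTestResult]:
    """Flag families whose phylogeny is consistent with the species tree.

    Gene trees are NJ on Jukes-Cantor ML distances; identical topologies
    (RF = 0) are consistent without testing, otherwise the SH test decides.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, SHTestResult] = {}
    for i, fam in enumerate(sorted(family_msas)):
        msa = family_msas[fam]
        gene_tree = nj_tree(jc_distance_matrix(msa))
        if rf_distance(gene_tree, species_tree) == 0:
            out[fam] = SHTestResult(fam, 0.0, 1.0, True, rf_shortcut=True)
            continue
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        out[fam] = sh_test(msa, species_tree, gene_tree, n_rell=n_rell,
                           seed=sub_seed, alpha=alpha, family_id=fam)
    return out


def species_tree_from_alignment(msa_nt: MSA) -> dendropy.Tree:
    """NJ species tree from the concatenated supermatrix (JC ML distances)."""
    return nj_tree(jc_distance_matrix(msa_nt))
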