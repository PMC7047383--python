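"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (full matrices, explicit
loops, exact rational arithmetic where feasible) and deliberately shares no
code with the package implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np

NEG = float("-inf")


# ---------------------------------------------------------------------------
# Alignment oracles (full-matrix Gotoh, three explicit layers)
# ---------------------------------------------------------------------------

def global_affine_score(a: str, b: str, sub, gap_open: float,
                        gap_ext: float) -> float:
    """Global affine-gap score; a gap of length L costs open + ext * L.

    ``sub(x, y)`` returns the substitution score of characters x, y.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_ext * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + sub(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_ext,
                          X[i - 1][j] - gap_ext)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_ext,
                          Y[i][j - 1] - gap_ext)
    return max(M[n][m], X[n][m], Y[n][m])


def local_affine_score(a: str, b: str, sub, gap_open: float,
                       gap_ext: float) -> float:
    """Smith-Waterman affine-gap score (same gap convention)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_ext,
                          E[i - 1][j] - gap_ext)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_ext,
                          F[i][j - 1] - gap_ext)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def dna_sub(match: float, mismatch: float):
    def sub(x, y):
        return match if x == y and x in "ACGT" else mismatch
    return sub


def blosum62_sub():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        return float(m[x, y])
    return sub


# ---------------------------------------------------------------------------
# Statistics oracles (exact enumeration)
# ---------------------------------------------------------------------------

def fisher_greater_p(f_in: int, f_out: int, b_in: int, b_out: int) -> float:
    """One-sided (greater) Fisher exact p by enumerating all tables with the
    observed margins, exact rational arithmetic."""
    row1 = f_in + f_out
    col1 = f_in + b_in
    total = f_in + f_out + b_in + b_out
    denom = math.comb(total, col1)
    num = 0
    for a in range(max(0, col1 - (total - row1)), min(row1, col1) + 1):
        if a >= f_in:
            num += math.comb(row1, a) * math.comb(total - row1, col1 - a)
    return num / denom


def wilcoxon_two_sided_p(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a, pair counting with 1/2 for ties) and
    the exact double-tail two-sided p by enumerating group assignments."""
    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    pooled = list(sample_a) + list(sample_b)
    n_a, n_b = len(sample_a), len(sample_b)
    u_obs = u_stat(sample_a, sample_b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n_a):
        in_a = set(comb)
        ga = [pooled[i] for i in idx if i in in_a]
        gb = [pooled[i] for i in idx if i not in in_a]
        us.append(u_stat(ga, gb))
    lo = min(u_obs, n_a * n_b - u_obs)
    hi = max(u_obs, n_a * n_b - u_obs)
    count = sum(1 for u in us if u <= lo + 1e-9 or u >= hi - 1e-9)
    return u_obs, min(1.0, count / len(us))


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on midranks, explicit formula) and the exact
    two-sided permutation p over all n! permutations."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    def pearson(u, v):
        n = len(u)
        mu = sum(u) / n
        mv = sum(v) / n
        cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
        su = math.sqrt(sum((a - mu) ** 2 for a in u))
        sv = math.sqrt(sum((b - mv) ** 2 for b in v))
        return cov / (su * sv)

    rx, ry = midranks(list(x)), midranks(list(y))
    rho = pearson(rx, ry)
    n_ge = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            n_ge += 1
    return rho, n_ge / total


# ---------------------------------------------------------------------------
# Additive trees for NJ recovery
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator,
                         min_len: float = 0.05, max_len: float = 1.0):
    """Random unrooted binary topology with positive branch lengths.

    Returns (newick, labels, distance matrix) where the matrix holds exact
    path-length distances (the tree metric is additive by construction).
    """
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    # build by sequential taxon insertion into a growing edge list
    # nodes: 0..n_taxa-1 are leaves; internal nodes numbered upward
    edges: dict[tuple[int, int], float] = {}
    next_node = n_taxa

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    def del_edge(u, v):
        del edges[(min(u, v), max(u, v))]

    def rand_len():
        return float(rng.uniform(min_len, max_len))

    add_edge(0, 1, rand_len())
    for leaf in range(2, n_taxa):
        u, v = list(edges)[int(rng.integers(len(edges)))]
        w = edges[(u, v)]
        mid = next_node
        next_node += 1
        del_edge(u, v)
        split = float(rng.uniform(0.25, 0.75)) * w
        add_edge(u, mid, max(min_len / 4, split))
        add_edge(mid, v, max(min_len / 4, w - split))
        add_edge(mid, leaf, rand_len())

    # all-pairs path lengths by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dists_from(s):
        out = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            d[i, j] = di[j]

    # newick for topology comparison (root arbitrarily at internal node n_taxa)
    def newick(u, parent):
        kids = [(v, w) for v, w in adj[u] if v != parent]
        if not kids:
            return labels[u]
        return "(" + ",".join(f"{newick(v, u)}:{w:.6f}" for v, w in kids) + ")"

    root = n_taxa if n_taxa in adj else 0
    return newick(root, None) + ";", labels, d


# ---------------------------------------------------------------------------
# Tree likelihood by internal-state enumeration
# ---------------------------------------------------------------------------

def enumerate_tree_loglik(tree, tip_codes: dict[str, np.ndarray],
                          q: np.ndarray, freqs: np.ndarray,
                          cat_rates: np.ndarray) -> np.ndarray:
    """Per-column log-likelihood of a rooted dendropy tree by brute-force
    summation over all internal-node state assignments (scipy expm matrices).

    ``tip_codes`` maps taxon label -> int8 codes (negative = missing, which
    contributes likelihood 1 for any state).
    """
    from itertools import product

    from scipy.linalg import expm

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    tips = [nd for nd in tree.preorder_node_iter() if nd.is_leaf()]
    ncols = len(next(iter(tip_codes.values())))
    out = np.zeros(ncols)
    pm_cache = {}
    for rate in cat_rates:
        for nd in internal + tips:
            if nd.parent_node is not None:
                pm_cache[(float(rate), id(nd))] = expm(
                    q * float(rate) * nd.edge.length)
    for col in range(ncols):
        tot = 0.0
        for rate in cat_rates:
            like = 0.0
            for states in product(range(4), repeat=len(internal)):
                st = {id(nd): s for nd, s in zip(internal, states)}
                term = freqs[st[id(tree.seed_node)]]
                for nd in internal:
                    if nd.parent_node is not None:
                        pm = pm_cache[(float(rate), id(nd))]
                        term *= pm[st[id(nd.parent_node)], st[id(nd)]]
                for nd in tips:
                    code = tip_codes[nd.taxon.label][col]
                    pm = pm_cache[(float(rate), id(nd))]
                    if code < 0:
                        term *= 1.0
                    else:
                        term *= pm[st[id(nd.parent_node)], int(code)]
                like += term
            tot += like
        out[col] = math.log(tot / len(cat_rates))
    return out


# ---------------------------------------------------------------------------
# MCL by literal hand iteration (dense matrices)
# ---------------------------------------------------------------------------

def mcl_dense(nodes, edges, inflation: float, max_iter: int = 200,
              tol: float = 1e-6):
    """Dense-matrix MCL: add self loops, column-normalize, square, inflate,
    repeat; clusters = connected components of the limit's support."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for (a, b), w in edges.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    m += np.eye(n)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        nxt = m @ m
        nxt = np.power(nxt, inflation)
        nxt[nxt < 1e-12] = 0.0
        s = nxt.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        nxt = nxt / s
        if np.abs(nxt - m).max() < tol:
            m = nxt
            break
        m = nxt
    support = (m + m.T) > 1e-6
    seen = set()
    clusters = []
    for i in range(n):
        if i in seen:
            continue
        comp = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in range(n):
                if support[u, v] and v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        clusters.append(frozenset(nodes[k] for k in comp))
    return sorted(clusters, key=lambda c: (-len(c), sorted(c)))
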