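"""Pan-genome construction: protein similarity graph, MCL, partitioning.

All CDSs are clustered into homologous families with the Markov Cluster
algorithm (inflation 2.0) on a bit-score-ratio similarity graph
(cutoff 0.4): the weight of an edge between proteins a and b is
``S(a,b) / min(S(a,a), S(b,b))`` where S is the Smith-Waterman score under
BLOSUM62 with affine gaps (open 11, extend 1). A shared-5-mer prefilter
keeps the all-vs-all step near-linear for unrelated proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import align


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if w > 1.0 + 1e-9:
            raise ValueError("edge weights must be <= 1")
        self.edges[(a, b) if a < b else (b, a)] = w


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset[str]
    copy_profile: dict[str, int] = field(default_factory=dict)


@dataclass
class PanGenome:
    families: list[GeneFamily]
    partition: dict[str, str]  # family_id -> core | dispensable | unique
    matrix: pd.DataFrame       # genomes x families, binary presence
    genome_of: dict[str, str]  # cds_id -> genome_id
    core_fraction: dict[str, float] = field(default_factory=dict)
    mcl_converged: bool = True

    def family_of(self) -> dict[str, str]:
        return {cds: f.family_id for f in self.families for cds in f.members}

    def counts(self) -> dict[str, int]:
        c = {"total": len(self.families), "core": 0, "dispensable": 0, "unique": 0}
        for p in self.partition.values():
            c[p] += 1
        return c


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_similarity(cds_proteins: dict[str, str],
                          min_ratio: float = 0.4,
                          min_shared_kmers: int = 2) -> SimilarityGraph:
    """Bit-score-ratio graph over all protein pairs sharing 5-mers.

    Only pairs sharing at least ``min_shared_kmers`` distinct 5-mers are
    aligned (homologs passing the 0.4 bit-score-ratio cutoff share many;
    unrelated proteins rarely share more than one by chance); edges below
    ``min_ratio`` are dropped.
    """
    if not cds_proteins:
        raise ValueError("empty CDS collection")
    nodes = sorted(cds_proteins)
    submat = align.blosum62_matrix()
    self_score = {
        n: float(np.sum(submat[align.encode_protein(cds_proteins[n]),
                               align.encode_protein(cds_proteins[n])]))
        for n in nodes
    }
    # inverted 5-mer index -> shared-k-mer counts per pair
    index: dict[str, list[str]] = {}
    for n in nodes:
        for kmer in _kmer_set(cds_proteins[n]):
            index.setdefault(kmer, []).append(n)
    shared: dict[tuple[str, str], int] = {}
    for members in index.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                pair = (a, b) if a < b else (b, a)
                shared[pair] = shared.get(pair, 0) + 1
    candidates = {p for p, c in shared.items() if c >= min_shared_kmers}

    graph = SimilarityGraph(nodes)
    for a, b in sorted(candidates):
        s = align.local_protein_score(cds_proteins[a], cds_proteins[b], submat)
        ratio = s / min(self_score[a], self_score[b])
        if ratio >= min_ratio:
            graph.add_edge(a, b, min(1.0, ratio))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(graph: SimilarityGraph, inflation: float = 2.0,
                max_iter: int = 200, tol: float = 1e-6,
                ) -> tuple[list[frozenset[str]], bool]:
    """Markov Cluster algorithm on the similarity graph.

    Self-loops of weight 1 are added before iteration (standard
    regularization, guarantees convergence on isolated nodes). Expansion is
    matrix squaring; inflation is an elementwise power followed by column
    renormalization. Clusters are the connected components of the limit
    matrix's nonzero structure. Returns (clusters, converged).
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("graph must contain at least one node")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for (a, b), w in graph.edges.items():
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
        vals += [w, w]
    rows += list(range(n))
    cols += list(range(n))
    vals += [1.0] * n
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    m = _normalize_columns(m)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, inflation)
        inflated.data[inflated.data < 1e-12] = 0.0
        inflated.eliminate_zeros()
        inflated = _normalize_columns(inflated)
        diff = abs(inflated - m).max()
        m = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning the "
                      "current clustering", RuntimeWarning)

    structure = m + m.T
    structure.data[structure.data < 1e-6] = 0.0
    structure.eliminate_zeros()
    n_comp, labels = sp.csgraph.connected_components(structure, directed=False)
    clusters: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    ordered = sorted((frozenset(c) for c in clusters.values()),
                     key=lambda c: (-len(c), sorted(c)))
    return ordered, converged


def _normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
    colsum = np.asarray(m.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0
    return (m @ sp.diags(1.0 / colsum)).tocsr()


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def build_families(clusters: list[frozenset[str]],
                   genome_of: dict[str, str]) -> list[GeneFamily]:
    fams = []
    for i, members in enumerate(clusters):
        profile: dict[str, int] = {}
        for cds in members:
            g = genome_of[cds]
            profile[g] = profile.get(g, 0) + 1
        fams.append(GeneFamily(f"FAM{i + 1:05d}", members, profile))
    return fams


def partition_pangenome(families: list[GeneFamily], genome_ids: list[str],
                        genome_of: dict[str, str]) -> PanGenome:
    """Partition families into core / dispensable / unique.

    Core families occur in every genome, unique families in exactly one;
    everything else is dispensable. The presence/absence matrix is binary
    (>= 1 copy counts as present).
    """
    genome_ids = sorted(genome_ids)
    partition = {}
    data = np.zeros((len(genome_ids), len(families)), dtype=np.int8)
    gi = {g: i for i, g in enumerate(genome_ids)}
    for j, fam in enumerate(families):
        present = set(fam.copy_profile)
        unknown = present - set(genome_ids)
        if unknown:
            raise ValueError(f"family {fam.family_id} has members from unknown "
                             f"genomes {sorted(unknown)}")
        for g in present:
            data[gi[g], j] = 1
        if len(present) == len(genome_ids):
            partition[fam.family_id] = "core"
        elif len(present) == 1:
            partition[fam.family_id] = "unique"
        else:
            partition[fam.family_id] = "dispensable"
    matrix = pd.DataFrame(data, index=genome_ids,
                          columns=[f.family_id for f in families])
    n_core = sum(1 for v in partition.values() if v == "core")
    core_fraction = {
        g: n_core / max(1, int(matrix.loc[g].sum())) for g in genome_ids
    }
    return PanGenome(families, partition, matrix, dict(genome_of), core_fraction)


def pangenome_from_proteins(cds_proteins: dict[str, str],
                            genome_of: dict[str, str],
                            inflation: float = 2.0,
                            min_ratio: float = 0.4) -> PanGenome:
    """Similarity graph -> MCL -> partition, in one call."""
    graph = all_vs_all_similarity(cds_proteins, min_ratio=min_ratio)
    clusters, converged = mcl_cluster(graph, inflation=inflation)
    families = build_families(clusters, genome_of)
    pg = partition_pangenome(families, sorted(set(genome_of.values())),
                             genome_of)
    pg.mcl_converged = converged
    return pg


def single_copy_core(pangenome: PanGenome) -> list[str]:
    """Core families with exactly one copy in every genome."""
    n_genomes = pangenome.matrix.shape[0]
    out = []
    for fam in pangenome.families:
        if pangenome.partition[fam.family_id] != "core":
            continue
        if len(fam.copy_profile) == n_genomes and \
                all(c == 1 for c in fam.copy_profile.values()):
            out.append(fam.family_id)
    return out


# ---------------------------------------------------------------------------
# Presence/absence clustering
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between genome family repertoires."""
    genomes = sorted(matrix.index)
    m = matrix.loc[genomes].to_numpy(dtype=bool)
    inter = (m.astype(int) @ m.astype(int).T).astype(float)
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=genomes, columns=genomes)


def cluster_presence_absence(matrix: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Average-linkage clustering of genomes on Jaccard distance.

    Genomes are sorted lexicographically before linkage so equal-distance
    merges resolve deterministically. Returns (newick, matrix with rows in
    dendrogram leaf order).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two genomes")
    dist = jaccard_distance_matrix(matrix)
    genomes = list(dist.index)
    link = hierarchy.linkage(squareform(dist.to_numpy(), checks=False),
                             method="average")
    tree = hierarchy.to_tree(link)
    newick = _scipy_tree_to_newick(tree, genomes) + ";"
    order = [genomes[i] for i in hierarchy.leaves_list(link)]
    return newick, matrix.loc[order]


def _scipy_tree_to_newick(node, labels, parent_height: float | None = None) -> str:
    height = node.dist
    length = "" if parent_height is None else f":{max(0.0, parent_height - height):.6g}"
    if node.is_leaf():
        return f"{labels[node.id]}{length}"
    left = _scipy_tree_to_newick(node.left, labels, height)
    right = _scipy_tree_to_newick(node.right, labels, height)
    return f"({left},{right}){length}"
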