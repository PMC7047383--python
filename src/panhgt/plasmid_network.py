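"""Bipartite gene-family/plasmid network analysis.

Plasmid proteomes are clustered into families by a greedy representative
scheme (> 40% global-alignment identity over >= 80% of the shorter protein),
a bipartite graph connects plasmids to the families they carry, plasmids are
hierarchically clustered on Jaccard distance between family repertoires
(default cut 0.15, i.e. 85% similarity), and COG-category enrichment of a
focal gene set is tested with one-sided Fisher's exact tests (raw p-values,
no multiplicity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from . import align

logger = logging.getLogger(__name__)


@dataclass
class BipartiteNetwork:
    graph: nx.Graph
    plasmids: list[str]
    families: list[str]
    shared_families: set[str]  # present on >= 2 plasmids

    def plasmid_families(self, plasmid: str) -> set[str]:
        return set(self.graph.neighbors(plasmid))

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass
class PlasmidClustering:
    labels: dict[str, str]
    linkage: np.ndarray | None = None

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, lab in self.labels.items():
            out.setdefault(lab, set()).add(p)
        return out


# ---------------------------------------------------------------------------
# Protein clustering
# ---------------------------------------------------------------------------

def greedy_protein_cluster(proteins: dict[str, str],
                           min_similarity: float = 0.40,
                           min_coverage: float = 0.80) -> dict[str, set[str]]:
    """Greedy incremental clustering by decreasing length.

    Each protein joins the first existing cluster whose representative it
    matches at > ``min_similarity`` identity over >= ``min_coverage`` of the
    shorter sequence (global alignment, BLOSUM62 10/0.5), else founds a new
    cluster. Input order does not matter: proteins are canonically sorted.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    reps: list[tuple[str, str]] = []  # (family_id, representative sequence)
    members: dict[str, set[str]] = {}
    submat = align.blosum62_matrix()
    for pid in order:
        seq = proteins[pid]
        placed = False
        for fam_id, rep_seq in reps:
            shorter = min(len(seq), len(rep_seq))
            n_id, n_pairs, _ = align.global_protein_alignment_stats(
                seq, rep_seq, submat)
            if n_pairs >= min_coverage * shorter and n_pairs > 0 and \
                    n_id / n_pairs > min_similarity:
                members[fam_id].add(pid)
                placed = True
                break
        if not placed:
            fam_id = f"PF{len(reps) + 1:05d}"
            reps.append((fam_id, seq))
            members[fam_id] = {pid}
    return members


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def build_bipartite(plasmid_families: dict[str, set[str]]) -> BipartiteNetwork:
    """Plasmid and gene-family nodes; one edge per (plasmid, family) pair."""
    g = nx.Graph()
    plasmids = sorted(plasmid_families)
    fam_count: dict[str, int] = {}
    for p in plasmids:
        for f in plasmid_families[p]:
            fam_count[f] = fam_count.get(f, 0) + 1
    families = sorted(fam_count)
    shared = {f for f, c in fam_count.items() if c >= 2}
    for p in plasmids:
        g.add_node(p, partition="plasmid")
    for f in families:
        g.add_node(f, partition="family", shared=f in shared)
    for p in plasmids:
        for f in sorted(plasmid_families[p]):
            g.add_edge(p, f)
    return BipartiteNetwork(g, plasmids, families, shared)


def bipartite_from_proteomes(proteomes: dict[str, dict[str, str]],
                             min_similarity: float = 0.40,
                             ) -> tuple[BipartiteNetwork, dict[str, set[str]]]:
    """Cluster all plasmid proteins together, then build the network."""
    all_proteins = {f"{p}::{pid}": seq
                    for p, prots in proteomes.items()
                    for pid, seq in prots.items()}
    fams = greedy_protein_cluster(all_proteins, min_similarity=min_similarity)
    plasmid_families: dict[str, set[str]] = {p: set() for p in proteomes}
    for fam, mem in fams.items():
        for tag in mem:
            plasmid_families[tag.split("::", 1)[0]].add(fam)
    return build_bipartite(plasmid_families), fams


def cluster_plasmids(network: BipartiteNetwork,
                     cut: float = 0.15) -> PlasmidClustering:
    """Average-linkage clustering of plasmids on Jaccard distance, cut at
    the configured height (0.15 = 85% repertoire similarity)."""
    plasmids = network.plasmids
    if len(plasmids) < 2:
        raise ValueError("need at least two plasmids")
    sets = {p: network.plasmid_families(p) for p in plasmids}
    n = len(plasmids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[plasmids[i]], sets[plasmids[j]]
            union = len(a | b)
            dist = 1.0 - (len(a & b) / union if union else 1.0)
            d[i, j] = d[j, i] = dist
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for p, lab in zip(plasmids, raw):
        groups.setdefault(int(lab), []).append(p)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), sorted(ms)))
    labels = {p: f"PC{k + 1}" for k, ms in enumerate(ordered) for p in ms}
    return PlasmidClustering(labels, link)


# ---------------------------------------------------------------------------
# COG enrichment
# ---------------------------------------------------------------------------

def cog_enrichment(focus_genes: set[str], background_genes: set[str],
                   categories: dict[str, str | None],
                   alpha: float = 0.01) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment per COG category.

    Genes without a category are excluded from both sets; the background is
    treated as a disjoint comparison set. Raw p-values are reported (no
    multiple-testing correction), mirroring common practice in descriptive
    pan-genome papers; the column name makes this explicit.
    """
    if not focus_genes:
        raise ValueError("empty focus set")
    focus = {g for g in focus_genes if categories.get(g)}
    background = {g for g in background_genes if categories.get(g)} - focus
    cats = sorted({categories[g] for g in focus | background})
    rows = []
    for cat in cats:
        f_in = sum(1 for g in focus if categories[g] == cat)
        f_out = len(focus) - f_in
        b_in = sum(1 for g in background if categories[g] == cat)
        b_out = len(background) - b_in
        _, p = fisher_exact([[f_in, f_out], [b_in, b_out]],
                            alternative="greater")
        rows.append({"category": cat, "focus_in": f_in, "focus_out": f_out,
                     "background_in": b_in, "background_out": b_out,
                     "raw_p": float(p), "enriched": bool(p < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_gexf(network: BipartiteNetwork,
                clustering: PlasmidClustering | None, path) -> None:
    """GEXF export with partition/shared/cluster/degree attributes and node
    size proportional to degree."""
    g = network.graph.copy()
    for node in g.nodes:
        deg = g.degree(node)
        g.nodes[node]["degree"] = int(deg)
        g.nodes[node]["viz"] = {"size": float(max(1, deg))}
        if clustering and node in clustering.labels:
            g.nodes[node]["cluster"] = clustering.labels[node]
        if "shared" in g.nodes[node]:
            g.nodes[node]["shared"] = bool(g.nodes[node]["shared"])
    nx.write_gexf(g, path)
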