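"""Symbiosis-gene extraction, per-gene bootstrap trees, host concordance.

The 12 marker genes (nodABC, fixABC, nifHDKENB) determine symbiotic host
specificity in rhizobia and travel on symbiosis plasmids; their gene trees
typically track the host of origin rather than the species tree. This module
extracts the markers by annotated gene name, builds NJ trees with bootstrap
supports from the codon alignment, and quantifies how strongly tree
structure follows host labels (per-host monophyly plus the ratio of mean
within-host to mean between-host patristic distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np

from .genome_io import SYMBIOSIS_GENES, CDSFeature, GenomeRecord
from .phylo import MSA, align_family, backtranslate, jc_distance_matrix, nj_tree

logger = logging.getLogger(__name__)


@dataclass
class SymbiosisGeneSet:
    genes: dict[str, dict[str, str]]            # genome -> gene name -> cds_id
    features: dict[str, dict[str, CDSFeature]]  # genome -> gene name -> feature
    complete: dict[str, bool] = field(default_factory=dict)

    def genomes_with(self, gene_name: str) -> list[str]:
        return sorted(g for g, d in self.genes.items() if gene_name in d)


def extract_symbiosis_genes(genomes: list[GenomeRecord],
                            gene_names: tuple[str, ...] = SYMBIOSIS_GENES,
                            ) -> SymbiosisGeneSet:
    """Name-based lookup of the 12 symbiosis genes per genome.

    Duplicated names keep the longer CDS (warning logged); genomes missing
    any of the 12 are flagged incomplete but contribute the genes they have.
    """
    genes: dict[str, dict[str, str]] = {}
    feats: dict[str, dict[str, CDSFeature]] = {}
    complete: dict[str, bool] = {}
    for g in genomes:
        found: dict[str, CDSFeature] = {}
        for c in g.cds:
            if c.gene_name in gene_names:
                prev = found.get(c.gene_name)
                if prev is not None:
                    logger.warning("duplicate %s in %s; keeping the longer CDS",
                                   c.gene_name, g.genome_id)
                    if len(c.nt_seq) <= len(prev.nt_seq):
                        continue
                found[c.gene_name] = c
        genes[g.genome_id] = {name: f.cds_id for name, f in found.items()}
        feats[g.genome_id] = found
        complete[g.genome_id] = set(found) == set(gene_names)
        if not complete[g.genome_id]:
            missing = sorted(set(gene_names) - set(found))
            logger.warning("symbiosis gene extraction incomplete for %s "
                           "(missing %s)", g.genome_id, ",".join(missing))
    return SymbiosisGeneSet(genes, feats, complete)


# ---------------------------------------------------------------------------
# Per-gene bootstrap trees
# ---------------------------------------------------------------------------

def _codon_alignment(gene_name: str, gene_set: SymbiosisGeneSet) -> MSA:
    genomes = gene_set.genomes_with(gene_name)
    aa = {g: gene_set.features[g][gene_name].aa_seq for g in genomes}
    nt = {g: gene_set.features[g][gene_name].nt_seq for g in genomes}
    return backtranslate(align_family(aa), nt)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits as the smaller (tie: lexicographic) side."""
    taxa = {t.label for t in tree.taxon_namespace}
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        other = taxa - below
        if not other or not below:
            continue
        if len(below) < 2 or len(other) < 2:
            continue
        side = min((frozenset(below), frozenset(other)),
                   key=lambda s: (len(s), sorted(s)))
        out.add(side)
    return out


def symbiosis_gene_tree(gene_name: str, gene_set: SymbiosisGeneSet,
                        n_boot: int = 1000, seed: int = 0) -> dendropy.Tree:
    """NJ tree on JC distances from the codon alignment with bootstrap
    supports (% of codon-column resampling replicates containing each split,
    stored as internal node labels)."""
    genomes = gene_set.genomes_with(gene_name)
    if len(genomes) < 4:
        raise ValueError(f"{gene_name} present in only {len(genomes)} genomes; "
                         "need at least 4")
    msa = _codon_alignment(gene_name, gene_set)
    tree = nj_tree(jc_distance_matrix(msa))
    n_codons = msa.n_cols // 3
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree)}
    for _ in range(n_boot):
        cols = rng.integers(0, n_codons, size=n_codons)
        rows = ["".join(row[3 * c:3 * c + 3] for c in cols) for row in msa.rows]
        btree = nj_tree(jc_distance_matrix(MSA(list(msa.ids), rows, "nt")))
        bsplits = _bipartitions(btree)
        for bp in counts:
            if bp in bsplits:
                counts[bp] += 1
    taxa = {t.label for t in tree.taxon_namespace}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = min((below, frozenset(taxa - below)),
                   key=lambda s: (len(s), sorted(s)))
        if side in counts:
            node.label = str(round(counts[side] / n_boot * 100))
    return tree


# ---------------------------------------------------------------------------
# Host concordance
# ---------------------------------------------------------------------------

@dataclass
class HostConcordance:
    monophyletic: dict[str, bool]
    within_between_ratio: float  # nan when undefined (single host)
    defined: bool = True


def host_concordance(tree: dendropy.Tree,
                     host_labels: dict[str, str]) -> HostConcordance:
    """Monophyly per host label plus within/between patristic distance ratio."""
    tips = {t.label for t in tree.taxon_namespace}
    hosts = {g: h for g, h in host_labels.items() if g in tips}
    if len(set(hosts.values())) < 2:
        return HostConcordance({h: True for h in set(hosts.values())},
                               float("nan"), defined=False)
    splits = _bipartitions(tree)
    mono = {}
    for host in sorted(set(hosts.values())):
        members = frozenset(g for g, h in hosts.items() if h == host)
        if len(members) == 1:
            mono[host] = True
        elif len(members) == len(tips):
            mono[host] = True
        else:
            side = min((members, frozenset(tips - members)),
                       key=lambda s: (len(s), sorted(s)))
            mono[host] = side in splits
    pdm = tree.phylogenetic_distance_matrix()
    taxon_of = {t.label: t for t in tree.taxon_namespace}
    within, between = [], []
    for a, b in combinations(sorted(hosts), 2):
        d = pdm.patristic_distance(taxon_of[a], taxon_of[b])
        (within if hosts[a] == hosts[b] else between).append(d)
    if not within or not between or np.mean(between) == 0:
        return HostConcordance(mono, float("nan"), defined=False)
    return HostConcordance(mono, float(np.mean(within) / np.mean(between)))
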