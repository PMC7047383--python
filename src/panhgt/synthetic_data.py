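"""Synthetic rhizobial genome collections with planted ground truth.

The generator emulates the structure the downstream inference expects to
resolve: several species clusters separated by > 5% nucleotide divergence
with < 1% divergence within species, a chromosome + plasmid replicon
architecture including one symbiosis plasmid carrying a contiguous 12-gene
symbiosis cluster (nodABC, fixABC, nifHDKENB), per-family gene gain/loss
producing core/dispensable/unique pan-genome structure, and optional planted
recent-HGT events producing near-identical homologs between otherwise
divergent species.

Sequences evolve along a pure-birth species tree under an HKY model
(kappa = 2, uniform base frequencies) with per-site substitution probability
equal to the branch length; no indels are simulated so alignment identity
maps directly onto divergence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .genome_io import (
    SYMBIOSIS_GENES,
    CDSFeature,
    GenomeRecord,
    Replicon,
    RepliconKind,
    TruthTables,
)

_BASES = "ACGT"
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)  # A<->G, C<->T
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


@dataclass(frozen=True)
class HGTPlanEntry:
    """One planned recent-transfer event between two species."""

    donor_species: str
    recipient_species: str
    n_genes: int
    residual_divergence: float = 0.005

    def __post_init__(self):
        if self.donor_species == self.recipient_species:
            raise ValueError("donor and recipient species must differ")
        if not 0 <= self.residual_divergence <= 0.015:
            raise ValueError("residual divergence must lie in [0, 0.015] so that "
                             "planted transfers exceed the 98.5% similarity threshold")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 6
    genomes_per_species: int = 2
    core_families: int = 80
    accessory_families: int = 60
    family_gain_loss_rate: float = 0.1
    mean_gene_len_codons: int = 150
    # Mean neutral intergenic DNA per gene slot. Keeps any planted HGT a
    # small fraction of total genome length (as in real rhizobia, where
    # transferred genes are a few percent of a multi-megabase genome), so
    # whole-genome ANI between donor and recipient species stays below the
    # species threshold even after planting.
    intergenic_bp: int = 600
    between_species_divergence: float = 0.08
    within_species_divergence: float = 0.01
    hgt_plan: tuple[HGTPlanEntry, ...] = ()
    plasmids_per_genome: int = 2
    plasmid_groups: int = 2
    hgt_to_symbiosis_plasmid_prob: float = 0.8
    symbiosis_genes: tuple[str, ...] = SYMBIOSIS_GENES
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.within_species_divergence < self.between_species_divergence:
            raise ValueError("require 0 <= within < between species divergence")
        if self.core_families < len(self.symbiosis_genes):
            raise ValueError("core_families must cover the 12 symbiosis genes")

    @property
    def species_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_species)]


@dataclass
class SyntheticCollection:
    genomes: list[GenomeRecord]
    truth: TruthTables
    config: SimulationConfig
    hgt_families: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    # genome_id -> replicon slot ("chr", "pSym", "p1", ...) -> neutral
    # intergenic backbone sequence, distributed between genes at assembly
    backbones: dict[str, dict[str, str]] = field(default_factory=dict)

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


# ---------------------------------------------------------------------------
# Species / genome trees
# ---------------------------------------------------------------------------

def simulate_species_tree(n_species: int, seed: int,
                          between_divergence: float = 0.08) -> dendropy.Tree:
    """Rooted pure-birth species tree with guaranteed species separation.

    Branch lengths are scaled so the pure-birth part contributes half of
    ``between_divergence`` to the mean root-to-tip path and every species
    then receives a terminal stem of ``between_divergence / 2``; every
    between-species path is therefore at least ``between_divergence`` while
    the mean root-to-tip depth stays at approximately that value.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=random.Random(seed))
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    mean_depth = float(np.mean(depths)) or 1.0
    half = between_divergence / 2.0
    scale = half / mean_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + half
    # deterministic species labels, ordered by the tree's own leaf order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1}"
    return tree


def genome_tree_from_species_tree(species_tree: dendropy.Tree,
                                  genomes_per_species: int,
                                  within_divergence: float) -> dendropy.Tree:
    """Expand each species tip into its sampled genomes.

    Each genome hangs off its species node by a terminal "population" branch
    of ``within_divergence / 2`` so within-species pairs diverge by
    ``within_divergence``.
    """
    tree = species_tree.clone(depth=1)
    tns = dendropy.TaxonNamespace()
    for leaf in list(tree.leaf_node_iter()):
        species = leaf.taxon.label
        leaf.taxon = None
        for k in range(genomes_per_species):
            child = leaf.new_child(edge_length=within_divergence / 2.0)
            child.taxon = tns.new_taxon(label=f"{species}_{k + 1}")
    tree.taxon_namespace = tns
    return tree


def genome_species_map(config: SimulationConfig) -> dict[str, str]:
    return {f"{sp}_{k + 1}": sp
            for sp in config.species_labels
            for k in range(config.genomes_per_species)}


# ---------------------------------------------------------------------------
# Pan-genome structure
# ---------------------------------------------------------------------------

def simulate_pangenome(genome_tree: dendropy.Tree, config: SimulationConfig,
                       seed: int) -> dict[str, set[str]]:
    """Family -> set of genome ids.

    Core families are present everywhere. Each accessory family is gained on
    a uniformly chosen branch and lost independently on each branch below the
    gain with probability ``family_gain_loss_rate`` (a loss removes the whole
    subtree). Families absent from every genome are dropped.
    """
    rng = np.random.default_rng(seed)
    genome_ids = sorted(t.label for t in genome_tree.taxon_namespace)
    presence: dict[str, set[str]] = {}
    for i in range(config.core_families):
        presence[_core_family_id(i, config)] = set(genome_ids)

    edges = [e for e in genome_tree.preorder_edge_iter() if e.head_node.parent_node]
    for j in range(config.accessory_families):
        gain_edge = edges[int(rng.integers(len(edges)))]
        members: set[str] = set()

        def walk(node, alive: bool):
            if node.is_leaf():
                if alive:
                    members.add(node.taxon.label)
                return
            for child in node.child_nodes():
                lost = alive and rng.random() < config.family_gain_loss_rate
                walk(child, alive and not lost)

        head = gain_edge.head_node
        if head.is_leaf():
            members.add(head.taxon.label)
        else:
            walk(head, True)
        if members:
            presence[f"A{j + 1:04d}"] = members
    return presence


def _core_family_id(i: int, config: SimulationConfig) -> str:
    if i < len(config.symbiosis_genes):
        return config.symbiosis_genes[i]
    return f"C{i + 1:04d}"


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _random_root_gene(rng: np.random.Generator, mean_codons: int) -> np.ndarray:
    n_codons = max(30, int(rng.poisson(mean_codons)))
    out = np.empty(3 * n_codons, dtype=np.int8)
    for c in range(n_codons):
        while True:
            codon = rng.integers(0, 4, size=3)
            if (codon[0], codon[1], codon[2]) not in _STOPS:
                break
        out[3 * c:3 * c + 3] = codon
    return out


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator,
            kappa: float = 2.0, coding: bool = True) -> np.ndarray:
    """One branch of HKY evolution: per-site substitution probability p.

    ``coding=False`` skips the stop-codon reversion (neutral intergenic DNA).
    """
    out = seq.copy()
    if p <= 0:
        return out
    hits = np.nonzero(rng.random(len(seq)) < min(p, 0.75))[0]
    if len(hits) == 0:
        return out
    u = rng.random(len(hits))
    p_ts = kappa / (kappa + 2.0)
    for idx, site in enumerate(hits):
        base = out[site]
        if u[idx] < p_ts:
            out[site] = _TRANSITION[base]
        else:
            # one of the two transversion partners, equally likely
            tv = [b for b in range(4) if b != base and b != _TRANSITION[base]]
            out[site] = tv[0] if u[idx] < p_ts + (1 - p_ts) / 2 else tv[1]
    if coding:
        # revert substitutions that created an in-frame stop codon
        for c in np.unique(hits // 3):
            codon = (out[3 * c], out[3 * c + 1], out[3 * c + 2])
            if codon in _STOPS:
                out[3 * c:3 * c + 3] = seq[3 * c:3 * c + 3]
    return out


def evolve_sequences(genome_tree: dendropy.Tree, families: dict[str, set[str]],
                     config: SimulationConfig, seed: int,
                     ) -> dict[str, dict[str, str]]:
    """family -> genome -> nucleotide sequence (stop-free ORFs, no indels)."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for fam in sorted(families):
        root = _random_root_gene(rng, config.mean_gene_len_codons)
        tip_seqs: dict[str, np.ndarray] = {}

        def walk(node, seq):
            for child in node.child_nodes():
                cseq = _mutate(seq, child.edge.length or 0.0, rng)
                if child.is_leaf():
                    tip_seqs[child.taxon.label] = cseq
                else:
                    walk(child, cseq)

        walk(genome_tree.seed_node, root)
        members = families[fam]
        out[fam] = {g: _decode(tip_seqs[g]) for g in sorted(members)}
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _backbone_lengths(config: SimulationConfig) -> dict[str, int]:
    """Neutral intergenic backbone length per replicon slot.

    Sized to ``intergenic_bp`` per expected gene on the slot (plasmid slots
    use their fixed template size; the chromosome uses its core complement
    plus half the accessory families as the expected accessory load).
    """
    templates = _plasmid_templates(config) if config.plasmids_per_genome > 0 else {0: {}}
    t0 = templates[0]
    on_plasmids = sum(len(v) for v in t0.values())
    chr_genes = max(1, config.core_families - on_plasmids
                    + config.accessory_families // 2)
    lengths = {"chr": config.intergenic_bp * chr_genes}
    for slot, fams in t0.items():
        lengths[slot] = config.intergenic_bp * max(1, len(fams))
    return lengths


def evolve_backbones(genome_tree: dendropy.Tree, config: SimulationConfig,
                     seed: int) -> dict[str, dict[str, str]]:
    """genome -> slot -> neutral intergenic sequence, evolved on the tree."""
    rng = np.random.default_rng(seed)
    lengths = _backbone_lengths(config)
    out: dict[str, dict[str, str]] = {}
    for slot in sorted(lengths):
        root = rng.integers(0, 4, size=lengths[slot]).astype(np.int8)
        tip_seqs: dict[str, np.ndarray] = {}

        def walk(node, seq):
            for child in node.child_nodes():
                cseq = _mutate(seq, child.edge.length or 0.0, rng, coding=False)
                if child.is_leaf():
                    tip_seqs[child.taxon.label] = cseq
                else:
                    walk(child, cseq)

        walk(genome_tree.seed_node, root)
        for gid, codes in tip_seqs.items():
            out.setdefault(gid, {})[slot] = _decode(codes)
    return out


# ---------------------------------------------------------------------------
# Replicon assignment & genome assembly
# ---------------------------------------------------------------------------

def _plasmid_templates(config: SimulationConfig) -> dict[int, dict[str, list[str]]]:
    """Per plasmid group: replicon slot -> ordered family template.

    Templates draw on core families only, so every plasmid built from the
    same template has identical gene content and planted plasmid clusters
    are unambiguous; variable (accessory) content lives on the chromosome.
    """
    sym = list(config.symbiosis_genes)
    other_core = [_core_family_id(i, config)
                  for i in range(len(sym), config.core_families)]
    templates: dict[int, dict[str, list[str]]] = {}
    n_groups = max(1, config.plasmid_groups)
    per_group = 8
    for g in range(n_groups):
        t: dict[str, list[str]] = {}
        if config.plasmids_per_genome >= 1:
            extra = other_core[g * per_group:(g + 1) * per_group]
            t["pSym"] = sym + extra
        if config.plasmids_per_genome >= 2:
            start = n_groups * per_group + g * per_group
            acc_fams = other_core[start:start + per_group]
            n_acc = config.plasmids_per_genome - 1
            for k in range(n_acc):
                t[f"p{k + 1}"] = acc_fams[k::n_acc]
        templates[g] = t
    return templates


def assign_replicons(collection: SyntheticCollection,
                     config: SimulationConfig | None = None) -> SyntheticCollection:
    """Distribute each genome's CDSs over chromosome + plasmids.

    The 12 symbiosis genes occupy contiguous slots at the start of the
    symbiosis plasmid; template families follow; everything else goes to the
    chromosome. Species in the same plasmid group share templates and hence
    a planted plasmid-cluster label.
    """
    config = config or collection.config
    templates = _plasmid_templates(config)
    species_of = collection.truth.species_of_genome
    species_order = config.species_labels
    new_genomes = []
    truth = collection.truth
    truth.plasmid_clusters = {}
    for genome in collection.genomes:
        sp = species_of[genome.genome_id]
        group = species_order.index(sp) % max(1, config.plasmid_groups)
        template = templates[group]
        fam_to_slot: dict[str, str] = {}
        for slot, fams in template.items():
            for f in fams:
                fam_to_slot[f] = slot
        slot_cds: dict[str, list[CDSFeature]] = {"chr": []}
        for slot in template:
            slot_cds[slot] = []
        for c in genome.cds:
            fam = truth.family_of_cds[c.cds_id]
            slot_cds.setdefault(fam_to_slot.get(fam, "chr"), []).append(c)
        # order: symbiosis genes contiguous and in canonical order, then by family
        sym_rank = {g: i for i, g in enumerate(config.symbiosis_genes)}

        def order_key(c: CDSFeature):
            fam = truth.family_of_cds[c.cds_id]
            return (0, sym_rank[fam]) if fam in sym_rank else (1, fam)

        assignments = []
        for slot in ["chr"] + sorted(s for s in slot_cds if s != "chr"):
            kind = (RepliconKind.CHROMOSOME if slot == "chr"
                    else RepliconKind.SYMBIOSIS_PLASMID if slot == "pSym"
                    else RepliconKind.PLASMID)
            cds = sorted(slot_cds[slot], key=order_key)
            assignments.append((f"{genome.genome_id}_{slot}", kind, cds))
        new_genomes.append(_build_genome(
            genome.genome_id, assignments, genome.metadata,
            collection.backbones.get(genome.genome_id)))
        for slot in template:
            rid = f"{genome.genome_id}_{slot}"
            truth.plasmid_clusters[(genome.genome_id, rid)] = f"{slot}_group{group}"
    return SyntheticCollection(new_genomes, truth, config,
                               collection.hgt_families, collection.backbones)


def _build_genome(genome_id: str, assignments, metadata,
                  backbones: dict[str, str] | None = None) -> GenomeRecord:
    """Lay CDSs on each replicon with the slot's intergenic backbone split
    evenly between genes, and recompute coordinates."""
    from Bio.Seq import Seq

    backbones = backbones or {}
    replicons = []
    all_cds = []
    for rid, kind, cds_list in assignments:
        slot = rid[len(genome_id) + 1:]
        backbone = backbones.get(slot, "")
        n = len(cds_list)
        chunk = len(backbone) // (n + 1) if n else 0
        pos = 0
        parts = []
        used = 0
        for c in cds_list:
            spacer = backbone[used:used + chunk]
            used += chunk
            parts.append(spacer)
            pos += len(spacer)
            genomic = c.nt_seq if c.strand == "+" else str(
                Seq(c.nt_seq).reverse_complement())
            parts.append(genomic)
            all_cds.append(replace(c, replicon_id=rid, start=pos,
                                   end=pos + len(c.nt_seq)))
            pos += len(c.nt_seq)
        parts.append(backbone[used:])
        replicons.append(Replicon(rid, kind, "".join(parts)))
    return GenomeRecord(genome_id, replicons, all_cds, dict(metadata))


# ---------------------------------------------------------------------------
# HGT planting
# ---------------------------------------------------------------------------

def plant_hgt(collection: SyntheticCollection,
              hgt_plan: tuple[HGTPlanEntry, ...] | list[HGTPlanEntry],
              seed: int) -> SyntheticCollection:
    """Replace recipient gene copies with near-identical donor copies.

    For each planned event, ``n_genes`` families shared (single-copy) by
    every donor and every recipient genome are chosen; every recipient
    genome's copy is overwritten by the first donor genome's sequence mutated
    at the plan's residual divergence, and the gene relocates to the
    recipient's symbiosis plasmid with probability
    ``hgt_to_symbiosis_plasmid_prob`` (else chromosome). The other donor
    genomes' copies are harmonized to the transferred sequence, so the
    donor-to-recipient divergence at the planted loci equals the residual
    regardless of which donor genome is later chosen as the species
    representative (a recent transfer is close to the whole donor
    population). Truth records the replaced CDS ids of the first recipient
    genome.
    """
    rng = np.random.default_rng(seed)
    config = collection.config
    truth = collection.truth
    species_of = truth.species_of_genome
    fam_of = truth.family_of_cds
    genomes = {g.genome_id: g for g in collection.genomes}
    # family -> genome -> CDSFeature
    fam_members: dict[str, dict[str, list[CDSFeature]]] = {}
    for g in collection.genomes:
        for c in g.cds:
            fam_members.setdefault(fam_of[c.cds_id], {}).setdefault(
                g.genome_id, []).append(c)

    moved: dict[str, dict[str, str]] = {}  # genome -> cds_id -> new slot
    new_seq: dict[str, str] = {}
    for plan in hgt_plan:
        donor_gs = sorted(g for g, s in species_of.items()
                          if s == plan.donor_species)
        recip_gs = sorted(g for g, s in species_of.items()
                          if s == plan.recipient_species)
        if not donor_gs or not recip_gs:
            raise ValueError(f"unknown species in plan {plan}")
        donor = donor_gs[0]
        candidates = sorted(
            fam for fam, members in fam_members.items()
            if fam not in config.symbiosis_genes
            and all(len(members.get(d, [])) == 1 for d in donor_gs)
            and all(len(members.get(r, [])) == 1 for r in recip_gs))
        if len(candidates) < plan.n_genes:
            raise ValueError(
                f"plan {plan.donor_species}->{plan.recipient_species} needs "
                f"{plan.n_genes} shared single-copy families but only "
                f"{len(candidates)} are available (deficit "
                f"{plan.n_genes - len(candidates)})")
        chosen = list(rng.choice(candidates, size=plan.n_genes, replace=False))
        pair = tuple(sorted((plan.donor_species, plan.recipient_species)))
        truth.hgt_genes.setdefault(pair, [])
        collection.hgt_families.setdefault(pair, []).extend(chosen)
        for fam in chosen:
            donor_nt = fam_members[fam][donor][0].nt_seq
            donor_codes = np.array([_BASES.index(b) for b in donor_nt],
                                   dtype=np.int8)
            to_sym = rng.random() < config.hgt_to_symbiosis_plasmid_prob
            for dg in donor_gs[1:]:  # harmonize the donor population
                new_seq[fam_members[fam][dg][0].cds_id] = donor_nt
            for ri, rg in enumerate(recip_gs):
                c = fam_members[fam][rg][0]
                mutated = _mutate(donor_codes, plan.residual_divergence, rng)
                new_seq[c.cds_id] = _decode(mutated)
                if to_sym and genomes[rg].symbiosis_plasmid is not None:
                    moved.setdefault(rg, {})[c.cds_id] = "pSym"
                else:
                    moved.setdefault(rg, {})[c.cds_id] = "chr"
                if ri == 0:
                    truth.hgt_genes[pair].append(c.cds_id)

    # rebuild affected genomes
    new_genomes = []
    for g in collection.genomes:
        g_moves = moved.get(g.genome_id, {})
        touched = g_moves or any(c.cds_id in new_seq for c in g.cds)
        if not touched:
            new_genomes.append(g)
            continue
        slot_cds: dict[str, list[CDSFeature]] = {}
        kind_of: dict[str, RepliconKind] = {}
        for r in g.replicons:
            slot = r.replicon_id[len(g.genome_id) + 1:]
            slot_cds[slot] = []
            kind_of[slot] = r.kind
        for c in g.cds:
            if c.cds_id in new_seq:
                nt = new_seq[c.cds_id]
                from .genome_io import _translate
                c = replace(c, nt_seq=nt, aa_seq=_translate(nt))
            slot = c.replicon_id[len(g.genome_id) + 1:]
            slot = g_moves.get(c.cds_id, slot)
            slot_cds[slot].append(c)
        sym_rank = {gene: i for i, gene in enumerate(config.symbiosis_genes)}
        fam_of_local = truth.family_of_cds

        def order_key(c: CDSFeature):
            fam = fam_of_local[c.cds_id]
            return (0, sym_rank[fam]) if fam in sym_rank else (1, fam)

        assignments = [(f"{g.genome_id}_{slot}", kind_of[slot],
                        sorted(slot_cds[slot], key=order_key))
                       for slot in ["chr"] + sorted(s for s in slot_cds if s != "chr")]
        new_genomes.append(_build_genome(g.genome_id, assignments, g.metadata,
                                         collection.backbones.get(g.genome_id)))
    return SyntheticCollection(new_genomes, truth, config,
                               collection.hgt_families, collection.backbones)


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------

def simulate_collection(config: SimulationConfig) -> SyntheticCollection:
    """Full simulation: tree -> pan-genome -> sequences -> replicons -> HGT."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(7)]
    species_tree = simulate_species_tree(config.n_species, seeds[0],
                                         config.between_species_divergence)
    gtree = genome_tree_from_species_tree(species_tree,
                                          config.genomes_per_species,
                                          config.within_species_divergence)
    families = simulate_pangenome(gtree, config, seeds[1])
    seqs = evolve_sequences(gtree, families, config, seeds[2])
    backbones = evolve_backbones(gtree, config, seeds[5]) \
        if config.intergenic_bp > 0 else {}
    species_of = genome_species_map(config)
    strand_rng = np.random.default_rng(seeds[3])
    strand_of = {fam: ("+" if strand_rng.random() < 0.5 else "-")
                 for fam in sorted(families)}

    truth = TruthTables(species_of_genome=dict(species_of))
    genomes = []
    from .genome_io import _translate

    for gid in sorted(species_of):
        cds_list = []
        for fam in sorted(families):
            if gid not in families[fam]:
                continue
            nt = seqs[fam][gid]
            cds_id = f"{gid}.{fam}"
            gene_name = fam if fam in config.symbiosis_genes else None
            cds_list.append(CDSFeature(
                cds_id=cds_id, replicon_id=f"{gid}_chr", start=0, end=len(nt),
                strand=strand_of[fam], nt_seq=nt, aa_seq=_translate(nt),
                product=f"{fam} family protein", gene_name=gene_name))
            truth.family_of_cds[cds_id] = fam
        genome = _build_genome(
            gid, [(f"{gid}_chr", RepliconKind.CHROMOSOME, cds_list)],
            {"species_cluster": species_of[gid], "genus": "Rhizobium",
             "host": "Phaseolus vulgaris"},
            backbones.get(gid))
        genomes.append(genome)

    coll = SyntheticCollection(genomes, truth, config, backbones=backbones)
    if config.plasmids_per_genome > 0:
        coll = assign_replicons(coll, config)
    if config.hgt_plan:
        coll = plant_hgt(coll, config.hgt_plan, seeds[4])
    return coll


def write_collection(collection: SyntheticCollection, outdir) -> None:
    """Per-genome FASTA + GFF3, metadata.tsv and truth/*.tsv."""
    from pathlib import Path

    import pandas as pd

    from .genome_io import write_genome, write_metadata

    outdir = Path(outdir)
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for g in collection.genomes:
        write_genome(g, gdir)
    write_metadata(collection.genomes, outdir / "metadata.tsv")
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    t = collection.truth
    pd.DataFrame(sorted(t.species_of_genome.items()),
                 columns=["genome_id", "species"]).to_csv(
        tdir / "species.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.family_of_cds.items()),
                 columns=["cds_id", "family_id"]).to_csv(
        tdir / "families.tsv", sep="\t", index=False)
    rows = [{"species_a": a, "species_b": b, "cds_id": c}
            for (a, b), cds in sorted(t.hgt_genes.items()) for c in cds]
    pd.DataFrame(rows, columns=["species_a", "species_b", "cds_id"]).to_csv(
        tdir / "hgt_genes.tsv", sep="\t", index=False)
    rows = [{"genome_id": g, "replicon_id": r, "cluster": label}
            for (g, r), label in sorted(t.plasmid_clusters.items())]
    pd.DataFrame(rows, columns=["genome_id", "replicon_id", "cluster"]).to_csv(
        tdir / "plasmid_clusters.tsv", sep="\t", index=False)
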