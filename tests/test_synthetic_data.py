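import dataclasses

import numpy as np
import pytest

from panhgt import synthetic_data as sd


def test_determinism_same_seed(small_config):
    a = sd.simulate_collection(small_config)
    b = sd.simulate_collection(small_config)
    for ga, gb in zip(a.genomes, b.genomes):
        assert ga.genome_id == gb.genome_id
        assert [r.sequence for r in ga.replicons] == \
            [r.sequence for r in gb.replicons]
        assert [(c.cds_id, c.nt_seq) for c in ga.cds] == \
            [(c.cds_id, c.nt_seq) for c in gb.cds]


def test_different_seed_differs(small_config):
    a = sd.simulate_collection(small_config)
    b = sd.simulate_collection(dataclasses.replace(small_config, seed=8))
    assert a.genomes[0].replicons[0].sequence != \
        b.genomes[0].replicons[0].sequence


def test_truth_tables_cover_all_cds(small_collection):
    truth = small_collection.truth
    all_cds = {c.cds_id for g in small_collection.genomes for c in g.cds}
    assert set(truth.family_of_cds) == all_cds
    assert set(truth.species_of_genome) == \
        {g.genome_id for g in small_collection.genomes}


def test_genome_architecture(small_collection):
    cfg = small_collection.config
    for g in small_collection.genomes:
        kinds = [r.kind.value for r in g.replicons]
        assert kinds.count("chromosome") == 1
        assert kinds.count("symbiosis_plasmid") == 1
        assert len(g.replicons) == 1 + cfg.plasmids_per_genome
        # CDS sequences match their genomic coordinates
        from Bio.Seq import Seq
        seq_of = {r.replicon_id: r.sequence for r in g.replicons}
        for c in g.cds:
            genomic = seq_of[c.replicon_id][c.start:c.end]
            expect = c.nt_seq if c.strand == "+" else \
                str(Seq(c.nt_seq).reverse_complement())
            assert genomic == expect
            assert "*" not in c.aa_seq


def test_symbiosis_genes_contiguous_on_psym(small_collection):
    for g in small_collection.genomes:
        sym = g.symbiosis_plasmid
        on_sym = sorted(g.cds_by_replicon(sym.replicon_id),
                        key=lambda c: c.start)
        names = [c.gene_name for c in on_sym if c.gene_name]
        assert names == list(sd.SYMBIOSIS_GENES)


def test_within_vs_between_divergence(small_collection):
    truth = small_collection.truth
    fam_seqs: dict[str, dict[str, str]] = {}
    for g in small_collection.genomes:
        for c in g.cds:
            fam_seqs.setdefault(truth.family_of_cds[c.cds_id],
                                {})[g.genome_id] = c.nt_seq

    def ident(a, b):
        return np.mean([x == y for x, y in zip(a, b)])

    within, between = [], []
    sp = truth.species_of_genome
    for fam, seqs in fam_seqs.items():
        gids = sorted(seqs)
        for i in range(len(gids)):
            for j in range(i + 1, len(gids)):
                a, b = gids[i], gids[j]
                if len(seqs[a]) != len(seqs[b]):
                    continue
                d = 1 - ident(seqs[a], seqs[b])
                (within if sp[a] == sp[b] else between).append(d)
    assert np.mean(within) < 0.02
    assert np.mean(between) > 0.05
    assert np.mean(between) > 3 * np.mean(within)


def test_hgt_plan_plants_near_identical_copies(small_hgt_collection):
    col = small_hgt_collection
    truth = col.truth
    planted = truth.hgt_genes[("S1", "S2")]
    assert len(planted) == 8
    fam_of = truth.family_of_cds
    donor_seqs = {fam_of[c.cds_id]: c.nt_seq
                  for c in col.genome("S1_1").cds}
    idents = []
    for cds_id in planted:
        gid = cds_id.split(".")[0]
        c = next(c for c in col.genome(gid).cds if c.cds_id == cds_id)
        fam = fam_of[cds_id]
        a, b = donor_seqs[fam], c.nt_seq
        ident = np.mean([x == y for x, y in zip(a, b)])
        # residual divergence 0.4%; allow binomial spread on short genes
        assert ident > 0.975
        idents.append(ident)
    assert np.mean(idents) > 0.99
    # harmonization: second donor genome identical to donor at planted loci
    planted_fams = {fam_of[c] for c in planted}
    for c in col.genome("S1_2").cds:
        fam = fam_of[c.cds_id]
        if fam in planted_fams:
            assert c.nt_seq == donor_seqs[fam]


def test_hgt_plan_validation():
    with pytest.raises(ValueError):
        sd.HGTPlanEntry("S1", "S1", 5)
    with pytest.raises(ValueError):
        sd.HGTPlanEntry("S1", "S2", 5, residual_divergence=0.05)


def test_hgt_plan_deficit_error(small_config):
    cfg = dataclasses.replace(
        small_config, hgt_plan=(sd.HGTPlanEntry("S1", "S2", 10000),))
    with pytest.raises(ValueError, match="deficit"):
        sd.simulate_collection(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        sd.SimulationConfig(n_species=1)
    with pytest.raises(ValueError):
        sd.SimulationConfig(within_species_divergence=0.2,
                            between_species_divergence=0.1)
    with pytest.raises(ValueError):
        sd.SimulationConfig(core_families=5)


def test_write_collection(tmp_path, small_collection):
    sd.write_collection(small_collection, tmp_path)
    gdir = tmp_path / "genomes"
    fastas = sorted(p.name for p in gdir.glob("*.fasta"))
    assert len(fastas) == len(small_collection.genomes)
    assert (tmp_path / "truth" / "species.tsv").exists()
    assert (tmp_path / "metadata.tsv").exists()


def test_species_tree_separation():
    tree = sd.simulate_species_tree(5, seed=3, between_divergence=0.08)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            assert pdm.patristic_distance(taxa[i], taxa[j]) >= 0.08 - 1e-9
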