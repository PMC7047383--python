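"""End-to-end orchestration: simulate/load -> pan-genome -> ANI -> trees ->
vertical screen -> recent HGT -> plasmid network -> symbiosis -> report.

Every stage writes plain-text outputs (TSV/Newick/GEXF/JSON) into the run
directory together with a manifest recording parameters, seed and package
versions; reruns with the same seed are byte-identical for deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani_species, hgt, pangenome as pg, phylo, plasmid_network, symbiosis
from .genome_io import GenomeRecord, TruthTables
from .synthetic_data import SimulationConfig, SyntheticCollection, simulate_collection, write_collection

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the study's stated settings."""

    inflation: float = 2.0
    cutoff: float = 0.4
    ani_threshold: float = 95.0
    sim_threshold: float = 98.5
    min_hgt_genes: int = 50
    alpha: float = 0.05
    rell: int = 1000
    plasmid_cut: float = 0.15
    boot: int = 1000
    seed: int = 0
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        sim_data = {k: v for k, v in data.items() if k in sim_keys}
        run_data = {k: v for k, v in data.items() if k in run_keys}
        unknown = set(data) - sim_keys - run_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = SimulationConfig(**sim_data) if sim_data else None
        return cls(simulation=sim, **run_data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["hgt_plan"] = [
                dataclasses.asdict(p) for p in self.simulation.hgt_plan]
        return d


def run_all(config: RunConfig, outdir,
            collection: SyntheticCollection | None = None) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("[%.1fs] stage: %s", time.time() - t0, name)

    if collection is None:
        stage("simulate")
        sim = config.simulation or SimulationConfig(seed=config.seed)
        collection = simulate_collection(sim)
        write_collection(collection, outdir / "input")
    genomes = collection.genomes
    truth = collection.truth

    # --- pan-genome -------------------------------------------------------
    stage("pangenome")
    proteins = {c.cds_id: c.aa_seq for g in genomes for c in g.cds}
    genome_of = {c.cds_id: g.genome_id for g in genomes for c in g.cds}
    pan = pg.pangenome_from_proteins(proteins, genome_of,
                                     inflation=config.inflation,
                                     min_ratio=config.cutoff)
    fam_rows = [{"family_id": f.family_id, "cds_id": c,
                 "genome_id": genome_of[c]}
                for f in pan.families for c in sorted(f.members)]
    pd.DataFrame(fam_rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
    pan.matrix.to_csv(outdir / "matrix.tsv", sep="\t")
    pd.DataFrame(sorted(pan.partition.items()),
                 columns=["family_id", "partition"]).to_csv(
        outdir / "partition.tsv", sep="\t", index=False)
    newick, _ = pg.cluster_presence_absence(pan.matrix)
    (outdir / "dendrogram.nwk").write_text(newick + "\n")

    # --- ANI & species ----------------------------------------------------
    stage("ani")
    ani = ani_species.ani_matrix(genomes)
    ani.to_csv(outdir / "ani.tsv", sep="\t")
    clustering = ani_species.delineate_species(ani, config.ani_threshold)
    pd.DataFrame(sorted(clustering.labels.items()),
                 columns=["genome_id", "cluster"]).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)

    # --- species tree & vertical screen ------------------------------------
    stage("species tree")
    scc = pg.single_copy_core(pan)
    fam_msas = {}
    fam_by_id = {f.family_id: f for f in pan.families}
    for fam_id in scc:
        members = sorted(fam_by_id[fam_id].members)
        cds_of = {genome_of[c]: c for c in members}
        feats = {g.genome_id: None for g in genomes}
        for g in genomes:
            for c in g.cds:
                if c.cds_id == cds_of.get(g.genome_id):
                    feats[g.genome_id] = c
        aa = {gid: f.aa_seq for gid, f in feats.items() if f}
        nt = {gid: f.nt_seq for gid, f in feats.items() if f}
        msa_aa = phylo.align_family(aa)
        fam_msas[fam_id] = phylo.backtranslate(msa_aa, nt)
    species_tree = None
    if fam_msas:
        concat, _ = phylo.concatenate(
            list(fam_msas.values()), sorted(g.genome_id for g in genomes))
        species_tree = phylo.species_tree_from_alignment(concat)
        (outdir / "species.nwk").write_text(
            species_tree.as_string(schema="newick"))
        stage("vertical screen")
        screen = phylo.vertical_screen(fam_msas, species_tree,
                                       alpha=config.alpha, n_rell=config.rell,
                                       seed=config.seed)
        fam_replicons = _family_replicons(genomes, pan)
        rows = [{"family_id": f, "delta_lnl": r.delta_lnl, "p": r.p_value,
                 "consistent": r.consistent, "rf_shortcut": r.rf_shortcut,
                 "replicon_of_members": fam_replicons.get(f, "")}
                for f, r in sorted(screen.items())]
        pd.DataFrame(rows).to_csv(outdir / "screen.tsv", sep="\t", index=False)
    else:
        screen = {}

    # --- recent HGT ---------------------------------------------------------
    stage("hgt")
    events, fits = hgt.detect_recent_hgt(
        genomes, pan, clustering.labels, ani, threshold=config.sim_threshold,
        min_genes=config.min_hgt_genes, ani_cutoff=config.ani_threshold,
        seed=config.seed)
    ref = max(genomes, key=lambda g: (g.size_bp, g.genome_id))
    ev_rows = []
    loc_rows = []
    for e in events:
        hgt.localize_genes(e, ref, pan)
        ev_rows.append({"species_a": e.species_a, "species_b": e.species_b,
                        "n_hgt": e.n_hgt, "significant": e.significant,
                        "method": e.fit.method if e.fit else ""})
        for rep, cnt in sorted(e.replicon_counts.items()):
            loc_rows.append({"species_a": e.species_a, "species_b": e.species_b,
                             "replicon": rep, "count": cnt})
    pd.DataFrame(ev_rows, columns=["species_a", "species_b", "n_hgt",
                                   "significant", "method"]).to_csv(
        outdir / "events.tsv", sep="\t", index=False)
    pd.DataFrame(loc_rows, columns=["species_a", "species_b", "replicon",
                                    "count"]).to_csv(
        outdir / "replicon_counts.tsv", sep="\t", index=False)
    fits_json = {
        f"{sa}|{sb}": {"mu_v": fit.mu_v, "sd_v": fit.sd_v, "w_v": fit.w_v,
                       "mu_t": fit.mu_t, "sd_t": fit.sd_t, "w_t": fit.w_t,
                       "n_hgt": fit.n_hgt, "converged": fit.converged,
                       "method": fit.method}
        for (sa, sb), (fit, _) in sorted(fits.items())}
    (outdir / "mixture_fits.json").write_text(
        json.dumps(fits_json, indent=1, sort_keys=True))
    rho = p_rho = float("nan")
    if len(events) >= 5:
        reps = hgt.species_representatives(genomes, clustering.labels)
        pair_ani = {
            tuple(sorted((sa, sb))): float(
                ani.loc[reps[sa].genome_id, reps[sb].genome_id])
            for (sa, sb) in fits}
        rho, p_rho = hgt.hgt_ani_correlation(events, pair_ani)

    # --- plasmid network ----------------------------------------------------
    stage("plasmid network")
    proteomes = {}
    for g in genomes:
        sym = g.symbiosis_plasmid
        if sym is None:
            continue
        proteomes[sym.replicon_id] = {
            c.cds_id: c.aa_seq for c in g.cds_by_replicon(sym.replicon_id)}
    plasmid_labels = {}
    if len(proteomes) >= 2:
        network, _ = plasmid_network.bipartite_from_proteomes(proteomes)
        pclust = plasmid_network.cluster_plasmids(network, cut=config.plasmid_cut)
        plasmid_labels = pclust.labels
        plasmid_network.export_gexf(network, pclust, outdir / "network.gexf")
        pd.DataFrame(sorted(pclust.labels.items()),
                     columns=["plasmid", "cluster"]).to_csv(
            outdir / "plasmid_clusters.tsv", sep="\t", index=False)

    # --- symbiosis genes ----------------------------------------------------
    stage("symbiosis")
    gene_set = symbiosis.extract_symbiosis_genes(genomes)
    host_of = {g.genome_id: g.metadata.get("host", "") for g in genomes}
    conc_rows = []
    sym_dir = outdir / "symbiosis_trees"
    sym_dir.mkdir(exist_ok=True)
    for gene in sorted({n for d in gene_set.genes.values() for n in d}):
        if len(gene_set.genomes_with(gene)) < 4:
            continue
        tree = symbiosis.symbiosis_gene_tree(gene, gene_set,
                                             n_boot=config.boot,
                                             seed=config.seed)
        (sym_dir / f"{gene}.nwk").write_text(tree.as_string(schema="newick"))
        conc = symbiosis.host_concordance(tree, host_of)
        conc_rows.append({"gene": gene,
                          "within_between_ratio": conc.within_between_ratio,
                          "n_monophyletic_hosts":
                              sum(conc.monophyletic.values()),
                          "n_hosts": len(conc.monophyletic)})
    pd.DataFrame(conc_rows, columns=["gene", "within_between_ratio",
                                     "n_monophyletic_hosts", "n_hosts"]).to_csv(
        outdir / "concordance.tsv", sep="\t", index=False)

    # --- manifest & report --------------------------------------------------
    manifest = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "parameter_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))

    summary = build_report(
        pan=pan, clustering=clustering, scc=scc, screen=screen,
        events=events, plasmid_labels=plasmid_labels,
        hgt_ani_rho=rho, hgt_ani_p=p_rho,
        truth=truth if truth and truth.species_of_genome else None)
    (outdir / "report.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str))
    (outdir / "report.md").write_text(_report_markdown(summary))
    return outdir


def _family_replicons(genomes: list[GenomeRecord], pan: pg.PanGenome) -> dict[str, str]:
    fam_of = pan.family_of()
    out: dict[str, set[str]] = {}
    for g in genomes:
        for c in g.cds:
            fam = fam_of.get(c.cds_id)
            if fam is None:
                continue
            kind = next(r.kind.value for r in g.replicons
                        if r.replicon_id == c.replicon_id)
            out.setdefault(fam, set()).add(kind)
    return {f: ",".join(sorted(k)) for f, k in out.items()}


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("panhgt", "numpy", "scipy", "pandas", "biopython", "dendropy",
                "networkx", "numba"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def build_report(pan, clustering, scc, screen, events, plasmid_labels,
                 hgt_ani_rho, hgt_ani_p, truth: TruthTables | None = None) -> dict:
    counts = pan.counts()
    sig = [e for e in events if e.significant]
    n_hgt_values = [e.n_hgt for e in sig]
    loc_totals: dict[str, int] = {}
    for e in sig:
        for rep, cnt in e.replicon_counts.items():
            loc_totals[rep] = loc_totals.get(rep, 0) + cnt
    total_loc = sum(loc_totals.values())
    summary = {
        "pangenome": counts,
        "n_species_clusters": len(clustering.clusters()),
        "n_single_copy_core": len(scc),
        "n_screened": len(screen),
        "n_consistent": sum(1 for r in screen.values() if r.consistent),
        "n_significant_hgt_pairs": len(sig),
        "hgt_n_mean": float(np.mean(n_hgt_values)) if n_hgt_values else 0.0,
        "hgt_n_sd": float(np.std(n_hgt_values, ddof=1))
        if len(n_hgt_values) > 1 else 0.0,
        "hgt_replicon_shares": {
            rep: cnt / total_loc for rep, cnt in sorted(loc_totals.items())
        } if total_loc else {},
        "hgt_ani_spearman_rho": hgt_ani_rho,
        "hgt_ani_spearman_p": hgt_ani_p,
        "n_plasmid_clusters": len(set(plasmid_labels.values())),
    }
    if truth is not None:
        summary["truth"] = {
            "n_species": len(set(truth.species_of_genome.values())),
            "n_families": len(truth.families()),
            "n_hgt_pairs": len(truth.hgt_genes),
        }
    return summary


def _report_markdown(summary: dict) -> str:
    pan = summary["pangenome"]
    lines = [
        "# Run summary",
        "",
        f"- Gene families: {pan['total']} (core {pan['core']}, dispensable "
        f"{pan['dispensable']}, unique {pan['unique']})",
        f"- Species clusters at the ANI threshold: "
        f"{summary['n_species_clusters']}",
        f"- Single-copy core families: {summary['n_single_copy_core']}",
        f"- Families with species-tree-consistent phylogenies: "
        f"{summary['n_consistent']} / {summary['n_screened']}",
        f"- Significant recent-HGT species pairs: "
        f"{summary['n_significant_hgt_pairs']} "
        f"(mean n_hgt {summary['hgt_n_mean']:.1f}, "
        f"sd {summary['hgt_n_sd']:.1f})",
        f"- HGT count vs ANI Spearman rho: "
        f"{summary['hgt_ani_spearman_rho']}",
        f"- Plasmid clusters: {summary['n_plasmid_clusters']}",
        "",
    ]
    return "\n".join(lines)


def report(run_dir) -> dict:
    """Load a completed run directory and return its summary."""
    run_dir = Path(run_dir)
    path = run_dir / "report.json"
    if not path.exists():
        raise FileNotFoundError(f"no report.json in {run_dir}; incomplete run")
    return json.loads(path.read_text())
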