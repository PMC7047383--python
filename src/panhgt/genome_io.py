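"""Genome model and FASTA/GFF3 input-output.

The in-memory model is a :class:`GenomeRecord` holding an ordered list of
replicons (exactly one chromosome, any number of plasmids, optionally a
designated symbiosis plasmid) and strand-aware CDS features. Internal
coordinates are 0-based half-open; GFF3 on disk is 1-based inclusive, the
conversion happens at the I/O boundary.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SYMBIOSIS_GENES = (
    "nodA", "nodB", "nodC",
    "fixA", "fixB", "fixC",
    "nifH", "nifD", "nifK", "nifE", "nifN", "nifB",
)


class RepliconKind(str, enum.Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    SYMBIOSIS_PLASMID = "symbiosis_plasmid"


@dataclass
class CDSFeature:
    """A protein-coding feature; ``nt_seq`` is always the coding strand."""

    cds_id: str
    replicon_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    nt_seq: str
    aa_seq: str
    product: str = ""
    cog_category: str | None = None
    gene_name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CDS interval for {self.cds_id}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.cds_id}")


@dataclass
class Replicon:
    replicon_id: str
    kind: RepliconKind
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        """GC fraction; N is excluded from the denominator."""
        s = self.sequence.upper()
        acgt = sum(s.count(c) for c in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt


@dataclass
class GenomeRecord:
    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)
    cds: list[CDSFeature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.replicon_id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicon ids in genome {self.genome_id}")
        n_chrom = sum(1 for r in self.replicons if r.kind is RepliconKind.CHROMOSOME)
        if self.replicons and n_chrom != 1:
            raise ValueError(
                f"genome {self.genome_id} has {n_chrom} chromosomes; exactly one required")

    @property
    def size_bp(self) -> int:
        return sum(r.length for r in self.replicons)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(f"no replicon {replicon_id!r} in genome {self.genome_id}")

    def cds_by_replicon(self, replicon_id: str) -> list[CDSFeature]:
        return [c for c in self.cds if c.replicon_id == replicon_id]

    @property
    def symbiosis_plasmid(self) -> Replicon | None:
        for r in self.replicons:
            if r.kind is RepliconKind.SYMBIOSIS_PLASMID:
                return r
        return None


@dataclass
class TruthTables:
    """Planted ground truth emitted by the simulator.

    ``hgt_genes`` maps an (ordered lexicographically) species-pair tuple to
    the list of recipient CDS ids whose sequence was replaced by a donor
    copy. ``plasmid_clusters`` maps (genome_id, replicon_id) to a template
    label; plasmids built from the same family template share a label.
    """

    species_of_genome: dict[str, str] = field(default_factory=dict)
    family_of_cds: dict[str, str] = field(default_factory=dict)
    hgt_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    plasmid_clusters: dict[tuple[str, str], str] = field(default_factory=dict)

    def families(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cds_id, fam in self.family_of_cds.items():
            out.setdefault(fam, set()).add(cds_id)
        return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _translate(nt: str) -> str:
    aa = str(Seq(nt).translate())
    return aa[:-1] if aa.endswith("*") else aa


def read_genome(fasta_path, gff3_path, metadata_row: dict | None = None) -> GenomeRecord:
    """Load one genome from a FASTA + GFF3 pair.

    Replicon kind is taken from the GFF3 ``region`` feature's
    ``replicon_kind`` attribute (defaulting to chromosome for the first
    record otherwise). CDS features whose length is not divisible by 3 are
    skipped with a logged warning; the skip count is stored in
    ``metadata['n_skipped_cds']``.
    """
    import gffutils

    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genome_id = metadata_row.get("genome_id") if metadata_row else None
    if not genome_id:
        genome_id = fasta_path.stem

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    kinds: dict[str, RepliconKind] = {}
    for region in db.features_of_type("region"):
        kind = region.attributes.get("replicon_kind", ["chromosome"])[0]
        kinds[region.seqid] = RepliconKind(kind)

    replicons = []
    for i, (rid, seq) in enumerate(seqs.items()):
        kind = kinds.get(rid, RepliconKind.CHROMOSOME if i == 0 else RepliconKind.PLASMID)
        replicons.append(Replicon(rid, kind, seq))

    cds_list = []
    n_skipped = 0
    for feat in db.features_of_type("CDS"):
        if feat.seqid not in seqs:
            raise ValueError(
                f"GFF3 seqid {feat.seqid!r} not present in FASTA {fasta_path.name}")
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        nt = seqs[feat.seqid][start:end]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        if len(nt) % 3 != 0:
            n_skipped += 1
            logger.warning("skipping CDS %s: length %d not divisible by 3",
                           feat.id, len(nt))
            continue
        attrs = feat.attributes
        cds_list.append(CDSFeature(
            cds_id=attrs.get("ID", [feat.id])[0],
            replicon_id=feat.seqid,
            start=start,
            end=end,
            strand=feat.strand,
            nt_seq=nt,
            aa_seq=_translate(nt),
            product=attrs.get("product", [""])[0],
            cog_category=attrs.get("cog", [None])[0],
            gene_name=attrs.get("gene", [None])[0],
        ))

    meta = dict(metadata_row or {})
    meta["n_skipped_cds"] = n_skipped
    return GenomeRecord(genome_id, replicons, cds_list, meta)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeRecord, outdir) -> tuple[Path, Path]:
    """Write FASTA (80-column) and GFF3 for one genome; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / f"{genome.genome_id}.fasta"
    gff3_path = outdir / f"{genome.genome_id}.gff3"

    records = [SeqRecord(Seq(r.sequence), id=r.replicon_id, description="")
               for r in genome.replicons]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)

    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genome.replicons:
            fh.write(f"##sequence-region {r.replicon_id} 1 {r.length}\n")
        for r in genome.replicons:
            fh.write("\t".join([
                r.replicon_id, "panhgt", "region", "1", str(r.length),
                ".", "+", ".",
                f"ID=region:{r.replicon_id};replicon_kind={r.kind.value}",
            ]) + "\n")
        for c in genome.cds:
            attrs = [f"ID={c.cds_id}"]
            if c.product:
                attrs.append(f"product={c.product}")
            if c.gene_name:
                attrs.append(f"gene={c.gene_name}")
            if c.cog_category:
                attrs.append(f"cog={c.cog_category}")
            fh.write("\t".join([
                c.replicon_id, "panhgt", "CDS", str(c.start + 1), str(c.end),
                ".", c.strand, "0", ";".join(attrs),
            ]) + "\n")
    return fasta_path, gff3_path


def write_metadata(genomes: list[GenomeRecord], path) -> Path:
    """TSV with one row per genome (genome_id + metadata columns)."""
    import pandas as pd

    keys = sorted({k for g in genomes for k in g.metadata})
    rows = [{"genome_id": g.genome_id, **{k: g.metadata.get(k, "") for k in keys}}
            for g in genomes]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Stats
# ---------------------------------------------------------------------------

def genome_stats(genome: GenomeRecord) -> dict:
    """Size, G+C (to 0.1%), CDS count and per-replicon breakdown."""
    seq_all = "".join(r.sequence for r in genome.replicons).upper()
    acgt = sum(seq_all.count(c) for c in "ACGT")
    gc = (seq_all.count("G") + seq_all.count("C")) / acgt * 100 if acgt else 0.0
    per_replicon = {
        r.replicon_id: {
            "kind": r.kind.value,
            "length": r.length,
            "gc_percent": round(r.gc_content * 100, 1),
            "n_cds": len(genome.cds_by_replicon(r.replicon_id)),
        }
        for r in genome.replicons
    }
    return {
        "genome_id": genome.genome_id,
        "size_bp": genome.size_bp,
        "gc_percent": round(gc, 1),
        "n_cds": len(genome.cds),
        "per_replicon": per_replicon,
    }
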