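"""Average nucleotide identity and 95%-threshold species delineation.

ANI follows the fragment convention of JSpecies-style ANIb/ANIm: the query
genome is cut into consecutive 1020-bp fragments, each fragment is locally
aligned to the subject (match +1, mismatch -1, gap open 5, extend 2), and a
fragment is retained when its best alignment has > 30% identity over an
alignable region covering >= 70% of the fragment. ANI is the mean identity
of retained fragments, the aligned fraction is retained/total, and the
reported value is the mean of both directions.

Alignment is seeded: shared 15-mers between fragment and subject (either
strand) choose the diagonal, and a banded Smith-Waterman explores +-16
around it. Random fragments with no shared 15-mer, or whose local alignment
does not extend over 70% of the fragment, are dropped - unrelated genomes
therefore retain no fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit, types
from numba.typed import Dict as NumbaDict

from .align import banded_local_dna_stats, encode_dna
from .genome_io import GenomeRecord

FRAGMENT_LEN = 1020
SEED_K = 15
BAND = 8
MIN_IDENTITY = 0.30
MIN_COVERAGE = 0.70


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float                # percent; nan when undefined
    aligned_fraction: float   # percent of fragments retained
    defined: bool = True


@dataclass
class SpeciesClustering:
    labels: dict[str, str]  # genome_id -> cluster label (R1, R2, ...)

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, lab in self.labels.items():
            out.setdefault(lab, set()).add(g)
        return out


def _genome_sequence(genome: GenomeRecord) -> str:
    return "".join(r.sequence for r in genome.replicons)


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


@njit(cache=False)
def _build_index(codes, k):
    """First occurrence position of every k-mer (2-bit packed; N skipped)."""
    index = NumbaDict.empty(types.int64, types.int64)
    for i in range(len(codes) - k + 1):
        h = 0
        ok = True
        for j in range(k):
            c = codes[i + j]
            if c > 3:
                ok = False
                break
            h = (h << 2) | np.int64(c)
        if ok and h not in index:
            index[h] = i
    return index


@njit(cache=False)
def _vote_offset(frag, index, k, step):
    """Most-voted diagonal (target pos - fragment pos) over sampled k-mers.

    Returns (offset, votes); votes == 0 means no shared k-mer. Vote ties go
    to the smallest diagonal for determinism.
    """
    votes = NumbaDict.empty(types.int64, types.int64)
    best_off = np.int64(0)
    best_v = np.int64(0)
    for i in range(0, len(frag) - k + 1, step):
        h = 0
        ok = True
        for j in range(k):
            c = frag[i + j]
            if c > 3:
                ok = False
                break
            h = (h << 2) | np.int64(c)
        if not ok or h not in index:
            continue
        d = index[h] - i
        v = votes.get(d, np.int64(0)) + 1
        votes[d] = v
        if v > best_v or (v == best_v and d < best_off):
            best_v = v
            best_off = d
    return best_off, best_v


class _SubjectPrep:
    """Cached per-genome search structures (k-mer indexes, encodings)."""

    __slots__ = ("fwd", "rev", "enc_fwd", "enc_rev")

    def __init__(self, subject: str):
        self.enc_fwd = encode_dna(subject)
        self.enc_rev = encode_dna(_revcomp(subject))
        self.fwd = _build_index(self.enc_fwd, SEED_K)
        self.rev = _build_index(self.enc_rev, SEED_K)


def _one_direction(query: str, prep: _SubjectPrep) -> tuple[float, int, int]:
    """(sum of retained identities, n retained, n fragments)."""
    enc_query = encode_dna(query)
    n_frag = 0
    retained = 0
    total_identity = 0.0
    for start in range(0, len(query) - FRAGMENT_LEN + 1, FRAGMENT_LEN):
        frag = enc_query[start:start + FRAGMENT_LEN]
        n_frag += 1
        off_f, v_f = _vote_offset(frag, prep.fwd, SEED_K, 8)
        off_r, v_r = _vote_offset(frag, prep.rev, SEED_K, 8)
        # align only the strand with the stronger seed support (both on ties)
        candidates = []
        if v_f and v_f >= v_r:
            candidates.append((off_f, prep.enc_fwd))
        if v_r and v_r >= v_f:
            candidates.append((off_r, prep.enc_rev))
        best = None
        for off, subj in candidates:
            stats = banded_local_dna_stats(frag, subj, int(off), BAND)
            if best is None or stats[0] > best[0]:
                best = stats
        if best is None:
            continue
        _, n_id, n_pairs, aln_len, span = best
        if aln_len == 0 or span < MIN_COVERAGE * len(frag):
            continue
        identity = n_id / aln_len
        if identity <= MIN_IDENTITY:
            continue
        retained += 1
        total_identity += identity
    return total_identity, retained, max(1, n_frag)


def compute_ani(genome_a: GenomeRecord, genome_b: GenomeRecord,
                prep_a: _SubjectPrep | None = None,
                prep_b: _SubjectPrep | None = None) -> ANIResult:
    """Symmetrized fragment ANI between two genomes.

    ``prep_a``/``prep_b`` allow reusing the per-genome k-mer indexes across
    many pairs (as :func:`ani_matrix` does).
    """
    seq_a = _genome_sequence(genome_a)
    seq_b = _genome_sequence(genome_b)
    if not seq_a or not seq_b:
        raise ValueError("both genomes must be non-empty")
    prep_a = prep_a or _SubjectPrep(seq_a)
    prep_b = prep_b or _SubjectPrep(seq_b)
    sums, counts, totals = zip(_one_direction(seq_a, prep_b),
                               _one_direction(seq_b, prep_a))
    retained = sum(counts)
    if retained == 0:
        return ANIResult(genome_a.genome_id, genome_b.genome_id,
                         float("nan"), 0.0, defined=False)
    ani = sum(sums) / retained * 100.0
    aligned = retained / sum(totals) * 100.0
    return ANIResult(genome_a.genome_id, genome_b.genome_id, ani, aligned)


def ani_matrix(genomes: list[GenomeRecord]) -> pd.DataFrame:
    """Symmetric ANI matrix (percent) with a 100 diagonal.

    Undefined pairs (no retained fragments) are stored as NaN and treated as
    below any delineation threshold downstream.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.genome_id for g in genomes]
    preps = [_SubjectPrep(_genome_sequence(g)) for g in genomes]
    m = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            r = compute_ani(genomes[i], genomes[j], preps[i], preps[j])
            m.iloc[i, j] = m.iloc[j, i] = r.ani
    return m


def delineate_species(matrix: pd.DataFrame,
                      threshold: float = 95.0) -> SpeciesClustering:
    """Single-linkage clusters over the graph of pairs with ANI >= threshold.

    Labels R1, R2, ... are assigned by decreasing cluster size, ties broken
    by the lexicographically smallest member.
    """
    import scipy.sparse as sp

    ids = sorted(matrix.index)
    m = matrix.loc[ids, ids].to_numpy(dtype=float)
    adj = np.nan_to_num(m, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for g, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(g)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), sorted(ms)))
    out = {}
    for k, members in enumerate(ordered):
        for g in members:
            out[g] = f"R{k + 1}"
    return SpeciesClustering(out)
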