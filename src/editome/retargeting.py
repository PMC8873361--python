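"""Edited mature miRNA construction and PAR-CLIP seed-match target prediction.

An editing event is applied to a mature arm to build the edited sequence
variant (a 5' addition shifts the whole seed register by one). Targets are
read off PAR-CLIP evidence: reads are aligned to transcripts with T-to-C
conversions not counted as mismatches, overlapping reads are merged into
clusters, clusters with crosslink-diagnostic T-to-C reads are searched for
reverse-complement matches to the seed (nucleotides 1-8), and each match is
scored with a transparent background probability p_s (chance of a match at
least that long in a window of the cluster's span under i.i.d. cluster base
frequencies - smaller is better).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .align import revcomp
from .io_formats import MatureArm, Precursor, dna_to_rna, rna_to_dna

logger = logging.getLogger(__name__)

__all__ = [
    "MatureVariant",
    "ParClipCluster",
    "TargetSite",
    "apply_edit",
    "mature_variant",
    "align_parclip",
    "find_clusters",
    "predict_targets",
    "compare_target_sets",
    "targets_to_genes",
    "prioritize_new_targets",
    "SEED_FLANK",
]

#: flank around a cluster searched for seed matches (crosslinks sit near,
#: not on, the complementary site)
SEED_FLANK = 10


@dataclass(frozen=True)
class MatureVariant:
    """A mature miRNA sequence, original or carrying one applied edit."""

    base_name: str
    suffix: str  # "" for the unedited form, else e.g. "_26c"
    sequence: str  # DNA alphabet, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", rna_to_dna(self.sequence.upper()))
        if not 18 <= len(self.sequence) <= 25:
            raise ValueError(
                f"{self.name}: mature sequence length {len(self.sequence)} "
                "outside 18..25"
            )

    @property
    def name(self) -> str:
        return self.base_name + self.suffix

    @property
    def seed(self) -> str:
        """Seed region: the first to eighth nucleotide."""
        return self.sequence[:8]

    @property
    def rna(self) -> str:
        return dna_to_rna(self.sequence)


def mature_variant(precursor: Precursor, arm: MatureArm) -> MatureVariant:
    """The unedited mature form of an arm."""
    return MatureVariant(
        base_name=precursor.id,
        suffix="",
        sequence=precursor.seq[arm.p_start - 1 : arm.p_end],
    )


def apply_edit(precursor: Precursor, arm: MatureArm, site) -> MatureVariant:
    """Build the edited mature sequence a site call implies for this arm.

    5'-editing prepends the added base (shifting the seed register), a
    central substitution replaces the base (A-to-I renders as G), a 3' tail
    appends, a central deletion removes the base. The variant is suffixed
    ``_<pos><alt>`` after the hairpin name, the convention edited mature
    forms are reported under.
    """
    mature = precursor.seq[arm.p_start - 1 : arm.p_end]
    pos, alt = site.p_pos, site.alt_symbol
    if alt.upper() == site.ref_base.upper():
        raise ValueError(f"{site.name}: variant equals the template base")
    suffix = f"_{pos}{dna_to_rna(alt)}"
    if arm.p_start - 2 <= pos < arm.p_start:
        seq = alt.upper() + mature
    elif arm.p_start <= pos <= arm.p_end:
        k = pos - arm.p_start
        if alt == "-":
            seq = mature[:k] + mature[k + 1 :]
        else:
            seq = mature[:k] + alt.upper() + mature[k + 1 :]
    elif arm.p_end < pos <= arm.p_end + 3:
        seq = mature + alt.upper()
    else:
        raise ValueError(f"{site.name}: site is not adjacent to arm {arm.name}")
    return MatureVariant(base_name=precursor.id, suffix=suffix, sequence=seq)


@dataclass(frozen=True)
class ParClipRead:
    """One PAR-CLIP read placed on a transcript (1-based inclusive span)."""

    read_id: str
    mrna_id: str
    start: int
    end: int
    count: int
    t2c: int  # template-T positions read as C


@dataclass(frozen=True)
class ParClipCluster:
    mrna_id: str
    start: int
    end: int
    total_reads: int
    t2c_read_count: int


@dataclass(frozen=True)
class TargetSite:
    mrna_id: str
    start: int  # 1-based inclusive span of the seed match on the transcript
    end: int
    match_class: str  # 8mer | 7mer | 6mer
    p_s: float
    cluster: ParClipCluster


def align_parclip(reads, mrnas: dict[str, str], max_mismatch: int = 1):
    """Place reads on transcripts; T-to-C conversions are not mismatches.

    Keeps, per read, all placements with the fewest non-conversion
    mismatches (up to ``max_mismatch``). A conversion only counts where the
    template is T and the read shows C.
    """
    enc = {m: np.frombuffer(s.upper().encode(), dtype=np.uint8) for m, s in mrnas.items()}
    T, C = ord("T"), ord("C")
    placements = []
    for read in reads:
        q = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        m = len(q)
        best = None
        cands = []
        for mid, arr in enc.items():
            if len(arr) < m:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, m)
            diff = win != q
            conv = (win == T) & (q == C)
            mism = (diff & ~conv).sum(axis=1)
            t2c = (diff & conv).sum(axis=1)
            for pos0 in np.nonzero(mism <= max_mismatch)[0]:
                score = int(mism[pos0])
                cands.append((score, mid, int(pos0), int(t2c[pos0])))
                if best is None or score < best:
                    best = score
        if best is None:
            continue
        for score, mid, pos0, t2c in sorted(c for c in cands if c[0] == best):
            placements.append(
                ParClipRead(
                    read_id=read.id,
                    mrna_id=mid,
                    start=pos0 + 1,
                    end=pos0 + m,
                    count=read.count,
                    t2c=t2c,
                )
            )
    return placements


def find_clusters(placements) -> list[ParClipCluster]:
    """Merge overlapping read placements into clusters per transcript.

    Each cluster records its total read count and how many reads carry at
    least one T-to-C conversion.
    """
    by_mrna: dict[str, list[ParClipRead]] = defaultdict(list)
    for p in placements:
        by_mrna[p.mrna_id].append(p)
    clusters = []
    for mid in sorted(by_mrna):
        reads = sorted(by_mrna[mid], key=lambda r: (r.start, r.end))
        cur: list[ParClipRead] = []
        cur_end = -1
        for r in reads:
            if cur and r.start > cur_end:
                clusters.append(_close_cluster(mid, cur))
                cur = []
            cur.append(r)
            cur_end = max(cur_end, r.end)
        if cur:
            clusters.append(_close_cluster(mid, cur))
    return clusters


def _close_cluster(mid: str, reads) -> ParClipCluster:
    return ParClipCluster(
        mrna_id=mid,
        start=min(r.start for r in reads),
        end=max(r.end for r in reads),
        total_reads=sum(r.count for r in reads),
        t2c_read_count=sum(r.count for r in reads if r.t2c > 0),
    )


def _match_probability(motif: str, freqs: dict[str, float]) -> float:
    p = 1.0
    for b in motif:
        p *= freqs.get(b, 0.25)
    return p


def seed_match_pvalue(window: str, motif: str) -> float:
    """p_s: chance of >=1 occurrence of ``motif`` in an i.i.d. window.

    Base frequencies are estimated from the window itself (quarter
    pseudocounts keep them positive); the window offers
    ``len(window) - len(motif) + 1`` start positions.
    """
    n_pos = len(window) - len(motif) + 1
    if n_pos <= 0:
        return 1.0
    counts = {b: window.count(b) + 0.25 for b in "ACGT"}
    tot = sum(counts.values())
    freqs = {b: c / tot for b, c in counts.items()}
    p_hit = _match_probability(motif, freqs)
    return float(1.0 - (1.0 - p_hit) ** n_pos)


def predict_targets(mirna: MatureVariant, mrnas: dict[str, str], clusters,
                    min_t2c: int = 1, min_class: str = "6mer") -> list[TargetSite]:
    """Seed-match search inside T-to-C-supported clusters (+/- SEED_FLANK nt).

    Match classes follow canonical seed pairing: 8mer = reverse complement of
    miRNA positions 1-8, 7mer = 2-8, 6mer = 2-7; the longest match found in a
    cluster wins and is scored with :func:`seed_match_pvalue`. Clusters below
    ``min_t2c`` diagnostic reads are skipped regardless of sequence match.
    ``min_class`` restricts the accepted tiers (a seed shifted by a 5'
    addition still shares its 6mer/7mer with the original register, so
    register-discriminating comparisons are run at the 8mer tier).
    """
    seed = mirna.seed
    motifs = [
        ("8mer", revcomp(seed[0:8])),
        ("7mer", revcomp(seed[1:8])),
        ("6mer", revcomp(seed[1:7])),
    ]
    keep = {"8mer": 1, "7mer": 2, "6mer": 3}[min_class]
    motifs = motifs[:keep]
    sites = []
    for cl in clusters:
        if cl.t2c_read_count < min_t2c:
            continue
        seq = mrnas[cl.mrna_id].upper()
        w_start = max(1, cl.start - SEED_FLANK)
        w_end = min(len(seq), cl.end + SEED_FLANK)
        window = seq[w_start - 1 : w_end]
        best = None
        for cls, motif in motifs:
            k = window.find(motif)
            if k >= 0:
                best = TargetSite(
                    mrna_id=cl.mrna_id,
                    start=w_start + k,
                    end=w_start + k + len(motif) - 1,
                    match_class=cls,
                    p_s=seed_match_pvalue(window, motif),
                    cluster=cl,
                )
                break
        if best is not None:
            sites.append(best)
    return sites


def compare_target_sets(orig, edited):
    """Gene-level set algebra: (common, new, lost) of edited vs original targets."""
    orig, edited = set(orig), set(edited)
    return orig & edited, edited - orig, orig - edited


def targets_to_genes(sites, gene_table) -> set[str]:
    """Collapse target sites to gene ids via a transcript -> gene table."""
    tx2gene = dict(zip(gene_table["transcript_id"], gene_table["gene_id"]))
    genes = set()
    for s in sites:
        g = tx2gene.get(s.mrna_id)
        if g is None:
            logger.warning("transcript %s missing from gene table; skipped", s.mrna_id)
            continue
        genes.add(g)
    return genes


def prioritize_new_targets(new_sites, gene_table, min_reads: int = 10) -> list[str]:
    """Deduplicated coding genes whose best cluster has >= min_reads reads.

    ``gene_table`` needs columns transcript_id, gene_id, coding (boolean).
    Genes missing from the table are excluded with a warning.
    """
    tx2gene = dict(zip(gene_table["transcript_id"], gene_table["gene_id"]))
    coding = dict(zip(gene_table["gene_id"], gene_table["coding"]))
    best_reads: dict[str, int] = {}
    for s in new_sites:
        g = tx2gene.get(s.mrna_id)
        if g is None:
            logger.warning("transcript %s missing from gene table; excluded", s.mrna_id)
            continue
        best_reads[g] = max(best_reads.get(g, 0), s.cluster.total_reads)
    return sorted(
        g for g, reads in best_reads.items() if coding.get(g, False) and reads >= min_reads
    )
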