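"""Placement of small-RNA reads on pre-miRNA hairpins and cross-mapping correction.

The aligner is a native exact/1-mismatch windowed comparison tuned to the
geometry of the problem (reads of 18-30 nt against hairpins of <= a few
hundred nt). A placement may carry, besides up to ``max_sub`` internal
substitutions, a run of up to 3 non-templated bases at the read 3' end
(``tail3``) and up to 2 extra bases at the 5' end (``add5``) when these sit
immediately upstream of a mature arm. A single-base insertion or deletion is
attempted only for reads that admit no ungapped placement.

Multi-mapped reads are resolved by cross-mapping correction: each read's
weight is reallocated among its genomic loci in proportion to the local
expression of perfectly matching reads, iterated to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import Precursor, ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EditOp",
    "WeightedAlignment",
    "GenomicHit",
    "align_to_precursors",
    "genomic_multimap",
    "cross_map_correct",
    "write_sam",
]

MAX_TAIL3 = 3  # longest run of non-templated 3' bases accepted
MAX_ADD5 = 2  # most extra 5' bases accepted upstream of an arm start

_SENTINEL = 255  # pad byte that matches nothing


@dataclass(frozen=True)
class EditOp:
    """One deviation of a read from its hairpin template.

    ``p_pos`` is the 1-based precursor position (virtual when the base lies
    beyond the hairpin boundary); ``ref_base`` is the template base (or ``-``
    off-template / for insertions) and ``alt_base`` the read base in lowercase
    (``-`` for deletions).
    """

    p_pos: int
    ref_base: str
    alt_base: str
    kind: str  # substitution | insertion | deletion | tail3 | add5


@dataclass(frozen=True)
class WeightedAlignment:
    read_id: str
    precursor_id: str
    p_offset: int  # 1-based precursor position of the first aligned base
    ops: tuple[EditOp, ...]
    weight: float
    count: int
    read_seq: str = ""

    @property
    def read_length(self) -> int:
        return len(self.read_seq)


@dataclass(frozen=True)
class GenomicHit:
    read_id: str
    chrom: str
    g_pos: int  # 1-based leftmost position on the plus strand
    strand: str
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _PrecursorIndex:
    """Padded byte array per precursor for vectorised window comparison."""

    def __init__(self, precursor: Precursor):
        self.precursor = precursor
        body = _encode(precursor.seq)
        self.pad_left = MAX_ADD5
        self.pad_right = MAX_TAIL3 + 1
        self.arr = np.concatenate(
            [
                np.full(self.pad_left, _SENTINEL, dtype=np.uint8),
                body,
                np.full(self.pad_right, _SENTINEL, dtype=np.uint8),
            ]
        )


def _add5_window_ok(precursor: Precursor, p_pos: int) -> bool:
    """True when a non-templated 5' base at p_pos sits just upstream of an arm."""
    if p_pos < 1:
        return True
    return any(a.p_start - MAX_ADD5 <= p_pos <= a.p_start - 1 for a in precursor.arms)


def _ungapped_candidates(read_arr, idx: _PrecursorIndex, max_sub: int):
    """Yield (offset0, mismatch_index_array) for placements worth classifying.

    offset0 is the 0-based position of the read's first base in precursor
    coordinates (may be negative down to -MAX_ADD5).
    """
    m = len(read_arr)
    arr = idx.arr
    n_win = len(arr) - m + 1
    if n_win <= 0:
        return
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = windows != read_arr
    budget = max_sub + MAX_ADD5 + MAX_TAIL3
    counts = mism.sum(axis=1)
    for w in np.nonzero(counts <= budget)[0]:
        yield int(w) - idx.pad_left, np.nonzero(mism[w])[0]


def _classify_placement(read: ReadRecord, precursor: Precursor, offset0: int,
                        mis_idx: np.ndarray, max_sub: int):
    """Turn a placement's mismatch positions into ops; return (score, ops) or None.

    score = (internal_edits, n_indels, -templated_matches); lower is better.
    """
    m = len(read.seq)
    L = len(precursor.seq)
    first_pos = offset0 + 1  # 1-based precursor position of read base 1
    # reject overhang beyond the allowed non-templated runs
    if first_pos < 1 - MAX_ADD5 or first_pos + m - 1 > L + MAX_TAIL3:
        return None

    mis = set(int(i) for i in mis_idx)
    # leading run of mismatches -> candidate add5 bases
    lead = 0
    while lead < m and lead in mis:
        lead += 1
    trail = 0
    while trail < m and (m - 1 - trail) in mis:
        trail += 1
    if lead == m:  # nothing templated at all
        return None

    # add5 bases are the lead-run positions closest to the templated block
    add5_idx = []
    for i in range(lead - 1, -1, -1):
        if len(add5_idx) >= MAX_ADD5:
            break
        if _add5_window_ok(precursor, first_pos + i):
            add5_idx.append(i)
        else:
            break
    add5_idx = set(add5_idx)
    tail_idx = set(range(m - min(trail, MAX_TAIL3), m))

    # off-template positions must be absorbed by the add5/tail runs
    for i in mis:
        pos = first_pos + i
        if (pos < 1 and i not in add5_idx) or (pos > L and i not in tail_idx):
            return None

    ops = []
    n_sub = 0
    for i in sorted(mis):
        pos = first_pos + i
        ref = precursor.base(pos)
        alt = read.seq[i].lower()
        if i in add5_idx:
            ops.append(EditOp(pos, ref, alt, "add5"))
        elif i in tail_idx:
            ops.append(EditOp(pos, ref, alt, "tail3"))
        else:
            n_sub += 1
            ops.append(EditOp(pos, ref, alt, "substitution"))
    if n_sub > max_sub:
        return None
    matched = m - len(mis)
    return (n_sub, 0, -matched), tuple(ops)


def _gapped_placements(read: ReadRecord, precursor: Precursor, max_sub: int):
    """Single-indel placements (fallback when no ungapped placement exists)."""
    m = len(read.seq)
    seq = precursor.seq
    L = len(seq)
    results = []
    # deletion: one template base inside the read span is skipped
    for offset0 in range(0, L - m):
        for k in range(1, m):  # deletion after read base k
            n_mis = 0
            ok = True
            for i in range(m):
                tpos = offset0 + i + (1 if i >= k else 0)
                if seq[tpos] != read.seq[i]:
                    n_mis += 1
                    if n_mis > max_sub:
                        ok = False
                        break
            if not ok:
                continue
            del_pos = offset0 + k + 1  # 1-based skipped template position
            ops = [EditOp(del_pos, seq[del_pos - 1], "-", "deletion")]
            for i in range(m):
                tpos = offset0 + i + (1 if i >= k else 0)
                if seq[tpos] != read.seq[i]:
                    ops.append(
                        EditOp(tpos + 1, seq[tpos], read.seq[i].lower(), "substitution")
                    )
            ops.sort(key=lambda o: o.p_pos)
            score = (n_mis + 1, 1, -(m - n_mis))
            results.append((score, offset0 + 1, tuple(ops)))
    # insertion: one read base inside the span is non-templated
    for offset0 in range(0, L - m + 2):
        for k in range(1, m - 1):  # read base k is inserted
            if offset0 + m - 1 > L:
                continue
            n_mis = 0
            ok = True
            for i in range(m):
                if i == k:
                    continue
                tpos = offset0 + i - (1 if i > k else 0)
                if tpos >= L or seq[tpos] != read.seq[i]:
                    n_mis += 1
                    if n_mis > max_sub:
                        ok = False
                        break
            if not ok:
                continue
            ins_pos = offset0 + k  # template position the extra base precedes
            ops = [EditOp(ins_pos, "-", read.seq[k].lower(), "insertion")]
            for i in range(m):
                if i == k:
                    continue
                tpos = offset0 + i - (1 if i > k else 0)
                if seq[tpos] != read.seq[i]:
                    ops.append(
                        EditOp(tpos + 1, seq[tpos], read.seq[i].lower(), "substitution")
                    )
            ops.sort(key=lambda o: o.p_pos)
            score = (n_mis + 1, 1, -(m - 1 - n_mis))
            results.append((score, offset0 + 1, tuple(ops)))
    return results


def align_to_precursors(reads, precursors, max_sub: int = 2):
    """Place every read on its best-scoring hairpin locations.

    Best means fewest internal edits, then longest templated match; all tied
    placements are kept, each with initial weight ``1/n``. Reads that align
    nowhere are dropped and counted in a log summary.

    ``max_sub`` defaults to 2 internal substitutions: an edited read carrying
    one ordinary sequencing error (about 2% of reads at Q30 and 22 nt) must
    still be placeable, or editing levels acquire a systematic downward bias
    of roughly the per-read error probability. A BLAST-like local aligner
    tolerates such reads; the stricter 1-mismatch contract applies to the
    genome-wide search, not the hairpin placement.
    """
    indexes = [_PrecursorIndex(p) for p in sorted(precursors, key=lambda p: p.id)]
    alignments = []
    n_dropped = 0
    for read in reads:
        read_arr = _encode(read.seq)
        best_score = None
        placements = []  # (score, precursor_id, offset1, ops)
        for idx in indexes:
            for offset0, mis_idx in _ungapped_candidates(read_arr, idx, max_sub):
                res = _classify_placement(read, idx.precursor, offset0, mis_idx, max_sub)
                if res is None:
                    continue
                score, ops = res
                placements.append((score, idx.precursor.id, offset0 + 1, ops))
                if best_score is None or score < best_score:
                    best_score = score
        if best_score is None:
            for idx in indexes:
                for score, offset1, ops in _gapped_placements(read, idx.precursor, max_sub):
                    placements.append((score, idx.precursor.id, offset1, ops))
                    if best_score is None or score < best_score:
                        best_score = score
        if best_score is None:
            n_dropped += 1
            continue
        winners = sorted(
            [p for p in placements if p[0] == best_score],
            key=lambda p: (p[1], p[2]),
        )
        # equivalent indel placements at one locus (homopolymer ambiguity)
        # collapse to the leftmost-indel representation
        seen = set()
        deduped = []
        for p in winners:
            key = (p[1], p[2])
            if key not in seen:
                seen.add(key)
                deduped.append(p)
        winners = deduped
        w = 1.0 / len(winners)
        for _, prec_id, offset1, ops in winners:
            alignments.append(
                WeightedAlignment(
                    read_id=read.id,
                    precursor_id=prec_id,
                    p_offset=offset1,
                    ops=ops,
                    weight=w,
                    count=read.count,
                    read_seq=read.seq,
                )
            )
    if n_dropped:
        logger.info("align_to_precursors: %d reads aligned nowhere (dropped)", n_dropped)
    return alignments


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def genomic_multimap(reads, genome: dict[str, str], max_mismatch: int = 1):
    """All genomic placements of each read with at most one mismatch.

    Mirrors an exhaustive ``-a -v 1`` short-read search over both strands of
    the (small, in-memory) genome.
    """
    chrom_arrays = {c: _encode(s.upper()) for c, s in genome.items()}
    hits = []
    for read in reads:
        for strand in "+-":
            query = read.seq if strand == "+" else revcomp(read.seq)
            q = _encode(query)
            m = len(q)
            for chrom, arr in chrom_arrays.items():
                if len(arr) < m:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(arr, m)
                mm = (windows != q).sum(axis=1)
                for pos0 in np.nonzero(mm <= max_mismatch)[0]:
                    hits.append(
                        GenomicHit(
                            read_id=read.id,
                            chrom=chrom,
                            g_pos=int(pos0) + 1,
                            strand=strand,
                            mismatches=int(mm[pos0]),
                        )
                    )
    return hits


def _expected_genomic_start(aln: WeightedAlignment, precursor: Precursor) -> int:
    """Leftmost plus-strand genome coordinate implied by a hairpin placement."""
    if precursor.strand == "+":
        return precursor.g_start + aln.p_offset - 1
    return precursor.g_end - (aln.p_offset - 1) - (aln.read_length - 1)


def cross_map_correct(alignments, hits, precursors, tol: float = 1e-6,
                      max_iter: int = 50):
    """Reallocate multi-mapped read weights by local perfect-match expression.

    Each read's weight at genomic locus L is iterated to
    ``expression(L) / sum(expression over its loci)`` where expression counts
    only perfectly matching read mass, until the largest weight change is
    below ``tol`` (or ``max_iter`` sweeps). Reads whose candidate loci all
    have zero perfect-match expression keep uniform weights. Returns the
    alignments with corrected weights; per-read weights always sum to 1
    across loci.
    """
    by_read: dict[str, list[GenomicHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    counts: dict[str, int] = {}
    for a in alignments:
        counts[a.read_id] = a.count

    def locus_key(h: GenomicHit):
        return (h.chrom, h.g_pos, h.strand)

    weights: dict[str, dict[tuple, float]] = {}
    perfect: dict[str, dict[tuple, bool]] = {}
    for rid, rhits in by_read.items():
        loci = {locus_key(h): h for h in rhits}
        n = len(loci)
        weights[rid] = {k: 1.0 / n for k in loci}
        perfect[rid] = {k: h.mismatches == 0 for k, h in loci.items()}

    n_fallback = 0
    for _ in range(max_iter):
        expr: dict[tuple, float] = {}
        for rid, w in weights.items():
            c = counts.get(rid, 1)
            for k, wk in w.items():
                if perfect[rid][k]:
                    expr[k] = expr.get(k, 0.0) + c * wk
        max_change = 0.0
        for rid, w in weights.items():
            if len(w) == 1:
                continue
            denom = sum(expr.get(k, 0.0) for k in w)
            if denom <= 0.0:
                continue
            for k in w:
                new = expr.get(k, 0.0) / denom
                max_change = max(max_change, abs(new - w[k]))
                w[k] = new
        if max_change < tol:
            break
    n_fallback = sum(
        1
        for rid, w in weights.items()
        if len(w) > 1 and not any(perfect[rid][k] for k in w)
    )
    if n_fallback:
        logger.info(
            "cross_map_correct: %d multi-locus reads had no perfect-match "
            "expression at any locus; uniform weights kept",
            n_fallback,
        )

    prec_by_id = {p.id: p for p in precursors}
    corrected = []
    for aln in alignments:
        rhits = by_read.get(aln.read_id)
        if not rhits:
            corrected.append(aln)
            continue
        prec = prec_by_id[aln.precursor_id]
        g0 = _expected_genomic_start(aln, prec)
        match = None
        for h in rhits:
            if h.chrom == prec.chrom and h.strand == prec.strand and abs(h.g_pos - g0) <= MAX_TAIL3:
                match = locus_key(h)
                break
        if match is None:
            corrected.append(aln)
            continue
        corrected.append(replace(aln, weight=weights[aln.read_id][match]))
    return corrected


def write_sam(alignments, precursors, path) -> None:
    """Export hairpin placements as SAM, one record per placement.

    The cross-mapping weight is carried in the ``XW`` float tag. Non-templated
    5'/3' bases are soft-clipped; internal substitutions stay inside M runs.
    """
    import pysam

    order = sorted(precursors, key=lambda p: p.id)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": p.id, "LN": len(p.seq)} for p in order],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            n5 = sum(1 for o in aln.ops if o.kind == "add5")
            n3 = sum(1 for o in aln.ops if o.kind == "tail3")
            core = aln.read_length - n5 - n3
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.read_seq
            seg.reference_id = out.header.references.index(aln.precursor_id)
            seg.reference_start = aln.p_offset - 1 + n5  # first templated base
            cigar = []
            if n5:
                cigar.append((4, n5))
            cigar.append((0, core))
            if n3:
                cigar.append((4, n3))
            seg.cigartuples = cigar
            seg.mapping_quality = 255
            seg.set_tag("XW", float(aln.weight), "f")
            seg.set_tag("XC", int(aln.count))
            out.write(seg)
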