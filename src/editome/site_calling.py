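"""Per-sample mutation/editing (M/E) site calling on pre-miRNA hairpins.

Weighted read placements are tallied per precursor position, every observed
alternative base becomes a candidate site, and candidates are screened with a
binomial sequencing-error model, Benjamini-Hochberg correction and the level /
support thresholds. The resulting calls carry the field's naming convention
(``hsa-mir-10b_26_A_c``: hairpin, 1-based position, templated base uppercase,
variant lowercase).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from scipy.stats import binom

from .align import (
    WeightedAlignment,
    align_to_precursors,
    cross_map_correct,
    genomic_multimap,
)
from .io_formats import Precursor, format_site_name, quality_filter
from .stats import bh_adjust

__all__ = [
    "PositionTally",
    "SiteCall",
    "SampleCalls",
    "tally_positions",
    "site_significance",
    "classify_site",
    "significant_sites",
    "tptm_normalize",
    "call_sample",
    "DEFAULT_P_ERR",
]

#: per-base error probability implied by the Q30 read-quality threshold
DEFAULT_P_ERR = 1e-3

CENTRAL_CATEGORIES = ("A-to-I", "C-to-U", "Other", "indel")
END3_CATEGORIES = ("3'-A", "3'-U", "3'-Other")


@dataclass
class PositionTally:
    """Weighted read mass observed at one hairpin position.

    ``alt_mass`` maps each non-templated symbol to its weighted mass,
    ``alt_count`` to its raw (unweighted) read support, and ``alt_kind_mass``
    to the mass per edit-op kind, which later decides whether a variant is a
    3' tail, a 5' addition or an internal change.
    """

    precursor_id: str
    p_pos: int
    ref_base: str
    coverage: float = 0.0
    alt_mass: dict = field(default_factory=lambda: defaultdict(float))
    alt_count: dict = field(default_factory=lambda: defaultdict(int))
    alt_kind_mass: dict = field(default_factory=lambda: defaultdict(lambda: defaultdict(float)))


@dataclass(frozen=True)
class SiteCall:
    """One called M/E site in one sample."""

    name: str
    precursor_id: str
    p_pos: int
    ref_base: str
    alt_symbol: str  # lowercase base or '-'
    region: str  # central | end5 | end3 | outside-arm
    category: str
    coverage_weight: float
    edited_weight: float
    edited_read_count: int
    level: float
    p_raw: float
    p_adj: float = float("nan")
    tptm: float = float("nan")


@dataclass
class SampleCalls:
    """Everything site calling produces for one sample."""

    sample_id: str
    significant: list
    insignificant: list
    sample_total: float
    coverage: dict  # (precursor_id, p_pos) -> weighted coverage
    alignments: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    log: dict = field(default_factory=dict)

    @property
    def all_sites(self):
        return self.significant + self.insignificant


def tally_positions(alignments, precursor: Precursor):
    """Aggregate weighted alignments of one hairpin into per-position tallies.

    A read covers its own span plus the single position beyond each end (the
    tailing / 5'-addition opportunity), so the level of an end-modification
    site is the fraction of arm reads actually carrying the extra base rather
    than a ratio over tailed reads only.
    """
    tallies: dict[int, PositionTally] = {}

    def get(pos: int) -> PositionTally:
        t = tallies.get(pos)
        if t is None:
            t = PositionTally(precursor.id, pos, precursor.base(pos))
            tallies[pos] = t
        return t

    for aln in alignments:
        if aln.precursor_id != precursor.id:
            raise ValueError(
                f"alignment of {aln.read_id} references {aln.precursor_id}, "
                f"not {precursor.id}"
            )
        mass = aln.weight * aln.count
        start = aln.p_offset
        end = aln.p_offset + aln.read_length - 1
        n_ins = sum(1 for o in aln.ops if o.kind == "insertion")
        n_del = sum(1 for o in aln.ops if o.kind == "deletion")
        # insertions consume read but no template; deletions the reverse
        end += n_del - n_ins
        for pos in range(start - 1, end + 2):
            get(pos).coverage += mass
        for op in aln.ops:
            t = get(op.p_pos)
            alt = op.alt_base.lower() if op.alt_base != "-" else "-"
            t.alt_mass[alt] += mass
            t.alt_count[alt] += aln.count
            t.alt_kind_mass[alt][op.kind] += mass
    return [tallies[k] for k in sorted(tallies)]


def site_significance(tally: PositionTally, alt: str, p_err: float = DEFAULT_P_ERR) -> float:
    """One-sided binomial tail P[X >= k | n, p_err] for one candidate variant.

    k is the rounded edited mass and n the rounded coverage, so the test runs
    on integer read support as a binomial demands.
    """
    k = int(round(tally.alt_mass[alt]))
    n = int(round(tally.coverage))
    if k > n:
        raise ValueError(
            f"{tally.precursor_id}:{tally.p_pos} edited support {k} exceeds coverage {n}"
        )
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p_err))


def _resolve_region(precursor: Precursor, p_pos: int) -> str:
    for arm in precursor.arms:
        if arm.p_start <= p_pos <= arm.p_end:
            return "central"
    for arm in precursor.arms:
        if arm.p_end < p_pos <= arm.p_end + 3:
            return "end3"
    for arm in precursor.arms:
        if arm.p_start - 2 <= p_pos < arm.p_start:
            return "end5"
    return "outside-arm"


def classify_site(precursor: Precursor, p_pos: int, ref: str, alt: str,
                  kind_mass: dict | None = None) -> tuple[str, str]:
    """Assign the (region, category) of one candidate variant.

    Decision order: 3'-end events (position past a mature 3' end, or variant
    mass dominated by non-templated tail ops) split by the added base; then
    5' additions; then central substitutions (A>g is A-to-I since inosine
    reads as G, C>u is C-to-U); then central indels. Anything not adjacent to
    an arm is ``outside-arm`` and excluded from reports.
    """
    kind_mass = kind_mass or {}
    major_kind = max(kind_mass, key=kind_mass.get) if kind_mass else "substitution"
    region = _resolve_region(precursor, p_pos)

    past_3p = any(a.p_end < p_pos <= a.p_end + 3 for a in precursor.arms)
    if major_kind == "tail3" or (past_3p and region != "central"):
        if alt == "a":
            return "end3", "3'-A"
        if alt in ("t", "u"):
            return "end3", "3'-U"
        return "end3", "3'-Other"

    before_5p = any(a.p_start - 2 <= p_pos < a.p_start for a in precursor.arms)
    if major_kind == "add5" or (before_5p and major_kind == "substitution"):
        return "end5", "5'-editing"

    if region == "central":
        if major_kind in ("insertion", "deletion") or alt == "-":
            return "central", "indel"
        if ref == "A" and alt == "g":
            return "central", "A-to-I"
        if ref == "C" and alt in ("t", "u"):
            return "central", "C-to-U"
        return "central", "Other"
    return "outside-arm", "outside-arm"


def significant_sites(sites, min_level: float = 0.05, min_reads: int = 10,
                      alpha: float = 0.05):
    """Split candidate calls into significant sites and the insignificant rest.

    A site is significant when its level is at least ``min_level``, at least
    ``min_reads`` raw reads support the variant, and its BH-adjusted binomial
    p-value (computed here over all candidates passed in) is below ``alpha``.
    The insignificant side channel keeps every other candidate for cohort
    prevalence accounting.
    """
    sites = list(sites)
    adj = bh_adjust([s.p_raw for s in sites]) if sites else []
    sig, insig = [], []
    for s, p_adj in zip(sites, adj):
        s = replace(s, p_adj=p_adj)
        if s.level >= min_level and s.edited_read_count >= min_reads and p_adj < alpha:
            sig.append(s)
        else:
            insig.append(s)
    return sig, insig


def tptm_normalize(mass: float, sample_total: float) -> float:
    """Tags per ten million: mass scaled to a 1e7 mapped-mass library."""
    if sample_total == 0:
        raise ValueError("sample total mass is zero; cannot normalize")
    return mass * 1e7 / sample_total


def call_sample(reads, precursors, genome=None, sample_id: str = "sample",
                q_min: int = 30, span: int = 25, len_min: int = 18,
                max_sub: int = 2, p_err: float = DEFAULT_P_ERR,
                min_level: float = 0.05, min_reads: int = 10,
                alpha: float = 0.05, keep_alignments: bool = True) -> SampleCalls:
    """Run the full single-sample pipeline: filter, align, correct, tally, test.

    ``genome`` (a mapping of sequence name to sequence) enables genomic
    multi-map search and cross-mapping weight correction; without it every
    read keeps its uniform per-placement weight.
    """
    n_in = sum(r.count for r in reads)
    filtered = quality_filter(reads, q_min=q_min, span=span, len_min=len_min)
    alignments = align_to_precursors(filtered, precursors, max_sub=max_sub)
    hits = []
    if genome is not None:
        aligned_ids = {a.read_id for a in alignments}
        aligned_reads = [r for r in filtered if r.id in aligned_ids]
        hits = genomic_multimap(aligned_reads, genome)
        alignments = cross_map_correct(alignments, hits, precursors)

    sample_total = sum(a.weight * a.count for a in alignments)
    by_prec: dict[str, list[WeightedAlignment]] = defaultdict(list)
    for a in alignments:
        by_prec[a.precursor_id].append(a)

    coverage: dict[tuple[str, int], float] = {}
    candidates: list[SiteCall] = []
    for prec in sorted(precursors, key=lambda p: p.id):
        if prec.id not in by_prec:
            continue
        for tally in tally_positions(by_prec[prec.id], prec):
            coverage[(prec.id, tally.p_pos)] = tally.coverage
            for alt in sorted(tally.alt_mass):
                region, category = classify_site(
                    prec, tally.p_pos, tally.ref_base, alt, tally.alt_kind_mass[alt]
                )
                if category == "outside-arm":
                    continue
                level = tally.alt_mass[alt] / tally.coverage if tally.coverage else 0.0
                candidates.append(
                    SiteCall(
                        name=format_site_name(prec.id, tally.p_pos, tally.ref_base, alt),
                        precursor_id=prec.id,
                        p_pos=tally.p_pos,
                        ref_base=tally.ref_base,
                        alt_symbol=alt,
                        region=region,
                        category=category,
                        coverage_weight=tally.coverage,
                        edited_weight=tally.alt_mass[alt],
                        edited_read_count=tally.alt_count[alt],
                        level=min(level, 1.0),
                        p_raw=site_significance(tally, alt, p_err),
                    )
                )
    sig, insig = significant_sites(candidates, min_level, min_reads, alpha)
    if sample_total > 0:
        sig = [replace(s, tptm=tptm_normalize(s.edited_weight, sample_total)) for s in sig]
        insig = [replace(s, tptm=tptm_normalize(s.edited_weight, sample_total)) for s in insig]
    return SampleCalls(
        sample_id=sample_id,
        significant=sig,
        insignificant=insig,
        sample_total=sample_total,
        coverage=coverage,
        alignments=alignments if keep_alignments else [],
        hits=hits if keep_alignments else [],
        log={
            "reads_in": n_in,
            "reads_after_filter": sum(r.count for r in filtered),
            "reads_aligned": len({a.read_id for a in alignments}),
            "candidate_sites": len(candidates),
            "significant_sites": len(sig),
        },
    )
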