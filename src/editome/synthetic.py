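"""Synthetic references, cohorts and PAR-CLIP libraries with known ground truth.

The generator emulates the statistical structure the detection pipeline
assumes: hairpin-derived reads at a configurable depth with small 5'/3' end
jitter, planted editing events (central substitutions, non-templated 3'
tails and 5' additions, deletions) carried independently per read at a
per-group true level, homozygous SNPs at level 1.0 in carrier samples,
per-base sequencing error tied to a stated quality (Q30 <-> 1e-3 by
default), decoy genomic loci for cross-mapping and pseudo-site tests, and
T-to-C-converted crosslink reads over synthetic transcripts.

Everything is deterministic under a fixed master seed; per-sample streams
are spawned from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .io_formats import (
    MatureArm,
    Precursor,
    ReadRecord,
    SnpRecord,
    format_site_name,
    write_precursors,
    write_sample_sheet,
    write_snps,
)

__all__ = [
    "PlannedEvent",
    "PlannedSnp",
    "SimulationSpec",
    "Reference",
    "simulate_reference",
    "simulate_sample",
    "simulate_cohort",
    "simulate_cohort_matrix",
    "ParClipPlan",
    "simulate_parclip",
    "default_spec",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlannedEvent:
    """One editing event to plant, with its per-group true level."""

    precursor: int  # index into the reference's precursor list
    arm: str  # '5p' | '3p'
    kind: str  # central | tail3 | add5 | deletion
    alt: str  # added/substituted base (DNA); '-' for deletions
    levels: dict[str, float]
    offset: int = 10  # 1-based position within the arm (central/deletion)
    ref: str | None = None  # force this template base (central events)
    decoy: bool = False  # plant an exact genomic copy of the edited arm

    def __post_init__(self) -> None:
        for g, lv in self.levels.items():
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"level {lv} for group {g} outside [0,1]")


@dataclass(frozen=True)
class PlannedSnp:
    """A homozygous variant carried at level 1.0 by a fraction of samples."""

    precursor: int
    arm: str
    offset: int
    alt: str
    carrier_fraction: float = 1.0


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the real two-group brain cohort design: 28 disease
    prefrontal-cortex samples vs 38 control ones, reads at the Q30 error
    rate, and sequencing depth high enough for 5%-level sites to clear the
    10-read support criterion.
    """

    n_precursors: int = 10
    length_range: tuple[int, int] = (74, 100)
    arm_length: int = 22
    depth: int = 1000  # reads per mature arm per sample
    error_rate: float = 1e-3
    end_jitter: int = 1  # max random 5'/3' templated trimming per read
    group_sizes: dict[str, int] = field(default_factory=lambda: {"HD-PC": 28, "PC": 38})
    events: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    copy_decoys: list = field(default_factory=list)  # (precursor_idx, arm, n_mismatch)

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 < self.error_rate <= 0.01:
            problems.append(f"error_rate {self.error_rate} outside (0, 0.01]")
        if self.length_range[0] < 2 * self.arm_length + 26:
            problems.append(
                "precursors too short for two arms with ends and a loop: "
                f"min length {self.length_range[0]} < {2 * self.arm_length + 26}"
            )
        for ev in self.events:
            if not 0 <= ev.precursor < self.n_precursors:
                problems.append(f"event precursor index {ev.precursor} out of range")
            if ev.kind in ("central", "deletion") and not 1 <= ev.offset <= self.arm_length:
                problems.append(f"event offset {ev.offset} outside the arm")
        if problems:
            raise ValueError("inconsistent simulation spec: " + "; ".join(problems))

    @property
    def quality(self) -> int:
        return int(round(-10.0 * math.log10(self.error_rate)))


@dataclass
class Reference:
    """A materialised synthetic reference with its truth table."""

    genome: dict[str, str]
    precursors: list[Precursor]
    truth: pd.DataFrame  # one row per planted event
    snp_records: list[SnpRecord]
    spec: SimulationSpec


def _random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _other_base(rng, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in {a.upper() for a in avoid}]
    return choices[int(rng.integers(0, len(choices)))]


_EXPECTED_CATEGORY = {
    ("central", "A", "g"): "A-to-I",
    ("central", "C", "t"): "C-to-U",
}


def _expected_category(kind: str, ref: str, alt: str, decoy: bool) -> str:
    if decoy:
        return "pseudo"
    if kind == "tail3":
        return {"a": "3'-A", "t": "3'-U"}.get(alt.lower(), "3'-Other")
    if kind == "add5":
        return "5'-editing"
    if kind == "deletion":
        return "indel"
    if kind == "snp":
        return "SNP"
    return _EXPECTED_CATEGORY.get(("central", ref.upper(), alt.lower()), "Other")


def simulate_reference(spec: SimulationSpec, seed: int) -> Reference:
    """Build hairpins, embed them (and decoys) in a genome, emit the truth table."""
    rng = np.random.default_rng(seed)
    arm_len = spec.arm_length

    seqs: list[list[str]] = []
    arm_coords: list[dict[str, MatureArm]] = []
    strands = []
    for i in range(spec.n_precursors):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seqs.append(list(_random_seq(rng, L)))
        arms = {
            "5p": MatureArm(f"sim-mir-{i:02d}-5p", 10, 10 + arm_len - 1),
            "3p": MatureArm(f"sim-mir-{i:02d}-3p", L - 9 - arm_len + 1, L - 9),
        }
        arm_coords.append(arms)
        strands.append("-" if i % 4 == 3 else "+")

    # materialise planted events onto concrete precursor positions
    truth_rows = []
    for ev in spec.events:
        arm = arm_coords[ev.precursor][ev.arm]
        seq = seqs[ev.precursor]
        if ev.kind in ("central", "deletion"):
            pos = arm.p_start + ev.offset - 1
        elif ev.kind == "tail3":
            pos = arm.p_end + 1
        elif ev.kind == "add5":
            pos = arm.p_start - 1
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        if ev.kind == "central":
            ref = ev.ref or (
                seq[pos - 1] if seq[pos - 1].upper() != ev.alt.upper()
                else _other_base(rng, ev.alt)
            )
            seq[pos - 1] = ref
        elif ev.kind == "deletion":
            # deletions in homopolymers are left-normalised by aligners; force
            # an unambiguous context so the planted position is recoverable
            if seq[pos - 2].upper() == seq[pos - 1].upper():
                seq[pos - 2] = _other_base(rng, seq[pos - 1])
            if pos < len(seq) and seq[pos].upper() == seq[pos - 1].upper():
                seq[pos] = _other_base(rng, seq[pos - 1])
            ref = seq[pos - 1]
        else:  # non-templated additions: template must differ from the added base
            if seq[pos - 1].upper() == ev.alt.upper():
                seq[pos - 1] = _other_base(rng, ev.alt)
            ref = seq[pos - 1]
        alt_sym = "-" if ev.kind == "deletion" else ev.alt.lower()
        truth_rows.append(
            {
                "precursor_idx": ev.precursor,
                "arm": ev.arm,
                "kind": ev.kind,
                "p_pos": pos,
                "ref": ref,
                "alt": alt_sym,
                "category": _expected_category(ev.kind, ref, alt_sym, ev.decoy),
                "decoy": ev.decoy,
                **{f"level_{g}": lv for g, lv in ev.levels.items()},
            }
        )

    snp_rows = []
    for sp in spec.snps:
        arm = arm_coords[sp.precursor][sp.arm]
        seq = seqs[sp.precursor]
        pos = arm.p_start + sp.offset - 1
        if seq[pos - 1].upper() == sp.alt.upper():
            seq[pos - 1] = _other_base(rng, sp.alt)
        snp_rows.append(
            {
                "precursor_idx": sp.precursor,
                "arm": sp.arm,
                "kind": "snp",
                "p_pos": pos,
                "ref": seq[pos - 1],
                "alt": sp.alt.lower(),
                "category": "SNP",
                "decoy": False,
                "carrier_fraction": sp.carrier_fraction,
            }
        )

    # assemble the genome: hairpins (strand-aware) with random spacers, then decoys
    chrom = "chrS"
    pieces = []
    cursor = 0
    precursors = []
    for i, seq in enumerate(seqs):
        spacer = _random_seq(rng, int(rng.integers(40, 61)))
        pieces.append(spacer)
        cursor += len(spacer)
        hairpin = "".join(seq)
        embedded = hairpin if strands[i] == "+" else revcomp(hairpin)
        g_start = cursor + 1
        pieces.append(embedded)
        cursor += len(embedded)
        precursors.append(
            Precursor(
                id=f"sim-mir-{i:02d}",
                seq=hairpin,
                chrom=chrom,
                g_start=g_start,
                g_end=cursor,
                strand=strands[i],
                arms=tuple(arm_coords[i].values()),
            )
        )

    def arm_sequence(idx: int, arm_key: str) -> str:
        a = arm_coords[idx][arm_key]
        return "".join(seqs[idx][a.p_start - 1 : a.p_end])

    # decoy loci: exact copies of edited arms (pseudo) or raw arms (cross-mapping)
    for row in truth_rows:
        if not row["decoy"]:
            continue
        a = arm_coords[row["precursor_idx"]][row["arm"]]
        arm_seq = arm_sequence(row["precursor_idx"], row["arm"])
        k = row["p_pos"] - a.p_start
        if row["kind"] == "central":
            edited = arm_seq[:k] + row["alt"].upper() + arm_seq[k + 1 :]
        elif row["kind"] == "deletion":
            edited = arm_seq[:k] + arm_seq[k + 1 :]
        elif row["kind"] == "tail3":
            edited = arm_seq + row["alt"].upper()
        else:  # add5
            edited = row["alt"].upper() + arm_seq
        spacer = _random_seq(rng, int(rng.integers(40, 61)))
        pieces.append(spacer + edited)
        cursor += len(spacer) + len(edited)
    for idx, arm_key, n_mm in spec.copy_decoys:
        arm_seq = list(arm_sequence(idx, arm_key))
        for _ in range(n_mm):
            j = int(rng.integers(0, len(arm_seq)))
            arm_seq[j] = _other_base(rng, arm_seq[j])
        spacer = _random_seq(rng, int(rng.integers(40, 61)))
        pieces.append(spacer + "".join(arm_seq))
        cursor += len(spacer) + len(arm_seq)
    pieces.append(_random_seq(rng, 50))
    genome = {chrom: "".join(pieces)}

    snp_records = []
    for j, row in enumerate(snp_rows):
        prec = precursors[row["precursor_idx"]]
        g_pos = prec.genomic_position(row["p_pos"])
        ref, alt = row["ref"].upper(), row["alt"].upper()
        if prec.strand == "-":
            ref, alt = revcomp(ref), revcomp(alt)
        snp_records.append(SnpRecord(f"rsSIM{j:04d}", prec.chrom, g_pos, ref, alt))

    truth = pd.DataFrame(truth_rows + snp_rows)
    if len(truth):
        truth["precursor"] = [
            precursors[i].id for i in truth["precursor_idx"]
        ]
        truth["name"] = [
            format_site_name(precursors[r.precursor_idx].id, r.p_pos, r.ref, r.alt)
            for r in truth.itertuples()
        ]
    return Reference(genome, precursors, truth, snp_records, spec)


def simulate_sample(reference: Reference, group: str, rng,
                    sample_id: str = "sample", depth: int | None = None):
    """Draw one sample's reads from every mature arm with planted events applied.

    Each read independently carries each planted event at the group's true
    level; tails and 5' additions are only attached to untrimmed ends so the
    non-templated base sits at its planned virtual position. SNP carrier
    status is drawn once per sample. I.i.d. per-base errors are added last,
    with constant qualities consistent with the error rate.
    """
    spec = reference.spec
    depth = depth if depth is not None else spec.depth
    q = spec.quality
    truth = reference.truth
    carrier: dict[int, bool] = {}
    if len(truth):
        for idx, row in truth[truth["kind"] == "snp"].iterrows():
            carrier[idx] = bool(rng.random() < row["carrier_fraction"])

    reads = []
    for prec in reference.precursors:
        prec_rows = (
            truth[truth["precursor"] == prec.id] if len(truth) else truth
        )
        for arm in prec.arms:
            arm_key = "5p" if arm.name.endswith("5p") else "3p"
            if len(prec_rows):
                arm_rows = prec_rows[prec_rows["arm"] == arm_key]
                rows = list(zip(arm_rows.index, arm_rows.to_dict("records")))
            else:
                rows = []
            for i in range(depth):
                s_j = int(rng.integers(0, spec.end_jitter + 1))
                e_j = int(rng.integers(0, spec.end_jitter + 1))
                start = arm.p_start + s_j
                end = arm.p_end - e_j
                bases = list(prec.seq[start - 1 : end])
                deletions = []
                for idx, row in rows:
                    p_pos = int(row["p_pos"])
                    if row["kind"] == "snp":
                        if carrier.get(idx, False) and start <= p_pos <= end:
                            bases[p_pos - start] = row["alt"].upper()
                        continue
                    level = row.get(f"level_{group}", 0.0)
                    if not (level == level and level > 0 and rng.random() < level):
                        continue
                    if row["kind"] == "central" and start <= p_pos <= end:
                        bases[p_pos - start] = row["alt"].upper()
                    elif row["kind"] == "deletion" and start <= p_pos <= end:
                        deletions.append(p_pos)
                    elif row["kind"] == "tail3" and e_j == 0:
                        bases.append(row["alt"].upper())
                    elif row["kind"] == "add5" and s_j == 0:
                        bases.insert(0, row["alt"].upper())
                        start -= 1  # keep index arithmetic for later events
                for p in sorted(deletions, reverse=True):
                    del bases[p - start]
                err = rng.random(len(bases)) < spec.error_rate
                for k in np.nonzero(err)[0]:
                    bases[k] = _other_base(rng, bases[k])
                seq = "".join(bases)
                reads.append(
                    ReadRecord(
                        id=f"{sample_id}.{prec.id}.{arm_key}.{i}",
                        seq=seq,
                        qual=(q,) * len(seq),
                    )
                )
    return reads


def simulate_cohort(reference: Reference, master_seed: int):
    """All samples of the two-group design; per-sample streams spawned from the seed.

    Returns ``(groups, reads_by_sample, truth)`` where groups maps sample id
    to group label.
    """
    spec = reference.spec
    n_total = sum(spec.group_sizes.values())
    children = np.random.SeedSequence(master_seed).spawn(n_total)
    groups: dict[str, str] = {}
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    k = 0
    for group, n in spec.group_sizes.items():
        for j in range(n):
            sid = f"{group}_{j:02d}"
            rng = np.random.default_rng(children[k])
            groups[sid] = group
            reads_by_sample[sid] = simulate_sample(reference, group, rng, sample_id=sid)
            k += 1
    return groups, reads_by_sample, reference.truth


def simulate_cohort_matrix(site_levels, group_sizes: dict[str, int], depth: int,
                           master_seed: int, error_rate: float = 1e-3,
                           min_level: float = 0.05, min_reads: int = 10,
                           alpha: float = 0.05):
    """Read-free cohort matrix: per-cell levels sampled straight from the model.

    For each site and sample the edited-read count is Binomial(depth, theta)
    for the sample group's true level theta — exactly the distribution the
    read-level generator induces at a central position — and per-sample
    significance reproduces the calling criteria (level, support, BH-adjusted
    binomial error test). ``site_levels`` maps site name to
    ``{group: true_level}``. Useful where hundreds of cohorts are needed.
    """
    from scipy.stats import binom

    from .cohort import CohortMatrix
    from .stats import bh_adjust

    rng = np.random.default_rng(master_seed)
    sample_ids, groups = [], {}
    for group, n in group_sizes.items():
        for j in range(n):
            sid = f"{group}_{j:02d}"
            sample_ids.append(sid)
            groups[sid] = group

    names = list(site_levels)
    k = np.empty((len(names), len(sample_ids)), dtype=int)
    for i, name in enumerate(names):
        for j, sid in enumerate(sample_ids):
            theta = site_levels[name].get(groups[sid], 0.0)
            k[i, j] = rng.binomial(depth, theta)
    levels = k / depth
    coverage = np.full_like(levels, float(depth))
    p_raw = binom.sf(k - 1, depth, error_rate)
    p_raw[k == 0] = 1.0
    signif = np.zeros_like(levels, dtype=bool)
    for j in range(len(sample_ids)):
        p_adj = np.array(bh_adjust(p_raw[:, j]))
        signif[:, j] = (levels[:, j] >= min_level) & (k[:, j] >= min_reads) & (p_adj < alpha)

    idx = pd.Index(names)
    cols = pd.Index(sample_ids)
    lv = pd.DataFrame(levels, index=idx, columns=cols)
    return CohortMatrix(
        levels=lv,
        coverage=pd.DataFrame(coverage, index=idx, columns=cols),
        support=pd.DataFrame(k, index=idx, columns=cols),
        significant=pd.DataFrame(signif, index=idx, columns=cols),
        tptm=lv * 1e7 / depth,
        groups=groups,
        site_meta=None,
    )


@dataclass
class ParClipPlan:
    """Layout of a synthetic PAR-CLIP experiment over random transcripts."""

    n_transcripts: int = 12
    tx_length: int = 300
    read_length: int = 30
    reads_per_cluster: int = 20
    conversion_rate: float = 0.5
    planted: list = field(default_factory=list)  # (tx_idx, variant_name, match_class)
    background_per_tx: int = 1
    non_coding: tuple[int, ...] = ()


def _scrub_motifs(rng, seq: list[str], motifs6: list[str], motifs8: list[str],
                  core: set[int], flank: set[int]) -> None:
    """Remove chance seed matches so the planted truth is exact.

    ``core`` indices are planted motif bases and are never mutated; ``flank``
    marks the searchable neighbourhood of planted sites. Any 6mer occurrence
    outside the flank is destroyed, and any 8mer occurrence anywhere whose
    span is not fully inside a planted core is destroyed by mutating one of
    its non-core bases (a shifted-register 8mer always overhangs the core,
    so such a base exists).
    """
    for _ in range(20):
        text = "".join(seq)
        dirty = False
        for motif in motifs6:
            start = 0
            while True:
                k = text.find(motif, start)
                if k < 0:
                    break
                span = range(k, k + len(motif))
                if not any(j in flank for j in span):
                    j = int(rng.choice([j for j in span if j not in core]))
                    seq[j] = _other_base(rng, seq[j])
                    dirty = True
                start = k + 1
        text = "".join(seq)
        for motif in motifs8:
            start = 0
            while True:
                k = text.find(motif, start)
                if k < 0:
                    break
                span = range(k, k + len(motif))
                free = [j for j in span if j not in core]
                if free:
                    j = int(rng.choice(free))
                    seq[j] = _other_base(rng, seq[j])
                    dirty = True
                start = k + 1
        if not dirty:
            return


def simulate_parclip(variants, plan: ParClipPlan, seed: int):
    """Crosslink reads over synthetic transcripts with planted seed-match sites.

    ``variants`` is a list of MatureVariant; ``plan.planted`` places the
    reverse complement of a variant's seed (8mer, or the shorter classes) at
    the centre of a transcript, with a read pile-up over it. Chance seed
    matches of any listed variant elsewhere are scrubbed so the planted
    truth is exact. Each read converts each template T to C independently at
    the conversion rate. Returns (mrnas, reads, gene_table, truth).
    """
    from .align import revcomp as _rc

    rng = np.random.default_rng(seed)
    by_name = {v.name: v for v in variants}
    motifs6 = sorted({_rc(v.seed[1:7]) for v in variants})
    motifs8 = sorted({_rc(v.seed[0:8]) for v in variants})

    mrnas: dict[str, list[str]] = {}
    core: dict[str, set[int]] = {}
    flank: dict[str, set[int]] = {}
    for i in range(plan.n_transcripts):
        mrnas[f"tx{i:02d}"] = list(_random_seq(rng, plan.tx_length))
        core[f"tx{i:02d}"] = set()
        flank[f"tx{i:02d}"] = set()

    truth_rows = []
    site_pos: dict[str, list[int]] = {m: [] for m in mrnas}
    for tx_idx, variant_name, match_class in plan.planted:
        v = by_name[variant_name]
        if match_class == "8mer":
            motif = _rc(v.seed[0:8])
        elif match_class == "7mer":
            motif = _rc(v.seed[1:8])
        else:
            motif = _rc(v.seed[1:7])
        tid = f"tx{tx_idx:02d}"
        pos = plan.tx_length // 2  # 1-based motif start
        seq = mrnas[tid]
        seq[pos - 1 : pos - 1 + len(motif)] = list(motif)
        core[tid].update(range(pos - 1, pos - 1 + len(motif)))
        flank[tid].update(range(pos - 1 - 8, pos - 1 + len(motif) + 8))
        site_pos[tid].append(pos)
        truth_rows.append(
            {
                "transcript": tid,
                "gene": f"G{tx_idx:02d}",
                "variant": variant_name,
                "pos": pos,
                "match_class": match_class,
            }
        )
    for tid, seq in mrnas.items():
        _scrub_motifs(rng, seq, motifs6, motifs8, core[tid], flank[tid])
    mrnas_str = {tid: "".join(seq) for tid, seq in mrnas.items()}

    reads = []
    n = 0

    def emit_pile(tid: str, center: int, n_reads: int):
        nonlocal n
        seq = mrnas_str[tid]
        m = plan.read_length
        for _ in range(n_reads):
            lo = max(0, center - m + 4)
            hi = min(len(seq) - m, center - 4)
            start0 = int(rng.integers(lo, max(lo + 1, hi + 1)))
            bases = list(seq[start0 : start0 + m])
            for k, b in enumerate(bases):
                if b == "T" and rng.random() < plan.conversion_rate:
                    bases[k] = "C"
            reads.append(
                ReadRecord(id=f"pc{n:05d}", seq="".join(bases), qual=(40,) * m)
            )
            n += 1

    for tid, positions in site_pos.items():
        for pos in positions:
            emit_pile(tid, pos + 3, plan.reads_per_cluster)
    for i, tid in enumerate(mrnas_str):
        for _ in range(plan.background_per_tx):
            center = int(rng.integers(plan.read_length, plan.tx_length // 3))
            emit_pile(tid, center, plan.reads_per_cluster)

    gene_table = pd.DataFrame(
        {
            "transcript_id": list(mrnas_str),
            "gene_id": [f"G{i:02d}" for i in range(plan.n_transcripts)],
            "coding": [i not in plan.non_coding for i in range(plan.n_transcripts)],
        }
    )
    return mrnas_str, reads, gene_table, pd.DataFrame(truth_rows)


def default_spec(group_sizes: dict[str, int] | None = None,
                 depth: int = 1000) -> SimulationSpec:
    """A representative study plan covering every planted event category."""
    lv = lambda a, b: {"HD-PC": a, "PC": b}  # noqa: E731
    return SimulationSpec(
        n_precursors=10,
        depth=depth,
        group_sizes=group_sizes or {"HD-PC": 28, "PC": 38},
        events=[
            PlannedEvent(0, "5p", "central", "g", lv(0.2, 0.2), offset=10, ref="A"),
            PlannedEvent(1, "5p", "central", "t", lv(0.3, 0.3), offset=12, ref="C"),
            PlannedEvent(2, "3p", "central", "c", lv(0.25, 0.25), offset=8, ref="G"),
            PlannedEvent(3, "5p", "tail3", "a", lv(0.4, 0.1)),
            PlannedEvent(4, "3p", "tail3", "t", lv(0.3, 0.3)),
            PlannedEvent(5, "5p", "tail3", "g", lv(0.3, 0.3)),
            PlannedEvent(6, "3p", "add5", "c", lv(0.35, 0.1)),
            PlannedEvent(7, "5p", "deletion", "-", lv(0.3, 0.3), offset=11),
            PlannedEvent(8, "5p", "central", "g", lv(0.5, 0.5), offset=9, ref="A",
                         decoy=True),
        ],
        snps=[PlannedSnp(9, "5p", 7, "g"), PlannedSnp(3, "3p", 5, "a")],
        copy_decoys=[(1, "3p", 0)],
    )


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.id}\n{r.seq}\n+\n"
                + "".join(chr(q + 33) for q in r.qual)
                + "\n"
            )


def write_reference(reference: Reference, outdir) -> None:
    """Write genome/precursor FASTA, annotation, SNP table and truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in reference.genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    write_precursors(
        reference.precursors,
        os.path.join(outdir, "precursors.fa"),
        os.path.join(outdir, "annotation.tsv"),
    )
    write_snps(reference.snp_records, os.path.join(outdir, "snps.tsv"))
    reference.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def write_cohort(reference: Reference, master_seed: int, outdir):
    """Materialise a full cohort (FASTQ per sample + sample sheet) on disk."""
    import os

    groups, reads_by_sample, _ = simulate_cohort(reference, master_seed)
    os.makedirs(outdir, exist_ok=True)
    write_reference(reference, outdir)
    for sid, reads in reads_by_sample.items():
        write_fastq(reads, os.path.join(outdir, f"{sid}.fastq"))
    write_sample_sheet(groups, os.path.join(outdir, "samples.tsv"))
    return groups
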