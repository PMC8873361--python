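"""Readers, writers and domain records for every external file the pipeline touches.

Sequences are held internally in the DNA alphabet (``U`` mapped to ``T`` on
ingest) so comparison against the genome is uniform; site names and any
RNA-sourced output are emitted back in the RNA alphabet. All precursor
coordinates are 1-based inclusive, so position 26 of ``hsa-mir-10b_26_A_c``
is the 26th base of the hairpin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureArm",
    "Precursor",
    "ReadRecord",
    "SnpRecord",
    "load_precursors",
    "write_precursors",
    "load_reads",
    "collapse_reads",
    "quality_filter",
    "parse_site_name",
    "format_site_name",
    "write_site_table",
    "read_site_table",
    "SITE_TABLE_COLUMNS",
    "load_snps",
    "write_snps",
    "read_sample_sheet",
    "write_sample_sheet",
    "DELETION_SYMBOL",
]

#: alt symbol used for a deleted base in site names
DELETION_SYMBOL = "-"

_RNA2DNA = str.maketrans("Uu", "Tt")
_DNA2RNA = str.maketrans("Tt", "Uu")


def rna_to_dna(seq: str) -> str:
    return seq.translate(_RNA2DNA)


def dna_to_rna(seq: str) -> str:
    return seq.translate(_DNA2RNA)


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA product located on its hairpin (1-based inclusive)."""

    name: str
    p_start: int
    p_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.p_start < self.p_end):
            raise ValueError(
                f"arm {self.name}: invalid interval {self.p_start}..{self.p_end}"
            )
        if self.p_end - self.p_start + 1 < 18:
            raise ValueError(f"arm {self.name}: mature arms must span >= 18 nt")

    @property
    def length(self) -> int:
        return self.p_end - self.p_start + 1


@dataclass(frozen=True)
class Precursor:
    """A pre-miRNA hairpin with its genomic locus and mature arm coordinates.

    ``seq`` is stored uppercase DNA; ``source_alphabet`` remembers whether the
    FASTA used U so the sequence can be emitted back unchanged.
    """

    id: str
    seq: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    arms: tuple[MatureArm, ...] = field(default_factory=tuple)
    source_alphabet: str = "dna"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", rna_to_dna(self.seq.upper()))
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -, got {self.strand!r}")
        if self.g_end - self.g_start + 1 != len(self.seq):
            raise ValueError(
                f"{self.id}: genomic span {self.g_start}..{self.g_end} does not "
                f"match sequence length {len(self.seq)}"
            )
        for arm in self.arms:
            if arm.p_end > len(self.seq):
                raise ValueError(
                    f"{self.id}: arm {arm.name} end {arm.p_end} exceeds "
                    f"precursor length {len(self.seq)}"
                )
        spans = sorted((a.p_start, a.p_end) for a in self.arms)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.id}: mature arm intervals overlap")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, p_pos: int) -> str:
        """Template base at 1-based precursor position, '-' outside the hairpin."""
        if 1 <= p_pos <= len(self.seq):
            return self.seq[p_pos - 1]
        return "-"

    def genomic_position(self, p_pos: int) -> int:
        """Genomic coordinate of a precursor position, honouring strand."""
        if self.strand == "+":
            return self.g_start + p_pos - 1
        return self.g_end - p_pos + 1


@dataclass(frozen=True)
class ReadRecord:
    """One (possibly collapsed) small-RNA read with Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", rna_to_dna(self.seq.upper()))
        object.__setattr__(self, "qual", tuple(self.qual))
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1")


@dataclass(frozen=True)
class SnpRecord:
    """A known single-nucleotide polymorphism (plus-strand alleles)."""

    rsid: str
    chrom: str
    g_pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


_ANNO_COLUMNS = [
    "precursor_id",
    "chrom",
    "start",
    "end",
    "strand",
    "arm_name",
    "arm_start",
    "arm_end",
]


def load_precursors(fasta_path, annotation_path) -> list[Precursor]:
    """Load hairpins from a FASTA plus a TSV of genomic loci and arm coordinates.

    The annotation has one row per mature arm with columns
    ``precursor_id, chrom, start, end, strand, arm_name, arm_start, arm_end``.
    Every FASTA record must be annotated; every invariant violation is a hard
    error naming the offending precursor.
    """
    anno = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in _ANNO_COLUMNS if c not in anno.columns]
    if missing_cols:
        raise ValueError(f"annotation is missing columns: {missing_cols}")
    by_id = dict(tuple(anno.groupby("precursor_id", sort=False)))

    precursors = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rows = by_id.get(rec.id)
        if rows is None:
            raise ValueError(f"no annotation for FASTA record {rec.id!r}")
        raw = str(rec.seq)
        alphabet = "rna" if ("U" in raw.upper()) else "dna"
        first = rows.iloc[0]
        arms = tuple(
            MatureArm(r.arm_name, int(r.arm_start), int(r.arm_end))
            for r in rows.itertuples()
        )
        precursors.append(
            Precursor(
                id=rec.id,
                seq=raw,
                chrom=str(first.chrom),
                g_start=int(first.start),
                g_end=int(first.end),
                strand=str(first.strand),
                arms=arms,
                source_alphabet=alphabet,
            )
        )
    return precursors


def write_precursors(precursors, fasta_path, annotation_path) -> None:
    """Inverse of :func:`load_precursors` (sequences re-emitted per source alphabet)."""
    with open(fasta_path, "w") as fh:
        for p in precursors:
            seq = dna_to_rna(p.seq) if p.source_alphabet == "rna" else p.seq
            fh.write(f">{p.id}\n{seq}\n")
    rows = []
    for p in precursors:
        for arm in p.arms:
            rows.append(
                (p.id, p.chrom, p.g_start, p.g_end, p.strand, arm.name, arm.p_start, arm.p_end)
            )
    pd.DataFrame(rows, columns=_ANNO_COLUMNS).to_csv(annotation_path, sep="\t", index=False)


def load_reads(fastq_path) -> list[ReadRecord]:
    """Read a Phred+33 FASTQ into uncollapsed single-count records."""
    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        reads.append(
            ReadRecord(
                id=rec.id,
                seq=str(rec.seq),
                qual=tuple(rec.letter_annotations["phred_quality"]),
                count=1,
            )
        )
    return reads


def collapse_reads(reads) -> list[ReadRecord]:
    """Merge identical sequences, summing counts; first-seen id and qualities kept."""
    merged: dict[str, ReadRecord] = {}
    for r in reads:
        prev = merged.get(r.seq)
        if prev is None:
            merged[r.seq] = r
        else:
            merged[r.seq] = replace(prev, count=prev.count + r.count)
    return list(merged.values())


def quality_filter(reads, q_min: int = 30, span: int = 25, len_min: int = 18):
    """Quality- and length-screen reads, then collapse identical survivors.

    A read is kept when every one of its first ``span`` bases (all bases for
    shorter reads) has quality >= ``q_min`` and its length strictly exceeds
    ``len_min``. Identical surviving sequences are collapsed with summed counts,
    which makes the operation idempotent.
    """
    kept = []
    for r in reads:
        if len(r.seq) <= len_min:
            continue
        if any(q < q_min for q in r.qual[:span]):
            continue
        kept.append(r)
    return collapse_reads(kept)


_SITE_RE = re.compile(r"^(?P<prec>.+)_(?P<pos>\d+)_(?P<ref>[ACGTU-])_(?P<alt>[acgtu-])$")


def parse_site_name(name: str) -> tuple[str, int, str, str]:
    """Split ``<precursor>_<pos>_<REF>_<alt>`` into its components.

    Returns DNA-normalised bases (``U``/``u`` mapped to ``T``/``t``); the
    reference is uppercase, the variant lowercase or ``-`` for a deletion.
    """
    m = _SITE_RE.match(name)
    if m is None:
        raise ValueError(f"malformed site name: {name!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise ValueError(f"malformed site name (position {pos}): {name!r}")
    return (
        m.group("prec"),
        pos,
        rna_to_dna(m.group("ref")),
        rna_to_dna(m.group("alt")),
    )


def format_site_name(precursor_id: str, pos: int, ref: str, alt: str) -> str:
    """Inverse of :func:`parse_site_name`; bases are emitted in the RNA alphabet."""
    return f"{precursor_id}_{pos}_{dna_to_rna(ref.upper())}_{dna_to_rna(alt.lower())}"


#: stable column order of the per-sample site report
SITE_TABLE_COLUMNS = [
    "name",
    "precursor",
    "position",
    "ref",
    "alt",
    "category",
    "region",
    "coverage",
    "edited_weight",
    "level",
    "p_raw",
    "p_adj",
    "tptm",
    "support",
]


def _fmt6(x: float) -> str:
    return f"{float(x):.6g}"


def write_site_table(sites, path) -> None:
    """Write site calls as TSV with floats at 6 significant digits.

    Re-reading with :func:`read_site_table` reproduces every field at the
    written precision; an empty list yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.name,
                        s.precursor_id,
                        str(s.p_pos),
                        dna_to_rna(s.ref_base),
                        dna_to_rna(s.alt_symbol),
                        s.category,
                        s.region,
                        _fmt6(s.coverage_weight),
                        _fmt6(s.edited_weight),
                        _fmt6(s.level),
                        _fmt6(s.p_raw),
                        _fmt6(s.p_adj),
                        _fmt6(s.tptm),
                        str(s.edited_read_count),
                    ]
                )
                + "\n"
            )


def read_site_table(path) -> list:
    """Inverse of :func:`write_site_table`."""
    from .site_calling import SiteCall  # deferred: SiteCall lives with the caller

    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_TABLE_COLUMNS:
            raise ValueError(f"unexpected site table header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                SiteCall(
                    name=f[0],
                    precursor_id=f[1],
                    p_pos=int(f[2]),
                    ref_base=rna_to_dna(f[3]),
                    alt_symbol=rna_to_dna(f[4]),
                    category=f[5],
                    region=f[6],
                    coverage_weight=float(f[7]),
                    edited_weight=float(f[8]),
                    level=float(f[9]),
                    p_raw=float(f[10]),
                    p_adj=float(f[11]),
                    tptm=float(f[12]),
                    edited_read_count=int(f[13]),
                )
            )
    return sites


def load_snps(tsv_path) -> list[SnpRecord]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    return [
        SnpRecord(str(r.rsid), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]


def write_snps(snps, tsv_path) -> None:
    pd.DataFrame(
        [(s.rsid, s.chrom, s.g_pos, s.ref_allele, s.alt_allele) for s in snps],
        columns=["rsid", "chrom", "pos", "ref", "alt"],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_sample_sheet(tsv_path) -> dict[str, str]:
    """Sample sheet TSV (sample_id, group) -> ordered mapping."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dupes}")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_sheet(groups: dict[str, str], tsv_path) -> None:
    pd.DataFrame(groups.items(), columns=["sample_id", "group"]).to_csv(
        tsv_path, sep="\t", index=False
    )
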