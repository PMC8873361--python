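"""Cohort-level aggregation and annotation of per-sample M/E site calls.

Per-sample calls are merged into a sites x samples matrix, screened for
prevalence (a site must reach significance in enough samples to rule out
recurrent sequencing error), and annotated: known-SNP overlap, pseudo sites
whose supporting reads are templated products of another genomic locus, and
cross-species conservation of the editing type at the same mature position.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import Precursor, SnpRecord, dna_to_rna
from .stats import percentage

__all__ = [
    "CohortMatrix",
    "CategorySummary",
    "aggregate",
    "prevalence_threshold",
    "prevalence_filter",
    "annotate_snps",
    "flag_pseudo",
    "annotate_conservation",
    "category_summary",
    "neighbor_base_distribution",
    "end_edit_distribution",
]


@dataclass
class CohortMatrix:
    """Editing levels, coverage, support and significance across a cohort.

    Rows are site names, columns sample ids. ``levels`` holds the per-sample
    editing level wherever the variant was observed at all (NaN otherwise);
    ``coverage`` the weighted position coverage regardless of observation;
    ``significant`` whether the per-sample call passed all criteria. A row
    exists iff the site was significant in at least one sample.
    """

    levels: pd.DataFrame
    coverage: pd.DataFrame
    support: pd.DataFrame
    significant: pd.DataFrame
    tptm: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    site_meta: pd.DataFrame | None = None  # per-site precursor/position/category

    @property
    def site_names(self) -> list[str]:
        return list(self.levels.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.columns)

    def subset(self, names) -> "CohortMatrix":
        names = list(names)
        return CohortMatrix(
            levels=self.levels.loc[names],
            coverage=self.coverage.loc[names],
            support=self.support.loc[names],
            significant=self.significant.loc[names],
            tptm=self.tptm.loc[names],
            groups=dict(self.groups),
            site_meta=None if self.site_meta is None else self.site_meta.loc[names],
        )


def aggregate(samples, groups: dict[str, str] | None = None) -> CohortMatrix:
    """Merge per-sample calls (mapping sample_id -> SampleCalls) into a matrix.

    Site identity is the full site name. Cells carry each sample's level even
    where the site was insignificant there, which the differential tests need.
    """
    sample_ids = list(samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    row_names: list[str] = []
    meta_rows = {}
    for sid in sample_ids:
        for s in samples[sid].significant:
            if s.name not in meta_rows:
                row_names.append(s.name)
            meta_rows.setdefault(
                s.name,
                {
                    "precursor": s.precursor_id,
                    "position": s.p_pos,
                    "ref": s.ref_base,
                    "alt": s.alt_symbol,
                    "region": s.region,
                    "category": s.category,
                },
            )

    shape = (len(row_names), len(sample_ids))
    levels = pd.DataFrame(np.nan, index=row_names, columns=sample_ids)
    coverage = pd.DataFrame(np.nan, index=row_names, columns=sample_ids)
    support = pd.DataFrame(np.zeros(shape), index=row_names, columns=sample_ids)
    signif = pd.DataFrame(np.zeros(shape, dtype=bool), index=row_names, columns=sample_ids)
    tptm = pd.DataFrame(np.nan, index=row_names, columns=sample_ids)
    wanted = set(row_names)

    for sid in sample_ids:
        calls = samples[sid]
        for s, is_sig in [(x, True) for x in calls.significant] + [
            (x, False) for x in calls.insignificant
        ]:
            if s.name not in wanted:
                continue
            levels.at[s.name, sid] = s.level
            support.at[s.name, sid] = s.edited_read_count
            signif.at[s.name, sid] = is_sig
            tptm.at[s.name, sid] = s.tptm
        for name in row_names:
            m = meta_rows[name]
            cov = calls.coverage.get((m["precursor"], m["position"]))
            if cov is not None:
                coverage.at[name, sid] = cov
    return CohortMatrix(
        levels=levels,
        coverage=coverage,
        support=support,
        significant=signif,
        tptm=tptm,
        groups=dict(groups or {}),
        site_meta=pd.DataFrame.from_dict(meta_rows, orient="index").reindex(row_names),
    )


def prevalence_threshold(n_samples: int, fraction: float = 0.07) -> int:
    """Minimum number of significant samples a site must reach (ceil, >= 1)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return max(1, math.ceil(n_samples * fraction - 1e-9))


def prevalence_filter(matrix: CohortMatrix, fraction: float = 0.07) -> CohortMatrix:
    """Keep rows significant in at least ``prevalence_threshold`` samples."""
    thr = prevalence_threshold(len(matrix.sample_ids), fraction)
    keep = matrix.significant.sum(axis=1) >= thr
    return matrix.subset(matrix.significant.index[keep])


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def annotate_snps(sites, snps, matrix: CohortMatrix, precursors):
    """Relabel called substitutions that are actually known polymorphisms.

    A site becomes category ``SNP`` when (i) its genomic position equals a
    SNP-table entry, (ii) both alleles match (reverse-complemented for minus
    strand hairpins, since SNP tables report plus-strand alleles), and
    (iii) its level reaches 100% in at least one sample of the cohort.
    """
    prec_by_id = {p.id: p for p in precursors}
    snp_index = {}
    for s in snps:
        snp_index.setdefault((s.chrom, s.g_pos), []).append(s)

    out = []
    for site in sites:
        if site.alt_symbol == "-" or site.ref_base == "-":
            out.append(site)
            continue
        prec = prec_by_id[site.precursor_id]
        if not (1 <= site.p_pos <= len(prec.seq)):
            if site.region == "central":
                raise ValueError(
                    f"{site.name}: central site outside precursor genomic span"
                )
            out.append(site)  # virtual tail position, cannot be genomic
            continue
        g_pos = prec.genomic_position(site.p_pos)
        ref, alt = site.ref_base.upper(), site.alt_symbol.upper()
        if prec.strand == "-":
            ref = ref.translate(_COMP)
            alt = alt.translate(_COMP)
        hit = False
        for snp in snp_index.get((prec.chrom, g_pos), []):
            if snp.ref_allele == ref and snp.alt_allele == alt:
                hit = True
                break
        if hit and site.name in matrix.levels.index:
            max_level = matrix.levels.loc[site.name].max(skipna=True)
            if max_level >= 1.0 - 1e-9:
                out.append(replace(site, category="SNP"))
                continue
        out.append(site)
    return out


def flag_pseudo(sites, samples, precursors, threshold: float = 0.5):
    """Flag sites whose edited reads are templated products of another locus.

    For each site the weighted mass of its supporting reads is split into
    mass explainable elsewhere (the read has a perfect genomic hit outside
    its own hairpin locus) and the rest; strictly more than ``threshold`` of
    explainable mass flags the site ``pseudo``. ``samples`` maps sample id to
    SampleCalls (alignments and genomic hits must have been kept).
    """
    prec_by_id = {p.id: p for p in precursors}
    edited_mass: dict[str, float] = defaultdict(float)
    foreign_mass: dict[str, float] = defaultdict(float)
    keys = {(s.precursor_id, s.p_pos, s.alt_symbol): s.name for s in sites}

    for calls in samples.values():
        perfect_elsewhere: dict[str, bool] = {}
        for h in calls.hits:
            if h.mismatches != 0:
                continue
            prec_loci = []
            for p in precursors:
                if h.chrom == p.chrom and p.g_start - 3 <= h.g_pos <= p.g_end + 3:
                    prec_loci.append(p.id)
            if not prec_loci:
                perfect_elsewhere[h.read_id] = True
        for aln in calls.alignments:
            for op in aln.ops:
                alt = op.alt_base.lower() if op.alt_base != "-" else "-"
                name = keys.get((aln.precursor_id, op.p_pos, alt))
                if name is None:
                    continue
                mass = aln.weight * aln.count
                edited_mass[name] += mass
                if perfect_elsewhere.get(aln.read_id, False):
                    foreign_mass[name] += mass

    out = []
    for site in sites:
        total = edited_mass.get(site.name, 0.0)
        if total > 0 and foreign_mass.get(site.name, 0.0) > threshold * total:
            out.append(replace(site, category="pseudo"))
        else:
            out.append(site)
    return out


def annotate_conservation(sites, precursors, species_tables):
    """Flag sites whose editing type recurs at the same mature position elsewhere.

    ``species_tables`` is a list of ``(species, entries)`` where each entry is
    ``(arm_name, mature_pos, category)`` with the position 1-based relative to
    the mature miRNA 5' end. A site is conserved when at least one other
    species shows the same category at the same mature position of the same
    arm. Sites outside any arm are never conserved.
    """
    prec_by_id = {p.id: p for p in precursors}
    lookup = defaultdict(set)
    for species, entries in species_tables:
        for arm_name, mature_pos, category in entries:
            lookup[(arm_name, mature_pos, category)].add(species)

    flags = {}
    for site in sites:
        prec = prec_by_id[site.precursor_id]
        conserved = False
        for arm in prec.arms:
            if arm.p_start <= site.p_pos <= arm.p_end:
                mature_pos = site.p_pos - arm.p_start + 1
                if lookup.get((arm.name, mature_pos, site.category)):
                    conserved = True
                break
        flags[site.name] = conserved
    return flags


@dataclass(frozen=True)
class CategorySummary:
    """Per-category site counts with display percentages (one decimal)."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def category_summary(sites_or_counts) -> CategorySummary:
    """Count sites per category; percentages at one decimal, half away from zero.

    Accepts either a list of site calls or a ready mapping category -> count
    (so printed count tables can be summarised directly).
    """
    if isinstance(sites_or_counts, dict):
        counts = dict(sites_or_counts)
    else:
        counts = defaultdict(int)
        for s in sites_or_counts:
            counts[s.category] += 1
        counts = dict(counts)
    total = sum(counts.values())
    if total == 0:
        return CategorySummary({}, {}, 0)
    pct = {c: percentage(n, total, 1) for c, n in counts.items()}
    return CategorySummary(counts, pct, total)


def neighbor_base_distribution(sites, precursors, category: str):
    """Base frequencies immediately 5' and 3' of edited positions of one category.

    Returns ``(freq5, freq3, skipped)`` with bases in the RNA alphabet;
    ``skipped`` counts boundary sites whose flanking base fell outside the
    hairpin on that side.
    """
    prec_by_id = {p.id: p for p in precursors}
    side5: dict[str, int] = defaultdict(int)
    side3: dict[str, int] = defaultdict(int)
    skipped = {"5": 0, "3": 0}
    for s in sites:
        if s.category != category:
            continue
        prec = prec_by_id[s.precursor_id]
        b5 = prec.base(s.p_pos - 1)
        b3 = prec.base(s.p_pos + 1)
        if b5 == "-":
            skipped["5"] += 1
        else:
            side5[dna_to_rna(b5)] += 1
        if b3 == "-":
            skipped["3"] += 1
        else:
            side3[dna_to_rna(b3)] += 1

    def norm(d):
        tot = sum(d.values())
        return {b: n / tot for b, n in sorted(d.items())} if tot else {}

    return norm(side5), norm(side3), skipped


def end_edit_distribution(sites, precursors):
    """Histogram of edited-position multiplicity per hairpin and region class.

    Returns ``{region: {k: n_precursors}}`` for region in (end5, end3,
    central): the number of hairpins carrying exactly k distinct edited
    positions in that region.
    """
    per_prec: dict[str, dict[str, set]] = defaultdict(
        lambda: {"end5": set(), "end3": set(), "central": set()}
    )
    for s in sites:
        if s.region in ("end5", "end3", "central"):
            per_prec[s.precursor_id][s.region].add(s.p_pos)
    hist = {"end5": defaultdict(int), "end3": defaultdict(int), "central": defaultdict(int)}
    for counts in per_prec.values():
        for region, positions in counts.items():
            if positions:
                hist[region][len(positions)] += 1
    return {r: dict(h) for r, h in hist.items()}
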