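"""End-to-end orchestration: per-sample calling, cohort assembly, annotation."""

from __future__ import annotations

from .cohort import aggregate, annotate_snps, flag_pseudo, prevalence_filter
from .site_calling import call_sample

__all__ = ["run_cohort"]


def run_cohort(reads_by_sample: dict, groups: dict, precursors, genome=None,
               snps=None, prevalence_fraction: float = 0.07,
               keep_alignments: bool = True, **call_kwargs):
    """Call every sample, aggregate, prevalence-filter and annotate the cohort.

    Returns ``(matrix, samples)`` where ``matrix`` is the prevalence-filtered
    cohort matrix with SNP and pseudo relabelling applied to its site
    metadata, and ``samples`` maps sample id to the per-sample calls.
    """
    samples = {
        sid: call_sample(
            reads,
            precursors,
            genome=genome,
            sample_id=sid,
            keep_alignments=keep_alignments,
            **call_kwargs,
        )
        for sid, reads in reads_by_sample.items()
    }
    matrix = aggregate(samples, groups)
    matrix = prevalence_filter(matrix, prevalence_fraction)

    # one representative call per retained site, for annotation and reporting
    rep = {}
    for calls in samples.values():
        for s in calls.significant:
            if s.name in matrix.levels.index and s.name not in rep:
                rep[s.name] = s
    sites = [rep[name] for name in matrix.site_names]
    if snps:
        sites = annotate_snps(sites, snps, matrix, precursors)
    if genome is not None and keep_alignments:
        sites = flag_pseudo(sites, samples, precursors)
    if matrix.site_meta is not None:
        matrix.site_meta = matrix.site_meta.copy()
        for s in sites:
            matrix.site_meta.at[s.name, "category"] = s.category
    return matrix, samples
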