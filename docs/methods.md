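# Methods

## Model and procedure

`editome` treats a miRNA mutation/editing (M/E) site as a hairpin position
where aligned reads systematically deviate from the templated base. The
per-sample procedure is:

1. **Quality screen.** A read is kept when each of its first 25 bases has
   Phred quality ≥ 30 and its length exceeds 18 nt; identical survivors are
   collapsed with summed counts. The 25-base window (rather than the whole
   read) reflects that the 3' end of short RNA reads carries adapter- and
   tail-derived sequence; the screen is idempotent by construction.
2. **Hairpin placement.** A windowed exact/near-exact comparison places each
   unique read on every hairpin, scoring placements by (internal edits,
   indel count, −templated matches) and keeping all tied best placements
   with initial weight 1/n. Besides internal substitutions the aligner
   models a contiguous non-templated 3' run of ≤ 3 nt (`tail3`), ≤ 2 extra
   5' bases immediately upstream of a mature arm (`add5`), and — only for
   reads with no ungapped placement — a single-base insertion or deletion.
   Indels in homopolymers are reported left-aligned.
3. **Genome check and cross-mapping correction.** Reads are searched against
   the genome exhaustively at ≤ 1 mismatch (both strands). A multi-mapped
   read's weight at locus L is iterated to expression(L)/Σ expression(loci),
   where expression counts only perfect-match read mass, until the largest
   change is < 1e-6 (≤ 50 sweeps). If no candidate locus has perfect
   expression the read keeps uniform weights. At the fixed point a shared
   read's split equals the ratio of perfect-match expressions regardless of
   its own contribution (w·Σc = c_l has a unique solution), which the test
   suite uses as a closed-form oracle.
4. **Tally and test.** Weighted masses are accumulated per position; each
   observed alternative symbol becomes a candidate site with level
   m_alt/m_cov and a one-sided binomial tail p-value at
   p_err = 10^(−Q/10) = 1e-3, evaluated on rounded integer masses.
   Benjamini–Hochberg correction is applied per sample over all candidates.
   Significance requires level ≥ 5%, raw read support ≥ 10 and adjusted
   p < 0.05; support uses raw counts (guarding against phantom fractional
   evidence) while levels use weights (handling multi-mapping).
5. **Cohort stage.** Calls are merged on full site names; rows must be
   significant in ≥ ⌈0.07·n⌉ samples (8 of 111 in the study design —
   ceiling reproduces that printed threshold). SNP relabelling requires a
   position/allele match against the SNP table (alleles
   reverse-complemented for minus-strand hairpins, since SNP tables report
   plus-strand alleles) and a 100% level in ≥ 1 sample. A site is *pseudo*
   when strictly more than half of its edited read mass has a perfect
   genomic hit outside its own hairpin locus — i.e. the "edited" read is
   another locus's templated product. This operationalisation is this
   package's own; the class is conventionally reported but rarely defined.
6. **Differential testing.** Editing levels per site are compared between
   groups with a two-sided Mann–Whitney U test: exact permutation
   enumeration (midranks, ties included) when the pooled size is ≤ 12,
   otherwise the normal approximation with tie-corrected variance and
   continuity correction. Missing cells count as level 0 when the position
   was covered by ≥ 10 weighted reads in that sample (callable-zero) and
   are excluded otherwise, so prevalence-passing sites keep full group
   sizes. FDR is BH over all tested sites; summaries report both tiers
   (raw p < α and FDR < α) with direction percentages at two decimals.
7. **Retargeting.** An edit applied to a mature arm yields the edited
   variant (5' addition prepends and shifts the seed register; A-to-I
   renders as G), named `<hairpin>_<pos><alt>`. PAR-CLIP reads are aligned
   to transcripts with T-to-C conversions not counted as mismatches
   (≤ 1 other mismatch), overlapping reads merge into clusters, and
   clusters with ≥ 1 diagnostic T-to-C read are searched (± 10 nt flank —
   crosslinks sit near, not on, the complementary site) for reverse
   complements of the seed: 8mer (positions 1–8), 7mer (2–8), 6mer (2–7).
   Each match gets p_s = 1 − (1 − Π f(b))^(W − m + 1), the chance of ≥ 1
   occurrence of the motif in an i.i.d. window with the cluster's base
   frequencies (quarter pseudocounts); p_s is anti-monotone in match
   length by construction. Target sets are collapsed to genes before set
   comparison; new-target prioritisation keeps deduplicated coding genes
   whose best cluster has ≥ 10 reads.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| q_min / span / len_min | 30 / 25 / 18 | Phred, nt | quality screen of the study protocol |
| max_sub (hairpin) | 2 | substitutions | see "numerical choices" below |
| max mismatch (genome) | 1 | mismatches | exhaustive -v 1-style search contract |
| tail3 / add5 caps | 3 / 2 | nt | observed single-base tails and 5' additions; caps bound ambiguity |
| p_err | 1e-3 | probability | error rate implied by the Q30 threshold |
| min_level / min_reads / alpha | 0.05 / 10 / 0.05 | — | significance criteria of the method |
| prevalence fraction | 0.07 | — | recurrent-error guard (8 of 111 samples) |
| cross-map tol / iters | 1e-6 / 50 | — | fixed-point convergence; deterministic |
| exact-MWU limit | 12 | pooled n | C(12,6)=924 enumerations is instant |
| seed flank | 10 | nt | cluster-to-seed-match distance |

## What the generator emulates — and what it does not

`synthetic.SimulationSpec` encodes the study conditions: a two-group cohort
(defaults 28 vs 38 samples, the disease/control prefrontal-cortex design),
reads drawn per mature arm at a set depth with 0–1 nt templated end jitter,
each planted event carried independently per read at its group's true level
(central substitutions, 3' tails and 5' additions on untrimmed ends,
deletions), homozygous SNPs at level 1.0 in carrier samples, i.i.d. per-base
errors at the Q30-implied rate with constant matching quality strings,
decoy genomic loci (exact/1-mismatch arm copies for cross-mapping; exact
copies of *edited* arms for pseudo sites), and crosslink read pile-ups with
per-template-T conversion. Deletions are planted in homopolymer-free
context so the left-aligned call matches the planned position. Everything
is deterministic under a fixed master seed (per-sample streams are spawned
from it).

Not emulated: realistic expression differences across miRNA families,
ligation bias, adapter read-through, quality-score decay along the read,
or genome-scale mapping ambiguity. Passing tests therefore demonstrate the
statistical machinery under the stated error model, not robustness to
library-preparation artefacts.

The generator also provides a read-free path (`simulate_cohort_matrix`)
that samples each cohort cell's edited count directly as Bin(depth, θ) —
exactly the distribution the read-level path induces at a central position
— and reproduces the per-sample significance criteria on those counts. The
type-I (200 null cohorts) and power checks use this path so hundreds of
cohort replicates stay cheap; the read-level path is validated separately
by the recovery and classification checks, which run the full pipeline.

## Numerical choices

- **Hairpin `max_sub` = 2.** With a 1-substitution cap, an edited read that
  also carries one ordinary sequencing error (≈ 2% of 22-nt reads at Q30)
  cannot be placed, which depletes edited mass but not coverage and biases
  levels down by ≈ the per-read error probability (measured: −2.2% relative
  at θ = 0.5). A BLAST-like local aligner places such reads; the strict
  1-mismatch contract belongs to the genome-wide search and is kept there.
- **Coverage for end positions.** A read contributes coverage to its own
  span plus one position beyond each end — the tailing/5'-addition
  opportunity. The level of a 3'-A site is then the fraction of arm reads
  actually tailed, not a ratio over tailed reads only, and planted end-edit
  levels are recovered on the same scale as central ones.
- **Exact MWU with ties.** The exact path enumerates group assignments of
  the pooled values with midranks, so tied level data (common: many exact
  zeros) get a genuine permutation p. Two-sided p = 2·min(tails), capped
  at 1; degenerate data (zero tie-corrected variance) gives p = 1.
- **Rounding for display.** Percentages round half away from zero — one
  decimal in category summaries, two in differential summaries — matching
  how such tables are conventionally printed.
- **Binomial test on rounded masses.** The test needs integers; weighted
  masses are rounded, which changes k by < 1 read and is negligible at the
  10-read support floor.
- **Register-discriminating target comparison.** A seed shifted by one 5'
  base retains the other register's 6mer (and its sites retain the shifted
  7mer) *by construction*, so original-vs-edited set comparisons are run at
  the 8mer tier (`predict_targets(..., min_class="8mer")`); the
  6mer/7mer tiers remain available for single-variant target scans.
- **Site names.** Emitted in the RNA alphabet (`U`, `u`), stored internally
  as DNA so genome comparison is uniform; parse/format is a bijection on
  valid names. Deletion alt symbol is `-`.

## Known limitations

- The pseudo-site rule (> 50% of edited mass perfectly explainable
  elsewhere) and the p_s background model are this package's own
  transparent constructions; the upstream tools they echo do not publish
  their exact formulas (the target module is labelled "MiCPAR-lite"
  accordingly).
- The hairpin aligner is exhaustive over ≤ a few hundred nt references and
  in-memory genomes of fixture scale; it is not a general-purpose
  short-read mapper.
- The continuity-corrected normal MWU p deviates from the exact permutation
  p by up to ≈ 0.0105 near p = 0.5 at n = 8/8; agreement is far tighter in
  the decision-relevant range (< 0.01 below p = 0.2).
- SNP annotation requires an exact 100% level in at least one sample; at
  very high coverage a carrier sample may show 99.9% through a single
  sequencing error, so cohorts with few carrier samples can under-call SNPs
  at extreme depth.
- Conservation annotation expects species tables already expressed in
  matched arm names and mature coordinates; no ortholog mapping or
  lift-over is attempted.
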