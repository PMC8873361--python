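"""Cohort matrix assembly, prevalence/SNP/pseudo/conservation annotation, summaries."""

import numpy as np
import pytest

from editome.cohort import (
    aggregate,
    annotate_conservation,
    annotate_snps,
    category_summary,
    end_edit_distribution,
    neighbor_base_distribution,
    prevalence_filter,
    prevalence_threshold,
)
from editome.io_formats import SnpRecord
from editome.site_calling import SampleCalls, SiteCall


def _site(name="mirX_52_A_g", level=0.2, prec="mirX", pos=52, ref="A", alt="g",
          region="central", category="A-to-I", reads=50):
    return SiteCall(
        name=name, precursor_id=prec, p_pos=pos, ref_base=ref, alt_symbol=alt,
        region=region, category=category, coverage_weight=reads / max(level, 1e-9),
        edited_weight=float(reads), edited_read_count=reads, level=level,
        p_raw=1e-9, p_adj=1e-8, tptm=10.0,
    )


def _calls(sid, sig=(), insig=(), coverage=None):
    return SampleCalls(
        sample_id=sid, significant=list(sig), insignificant=list(insig),
        sample_total=1e6, coverage=coverage or {}, log={},
    )


class TestAggregate:
    def test_shared_site_one_row_two_cells(self):
        s = _site()
        m = aggregate({"a": _calls("a", [s]), "b": _calls("b", [s])})
        assert m.site_names == ["mirX_52_A_g"]
        assert m.levels.notna().sum().sum() == 2

    def test_disjoint_sites_rows_add(self):
        m = aggregate(
            {
                "a": _calls("a", [_site("mirX_52_A_g")]),
                "b": _calls("b", [_site("mirX_60_C_u", pos=60, ref="C", alt="t")]),
            }
        )
        assert len(m.site_names) == 2

    def test_empty(self):
        m = aggregate({})
        assert m.site_names == [] and m.sample_ids == []

    def test_insignificant_levels_fill_cells(self):
        s = _site()
        weak = _site(level=0.01, reads=3)
        m = aggregate({"a": _calls("a", [s]), "b": _calls("b", [], [weak])})
        assert m.levels.at["mirX_52_A_g", "b"] == pytest.approx(0.01)
        assert not m.significant.at["mirX_52_A_g", "b"]


class TestPrevalence:
    @pytest.mark.parametrize(
        "n,frac,expected", [(111, 0.07, 8), (100, 0.07, 7), (1, 0.07, 1)]
    )
    def test_threshold(self, n, frac, expected):
        assert prevalence_threshold(n, frac) == expected

    def test_nonpositive_n_is_error(self):
        with pytest.raises(ValueError):
            prevalence_threshold(0)

    def _matrix(self, n_sig, n_samples):
        s = _site()
        samples = {}
        for i in range(n_samples):
            sid = f"s{i:03d}"
            samples[sid] = _calls(sid, [s] if i < n_sig else [], [s] if i >= n_sig else [])
        return aggregate(samples)

    def test_boundary_kept_and_dropped(self):
        kept = prevalence_filter(self._matrix(8, 111), 0.07)
        assert kept.site_names == ["mirX_52_A_g"]
        dropped = prevalence_filter(self._matrix(7, 111), 0.07)
        assert dropped.site_names == []

    def test_fraction_zero_is_identity(self):
        m = self._matrix(1, 20)
        assert prevalence_filter(m, 0.0).site_names == m.site_names

    def test_row_set_monotone_in_fraction(self):
        m = self._matrix(8, 111)
        prev = None
        for frac in (0.0, 0.05, 0.07, 0.2, 1.0):
            rows = set(prevalence_filter(m, frac).site_names)
            if prev is not None:
                assert rows <= prev
            prev = rows


class TestAnnotateSnps:
    def _fixture(self, toy_precursor, max_level, ref="A", alt="G", strand_prec=None):
        prec = strand_prec or toy_precursor
        site = _site(name="mirX_52_A_g", prec=prec.id)
        g_pos = prec.genomic_position(52)
        snp = SnpRecord("rs1", prec.chrom, g_pos, ref, alt)
        low = _site(level=max_level)
        m = aggregate({"a": _calls("a", [low])})
        return [site], [snp], m, [prec]

    def test_full_criteria_relabel(self, toy_precursor):
        sites, snps, m, precs = self._fixture(toy_precursor, 1.0)
        (out,) = annotate_snps(sites, snps, m, precs)
        assert out.category == "SNP"

    def test_level_below_one_not_snp(self, toy_precursor):
        sites, snps, m, precs = self._fixture(toy_precursor, 0.8)
        (out,) = annotate_snps(sites, snps, m, precs)
        assert out.category == "A-to-I"

    def test_swapped_alleles_not_snp(self, toy_precursor):
        sites, snps, m, precs = self._fixture(toy_precursor, 1.0, ref="G", alt="A")
        (out,) = annotate_snps(sites, snps, m, precs)
        assert out.category == "A-to-I"

    def test_minus_strand_alleles_reverse_complemented(self, toy_precursor):
        from dataclasses import replace

        minus = replace(toy_precursor, strand="-")
        # plus-strand table for an A>g change on a minus hairpin reads T>C
        sites, snps, m, precs = self._fixture(
            toy_precursor, 1.0, ref="T", alt="C", strand_prec=minus
        )
        (out,) = annotate_snps(sites, snps, m, precs)
        assert out.category == "SNP"


class TestConservation:
    def test_same_type_same_mature_position_conserved(self, toy_precursor):
        site = _site(pos=55)  # mature position 6 of the 3p arm (starts at 50)
        tables = [("macaque", [("mirX-3p", 6, "A-to-I")])]
        flags = annotate_conservation([site], [toy_precursor], tables)
        assert flags["mirX_52_A_g"] is True

    def test_type_mismatch_not_conserved(self, toy_precursor):
        site = _site(pos=55)
        tables = [("macaque", [("mirX-3p", 6, "C-to-U")])]
        assert annotate_conservation([site], [toy_precursor], tables)[
            "mirX_52_A_g"] is False

    def test_empty_tables_all_false(self, toy_precursor):
        assert annotate_conservation([_site(pos=55)], [toy_precursor], [])[
            "mirX_52_A_g"] is False

    def test_outside_arm_never_conserved(self, toy_precursor):
        site = _site(pos=40)  # loop
        tables = [("macaque", [("mirX-3p", 6, "A-to-I")])]
        assert annotate_conservation([site], [toy_precursor], tables)[
            "mirX_52_A_g"] is False


class TestCategorySummary:
    def test_study_scale_percentages(self):
        counts = {
            "3'-A": 515, "3'-U": 456, "3'-Other": 76, "A-to-I": 27, "C-to-U": 4,
            "Other": 13, "5'-editing": 55, "SNP": 30, "pseudo": 6,
        }
        cs = category_summary(counts)
        assert cs.total == 1182
        assert cs.percentages["3'-A"] == 43.6
        assert cs.percentages["3'-U"] == 38.6
        assert cs.percentages["A-to-I"] == 2.3
        assert cs.percentages["C-to-U"] == 0.3
        assert cs.percentages["3'-Other"] == 6.4
        assert cs.percentages["Other"] == 1.1

    def test_single_and_split(self):
        assert category_summary({"3'-A": 7}).percentages == {"3'-A": 100.0}
        cs = category_summary({"a": 3, "b": 3})
        assert cs.percentages == {"a": 50.0, "b": 50.0}

    def test_counts_recompute_percentages(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = {f"c{i}": int(rng.integers(1, 50)) for i in range(5)}
            cs = category_summary(counts)
            total = sum(counts.values())
            for c, n in counts.items():
                assert cs.percentages[c] == pytest.approx(
                    np.floor(100 * n / total * 10 + 0.5) / 10
                )

    def test_empty(self):
        assert category_summary([]).total == 0


class TestNeighborBases:
    def test_constructed_uag_context(self, toy_precursor):
        # find template positions whose flanks we can assert directly
        pos = 52
        site = _site(pos=pos)
        f5, f3, skipped = neighbor_base_distribution([site], [toy_precursor], "A-to-I")
        from editome.io_formats import dna_to_rna

        assert f5 == {dna_to_rna(toy_precursor.base(pos - 1)): 1.0}
        assert f3 == {dna_to_rna(toy_precursor.base(pos + 1)): 1.0}

    def test_empty_filtered_set(self, toy_precursor):
        f5, f3, _ = neighbor_base_distribution([], [toy_precursor], "C-to-U")
        assert f5 == {} and f3 == {}


class TestEndEditDistribution:
    def test_two_3prime_sites_one_precursor(self):
        sites = [
            _site("mirX_72_G_a", pos=72, region="end3", category="3'-A"),
            _site("mirX_73_G_a", pos=73, region="end3", category="3'-A"),
        ]
        hist = end_edit_distribution(sites, [])
        assert hist["end3"] == {2: 1} and hist["central"] == {}

    def test_empty(self):
        hist = end_edit_distribution([], [])
        assert all(h == {} for h in hist.values())

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sites = []
            for i in range(int(rng.integers(1, 30))):
                prec = f"p{rng.integers(0, 5)}"
                region = ["end5", "end3", "central"][rng.integers(0, 3)]
                pos = int(rng.integers(1, 40))
                sites.append(
                    _site(f"{prec}_{pos}_A_g", prec=prec, pos=pos, region=region)
                )
            hist = end_edit_distribution(sites, [])
            # brute-force recount
            from collections import defaultdict

            per = defaultdict(set)
            for s in sites:
                per[(s.precursor_id, s.region)].add(s.p_pos)
            expect = {"end5": defaultdict(int), "end3": defaultdict(int),
                      "central": defaultdict(int)}
            for (p, r), positions in per.items():
                expect[r][len(positions)] += 1
            assert {r: dict(h) for r, h in expect.items()} == hist


class TestPseudoFlag:
    def test_boundary_rule_strictly_greater(self, toy_precursor):
        from editome.align import EditOp, GenomicHit, WeightedAlignment
        from editome.cohort import flag_pseudo

        site = _site()
        op = EditOp(52, "A", "g", "substitution")

        def sample_with(foreign_fraction):
            alns, hits = [], []
            for i in range(10):
                rid = f"r{i}"
                alns.append(
                    WeightedAlignment(rid, "mirX", 50, (op,), 1.0, 1, "A" * 22)
                )
                if i < foreign_fraction * 10:
                    hits.append(GenomicHit(rid, "chr9", 5000, "+", 0))
                else:
                    hits.append(GenomicHit(rid, "chr1", 150, "+", 1))
            return {
                "s": SampleCalls("s", [site], [], 1e6, {}, alignments=alns, hits=hits)
            }

        (exactly_half,) = flag_pseudo([site], sample_with(0.5), [toy_precursor])
        assert exactly_half.category == "A-to-I"  # 50% explainable: not pseudo
        (majority,) = flag_pseudo([site], sample_with(0.6), [toy_precursor])
        assert majority.category == "pseudo"
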