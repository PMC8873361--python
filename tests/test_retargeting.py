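"""Edited mature variants, PAR-CLIP clusters, seed matching and target sets."""

import numpy as np
import pandas as pd
import pytest

from editome.align import revcomp
from editome.io_formats import MatureArm, Precursor, ReadRecord
from editome.retargeting import (
    MatureVariant,
    ParClipCluster,
    align_parclip,
    apply_edit,
    compare_target_sets,
    find_clusters,
    mature_variant,
    predict_targets,
    prioritize_new_targets,
    seed_match_pvalue,
    targets_to_genes,
)
from editome.site_calling import SiteCall

from conftest import random_seq


def _site(prec, pos, ref, alt, name=None):
    return SiteCall(
        name=name or f"{prec}_{pos}_{ref}_{alt}", precursor_id=prec, p_pos=pos,
        ref_base=ref, alt_symbol=alt, region="central", category="Other",
        coverage_weight=100, edited_weight=20, edited_read_count=20, level=0.2,
        p_raw=1e-9,
    )


class TestApplyEdit:
    def test_five_prime_addition_prepends_and_shifts_seed(self, toy_precursor):
        arm = toy_precursor.arms[1]  # 50-71
        orig = mature_variant(toy_precursor, arm)
        site = _site("mirX", 49, toy_precursor.base(49),
                     "c" if toy_precursor.base(49) != "C" else "g")
        edited = apply_edit(toy_precursor, arm, site)
        assert edited.sequence == site.alt_symbol.upper() + orig.sequence
        assert edited.suffix == f"_49{site.alt_symbol}"
        assert edited.seed == (site.alt_symbol.upper() + orig.seed)[:8]

    def test_central_substitution_renders_uppercase(self, toy_precursor):
        arm = toy_precursor.arms[1]
        ref = toy_precursor.base(55)
        alt = "g" if ref != "G" else "a"
        edited = apply_edit(toy_precursor, arm, _site("mirX", 55, ref, alt))
        k = 55 - arm.p_start
        assert edited.sequence[k] == alt.upper()
        assert len(edited.sequence) == arm.length

    def test_tail_appends(self, toy_precursor):
        arm = toy_precursor.arms[1]
        ref = toy_precursor.base(72)
        alt = "a" if ref != "A" else "t"
        edited = apply_edit(toy_precursor, arm, _site("mirX", 72, ref, alt))
        assert edited.sequence.endswith(alt.upper())
        assert len(edited.sequence) == arm.length + 1

    def test_identity_edit_is_error(self, toy_precursor):
        arm = toy_precursor.arms[1]
        ref = toy_precursor.base(55)
        with pytest.raises(ValueError):
            apply_edit(toy_precursor, arm, _site("mirX", 55, ref, ref.lower()))

    def test_far_site_is_error(self, toy_precursor):
        arm = toy_precursor.arms[1]
        with pytest.raises(ValueError, match="not adjacent"):
            apply_edit(toy_precursor, arm, _site("mirX", 10, "A", "g"))


class TestClusters:
    def _reads_over(self, seq, start0, n, span=30, rid0=0, convert=()):
        reads = []
        for i in range(n):
            s = start0 + (i % 3)
            bases = list(seq[s : s + span])
            for k in convert:
                if 0 <= k - s < span and seq[k] == "T":
                    bases[k - s] = "C"
            reads.append(ReadRecord(f"q{rid0 + i}", "".join(bases), (40,) * span))
        return reads

    def test_overlapping_reads_merge_and_count_t2c(self):
        seq = random_seq(31, 400)
        t_positions = [i for i, b in enumerate(seq) if b == "T" and 60 <= i < 80]
        reads = self._reads_over(seq, 50, 7)
        reads += self._reads_over(seq, 52, 5, rid0=7, convert=t_positions[:1])
        placements = align_parclip(reads, {"tx": seq})
        (cluster,) = find_clusters(placements)
        assert cluster.total_reads == 12
        assert cluster.t2c_read_count == 5

    def test_gap_separates_clusters(self):
        seq = random_seq(31, 400)
        reads = self._reads_over(seq, 10, 4) + self._reads_over(seq, 200, 4, rid0=4)
        clusters = find_clusters(align_parclip(reads, {"tx": seq}))
        assert len(clusters) == 2

    def test_c_at_template_c_not_a_conversion(self):
        seq = "A" * 50 + "C" + "A" * 49  # no template T anywhere
        reads = [ReadRecord("q0", seq[40:70], (40,) * 30)]
        placements = align_parclip(reads, {"tx": seq})
        (cluster,) = find_clusters(placements)
        assert cluster.t2c_read_count == 0


class TestPredictTargets:
    def _setup(self, with_motif=True, t2c=5):
        mirna = MatureVariant("mir", "", "TGAGGTAGTAGGTTGTATAGTT")
        seq = list(random_seq(33, 200))
        if with_motif:
            motif = revcomp(mirna.seed)
            seq[100:108] = list(motif)
        seq = "".join(seq)
        cluster = ParClipCluster("tx", 95, 125, total_reads=12, t2c_read_count=t2c)
        return mirna, {"tx": seq}, [cluster]

    def test_planted_8mer_found(self):
        mirna, mrnas, clusters = self._setup()
        (site,) = predict_targets(mirna, mrnas, clusters)
        assert site.match_class == "8mer" and site.start == 101

    def test_t2c_filter_blocks_match(self):
        mirna, mrnas, clusters = self._setup(t2c=0)
        assert predict_targets(mirna, mrnas, clusters) == []

    def test_p_s_antimonotone_in_match_length(self):
        window = random_seq(35, 60)
        motif8 = "ATTACGCA"
        assert seed_match_pvalue(window, motif8) <= seed_match_pvalue(
            window, motif8[1:]
        ) <= seed_match_pvalue(window, motif8[1:7])

    def test_p_s_calibrated_on_random_clusters(self):
        """6mer hit frequency over random windows tracks the p_s prediction."""
        rng = np.random.default_rng(12)
        motif = "ATTACG"
        hits, preds = 0, []
        n = 2000
        for _ in range(n):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            hits += motif in w
            preds.append(seed_match_pvalue(w, motif))
        expected = float(np.mean(preds))
        observed = hits / n
        sd = (expected * (1 - expected) / n) ** 0.5
        assert abs(observed - expected) < 4 * sd + 1e-3


class TestTargetSets:
    def test_set_algebra_example(self):
        common, new, lost = compare_target_sets({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert (common, new, lost) == ({"g2", "g3"}, {"g4"}, {"g1"})

    def test_identity(self):
        common, new, lost = compare_target_sets({"g1"}, {"g1"})
        assert new == set() and lost == set()

    def test_cardinality_identities(self):
        rng = np.random.default_rng(4)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(20):
            orig = set(rng.choice(pool, size=rng.integers(0, 20), replace=False))
            edited = set(rng.choice(pool, size=rng.integers(0, 20), replace=False))
            common, new, lost = compare_target_sets(orig, edited)
            assert len(common) + len(new) == len(edited)
            assert len(common) + len(lost) == len(orig)


class TestPrioritize:
    def _gene_table(self):
        return pd.DataFrame(
            {
                "transcript_id": ["tx0", "tx1", "tx2"],
                "gene_id": ["G0", "G1", "G2"],
                "coding": [True, True, False],
            }
        )

    def _site(self, tx, reads):
        cl = ParClipCluster(tx, 10, 60, total_reads=reads, t2c_read_count=3)
        from editome.retargeting import TargetSite

        return TargetSite(tx, 20, 27, "8mer", 0.001, cl)

    def test_read_threshold_and_coding_filter(self):
        sites = [self._site("tx0", 12), self._site("tx1", 9), self._site("tx2", 50)]
        assert prioritize_new_targets(sites, self._gene_table()) == ["G0"]

    def test_missing_gene_excluded(self):
        sites = [self._site("txX", 40)]
        assert prioritize_new_targets(sites, self._gene_table()) == []


@pytest.fixture(scope="module")
def scenario():
    from editome.synthetic import ParClipPlan, simulate_parclip

    orig = MatureVariant("mir-sim", "", "TGAGGTAGTAGGTTGTATAGTT")
    edited = MatureVariant("mir-sim", "_9c", "CTGAGGTAGTAGGTTGTATAGT")
    plan = ParClipPlan(
        planted=[
            (0, orig.name, "8mer"),
            (1, orig.name, "8mer"),
            (2, edited.name, "8mer"),
            (3, edited.name, "8mer"),
            (4, edited.name, "8mer"),
        ],
        non_coding=(4,),
    )
    mrnas, reads, gene_table, truth = simulate_parclip([orig, edited], plan, 5)
    clusters = find_clusters(align_parclip(reads, mrnas))
    return orig, edited, mrnas, clusters, gene_table


class TestEndToEndRetargeting:

    def test_planted_edited_only_targets_are_exactly_the_new_set(self, scenario):
        orig, edited, mrnas, clusters, gene_table = scenario
        go = targets_to_genes(
            predict_targets(orig, mrnas, clusters, min_class="8mer"), gene_table)
        ge = targets_to_genes(
            predict_targets(edited, mrnas, clusters, min_class="8mer"), gene_table)
        common, new, lost = compare_target_sets(go, ge)
        assert new == {"G02", "G03", "G04"}
        assert lost == {"G00", "G01"}

    def test_zero_conversion_rate_no_targets(self):
        from editome.synthetic import ParClipPlan, simulate_parclip

        mirna = MatureVariant("mir-sim", "", "TGAGGTAGTAGGTTGTATAGTT")
        plan = ParClipPlan(planted=[(0, mirna.name, "8mer")], conversion_rate=0.0)
        mrnas, reads, gene_table, _ = simulate_parclip([mirna], plan, 5)
        clusters = find_clusters(align_parclip(reads, mrnas))
        assert predict_targets(mirna, mrnas, clusters) == []

    def test_seed_shift_hides_original_8mers_from_edited_variant(self):
        """A 5' addition shifts the seed register: planted original 8mer sites
        are overwhelmingly not recovered for the edited variant at 8mer tier."""
        from editome.synthetic import ParClipPlan, simulate_parclip

        orig = MatureVariant("mir-sim", "", "TGAGGTAGTAGGTTGTATAGTT")
        edited = MatureVariant("mir-sim", "_9c", "CTGAGGTAGTAGGTTGTATAGT")
        plan = ParClipPlan(
            n_transcripts=100,
            planted=[(i, orig.name, "8mer") for i in range(100)],
            background_per_tx=0,
        )
        mrnas, reads, gene_table, _ = simulate_parclip([orig, edited], plan, 9)
        clusters = find_clusters(align_parclip(reads, mrnas))
        orig_targets = targets_to_genes(
            predict_targets(orig, mrnas, clusters, min_class="8mer"), gene_table)
        edited_targets = targets_to_genes(
            predict_targets(edited, mrnas, clusters, min_class="8mer"), gene_table)
        assert len(orig_targets) == 100
        assert len(orig_targets - edited_targets) >= 50
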