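"""Toy aligner and the variant-calling stages: placement rules, the
pileup recount oracle, somatic algebra, LOH, CNV ratios and effect
annotation."""
import math

import numpy as np
import pytest

from genomodel.align import Alignment, align_reads
from genomodel.ops import (GeneAnnotation, annotate_effects, build_pileup,
                           call_indels_pileup, call_snvs_pileup, cnv_depth_ratio,
                           loh_annotate, normalize_indel, somatic_subtract)
from genomodel.variants import Variant, VariantSet

_rng = np.random.default_rng(2024)
REF = {"chr1": "".join(_rng.choice(list("ACGT"), size=300)),
       "chr2": "".join(_rng.choice(list("ACGT"), size=200))}
REPEAT_REF = {"chrR": "ACGTACGGTACCTTAGGCATAACGTGGCCA" * 10}


class TestAligner:
    def test_exact_unique_substring_placement(self):
        read = REF["chr1"][40:70]
        [a] = align_reads([("r1", read)], REF, seed_length=10, max_mismatches=2)
        assert (a.chrom, a.start, a.mapping_quality) == ("chr1", 41, 60)
        assert a.cigar == [("M", 30)]

    def test_repeat_locus_gets_leftmost_and_mapq_zero(self):
        # chrR is a 30-mer repeated 10x: any in-period read is ambiguous
        read = REPEAT_REF["chrR"][30:50]
        [a] = align_reads([("r1", read)], REPEAT_REF, seed_length=10,
                          max_mismatches=0)
        assert (a.start, a.mapping_quality) == (1, 0)

    def test_too_many_mismatches_is_unmapped(self):
        read = "A" * 30
        assert align_reads([("r1", read)], {"chr1": "CGTG" * 20},
                           seed_length=10, max_mismatches=2) == []

    def test_mismatch_outside_seed_is_rescued_by_other_seeds(self):
        read = list(REF["chr2"][25:55])
        read[2] = "A" if read[2] != "A" else "C"   # error inside the first seed
        [a] = align_reads([("r1", "".join(read))], REF, seed_length=10,
                          max_mismatches=2)
        assert (a.chrom, a.start) == ("chr2", 26)

    def test_seed_longer_than_read_is_an_error(self):
        with pytest.raises(ValueError, match="seed_length"):
            align_reads([("r1", "ACGT")], REF, seed_length=10)

    def test_single_deletion_read_gets_gapped_cigar(self):
        ref = {"c": "ATGCCGTAGACCTGGATTACCAGTGCAGGTCCAATGCTAGCTTAAGCCGT"}
        hap = ref["c"][:20] + ref["c"][23:]        # 3 bp deletion after base 20
        read = hap[5:40]
        [a] = align_reads([("r1", read)], ref, seed_length=10, max_mismatches=1)
        ops = [op for op, _ in a.cigar]
        assert ops == ["M", "D", "M"]
        assert sum(n for op, n in a.cigar if op == "D") == 3


class TestPileupCalling:
    def _reads_over(self, base_at_50, n_alt, n_total):
        ref = REF["chr1"]
        reads = []
        for i in range(n_total):
            s = list(ref[30:70])
            if i < n_alt:
                s[20] = base_at_50          # position 51 (1-based)
            reads.append(Alignment(f"r{i}", "chr1", 31, "+", [("M", 40)],
                                   "".join(s), 60))
        return reads

    def test_all_alt_reads_give_vaf_one(self):
        alt = "G" if REF["chr1"][50] != "G" else "T"
        calls = call_snvs_pileup(self._reads_over(alt, 10, 10), REF,
                                 min_depth=5, min_vaf=0.2)
        [v] = [v for v in calls if v.pos == 51]
        assert v.vaf == 1.0 and v.alt == alt

    def test_vaf_threshold_is_a_sharp_cut(self):
        alt = "G" if REF["chr1"][50] != "G" else "T"
        reads = self._reads_over(alt, 2, 10)
        assert not [v for v in call_snvs_pileup(reads, REF, min_depth=5, min_vaf=0.3)
                    if v.pos == 51]
        [v] = [v for v in call_snvs_pileup(reads, REF, min_depth=5, min_vaf=0.2)
               if v.pos == 51]
        assert v.vaf == pytest.approx(0.2)

    def test_below_min_depth_never_calls(self):
        alt = "G" if REF["chr1"][50] != "G" else "T"
        reads = self._reads_over(alt, 4, 4)
        assert not [v for v in call_snvs_pileup(reads, REF, min_depth=5, min_vaf=0.1)
                    if v.pos == 51]

    def test_low_mapq_reads_are_excluded(self):
        alt = "G" if REF["chr1"][50] != "G" else "T"
        reads = self._reads_over(alt, 10, 10)
        for r in reads:
            r.mapping_quality = 0
        assert len(call_snvs_pileup(reads, REF, min_depth=1, min_vaf=0.1,
                                    min_mapq=1)) == 0

    def test_pileup_recount_oracle(self):
        """Caller output matches a naive per-position recount on a random
        read pool."""
        rng = np.random.default_rng(41)
        ref = {"c": "".join(rng.choice(list("ACGT"), size=400))}
        reads = []
        for i in range(300):
            start = int(rng.integers(0, 360))
            s = list(ref["c"][start:start + 40])
            for p in rng.choice(40, size=rng.integers(0, 3), replace=False):
                s[p] = str(rng.choice(list("ACGT")))
            reads.append(Alignment(f"r{i}", "c", start + 1, "+", [("M", 40)],
                                   "".join(s), 60))
        calls = call_snvs_pileup(reads, ref, min_depth=8, min_vaf=0.2)
        # brute force recount
        counts = {}
        for a in reads:
            for i, base in enumerate(a.sequence):
                counts.setdefault(a.start + i, {}).setdefault(base, 0)
                counts[a.start + i][base] += 1
        expected = set()
        for pos, c in counts.items():
            depth = sum(c.values())
            refb = ref["c"][pos - 1]
            alts = sorted(((n, b) for b, n in c.items() if b != refb),
                          key=lambda t: (-t[0], t[1]))
            if depth >= 8 and alts and alts[0][0] / depth >= 0.2:
                expected.add((pos, alts[0][1]))
        assert {(v.pos, v.alt) for v in calls} == expected


class TestIndels:
    def test_left_normalization_shifts_through_repeats(self):
        ref = {"c": "GGGAAAATTTT"}
        # deleting any single A in the run normalizes to the leftmost
        key = normalize_indel(ref, "c", anchor=6, del_len=1)
        assert key == ("c", 3, "GA", "G")

    def test_indel_calls_from_cigar_alignments(self):
        ref = {"c": "ATGCCGTAGACCTGGATTACCAGTGCAGG"}
        alns = [Alignment(f"r{i}", "c", 1, "+", [("M", 10), ("D", 2), ("M", 10)],
                          ref["c"][:10] + ref["c"][12:22], 60) for i in range(10)]
        calls = call_indels_pileup(alns, ref, min_depth=5, min_vaf=0.2)
        assert len(calls) == 1
        v = calls.variants[0]
        assert len(v.ref) == 3 and len(v.alt) == 1


def _pileup_from(ref, reads):
    return build_pileup(reads, ref)


class TestSomaticSubtract:
    def _tumor(self):
        return VariantSet([Variant("chr1", 51, REF["chr1"][50], "G",
                                   depth=20, alt_count=10)])

    def test_variant_in_normal_set_removed(self):
        out = somatic_subtract(self._tumor(), self._tumor(),
                               build_pileup([], REF), 0.05)
        assert len(out) == 0

    def test_zero_normal_vaf_retained_and_flagged(self):
        logs = []
        out = somatic_subtract(self._tumor(), VariantSet([]),
                               build_pileup([], REF), 0.05, log=logs.append)
        assert len(out) == 1 and "SOMATIC" in out.variants[0].flags
        assert any("no normal coverage" in m for m in logs)

    def test_normal_fraction_above_threshold_removed(self):
        # 2/25 = 0.08 supporting reads in normal, threshold 0.05
        normal_reads = []
        for i in range(25):
            s = list(REF["chr1"][40:60])
            if i < 2:
                s[10] = "G"
            normal_reads.append(Alignment(f"n{i}", "chr1", 41, "+", [("M", 20)],
                                          "".join(s), 60))
        out = somatic_subtract(self._tumor(), VariantSet([]),
                               build_pileup(normal_reads, REF), max_normal_vaf=0.05)
        assert len(out) == 0

    def test_somatic_algebra_identities(self):
        t = VariantSet([Variant("chr1", i, "A" if REF["chr1"][i-1] != "A" else "C",
                                "T" if REF["chr1"][i-1] != "T" else "G",
                                depth=10, alt_count=5) for i in (5, 15, 25)])
        empty_pu = build_pileup([], REF)
        flagged = somatic_subtract(t, VariantSet([]), empty_pu, 0.05)
        assert flagged.keys() == t.keys()
        assert all("SOMATIC" in v.flags for v in flagged)
        assert len(somatic_subtract(t, t, empty_pu, 0.05)) == 0


class TestLoh:
    def _het(self, pos, tumor_vaf):
        ref = REF["chr1"][pos - 1]
        alt = "G" if ref != "G" else "T"
        normal = Variant("chr1", pos, ref, alt, depth=30, alt_count=15)
        tumor = Variant("chr1", pos, ref, alt, depth=40,
                        alt_count=int(round(tumor_vaf * 40)))
        return normal, tumor

    def test_het_to_hom_gets_flag(self):
        n, t = self._het(51, 0.98)
        out = loh_annotate(VariantSet([n]), VariantSet([t]), 0.9)
        assert "LOH" in out.variants[0].flags

    def test_het_staying_het_unflagged(self):
        n, t = self._het(51, 0.5)
        out = loh_annotate(VariantSet([n]), VariantSet([t]), 0.9)
        assert "LOH" not in out.variants[0].flags

    def test_het_missing_from_tumor_is_logged_not_flagged(self):
        n, _ = self._het(51, 0.5)
        logs = []
        out = loh_annotate(VariantSet([n]), VariantSet([]), 0.9, log=logs.append)
        assert len(out) == 0 and any("absent from tumor" in m for m in logs)


class TestCnv:
    def _alns(self, starts, chrom="chr1"):
        return [Alignment(f"r{i}", chrom, s, "+", [("M", 10)], "A" * 9 + "C", 60)
                for i, s in enumerate(starts)]

    def test_identical_samples_give_zero_ratio(self):
        a = self._alns(range(1, 200, 5))
        rows = cnv_depth_ratio(a, a, window_size=50)
        assert all(r == pytest.approx(0.0, abs=1e-9) for _, _, r in rows)

    def test_doubled_window_ratio_near_one(self):
        normal = self._alns(list(range(1, 401, 5)))
        tumor = normal + self._alns(range(1, 100, 5))   # ~2x over first window
        rows = cnv_depth_ratio(tumor, normal, window_size=100)
        first = rows[0][2]
        # library-size normalization shifts everything by log2(80/100)
        shift = math.log2(len(normal) / len(tumor))
        assert first == pytest.approx(1.0 + shift, abs=0.1)

    def test_empty_window_in_both_is_zero(self):
        rows = cnv_depth_ratio(self._alns([1]), self._alns([1]), window_size=10,
                               chrom_lengths={"chr1": 30})
        assert [r for _, w, r in rows if w > 10] == [0.0, 0.0]


class TestAnnotation:
    ANN = GeneAnnotation([("chr1", 101, 200, "gA", "coding"),
                          ("chr1", 201, 260, "gA", "utr"),
                          ("chr1", 261, 300, "gA", "intron")])

    def _v(self, pos):
        ref = REF["chr1"][pos - 1]
        return Variant("chr1", pos, ref, "G" if ref != "G" else "T")

    def test_coding_variant_is_tier1(self):
        [v] = annotate_effects(VariantSet([self._v(150)]), self.ANN).variants
        assert v.info_dict() == {"GENE": "gA", "RCLASS": "coding", "TIER": "1"}

    def test_no_overlap_is_intergenic_lowest_tier(self):
        [v] = annotate_effects(VariantSet([self._v(50)]), self.ANN).variants
        assert v.info_dict()["RCLASS"] == "intergenic"
        assert v.info_dict()["TIER"] == "4"

    def test_half_open_bed_boundary_excluded(self):
        """BED row chr1 100 200 covers 1-based 101..200: position 201 of a
        half-open (100, 200] interval must NOT overlap."""
        from genomodel.formats import write_bed  # noqa: F401  (doc anchor)
        import genomodel.formats as fmts
        bed = VariantSet([Variant("chr1", 101, ".", "gA|coding", end=200)])
        ann = GeneAnnotation.from_bed_rows(bed)
        assert ann.classify("chr1", 200) == ("gA", "coding")
        assert ann.classify("chr1", 201) == (".", "intergenic")

    def test_annotation_is_order_invariant(self):
        vs = [self._v(p) for p in (290, 150, 230, 50)]
        a = annotate_effects(VariantSet(vs), self.ANN)
        b = annotate_effects(VariantSet(list(reversed(vs))), self.ANN)
        assert a == b
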