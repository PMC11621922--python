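"""Variant normalization, filter cascade, SV annotation, and contexts."""

import itertools

import pytest

from hrdscar.simulate import simulate_variants
from hrdscar.variants import (
    BreakendPair,
    FilterThresholds,
    VariantRecord,
    annotate_sv_event,
    classify_indel_context,
    classify_msi,
    count_contexts,
    filter_small_variants,
    filter_structural_variants,
    normalize_variants,
    read_vcf,
    snv_trinucleotide_context,
)


def rec(chrom="c", pos=1, ref="A", alt="G", **kw):
    defaults = dict(
        sample_id="S1", qual=500.0, filter_status="PASS",
        allele_frequency=0.5, confidence_region="high",
    )
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **(defaults | kw))


def bnd(qual=1500.0, AS=1, RAS=1, **kw):
    defaults = dict(
        sample_id="S1", chrom1="c1", pos1=100, orient1="+",
        chrom2="c1", pos2=600, orient2="-",
        filter_status="PASS", allele_frequency=0.5,
    )
    return BreakendPair(qual=qual, assembly_support=(AS, RAS), **(defaults | kw))


class TestNormalize:
    REF = {"c": "GGGCCATATATGCCGTACGTAC"}
    #            0123456789...   (0-based); 1-based pos = index + 1

    def test_biallelic_snv_unchanged(self):
        r = rec(pos=6, ref="A", alt="T")
        assert normalize_variants([r], self.REF) == [r]

    def test_mnv_split_into_constituent_snvs(self):
        r = rec(pos=4, ref="CC", alt="GT")
        out = normalize_variants([r], self.REF)
        assert [(o.pos, o.ref, o.alt) for o in out] == [(4, "C", "G"), (5, "C", "T")]

    def test_mnv_with_matching_middle_base_emits_only_differences(self):
        r = rec(pos=13, ref="CCG", alt="GCT")
        out = normalize_variants([r], self.REF)
        assert [(o.pos, o.ref, o.alt) for o in out] == [(13, "C", "G"), (15, "G", "T")]

    def test_multiallelic_separated(self):
        r = rec(pos=6, ref="A", alt="T,C")
        out = normalize_variants([r], self.REF)
        assert [(o.ref, o.alt) for o in out] == [("A", "T"), ("A", "C")]

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match reference"):
            normalize_variants([rec(pos=1, ref="T", alt="A")], self.REF)

    def test_right_aligned_deletion_left_aligned_against_enumeration(self):
        # delete one AT unit from the (AT)x3 run at 1-based positions 6-11
        right = rec(pos=9, ref="TAT", alt="T")
        (out,) = normalize_variants([right], self.REF)
        # enumeration oracle: all equivalent 1-unit deletions of this run;
        # the 5'-most representation anchors at position 5 (C) deleting "AT"
        equivalents = [rec(pos=5 + 2 * k, ref="CAT" if k == 0 else "TAT"[0] + "AT",
                           alt="C" if k == 0 else "T") for k in range(3)]
        normalized = {
            normalize_variants([e], self.REF)[0].key for e in equivalents
        }
        assert normalized == {out.key}
        assert (out.pos, out.ref, out.alt) == (5, "CAT", "C")

    def test_insertion_left_aligned(self):
        # insert AT into the run, represented mid-run
        mid = rec(pos=9, ref="T", alt="TAT")
        (out,) = normalize_variants([mid], self.REF)
        assert (out.pos, out.ref, out.alt) == (5, "C", "CAT")

    def test_parsimony_trims_shared_bases(self):
        r = rec(pos=13, ref="CCGT", alt="CCT")
        (out,) = normalize_variants([r], self.REF)
        assert len(out.ref) == 2 and len(out.alt) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_simulated_records(self, seed):
        sim = simulate_variants(
            {"clean": 3, "del.mh": 2, "del.rep": 2, "ins.rep": 2}, seed=seed
        )
        once = normalize_variants(sim.records, sim.reference)
        twice = normalize_variants(once, sim.reference)
        assert [r.key for r in once] == [r.key for r in twice]


class TestSmallVariantFilter:
    def test_empty_input_empty_output(self):
        assert filter_small_variants([], {}) == []

    def test_af_boundary_inclusive(self):
        removed = rec(allele_frequency=0.05)
        kept = rec(allele_frequency=0.10)
        assert filter_small_variants([removed, kept], {}) == [kept]

    def test_quality_cutoff_depends_on_confidence_region(self):
        high_ok = rec(qual=170, confidence_region="high")
        high_bad = rec(qual=169, confidence_region="high")
        low_ok = rec(qual=240, confidence_region="low")
        low_bad = rec(qual=239, confidence_region="low")
        na_strict = rec(qual=200, confidence_region="NA")  # stricter cutoff
        out = filter_small_variants([high_ok, high_bad, low_ok, low_bad, na_strict], {})
        assert out == [high_ok, low_ok]

    def test_recurrence_rule_removes_three_or_more(self):
        r = rec()
        assert filter_small_variants([r], {r.key: 2}) == [r]
        assert filter_small_variants([r], {r.key: 3}) == []

    def test_single_violation_checklist(self):
        sim = simulate_variants(seed=0)  # 4 clean + one of each violation
        out = filter_small_variants(sim.records, sim.cohort_recurrence)
        retained_keys = {r.key for r in out}
        expected = {
            tuple(t["key"]) for t in sim.truth["records"] if t["retain"]
        }
        assert retained_keys == {(k[0], k[1], k[2], k[3]) for k in expected}
        assert len(out) == 4

    def test_order_independence_of_rules(self):
        sim = simulate_variants(seed=1)
        base = filter_small_variants(sim.records, sim.cohort_recurrence)
        shuffled = filter_small_variants(
            sim.records[::-1], sim.cohort_recurrence
        )
        assert {r.key for r in base} == {r.key for r in shuffled}


class TestStructuralVariantFilter:
    def test_boundary_qual_retained(self):
        assert filter_structural_variants([bnd(qual=1000)], {}) != []
        assert filter_structural_variants([bnd(qual=999)], {}) == []

    def test_assembly_support_required_from_both_sides(self):
        assert filter_structural_variants([bnd(AS=5, RAS=0)], {}) == []
        assert filter_structural_variants([bnd(AS=0, RAS=5)], {}) == []
        assert filter_structural_variants([bnd(AS=1, RAS=1)], {}) != []

    def test_common_rules_apply(self):
        assert filter_structural_variants([bnd(pon_flag=True)], {}) == []
        assert filter_structural_variants([bnd(allele_frequency=0.05)], {}) == []
        p = bnd()
        assert filter_structural_variants([p], {p.key: 3}) == []


class TestSVAnnotation:
    def test_interchromosomal_is_translocation(self):
        pair = bnd(chrom1="c1", pos1=100, chrom2="c2", pos2=200)
        event = annotate_sv_event(pair)
        assert (event.type, event.length) == ("TRA", None)

    @pytest.mark.parametrize(
        "o1,o2,expected",
        [("+", "-", "DEL"), ("-", "+", "DUP"), ("+", "+", "INV"), ("-", "-", "INV")],
    )
    def test_orientation_truth_table(self, o1, o2, expected):
        pair = bnd(pos1=1000, pos2=6000, orient1=o1, orient2=o2)
        event = annotate_sv_event(pair)
        assert (event.type, event.length) == (expected, 5000)

    def test_exhaustive_over_orientations_and_chromosomes(self):
        truth = {("+", "-"): "DEL", ("-", "+"): "DUP",
                 ("+", "+"): "INV", ("-", "-"): "INV"}
        for o1, o2, same in itertools.product("+-", "+-", [True, False]):
            pair = bnd(chrom2="c1" if same else "c2", pos1=100, pos2=900,
                       orient1=o1, orient2=o2)
            event = annotate_sv_event(pair)
            assert event.type == (truth[(o1, o2)] if same else "TRA")

    def test_unordered_breakends_canonicalized(self):
        pair = bnd(pos1=6000, orient1="-", pos2=1000, orient2="+")
        event = annotate_sv_event(pair)  # reordered to (+ at 1000, - at 6000)
        assert (event.type, event.length) == ("DEL", 5000)

    def test_identical_positions_rejected(self):
        with pytest.raises(ValueError, match="identical positions"):
            annotate_sv_event(bnd(pos1=500, pos2=500))


class TestIndelContext:
    def test_deletion_in_tandem_repeat(self):
        ref = {"c": "GGGG" + "ATATAT" + "CTTTTTTTTT"}
        r = rec(pos=4, ref="GAT", alt="G")
        category, n = classify_indel_context(r, ref)
        assert category == "rep" and n == 3

    def test_deletion_with_two_bp_microhomology(self):
        ref = {"c": "AAAC" + "GTCA" + "GTGGGCCCAA"}
        r = rec(pos=4, ref="CGTCA", alt="C")
        category, h = classify_indel_context(r, ref)
        assert category == "mh" and h == 2

    def test_deletion_without_homology_or_repeat(self):
        ref = {"c": "AAAG" + "GGGG" + "TTTTCCCCAA"}
        r = rec(pos=4, ref="GGGGG", alt="G")
        category, _ = classify_indel_context(r, ref)
        assert category == "none"

    def test_insertion_contexts(self):
        ref = {"c": "AAAC" + "GTGACCCCGG"}
        category, h = classify_indel_context(rec(pos=4, ref="C", alt="CGTCA"), ref)
        assert category == "mh" and h == 2
        ref2 = {"c": "AAAG" + "ATATCCGGCC"}
        category, n = classify_indel_context(rec(pos=4, ref="G", alt="GAT"), ref2)
        assert category == "rep" and n == 3

    def test_exhaustive_scan_oracle_on_random_deletions(self):
        # brute-force string oracle over a fixed random-ish reference
        import numpy as np

        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = {"c": seq}
        for _ in range(60):
            start = int(rng.integers(10, 350))
            length = int(rng.integers(1, 6))
            anchor = seq[start - 1]
            deleted = seq[start : start + length]
            r = rec(pos=start, ref=anchor + deleted, alt=anchor)
            category, _ = classify_indel_context(r, ref)
            flank = seq[start + length :]
            # oracle: repeat = unit continues >= 1 copy for >= 2 total copies
            unit = None
            for ulen in range(1, length + 1):
                if length % ulen == 0 and deleted[:ulen] * (length // ulen) == deleted:
                    unit = deleted[:ulen]
                    break
            copies_after = 0
            while flank.startswith(unit * (copies_after + 1)):
                copies_after += 1
            is_rep = copies_after >= 1 and (length // len(unit)) + copies_after >= 2
            mh = 0
            for a, b in zip(deleted, flank):
                if a != b:
                    break
                mh += 1
            expected = "rep" if is_rep else ("mh" if mh >= 2 else "none")
            assert category == expected

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError, match="not an indel"):
            classify_indel_context(rec(ref="A", alt="G"), {"c": "AAAA"})


class TestSNVContext:
    REF = {"c": "AACGT"}

    def test_pyrimidine_reference_kept_as_is(self):
        r = rec(pos=3, ref="C", alt="T")  # A C G
        assert snv_trinucleotide_context(r, self.REF) == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        r = rec(pos=4, ref="G", alt="A")  # C G T -> revcomp A C G
        assert snv_trinucleotide_context(r, self.REF) == "A[C>T]G"

    def test_n_in_flank_excluded(self):
        r = rec(pos=2, ref="A", alt="G")
        assert snv_trinucleotide_context(r, {"c": "NACGT"}) is None

    def test_counts_partition_classifiable_snvs(self):
        sim = simulate_variants({"clean": 8}, seed=2)
        counts = count_contexts(sim.records, reference=sim.reference)
        assert counts.n_snv == 8


class TestContextCountsAndMSI:
    def test_planted_context_counts_recovered(self):
        spec = {"del.mh": 10, "del.rep": 5, "ins.mh": 3, "ins.rep": 2,
                "del.none": 4, "ins.none": 1}
        sim = simulate_variants(spec, seed=3)
        counts = count_contexts(sim.records, reference=sim.reference)
        assert counts.indel == spec | {
            k: 0 for k in counts.indel if k not in spec
        }

    def test_sv_type_length_bins(self):
        pairs = [
            bnd(pos1=1000, pos2=6000),                      # DEL 5 kb
            bnd(pos1=1000, pos2=3000, orient1="-", orient2="+"),  # DUP 2 kb
            bnd(chrom2="c9", pos2=500),                     # TRA
        ]
        counts = count_contexts([], pairs, reference=None)
        assert counts.sv == {"DEL.1e3-1e4": 1, "DUP.1e3-1e4": 1, "TRA": 1}

    def test_msi_threshold_semantics(self):
        assert classify_msi(0) is False
        assert classify_msi(9_999) is False
        assert classify_msi(10_000) is True
        with pytest.raises(ValueError):
            classify_msi(-1)


class TestVCFRoundTrip:
    def test_simulated_vcf_readable_with_pysam(self, tmp_path):
        sim = simulate_variants(seed=4)
        sim.write(tmp_path)
        records = read_vcf(tmp_path / "variants.vcf", sample_id="S1")
        assert {r.key for r in records} == {r.key for r in sim.records}
        by_key = {r.key: r for r in records}
        for orig in sim.records:
            loaded = by_key[orig.key]
            assert loaded.allele_frequency == pytest.approx(orig.allele_frequency)
            assert loaded.pon_flag == orig.pon_flag
            assert loaded.blacklist_hits == orig.blacklist_hits
            assert (loaded.filter_status == "PASS") == (orig.filter_status == "PASS")

    def test_fasta_readable_with_pyfaidx(self, tmp_path):
        from pyfaidx import Fasta

        sim = simulate_variants({"del.rep": 2, "clean": 1}, seed=5)
        sim.write(tmp_path)
        fasta = Fasta(str(tmp_path / "ref.fa"))
        counts = count_contexts(sim.records, reference=fasta)
        assert counts.indel["del.rep"] == 2
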