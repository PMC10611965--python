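import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    insert_at,
    oracle_normalize_deletion,
    oracle_normalize_insertion,
)
from amplicall.alignment import AlignmentParams, align_read
from amplicall.errors import ParameterError
from amplicall.genotyping import (
    GenotypeCall,
    GenotypeSignature,
    RawIndel,
    SampleReport,
    call_genotypes,
    extract_indels,
    left_normalize,
    read_contribution,
    signature_of_read,
)
from amplicall.read_prep import UniqueRead
from amplicall.reference_io import ReferenceRegion
from amplicall.simulate import (
    apply_signature,
    deletion_variant,
    insertion_variant,
    random_region,
)


def _region(seq, start=1, chrom="chrT"):
    return ReferenceRegion(chrom, start, start + len(seq) - 1, seq)


class TestExtractIndels:
    def test_single_deletion_extracted(self):
        region = random_region(40, seed=3)
        hap = region.sequence[:19] + region.sequence[20:]  # drop base 20
        raw = extract_indels(align_read(hap, region), region)
        assert [(r.kind, len(r.seq)) for r in raw] == [("deletion", 1)]

    def test_perfect_match_yields_no_indels(self, region296):
        assert extract_indels(align_read(region296.sequence, region296), region296) == []

    def test_63nt_deletion_survives_extraction(self, region296):
        hap = region296.sequence[:110] + region296.sequence[173:]
        raw = extract_indels(align_read(hap, region296), region296)
        assert [(r.kind, len(r.seq)) for r in raw] == [("deletion", 63)]

    def test_substitutions_are_ignored(self, region296):
        read = "T" + region296.sequence[1:150] + "A" + region296.sequence[151:]
        raw = extract_indels(align_read(read, region296), region296)
        assert raw == []


class TestLeftNormalize:
    def test_homopolymer_deletion_shifts_left(self, tiny_region):
        # any of the three A's deleted from GCAAAT is the same allele
        for offset in (3, 4, 5):
            v = left_normalize(RawIndel("deletion", offset, "A"), tiny_region)
            assert (v.pos, v.ref, v.alt) == (2, "CA", "C")

    def test_no_repeat_context_no_shift(self):
        v = left_normalize(RawIndel("deletion", 3, "G"), _region("ATGCA"))
        assert (v.pos, v.ref, v.alt) == (2, "TG", "T")

    def test_idempotent(self, tiny_region):
        v = left_normalize(RawIndel("deletion", 5, "A"), tiny_region)
        again = left_normalize(
            RawIndel("deletion", tiny_region.genomic_to_local(v.pos) + 1, v.ref[1:]),
            tiny_region,
        )
        assert again == v

    def test_boundary_indel_right_anchored(self):
        region = _region("AAAGT")
        v = left_normalize(RawIndel("deletion", 2, "A"), region)
        assert v.right_anchored
        assert (v.pos, v.ref, v.alt) == (1, "AA", "A")

    def test_insertion_in_homopolymer_shifts_left(self, tiny_region):
        # inserting an A anywhere inside the AAA run is one allele
        for before in (4, 5, 6):
            v = left_normalize(RawIndel("insertion", before, "A"), tiny_region)
            assert (v.pos, v.ref, v.alt) == (2, "C", "CA")

    @settings(max_examples=80, derandomize=True)
    @given(data=st.data())
    def test_matches_enumeration_oracle_in_repeat_contexts(self, data):
        """Normalization lands on the minimum-position member of the
        brute-force-enumerated equivalence class, and substituting ALT for
        REF at POS reconstructs the edited haplotype."""
        unit = data.draw(st.sampled_from(["A", "T", "AT", "GC", "AAC"]))
        reps = data.draw(st.integers(min_value=2, max_value=5))
        flank1 = "".join(data.draw(st.lists(st.sampled_from("ACGT"), min_size=3, max_size=8)))
        flank2 = "".join(data.draw(st.lists(st.sampled_from("ACGT"), min_size=3, max_size=8)))
        seq = flank1 + unit * reps + flank2
        region = _region(seq, start=101)
        if data.draw(st.booleans()):
            L = data.draw(st.integers(min_value=1, max_value=3))
            i0 = data.draw(st.integers(min_value=1, max_value=len(seq) - L))
            v = left_normalize(RawIndel("deletion", i0 + 1, seq[i0 : i0 + L]), region)
            pos, ref, alt = oracle_normalize_deletion(seq, 101, i0, L)
            edited = seq[:i0] + seq[i0 + L :]
        else:
            ins = data.draw(st.sampled_from([unit, unit[0], "G", "TT"]))
            i0 = data.draw(st.integers(min_value=1, max_value=len(seq)))
            v = left_normalize(RawIndel("insertion", i0 + 1, ins), region)
            pos, ref, alt = oracle_normalize_insertion(seq, 101, i0, ins)
            edited = insert_at(seq, i0, ins)
        assert (v.pos, v.ref, v.alt) == (pos, ref, alt)
        local = v.pos - 101
        assert seq[:local] + v.alt + seq[local + len(v.ref) :] == edited


class TestSignatures:
    def test_wt_read_has_empty_signature(self, region296):
        sig = signature_of_read(align_read(region296.sequence, region296), region296)
        assert sig.is_wt and sig.key == "WT"

    def test_two_indels_sorted_by_position(self, region296):
        dv = deletion_variant(region296, 200, 2)
        iv = insertion_variant(region296, 80, "GG")
        hap = apply_signature(region296, GenotypeSignature((iv, dv)))
        sig = signature_of_read(align_read(hap, region296), region296)
        assert sig.variants == (iv, dv)
        assert [v.pos for v in sig.variants] == sorted(v.pos for v in sig.variants)

    def test_substitution_errors_do_not_change_signature(self, region296, rng):
        """Reads from the same edited allele with extra point errors genotype
        identically — robustness to polymerase/sequencer substitutions."""
        dv = deletion_variant(region296, 150, 3)
        hap = apply_signature(region296, GenotypeSignature((dv,)))
        clean = signature_of_read(align_read(hap, region296), region296)
        for _ in range(5):
            p = int(rng.integers(5, len(hap) - 5))
            base = "ACGT"[(("ACGT".index(hap[p])) + 1) % 4]
            noisy = hap[:p] + base + hap[p + 1 :]
            assert signature_of_read(align_read(noisy, region296), region296) == clean


class TestCallGenotypes:
    def test_two_allele_mixture_proportions(self, region296):
        hap_del = apply_signature(
            region296, GenotypeSignature((deletion_variant(region296, 148, 2),))
        )
        hap_ins = apply_signature(
            region296, GenotypeSignature((insertion_variant(region296, 150, "T"),))
        )
        uniques = [UniqueRead(hap_del, 6000, 1), UniqueRead(hap_ins, 3900, 2)]
        report = call_genotypes(uniques, 10_000, region296, cutoff=30)
        assert [round(c.proportion, 2) for c in report.calls] == [0.60, 0.39]
        assert all(c.is_major for c in report.calls)
        assert report.n_retained_reads == 9900

    def test_exactly_one_percent_is_major(self, region296):
        hap = apply_signature(
            region296, GenotypeSignature((deletion_variant(region296, 148, 2),))
        )
        uniques = [UniqueRead(region296.sequence, 9900, 1), UniqueRead(hap, 100, 2)]
        report = call_genotypes(uniques, 10_000, region296)
        by_key = {c.signature.key: c for c in report.calls}
        call = next(c for k, c in by_key.items() if k != "WT")
        assert call.proportion == pytest.approx(0.01)
        assert call.is_major

    def test_all_wt_single_call(self, region296):
        report = call_genotypes([UniqueRead(region296.sequence, 800, 1)], 1000, region296)
        assert len(report.calls) == 1
        assert report.calls[0].signature.is_wt
        assert report.calls[0].proportion == pytest.approx(0.8)

    def test_zero_retained_reads_is_empty_report(self, region296):
        report = call_genotypes([], 1000, region296)
        assert report.calls == [] and report.read_contribution == 0.0

    def test_total_less_than_retained_rejected(self, region296):
        with pytest.raises(ParameterError):
            call_genotypes([UniqueRead(region296.sequence, 10, 1)], 5, region296)

    def test_bad_threshold_rejected(self, region296):
        with pytest.raises(ParameterError):
            call_genotypes([], 10, region296, major_threshold=0.0)


class TestReadContribution:
    def _report(self, majors, minors, n_retained):
        calls = [
            GenotypeCall(GenotypeSignature(), n, n / 1000, True) for n in majors
        ] + [
            GenotypeCall(GenotypeSignature(), n, n / 1000, False) for n in minors
        ]
        return SampleReport(
            sample_id="s", n_total_reads=1000, n_unique_reads=5, cutoff=30,
            n_retained_reads=n_retained, calls=calls,
        )

    def test_all_retained_support_majors(self):
        assert read_contribution(self._report([500, 400], [], 900)) == 1.0

    def test_partial_support(self):
        assert read_contribution(self._report([800], [50], 900)) == pytest.approx(800 / 900)

    def test_no_retained_reads(self):
        assert read_contribution(self._report([], [], 0)) == 0.0
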