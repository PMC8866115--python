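"""Indel normalization, deletion classification, TNT scoring and spectra."""

import numpy as np
import pytest

from top1tam.indel_classify import (
    FRAMESHIFT_PLUS2_LABELS,
    ID83_LABELS,
    IndelCall,
    SpectrumVector,
    canonical_dinucleotide_class,
    classify_deletion,
    deletion_is_tnt_compliant,
    normalize_indel,
    score_tnt,
    spectrum_from_indels,
    subtract_background,
)
from top1tam.sequence import revcomp

from _oracles import oracle_classify


class TestNormalize:
    def test_left_alignment_in_repeat(self):
        seqs = {"c": "GGCTCTCTAA"}
        call = IndelCall("c", 6, "CT", "")  # 3' register of (CT)3
        norm = normalize_indel(call, seqs)
        assert (norm.position, norm.ref_allele) == (2, "CT")

    def test_idempotent(self):
        seqs = {"c": "GGCTCTCTAA"}
        norm = normalize_indel(IndelCall("c", 2, "CT", ""), seqs)
        assert normalize_indel(norm, seqs) == norm

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            normalize_indel(IndelCall("c", 0, "TT", ""), {"c": "GGCC"})

    def test_randomized_rewritings_normalize_identically(self, seed13_sequence, rng):
        """Any equivalent register of a planted deletion maps to one record."""
        seq = seed13_sequence
        seqs = {"chr1": seq}
        for _ in range(50):
            d = int(rng.integers(2, 6))
            pos = int(rng.integers(1, len(seq) - d))
            canon = normalize_indel(IndelCall("chr1", pos, seq[pos : pos + d], ""), seqs)
            # rewrite at every register that leaves the same resulting sequence
            target = seq[:pos] + seq[pos + d :]
            for p in range(max(0, pos - 8), min(len(seq) - d, pos + 8)):
                if seq[:p] + seq[p + d :] == target:
                    alt = normalize_indel(
                        IndelCall("chr1", p, seq[p : p + d], ""), seqs
                    )
                    assert alt == canon


class TestClassify:
    def test_str_deletion(self):
        seqs = {"c": "GGACTCTCTGAA"}
        c = classify_deletion(IndelCall("c", 3, "CT", ""), seqs)
        assert c.context == "STR"
        assert c.repeat_copies == 3
        assert c.tnt_compliant  # CTCT contains T-C-T
        assert c.canonical_class == "CT"

    def test_snmh_deletion(self):
        seqs = {"c": "AGTCTGA"}
        c = classify_deletion(IndelCall("c", 2, "TC", ""), seqs)
        assert c.context == "MH"
        assert c.mh_length == 1
        assert c.repeat_copies == 1
        assert c.tnt_compliant  # T-C-T present

    def test_no_thymidine_on_either_strand_not_compliant(self):
        seqs = {"c": "GGCGCGCGGG"}
        c = classify_deletion(IndelCall("c", 2, "CG", ""), seqs)
        assert c.context == "STR" and not c.tnt_compliant

    def test_ca_repeat_compliant_via_complementary_strand(self):
        """A CA-repeat deletion reads TG on the other strand, where T-G-T
        satisfies the motif; scoring is strand-collapsed."""
        seqs = {"c": "GGCACACAGG"}
        c = classify_deletion(IndelCall("c", 2, "CA", ""), seqs)
        assert c.context == "STR" and c.tnt_compliant

    def test_n_overlap_flagged_other(self):
        seqs = {"c": "GGCNTAGG"}
        c = classify_deletion(IndelCall("c", 3, "NT", ""), seqs)
        assert c.context == "other" and c.warning

    def test_exhaustive_oracle_agreement(self, seed13_sequence):
        """Every 2-5 bp deletion matches the brute-force string oracle."""
        seq = seed13_sequence
        seqs = {"chr1": seq}
        for d in (2, 3, 4, 5):
            for pos in range(1, len(seq) - d):
                left = pos
                while left > 0 and seq[left - 1] == seq[left + d - 1]:
                    left -= 1
                if left != pos:
                    continue  # classify only normalized (left-aligned) records
                c = classify_deletion(IndelCall("chr1", pos, seq[pos : pos + d], ""), seqs)
                o = oracle_classify(seq, pos, d)
                got = {
                    "context": c.context,
                    "repeat_copies": c.repeat_copies,
                    "mh_length": c.mh_length,
                    "tnt": c.tnt_compliant,
                }
                assert got == o, f"d={d} pos={pos} {seq[pos - 6:pos + d + 6]}"

    def test_reverse_complement_invariance(self, seed13_sequence, rng):
        seq = seed13_sequence
        rseq = revcomp(seq)
        for _ in range(200):
            d = int(rng.integers(2, 6))
            pos = int(rng.integers(1, len(seq) - d - 1))
            fwd = classify_deletion(
                normalize_indel(IndelCall("c", pos, seq[pos : pos + d], ""), {"c": seq}),
                {"c": seq},
            )
            rpos = len(seq) - pos - d
            rev = classify_deletion(
                normalize_indel(
                    IndelCall("c", rpos, rseq[rpos : rpos + d], ""), {"c": rseq}
                ),
                {"c": rseq},
            )
            assert fwd.context == rev.context
            assert fwd.repeat_copies == rev.repeat_copies
            assert fwd.mh_length == rev.mh_length
            assert fwd.tnt_compliant == rev.tnt_compliant
            if d == 2 and fwd.canonical_class is not None:
                assert fwd.canonical_class == rev.canonical_class

    def test_score_tnt_matches_classification(self, seed13_sequence):
        seqs = {"chr1": seed13_sequence}
        for pos in range(1, 300):
            call = normalize_indel(
                IndelCall("chr1", pos, seed13_sequence[pos : pos + 2], ""), seqs
            )
            c = classify_deletion(call, seqs)
            assert score_tnt(c, seqs) == c.tnt_compliant
            assert deletion_is_tnt_compliant(seed13_sequence, pos, 2) == c.tnt_compliant


class TestCanonicalClasses:
    def test_ga_maps_to_ct_class(self):
        assert canonical_dinucleotide_class("GA") == "CT"

    def test_at_is_its_own_class(self):
        assert canonical_dinucleotide_class("AT") == "AT"

    def test_partition_of_heterodimers(self):
        """The 14 two-base dinucleotides map onto exactly six classes."""
        members: dict[str, set] = {}
        for a in "ACGT":
            for b in "ACGT":
                if a == b and a in "AT":
                    with pytest.raises(ValueError):
                        canonical_dinucleotide_class(a + b)
                    continue
                members.setdefault(canonical_dinucleotide_class(a + b), set()).add(a + b)
        assert set(members) == {"AT", "TA", "CC", "CG", "CT", "AC"}
        assert sum(len(v) for v in members.values()) == 14
        assert members["CT"] == {"CT", "TC", "GA", "AG"}

    def test_complement_grouping(self):
        for di in ("CT", "TC", "GA", "AG", "AC", "CA", "GT", "TG", "CC", "GG"):
            assert canonical_dinucleotide_class(di) == canonical_dinucleotide_class(
                revcomp(di)
            )

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            canonical_dinucleotide_class("NX")


class TestSpectra:
    def test_scheme_sizes(self):
        assert len(ID83_LABELS) == 83
        assert len(set(ID83_LABELS)) == 83
        assert set(FRAMESHIFT_PLUS2_LABELS) <= set(ID83_LABELS)

    def test_empty_input_zero_vector(self):
        s = spectrum_from_indels([], {"c": "ACGT"})
        assert s.n_categories == 83 and s.total == 0

    def test_single_str_deletion_bins_once(self):
        seqs = {"c": "GGACTCTCTGAA"}
        s = spectrum_from_indels([IndelCall("c", 3, "CT", "")], seqs)
        d = s.as_dict()
        assert d["2:Del:R:2"] == 1  # 2 bp deletion, 3 copies -> 2 extra units
        assert s.total == 1

    def test_conservation_and_truth_histogram(self, seed13_sequence, rng):
        """Spectrum totals equal the classifiable input count."""
        seqs = {"chr1": seed13_sequence}
        calls = []
        for _ in range(300):
            d = int(rng.integers(1, 6))
            pos = int(rng.integers(1, len(seed13_sequence) - d))
            calls.append(
                normalize_indel(
                    IndelCall("chr1", pos, seed13_sequence[pos : pos + d], ""), seqs
                )
            )
        s = spectrum_from_indels(calls, seqs)
        assert s.total == len(calls)

    def test_subset_scheme(self):
        seqs = {"c": "GGACTCTCTGAA"}
        s = spectrum_from_indels(
            [IndelCall("c", 3, "CT", "")], seqs, scheme=("2:Del:R:2", "2:Del:M:1")
        )
        assert s.counts.tolist() == [1.0, 0.0]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            spectrum_from_indels([], {"c": "ACGT"}, scheme="SBS-96")


class TestSubtractBackground:
    def _vec(self, counts):
        labels = tuple(f"k{i}" for i in range(len(counts)))
        return SpectrumVector(labels, np.array(counts, dtype=float), scheme="test")

    def test_equal_spectra_cancel(self):
        ko = self._vec([3, 5, 2])
        assert subtract_background(ko, [ko, ko]).total == 0

    def test_negative_values_clamped_to_zero(self):
        res = subtract_background(self._vec([3, 0]), [self._vec([5, 0])])
        assert res.counts.tolist() == [0.0, 0.0]

    def test_matches_direct_arithmetic(self, rng):
        ko = self._vec(rng.integers(0, 30, size=10))
        wts = [self._vec(rng.integers(0, 30, size=10)) for _ in range(3)]
        res = subtract_background(ko, wts)
        manual = np.maximum(
            0, ko.counts - np.mean([w.counts for w in wts], axis=0)
        )
        np.testing.assert_allclose(res.counts, manual)

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            subtract_background(self._vec([1]), [SpectrumVector(("z",), [1.0], "other")])
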