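import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varsieve as vs
from varsieve.errors import (
    AmbiguousAlleleError,
    ReferenceMismatchError,
    TagInconsistencyError,
    UnsortedInputError,
    VcfParseError,
)
from varsieve.vcf_model import FAIL, PASS, UNSET

from conftest import write_vcf_text


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "G", vs.VarClass.SNP),
            ("A", "ATT", vs.VarClass.INS),
            ("ATT", "A", vs.VarClass.DEL),
            ("AT", "GC", vs.VarClass.MNP),
            ("ACG", "TT", vs.VarClass.COMPLEX),
            ("AC", "TGG", vs.VarClass.COMPLEX),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert vs.classify_variant(ref, alt) is expected

    def test_ambiguity_character_raises(self):
        with pytest.raises(AmbiguousAlleleError):
            vs.classify_variant("N", "A")

    def test_empty_allele_raises(self):
        with pytest.raises(ValueError):
            vs.classify_variant("", "A")


class TestVariantCall:
    def test_invariants(self):
        with pytest.raises(ValueError):
            vs.VariantCall("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            vs.VariantCall("chr1", 5, "A", "A")

    def test_ambiguous_flag(self):
        call = vs.VariantCall("chr1", 5, "N", "A")
        assert call.is_ambiguous_allele
        assert call.var_class is None

    def test_footprint(self):
        call = vs.VariantCall("chr1", 700, "ACGT", "A")
        assert call.ref_footprint == (699, 703)


class TestParseVcf:
    def test_simple_snp(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t50\tPASS\tDP=20;AO=18"
        )
        calls = vs.parse_vcf(path, pipeline_id="x")
        assert len(calls) == 1
        c = calls[0]
        assert c.key == ("chr1", 100, "A", "G")
        assert c.qual == 50
        assert c.filter_status == PASS
        assert c.var_class is vs.VarClass.SNP
        assert c.tags["DP"] == 20
        assert c.pipeline_id == "x"

    def test_multiallelic_split(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "a.vcf", "chr1\t100\t.\tA\tG,T\t50\tPASS\tDP=20;AO=12,6"
        )
        calls = vs.parse_vcf(path)
        assert [c.alt for c in calls] == ["G", "T"]
        assert all(c.site_alt_count == 2 for c in calls)
        # Number=A tag split per alt; Number=1 tag shared
        assert [c.tags["AO"] for c in calls] == [12, 6]
        assert [c.tags["DP"] for c in calls] == [20, 20]

    def test_ambiguous_ref_flagged(self, tmp_path):
        path = write_vcf_text(tmp_path / "a.vcf", "chr1\t100\t.\tN\tG\t50\tPASS\t.")
        (call,) = vs.parse_vcf(path)
        assert call.is_ambiguous_allele

    def test_filter_states(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "a.vcf",
            "chr1\t10\t.\tA\tG\t50\tPASS\t.\n"
            "chr1\t20\t.\tA\tG\t50\tq10\t.\n"
            "chr1\t30\t.\tA\tG\t50\t.\t.",
        )
        states = [c.filter_status for c in vs.parse_vcf(path)]
        assert states == [PASS, FAIL, UNSET]

    def test_malformed_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            vs.parse_vcf(path)


REF = "CAAATGGCTAGCTTACGATCGATCGATTAGCCATG"


class TestNormalizeCall:
    def test_identity_snp(self):
        call = vs.VariantCall("c", 6, "G", "T")
        out = vs.normalize_call(call, {"c": REF})
        assert [c.key for c in out] == [("c", 6, "G", "T")]

    def test_mnp_decomposition(self):
        # REF[9:11] = "AG"
        call = vs.VariantCall("c", 10, "AG", "GC")
        out = vs.normalize_call(call, {"c": REF})
        assert [(c.pos, c.ref, c.alt) for c in out] == [(10, "A", "G"), (11, "G", "C")]
        assert all(c.mnp_derived for c in out)
        assert all(c.var_class is vs.VarClass.SNP for c in out)

    def test_homopolymer_left_shift(self):
        # CAAAT...: insertion of A at pos 4 left-aligns to the pos-1 anchor
        call = vs.VariantCall("c", 4, "A", "AA")
        (out,) = vs.normalize_call(call, {"c": REF})
        assert (out.pos, out.ref, out.alt) == (1, "C", "CA")
        assert out.var_class is vs.VarClass.INS

    def test_trims_shared_bases(self):
        # REF[18:22] = "TCGA"; TCGA->TCTA is a SNP at the third base
        call = vs.VariantCall("c", 19, "TCGA", "TCTA")
        (out,) = vs.normalize_call(call, {"c": REF})
        assert (out.pos, out.ref, out.alt) == (21, "G", "T")

    def test_complex_kept_whole(self):
        call = vs.VariantCall("c", 6, "GGC", "TT")
        (out,) = vs.normalize_call(call, {"c": REF})
        assert out.var_class is vs.VarClass.COMPLEX

    def test_reference_mismatch(self):
        call = vs.VariantCall("c", 6, "T", "A")
        with pytest.raises(ReferenceMismatchError):
            vs.normalize_call(call, {"c": REF})

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_idempotent(self, data):
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=10, max_size=40), label="seq"
        )
        pos = data.draw(st.integers(2, len(seq) - 5), label="pos")
        ref_len = data.draw(st.integers(1, 4), label="ref_len")
        ref = seq[pos - 1 : pos - 1 + ref_len]
        alt = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4), label="alt")
        if ref == alt:
            alt = alt + "T" if ref != alt + "T" else alt + "C"
        call = vs.VariantCall("c", pos, ref, alt)
        once = vs.normalize_call(call, {"c": seq})
        twice = [x for c in once for x in vs.normalize_call(c, {"c": seq})]
        assert [c.key for c in once] == [c.key for c in twice]


class TestExtractCharacteristics:
    dialect = vs.BUILTIN_DIALECTS["generic"]

    def make(self, qual=None, **tags):
        return vs.VariantCall("chr1", 100, "A", "G", qual=qual, tags=tags)

    def test_vaf_from_counts(self):
        chars = vs.extract_characteristics(self.make(DP=50, AO=48), self.dialect)
        assert chars.vaf == pytest.approx(0.96)
        assert chars.depth == 50
        assert chars.alt_reads == 48

    def test_strand_min_pct(self):
        chars = vs.extract_characteristics(self.make(SAF=1, SAR=19), self.dialect)
        assert chars.strand_min_pct == pytest.approx(5.0)

    def test_strand_conservation(self):
        chars = vs.extract_characteristics(self.make(SAF=7, SAR=13), self.dialect)
        other = 100.0 * 13 / 20
        assert chars.strand_min_pct + other == pytest.approx(100.0)
        assert chars.strand_min_pct <= 50

    def test_qd_fallback(self):
        chars = vs.extract_characteristics(
            self.make(qual=300.0, AO=10), self.dialect
        )
        assert chars.qd == pytest.approx(30.0)
        assert chars.qd_from_tag is False

    def test_qd_tag_preferred(self):
        call = self.make(qual=300.0, AO=10, QD=2.5)
        chars = vs.extract_characteristics(call, vs.BUILTIN_DIALECTS["gatkish"])
        assert chars.qd == pytest.approx(2.5)
        assert chars.qd_from_tag is True

    def test_unmapped_is_unavailable_not_zero(self):
        lean = vs.BUILTIN_DIALECTS["lean"]
        chars = vs.extract_characteristics(self.make(DP=50, AO=48, SAF=1, SAR=19), lean)
        assert chars.strand_min_pct is None
        assert chars.direction_min_pct is None

    def test_depth_zero_inconsistency(self):
        with pytest.raises(TagInconsistencyError):
            vs.extract_characteristics(self.make(DP=0, AO=3), self.dialect)

    def test_availability_monotone_in_dialect_richness(self):
        call = self.make(qual=50.0, DP=30, AO=28, SAF=10, SAR=18, RPL=14, RPR=14)
        lean = vs.extract_characteristics(call, vs.BUILTIN_DIALECTS["lean"])
        rich = vs.extract_characteristics(call, vs.BUILTIN_DIALECTS["generic"])
        for name in vs.CallCharacteristics.NAMES:
            if lean.available(name):
                assert rich.available(name)


def brute_force_distances(calls):
    """All-pairs oracle for distances_to_nearest."""
    out = []
    for c in calls:
        d_snp = d_indel = None
        for other in calls:
            if other.chrom != c.chrom or other.pos == c.pos:
                continue
            d = abs(other.pos - c.pos)
            if other.var_class is vs.VarClass.SNP:
                d_snp = d if d_snp is None else min(d_snp, d)
            elif other.var_class in (vs.VarClass.INS, vs.VarClass.DEL):
                d_indel = d if d_indel is None else min(d_indel, d)
        out.append((d_snp, d_indel))
    return out


class TestDistances:
    def test_example(self):
        calls = [
            vs.VariantCall("c", 100, "A", "G"),
            vs.VariantCall("c", 103, "T", "C"),
            vs.VariantCall("c", 150, "A", "AT"),
        ]
        dists = vs.distances_to_nearest(calls)
        assert dists[0] == (3, 50)
        assert dists[1] == (3, 47)
        assert dists[2] == (47, None)

    def test_lone_snp(self):
        (d,) = vs.distances_to_nearest([vs.VariantCall("c", 10, "A", "G")])
        assert d == (None, None)

    def test_unsorted_raises(self):
        calls = [vs.VariantCall("c", 20, "A", "G"), vs.VariantCall("c", 10, "A", "G")]
        with pytest.raises(UnsortedInputError):
            vs.distances_to_nearest(calls)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        calls = []
        for _ in range(120):
            chrom = "c" + str(rng.integers(1, 3))
            pos = int(rng.integers(1, 500))
            if rng.random() < 0.6:
                calls.append(vs.VariantCall(chrom, pos, "A", "G"))
            else:
                calls.append(vs.VariantCall(chrom, pos, "A", "AT"))
        calls.sort(key=lambda c: (c.chrom, c.pos))
        assert vs.distances_to_nearest(calls) == brute_force_distances(calls)

    @settings(max_examples=100, deadline=None)
    @given(
        positions=st.lists(st.integers(1, 200), min_size=2, max_size=30, unique=True)
    )
    def test_nearest_snp_symmetry(self, positions):
        calls = sorted(
            (vs.VariantCall("c", p, "A", "G") for p in positions),
            key=lambda c: c.pos,
        )
        dists = vs.distances_to_nearest(calls)
        by_pos = {c.pos: d for c, (d, _) in zip(calls, dists)}
        for c, (d_snp, _) in zip(calls, dists):
            assert d_snp is not None and d_snp >= 1
            # if A's nearest SNP is at distance d, that neighbour's own
            # nearest-SNP distance cannot exceed d
            for neighbour in (c.pos - d_snp, c.pos + d_snp):
                if neighbour in by_pos:
                    assert by_pos[neighbour] <= d_snp
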