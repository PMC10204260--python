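"""Domain types, ISCN notation, type inference and reciprocal overlap."""

import pytest

from cnvreclass.core import (
    AmbiguousTypeError,
    Assembly,
    AssemblyMismatchError,
    Classification,
    ClassChange,
    CNVType,
    CopyState,
    GenomicInterval,
    ISCNParseError,
    Inheritance,
    NoCopyChangeError,
    Sex,
    SexRequiredError,
    ValidationError,
    ChangeDirection,
    format_iscn,
    infer_type,
    parse_iscn,
    parse_iscn_one,
    reciprocal_overlap,
)

# The twelve published CNV notation strings, in canonical form.
TABLE_STRINGS = [
    "1q24.3(172050936-172181677)x1",
    "Xq26.2(132717085-132924462)x1",
    "1q21.1(145818702-147824207)x3",
    "4q31.23(148911418-149103259)x1",
    "Xq27.1(139103383-139763381)x2~3",
    "Xq27.1(139103383-139801281)x2",
    "2p16.3(51172123-51314430)x1",
    "2p16.3(51251498-51491417)x1",
    "2q12.3q13(109320835-110427254)x1",
    "15q11.2(22765628-23191062)x1",
    "16p11.2(28615644-29042118)x3",
    "17q12(34817422-36243028)x3",
]


class TestISCN:
    @pytest.mark.parametrize("text", TABLE_STRINGS)
    def test_round_trip_is_bit_exact(self, text):
        rec = parse_iscn_one(text)
        assert str(format_iscn(rec)) == text
        # parse -> format -> parse is a fixed point
        assert parse_iscn_one(str(format_iscn(rec))) == rec

    def test_colon_and_band_styles_agree(self):
        a = parse_iscn_one("arr [hg19] chr1:(145818702-147824207)x3")
        b = parse_iscn_one("1q21.1(145818702-147824207)x3")
        assert (a.chrom, a.start, a.end, a.copy_state) == (
            b.chrom, b.start, b.end, b.copy_state
        )
        assert a.assembly is Assembly.HG19
        assert b.assembly is Assembly.UNSPECIFIED

    def test_mosaic_copy_range_and_underscore_separator(self):
        rec = parse_iscn_one("Xq27.1(139103383_139801281)x2")
        assert (rec.chrom, rec.band) == ("X", "q27.1")
        assert (rec.start, rec.end) == (139103383, 139801281)
        mosaic = parse_iscn_one("Xq27.1(139103383-139763381)x2~3")
        assert mosaic.copy_state == CopyState(2, 3)
        assert str(format_iscn(mosaic)).endswith("x2~3")

    def test_trailing_inheritance_token(self):
        rec = parse_iscn_one("arr [hg19] chr1:(145818702-147824207)x3 dn")
        assert rec.inheritance is Inheritance.DE_NOVO

    def test_multiple_loci(self):
        recs = parse_iscn(
            "arr [hg19] 1q21.1(145818702-147824207)x3, 2p16.3(51172123-51314430)x1"
        )
        assert [r.chrom for r in recs] == ["1", "2"]
        assert all(r.assembly is Assembly.HG19 for r in recs)

    def test_malformed_token_names_position(self):
        with pytest.raises(ISCNParseError) as exc:
            parse_iscn("1q21.1(145818702-147824207)x3 nonsense")
        assert "nonsense" in str(exc.value)

    def test_start_after_end_rejected(self):
        with pytest.raises(ValidationError):
            parse_iscn("1q21.1(147824207-145818702)x3")

    def test_arr_prefix_formatting(self):
        rec = parse_iscn_one("arr [hg19] 15q11.2(22765628-23191062)x1")
        assert (
            str(format_iscn(rec, style="with_arr_prefix"))
            == "arr [hg19] 15q11.2(22765628-23191062)x1"
        )

    def test_missing_band_falls_back_to_coordinate_form(self):
        rec = parse_iscn_one("chr7:(1000-2000)x1")
        out = format_iscn(rec)
        assert out.coordinate_only
        assert str(out) == "chr7:(1000-2000)x1"


class TestInferType:
    def test_autosomal_deletion(self):
        assert infer_type(CopyState(1, 1), "2", Sex.F) is CNVType.LOSS
        assert infer_type(CopyState(1, 1), "2", Sex.M) is CNVType.LOSS

    def test_autosomal_duplication(self):
        assert infer_type(CopyState(3, 3), "16", Sex.M) is CNVType.GAIN

    def test_diploid_autosome_is_no_copy_change(self):
        with pytest.raises(NoCopyChangeError):
            infer_type(CopyState(2, 2), "5", Sex.F)

    def test_x2_female_chrX_needs_label(self):
        with pytest.raises((AmbiguousTypeError, NoCopyChangeError)):
            infer_type(CopyState(2, 2), "X", Sex.F)
        assert infer_type(CopyState(2, 2), "X", Sex.F, CNVType.GAIN) is CNVType.GAIN

    def test_chrX_unknown_sex_requires_sex_or_label(self):
        with pytest.raises(SexRequiredError):
            infer_type(CopyState(1, 1), "X", Sex.UNKNOWN)
        assert (
            infer_type(CopyState(1, 1), "X", Sex.UNKNOWN, CNVType.LOSS)
            is CNVType.LOSS
        )

    def test_straddling_mosaic_needs_label(self):
        with pytest.raises(AmbiguousTypeError):
            infer_type(CopyState(1, 3), "4", Sex.F)

    def test_chrY_ploidy(self):
        assert infer_type(CopyState(0, 0), "Y", Sex.M) is CNVType.LOSS
        assert infer_type(CopyState(2, 2), "Y", Sex.M) is CNVType.GAIN


class TestReciprocalOverlap:
    def test_identity_is_one(self):
        a = GenomicInterval("1", 100, 199)
        assert reciprocal_overlap(a, a) == 1.0

    def test_half_overlap(self):
        # two 100-bp intervals sharing 50 bases
        a = GenomicInterval("1", 100, 199)
        b = GenomicInterval("1", 150, 249)
        assert reciprocal_overlap(a, b) == pytest.approx(0.5)

    def test_disjoint_and_other_chrom_are_zero(self):
        a = GenomicInterval("1", 100, 199)
        assert reciprocal_overlap(a, GenomicInterval("1", 300, 400)) == 0.0
        assert reciprocal_overlap(a, GenomicInterval("2", 100, 199)) == 0.0

    def test_assembly_mismatch_instructs_liftover(self):
        a = GenomicInterval("1", 100, 199, Assembly.HG18)
        b = GenomicInterval("1", 100, 199, Assembly.HG19)
        with pytest.raises(AssemblyMismatchError):
            reciprocal_overlap(a, b)


def test_interval_invariants():
    with pytest.raises(ValidationError):
        GenomicInterval("1", 10, 5)
    with pytest.raises(ValidationError):
        GenomicInterval("chr25", 1, 10)
    assert GenomicInterval("chrX", 5, 5).chrom == "X"
    assert GenomicInterval("1", 10, 19).length == 10


def test_class_change_direction_antisymmetric():
    for a in Classification:
        for b in Classification:
            fwd = ClassChange("x", a, b).direction
            rev = ClassChange("x", b, a).direction
            if a == b:
                assert fwd is rev is ChangeDirection.NONE
            else:
                assert {fwd, rev} == {ChangeDirection.UP, ChangeDirection.DOWN}


def test_classification_total_order():
    order = [
        Classification.BENIGN,
        Classification.LIKELY_BENIGN,
        Classification.UNCERTAIN,
        Classification.LIKELY_PATHOGENIC,
        Classification.PATHOGENIC,
    ]
    assert sorted(Classification) == order
    # a likely-benign to benign move counts as a downgrade
    assert (
        ClassChange("x", Classification.LIKELY_BENIGN, Classification.BENIGN).direction
        is ChangeDirection.DOWN
    )
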