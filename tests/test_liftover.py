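"""Chain-file parsing and interval lifting against hand-constructed chains."""

import pytest

from cnvreclass.core import (
    Assembly,
    AssemblyMismatchError,
    Classification,
    CNVCall,
    CopyState,
    GenomicInterval,
)
from cnvreclass.liftover import (
    ChainParseError,
    LiftStatus,
    lift_cohort,
    lift_interval,
    read_chain,
)

SIZE = 249_250_621


def chain_file(tmp_path, text, name="hg18ToHg19.over.chain"):
    path = tmp_path / name
    path.write_text(text)
    return path


IDENTITY = f"chain 1000 chr1 {SIZE} + 0 1000000 chr1 {SIZE} + 0 1000000 1\n1000000\n\n"
SHIFT100 = f"chain 1000 chr1 {SIZE} + 0 1000000 chr1 {SIZE} + 100 1000100 1\n1000000\n\n"
SHIFT_BACK = f"chain 1000 chr1 {SIZE} + 100 1000100 chr1 {SIZE} + 0 1000000 1\n1000000\n\n"
# two blocks with a 10-bp insertion on the target between them
TWO_BLOCK = f"chain 900 chr1 {SIZE} + 0 2000 chr1 {SIZE} + 0 2010 2\n1000 0 10\n1000\n\n"
# 100-bp unaligned stretch on the source between blocks
SOURCE_GAP = f"chain 900 chr1 {SIZE} + 0 2000 chr1 {SIZE} + 0 1900 3\n950 100 0\n950\n\n"
NEG_STRAND = f"chain 800 chr1 {SIZE} + 0 1000 chr1 1000 - 0 1000 4\n1000\n\n"


class TestReadChain:
    def test_identity_chain_maps_to_itself(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, IDENTITY))
        assert chains.source_assembly is Assembly.HG18
        assert chains.target_assembly is Assembly.HG19
        res = lift_interval(GenomicInterval("1", 1000, 2000, Assembly.HG18), chains)
        assert res.status is LiftStatus.MAPPED
        assert (res.mapped_interval.start, res.mapped_interval.end) == (1000, 2000)
        assert res.mapped_fraction == 1.0

    def test_two_block_chain_reflects_target_insertion(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, TWO_BLOCK))
        chain = chains.chains[0]
        assert [(b.t_start, b.q_start, b.size) for b in chain.blocks] == [
            (0, 0, 1000),
            (1000, 1010, 1000),
        ]
        # an interval spanning the junction widens by the 10-bp insertion
        res = lift_interval(GenomicInterval("1", 901, 1100, Assembly.HG18), chains)
        assert res.status is LiftStatus.MAPPED
        assert (res.mapped_interval.start, res.mapped_interval.end) == (901, 1110)

    def test_negative_strand_target_reverses_coordinates(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, NEG_STRAND))
        res = lift_interval(GenomicInterval("1", 1, 100, Assembly.HG18), chains)
        # per the chain spec, '-' strand q coordinates count from the
        # reverse-complement start: source base 0 maps to plus-strand 999
        assert res.status is LiftStatus.MAPPED
        assert (res.mapped_interval.start, res.mapped_interval.end) == (901, 1000)

    def test_malformed_header_reports_line(self, tmp_path):
        with pytest.raises(ChainParseError) as exc:
            read_chain(chain_file(tmp_path, "chain 1000 chr1 100 +\n"))
        assert exc.value.line_number == 1

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ChainParseError):
            read_chain(chain_file(tmp_path, ""))

    def test_block_sum_mismatch_rejected(self, tmp_path):
        bad = f"chain 1000 chr1 {SIZE} + 0 1000000 chr1 {SIZE} + 0 1000000 1\n12345\n\n"
        with pytest.raises(ChainParseError):
            read_chain(chain_file(tmp_path, bad))


class TestLiftInterval:
    def test_plus_100_shift(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, SHIFT100))
        res = lift_interval(GenomicInterval("1", 1000, 2000, Assembly.HG18), chains)
        assert res.status is LiftStatus.MAPPED
        assert (res.mapped_interval.start, res.mapped_interval.end) == (1100, 2100)

    def test_interval_in_gap_is_unmapped(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, SOURCE_GAP))
        res = lift_interval(GenomicInterval("1", 960, 1040, Assembly.HG18), chains)
        assert res.status is LiftStatus.UNMAPPED
        assert res.mapped_interval is None

    def test_partial_when_gap_eats_coverage(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, SOURCE_GAP))
        # interval straddles the 100-bp source gap: 100/300 bases unaligned
        res = lift_interval(GenomicInterval("1", 851, 1150, Assembly.HG18), chains)
        assert res.status is LiftStatus.PARTIAL
        assert res.mapped_fraction == pytest.approx(200 / 300)

    def test_mapped_fraction_monotone_in_gap_size(self, tmp_path):
        fractions = []
        for gap in (0, 50, 200):
            text = (
                f"chain 900 chr1 {SIZE} + 0 2000 chr1 {SIZE} + 0 {2000 - gap} g\n"
                f"950 {gap} 0\n{1050 - gap}\n\n"
            )
            chains = read_chain(chain_file(tmp_path, text, f"g{gap}.chain"))
            res = lift_interval(
                GenomicInterval("1", 1, 2000, Assembly.HG18), chains, min_match=0.5
            )
            fractions.append(res.mapped_fraction)
        assert fractions == sorted(fractions, reverse=True)

    def test_assembly_mismatch_rejected(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, IDENTITY))
        with pytest.raises(AssemblyMismatchError):
            lift_interval(GenomicInterval("1", 1000, 2000, Assembly.HG19), chains)

    def test_min_match_validated(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, IDENTITY))
        with pytest.raises(ValueError):
            lift_interval(
                GenomicInterval("1", 1000, 2000, Assembly.HG18), chains, min_match=1.5
            )


def _call(i, start, end):
    return CNVCall(
        id=f"c{i}",
        interval=GenomicInterval("1", start, end, Assembly.HG18),
        band="p36.1",
        copy_state=CopyState(1, 1),
        initial_class=Classification.UNCERTAIN,
    )


class TestLiftCohort:
    def test_all_mapped_empty_report(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, IDENTITY))
        calls = [_call(1, 10, 100), _call(2, 500, 900), _call(3, 2000, 3000)]
        lifted, report = lift_cohort(calls, chains)
        assert len(lifted) == 3 and report == []
        assert all(c.interval.assembly is Assembly.HG19 for c in lifted)

    def test_unmapped_call_goes_to_report(self, tmp_path):
        chains = read_chain(chain_file(tmp_path, SOURCE_GAP))
        calls = [_call(1, 10, 100), _call(2, 960, 1040), _call(3, 1200, 1300)]
        lifted, report = lift_cohort(calls, chains)
        assert [c.id for c in lifted] == ["c1", "c3"]
        assert len(report) == 1 and report[0]["id"] == "c2"
        assert report[0]["status"] == "unmapped"

    def test_inverse_chains_round_trip(self, tmp_path):
        fwd = read_chain(chain_file(tmp_path, SHIFT100, "hg18ToHg19.chain"))
        back = read_chain(chain_file(tmp_path, SHIFT_BACK, "hg19ToHg18.chain"))
        calls = [_call(1, 1000, 2000), _call(2, 5000, 7000), _call(3, 101, 300)]
        there, rep1 = lift_cohort(calls, fwd)
        back_again, rep2 = lift_cohort(there, back)
        assert rep1 == rep2 == []
        for orig, rt in zip(calls, back_again):
            assert (orig.interval.start, orig.interval.end) == (
                rt.interval.start, rt.interval.end
            )
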