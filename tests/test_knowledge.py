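"""Snapshot loading, validation and interval queries."""

import datetime as dt

import pytest

from cnvreclass.core import (
    Assembly,
    AssemblyMismatchError,
    Classification,
    CNVType,
    GenomicInterval,
    ValidationError,
)
from cnvreclass.knowledge import (
    Containment,
    DosageLevel,
    DosageRecord,
    GeneModel,
    KnowledgeSnapshot,
    LiteratureCase,
    PhenotypeSpecificity,
    PopulationCNV,
    load_snapshot,
)

HG19 = Assembly.HG19


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end, HG19)


@pytest.fixture()
def small_snapshot():
    return KnowledgeSnapshot(
        snapshot_date=dt.date(2020, 1, 1),
        assembly=HG19,
        genes=[
            GeneModel("AAA", iv("1", 1000, 2000)),
            GeneModel("BBB", iv("1", 5000, 9000)),
            GeneModel("NCR", iv("1", 1200, 1300), is_protein_coding=False),
        ],
        population=[
            PopulationCNV(iv("1", 1000, 2000), CNVType.LOSS, "cohortA", 50, 1000,
                          dt.date(2019, 1, 1)),
            PopulationCNV(iv("1", 1000, 2000), CNVType.GAIN, "cohortB", 3, 1000,
                          dt.date(2019, 1, 1)),
            PopulationCNV(iv("1", 1500, 2500), CNVType.LOSS, "cohortC", 2, 1000,
                          dt.date(2019, 1, 1)),
        ],
    )


class TestSnapshotRoundTrip:
    def test_write_then_load_preserves_queries(self, small_snapshot, tmp_path):
        small_snapshot.write(tmp_path / "snap")
        loaded = load_snapshot(tmp_path / "snap")
        assert loaded.snapshot_date == small_snapshot.snapshot_date
        assert loaded.assembly is HG19
        q = iv("1", 900, 2100)
        assert [g.symbol for g, _ in loaded.genes_in(q)] == [
            g.symbol for g, _ in small_snapshot.genes_in(q)
        ]
        assert len(loaded.population) == 3

    def test_missing_table_named(self, small_snapshot, tmp_path):
        small_snapshot.write(tmp_path / "snap")
        (tmp_path / "snap" / "dosage.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="dosage"):
            load_snapshot(tmp_path / "snap")

    def test_invalid_population_row_reported(self, small_snapshot, tmp_path):
        small_snapshot.write(tmp_path / "snap")
        path = tmp_path / "snap" / "population.tsv"
        lines = path.read_text().splitlines()
        lines[1] = lines[1].replace("\t50\t1000\t", "\t5000\t1000\t")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="population.tsv row 2"):
            load_snapshot(tmp_path / "snap")

    def test_empty_optional_tables_load(self, tmp_path):
        snap = KnowledgeSnapshot(dt.date(2020, 1, 1), HG19,
                                 genes=[GeneModel("AAA", iv("1", 1, 10))])
        snap.write(tmp_path / "snap")
        loaded = load_snapshot(tmp_path / "snap")
        assert loaded.literature == () and loaded.population == ()


class TestInvariants:
    def test_record_post_dating_snapshot_rejected(self):
        with pytest.raises(ValidationError, match="post-dates"):
            KnowledgeSnapshot(
                dt.date(2015, 1, 1), HG19,
                population=[PopulationCNV(iv("1", 1, 10), CNVType.LOSS, "c", 1, 10,
                                          dt.date(2019, 1, 1))],
            )

    def test_duplicate_gene_symbol_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            KnowledgeSnapshot(
                dt.date(2020, 1, 1), HG19,
                genes=[GeneModel("AAA", iv("1", 1, 10)),
                       GeneModel("AAA", iv("2", 1, 10))],
            )

    def test_carriers_cannot_exceed_cohort(self):
        with pytest.raises(ValidationError):
            PopulationCNV(iv("1", 1, 10), CNVType.LOSS, "c", 11, 10)

    def test_dosage_needs_one_evaluated_level(self):
        with pytest.raises(ValidationError):
            DosageRecord("G", iv("1", 1, 10))

    def test_cross_assembly_query_rejected(self, small_snapshot):
        with pytest.raises(AssemblyMismatchError):
            small_snapshot.genes_in(GenomicInterval("1", 1, 10, Assembly.HG18))


class TestGenesIn:
    def test_full_and_partial_containment(self, small_snapshot):
        hits = small_snapshot.genes_in(iv("1", 900, 6000))
        by_symbol = {g.symbol: c for g, c in hits}
        assert by_symbol["AAA"] is Containment.FULL
        assert by_symbol["BBB"] is Containment.PARTIAL  # straddles query end
        assert by_symbol["NCR"] is Containment.FULL

    def test_no_genes_empty(self, small_snapshot):
        assert small_snapshot.genes_in(iv("2", 1, 10_000)) == []

    def test_fixture_gpc3_fully_contained(self, fixture_bundle):
        xq262 = iv("X", 132717085, 132924462)
        hits = fixture_bundle.snapshot_current.genes_in(xq262)
        assert ("GPC3", Containment.FULL) in [(g.symbol, c) for g, c in hits]


class TestPopulationSupport:
    def test_identical_interval_full_overlap(self, small_snapshot):
        hits = small_snapshot.population_support(iv("1", 1000, 2000), CNVType.LOSS)
        assert hits[0][1] == 1.0
        rec, ro, common = hits[0]
        assert rec.cohort_name == "cohortA" and common  # 5% >= 1% frequency arm

    def test_type_mismatch_excluded(self, small_snapshot):
        hits = small_snapshot.population_support(iv("1", 1000, 2000), CNVType.LOSS)
        assert all(r.cnv_type is CNVType.LOSS for r, _, _ in hits)

    def test_min_recip_cutoff_matches_brute_force(self, small_snapshot):
        from cnvreclass.core import reciprocal_overlap

        q = iv("1", 1000, 2000)
        for cutoff in (0.3, 0.5, 0.8, 1.0):
            got = {r.cohort_name for r, _, _ in
                   small_snapshot.population_support(q, CNVType.LOSS, cutoff)}
            want = {
                r.cohort_name
                for r in small_snapshot.population
                if r.cnv_type is CNVType.LOSS
                and reciprocal_overlap(q, r.interval) >= cutoff
            }
            assert got == want


class TestDosageAndRecurrent:
    def test_fixture_nrxn1_sufficient_hit(self, fixture_bundle):
        q = iv("2", 51172123, 51314430)
        dosage, _ = fixture_bundle.snapshot_current.dosage_and_recurrent_hits(
            q, CNVType.LOSS
        )
        hit = [(r, c) for r, c in dosage if r.target == "NRXN1"]
        assert hit and hit[0][0].haploinsufficiency is DosageLevel.SUFFICIENT_EVIDENCE
        assert hit[0][1] is Containment.FULL

    def test_fixture_1q21_query_larger_flag(self, fixture_bundle):
        q = iv("1", 145818702, 147824207)
        _, recurrent = fixture_bundle.snapshot_current.dosage_and_recurrent_hits(
            q, CNVType.GAIN
        )
        distal = [h for h in recurrent if "1q21.1" in h[0].name]
        assert distal
        rec, ro, query_larger = distal[0]
        assert query_larger and 0 < ro < 1

    def test_no_overlap_both_empty(self, small_snapshot):
        d, r = small_snapshot.dosage_and_recurrent_hits(iv("9", 1, 100), CNVType.LOSS)
        assert d == [] and r == []


def test_query_results_independent_of_insertion_order():
    recs = [
        PopulationCNV(iv("1", s, s + 999), CNVType.LOSS, f"c{s}", 10, 100,
                      dt.date(2019, 1, 1))
        for s in (1000, 1400, 1800, 5000)
    ]
    a = KnowledgeSnapshot(dt.date(2020, 1, 1), HG19, population=recs)
    b = KnowledgeSnapshot(dt.date(2020, 1, 1), HG19, population=list(reversed(recs)))
    q = iv("1", 1200, 2400)
    got_a = [(r.cohort_name, ro) for r, ro, _ in
             a.population_support(q, CNVType.LOSS, 0.1)]
    got_b = [(r.cohort_name, ro) for r, ro, _ in
             b.population_support(q, CNVType.LOSS, 0.1)]
    assert got_a == got_b
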