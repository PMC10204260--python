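"""Versioned local knowledge snapshots standing in for DGV, ClinVar, DECIPHER,
the ClinGen dosage map, OMIM and the literature.

A snapshot is a dated, assembly-locked bundle of five record tables.  The
dating is what makes "initial-era" versus "current-era" reanalysis
expressible: the same cohort queried against two snapshots yields different
evidence, and the record deltas between them are what drive reclassification.

All coordinates in snapshot TSVs are 1-based inclusive.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .core import (
    Assembly,
    AssemblyMismatchError,
    Classification,
    CNVType,
    GenomicInterval,
    ValidationError,
    reciprocal_overlap,
)

__all__ = [
    "GeneModel",
    "DosageLevel",
    "DosageRecord",
    "RecurrentRegion",
    "PopulationCNV",
    "LiteratureCase",
    "PhenotypeSpecificity",
    "Penetrance",
    "Containment",
    "KnowledgeSnapshot",
    "load_snapshot",
    "genes_in",
    "population_support",
    "dosage_and_recurrent_hits",
    "SNAPSHOT_TABLES",
]


class DosageLevel(str, enum.Enum):
    SUFFICIENT_EVIDENCE = "sufficient_evidence"
    EMERGING = "emerging"
    LITTLE = "little"
    UNLIKELY = "unlikely"
    NOT_EVALUATED = "not_evaluated"


class Penetrance(str, enum.Enum):
    FULL = "full"
    INCOMPLETE = "incomplete"


class PhenotypeSpecificity(str, enum.Enum):
    CONSISTENT = "consistent"
    NONSPECIFIC = "nonspecific"
    INCONSISTENT = "inconsistent"


class Containment(str, enum.Enum):
    FULL = "full"       # record interval entirely inside the query
    PARTIAL = "partial"


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    interval: GenomicInterval
    is_protein_coding: bool = True
    omim_morbid: bool = False


@dataclass(frozen=True)
class DosageRecord:
    """ClinGen-style dosage-sensitivity curation for a gene or region."""

    target: str  # gene symbol, or "" for a pure region record
    interval: GenomicInterval
    haploinsufficiency: DosageLevel = DosageLevel.NOT_EVALUATED
    triplosensitivity: DosageLevel = DosageLevel.NOT_EVALUATED
    source_date: dt.date = dt.date(1970, 1, 1)

    def __post_init__(self):
        if (
            self.haploinsufficiency is DosageLevel.NOT_EVALUATED
            and self.triplosensitivity is DosageLevel.NOT_EVALUATED
        ):
            raise ValidationError(
                f"dosage record {self.target or self.interval}: at least one of "
                "HI/TS must be evaluated"
            )


@dataclass(frozen=True)
class RecurrentRegion:
    """Expert-curated recurrent CNV region (e.g. 15q11.2 BP1-BP2)."""

    name: str
    interval: GenomicInterval
    cnv_type: CNVType
    established_class: Classification
    penetrance: Penetrance = Penetrance.FULL
    source_date: dt.date = dt.date(1970, 1, 1)

    def __post_init__(self):
        if self.established_class not in (
            Classification.BENIGN,
            Classification.PATHOGENIC,
        ):
            raise ValidationError(
                f"recurrent region {self.name}: established_class must be "
                "benign or pathogenic"
            )


@dataclass(frozen=True)
class PopulationCNV:
    """A CNV observed in a general-population cohort (DGV-style)."""

    interval: GenomicInterval
    cnv_type: CNVType
    cohort_name: str
    n_carriers: int
    cohort_size: int
    source_date: dt.date = dt.date(1970, 1, 1)

    def __post_init__(self):
        if not (0 <= self.n_carriers <= self.cohort_size):
            raise ValidationError(
                f"population record {self.interval}: 0 <= n_carriers <= cohort_size "
                f"violated ({self.n_carriers}/{self.cohort_size})"
            )

    @property
    def frequency(self) -> float:
        return self.n_carriers / self.cohort_size


@dataclass(frozen=True)
class LiteratureCase:
    """Aggregated published case evidence for a CNV locus (PubMed/DECIPHER/ClinVar)."""

    interval: GenomicInterval
    cnv_type: CNVType
    n_de_novo_consistent: int = 0
    n_unknown_inheritance: int = 0
    phenotype_specificity: PhenotypeSpecificity = PhenotypeSpecificity.NONSPECIFIC
    source_date: dt.date = dt.date(1970, 1, 1)

    def __post_init__(self):
        if self.n_de_novo_consistent < 0 or self.n_unknown_inheritance < 0:
            raise ValidationError("literature case counts must be >= 0")


SNAPSHOT_TABLES = ("genes", "dosage", "recurrent", "population", "literature")


class KnowledgeSnapshot:
    """Dated, assembly-locked, interval-indexed bundle of knowledge records."""

    def __init__(
        self,
        snapshot_date: dt.date,
        assembly: Assembly,
        genes: Iterable[GeneModel] = (),
        dosage: Iterable[DosageRecord] = (),
        recurrent: Iterable[RecurrentRegion] = (),
        population: Iterable[PopulationCNV] = (),
        literature: Iterable[LiteratureCase] = (),
        provenance: str = "",
    ):
        self.snapshot_date = _parse_date(snapshot_date)
        self.assembly = Assembly(assembly)
        self.genes = tuple(genes)
        self.dosage = tuple(dosage)
        self.recurrent = tuple(recurrent)
        self.population = tuple(population)
        self.literature = tuple(literature)
        self.provenance = provenance
        self._validate()
        self._trees = {name: {} for name in SNAPSHOT_TABLES}
        for name in SNAPSHOT_TABLES:
            for rec in getattr(self, name):
                iv = rec.interval
                tree = self._trees[name].setdefault(iv.chrom, IntervalTree())
                # interval tree uses half-open keys; store 1-based inclusive as [s, e+1)
                tree.addi(iv.start, iv.end + 1, rec)

    def _validate(self):
        seen = set()
        for g in self.genes:
            if g.symbol in seen:
                raise ValidationError(f"duplicate gene symbol {g.symbol!r} in snapshot")
            seen.add(g.symbol)
        for name in SNAPSHOT_TABLES:
            for rec in getattr(self, name):
                if rec.interval.assembly not in (self.assembly, Assembly.UNSPECIFIED):
                    raise ValidationError(
                        f"{name} record {rec.interval} not on snapshot assembly "
                        f"{self.assembly.value}"
                    )
                src = getattr(rec, "source_date", None)
                if src is not None and src > self.snapshot_date:
                    raise ValidationError(
                        f"{name} record {rec.interval} post-dates snapshot "
                        f"({src} > {self.snapshot_date})"
                    )

    # -- queries ------------------------------------------------------------

    def _check_assembly(self, interval: GenomicInterval):
        if interval.assembly not in (self.assembly, Assembly.UNSPECIFIED):
            raise AssemblyMismatchError(
                f"query on {interval.assembly.value} vs snapshot "
                f"{self.assembly.value}; liftover first"
            )

    def _overlapping(self, table: str, interval: GenomicInterval):
        tree = self._trees[table].get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end + 1)]
        return sorted(hits, key=lambda r: (r.interval.start, r.interval.end))

    def genes_in(self, interval: GenomicInterval):
        """Genes overlapping >=1 bp, each labelled full (gene inside query) or partial."""
        self._check_assembly(interval)
        out = []
        for gene in self._overlapping("genes", interval):
            cont = (
                Containment.FULL
                if interval.contains(gene.interval)
                else Containment.PARTIAL
            )
            out.append((gene, cont))
        return out

    def population_support(
        self,
        interval: GenomicInterval,
        cnv_type: CNVType,
        min_recip: float = 0.7,
        common_frequency: float = 0.01,
        common_carriers: int = 5,
    ):
        """Population CNVs of the same type at reciprocal overlap >= min_recip.

        Returns (record, reciprocal_overlap, common_flag) sorted by overlap
        descending.  ``common`` is set when frequency >= common_frequency OR
        n_carriers >= common_carriers in that cohort — the looser carrier arm
        captures "seen in the general population in at least one cohort".
        """
        if not (0 < min_recip <= 1):
            raise ValueError(f"min_recip must be in (0,1], got {min_recip}")
        self._check_assembly(interval)
        out = []
        for rec in self._overlapping("population", interval):
            if rec.cnv_type != cnv_type:
                continue
            ro = reciprocal_overlap(interval, rec.interval)
            if ro >= min_recip:
                common = (
                    rec.frequency >= common_frequency
                    or rec.n_carriers >= common_carriers
                )
                out.append((rec, ro, common))
        out.sort(key=lambda t: -t[1])
        return out

    def dosage_and_recurrent_hits(self, interval: GenomicInterval, cnv_type: CNVType):
        """Dosage records with containment + recurrent regions with overlap.

        Recurrent hits carry the reciprocal overlap and a query-larger flag
        (True when the query CNV extends beyond the curated region, as for a
        duplication larger than a classical syndrome region).
        """
        self._check_assembly(interval)
        dosage_hits = []
        for rec in self._overlapping("dosage", interval):
            cont = (
                Containment.FULL
                if interval.contains(rec.interval)
                else Containment.PARTIAL
            )
            dosage_hits.append((rec, cont))
        recurrent_hits = []
        for rec in self._overlapping("recurrent", interval):
            ro = reciprocal_overlap(interval, rec.interval)
            query_larger = interval.length > rec.interval.length
            recurrent_hits.append((rec, ro, query_larger))
        return dosage_hits, recurrent_hits

    def literature_for(
        self, interval: GenomicInterval, cnv_type: CNVType, min_recip: float = 0.7
    ):
        """Literature case records of the same type at reciprocal overlap >= min_recip."""
        self._check_assembly(interval)
        out = []
        for rec in self._overlapping("literature", interval):
            if rec.cnv_type != cnv_type:
                continue
            ro = reciprocal_overlap(interval, rec.interval)
            if ro >= min_recip:
                out.append((rec, ro))
        out.sort(key=lambda t: -t[1])
        return out

    # -- persistence --------------------------------------------------------

    def to_frames(self) -> dict:
        def ivl(r):
            return {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
            }

        frames = {
            "genes": pd.DataFrame(
                [
                    {
                        "symbol": g.symbol,
                        **ivl(g),
                        "is_protein_coding": int(g.is_protein_coding),
                        "omim_morbid": int(g.omim_morbid),
                    }
                    for g in self.genes
                ],
                columns=[
                    "symbol", "chrom", "start", "end",
                    "is_protein_coding", "omim_morbid",
                ],
            ),
            "dosage": pd.DataFrame(
                [
                    {
                        "target": d.target,
                        **ivl(d),
                        "haploinsufficiency": d.haploinsufficiency.value,
                        "triplosensitivity": d.triplosensitivity.value,
                        "source_date": d.source_date.isoformat(),
                    }
                    for d in self.dosage
                ],
                columns=[
                    "target", "chrom", "start", "end",
                    "haploinsufficiency", "triplosensitivity", "source_date",
                ],
            ),
            "recurrent": pd.DataFrame(
                [
                    {
                        "name": r.name,
                        **ivl(r),
                        "cnv_type": r.cnv_type.value,
                        "established_class": r.established_class.label,
                        "penetrance": r.penetrance.value,
                        "source_date": r.source_date.isoformat(),
                    }
                    for r in self.recurrent
                ],
                columns=[
                    "name", "chrom", "start", "end", "cnv_type",
                    "established_class", "penetrance", "source_date",
                ],
            ),
            "population": pd.DataFrame(
                [
                    {
                        **ivl(p),
                        "cnv_type": p.cnv_type.value,
                        "cohort_name": p.cohort_name,
                        "n_carriers": p.n_carriers,
                        "cohort_size": p.cohort_size,
                        "source_date": p.source_date.isoformat(),
                    }
                    for p in self.population
                ],
                columns=[
                    "chrom", "start", "end", "cnv_type", "cohort_name",
                    "n_carriers", "cohort_size", "source_date",
                ],
            ),
            "literature": pd.DataFrame(
                [
                    {
                        **ivl(c),
                        "cnv_type": c.cnv_type.value,
                        "n_de_novo_consistent": c.n_de_novo_consistent,
                        "n_unknown_inheritance": c.n_unknown_inheritance,
                        "phenotype_specificity": c.phenotype_specificity.value,
                        "source_date": c.source_date.isoformat(),
                    }
                    for c in self.literature
                ],
                columns=[
                    "chrom", "start", "end", "cnv_type", "n_de_novo_consistent",
                    "n_unknown_inheritance", "phenotype_specificity", "source_date",
                ],
            ),
        }
        return frames

    def write(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "snapshot_date": self.snapshot_date.isoformat(),
            "assembly": self.assembly.value,
            "provenance": self.provenance,
        }
        (directory / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True)
        )


def _iv(row, assembly: Assembly) -> GenomicInterval:
    return GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), assembly)


def load_snapshot(directory) -> KnowledgeSnapshot:
    """Load and validate a snapshot directory (five TSV tables + manifest.yaml).

    Missing tables raise an error naming the table; rows violating record
    invariants raise row-level validation errors.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"snapshot manifest missing: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    assembly = Assembly(manifest["assembly"])
    snapshot_date = _parse_date(manifest["snapshot_date"])

    tables = {}
    for name in SNAPSHOT_TABLES:
        path = directory / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"snapshot table missing: {name}.tsv")
        tables[name] = pd.read_csv(path, sep="\t", dtype={"chrom": str})

    def rowwise(frame, builder, name):
        out = []
        for i, row in frame.iterrows():
            try:
                out.append(builder(row))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{name}.tsv row {i + 2}: {exc}") from exc
        return out

    genes = rowwise(
        tables["genes"],
        lambda r: GeneModel(
            symbol=str(r["symbol"]),
            interval=_iv(r, assembly),
            is_protein_coding=bool(int(r["is_protein_coding"])),
            omim_morbid=bool(int(r["omim_morbid"])),
        ),
        "genes",
    )
    dosage = rowwise(
        tables["dosage"],
        lambda r: DosageRecord(
            target=str(r["target"]),
            interval=_iv(r, assembly),
            haploinsufficiency=DosageLevel(r["haploinsufficiency"]),
            triplosensitivity=DosageLevel(r["triplosensitivity"]),
            source_date=_parse_date(r["source_date"]),
        ),
        "dosage",
    )
    recurrent = rowwise(
        tables["recurrent"],
        lambda r: RecurrentRegion(
            name=str(r["name"]),
            interval=_iv(r, assembly),
            cnv_type=CNVType(r["cnv_type"]),
            established_class=Classification.from_label(r["established_class"]),
            penetrance=Penetrance(r["penetrance"]),
            source_date=_parse_date(r["source_date"]),
        ),
        "recurrent",
    )
    population = rowwise(
        tables["population"],
        lambda r: PopulationCNV(
            interval=_iv(r, assembly),
            cnv_type=CNVType(r["cnv_type"]),
            cohort_name=str(r["cohort_name"]),
            n_carriers=int(r["n_carriers"]),
            cohort_size=int(r["cohort_size"]),
            source_date=_parse_date(r["source_date"]),
        ),
        "population",
    )
    literature = rowwise(
        tables["literature"],
        lambda r: LiteratureCase(
            interval=_iv(r, assembly),
            cnv_type=CNVType(r["cnv_type"]),
            n_de_novo_consistent=int(r["n_de_novo_consistent"]),
            n_unknown_inheritance=int(r["n_unknown_inheritance"]),
            phenotype_specificity=PhenotypeSpecificity(r["phenotype_specificity"]),
            source_date=_parse_date(r["source_date"]),
        ),
        "literature",
    )
    return KnowledgeSnapshot(
        snapshot_date=snapshot_date,
        assembly=assembly,
        genes=genes,
        dosage=dosage,
        recurrent=recurrent,
        population=population,
        literature=literature,
        provenance=str(manifest.get("provenance", "")),
    )


# Module-level functional aliases mirroring the query surface.

def genes_in(snapshot: KnowledgeSnapshot, interval: GenomicInterval):
    return snapshot.genes_in(interval)


def population_support(
    snapshot: KnowledgeSnapshot,
    interval: GenomicInterval,
    cnv_type: CNVType,
    min_recip: float = 0.7,
    **kwargs,
):
    return snapshot.population_support(interval, cnv_type, min_recip, **kwargs)


def dosage_and_recurrent_hits(
    snapshot: KnowledgeSnapshot, interval: GenomicInterval, cnv_type: CNVType
):
    return snapshot.dosage_and_recurrent_hits(interval, cnv_type)
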