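"""Mapping from knowledge-base query results to rubric evidence items.

This implements the machine-derivable part of CNV curation: gene content
(section 1), established dosage-sensitive genes and recurrent regions
(section 2), gene-count bins (section 3), population frequency and published
case counts (section 4), and proband inheritance (section 5).  Sections that
need patient-level judgement — phenotype fit, segregation counts,
case-control statistics — are reachable only through :func:`merge_manual`,
mirroring diagnostic practice of an automatic screen followed by expert
curation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .core import (
    CNVCall,
    CNVType,
    Inheritance,
    ValidationError,
)
from .knowledge import (
    Containment,
    DosageLevel,
    KnowledgeSnapshot,
    PhenotypeSpecificity,
)
from .core import Classification

__all__ = [
    "EvidenceSource",
    "EvidenceItem",
    "BundleMode",
    "EvidenceBundle",
    "EvidenceConfig",
    "build_evidence",
    "merge_manual",
]


class EvidenceSource(str, enum.Enum):
    GENE_CONTENT = "gene_content"
    DOSAGE_MAP = "dosage_map"
    RECURRENT_REGION = "recurrent_region"
    POPULATION = "population"
    LITERATURE = "literature"
    INHERITANCE = "inheritance"
    MANUAL = "manual"


@dataclass(frozen=True)
class EvidenceItem:
    section_code: str
    points: float
    rationale: str
    source: EvidenceSource


class BundleMode(str, enum.Enum):
    AUTOMATIC = "automatic"
    CURATED = "curated"


@dataclass
class EvidenceBundle:
    cnv_id: str
    snapshot_date: object
    items: list
    mode: BundleMode = BundleMode.AUTOMATIC

    def __post_init__(self):
        if self.mode is BundleMode.AUTOMATIC and any(
            i.source is EvidenceSource.MANUAL for i in self.items
        ):
            raise ValidationError(
                f"bundle {self.cnv_id}: automatic mode cannot contain manual items"
            )


@dataclass(frozen=True)
class EvidenceConfig:
    """Tunables of the automatic evidence mapping.

    min_recip: reciprocal overlap for population / literature matching (the
    community's 'same CNV' convention).  common_frequency / common_carriers:
    the two arms of the 'common in the general population' call — a cohort
    frequency of at least 1 %, or at least 5 carriers in a single cohort.
    moderate_population_points: points for a multi-carrier match below the
    frequency arm.  recurrent_recip: reciprocal overlap accepted for a
    recurrent-region match when the region is not fully contained in the
    query.  literature_points: de-novo-case-count -> points ladder, capped
    by the section-4 range.
    """

    min_recip: float = 0.7
    common_frequency: float = 0.01
    common_carriers: int = 5
    strong_population_points: float = -1.0
    moderate_population_points: float = -0.9
    recurrent_recip: float = 0.8
    literature_points: tuple = ((3, 0.9), (2, 0.6), (1, 0.45))
    # De novo occurrence is recorded automatically, but its points require a
    # judgement of phenotype consistency, which is curation work: the
    # automatic item defaults to 0 and a manual 5A item assigns the value.
    automatic_de_novo_points: float = 0.0
    unaffected_parent_points: float = -0.3


def _codes(cnv_type: CNVType) -> dict:
    p = "L" if cnv_type is CNVType.LOSS else "G"
    return {k: f"{p}{k}" for k in
            ("1A", "1B", "2A", "2C", "2F", "3A", "3B", "3C", "4", "4O", "5A", "5D", "5F")}


def _gene_count_bin(cnv_type: CNVType, n: int) -> tuple:
    if cnv_type is CNVType.LOSS:
        if n >= 35:
            return "3C", 0.9
        if n >= 25:
            return "3B", 0.45
        return "3A", 0.0
    if n >= 50:
        return "3C", 0.9
    if n >= 35:
        return "3B", 0.45
    return "3A", 0.0


def build_evidence(
    call: CNVCall,
    snapshot: KnowledgeSnapshot,
    config: EvidenceConfig = EvidenceConfig(),
) -> EvidenceBundle:
    """Derive an automatic evidence bundle for one CNV against one snapshot.

    Pure function of (call, snapshot, config): identical inputs produce
    identical bundles.  Assembly mismatches raise before any query runs.
    """
    cnv_type = call.cnv_type
    iv = call.interval
    C = _codes(cnv_type)
    items: list[EvidenceItem] = []

    # Section 1 + 3: gene content
    gene_hits = snapshot.genes_in(iv)
    coding = [(g, c) for g, c in gene_hits if g.is_protein_coding]
    if coding:
        items.append(
            EvidenceItem(
                C["1A"], 0.0,
                f"contains {len(coding)} protein-coding gene(s): "
                + ", ".join(g.symbol for g, _ in coding[:6])
                + ("..." if len(coding) > 6 else ""),
                EvidenceSource.GENE_CONTENT,
            )
        )
        bin_suffix, pts = _gene_count_bin(cnv_type, len(coding))
        items.append(
            EvidenceItem(
                C[bin_suffix], pts,
                f"{len(coding)} protein-coding genes in interval",
                EvidenceSource.GENE_CONTENT,
            )
        )
    else:
        items.append(
            EvidenceItem(
                C["1B"], -0.6,
                "no protein-coding gene content",
                EvidenceSource.GENE_CONTENT,
            )
        )

    # Section 2: dosage map + recurrent regions
    dosage_hits, recurrent_hits = snapshot.dosage_and_recurrent_hits(iv, cnv_type)
    level_attr = (
        "haploinsufficiency" if cnv_type is CNVType.LOSS else "triplosensitivity"
    )
    best_full = best_partial = None
    for rec, cont in dosage_hits:
        if getattr(rec, level_attr) is not DosageLevel.SUFFICIENT_EVIDENCE:
            continue
        if cont is Containment.FULL and best_full is None:
            best_full = rec
        elif cont is Containment.PARTIAL and best_partial is None:
            best_partial = rec
    if best_full is not None:
        items.append(
            EvidenceItem(
                C["2A"], 1.0,
                f"complete overlap of established "
                f"{'HI' if cnv_type is CNVType.LOSS else 'TS'} gene "
                f"{best_full.target or str(best_full.interval)}",
                EvidenceSource.DOSAGE_MAP,
            )
        )
    elif best_partial is not None and cnv_type is CNVType.LOSS:
        # Partial gene disruption: suggested 0.90 pending breakpoint review.
        items.append(
            EvidenceItem(
                C["2C"], 0.9,
                f"partial overlap of established HI gene "
                f"{best_partial.target or str(best_partial.interval)} "
                "involving coding sequence",
                EvidenceSource.DOSAGE_MAP,
            )
        )
    if best_full is None:
        for rec, ro, query_larger in recurrent_hits:
            if rec.cnv_type != cnv_type:
                continue
            if rec.established_class is Classification.PATHOGENIC:
                contained = iv.contains(rec.interval)
                if contained or ro >= config.recurrent_recip:
                    side = "query larger than region" if query_larger else (
                        "query within/at region")
                    items.append(
                        EvidenceItem(
                            C["2A"], 1.0,
                            f"overlap of established recurrent {cnv_type.value} "
                            f"region {rec.name} "
                            f"(reciprocal {ro:.2f}, {side}, "
                            f"penetrance {rec.penetrance.value})",
                            EvidenceSource.RECURRENT_REGION,
                        )
                    )
                    break
    for rec, ro, query_larger in recurrent_hits:
        if (
            rec.established_class is Classification.BENIGN
            and rec.cnv_type == cnv_type
            and rec.interval.contains(iv)
        ):
            items.append(
                EvidenceItem(
                    C["2F"] if cnv_type is CNVType.LOSS else f"G2D",
                    -1.0,
                    f"contained within established benign region {rec.name}",
                    EvidenceSource.RECURRENT_REGION,
                )
            )
            break

    # Section 4: population frequency (benign direction) and literature cases
    pop = snapshot.population_support(
        iv, cnv_type, config.min_recip,
        common_frequency=config.common_frequency,
        common_carriers=config.common_carriers,
    )
    common = [(rec, ro) for rec, ro, is_common in pop if is_common]
    if common:
        rec, ro = common[0]
        strong = rec.frequency >= config.common_frequency
        pts = (
            config.strong_population_points
            if strong
            else config.moderate_population_points
        )
        items.append(
            EvidenceItem(
                C["4O"], pts,
                f"overlapping {cnv_type.value} in general population: "
                f"{rec.cohort_name} {rec.n_carriers}/{rec.cohort_size} "
                f"(freq {rec.frequency:.4f}, reciprocal {ro:.2f}, "
                f"{'frequency' if strong else 'carrier-count'} arm)",
                EvidenceSource.POPULATION,
            )
        )
    lit = snapshot.literature_for(iv, cnv_type, config.min_recip)
    n_dn = sum(
        rec.n_de_novo_consistent
        for rec, _ in lit
        if rec.phenotype_specificity is PhenotypeSpecificity.CONSISTENT
    )
    if n_dn > 0:
        pts = 0.0
        for threshold, value in config.literature_points:
            if n_dn >= threshold:
                pts = value
                break
        items.append(
            EvidenceItem(
                C["4"], pts,
                f"{n_dn} published de novo case(s) with consistent phenotype "
                f"across {len(lit)} matching report(s)",
                EvidenceSource.LITERATURE,
            )
        )

    # Section 5: proband inheritance (applied once per call)
    inh = call.inheritance
    if inh is Inheritance.DE_NOVO:
        items.append(
            EvidenceItem(
                C["5A"], config.automatic_de_novo_points,
                "de novo occurrence in the proband "
                "(phenotype consistency left to curation)",
                EvidenceSource.INHERITANCE,
            )
        )
    elif inh.is_inherited:
        if call.parent_affected is False:
            items.append(
                EvidenceItem(
                    C["5D"], config.unaffected_parent_points,
                    f"inherited ({inh.value}) from an unaffected parent",
                    EvidenceSource.INHERITANCE,
                )
            )
        else:
            items.append(
                EvidenceItem(
                    C["5F"], 0.0,
                    f"inherited ({inh.value}); parental phenotype not assessed",
                    EvidenceSource.INHERITANCE,
                )
            )
    # non_maternal / non_paternal / unknown contribute no points and no item.

    return EvidenceBundle(
        cnv_id=call.id,
        snapshot_date=snapshot.snapshot_date,
        items=items,
        mode=BundleMode.AUTOMATIC,
    )


def merge_manual(
    bundle: EvidenceBundle,
    manual_items: Iterable[EvidenceItem],
    rubric=None,
) -> EvidenceBundle:
    """Fold curator-supplied items into an automatic bundle.

    A manual item replaces every automatic item with the same section code;
    other manual items are appended.  The result is a curated bundle; the
    input bundle is left untouched.  When a rubric is given, manual points
    outside their section's configured range are rejected.
    """
    manual_items = list(manual_items)
    for item in manual_items:
        if item.source is not EvidenceSource.MANUAL:
            raise ValidationError(
                f"manual item for {bundle.cnv_id} has source {item.source.value}"
            )
        if rubric is not None:
            rng = rubric.section(item.section_code)
            if not (rng.min_points <= item.points <= rng.max_points):
                raise ValidationError(
                    f"manual item {item.section_code} for {bundle.cnv_id}: points "
                    f"{item.points} outside range "
                    f"[{rng.min_points}, {rng.max_points}]"
                )
    override_codes = {i.section_code for i in manual_items}
    kept = [i for i in bundle.items if i.section_code not in override_codes]
    return EvidenceBundle(
        cnv_id=bundle.cnv_id,
        snapshot_date=bundle.snapshot_date,
        items=kept + manual_items,
        mode=BundleMode.CURATED,
    )
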