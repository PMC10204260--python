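"""Tabular I/O: cohort tables, manual evidence, result exports, BED.

Cohort TSVs carry 1-based inclusive coordinates (plus the canonical ISCN
string for readability); BED export converts to 0-based half-open at this
boundary.  Cohort-level metadata (total test count, snapshot dates) ride in
``# key=value`` header comments.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .acmg import ACMGResult
from .core import (
    Assembly,
    Classification,
    CNVCall,
    CNVType,
    CopyState,
    GenomicInterval,
    Inheritance,
    Sex,
    TestContext,
    format_iscn,
    parse_iscn_one,
)
from .evidence import EvidenceItem, EvidenceSource
from .reanalysis import CohortStudy

__all__ = [
    "COHORT_COLUMNS",
    "write_cohort",
    "read_cohort",
    "write_manual_evidence",
    "read_manual_evidence",
    "write_results",
    "cohort_to_bed",
]

COHORT_COLUMNS = [
    "id", "patient_id", "iscn", "chrom", "start", "end", "band",
    "copy_low", "copy_high", "cnv_type", "inheritance", "sex",
    "test_year", "context", "initial_class", "final_class",
    "phenotype", "assembly",
]


def _call_row(call: CNVCall) -> dict:
    return {
        "id": call.id,
        "patient_id": call.patient_id,
        "iscn": str(format_iscn(call)),
        "chrom": call.interval.chrom,
        "start": call.interval.start,
        "end": call.interval.end,
        "band": call.band,
        "copy_low": call.copy_state.low,
        "copy_high": call.copy_state.high,
        "cnv_type": call.cnv_type.value,
        "inheritance": call.inheritance.value,
        "sex": call.patient_sex.value,
        "test_year": call.test_year,
        "context": call.context.value,
        "initial_class": call.initial_class.label,
        "final_class": call.final_class.label if call.final_class else "",
        "phenotype": ";".join(call.phenotype),
        "assembly": call.interval.assembly.value,
    }


def write_cohort(cohort: CohortStudy, path) -> None:
    path = Path(path)
    header = (
        f"# n_total_tests={cohort.n_total_tests}\n"
        f"# initial_snapshot_date={cohort.initial_snapshot_date or ''}\n"
        f"# reanalysis_snapshot_date={cohort.reanalysis_snapshot_date or ''}\n"
    )
    frame = pd.DataFrame([_call_row(c) for c in cohort.calls], columns=COHORT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def read_cohort(path) -> CohortStudy:
    """Read a cohort TSV; rows may give coordinates or only an ISCN string."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        text = line.lstrip("#").strip()
        if "=" in text:
            k, v = text.split("=", 1)
            meta[k.strip()] = v.strip()
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                        dtype={"chrom": str, "band": str}, keep_default_na=False)
    calls = []
    for _, row in frame.iterrows():
        if str(row.get("chrom", "")) and str(row.get("start", "")) != "":
            interval = GenomicInterval(
                str(row["chrom"]), int(row["start"]), int(row["end"]),
                Assembly(row.get("assembly", "unspecified") or "unspecified"),
            )
            band = str(row.get("band", "") or "")
            cs = CopyState(int(row["copy_low"]), int(row["copy_high"]))
        else:
            rec = parse_iscn_one(str(row["iscn"]))
            interval, band, cs = rec.interval, rec.band, rec.copy_state
        type_label = None
        if str(row.get("cnv_type", "")):
            type_label = CNVType(str(row["cnv_type"]))
        final = str(row.get("final_class", "") or "")
        calls.append(
            CNVCall(
                id=str(row["id"]),
                interval=interval,
                band=band,
                copy_state=cs,
                inheritance=Inheritance(str(row["inheritance"])),
                patient_id=str(row["patient_id"]),
                patient_sex=Sex(str(row["sex"])),
                test_year=int(row["test_year"]),
                context=TestContext(str(row["context"])),
                initial_class=Classification.from_label(str(row["initial_class"])),
                final_class=Classification.from_label(final) if final else None,
                phenotype=tuple(p for p in str(row.get("phenotype", "")).split(";") if p),
                type_label=type_label,
            )
        )

    def _date(key):
        v = meta.get(key, "")
        return dt.date.fromisoformat(v) if v else None

    return CohortStudy(
        calls=calls,
        n_total_tests=int(meta.get("n_total_tests", 0) or 0),
        initial_snapshot_date=_date("initial_snapshot_date"),
        reanalysis_snapshot_date=_date("reanalysis_snapshot_date"),
    )


def write_manual_evidence(manual: dict, path) -> None:
    """Write curator evidence: one row per (cnv_id, section_code)."""
    rows = [
        {
            "cnv_id": cnv_id,
            "section_code": item.section_code,
            "points": item.points,
            "rationale": item.rationale,
        }
        for cnv_id, items in manual.items()
        for item in items
    ]
    pd.DataFrame(rows, columns=["cnv_id", "section_code", "points", "rationale"]).to_csv(
        path, sep="\t", index=False
    )


def read_manual_evidence(path) -> dict:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    manual: dict = {}
    for _, row in frame.iterrows():
        manual.setdefault(str(row["cnv_id"]), []).append(
            EvidenceItem(
                section_code=str(row["section_code"]),
                points=float(row["points"]),
                rationale=str(row["rationale"]),
                source=EvidenceSource.MANUAL,
            )
        )
    return manual


def write_results(results: Iterable, path, header_comment: str = "") -> None:
    """Export scored results as TSV (cnv_id, score, class, per-section columns)."""
    results = list(results)
    acmg = [r[0] if isinstance(r, tuple) else r for r in results]
    codes = sorted({code for r in acmg for code in r.per_section})
    rows = []
    for r in acmg:
        row = {
            "cnv_id": r.cnv_id,
            "total_score": f"{r.total_score:.2f}",
            "classification": r.classification.label,
            "rubric_version": r.rubric_version,
            "snapshot_date": r.snapshot_date or "",
        }
        for code in codes:
            row[code] = (
                f"{r.per_section[code]:.2f}" if code in r.per_section else ""
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def cohort_to_bed(cohort: CohortStudy, path) -> None:
    """BED4+ export: 0-based half-open, name=id, extra columns as key=value."""
    with open(Path(path), "w") as fh:
        for call in cohort.calls:
            extras = ";".join(
                [
                    f"type={call.cnv_type.value}",
                    f"copy={call.copy_state}",
                    f"inheritance={call.inheritance.value}",
                    f"patient={call.patient_id}",
                    f"year={call.test_year}",
                ]
            )
            fh.write(
                f"chr{call.interval.chrom}\t{call.interval.start - 1}\t"
                f"{call.interval.end}\t{call.id}\t{extras}\n"
            )
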