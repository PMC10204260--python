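"""Point aggregation and classification under the 2020 ACMG/ClinGen CNV rubric.

Scores are totted up in integer hundredths (fixed point) so that the
published category boundaries (0.99 / 0.90 / -0.90 / -0.99) never suffer
float rounding: +0.90 is likely pathogenic, +0.89 is uncertain, exactly.
Each evidence item is clamped to its section's configured range *before*
summation, matching the per-category maxima of the published tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .core import Classification, ValidationError
from .evidence import EvidenceBundle, EvidenceItem

__all__ = [
    "SectionRange",
    "RubricConfig",
    "ACMGResult",
    "load_rubric",
    "score_bundle",
    "classify",
    "explain",
]


def to_hundredths(points: float) -> int:
    # round-half-away-from-zero keeps +-0.005 inputs symmetric
    scaled = points * 100
    return int(scaled + 0.5) if scaled >= 0 else -int(-scaled + 0.5)


@dataclass(frozen=True)
class SectionRange:
    code: str
    min_points: float
    max_points: float
    default_points: float
    description: str = ""

    def __post_init__(self):
        if not (self.min_points <= self.default_points <= self.max_points):
            raise ValidationError(
                f"section {self.code}: require min <= default <= max"
            )

    def clamp(self, points: float) -> float:
        return min(self.max_points, max(self.min_points, points))


@dataclass
class RubricConfig:
    """Versioned point table + classification thresholds (hundredths)."""

    version: str
    sections: dict  # code -> SectionRange (loss and gain codes together)
    pathogenic_min: int = 99
    likely_pathogenic_min: int = 90
    likely_benign_max: int = -90
    benign_max: int = -99

    def __post_init__(self):
        if not (
            self.benign_max < self.likely_benign_max < 0
            < self.likely_pathogenic_min < self.pathogenic_min
        ):
            raise ValidationError("rubric thresholds are not properly ordered")

    def section(self, code: str) -> SectionRange:
        try:
            return self.sections[code]
        except KeyError:
            raise ValidationError(
                f"unknown section code {code!r} for rubric {self.version}"
            ) from None


def load_rubric(version: str = "v2020") -> RubricConfig:
    """Load a packaged rubric point table by version tag."""
    ref = resources.files("cnvreclass.data").joinpath(f"rubric_{version}.yaml")
    raw = yaml.safe_load(ref.read_text())
    sections = {}
    for side in ("loss", "gain"):
        for code, entry in raw["sections"][side].items():
            sections[code] = SectionRange(
                code=code,
                min_points=float(entry["min"]),
                max_points=float(entry["max"]),
                default_points=float(entry["default"]),
                description=str(entry.get("description", "")),
            )
    th = raw["thresholds_hundredths"]
    return RubricConfig(
        version=str(raw["version"]),
        sections=sections,
        pathogenic_min=int(th["pathogenic_min"]),
        likely_pathogenic_min=int(th["likely_pathogenic_min"]),
        likely_benign_max=int(th["likely_benign_max"]),
        benign_max=int(th["benign_max"]),
    )


def classify(score: float, rubric: RubricConfig) -> Classification:
    """Map a total score to the unique category whose range contains it."""
    h = to_hundredths(score)
    if h >= rubric.pathogenic_min:
        return Classification.PATHOGENIC
    if h >= rubric.likely_pathogenic_min:
        return Classification.LIKELY_PATHOGENIC
    if h <= rubric.benign_max:
        return Classification.BENIGN
    if h <= rubric.likely_benign_max:
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN


@dataclass
class ACMGResult:
    cnv_id: str
    total_score: float
    classification: Classification
    per_section: dict  # code -> clamped points
    rubric_version: str
    snapshot_date: Optional[dt.date] = None

    @property
    def score_hundredths(self) -> int:
        return to_hundredths(self.total_score)


def score_bundle(bundle: EvidenceBundle, rubric: RubricConfig) -> ACMGResult:
    """Clamp each item to its section range, sum, classify.

    All items must come from a single rubric side (loss codes L*, gain codes
    G*); mixing raises an error, as does any unknown section code.
    """
    sides = {item.section_code[0].upper() for item in bundle.items}
    if not sides <= {"L", "G"}:
        bad = sorted(c for c in sides if c not in "LG")
        raise ValidationError(f"unrecognized section code prefix(es): {bad}")
    if len(sides) > 1:
        raise ValidationError(
            f"bundle {bundle.cnv_id} mixes loss and gain section codes"
        )
    per_section: dict = {}
    total_h = 0
    for item in bundle.items:
        rng = rubric.section(item.section_code)
        clamped = rng.clamp(item.points)
        per_section[item.section_code] = (
            per_section.get(item.section_code, 0.0) + clamped
        )
        total_h += to_hundredths(clamped)
    total = total_h / 100.0
    return ACMGResult(
        cnv_id=bundle.cnv_id,
        total_score=total,
        classification=classify(total, rubric),
        per_section=per_section,
        rubric_version=rubric.version,
        snapshot_date=bundle.snapshot_date,
    )


def explain(result: ACMGResult, bundle: EvidenceBundle) -> str:
    """Deterministic per-section audit report for one scored CNV."""
    if result.cnv_id != bundle.cnv_id:
        raise ValidationError(
            f"result is for {result.cnv_id!r} but bundle is for {bundle.cnv_id!r}"
        )
    lines = [
        f"# ACMG evidence report: {result.cnv_id}",
        f"rubric: {result.rubric_version}    "
        f"snapshot: {result.snapshot_date}    mode: {bundle.mode.value}",
        "",
        "| section | points | source | rationale |",
        "|---------|--------|--------|-----------|",
    ]
    for item in sorted(bundle.items, key=lambda i: (i.section_code, i.source.value)):
        lines.append(
            f"| {item.section_code} | {item.points:+.2f} | {item.source.value} "
            f"| {item.rationale} |"
        )
    if not bundle.items:
        lines.append("| (none) | +0.00 | - | no evidence: all sections zero |")
    lines += [
        "",
        f"total score: {result.total_score:+.2f}",
        f"classification: {result.classification.label}",
        "",
    ]
    return "\n".join(lines)
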