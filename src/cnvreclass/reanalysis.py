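"""Study orchestration: reinterpretation of a VUS cohort against a knowledge
snapshot, and the automatic triage screen that decides which CNVs need
manual curation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .acmg import ACMGResult, RubricConfig, load_rubric, score_bundle
from .core import Classification, ClassChange, CNVCall, ValidationError
from .evidence import (
    EvidenceBundle,
    EvidenceConfig,
    build_evidence,
    merge_manual,
)
from .knowledge import KnowledgeSnapshot

__all__ = [
    "CohortStudy",
    "TriageResult",
    "reanalyze",
    "triage",
    "change_table",
    "REANALYSIS_INTERVAL_MONTHS",
]

# Recommended maximum age of the knowledge snapshot relative to the last
# review before a re-run is advised (documentation + CLI warning only).
REANALYSIS_INTERVAL_MONTHS = 24


@dataclass
class CohortStudy:
    """Patients x CNVs substrate of the study statistics.

    ``calls`` hold initially-VUS CNVs only; ``n_total_tests`` is the number
    of array tests the VUS cohort was drawn from (used for the VUS-bearing
    test fraction).
    """

    calls: list
    n_total_tests: int = 0
    initial_snapshot_date: Optional[dt.date] = None
    reanalysis_snapshot_date: Optional[dt.date] = None

    def __post_init__(self):
        # The study cohort is VUS-only; anything else is excluded at load.
        self.calls = [
            c for c in self.calls if c.initial_class is Classification.UNCERTAIN
        ]

    @property
    def patients(self) -> dict:
        index: dict = {}
        for call in self.calls:
            index.setdefault(call.patient_id, []).append(call)
        return index

    @property
    def n_patients(self) -> int:
        return len({c.patient_id for c in self.calls})

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def reanalyze(
    cohort: CohortStudy,
    snapshot: KnowledgeSnapshot,
    manual_evidence: Optional[Mapping] = None,
    rubric: Optional[RubricConfig] = None,
    config: EvidenceConfig = EvidenceConfig(),
):
    """Re-score every call against a snapshot; returns [(ACMGResult, ClassChange)].

    Per call: build automatic evidence, optionally merge the curator's manual
    items (``manual_evidence`` maps cnv_id -> list of EvidenceItem), score,
    and compare with the initial class.  Deterministic given its inputs; the
    input calls also get ``final_class`` set for downstream statistics.
    """
    rubric = rubric or load_rubric()
    results = []
    for call in cohort.calls:
        if call.initial_class is None:
            raise ValidationError(f"call {call.id} lacks an initial class")
        bundle = build_evidence(call, snapshot, config)
        if manual_evidence and call.id in manual_evidence:
            bundle = merge_manual(bundle, manual_evidence[call.id], rubric)
        result = score_bundle(bundle, rubric)
        call.final_class = result.classification
        results.append(
            (
                result,
                ClassChange(
                    cnv_id=call.id,
                    from_class=call.initial_class,
                    to_class=result.classification,
                ),
            )
        )
    return results


@dataclass(frozen=True)
class TriageResult:
    cnv_id: str
    automatic_class: Classification

    @property
    def flagged_for_curation(self) -> bool:
        return self.automatic_class in (
            Classification.LIKELY_PATHOGENIC,
            Classification.PATHOGENIC,
        )


def triage(
    cohort: CohortStudy,
    snapshot: KnowledgeSnapshot,
    rubric: Optional[RubricConfig] = None,
    config: EvidenceConfig = EvidenceConfig(),
):
    """Automatic-only screen: classify every call without manual evidence.

    A call is flagged for manual curation iff its automatic class is likely
    pathogenic or pathogenic; downstream sensitivity/specificity compare the
    flags with the final curated classes.
    """
    rubric = rubric or load_rubric()
    out = []
    for call in cohort.calls:
        bundle = build_evidence(call, snapshot, config)
        result = score_bundle(bundle, rubric)
        out.append(TriageResult(cnv_id=call.id, automatic_class=result.classification))
    return out


def change_table(changes: Iterable[ClassChange]) -> pd.DataFrame:
    """5x5 from-class x to-class count matrix; diagonal = unchanged."""
    labels = [c.label for c in Classification]
    mat = pd.DataFrame(
        np.zeros((5, 5), dtype=int), index=labels, columns=labels
    )
    for ch in changes:
        mat.loc[ch.from_class.label, ch.to_class.label] += 1
    mat.index.name = "from"
    mat.columns.name = "to"
    return mat
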