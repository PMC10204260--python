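"""Cohort-level summary statistics of a reinterpretation study.

All percentages recompute exactly from underlying integer counts
(``fractions.Fraction`` internally); reported values round to one decimal,
matching the reporting style of clinical reinterpretation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ChangeDirection, Classification, ClassChange, CNVType
from .reanalysis import CohortStudy, TriageResult

__all__ = [
    "RateSummary",
    "ConfusionSummary",
    "TrendFit",
    "reclassification_rates",
    "confusion_metrics",
    "cumulative_trend",
    "compare_slopes",
    "breakdowns",
    "DEFAULT_SIZE_BINS",
]

_PLP = (Classification.LIKELY_PATHOGENIC, Classification.PATHOGENIC)


def _pct(fr: Fraction) -> float:
    return round(float(fr) * 100, 1)


@dataclass
class RateSummary:
    """Headline reclassification rates; exact fractions + 1-decimal percents."""

    n_patients: int
    n_calls: int
    n_patients_changed: int
    n_down: int
    n_up: int
    n_patients_plp: int
    n_total_tests: int = 0

    @property
    def patient_rate(self) -> Fraction:
        return Fraction(self.n_patients_changed, self.n_patients)

    @property
    def cnv_down_rate(self) -> Fraction:
        return Fraction(self.n_down, self.n_calls)

    @property
    def cnv_up_rate(self) -> Fraction:
        return Fraction(self.n_up, self.n_calls)

    @property
    def patient_plp_rate(self) -> Fraction:
        return Fraction(self.n_patients_plp, self.n_patients)

    @property
    def vus_test_rate(self) -> Optional[Fraction]:
        if self.n_total_tests <= 0:
            return None
        return Fraction(self.n_patients, self.n_total_tests)

    def as_percent(self) -> dict:
        out = {
            "patient_rate": _pct(self.patient_rate),
            "cnv_down_rate": _pct(self.cnv_down_rate),
            "cnv_up_rate": _pct(self.cnv_up_rate),
            "patient_plp_rate": _pct(self.patient_plp_rate),
        }
        if self.vus_test_rate is not None:
            out["vus_test_rate"] = _pct(self.vus_test_rate)
        return out


def reclassification_rates(
    cohort: CohortStudy, changes: Sequence[ClassChange]
) -> RateSummary:
    """Patient- and CNV-level reclassification rates.

    A patient counts as reclassified when at least one of their VUS calls
    changed class; the LP/P patient rate counts patients with at least one
    call ending likely pathogenic or pathogenic.
    """
    if not cohort.calls:
        raise ValueError("empty cohort")
    by_id = {ch.cnv_id: ch for ch in changes}
    patients = cohort.patients
    n_changed_patients = sum(
        any(
            by_id[c.id].direction is not ChangeDirection.NONE
            for c in calls
            if c.id in by_id
        )
        for calls in patients.values()
    )
    n_plp_patients = sum(
        any(c.id in by_id and by_id[c.id].to_class in _PLP for c in calls)
        for calls in patients.values()
    )
    dirs = [by_id[c.id].direction for c in cohort.calls if c.id in by_id]
    return RateSummary(
        n_patients=len(patients),
        n_calls=len(cohort.calls),
        n_patients_changed=n_changed_patients,
        n_down=sum(d is ChangeDirection.DOWN for d in dirs),
        n_up=sum(d is ChangeDirection.UP for d in dirs),
        n_patients_plp=n_plp_patients,
        n_total_tests=cohort.n_total_tests,
    )


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fn)

    def as_percent(self) -> dict:
        return {
            "sensitivity": _pct(self.sensitivity),
            "specificity": _pct(self.specificity),
            "precision": _pct(self.precision),
            "npv": _pct(self.npv),
        }


def confusion_metrics(
    triage_results: Sequence[TriageResult],
    final_classes: Sequence,
) -> ConfusionSummary:
    """2x2 table of the automatic LP/P flag against the final curated class.

    ``final_classes`` is either a parallel list of Classification, or a list
    of (cnv_id, Classification) pairs / dict keyed by cnv_id — in the keyed
    forms IDs must match the triage list exactly.
    """
    if isinstance(final_classes, dict):
        pairs = [(t, final_classes.get(t.cnv_id)) for t in triage_results]
        if any(f is None for _, f in pairs):
            raise ValueError("final classes missing for some triage cnv_ids")
    elif final_classes and isinstance(final_classes[0], tuple):
        lookup = dict(final_classes)
        if set(lookup) != {t.cnv_id for t in triage_results}:
            raise ValueError("cnv_id mismatch between triage and final lists")
        pairs = [(t, lookup[t.cnv_id]) for t in triage_results]
    else:
        if len(final_classes) != len(triage_results):
            raise ValueError("triage and final lists differ in length")
        pairs = list(zip(triage_results, final_classes))
    tp = fp = tn = fn = 0
    for t, final in pairs:
        pred = t.flagged_for_curation
        truth = final in _PLP
        if pred and truth:
            tp += 1
        elif pred:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class TrendFit:
    slope_pct_per_year: float
    intercept_pct: float
    r_squared: float
    slope_se_pct: float
    years: tuple
    cumulative_pct: tuple
    n_positive: int
    denominator: int


def cumulative_trend(
    cohort: CohortStudy,
    changes: Sequence[ClassChange],
    positive_set: str = "all",
) -> TrendFit:
    """OLS fit of the cumulative reclassified fraction against test year.

    For each test year y (ascending) the cumulative fraction is the number
    of reclassified calls with test_year <= y over the full call count.
    ``positive_set`` is 'all' (any class change) or 'plp' (calls ending
    likely pathogenic / pathogenic only).  The slope is reported in percent
    per year.
    """
    by_id = {c.id: c for c in cohort.calls}
    years_all = sorted({c.test_year for c in cohort.calls})
    if len(years_all) < 3:
        raise ValueError("cumulative trend needs >= 3 distinct test years")
    if positive_set == "all":
        positives = [
            ch for ch in changes if ch.direction is not ChangeDirection.NONE
        ]
    elif positive_set == "plp":
        positives = [ch for ch in changes if ch.to_class in _PLP]
    else:
        raise ValueError(f"positive_set must be 'all' or 'plp', not {positive_set!r}")
    denom = len(cohort.calls)
    pos_years = sorted(by_id[ch.cnv_id].test_year for ch in positives)
    cumulative = []
    for y in years_all:
        n = sum(1 for py in pos_years if py <= y)
        cumulative.append(100.0 * n / denom)
    x = np.array(years_all, dtype=float) - years_all[0]
    y = np.array(cumulative)
    fit = sps.linregress(x, y)
    return TrendFit(
        slope_pct_per_year=float(fit.slope),
        intercept_pct=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        slope_se_pct=float(fit.stderr),
        years=tuple(years_all),
        cumulative_pct=tuple(round(v, 4) for v in cumulative),
        n_positive=len(positives),
        denominator=denom,
    )


def compare_slopes(fit_a: TrendFit, fit_b: TrendFit) -> dict:
    """Two-sample t-style test on the slope difference of two trend fits.

    Uses the standard error of the slope difference with residual-based
    standard errors from each fit; df = n_a + n_b - 4.
    """
    diff = fit_a.slope_pct_per_year - fit_b.slope_pct_per_year
    se = float(np.hypot(fit_a.slope_se_pct, fit_b.slope_se_pct))
    df = len(fit_a.years) + len(fit_b.years) - 4
    if se == 0:
        p = 0.0 if diff != 0 else 1.0
        t = np.inf if diff != 0 else 0.0
    else:
        t = diff / se
        p = 2 * float(sps.t.sf(abs(t), df))
    return {
        "slope_difference_pct_per_year": diff,
        "se": se,
        "t": float(t),
        "df": df,
        "p_value": p,
        "method": "t test on slope difference, SE = sqrt(se_a^2 + se_b^2)",
    }


DEFAULT_SIZE_BINS = (
    ("<100 kb", 0, 100_000),
    ("100-500 kb", 100_000, 500_000),
    ("500 kb-1 Mb", 500_000, 1_000_000),
    (">=1 Mb", 1_000_000, None),
)


def breakdowns(
    cohort: CohortStudy,
    changes: Sequence[ClassChange],
    size_bins=DEFAULT_SIZE_BINS,
) -> dict:
    """Counts and change rates by size bin, CNV type, inheritance and context.

    Returns a dict of DataFrames.  The size table additionally reports the
    share of calls under 500 kb for three subsets (all VUS, downgraded,
    benign-only) because published summaries quote them under slightly
    different subset definitions.
    """
    by_id = {ch.cnv_id: ch for ch in changes}

    def direction(call):
        ch = by_id.get(call.id)
        return ch.direction if ch is not None else ChangeDirection.NONE

    rows = []
    for call in cohort.calls:
        ch = by_id.get(call.id)
        rows.append(
            {
                "id": call.id,
                "length": call.length,
                "cnv_type": call.cnv_type.value,
                "inheritance": call.inheritance.value,
                "context": call.context.value,
                "direction": direction(call).value,
                "final": (ch.to_class.label if ch else call.initial_class.label),
            }
        )
    df = pd.DataFrame(rows)

    def bin_label(length):
        for label, lo, hi in size_bins:
            if length >= lo and (hi is None or length < hi):
                return label
        return "other"

    df["size_bin"] = df["length"].map(bin_label)

    def table(by):
        g = df.groupby(by, sort=False)
        out = pd.DataFrame(
            {
                "n": g.size(),
                "n_changed": g.apply(
                    lambda s: int((s["direction"] != "none").sum()),
                    include_groups=False,
                ),
                "n_down": g.apply(
                    lambda s: int((s["direction"] == "down").sum()),
                    include_groups=False,
                ),
                "n_up": g.apply(
                    lambda s: int((s["direction"] == "up").sum()),
                    include_groups=False,
                ),
            }
        )
        out["change_rate_pct"] = (100 * out["n_changed"] / out["n"]).round(1)
        return out

    order = [b[0] for b in size_bins]
    size_table = table("size_bin").reindex(order).fillna(0).astype(
        {"n": int, "n_changed": int, "n_down": int, "n_up": int}
    )

    under500 = df["length"] < 500_000
    shares = pd.DataFrame(
        [
            {
                "subset": "all VUS",
                "n": len(df),
                "n_under_500kb": int(under500.sum()),
            },
            {
                "subset": "downgraded (B+LB)",
                "n": int((df["direction"] == "down").sum()),
                "n_under_500kb": int(((df["direction"] == "down") & under500).sum()),
            },
            {
                "subset": "reclassified benign only",
                "n": int((df["final"] == "benign").sum()),
                "n_under_500kb": int(((df["final"] == "benign") & under500).sum()),
            },
        ]
    )
    shares["pct_under_500kb"] = (
        100 * shares["n_under_500kb"] / shares["n"].replace(0, np.nan)
    ).round(1)

    return {
        "size": size_table,
        "size_under_500kb": shares,
        "type": table("cnv_type"),
        "inheritance": table("inheritance"),
        "context": table("context"),
    }
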