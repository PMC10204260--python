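"""Reclassification rates, confusion metrics, trend regression, breakdowns."""

import datetime as dt
from fractions import Fraction

import numpy as np
import pytest

from cnvreclass.core import (
    Assembly,
    Classification,
    ClassChange,
    CNVCall,
    CopyState,
    GenomicInterval,
)
from cnvreclass.reanalysis import CohortStudy, TriageResult
from cnvreclass.stats import (
    breakdowns,
    compare_slopes,
    confusion_metrics,
    cumulative_trend,
    reclassification_rates,
)

HG19 = Assembly.HG19
VUS = Classification.UNCERTAIN


def make_call(cid, pid, year=2012, start=1_000_000, length=100_000):
    return CNVCall(
        id=cid, interval=GenomicInterval("1", start, start + length - 1, HG19),
        band="p36.1", copy_state=CopyState(1, 1), patient_id=pid,
        test_year=year, initial_class=VUS,
    )


class TestRates:
    def test_fixture_headline_rates(self, fixture_bundle, fixture_results):
        rates = reclassification_rates(
            fixture_bundle.cohort, [ch for _, ch in fixture_results]
        )
        assert rates.patient_rate == Fraction(106, 259)
        assert rates.cnv_down_rate == Fraction(112, 372)
        assert rates.cnv_up_rate == Fraction(12, 372)
        assert rates.patient_plp_rate == Fraction(12, 259)
        assert rates.vus_test_rate == Fraction(259, 1641)
        assert rates.as_percent() == {
            "patient_rate": 40.9,
            "cnv_down_rate": 30.1,
            "cnv_up_rate": 3.2,
            "patient_plp_rate": 4.6,
            "vus_test_rate": 15.8,
        }

    def test_zero_changes_all_rates_zero(self):
        calls = [make_call("a", "p1"), make_call("b", "p2")]
        cohort = CohortStudy(calls=calls)
        changes = [ClassChange(c.id, VUS, VUS) for c in calls]
        rates = reclassification_rates(cohort, changes)
        assert rates.patient_rate == 0 and rates.cnv_down_rate == 0

    def test_single_patient_single_change_is_hundred_percent(self):
        cohort = CohortStudy(calls=[make_call("a", "p1")])
        changes = [ClassChange("a", VUS, Classification.PATHOGENIC)]
        rates = reclassification_rates(cohort, changes)
        assert rates.patient_rate == 1 and rates.patient_plp_rate == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            reclassification_rates(CohortStudy(calls=[]), [])


def tri(cid, cls):
    return TriageResult(cnv_id=cid, automatic_class=cls)


class TestConfusion:
    def test_perfect_triage(self):
        t = [tri("a", Classification.PATHOGENIC), tri("b", VUS)]
        final = [Classification.PATHOGENIC, VUS]
        c = confusion_metrics(t, final)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)
        assert c.specificity == 1 and c.precision == 1

    def test_all_flagged_degenerate(self):
        t = [tri(f"c{i}", Classification.LIKELY_PATHOGENIC) for i in range(4)]
        final = [Classification.PATHOGENIC] + [VUS] * 3
        c = confusion_metrics(t, final)
        assert c.sensitivity == 1 and c.specificity == 0

    def test_id_mismatch_rejected(self):
        t = [tri("a", VUS)]
        with pytest.raises(ValueError):
            confusion_metrics(t, [("b", VUS)])

    def test_agrees_with_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(42)
        classes = list(Classification)
        plp = {Classification.LIKELY_PATHOGENIC, Classification.PATHOGENIC}
        for _ in range(50):
            n = int(rng.integers(1, 60))
            auto = [classes[i] for i in rng.integers(0, 5, n)]
            final = [classes[i] for i in rng.integers(0, 5, n)]
            t = [tri(f"c{i}", a) for i, a in enumerate(auto)]
            c = confusion_metrics(t, final)
            tp = sum(a in plp and f in plp for a, f in zip(auto, final))
            fp = sum(a in plp and f not in plp for a, f in zip(auto, final))
            fn = sum(a not in plp and f in plp for a, f in zip(auto, final))
            tn = n - tp - fp - fn
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)


class TestCumulativeTrend:
    def test_fixture_slopes_round_to_published_values(self, fixture_bundle,
                                                      fixture_results):
        changes = [ch for _, ch in fixture_results]
        fit_all = cumulative_trend(fixture_bundle.cohort, changes, "all")
        fit_plp = cumulative_trend(fixture_bundle.cohort, changes, "plp")
        assert round(fit_all.slope_pct_per_year, 1) == 4.2
        assert round(fit_plp.slope_pct_per_year, 1) == 0.4
        assert fit_all.r_squared > 0.999

    def test_exactly_linear_series_recovered(self):
        # one changed call per year over ten calls: slope = 10 %/yr exactly
        calls = [make_call(f"c{i}", f"p{i}", year=2010 + i) for i in range(5)]
        calls += [make_call(f"u{i}", f"q{i}", year=2010 + i) for i in range(5)]
        cohort = CohortStudy(calls=calls)
        changes = [ClassChange(f"c{i}", VUS, Classification.BENIGN) for i in range(5)]
        changes += [ClassChange(f"u{i}", VUS, VUS) for i in range(5)]
        fit = cumulative_trend(cohort, changes, "all")
        assert fit.slope_pct_per_year == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_slope_zero(self):
        calls = [make_call(f"c{i}", f"p{i}", year=2010 + i) for i in range(4)]
        cohort = CohortStudy(calls=calls)
        changes = [ClassChange(c.id, VUS, VUS) for c in calls]
        fit = cumulative_trend(cohort, changes, "all")
        assert fit.slope_pct_per_year == pytest.approx(0.0)

    def test_fewer_than_three_years_rejected(self):
        calls = [make_call("a", "p1", 2010), make_call("b", "p2", 2011)]
        with pytest.raises(ValueError):
            cumulative_trend(CohortStudy(calls=calls), [], "all")

    def test_slope_difference_is_significant_on_fixture(self, fixture_bundle,
                                                        fixture_results):
        changes = [ch for _, ch in fixture_results]
        fit_all = cumulative_trend(fixture_bundle.cohort, changes, "all")
        fit_plp = cumulative_trend(fixture_bundle.cohort, changes, "plp")
        cmp = compare_slopes(fit_all, fit_plp)
        assert cmp["slope_difference_pct_per_year"] > 0
        assert cmp["p_value"] < 0.05


class TestBreakdowns:
    def test_fixture_size_and_type_shares(self, fixture_bundle, fixture_results):
        tables = breakdowns(fixture_bundle.cohort, [ch for _, ch in fixture_results])
        shares = tables["size_under_500kb"].set_index("subset")
        assert shares.loc["all VUS", "n_under_500kb"] == 283
        assert round(shares.loc["all VUS", "pct_under_500kb"]) == 76
        assert shares.loc["downgraded (B+LB)", "pct_under_500kb"] == 75.0
        types = tables["type"]
        assert types.loc["loss", "n"] == 201 and types.loc["gain", "n"] == 171
        assert round(100 * types.loc["loss", "n"] / 372) == 54

    def test_single_call_cohort_has_one_nonzero_bin(self):
        cohort = CohortStudy(calls=[make_call("a", "p1", length=250_000)])
        tables = breakdowns(cohort, [ClassChange("a", VUS, VUS)])
        size = tables["size"]
        assert size["n"].sum() == 1
        assert size.loc["100-500 kb", "n"] == 1

    def test_counts_recompose_exactly(self, fixture_bundle, fixture_results):
        tables = breakdowns(fixture_bundle.cohort, [ch for _, ch in fixture_results])
        for name in ("size", "type", "inheritance", "context"):
            t = tables[name]
            assert t["n"].sum() == 372
            assert t["n_changed"].sum() == 124
            assert (t["n_down"] + t["n_up"]).equals(t["n_changed"])
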