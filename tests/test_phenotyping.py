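import datetime as dt
from itertools import combinations

import numpy as np
import pytest

from claimscohort.phenotyping import (
    CohortAssignment,
    apply_exclusions,
    assign_cohorts,
    baseline_eligible,
    established_mdd_date,
    sisa_index,
    trd_index,
)
from conftest import make_bundle

D = dt.date


class TestEstablishedMdd:
    def test_same_day_claims_do_not_establish(self, window, registry):
        b = make_bundle(claims=[(D(2016, 2, 1), "F32.9"), (D(2016, 2, 1), "F33.1")])
        assert established_mdd_date(b, window, registry) is None

    def test_375_day_gap_fails_354_day_gap_passes(self, window, registry):
        b = make_bundle(claims=[(D(2016, 2, 1), "F32.9"), (D(2017, 2, 10), "F32.9")])
        assert established_mdd_date(b, window, registry) is None
        b = make_bundle(claims=[(D(2016, 2, 1), "F32.9"), (D(2017, 1, 20), "F32.9")])
        assert established_mdd_date(b, window, registry) == D(2017, 1, 20)

    def test_365_day_gap_is_inclusive(self, window, registry):
        b = make_bundle(claims=[(D(2016, 2, 1), "F32.9"), (D(2017, 1, 31), "F32.9")])
        assert established_mdd_date(b, window, registry) == D(2017, 1, 31)

    def test_inpatient_discharge_beats_later_pair(self, window, registry):
        b = make_bundle(claims=[
            (D(2016, 3, 1), "F32.9", "inpatient", D(2016, 3, 5)),
            (D(2017, 1, 1), "F33.0"),
            (D(2017, 2, 1), "F33.0"),
        ])
        assert established_mdd_date(b, window, registry) == D(2016, 3, 5)

    def test_any_claim_position(self, window, registry):
        b = make_bundle(claims=[
            (D(2016, 2, 1), ("I10", "F32.9")),
            (D(2016, 3, 1), ("E11.9", "F33.0")),
        ])
        assert established_mdd_date(b, window, registry) == D(2016, 3, 1)


def _est(day=D(2016, 1, 15)):
    """Claim pair establishing the diagnosis on `day`."""
    return [(day - dt.timedelta(days=30), "F32.9"), (day, "F32.9")]


class TestTrdIndex:
    def test_three_ingredients_over_370_days_needs_refill(self, window, registry):
        d0 = D(2017, 1, 1)
        fills = [
            (d0, "sertraline"),
            (d0 + dt.timedelta(days=100), "bupropion"),
            (d0 + dt.timedelta(days=370), "venlafaxine"),
        ]
        b = make_bundle(claims=_est(), fills=fills)
        assert trd_index(b, window, registry)[0] is None
        # a sertraline refill inside the trailing window completes the set
        fills.append((d0 + dt.timedelta(days=200), "sertraline"))
        b = make_bundle(claims=_est(), fills=fills)
        assert trd_index(b, window, registry)[0] == d0 + dt.timedelta(days=370)

    def test_ad_plus_atypical(self, window, registry):
        b = make_bundle(claims=_est(), fills=[
            (D(2017, 1, 1), "fluoxetine"), (D(2017, 1, 31), "quetiapine"),
        ])
        date, audit = trd_index(b, window, registry)
        assert date == D(2017, 1, 31)
        assert {i for _, i, _ in audit} == {"fluoxetine", "quetiapine"}

    def test_same_ingredient_thrice_never_qualifies(self, window, registry):
        b = make_bundle(claims=_est(), fills=[
            (D(2017, 1, 1), "sertraline"), (D(2017, 2, 1), "sertraline"),
            (D(2017, 3, 1), "sertraline"),
        ])
        assert trd_index(b, window, registry)[0] is None

    def test_fills_before_established_mdd_ignored(self, window, registry):
        b = make_bundle(claims=_est(D(2017, 6, 1)), fills=[
            (D(2017, 1, 1), "sertraline"), (D(2017, 2, 1), "bupropion"),
            (D(2017, 7, 1), "venlafaxine"),
        ])
        assert trd_index(b, window, registry)[0] is None

    def test_unknown_ingredient_skipped(self, window, registry):
        b = make_bundle(claims=_est(), fills=[
            (D(2017, 1, 1), "sertraline"), (D(2017, 1, 2), "mystery_pill"),
            (D(2017, 1, 3), "bupropion"),
        ])
        assert trd_index(b, window, registry)[0] is None

    def test_completing_fill_must_be_in_identification_period(self, window, registry):
        b = make_bundle(claims=_est(), fills=[
            (D(2019, 6, 1), "sertraline"), (D(2019, 6, 15), "bupropion"),
            (D(2019, 8, 1), "venlafaxine"),  # after identification end
        ])
        assert trd_index(b, window, registry)[0] is None

    def test_no_established_mdd_returns_none(self, window, registry):
        b = make_bundle(fills=[(D(2017, 1, 1), "sertraline"),
                               (D(2017, 1, 2), "bupropion"),
                               (D(2017, 1, 3), "venlafaxine")])
        assert trd_index(b, window, registry)[0] is None


def brute_force_trd_index(bundle, window, registry):
    """Exhaustive search over all fill subsets for the earliest completing
    date of a qualifying set — the independent oracle for trd_index."""
    est = established_mdd_date(bundle, window, registry)
    if est is None:
        return None
    fills = []
    for f in bundle.pharmacy_fills:
        cls = registry.drug_class(f.ingredient)
        if cls in ("antidepressant", "atypical_antipsychotic") and f.fill_date >= est:
            fills.append((f.fill_date, f.ingredient.lower(), cls))
    best = None
    for r in range(1, len(fills) + 1):
        for sub in combinations(fills, r):
            dates = [d for d, _, _ in sub]
            if (max(dates) - min(dates)).days > 365:
                continue
            ads = {i for _, i, c in sub if c == "antidepressant"}
            aaps = {i for _, i, c in sub if c == "atypical_antipsychotic"}
            if not (len(ads) >= 3 or (ads and aaps)):
                continue
            completing = max(dates)
            if not (window.identification_start <= completing <= window.identification_end):
                continue
            if best is None or completing < best:
                best = completing
    return best


def random_fill_bundle(rng, max_fills=12):
    ingredients = ["sertraline", "fluoxetine", "bupropion", "venlafaxine",
                   "quetiapine", "aripiprazole", "alprazolam", "mystery"]
    est_day = D(2016, 3, 1)
    n = int(rng.integers(0, max_fills + 1))
    fills = [
        (est_day + dt.timedelta(days=int(rng.integers(-200, 1400))),
         ingredients[int(rng.integers(0, len(ingredients)))])
        for _ in range(n)
    ]
    return make_bundle(claims=_est(est_day), fills=fills,
                       spans=[(D(2014, 1, 1), D(2021, 12, 31))])


class TestTrdWindowScannerOracle:
    def test_matches_exhaustive_subset_search(self, window, registry):
        rng = np.random.default_rng(42)
        for _ in range(200):
            b = random_fill_bundle(rng)
            assert trd_index(b, window, registry)[0] == \
                brute_force_trd_index(b, window, registry)


class TestSisaIndex:
    def test_attributed_by_recent_mdd_claim(self, window, registry):
        b = make_bundle(claims=_est(D(2018, 1, 15)) + [(D(2018, 6, 1), "R45.851")])
        assert sisa_index(b, window, registry) == D(2018, 6, 1)

    def test_attribution_fails_beyond_365_days(self, window, registry):
        b = make_bundle(claims=[
            (D(2016, 2, 1), "F32.9"), (D(2016, 3, 1), "F32.9"),
            (D(2017, 6, 1), "T39.1X2A"),  # 457 days after last MDD claim
        ])
        assert sisa_index(b, window, registry) is None

    def test_prior_er_encounter_attributes_at_any_time(self, window, registry):
        b = make_bundle(claims=[
            (D(2016, 2, 1), "F32.9", "ER"), (D(2016, 3, 1), "F32.9"),
            (D(2017, 6, 1), "T39.1X2A"),
        ])
        assert sisa_index(b, window, registry) == D(2017, 6, 1)

    def test_claim_before_established_mdd_skipped(self, window, registry):
        b = make_bundle(claims=[
            (D(2017, 1, 1), "R45.851"),
            (D(2017, 2, 1), "F32.9"), (D(2017, 3, 1), "F32.9"),
            (D(2017, 6, 1), "R45.851"),
        ])
        assert sisa_index(b, window, registry) == D(2017, 6, 1)

    def test_claim_outside_identification_period(self, window, registry):
        b = make_bundle(claims=_est(D(2019, 1, 15)) + [(D(2019, 8, 1), "R45.851")])
        assert sisa_index(b, window, registry) is None


class TestExclusions:
    def test_bipolar_any_time_excludes_all_cohorts(self, window, registry):
        idx = D(2018, 1, 1)
        b = make_bundle(claims=[(D(2016, 1, 5), "F31.9")])
        for cohort in ("trd", "sisa", "mdd_alone"):
            assert apply_exclusions(b, cohort, idx, registry, window) == ["bipolar_mania"]

    def test_dementia_183_day_boundary(self, window, registry):
        idx = D(2018, 1, 1)
        b = make_bundle(claims=[(idx - dt.timedelta(days=100), "F03.90")])
        assert apply_exclusions(b, "trd", idx, registry, window) == ["dementia_6mo"]
        b = make_bundle(claims=[(idx - dt.timedelta(days=200), "F03.90")])
        assert apply_exclusions(b, "trd", idx, registry, window) == []
        b = make_bundle(claims=[(idx - dt.timedelta(days=183), "F03.90")])
        assert apply_exclusions(b, "trd", idx, registry, window) == ["dementia_6mo"]

    def test_index_day_itself_not_in_lookback(self, window, registry):
        idx = D(2018, 1, 1)
        b = make_bundle(claims=[(idx, "F03.90")])
        assert apply_exclusions(b, "trd", idx, registry, window) == []

    def test_autism_excludes_sisa_only(self, window, registry):
        idx = D(2018, 1, 1)
        b = make_bundle(claims=[(idx - dt.timedelta(days=30), "F84.0")])
        assert apply_exclusions(b, "trd", idx, registry, window) == []
        assert apply_exclusions(b, "sisa", idx, registry, window) == ["autism_6mo"]
        assert apply_exclusions(b, "mdd_alone", idx, registry, window) == []


class TestBaselineEligible:
    def test_exact_183_day_coverage(self, window, registry):
        idx = D(2018, 1, 1)
        b = make_bundle(spans=[(idx - dt.timedelta(days=183), D(2019, 12, 31))])
        assert baseline_eligible(b, idx, window)
        b = make_bundle(spans=[(idx - dt.timedelta(days=100), D(2019, 12, 31))])
        assert not baseline_eligible(b, idx, window)

    def test_one_day_gap_fails_at_zero_tolerance(self, window):
        idx = D(2018, 1, 1)
        b = make_bundle(spans=[
            (D(2016, 1, 1), D(2017, 9, 1)),
            (D(2017, 9, 3), D(2019, 12, 31)),  # 2017-09-02 uncovered
        ])
        assert not baseline_eligible(b, idx, window)

    def test_gap_within_tolerance_passes(self, window):
        import dataclasses

        relaxed = dataclasses.replace(window, baseline_gap_tolerance_days=30)
        idx = D(2018, 1, 1)
        b = make_bundle(spans=[
            (D(2016, 1, 1), D(2017, 9, 1)),
            (D(2017, 9, 16), D(2019, 12, 31)),  # 14-day gap
        ])
        assert baseline_eligible(b, idx, relaxed)


class TestAssignCohorts:
    def test_dual_membership_keeps_distinct_indices(self, window, registry):
        claims = _est(D(2017, 1, 15)) + [
            (D(2017, 6, 1), "F33.0"),  # attributes the later SI claim
            (D(2018, 3, 1), "R45.851"),
        ]
        fills = [(D(2017, 2, 1), "sertraline"), (D(2017, 3, 1), "bupropion"),
                 (D(2017, 4, 1), "venlafaxine")]
        b = make_bundle(claims=claims, fills=fills)
        [a], _ = assign_cohorts([b], window, registry)
        assert a.in_trd and a.in_sisa and not a.in_mdd_alone
        assert a.trd_index == D(2017, 4, 1)
        assert a.sisa_index == D(2018, 3, 1)

    def test_mdd_alone_index_is_second_claim_date(self, window, registry):
        b = make_bundle(claims=[(D(2017, 1, 1), "F32.9"), (D(2017, 5, 1), "F33.0")])
        [a], _ = assign_cohorts([b], window, registry)
        assert a.in_mdd_alone and a.mdd_alone_index == D(2017, 5, 1)
        assert not a.in_trd and not a.in_sisa

    def test_single_claim_never_enters_frame(self, window, registry):
        b = make_bundle(claims=[(D(2017, 1, 1), "F32.9")])
        [a], _ = assign_cohorts([b], window, registry)
        assert not (a.in_trd or a.in_sisa or a.in_mdd_alone)

    def test_noise_claim_never_changes_assignment(self, window, registry):
        claims = _est(D(2017, 1, 15)) + [(D(2018, 3, 1), "R45.851")]
        b = make_bundle(claims=claims)
        noisy = make_bundle(claims=claims + [(D(2017, 8, 1), "J06.9")])
        [a], _ = assign_cohorts([b], window, registry)
        [an], _ = assign_cohorts([noisy], window, registry)
        for field in ("in_trd", "trd_index", "in_sisa", "sisa_index",
                      "in_mdd_alone", "mdd_alone_index"):
            assert getattr(a, field) == getattr(an, field)

    def test_excluded_trd_candidate_falls_to_mdd_alone(self, window, registry):
        claims = _est(D(2017, 1, 15)) + [(D(2017, 3, 15), "F03.90")]
        fills = [(D(2017, 2, 1), "sertraline"), (D(2017, 3, 1), "bupropion"),
                 (D(2017, 4, 1), "venlafaxine")]
        b = make_bundle(claims=claims, fills=fills)
        [a], _ = assign_cohorts([b], window, registry)
        assert not a.in_trd and a.in_mdd_alone
        assert "trd:dementia_6mo" in a.exclusion_reasons

    def test_membership_invariant(self, window, registry):
        a = CohortAssignment(patient_id="x", in_trd=True, trd_index=D(2017, 1, 1))
        assert a.memberships() == [("trd", D(2017, 1, 1))]
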