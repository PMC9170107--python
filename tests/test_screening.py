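"""Campaign statistics: rates, NNS, Fisher test, kappa, scores, accuracy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

import afscreen as af
from afscreen.params import ValidationError
from afscreen.screening import ContingencyTable2x2


def brute_force_fisher(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins
    and sum the exact hypergeometric probabilities no larger than the
    observed one (integer combinatorics, no scipy)."""
    n1, n2, m = a + b, c + d, a + c
    denom = math.comb(n1 + n2, m)
    weight = lambda k: math.comb(n1, k) * math.comb(n2, m - k)
    w_obs = weight(a)
    total = sum(
        w for k in range(max(0, m - n2), min(m, n1) + 1)
        if (w := weight(k)) <= w_obs or math.isclose(w, w_obs, rel_tol=1e-11)
    )
    return total / denom


class TestDetectionRate:
    def test_campaign_headline_rates(self):
        assert af.detection_rate(15, 1607).percent() == 0.93
        assert af.detection_rate(10, 628).percent() == 1.59
        assert af.detection_rate(5, 977).percent() == 0.51

    def test_zero_detections(self):
        r = af.detection_rate(0, 100)
        assert r.rate == 0.0
        assert r.ci_low == 0.0
        assert r.ci_high > 0.0

    def test_zero_screened_rejected(self):
        with pytest.raises(ValidationError):
            af.detection_rate(0, 0)

    def test_ci_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (100, 1000, 10_000):
            k = n // 100
            r = af.detection_rate(k, n)
            assert r.ci_low <= r.rate <= r.ci_high
            widths.append(r.ci_high - r.ci_low)
        assert widths == sorted(widths, reverse=True)

    def test_ci_matches_statsmodels_exact_interval(self):
        lo, hi = af.clopper_pearson(15, 1607)
        sm_lo, sm_hi = proportion_confint(15, 1607, method="beta")
        assert lo == pytest.approx(sm_lo)
        assert hi == pytest.approx(sm_hi)


class TestNNS:
    @pytest.mark.parametrize(
        "detected,screened,expected",
        [(15, 1607, 107), (100, 100, 1)],
    )
    def test_rounded_to_nearest_integer(self, detected, screened, expected):
        assert round(af.nns(detected, screened)) == expected

    def test_hypertensive_stratum_one_decimal(self):
        assert round(af.nns(10, 628), 1) == 62.8

    def test_zero_detected_is_infinite(self):
        assert math.isinf(af.nns(0, 50))


class TestFisherExact:
    def test_equal_row_proportions_give_p_one(self):
        assert af.fisher_exact(ContingencyTable2x2(5, 95, 10, 190)) == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self):
        assert af.fisher_exact(ContingencyTable2x2(0, 10, 0, 20)) == 1.0

    def test_matches_enumeration_oracle_on_spot_table(self):
        p = af.fisher_exact(ContingencyTable2x2(2, 8, 6, 4))
        assert p == pytest.approx(brute_force_fisher(2, 8, 6, 4), abs=1e-10)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = af.fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(brute_force_fisher(a, b, c, d), abs=1e-9)

    def test_published_hypertension_table(self):
        """The correct two-sided Fisher p on the printed counts is 0.0343
        (R's fisher.test agrees); the publication prints 0.035, which only
        arises from double-counting the cases in the stratum totals."""
        p = af.fisher_exact(ContingencyTable2x2(10, 618, 5, 972))
        assert round(p, 3) == 0.034

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestStratifiedDetection:
    def test_hypertension_row_from_fixture(self, study_fixture):
        res = af.stratified_detection(study_fixture, "hypertension")
        assert res["rate_pos"].percent() == 1.59
        assert res["rate_neg"].percent() == 0.51

    def test_zero_positive_stratum(self, study_fixture):
        res = af.stratified_detection(study_fixture, "stroke_tia")
        assert res["table"].a == 0
        assert res["rate_pos"].rate == 0.0
        assert res["table"].b == 43

    def test_unknown_factor_rejected(self, study_fixture):
        with pytest.raises(ValidationError):
            af.stratified_detection(study_fixture, "smoking")

    def test_empty_stratum_flagged(self, study_fixture):
        df = study_fixture.copy()
        df["chf"] = False
        with pytest.raises(ValidationError, match="empty stratum"):
            af.stratified_detection(df, "chf")

    def test_exclude_treated_shrinks_denominators(self, study_fixture):
        full = af.stratified_detection(study_fixture, "diabetes")
        at_risk = af.stratified_detection(study_fixture, "diabetes",
                                          exclude_treated=True)
        assert at_risk["table"].total == full["table"].total - 43


class TestCohenKappa:
    def test_identical_sequences_give_one(self):
        labels = ["AF", "non_af", "AF", "non_af", "non_af"]
        assert af.cohen_kappa(labels, labels) == 1.0

    def test_hand_computed_agreement_table(self):
        """20/5/10/65 agreement table: p_o = 0.85, p_e = 0.60, kappa = 0.625."""
        a = ["x"] * 25 + ["y"] * 75
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 65
        assert af.cohen_kappa(a, b) == pytest.approx(0.625)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["AF", "non_af", "uninterpretable"], size=500)
        b = rng.choice(["AF", "non_af", "uninterpretable"], size=500)
        assert af.cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.choice(["p", "q"], size=10_000, p=[0.3, 0.7])
        b = rng.choice(["p", "q"], size=10_000, p=[0.3, 0.7])
        assert abs(af.cohen_kappa(a, b)) < 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["AF", "non_af"], size=300)
        b = rng.choice(["AF", "non_af"], size=300)
        swap = {"AF": "Z", "non_af": "A"}
        assert af.cohen_kappa(a, b) == pytest.approx(
            af.cohen_kappa([swap[x] for x in a], [swap[x] for x in b])
        )

    def test_constant_identical_raters_undefined(self):
        with pytest.raises(ValidationError):
            af.cohen_kappa(["AF"] * 5, ["AF"] * 5)


class TestScoreSummary:
    def test_published_breakdowns(self):
        mean, sd = af.score_summary({0: 3, 1: 8, 2: 2, 3: 2})
        assert (round(mean, 1), round(sd, 1)) == (1.2, 0.9)
        mean, sd = af.score_summary({1: 1, 2: 5, 3: 6, 4: 2, 5: 1})
        assert (round(mean, 1), round(sd, 1)) == (2.8, 1.0)

    def test_degenerate_distribution(self):
        assert af.score_summary({2: 10}) == (2.0, 0.0)

    def test_single_observation_rejected(self):
        with pytest.raises(ValidationError):
            af.score_summary({3: 1})


class TestDiagAccuracy:
    def test_perfect_classifier(self):
        res = af.diag_accuracy(ContingencyTable2x2(30, 0, 0, 990))
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 1.0

    def test_hand_computed_rates(self):
        res = af.diag_accuracy(ContingencyTable2x2(29, 40, 1, 950))
        assert res["sensitivity"] == pytest.approx(29 / 30)
        assert res["specificity"] == pytest.approx(950 / 990)

    def test_ci_matches_exact_binomial_enumeration(self):
        """Clopper-Pearson bounds are the binomial parameters at which the
        observed count is exactly at the 2.5% tail, found by bisection."""
        res = af.diag_accuracy(ContingencyTable2x2(29, 40, 1, 950))
        lo, hi = res["sensitivity_ci"]

        def tail_ge(p):  # P(X >= 29), n = 30
            return sum(
                math.comb(30, k) * p**k * (1 - p) ** (30 - k) for k in range(29, 31)
            )

        def bisect(f, target, a, b):
            for _ in range(200):
                mid = (a + b) / 2
                if f(mid) < target:
                    a = mid
                else:
                    b = mid
            return (a + b) / 2

        assert lo == pytest.approx(bisect(tail_ge, 0.025, 0.0, 1.0), abs=1e-6)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            af.diag_accuracy(ContingencyTable2x2(0, 10, 0, 20))

    def test_wilson_option(self):
        res = af.diag_accuracy(ContingencyTable2x2(29, 40, 1, 950), ci_method="wilson")
        lo, hi = res["sensitivity_ci"]
        assert lo < 29 / 30 < hi


class TestComputeScores:
    @pytest.mark.parametrize(
        "record,expected",
        [
            (dict(age=80, sex="women", chf=False, hypertension=True, diabetes=False,
                  stroke_tia=False, vascular=False), (2, 4)),
            (dict(age=66, sex="men", chf=False, hypertension=False, diabetes=False,
                  stroke_tia=False, vascular=False), (0, 1)),
            (dict(age=70, sex="men", chf=True, hypertension=True, diabetes=True,
                  stroke_tia=True, vascular=True), (5, 7)),
        ],
    )
    def test_score_definitions(self, record, expected):
        assert af.compute_scores(record) == expected

    def test_missing_component_named(self):
        with pytest.raises(ValidationError, match="vascular"):
            af.compute_scores(dict(age=70, sex="men", chf=False, hypertension=False,
                                   diabetes=False, stroke_tia=False, vascular=None))

    @given(
        age=st.integers(65, 100),
        female=st.booleans(),
        chf=st.booleans(), htn=st.booleans(), dm=st.booleans(),
        stia=st.booleans(), vasc=st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_vasc_score_dominates_chads2_from_age_65(self, age, female, chf, htn,
                                                     dm, stia, vasc):
        record = dict(age=age, sex="women" if female else "men", chf=chf,
                      hypertension=htn, diabetes=dm, stroke_tia=stia, vascular=vasc)
        chads2, vasc_score = af.compute_scores(record)
        assert vasc_score >= chads2
        assert vasc_score >= 1  # every subject aged >= 65 scores at least the age point
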