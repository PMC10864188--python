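"""Kaplan-Meier, log-rank, risk partitioning, strata, EFS and C-index."""

import numpy as np
import pytest

from pamlcat import (
    ClinicalRecord,
    SurvivalRecord,
    assign_strata,
    concordance_bootstrap,
    efs_encode,
    fit_risk_partition,
    harrell_c,
    km_estimate,
    logrank_test,
    risk_map_from_defaults,
)
from pamlcat.survival import RiskGroupMap, STRATUM_LABELS
from conftest import make_clinical


def records(times, events, category=None, prefix="r"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e), category=category)
        for i, (t, e) in enumerate(zip(times, events))
    ]


def exp_records(rng, hazard, n, category=None, horizon=10.0, prefix="r"):
    t = rng.exponential(1 / hazard, n)
    c = rng.uniform(0, horizon, n)
    return [
        SurvivalRecord(f"{category or prefix}{i}", float(min(a, b)), bool(a <= b),
                       category=category)
        for i, (a, b) in enumerate(zip(t, c))
    ]


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        fit = km_estimate(records([1, 2, 3], [1, 1, 1]))
        assert fit.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert fit.survival_at(0) == 1.0

    def test_all_censored_survival_is_one(self):
        fit = km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert len(fit.times) == 0
        assert fit.survival_at(99) == 1.0

    def test_hand_computed_mixed_fixture(self):
        # events at 1 (n=5) and 4 (n=2); censored at 2, 3; event at 5 (n=1)
        fit = km_estimate(records([1, 2, 3, 4, 5], [1, 0, 0, 1, 1]))
        assert fit.survival == pytest.approx([4 / 5, 4 / 5 * 1 / 2, 0.0])

    def test_matches_lifelines_on_100_random_fixtures(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 60))
            t = np.round(rng.exponential(2, n), 2) + 0.01
            e = rng.random(n) < rng.uniform(0.2, 0.9)
            fit = km_estimate(records(t, e))
            if len(fit.times) == 0:
                continue
            kmf = KaplanMeierFitter().fit(t, e)
            theirs = kmf.survival_function_at_times(fit.times).to_numpy()
            np.testing.assert_allclose(fit.survival, theirs, atol=1e-10)

    def test_non_increasing_and_right_continuous(self):
        rng = np.random.default_rng(12)
        fit = km_estimate(records(rng.exponential(1, 80), rng.random(80) < 0.6))
        assert (np.diff(fit.survival) <= 1e-15).all()
        assert fit.survival_at(fit.times[0]) == pytest.approx(fit.survival[0])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = records([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        a = exp_records(rng, 0.2, 50, prefix="a")
        b = exp_records(rng, 0.6, 50, prefix="b")
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic
        )

    def test_matches_lifelines_three_groups_with_ties(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(14)
        groups = [
            records(np.round(rng.exponential(2, 40), 1), rng.random(40) < 0.7,
                    prefix=f"g{k}")
            for k in range(3)
        ]
        res = logrank_test(groups)
        t = np.concatenate([[r.time for r in g] for g in groups])
        e = np.concatenate([[r.event for r in g] for g in groups])
        lab = np.concatenate([[k] * 40 for k in range(3)])
        theirs = multivariate_logrank_test(t, lab, e)
        assert res.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(15)
        detected = sum(
            logrank_test(
                [exp_records(np.random.default_rng(s), 0.2, 200),
                 exp_records(np.random.default_rng(1000 + s), 0.6, 200)]
            ).p_value
            < 0.001
            for s in range(20)
        )
        assert detected == 20


class TestRiskPartition:
    def test_three_separated_categories_three_groups(self):
        rng = np.random.default_rng(16)
        recs = (
            exp_records(rng, 0.05, 150, category="good")
            + exp_records(rng, 0.15, 150, category="mid")
            + exp_records(rng, 0.45, 150, category="bad")
        )
        m = fit_risk_partition(recs)
        assert m.mapping == {"good": "low", "mid": "intermediate", "bad": "high"}
        assert m.provenance == "fitted"

    def test_identical_hazards_stay_one_group(self):
        base = list(np.linspace(0.5, 8, 40)) * 2
        events = [1, 0] * 40
        recs = records(base, events, category="A", prefix="a") + records(
            base, events, category="B", prefix="b"
        )
        with pytest.warns(UserWarning):
            m = fit_risk_partition(recs)
        assert set(m.mapping.values()) == {"intermediate"}

    def test_category_input_order_irrelevant(self):
        rng = np.random.default_rng(17)
        recs = (
            exp_records(rng, 0.05, 100, category="g")
            + exp_records(rng, 0.2, 100, category="m")
            + exp_records(rng, 0.6, 100, category="b")
        )
        m1 = fit_risk_partition(recs)
        m2 = fit_risk_partition(list(reversed(recs)))
        assert m1.mapping == m2.mapping

    def test_six_categories_from_three_tiers_group_by_tier(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            recs = []
            for name, h in [("a1", 0.05), ("a2", 0.05), ("b1", 0.15),
                            ("b2", 0.15), ("c1", 0.45), ("c2", 0.45)]:
                recs += exp_records(rng, h, 150, category=name)
            m = fit_risk_partition(recs)
            want = {"a1": "low", "a2": "low", "b1": "intermediate",
                    "b2": "intermediate", "c1": "high", "c2": "high"}
            hits += m.mapping == want
        assert hits >= 45  # tier recovery in >= 90% of seeds


class TestStrata:
    def test_six_distinct_labels(self):
        rmap = RiskGroupMap(mapping={"L": "low", "M": "intermediate", "H": "high"})
        recs, mrd = [], {}
        i = 0
        for cat in "LMH":
            for pos in (False, True):
                recs.append(SurvivalRecord(f"s{i}", 1.0, True, category=cat))
                mrd[f"s{i}"] = pos
                i += 1
        sa = assign_strata(recs, rmap, mrd)
        assert sorted(sa.strata.values()) == sorted(STRATUM_LABELS)
        assert sa.strata["s0"] == "low/MRD-"

    def test_missing_mrd_excluded_and_reported(self):
        rmap = RiskGroupMap(mapping={"L": "low"})
        recs = [SurvivalRecord("a", 1, True, category="L"),
                SurvivalRecord("b", 1, True, category="L")]
        sa = assign_strata(recs, rmap, {"a": True, "b": None})
        assert sa.excluded == ["b"] and list(sa.strata) == ["a"]

    def test_unmapped_category_is_error(self):
        rmap = RiskGroupMap(mapping={"L": "low"})
        with pytest.raises(KeyError):
            assign_strata([SurvivalRecord("a", 1, True, category="X")],
                          rmap, {"a": True})


class TestEfsEncoding:
    def test_nonresponse_is_event_at_time_zero(self):
        rec = efs_encode(make_clinical(nonresponse=True, efs_time=None,
                                       efs_event=None, relapse_flag=False))
        assert rec.time == 0.0 and rec.event

    def test_censored_survivor(self):
        rec = efs_encode(make_clinical(efs_time=4.2, efs_event=False))
        assert rec.time == 4.2 and not rec.event

    def test_relapse_event(self):
        rec = efs_encode(make_clinical(efs_time=1.2, efs_event=True,
                                       relapse_flag=True))
        assert rec.time == 1.2 and rec.event

    def test_contradictory_flags_error(self):
        with pytest.raises(ValueError):
            efs_encode(make_clinical(nonresponse=True, relapse_flag=True))


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        e = np.ones(5, dtype=bool)
        score = np.array([1, 2, 3, 4, 5], dtype=float)  # higher = riskier
        assert harrell_c(t, e, score) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(2, 500)
        e = rng.random(500) < 0.7
        c = harrell_c(t, e, rng.random(500))
        assert abs(c - 0.5) < 0.05

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(19)
        t = rng.exponential(2, 200)
        e = rng.random(200) < 0.6
        s = rng.random(200)
        ours = harrell_c(t, e, s)
        theirs = 1 - concordance_index(t, s, e)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bootstrap_interval_excludes_half_for_ordered_strata(self):
        rng = np.random.default_rng(20)
        recs, scores = [], []
        for level, h in enumerate([0.05, 0.2, 0.8]):
            rs = exp_records(rng, h, 120, prefix=f"lv{level}_")
            recs += rs
            scores += [level] * len(rs)
        res = concordance_bootstrap(recs, {"risk": scores}, n_boot=300, seed=1)
        lo, hi = res.intervals["risk"]
        assert lo > 0.5
        assert res.c_index["risk"] > 0.6

    def test_no_usable_pairs_is_error(self):
        t = np.ones(4)
        e = np.zeros(4, dtype=bool)
        with pytest.raises(ValueError):
            harrell_c(t, e, np.arange(4.0))
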