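"""Charlson scoring, Kaplan-Meier survival, rates, relative risk, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from phenotyper.outcomes import (
    charlson_index,
    cluster_outcomes,
    cohort_summary,
    km_survival,
    load_charlson_map,
    medication_rates,
    rate_comparison,
    relative_risk,
    return_rates,
)

CMAP = load_charlson_map()


class TestCharlson:
    def test_empty_codes_zero(self):
        assert charlson_index([], CMAP) == 0

    def test_mi_plus_metastatic_is_seven(self):
        assert charlson_index(["I21.0", "C79.9"], CMAP) == 7

    def test_duplicates_counted_once(self):
        assert charlson_index(["I21.0", "I21.9", "I22"], CMAP) == 1

    def test_metastatic_supersedes_other_malignancy(self):
        assert charlson_index(["C50.9", "C78.0"], CMAP) == 6

    def test_severe_liver_supersedes_mild(self):
        assert charlson_index(["K70.3", "K72.1"], CMAP) == 3

    def test_complicated_diabetes_supersedes_uncomplicated(self):
        assert charlson_index(["E11.9", "E11.2"], CMAP) == 2

    def test_unmatched_codes_score_zero(self):
        assert charlson_index(["Z99.9", "XYZ"], CMAP) == 0

    def test_longest_prefix_wins(self):
        # I25.2 is old MI (weight 1); bare I25 is not a Charlson category
        assert charlson_index(["I252"], CMAP) == 1
        assert charlson_index(["I251"], CMAP) == 0


def km_oracle(times, events, t):
    """Independent product-limit computation by explicit risk-set enumeration."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for ti in sorted(set(times[events == 1])):
        if ti > t:
            break
        at_risk = (times >= ti).sum()
        deaths = ((times == ti) & (events == 1)).sum()
        s *= 1 - deaths / at_risk
    return s


class TestKaplanMeier:
    def test_no_deaths_survival_one(self):
        _, s = km_survival([400.0] * 10, [0] * 10, horizon=365)
        assert s == 1.0

    def test_hand_computed_product_limit(self):
        """{1: death, 2: censor, 3: death} -> S(1)=2/3, S(3)=0."""
        curve, s3 = km_survival([1, 2, 3], [1, 0, 1], horizon=3)
        sf = dict(zip(curve["time"], curve["survival"]))
        assert sf[1.0] == pytest.approx(2 / 3)
        assert s3 == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_survival([], [], horizon=365)

    def test_oracle_equivalence_simulated(self):
        rng = np.random.default_rng(17)
        times = np.ceil(rng.exponential(500, size=200))
        events = (times <= 730).astype(int)
        times = np.minimum(times, 730)
        curve, s365 = km_survival(times, events, horizon=365)
        assert s365 == pytest.approx(km_oracle(times, events, 365), abs=1e-12)
        for t in (30, 180, 700):
            si = curve[curve["time"] <= t]["survival"].iloc[-1]
            assert si == pytest.approx(km_oracle(times, events, t), abs=1e-12)


class TestRates:
    def records(self, rows):
        return pd.DataFrame(rows)

    def test_no_returns_all_zero(self):
        recs = self.records([
            {"return_days": [], "opioid_return_days": []} for _ in range(5)
        ])
        assert set(return_rates(recs).values()) == {0.0}

    def test_day_183_counts_in_six_month_window(self):
        recs = self.records([{"return_days": [183], "opioid_return_days": [184]}])
        rates = return_rates(recs)
        assert rates["all_cause_183d"] == 1.0
        assert rates["opioid_183d"] == 0.0
        assert rates["opioid_365d"] == 1.0

    def test_medication_rates(self):
        recs = pd.DataFrame({
            "buprenorphine_rx": [0] * 10,
            "methadone_rx": [1, 1, 1] + [0] * 7,
            "naloxone_rx": [0] * 10,
        })
        rates = medication_rates(recs)
        assert rates == {"buprenorphine": 0.0, "methadone": 0.3, "naloxone": 0.0}


class TestRelativeRisk:
    def test_uniform_distribution_rr_one(self):
        assert relative_risk(10, 100, 100, 1000) == pytest.approx(1.0)

    def test_cohort_counts_alcohol(self):
        assert relative_risk(3605, 6506, 28233, 82577) == pytest.approx(1.7115, abs=5e-4)

    def test_cohort_counts_delirium(self):
        assert relative_risk(2069, 8634, 9487, 82577) == pytest.approx(2.389, abs=5e-4)

    def test_absent_outside_cluster_infinite(self):
        assert math.isinf(relative_risk(5, 100, 5, 1000))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relative_risk(1, 0, 10, 100)
        with pytest.raises(ValueError):
            relative_risk(1, 100, 10, 100)


class TestRateComparison:
    def test_identical_rates_neutral(self):
        stat, p, flag = rate_comparison(20, 100, 20, 100)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert flag == "neutral"

    def test_worked_example_increased(self):
        stat, _p, flag = rate_comparison(300, 1000, 100, 1000)
        assert stat == pytest.approx(125.0, abs=1e-9)
        assert flag == "increased"

    def test_direction_antisymmetric(self):
        _, _, f1 = rate_comparison(300, 1000, 100, 1000)
        _, _, f2 = rate_comparison(100, 1000, 300, 1000)
        assert (f1, f2) == ("increased", "decreased")

    def test_degenerate_table_neutral_with_warning(self):
        with pytest.warns(UserWarning):
            _, p, flag = rate_comparison(0, 50, 0, 50)
        assert (p, flag) == (1.0, "neutral")

    def test_oracle_equivalence_fixture(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n1, n2 = int(rng.integers(20, 200)), int(rng.integers(20, 200))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            obs = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            stat_oracle = ((obs - exp) ** 2 / exp).sum()
            stat, p, _ = rate_comparison(a, n1, b, n2)
            assert stat == pytest.approx(stat_oracle, abs=1e-10)
            assert p == pytest.approx(float(chi2.sf(stat_oracle, 1)), abs=1e-10)


class TestCohortSummary:
    def make_encounters(self, n, var_count, cluster):
        return pd.DataFrame({
            "encounter_id": [f"{cluster}-{i}" for i in range(n)],
            "age": np.linspace(20, 80, n),
            "sex": ["Male"] * (n // 2) + ["Female"] * (n - n // 2),
            "insurance": ["Medicaid"] * n,
            "race": ["White"] * n,
            "ethnicity": ["Non-Hispanic"] * n,
            "esi": [3] * n,
            "disposition": ["discharge"] * n,
            "sud": [True] * var_count + [False] * (n - var_count),
        })

    def test_percentages_match_hand_computation(self):
        enc = pd.concat([
            self.make_encounters(500, 400, "A"),
            self.make_encounters(500, 100, "B"),
        ], ignore_index=True)
        labels = pd.Series(
            [0] * 500 + [1] * 500, index=enc["encounter_id"]
        )
        table = cohort_summary(enc, labels, binary_vars=["sud"])
        sud = table[table["variable"] == "sud"].iloc[0]
        assert sud["overall"] == "500 (50.0)"
        assert sud["0"] == "400 (80.0)"
        assert sud["1"] == "100 (20.0)"

    def test_empty_variable_zero(self):
        enc = self.make_encounters(10, 0, "A")
        labels = pd.Series([0] * 5 + [1] * 5, index=enc["encounter_id"])
        table = cohort_summary(enc, labels, binary_vars=["sud"])
        assert table[table["variable"] == "sud"].iloc[0]["overall"] == "0 (0.0)"

    def test_unlabeled_encounter_rejected(self):
        enc = self.make_encounters(4, 2, "A")
        labels = pd.Series([0, 0], index=enc["encounter_id"][:2])
        with pytest.raises(ValueError):
            cohort_summary(enc, labels)


def _records(n, hazard, rng, p12=0.3, methadone=0.4, prefix="E"):
    t = np.ceil(rng.exponential(1 / hazard, size=n))
    death = (t <= 730).astype(int)
    t = np.minimum(t, 730)
    ret = [[int(rng.integers(1, 366))] if rng.random() < p12 else [] for _ in range(n)]
    return pd.DataFrame({
        "encounter_id": [f"{prefix}{i}" for i in range(n)],
        "followup_days": t,
        "death": death,
        "return_days": ret,
        "opioid_return_days": [[] for _ in range(n)],
        "buprenorphine_rx": rng.random(n) < 0.1,
        "methadone_rx": rng.random(n) < methadone,
        "naloxone_rx": rng.random(n) < 0.1,
        "diagnosis_codes": [[] for _ in range(n)],
    })


class TestClusterOutcomes:
    def test_single_cluster_equals_whole_cohort(self):
        rng = np.random.default_rng(31)
        recs = _records(300, 2e-4, rng)
        labels = pd.Series(0, index=recs["encounter_id"])
        report = cluster_outcomes(recs, labels)
        row = report.per_cluster.loc[0]
        _, s365 = km_survival(recs["followup_days"], recs["death"], 365)
        assert row["survival_365d"] == pytest.approx(s365)
        assert row["n"] == 300
        assert row["methadone"] == pytest.approx(recs["methadone_rx"].mean())

    def test_planted_hazards_recovered(self):
        rng = np.random.default_rng(37)
        hazards = {0: 1e-4, 1: 5e-4}
        frames, labels = [], []
        for c, lam in hazards.items():
            f = _records(2000, lam, rng, prefix=f"C{c}-")
            frames.append(f)
            labels.extend([c] * len(f))
        recs = pd.concat(frames, ignore_index=True)
        labels = pd.Series(labels, index=recs["encounter_id"].to_numpy())
        report = cluster_outcomes(recs, labels)
        for c, lam in hazards.items():
            expect = math.exp(-365 * lam)
            se = math.sqrt(expect * (1 - expect) / 2000)
            got = report.per_cluster.loc[c, "survival_365d"]
            assert abs(got - expect) <= 3 * se
        # clearly different hazards: log-rank separates them
        assert report.logrank_p.loc[0, 1] < 0.05

    def test_logrank_type_one_error_rate(self):
        """Equal-hazard clusters reject at ~5% under repeated simulation."""
        rng = np.random.default_rng(41)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            t1 = np.minimum(np.ceil(rng.exponential(900, 80)), 730)
            t2 = np.minimum(np.ceil(rng.exponential(900, 80)), 730)
            from lifelines.statistics import logrank_test

            res = logrank_test(t1, t2, event_observed_A=(t1 < 730).astype(int),
                               event_observed_B=(t2 < 730).astype(int))
            rejections += res.p_value < 0.05
        # 3 SEs around 5% of 200 replicates
        assert abs(rejections / n_rep - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_rep)
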