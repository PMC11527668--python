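from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_dataset
from pvsignal.dictionary import DrugDictionary, PTQuerySet
from pvsignal.onset import (chi2_rxc, compute_tto, kruskal_wallis,
                            mann_whitney, outcome_rates, quartiles,
                            summarize_tto)
from pvsignal.selection import select_cases

DICT = DrugDictionary(entries={"StudyDrug": {"STUDYDRUG"}})
PTS = PTQuerySet(name="target", pts=frozenset({"Acute kidney injury"}))


def _onset_dataset(cases):
    """cases: list of (pid, start_dt, event_dt)."""
    demo = [dict(primaryid=p, caseid=f"C{p}", fda_dt="20230101", event_dt=e)
            for p, s, e in cases]
    drug = [dict(primaryid=p, drug_seq="1", role_cod="PS", drugname="STUDYDRUG")
            for p, s, e in cases]
    reac = [dict(primaryid=p, pt="Acute kidney injury") for p, s, e in cases]
    ther = [dict(primaryid=p, dsg_drug_seq="1", start_dt=s, end_dt="")
            for p, s, e in cases]
    return make_dataset(demo=demo, drug=drug, reac=reac, ther=ther)


class TestComputeTTO:
    def test_day_difference_and_same_day_onset(self):
        ds = _onset_dataset([("1", "20210301", "20210316"),
                             ("2", "20210301", "20210301")])
        cohort = select_cases(ds, DICT, PTS)
        tto = compute_tto(cohort, ds)
        got = dict(zip(tto.records["primaryid"], tto.records["tto_days"]))
        assert got == {"1": 15, "2": 0}

    def test_event_before_start_excluded_with_reason(self):
        ds = _onset_dataset([("1", "20210310", "20210301")])
        cohort = select_cases(ds, DICT, PTS)
        tto = compute_tto(cohort, ds)
        assert tto.n_used == 0
        assert tto.exclusions["event_precedes_start"] == 1

    def test_partial_dates_excluded_not_imputed(self):
        ds = _onset_dataset([("1", "202103", "20210316"),    # month-precision start
                             ("2", "20210301", "2021"),      # year-precision event
                             ("3", "", "20210316"),          # missing start
                             ("4", "20210301", "")])         # missing event
        cohort = select_cases(ds, DICT, PTS)
        tto = compute_tto(cohort, ds)
        assert tto.n_used == 0
        assert tto.exclusions["partial_start_date"] == 1
        assert tto.exclusions["partial_event_date"] == 1
        assert tto.exclusions["missing_start_date"] == 1
        assert tto.exclusions["missing_event_date"] == 1

    def test_earliest_day_precision_start_anchors_onset(self):
        ds = _onset_dataset([("1", "20210310", "20210316")])
        extra = pd.DataFrame([dict(primaryid="1", dsg_drug_seq="1",
                                   start_dt="20210301", end_dt="")]).astype(str)
        ds.ther = pd.concat([ds.ther, extra], ignore_index=True)
        cohort = select_cases(ds, DICT, PTS)
        tto = compute_tto(cohort, ds)
        assert tto.records["tto_days"].tolist() == [15]

    def test_used_plus_excluded_equals_input(self):
        ds = _onset_dataset([("1", "20210301", "20210316"),
                             ("2", "20210310", "20210301"),
                             ("3", "", "20210316")])
        cohort = select_cases(ds, DICT, PTS)
        tto = compute_tto(cohort, ds)
        assert tto.n_used + sum(tto.exclusions.values()) == tto.n_input == 3


class TestQuartiles:
    def test_odd_length(self):
        assert quartiles([1, 2, 3, 4, 5]) == (2.0, 3.0, 4.0)

    def test_linear_interpolation_produces_fractional_quartiles(self):
        # hand interpolation: positions 0.25*(n-1)=1.25 and 3.75
        q1, med, q3 = quartiles([6, 6, 10, 20, 56, 56])
        assert q1 == pytest.approx(6 + 0.25 * (10 - 6))
        assert med == pytest.approx(15.0)
        assert q3 == pytest.approx(20 + 0.75 * (56 - 20))

    def test_summarize_groups_and_early_onset_fractions(self):
        records = pd.DataFrame({
            "primaryid": [str(i) for i in range(6)],
            "drug": ["A"] * 5 + ["B"],
            "start_date": [None] * 6, "event_date": [None] * 6,
            "tto_days": [1, 2, 3, 4, 100, 7],
        })
        from pvsignal.onset import TTOResult
        summary = summarize_tto(TTOResult(records=records, exclusions={}, n_input=6))
        row = summary.per_drug.set_index("drug").loc["A"]
        assert row["median"] == 3.0 and row["n"] == 5
        assert row["frac_le_30"] == pytest.approx(0.8)
        assert summary.overall["median"] == 3.5


class TestMannWhitney:
    def test_complete_separation_small_groups(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0.0

    def test_exact_enumeration_p_value(self):
        r = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 70, abs=1e-12)
        assert r.method == "mann_whitney_exact"

    def test_identical_groups_give_p_one(self):
        r = mann_whitney([5, 5, 5], [5, 5])
        assert r.p_value == 1.0 and r.note

    def test_equal_distributions_center_u(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic == 8.0  # n*m/2
        assert r.p_value > 0.9


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1..9 in three blocks: H = 12/(9*10) * sum n_i*(rbar_i-5)^2 = 7.2
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2, abs=1e-12)
        assert r.df == 2

    def test_identical_observations_flagged(self):
        r = kruskal_wallis([[3, 3], [3, 3], [3]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_invariant_under_monotone_transform(self):
        groups = [[1, 5, 9], [2, 4, 20], [3, 8, 30]]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_two_groups_consistent_with_mann_whitney_chi_square(self):
        x, y = [1, 4, 6, 9, 12], [2, 3, 5, 20, 30]
        h = kruskal_wallis([x, y])
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert h.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestChi2:
    def test_pearson_and_yates_closed_forms(self):
        a, b, c, d = 10, 20, 20, 10
        n = a + b + c + d
        margins = (a + b) * (c + d) * (a + c) * (b + d)
        pearson = chi2_rxc([[a, b], [c, d]], force_yates=False)
        assert pearson.statistic == pytest.approx(n * (a * d - b * c) ** 2 / margins,
                                                  abs=1e-9)
        assert pearson.statistic == pytest.approx(6.667, abs=5e-4)
        yates = chi2_rxc([[a, b], [c, d]], force_yates=True)
        assert yates.statistic == pytest.approx(
            n * (abs(a * d - b * c) - n / 2) ** 2 / margins, abs=1e-9)
        assert yates.statistic == pytest.approx(5.4, abs=1e-12)

    def test_yates_auto_applied_when_expected_below_five(self):
        small = chi2_rxc([[2, 8], [3, 7]])
        assert small.correction
        large = chi2_rxc([[100, 100], [100, 100]])
        assert not large.correction

    def test_yates_never_exceeds_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table = rng.integers(1, 50, size=(2, 2))
            p = chi2_rxc(table, force_yates=False).statistic
            y = chi2_rxc(table, force_yates=True).statistic
            assert y <= p + 1e-12

    def test_identical_rows_give_zero(self):
        r = chi2_rxc([[5, 10], [5, 10]], force_yates=False)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_margin_names_the_margin(self):
        with pytest.raises(ValueError, match="column margin 1"):
            chi2_rxc([[5, 0], [5, 0]])


class TestOutcomeRates:
    def _cohort_dataset(self):
        ds = _onset_dataset([("1", "20210301", "20210316"),
                             ("2", "20210301", "20210316"),
                             ("3", "20210301", "20210316"),
                             ("4", "20210301", "20210316")])
        outc = [dict(primaryid="1", outc_cod="HO"),
                dict(primaryid="2", outc_cod="HO"),
                dict(primaryid="2", outc_cod="DE"),
                dict(primaryid="3", outc_cod="OT")]
        ds.outc = pd.DataFrame(outc).astype(str)
        return ds

    def test_cohort_denominator_rates(self):
        ds = self._cohort_dataset()
        cohort = select_cases(ds, DICT, PTS)
        summary = outcome_rates(cohort, ds, denominator_mode="cohort_reports")
        assert summary.overall["hospitalization_rate"] == 50.0
        assert summary.overall["fatality_rate"] == 25.0
        assert summary.overall["denominator"] == 4

    def test_reports_with_outcome_denominator(self):
        ds = self._cohort_dataset()
        cohort = select_cases(ds, DICT, PTS)
        summary = outcome_rates(cohort, ds, denominator_mode="reports_with_outcome")
        assert summary.overall["denominator"] == 3
        assert summary.overall["hospitalization_rate"] == pytest.approx(66.67)

    def test_rate_matches_binomial_sampling(self):
        from pvsignal.io import deduplicate
        from pvsignal.simulate import DrugSpec, GeneratorConfig, generate
        config = GeneratorConfig(
            n_reports=40_000, seed=3, background_event_prob=0.05,
            drugs=(DrugSpec("StudyDrug", "STUDYDRUG", 0.20, 8.0),),
            missing_event_date_rate=0.0, missing_start_date_rate=0.0)
        dataset, _ = generate(config)
        dataset = deduplicate(dataset)
        cohort = select_cases(dataset, config.dictionary(), config.pt_query_set())
        summary = outcome_rates(cohort, dataset, denominator_mode="cohort_reports")
        # generator plants P(HO | target event) = 0.28; cohort is ~2,400
        # reports, so the binomial 3-sigma band is about +/-2.7 points
        assert summary.overall["hospitalization_rate"] == pytest.approx(28.0, abs=2.7)
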