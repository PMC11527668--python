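from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_dataset
from pvsignal.signals import (ContingencyTable, DisproportionalityModel,
                              SignalCriteria, SignalResult, build_contingency,
                              compute_ebgm, compute_ic, compute_prr,
                              compute_ror, compute_signal, evaluate_criteria,
                              signal_scan)

FIXTURE = ContingencyTable(20, 80, 30, 870)
NULL_TABLE = ContingencyTable(10, 10, 10, 10)

positive_cells = st.integers(min_value=1, max_value=2000)
tables = st.builds(ContingencyTable, positive_cells, positive_cells,
                   positive_cells, positive_cells)


class TestPointEstimates:
    def test_fixture_table_all_four_statistics(self):
        ror, lo, hi = compute_ror(FIXTURE)
        assert ror == pytest.approx(7.25, abs=1e-12)
        prr, chi2 = compute_prr(FIXTURE)
        assert prr == pytest.approx(0.4 / (80.0 / 950.0), abs=1e-12)
        assert prr == pytest.approx(4.75, abs=1e-2)
        # closed-form Pearson chi2: N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 20, 80, 30, 870
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, abs=1e-9)
        assert chi2 == pytest.approx(52.63, abs=5e-3)
        ic, ic025 = compute_ic(FIXTURE)
        assert ic == pytest.approx(2.0, abs=1e-12)
        ebgm, ebgm05 = compute_ebgm(FIXTURE)
        assert ebgm == pytest.approx(4.0, abs=1e-12)
        assert ebgm05 == pytest.approx(2.40, abs=5e-3)

    def test_null_table_is_exactly_null(self):
        ror, lo, hi = compute_ror(NULL_TABLE)
        assert ror == 1.0 and lo < 1.0 < hi
        prr, chi2 = compute_prr(NULL_TABLE)
        assert prr == 1.0 and chi2 == 0.0
        ic, ic025 = compute_ic(NULL_TABLE)
        assert ic == 0.0 and math.isnan(ic025)  # no positive IC, no lower bound
        ebgm, _ = compute_ebgm(NULL_TABLE)
        assert ebgm == 1.0

    def test_woolf_interval_matches_independent_reference(self):
        # statsmodels provides the log-OR and its standard error; the
        # interval multiplier is the printed 1.96 rather than norm.ppf
        sm = pytest.importorskip("statsmodels.api")
        t22 = sm.stats.Table2x2(np.array([[20, 30], [80, 870]]))
        ror, lo, hi = compute_ror(FIXTURE)
        assert ror == pytest.approx(t22.oddsratio, abs=1e-9)
        assert lo == pytest.approx(
            math.exp(t22.log_oddsratio - 1.96 * t22.log_oddsratio_se), abs=1e-9)
        assert hi == pytest.approx(
            math.exp(t22.log_oddsratio + 1.96 * t22.log_oddsratio_se), abs=1e-9)

    def test_four_cell_chi2_matches_scipy(self):
        from scipy.stats import chi2_contingency
        _, chi2 = compute_prr(FIXTURE)
        ref, _, _, _ = chi2_contingency(np.array([[20, 80], [30, 870]]),
                                        correction=False)
        assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_a_cell_variant_uses_only_exposed_event_term(self):
        a, b, c, d = FIXTURE.cells
        n = FIXTURE.n_total
        e_a = (a + b) * (a + c) / n
        _, chi2 = compute_prr(FIXTURE, chi2_variant="a_cell")
        assert chi2 == pytest.approx((a - e_a) ** 2 / e_a, abs=1e-12)

    def test_canonical_interval_mode_is_additive_on_log2_scale(self):
        ic, ic025 = compute_ic(FIXTURE, interval_mode="canonical")
        s = math.sqrt(1 / 20 + 1 / 80 + 1 / 30 + 1 / 870)
        assert ic025 == pytest.approx(ic - 1.96 * s / math.log(2), abs=1e-12)


class TestZeroCells:
    def test_zero_cell_yields_undefined_without_correction(self):
        t = ContingencyTable(0, 10, 10, 100)
        assert math.isnan(compute_ror(t)[0])
        assert math.isnan(compute_ic(t)[0])

    def test_continuity_correction_restores_definition(self):
        t = ContingencyTable(0, 10, 10, 100)
        ror, lo, hi = compute_ror(t, continuity_correction=True)
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))

    def test_correction_leaves_large_cell_flags_unchanged(self):
        # a statistic exactly at its threshold could flip in principle, but on
        # generic tables with all cells >= 10 the +0.5 shift is negligible
        rng = np.random.default_rng(2024)
        for _ in range(500):
            cells = rng.integers(10, 1000, size=4)
            t = ContingencyTable(*cells)
            plain = compute_signal(t).flags
            corrected = compute_signal(t.corrected(),
                                       n_reports=int(t.a)).flags
            assert plain == corrected


class TestAlgebraicStructure:
    @settings(max_examples=300, derandomize=True)
    @given(tables)
    def test_ic_is_log2_of_ebgm(self, t):
        ic, _ = compute_ic(t)
        ebgm, _ = compute_ebgm(t)
        assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(tables)
    def test_ror_exceeds_prr_exceeds_ebgm_iff_positive_association(self, t):
        ror = compute_ror(t)[0]
        prr = compute_prr(t)[0]
        ebgm = compute_ebgm(t)[0]
        if t.a * t.d > t.b * t.c:
            assert ror > prr > ebgm
        elif t.a * t.d == t.b * t.c:
            assert ror == pytest.approx(prr, rel=1e-12)
            assert prr == pytest.approx(ebgm, rel=1e-12)
        else:
            assert ror < prr < ebgm


class TestCriteria:
    def _result(self, n, ci_low, prr, chi2, ic025, ebgm05):
        r = SignalResult(drug="x", table=NULL_TABLE, n_reports=n,
                         ror=ci_low + 1, ror_ci95=(ci_low, ci_low + 2),
                         prr=prr, chi2=chi2, ic=0.0, ic025=ic025,
                         ebgm=1.0, ebgm05=ebgm05)
        return evaluate_criteria(r)

    def test_published_style_strong_rows_flag_all_four(self):
        # values as printed for the strongly associated drugs
        niraparib = self._result(1203, 3.41, 3.48, 1851.32, 1.69, 3.29)
        rucaparib = self._result(324, 2.55, 2.75, 411.70, 1.31, 2.51)
        veliparib = self._result(4, 8.79, 19.80, 72.62, 1.30, 7.25)
        for flags in (niraparib, rucaparib, veliparib):
            assert flags["all"]

    def test_weak_row_fails_everything(self):
        talazoparib = self._result(21, 0.46, 0.84, 0.36, float("nan"), 0.51)
        assert not any(talazoparib.values())

    def test_moderate_row_passes_ror_but_fails_prr(self):
        olaparib = self._result(292, 1.40, 1.57, 58.52, 0.57, 1.42)
        assert olaparib["ror"] and not olaparib["prr"] and not olaparib["all"]

    def test_null_table_flags_nothing(self):
        result = compute_signal(NULL_TABLE)
        assert not any(result.flags.values())

    def test_undefined_statistics_evaluate_false(self):
        flags = self._result(5, float("nan"), float("nan"), float("nan"),
                             float("nan"), float("nan"))
        assert not any(flags.values())


class TestBuildContingency:
    def test_toy_counts(self, toy_dataset, parp_dictionary, renal_pts):
        t = build_contingency(toy_dataset, parp_dictionary, renal_pts, "Niraparib")
        assert t.cells == (3, 1, 2, 4)

    def test_permuted_rows_identical_table(self, toy_dataset, parp_dictionary,
                                           renal_pts):
        shuffled = toy_dataset.copy()
        shuffled.drug = shuffled.drug.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled.reac = shuffled.reac.sample(frac=1, random_state=2).reset_index(drop=True)
        a = build_contingency(toy_dataset, parp_dictionary, renal_pts, "Niraparib")
        b = build_contingency(shuffled, parp_dictionary, renal_pts, "Niraparib")
        assert a.cells == b.cells

    def test_unknown_drug_is_hard_error(self, toy_dataset, parp_dictionary, renal_pts):
        with pytest.raises(ValueError, match="not in dictionary"):
            build_contingency(toy_dataset, parp_dictionary, renal_pts, "Aspirin")

    def test_occurrence_unit_counts_reaction_rows(self, toy_dataset,
                                                  parp_dictionary, renal_pts):
        t = build_contingency(toy_dataset, parp_dictionary, renal_pts,
                              "Niraparib", counting_unit="occurrences")
        # 10 reaction rows: 3 exposed-target, 1 unexposed-target, 2 exposed-decoy
        assert t.cells == (3, 1, 2, 4)
        assert t.n_total == len(toy_dataset.reac)

    def test_observed_counts_within_4_sigma_of_generator_expectation(self):
        from pvsignal.io import deduplicate
        from pvsignal.simulate import DrugSpec, GeneratorConfig, expected_table, generate
        config = GeneratorConfig(
            n_reports=50_000, seed=77, background_event_prob=0.02,
            drugs=(DrugSpec("StudyDrug", "STUDYDRUG", 0.01, 8.0),),
            concomitant_rate=0.0)
        dataset, _ = generate(config)
        dataset = deduplicate(dataset)
        t = build_contingency(dataset, config.dictionary(),
                              config.pt_query_set(), "StudyDrug")
        ea, eb, ec, ed = expected_table(config, "StudyDrug")
        # binomial standard deviations from the closed-form cell probabilities
        n = config.n_reports
        for observed, expected in zip(t.cells, (ea, eb, ec, ed)):
            p = expected / n
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(observed - expected) <= 4 * sigma


class TestScan:
    def test_requires_deduplicated_dataset(self, toy_dataset, parp_dictionary,
                                           renal_pts):
        raw = toy_dataset.copy()
        raw.meta["deduplicated"] = False
        with pytest.raises(ValueError, match="dedup"):
            DisproportionalityModel(raw, parp_dictionary, renal_pts)

    def test_one_result_per_generic_in_dictionary_order(self, toy_dataset,
                                                        parp_dictionary, renal_pts):
        results = signal_scan(toy_dataset, parp_dictionary, renal_pts)
        assert [r.drug for r in results] == parp_dictionary.generics

    def test_absent_drug_has_zero_n_and_no_flags(self, toy_dataset,
                                                 parp_dictionary, renal_pts):
        fit = DisproportionalityModel(toy_dataset, parp_dictionary, renal_pts).fit()
        veliparib = fit["Veliparib"]
        assert veliparib.n_reports == 0
        assert math.isnan(veliparib.ror)
        assert not any(veliparib.flags.values())

    def test_scan_is_deterministic(self, toy_dataset, parp_dictionary, renal_pts):
        a = DisproportionalityModel(toy_dataset, parp_dictionary, renal_pts).fit()
        b = DisproportionalityModel(toy_dataset, parp_dictionary, renal_pts).fit()
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_summary_renders(self, toy_dataset, parp_dictionary, renal_pts):
        text = DisproportionalityModel(toy_dataset, parp_dictionary,
                                       renal_pts).fit().summary()
        assert "Niraparib" in text and "EBGM" in text

    def test_planted_associations_recovered_in_flags(self):
        from pvsignal.io import deduplicate
        from pvsignal.simulate import DrugSpec, GeneratorConfig, generate
        config = GeneratorConfig(
            n_reports=100_000, seed=11,
            drugs=(DrugSpec("DrugA", "DRUGA", 0.01, 1.0),
                   DrugSpec("DrugB", "DRUGB", 0.01, 2.0),
                   DrugSpec("DrugC", "DRUGC", 0.01, 8.0)))
        dataset, _ = generate(config)
        fit = DisproportionalityModel(deduplicate(dataset), config.dictionary(),
                                      config.pt_query_set()).fit()
        assert not fit["DrugA"].flags["all"]
        assert fit["DrugC"].flags["all"]


def test_rounded_presentation_uses_half_up_two_decimals():
    r = compute_signal(FIXTURE, drug="x")
    out = r.rounded()
    assert out["ROR"] == 7.25 and out["EBGM"] == 4.0 and out["chi2"] == 52.63
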