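"""Time-to-onset and outcome analysis for a selected cohort.

Time to onset (TTO) is the whole-day difference between the adverse-event
onset date and the start of therapy with the matched drug.  Only
day-precision dates on both ends are used — partial dates are excluded, not
imputed, because imputation would manufacture the very medians under study.
Events dated before therapy start are data errors and are excluded with an
explicit reason; identical dates give TTO 0 (onset at first dose).

Group comparisons use the field's nonparametric conventions: Mann–Whitney
for two groups, Kruskal–Wallis for more, and Pearson or Yates-corrected
chi-square for rate contrasts (Yates when a 2x2 expected frequency drops
below five).  scipy.stats provides the machinery behind this module's
surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dates import DatePrecision, parse_date
from .io import SRSDataset, OUTCOME_CODES
from .selection import CaseCohort, percent

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "missing_start_date", "missing_event_date",
    "partial_start_date", "partial_event_date",
    "event_precedes_start", "no_linked_therapy",
)


@dataclass
class OnsetRecord:
    primaryid: str
    drug: str
    start_date: object
    event_date: object
    tto_days: int


@dataclass
class TTOResult:
    records: pd.DataFrame                 # primaryid, drug, start_date, event_date, tto_days
    exclusions: Dict[str, int]            # reason -> count
    n_input: int

    @property
    def n_used(self) -> int:
        return len(self.records)


def compute_tto(cohort: CaseCohort, dataset: SRSDataset) -> TTOResult:
    """Per-(report, drug) time to onset in days, with a categorized exclusion log.

    The therapy row is linked through the matched drug row's drug_seq; when
    several linked therapy rows carry day-precision start dates, the
    earliest start anchors onset.
    """
    ther = dataset.ther.astype({"primaryid": str})
    demo = dataset.demo.astype({"primaryid": str})
    matches = cohort.matches.astype({"primaryid": str, "drug_seq": str})

    event_lookup = dict(zip(demo["primaryid"], demo["event_dt"]))
    seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else "drug_seq"
    linked = matches.merge(ther, left_on=["primaryid", "drug_seq"],
                           right_on=["primaryid", seq_col], how="left")

    exclusions = {r: 0 for r in EXCLUSION_REASONS}
    rows: List[dict] = []
    pairs = linked.groupby(["primaryid", "drug"], sort=True)
    n_input = 0
    for (pid, drug), grp in pairs:
        n_input += 1
        event_raw = event_lookup.get(pid, "")
        event, event_prec = parse_date(event_raw)
        starts = []
        any_start_raw = False
        any_partial_start = False
        for raw in grp["start_dt"] if "start_dt" in grp.columns else []:
            value, prec = parse_date(raw)
            if str(raw).strip() not in {"", "nan", "None"}:
                any_start_raw = True
            if value is None:
                continue
            if prec == DatePrecision.DAY:
                starts.append(value)
            else:
                any_partial_start = True
        if "start_dt" not in linked.columns or grp["start_dt"].isna().all():
            exclusions["no_linked_therapy"] += 1
            continue
        if not starts:
            if any_partial_start:
                exclusions["partial_start_date"] += 1
            elif any_start_raw:
                exclusions["missing_start_date"] += 1
            else:
                exclusions["missing_start_date"] += 1
            continue
        if event is None:
            exclusions["missing_event_date"] += 1
            continue
        if event_prec != DatePrecision.DAY:
            exclusions["partial_event_date"] += 1
            continue
        start = min(starts)
        delta = (event - start).days
        if delta < 0:
            exclusions["event_precedes_start"] += 1
            continue
        rows.append({"primaryid": pid, "drug": drug,
                     "start_date": start, "event_date": event, "tto_days": int(delta)})

    records = pd.DataFrame(rows, columns=["primaryid", "drug", "start_date",
                                          "event_date", "tto_days"])
    logger.info("compute_tto: %d/%d pairs usable; exclusions %s",
                len(records), n_input,
                {k: v for k, v in exclusions.items() if v})
    return TTOResult(records=records, exclusions=exclusions, n_input=n_input)


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


@dataclass
class OnsetSummary:
    per_drug: pd.DataFrame     # drug, n, median, q1, q3, frac_le_30, frac_le_90
    overall: Dict[str, float]
    exclusions: Dict[str, int]


def summarize_tto(tto: TTOResult, min_n: int = 1) -> OnsetSummary:
    """Median/IQR per drug plus early-onset fractions (<=30, <=90 days)."""
    records = tto.records
    rows = []
    for drug, grp in records.groupby("drug", sort=True):
        vals = grp["tto_days"].to_numpy(dtype=float)
        if len(vals) < min_n:
            logger.info("summarize_tto: drug %s has %d record(s), below min_n", drug, len(vals))
            continue
        q1, med, q3 = quartiles(vals)
        rows.append({"drug": drug, "n": len(vals), "median": med, "q1": q1, "q3": q3,
                     "frac_le_30": float(np.mean(vals <= 30)),
                     "frac_le_90": float(np.mean(vals <= 90))})
    per_drug = pd.DataFrame(rows, columns=["drug", "n", "median", "q1", "q3",
                                           "frac_le_30", "frac_le_90"])
    overall: Dict[str, float] = {}
    if len(records):
        q1, med, q3 = quartiles(records["tto_days"])
        overall = {"n": float(len(records)), "median": med, "q1": q1, "q3": q3,
                   "frac_le_30": float(np.mean(records["tto_days"] <= 30)),
                   "frac_le_90": float(np.mean(records["tto_days"] <= 90))}
    return OnsetSummary(per_drug=per_drug, overall=overall, exclusions=dict(tto.exclusions))


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    correction: bool = False
    note: str = ""


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U.

    Exact null enumeration when both groups have n <= 8 and no cross-group
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(list(group_a), dtype=float)
    y = np.asarray(list(group_b), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("mann_whitney", statistic=len(x) * len(y) / 2.0, p_value=1.0,
                          note="all observations identical")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return TestResult(f"mann_whitney_{method}", statistic=float(res.statistic),
                      p_value=float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H; p from chi-square with k-1 df."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", statistic=0.0, p_value=1.0,
                          df=len(groups) - 1, note="all observations identical")
    h, p = stats.kruskal(*groups)
    return TestResult("kruskal_wallis", statistic=float(h), p_value=float(p),
                      df=len(groups) - 1)


def chi2_rxc(counts, force_yates: Optional[bool] = None) -> TestResult:
    """Pearson chi-square on an r x c count table.

    For 2x2 tables the Yates continuity correction is applied automatically
    when any expected frequency is below five (or on demand via
    ``force_yates``); larger tables always use the plain Pearson statistic.
    Raises on a zero margin, naming it.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row margin {i} is zero")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column margin {j} is zero")
    expected = np.outer(row_sums, col_sums) / table.sum()
    is_2x2 = table.shape == (2, 2)
    if is_2x2:
        yates = force_yates if force_yates is not None else bool((expected < 5).any())
    else:
        yates = False
    stat, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return TestResult("chi2_yates" if yates else "chi2_pearson",
                      statistic=float(stat), p_value=float(p), df=float(df),
                      correction=yates)


@dataclass
class OutcomeSummary:
    per_drug: pd.DataFrame       # drug, n_reports, n_with_outcome, per-code counts, rates
    overall: Dict[str, object]
    denominator_mode: str


def outcome_rates(cohort: CaseCohort, dataset: SRSDataset,
                  denominator_mode: str = "cohort_reports") -> OutcomeSummary:
    """Outcome-code counts and hospitalization/fatality rates per drug.

    ``cohort_reports`` divides by all cohort reports for the drug;
    ``reports_with_outcome`` divides by reports carrying at least one
    outcome code.  Both denominators are carried in the output — published
    rates are ambiguous on this point, so neither is privileged silently.
    """
    if denominator_mode not in {"cohort_reports", "reports_with_outcome"}:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    outc = dataset.outc.astype({"primaryid": str})
    code = outc["outc_cod"].astype(str).str.strip().str.upper()
    outc = pd.DataFrame({"primaryid": outc["primaryid"], "code": code}).drop_duplicates()

    def summarize(pids: set) -> Dict[str, object]:
        sub = outc[outc["primaryid"].isin(pids)]
        n_with = sub["primaryid"].nunique()
        counts = {c: int((sub["code"] == c).sum()) for c in OUTCOME_CODES}
        denom = len(pids) if denominator_mode == "cohort_reports" else n_with
        return {
            "n_reports": len(pids), "n_with_outcome": int(n_with),
            **{f"n_{c}": counts[c] for c in OUTCOME_CODES},
            "hospitalization_rate": percent(counts["HO"], denom) if denom else float("nan"),
            "fatality_rate": percent(counts["DE"], denom) if denom else float("nan"),
            "denominator": denom,
        }

    rows = []
    for drug, grp in cohort.rows.groupby("drug", sort=True):
        pids = set(grp["primaryid"].astype(str))
        rows.append({"drug": drug, **summarize(pids)})
    per_drug = pd.DataFrame(rows)
    overall = summarize(cohort.primaryids())
    return OutcomeSummary(per_drug=per_drug, overall=overall,
                          denominator_mode=denominator_mode)
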