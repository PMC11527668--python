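"""Disproportionality statistics for drug–event signal detection.

For one drug D and one event set E over a deduplicated report database, the
2x2 contingency table is

    a = reports with D (as suspect) and E        b = reports with E, not D
    c = reports with D, not E                    d = neither

and four frequentist/Bayesian measures are computed, each with its
conventional signal criterion:

======  ===============================================  ====================
ROR     (a/b)/(c/d), Woolf CI on the log scale           CI lower > 1, N >= 2
PRR     (a/(a+c))/(b/(b+d)), with a chi-square           PRR >= 2, chi2 >= 4,
                                                         N >= 3
IC      log2( a*N / ((a+c)(a+b)) )                       IC025 > 0
EBGM    a*N / ((a+c)(a+b))  (relative reporting ratio)   EBGM05 > 2, N > 0
======  ===============================================  ====================

Interval formulas follow the source formulation exactly by default
(``interval_mode="verbatim"``): the IC lower bound is the *multiplicative*
IC*exp(-1.96*s) with s = sqrt(1/a+1/b+1/c+1/d), defined only when IC > 0;
EBGM05 = EBGM*exp(-1.64*s) (a 90% one-sided bound).  Note that under these
printed formulas EBGM carries no Bayesian shrinkage — it is the unshrunk
relative reporting ratio, and IC = log2(EBGM) identically.  A "canonical"
mode replaces the IC bound with the additive delta-method bound on the log2
scale.  The chi-square accompanying PRR defaults to the four-cell Pearson
statistic; an ``a_cell`` variant using only the (a, E_a) term is selectable.

Zero cells make the measures undefined; results then carry NaN and evaluate
to no signal, unless the Haldane–Anscombe +0.5 continuity correction is
switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .dictionary import DrugDictionary, PTQuerySet, normalize_pt
from .io import SRSDataset
from .selection import round_half_up

__all__ = [
    "ContingencyTable", "SignalCriteria", "SignalResult",
    "compute_ror", "compute_prr", "compute_ic", "compute_ebgm",
    "compute_signal", "build_contingency", "evaluate_criteria", "signal_scan",
    "DisproportionalityModel", "DisproportionalityResults",
]

NAN = float("nan")


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 drug-by-event report counts (a, b, c, d)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")
        if self.n_total <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def corrected(self) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction (+0.5 to every cell)."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def has_zero_cell(self) -> bool:
        return any(v == 0 for v in self.cells)

    def _s(self) -> float:
        """sqrt(1/a + 1/b + 1/c + 1/d), the shared log-scale spread term."""
        return math.sqrt(sum(1.0 / v for v in self.cells))


def _maybe_correct(table: ContingencyTable, continuity: bool) -> Optional[ContingencyTable]:
    if not table.has_zero_cell():
        return table
    return table.corrected() if continuity else None


def compute_ror(table: ContingencyTable, continuity_correction: bool = False
                ) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% Woolf CI; NaNs on a zero cell."""
    t = _maybe_correct(table, continuity_correction)
    if t is None:
        return NAN, NAN, NAN
    ror = (t.a * t.d) / (t.b * t.c)
    half = 1.96 * t._s()
    return ror, ror * math.exp(-half), ror * math.exp(half)


def compute_prr(table: ContingencyTable, chi2_variant: str = "four_cell",
                continuity_correction: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and its chi-square.

    ``four_cell``: Pearson statistic summed over all four cells (equivalently
    N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))).  ``a_cell``: only the exposed-event
    term (a - E_a)^2 / E_a.
    """
    if chi2_variant not in {"four_cell", "a_cell"}:
        raise ValueError(f"unknown chi2 variant {chi2_variant!r}")
    t = _maybe_correct(table, continuity_correction)
    if t is None:
        return NAN, NAN
    a, b, c, d = t.cells
    n = t.n_total
    if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
        return NAN, NAN
    prr = (a / (a + c)) / (b / (b + d))
    row = (a + b, c + d)
    col = (a + c, b + d)
    if chi2_variant == "a_cell":
        e_a = row[0] * col[0] / n
        chi2 = (a - e_a) ** 2 / e_a
    else:
        chi2 = 0.0
        for i, o in enumerate((a, b, c, d)):
            e = row[i // 2] * col[i % 2] / n
            chi2 += (o - e) ** 2 / e
    return prr, chi2


def compute_ic(table: ContingencyTable, interval_mode: str = "verbatim",
               continuity_correction: bool = False) -> tuple[float, float]:
    """Information component log2(a*N/((a+c)(a+b))) and its lower bound.

    Verbatim mode: IC025 = IC * exp(-1.96*s), defined only for IC > 0
    (a negative IC has no meaningful multiplicative lower bound and is
    reported without one).  Canonical mode: IC - 1.96*s/ln2, the additive
    delta-method bound on the log2 scale.
    """
    if interval_mode not in {"verbatim", "canonical"}:
        raise ValueError(f"unknown interval mode {interval_mode!r}")
    t = _maybe_correct(table, continuity_correction)
    if t is None:
        return NAN, NAN
    a, b, c, d = t.cells
    ic = math.log2(a * t.n_total / ((a + c) * (a + b)))
    s = t._s()
    if interval_mode == "canonical":
        return ic, ic - 1.96 * s / math.log(2)
    if ic <= 0:
        return ic, NAN
    return ic, ic * math.exp(-1.96 * s)


def compute_ebgm(table: ContingencyTable, continuity_correction: bool = False
                 ) -> tuple[float, float]:
    """Relative reporting ratio a*N/((a+c)(a+b)) and its 90% one-sided lower bound.

    As formulated here this is the unshrunk empirical ratio (no gamma-Poisson
    shrinkage); EBGM05 = EBGM * exp(-1.64*s).
    """
    t = _maybe_correct(table, continuity_correction)
    if t is None:
        return NAN, NAN
    a, b, c, d = t.cells
    ebgm = a * t.n_total / ((a + c) * (a + b))
    return ebgm, ebgm * math.exp(-1.64 * t._s())


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm signal thresholds (all configurable)."""

    ror_ci_low: float = 1.0
    ror_min_n: int = 2
    prr_min: float = 2.0
    prr_min_chi2: float = 4.0
    prr_min_n: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    mgps_min_n: int = 1  # N > 0


@dataclass
class SignalResult:
    """One drug's full disproportionality readout (one report-table row)."""

    drug: str
    table: ContingencyTable
    n_reports: int
    ror: float = NAN
    ror_ci95: tuple = (NAN, NAN)
    prr: float = NAN
    chi2: float = NAN
    ic: float = NAN
    ic025: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    flags: Dict[str, bool] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> Dict[str, object]:
        """Presentation form: 2-decimal round-half-up, NaN -> None."""
        def r(x):
            return None if (x is None or (isinstance(x, float) and math.isnan(x))) \
                else round_half_up(x, ndigits)
        return {
            "drug": self.drug, "N": self.n_reports,
            "ROR": r(self.ror), "ROR_CI95_low": r(self.ror_ci95[0]),
            "ROR_CI95_high": r(self.ror_ci95[1]),
            "PRR": r(self.prr), "chi2": r(self.chi2),
            "IC": r(self.ic), "IC025": r(self.ic025),
            "EBGM": r(self.ebgm), "EBGM05": r(self.ebgm05),
            **{f"flag_{k}": v for k, v in self.flags.items()},
        }


def evaluate_criteria(result: SignalResult,
                      criteria: SignalCriteria = SignalCriteria()) -> Dict[str, bool]:
    """Apply the four signal criteria; undefined statistics evaluate False."""
    def ok(x, threshold, strict=True):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return False
        return x > threshold if strict else x >= threshold

    n = result.n_reports
    flags = {
        "ror": ok(result.ror_ci95[0], criteria.ror_ci_low) and n >= criteria.ror_min_n,
        "prr": (ok(result.prr, criteria.prr_min, strict=False)
                and ok(result.chi2, criteria.prr_min_chi2, strict=False)
                and n >= criteria.prr_min_n),
        "bcpnn": ok(result.ic025, criteria.ic025_min),
        "mgps": ok(result.ebgm05, criteria.ebgm05_min) and n >= criteria.mgps_min_n,
    }
    flags["all"] = all(flags.values())
    return flags


def compute_signal(table: ContingencyTable, drug: str = "",
                   criteria: SignalCriteria = SignalCriteria(),
                   chi2_variant: str = "four_cell",
                   interval_mode: str = "verbatim",
                   continuity_correction: bool = False,
                   n_reports: Optional[int] = None) -> SignalResult:
    """All four statistics plus criteria flags for one table."""
    ror, lo, hi = compute_ror(table, continuity_correction)
    prr, chi2 = compute_prr(table, chi2_variant, continuity_correction)
    ic, ic025 = compute_ic(table, interval_mode, continuity_correction)
    ebgm, ebgm05 = compute_ebgm(table, continuity_correction)
    result = SignalResult(
        drug=drug, table=table,
        n_reports=int(n_reports if n_reports is not None else table.a),
        ror=ror, ror_ci95=(lo, hi), prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05)
    result.flags = evaluate_criteria(result, criteria)
    return result


def _match_series(values: pd.Series, dictionary: DrugDictionary,
                  substring: bool = False) -> pd.Series:
    """Dictionary-match a name column via its unique values (fast on the
    highly repetitive drugname columns of report databases)."""
    uniques = pd.unique(values)
    lookup = {u: dictionary.match(u, substring=substring) for u in uniques}
    return values.map(lookup)


def _pt_hit_series(pts: pd.Series, pt_set: PTQuerySet) -> pd.Series:
    uniques = pd.unique(pts)
    lookup = {u: (normalize_pt(u) in pt_set.pts) for u in uniques}
    return pts.map(lookup)


def _positive_sets(dataset: SRSDataset, dictionary: DrugDictionary,
                   pt_set: PTQuerySet, role_filter: Iterable[str],
                   substring: bool = False):
    """Per-generic suspect-report pid sets and the event-positive pid set."""
    roles = {str(r).strip().upper() for r in role_filter}
    drug = dataset.drug
    matched = _match_series(drug["drugname"], dictionary, substring)
    if "prod_ai" in drug.columns:
        matched = matched.fillna(_match_series(drug["prod_ai"], dictionary, substring))
    role_ok = drug["role_cod"].astype(str).str.strip().str.upper().isin(roles)
    sub = pd.DataFrame({"primaryid": drug["primaryid"].astype(str),
                        "generic": matched})[matched.notna() & role_ok]
    drug_pids = {g: set(v) for g, v in sub.groupby("generic")["primaryid"]}

    reac = dataset.reac
    hit = _pt_hit_series(reac["pt"], pt_set)
    event_pids = set(reac.loc[hit, "primaryid"].astype(str))
    return drug_pids, event_pids


def _table_from_sets(exposed: set, event_pids: set, n_total: int) -> ContingencyTable:
    a = len(exposed & event_pids)
    b = len(event_pids) - a
    c = len(exposed) - a
    return ContingencyTable(a, b, c, n_total - a - b - c)


def build_contingency(dataset: SRSDataset, dictionary: DrugDictionary,
                      pt_set: PTQuerySet, drug: str,
                      role_filter: Iterable[str] = ("PS",),
                      counting_unit: str = "reports",
                      substring: bool = False) -> ContingencyTable:
    """2x2 table for one generic against the whole (deduplicated) database.

    ``counting_unit="reports"`` counts unique reports (the default);
    ``"occurrences"`` counts reaction rows (a report contributes once per
    coded PT), a convention some published tables appear to use.
    """
    if drug not in dictionary.entries:
        raise ValueError(f"drug {drug!r} not in dictionary {dictionary.name!r}")
    if counting_unit not in {"reports", "occurrences"}:
        raise ValueError(f"unknown counting unit {counting_unit!r}")
    drug_pids, event_pids = _positive_sets(dataset, dictionary, pt_set,
                                           role_filter, substring)
    exposed = drug_pids.get(drug, set())
    if counting_unit == "reports":
        return _table_from_sets(exposed, event_pids, dataset.n_reports)
    else:
        reac = dataset.reac
        pid = reac["primaryid"].astype(str)
        is_event = _pt_hit_series(reac["pt"], pt_set).to_numpy()
        is_exposed = pid.isin(exposed).to_numpy()
        a = int((is_event & is_exposed).sum())
        b = int((is_event & ~is_exposed).sum())
        c = int((~is_event & is_exposed).sum())
        d = int((~is_event & ~is_exposed).sum())
    return ContingencyTable(a, b, c, d)


def signal_scan(dataset: SRSDataset, dictionary: DrugDictionary,
                pt_set: PTQuerySet,
                criteria: SignalCriteria = SignalCriteria(),
                role_filter: Iterable[str] = ("PS",),
                counting_unit: str = "reports",
                chi2_variant: str = "four_cell",
                interval_mode: str = "verbatim",
                continuity_correction: bool = False,
                substring: bool = False) -> List[SignalResult]:
    """One :class:`SignalResult` per dictionary generic, in dictionary order."""
    model = DisproportionalityModel(
        dataset, dictionary=dictionary, pt_set=pt_set, criteria=criteria,
        role_filter=tuple(role_filter), counting_unit=counting_unit,
        chi2_variant=chi2_variant, interval_mode=interval_mode,
        continuity_correction=continuity_correction, substring=substring)
    return model.fit().results


class DisproportionalityModel:
    """Disproportionality scan of a report database for one drug dictionary
    against one event query set.

    Parameters mirror the analytic choices that matter: the drug role
    filter (default primary-suspect only), the counting unit, the
    chi-square variant, the interval-formula mode and the optional
    continuity correction.  ``fit()`` builds every 2x2 table and returns a
    :class:`DisproportionalityResults`.
    """

    def __init__(self, dataset: SRSDataset, dictionary: Optional[DrugDictionary] = None,
                 pt_set: Optional[PTQuerySet] = None,
                 criteria: SignalCriteria = SignalCriteria(),
                 role_filter: Sequence[str] = ("PS",),
                 counting_unit: str = "reports",
                 chi2_variant: str = "four_cell",
                 interval_mode: str = "verbatim",
                 continuity_correction: bool = False,
                 substring: bool = False) -> None:
        if not dataset.meta.get("deduplicated", False):
            raise ValueError("dataset must be deduplicated before signal scanning")
        self.dataset = dataset
        self.dictionary = dictionary or DrugDictionary.default_parp()
        self.pt_set = pt_set or PTQuerySet.default_renal()
        self.criteria = criteria
        self.role_filter = tuple(role_filter)
        self.counting_unit = counting_unit
        self.chi2_variant = chi2_variant
        self.interval_mode = interval_mode
        self.continuity_correction = continuity_correction
        self.substring = substring

    def fit(self) -> "DisproportionalityResults":
        results = []
        shared = None
        if self.counting_unit == "reports":
            shared = _positive_sets(self.dataset, self.dictionary, self.pt_set,
                                    self.role_filter, self.substring)
        for generic in self.dictionary.generics:
            if shared is not None:
                drug_pids, event_pids = shared
                table = _table_from_sets(drug_pids.get(generic, set()),
                                         event_pids, self.dataset.n_reports)
            else:
                table = build_contingency(
                    self.dataset, self.dictionary, self.pt_set, generic,
                    role_filter=self.role_filter, counting_unit=self.counting_unit,
                    substring=self.substring)
            results.append(compute_signal(
                table, drug=generic, criteria=self.criteria,
                chi2_variant=self.chi2_variant, interval_mode=self.interval_mode,
                continuity_correction=self.continuity_correction))
        return DisproportionalityResults(self, results)


class DisproportionalityResults:
    """Fitted signal-scan results: estimates, intervals and criteria flags."""

    def __init__(self, model: DisproportionalityModel,
                 results: List[SignalResult]) -> None:
        self.model = model
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, drug: str) -> SignalResult:
        for r in self.results:
            if r.drug == drug:
                return r
        raise KeyError(drug)

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Signal table: drug, N, the four statistics, intervals and flags."""
        if rounded:
            return pd.DataFrame([r.rounded() for r in self.results])
        rows = []
        for r in self.results:
            rows.append({
                "drug": r.drug, "N": r.n_reports,
                "ROR": r.ror, "ROR_CI95_low": r.ror_ci95[0],
                "ROR_CI95_high": r.ror_ci95[1], "PRR": r.prr, "chi2": r.chi2,
                "IC": r.ic, "IC025": r.ic025, "EBGM": r.ebgm, "EBGM05": r.ebgm05,
                **{f"flag_{k}": v for k, v in r.flags.items()},
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table (2-dp presentation rounding)."""
        df = self.to_frame(rounded=True)
        lines = ["Disproportionality scan",
                 f"  dictionary: {self.model.dictionary.name}"
                 f"   event set: {self.model.pt_set.name}",
                 f"  roles: {','.join(self.model.role_filter)}"
                 f"   unit: {self.model.counting_unit}"
                 f"   chi2: {self.model.chi2_variant}"
                 f"   intervals: {self.model.interval_mode}",
                 ""]
        lines.append(df.to_string(index=False, na_rep="-"))
        return "\n".join(lines)
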