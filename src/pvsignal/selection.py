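"""Case selection and descriptive summarisation.

A report enters the cohort when at least one of its drug rows matches the
dictionary with a role code in the role filter (default: primary suspect
only) AND at least one of its reaction rows carries a preferred term from
the query set.  A report appears once per matched generic, so the per-drug
block of the descriptive summary can exceed the distinct-report total when
two study drugs are co-suspected on one report; both conventions' counts
are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .dictionary import (DrugDictionary, PTQuerySet, load_indication_map,
                         load_region_map, normalize_pt)
from .io import SRSDataset, age_in_years

logger = logging.getLogger(__name__)

AGE_BINS = ["<30", "30-44", "45-64", "65-74", "75-84", ">=85", "unknown"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, ndigits: int = 2) -> float:
    """100*count/denominator, rounded half-up."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * count / denominator, ndigits)


def percent_shares(counts: Mapping[str, int],
                   denominator: Optional[int] = None) -> pd.DataFrame:
    """Counts -> (category, count, pct) with pct = 100*count/denominator.

    Default denominator is the sum of the counts, so shares total 100 up to
    rounding slack.
    """
    total = denominator if denominator is not None else sum(counts.values())
    return pd.DataFrame({
        "category": list(counts),
        "count": list(counts.values()),
        "pct": [percent(v, total) for v in counts.values()],
    })


@dataclass
class CaseCohort:
    """Selected reports of interest.

    ``rows`` holds one row per (report, matched generic); ``matches`` keeps
    the underlying matched drug rows (with drug_seq) for therapy linkage.
    """

    rows: pd.DataFrame          # primaryid, drug
    matches: pd.DataFrame       # primaryid, drug, drug_seq, role_cod
    params: Dict[str, object] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return self.rows["primaryid"].nunique()

    @property
    def n_report_drug_pairs(self) -> int:
        return len(self.rows)

    def primaryids(self) -> set:
        return set(self.rows["primaryid"].astype(str))


def select_cases(dataset: SRSDataset,
                 dictionary: DrugDictionary,
                 pt_set: PTQuerySet,
                 role_filter: Iterable[str] = ("PS",),
                 substring: bool = False) -> CaseCohort:
    """Intersect dictionary-matched (role-filtered) reports with PT-matched reports."""
    if not dictionary.entries:
        raise ValueError("drug dictionary is empty")
    if not len(pt_set):
        raise ValueError("PT query set is empty")
    roles = {str(r).strip().upper() for r in role_filter}
    if not roles:
        raise ValueError("role filter is empty")

    drug = dataset.drug

    def match_unique(col: pd.Series) -> pd.Series:
        lookup = {u: dictionary.match(u, substring=substring) for u in pd.unique(col)}
        return col.map(lookup)

    matched_generic = match_unique(drug["drugname"])
    if "prod_ai" in drug.columns:
        matched_generic = matched_generic.fillna(match_unique(drug["prod_ai"]))
    role_ok = drug["role_cod"].astype(str).str.strip().str.upper().isin(roles)
    matches = drug.loc[matched_generic.notna() & role_ok,
                       ["primaryid", "drug_seq", "role_cod"]].copy()
    matches["drug"] = matched_generic[matches.index]

    reac = dataset.reac
    pt_lookup = {u: (normalize_pt(u) in pt_set.pts) for u in pd.unique(reac["pt"])}
    pt_hit = reac["pt"].map(pt_lookup)
    positive_pids = set(reac.loc[pt_hit, "primaryid"].astype(str))

    matches = matches[matches["primaryid"].astype(str).isin(positive_pids)]
    matches = matches.reset_index(drop=True)
    rows = (matches[["primaryid", "drug"]]
            .drop_duplicates()
            .sort_values(["drug", "primaryid"], kind="mergesort")
            .reset_index(drop=True))
    params = {
        "dictionary": dictionary.name,
        "pt_set": pt_set.name,
        "role_filter": sorted(roles),
        "substring": substring,
    }
    logger.info("select_cases: %d report-drug pairs over %d distinct reports",
                len(rows), rows["primaryid"].nunique())
    return CaseCohort(rows=rows, matches=matches, params=params)


def assign_age_group(age_years: float) -> str:
    """Bin an age in years; boundaries are inclusive on the left."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    if age_years < 0:
        logger.warning("negative age %s binned as unknown", age_years)
        return "unknown"
    if age_years < 30:
        return "<30"
    if age_years < 45:
        return "30-44"
    if age_years < 65:
        return "45-64"
    if age_years < 75:
        return "65-74"
    if age_years < 85:
        return "75-84"
    return ">=85"


def map_region(country: object, region_map: Mapping[str, str]) -> str:
    """Country code/name -> continent label; unmapped -> 'unknown'."""
    key = str(country).strip().upper() if country is not None else ""
    if not key or key in {"NAN", "NONE"}:
        return "unknown"
    return region_map.get(key, "unknown")


@dataclass
class DescriptiveSummary:
    """Per-category counts and shares with explicit denominators per block."""

    blocks: Dict[str, pd.DataFrame]
    denominators: Dict[str, int]
    n_reports: int
    n_report_drug_pairs: int

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, df in self.blocks.items():
            part = df.copy()
            part.insert(0, "block", name)
            part["denominator"] = self.denominators[name]
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def summarize_cohort(cohort: CaseCohort, dataset: SRSDataset,
                     region_map: Optional[Mapping[str, str]] = None,
                     indication_map: Optional[Mapping[str, str]] = None) -> DescriptiveSummary:
    """Descriptive characteristics of the cohort's reports.

    Every block uses the distinct-report cohort size as denominator except
    the outcome block, which reports both the cohort denominator and the
    reports-with-any-outcome denominator (spontaneous reports may carry
    zero or many outcome codes).
    """
    if cohort.n_reports == 0:
        raise ValueError("cohort is empty")
    if region_map is None:
        region_map = load_region_map()
    if indication_map is None:
        indication_map = load_indication_map()

    pids = cohort.primaryids()
    demo = dataset.demo[dataset.demo["primaryid"].astype(str).isin(pids)].copy()
    n = len(demo)
    blocks: Dict[str, pd.DataFrame] = {}
    denoms: Dict[str, int] = {}

    region = demo["reporter_country"].map(lambda c: map_region(c, region_map))
    blocks["region"] = percent_shares(region.value_counts().to_dict(), n)
    denoms["region"] = n

    year = demo["fda_dt"].astype(str).str.slice(0, 4)
    year = year.where(year.str.fullmatch(r"\d{4}"), "unknown")
    counts = year.value_counts().sort_index().to_dict()
    blocks["year"] = percent_shares(counts, n)
    denoms["year"] = n

    sex = demo["sex"].astype(str).str.strip().str.upper()
    sex = sex.where(sex.isin(["M", "F"]), "unknown")
    blocks["sex"] = percent_shares(sex.value_counts().to_dict(), n)
    denoms["sex"] = n

    ages = [age_in_years(a, u) for a, u in zip(demo["age"], demo["age_cod"])]
    groups = pd.Series([assign_age_group(a) for a in ages])
    counts = {b: int((groups == b).sum()) for b in AGE_BINS if (groups == b).any()}
    blocks["age_group"] = percent_shares(counts, n)
    denoms["age_group"] = n

    # drug block: one count per (report, generic) pair; denominator is the
    # distinct-report cohort size, matching how report tables are printed
    drug_counts = cohort.rows["drug"].value_counts().to_dict()
    blocks["drug"] = percent_shares(drug_counts, n)
    denoms["drug"] = n

    indi = dataset.indi
    if len(indi):
        seq_col = "indi_drug_seq" if "indi_drug_seq" in indi.columns else "drug_seq"
        linked = indi.merge(
            cohort.matches.astype({"primaryid": str, "drug_seq": str}),
            left_on=["primaryid", seq_col], right_on=["primaryid", "drug_seq"],
            how="inner", suffixes=("", "_m"))
        if len(linked):
            grp = linked["indi_pt"].map(
                lambda p: indication_map.get(normalize_pt(p), "Other/unmapped"))
            per_report = (pd.DataFrame({"primaryid": linked["primaryid"], "group": grp})
                          .drop_duplicates())
            blocks["indication"] = percent_shares(per_report["group"].value_counts().to_dict(), n)
            denoms["indication"] = n

    outc = dataset.outc
    outc = outc[outc["primaryid"].astype(str).isin(pids)]
    if len(outc):
        code = outc["outc_cod"].astype(str).str.strip().str.upper()
        per_code = (pd.DataFrame({"primaryid": outc["primaryid"].astype(str), "code": code})
                    .drop_duplicates())
        counts = per_code["code"].value_counts().to_dict()
        n_with_outcome = per_code["primaryid"].nunique()
        block = percent_shares(counts, n)
        block["pct_of_reports_with_outcome"] = [
            percent(v, n_with_outcome) for v in counts.values()]
        blocks["outcome"] = block
        denoms["outcome"] = n
        denoms["outcome_reports_with_outcome"] = int(n_with_outcome)

    return DescriptiveSummary(blocks=blocks, denominators=denoms,
                              n_reports=n, n_report_drug_pairs=cohort.n_report_drug_pairs)
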