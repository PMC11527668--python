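"""Reading, validating and deduplicating SRS quarterly ASCII tables.

The FAERS dialect: one file per table kind (DEMO, DRUG, REAC, OUTC, RPSR,
THER, INDI), a header line, "$" as field separator, one record per line.
Input is decoded as Latin-1 (real extracts contain non-UTF-8 bytes); output
is written UTF-8.  Column names from both the PRIMARYID era and the older
ISR era are accepted through a synonym map.

Deduplication follows standard regulatory practice for spontaneous-report
databases: a case (CASEID) accumulates report versions (PRIMARYID) over
time, and analysis keeps only the latest version — maximal FDA receipt date,
ties broken by maximal PRIMARYID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .dates import date_sort_key

logger = logging.getLogger(__name__)

TABLE_KINDS = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

#: Canonical column order per table kind.  Unknown input columns are
#: preserved verbatim after these.
TABLE_COLUMNS: Dict[str, List[str]] = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "reporter_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "rpsr": ["primaryid", "rpsr_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
}

#: Column-name synonyms across FAERS eras, all lower-cased.
COLUMN_SYNONYMS: Dict[str, str] = {
    "isr": "primaryid",
    "case": "caseid",
    "case_id": "caseid",
    "gndr_cod": "sex",
    "occr_country": "reporter_country",
    "country": "reporter_country",
    "drugname_seq": "drug_seq",
    "drug_rec_act": "drug_rec_act",
}

MANDATORY_COLUMNS: Dict[str, List[str]] = {
    kind: (["primaryid", "caseid"] if kind == "demo" else ["primaryid"])
    for kind in TABLE_KINDS
}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Age-unit → years conversion.  DEC = decades; missing unit with an age
#: present is assumed YR (logged by callers).
AGE_UNIT_YEARS: Dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


@dataclass
class ReadReport:
    """Per-file parse accounting: nothing is silently dropped."""

    path: str
    table_kind: str
    n_rows: int = 0
    n_short_rows: int = 0        # padded with empty fields
    n_extra_field_rows: int = 0  # surplus fields captured in _extra
    warnings: List[str] = field(default_factory=list)


def _canonical_columns(header: Iterable[str]) -> List[str]:
    out = []
    for name in header:
        key = name.strip().lower()
        out.append(COLUMN_SYNONYMS.get(key, key))
    return out


def read_table(path: str | Path, table_kind: str) -> tuple[pd.DataFrame, ReadReport]:
    """Read one "$"-delimited SRS table.

    Returns a string-typed DataFrame in canonical column order (unknown
    columns preserved) plus a :class:`ReadReport`.  Raises ``ValueError``
    when a mandatory column is absent, naming the column.
    """
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    report = ReadReport(path=str(path), table_kind=table_kind)

    with open(path, "r", encoding="latin-1", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (no header)")

    header = _canonical_columns(lines[0].split("$"))
    for col in MANDATORY_COLUMNS[table_kind]:
        if col not in header:
            raise ValueError(f"{path}: mandatory column {col!r} missing from header")

    ncol = len(header)
    rows: List[List[str]] = []
    extras: List[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("$")
        extra = ""
        if len(fields) > ncol:
            extra = "$".join(fields[ncol:])
            fields = fields[:ncol]
            report.n_extra_field_rows += 1
            report.warnings.append(f"line {lineno}: {len(extra.split('$'))} extra field(s) captured")
        elif len(fields) < ncol:
            fields = fields + [""] * (ncol - len(fields))
            report.n_short_rows += 1
            report.warnings.append(f"line {lineno}: short row padded")
        rows.append([f.strip() for f in fields])
        extras.append(extra)

    df = pd.DataFrame(rows, columns=header, dtype=str) if rows else \
        pd.DataFrame(columns=header, dtype=str)
    if any(extras):
        df["_extra"] = extras
    report.n_rows = len(df)

    # canonical order first, then preserved unknowns
    known = [c for c in TABLE_COLUMNS[table_kind] if c in df.columns]
    other = [c for c in df.columns if c not in known]
    for c in TABLE_COLUMNS[table_kind]:
        if c not in df.columns:
            df[c] = ""
    df = df[[*TABLE_COLUMNS[table_kind], *[c for c in other if c not in TABLE_COLUMNS[table_kind]]]]
    return df, report


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a table in the same "$" dialect (UTF-8).

    Round-trips bit-exactly with :func:`read_table` for clean rows and
    day-precision dates.
    """
    cols = [c for c in TABLE_COLUMNS[table_kind] if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c != "_extra"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("$".join(cols) + "\n")
        if len(df):
            body = df[cols].astype(str).replace({"nan": "", "None": "", "<NA>": ""})
            for row in body.itertuples(index=False):
                fh.write("$".join(row) + "\n")


@dataclass
class SRSDataset:
    """The seven SRS tables plus provenance metadata.

    ``meta`` records at least: ``source`` label, ``deduplicated`` flag and,
    after deduplication, report counts before/after.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def copy(self) -> "SRSDataset":
        return SRSDataset(**{k: self.table(k).copy() for k in TABLE_KINDS},
                          meta=dict(self.meta))


def empty_dataset(source: str = "empty") -> SRSDataset:
    tables = {k: pd.DataFrame(columns=TABLE_COLUMNS[k], dtype=str) for k in TABLE_KINDS}
    return SRSDataset(**tables, meta={"source": source, "deduplicated": False})


def load_dataset(directory: str | Path, source: Optional[str] = None) -> tuple[SRSDataset, Dict[str, ReadReport]]:
    """Load a dataset from a directory of ``<kind>.txt`` files.

    Missing non-DEMO files become empty tables; a missing DEMO file is an
    error.
    """
    directory = Path(directory)
    tables: Dict[str, pd.DataFrame] = {}
    reports: Dict[str, ReadReport] = {}
    for kind in TABLE_KINDS:
        path = directory / f"{kind}.txt"
        if path.exists():
            tables[kind], reports[kind] = read_table(path, kind)
        elif kind == "demo":
            raise FileNotFoundError(f"{path}: DEMO table is required")
        else:
            tables[kind] = pd.DataFrame(columns=TABLE_COLUMNS[kind], dtype=str)
    ds = SRSDataset(**tables, meta={"source": source or str(directory),
                                    "deduplicated": False})
    return ds, reports


def save_dataset(dataset: SRSDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind in TABLE_KINDS:
        write_table(dataset.table(kind), directory / f"{kind}.txt", kind)


def _date_key_series(raw: pd.Series) -> pd.Series:
    """Vectorized :func:`pvsignal.dates.date_sort_key` over a column.

    Digit strings of length 8/6/4 get a comparable YYYYMMDD-scale key
    (partial dates sort at the start of their period); anything else falls
    back to the scalar parser (which validates month/day ranges).
    """
    s = raw.astype(str).str.strip()
    num = pd.to_numeric(s, errors="coerce")
    length = s.str.len()
    key = pd.Series(np.full(len(s), -1, dtype=np.int64), index=s.index)
    day = num.notna() & (length == 8)
    month = num.notna() & (length == 6)
    year = num.notna() & (length == 4)
    key[day] = num[day].astype(np.int64)
    key[month] = num[month].astype(np.int64) * 100 + 1
    key[year] = num[year].astype(np.int64) * 10000 + 101
    # fast path assumed valid calendar values; re-check suspicious ones
    mm = (key // 100) % 100
    dd = key % 100
    suspect = (day | month) & ((mm < 1) | (mm > 12) | (dd < 1) | (dd > 31))
    if suspect.any():
        key[suspect] = s[suspect].map(date_sort_key)
    return key


def _pid_rank(primaryid: pd.Series) -> pd.Series:
    """Numeric-aware ordering of PRIMARYID strings (digits compare as
    integers; anything else falls back to lexicographic within length)."""
    s = primaryid.astype(str)
    numeric = pd.to_numeric(s, errors="coerce")
    if numeric.notna().all():
        return numeric
    # mixed: order by (length, string) which matches numeric order for
    # unpadded digit strings and is total for the rest
    return s.str.len().astype(float) * 1e12 + s.map(lambda v: float(abs(hash(v)) % 10**9))


def deduplicate(dataset: SRSDataset) -> SRSDataset:
    """Keep one report version per case: max FDA_DT, ties by max PRIMARYID.

    Reports lacking CASEID cannot be grouped and are kept as singletons
    (counted in ``meta['n_missing_caseid']``).  Child-table rows belonging
    to removed versions are dropped, restoring referential integrity.
    """
    demo = dataset.demo.copy()
    n_before = len(demo)
    arr = np.char.strip(demo["caseid"].astype(str).to_numpy().astype(str))
    missing_case = pd.Series(
        (arr == "") | (arr == "nan") | (arr == "None") | (arr == "<NA>"),
        index=demo.index)

    work = demo.loc[~missing_case].copy()
    if len(work):
        work["_fda_key"] = _date_key_series(work["fda_dt"])
        work["_pid_key"] = _pid_rank(work["primaryid"])
        work = work.sort_values(["caseid", "_fda_key", "_pid_key"], kind="mergesort")
        work = work.groupby("caseid", sort=False).tail(1)
        work = work.drop(columns=["_fda_key", "_pid_key"])

    kept = pd.concat([work, demo.loc[missing_case]]) if missing_case.any() else work
    kept = kept.loc[demo.index.intersection(kept.index)]  # original order
    kept_pids = set(kept["primaryid"].astype(str))

    out = {}
    for kind in TABLE_KINDS:
        if kind == "demo":
            out[kind] = kept.reset_index(drop=True)
        else:
            t = dataset.table(kind)
            if len(t):
                out[kind] = t[t["primaryid"].astype(str).isin(kept_pids)].reset_index(drop=True)
            else:
                out[kind] = t.copy()

    meta = dict(dataset.meta)
    meta.update({
        "deduplicated": True,
        "n_reports_before_dedup": n_before,
        "n_reports_after_dedup": len(kept),
        "n_missing_caseid": int(missing_case.sum()),
    })
    logger.info("deduplicate: %d -> %d reports (%d without caseid kept as singletons)",
                n_before, len(kept), int(missing_case.sum()))
    return SRSDataset(**out, meta=meta)


@dataclass
class ValidationIssue:
    kind: str
    table: str
    count: int
    detail: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def counts(self) -> Dict[str, int]:
        return {f"{i.table}:{i.kind}": i.count for i in self.issues}


def validate_dataset(dataset: SRSDataset) -> ValidationReport:
    """Structural checks; never mutates.

    Flags orphan primaryids in non-DEMO tables, duplicate primaryids in
    DEMO, duplicate (primaryid, drug_seq) pairs, and illegal role/outcome
    codes.
    """
    report = ValidationReport()
    demo_pids = set(dataset.demo["primaryid"].astype(str))

    dup_demo = dataset.demo["primaryid"].astype(str).duplicated().sum()
    if dup_demo:
        report.issues.append(ValidationIssue("duplicate_primaryid", "demo", int(dup_demo),
                                             "primaryid repeated in DEMO"))
    for kind in TABLE_KINDS:
        if kind == "demo":
            continue
        t = dataset.table(kind)
        if not len(t):
            continue
        orphans = ~t["primaryid"].astype(str).isin(demo_pids)
        if orphans.any():
            report.issues.append(ValidationIssue("orphan_primaryid", kind, int(orphans.sum()),
                                                 "primaryid absent from DEMO"))
    drug = dataset.drug
    if len(drug):
        dup = drug.duplicated(subset=["primaryid", "drug_seq"]).sum()
        if dup:
            report.issues.append(ValidationIssue("duplicate_drug_seq", "drug", int(dup),
                                                 "(primaryid, drug_seq) repeated"))
        bad_role = ~drug["role_cod"].astype(str).str.strip().str.upper().isin([*ROLE_CODES, ""])
        if bad_role.any():
            report.issues.append(ValidationIssue("illegal_role_code", "drug", int(bad_role.sum()),
                                                 f"role_cod outside {ROLE_CODES}"))
    outc = dataset.outc
    if len(outc):
        bad = ~outc["outc_cod"].astype(str).str.strip().str.upper().isin([*OUTCOME_CODES, ""])
        if bad.any():
            report.issues.append(ValidationIssue("illegal_outcome_code", "outc", int(bad.sum()),
                                                 f"outc_cod outside {OUTCOME_CODES}"))
    return report


def age_in_years(age: object, age_unit: object) -> float:
    """Normalize a reported age to years; NaN when unusable.

    Missing unit with an age present is assumed to be years (the dominant
    FAERS convention); the assumption is the caller's to log.
    """
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(value):
        return float("nan")
    unit = str(age_unit).strip().upper() if age_unit is not None else ""
    if unit in {"", "NAN", "NONE"}:
        unit = "YR"
    factor = AGE_UNIT_YEARS.get(unit)
    if factor is None:
        return float("nan")
    return value * factor
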