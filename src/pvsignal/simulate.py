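"""Synthetic spontaneous-reporting-system generator with known ground truth.

The generator emulates the structure that makes SRS analysis non-trivial —
duplicate case versions, role-coded drug rows, PT-coded reactions, partial
and missing therapy/event dates, coded outcomes — while keeping the
drug–event association analytically known, so every pipeline stage can be
validated against closed-form expectations.

Sampling model (exclusive-exposure default): each report is exposed to at
most one study drug, drug j with marginal probability p_j, or to a
background drug otherwise.  A report carries a target event with
probability

    q_j = p0 * theta_j / (1 - p0 + p0 * theta_j)   if exposed to drug j
    p0                                              otherwise,

i.e. exposure multiplies the background odds p0/(1-p0) by theta_j.  With a
single study drug (or all other thetas at 1) the population 2x2 odds ratio
equals theta exactly, making theta the recoverable ground truth for the
reporting odds ratio.  Time to onset is log-normal, parameterized by its
median (the natural scale for the right-skewed onset distributions seen in
practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dictionary import DrugDictionary, PTQuerySet
from .io import SRSDataset, TABLE_KINDS, TABLE_COLUMNS, deduplicate

DEFAULT_TARGET_PTS = (
    "Acute kidney injury", "Blood creatinine increased", "Renal impairment",
    "Glomerular filtration rate decreased", "Oliguria", "Anuria",
)

DEFAULT_DECOY_PTS = (
    "Nausea", "Fatigue", "Anaemia", "Headache", "Vomiting", "Diarrhoea",
    "Thrombocytopenia", "Decreased appetite", "Dizziness", "Rash",
)

DEFAULT_BACKGROUND_DRUGS = (
    "CARBOPLATIN", "PACLITAXEL", "BEVACIZUMAB", "PEMBROLIZUMAB",
    "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
)

DEFAULT_INDICATIONS = ("Ovarian cancer", "Breast cancer", "Prostate cancer")


@dataclass(frozen=True)
class DrugSpec:
    """One simulated study drug: generic, the verbatim synonym written to
    the drugname field, its exposure marginal, and the association odds
    multiplier theta (theta = 1 is the null)."""

    generic: str
    synonym: str
    marginal: float
    theta: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int
    drugs: Tuple[DrugSpec, ...]
    seed: int
    background_event_prob: float = 0.02
    target_pts: Tuple[str, ...] = DEFAULT_TARGET_PTS
    decoy_pts: Tuple[str, ...] = DEFAULT_DECOY_PTS
    background_drugs: Tuple[str, ...] = DEFAULT_BACKGROUND_DRUGS
    indications: Tuple[str, ...] = DEFAULT_INDICATIONS
    duplicate_rate: float = 0.0
    missing_event_date_rate: float = 0.10
    missing_start_date_rate: float = 0.10
    concomitant_rate: float = 0.30
    tto_median_days: float = 15.0
    tto_log_sd: float = 1.3
    sex_probs: Tuple[Tuple[str, float], ...] = (("F", 0.68), ("M", 0.22), ("", 0.10))
    country_probs: Tuple[Tuple[str, float], ...] = (
        ("US", 0.60), ("JP", 0.15), ("GB", 0.08), ("DE", 0.07), ("CN", 0.05),
        ("BR", 0.03), ("ZA", 0.02))
    outcome_probs: Tuple[Tuple[str, float], ...] = (
        ("HO", 0.28), ("DE", 0.04), ("LT", 0.05), ("DS", 0.01), ("OT", 0.60))
    background_outcome_ot_prob: float = 0.35
    date_start: str = "2015-01-01"
    date_end: str = "2023-09-30"
    exclusive: bool = True

    def __post_init__(self) -> None:
        probs = [d.marginal for d in self.drugs]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("drug marginals must be in [0, 1]")
        if self.exclusive and sum(probs) > 1.0:
            raise ValueError("sum of drug marginals exceeds 1 under exclusive exposure")
        if not (0.0 <= self.background_event_prob <= 1.0):
            raise ValueError("background_event_prob must be in [0, 1]")
        if any(d.theta <= 0 for d in self.drugs):
            raise ValueError("theta must be positive")
        if self.tto_median_days <= 0:
            raise ValueError("tto_median_days must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def exposed_event_prob(self, drug: DrugSpec) -> float:
        p0 = self.background_event_prob
        return p0 * drug.theta / (1.0 - p0 + p0 * drug.theta)

    def dictionary(self) -> DrugDictionary:
        return DrugDictionary(
            entries={d.generic: {d.generic, d.synonym} for d in self.drugs},
            name="synthetic")

    def pt_query_set(self) -> PTQuerySet:
        return PTQuerySet(name="synthetic_targets", pts=frozenset(self.target_pts))


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle comparisons."""

    theta: Dict[str, float]
    expected_cells: Dict[str, Tuple[float, float, float, float]]
    tto_median_days: float
    duplicate_map: Dict[str, str] = field(default_factory=dict)  # caseid -> surviving primaryid
    n_cases: int = 0


def expected_table(config: GeneratorConfig, drug: str
                   ) -> Tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) for one study drug.

    Under exclusive exposure: a = n*p_j*q_j, the event margin is
    n*(sum_k p_k*q_k + (1 - sum p)*p0), and b, c, d follow from margins.
    """
    spec = next((d for d in config.drugs if d.generic == drug), None)
    if spec is None:
        raise ValueError(f"drug {drug!r} not in generator config")
    n = float(config.n_reports)
    p0 = config.background_event_prob
    q = {d.generic: config.exposed_event_prob(d) for d in config.drugs}
    p_any = sum(d.marginal for d in config.drugs)
    event_rate = sum(d.marginal * q[d.generic] for d in config.drugs) + (1 - p_any) * p0
    a = n * spec.marginal * q[drug]
    b = n * event_rate - a
    c = n * spec.marginal - a
    d_ = n - a - b - c
    return a, b, c, d_


def _fixed_width_str(values: np.ndarray, width: int) -> np.ndarray:
    """Vectorized nonnegative-int -> zero-padded fixed-width string (object
    dtype, so DataFrame construction does not recopy)."""
    a = np.asarray(values, dtype=np.int64)
    digits = np.empty((len(a), width), dtype=np.uint32)
    for k in range(width):
        digits[:, width - 1 - k] = (a // 10 ** k) % 10 + ord("0")
    return digits.view(f"<U{width}").ravel().astype(object)


def _yyyymmdd(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD string array."""
    y = dates.astype("datetime64[Y]").astype(int) + 1970
    m = dates.astype("datetime64[M]").astype(int) % 12 + 1
    d = (dates - dates.astype("datetime64[M]")).astype(int) + 1
    return _fixed_width_str(y * 10000 + m * 100 + d, 8)


def _categorical(rng: np.random.Generator, pairs: Sequence[Tuple[str, float]],
                 n: int) -> np.ndarray:
    labels = np.array([p[0] for p in pairs], dtype=object)
    probs = np.array([p[1] for p in pairs], dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), size=n, p=probs)]


def generate(config: GeneratorConfig) -> Tuple[SRSDataset, GroundTruth]:
    """Sample a full seven-table dataset plus its ground truth.

    Reproducible: a fixed config (seed included) yields byte-identical
    tables when written with the dialect writer.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs

    # exposure: index k < len(drugs) = study drug k, == len(drugs) = background
    probs = np.array([d.marginal for d in drugs] + [1.0 - sum(d.marginal for d in drugs)])
    exposure = rng.choice(len(drugs) + 1, size=n, p=probs)
    event_prob = np.full(n, config.background_event_prob)
    for k, d in enumerate(drugs):
        event_prob[exposure == k] = config.exposed_event_prob(d)
    event = rng.random(n) < event_prob

    pid = _fixed_width_str(1000001 + np.arange(n), 7)
    caseid = _fixed_width_str(5000001 + np.arange(n), 7)

    start_span = (np.datetime64(config.date_end) - np.datetime64(config.date_start)).astype(int)
    start = (np.datetime64(config.date_start)
             + rng.integers(0, start_span, size=n).astype("timedelta64[D]"))
    tto = np.round(np.exp(rng.normal(np.log(config.tto_median_days),
                                     config.tto_log_sd, size=n))).astype(int)
    event_date = start + tto.astype("timedelta64[D]")
    fda = event_date + rng.integers(1, 120, size=n).astype("timedelta64[D]")

    start_s = _yyyymmdd(start)
    event_s = _yyyymmdd(event_date)
    start_s[rng.random(n) < config.missing_start_date_rate] = ""
    event_s[rng.random(n) < config.missing_event_date_rate] = ""

    age = np.clip(rng.normal(66, 12, size=n), 20, 100).round(0)
    age_s = _fixed_width_str(age.astype(int), 3)
    age_s[rng.random(n) < 0.10] = ""
    sex = _categorical(rng, config.sex_probs, n)
    country = _categorical(rng, config.country_probs, n)

    demo = pd.DataFrame({
        "primaryid": pid, "caseid": caseid, "fda_dt": _yyyymmdd(fda),
        "event_dt": event_s, "age": age_s,
        "age_cod": np.where(age_s == "", "", "YR"), "sex": sex,
        "reporter_country": country,
    })

    drugname = np.empty(n, dtype=object)
    bg = rng.choice(len(config.background_drugs), size=n)
    drugname[:] = np.array(config.background_drugs, dtype=object)[bg]
    for k, d in enumerate(drugs):
        drugname[exposure == k] = d.synonym
    drug_rows = [pd.DataFrame({
        "primaryid": pid, "drug_seq": np.full(n, "1"), "role_cod": np.full(n, "PS"),
        "drugname": drugname, "prod_ai": drugname})]
    conc_mask = rng.random(n) < config.concomitant_rate
    if conc_mask.any():
        conc_names = np.array(config.background_drugs, dtype=object)[
            rng.choice(len(config.background_drugs), size=int(conc_mask.sum()))]
        drug_rows.append(pd.DataFrame({
            "primaryid": pid[conc_mask], "drug_seq": "2", "role_cod": "C",
            "drugname": conc_names, "prod_ai": conc_names}))
    drug = pd.concat(drug_rows, ignore_index=True)

    decoy = np.array(config.decoy_pts, dtype=object)[
        rng.choice(len(config.decoy_pts), size=n)]
    reac_rows = [pd.DataFrame({"primaryid": pid, "pt": decoy})]
    if event.any():
        target = np.array(config.target_pts, dtype=object)[
            rng.choice(len(config.target_pts), size=int(event.sum()))]
        reac_rows.append(pd.DataFrame({"primaryid": pid[event], "pt": target}))
    reac = pd.concat(reac_rows, ignore_index=True)

    ther = pd.DataFrame({
        "primaryid": pid, "dsg_drug_seq": np.full(n, "1"),
        "start_dt": start_s, "end_dt": np.full(n, "")})

    outc_rows = []
    for code, p in config.outcome_probs:
        mask = event & (rng.random(n) < p)
        if mask.any():
            outc_rows.append(pd.DataFrame({"primaryid": pid[mask], "outc_cod": code}))
    bg_mask = (~event) & (rng.random(n) < config.background_outcome_ot_prob)
    if bg_mask.any():
        outc_rows.append(pd.DataFrame({"primaryid": pid[bg_mask], "outc_cod": "OT"}))
    outc = (pd.concat(outc_rows, ignore_index=True) if outc_rows
            else pd.DataFrame(columns=TABLE_COLUMNS["outc"], dtype=str))
    if len(outc):
        outc = outc.sort_values(["primaryid", "outc_cod"], kind="mergesort").reset_index(drop=True)

    exposed_mask = exposure < len(drugs)
    if exposed_mask.any():
        indi_pts = np.array(config.indications, dtype=object)[
            rng.choice(len(config.indications), size=int(exposed_mask.sum()),
                       p=_indication_probs(len(config.indications)))]
        indi = pd.DataFrame({"primaryid": pid[exposed_mask],
                             "indi_drug_seq": "1", "indi_pt": indi_pts})
    else:
        indi = pd.DataFrame(columns=TABLE_COLUMNS["indi"], dtype=str)

    rpsr = pd.DataFrame({"primaryid": pid,
                         "rpsr_cod": _categorical(rng, (("HP", 0.6), ("CSM", 0.3), ("FGN", 0.1)), n)})

    dataset = SRSDataset(demo=demo, drug=drug, reac=reac, outc=outc,
                         rpsr=rpsr, ther=ther, indi=indi,
                         meta={"source": "synthetic", "deduplicated": False,
                               "seed": config.seed})
    truth = GroundTruth(
        theta={d.generic: d.theta for d in drugs},
        expected_cells={d.generic: expected_table(config, d.generic) for d in drugs},
        tto_median_days=config.tto_median_days,
        n_cases=n)

    if config.duplicate_rate > 0:
        dataset, dup_map = inject_duplicates(dataset, config.duplicate_rate,
                                             rng=rng)
        truth.duplicate_map = dup_map
    return dataset, truth


def _indication_probs(k: int) -> np.ndarray:
    base = np.array([0.8, 0.1, 0.1][:k], dtype=float)
    if len(base) < k:
        base = np.concatenate([base, np.full(k - len(base), 0.1)])
    return base / base.sum()


def inject_duplicates(dataset: SRSDataset, rate: float,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None
                      ) -> Tuple[SRSDataset, Dict[str, str]]:
    """Re-emit a fraction of cases as a later report version.

    The new version shares the caseid, gets a fresh (larger) primaryid and a
    strictly later FDA date, and carries copies of all child rows.  Returns
    the augmented dataset and the caseid -> intended-survivor map that
    deduplication must recover.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    demo = dataset.demo
    n = len(demo)
    k = int(round(rate * n))
    if k == 0:
        return dataset.copy(), {}
    pick = np.sort(rng.choice(n, size=k, replace=False))
    chosen = demo.iloc[pick].copy()

    numeric_pids = pd.to_numeric(demo["primaryid"], errors="coerce")
    base = int(np.nanmax(numeric_pids)) if numeric_pids.notna().any() else 9000000
    new_pids = (base + 1 + np.arange(k)).astype(str)
    old_pids = chosen["primaryid"].astype(str).to_numpy()

    fda = chosen["fda_dt"].map(lambda s: np.datetime64(
        f"{s[:4]}-{s[4:6]}-{s[6:8]}") if len(str(s)) == 8 else np.datetime64("2020-01-01"))
    new_fda = fda.to_numpy() + rng.integers(1, 300, size=k).astype("timedelta64[D]")

    new_demo = chosen.copy()
    new_demo["primaryid"] = new_pids
    new_demo["fda_dt"] = _yyyymmdd(new_fda.astype("datetime64[D]"))

    pid_map = dict(zip(old_pids, new_pids))
    out = {"demo": pd.concat([demo, new_demo], ignore_index=True)}
    for kind in TABLE_KINDS:
        if kind == "demo":
            continue
        t = dataset.table(kind)
        if len(t) == 0:
            out[kind] = t.copy()
            continue
        child = t[t["primaryid"].astype(str).isin(pid_map)].copy()
        child["primaryid"] = child["primaryid"].astype(str).map(pid_map)
        out[kind] = pd.concat([t, child], ignore_index=True)

    dup_map = dict(zip(chosen["caseid"].astype(str), new_pids))
    meta = dict(dataset.meta)
    meta["n_injected_duplicates"] = k
    return SRSDataset(**out, meta=meta), dup_map


# ---------------------------------------------------------------------------
# Simulation studies (shared by the test suite and the acceptance script)
# ---------------------------------------------------------------------------

def _scan_flags(config: GeneratorConfig):
    from .signals import DisproportionalityModel
    dataset, truth = generate(config)
    dataset = deduplicate(dataset)
    model = DisproportionalityModel(dataset, dictionary=config.dictionary(),
                                    pt_set=config.pt_query_set())
    return model.fit(), truth


def null_flag_rate(n_seeds: int, base_seed: int,
                   n_reports: int = 50_000,
                   n_drugs: int = 3,
                   marginal: float = 0.01,
                   background_event_prob: float = 0.02) -> float:
    """Fraction of drug scans flagged by all four criteria under theta = 1.

    Empirical type-I control: with no planted association the all-four
    conjunction should fire on well under 5% of simulated drugs.
    """
    drugs = tuple(DrugSpec(f"Drug{k}", f"DRUG{k}", marginal, 1.0)
                  for k in range(n_drugs))
    flagged = 0
    total = 0
    for i in range(n_seeds):
        config = GeneratorConfig(
            n_reports=n_reports, drugs=drugs, seed=base_seed + i,
            background_event_prob=background_event_prob,
            missing_event_date_rate=0.0, missing_start_date_rate=0.0,
            concomitant_rate=0.0)
        fit, _ = _scan_flags(config)
        for r in fit.results:
            total += 1
            flagged += int(r.flags["all"])
    return flagged / total


def ror_recovery(n_datasets: int, base_seed: int, theta: float = 3.0,
                 n_reports: int = 70_000, marginal: float = 0.01,
                 background_event_prob: float = 0.02) -> Dict[str, float]:
    """Parameter recovery for the reporting odds ratio at a planted theta.

    Returns the median estimated ROR across datasets and the fraction of
    95% CIs covering theta.
    """
    drugs = (DrugSpec("StudyDrug", "STUDYDRUG", marginal, theta),)
    rors: List[float] = []
    covered = 0
    for i in range(n_datasets):
        config = GeneratorConfig(
            n_reports=n_reports, drugs=drugs, seed=base_seed + i,
            background_event_prob=background_event_prob,
            missing_event_date_rate=0.0, missing_start_date_rate=0.0,
            concomitant_rate=0.0)
        fit, _ = _scan_flags(config)
        r = fit.results[0]
        rors.append(r.ror)
        lo, hi = r.ror_ci95
        if not np.isnan(lo) and lo <= theta <= hi:
            covered += 1
    return {"median_ror": float(np.median(rors)),
            "ci_coverage": covered / n_datasets,
            "n_datasets": n_datasets}


def kruskal_nominal_size(n_sims: int, base_seed: int, n_groups: int = 4,
                         group_size: int = 50, alpha: float = 0.05,
                         tto_median: float = 15.0, tto_log_sd: float = 1.3) -> float:
    """Empirical rejection rate of Kruskal–Wallis under equal onset
    distributions (should sit at the nominal level)."""
    from .onset import kruskal_wallis
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for _ in range(n_sims):
        groups = [np.round(np.exp(rng.normal(np.log(tto_median), tto_log_sd,
                                             size=group_size)))
                  for _ in range(n_groups)]
        if kruskal_wallis(groups).p_value < alpha:
            rejections += 1
    return rejections / n_sims


def dedup_recovery(config: GeneratorConfig) -> Dict[str, object]:
    """Generate with duplicates, deduplicate, compare against ground truth."""
    dataset, truth = generate(config)
    deduped = deduplicate(dataset)
    kept = dict(zip(deduped.demo["caseid"].astype(str),
                    deduped.demo["primaryid"].astype(str)))
    mismatches = sum(1 for case, survivor in truth.duplicate_map.items()
                     if kept.get(case) != survivor)
    return {"n_cases": truth.n_cases,
            "n_duplicated": len(truth.duplicate_map),
            "n_mismatched_survivors": mismatches,
            "n_after_dedup": deduped.n_reports}
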