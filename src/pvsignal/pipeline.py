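"""End-to-end pipeline orchestration with provenance logging.

A single plain-text key=value config resolves every analytic choice (role
filter, chi-square variant, interval mode, counting unit, denominators,
corrections) so that a "verbatim-formulas" run and a "canonical-statistics"
run differ only in config.  Outputs are delimited UTF-8 text; the manifest
records the resolved config, input checksums and the case-selection funnel
(raw -> deduplicated -> cohort) and is byte-stable for a fixed config, with
timestamps confined to the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from .dictionary import DrugDictionary, PTQuerySet
from .io import deduplicate, load_dataset, validate_dataset
from .onset import compute_tto, outcome_rates, summarize_tto
from .selection import select_cases, summarize_cohort
from .signals import DisproportionalityModel
from .simulate import DrugSpec, GeneratorConfig, generate

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("descriptive_summary.csv", "signal_table.csv",
                "onset_summary.csv", "outcome_summary.csv", "manifest.txt")


@dataclass
class PipelineConfig:
    """Fully-resolved analytic configuration.

    Every option has an explicit default mirroring the verbatim analysis:
    primary-suspect role filter, report-level counting, four-cell
    chi-square, multiplicative interval formulas, no continuity correction.
    """

    mode: str = "synthetic"                 # synthetic | files
    input_dir: Optional[str] = None
    out_dir: str = "pvsignal_out"
    seed: int = 0
    dictionary_path: Optional[str] = None
    pt_set_path: Optional[str] = None
    role_filter: Tuple[str, ...] = ("PS",)
    chi2_variant: str = "four_cell"
    interval_mode: str = "verbatim"
    continuity_correction: bool = False
    counting_unit: str = "reports"
    denominator_mode: str = "cohort_reports"
    substring_match: bool = False
    # synthetic-mode generator settings
    n_reports: int = 50_000
    drugs: str = "DrugA:DRUGA:0.01:1.0;DrugB:DRUGB:0.01:2.0;DrugC:DRUGC:0.01:8.0"
    background_event_prob: float = 0.02
    duplicate_rate: float = 0.05
    tto_median_days: float = 15.0
    tto_log_sd: float = 1.3
    missing_event_date_rate: float = 0.10
    missing_start_date_rate: float = 0.10

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse ``key = value`` lines ('#' comments allowed)."""
        values: Dict[str, object] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls._coerce(values)

    @classmethod
    def _coerce(cls, values: Dict[str, object]) -> "PipelineConfig":
        kwargs: Dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in values.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key].type
            if key == "role_filter":
                kwargs[key] = tuple(s.strip().upper() for s in str(raw).split(",") if s.strip())
            elif ftype in ("int", int):
                kwargs[key] = int(raw)
            elif ftype in ("float", float):
                kwargs[key] = float(raw)
            elif ftype in ("bool", bool):
                kwargs[key] = str(raw).strip().lower() in {"1", "true", "yes", "on"}
            else:
                kwargs[key] = raw if not isinstance(raw, str) else raw
        return cls(**kwargs)

    def generator_config(self) -> GeneratorConfig:
        specs = []
        for part in self.drugs.split(";"):
            part = part.strip()
            if not part:
                continue
            generic, synonym, marginal, theta = part.split(":")
            specs.append(DrugSpec(generic.strip(), synonym.strip(),
                                  float(marginal), float(theta)))
        return GeneratorConfig(
            n_reports=self.n_reports, drugs=tuple(specs), seed=self.seed,
            background_event_prob=self.background_event_prob,
            duplicate_rate=self.duplicate_rate,
            tto_median_days=self.tto_median_days, tto_log_sd=self.tto_log_sd,
            missing_event_date_rate=self.missing_event_date_rate,
            missing_start_date_rate=self.missing_start_date_rate)

    def resolve_dictionary(self) -> DrugDictionary:
        if self.dictionary_path:
            return DrugDictionary.from_file(self.dictionary_path)
        if self.mode == "synthetic":
            return self.generator_config().dictionary()
        return DrugDictionary.default_parp()

    def resolve_pt_set(self) -> PTQuerySet:
        if self.pt_set_path:
            return PTQuerySet.from_file(self.pt_set_path)
        if self.mode == "synthetic":
            return self.generator_config().pt_query_set()
        return PTQuerySet.default_renal()

    def snapshot(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        d["role_filter"] = ",".join(self.role_filter)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(path: Path, entries: Dict[str, object]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(entries):
            fh.write(f"{key} = {entries[key]}\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute ingest -> dedup -> select -> summarize -> signal -> onset ->
    outcomes, writing all outputs (and the manifest, even on failure) to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pvsignal")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: Dict[str, object] = {"pvsignal_version": __version__}
    for key, value in config.snapshot().items():
        manifest[f"config.{key}"] = value
    stages: List[str] = []
    try:
        if config.mode == "synthetic":
            gen = config.generator_config()
            dataset, truth = generate(gen)
            manifest["input.generator"] = json.dumps(
                dataclasses.asdict(gen), default=str, sort_keys=True)
            (out / "ground_truth.json").write_text(json.dumps({
                "theta": truth.theta,
                "expected_cells": truth.expected_cells,
                "tto_median_days": truth.tto_median_days,
                "n_cases": truth.n_cases,
                "n_duplicated": len(truth.duplicate_map),
            }, sort_keys=True, indent=1), encoding="utf-8")
        elif config.mode == "files":
            if not config.input_dir:
                raise ValueError("files mode requires input_dir")
            dataset, reports = load_dataset(config.input_dir)
            for kind, rep in reports.items():
                manifest[f"input.checksum.{kind}"] = _sha256(Path(rep.path))
                logger.info("read %s: %d rows, %d short, %d extra-field",
                            rep.path, rep.n_rows, rep.n_short_rows, rep.n_extra_field_rows)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        stages.append("ingest")
        manifest["funnel.n_raw"] = dataset.n_reports

        dataset = deduplicate(dataset)
        stages.append("dedup")
        manifest["funnel.n_dedup"] = dataset.n_reports
        validation = validate_dataset(dataset)
        for issue in validation.issues:
            logger.warning("validation: %s %s count=%d", issue.table, issue.kind, issue.count)
        manifest["validation.n_issues"] = len(validation.issues)

        dictionary = config.resolve_dictionary()
        pt_set = config.resolve_pt_set()
        cohort = select_cases(dataset, dictionary, pt_set,
                              role_filter=config.role_filter,
                              substring=config.substring_match)
        stages.append("select")
        manifest["funnel.n_cohort"] = cohort.n_reports
        manifest["funnel.n_cohort_drug_pairs"] = cohort.n_report_drug_pairs

        summary = summarize_cohort(cohort, dataset)
        summary.to_frame().to_csv(out / "descriptive_summary.csv", index=False)
        stages.append("summarize")

        model = DisproportionalityModel(
            dataset, dictionary=dictionary, pt_set=pt_set,
            role_filter=config.role_filter, counting_unit=config.counting_unit,
            chi2_variant=config.chi2_variant, interval_mode=config.interval_mode,
            continuity_correction=config.continuity_correction,
            substring=config.substring_match)
        fit = model.fit()
        fit.to_frame().to_csv(out / "signal_table.csv", index=False)
        stages.append("signal")

        tto = compute_tto(cohort, dataset)
        onset = summarize_tto(tto)
        per_drug = onset.per_drug.copy()
        if onset.overall:
            overall_row = {"drug": "ALL", **{k: v for k, v in onset.overall.items()
                                             if k in {"n", "median", "q1", "q3",
                                                      "frac_le_30", "frac_le_90"}}}
            per_drug = pd.concat([per_drug, pd.DataFrame([overall_row])], ignore_index=True)
        per_drug.to_csv(out / "onset_summary.csv", index=False)
        for reason, count in tto.exclusions.items():
            if count:
                logger.info("tto exclusion %s: %d", reason, count)
        manifest["onset.n_used"] = tto.n_used
        manifest["onset.n_excluded"] = tto.n_input - tto.n_used
        stages.append("onset")

        outcomes = outcome_rates(cohort, dataset, denominator_mode=config.denominator_mode)
        per_drug = outcomes.per_drug.copy()
        overall_row = {"drug": "ALL", **outcomes.overall}
        per_drug = pd.concat([per_drug, pd.DataFrame([overall_row])], ignore_index=True)
        per_drug.to_csv(out / "outcome_summary.csv", index=False)
        stages.append("outcomes")
    finally:
        manifest["stages_completed"] = ",".join(stages)
        _write_manifest(out / "manifest.txt", manifest)
        root.removeHandler(handler)
        handler.close()
    return out


def write_report(out_dir: str | Path) -> Path:
    """Merge stage outputs in ``out_dir`` into one plain-text report."""
    out = Path(out_dir)
    sections = []
    for name in OUTPUT_FILES:
        path = out / name
        if not path.exists():
            continue
        sections.append(f"===== {name} =====")
        if name.endswith(".csv"):
            sections.append(pd.read_csv(path).to_string(index=False, na_rep="-"))
        else:
            sections.append(path.read_text(encoding="utf-8").rstrip())
        sections.append("")
    report = out / "report.txt"
    report.write_text("\n".join(sections), encoding="utf-8")
    return report
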