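"""End-to-end study pipeline and machine-readable reports.

Stages run in order: ingest (or simulate) -> impute -> dedup -> exclude ->
flag -> signal -> onset -> risk, each logged with in/out counts.  The
report mirrors the shape of published pharmacovigilance tables: a
demographics table per drug among cases, the four-algorithm signal table
at SMQ level, the per-PT signal profile, onset/dose summaries and the
logistic-regression/nomogram outputs.  Every percentage is emitted with
its numerator and denominator.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, model_validator

from ._util import pct
from .io import (OUTCOME_CODES, SOURCE_CODES, QuarterBundle, load_synonyms,
                 read_quarter_dir)
from .onset import OnsetFrame, compute_onsets, onset_summary
from .preprocess import CleaningReport, clean, primary_suspect_map
from .risk import (LogisticFit, NomogramSpec, build_case_control,
                   build_nomogram, multivariate_fit, univariate_or)
from .signals import SignalFrame, SignalThresholds, detect_signals
from .smq import flag_cases, load_smq
from .synthetic import SynthConfig, TruthLedger, simulate

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineConfig(BaseModel, arbitrary_types_allowed=True):
    """Configuration of one pipeline run (synthetic or on-disk input)."""

    synthetic: SynthConfig | None = None
    input_dir: Path | None = None
    input_suffix: str = ""
    smq_path: Path | None = None
    synonyms_path: Path | None = None
    narrow_only: bool = False
    thresholds: SignalThresholds = SignalThresholds()
    entry_p: float | None = None
    reference_drug: str = "lorlatinib"
    min_cases_for_risk: int = 25
    output_dir: Path | None = None
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of synthetic config or input_dir is required")
        for p in (self.smq_path, self.synonyms_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"referenced file does not exist: {p}")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input directory does not exist: {self.input_dir}")
        if self.synthetic is not None and self.seed is not None:
            self.synthetic = self.synthetic.model_copy(
                update={"seed": self.seed})
        return self


@dataclass
class StudyReport:
    """All numeric outputs of one pipeline run."""

    cleaning: CleaningReport
    demographics: pd.DataFrame
    signals: SignalFrame
    onset: OnsetFrame
    onset_summary: pd.DataFrame
    univariate: pd.DataFrame | None
    fit: LogisticFit | None
    nomogram: NomogramSpec | None
    n_cases: int
    n_study_reports: int
    ledger: TruthLedger | None = None

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        json.dump(self.cleaning.to_dict(),
                  open(outdir / "cleaning_report.json", "w"), indent=2)
        self.demographics.to_csv(outdir / "demographics.csv", index=False)
        self.signals.table.to_csv(outdir / "signals.csv", index=False)
        self.onset_summary.to_csv(outdir / "onset_summary.csv", index=False)
        if self.univariate is not None:
            self.univariate.to_csv(outdir / "univariate_or.csv", index=False)
        if self.fit is not None:
            self.fit.table.to_csv(outdir / "multivariate_fit.csv")
        if self.nomogram is not None:
            spec = {"scale": self.nomogram.scale,
                    "base_lp": self.nomogram.base_lp,
                    "entries": {k: {"coef": e.coef, "xmin": e.xmin,
                                    "xmax": e.xmax,
                                    "points_max": e.points_max}
                                for k, e in self.nomogram.entries.items()}}
            json.dump(spec, open(outdir / "nomogram.json", "w"), indent=2)


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, err) from err
    log.info("stage %-8s done in %.2fs", name, time.perf_counter() - t0)
    return out


def summarize_demographics(bundle: QuarterBundle, case_flags,
                           study_map) -> pd.DataFrame:
    """Per-drug demographics among cases, in the published-table shape.

    Two denominator conventions: drug shares are percentages of all cases;
    outcome percentages are over outcome *records* within drug (a report
    can carry several outcomes).  Numerator and denominator accompany
    every percentage.
    """
    case_ids = [i for i in study_map.index if case_flags.get(i, False)]
    drugs = sorted(set(study_map.loc[case_ids]))
    demo = bundle.demo.set_index("primaryid").loc[case_ids]
    outc = bundle.outc[bundle.outc["primaryid"].isin(set(case_ids))]
    total = len(case_ids)
    rows = []

    def add(section, category, drug, n, denom):
        rows.append({"section": section, "category": category, "drug": drug,
                     "count": int(n), "denominator": int(denom),
                     "pct": pct(n, denom) if denom else float("nan")})

    for d in drugs:
        ids = [i for i in case_ids if study_map[i] == d]
        sub = demo.loc[ids]
        add("total", "cases", d, len(ids), total)
        age = sub["age_yr"]
        add("age", "18-64", d, ((age >= 18) & (age < 65)).sum(), len(ids))
        add("age", "65-84", d, ((age >= 65) & (age < 85)).sum(), len(ids))
        add("age", ">=85", d, (age >= 85).sum(), len(ids))
        add("age", "unknown", d, age.isna().sum(), len(ids))
        sex = sub["sex"].str.strip().str.upper()
        add("sex", "male", d, (sex == "M").sum(), len(ids))
        add("sex", "female", d, (sex == "F").sum(), len(ids))
        add("sex", "unknown", d, (~sex.isin(["M", "F"])).sum(), len(ids))
        src = sub["occp_cod"].str.strip().str.upper()
        for code, label in SOURCE_CODES.items():
            add("source", label, d, (src == code).sum(), len(ids))
        add("source", "unknown", d,
            (~src.isin(list(SOURCE_CODES))).sum(), len(ids))
        oc = outc[outc["primaryid"].isin(set(ids))]["outc_cod"] \
            .str.strip().str.upper()
        denom = len(oc)
        for code, label in OUTCOME_CODES.items():
            add("outcome", label, d, (oc == code).sum(), denom)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run the full study; any stage failure raises a stage-named error."""
    synonyms = _stage("config", load_synonyms, config.synonyms_path)
    smq = _stage("config", load_smq, config.smq_path,
                 narrow_only=config.narrow_only)

    ledger = None
    if config.synthetic is not None:
        bundle, ledger = _stage("simulate", simulate, config.synthetic)
    else:
        bundle = _stage("ingest", read_quarter_dir, config.input_dir,
                        config.input_suffix)

    cleaned, cleaning = _stage("clean", clean, bundle)
    study_map = _stage("select", primary_suspect_map, cleaned, synonyms)
    flags = _stage("flag", flag_cases, cleaned, smq)
    sig = _stage("signal", detect_signals, cleaned, synonyms, smq,
                 config.thresholds)
    demographics = _stage("report", summarize_demographics, cleaned, flags,
                          study_map)
    onsets = _stage("onset", compute_onsets, cleaned, study_map, flags)
    osum = _stage("onset", onset_summary, onsets.records)

    n_cases = int(sum(flags.get(i, False) for i in study_map.index))
    univariate = fit = nomogram = None
    if n_cases >= config.min_cases_for_risk:
        matrix = _stage("risk", build_case_control, cleaned, study_map,
                        flags, config.reference_drug)
        uni_rows = []
        for cov in [c for c in matrix.columns if c != "outcome"]:
            est, lo, hi, p = univariate_or(matrix, cov)
            uni_rows.append({"covariate": cov, "or": est, "ci_low": lo,
                             "ci_high": hi, "p": p})
        univariate = pd.DataFrame(uni_rows)
        fit = _stage("risk", multivariate_fit, matrix,
                     entry_p=config.entry_p)
        nomogram = _stage("risk", build_nomogram, fit)

    report = StudyReport(
        cleaning=cleaning, demographics=demographics, signals=sig,
        onset=onsets, onset_summary=osum, univariate=univariate, fit=fit,
        nomogram=nomogram, n_cases=n_cases,
        n_study_reports=len(study_map), ledger=ledger)
    if config.output_dir is not None:
        report.save(config.output_dir)
    return report
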