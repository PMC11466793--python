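"""Synthetic FAERS-like data with planted ground truth.

The generator emulates the structure of spontaneous adverse-event reports:
one primary-suspect drug per report, MedDRA-PT-coded reactions, therapy
start dates, duplicate case versions, follow-ups and partially missing
demographics.  Drug–event associations are planted as relative risks, so
every downstream stage (cleaning, case finding, disproportionality, onset
and risk modelling) can be checked against exact truth recorded in a
side ledger.

Report-identifier semantics mirror FAERS: the case id is the report id of
the first version; later versions (duplicates, follow-ups) get new, larger
report ids but keep the case id.
"""
from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit, logit

from .io import TABLE_COLUMNS, QuarterBundle, normalize_bundle, write_quarter

_BASE_ID = 10_000_000
_DUP_OFFSET = 40_000_000
_FUP_OFFSET = 80_000_000

NSCLC_PT = ("10061873", "Non-small cell lung cancer")


class DrugSpec(BaseModel):
    """One study drug: background use probability plus onset/dose models."""

    name: str
    use_prob: float = Field(ge=0.0, le=1.0)
    daily_dose_mg: float = Field(gt=0.0, default=500.0)
    onset_median_days: float = Field(gt=0.0, default=45.0)
    onset_sigma: float = Field(gt=0.0, default=1.8)
    brand_names: list[str] = []


class EventSpec(BaseModel):
    """A MedDRA preferred term with its background reporting probability."""

    pt_code: str
    pt_name: str
    background_prob: float = Field(ge=0.0, le=1.0)


class ConcomitantSpec(BaseModel):
    """A concomitant drug, its indication PT and its planted effect on the
    odds of the study events (ild_or = 1 means no effect)."""

    name: str
    prevalence: float = Field(ge=0.0, le=1.0)
    indication_pt_code: str
    indication_pt_name: str
    ild_or: float = Field(gt=0.0, default=1.0)


class SynthConfig(BaseModel):
    """Full configuration of the synthetic reporting database.

    ``planted_rr[drug][pt_code]`` multiplies the background probability of
    that PT for reports whose primary suspect is ``drug``; omitted pairs
    default to relative risk 1.  All randomness flows from ``seed``;
    identical (config, seed) yields byte-identical output files.
    """

    n_reports: int = Field(gt=0)
    drugs: list[DrugSpec]
    background_drugs: list[str] = ["carboplatin", "pembrolizumab",
                                   "osimertinib", "durvalumab", "cisplatin",
                                   "docetaxel", "gefitinib", "nivolumab"]
    events: list[EventSpec]
    filler_events: list[EventSpec]
    planted_rr: dict[str, dict[str, float]] = {}
    concomitants: list[ConcomitantSpec] = []
    female_ild_or: float = Field(gt=0.0, default=1.0)

    age_mean: float = 62.0
    age_sd: float = 13.0
    minor_rate: float = Field(ge=0.0, le=1.0, default=0.02)
    female_prop: float = Field(ge=0.0, le=1.0, default=0.5)
    weight_mean: float = 68.0
    weight_sd: float = 15.0
    countries: list[str] = ["US", "JP", "CN", "FR", "DE"]
    country_probs: list[float] = [0.45, 0.25, 0.12, 0.10, 0.08]
    source_probs: dict[str, float] = {"MD": 0.55, "PH": 0.08, "CN": 0.15,
                                      "OT": 0.22}
    outcome_probs: dict[str, float] = {"HO": 0.40, "DS": 0.02, "LT": 0.10,
                                       "DE": 0.19, "OT": 0.29}

    missingness: dict[str, float] = {"event_dt": 0.10, "age": 0.15,
                                     "sex": 0.05, "reporter_country": 0.05,
                                     "wt": 0.30, "occp_cod": 0.02}
    duplicate_rate: float = Field(ge=0.0, le=1.0, default=0.05)
    followup_rate: float = Field(ge=0.0, le=1.0, default=0.10)
    partial_date_rate: float = Field(ge=0.0, le=1.0, default=0.05)
    brand_name_rate: float = Field(ge=0.0, le=1.0, default=0.20)
    #: Probability that a drug's indication is actually recorded in INDI —
    #: spontaneous reports carry notoriously incomplete indication fields.
    indication_recorded_rate: float = Field(ge=0.0, le=1.0, default=0.70)
    age_in_months_rate: float = Field(ge=0.0, le=1.0, default=0.05)
    weight_in_lbs_rate: float = Field(ge=0.0, le=1.0, default=0.10)
    filler_mean_extra: float = Field(ge=0.0, default=0.6)

    start_date_min: dt.date = dt.date(2019, 1, 1)
    start_date_max: dt.date = dt.date(2023, 6, 30)
    seed: int = 0

    @field_validator("country_probs")
    @classmethod
    def _probs_valid(cls, v):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("country_probs must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _check(self):
        if sum(d.use_prob for d in self.drugs) > 1.0 + 1e-12:
            raise ValueError("drug use probabilities must sum to <= 1")
        for drug, m in self.planted_rr.items():
            for pt, rr in m.items():
                if rr < 0:
                    raise ValueError(f"planted rr must be >= 0 ({drug}, {pt})")
        for probs in (self.source_probs, self.outcome_probs):
            if any(p < 0 for p in probs.values()) or sum(probs.values()) > 1 + 1e-9:
                raise ValueError("categorical probabilities invalid")
        if any(not 0 <= r <= 1 for r in self.missingness.values()):
            raise ValueError("missingness rates must be in [0, 1]")
        return self

    def rr(self, drug: str, pt_code: str) -> float:
        return self.planted_rr.get(drug, {}).get(pt_code, 1.0)


@dataclass
class TruthLedger:
    """Per-report planted truth plus injection counts.

    ``reports`` has one row per base case; ``counts`` records exactly how
    many duplicate/follow-up versions were emitted and how many cases have
    a (still observable) age under 18, so expected post-cleaning counts are
    computable without re-running the pipeline.
    """

    reports: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {"counts": self.counts,
                   "reports": self.reports.to_dict(orient="list")}
        Path(path).write_text(json.dumps(payload, default=str))


def _fmt_date(dates: np.ndarray, partial: np.ndarray, rng) -> np.ndarray:
    """YYYYMMDD strings; a `partial` subset truncated to YYYYMM or YYYY."""
    out = np.array([d.strftime("%Y%m%d") for d in dates], dtype=object)
    if partial.any():
        to_month = partial & (rng.random(len(out)) < 0.5)
        to_year = partial & ~to_month
        out[to_month] = [s[:6] for s in out[to_month]]
        out[to_year] = [s[:4] for s in out[to_year]]
    return out


def generate_bundle(config: SynthConfig) -> tuple[QuarterBundle, TruthLedger]:
    """Generate the base bundle: one initial version per case.

    Event occurrence for (drug, PT) is Bernoulli with probability
    min(1, rr x background), modified on the odds scale by the planted
    sex and concomitant-drug effects.  The onset date of a report is its
    therapy start plus a draw from the suspect drug's log-normal onset
    model (study events) or a uniform background delay otherwise.
    """
    n = config.n_reports
    rng = np.random.default_rng([config.seed, 0])

    drug_names = [d.name for d in config.drugs]
    n_bg = len(config.background_drugs)
    bg_prob = max(0.0, 1.0 - sum(d.use_prob for d in config.drugs))
    probs = np.array([d.use_prob for d in config.drugs]
                     + [bg_prob / n_bg] * n_bg)
    probs = probs / probs.sum()
    all_names = drug_names + list(config.background_drugs)
    drug_idx = rng.choice(len(all_names), size=n, p=probs)
    ps_drug = np.array(all_names, dtype=object)[drug_idx]
    is_study = drug_idx < len(drug_names)

    # demographics
    age = rng.normal(config.age_mean, config.age_sd, n)
    minors = rng.random(n) < config.minor_rate
    age[minors] = rng.uniform(2.0, 17.0, minors.sum())
    age = np.clip(np.round(age), 2, 100)
    sex = np.where(rng.random(n) < config.female_prop, "F", "M")
    weight = np.clip(rng.normal(config.weight_mean, config.weight_sd, n),
                     35.0, 180.0)
    country = rng.choice(config.countries, size=n,
                         p=np.asarray(config.country_probs))
    def _cat(probs_map):
        keys = list(probs_map) + [""]
        p = np.array(list(probs_map.values()))
        p = np.append(p, max(0.0, 1.0 - p.sum()))
        return rng.choice(keys, size=n, p=p / p.sum())
    source = _cat(config.source_probs)
    outcome = _cat(config.outcome_probs)

    # concomitant drugs
    n_con = len(config.concomitants)
    con = (rng.random((n, n_con))
           < np.array([c.prevalence for c in config.concomitants])) \
        if n_con else np.zeros((n, 0), bool)

    # planted study events: per-PT Bernoulli with odds-scale modifiers
    log_or = np.zeros(n)
    if config.female_ild_or != 1.0:
        log_or += (sex == "F") * math.log(config.female_ild_or)
    for j, c in enumerate(config.concomitants):
        if c.ild_or != 1.0:
            log_or += con[:, j] * math.log(c.ild_or)
    # Baseline: per-PT Bernoulli at min(1, rr x background).  The planted
    # sex/concomitant odds ratios act on *report-level* occurrence (the
    # union over PTs): exact union-level augmentation or thinning moves
    # the union probability to expit(logit(p_union) + log odds), leaving
    # the per-PT mechanism untouched whenever all modifiers are 1.
    p_mat = np.zeros((n, len(config.events)))
    for k, ev in enumerate(config.events):
        rr_by_drug = np.array([config.rr(name, ev.pt_code)
                               for name in all_names])
        p_mat[:, k] = np.clip(rr_by_drug[drug_idx] * ev.background_prob,
                              0.0, 0.99)
    occur = rng.random((n, len(config.events))) < p_mat
    if np.any(log_or != 0.0):
        p_union = 1.0 - np.prod(1.0 - p_mat, axis=1)
        with np.errstate(divide="ignore"):
            lo = np.where(p_union > 0,
                          logit(np.maximum(p_union, 1e-12)), -np.inf)
        p_target = np.where(np.isfinite(lo), expit(lo + log_or), 0.0)
        u = occur.any(axis=1)
        boost = np.where(p_union < 1.0,
                         (p_target - p_union) / (1.0 - p_union), 0.0)
        add = ~u & (rng.random(n) < np.clip(boost, 0.0, 1.0))
        if add.any():
            w = p_mat[add]
            w = w / w.sum(axis=1, keepdims=True)
            picks = (w.cumsum(axis=1)
                     > rng.random((int(add.sum()), 1))).argmax(axis=1)
            occur[np.flatnonzero(add), picks] = True
        keep_p = np.where(p_union > 0, p_target / p_union, 1.0)
        drop = u & (rng.random(n) >= np.clip(keep_p, 0.0, 1.0))
        occur[drop, :] = False
    any_study_event = occur.any(axis=1)

    # therapy start and onset
    span = (config.start_date_max - config.start_date_min).days
    start_offset = rng.integers(0, span + 1, n)
    start_dates = np.array([config.start_date_min + dt.timedelta(int(o))
                            for o in start_offset], dtype=object)
    tto = rng.integers(0, 366, n).astype(float)
    for i, d in enumerate(config.drugs):
        m = (drug_idx == i) & any_study_event
        if m.any():
            draw = rng.lognormal(math.log(d.onset_median_days),
                                 d.onset_sigma, int(m.sum()))
            tto[m] = np.round(draw)
    event_dates = np.array([s + dt.timedelta(int(t))
                            for s, t in zip(start_dates, tto)], dtype=object)

    # filler reactions: every report gets at least one background PT
    fill_w = np.array([e.background_prob for e in config.filler_events])
    fill_w = fill_w / fill_w.sum()
    n_fill = 1 + rng.poisson(config.filler_mean_extra, n)
    fill_choices = [rng.choice(len(config.filler_events), size=k,
                               p=fill_w) for k in n_fill]

    primaryid = (np.arange(n) + _BASE_ID).astype(str)
    caseid = primaryid.copy()

    # --- DEMO raw strings
    age_mon = rng.random(n) < config.age_in_months_rate
    age_str = np.where(age_mon, (age * 12).astype(int).astype(str),
                       age.astype(int).astype(str))
    age_cod = np.where(age_mon, "MON", "YR")
    wt_lbs = rng.random(n) < config.weight_in_lbs_rate
    wt_val = np.where(wt_lbs, weight / 0.4536, weight)
    wt_str = np.array([f"{v:.1f}" for v in wt_val], dtype=object)
    wt_cod = np.where(wt_lbs, "LBS", "KG")
    partial = rng.random(n) < config.partial_date_rate
    event_dt = _fmt_date(event_dates, partial, rng)
    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "i_f_code": "I",
        "event_dt": event_dt, "age": age_str, "age_cod": age_cod,
        "sex": sex, "wt": wt_str, "wt_cod": wt_cod,
        "reporter_country": country, "occp_cod": source}, dtype=str)

    # --- DRUG / INDI / THER
    brand = rng.random(n) < config.brand_name_rate
    name_shown = ps_drug.copy()
    for i, d in enumerate(config.drugs):
        if d.brand_names:
            m = (drug_idx == i) & brand
            name_shown[m] = d.brand_names[0]
    dose = np.where(is_study,
                    [str(int(config.drugs[j].daily_dose_mg)) if j < len(
                        drug_names) else "" for j in drug_idx], "")
    drug_rows = [pd.DataFrame({
        "primaryid": primaryid, "drug_seq": "1", "role_cod": "PS",
        "drugname": name_shown, "dose_amt": dose,
        "dose_unit": np.where(is_study, "MG", ""), "dur": "",
        "dur_cod": ""}, dtype=str)]
    rec = rng.random(n) < config.indication_recorded_rate
    indi_rows = [pd.DataFrame({
        "primaryid": primaryid[is_study & rec], "indi_drug_seq": "1",
        "indi_pt_code": NSCLC_PT[0], "indi_pt": NSCLC_PT[1]}, dtype=str)]
    for j, c in enumerate(config.concomitants):
        m = con[:, j]
        if not m.any():
            continue
        seq = str(2 + j)
        drug_rows.append(pd.DataFrame({
            "primaryid": primaryid[m], "drug_seq": seq, "role_cod": "C",
            "drugname": c.name, "dose_amt": "", "dose_unit": "",
            "dur": "", "dur_cod": ""}, dtype=str))
        m_rec = m & (rng.random(n) < config.indication_recorded_rate)
        if m_rec.any():
            indi_rows.append(pd.DataFrame({
                "primaryid": primaryid[m_rec], "indi_drug_seq": seq,
                "indi_pt_code": c.indication_pt_code,
                "indi_pt": c.indication_pt_name}, dtype=str))
    start_partial = rng.random(n) < config.partial_date_rate
    ther = pd.DataFrame({
        "primaryid": primaryid, "dsg_drug_seq": "1",
        "start_dt": _fmt_date(start_dates, start_partial, rng),
        "end_dt": ""}, dtype=str)

    # --- REAC
    reac_parts = []
    for k, ev in enumerate(config.events):
        m = occur[:, k]
        if m.any():
            reac_parts.append(pd.DataFrame({
                "primaryid": primaryid[m], "pt_code": ev.pt_code,
                "pt": ev.pt_name}, dtype=str))
    fill_ids, fill_codes, fill_names = [], [], []
    for i, choices in enumerate(fill_choices):
        for k in sorted(set(int(c) for c in choices)):
            fill_ids.append(primaryid[i])
            fill_codes.append(config.filler_events[k].pt_code)
            fill_names.append(config.filler_events[k].pt_name)
    reac_parts.append(pd.DataFrame({
        "primaryid": fill_ids, "pt_code": fill_codes, "pt": fill_names},
        dtype=str))
    reac = pd.concat(reac_parts, ignore_index=True)

    outc = pd.DataFrame({"primaryid": primaryid[outcome != ""],
                         "outc_cod": outcome[outcome != ""]}, dtype=str)

    bundle = normalize_bundle(QuarterBundle(
        demo=demo, drug=pd.concat(drug_rows, ignore_index=True),
        reac=reac, ther=ther,
        indi=pd.concat(indi_rows, ignore_index=True), outc=outc))
    bundle.check_referential_integrity()

    ledger_df = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "ps_drug": ps_drug,
        "is_study_drug": is_study, "true_age_yr": age, "true_sex": sex,
        "true_country": country, "true_weight_kg": weight,
        "true_event_dt": [d.strftime("%Y%m%d") for d in event_dates],
        "is_minor": age < 18, "has_study_event": any_study_event,
        "tto_days": tto})
    for j, c in enumerate(config.concomitants):
        ledger_df[f"con_{c.name}"] = con[:, j] if n_con else False
    ledger = TruthLedger(reports=ledger_df, counts={
        "n_base_reports": n,
        "n_under18_true": int((age < 18).sum()),
        "n_duplicate_versions": 0, "n_followup_versions": 0,
        "n_under18_observed": int((age < 18).sum())})
    return bundle, ledger


_BLANKABLE = {"event_dt": ["event_dt"], "age": ["age", "age_cod"],
              "sex": ["sex"], "reporter_country": ["reporter_country"],
              "wt": ["wt", "wt_cod"], "occp_cod": ["occp_cod"]}


def inject_duplicates_and_missingness(
        bundle: QuarterBundle, config: SynthConfig,
        ledger: TruthLedger) -> tuple[QuarterBundle, TruthLedger]:
    """Blank demographics at the configured rates and emit extra case
    versions.

    Duplicate versions are exact copies of the (post-blanking) initial
    version under a new, larger report id — the situation version-level
    de-duplication must detect.  Follow-up versions carry the pre-blanking
    truth (fully populated demographics) and the follow-up flag, so later
    versions are at least as complete as the initial one.
    """
    rng = np.random.default_rng([config.seed, 1])
    demo = bundle.demo.copy()
    n = len(demo)
    truth = demo.copy()  # pre-blanking values for follow-up versions

    blank_flags = {}
    for fld, cols in _BLANKABLE.items():
        rate = config.missingness.get(fld, 0.0)
        m = rng.random(n) < rate
        blank_flags[fld] = m
        for c in cols:
            demo.loc[m, c] = ""
    led = ledger.reports.copy()
    for fld, m in blank_flags.items():
        led[f"blank_{fld}"] = m

    children = {name: [bundle.table(name)[TABLE_COLUMNS[name]].copy()]
                for name in ("drug", "reac", "ther", "indi", "outc")}

    def _emit_versions(mask: np.ndarray, rows: pd.DataFrame,
                       offset: int, i_f: str | None) -> pd.DataFrame:
        sel = rows[mask].copy()
        old = sel["primaryid"].copy()
        sel["primaryid"] = (old.astype(int) + offset).astype(str)
        if i_f is not None:
            sel["i_f_code"] = i_f
        id_map = dict(zip(old, sel["primaryid"]))
        for name, parts in children.items():
            child = parts[0]
            extra = child[child["primaryid"].isin(id_map)].copy()
            extra["primaryid"] = extra["primaryid"].map(id_map)
            parts.append(extra)
        return sel

    dup_mask = rng.random(n) < config.duplicate_rate
    fup_mask = rng.random(n) < config.followup_rate
    demo_parts = [demo]
    if dup_mask.any():
        demo_parts.append(_emit_versions(dup_mask, demo, _DUP_OFFSET, None))
    if fup_mask.any():
        demo_parts.append(_emit_versions(fup_mask, truth, _FUP_OFFSET, "F"))

    new_demo = pd.concat(demo_parts, ignore_index=True)
    out = QuarterBundle(
        demo=new_demo,
        **{name: pd.concat(parts, ignore_index=True)
           for name, parts in children.items()})
    out = normalize_bundle(out)
    out.check_referential_integrity()

    led["has_duplicate"] = dup_mask
    led["has_followup"] = fup_mask
    counts = dict(ledger.counts)
    counts["n_duplicate_versions"] = int(dup_mask.sum())
    counts["n_followup_versions"] = int(fup_mask.sum())
    counts["n_under18_observed"] = int(
        (led["is_minor"] & ~led["blank_age"]).sum())
    counts["n_total_versions"] = len(new_demo)
    return out, TruthLedger(reports=led, counts=counts)


def simulate(config: SynthConfig) -> tuple[QuarterBundle, TruthLedger]:
    """generate_bundle followed by duplicate/missingness injection."""
    bundle, ledger = generate_bundle(config)
    return inject_duplicates_and_missingness(bundle, config, ledger)


def write_synthetic_quarter(config: SynthConfig, directory: str | Path,
                            suffix: str = "") -> dict[str, Path]:
    """Simulate and write the quarterly files plus the JSON truth ledger."""
    bundle, ledger = simulate(config)
    paths = write_quarter(bundle, directory, suffix=suffix)
    ledger_path = Path(directory) / f"truth_ledger{suffix}.json"
    ledger.to_json(ledger_path)
    paths["truth_ledger"] = ledger_path
    return paths


# ---------------------------------------------------------------------------
# stock configurations

ILD_EVENTS = [
    EventSpec(pt_code="10022611", pt_name="Interstitial lung disease",
              background_prob=0.0040),
    EventSpec(pt_code="10035742", pt_name="Pneumonitis",
              background_prob=0.0040),
    EventSpec(pt_code="10037383", pt_name="Pulmonary fibrosis",
              background_prob=0.0020),
    EventSpec(pt_code="10066728", pt_name="Acute interstitial pneumonitis",
              background_prob=0.0008),
    EventSpec(pt_code="10078268", pt_name="Idiopathic interstitial pneumonia",
              background_prob=0.0006),
    EventSpec(pt_code="10087834", pt_name="Interstitial lung abnormality",
              background_prob=0.0006),
]

FILLER_EVENTS = [
    EventSpec(pt_code="10019211", pt_name="Headache", background_prob=0.10),
    EventSpec(pt_code="10012735", pt_name="Diarrhoea", background_prob=0.12),
    EventSpec(pt_code="10016256", pt_name="Fatigue", background_prob=0.14),
    EventSpec(pt_code="10047700", pt_name="Vomiting", background_prob=0.09),
    EventSpec(pt_code="10037844", pt_name="Rash", background_prob=0.08),
    EventSpec(pt_code="10013573", pt_name="Dizziness", background_prob=0.07),
    EventSpec(pt_code="10037660", pt_name="Pyrexia", background_prob=0.08),
    EventSpec(pt_code="10002034", pt_name="Anaemia", background_prob=0.08),
    EventSpec(pt_code="10011224", pt_name="Cough", background_prob=0.12),
    EventSpec(pt_code="10013968", pt_name="Dyspnoea", background_prob=0.12),
]

#: The five ALK TKIs with label daily doses and onset models whose medians
#: follow the reported per-drug onset times (29/70/49/7/36 days).
ALK_DRUGS = [
    DrugSpec(name="crizotinib", use_prob=0.0455, daily_dose_mg=500,
             onset_median_days=29, onset_sigma=1.8, brand_names=["Xalkori"]),
    DrugSpec(name="ceritinib", use_prob=0.0096, daily_dose_mg=450,
             onset_median_days=70, onset_sigma=1.8, brand_names=["Zykadia"]),
    DrugSpec(name="alectinib", use_prob=0.0233, daily_dose_mg=1200,
             onset_median_days=49, onset_sigma=1.8, brand_names=["Alecensa"]),
    DrugSpec(name="brigatinib", use_prob=0.0107, daily_dose_mg=180,
             onset_median_days=7, onset_sigma=1.8, brand_names=["Alunbrig"]),
    DrugSpec(name="lorlatinib", use_prob=0.0124, daily_dose_mg=100,
             onset_median_days=36, onset_sigma=1.8, brand_names=["Lorbrena"]),
]

#: Concomitant medications with indication PTs; the planted odds ratios
#: follow the multivariable estimates of the source analysis.
STUDY_CONCOMITANTS = [
    ConcomitantSpec(name="amlodipine", prevalence=0.05,
                    indication_pt_code="10020772",
                    indication_pt_name="Hypertension", ild_or=10.1),
    ConcomitantSpec(name="furosemide", prevalence=0.04,
                    indication_pt_code="10020772",
                    indication_pt_name="Hypertension", ild_or=2.6),
    ConcomitantSpec(name="magnesium oxide", prevalence=0.03,
                    indication_pt_code="10010774",
                    indication_pt_name="Constipation", ild_or=33.7),
    ConcomitantSpec(name="lansoprazole", prevalence=0.04,
                    indication_pt_code="10017944",
                    indication_pt_name="Gastric disorder", ild_or=9.8),
    ConcomitantSpec(name="pantoprazole", prevalence=0.05,
                    indication_pt_code="10017944",
                    indication_pt_name="Gastric disorder", ild_or=4.9),
    ConcomitantSpec(name="acetaminophen", prevalence=0.08,
                    indication_pt_code="10033371",
                    indication_pt_name="Pain", ild_or=2.5),
    ConcomitantSpec(name="oxycodone", prevalence=0.05,
                    indication_pt_code="10033371",
                    indication_pt_name="Pain", ild_or=3.5),
    ConcomitantSpec(name="metoclopramide", prevalence=0.04,
                    indication_pt_code="10028813",
                    indication_pt_name="Nausea", ild_or=4.4),
    ConcomitantSpec(name="metformin", prevalence=0.05,
                    indication_pt_code="10012601",
                    indication_pt_name="Diabetes mellitus", ild_or=1.0),
    ConcomitantSpec(name="atorvastatin", prevalence=0.06,
                    indication_pt_code="10058108",
                    indication_pt_name="Dyslipidaemia", ild_or=1.0),
]

#: Per-drug relative risks of the ILD preferred terms, following the
#: reported per-drug signal strengths (crizotinib 4.6 ... lorlatinib 2.5).
STUDY_RRS = {"crizotinib": 4.6, "ceritinib": 3.7, "alectinib": 4.7,
             "brigatinib": 6.2, "lorlatinib": 2.5}


def study_config(n_reports: int = 50_000, seed: int = 0,
                 **overrides) -> SynthConfig:
    """Study-condition configuration: five ALK TKIs with planted ILD
    relative risks, concomitant-drug effects and a planted female excess."""
    planted = {d: {ev.pt_code: rr for ev in ILD_EVENTS}
               for d, rr in STUDY_RRS.items()}
    kw = dict(n_reports=n_reports, drugs=ALK_DRUGS, events=ILD_EVENTS,
              filler_events=FILLER_EVENTS, planted_rr=planted,
              concomitants=STUDY_CONCOMITANTS, female_ild_or=2.2, seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def null_config(n_reports: int = 50_000, seed: int = 0,
                **overrides) -> SynthConfig:
    """Null model: every planted relative risk and odds ratio is 1."""
    conc = [c.model_copy(update={"ild_or": 1.0}) for c in STUDY_CONCOMITANTS]
    kw = dict(n_reports=n_reports, drugs=ALK_DRUGS, events=ILD_EVENTS,
              filler_events=FILLER_EVENTS, planted_rr={}, concomitants=conc,
              female_ild_or=1.0, seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def single_signal_config(n_reports: int = 50_000, seed: int = 0,
                         drug: str = "crizotinib",
                         pt_code: str = "10022611", rr: float = 5.0,
                         **overrides) -> SynthConfig:
    """Null model plus exactly one planted (drug, PT) relative risk."""
    cfg = null_config(n_reports=n_reports, seed=seed, **overrides)
    return cfg.model_copy(update={"planted_rr": {drug: {pt_code: rr}}})


def simulate_covariate_matrix(beta: dict[str, float], intercept: float,
                              n: int, seed: int,
                              prevalence: dict[str, float] | None = None
                              ) -> pd.DataFrame:
    """Draw a binary covariate matrix and logistic outcomes with known
    coefficients — the ground truth for parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    prevalence = prevalence or {}
    cols = {}
    lp = np.full(n, intercept, dtype=float)
    for name, b in beta.items():
        x = (rng.random(n) < prevalence.get(name, 0.3)).astype(float)
        cols[name] = x
        lp += b * x
    out = pd.DataFrame(cols)
    out.insert(0, "outcome", (rng.random(n) < expit(lp)).astype(int))
    return out
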