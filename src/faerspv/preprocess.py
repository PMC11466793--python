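"""Cleaning of spontaneous-report bundles.

Three stages, run in order:

1. **Single missing-value imputation** — within a case, a version missing
   exactly one of {event date, age, sex, reporter country} receives that
   field's maximum value among versions of the same case that have all
   four fields populated.  Versions missing two or more fields are left
   untouched.
2. **Two-step de-duplication** — step 1 collapses versions of a case that
   are identical on (case id, initial/follow-up code, event date, age,
   sex, reporter country, sorted drug-name set, sorted outcome set),
   keeping the most recent version (largest report id).  Step 2 collapses
   reports — across cases — identical on (event date, age, sex, reporter
   country, sorted drug-name set, sorted reaction set).
3. **Exclusions** — reports with a known age under 18 years are removed;
   unknown ages are retained.

"Most recent version" is operationalised as the largest numeric report id,
which FAERS assigns monotonically; this is robust when event dates are
partial.  All three stages are idempotent and independent of input row
order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import QuarterBundle, map_drug_names, normalize_bundle

IMPUTE_FIELDS = ("event_dt", "age_yr", "sex", "reporter_country")


@dataclass
class CleaningReport:
    """Counts emitted by the cleaning pipeline.

    Invariant: retained = input_reports - duplicates_removed
    - under18_removed.
    """

    input_reports: int = 0
    duplicates_removed: int = 0
    under18_removed: int = 0
    retained: int = 0
    step1_removed: int = 0
    step2_removed: int = 0
    imputed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"input_reports": self.input_reports,
                "duplicates_removed": self.duplicates_removed,
                "step1_removed": self.step1_removed,
                "step2_removed": self.step2_removed,
                "under18_removed": self.under18_removed,
                "retained": self.retained, "imputed": dict(self.imputed)}

    def check(self) -> None:
        assert self.retained == (self.input_reports - self.duplicates_removed
                                 - self.under18_removed)


def _presence(demo: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame: which of the four demographic fields are populated."""
    return pd.DataFrame({
        "event_dt": demo["event_dt"].str.strip() != "",
        "age_yr": demo["age_yr"].notna(),
        "sex": demo["sex"].str.strip() != "",
        "reporter_country": demo["reporter_country"].str.strip() != ""},
        index=demo.index)


def impute_missing(bundle: QuarterBundle) -> tuple[QuarterBundle, dict]:
    """Single missing-value imputation across versions of the same case.

    Only versions missing exactly one field are imputed, and only from
    donor versions (same case) with all four fields populated, taking the
    maximum donor value — numeric for age, lexicographic for the string
    fields (chronological for YYYYMMDD dates).
    """
    bundle = bundle.copy()
    demo = bundle.demo
    counts = {f: 0 for f in IMPUTE_FIELDS}
    multi = demo["caseid"].duplicated(keep=False)
    if not multi.any():
        return bundle, counts
    present = _presence(demo[multi])
    n_missing = (~present).sum(axis=1)
    donors = demo[multi][n_missing == 0]
    if donors.empty:
        return bundle, counts

    donor_max = donors.groupby("caseid").agg(
        event_dt=("event_dt", "max"), age_yr=("age_yr", "max"),
        sex=("sex", "max"), reporter_country=("reporter_country", "max"))
    recipients = demo.index[(n_missing == 1)
                            & demo["caseid"].isin(donor_max.index)]
    for fld in IMPUTE_FIELDS:
        rows = [i for i in recipients if not present.at[i, fld]]
        if not rows:
            continue
        values = donor_max.loc[demo.loc[rows, "caseid"], fld].to_numpy()
        if fld == "age_yr":
            demo.loc[rows, "age_yr"] = values
            demo.loc[rows, "age"] = [f"{v:g}" for v in values]
            demo.loc[rows, "age_cod"] = "YR"
        else:
            demo.loc[rows, fld] = values
        counts[fld] = len(rows)
    normalize_bundle(bundle)
    return bundle, counts


def _sorted_set_key(table: pd.DataFrame, value_col: str,
                    ids: pd.Series) -> pd.Series:
    """Per-report sorted unique value set as a joined string key."""
    t = table[["primaryid", value_col]].copy()
    t[value_col] = t[value_col].str.strip().str.lower()
    t = t.drop_duplicates().sort_values(["primaryid", value_col])
    pid = t["primaryid"].to_numpy()
    vals = t[value_col].to_numpy(dtype=object)
    if len(vals) == 0:
        return pd.Series("", index=ids.index)
    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    sep = np.full(len(vals), "|", dtype=object)
    sep[starts] = ""
    joined = np.add.reduceat(sep + vals, starts)
    key = pd.Series(joined, index=pid[starts])
    return ids.map(key).fillna("")


def _dedup_keys(bundle: QuarterBundle) -> pd.DataFrame:
    demo = bundle.demo
    ids = demo["primaryid"]
    age_key = bundle.demo["age_yr"].round(4).astype(str).replace("nan", "")
    return pd.DataFrame({
        "primaryid": ids,
        "primaryid_num": pd.to_numeric(ids),
        "caseid": demo["caseid"],
        "i_f_code": demo["i_f_code"].str.strip().str.upper(),
        "event_dt": demo["event_dt"].str.strip(),
        "age": age_key,
        "sex": demo["sex"].str.strip().str.upper(),
        "country": demo["reporter_country"].str.strip().str.upper(),
        "drugset": _sorted_set_key(bundle.drug, "drugname", ids),
        "outcset": _sorted_set_key(bundle.outc, "outc_cod", ids),
        "reacset": _sorted_set_key(bundle.reac, "pt_code", ids)},
        index=demo.index)


STEP1_KEY = ["caseid", "i_f_code", "event_dt", "age", "sex", "country",
             "drugset", "outcset"]
STEP2_KEY = ["event_dt", "age", "sex", "country", "drugset", "reacset"]


def _joint_key(keys: pd.DataFrame, cols: list[str]) -> pd.Series:
    out = keys[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + "\x1f" + keys[c].astype(str)
    return out


def deduplicate(bundle: QuarterBundle) -> tuple[QuarterBundle,
                                                CleaningReport]:
    """Two-step de-duplication; keeps the largest report id per key group."""
    report = CleaningReport(input_reports=bundle.n_reports)
    keys = _dedup_keys(bundle)

    keep1 = keys.loc[keys.groupby(_joint_key(keys, STEP1_KEY), sort=False)[
        "primaryid_num"].idxmax(), "primaryid"]
    report.step1_removed = len(keys) - len(keep1)

    keys2 = keys[keys["primaryid"].isin(set(keep1))]
    keep2 = keys2.loc[keys2.groupby(_joint_key(keys2, STEP2_KEY), sort=False)[
        "primaryid_num"].idxmax(), "primaryid"]
    report.step2_removed = len(keys2) - len(keep2)

    report.duplicates_removed = report.step1_removed + report.step2_removed
    report.retained = len(keep2)
    return bundle.restrict(keep2), report


def apply_exclusions(bundle: QuarterBundle,
                     report: CleaningReport | None = None
                     ) -> tuple[QuarterBundle, CleaningReport]:
    """Remove reports with a known age below 18 years.

    Reports with unknown age are retained — the exclusion targets known
    paediatric ages only, and published demographic tables keep an
    "Unknown" age stratum.
    """
    if report is None:
        report = CleaningReport(input_reports=bundle.n_reports,
                                retained=bundle.n_reports)
    demo = bundle.demo
    minors = demo["age_yr"].notna() & (demo["age_yr"] < 18.0)
    report.under18_removed = int(minors.sum())
    report.retained -= report.under18_removed
    out = bundle.restrict(demo.loc[~minors, "primaryid"])
    report.check()
    return out, report


def clean(bundle: QuarterBundle) -> tuple[QuarterBundle, CleaningReport]:
    """Full cleaning pipeline: impute -> deduplicate -> exclude."""
    bundle, imputed = impute_missing(bundle)
    bundle, report = deduplicate(bundle)
    report.imputed = imputed
    bundle, report = apply_exclusions(bundle, report)
    return bundle, report


def primary_suspect_map(bundle: QuarterBundle,
                        synonyms: dict[str, str]) -> pd.Series:
    """Map report id -> generic study-drug name for reports whose primary
    suspect matches the synonym table (the study-set selector)."""
    ps = bundle.drug[bundle.drug["role_cod"].str.strip().str.upper() == "PS"]
    generic = map_drug_names(ps["drugname"], synonyms)
    hit = ps[generic.notna()]
    out = pd.Series(generic[generic.notna()].to_numpy(),
                    index=hit["primaryid"].to_numpy(), dtype=object)
    return out[~out.index.duplicated()]
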