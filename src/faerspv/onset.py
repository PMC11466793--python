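"""Time-to-onset and cumulative dose at onset for flagged cases.

Time to onset is the event date minus the earliest therapy start of the
primary-suspect drug, in whole days (partial dates having been imputed to
interval midpoints at read time).  Negative intervals are treated as
missing and counted as anomalies.  Cumulative dose is
daily dose (mg/day) x time to onset (days) / body weight (kg).
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QuarterBundle

WEEKS4_DAYS = 28
WEEKS8_DAYS = 56


def time_to_onset(start_date: dt.date | None,
                  event_date: dt.date | None) -> float:
    """Whole days between therapy start and event; NaN when either date is
    missing or the interval is negative."""
    if start_date is None or event_date is None:
        return math.nan
    days = (event_date - start_date).days
    return float(days) if days >= 0 else math.nan


def cumulative_dose(dose_mg_day: float, tto_days: float,
                    weight_kg: float) -> float:
    """Cumulative dose at onset in mg/kg; NaN if any input is missing."""
    if any(x is None or (isinstance(x, float) and math.isnan(x))
           for x in (dose_mg_day, tto_days, weight_kg)):
        return math.nan
    return dose_mg_day * tto_days / weight_kg


@dataclass
class OnsetFrame:
    """Per-case onset records plus the anomaly count (event before start)."""

    records: pd.DataFrame
    anomalies: int


def compute_onsets(bundle: QuarterBundle, study_map: pd.Series,
                   case_flags: pd.Series) -> OnsetFrame:
    """Onset records for every flagged case with a study primary suspect.

    The earliest THER start for the suspect drug sequence is used as the
    first exposure.
    """
    ids = [i for i in study_map.index if case_flags.get(i, False)]
    demo = bundle.demo.set_index("primaryid")
    ther = bundle.ther[bundle.ther["dsg_drug_seq"].str.strip() == "1"]
    start = ther.dropna(subset=["start_date"]).groupby(
        "primaryid")["start_date"].min()
    ps = bundle.drug[bundle.drug["role_cod"].str.strip().str.upper() == "PS"]
    dose = ps.set_index("primaryid")["dose_mg_day"]
    dose = dose[~dose.index.duplicated()]

    rows, anomalies = [], 0
    for rid in ids:
        ev = demo.at[rid, "event_date"]
        st = start.get(rid)
        tto = time_to_onset(st, ev)
        if st is not None and ev is not None and (ev - st).days < 0:
            anomalies += 1
        wt = demo.at[rid, "wt_kg"]
        cd = cumulative_dose(dose.get(rid, math.nan), tto,
                             wt if pd.notna(wt) else math.nan)
        rows.append({"primaryid": rid, "drug": study_map[rid],
                     "tto_days": tto,
                     "within_4wk": bool(tto <= WEEKS4_DAYS)
                     if not math.isnan(tto) else None,
                     "within_8wk": bool(tto <= WEEKS8_DAYS)
                     if not math.isnan(tto) else None,
                     "cumulative_dose_mg_kg": cd})
    cols = ["primaryid", "drug", "tto_days", "within_4wk", "within_8wk",
            "cumulative_dose_mg_kg"]
    return OnsetFrame(records=pd.DataFrame(rows, columns=cols),
                      anomalies=anomalies)


def onset_summary(records: pd.DataFrame,
                  pooled_label: str = "ALK TKIs") -> pd.DataFrame:
    """Median/Q1/Q3 of time to onset (linear-interpolation quartiles),
    fractions within 4 and 8 weeks, and the median cumulative dose, per
    drug and pooled.  Groups without a known onset yield an empty (NaN)
    summary row rather than an error."""
    groups = [(pooled_label, records)]
    groups += [(d, g) for d, g in records.groupby("drug")]
    rows = []
    for label, g in groups:
        tto = g["tto_days"].dropna().to_numpy()
        dosev = g["cumulative_dose_mg_kg"].dropna().to_numpy()
        if tto.size:
            q1, med, q3 = np.percentile(tto, [25, 50, 75])
            f4 = float((tto <= WEEKS4_DAYS).mean() * 100)
            f8 = float((tto <= WEEKS8_DAYS).mean() * 100)
        else:
            q1 = med = q3 = f4 = f8 = math.nan
        rows.append({"drug": label, "n": len(g), "n_known_tto": tto.size,
                     "median_days": med, "q1_days": q1, "q3_days": q3,
                     "pct_within_4wk": f4, "pct_within_8wk": f8,
                     "median_cumulative_dose_mg_kg":
                         float(np.median(dosev)) if dosev.size else math.nan})
    return pd.DataFrame(rows)
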