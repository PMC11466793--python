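"""Reading and writing FAERS quarterly ASCII bundles.

FAERS quarters are distributed as "$"-delimited text tables (DEMO, DRUG,
REAC, THER, INDI, OUTC) with a header row, linked by ``primaryid``.  This
module parses them into a :class:`QuarterBundle` of typed pandas frames,
normalising ages to years and weights to kilograms at read time while
preserving every raw field so that a read/write round trip is bit-exact.

Dates in FAERS may be partial (``YYYYMMDD``, ``YYYYMM`` or ``YYYY``).  For
interval arithmetic partial dates are imputed to the interval midpoint
(15th of the month, 1 July of the year) and the original precision is kept
alongside.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import data_path

log = logging.getLogger(__name__)

DELIMITER = "$"

#: Mandatory columns per table, in file order.
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "i_f_code", "event_dt", "age", "age_cod",
             "sex", "wt", "wt_cod", "reporter_country", "occp_cod"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname",
             "dose_amt", "dose_unit", "dur", "dur_cod"],
    "reac": ["primaryid", "pt_code", "pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt_code", "indi_pt"],
    "outc": ["primaryid", "outc_cod"],
}
TABLE_NAMES = tuple(TABLE_COLUMNS)

#: Age-unit codes -> multiplier into years.
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
                     "DY": 1.0 / 365.25, "WK": 1.0 / 52.18}
#: Weight-unit codes -> multiplier into kg.
WEIGHT_UNIT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.4536, "LB": 0.4536}

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: Outcome codes as used in the OUTC table.
OUTCOME_CODES = {"HO": "hospitalization", "DS": "disability",
                 "LT": "life_threatening", "DE": "death", "OT": "other"}

#: Occupation (report source) codes in DEMO.
SOURCE_CODES = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
                "OT": "other"}


class FaersFormatError(ValueError):
    """Raised when a quarterly file violates the expected layout."""


@dataclass
class QuarterBundle:
    """The six linked FAERS tables for one or more quarters.

    Raw columns (strings, possibly empty) mirror the file contents; derived
    columns (``age_yr``, ``wt_kg``, parsed dates) are added by
    :func:`normalize_bundle` and dropped again on write.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    issues: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "QuarterBundle":
        return QuarterBundle(**{n: self.table(n).copy() for n in TABLE_NAMES},
                             issues=dict(self.issues))

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def report_ids(self) -> pd.Index:
        return pd.Index(self.demo["primaryid"])

    def check_referential_integrity(self) -> None:
        """Every child-table primaryid must exist in DEMO."""
        ids = set(self.demo["primaryid"])
        for name in TABLE_NAMES[1:]:
            extra = set(self.table(name)["primaryid"]) - ids
            if extra:
                raise FaersFormatError(
                    f"{name.upper()} rows reference unknown report ids, "
                    f"e.g. {sorted(extra)[:3]}")

    def restrict(self, report_ids) -> "QuarterBundle":
        """Sub-bundle containing only the given report ids (all tables)."""
        keep = set(report_ids)
        out = {}
        for name in TABLE_NAMES:
            t = self.table(name)
            out[name] = t[t["primaryid"].isin(keep)].reset_index(drop=True)
        return QuarterBundle(**out, issues=dict(self.issues))


# ---------------------------------------------------------------------------
# date handling

def parse_faers_date(s: str) -> tuple[dt.date | None, str | None]:
    """Parse a possibly-partial FAERS date string.

    Returns ``(date, precision)`` where precision is ``day``/``month``/
    ``year``; partial dates are imputed to the midpoint of the stated
    interval (month -> 15th, year -> 1 July).  Unparseable input yields
    ``(None, None)``.
    """
    s = (s or "").strip()
    if not s.isdigit():
        return None, None
    try:
        if len(s) == 8:
            return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
        if len(s) == 6:
            return dt.date(int(s[:4]), int(s[4:6]), 15), "month"
        if len(s) == 4:
            return dt.date(int(s), 7, 1), "year"
    except ValueError:
        return None, None
    return None, None


def _parse_date_column(col: pd.Series) -> tuple[pd.Series, pd.Series]:
    parsed = col.map(parse_faers_date)
    dates = parsed.map(lambda t: t[0])
    prec = parsed.map(lambda t: t[1])
    return dates, prec


# ---------------------------------------------------------------------------
# normalisation

def _to_float(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col.str.strip(), errors="coerce")


def normalize_bundle(bundle: QuarterBundle) -> QuarterBundle:
    """Attach derived columns (units normalised, dates parsed) in place."""
    demo = bundle.demo
    age = _to_float(demo["age"])
    # blank unit code with a numeric age is conventionally years
    age_cod = demo["age_cod"].str.strip().str.upper().replace("", "YR")
    factor = age_cod.map(AGE_UNIT_TO_YEARS)
    demo["age_yr"] = age * factor

    wt = _to_float(demo["wt"])
    wt_cod = demo["wt_cod"].str.strip().str.upper().replace("", "KG")
    demo["wt_kg"] = wt * wt_cod.map(WEIGHT_UNIT_TO_KG)
    implausible = (demo["wt_kg"] <= 0) | (demo["wt_kg"] >= 500)
    demo["wt_implausible"] = implausible.fillna(False)
    demo.loc[demo["wt_implausible"], "wt_kg"] = np.nan

    demo["event_date"], demo["event_date_precision"] = _parse_date_column(
        demo["event_dt"])

    ther = bundle.ther
    ther["start_date"], ther["start_precision"] = _parse_date_column(
        ther["start_dt"])
    ther["end_date"], ther["end_precision"] = _parse_date_column(
        ther["end_dt"])

    drug = bundle.drug
    drug["dose_mg_day"] = _to_float(drug["dose_amt"]).where(
        drug["dose_unit"].str.strip().str.upper().isin(["MG", ""]))
    dur = _to_float(drug["dur"])
    dur_factor = drug["dur_cod"].str.strip().str.upper().replace("", "DAY").map(
        {"DAY": 1.0, "WK": 7.0, "MON": 30.44, "YR": 365.25})
    drug["duration_days"] = dur * dur_factor
    return bundle


def strip_derived(bundle: QuarterBundle) -> QuarterBundle:
    """Return a copy holding only the raw file columns."""
    out = {}
    for name in TABLE_NAMES:
        out[name] = bundle.table(name)[TABLE_COLUMNS[name]].copy()
    return QuarterBundle(**out, issues=dict(bundle.issues))


# ---------------------------------------------------------------------------
# read / write

def _read_table(path: Path, name: str) -> tuple[pd.DataFrame, int]:
    cols = TABLE_COLUMNS[name]
    with open(path, encoding="utf-8", errors="replace") as fh:
        header = fh.readline().rstrip("\n").split(DELIMITER)
        missing = [c for c in cols if c not in header]
        if missing:
            raise FaersFormatError(
                f"{name.upper()} file {path} is missing mandatory "
                f"column(s) {missing}")
        idx = [header.index(c) for c in cols]
        width = len(header)
        rows, bad = [], 0
        for line in fh:
            fields = line.rstrip("\n").split(DELIMITER)
            if len(fields) != width:
                bad += 1
                continue
            rows.append([fields[i] for i in idx])
    if bad:
        log.warning("%s: skipped %d malformed row(s) in %s", name, bad, path)
    df = pd.DataFrame(rows, columns=cols, dtype=str)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
    return df, bad


def read_quarter(paths: dict[str, str | Path]) -> QuarterBundle:
    """Read one quarter from a ``{table name: path}`` map.

    Malformed rows (wrong field count) are counted in ``bundle.issues`` and
    skipped; a missing mandatory header column raises
    :class:`FaersFormatError`.
    """
    missing = [n for n in TABLE_NAMES if n not in paths]
    if missing:
        raise FaersFormatError(f"no path given for table(s) {missing}")
    tables, issues = {}, {}
    for name in TABLE_NAMES:
        tables[name], bad = _read_table(Path(paths[name]), name)
        if bad:
            issues[f"{name}_malformed_rows"] = bad
    bundle = QuarterBundle(**tables, issues=issues)
    bundle.check_referential_integrity()
    return normalize_bundle(bundle)


def read_quarter_dir(directory: str | Path, suffix: str = "") -> QuarterBundle:
    """Convenience wrapper: read ``DEMO<suffix>.txt`` etc. from a directory."""
    directory = Path(directory)
    paths = {n: directory / f"{n.upper()}{suffix}.txt" for n in TABLE_NAMES}
    absent = [str(p) for p in paths.values() if not p.exists()]
    if absent:
        raise FaersFormatError(f"missing quarterly file(s): {absent}")
    return read_quarter(paths)


def write_quarter(bundle: QuarterBundle, directory: str | Path,
                  suffix: str = "") -> dict[str, Path]:
    """Write the raw columns of every table as "$"-delimited text.

    Returns the ``{table name: path}`` map suitable for :func:`read_quarter`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        cols = TABLE_COLUMNS[name]
        path = directory / f"{name.upper()}{suffix}.txt"
        t = bundle.table(name)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(DELIMITER.join(cols) + "\n")
            for row in t[cols].itertuples(index=False):
                fh.write(DELIMITER.join(row) + "\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# drug-name standardisation (bundled synonym table)

def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the ALK-TKI generic+brand synonym table.

    Returns a lowercase synonym -> generic-name map.  The bundled default
    covers the five approved ALK tyrosine-kinase inhibitors and their brand
    names.
    """
    src = Path(path) if path is not None else data_path("alk_tki_synonyms.csv")
    table = pd.read_csv(src, dtype=str)
    if not {"generic", "synonym"} <= set(table.columns):
        raise FaersFormatError("synonym table needs columns generic, synonym")
    return {s.strip().lower(): g.strip().lower()
            for g, s in zip(table["generic"], table["synonym"])}


def match_generic(name: str, synonyms: dict[str, str]) -> str | None:
    """Map a reported drug name to its generic form (case-insensitive)."""
    return synonyms.get((name or "").strip().lower())


def map_drug_names(names: pd.Series, synonyms: dict[str, str]) -> pd.Series:
    return names.str.strip().str.lower().map(synonyms)
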