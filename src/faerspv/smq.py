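"""Case finding through Standardised MedDRA Queries (SMQs).

An SMQ is a curated set of preferred terms (PTs) defining a medical
concept; the bundled default is the interstitial-lung-disease query
(code 20000042) with its narrow-scope PTs plus a few broad-scope extras.
A report is a case iff at least one of its reaction PTs belongs to the
query — counted once per report regardless of how many PTs match.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import data_path
from .io import FaersFormatError, QuarterBundle

ILD_SMQ_CODE = "20000042"


@dataclass(frozen=True)
class SmqDefinition:
    smq_code: str
    smq_name: str
    pt_codes: frozenset[str]
    scope: dict  # pt_code -> "narrow" | "broad"

    def __post_init__(self):
        if not self.pt_codes:
            raise FaersFormatError("SMQ definition has an empty PT list")

    def narrow(self) -> "SmqDefinition":
        codes = frozenset(c for c in self.pt_codes
                          if self.scope.get(c) == "narrow")
        return SmqDefinition(self.smq_code, self.smq_name, codes,
                             {c: "narrow" for c in codes})


def load_smq(path: str | Path | None = None,
             narrow_only: bool = False) -> SmqDefinition:
    """Load an SMQ definition CSV (columns smq_code, smq_name, pt_code,
    pt_name, scope).  Without a path the bundled ILD query is used."""
    src = Path(path) if path is not None else data_path("smq_ild.csv")
    table = pd.read_csv(src, dtype=str)
    required = {"smq_code", "smq_name", "pt_code", "pt_name", "scope"}
    if not required <= set(table.columns):
        raise FaersFormatError(
            f"SMQ file missing column(s) {sorted(required - set(table.columns))}")
    if table.empty:
        raise FaersFormatError("SMQ definition has an empty PT list")
    bad = table[~table["pt_code"].str.fullmatch(r"\d{8}")]
    if not bad.empty:
        raise FaersFormatError(
            f"PT codes must be 8-digit integers, got {bad['pt_code'].iloc[0]!r}")
    smq = SmqDefinition(
        smq_code=table["smq_code"].iloc[0],
        smq_name=table["smq_name"].iloc[0],
        pt_codes=frozenset(table["pt_code"]),
        scope=dict(zip(table["pt_code"], table["scope"].str.lower())))
    return smq.narrow() if narrow_only else smq


def flag_cases(bundle: QuarterBundle, smq: SmqDefinition) -> pd.Series:
    """Boolean case flag per report id (a pure function of the reaction
    sets and the SMQ)."""
    hits = bundle.reac.loc[
        bundle.reac["pt_code"].isin(smq.pt_codes), "primaryid"]
    flags = pd.Series(False, index=pd.Index(bundle.demo["primaryid"]),
                      name="case")
    flags[flags.index.isin(set(hits))] = True
    return flags


def pt_case_sets(bundle: QuarterBundle,
                 report_ids=None) -> dict[str, set[str]]:
    """Report-id sets per reaction PT (for per-PT signal profiles)."""
    reac = bundle.reac
    if report_ids is not None:
        reac = reac[reac["primaryid"].isin(set(report_ids))]
    return {pt: set(g) for pt, g in reac.groupby("pt_code")["primaryid"]}
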