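"""Logistic risk modelling of ILD among ALK-TKI reports, plus a nomogram.

The covariate matrix has one row per cleaned study report.  Age groups
follow the demographic-table convention (18–64 reference, 65–84, >=85,
unknown); the study-drug indicators use lorlatinib as the reference
level; concomitant diseases are derived from the indication PTs of
non-suspect drugs (spontaneous-report databases carry no comorbidity
table); concomitant drugs are the non-suspect DRUG rows matched by name.

The nomogram re-expresses the fitted model: each covariate contributes
points proportional to its coefficient's contribution range, the largest
contribution spanning exactly 100 points, and total points map back to
predicted probability through the reconstructed linear predictor — an
exact, invertible transformation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .io import QuarterBundle
from .signals import Z95

#: Concomitant-disease indicators <- indication PT codes of non-suspect drugs.
DISEASE_PTS = {
    "hypertension": {"10020772"},
    "diabetes_mellitus": {"10012601"},
    "dyslipidemia": {"10058108"},
    "gastric_disorder": {"10017944"},
    "pain": {"10033371"},
    "nausea": {"10028813"},
    "constipation": {"10010774"},
}

CONCOMITANT_DRUGS = ("amlodipine", "furosemide", "magnesium oxide",
                     "lansoprazole", "pantoprazole", "acetaminophen",
                     "oxycodone", "metoclopramide")

REFERENCE_DRUG = "lorlatinib"


class SeparationError(RuntimeError):
    pass


def build_case_control(bundle: QuarterBundle, study_map: pd.Series,
                       case_flags: pd.Series,
                       reference_drug: str = REFERENCE_DRUG) -> pd.DataFrame:
    """Covariate matrix (one row per study report) with the ILD outcome."""
    ids = list(study_map.index)
    demo = bundle.demo.set_index("primaryid").loc[ids]
    out = pd.DataFrame(index=pd.Index(ids, name="primaryid"))
    out["outcome"] = [int(case_flags.get(i, False)) for i in ids]

    age = demo["age_yr"]
    out["age_65_84"] = ((age >= 65) & (age < 85)).astype(int)
    out["age_ge_85"] = (age >= 85).astype(int)
    out["age_unknown"] = age.isna().astype(int)
    sex = demo["sex"].str.strip().str.upper()
    out["sex_female"] = (sex == "F").astype(int)
    out["sex_unknown"] = (~sex.isin(["F", "M"])).astype(int)

    for d in sorted(study_map.unique()):
        if d != reference_drug:
            out[f"drug_{d}"] = (study_map.loc[ids] == d).astype(int) \
                .to_numpy()

    nonsusp = bundle.drug[
        (bundle.drug["role_cod"].str.strip().str.upper() != "PS")
        & bundle.drug["primaryid"].isin(set(ids))]
    con_names = nonsusp["drugname"].str.strip().str.lower()
    for name in CONCOMITANT_DRUGS:
        with_drug = set(nonsusp.loc[con_names == name, "primaryid"])
        out[f"con_{name.replace(' ', '_')}"] = [
            int(i in with_drug) for i in ids]

    nonsusp_seq = set(zip(nonsusp["primaryid"], nonsusp["drug_seq"]))
    indi = bundle.indi[bundle.indi["primaryid"].isin(set(ids))]
    indi_nonsusp = indi[[(r, s) in nonsusp_seq for r, s in
                         zip(indi["primaryid"], indi["indi_drug_seq"])]]
    for disease, codes in DISEASE_PTS.items():
        with_dis = set(indi_nonsusp.loc[
            indi_nonsusp["indi_pt_code"].isin(codes), "primaryid"])
        out[f"dis_{disease}"] = [int(i in with_dis) for i in ids]
    return out.reset_index(drop=True)


def univariate_or(matrix: pd.DataFrame,
                  covariate: str) -> tuple[float, float, float, float]:
    """Cross-product odds ratio of the covariate x outcome 2x2 table with
    Woolf CI and Wald p-value.  NaNs when a stratum is empty."""
    x = matrix[covariate].astype(int)
    y = matrix["outcome"].astype(int)
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    if min(a, b, c, d) == 0:
        return (math.nan,) * 4
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(est) / se
    p = 2 * norm.sf(abs(z))
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), p


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    table: pd.DataFrame  # coef, se, or, ci_low, ci_high, p per covariate
    intercept: float
    intercept_se: float
    converged: bool
    n: int
    dropped: list = field(default_factory=list)

    @property
    def covariates(self) -> list[str]:
        return list(self.table.index)


def multivariate_fit(matrix: pd.DataFrame,
                     covariates: list[str] | None = None,
                     entry_p: float | None = None) -> LogisticFit:
    """Fit the multivariable logistic model by IRLS (statsmodels).

    Constant (no-information) covariates are dropped with a warning;
    ``entry_p`` optionally restricts entry to covariates with a
    univariate Wald p below the threshold.  Perfect separation raises
    :class:`SeparationError` naming an offending covariate.
    """
    covs = [c for c in (covariates or [c for c in matrix.columns
                                       if c != "outcome"])]
    if entry_p is not None:
        covs = [c for c in covs
                if (p := univariate_or(matrix, c)[3]) == p and p < entry_p]
    dropped = [c for c in covs if matrix[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"covariate {c!r} is constant; dropped from the fit",
                      stacklevel=2)
    covs = [c for c in covs if c not in dropped]
    aliased = _aliased_covariates(matrix, covs)
    for c in aliased:
        warnings.warn(f"covariate {c!r} is collinear with earlier columns; "
                      "dropped from the fit", stacklevel=2)
    dropped += aliased
    covs = [c for c in covs if c not in aliased]
    if len(matrix) <= 10 * len(covs):
        warnings.warn(f"only {len(matrix)} rows for {len(covs)} covariates; "
                      "estimates may be unstable", stacklevel=2)

    X = sm.add_constant(matrix[covs].astype(float), has_constant="add")
    y = matrix["outcome"].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error",
                                  sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", False):
                    raise np.linalg.LinAlgError("newton did not converge")
            except np.linalg.LinAlgError:
                # quasi-separated or ill-conditioned likelihoods can break
                # Newton's Hessian solve; L-BFGS handles them gracefully
                res = sm.Logit(y, X).fit(method="lbfgs", disp=0, maxiter=2000)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
        sep = _separating_covariate(matrix, covs)
        raise SeparationError(
            f"perfect separation (offending covariate: {sep})") from err

    params = res.params.drop("const")
    se = res.bse.drop("const")
    table = pd.DataFrame({
        "coef": params, "se": se, "or": np.exp(params),
        "ci_low": np.exp(params - Z95 * se),
        "ci_high": np.exp(params + Z95 * se),
        "p": res.pvalues.drop("const")})
    return LogisticFit(table=table, intercept=float(res.params["const"]),
                       intercept_se=float(res.bse["const"]),
                       converged=bool(res.mle_retvals.get("converged", True)),
                       n=len(matrix), dropped=dropped)


def _aliased_covariates(matrix: pd.DataFrame, covs: list[str],
                        tol: float = 1e-8) -> list[str]:
    """Covariates linearly dependent on the intercept and earlier columns
    (greedy left-to-right rank check via QR)."""
    n = len(matrix)
    basis = [np.ones(n)]
    aliased = []
    for c in covs:
        x = matrix[c].to_numpy(float)
        q, _ = np.linalg.qr(np.column_stack(basis))
        resid = x - q @ (q.T @ x)
        if np.linalg.norm(resid) < tol * max(1.0, np.linalg.norm(x)):
            aliased.append(c)
        else:
            basis.append(x)
    return aliased


def _separating_covariate(matrix: pd.DataFrame, covs: list[str]) -> str:
    y = matrix["outcome"].astype(int)
    for c in covs:
        x = matrix[c]
        tab = pd.crosstab(x, y)
        if (tab == 0).any().any():
            return c
    return "unknown"


@dataclass
class NomogramEntry:
    coef: float
    xmin: float
    xmax: float
    base: float   # min over the range of coef * x
    points_max: float

    def points(self, x: float) -> float:
        return (self.coef * x - self.base) * self._per_unit

    _per_unit: float = 0.0


@dataclass
class NomogramSpec:
    """Point scales per covariate plus the points -> probability mapping."""

    entries: dict
    base_lp: float       # intercept + sum of per-covariate minima
    scale: float         # largest contribution range = 100 points

    def total_points(self, profile: dict) -> float:
        missing = set(self.entries) - set(profile)
        if missing:
            raise ValueError(f"profile missing covariate(s) {sorted(missing)}")
        total = 0.0
        for name, e in self.entries.items():
            x = float(profile[name])
            if not e.xmin <= x <= e.xmax:
                raise ValueError(
                    f"{name}={x} outside nomogram range [{e.xmin}, {e.xmax}]")
            total += (e.coef * x - e.base) * 100.0 / self.scale
        return total

    def probability(self, total_points: float) -> float:
        return float(expit(self.base_lp + self.scale * total_points / 100.0))


def build_nomogram(fit: LogisticFit,
                   ranges: dict | None = None) -> NomogramSpec:
    """Derive the point scales from a converged fit.

    Each covariate's contribution range is |coef| * (xmax - xmin) (binary
    covariates span 0..1 by default); the largest range maps to exactly
    100 points.  Negative coefficients award their points at the low end
    of the covariate, keeping the points -> probability curve monotone.
    """
    if not fit.converged:
        raise ValueError("refusing to build a nomogram from an unconverged fit")
    ranges = ranges or {}
    entries: dict[str, NomogramEntry] = {}
    for name, coef in fit.table["coef"].items():
        xmin, xmax = ranges.get(name, (0.0, 1.0))
        lo, hi = sorted((coef * xmin, coef * xmax))
        entries[name] = NomogramEntry(coef=float(coef), xmin=xmin, xmax=xmax,
                                      base=lo, points_max=hi - lo)
    scale = max(e.points_max for e in entries.values())
    if scale <= 0:
        raise ValueError("all covariates have zero contribution range")
    for e in entries.values():
        e._per_unit = 100.0 / scale
        e.points_max = e.points_max * 100.0 / scale
    base_lp = fit.intercept + sum(e.base for e in entries.values())
    return NomogramSpec(entries=entries, base_lp=base_lp, scale=scale)


def predict_risk(nomogram: NomogramSpec, profile: dict) -> float:
    """Predicted probability for a covariate profile via the point scale;
    exactly reproduces the logistic model's prediction."""
    return nomogram.probability(nomogram.total_points(profile))


def predict_fit(fit: LogisticFit, profile: dict) -> float:
    """Direct model prediction (the round-trip reference for the nomogram)."""
    lp = fit.intercept + sum(fit.table.at[c, "coef"] * float(profile[c])
                             for c in fit.covariates)
    return float(expit(lp))
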