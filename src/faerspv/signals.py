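"""Disproportionality analysis on drug–event 2x2 tables.

Four estimators compare how often an event is reported with a drug
against the rest of the database, each with its conventional interval:

* **ROR** — reporting odds ratio ad/bc with a log-scale Wald 95% CI.
* **PRR** — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the
  Pearson chi-square (no continuity correction by default).
* **IC** — the BCPNN information component, a shrunk log2
  observed/expected ratio: IC = log2((a+0.5)/(E+0.5)) with
  IC025 = IC - 3.3(a+0.5)^-1/2 - 2(a+0.5)^-3/2, E = (a+b)(a+c)/N.
* **EBGM** — the multi-item gamma-Poisson shrinker: observed counts are
  modelled as Poisson with mean lambda*E and lambda drawn from a
  two-component gamma mixture prior fitted by maximum marginal likelihood
  over all drug–event pairs of the database.  EBGM = 2^{E[log2 lambda]}
  under the (conjugate gamma-mixture) posterior; EB05/EB95 are its
  posterior 5th/95th percentiles.

The joint signal criterion requires a >= 3, ROR lower CI > 1, PRR >= 2
with chi-square >= 4, IC025 > 0 and EB05 > 2; per-algorithm flags are
also reported individually.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import gamma as gamma_dist

from .io import QuarterBundle
from .preprocess import primary_suspect_map
from .smq import SmqDefinition, flag_cases, pt_case_sets

Z95 = 1.959963984540054


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug–event pair.

    a: drug & event; b: drug, no event; c: event, no drug; d: neither.
    Each cleaned report contributes to exactly one cell.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EstimatorError("negative cell count")
        if self.n == 0:
            raise EstimatorError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count under independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def build_table(event_ids: set, drug_ids: set,
                universe: set) -> ContingencyTable:
    """2x2 table partitioning the cleaned report universe."""
    if not universe:
        raise EstimatorError("empty report universe")
    ev = event_ids & universe
    dr = drug_ids & universe
    a = len(ev & dr)
    b = len(dr) - a
    c = len(ev) - a
    return ContingencyTable(a=a, b=b, c=c, d=len(universe) - a - b - c)


def ror(table: ContingencyTable,
        zero_correction: float | None = 0.5) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    A zero cell makes the estimate undefined; with ``zero_correction``
    set (default 0.5) the correction is added to every cell instead.
    Returns NaNs for an undefined result rather than raising.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if zero_correction is None:
            return (math.nan,) * 3
        a, b, c, d = (x + zero_correction for x in (a, b, c, d))
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def prr(table: ContingencyTable,
        yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square.

    chi2 = N(|ad-bc| - yates*N/2)^2 / [(a+b)(c+d)(a+c)(b+d)].
    Returns NaNs when a margin needed by the ratio is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if (a + b) == 0 or (c + d) == 0 or c == 0:
        return math.nan, math.nan
    est = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return est, math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff * diff / denom
    return est, chi2


def information_component(table: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its lower 2.5% credibility bound."""
    e = table.expected
    a5 = table.a + 0.5
    ic = math.log2(a5 / (e + 0.5))
    ic025 = ic - 3.3 * a5 ** -0.5 - 2.0 * a5 ** -1.5
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS / EBGM

@dataclass
class MgpsPrior:
    """Two-component gamma mixture prior lambda ~ p*Gamma(a1, b1) +
    (1-p)*Gamma(a2, b2) (shape/rate), fitted by maximum marginal
    likelihood."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    converged: bool = False
    loglik: float = -math.inf

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise EstimatorError("gamma hyperparameters must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise EstimatorError("mixture weight must lie in [0, 1]")

    def cdf(self, lam: float) -> float:
        return (self.p * gamma_dist.cdf(lam, self.alpha1, scale=1 / self.beta1)
                + (1 - self.p) * gamma_dist.cdf(lam, self.alpha2,
                                                scale=1 / self.beta2))


class MgpsConvergenceError(RuntimeError):
    def __init__(self, prior: MgpsPrior):
        super().__init__("MGPS prior fit did not converge from any start")
        self.best = prior


def _nb_logpmf(a, alpha, beta, e):
    """Marginal of a | Gamma(alpha, beta) prior and Poisson(lambda*e)."""
    a = np.asarray(a, float)
    e = np.asarray(e, float)
    return (gammaln(alpha + a) - gammaln(alpha) - gammaln(a + 1.0)
            + alpha * np.log(beta / (beta + e))
            + a * np.log(e / (beta + e)))


def mixture_loglik(theta: np.ndarray, a: np.ndarray,
                   e: np.ndarray) -> float:
    """Log marginal likelihood at theta = (log a1, log b1, log a2, log b2,
    logit p); parameters clamped to a wide but finite range for the
    optimizer's sake."""
    with np.errstate(all="ignore"):
        a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -25.0, 25.0))
        p = float(np.clip(expit(theta[4]), 1e-12, 1 - 1e-12))
        l1 = _nb_logpmf(a, a1, b1, e)
        l2 = _nb_logpmf(a, a2, b2, e)
        m = np.maximum(l1, l2)
        out = np.sum(m + np.log(p * np.exp(l1 - m)
                                + (1 - p) * np.exp(l2 - m)))
    return float(out) if np.isfinite(out) else -1e300


#: Deterministic multi-start grid around the classic gamma-Poisson
#: shrinker defaults (alpha1=0.2, beta1=0.1, alpha2=2, beta2=4, p=1/3).
_STARTS = [
    (0.2, 0.1, 2.0, 4.0, 1 / 3),
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 5.0, 5.0, 0.2),
    (2.0, 2.0, 0.2, 0.2, 0.5),
    (0.1, 0.1, 10.0, 10.0, 0.5),
    (1.0, 2.0, 2.0, 1.0, 0.8),
    (3.0, 3.0, 0.5, 1.0, 0.1),
    (0.2, 0.2, 1.0, 2.0, 0.9),
]


def fit_mgps(a, e, n_starts: int = 8) -> MgpsPrior:
    """Fit the mixture prior to all drug–event pairs of the database.

    Quasi-Newton (L-BFGS-B) on log/logit-transformed parameters from
    ``n_starts`` deterministic starting points; the best attained optimum
    wins.  Raises :class:`MgpsConvergenceError` carrying the best
    parameters if no start converges.
    """
    a = np.asarray(a, float)
    e = np.asarray(e, float)
    if a.size < 2:
        raise EstimatorError("MGPS needs at least 2 drug–event pairs")
    if np.any(e <= 0):
        raise EstimatorError("expected counts must be positive")

    best, best_val, any_ok = None, math.inf, False
    for start in _STARTS[:n_starts]:
        theta0 = np.array([math.log(start[0]), math.log(start[1]),
                           math.log(start[2]), math.log(start[3]),
                           logit(start[4])])
        res = minimize(lambda th: -mixture_loglik(th, a, e), theta0,
                       method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12,
                                "gtol": 1e-8})
        if res.fun < best_val:
            best, best_val = res, res.fun
            any_ok = any_ok or res.success
        else:
            any_ok = any_ok or res.success
    a1, b1, a2, b2 = np.exp(np.clip(best.x[:4], -25.0, 25.0))
    prior = MgpsPrior(alpha1=float(a1), beta1=float(b1), alpha2=float(a2),
                      beta2=float(b2), p=float(expit(best.x[4])),
                      converged=bool(any_ok), loglik=float(-best_val))
    if not any_ok:
        raise MgpsConvergenceError(prior)
    return prior


def _posterior(a: float, e: float, prior: MgpsPrior):
    """Posterior mixture: weights and updated (shape, rate) pairs."""
    l1 = float(_nb_logpmf(a, prior.alpha1, prior.beta1, e))
    l2 = float(_nb_logpmf(a, prior.alpha2, prior.beta2, e))
    w1 = prior.p * math.exp(l1 - max(l1, l2))
    w2 = (1 - prior.p) * math.exp(l2 - max(l1, l2))
    q1 = w1 / (w1 + w2)
    return ((q1, prior.alpha1 + a, prior.beta1 + e),
            (1 - q1, prior.alpha2 + a, prior.beta2 + e))


def ebgm(a: float, e: float,
         prior: MgpsPrior) -> tuple[float, float, float]:
    """Empirical Bayes geometric mean with (EB05, EB95) posterior interval.

    The posterior over lambda is an exact two-component gamma mixture;
    quantiles are obtained by root finding on its CDF.
    """
    if not prior.converged:
        raise EstimatorError("refusing EBGM from an unconverged MGPS prior")
    comps = _posterior(a, e, prior)
    meanlog = sum(q * (digamma(al) - math.log(be)) for q, al, be in comps)
    point = math.exp(meanlog)

    def cdf(x):
        return sum(q * gamma_dist.cdf(x, al, scale=1 / be)
                   for q, al, be in comps)

    active = [c for c in comps if c[0] > 0] or list(comps)
    lo = min(gamma_dist.ppf(1e-5, al, scale=1 / be)
             for _q, al, be in active) * 0.5
    hi = max(gamma_dist.ppf(1 - 1e-7, al, scale=1 / be)
             for _q, al, be in active) * 2 + 1.0
    qs = [brentq(lambda x: cdf(x) - level, max(lo, 1e-300), hi,
                 xtol=1e-12, rtol=8.9e-16) for level in (0.05, 0.95)]
    return point, qs[0], qs[1]


# ---------------------------------------------------------------------------
# signal detection over a cleaned bundle

@dataclass
class SignalThresholds:
    """Joint signal criterion (standard pharmacovigilance defaults)."""

    min_a: int = 3
    ror_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    eb05_min: float = 2.0
    yates: bool = False
    zero_correction: float | None = 0.5


@dataclass
class SignalFrame:
    """detect_signals output: one row per drug–event pair plus the fitted
    MGPS prior used for the EBGM column."""

    table: pd.DataFrame
    prior: MgpsPrior
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)


def database_pair_counts(bundle: QuarterBundle,
                         all_ps: pd.Series) -> pd.DataFrame:
    """(drug, pt, a, E) over every primary-suspect drug and PT in the
    database — the MGPS fitting set."""
    reac = bundle.reac[["primaryid", "pt_code"]].drop_duplicates()
    ps = all_ps.rename("drug").rename_axis("primaryid").reset_index()
    merged = reac.merge(ps, on="primaryid", how="inner")
    n = bundle.n_reports
    n_drug = ps.groupby("drug")["primaryid"].nunique()
    n_pt = reac.groupby("pt_code")["primaryid"].nunique()
    pairs = (merged.groupby(["drug", "pt_code"])["primaryid"].nunique()
             .rename("a").reset_index())
    pairs["e"] = (n_drug.loc[pairs["drug"]].to_numpy()
                  * n_pt.loc[pairs["pt_code"]].to_numpy() / n)
    return pairs


def full_primary_suspect_map(bundle: QuarterBundle,
                             synonyms: dict[str, str]) -> pd.Series:
    """Primary-suspect drug per report for the whole database: study drugs
    collapsed to generic names, everything else kept verbatim."""
    ps = bundle.drug[bundle.drug["role_cod"].str.strip().str.upper() == "PS"]
    names = ps["drugname"].str.strip().str.lower()
    mapped = names.map(synonyms).fillna(names)
    out = pd.Series(mapped.to_numpy(), index=ps["primaryid"].to_numpy(),
                    dtype=object)
    return out[~out.index.duplicated()]


def _estimate_row(table: ContingencyTable, prior: MgpsPrior,
                  th: SignalThresholds) -> dict:
    r, r_lo, r_hi = ror(table, zero_correction=th.zero_correction)
    p, chi2 = prr(table, yates=th.yates)
    ic, ic025 = information_component(table)
    g, g05, g95 = ebgm(table.a, max(table.expected, 1e-9), prior)
    sig_ror = table.a >= th.min_a and r_lo > th.ror_lower
    sig_prr = (not math.isnan(p)) and p >= th.prr_min and chi2 >= th.chi2_min
    sig_ic = ic025 > th.ic025_min
    sig_ebgm = g05 > th.eb05_min
    return {"a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "expected": table.expected,
            "ror": r, "ror_low": r_lo, "ror_high": r_hi,
            "prr": p, "chi2": chi2, "ic": ic, "ic025": ic025,
            "ebgm": g, "eb05": g05, "eb95": g95,
            "sig_ror": sig_ror, "sig_prr": sig_prr, "sig_ic": sig_ic,
            "sig_ebgm": sig_ebgm,
            "signal": bool(table.a >= th.min_a and sig_ror and sig_prr
                           and sig_ic and sig_ebgm)}


POOLED_LABEL = "ALK TKIs"


def detect_signals(bundle: QuarterBundle, synonyms: dict[str, str],
                   smq: SmqDefinition,
                   thresholds: SignalThresholds | None = None,
                   ) -> SignalFrame:
    """Run all four algorithms per study drug at SMQ level and per
    (study drug, PT) pair over a cleaned bundle."""
    th = thresholds or SignalThresholds()
    universe = set(bundle.demo["primaryid"])
    if not universe:
        raise EstimatorError("empty report universe")

    all_ps = full_primary_suspect_map(bundle, synonyms)
    pairs = database_pair_counts(bundle, all_ps)
    prior = fit_mgps(pairs["a"].to_numpy(), pairs["e"].to_numpy())

    study_map = primary_suspect_map(bundle, synonyms)
    drug_ids = {d: set(study_map.index[study_map == d])
                for d in sorted(study_map.unique())}
    drug_ids[POOLED_LABEL] = set(study_map.index)

    flags = flag_cases(bundle, smq)
    case_ids = set(flags.index[flags])
    rows = []
    for drug, ids in drug_ids.items():
        t = build_table(case_ids, ids, universe)
        rows.append({"drug": drug, "event": smq.smq_name, "level": "smq",
                     **_estimate_row(t, prior, th)})

    per_pt = pt_case_sets(bundle)
    study_ids = drug_ids[POOLED_LABEL]
    for drug in sorted(set(drug_ids) - {POOLED_LABEL}):
        ids = drug_ids[drug]
        for pt in sorted(per_pt):
            ev = per_pt[pt]
            if not ev & ids:
                continue
            t = build_table(ev, ids, universe)
            rows.append({"drug": drug, "event": pt, "level": "pt",
                         **_estimate_row(t, prior, th)})
    return SignalFrame(table=pd.DataFrame(rows), prior=prior, thresholds=th)
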