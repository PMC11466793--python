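"""Shared fixtures and independent numerical oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist

from faerspv.io import TABLE_COLUMNS, QuarterBundle, normalize_bundle
from faerspv.preprocess import clean
from faerspv.synthetic import simulate, study_config


def make_bundle(demo_rows, drug_rows=(), reac_rows=(), ther_rows=(),
                indi_rows=(), outc_rows=()) -> QuarterBundle:
    """Build a bundle from partial row dicts; unspecified raw fields are
    empty strings."""
    tables = {}
    for name, rows in (("demo", demo_rows), ("drug", drug_rows),
                       ("reac", reac_rows), ("ther", ther_rows),
                       ("indi", indi_rows), ("outc", outc_rows)):
        cols = TABLE_COLUMNS[name]
        data = [{c: str(r.get(c, "")) for c in cols} for r in rows]
        tables[name] = pd.DataFrame(data, columns=cols, dtype=str) \
            if data else pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
    return normalize_bundle(QuarterBundle(**tables))


def ebgm_quadrature(a: float, e: float, prior, ngrid: int = 20000):
    """Brute-force posterior oracle for the gamma-Poisson shrinker.

    Numerically integrates prior(lambda) x Poisson(a; lambda*e) on a log
    grid; returns the geometric mean and the 5th/95th posterior
    percentiles.  Independent of the analytic conjugate-mixture route.
    """
    lo = min(gamma_dist.ppf(1e-10, prior.alpha1 + a,
                            scale=1 / (prior.beta1 + e)),
             gamma_dist.ppf(1e-10, prior.alpha2 + a,
                            scale=1 / (prior.beta2 + e)))
    hi = max(gamma_dist.ppf(1 - 1e-10, prior.alpha1 + a,
                            scale=1 / (prior.beta1 + e)),
             gamma_dist.ppf(1 - 1e-10, prior.alpha2 + a,
                            scale=1 / (prior.beta2 + e)))
    u = np.linspace(np.log(max(lo, 1e-12)), np.log(hi), ngrid)
    lam = np.exp(u)
    logpost = np.logaddexp(
        np.log(prior.p) + gamma_dist.logpdf(lam, prior.alpha1,
                                            scale=1 / prior.beta1),
        np.log1p(-prior.p) + gamma_dist.logpdf(lam, prior.alpha2,
                                               scale=1 / prior.beta2)) \
        + a * np.log(lam * e) - lam * e + u  # + u: log-grid Jacobian
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    geo = float(np.exp(np.sum(w * u)))
    cum = np.cumsum(w) - 0.5 * w
    q05 = float(np.exp(np.interp(0.05, cum, u)))
    q95 = float(np.exp(np.interp(0.95, cum, u)))
    return geo, q05, q95


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic database under study conditions."""
    bundle, ledger = simulate(study_config(8000, seed=3))
    return bundle, ledger


@pytest.fixture(scope="session")
def small_cleaned(small_sim):
    bundle, ledger = small_sim
    cleaned, report = clean(bundle)
    return cleaned, report, ledger
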