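"""Small shared helpers (rounding conventions, resource paths)."""
from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources


def pct(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage with half-up rounding, the convention used in published
    spontaneous-report tables (e.g. 6.875% -> 6.9, not banker's 6.8)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def data_path(name: str):
    """Path to a bundled data file (context-manager free: files() traversable)."""
    return resources.files("faerspv.data").joinpath(name)


def load_reference_counts() -> dict:
    """Published marginal counts bundled for arithmetic-consistency checks."""
    with data_path("reference_counts.json").open() as fh:
        return json.load(fh)
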