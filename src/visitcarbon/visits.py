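"""The visit table: aggregated counts by (city, fiscal quarter, modality)."""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError
from .geography import QUARTERS

VISIT_COLUMNS = ["city", "fiscal_quarter", "modality", "count"]
MODALITIES = ("in-person", "virtual")


def validate_visit_table(visits: pd.DataFrame) -> None:
    """Check schema and invariants: positive counts, known quarters/modalities,
    unique (city, quarter, modality) keys."""
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValidationError(f"visit table missing columns: {sorted(missing)}")
    if len(visits) == 0:
        return
    if (visits["count"] < 1).any():
        raise ValidationError("visit counts must be positive integers")
    if (visits["count"] != visits["count"].astype(int)).any():
        raise ValidationError("visit counts must be integers")
    bad_q = set(visits["fiscal_quarter"]) - set(QUARTERS)
    if bad_q:
        raise ValidationError(f"unknown fiscal quarters: {sorted(bad_q)}")
    bad_m = set(visits["modality"]) - set(MODALITIES)
    if bad_m:
        raise ValidationError(f"unknown modalities: {sorted(bad_m)}")
    keys = visits[["city", "fiscal_quarter", "modality"]]
    if keys.duplicated().any():
        raise ValidationError("duplicate (city, quarter, modality) keys")


def read_visits(path) -> pd.DataFrame:
    visits = pd.read_csv(path)
    validate_visit_table(visits)
    return visits


def write_visits(visits: pd.DataFrame, path) -> None:
    validate_visit_table(visits)
    visits.to_csv(path, index=False)
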