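"""Bundled example data.

``published_consumption()`` returns 26-week broad-spectrum antibiotic
consumption totals (DDDs) from a published five-ward hospital surveillance
study that measured the same quantity two ways: pharmacy sales net of
returns, and weekly ward stock accounting.  Rows are ward x reporting class;
ward and grand totals are *not* included — they are meant to be computed by
summation.  Carbapenem cells in the urology wards are genuine zeros (no use).

``published_flow_totals()`` returns the study's 26-week non-consumption flow
totals in DDDs (discards, discharge take-aways, loans out, loans in).
"""

from __future__ import annotations

import pandas as pd

CLASSES = (
    "2nd generation cephalosporins",
    "3rd generation cephalosporins",
    "Carbapenems",
    "Ciprofloxacin parenteral",
    "Ciprofloxacin oral",
)

_ROWS = [
    # ward, class, pharmacy DDDs, ward DDDs
    ("pulmonary", CLASSES[0], 445.0, 432.5),
    ("pulmonary", CLASSES[1], 328.8, 360.3),
    ("pulmonary", CLASSES[2], 180.0, 171.0),
    ("pulmonary", CLASSES[3], 16.0, 26.4),
    ("pulmonary", CLASSES[4], 175.0, 204.0),
    ("gastro_infect", CLASSES[0], 205.0, 231.0),
    ("gastro_infect", CLASSES[1], 161.3, 152.5),
    ("gastro_infect", CLASSES[2], 103.0, 96.3),
    ("gastro_infect", CLASSES[3], 128.0, 130.0),
    ("gastro_infect", CLASSES[4], 280.0, 288.3),
    ("endo_haem", CLASSES[0], 125.0, 128.0),
    ("endo_haem", CLASSES[1], 101.3, 111.3),
    ("endo_haem", CLASSES[2], 80.0, 76.0),
    ("endo_haem", CLASSES[3], 52.0, 46.8),
    ("endo_haem", CLASSES[4], 310.0, 314.0),
    ("urology_1", CLASSES[0], 70.0, 62.5),
    ("urology_1", CLASSES[1], 46.3, 32.8),
    ("urology_1", CLASSES[2], 0.0, 0.0),
    ("urology_1", CLASSES[3], 124.0, 131.2),
    ("urology_1", CLASSES[4], 375.0, 346.3),
    ("urology_2", CLASSES[0], 72.5, 63.0),
    ("urology_2", CLASSES[1], 30.0, 19.0),
    ("urology_2", CLASSES[2], 0.0, 0.0),
    ("urology_2", CLASSES[3], 144.0, 144.4),
    ("urology_2", CLASSES[4], 425.0, 402.3),
]


def published_consumption() -> pd.DataFrame:
    """26-week DDD totals per ward x class, both measurement methods."""
    return pd.DataFrame(
        _ROWS, columns=["ward_id", "agent_class", "pharmacy_ddd", "ward_ddd"]
    )


def published_flow_totals() -> dict[str, float]:
    """26-week non-consumption flow totals (DDDs)."""
    return {
        "discard": 10.5,
        "discharge_takeaway": 18.0,
        "loan_out": 14.5,
        "loan_in": 9.0,
    }


def oral_classes() -> tuple[str, ...]:
    return (CLASSES[4],)


def parenteral_classes() -> tuple[str, ...]:
    return CLASSES[:4]
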