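"""Shared fixtures: acceptance-test measurement tables and small datasets.

The measurement tables are the published acceptance-test sheets for a
Carestream DRX detector (EI accuracy at 170 cm SID / 112 cm SCD with a
center-to-periphery ratio of 1.112) and the table phototimer calibrations
(target 1400 at acceptance; initial target 1600 vs final target 1400 on the
retrofit unit). They serve as fixed oracles: the printed derived columns
must be recoverable from the printed inputs.
"""

from __future__ import annotations

import pandas as pd
import pytest

from eiqc.calibration import EIAccuracyMeasurement, PhototimerMeasurement
from eiqc.ei import GeometrySpec
from eiqc.records import ExposureDataset

# (mas, chamber_mr, detector_mr, displayed_ei, calculated_ei, deviation, pct_error)
EI_ACCURACY_TABLE = [
    (1.0, 0.35, 0.169, 1328, 1228, 100, 8.2),
    (1.6, 0.64, 0.309, 1572, 1490, 82, 5.5),
    (2.0, 0.89, 0.429, 1703, 1633, 70, 4.3),
    (2.5, 1.20, 0.579, 1824, 1763, 61, 3.5),
    (3.2, 1.59, 0.767, 1943, 1885, 58, 3.1),
    (4.0, 2.04, 0.984, 2054, 1993, 61, 3.1),
    (5.0, 2.70, 1.303, 2173, 2115, 58, 2.8),
    (6.4, 3.46, 1.669, 2284, 2223, 61, 2.8),
]

#: mAs stations whose printed detector exposure is exact to 3 decimals
#: (the rest carry upstream rounding of the chamber reading).
EXACT_DETECTOR_ROWS = {1.0, 1.6, 2.5, 3.2, 5.0}
EXACT_EI_ROWS = {1.0, 1.6, 2.5, 3.2, 4.0}

# (phantom_cm, kvp, mas, displayed_ei, deviation, pct_error) at target 1400
PHOTOTIMER_TABLE = [
    (5, 50, 4.2, 1393, -7, -0.5),
    (7.5, 55, 4.5, 1398, -2, -0.1),
    (7.5, 65, 2.2, 1388, -12, -0.9),
    (12.5, 75, 3.0, 1401, 1, 0.1),
    (12.5, 85, 1.7, 1411, 11, 0.8),
    (12.5, 95, 1.2, 1437, 37, 2.6),
    (20, 110, 2.5, 1479, 79, 5.6),
    (20, 130, 1.5, 1496, 96, 6.9),
]

# (phantom_cm, kvp, initial_ei, initial_dev, final_ei, final_dev)
# initial target 1600, final target 1400
RECAL_TABLE = [
    (5, 50, 1579, -21, 1427, 27),
    (7.5, 55, 1562, -38, 1401, 1),
    (7.5, 65, 1537, -63, 1401, 1),
    (12.5, 75, 1540, -60, 1360, -40),
    (12.5, 85, 1518, -82, 1365, -35),
    (12.5, 95, 1491, -109, 1357, -43),
    (20, 110, 1532, -68, 1310, -90),
    (20, 130, 1551, -49, 1337, -63),
]

# 2015 per-protocol medians for the compliant integrated unit and the
# noncompliant retrofit unit, against the 1400±300 monthly band.
PROTOCOL_MEDIANS_COMPLIANT = {"chest": 1397, "abdomen": 1431, "knee": 1525, "wrist": 1570}
PROTOCOL_MEDIANS_NONCOMPLIANT = {
    "chest": 1758,
    "abdomen": 1614,
    "knee": 1758,
    "lspine": 1652,
    "hip": 1770,
}


@pytest.fixture
def acceptance_geometry() -> GeometrySpec:
    return GeometrySpec(sid_cm=170.0, scd_cm=112.0, center_periphery_ratio=1.112)


@pytest.fixture
def accuracy_measurements() -> list[EIAccuracyMeasurement]:
    return [EIAccuracyMeasurement(mas, chamber, displayed)
            for mas, chamber, _, displayed, *_ in EI_ACCURACY_TABLE]


@pytest.fixture
def phototimer_measurements() -> list[PhototimerMeasurement]:
    return [PhototimerMeasurement(cm, kvp, ei, mas=mas)
            for cm, kvp, mas, ei, *_ in PHOTOTIMER_TABLE]


@pytest.fixture
def recal_initial() -> list[PhototimerMeasurement]:
    return [PhototimerMeasurement(cm, kvp, ini) for cm, kvp, ini, _, _, _ in RECAL_TABLE]


@pytest.fixture
def recal_final() -> list[PhototimerMeasurement]:
    return [PhototimerMeasurement(cm, kvp, fin) for cm, kvp, _, _, fin, _ in RECAL_TABLE]


def make_dataset(rows: list[dict]) -> ExposureDataset:
    """Build a small in-memory dataset from partial row dicts."""
    if not rows:
        from eiqc.records import _empty_frame

        return ExposureDataset(_empty_frame())
    defaults = {
        "timestamp": pd.Timestamp("2015-01-15 08:00:00"),
        "unit_id": "A1",
        "department": "A",
        "body_part": "abdomen",
        "projection": "AP",
        "tech_id": "T01",
        "ei": 1400,
        "rejected": False,
        "reject_reason": None,
        "kvp": None,
        "mas": None,
    }
    df = pd.DataFrame([{**defaults, **row} for row in rows])
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    df["ei"] = df["ei"].astype("int64")
    df["rejected"] = df["rejected"].astype(bool)
    return ExposureDataset(df)


@pytest.fixture
def tiny_dataset() -> ExposureDataset:
    return make_dataset(
        [
            {"timestamp": "2014-11-30 23:59:00", "ei": 1600},
            {"timestamp": "2014-12-01 00:00:00", "ei": 1400},
            {"timestamp": "2014-12-15 12:00:00", "ei": 1450, "rejected": True,
             "reject_reason": "positioning"},
            {"timestamp": "2015-01-05 09:30:00", "ei": 1380, "unit_id": "A2",
             "body_part": "chest", "projection": "PA"},
        ]
    )
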