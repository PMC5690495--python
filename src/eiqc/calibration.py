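"""Detector acceptance-testing computations.

Two assessments are performed when a digital detector enters (or re-enters)
clinical service:

* **EI display accuracy** — the detector is exposed at several mAs stations,
  the exposure is measured with an ion chamber at the field periphery,
  referred to the detector plane by the geometric correction in
  :mod:`eiqc.ei`, and converted to a *calculated* EI. The EI *displayed* by
  the detector software (fixed-ROI readout on a uniform field) must agree
  with the calculated value within a percentage tolerance, 10% by default.

* **Phototimer (AEC) calibration** — the automatic exposure control is
  exercised over a ladder of Lucite phantom thicknesses and kVp stations and
  must land the displayed EI within a tolerance band around the institutional
  target EI (±150 by default). The manufacturer's ideal ±20 band is reported
  as an informational flag only; in practice AEC systems cannot hold it
  across all kVp and ±150 is the realistic acceptance band.

Measurement sheets are plain delimited text with headered columns; readers
and writers mirroring the assessment tables are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ei import GeometrySpec, detector_exposure_from_chamber, ei_from_exposure, round_ei

__all__ = [
    "EIAccuracyMeasurement",
    "EIAccuracyResult",
    "PhototimerMeasurement",
    "PhototimerResult",
    "CalibrationComparison",
    "assess_ei_accuracy",
    "assess_phototimer",
    "compare_calibrations",
    "read_accuracy_sheet",
    "read_phototimer_sheet",
    "accuracy_results_table",
    "phototimer_results_table",
]

IDEAL_AEC_TOLERANCE = 20  # manufacturer's ideal band, informational only


@dataclass(frozen=True)
class EIAccuracyMeasurement:
    """One EI-accuracy exposure: technique, chamber reading, displayed EI."""

    mas: float
    chamber_mr: float
    displayed_ei: int

    def __post_init__(self) -> None:
        if not self.mas > 0:
            raise ValueError(f"mas must be > 0, got {self.mas!r}")
        if not self.chamber_mr > 0:
            raise ValueError(f"chamber_mr must be > 0, got {self.chamber_mr!r}")


@dataclass(frozen=True)
class EIAccuracyResult:
    """Computed row of an EI-accuracy assessment.

    ``deviation`` is displayed minus rounded calculated EI (integer EI
    points); ``percent_error`` is the displayed-vs-calculated disagreement
    relative to the *unrounded* calculated EI, in percent.
    """

    measurement: EIAccuracyMeasurement
    detector_mr: float
    calculated_ei: float
    calculated_ei_rounded: int
    deviation: int
    percent_error: float
    passed: bool


@dataclass(frozen=True)
class PhototimerMeasurement:
    """One AEC exposure: phantom thickness, kVp, optional mAs, displayed EI."""

    phantom_cm: float
    kvp: float
    displayed_ei: int
    mas: float | None = None

    def __post_init__(self) -> None:
        if not 5 <= self.phantom_cm <= 20:
            raise ValueError(f"phantom_cm outside tested range [5, 20]: {self.phantom_cm!r}")
        if not 50 <= self.kvp <= 130:
            raise ValueError(f"kvp outside tested range [50, 130]: {self.kvp!r}")


@dataclass(frozen=True)
class PhototimerResult:
    """Computed row of an AEC calibration assessment against a target EI."""

    measurement: PhototimerMeasurement
    target_ei: int
    deviation: int
    percent_error: float
    within_tolerance: bool
    within_ideal: bool  # informational ±20 manufacturer band, never pass/fail


@dataclass(frozen=True)
class CalibrationComparison:
    """Paired initial-vs-final AEC calibration, keyed by (phantom_cm, kvp).

    ``table`` has one row per key with both displayed EIs, both deviations
    from their respective targets, and ``shift`` = final − initial displayed
    EI. ``mean_shift`` averages the shift over all keys.
    """

    table: pd.DataFrame
    initial_target: int
    final_target: int
    mean_shift: float


def assess_ei_accuracy(
    measurements: Sequence[EIAccuracyMeasurement],
    geom: GeometrySpec,
    tolerance_percent: float = 10.0,
) -> list[EIAccuracyResult]:
    """Assess displayed-EI accuracy against chamber measurements.

    For each row the chamber reading is referred to the detector plane,
    converted to a calculated EI, and compared with the displayed EI. A row
    passes when ``|percent_error| <= tolerance_percent`` (inclusive); the
    detector passes overall when every row passes.
    """
    if len(measurements) == 0:
        raise ValueError("assess_ei_accuracy requires at least one measurement")
    results = []
    for i, m in enumerate(measurements):
        if not isinstance(m, EIAccuracyMeasurement):
            raise TypeError(f"row {i}: expected EIAccuracyMeasurement, got {type(m).__name__}")
        detector_mr = detector_exposure_from_chamber(m.chamber_mr, geom)
        calc = ei_from_exposure(detector_mr)
        calc_rounded = round_ei(calc)
        deviation = int(m.displayed_ei) - calc_rounded
        percent_error = (m.displayed_ei - calc) / calc * 100.0
        results.append(
            EIAccuracyResult(
                measurement=m,
                detector_mr=detector_mr,
                calculated_ei=calc,
                calculated_ei_rounded=calc_rounded,
                deviation=deviation,
                percent_error=percent_error,
                passed=abs(percent_error) <= tolerance_percent,
            )
        )
    return results


def assess_phototimer(
    measurements: Sequence[PhototimerMeasurement],
    target_ei: int,
    tolerance: int = 150,
) -> list[PhototimerResult]:
    """Assess AEC performance against a target EI.

    Deviation is displayed minus target in EI points; percent error is
    deviation over target. ``within_tolerance`` is inclusive at
    ``|deviation| <= tolerance``; the informational ``within_ideal`` flag
    uses the manufacturer's ±20 band.
    """
    if len(measurements) == 0:
        raise ValueError("assess_phototimer requires at least one measurement")
    if not target_ei > 0:
        raise ValueError(f"target_ei must be > 0, got {target_ei!r}")
    results = []
    for m in measurements:
        deviation = int(m.displayed_ei) - int(target_ei)
        results.append(
            PhototimerResult(
                measurement=m,
                target_ei=int(target_ei),
                deviation=deviation,
                percent_error=deviation / target_ei * 100.0,
                within_tolerance=abs(deviation) <= tolerance,
                within_ideal=abs(deviation) <= IDEAL_AEC_TOLERANCE,
            )
        )
    return results


def compare_calibrations(
    initial: Sequence[PhototimerMeasurement],
    final: Sequence[PhototimerMeasurement],
    initial_target: int,
    final_target: int,
) -> CalibrationComparison:
    """Pair an initial and a final AEC calibration run, key by (phantom, kVp).

    Both runs must cover exactly the same (phantom_cm, kvp) stations; a
    mismatch raises with the offending keys listed. The returned table keeps
    station order of the initial run.
    """

    def keyed(ms: Iterable[PhototimerMeasurement]) -> dict[tuple[float, float], PhototimerMeasurement]:
        out: dict[tuple[float, float], PhototimerMeasurement] = {}
        for m in ms:
            key = (m.phantom_cm, m.kvp)
            if key in out:
                raise ValueError(f"duplicate calibration station {key}")
            out[key] = m
        return out

    ini, fin = keyed(initial), keyed(final)
    unmatched = sorted(set(ini) ^ set(fin))
    if unmatched:
        raise ValueError(f"unmatched calibration stations: {unmatched}")
    rows = []
    for key, mi in ini.items():
        mf = fin[key]
        rows.append(
            {
                "phantom_cm": key[0],
                "kvp": key[1],
                "initial_ei": mi.displayed_ei,
                "initial_deviation": mi.displayed_ei - initial_target,
                "final_ei": mf.displayed_ei,
                "final_deviation": mf.displayed_ei - final_target,
                "shift": mf.displayed_ei - mi.displayed_ei,
            }
        )
    table = pd.DataFrame(rows)
    return CalibrationComparison(
        table=table,
        initial_target=int(initial_target),
        final_target=int(final_target),
        mean_shift=float(table["shift"].mean()),
    )


# ---------------------------------------------------------------------------
# Measurement-sheet I/O (delimited text, headered columns matching the types)

def read_accuracy_sheet(path: str | Path, delimiter: str = ",") -> list[EIAccuracyMeasurement]:
    """Read an EI-accuracy sheet with columns mas, chamber_mr, displayed_ei."""
    df = pd.read_csv(path, sep=delimiter)
    missing = {"mas", "chamber_mr", "displayed_ei"} - set(df.columns)
    if missing:
        raise ValueError(f"accuracy sheet {path} missing columns: {sorted(missing)}")
    return [
        EIAccuracyMeasurement(float(r.mas), float(r.chamber_mr), int(r.displayed_ei))
        for r in df.itertuples()
    ]


def read_phototimer_sheet(path: str | Path, delimiter: str = ",") -> list[PhototimerMeasurement]:
    """Read an AEC sheet with columns phantom_cm, kvp, displayed_ei [, mas]."""
    df = pd.read_csv(path, sep=delimiter)
    missing = {"phantom_cm", "kvp", "displayed_ei"} - set(df.columns)
    if missing:
        raise ValueError(f"phototimer sheet {path} missing columns: {sorted(missing)}")
    has_mas = "mas" in df.columns
    return [
        PhototimerMeasurement(
            float(r.phantom_cm),
            float(r.kvp),
            int(r.displayed_ei),
            mas=float(r.mas) if has_mas and pd.notna(r.mas) else None,
        )
        for r in df.itertuples()
    ]


def accuracy_results_table(results: Sequence[EIAccuracyResult]) -> pd.DataFrame:
    """Tabulate EI-accuracy results in assessment-report column order."""
    return pd.DataFrame(
        {
            "mas": [r.measurement.mas for r in results],
            "chamber_mr": [r.measurement.chamber_mr for r in results],
            "detector_mr": [round(r.detector_mr, 3) for r in results],
            "displayed_ei": [r.measurement.displayed_ei for r in results],
            "calculated_ei": [r.calculated_ei_rounded for r in results],
            "deviation": [r.deviation for r in results],
            "percent_error": [round(r.percent_error, 1) for r in results],
            "passed": [r.passed for r in results],
        }
    )


def phototimer_results_table(results: Sequence[PhototimerResult]) -> pd.DataFrame:
    """Tabulate AEC assessment results in assessment-report column order."""
    return pd.DataFrame(
        {
            "phantom_cm": [r.measurement.phantom_cm for r in results],
            "kvp": [r.measurement.kvp for r in results],
            "mas": [r.measurement.mas for r in results],
            "displayed_ei": [r.measurement.displayed_ei for r in results],
            "deviation": [r.deviation for r in results],
            "percent_error": [round(r.percent_error, 1) for r in results],
            "within_tolerance": [r.within_tolerance for r in results],
            "within_ideal": [r.within_ideal for r in results],
        }
    )
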