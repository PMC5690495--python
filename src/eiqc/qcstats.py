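"""Distribution analytics over exposure-index samples.

The monthly QC review works from per-unit/per-protocol EI distributions:
summary moments (mean, median, SD, skewness, excess kurtosis), density
histograms normalized to unit area, the fraction of exposures inside the
institutional target range, reject rates, and per-month tracking series of a
location statistic.

The moment estimators deliberately follow the spreadsheet conventions used in
routine physics QC (sample SD with an n−1 denominator, the adjusted
Fisher–Pearson skewness, and the small-sample-corrected excess kurtosis) so
results are directly comparable with reviews done in a spreadsheet::

    s    = sqrt( Σ(x−x̄)² / (n−1) )
    g1'  = n/((n−1)(n−2)) · Σ((x−x̄)/s)³
    G2   = n(n+1)/((n−1)(n−2)(n−3)) · Σ((x−x̄)/s)⁴  −  3(n−1)²/((n−2)(n−3))

An estimator whose minimum sample size (or nonzero SD) is not met is reported
as absent rather than NaN-propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .records import ExposureDataset, filter_records, monthly_partition

__all__ = [
    "DistributionSummary",
    "EIHistogram",
    "TrackingSeries",
    "summarize",
    "histogram",
    "fraction_in_range",
    "reject_rate",
    "tracking_series",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_HIST_RANGE",
]

#: Default histogram bin width in EI points and EI range covered.
DEFAULT_BIN_WIDTH = 50.0
DEFAULT_HIST_RANGE = (500.0, 2600.0)


@dataclass(frozen=True)
class DistributionSummary:
    """Moments of an EI sample; fields are None below their minimum n."""

    n: int
    mean_ei: float
    median_ei: float
    sd_ei: float | None  # requires n >= 2
    skewness: float | None  # requires n >= 3 and sd > 0
    excess_kurtosis: float | None  # requires n >= 4 and sd > 0

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "mean_ei": self.mean_ei,
            "median_ei": self.median_ei,
            "sd_ei": self.sd_ei,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
        }


@dataclass(frozen=True)
class EIHistogram:
    """Density histogram of EI values: Σ density·width = 1.

    Out-of-range values are clipped into the end bins and counted in
    ``clipped_low`` / ``clipped_high`` rather than silently dropped.
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    n: int
    clipped_low: int = 0
    clipped_high: int = 0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def area(self) -> float:
        return float(np.sum(self.densities * np.diff(self.bin_edges)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "density": self.densities,
            }
        )


@dataclass(frozen=True)
class TrackingSeries:
    """Per-month location statistic for one unit/protocol.

    Months are strictly increasing; months with no records are omitted (and
    listed in ``skipped_months``).
    """

    unit: str | None
    body_part: str | None
    statistic: str
    months: tuple[pd.Period, ...]
    values: tuple[float, ...]
    counts: tuple[int, ...]
    skipped_months: tuple[pd.Period, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError("tracking-series months must be strictly increasing")

    def __len__(self) -> int:
        return len(self.months)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": [str(m) for m in self.months], self.statistic: self.values, "n": self.counts}
        )


def summarize(eis: Sequence[float] | np.ndarray) -> DistributionSummary:
    """Summary moments of an EI sample using the spreadsheet estimators."""
    x = np.asarray(eis, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("summarize requires a nonempty sample")
    mean = float(np.mean(x))
    median = float(np.median(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else None

    skew = kurt = None
    if sd is not None and sd > 0:
        z = (x - mean) / sd
        if n >= 3:
            skew = float(n / ((n - 1) * (n - 2)) * np.sum(z**3))
        if n >= 4:
            kurt = float(
                n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * np.sum(z**4)
                - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
            )
    return DistributionSummary(n, mean, median, sd, skew, kurt)


def histogram(
    eis: Sequence[float] | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] = DEFAULT_HIST_RANGE,
) -> EIHistogram:
    """Unit-area density histogram with left-closed, right-open bins.

    The range is covered by equal bins of ``bin_width`` (the last bin is
    shortened if the range is not an exact multiple, and closes on the
    right). Values outside the range are clipped into the end bins.
    """
    x = np.asarray(eis, dtype=float)
    if x.size == 0:
        raise ValueError("histogram requires a nonempty sample")
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width!r}")
    lo, hi = range
    if not hi > lo:
        raise ValueError(f"empty histogram range {range!r}")
    edges = np.arange(lo, hi, bin_width)
    edges = np.append(edges, hi)
    clipped_low = int(np.sum(x < lo))
    clipped_high = int(np.sum(x > hi))
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=edges)
    densities = counts / (x.size * np.diff(edges))
    return EIHistogram(
        bin_edges=edges,
        densities=densities,
        n=int(x.size),
        clipped_low=clipped_low,
        clipped_high=clipped_high,
    )


def fraction_in_range(eis: Sequence[float] | np.ndarray, target: float, tol: float) -> float:
    """Proportion of EI values in [target − tol, target + tol], inclusive."""
    x = np.asarray(eis, dtype=float)
    if x.size == 0:
        raise ValueError("fraction_in_range requires a nonempty sample")
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol!r}")
    return float(np.mean((x >= target - tol) & (x <= target + tol)))


def reject_rate(
    ds: ExposureDataset, by: Sequence[str] | None = None
) -> float | dict[Hashable, float]:
    """Reject (retake) rate overall or per group.

    ``by`` names record columns to group on (e.g. ``["unit_id",
    "body_part"]``). Groups with zero exposures cannot occur and are hence
    omitted; the overall rate of an empty dataset is an error.
    """
    df = ds.df
    if by is None:
        if df.empty:
            raise ValueError("reject rate of an empty dataset is undefined")
        return float(df["rejected"].mean())
    rates = df.groupby(list(by), sort=True)["rejected"].mean()
    return {k: float(v) for k, v in rates.items()}


def tracking_series(
    ds: ExposureDataset,
    unit: str | None = None,
    body_part: str | None = None,
    statistic: str = "median",
) -> TrackingSeries:
    """Per-month location statistic over accepted records of a unit/protocol.

    ``statistic`` is ``"median"`` (default, robust to the technique
    subpopulations) or ``"mean"``. Months inside the observed span with no
    accepted records are omitted from the series and reported in
    ``skipped_months``.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    sub = filter_records(ds, unit=unit, body_part=body_part, accepted_only=True)
    if len(sub) == 0:
        return TrackingSeries(unit, body_part, statistic, (), (), ())
    parts = monthly_partition(sub)
    months = list(parts)
    fn = np.median if statistic == "median" else np.mean
    values = tuple(float(fn(part.eis(accepted_only=True))) for part in parts.values())
    counts = tuple(len(part) for part in parts.values())
    full_span = pd.period_range(months[0], months[-1], freq="M")
    skipped = tuple(m for m in full_span if m not in parts)
    return TrackingSeries(unit, body_part, statistic, tuple(months), values, counts, skipped)
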