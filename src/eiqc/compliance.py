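"""Institutional compliance rules and the monthly QC report.

The institution fixes a target EI (1400 here) and two tolerance bands:

* **dataset band**, target ± 150 — the accuracy of a phototimer
  recalibration; a practice change is judged *effective* when the dataset
  mean EI lands inside it;
* **monthly band**, target ± 300 — twice the dataset variability, allowed
  because monthly per-protocol samples are small; a protocol is *on-target*
  when its monthly location statistic stays inside it.

The engine evaluates these bands (inclusive endpoints throughout), measures
the effect of an intervention as the before/after change in monthly medians
together with its implied relative exposure change, and assembles the whole
monthly feedback bundle: per-protocol summary tables, reject rates,
fraction-in-range, tracking series, compliance findings, and mixture
decompositions of out-of-range protocols.

The dataset-level rule uses the mean and monthly rules use the median by
default; both statistics are policy fields because practice varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ei import exposure_change_from_delta
from .mixture import DEFAULT_TARGET_LEDGER, MixtureFit, TargetAttribution, attribute_components, select_components
from .qcstats import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_HIST_RANGE,
    DistributionSummary,
    EIHistogram,
    TrackingSeries,
    fraction_in_range,
    histogram,
    reject_rate,
    summarize,
    tracking_series,
)
from .records import ExposureDataset, filter_records

__all__ = [
    "TargetPolicy",
    "ComplianceFinding",
    "InterventionEffect",
    "ReportOptions",
    "UnitReport",
    "QCReport",
    "dataset_compliance",
    "monthly_compliance",
    "intervention_effect",
    "build_report",
]


@dataclass(frozen=True)
class TargetPolicy:
    """Institutional target EI and its tolerance bands.

    By default the monthly band is twice the dataset band, reflecting the
    extra variability tolerated in small monthly samples.
    """

    target_ei: int = 1400
    dataset_tol: int = 150
    monthly_tol: int = 300
    dataset_statistic: str = "mean"
    monthly_statistic: str = "median"

    def __post_init__(self) -> None:
        if self.dataset_tol <= 0 or self.monthly_tol <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("dataset_statistic", "monthly_statistic"):
            if getattr(self, name) not in ("mean", "median"):
                raise ValueError(f"{name} must be 'mean' or 'median'")

    @property
    def dataset_bounds(self) -> tuple[int, int]:
        return (self.target_ei - self.dataset_tol, self.target_ei + self.dataset_tol)

    @property
    def monthly_bounds(self) -> tuple[int, int]:
        return (self.target_ei - self.monthly_tol, self.target_ei + self.monthly_tol)


@dataclass(frozen=True)
class ComplianceFinding:
    """One evaluated rule: a value against inclusive bounds.

    ``status`` is ``"effective"`` / ``"on-target"`` when the value lies
    inside the bounds (dataset / monthly scope respectively) and
    ``"out-of-range"`` otherwise.
    """

    scope: str
    statistic: str
    value: float
    lower: float
    upper: float
    status: str

    def __post_init__(self) -> None:
        inside = self.lower <= self.value <= self.upper
        if inside != (self.status != "out-of-range"):
            raise ValueError(f"status {self.status!r} inconsistent with value/bounds")

    @property
    def in_range(self) -> bool:
        return self.status != "out-of-range"


@dataclass(frozen=True)
class InterventionEffect:
    """Before/after medians across a practice change and the implied dose change."""

    before_median: float
    after_median: float

    @property
    def delta_ei(self) -> float:
        return self.after_median - self.before_median

    @property
    def exposure_change_fraction(self) -> float:
        return exposure_change_from_delta(self.delta_ei)


def dataset_compliance(summary: DistributionSummary, policy: TargetPolicy) -> ComplianceFinding:
    """Judge a dataset-level distribution effective or out-of-range."""
    stat = policy.dataset_statistic
    value = summary.mean_ei if stat == "mean" else summary.median_ei
    lo, hi = policy.dataset_bounds
    status = "effective" if lo <= value <= hi else "out-of-range"
    return ComplianceFinding("dataset", stat, float(value), lo, hi, status)


def monthly_compliance(
    series: TrackingSeries | Mapping[str, float] | Sequence[float],
    policy: TargetPolicy,
) -> tuple[list[ComplianceFinding], int]:
    """Judge each entry of a monthly (or per-protocol) series on-target.

    Accepts a :class:`TrackingSeries`, a mapping from label to location
    statistic, or a bare sequence of values. Returns the per-entry findings
    and the out-of-range count.
    """
    if isinstance(series, TrackingSeries):
        labeled = [(str(m), v) for m, v in zip(series.months, series.values)]
        stat = series.statistic
    elif isinstance(series, Mapping):
        labeled = [(str(k), float(v)) for k, v in series.items()]
        stat = policy.monthly_statistic
    else:
        labeled = [(f"entry-{i}", float(v)) for i, v in enumerate(series)]
        stat = policy.monthly_statistic
    if not labeled:
        raise ValueError("monthly_compliance requires at least one entry")
    lo, hi = policy.monthly_bounds
    findings = [
        ComplianceFinding(scope, stat, value, lo, hi, "on-target" if lo <= value <= hi else "out-of-range")
        for scope, value in labeled
    ]
    return findings, sum(not f.in_range for f in findings)


def intervention_effect(series: TrackingSeries, changepoint: str | pd.Period) -> InterventionEffect:
    """Quantify a practice change from a monthly tracking series.

    Months strictly before ``changepoint`` are "before"; the changepoint
    month and later are "after". Each side is summarized by the median of
    its monthly values; the EI drop converts to a relative exposure change
    via the log scale (a 200-point drop is roughly a 40% dose reduction).
    """
    cp = pd.Period(changepoint, freq="M")
    before = [v for m, v in zip(series.months, series.values) if m < cp]
    after = [v for m, v in zip(series.months, series.values) if m >= cp]
    if not before or not after:
        raise ValueError(
            f"changepoint {cp} leaves an empty side (before={len(before)}, after={len(after)})"
        )
    return InterventionEffect(float(np.median(before)), float(np.median(after)))


# ---------------------------------------------------------------------------
# Report assembly


@dataclass(frozen=True)
class ReportOptions:
    """Knobs for report assembly; defaults follow routine monthly review."""

    bin_width: float = DEFAULT_BIN_WIDTH
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE
    target_ledger: tuple[tuple[str, int], ...] = DEFAULT_TARGET_LEDGER
    mixture_k_max: int = 3
    mixture_min_n: int = 100  # don't decompose tiny protocols
    attribution_tol: float = 100.0


@dataclass
class UnitReport:
    """All findings for one X-ray unit."""

    unit_id: str
    n_records: int
    n_accepted: int
    protocol_table: pd.DataFrame  # protocol, n, median, sd, pct_of_dataset, status
    reject_rates: dict
    fraction_in_range: float | None
    dataset_findings: dict[str, ComplianceFinding]
    monthly_findings: dict[str, list[ComplianceFinding]]
    monthly_out_of_range: dict[str, int]
    tracking: dict[str, TrackingSeries]
    histograms: dict[str, EIHistogram]
    mixtures: dict[str, tuple[MixtureFit, TargetAttribution]]


@dataclass
class QCReport:
    """The full feedback bundle across units; deterministic for a given input."""

    policy: TargetPolicy
    options: ReportOptions
    units: dict[str, UnitReport] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.units

    def findings_frame(self) -> pd.DataFrame:
        """Machine-readable flat table of every compliance finding."""
        rows = []
        for unit_id in sorted(self.units):
            u = self.units[unit_id]
            for protocol in sorted(u.dataset_findings):
                f = u.dataset_findings[protocol]
                rows.append(
                    {
                        "unit": unit_id,
                        "protocol": protocol,
                        "scope": f.scope,
                        "statistic": f.statistic,
                        "value": f.value,
                        "lower": f.lower,
                        "upper": f.upper,
                        "status": f.status,
                    }
                )
            for protocol in sorted(u.monthly_findings):
                for f in u.monthly_findings[protocol]:
                    rows.append(
                        {
                            "unit": unit_id,
                            "protocol": protocol,
                            "scope": f.scope,
                            "statistic": f.statistic,
                            "value": f.value,
                            "lower": f.lower,
                            "upper": f.upper,
                            "status": f.status,
                        }
                    )
        return pd.DataFrame(
            rows, columns=["unit", "protocol", "scope", "statistic", "value", "lower", "upper", "status"]
        )

    def save(self, out_dir: str | Path, plots: bool = False) -> None:
        """Write the bundle as delimited-text tables (and optional plots)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.findings_frame().to_csv(out / "findings.csv", index=False)
        lines = [f"QC report — target EI {self.policy.target_ei}"]
        if self.empty:
            lines.append("no data")
        for unit_id in sorted(self.units):
            u = self.units[unit_id]
            u.protocol_table.to_csv(out / f"{unit_id}_protocols.csv", index=False)
            for protocol in sorted(u.tracking):
                u.tracking[protocol].to_frame().to_csv(
                    out / f"{unit_id}_{protocol}_tracking.csv", index=False
                )
            for protocol in sorted(u.histograms):
                u.histograms[protocol].to_frame().to_csv(
                    out / f"{unit_id}_{protocol}_histogram.csv", index=False
                )
            for protocol in sorted(u.mixtures):
                _, attribution = u.mixtures[protocol]
                attribution.to_frame().to_csv(
                    out / f"{unit_id}_{protocol}_mixture.csv", index=False
                )
            frac = "n/a" if u.fraction_in_range is None else f"{u.fraction_in_range:.1%}"
            lines.append(
                f"unit {unit_id}: {u.n_accepted}/{u.n_records} accepted, "
                f"fraction in target range {frac}, "
                f"{sum(u.monthly_out_of_range.values())} monthly out-of-range findings"
            )
            if plots:
                self._plot_unit(u, out)
        (out / "summary.txt").write_text("\n".join(lines) + "\n")

    def _plot_unit(self, u: UnitReport, out: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for protocol, hist in sorted(u.histograms.items()):
            fig, ax = plt.subplots(figsize=(7, 4))
            ax.stairs(hist.densities, hist.bin_edges, fill=True, alpha=0.6)
            lo, hi = self.policy.monthly_bounds
            ax.axvspan(lo, hi, color="green", alpha=0.1, label="monthly band")
            ax.axvline(self.policy.target_ei, color="k", ls="--", label="target EI")
            ax.set_xlabel("Exposure index")
            ax.set_ylabel("Density")
            ax.set_title(f"{u.unit_id} {protocol} (n={hist.n})")
            ax.legend()
            fig.savefig(out / f"{u.unit_id}_{protocol}_histogram.png", dpi=120)
            plt.close(fig)


def build_report(
    ds: ExposureDataset,
    policy: TargetPolicy | None = None,
    options: ReportOptions | None = None,
) -> QCReport:
    """Assemble the monthly QC feedback bundle for a dataset.

    Per unit: a protocol summary table (count, median, SD, share of the
    unit's accepted images), reject rates per protocol, the fraction of
    accepted EIs inside the monthly target band, per-protocol monthly
    tracking and compliance findings, density histograms, and — for
    protocols whose dataset statistic falls out of range — a BIC-selected
    mixture decomposition with target attribution. Deterministic: the same
    dataset and config produce identical tables.
    """
    policy = policy or TargetPolicy()
    options = options or ReportOptions()
    report = QCReport(policy=policy, options=options)
    df = ds.df
    if df.empty:
        return report

    for unit_id in sorted(df["unit_id"].unique()):
        unit_ds = filter_records(ds, unit=unit_id)
        accepted = unit_ds.accepted()
        unit_eis = accepted.eis()
        protocols = sorted(unit_ds.df["body_part"].unique())

        rows = []
        dataset_findings: dict[str, ComplianceFinding] = {}
        monthly_findings: dict[str, list[ComplianceFinding]] = {}
        monthly_oor: dict[str, int] = {}
        tracking: dict[str, TrackingSeries] = {}
        histograms: dict[str, EIHistogram] = {}
        mixtures: dict[str, tuple[MixtureFit, TargetAttribution]] = {}

        for protocol in protocols:
            proto_eis = filter_records(accepted, body_part=protocol).eis()
            if proto_eis.size == 0:
                continue
            summary = summarize(proto_eis)
            finding = dataset_compliance(summary, policy)
            dataset_findings[protocol] = finding
            series = tracking_series(unit_ds, unit=unit_id, body_part=protocol,
                                     statistic=policy.monthly_statistic)
            tracking[protocol] = series
            if len(series):
                findings, n_out = monthly_compliance(series, policy)
                monthly_findings[protocol] = findings
                monthly_oor[protocol] = n_out
            histograms[protocol] = histogram(proto_eis, options.bin_width, options.hist_range)
            rows.append(
                {
                    "protocol": protocol,
                    "n": summary.n,
                    "median_ei": summary.median_ei,
                    "sd_ei": summary.sd_ei,
                    "pct_of_dataset": 100.0 * summary.n / unit_eis.size if unit_eis.size else np.nan,
                    "status": finding.status,
                }
            )
            flagged = finding.status == "out-of-range" or monthly_oor.get(protocol, 0) > 0
            if flagged and proto_eis.size >= max(30, options.mixture_min_n):
                fit = select_components(proto_eis, k_max=options.mixture_k_max)
                attribution = attribute_components(fit, options.target_ledger, options.attribution_tol)
                mixtures[protocol] = (fit, attribution)

        report.units[unit_id] = UnitReport(
            unit_id=unit_id,
            n_records=len(unit_ds),
            n_accepted=len(accepted),
            protocol_table=pd.DataFrame(
                rows, columns=["protocol", "n", "median_ei", "sd_ei", "pct_of_dataset", "status"]
            ),
            reject_rates=reject_rate(unit_ds, by=["body_part"]) if len(unit_ds) else {},
            fraction_in_range=(
                fraction_in_range(unit_eis, policy.target_ei, policy.monthly_tol)
                if unit_eis.size
                else None
            ),
            dataset_findings=dataset_findings,
            monthly_findings=monthly_findings,
            monthly_out_of_range=monthly_oor,
            tracking=tracking,
            histograms=histograms,
            mixtures=mixtures,
        )
    return report
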