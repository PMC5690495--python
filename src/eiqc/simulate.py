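"""Seeded generator of synthetic exposure-event streams.

Real EI tracking data are mixtures of technique subpopulations: AEC exposures
cluster near the currently calibrated target EI while manual techniques
linger near historical targets (1800 from the CR era, 1600 from early DR
retrofits, 1400 after the final recalibration). The generator emulates
exactly that structure — per unit and protocol, each month's exposures are
drawn from a configured Gaussian mixture, rounded to integer EI and clipped
to [0, 3500]; reject flags, technologist IDs, projections and uniform
in-month timestamps complete the record. A recalibration or a behavioral
intervention is a *changepoint*: from a given month on, the protocol draws
from a different component list.

Every run returns both the dataset and a :class:`GenerationManifest` holding
the exact per-month/per-protocol/per-component counts and the parameters they
were drawn from. The manifest — not any published summary table — is the
ground truth downstream tests compare against.

A library of built-in scenarios models a two-department institution with one
integrated and one retrofit unit per department (A1/A2/B1/B2), abdomen and
chest protocols, and the 2014 (Jan–Nov 2014, target era 1600 on retrofits)
and 2015 (Dec 2014–May 2015, target 1400 everywhere) review windows. Volumes
match that situation's published per-window image counts; component weights
are plausible reconstructions, documented as approximate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import COLUMNS, ExposureDataset

__all__ = [
    "ComponentSpec",
    "ProtocolConfig",
    "UnitConfig",
    "ScenarioConfig",
    "GenerationManifest",
    "generate",
    "institution_scenario",
    "intervention_scenario",
    "INSTITUTION_UNITS",
    "INSTITUTION_YEARS",
    "INSTITUTION_PROTOCOLS",
]

EI_CLIP = (0, 3500)
_MIN_COMPONENT_SD = 20.0  # narrower than real technique scatter ever gets


@dataclass(frozen=True)
class ComponentSpec:
    """One technique subpopulation of a protocol's EI distribution."""

    label: str
    weight: float
    mean_ei: float
    sd_ei: float

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"component {self.label!r}: weight must be in (0, 1], got {self.weight}")
        if self.sd_ei < _MIN_COMPONENT_SD:
            raise ValueError(
                f"component {self.label!r}: sd_ei must be >= {_MIN_COMPONENT_SD}, got {self.sd_ei}"
            )


def _check_weights(components: Sequence[ComponentSpec], where: str) -> None:
    total = sum(c.weight for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{where}: component weights sum to {total}, not 1")


@dataclass
class ProtocolConfig:
    """One body-part protocol on one unit.

    ``monthly_volume`` is an integer count applied to every month, a mapping
    from month string (``"2014-03"``) to count, or a float Poisson rate.
    ``changepoints`` maps a month string to the component list in force from
    that month onward.
    """

    body_part: str
    monthly_volume: int | float | Mapping[str, int]
    components: list[ComponentSpec]
    projections: Mapping[str, float] = field(default_factory=lambda: {"AP": 1.0})
    changepoints: dict[str, list[ComponentSpec]] = field(default_factory=dict)

    def components_for(self, month: pd.Period) -> list[ComponentSpec]:
        active = self.components
        for cp_month in sorted(self.changepoints, key=lambda m: pd.Period(m, "M")):
            if pd.Period(cp_month, "M") <= month:
                active = self.changepoints[cp_month]
        return active

    def volume_for(self, month: pd.Period, rng: np.random.Generator) -> int:
        if isinstance(self.monthly_volume, Mapping):
            return int(self.monthly_volume.get(str(month), 0))
        if isinstance(self.monthly_volume, float):
            return int(rng.poisson(self.monthly_volume))
        return int(self.monthly_volume)


@dataclass
class UnitConfig:
    """One X-ray unit: identity plus its protocols."""

    unit_id: str
    department: str
    unit_type: str  # "integrated" or "retrofit"
    protocols: list[ProtocolConfig]


@dataclass
class ScenarioConfig:
    """A full generation scenario; seeded and fully reproducible."""

    units: list[UnitConfig]
    start_month: str
    n_months: int
    reject_prob: float = 0.08
    techs: Mapping[str, float] = field(
        default_factory=lambda: {f"T{i:02d}": 1 / 6 for i in range(1, 7)}
    )
    seed: int = 0

    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.n_months, freq="M")

    def validate(self) -> None:
        if self.n_months < 1:
            raise ValueError(f"n_months must be >= 1, got {self.n_months}")
        if not 0 <= self.reject_prob <= 1:
            raise ValueError(f"reject_prob must be in [0, 1], got {self.reject_prob}")
        if not self.techs or abs(sum(self.techs.values()) - 1.0) > 1e-9:
            raise ValueError("technologist roster weights must be nonempty and sum to 1")
        window = set(str(m) for m in self.months())
        for unit in self.units:
            for proto in unit.protocols:
                where = f"{unit.unit_id}/{proto.body_part}"
                if not proto.components:
                    raise ValueError(f"{where}: needs at least one component")
                _check_weights(proto.components, where)
                if not proto.projections or abs(sum(proto.projections.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{where}: projection weights must sum to 1")
                if isinstance(proto.monthly_volume, Mapping):
                    if any(v < 0 for v in proto.monthly_volume.values()):
                        raise ValueError(f"{where}: monthly volumes must be >= 0")
                elif proto.monthly_volume < 0:
                    raise ValueError(f"{where}: monthly_volume must be >= 0")
                for cp_month, comps in proto.changepoints.items():
                    if str(pd.Period(cp_month, "M")) not in window:
                        raise ValueError(f"{where}: changepoint {cp_month} outside the window")
                    _check_weights(comps, f"{where}@{cp_month}")

    # -- structured-text round trip -----------------------------------------
    def to_dict(self) -> dict:
        def comp(c: ComponentSpec) -> dict:
            return {"label": c.label, "weight": c.weight, "mean_ei": c.mean_ei, "sd_ei": c.sd_ei}

        return {
            "start_month": self.start_month,
            "n_months": self.n_months,
            "reject_prob": self.reject_prob,
            "techs": dict(self.techs),
            "seed": self.seed,
            "units": [
                {
                    "unit_id": u.unit_id,
                    "department": u.department,
                    "unit_type": u.unit_type,
                    "protocols": [
                        {
                            "body_part": p.body_part,
                            "monthly_volume": (
                                dict(p.monthly_volume)
                                if isinstance(p.monthly_volume, Mapping)
                                else p.monthly_volume
                            ),
                            "projections": dict(p.projections),
                            "components": [comp(c) for c in p.components],
                            "changepoints": {
                                m: [comp(c) for c in comps] for m, comps in p.changepoints.items()
                            },
                        }
                        for p in u.protocols
                    ],
                }
                for u in self.units
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        def comp(c: Mapping) -> ComponentSpec:
            return ComponentSpec(c["label"], c["weight"], c["mean_ei"], c["sd_ei"])

        units = [
            UnitConfig(
                unit_id=u["unit_id"],
                department=u["department"],
                unit_type=u["unit_type"],
                protocols=[
                    ProtocolConfig(
                        body_part=p["body_part"],
                        monthly_volume=p["monthly_volume"],
                        components=[comp(c) for c in p["components"]],
                        projections=p.get("projections", {"AP": 1.0}),
                        changepoints={
                            m: [comp(c) for c in comps]
                            for m, comps in p.get("changepoints", {}).items()
                        },
                    )
                    for p in u["protocols"]
                ],
            )
            for u in d["units"]
        ]
        return cls(
            units=units,
            start_month=d["start_month"],
            n_months=d["n_months"],
            reject_prob=d.get("reject_prob", 0.08),
            techs=d.get("techs", {f"T{i:02d}": 1 / 6 for i in range(1, 7)}),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GenerationManifest:
    """Exact ground truth of a generation run.

    ``counts`` has one row per (unit, body part, month, component) with the
    generated count and the component parameters in force; the manifest is
    the oracle every downstream statistical test compares against.
    """

    counts: pd.DataFrame
    config: ScenarioConfig

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    def count(
        self,
        unit: str | None = None,
        body_part: str | None = None,
        month: str | None = None,
    ) -> int:
        df = self.counts
        if unit is not None:
            df = df[df["unit_id"] == unit]
        if body_part is not None:
            df = df[df["body_part"] == body_part]
        if month is not None:
            df = df[df["month"] == month]
        return int(df["count"].sum())

    def _cell(self, unit: str, body_part: str, month: str | None) -> pd.DataFrame:
        df = self.counts
        df = df[(df["unit_id"] == unit) & (df["body_part"] == body_part)]
        if month is not None:
            df = df[df["month"] == month]
        return df

    def mixture_mean(self, unit: str, body_part: str, month: str | None = None) -> float:
        """Configured mixture mean, count-weighted over the selected cells."""
        df = self._cell(unit, body_part, month)
        w = df["weight"] * df.groupby("month")["count"].transform("sum") if month is None else df["weight"]
        # weight components by configured mixing fraction and month volume
        return float(np.average(df["mean_ei"], weights=w))

    def mixture_sd(self, unit: str, body_part: str, month: str | None = None) -> float:
        """Configured mixture SD (between- plus within-component spread)."""
        df = self._cell(unit, body_part, month)
        w = (df["weight"] * df.groupby("month")["count"].transform("sum")).to_numpy() if month is None else df["weight"].to_numpy()
        w = w / w.sum()
        mu = float(np.sum(w * df["mean_ei"]))
        second = float(np.sum(w * (df["sd_ei"] ** 2 + df["mean_ei"] ** 2)))
        return float(np.sqrt(second - mu**2))


_REJECT_REASONS = ("positioning", "exposure", "motion", "artifact")


def generate(config: ScenarioConfig) -> tuple[ExposureDataset, GenerationManifest]:
    """Generate an exposure-event stream and its ground-truth manifest.

    Fully reproducible from ``config.seed``: iteration order is fixed
    (units, then protocols, then months, in configured order), and every
    draw comes from one ``numpy`` generator. EIs are drawn per component,
    rounded half away from zero to integers, then clipped to [0, 3500].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tech_ids = list(config.techs)
    tech_w = np.array([config.techs[t] for t in tech_ids], dtype=float)
    tech_w = tech_w / tech_w.sum()

    rows: list[pd.DataFrame] = []
    manifest_rows: list[dict] = []
    for unit in config.units:
        for proto in unit.protocols:
            proj_ids = list(proto.projections)
            proj_w = np.array([proto.projections[p] for p in proj_ids], dtype=float)
            proj_w = proj_w / proj_w.sum()
            for month in config.months():
                volume = proto.volume_for(month, rng)
                comps = proto.components_for(month)
                weights = np.array([c.weight for c in comps])
                means = np.array([c.mean_ei for c in comps])
                sds = np.array([c.sd_ei for c in comps])
                idx = rng.choice(len(comps), size=volume, p=weights)
                raw = rng.normal(means[idx], sds[idx])
                ei = np.clip(np.sign(raw) * np.floor(np.abs(raw) + 0.5), *EI_CLIP).astype(np.int64)
                start = month.to_timestamp()
                span = (month + 1).to_timestamp() - start
                offsets = rng.uniform(0, span.total_seconds(), size=volume)
                rejected = rng.random(volume) < config.reject_prob
                reasons = rng.choice(_REJECT_REASONS, size=volume)
                counts = np.bincount(idx, minlength=len(comps))
                for c, cnt in zip(comps, counts):
                    manifest_rows.append(
                        {
                            "unit_id": unit.unit_id,
                            "body_part": proto.body_part,
                            "month": str(month),
                            "component": c.label,
                            "weight": c.weight,
                            "mean_ei": c.mean_ei,
                            "sd_ei": c.sd_ei,
                            "count": int(cnt),
                        }
                    )
                if volume == 0:
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "timestamp": start + pd.to_timedelta(offsets, unit="s").round("s"),
                            "unit_id": unit.unit_id,
                            "department": unit.department,
                            "body_part": proto.body_part,
                            "projection": rng.choice(proj_ids, size=volume, p=proj_w),
                            "tech_id": rng.choice(tech_ids, size=volume, p=tech_w),
                            "ei": ei,
                            "rejected": rejected,
                            "reject_reason": np.where(rejected, reasons, None),
                            "kvp": np.nan,
                            "mas": np.nan,
                        }
                    )
                )

    if rows:
        df = pd.concat(rows, ignore_index=True)[COLUMNS]
    else:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in {
            "timestamp": "datetime64[ns]", "unit_id": object, "department": object,
            "body_part": object, "projection": object, "tech_id": object,
            "ei": np.int64, "rejected": bool, "reject_reason": object,
            "kvp": float, "mas": float}.items()})
    manifest = GenerationManifest(
        counts=pd.DataFrame(
            manifest_rows,
            columns=["unit_id", "body_part", "month", "component", "weight", "mean_ei", "sd_ei", "count"],
        ),
        config=config,
    )
    ds = ExposureDataset(df, {"source": f"<generated seed={config.seed}>", "log": []})
    return ds, manifest


# ---------------------------------------------------------------------------
# Built-in institutional scenarios

INSTITUTION_UNITS = ("A1", "A2", "B1", "B2")
INSTITUTION_YEARS = (2014, 2015)
INSTITUTION_PROTOCOLS = ("abdomen", "chest")

#: Review windows: the "2014" dataset covers Jan–Nov 2014, the "2015" dataset
#: Dec 2014–May 2015 (the retrofit recalibration to target 1400 sits between).
_WINDOWS = {2014: ("2014-01", 11), 2015: ("2014-12", 6)}

#: Published per-window image counts for each unit/protocol cell.
_VOLUMES: dict[tuple[str, int, str], int] = {
    ("A1", 2014, "abdomen"): 2262, ("A2", 2014, "abdomen"): 4020,
    ("B1", 2014, "abdomen"): 576, ("B2", 2014, "abdomen"): 313,
    ("A1", 2015, "abdomen"): 1822, ("A2", 2015, "abdomen"): 2800,
    ("B1", 2015, "abdomen"): 381, ("B2", 2015, "abdomen"): 241,
    ("A1", 2014, "chest"): 5187, ("A2", 2014, "chest"): 7151,
    ("B1", 2014, "chest"): 4589, ("B2", 2014, "chest"): 2006,
    ("A1", 2015, "chest"): 5629, ("A2", 2015, "chest"): 5810,
    ("B1", 2015, "chest"): 2874, ("B2", 2015, "chest"): 1816,
}

#: Approximate component structure per cell: (label, weight, mean, sd).
#: Peak locations follow the narrated technique history (current AEC target,
#: legacy DR target 1600, CR-era 1800); weights are plausible, not published.
_COMPONENTS: dict[tuple[str, int, str], list[tuple[str, float, float, float]]] = {
    ("A1", 2014, "abdomen"): [("AEC-current-1400", 0.85, 1400, 170), ("manual-high", 0.15, 1700, 180)],
    ("A1", 2015, "abdomen"): [("AEC-current-1400", 0.88, 1400, 160), ("manual-high", 0.12, 1680, 170)],
    ("B1", 2014, "abdomen"): [("AEC-current-1400", 0.90, 1270, 190), ("manual-high", 0.10, 1600, 200)],
    ("B1", 2015, "abdomen"): [("AEC-current-1400", 0.88, 1330, 210), ("manual-high", 0.12, 1650, 200)],
    ("A2", 2014, "abdomen"): [("legacy-DR-1600", 0.90, 1670, 210), ("legacy-CR-1800", 0.10, 1820, 60)],
    ("A2", 2015, "abdomen"): [
        ("AEC-current-1400", 0.15, 1400, 120),
        ("legacy-DR-1600", 0.77, 1640, 210),
        ("legacy-CR-1800", 0.08, 1820, 60),
    ],
    ("B2", 2014, "abdomen"): [("legacy-DR-1600", 1.0, 1675, 195)],
    ("B2", 2015, "abdomen"): [("AEC-current-1400", 0.85, 1420, 200), ("legacy-DR-1600", 0.15, 1650, 220)],
    ("A1", 2014, "chest"): [("AEC-current-1400", 0.85, 1390, 170), ("manual-high", 0.15, 1730, 180)],
    ("A1", 2015, "chest"): [("AEC-current-1400", 0.87, 1385, 160), ("manual-high", 0.13, 1710, 170)],
    ("B1", 2014, "chest"): [("AEC-current-1400", 1.0, 1265, 125)],
    ("B1", 2015, "chest"): [("AEC-current-1400", 1.0, 1280, 115)],
    ("A2", 2014, "chest"): [("legacy-CR-1800", 0.90, 1800, 200), ("legacy-DR-1600", 0.10, 1550, 150)],
    ("A2", 2015, "chest"): [("legacy-CR-1800", 0.92, 1800, 180), ("AEC-current-1400", 0.08, 1250, 80)],
    ("B2", 2014, "chest"): [("legacy-DR-1600", 1.0, 1560, 168)],
    ("B2", 2015, "chest"): [("AEC-current-1400", 0.88, 1320, 150), ("legacy-DR-1600", 0.12, 1600, 180)],
}

_PROJECTIONS = {"abdomen": {"AP": 0.8, "LAT": 0.2}, "chest": {"PA": 0.7, "LAT": 0.3}}


def _spread_volume(total: int, months: pd.PeriodIndex) -> dict[str, int]:
    """Distribute a window total over months as evenly as integers allow."""
    n = len(months)
    base, extra = divmod(total, n)
    return {str(m): base + (1 if i < extra else 0) for i, m in enumerate(months)}


def institution_scenario(unit: str, year: int, protocol: str, seed: int = 0) -> ScenarioConfig:
    """Built-in scenario for one unit/window/protocol cell.

    The four units span two departments (A/B), one Carestream-integrated
    ("1") and one GE-retrofit ("2") unit each. Window volumes equal the
    published per-cell image counts; component means sit at the narrated
    technique targets while weights are documented best-effort choices —
    published skewness/kurtosis are *not* reproduced by construction.
    """
    key = (unit, year, protocol)
    if key not in _VOLUMES:
        raise KeyError(
            f"unknown scenario {key}; valid: units {INSTITUTION_UNITS}, "
            f"years {INSTITUTION_YEARS}, protocols {INSTITUTION_PROTOCOLS}"
        )
    start, n_months = _WINDOWS[year]
    months = pd.period_range(start, periods=n_months, freq="M")
    components = [ComponentSpec(*c) for c in _COMPONENTS[key]]
    proto = ProtocolConfig(
        body_part=protocol,
        monthly_volume=_spread_volume(_VOLUMES[key], months),
        components=components,
        projections=dict(_PROJECTIONS[protocol]),
    )
    unit_cfg = UnitConfig(
        unit_id=unit,
        department=unit[0],
        unit_type="integrated" if unit.endswith("1") else "retrofit",
        protocols=[proto],
    )
    cfg = ScenarioConfig(units=[unit_cfg], start_month=start, n_months=n_months, seed=seed)
    cfg.validate()
    return cfg


def intervention_scenario(
    base: ScenarioConfig,
    month: str,
    to_label: str,
    fraction: float = 1.0,
) -> ScenarioConfig:
    """Derive a scenario with a practice-change changepoint.

    From ``month`` onward, every protocol moves ``fraction`` of the weight
    of each legacy component onto the component labeled ``to_label`` (which
    must exist in the protocol). ``fraction=1`` collapses practice onto the
    target component; ``fraction=0`` is the identity and returns an
    unmodified copy.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    window = [str(m) for m in base.months()]
    if str(pd.Period(month, "M")) not in window:
        raise ValueError(f"changepoint month {month} outside window {window[0]}..{window[-1]}")
    out = copy.deepcopy(base)
    if fraction == 0:
        return out
    for unit in out.units:
        for proto in unit.protocols:
            comps = proto.components_for(pd.Period(month, "M") - 1)
            labels = [c.label for c in comps]
            if to_label not in labels:
                raise ValueError(
                    f"{unit.unit_id}/{proto.body_part}: no component labeled {to_label!r} "
                    f"(have {labels})"
                )
            moved = sum(c.weight * fraction for c in comps if c.label != to_label)
            shifted = []
            for c in comps:
                if c.label == to_label:
                    shifted.append(replace(c, weight=c.weight + moved))
                elif c.weight * (1 - fraction) > 1e-12:
                    shifted.append(replace(c, weight=c.weight * (1 - fraction)))
            proto.changepoints[str(pd.Period(month, "M"))] = shifted
    out.validate()
    return out
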