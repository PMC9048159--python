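"""Repeatability/stability statistics, tolerance verdicts and report output.

The QA programme repeats every test three times on one day (repeatability)
and monthly over a year (stability), and summarises each measured component
by its mean and standard deviation.  This module holds the shared
:class:`Measurement` record, the summary statistics (sample SD, ``ddof=1``
— the repeat counts are small, so the denominator choice matters and is
fixed here), tolerance rules with inclusive bounds, a simple least-squares
trend screen, and CSV/JSON/plot report rendering.

The trend screen is a numeric aid layered on top of the visual trend
inspection a physicist would do; it is off by default in reports and
labelled as a screening heuristic, not a formal test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .core import QAError

__all__ = [
    "Measurement",
    "SummaryStats",
    "ToleranceRule",
    "summarize",
    "apply_tolerance",
    "trend_screen",
    "render_report",
    "default_tolerances",
    "save_measurements",
    "load_measurements",
]


@dataclass
class Measurement:
    """One QA result value with its provenance."""

    test: str
    component: str
    value: float
    units: str
    session: str = ""
    timestamp: datetime | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timestamp"] = self.timestamp.isoformat() if self.timestamp else None
        return d

    @staticmethod
    def from_dict(d: dict) -> "Measurement":
        ts = d.get("timestamp")
        return Measurement(
            test=d["test"],
            component=d["component"],
            value=float(d["value"]),
            units=d.get("units", ""),
            session=d.get("session", ""),
            timestamp=datetime.fromisoformat(ts) if ts else None,
            meta=d.get("meta", {}),
        )


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float | None  # None when n == 1 (sample SD undefined)
    min: float
    max: float

    @property
    def range(self) -> float:
        return self.max - self.min


def summarize(values) -> SummaryStats:
    """Mean, sample SD (n-1 denominator), min/max/range of a value list."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise QAError("cannot summarise an empty value list")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
    return SummaryStats(n=int(v.size), mean=float(v.mean()), sd=sd, min=float(v.min()), max=float(v.max()))


# -- tolerance rules ------------------------------------------------------


@dataclass(frozen=True)
class ToleranceRule:
    """One of: value <= limit ("le"), value >= limit ("ge"),
    |value - target| <= band ("band"), or no rule ("none").
    All bounds are inclusive."""

    kind: str  # le | ge | band | none
    limit: float | None = None
    target: float | None = None
    band: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("le", "ge", "band", "none"):
            raise ValueError(f"unknown tolerance kind {self.kind!r}")
        if self.kind in ("le", "ge") and self.limit is None:
            raise ValueError("le/ge rules need a limit")
        if self.kind == "band" and (self.target is None or self.band is None):
            raise ValueError("band rules need target and band")

    def describe(self) -> str:
        if self.kind == "le":
            return f"<= {self.limit}"
        if self.kind == "ge":
            return f">= {self.limit}"
        if self.kind == "band":
            return f"{self.target} +/- {self.band}"
        return "-"


def apply_tolerance(value, rule: ToleranceRule) -> dict:
    """Return a verdict dict {value, rule, verdict} with verdict in
    {"pass", "fail", "none"}."""
    v = value.value if isinstance(value, Measurement) else (value.mean if isinstance(value, SummaryStats) else float(value))
    if rule.kind == "none":
        verdict = "none"
    elif rule.kind == "le":
        verdict = "pass" if v <= rule.limit else "fail"
    elif rule.kind == "ge":
        verdict = "pass" if v >= rule.limit else "fail"
    else:
        verdict = "pass" if abs(v - rule.target) <= rule.band else "fail"
    return {"value": v, "rule": rule.describe(), "verdict": verdict}


def default_tolerances() -> dict[str, ToleranceRule]:
    """Tolerances for the controlled component vocabulary: ACR-manual limits
    for the image-quality metrics, the 2 mm radiotherapy distortion limit
    for shells within 25 cm, +/- 2 mm for mechanical offsets; components
    without a recognised clinical tolerance carry no rule."""
    t: dict[str, ToleranceRule] = {}
    for s in ("T1", "T2"):
        t[f"Spatial Resolution ({s})"] = ToleranceRule("le", limit=1.0)
        t[f"Slice Thickness ({s})"] = ToleranceRule("band", target=5.0, band=0.7)
        t[f"Slice Position ({s})"] = ToleranceRule("le", limit=5.0)
        t[f"Image Uniformity ({s})"] = ToleranceRule("ge", limit=82.0)
        t[f"Ghosting ({s})"] = ToleranceRule("le", limit=3.0)
        t[f"Low-Contrast Detection ({s})"] = ToleranceRule("ge", limit=37.0)
    for seq in ("2D", "3D"):
        t[f"Distortion d<10cm ({seq})"] = ToleranceRule("le", limit=2.0)
        t[f"Distortion 10<=d<15cm ({seq})"] = ToleranceRule("le", limit=2.0)
        t[f"Distortion 15<=d<20cm ({seq})"] = ToleranceRule("le", limit=2.0)
        t[f"Distortion 20<=d<25cm ({seq})"] = ToleranceRule("le", limit=2.0)
        t[f"Distortion d>=25cm ({seq})"] = ToleranceRule("none")
    for comp in (
        "EL Right-Left Offset",
        "EL Ant-Post Offset",
        "EL Lateral Coincidence",
        "EL Movements",
        "EL-IL Right-Left Difference",
        "IL Sup-Inf Offset",
        "Couch Movements",
    ):
        t[comp] = ToleranceRule("band", target=0.0, band=2.0)
    for comp in ("EL Pitch Angle", "EL Roll Angle", "EL Yaw Angle"):
        t[comp] = ToleranceRule("none")
    for comp in (
        "Right-Left Difference",
        "Ant-Post Difference",
        "Sup-Inf Difference",
        "Pitch Angle",
        "Roll Angle",
        "Yaw Angle",
        "Nonane Difference",
        "Undecane Difference",
        "Tridecane Difference",
        "SUV Difference",
    ):
        t[comp] = ToleranceRule("none")
    return t


# -- trend screen ---------------------------------------------------------


@dataclass
class TrendResult:
    slope: float
    stderr: float
    flagged: bool
    note: str = "screening aid (OLS slope vs session index), not a formal trend test"


def trend_screen(values, min_n: int = 6) -> TrendResult:
    """OLS slope of value against session index; flag when |slope| > 2*SE."""
    v = np.asarray(list(values), dtype=float)
    if v.size < min_n:
        raise QAError(f"trend screen needs at least {min_n} sessions, got {v.size}")
    x = np.arange(v.size, dtype=float)
    n = v.size
    xm, vm = x.mean(), v.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (v - vm)) / sxx)
    resid = v - (vm + slope * (x - xm))
    s2 = float(np.sum(resid**2) / (n - 2)) if n > 2 else 0.0
    se = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    return TrendResult(slope=slope, stderr=se, flagged=abs(slope) > 2.0 * se)


# -- session persistence and reporting ------------------------------------


def save_measurements(measurements: list[Measurement], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([m.to_dict() for m in measurements], indent=1))
    return path


def load_measurements(path: str | Path) -> list[Measurement]:
    return [Measurement.from_dict(d) for d in json.loads(Path(path).read_text())]


def render_report(
    measurements: list[Measurement],
    out_dir: str | Path | None = None,
    tolerances: dict[str, ToleranceRule] | None = None,
    plots: bool = False,
    trend: bool = False,
) -> pd.DataFrame:
    """Summarise sessions into a table shaped like a QA summary sheet.

    One row per (test, component): n sessions, mean, sample SD, min, max,
    range, tolerance rule and verdict on the mean.  Raises on mixed units
    within a component.  Optionally writes CSV + JSON (and per-test trend
    plots) under ``out_dir``.
    """
    if not measurements:
        raise QAError("no measurements to report")
    tolerances = tolerances if tolerances is not None else default_tolerances()

    rows = []
    df = pd.DataFrame([m.to_dict() for m in measurements])
    for (test, component), grp in df.groupby(["test", "component"], sort=False):
        units = grp["units"].unique()
        if len(units) > 1:
            raise QAError(f"mixed units for component {component!r}: {sorted(units)}")
        stats = summarize(grp["value"].to_numpy())
        rule = tolerances.get(component, ToleranceRule("none"))
        verdict = apply_tolerance(stats, rule)
        row = {
            "test": test,
            "component": component,
            "units": units[0],
            "n": stats.n,
            "mean": stats.mean,
            "sd": stats.sd,
            "min": stats.min,
            "max": stats.max,
            "range": stats.range,
            "reference": rule.describe(),
            "verdict": verdict["verdict"],
        }
        if trend and stats.n >= 6:
            tr = trend_screen(grp["value"].to_numpy())
            row["trend_slope"] = tr.slope
            row["trend_flagged"] = tr.flagged
        rows.append(row)
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "summary.json").write_text(table.to_json(orient="records", indent=1))
        if plots:
            _write_trend_plots(df, out_dir)
    return table


def _write_trend_plots(df: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for test, grp in df.groupby("test"):
        fig, ax = plt.subplots(figsize=(7, 4))
        for component, cgrp in grp.groupby("component"):
            ax.plot(range(len(cgrp)), cgrp["value"].to_numpy(), marker="o", label=component)
        ax.set_xlabel("session index")
        ax.set_ylabel(grp["units"].iloc[0])
        ax.set_title(test)
        ax.legend(fontsize=7)
        fig.tight_layout()
        safe = "".join(c if c.isalnum() else "_" for c in test)
        fig.savefig(out_dir / f"trend_{safe}.png", dpi=100)
        plt.close(fig)
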