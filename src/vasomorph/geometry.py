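"""Annulus geometry of single arterial cross-sections.

An artery cut perpendicular to its axis appears on a histological section as
an annulus characterized by two calibrated lengths: the external diameter
(ED, to the outer media boundary) and the internal diameter (ID, the lumen).
Everything else used in arterial morphometry is derived from these two
measurements:

    WTh  = (ED - ID) / 2            wall (media) thickness
    WLR  = WTh / ID                 wall-to-lumen ratio (reported as %)
    MCSA = pi * (ED^2 - ID^2) / 4   media cross-sectional area
    LCSA = pi * ID^2 / 4            lumen cross-sectional area
    EP   = pi * ED                  external perimeter
    IP   = pi * ID                  internal perimeter

All lengths are in micrometres; no unit conversion happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VesselMeasurement",
    "AnnulusMetrics",
    "MeasurementError",
    "derive_metrics",
    "derive_metrics_frame",
    "filter_measurements",
    "FilterReport",
    "read_measurements_csv",
    "write_measurements_csv",
    "REQUIRED_COLUMNS",
]

#: columns required in a measurement table / CSV
REQUIRED_COLUMNS = ("vessel_id", "organ", "group", "ED_um", "ID_um")
#: optional axis columns enabling the ellipticity filter
AXIS_COLUMNS = ("long_axis_um", "short_axis_um")

DERIVED_COLUMNS = ("WTh_um", "WLR_pct", "MCSA_um2", "LCSA_um2", "EP_um", "IP_um")


class MeasurementError(ValueError):
    """Raised when a vessel record violates the annulus invariants."""


@dataclass(frozen=True)
class VesselMeasurement:
    """One measured arterial cross-section."""

    vessel_id: str
    organ: str
    group: str
    ed_um: float
    id_um: float
    long_axis_um: float | None = None
    short_axis_um: float | None = None

    def validate(self) -> None:
        if not (self.ed_um > 0):
            raise MeasurementError(f"vessel {self.vessel_id!r}: ED must be > 0, got {self.ed_um}")
        if self.id_um < 0:
            raise MeasurementError(f"vessel {self.vessel_id!r}: ID must be >= 0, got {self.id_um}")
        if self.id_um >= self.ed_um:
            raise MeasurementError(
                f"vessel {self.vessel_id!r}: ID ({self.id_um}) must be < ED ({self.ed_um})"
            )
        if (self.long_axis_um is None) != (self.short_axis_um is None):
            raise MeasurementError(
                f"vessel {self.vessel_id!r}: long and short axis must be given together"
            )
        if self.long_axis_um is not None and self.short_axis_um is not None:
            if not (self.long_axis_um >= self.short_axis_um > 0):
                raise MeasurementError(
                    f"vessel {self.vessel_id!r}: need long_axis >= short_axis > 0"
                )

    @property
    def axis_ratio(self) -> float | None:
        if self.long_axis_um is None or self.short_axis_um is None:
            return None
        return self.long_axis_um / self.short_axis_um


@dataclass(frozen=True)
class AnnulusMetrics:
    """Quantities derived from one (ED, ID) pair.

    ``wlr`` is stored as a ratio; ``wlr_pct`` is the conventional percentage.
    ``wlr`` is NaN when ID = 0 (undefined, flagged by ``wlr_defined``).
    """

    wth_um: float
    wlr: float
    mcsa_um2: float
    lcsa_um2: float
    ep_um: float
    ip_um: float
    wlr_defined: bool = True

    @property
    def wlr_pct(self) -> float:
        return self.wlr * 100.0


def derive_metrics(m: VesselMeasurement, *, printed_form: bool = False) -> AnnulusMetrics:
    """Compute the derived annulus quantities for a single vessel.

    Parameters
    ----------
    m
        The measurement; must satisfy the type invariants (``ID < ED`` etc.).
    printed_form
        Compatibility switch: compute MCSA as ``pi*(ED^2/2 - ID^2/2)``, the
        half-difference-of-squares form found in some reports, instead of the
        annulus area ``pi*(ED^2 - ID^2)/4``.  The two differ by a constant
        factor of 2, so every direction-of-change result is unaffected.
    """
    m.validate()
    ed, idv = m.ed_um, m.id_um
    wth = (ed - idv) / 2.0
    if idv > 0:
        wlr = wth / idv
        defined = True
    else:
        wlr = math.nan
        defined = False
    mcsa = math.pi * (ed**2 - idv**2) / (2.0 if printed_form else 4.0)
    lcsa = math.pi * idv**2 / 4.0
    return AnnulusMetrics(
        wth_um=wth,
        wlr=wlr,
        mcsa_um2=mcsa,
        lcsa_um2=lcsa,
        ep_um=math.pi * ed,
        ip_um=math.pi * idv,
        wlr_defined=defined,
    )


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"measurement table missing columns: {missing}")
    ed = df["ED_um"].to_numpy(float)
    idv = df["ID_um"].to_numpy(float)
    bad = ~((ed > 0) & (idv >= 0) & (idv < ed))
    if bad.any():
        rows = df.loc[bad, "vessel_id"].tolist()[:10]
        raise MeasurementError(
            f"{int(bad.sum())} record(s) violate 0 <= ID < ED (e.g. vessel_id {rows})"
        )


def derive_metrics_frame(df: pd.DataFrame, *, printed_form: bool = False) -> pd.DataFrame:
    """Vectorized :func:`derive_metrics`; returns a copy with derived columns.

    WLR is emitted as a percentage column ``WLR_pct`` (NaN where ID = 0).
    """
    _validate_frame(df)
    out = df.copy()
    ed = out["ED_um"].to_numpy(float)
    idv = out["ID_um"].to_numpy(float)
    wth = (ed - idv) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        wlr = np.where(idv > 0, wth / idv, np.nan)
    out["WTh_um"] = wth
    out["WLR_pct"] = wlr * 100.0
    out["MCSA_um2"] = np.pi * (ed**2 - idv**2) / (2.0 if printed_form else 4.0)
    out["LCSA_um2"] = np.pi * idv**2 / 4.0
    out["EP_um"] = np.pi * ed
    out["IP_um"] = np.pi * idv
    return out


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_measurements`."""

    n_input: int = 0
    n_retained: int = 0
    n_ed_below: int = 0
    n_ed_above: int = 0
    n_axis_ratio: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_ed_below": self.n_ed_below,
            "n_ed_above": self.n_ed_above,
            "n_axis_ratio": self.n_axis_ratio,
        }


def filter_measurements(
    df: pd.DataFrame,
    ed_range: tuple[float, float] = (10.0, 50.0),
    max_axis_ratio: float = 1.50,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the measurement-protocol filters.

    Retains records with ED inside the closed interval ``ed_range`` and, when
    the axis columns are present, long/short axis ratio strictly below
    ``max_axis_ratio`` (a section with ratio exactly 1.50 is excluded: the
    protocol is "< 1.50").  Returns the retained records and an exclusion
    count report.  An empty result is a warning condition for callers, not an
    error.
    """
    lo, hi = ed_range
    if not (0 < lo < hi):
        raise ValueError(f"ed_range must be a positive closed interval, got {ed_range}")
    if not max_axis_ratio > 1:
        raise ValueError("max_axis_ratio must exceed 1")
    _validate_frame(df)

    report = FilterReport(n_input=len(df))
    ed = df["ED_um"].to_numpy(float)
    below = ed < lo
    above = ed > hi
    keep = ~(below | above)
    report.n_ed_below = int(below.sum())
    report.n_ed_above = int(above.sum())

    if all(c in df.columns for c in AXIS_COLUMNS):
        la = df["long_axis_um"].to_numpy(float)
        sa = df["short_axis_um"].to_numpy(float)
        has_axes = ~(np.isnan(la) | np.isnan(sa))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = la / sa
        too_elliptic = has_axes & ~(ratio < max_axis_ratio)
        report.n_axis_ratio = int((too_elliptic & keep).sum())
        keep &= ~too_elliptic

    out = df.loc[keep].reset_index(drop=True)
    report.n_retained = len(out)
    return out, report


def read_measurements_csv(path) -> pd.DataFrame:
    """Read the standard measurement CSV (UTF-8, header required)."""
    df = pd.read_csv(path, encoding="utf-8")
    _validate_frame(df)
    df["vessel_id"] = df["vessel_id"].astype(str)
    return df


def write_measurements_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Iterable[VesselMeasurement]) -> pd.DataFrame:
    """Convert dataclass records to the standard measurement table."""
    rows = []
    for m in records:
        m.validate()
        rows.append(
            {
                "vessel_id": m.vessel_id,
                "organ": m.organ,
                "group": m.group,
                "ED_um": m.ed_um,
                "ID_um": m.id_um,
                "long_axis_um": m.long_axis_um,
                "short_axis_um": m.short_axis_um,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and df[list(AXIS_COLUMNS)].isna().all().all():
        df = df.drop(columns=list(AXIS_COLUMNS))
    return df
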