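"""Hemodynamic indices derived from taper fits and caliber frequencies.

Under Poiseuille flow with constant viscosity and segment length, the
resistance of a lumen of radius r is proportional to ``1/(pi r^4)``; the
package reports this *relative resistance* (RR, um^-4) along the fitted
taper and aggregates it over the terminal ED 10-20 um window (TRR), where
the accumulated frequency of vessels is largest and peripheral resistance
is regulated.

Two capacity estimates are provided.  The frequency-weighted sum

    TC = sum_i (pi * ID_i^2 / 4) * f_i

uses the bin frequencies of the complex profile (an area-weighted "capacity"
in arbitrary units: the frequencies make it sensitive to sampling).  The
truncated-cone convention instead evaluates the caliber limits only:

    TC  = pi*h*(IDlc^2 + IDlc*IDsc + IDsc^2)/3
    TMV = pi*h*(EDlc^2 + EDlc*EDsc + EDsc^2)/3 - TC

with the diameters written into the cone formula as printed in the source
protocol.  A ``radius_convention`` flag divides by 4, i.e. evaluates the
geometric volume of the cone of revolution; all comparative uses are
unaffected by the constant factor, which is surfaced in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import TaperFit

__all__ = [
    "relative_resistance",
    "terminal_relative_resistance",
    "terminal_capacity_profile",
    "terminal_capacity_cone",
    "hemo_summary",
    "HemoSummary",
]


def relative_resistance(fit: TaperFit, ed_grid) -> pd.DataFrame:
    """Poiseuille relative resistance RR(ED) = 1/(pi*(ID(ED)/2)^4) along a fit."""
    ed = np.asarray(ed_grid, float)
    idv = fit.predict_id(ed)
    if np.any(idv <= 0):
        bad = float(ed[np.argmax(idv <= 0)])
        raise ValueError(f"predicted ID <= 0 at ED = {bad:g} um; RR undefined there")
    r = idv / 2.0
    rr = 1.0 / (math.pi * r**4)
    return pd.DataFrame({"ED_um": ed, "ID_um": idv, "RR_per_um4": rr})


def terminal_relative_resistance(
    fit: TaperFit, terminal_range: tuple[float, float] = (10.0, 20.0), n_grid: int = 201
) -> float:
    """Mean RR over the terminal caliber window (fine-grid average)."""
    lo, hi = terminal_range
    if lo < fit.ed_range[0] - 1e-9 or hi > fit.ed_range[1] + 1e-9:
        raise ValueError(
            f"terminal range {terminal_range} outside fitted range {fit.ed_range}"
        )
    grid = np.linspace(lo, hi, n_grid)
    rr = relative_resistance(fit, grid)["RR_per_um4"].to_numpy()
    return float(rr.mean())


def terminal_capacity_profile(intervals: pd.DataFrame, fit: TaperFit | None = None) -> float:
    """Frequency-weighted terminal capacity (arbitrary area-weighted units).

    ``ID_i`` is the regression-predicted mean ID of each bin when a fit is
    supplied (the protocol's choice), otherwise the observed bin mean ID;
    ``f_i`` is the bin frequency, which must sum to 1.
    """
    if "frequency" not in intervals.columns:
        raise ValueError("interval table lacks frequencies")
    freq = intervals["frequency"].to_numpy(float)
    if not math.isclose(freq.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"bin frequencies sum to {freq.sum():.6f}, expected 1")
    if fit is not None:
        idv = fit.predict_id(intervals["mean_ED"].to_numpy(float))
    else:
        idv = intervals["mean_ID"].to_numpy(float)
    return float(np.sum(math.pi * idv**2 / 4.0 * freq))


def terminal_capacity_cone(
    fit: TaperFit,
    ed_limits: tuple[float, float] = (10.0, 50.0),
    radius_convention: bool = False,
) -> tuple[float, float]:
    """Truncated-cone terminal capacity and terminal media volume.

    ``ed_limits = (EDsc, EDlc)`` are the smallest/largest caliber limits;
    ``h = EDlc - EDsc`` is the caliber span.  The formulas are evaluated with
    diameters as printed (see module docstring); ``radius_convention``
    divides both by 4 to give geometric cone volumes.
    """
    ed_sc, ed_lc = ed_limits
    if not ed_lc > ed_sc:
        raise ValueError("need EDlc > EDsc")
    id_sc, id_lc = (float(fit.predict_id(e)) for e in (ed_sc, ed_lc))
    if id_sc <= 0 or id_lc <= 0:
        raise ValueError("fit predicts non-positive ID at a caliber limit")
    h = ed_lc - ed_sc
    scale = 0.25 if radius_convention else 1.0
    tc = scale * math.pi * h * (id_lc**2 + id_lc * id_sc + id_sc**2) / 3.0
    tmv = scale * math.pi * h * (ed_lc**2 + ed_lc * ed_sc + ed_sc**2) / 3.0 - tc
    if tmv < 0:
        raise ValueError("negative TMV: fit implies ID > ED inside the caliber window")
    return tc, tmv


@dataclass
class HemoSummary:
    """Per-bed hemodynamic report."""

    organ: str
    group: str
    trr: float
    tc_profile: float | None
    tc_cone: float
    tmv_cone: float
    ed_limits: tuple[float, float]
    h: float
    terminal_range: tuple[float, float]
    radius_convention: bool

    def as_dict(self) -> dict:
        return {
            "organ": self.organ,
            "group": self.group,
            "TRR_per_um4": self.trr,
            "TC_profile": self.tc_profile,
            "TC_cone": self.tc_cone,
            "TMV_cone": self.tmv_cone,
            "ed_limits": list(self.ed_limits),
            "h_um": self.h,
            "terminal_range": list(self.terminal_range),
            "radius_convention": self.radius_convention,
            "note": (
                "cone formulas use diameters as printed; radius_convention=True "
                "divides by 4 for geometric volumes"
            ),
        }


def hemo_summary(
    fit: TaperFit,
    intervals: pd.DataFrame | None = None,
    ed_limits: tuple[float, float] = (10.0, 50.0),
    terminal_range: tuple[float, float] = (10.0, 20.0),
    radius_convention: bool = False,
) -> HemoSummary:
    """Assemble TRR, TC (both conventions) and TMV for one bed."""
    trr = terminal_relative_resistance(fit, terminal_range)
    tc_prof = None
    if intervals is not None:
        tc_prof = terminal_capacity_profile(intervals, fit)
    tc, tmv = terminal_capacity_cone(fit, ed_limits, radius_convention)
    return HemoSummary(
        organ=fit.organ,
        group=fit.group,
        trr=trr,
        tc_profile=tc_prof,
        tc_cone=tc,
        tmv_cone=tmv,
        ed_limits=ed_limits,
        h=ed_limits[1] - ed_limits[0],
        terminal_range=terminal_range,
        radius_convention=radius_convention,
    )
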