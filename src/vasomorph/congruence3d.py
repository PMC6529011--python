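"""3D line-congruence recognition of remodeling variants.

A control vascular bed is represented by its tapering line in (ED, ID, WTh)
space.  Each remodeling variant generates from that line a one-parameter
family of transformed lines: the deviation parameter t in [0, 1] scales
"up" dimensions by ``1 + 3*g*t`` (up to +300% at full deviation) and "down"
dimensions by ``1 - 0.99*g*t`` (down to -99%), with per-variant gradient
coefficients g realizing the signed MCSA/WLR constraints of the variant's
signature, and with dimensions constrained to "same" (WTh, MCSA) enforced
exactly through the annulus identities.  Sampling the family over a t-grid
sweeps the variant's transformation surface.

A remodeled (e.g. hypertensive) tapering line is *congruent* with a variant
when it lies along ONE member line of the family over its whole length:
the distance to a variant is the minimum over t of the maximum over the
remodeled line's sample points of the distance to the t-slice curve.  This
slice-correspondence criterion is what makes the method identifying:
distance to the swept surface as a point set is not, because the union of
transformed lines from the whole control line covers a wide 2D region that
engulfs other variants' lines.

States with ID <= 0 or ID >= ED (the family leaving the geometrically
valid cone), and grid points whose recomputed directions no longer match
the variant's signature, are clipped out of the family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .regression import TaperFit
from .variants import (
    DOWN,
    SAME,
    UP,
    VariantCatalogue,
    VariantSignature,
    canonical_catalogue,
)

__all__ = [
    "TransformFamily",
    "Surface",
    "CongruenceResult",
    "make_transform",
    "build_surface",
    "build_all_surfaces",
    "test_congruence",
    "max_feasible_t",
    "simulate_2d_shifts",
    "surface_to_frame",
    "WIDEN_LIMIT",
    "NARROW_LIMIT",
]

#: deviation limits: +300% for widening/thickening, -99% for narrowing/thinning
WIDEN_LIMIT = 3.0
NARROW_LIMIT = 0.99


def _up(t: np.ndarray, g: float) -> np.ndarray:
    return 1.0 + WIDEN_LIMIT * g * t


def _down(t: np.ndarray, g: float) -> np.ndarray:
    return 1.0 - NARROW_LIMIT * g * t


def _ratio_range(control: TaperFit, ed_grid: np.ndarray) -> tuple[float, float]:
    """Range of ED/ID along the control line (drives adaptive gradients)."""
    idv = control.predict_id(ed_grid)
    if np.any(idv <= 0):
        raise ValueError("control fit predicts non-positive ID on the grid")
    r = ed_grid / idv
    return float(r.min()), float(r.max())


@dataclass(frozen=True)
class TransformFamily:
    """One variant's transformation of a control line.

    ``transform(E, I, t)`` maps control states to remodeled states for a
    scalar or array t; invalid states must be filtered by the caller (they
    come back as NaN or geometrically invalid values).
    """

    variant: int
    signature: VariantSignature
    transform: Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    gradients: dict = field(default_factory=dict)


def make_transform(
    variant: int,
    control: TaperFit | None = None,
    ed_grid: np.ndarray | None = None,
    swap_3_4: bool = False,
) -> TransformFamily:
    """Build the deviation family for one catalogue variant.

    The gradient coefficients of the subtype triples are chosen relative to
    the control line's ED/ID ratio range so the family realizes its signed
    MCSA/WLR constraints; without a control fit a typical terminal-artery
    ratio range (1.7-2.3) is assumed.
    """
    if control is not None:
        if ed_grid is None:
            ed_grid = np.linspace(*control.ed_range, 41)
        r_min, r_max = _ratio_range(control, np.asarray(ed_grid, float))
    else:
        r_min, r_max = 1.7, 2.3

    cat = canonical_catalogue(swap_3_4=swap_3_4)
    sig = cat.signature(variant) if variant != 0 else VariantSignature(SAME, SAME, SAME, SAME, SAME)

    # adaptive ratios: for #8/#11 the ID gradient must exceed the ED gradient
    # but by less than the smallest ED/ID ratio (keeps WTh moving with ED);
    # for #15 it must lie between the largest ratio and the smallest ratio
    # squared (ID collapse fast enough to thicken the wall, slow enough to
    # shrink the media).
    rho_mid = (1.0 + r_min) / 2.0
    # sit 80% of the way toward the upper bound: stronger ED contraction
    # separates the family best from the WTh-preserving and ED-fixed variants
    rho_15 = r_max + 0.8 * (r_min**2 - r_max)
    if not (r_max < r_min**2):
        rho_15 = (r_max + r_min**2) / 2.0  # infeasible control line; clipping will warn

    M = lambda E, I: E**2 - I**2
    g: dict = {}

    if variant == 0:
        f = lambda E, I, t: (E * np.ones_like(t * E), I * np.ones_like(t * I))
    elif variant == 1:
        g = {"g_ed": 1.0, "g_id": 1.0}
        f = lambda E, I, t: (E * _up(t, 1.0), I * _down(t, 1.0))
    elif variant == 2:
        g = {"g_ed": 1.0}
        f = lambda E, I, t: (E * _up(t, 1.0), I * np.ones_like(t * I))
    elif (variant == 3) != swap_3_4:  # MCSA preserved
        g = {"g_ed": 1.0, "constraint": "MCSA same"}

        def f(E, I, t):
            Eh = E * _up(t, 1.0)
            rad = Eh**2 - M(E, I)
            return Eh, np.where(rad > 0, np.sqrt(np.abs(rad)), np.nan)
    elif (variant == 4) != swap_3_4:  # MCSA reduced
        g = {"g_ed": 0.2, "g_mcsa": 1.0}

        def f(E, I, t):
            Eh = E * _up(t, 0.2)
            rad = Eh**2 - M(E, I) * _down(t, 1.0)
            return Eh, np.where(rad > 0, np.sqrt(np.abs(rad)), np.nan)
    elif variant == 5:  # WTh preserved
        g = {"g_ed": 1.0, "constraint": "WTh same"}
        f = lambda E, I, t: (E * _up(t, 1.0), E * _up(t, 1.0) - (E - I))
    elif variant == 6:
        g = {"g_ed": 1.0, "g_id": 0.6}
        f = lambda E, I, t: (E * _up(t, 1.0), I * _up(t, 0.6))
    elif variant == 7:  # proportional growth, WLR preserved
        g = {"g_ed": 1.0, "g_id": 1.0}
        f = lambda E, I, t: (E * _up(t, 1.0), I * _up(t, 1.0))
    elif variant == 8:
        g = {"g_ed": 0.7, "g_id": min(1.0, 0.7 * rho_mid)}

        def f(E, I, t, _g=g):
            return E * _up(t, _g["g_ed"]), I * _up(t, _g["g_id"])
    elif variant == 9:
        g = {"g_id": 1.0}
        f = lambda E, I, t: (E * np.ones_like(t * E), I * _down(t, 1.0))
    elif variant == 10:
        g = {"g_id": 1.0}
        f = lambda E, I, t: (E * np.ones_like(t * E), I * _up(t, 1.0))
    elif variant == 11:
        g = {"g_ed": 0.7, "g_id": min(1.0, 0.7 * rho_mid)}

        def f(E, I, t, _g=g):
            return E * _down(t, _g["g_ed"]), I * _down(t, _g["g_id"])
    elif variant == 12:  # proportional shrink, WLR preserved
        g = {"g_ed": 1.0, "g_id": 1.0}
        f = lambda E, I, t: (E * _down(t, 1.0), I * _down(t, 1.0))
    elif variant == 13:
        g = {"g_ed": 0.8, "g_id": 0.4}
        f = lambda E, I, t: (E * _down(t, 0.8), I * _down(t, 0.4))
    elif variant == 14:  # WTh preserved
        g = {"g_ed": 1.0, "constraint": "WTh same"}
        f = lambda E, I, t: (E * _down(t, 1.0), E * _down(t, 1.0) - (E - I))
    elif variant == 15:
        g = {"g_id": 0.95, "g_ed": 0.95 / rho_15}

        def f(E, I, t, _g=g):
            return E * _down(t, _g["g_ed"]), I * _down(t, _g["g_id"])
    elif (variant == 16):  # MCSA preserved (not part of the 3/4 swap)
        g = {"g_ed": 1.0, "constraint": "MCSA same"}

        def f(E, I, t):
            Eh = E * _down(t, 1.0)
            rad = Eh**2 - M(E, I)
            return Eh, np.where(rad > 0, np.sqrt(np.abs(rad)), np.nan)
    elif variant == 17:  # MCSA increased
        # mild media growth with a firmer caliber contraction: the lumen
        # headroom (ID^2 = ED^2 - MCSA-equivalent) caps the product of the
        # two rates, and the ED contraction is what distinguishes the family
        # from the ED-fixed hypertrophic variant
        g = {"g_ed": 0.25, "g_mcsa": 0.12}

        def f(E, I, t):
            Eh = E * _down(t, 0.25)
            rad = Eh**2 - M(E, I) * _up(t, 0.12)
            return Eh, np.where(rad > 0, np.sqrt(np.abs(rad)), np.nan)
    elif variant == 18:
        g = {"g_ed": 1.0}
        f = lambda E, I, t: (E * _down(t, 1.0), I * np.ones_like(t * I))
    elif variant == 19:
        g = {"g_ed": 0.5, "g_id": 0.5}
        f = lambda E, I, t: (E * _down(t, 0.5), I * _up(t, 0.5))
    else:
        raise ValueError(f"unknown variant {variant}")

    def transform(E, I, t):
        E = np.asarray(E, float)
        I = np.asarray(I, float)
        t = np.asarray(t, float)
        with np.errstate(invalid="ignore"):
            Eh, Ih = f(E, I, t)
        return Eh, Ih

    return TransformFamily(variant=variant, signature=sig, transform=transform, gradients=g)


def _signature_mask(
    E: np.ndarray, I: np.ndarray, Eh: np.ndarray, Ih: np.ndarray, sig: VariantSignature,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Mask of transformed states that are valid annuli AND match ``sig``."""
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = np.isfinite(Eh) & np.isfinite(Ih) & (Ih > 0) & (Ih < Eh)
        pairs = {
            "d_ed": (E, Eh),
            "d_id": (I, Ih),
            "d_wth": ((E - I) / 2, (Eh - Ih) / 2),
            "d_mcsa": (E**2 - I**2, Eh**2 - Ih**2),
            "d_wlr": ((E - I) / (2 * I), (Eh - Ih) / (2 * Ih)),
        }
        for fieldname, (a, b) in pairs.items():
            want = getattr(sig, fieldname)
            close = np.isclose(a, b, rtol=rtol, atol=rtol)
            if want == SAME:
                ok = close
            elif want == UP:
                ok = (b > a) & ~close
            else:
                ok = (b < a) & ~close
            valid &= ok
    return valid


@dataclass
class Surface:
    """A variant's transformation surface sampled on (ed_grid x t_grid).

    ``points`` has shape (n_t, n_ed, 3) holding (ED, ID, WTh); ``valid``
    masks clipped states.  The t = 0 slice reproduces the control line.
    """

    variant: int
    family: TransformFamily
    ed_grid: np.ndarray
    t_grid: np.ndarray
    points: np.ndarray
    valid: np.ndarray
    clipped_fraction: float

    def slice_points(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Ordered (ED, ID, WTh) samples of the i-th t-slice with validity mask."""
        return self.points[i], self.valid[i]

    def slice_at_t(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Recompute a slice curve at an arbitrary t (used for refinement)."""
        E = self.ed_grid
        I = self._control_id
        Eh, Ih = self.family.transform(E, I, np.full_like(E, t))
        mask = _signature_mask(E, I, Eh, Ih, self.family.signature) if t > 0 else np.isfinite(Eh)
        pts = np.column_stack([Eh, Ih, (Eh - Ih) / 2.0])
        return pts, mask

    # populated by build_surface
    _control_id: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_surface(
    control: TaperFit,
    variant: int,
    n_t: int = 121,
    ed_grid: np.ndarray | None = None,
    t_max: float = 1.0,
    t_min: float = 0.0,
    swap_3_4: bool = False,
    warn_clip: float = 0.5,
) -> Surface:
    """Sample one variant's transformation surface from a control fit.

    Grid points whose transformed state leaves the valid annulus cone or
    violates the variant's signature are clipped out; if more than
    ``warn_clip`` of the surface is clipped a warning reports the family as
    largely unrealizable for this control line.
    """
    if ed_grid is None:
        ed_grid = np.linspace(*control.ed_range, 41)
    ed_grid = np.asarray(ed_grid, float)
    fam = make_transform(variant, control, ed_grid, swap_3_4=swap_3_4)
    I = control.predict_id(ed_grid)
    if np.any(I <= 0):
        raise ValueError("control fit predicts non-positive ID on the grid")
    t_grid = np.linspace(t_min, t_max, n_t)

    TT, EE = np.meshgrid(t_grid, ed_grid, indexing="ij")
    II = np.broadcast_to(I, EE.shape)
    Eh, Ih = fam.transform(EE, II, TT)
    valid = _signature_mask(EE, II, Eh, Ih, fam.signature)
    valid[np.isclose(TT, 0.0)] = np.isfinite(Eh[np.isclose(TT, 0.0)])  # t=0 is the control line
    pts = np.stack([Eh, Ih, (Eh - Ih) / 2.0], axis=-1)

    clipped = 1.0 - valid.mean()
    if clipped > warn_clip:
        warnings.warn(
            f"variant {variant}: {clipped:.0%} of the family clipped "
            "(constraints largely unrealizable for this control line)",
            stacklevel=2,
        )
    surf = Surface(
        variant=variant,
        family=fam,
        ed_grid=ed_grid,
        t_grid=t_grid,
        points=pts,
        valid=valid,
        clipped_fraction=float(clipped),
    )
    surf._control_id = np.asarray(I, float)
    return surf


def build_all_surfaces(
    control: TaperFit,
    catalogue: VariantCatalogue | None = None,
    include_null: bool = True,
    **kwargs,
) -> dict[int, Surface]:
    """Surfaces for every catalogue variant (cacheable across congruence tests)."""
    catalogue = catalogue or canonical_catalogue()
    numbers = ([0] if include_null else []) + [e.number for e in catalogue]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in numbers:
            out[v] = build_surface(
                control, v, swap_3_4=catalogue.swap_3_4, **kwargs
            )
    return out


def max_feasible_t(
    control: TaperFit, variant: int, n_t: int = 201, ed_grid: np.ndarray | None = None,
    swap_3_4: bool = False,
) -> float:
    """Largest deviation t at which the whole ed-grid stays in the family."""
    surf = build_surface(
        control, variant, n_t=n_t, ed_grid=ed_grid, swap_3_4=swap_3_4, warn_clip=1.1
    )
    full = surf.valid.all(axis=1)
    if not full.any():
        return 0.0
    # first t index where the slice loses a point; everything before is feasible
    bad = np.nonzero(~full)[0]
    last = len(surf.t_grid) - 1 if len(bad) == 0 else max(bad[0] - 1, 0)
    return float(surf.t_grid[last])


# ---------------------------------------------------------------------------
# congruence testing


@dataclass
class CongruenceResult:
    """Per-variant congruence distances of a remodeled line.

    ``distances`` maps variant number to a record with the best deviation
    parameter, the mean/max distance (um) of the remodeled samples to the
    best-matching member line, and the standardized score used for the
    congruence decision.  ``congruent`` may be empty or contain several
    variants; ties are never broken silently -- ``ranking`` orders all
    variants by score.
    """

    distances: dict[int, dict]
    congruent: list[int]
    ranking: list[int]
    tolerance_um: float | None
    z: float
    shared_ed_range: tuple[float, float]

    @property
    def best(self) -> int:
        return self.ranking[0]

    def as_records(self) -> list[dict]:
        return [
            {"variant": v, **self.distances[v], "congruent": v in self.congruent}
            for v in self.ranking
        ]


def _slice_line_distance(
    pts_line: np.ndarray, pts_slice: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Per-line-point distance to a slice treated as a polyline.

    Distances are taken to the segments joining consecutive valid slice
    samples (plus the samples themselves), so slice discretization does not
    inflate the metric; gaps where the family was clipped break the
    polyline rather than being bridged.
    """
    pts = pts_slice[valid]
    if len(pts) == 0:
        return np.full(len(pts_line), np.inf)
    seg_ok = valid[:-1] & valid[1:]
    d2 = ((pts_line[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    best = d2.min(axis=1)
    if seg_ok.any():
        a = pts_slice[:-1][seg_ok]
        b = pts_slice[1:][seg_ok]
        ab = b - a
        denom = (ab**2).sum(-1)
        denom = np.where(denom > 0, denom, 1.0)
        ap = pts_line[:, None, :] - a[None, :, :]
        tt = np.clip((ap * ab[None, :, :]).sum(-1) / denom[None, :], 0.0, 1.0)
        closest = a[None, :, :] + tt[..., None] * ab[None, :, :]
        d2s = ((pts_line[:, None, :] - closest) ** 2).sum(-1)
        best = np.minimum(best, d2s.min(axis=1))
    return np.sqrt(best)


def test_congruence(
    control: TaperFit,
    remodeled: TaperFit,
    catalogue: VariantCatalogue | None = None,
    tolerance: float | None = None,
    z: float = 3.0,
    floor_frac: float = 0.01,
    t_min: float = 0.05,
    n_line: int = 21,
    n_t: int = 121,
    surfaces: Mapping[int, Surface] | None = None,
    ed_subrange: tuple[float, float] | None = None,
) -> CongruenceResult:
    """Which remodeling variants is a remodeled tapering line congruent with?

    The remodeled line is sampled over its own fitted ED range (optionally
    restricted to ``ed_subrange``, e.g. to analyze proximal/distal segments
    separately); for each variant the distance is the minimum over the
    deviation parameter t of the maximum over samples of the distance to
    the t-slice member line, refined locally around the best coarse t.

    The congruence decision is noise-aware by default: distances are
    standardized by ``sqrt(se_pred(x)^2 * 1.25 + floor^2)`` -- the remodeled
    fit's coefficient-based prediction SE inflated for the correlated WTh
    coordinate, floored at ``floor_frac`` of the mean control ID -- and a
    variant is congruent when its standardized max distance is <= ``z``.
    Passing an absolute ``tolerance`` (um) switches to the plain criterion
    ``max distance <= tolerance``.  Member lines with t < ``t_min`` are
    excluded for non-null variants (a line that close to control is the
    null family's claim); the null variant 0 (no remodeling) is always
    evaluated against the control line itself.
    """
    catalogue = catalogue or canonical_catalogue()

    lo = max(control.ed_range[0], remodeled.ed_range[0])
    hi = min(control.ed_range[1], remodeled.ed_range[1])
    if lo >= hi:
        raise ValueError("control and remodeled fits share no ED range")

    # sample the remodeled line over its data support extended by half the
    # point spacing (recovering the occupied bin edges) but never beyond the
    # fit's stated range: the caliber span of the remodeled bed is evidence
    # -- a variant must also map the control span onto it
    xs = np.sort(remodeled.id_fit.x)
    if len(xs) >= 2:
        ext = float(np.median(np.diff(xs))) / 2.0
        s_lo = max(remodeled.ed_range[0], float(xs[0]) - ext)
        s_hi = min(remodeled.ed_range[1], float(xs[-1]) + ext)
    else:
        s_lo, s_hi = remodeled.ed_range
    if ed_subrange is not None:
        s_lo, s_hi = max(s_lo, ed_subrange[0]), min(s_hi, ed_subrange[1])
        if s_lo >= s_hi:
            raise ValueError("ed_subrange does not intersect the remodeled fitted range")
    x = np.linspace(s_lo, s_hi, n_line)
    id_r = remodeled.predict_id(x)
    if np.any(id_r <= 0):
        raise ValueError("degenerate remodeled fit: predicted ID <= 0 on its range")
    wth_r = remodeled.predict_wth(x)
    line = np.column_stack([x, id_r, wth_r])

    mean_ctrl_id = float(np.mean(control.predict_id(np.linspace(lo, hi, 64))))
    floor = floor_frac * mean_ctrl_id
    se = remodeled.id_fit.se_predict(x)
    se_eff = np.sqrt(se**2 * 1.25 + floor**2)

    if surfaces is None:
        surfaces = build_all_surfaces(control, catalogue, n_t=n_t)

    def _score(pts_slice, valid):
        """Symmetric line<->member-line proximity, standardized.

        Forward: every remodeled sample must be near the member line.
        Reverse: every member-line sample must be near the remodeled line,
        so a member line longer than the observed caliber span (predicting
        vessels the bed does not contain) is penalized too.  In subrange
        mode the reverse term only sees the analyzed caliber window -- the
        rest of the bed is deliberately out of scope there.
        """
        d_f = _slice_line_distance(line, pts_slice, valid)
        sc = float((d_f / se_eff).max())
        pts = pts_slice[valid]
        if ed_subrange is not None and len(pts):
            pad = 0.5 * (s_hi - s_lo) / max(n_line - 1, 1)
            pts = pts[(pts[:, 0] >= s_lo - pad) & (pts[:, 0] <= s_hi + pad)]
        if len(pts):
            d_r = _slice_line_distance(pts, line, np.ones(len(line), bool))
            se_r = np.interp(pts[:, 0], x, se_eff)
            sc = max(sc, float((d_r / se_r).max()))
        return sc, d_f

    distances: dict[int, dict] = {}
    for v, surf in surfaces.items():
        best = (np.inf, np.inf, 0.0, None)  # score, max_d, t, per-point distances
        for i, t in enumerate(surf.t_grid):
            if v != 0 and t < t_min:
                continue
            score, d = _score(*surf.slice_points(i))
            if score < best[0]:
                best = (score, float(d.max()), float(t), d)
        # local refinement around the best coarse t
        if best[3] is not None and v != 0 and len(surf.t_grid) > 1:
            dt = surf.t_grid[1] - surf.t_grid[0]
            for t in np.linspace(max(best[2] - dt, t_min), min(best[2] + dt, surf.t_grid[-1]), 25):
                score, d = _score(*surf.slice_at_t(float(t)))
                if score < best[0]:
                    best = (score, float(d.max()), float(t), d)
        score, max_d, t_best, d = best
        distances[v] = {
            "best_t": t_best,
            "mean_distance_um": float(np.mean(d)) if d is not None else np.inf,
            "max_distance_um": max_d,
            "score": score,
        }

    ranking = sorted(distances, key=lambda v: distances[v]["score"])
    if tolerance is not None:
        congruent = [v for v in ranking if distances[v]["max_distance_um"] <= tolerance]
    else:
        congruent = [v for v in ranking if distances[v]["score"] <= z]
    return CongruenceResult(
        distances=distances,
        congruent=congruent,
        ranking=ranking,
        tolerance_um=tolerance,
        z=z,
        shared_ed_range=(lo, hi),
    )


test_congruence.__test__ = False  # a library operation, not a pytest case


# ---------------------------------------------------------------------------
# 2D line-shift simulation


_DERIVED_2D = {
    "ED": lambda E, I: E,
    "ID": lambda E, I: I,
    "WTh": lambda E, I: (E - I) / 2,
    "EP": lambda E, I: np.pi * E,
    "IP": lambda E, I: np.pi * I,
    "MCSA": lambda E, I: np.pi * (E**2 - I**2) / 4,
    "LCSA": lambda E, I: np.pi * I**2 / 4,
    "total_area": lambda E, I: np.pi * E**2 / 4,
    "WLR": lambda E, I: (E - I) / (2 * I),
    "EP_over_IP": lambda E, I: E / I,
    "MCSA_over_LCSA": lambda E, I: (E**2 - I**2) / I**2,
}


def simulate_2d_shifts(
    control: TaperFit,
    catalogue: VariantCatalogue | None = None,
    t: float = 0.3,
    ed_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Direction of every 2D regression-line displacement, per variant.

    For each catalogue variant the control line is transformed at deviation
    ``t`` and the displacement direction of each derived dimension (linear
    sizes, areas and their ratios, each plotted against caliber) is
    recorded.  The table demonstrates 2D non-identifiability: no single
    dimension separates all 19 variants, because only three directions are
    possible per axis.
    """
    catalogue = catalogue or canonical_catalogue()
    if ed_grid is None:
        ed_grid = np.linspace(*control.ed_range, 41)
    ed_grid = np.asarray(ed_grid, float)
    I = control.predict_id(ed_grid)

    rows = []
    for e in catalogue:
        fam = make_transform(e.number, control, ed_grid, swap_3_4=catalogue.swap_3_4)
        tt = np.full_like(ed_grid, t)
        Eh, Ih = fam.transform(ed_grid, I, tt)
        ok = np.isfinite(Eh) & np.isfinite(Ih) & (Ih > 0) & (Ih < Eh)
        row = {"variant": e.number}
        for dim, fn in _DERIVED_2D.items():
            if not ok.any():
                row[dim] = "clipped"
                continue
            a = fn(ed_grid[ok], I[ok])
            b = fn(Eh[ok], Ih[ok])
            close = np.isclose(a, b, rtol=1e-9, atol=1e-9)
            up = (b > a) & ~close
            down = (b < a) & ~close
            if close.all():
                row[dim] = SAME
            elif up.all():
                row[dim] = UP
            elif down.all():
                row[dim] = DOWN
            else:
                row[dim] = "mixed"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def surface_to_frame(surface: Surface) -> pd.DataFrame:
    """Long-format (variant, t, ED, ID, WTh) table for 3D plotting."""
    rows = []
    for i, t in enumerate(surface.t_grid):
        pts = surface.points[i][surface.valid[i]]
        for p in pts:
            rows.append(
                {"variant": surface.variant, "t": float(t), "ED_um": p[0], "ID_um": p[1], "WTh_um": p[2]}
            )
    return pd.DataFrame(rows)
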