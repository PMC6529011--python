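"""Numerical classification of arterial remodeling conformations.

A remodeling event takes an annulus from a control state ``(EDn, IDn)`` to a
remodeled state ``(EDhr, IDhr)``.  Its *signature* is the direction of
change -- up, same or down -- of each of the five dimensions (ED, ID, WTh,
MCSA, WLR).  Treating arteries as thick-walled cylinders whose ED and ID
move independently, exhaustive search shows exactly 20 distinct non-trivial
signatures are geometrically realizable: 9 with ED increased, 2 with ED
constant and 9 with ED decreased.  The canonical catalogue numbers 19 of
them (#1-19); the remaining feasible pattern, (up, up, down, MCSA up,
down), is reported as feasible-but-uncatalogued.  Within the catalogue,
three triples (#6-8, #11-13, #15-17) share the directions of ED/ID/WTh and
are told apart by the *gradient* of change, expressed in the WLR or MCSA
coordinate of the 5-tuple.

Because several scalar indices in common use (WLR direction, MCSA
direction, the remodeling index RI and growth index GI) take the same value
on many different signatures, they cannot identify a conformation; the
:func:`nonidentifiability_report` quantifies this many-to-one structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
import numpy as np

from .regression import TaperFit

__all__ = [
    "UP",
    "SAME",
    "DOWN",
    "VariantSignature",
    "CatalogueEntry",
    "VariantCatalogue",
    "canonical_catalogue",
    "EXTRA_FEASIBLE_SIGNATURE",
    "NO_REMODELING",
    "signature_of_change",
    "enumerate_feasible_signatures",
    "classify_signature",
    "InfeasibleSignatureError",
    "signature_from_fits",
    "remodeling_indices",
    "RemodelingIndices",
    "nonidentifiability_report",
    "NonIdentifiabilityReport",
]

UP, SAME, DOWN = "up", "same", "down"
_ARROWS = {UP: "↑", SAME: "=", DOWN: "↓"}
_FROM_ARROW = {"↑": UP, "=": SAME, "↔": SAME, "↓": DOWN, "-": SAME}

#: variant number used for the null "no remodeling" entry
NO_REMODELING = 0


class InfeasibleSignatureError(ValueError):
    """The 5-tuple is not realizable by any valid annulus pair."""


@dataclass(frozen=True)
class VariantSignature:
    """Direction of change of (ED, ID, WTh, MCSA, WLR).

    ``d_mcsa``/``d_wlr`` may be ``None`` to express a partial signature
    (gradient information unavailable); the classifier then returns the set
    of compatible catalogue entries.
    """

    d_ed: str
    d_id: str
    d_wth: str
    d_mcsa: str | None = None
    d_wlr: str | None = None

    def as_tuple(self) -> tuple:
        return (self.d_ed, self.d_id, self.d_wth, self.d_mcsa, self.d_wlr)

    @property
    def is_complete(self) -> bool:
        return self.d_mcsa is not None and self.d_wlr is not None

    @property
    def is_null(self) -> bool:
        return all(d == SAME for d in self.as_tuple())

    def arrows(self) -> str:
        return "".join("?" if d is None else _ARROWS[d] for d in self.as_tuple())

    @classmethod
    def from_arrows(cls, arrows: str) -> "VariantSignature":
        """Build from five arrow characters, e.g. ``"↓↓↑↓↑"`` (ED, ID, WTh, MCSA, WLR)."""
        if len(arrows) != 5:
            raise ValueError("need exactly five arrow characters (ED, ID, WTh, MCSA, WLR)")
        d = [_FROM_ARROW[a] for a in arrows]
        return cls(*d)


def _direction(before: float, after: float, rtol: float = 1e-9) -> str:
    if math.isclose(before, after, rel_tol=rtol, abs_tol=rtol):
        return SAME
    return UP if after > before else DOWN


def signature_of_change(
    ed_n: float, id_n: float, ed_hr: float, id_hr: float, rtol: float = 1e-9
) -> VariantSignature:
    """Exact signature of a control -> remodeled annulus transition."""
    for ed, idv, lbl in ((ed_n, id_n, "control"), (ed_hr, id_hr, "remodeled")):
        if not (0 < idv < ed):
            raise ValueError(f"{lbl} state ({ed}, {idv}) is not a valid annulus (0 < ID < ED)")
    wth_n, wth_h = (ed_n - id_n) / 2, (ed_hr - id_hr) / 2
    mcsa_n, mcsa_h = ed_n**2 - id_n**2, ed_hr**2 - id_hr**2  # common pi/4 dropped
    wlr_n, wlr_h = wth_n / id_n, wth_h / id_hr
    return VariantSignature(
        d_ed=_direction(ed_n, ed_hr, rtol),
        d_id=_direction(id_n, id_hr, rtol),
        d_wth=_direction(wth_n, wth_h, rtol),
        d_mcsa=_direction(mcsa_n, mcsa_h, rtol),
        d_wlr=_direction(wlr_n, wlr_h, rtol),
    )


# ---------------------------------------------------------------------------
# the canonical catalogue

#: the feasible pattern that the canonical 19-entry catalogue does not number
EXTRA_FEASIBLE_SIGNATURE = VariantSignature(UP, UP, DOWN, UP, DOWN)


@dataclass(frozen=True)
class CatalogueEntry:
    number: int
    signature: VariantSignature
    gradient_note: str = ""


@dataclass(frozen=True)
class VariantCatalogue:
    """The ordered 19-variant catalogue plus the null (no change) entry."""

    entries: tuple[CatalogueEntry, ...]
    swap_3_4: bool = False

    def __post_init__(self):
        if len(self.entries) != 19:
            raise ValueError("catalogue must have exactly 19 entries")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def entry(self, number: int) -> CatalogueEntry:
        for e in self.entries:
            if e.number == number:
                return e
        raise KeyError(number)

    def signature(self, number: int) -> VariantSignature:
        return self.entry(number).signature

    def numbers_with(self, **directions) -> list[int]:
        """Entries whose signature matches every given field, e.g. d_wlr=UP."""
        out = []
        for e in self.entries:
            if all(getattr(e.signature, k) == v for k, v in directions.items()):
                out.append(e.number)
        return out

    def as_records(self) -> list[dict]:
        return [
            {
                "variant": e.number,
                "d_ED": e.signature.d_ed,
                "d_ID": e.signature.d_id,
                "d_WTh": e.signature.d_wth,
                "d_MCSA": e.signature.d_mcsa,
                "d_WLR": e.signature.d_wlr,
                "arrows": e.signature.arrows(),
                "gradient_note": e.gradient_note,
            }
            for e in self.entries
        ]


def canonical_catalogue(swap_3_4: bool = False) -> VariantCatalogue:
    """The fixed 19-variant catalogue.

    Variants #3/#4 share (ED up, ID up, WTh down, WLR down) and differ in the
    MCSA coordinate; by default #4 carries MCSA down (so classification of a
    distended-thinned bed with reduced MCSA reports 4) and #3 carries MCSA
    preserved.  ``swap_3_4`` exchanges the two numbers for users following
    the opposite convention.
    """
    g68 = "gradient subtype: ED vs ID growth rate sets the WLR direction"
    g1113 = "gradient subtype: ED vs ID shrink rate sets the WLR direction"
    g1517 = "gradient subtype: ED vs ID shrink rate sets the MCSA direction"
    mcsa3, mcsa4 = (DOWN, SAME) if swap_3_4 else (SAME, DOWN)
    note3 = "lumen distension with wall thinning; MCSA " + (
        "reduced" if swap_3_4 else "preserved"
    )
    note4 = "lumen distension with wall thinning; MCSA " + (
        "preserved" if swap_3_4 else "reduced"
    )
    e = [
        CatalogueEntry(1, VariantSignature(UP, DOWN, UP, UP, UP)),
        CatalogueEntry(2, VariantSignature(UP, SAME, UP, UP, UP)),
        CatalogueEntry(3, VariantSignature(UP, UP, DOWN, mcsa3, DOWN), note3),
        CatalogueEntry(4, VariantSignature(UP, UP, DOWN, mcsa4, DOWN), note4),
        CatalogueEntry(5, VariantSignature(UP, UP, SAME, UP, DOWN)),
        CatalogueEntry(6, VariantSignature(UP, UP, UP, UP, UP), g68),
        CatalogueEntry(7, VariantSignature(UP, UP, UP, UP, SAME), g68),
        CatalogueEntry(8, VariantSignature(UP, UP, UP, UP, DOWN), g68),
        CatalogueEntry(9, VariantSignature(SAME, DOWN, UP, UP, UP)),
        CatalogueEntry(10, VariantSignature(SAME, UP, DOWN, DOWN, DOWN)),
        CatalogueEntry(11, VariantSignature(DOWN, DOWN, DOWN, DOWN, UP), g1113),
        CatalogueEntry(12, VariantSignature(DOWN, DOWN, DOWN, DOWN, SAME), g1113),
        CatalogueEntry(13, VariantSignature(DOWN, DOWN, DOWN, DOWN, DOWN), g1113),
        CatalogueEntry(14, VariantSignature(DOWN, DOWN, SAME, DOWN, UP)),
        CatalogueEntry(15, VariantSignature(DOWN, DOWN, UP, DOWN, UP), g1517),
        CatalogueEntry(16, VariantSignature(DOWN, DOWN, UP, SAME, UP), g1517),
        CatalogueEntry(17, VariantSignature(DOWN, DOWN, UP, UP, UP), g1517),
        CatalogueEntry(18, VariantSignature(DOWN, SAME, DOWN, DOWN, DOWN)),
        CatalogueEntry(19, VariantSignature(DOWN, UP, DOWN, DOWN, DOWN)),
    ]
    return VariantCatalogue(entries=tuple(e), swap_3_4=swap_3_4)


# ---------------------------------------------------------------------------
# brute-force feasibility oracle


def enumerate_feasible_signatures(
    n_grid: int = 40, rtol: float = 1e-9, include_null: bool = False
) -> set[VariantSignature]:
    """Every direction 5-tuple realizable by a pair of valid annuli.

    Sweeps dense grids of ``(EDn, IDn) -> (EDhr, IDhr)`` over [1, 100] um
    with ``0 < ID < ED`` at both states, and additionally constructs the
    exact-equality families (WTh, MCSA and WLR preserved transitions) that a
    generic grid hits only with measure zero.  Directions use relative
    tolerance ``rtol``, so the constructed equalities classify as "same".
    """
    grid = np.linspace(1.0, 100.0, n_grid)
    pairs = [(e, i) for e in grid for i in grid if i < e]
    E0 = np.array([p[0] for p in pairs])
    I0 = np.array([p[1] for p in pairs])

    found: set[VariantSignature] = set()

    def add_states(e0, i0, e1, i1):
        e0, i0, e1, i1 = (np.asarray(a, float).ravel() for a in (e0, i0, e1, i1))
        ok = (i0 > 0) & (i0 < e0) & (i1 > 0) & (i1 < e1)
        e0, i0, e1, i1 = e0[ok], i0[ok], e1[ok], i1[ok]
        w0, w1 = (e0 - i0) / 2, (e1 - i1) / 2
        m0, m1 = e0**2 - i0**2, e1**2 - i1**2
        r0, r1 = w0 / i0, w1 / i1

        def dirs(a, b):
            same = np.isclose(a, b, rtol=rtol, atol=rtol)
            return np.where(same, SAME, np.where(b > a, UP, DOWN))

        cols = [dirs(e0, e1), dirs(i0, i1), dirs(w0, w1), dirs(m0, m1), dirs(r0, r1)]
        for tup in set(zip(*cols)):
            found.add(VariantSignature(*tup))

    # generic sweep: all grid pairs to all grid pairs (vectorized in blocks)
    n = len(pairs)
    block = 200
    for s in range(0, n, block):
        e0 = np.repeat(E0[s : s + block], n)
        i0 = np.repeat(I0[s : s + block], n)
        e1 = np.tile(E0, len(E0[s : s + block]))
        i1 = np.tile(I0, len(E0[s : s + block]))
        add_states(e0, i0, e1, i1)

    # constructed exact-equality families
    scales = np.array([0.3, 0.5, 0.8, 1.25, 2.0, 3.0])
    deltas = np.array([-20.0, -5.0, -0.5, 0.5, 5.0, 20.0])
    for k in scales:  # WLR preserved: proportional rescale
        add_states(E0, I0, k * E0, k * I0)
    for d in deltas:  # WTh preserved: translate both diameters
        add_states(E0, I0, E0 + d, I0 + d)
    # MCSA preserved: pick a new ED, solve the lumen that keeps ED^2 - ID^2
    for e1 in np.linspace(1.0, 100.0, n_grid):
        rad = e1**2 - (E0**2 - I0**2)
        ok = rad > 0
        add_states(E0[ok], I0[ok], np.full(ok.sum(), e1), np.sqrt(rad[ok]))

    if not include_null:
        found = {s for s in found if not s.is_null}
    return found


@lru_cache(maxsize=1)
def _feasible_complete_signatures() -> frozenset[tuple]:
    cat = canonical_catalogue()
    feas = {e.signature.as_tuple() for e in cat}
    feas.add(EXTRA_FEASIBLE_SIGNATURE.as_tuple())
    feas.add((SAME,) * 5)
    return frozenset(feas)


# ---------------------------------------------------------------------------
# classification


def classify_signature(
    sig: VariantSignature, catalogue: VariantCatalogue | None = None
) -> int | frozenset[int]:
    """Map a direction signature to its catalogue variant number.

    Returns the variant number for a complete, feasible signature;
    ``NO_REMODELING`` (0) for the all-same signature; a frozenset of
    candidate numbers for a partial signature (missing MCSA/WLR gradient
    information); raises :class:`InfeasibleSignatureError` for a 5-tuple no
    annulus pair can realize.
    """
    catalogue = catalogue or canonical_catalogue()
    if sig.is_complete:
        if sig.is_null:
            return NO_REMODELING
        if sig.as_tuple() not in _feasible_complete_signatures():
            raise InfeasibleSignatureError(
                f"signature {sig.arrows()} is not geometrically realizable"
            )
        for e in catalogue:
            if e.signature == sig:
                return e.number
        # feasible but outside the canonical 19 (the extra pattern)
        raise InfeasibleSignatureError(
            f"signature {sig.arrows()} is feasible but not in the canonical catalogue "
            "(the 20th pattern; see enumerate_feasible_signatures)"
        )
    matches = []
    for e in catalogue:
        ok = True
        for field in ("d_ed", "d_id", "d_wth", "d_mcsa", "d_wlr"):
            want = getattr(sig, field)
            if want is not None and getattr(e.signature, field) != want:
                ok = False
                break
        if ok:
            matches.append(e.number)
    if not matches:
        raise InfeasibleSignatureError(
            f"no catalogue entry is compatible with partial signature {sig.arrows()}"
        )
    if len(matches) == 1:
        return matches[0]
    return frozenset(matches)


def signature_from_fits(
    control: TaperFit,
    remodeled: TaperFit,
    ref_ed: float,
    rule: str = "threshold",
    delta: float = 0.05,
    alpha: float = 0.05,
) -> VariantSignature:
    """Direction signature of a remodeled bed relative to its control.

    States are matched by relative caliber position: ``ref_ed`` on the
    control fit corresponds to the same fractional position of the remodeled
    fit's ED range (a linear surrogate of accumulated-frequency matching, so
    that a bed whose vessels all widened is compared vessel-to-vessel rather
    than at coincident ED).  ID and WTh are evaluated on the two lines at the
    matched calibers; MCSA and WLR derive from those states.

    ``rule="threshold"`` calls a dimension changed when its relative change
    exceeds ``delta`` (default 5%); ``rule="statistical"`` uses the fits'
    coefficient covariances for a z-test at ``alpha`` on ID and WTh (ED and
    the derived dimensions keep the threshold rule, since the fits carry no
    sampling model for them).  With ``delta=0`` any noise produces a
    direction, never "same" -- hence the nonzero default.
    """
    if not (control.ed_range[0] <= ref_ed <= control.ed_range[1]):
        raise ValueError(f"ref_ed {ref_ed} outside control fitted range {control.ed_range}")
    ed_r = _matched_caliber(control, remodeled, ref_ed)

    id_c = float(control.predict_id(ref_ed))
    wth_c = float(control.predict_wth(ref_ed))
    id_r = float(remodeled.predict_id(ed_r))
    wth_r = float(remodeled.predict_wth(ed_r))
    if min(id_c, id_r) <= 0:
        raise ValueError("fit predicts non-positive ID at the matched caliber")

    mcsa_c, mcsa_r = ref_ed**2 - id_c**2, ed_r**2 - id_r**2
    wlr_c, wlr_r = wth_c / id_c, wth_r / id_r

    def thresh(a, b):
        if abs(b - a) <= delta * abs(a):
            return SAME
        return UP if b > a else DOWN

    def statistical(a, b, se):
        if se <= 0:
            return thresh(a, b)
        from scipy import stats as _st

        z = (b - a) / se
        if 2 * _st.norm.sf(abs(z)) >= alpha:
            return SAME
        return UP if b > a else DOWN

    if rule == "threshold":
        d_id = thresh(id_c, id_r)
        d_wth = thresh(wth_c, wth_r)
    elif rule == "statistical":
        se_id = math.hypot(
            float(control.id_fit.se_predict(ref_ed)), float(remodeled.id_fit.se_predict(ed_r))
        )
        se_wth = math.hypot(
            float(control.wth_fit.se_predict(ref_ed)),
            float(remodeled.wth_fit.se_predict(ed_r)),
        )
        d_id = statistical(id_c, id_r, se_id)
        d_wth = statistical(wth_c, wth_r, se_wth)
    else:
        raise ValueError(f"unknown rule {rule!r}")

    return VariantSignature(
        d_ed=thresh(ref_ed, ed_r),
        d_id=d_id,
        d_wth=d_wth,
        d_mcsa=thresh(mcsa_c, mcsa_r),
        d_wlr=thresh(wlr_c, wlr_r),
    )


def _matched_caliber(control: TaperFit, remodeled: TaperFit, ref_ed: float) -> float:
    """Remodeled caliber corresponding to a control caliber.

    Uses accumulated-frequency (quantile) matching when both fits retain
    their bed's caliber counts: a monotone remodeling map preserves vessel
    ranks, so the q-th quantile vessel of the control bed corresponds to the
    q-th quantile vessel of the remodeled bed regardless of how either bed
    was re-binned.  Falls back to relative position within the fitted point
    span when counts are unavailable.
    """

    def _quantile_grid(fit: TaperFit):
        x = np.asarray(fit.caliber_points, float)
        n = np.asarray(fit.caliber_counts, float)
        order = np.argsort(x)
        x, n = x[order], n[order]
        cum = (np.cumsum(n) - n / 2.0) / n.sum()
        return x, cum

    if (
        control.caliber_points is not None
        and control.caliber_counts is not None
        and remodeled.caliber_points is not None
        and remodeled.caliber_counts is not None
        and len(control.caliber_points) >= 2
        and len(remodeled.caliber_points) >= 2
    ):
        xc, qc = _quantile_grid(control)
        xr, qr = _quantile_grid(remodeled)
        q = float(np.interp(ref_ed, xc, qc))
        return float(np.interp(q, qr, xr))

    xc, xr = control.id_fit.x, remodeled.id_fit.x
    lo_c, hi_c = (float(xc.min()), float(xc.max())) if len(xc) >= 2 else control.ed_range
    lo_r, hi_r = (float(xr.min()), float(xr.max())) if len(xr) >= 2 else remodeled.ed_range
    pos = (ref_ed - lo_c) / (hi_c - lo_c)
    return lo_r + pos * (hi_r - lo_r)


# ---------------------------------------------------------------------------
# legacy scalar indices (for critique/reporting; never used to classify)


@dataclass(frozen=True)
class RemodelingIndices:
    """Remodeling index, hypertrophy fraction and growth index.

    RI assumes the bed followed the MCSA-preserving variant; the hypertrophy
    fraction assumes the ED-preserving variant; GI is the relative MCSA
    change.  ``ri``/``hypertrophy`` are NaN with an explanatory flag when
    their assumption is unreachable (negative radicand) or when
    ``IDn = IDhr`` (division by zero).
    """

    ri: float
    hypertrophy: float
    gi: float
    flags: tuple[str, ...] = ()


def remodeling_indices(
    ed_n: float, id_n: float, ed_hr: float, id_hr: float
) -> RemodelingIndices:
    for ed, idv, lbl in ((ed_n, id_n, "control"), (ed_hr, id_hr, "remodeled")):
        if not (0 < idv < ed):
            raise ValueError(f"{lbl} state ({ed}, {idv}) is not a valid annulus")
    mcsa_n = math.pi * (ed_n**2 - id_n**2) / 4
    mcsa_hr = math.pi * (ed_hr**2 - id_hr**2) / 4
    gi = (mcsa_hr - mcsa_n) / mcsa_n

    flags: list[str] = []
    ri = hyp = math.nan
    if math.isclose(id_n, id_hr, rel_tol=1e-12, abs_tol=1e-12):
        flags.append("IDn = IDhr: RI and hypertrophy undefined (division by zero)")
    else:
        denom = id_n - id_hr
        rad16 = ed_hr**2 - 4 * mcsa_n / math.pi
        if rad16 < 0:
            flags.append("MCSA-preserving state unreachable (negative radicand for ID16)")
        else:
            ri = (id_n - math.sqrt(rad16)) / denom
        rad9 = ed_n**2 - 4 * mcsa_hr / math.pi
        if rad9 < 0:
            flags.append("ED-preserving state unreachable (negative radicand for ID9)")
        else:
            hyp = (id_n - math.sqrt(rad9)) / denom
    return RemodelingIndices(ri=ri, hypertrophy=hyp, gi=gi, flags=tuple(flags))


# ---------------------------------------------------------------------------
# non-identifiability of scalar indices


#: 2D dimensions whose direction of change is determined by one signature field
_DIMENSION_FIELD = {
    "ED": "d_ed",
    "EP": "d_ed",  # perimeter = pi * diameter
    "total_area": "d_ed",  # pi ED^2 / 4
    "ID": "d_id",
    "IP": "d_id",
    "LCSA": "d_id",
    "WTh": "d_wth",
    "MCSA": "d_mcsa",
    "WLR": "d_wlr",
    "EP_over_IP": "d_wlr",  # EP/IP = ED/ID, monotone in WLR
    "MCSA_over_LCSA": "d_wlr",  # (ED/ID)^2 - 1, monotone in WLR
}


@dataclass
class NonIdentifiabilityReport:
    """How many catalogue variants share each value of each scalar index."""

    groups: dict[str, dict[str, list[int]]]
    wlr_up_count: int
    wlr_down_count: int
    wlr_same_count: int
    wlr_same_reported_elsewhere: int = 3  # the count quoted in the source narrative

    @property
    def every_index_many_to_one(self) -> bool:
        return all(
            any(len(v) > 1 for v in dim_groups.values())
            for dim_groups in self.groups.values()
        )

    def summary_lines(self) -> list[str]:
        lines = []
        for dim, dg in self.groups.items():
            parts = ", ".join(f"{d}: {sorted(v)}" for d, v in dg.items() if v)
            lines.append(f"{dim}: {parts}")
        lines.append(
            f"WLR increased in {self.wlr_up_count}, decreased in {self.wlr_down_count}, "
            f"unchanged in {self.wlr_same_count} catalogue variants "
            f"(narrative count for unchanged: {self.wlr_same_reported_elsewhere}; "
            "both are reported because they disagree)"
        )
        return lines


def nonidentifiability_report(
    catalogue: VariantCatalogue | None = None,
) -> NonIdentifiabilityReport:
    """Group catalogue variants by the value of every scalar 2D index.

    Demonstrates that no single linear size, area or ratio direction
    identifies a variant: every index value is shared by several entries.
    """
    catalogue = catalogue or canonical_catalogue()
    groups: dict[str, dict[str, list[int]]] = {}
    for dim, field in _DIMENSION_FIELD.items():
        dg: dict[str, list[int]] = {UP: [], SAME: [], DOWN: []}
        for e in catalogue:
            dg[getattr(e.signature, field)].append(e.number)
        groups[dim] = dg
    wlr = groups["WLR"]
    return NonIdentifiabilityReport(
        groups=groups,
        wlr_up_count=len(wlr[UP]),
        wlr_down_count=len(wlr[DOWN]),
        wlr_same_count=len(wlr[SAME]),
    )
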