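import copy
from dataclasses import replace

import numpy as np
import pytest

from vasomorph.congruence3d import build_surface, simulate_2d_shifts, test_congruence
from vasomorph.regression import fit_taper
from vasomorph.synthio import simulate_remodeled_intervals
from vasomorph.variants import DOWN, SAME, UP, canonical_catalogue, nonidentifiability_report


class TestSurfaces:
    def test_zero_deviation_reproduces_control_line(self, control_fit):
        for v in (1, 9, 16):
            surf = build_surface(control_fit, v, n_t=11, warn_clip=1.1)
            pts, valid = surf.slice_points(0)
            assert valid.all()
            assert pts[:, 0] == pytest.approx(surf.ed_grid)
            assert pts[:, 1] == pytest.approx(control_fit.predict_id(surf.ed_grid))

    def test_caliber_fixed_family_monotone(self, control_fit):
        """The ED-fixed variant: ED constant in t, ID strictly shrinking,
        WTh strictly growing."""
        surf = build_surface(control_fit, 9, n_t=21)
        ed = surf.points[:, :, 0]
        idv = surf.points[:, :, 1]
        wth = surf.points[:, :, 2]
        assert np.allclose(ed, ed[0])
        assert (np.diff(idv, axis=0) < 0).all()
        assert (np.diff(wth, axis=0) > 0).all()

    @pytest.mark.parametrize("variant", range(1, 20))
    def test_every_valid_point_matches_signature(self, control_fit, variant):
        """All surviving surface samples realize the variant's direction
        5-tuple relative to their control pre-image (the clipping contract)."""
        surf = build_surface(control_fit, variant, n_t=41, warn_clip=1.1)
        sig = surf.family.signature
        I = control_fit.predict_id(surf.ed_grid)
        for i, t in enumerate(surf.t_grid):
            if t == 0 or not surf.valid[i].any():
                continue
            pts = surf.points[i][surf.valid[i]]
            E0 = surf.ed_grid[surf.valid[i]]
            I0 = I[surf.valid[i]]
            for dim, a, b in (
                ("d_ed", E0, pts[:, 0]),
                ("d_id", I0, pts[:, 1]),
                ("d_wth", (E0 - I0) / 2, pts[:, 2]),
                ("d_mcsa", E0**2 - I0**2, pts[:, 0] ** 2 - pts[:, 1] ** 2),
                ("d_wlr", (E0 - I0) / (2 * I0), (pts[:, 0] - pts[:, 1]) / (2 * pts[:, 1])),
            ):
                want = getattr(sig, dim)
                if want == UP:
                    assert (b > a - 1e-12).all(), (variant, t, dim)
                elif want == DOWN:
                    assert (b < a + 1e-12).all(), (variant, t, dim)
                else:
                    assert np.allclose(a, b, rtol=1e-9), (variant, t, dim)

    def test_infeasible_family_truncated_with_warning(self, control_fit):
        # variant 10 (lumen widening at fixed caliber) must clip where ID >= ED
        with pytest.warns(UserWarning, match="clipped"):
            build_surface(control_fit, 10, n_t=41, warn_clip=0.05)


class TestCongruence:
    def test_unremodeled_line_congruent_only_with_null(self, control_fit, surfaces):
        res = test_congruence(control_fit, control_fit, surfaces=surfaces)
        assert res.congruent == [0]

    @pytest.mark.parametrize("variant", range(1, 20))
    def test_forward_simulation_recovered_uniquely(
        self, control_fit, surfaces, feasible_t, variant
    ):
        """Round trip: each variant's noise-free forward simulation is
        congruent with exactly its own transformation family."""
        t = min(0.3, 0.6 * feasible_t[variant])
        iv = simulate_remodeled_intervals(control_fit, variant, t)
        remodeled = fit_taper(iv, robust=False)
        res = test_congruence(control_fit, remodeled, surfaces=surfaces)
        assert res.congruent == [variant]
        assert res.best == variant

    def test_beyond_deviation_limit_empty_set_nearest_reported(
        self, control_fit, surfaces
    ):
        """A lumen collapsed past the -99% limit matches no family, but the
        nearest variant is still ranked."""
        sq = copy.deepcopy(control_fit)
        sq.id_fit = replace(sq.id_fit, slope=0.005 * control_fit.id_slope,
                            intercept=0.005 * control_fit.id_intercept)
        sq.wth_fit = replace(
            sq.wth_fit,
            slope=(1 - 0.005 * control_fit.id_slope) / 2,
            intercept=-0.005 * control_fit.id_intercept / 2,
        )
        # a state 0.5% past the -99% boundary sits ~0.1 um from the clipped
        # family edge, below the noise-aware band's floor; the absolute
        # tolerance mode resolves it
        res = test_congruence(control_fit, sq, surfaces=surfaces, tolerance=0.05)
        assert res.congruent == []
        assert res.best in range(1, 20)
        assert res.distances[res.best]["max_distance_um"] > 0.05

    def test_distances_nonnegative_and_ranked(self, control_fit, surfaces, feasible_t):
        iv = simulate_remodeled_intervals(control_fit, 9, 0.3)
        res = test_congruence(control_fit, fit_taper(iv, robust=False), surfaces=surfaces)
        scores = [res.distances[v]["score"] for v in res.ranking]
        assert all(s >= 0 for s in scores)
        assert scores == sorted(scores)

    def test_absolute_tolerance_mode(self, control_fit, surfaces):
        iv = simulate_remodeled_intervals(control_fit, 9, 0.3)
        remodeled = fit_taper(iv, robust=False)
        res = test_congruence(
            control_fit, remodeled, surfaces=surfaces, tolerance=0.3
        )
        assert 9 in res.congruent and len(res.congruent) <= 2

    def test_refinement_converges_with_grid_density(self, control_fit, feasible_t):
        """True-variant distance shrinks (or holds) as the t-grid refines."""
        iv = simulate_remodeled_intervals(control_fit, 14, min(0.3, 0.6 * feasible_t[14]))
        remodeled = fit_taper(iv, robust=False)
        coarse = test_congruence(control_fit, remodeled, n_t=31)
        fine = test_congruence(control_fit, remodeled, n_t=121)
        assert fine.distances[14]["max_distance_um"] <= coarse.distances[14][
            "max_distance_um"
        ] + 1e-9

    def test_gradient_subtypes_mutually_noncongruent(
        self, control_fit, surfaces, feasible_t
    ):
        """#15/#16/#17 generated from one control line never cross-match."""
        for v in (15, 16, 17):
            t = min(0.3, 0.6 * feasible_t[v])
            iv = simulate_remodeled_intervals(control_fit, v, t)
            res = test_congruence(
                control_fit, fit_taper(iv, robust=False), surfaces=surfaces
            )
            others = {15, 16, 17} - {v}
            assert res.congruent == [v]
            for o in others:
                assert res.distances[o]["score"] > res.z

    def test_subrange_analysis(self, control_fit, surfaces, feasible_t):
        """Restricting to a caliber segment still classifies that segment
        (the proximal/distal split analysis)."""
        t = min(0.3, 0.6 * feasible_t[9])
        iv = simulate_remodeled_intervals(control_fit, 9, t)
        remodeled = fit_taper(iv, robust=False)
        res = test_congruence(
            control_fit, remodeled, surfaces=surfaces, ed_subrange=(10, 20), n_line=11
        )
        assert 9 in res.congruent


class TestTwoDimensionalShifts:
    def test_no_single_dimension_separates_the_catalogue(self, control_fit):
        table = simulate_2d_shifts(control_fit, t=0.2)
        for dim in table.columns:
            assert table[dim].nunique() < 19, dim

    def test_lumen_shift_shared_by_many(self, control_fit):
        table = simulate_2d_shifts(control_fit, t=0.2)
        assert (table["ID"] == DOWN).sum() >= 2

    def test_ratio_groupings_match_catalogue_report(self, control_fit):
        """WLR-axis displacement grouping equals the catalogue's WLR groups
        wherever the family is realizable at this deviation."""
        table = simulate_2d_shifts(control_fit, t=0.2)
        rep = nonidentifiability_report()
        for direction in (UP, DOWN, SAME):
            got = set(table.index[table["WLR"] == direction])
            want = set(rep.groups["WLR"][direction])
            assert got <= want
            assert len(want - got) <= 2  # clipped families may drop out
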