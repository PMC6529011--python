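import math

import numpy as np
import pytest

from vasomorph.variants import (
    DOWN,
    EXTRA_FEASIBLE_SIGNATURE,
    NO_REMODELING,
    SAME,
    UP,
    InfeasibleSignatureError,
    VariantSignature,
    canonical_catalogue,
    classify_signature,
    enumerate_feasible_signatures,
    nonidentifiability_report,
    remodeling_indices,
    signature_from_fits,
    signature_of_change,
)


@pytest.fixture(scope="module")
def catalogue():
    return canonical_catalogue()


@pytest.fixture(scope="module")
def feasible():
    return enumerate_feasible_signatures(n_grid=40)


class TestCatalogue:
    def test_nineteen_entries_split_by_caliber_direction(self, catalogue):
        assert len(catalogue) == 19
        assert len(catalogue.numbers_with(d_ed=UP)) == 8
        assert len(catalogue.numbers_with(d_ed=SAME)) == 2
        assert len(catalogue.numbers_with(d_ed=DOWN)) == 9

    def test_wlr_direction_counts(self, catalogue):
        assert len(catalogue.numbers_with(d_wlr=UP)) == 9
        assert len(catalogue.numbers_with(d_wlr=DOWN)) == 8
        assert len(catalogue.numbers_with(d_wlr=SAME)) == 2

    def test_signatures_unique(self, catalogue):
        sigs = [e.signature for e in catalogue]
        assert len(set(sigs)) == 19

    def test_swap_3_4_exchanges_only_that_pair(self, catalogue):
        swapped = canonical_catalogue(swap_3_4=True)
        assert swapped.signature(3) == catalogue.signature(4)
        assert swapped.signature(4) == catalogue.signature(3)
        for n in set(range(1, 20)) - {3, 4}:
            assert swapped.signature(n) == catalogue.signature(n)


class TestFeasibilityOracle:
    def test_twenty_feasible_patterns(self, feasible):
        assert len(feasible) == 20

    def test_catalogue_plus_extra_is_the_feasible_set(self, catalogue, feasible):
        cat = {e.signature for e in catalogue}
        assert cat <= feasible
        assert feasible - cat == {EXTRA_FEASIBLE_SIGNATURE}

    def test_forced_completions(self, feasible):
        """Fixing ED and shrinking the lumen forces wall growth in every
        derived dimension; same with a widening caliber."""
        fixed_ed = {s for s in feasible if s.d_ed == SAME and s.d_id == DOWN}
        assert fixed_ed == {VariantSignature(SAME, DOWN, UP, UP, UP)}
        widen = {s for s in feasible if s.d_ed == UP and s.d_id == DOWN}
        assert widen == {VariantSignature(UP, DOWN, UP, UP, UP)}

    def test_every_feasible_signature_classifies_or_is_the_extra(
        self, catalogue, feasible
    ):
        for sig in feasible:
            if sig == EXTRA_FEASIBLE_SIGNATURE:
                with pytest.raises(InfeasibleSignatureError, match="20th"):
                    classify_signature(sig, catalogue)
            else:
                assert classify_signature(sig, catalogue) in range(1, 20)


class TestClassification:
    @pytest.mark.parametrize(
        "arrows,expected",
        [
            ("↓↓↑↓↑", 15),  # inward shrink, wall thickened, media lost
            ("=↓↑↑↑", 9),  # caliber fixed, lumen encroached
            ("↓↓=↓↑", 14),  # shrink at constant wall thickness
            ("↑↓↑↑↑", 1),  # widened caliber with lumen encroachment
            ("↑=↑↑↑", 2),
            ("↑↑↓↓↓", 4),  # distended, thinned, media lost (adrenal-type)
        ],
    )
    def test_direction_tuples_map_to_variant_numbers(self, catalogue, arrows, expected):
        sig = VariantSignature.from_arrows(arrows)
        assert classify_signature(sig, catalogue) == expected

    def test_null_signature_is_no_remodeling(self, catalogue):
        assert classify_signature(VariantSignature.from_arrows("====="), catalogue) == NO_REMODELING

    def test_round_trip_over_all_entries(self, catalogue):
        for e in catalogue:
            assert classify_signature(e.signature, catalogue) == e.number

    def test_partial_signature_returns_gradient_set(self, catalogue):
        sig = VariantSignature(UP, UP, UP, d_mcsa=UP, d_wlr=None)
        assert classify_signature(sig, catalogue) == frozenset({6, 7, 8})

    def test_infeasible_signature_rejected(self, catalogue):
        # widening both diameters cannot shrink the wall AND raise WLR
        with pytest.raises(InfeasibleSignatureError):
            classify_signature(VariantSignature(UP, UP, DOWN, DOWN, UP), catalogue)


class TestSignatureOfChange:
    def test_matches_catalogue_on_constructed_states(self):
        # kidney-like shrink at constant wall thickness: (33,13) -> (30,10)
        sig = signature_of_change(33, 13, 30, 10)
        assert sig == VariantSignature(DOWN, DOWN, SAME, DOWN, UP)
        assert classify_signature(sig) == 14

    def test_invalid_annulus_rejected(self):
        with pytest.raises(ValueError, match="annulus"):
            signature_of_change(10, 12, 20, 10)


class TestRemodelingIndices:
    def test_hand_worked_states(self):
        # (30,20) -> (28,16): ID16 = sqrt(784-500), ID9 = sqrt(900-528)
        r = remodeling_indices(30, 20, 28, 16)
        assert r.ri == pytest.approx((20 - math.sqrt(284)) / 4, rel=1e-9)
        assert r.hypertrophy == pytest.approx((20 - math.sqrt(372)) / 4, rel=1e-9)
        assert r.gi == pytest.approx(528 / 500 - 1, rel=1e-12)
        assert r.ri == pytest.approx(0.787, abs=5e-4)
        assert r.hypertrophy == pytest.approx(0.178, abs=5e-4)

    def test_gi_zero_when_media_conserved(self):
        r = remodeling_indices(30, 20, math.sqrt(30**2 - 20**2 + 16**2), 16)
        assert r.gi == pytest.approx(0.0, abs=1e-12)

    def test_gi_direct(self):
        # MCSAn = 100 -> MCSAhr = 125 (areas via matching diameters)
        ed_n = math.sqrt(4 * 100 / math.pi + 100)
        ed_hr = math.sqrt(4 * 125 / math.pi + 81)
        r = remodeling_indices(ed_n, 10, ed_hr, 9)
        assert r.gi == pytest.approx(0.25, rel=1e-9)

    def test_media_preserving_state_gives_unit_ri(self):
        # remodeled state constructed with MCSA exactly preserved
        ed_n, id_n = 30.0, 20.0
        ed_hr = 28.0
        id_hr = math.sqrt(ed_hr**2 - (ed_n**2 - id_n**2))
        r = remodeling_indices(ed_n, id_n, ed_hr, id_hr)
        assert r.ri == pytest.approx(1.0, rel=1e-12)

    def test_caliber_preserving_state_gives_unit_hypertrophy(self):
        ed_n, id_n = 30.0, 20.0
        id_hr = 16.0
        r = remodeling_indices(ed_n, id_n, ed_n, id_hr)
        assert r.hypertrophy == pytest.approx(1.0, rel=1e-12)

    def test_equal_lumens_flagged_undefined(self):
        r = remodeling_indices(30, 20, 32, 20)
        assert math.isnan(r.ri) and any("division" in f for f in r.flags)


class TestNonIdentifiability:
    def test_wlr_groups(self):
        rep = nonidentifiability_report()
        assert rep.wlr_up_count == 9
        assert rep.wlr_down_count == 8
        assert rep.wlr_same_count == 2
        # the narrative count (3) disagrees with the catalogue (2): both printed
        assert rep.wlr_same_reported_elsewhere == 3
        assert any("unchanged in 2" in line for line in rep.summary_lines())

    def test_every_scalar_index_many_to_one(self):
        rep = nonidentifiability_report()
        assert rep.every_index_many_to_one
        for dim, groups in rep.groups.items():
            sizes = [len(v) for v in groups.values() if v]
            assert max(sizes) > 1, dim

    def test_mcsa_down_group(self):
        rep = nonidentifiability_report()
        assert set(rep.groups["MCSA"][DOWN]) == {4, 10, 11, 12, 13, 14, 15, 18, 19}

    def test_ratio_indices_follow_wlr(self):
        rep = nonidentifiability_report()
        assert rep.groups["EP_over_IP"] == rep.groups["WLR"]
        assert rep.groups["MCSA_over_LCSA"] == rep.groups["WLR"]


class TestSignatureFromFits:
    def test_identical_fits_all_same(self, control_fit):
        sig = signature_from_fits(control_fit, control_fit, ref_ed=30.0)
        assert sig.is_null

    def test_forward_constructed_lumen_encroachment(self, control_fit):
        """ID scaled down 30% at fixed ED reads as the caliber-fixed variant."""
        import copy
        from dataclasses import replace

        remo = copy.deepcopy(control_fit)
        remo.id_fit = replace(remo.id_fit, slope=0.7 * remo.id_fit.slope,
                              intercept=0.7 * remo.id_fit.intercept)
        # WTh recomputed from the annulus identity at fixed ED
        remo.wth_fit = replace(
            remo.wth_fit,
            slope=(1 - 0.7 * control_fit.id_slope) / 2,
            intercept=-0.7 * control_fit.id_intercept / 2,
        )
        sig = signature_from_fits(control_fit, remo, ref_ed=30.0)
        assert sig == VariantSignature(SAME, DOWN, UP, UP, UP)
        assert classify_signature(sig) == 9

    def test_zero_threshold_never_same_under_noise(self, control_fit):
        import copy
        from dataclasses import replace

        remo = copy.deepcopy(control_fit)
        remo.id_fit = replace(remo.id_fit, intercept=remo.id_fit.intercept + 1e-4)
        remo.wth_fit = replace(remo.wth_fit, intercept=remo.wth_fit.intercept - 3e-5)
        sig = signature_from_fits(control_fit, remo, ref_ed=30.0, delta=0.0)
        assert SAME not in (sig.d_id, sig.d_wth, sig.d_mcsa, sig.d_wlr)

    def test_ref_outside_range_rejected(self, control_fit):
        with pytest.raises(ValueError, match="ref_ed"):
            signature_from_fits(control_fit, control_fit, ref_ed=99.0)
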