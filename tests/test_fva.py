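"""FBA/FVA engine, interval metrics and two-BOF comparison."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boftools.bof import BOF
from boftools.fva import (
    FluxRange,
    FVAError,
    InfeasibleModel,
    center_point_ratio,
    compare_objectives,
    fractional_overlap,
    install_bof,
    run_fva,
    solve_fba,
)
from conftest import build_model

# the four published example reactions with strongly shifted ranges
EXAMPLE_RANGES = [
    ("MCOATA", (0.0287, 0.0289), (0.0830, 0.0830), 2.88),
    ("UAGDP", (0.0628, 0.0629), (0.1020, 0.1020), 1.62),
    ("POR5", (0.0938, 0.0946), (0.0440, 0.0441), 0.47),
    ("TMDS", (0.0218, 0.0218), (0.0098, 0.0098), 0.45),
]


class TestFBA:
    def test_chain_optimum_is_uptake_cap(self, chain_model):
        mu, fluxes = solve_fba(chain_model)
        assert mu == pytest.approx(10.0)
        assert fluxes["R_AB"] == pytest.approx(10.0)

    def test_internal_bottleneck(self, chain_model):
        chain_model.reactions.R_AB.upper_bound = 4.0
        mu, _ = solve_fba(chain_model)
        assert mu == pytest.approx(4.0)

    def test_unproducible_precursor_gives_zero_growth(self):
        model = build_model(
            {
                "EX_A": ({"A": 1}, 0, 10),
                "BIOMASS": ({"A": -1, "GHOST": -1}, 0, 1000),
            },
            "BIOMASS",
        )
        mu, _ = solve_fba(model)
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_model_reported(self, chain_model):
        chain_model.reactions.R_AB.upper_bound = 4.0
        chain_model.reactions.BIOMASS.lower_bound = 5.0
        with pytest.raises(InfeasibleModel):
            solve_fba(chain_model)


class TestFVA:
    def test_chain_has_no_degrees_of_freedom(self, chain_model):
        ranges = {fr.reaction_id: fr for fr in run_fva(chain_model, 1.0)}
        for fr in ranges.values():
            assert (fr.vmin, fr.vmax) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_diamond_routes_are_interchangeable(self, diamond_model):
        ranges = {fr.reaction_id: fr for fr in run_fva(diamond_model, 1.0)}
        for rxn in ("R1", "R2"):
            assert ranges[rxn].vmin == pytest.approx(0.0)
            assert ranges[rxn].vmax == pytest.approx(10.0)

    def test_blocked_reaction_is_pinned_to_zero(self, chain_model):
        from cobra import Metabolite, Reaction

        orphan = Reaction("ORPHAN", lower_bound=0, upper_bound=1000)
        orphan.add_metabolites({Metabolite("X"): -1, Metabolite("Y"): 1})
        chain_model.add_reactions([orphan])
        ranges = {fr.reaction_id: fr for fr in run_fva(chain_model, 1.0)}
        assert (ranges["ORPHAN"].vmin, ranges["ORPHAN"].vmax) == (0.0, 0.0)

    def test_objective_range_degenerate_at_full_optimality(self, diamond_model):
        ranges = {fr.reaction_id: fr for fr in run_fva(diamond_model, 1.0)}
        obj = ranges["BIOMASS"]
        assert obj.width <= 1e-6
        assert obj.center == pytest.approx(10.0)

    def test_invalid_fraction_rejected(self, chain_model):
        with pytest.raises(FVAError, match="fraction"):
            run_fva(chain_model, 0.0)

    def test_suboptimal_fraction_widens_ranges(self, chain_model):
        ranges = {fr.reaction_id: fr for fr in run_fva(chain_model, 0.5)}
        assert ranges["BIOMASS"].vmin == pytest.approx(5.0)
        assert ranges["BIOMASS"].vmax == pytest.approx(10.0)


class TestFractionalOverlap:
    @pytest.mark.parametrize("rxn, m, e, _cp", EXAMPLE_RANGES)
    def test_published_example_ranges_are_disjoint(self, rxn, m, e, _cp):
        a = FluxRange(rxn + "_e", *e)
        b = FluxRange(rxn + "_m", *m)
        assert fractional_overlap(a, b) == 0.0

    def test_identical_intervals(self):
        r = FluxRange("r", 1.0, 2.0)
        assert fractional_overlap(r, r) == 1.0

    def test_half_overlap(self):
        assert fractional_overlap(
            FluxRange("a", 0.0, 2.0), FluxRange("b", 1.0, 3.0)
        ) == pytest.approx(0.5)

    def test_point_ranges_compare_centers(self):
        a = FluxRange("a", 1.0, 1.0)
        assert fractional_overlap(a, FluxRange("b", 1.0, 1.0)) == 1.0
        assert fractional_overlap(a, FluxRange("c", 2.0, 2.0)) == 0.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=4))
    def test_symmetric_bounded_and_affine_invariant(self, vals):
        a_lo, a_hi = sorted(vals[:2])
        b_lo, b_hi = sorted(vals[2:])
        a, b = FluxRange("a", a_lo, a_hi), FluxRange("b", b_lo, b_hi)
        xi = fractional_overlap(a, b)
        assert 0.0 <= xi <= 1.0
        assert xi == fractional_overlap(b, a)
        if min(a.width, b.width) > 1e-6:  # away from the point-range tolerance
            # common positive affine rescaling leaves xi unchanged
            shift, scale = 3.7, 2.5
            a2 = FluxRange("a", a_lo * scale + shift, a_hi * scale + shift)
            b2 = FluxRange("b", b_lo * scale + shift, b_hi * scale + shift)
            assert fractional_overlap(a2, b2) == pytest.approx(xi, abs=1e-9)


class TestCenterPointRatio:
    @pytest.mark.parametrize("rxn, m, e, cp", EXAMPLE_RANGES)
    def test_published_examples_reproduce(self, rxn, m, e, cp):
        ratio = center_point_ratio(FluxRange("e", *e), FluxRange("m", *m))
        assert round(ratio, 2) == cp

    def test_identical_ranges_give_unity(self):
        r = FluxRange("r", 0.5, 0.7)
        assert center_point_ratio(r, r) == 1.0

    def test_zero_reference_flagged_nan(self):
        out = center_point_ratio(FluxRange("e", 1, 1), FluxRange("m", -1, 1))
        assert math.isnan(out)


class TestInstallBof:
    def test_reinstalling_own_bof_preserves_optimum(self, diamond_model):
        mu0, _ = solve_fba(diamond_model)
        bof = BOF({"B": -1.0})
        diamond_model.reactions.BIOMASS.bounds = (0, 1000)
        mu1, _ = solve_fba(install_bof(diamond_model, bof))
        assert mu1 == pytest.approx(10.0)
        assert mu0 == pytest.approx(10.0)

    def test_doubling_coefficients_halves_growth(self, chain_model):
        mu0, _ = solve_fba(chain_model)
        mu2, _ = solve_fba(install_bof(chain_model, BOF({"B": -2.0})))
        assert mu2 == pytest.approx(mu0 / 2)

    def test_original_model_unmodified(self, chain_model):
        before = dict(chain_model.reactions.BIOMASS.metabolites)
        install_bof(chain_model, BOF({"A": -1.0}))
        assert dict(chain_model.reactions.BIOMASS.metabolites) == before

    def test_unknown_metabolite_rejected_by_name(self, chain_model):
        with pytest.raises(FVAError, match="GHOST"):
            install_bof(chain_model, BOF({"GHOST": -1.0}))

    def test_auto_create_adds_metabolite(self, chain_model):
        model = install_bof(chain_model, BOF({"B": -1, "GHOST": -0.1}), auto_create=True)
        assert "GHOST" in {m.id for m in model.metabolites}


class TestCompareObjectives:
    def toy(self):
        return build_model(
            {
                "EX_A": ({"A": 1}, 0, 10),
                "SYN_P": ({"A": -1, "P": 1}, 0, 1000),
                "SYN_Q": ({"A": -1, "Q": 1}, 0, 1000),
                "BIOMASS": ({"P": -1, "Q": -1}, 0, 1000),
            },
            "BIOMASS",
        )

    def test_self_comparison_is_null(self):
        bof = BOF({"P": -1.0, "Q": -1.0})
        report = compare_objectives(self.toy(), bof, bof)
        assert (report.per_reaction["cp_r"] == 1.0).all()
        assert report.summary["fraction_high_flux_cp_changed"] == 0.0
        assert (report.per_component["s_r"] == 1.0).all()

    def test_doubled_precursor_demand_doubles_synthesis_center(self):
        bofA = BOF({"P": -2.0, "Q": -1.0})
        bofB = BOF({"P": -1.0, "Q": -1.0})
        report = compare_objectives(self.toy(), bofA, bofB)
        # with uptake saturated, doubling P demand shifts flux toward SYN_P:
        # centers move from (5, 5) to (20/3, 10/3)
        assert report.per_reaction.loc["SYN_P", "cp_r"] == pytest.approx(4 / 3)
        assert report.per_reaction.loc["SYN_Q", "cp_r"] == pytest.approx(2 / 3)
        assert report.per_component.loc["P", "s_r"] == pytest.approx(2.0)

    def test_fixed_demand_model_gives_exact_cp(self):
        # free P synthesis demanded by biomass only: coefficient doubles CP_r
        model = build_model(
            {
                "EX_A": ({"A": 1}, 0, 10),
                "SYN_P": ({"A": -1, "P": 1}, 0, 1000),
                "EX_slack": ({"A": -1}, 0, 1000),
                "BIOMASS": ({"P": -1}, 1, 1),
            },
            "BIOMASS",
        )
        bofA, bofB = BOF({"P": -2.0}), BOF({"P": -1.0})
        report = compare_objectives(model, bofA, bofB)
        assert report.per_reaction.loc["SYN_P", "cp_r"] == pytest.approx(2.0)

    def test_infeasibility_identifies_bof(self):
        model = self.toy()
        model.reactions.BIOMASS.lower_bound = 11.0  # beyond uptake capacity
        with pytest.raises(InfeasibleModel, match="'a'"):
            compare_objectives(model, BOF({"P": -1.0}), BOF({"Q": -1.0}))

    def test_medium_override_applied(self, chain_model):
        bof = BOF({"B": -1.0})
        report = compare_objectives(
            chain_model, bof, bof, medium_overrides={"EX_A": 0.0}
        )
        # with uptake unchanged (lower bound already 0) nothing changes
        assert report.summary["n_reactions"] == 3
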