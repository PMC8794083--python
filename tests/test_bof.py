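"""Coefficient conversion, normalization, template merging and BOF metrics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boftools.bof import (
    BOF,
    BOFError,
    MetaboliteSpec,
    bof_mass,
    coefficient_ratio,
    mass_redistribution,
    mass_to_coefficients,
    merge_with_template,
    normalize_bof,
    residue_specs,
)
from boftools.composition import BiomassComposition, MonomerRecord

AB_SPECS = {"A": 2.0, "B": 1.0}  # plain molar masses [g/mmol]


def comp_of(**masses):
    return BiomassComposition(
        classes={"protein": (sum(masses.values()), None)},
        monomers=[MonomerRecord(m, "protein", w) for m, w in masses.items()],
    )


class TestMetaboliteSpec:
    def test_mass_from_formula(self):
        spec = MetaboliteSpec("ala", formula="C3H7NO2")
        assert spec.molar_mass == pytest.approx(0.0891, abs=1e-4)

    def test_inconsistent_mass_rejected(self):
        with pytest.raises(BOFError, match="inconsistent"):
            MetaboliteSpec("ala", formula="C3H7NO2", molar_mass=0.095)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(BOFError, match="positive"):
            MetaboliteSpec("x", molar_mass=0.0)


class TestMassToCoefficients:
    def test_simple_ratio(self):
        comp = comp_of(A=0.10)
        assert mass_to_coefficients(comp, {"A": 0.05}) == {"A": pytest.approx(-2.0)}

    def test_alanine_table_value(self):
        comp = BiomassComposition(
            classes={"protein": (0.046, None)},
            monomers=[MonomerRecord("Ala", "protein", 0.046)],
        )
        coeffs = mass_to_coefficients(comp, residue_specs())
        assert coeffs["Ala"] == pytest.approx(-0.6472, abs=5e-4)

    def test_zero_mass_omitted(self):
        comp = comp_of(A=0.1, B=0.0)
        assert set(mass_to_coefficients(comp, AB_SPECS)) == {"A"}

    def test_unsplit_pool_rejected(self):
        comp = BiomassComposition(
            classes={"protein": (0.05, None)},
            monomers=[MonomerRecord("Glu+Gln", "protein", 0.05)],
        )
        with pytest.raises(BOFError, match="split"):
            mass_to_coefficients(comp, residue_specs())

    def test_missing_spec_names_monomer(self):
        with pytest.raises(BOFError, match="'B'"):
            mass_to_coefficients(comp_of(B=0.1), {"A": 1.0})

    def test_round_trip_recovers_mass_fractions(self, measured_composition):
        specs = residue_specs()
        monomers = [
            r for r in measured_composition.monomers
            if not r.is_pool and not r.excluded and r.mass_fraction > 0
        ]
        comp = BiomassComposition(
            classes=dict(measured_composition.classes), monomers=monomers
        )
        coeffs = mass_to_coefficients(comp, specs)
        for rec in monomers:
            back = -coeffs[rec.monomer_id] * specs[rec.monomer_id].molar_mass
            assert back == pytest.approx(rec.mass_fraction, rel=1e-12)


class TestBofMass:
    def test_weighted_sum(self):
        assert bof_mass(BOF({"A": -0.3, "B": -0.2}), AB_SPECS) == pytest.approx(0.8)

    def test_empty_is_zero(self):
        assert bof_mass(BOF({}), {}) == 0.0

    def test_gam_only_is_zero(self):
        bof = BOF({}, gam=50.0)
        assert bof_mass(bof, {}) == 0.0

    def test_products_subtract(self):
        specs = {"A": 2.0, "P": 0.5}
        assert bof_mass(BOF({"A": -1.0, "P": 1.0}), specs) == pytest.approx(1.5)


class TestNormalize:
    def test_frozen_example(self):
        out = normalize_bof(BOF({"A": -0.3, "B": -0.2}), AB_SPECS)
        assert out.coefficients == pytest.approx({"A": -0.375, "B": -0.25})
        assert bof_mass(out, AB_SPECS) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        once = normalize_bof(BOF({"A": -0.3, "B": -0.2}), AB_SPECS)
        twice = normalize_bof(once, AB_SPECS)
        assert twice.coefficients == pytest.approx(once.coefficients)

    def test_zero_mass_rejected(self):
        with pytest.raises(BOFError, match="non-positive"):
            normalize_bof(BOF({}), {})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        coeffs=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_covariance(self, coeffs, scale):
        specs = {f"m{i}": 1.0 + 0.1 * i for i in range(len(coeffs))}
        bof = BOF({f"m{i}": -c for i, c in enumerate(coeffs)})
        scaled = BOF({m: c * scale for m, c in bof.coefficients.items()})
        a = normalize_bof(bof, specs)
        b = normalize_bof(scaled, specs)
        assert b.coefficients == pytest.approx(a.coefficients, rel=1e-9)
        assert bof_mass(a, specs) == pytest.approx(1.0, abs=1e-9)

    def test_gam_untouched_by_normalization(self):
        bof = BOF({"A": -0.5}, gam=40.0)
        out = normalize_bof(bof, {"A": 2.0})
        assert out.gam == 40.0


class TestGamSplit:
    def test_reaction_round_trip(self):
        stoich = {
            "atp_c": -54.0, "h2o_c": -48.6, "adp_c": 53.95, "pi_c": 53.95,
            "h_c": 53.95, "ala__L_c": -0.5,
        }
        bof = BOF.from_reaction_stoichiometry(stoich)
        assert bof.gam == pytest.approx(53.95)
        # metabolic ATP demand is what exceeds maintenance hydrolysis
        assert bof.coefficients["atp_c"] == pytest.approx(-0.05)
        assert bof.coefficients["h2o_c"] == pytest.approx(5.35)
        total = bof.total_coefficients()
        assert total == pytest.approx({k: v for k, v in stoich.items()})


class TestMerge:
    def template(self):
        return BOF({"ala__L_c": -0.5, "k_c": -0.19, "h2o_c": 0.5}, gam=50.0)

    def test_empty_measured_returns_template(self):
        merged = merge_with_template({}, self.template())
        assert merged.coefficients == self.template().coefficients
        assert merged.gam == 50.0

    def test_measured_replaces_template_only_where_measured(self):
        merged = merge_with_template({"Ala": -0.65}, self.template())
        assert merged.coefficients["ala__L_c"] == pytest.approx(-0.65)
        assert merged.coefficients["k_c"] == pytest.approx(-0.19)

    def test_byproduct_rebalanced_on_replacement(self):
        # water released per peptide bond follows the alanine coefficient
        merged = merge_with_template({"Ala": -0.65}, self.template())
        assert merged.coefficients["h2o_c"] == pytest.approx(0.5 + 0.15)

    def test_nmp_maps_to_ntp_with_ppi_release(self):
        template = BOF({"atp_c": -0.17, "ppi_c": 0.17})
        merged = merge_with_template({"AMP": -0.25}, template)
        assert merged.coefficients["atp_c"] == pytest.approx(-0.25)
        assert merged.coefficients["ppi_c"] == pytest.approx(0.25)

    def test_net_mass_equals_residue_mass_after_merge(self):
        # consuming c mmol ATP and releasing c mmol PPi leaves the AMP residue
        from cobra import Metabolite

        template = BOF({"atp_c": -0.17, "ppi_c": 0.17})
        merged = merge_with_template({"AMP": -0.25}, template)
        specs = {
            "atp_c": Metabolite("atp", formula="C10H12N5O13P3").formula_weight / 1000,
            "ppi_c": Metabolite("ppi", formula="HO7P2").formula_weight / 1000,
        }
        net = bof_mass(merged, specs)
        # BiGG formulas are deprotonated, so allow a ~1 proton/unit offset
        assert net == pytest.approx(0.25 * residue_specs()["AMP"].molar_mass, rel=5e-3)

    def test_removed_component_deleted_and_rebalanced(self):
        merged = merge_with_template({}, self.template(), removed=("ala__L_c",))
        assert "ala__L_c" not in merged.coefficients
        assert merged.coefficients.get("h2o_c", 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_unmapped_measured_id_rejected(self):
        with pytest.raises(BOFError, match="frobnicose"):
            merge_with_template({"frobnicose": -0.1}, self.template())

    def test_sign_collision_rejected(self):
        template = BOF({"ala__L_c": 0.4})
        with pytest.raises(BOFError, match="collides"):
            merge_with_template({"Ala": -0.2}, template)


class TestCoefficientRatio:
    def test_identical_bofs_all_one(self):
        bof = BOF({"A": -0.3, "B": -0.1})
        assert set(coefficient_ratio(bof, bof).values()) == {1.0}

    def test_simple_ratio(self):
        assert coefficient_ratio(BOF({"A": -0.2}), BOF({"A": -0.1}))["A"] == 2.0

    def test_absent_reference_flagged_infinite(self):
        ratios = coefficient_ratio(BOF({"A": -0.1}), BOF({"B": -0.1}))
        assert math.isinf(ratios["A"]) and ratios["B"] == 0.0


class TestMassRedistribution:
    def normalized(self, coeffs, specs):
        return normalize_bof(BOF(coeffs), specs)

    def test_identical_bofs_no_redistribution(self):
        specs = {"A": 1.0, "B": 1.0}
        bof = self.normalized({"A": -0.6, "B": -0.4}, specs)
        deltas, total = mass_redistribution(bof, bof, specs)
        assert total == 0.0 and all(d == 0 for d in deltas.values())

    def test_ten_percent_shift(self):
        specs = {"A": 1.0, "B": 1.0}
        a = self.normalized({"A": -0.6, "B": -0.4}, specs)
        b = self.normalized({"A": -0.5, "B": -0.5}, specs)
        deltas, total = mass_redistribution(a, b, specs)
        assert total == pytest.approx(0.10)
        assert deltas["A"] == pytest.approx(100.0)  # mg per g

    def test_positive_and_negative_parts_balance(self):
        specs = {"A": 1.3, "B": 0.7, "C": 2.1}
        a = self.normalized({"A": -0.5, "B": -0.2, "C": -0.11}, specs)
        b = self.normalized({"A": -0.1, "B": -0.6, "C": -0.25}, specs)
        deltas, _ = mass_redistribution(a, b, specs)
        gains = sum(d for d in deltas.values() if d > 0)
        losses = -sum(d for d in deltas.values() if d < 0)
        assert gains == pytest.approx(losses, rel=1e-9)

    def test_unnormalized_input_rejected(self):
        specs = {"A": 1.0}
        with pytest.raises(BOFError, match="not normalized"):
            mass_redistribution(BOF({"A": -2.0}), BOF({"A": -1.0}), specs)
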