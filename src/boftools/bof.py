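"""Biomass objective function construction, normalization and BOF-vs-BOF metrics.

A BOF is a signed stoichiometric coefficient map (mmol/gCDW, negative =
consumed) for one biomass pseudo-reaction, with the growth-associated
maintenance (GAM) ATP hydrolysis kept apart: ATP + H2O -> ADP + Pi + H is
mass-neutral, so GAM neither contributes to the molar mass of biomass nor gets
rescaled during normalization. Mass accounting always uses the *net
incorporated* mass of a precursor (its coefficient times molar mass, minus the
mass of convention byproducts such as PPi released per NTP), which makes the
numbers independent of the template's polymerization bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .composition import BiomassComposition
from .constants import GAM_SPECIES, RESIDUE_FORMULA, RESIDUE_MASS, TEMPLATE_ALIASES_BIGG

MASS_TOLERANCE = 1e-9


class BOFError(ValueError):
    """Invalid BOF construction or accounting input."""


def formula_weight(formula: str) -> float:
    """Molar mass [g/mmol] of an elemental formula string."""
    from cobra import Metabolite

    met = Metabolite("tmp", formula=formula)
    weight = met.formula_weight
    if weight is None or not math.isfinite(weight):
        raise BOFError(f"unparseable formula {formula!r}")
    return weight / 1000.0


@dataclass(frozen=True)
class MetaboliteSpec:
    """Identity, formula and molar mass [g/mmol] of one biomass component."""

    metabolite_id: str
    name: str = ""
    formula: str = ""
    molar_mass: float = 0.0
    role: str = "biomass_precursor"  # biomass_precursor | energy_cofactor | byproduct

    def __post_init__(self):
        mass = self.molar_mass
        if self.formula and not mass:
            object.__setattr__(self, "molar_mass", formula_weight(self.formula))
            return
        if mass <= 0:
            raise BOFError(f"{self.metabolite_id}: molar mass must be positive")
        if self.formula:
            expected = formula_weight(self.formula)
            if expected > 0 and abs(mass - expected) / expected > 0.005:
                raise BOFError(
                    f"{self.metabolite_id}: molar mass {mass} inconsistent with "
                    f"formula {self.formula} ({expected:.4f} g/mmol)"
                )


SpecMap = Mapping[str, "MetaboliteSpec | float"]


def _molar_mass(specs: SpecMap, metabolite_id: str) -> float:
    try:
        spec = specs[metabolite_id]
    except KeyError:
        # polymer constituents are recorded as "polymer_id:monomer_id"
        _, _, suffix = metabolite_id.rpartition(":")
        if suffix and suffix in specs:
            spec = specs[suffix]
        else:
            raise BOFError(f"no metabolite spec / molar mass for {metabolite_id!r}")
    return spec.molar_mass if isinstance(spec, MetaboliteSpec) else float(spec)


def residue_specs(overrides: Mapping[str, float] | None = None) -> dict[str, MetaboliteSpec]:
    """MetaboliteSpecs for the built-in monomer vocabulary (residue masses)."""
    masses = dict(RESIDUE_MASS)
    if overrides:
        masses.update(overrides)
    return {
        mid: MetaboliteSpec(mid, formula=RESIDUE_FORMULA.get(mid, ""), molar_mass=m)
        for mid, m in masses.items()
    }


@dataclass
class BOF:
    """One biomass pseudo-reaction: coefficients [mmol/gCDW] plus a GAM term.

    ``coefficients`` hold the metabolic (non-GAM) part; ``gam`` is the molar
    amount of ATP hydrolysis added on top through ``gam_species``.
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    gam: float = 0.0
    gam_species: Mapping[str, float] = field(default_factory=lambda: dict(GAM_SPECIES))

    def total_coefficients(self) -> dict[str, float]:
        """Full stoichiometry with the GAM hydrolysis folded back in."""
        out = dict(self.coefficients)
        for species, direction in self.gam_species.items():
            out[species] = out.get(species, 0.0) + self.gam * direction
        return {k: v for k, v in out.items() if v != 0.0}

    def precursors(self) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items() if v < 0}

    @classmethod
    def from_reaction_stoichiometry(
        cls,
        stoichiometry: Mapping[str, float],
        gam_species: Mapping[str, float] | None = None,
    ) -> "BOF":
        """Split a reaction's stoichiometry into GAM and metabolic parts.

        The GAM magnitude is read off the hydrolysis products (ADP/Pi/H), which
        occur in the BOF only through maintenance.
        """
        gam_species = dict(GAM_SPECIES) if gam_species is None else dict(gam_species)
        products = [s for s, d in gam_species.items() if d > 0]
        gam = min((stoichiometry.get(s, 0.0) for s in products), default=0.0)
        gam = max(gam, 0.0)
        coeffs = dict(stoichiometry)
        for species, direction in gam_species.items():
            value = coeffs.get(species, 0.0) - gam * direction
            if abs(value) < 1e-12:
                coeffs.pop(species, None)
            else:
                coeffs[species] = value
        return cls({k: v for k, v in coeffs.items() if v != 0.0}, gam, gam_species)


def template_bof_from_model(model, reaction_id: str | None = None) -> BOF:
    """Extract the objective (biomass) reaction of a model as a BOF."""
    if reaction_id is None:
        from .fva import objective_reaction

        reaction_id = objective_reaction(model).id
    reaction = model.reactions.get_by_id(reaction_id)
    stoich = {met.id: coef for met, coef in reaction.metabolites.items()}
    return BOF.from_reaction_stoichiometry(stoich)


def specs_from_model(model) -> dict[str, MetaboliteSpec]:
    """Molar masses for every model metabolite, from its elemental formula.

    Metabolites with generic-residue formulas (R/X groups) have no defined
    mass and are skipped.
    """
    import warnings

    specs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for met in model.metabolites:
            try:
                weight = met.formula_weight
            except Exception:
                continue
            if weight is None or not weight or not math.isfinite(weight):
                continue
            specs[met.id] = MetaboliteSpec(
                met.id, name=met.name, molar_mass=weight / 1000.0
            )
    return specs


def ecoli_merge_policy() -> "MergePolicy":
    """Merge policy for the E. coli genome-scale templates (iJO1366/iML1515).

    Maps the measured monomer vocabulary onto the template namespace, spreads
    the lumped lipid mass over the template's phosphatidylethanolamine species,
    maps whole peptidoglycan onto the murein precursor (two repeat units per
    murein5px4p) and whole LPS onto the KDO2-lipid A precursor, and drops
    monomers knowingly absent from the template.
    """
    return MergePolicy(
        lipid_species=("pe160_c", "pe160_p", "pe161_c", "pe161_p"),
        polymer_species={
            "peptidoglycan": ("murein5px4p_p", 2.0),
            "lps": ("kdo2lipid4_e", 1.0),
        },
        drop=("rhamnose", "ribose"),
    )


def mass_to_coefficients(
    comp: BiomassComposition, specs: SpecMap
) -> dict[str, float]:
    """Convert mass fractions [g/gCDW] to consumption coefficients [mmol/gCDW].

    ``c_i = -w_i / M_i`` with the residue molar mass; zero-mass monomers are
    omitted. Combined pools must have been split beforehand.
    """
    out: dict[str, float] = {}
    for rec in comp.monomers:
        if rec.excluded or rec.mass_fraction == 0.0:
            continue
        if rec.is_pool:
            raise BOFError(
                f"combined pool {rec.monomer_id} must be split before conversion"
            )
        out[rec.monomer_id] = -rec.mass_fraction / _molar_mass(specs, rec.monomer_id)
    return out


#: template-species-level polymerization byproducts, derived from the monomer
#: alias map: per mmol of species consumed, the byproducts released.
BYPRODUCTS_BIGG: dict[str, dict[str, float]] = {
    species: dict(byp) for species, byp in TEMPLATE_ALIASES_BIGG.values() if byp
}


@dataclass
class MergePolicy:
    """How measured components map into a template BOF's namespace.

    ``aliases`` maps monomer ids to (template id, byproducts-per-unit);
    ``byproducts`` gives the template's own polymerization conventions so that
    replacing or removing a precursor rebalances PPi/H2O release; ``lipid_species``
    lists the template's lipid precursors over which a lumped lipid mass is
    spread at fixed molar ratios; ``drop`` lists measured ids knowingly absent
    from the template.
    """

    aliases: Mapping[str, tuple[str, Mapping[str, float]]] = field(
        default_factory=lambda: dict(TEMPLATE_ALIASES_BIGG)
    )
    byproducts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in BYPRODUCTS_BIGG.items()}
    )
    lipid_species: tuple[str, ...] = ()
    drop: tuple[str, ...] = ()
    #: polymer id -> (template species id, repeat units per template unit)
    polymer_species: Mapping[str, tuple[str, float]] = field(default_factory=dict)


def merge_with_template(
    measured: Mapping[str, float],
    template: BOF,
    policy: MergePolicy | None = None,
    specs: SpecMap | None = None,
    lipid_mass: float | None = None,
    removed: tuple[str, ...] = (),
) -> BOF:
    """Overlay measured coefficients on a template BOF.

    Measured components replace the template's coefficients (byproduct release
    rebalanced by the difference); template-only components — inorganic ions,
    cofactors, GAM — are retained unchanged; components listed in ``removed``
    (measured as not detected) are deleted. A lumped ``lipid_mass`` [g/gCDW] is
    spread over ``policy.lipid_species`` preserving their template molar ratios.
    """
    policy = policy or MergePolicy()
    coeffs = dict(template.coefficients)

    def adjust_byproducts(template_id: str, delta_consumed: float) -> None:
        for b, per_unit in policy.byproducts.get(template_id, {}).items():
            coeffs[b] = coeffs.get(b, 0.0) + delta_consumed * per_unit

    unmapped = [
        m for m in measured
        if m not in policy.aliases and m not in coeffs and m not in policy.drop
    ]
    # ids already in the template namespace pass through unaliased
    for m in list(unmapped):
        if m.endswith(("_c", "_p", "_e")):
            unmapped.remove(m)
    if unmapped:
        raise BOFError(f"measured components with no template mapping: {unmapped}")

    for monomer, coef in measured.items():
        if monomer in policy.drop:
            continue
        template_id, _ = policy.aliases.get(monomer, (monomer, {}))
        old = coeffs.get(template_id, 0.0)
        if old > 0 and coef < 0:
            raise BOFError(
                f"{monomer} -> {template_id}: measured consumption collides with "
                "template production"
            )
        coeffs[template_id] = coef
        adjust_byproducts(template_id, abs(coef) - abs(old))

    for template_id in removed:
        old = coeffs.pop(template_id, 0.0)
        adjust_byproducts(template_id, -abs(old))

    if lipid_mass is not None:
        if not policy.lipid_species:
            raise BOFError("lipid_mass given but policy.lipid_species is empty")
        if specs is None:
            raise BOFError("lipid scaling requires metabolite specs")
        current = sum(
            abs(coeffs.get(s, 0.0)) * _molar_mass(specs, s)
            for s in policy.lipid_species
        )
        if current <= 0:
            raise BOFError("template lipid species carry no mass to rescale")
        factor = lipid_mass / current
        for s in policy.lipid_species:
            if s in coeffs:
                coeffs[s] *= factor

    coeffs = {k: v for k, v in coeffs.items() if abs(v) > 1e-15}
    return BOF(coeffs, template.gam, dict(template.gam_species))


def net_incorporated_mass(
    metabolite_id: str, specs: SpecMap,
    byproducts: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Net mass [g/mmol] one unit of a precursor leaves in biomass."""
    byproducts = BYPRODUCTS_BIGG if byproducts is None else byproducts
    mass = _molar_mass(specs, metabolite_id)
    for b, per_unit in byproducts.get(metabolite_id, {}).items():
        mass -= per_unit * _molar_mass(specs, b)
    return mass


def bof_mass(bof: BOF, specs: SpecMap) -> float:
    """Net mass of 1 mmol of biomass [g/mmol], GAM excluded.

    Sum of reactant masses minus product masses over the metabolic part; for a
    properly accounted BOF this is the molar mass of the biomass pseudo-species.
    """
    return float(
        -sum(c * _molar_mass(specs, m) for m, c in bof.coefficients.items())
    )


def normalize_bof(bof: BOF, specs: SpecMap) -> BOF:
    """Scale the metabolic coefficients so the biomass molar mass is 1 g/mmol.

    Idempotent and scale-covariant; the GAM term is left untouched.
    """
    mass = bof_mass(bof, specs)
    if mass <= 0:
        raise BOFError(f"cannot normalize BOF with non-positive mass {mass}")
    scaled = {m: c / mass for m, c in bof.coefficients.items()}
    return replace(bof, coefficients=scaled)


def is_normalized(bof: BOF, specs: SpecMap, tol: float = MASS_TOLERANCE) -> bool:
    return abs(bof_mass(bof, specs) - 1.0) <= tol


def coefficient_ratio(bofA: BOF, bofB: BOF) -> dict[str, float]:
    """Per-component coefficient ratio S_r = |alpha| / |beta| (A over B).

    Components present in A but absent (or zero) in B are flagged ``inf``;
    components absent from A get 0. GAM is compared through its own term.
    """
    out: dict[str, float] = {}
    a, b = bofA.coefficients, bofB.coefficients
    for m in sorted(set(a) | set(b)):
        alpha, beta = abs(a.get(m, 0.0)), abs(b.get(m, 0.0))
        if beta == 0.0:
            out[m] = math.inf if alpha > 0 else 1.0
        else:
            out[m] = alpha / beta
    return out


def mass_redistribution(
    bofA: BOF,
    bofB: BOF,
    specs: SpecMap,
    byproducts: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[dict[str, float], float]:
    """Per-precursor change in contributed mass between two normalized BOFs.

    Returns (per-component delta [mg per g biomass], total reallocated mass as
    a fraction of 1 g). Deltas use net incorporated masses, so byproduct
    species themselves carry no separate entry; the total is the summed
    positive part, which for equal-coverage BOFs equals the summed negative
    part by mass conservation.
    """
    for name, bof in (("first", bofA), ("second", bofB)):
        if not is_normalized(bof, specs, tol=1e-6):
            raise BOFError(
                f"{name} BOF is not normalized (mass {bof_mass(bof, specs):.6f})"
            )
    byproducts = BYPRODUCTS_BIGG if byproducts is None else byproducts
    deltas: dict[str, float] = {}
    a, b = bofA.coefficients, bofB.coefficients
    for m in sorted(set(a) | set(b)):
        if a.get(m, 0.0) >= 0 and b.get(m, 0.0) >= 0:
            continue  # released byproduct / output, accounted inside precursors
        net = net_incorporated_mass(m, specs, byproducts)
        deltas[m] = (abs(a.get(m, 0.0)) - abs(b.get(m, 0.0))) * net * 1000.0
    total = sum(d for d in deltas.values() if d > 0) / 1000.0
    return deltas, float(total)
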