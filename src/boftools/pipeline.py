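"""End-to-end assembly: measurements + sequences -> composition -> BOF.

This is the glue the command line and the synthetic recovery tests drive: fill
in what the assays could not measure (imputation, pool splitting, nucleotide
distributions), optionally expand polymer proxies, convert to molar
coefficients and normalize to a biomass molar mass of 1 g/mmol.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import bof as bofmod
from .composition import BiomassComposition, load_composition
from .inference import (
    PrevalenceVector,
    SequenceSet,
    impute_missing_monomers,
    nucleotide_distribution,
    proteome_prevalence,
    split_combined_pool,
)
from .polymers import PolymerDef, apply_polymer_proxies


def infer_composition(
    comp: BiomassComposition,
    seqs: SequenceSet | None = None,
    prevalence: PrevalenceVector | None = None,
    intercept: bool = True,
) -> BiomassComposition:
    """Resolve estimated rows, combined pools and nucleotide distributions.

    Protein rows flagged ``estimated`` with zero mass are imputed by OLS
    against proteome prevalence; ``A+B`` pools are split by prevalence; RNA and
    DNA monomer rows flagged ``estimated`` receive class total times the
    sequence-derived mass distribution. ``prevalence`` overrides the
    sequence-derived amino acid prevalence when given.
    """
    import copy

    comp = copy.deepcopy(comp)
    if prevalence is None and seqs is not None and seqs.by_role("protein_coding"):
        prevalence, _ = proteome_prevalence(seqs)

    protein = comp.class_records("protein")
    if prevalence is None:
        pool_members = [m for r in protein if r.is_pool for m in r.pool_members()]
        if pool_members:
            import warnings

            warnings.warn(
                "no prevalence source supplied; combined pools split evenly"
            )
            prevalence = PrevalenceVector(
                {m: 1.0 / len(pool_members) for m in pool_members}, "mass"
            )
    if prevalence is not None:
        measured = {
            r.monomer_id: r.mass_fraction
            for r in protein
            if r.status == "measured" and not r.is_pool
            and r.monomer_id in prevalence.entries
        }
        targets = [
            r.monomer_id for r in protein
            if r.status == "estimated" and r.mass_fraction == 0.0
        ]
        if targets:
            imputed = impute_missing_monomers(measured, prevalence, targets, intercept)
            for monomer, value in imputed.items():
                comp.replace_monomer(monomer, mass_fraction=value)
        for rec in [r for r in protein if r.is_pool]:
            a, b = rec.pool_members()
            mass_a, mass_b = split_combined_pool(rec.mass_fraction, (a, b), prevalence)
            comp.monomers = [m for m in comp.monomers if m.monomer_id != rec.monomer_id]
            for mid, mass in ((a, mass_a), (b, mass_b)):
                comp.monomers.append(
                    type(rec)(mid, rec.macro_class, mass, None, "estimated",
                              f"split from {rec.monomer_id}")
                )

    if seqs is not None:
        for cls, molecule in (("RNA", "RNA"), ("DNA", "dsDNA")):
            records = [
                r for r in comp.class_records(cls)
                if r.status == "estimated" and r.mass_fraction == 0.0
            ]
            if not records or cls not in comp.classes:
                continue
            mass_pv, _ = nucleotide_distribution(seqs, molecule)
            total = comp.classes[cls][0]
            for rec in records:
                comp.replace_monomer(
                    rec.monomer_id,
                    mass_fraction=total * mass_pv[rec.monomer_id],
                )
    return comp


def template_pool_prevalence(
    template: bofmod.BOF,
    pools: Sequence[tuple[str, str]] = (("Glu", "Gln"), ("Asp", "Asn")),
) -> PrevalenceVector:
    """Amino acid prevalence implied by a template BOF's own coefficients.

    Used to split deamidation pools when no proteome sequences are supplied:
    the template's molar ratios (times residue mass, for the mass basis) stand
    in for proteome prevalence over the pooled amino acids.
    """
    from .constants import TEMPLATE_ALIASES_BIGG

    specs = bofmod.residue_specs()
    entries: dict[str, float] = {}
    for a, b in pools:
        for aa in (a, b):
            template_id, _ = TEMPLATE_ALIASES_BIGG[aa]
            entries[aa] = (
                abs(template.coefficients.get(template_id, 0.0))
                * specs[aa].molar_mass
            )
    total = sum(entries.values())
    if total <= 0:
        raise ValueError("template carries none of the pooled amino acids")
    return PrevalenceVector({k: v / total for k, v in entries.items()}, "mass")


def build_bof(
    comp: BiomassComposition,
    specs: Mapping | None = None,
    polymer_defs: Sequence[PolymerDef] | Mapping[str, PolymerDef] | None = None,
    template: bofmod.BOF | None = None,
    policy: bofmod.MergePolicy | None = None,
    normalize: bool = True,
) -> tuple[bofmod.BOF, dict]:
    """Composition -> (BOF, build report).

    Applies polymer proxies when definitions are given, converts mass fractions
    to consumption coefficients, optionally merges with a template BOF
    (handling a lumped lipid record through the template's lipid species), and
    normalizes. The report carries coverage before/after proxies and the raw
    coefficient map.
    """
    from .composition import total_coverage
    from .polymers import polymer_adjusted_coverage

    specs = bofmod.residue_specs() if specs is None else specs
    report: dict = {"coverage": total_coverage(comp)}
    polymer_info: dict = {}
    if polymer_defs:
        comp, polymer_info = apply_polymer_proxies(comp, polymer_defs)
        total, per_class = polymer_adjusted_coverage(comp)
        report.update(
            adjusted_coverage=total,
            adjusted_class_totals=per_class,
            polymers=polymer_info,
        )
    extra_coefficients: dict[str, float] = {}
    if template is not None and policy is not None and policy.polymer_species:
        # map whole polymers onto the template's envelope precursor species and
        # drop their monomer-level records from the molar conversion
        if isinstance(polymer_defs, Mapping):
            defs_by_id = dict(polymer_defs)
        else:
            defs_by_id = {d.polymer_id: d for d in (polymer_defs or [])}
        drop_ids: set[str] = set()
        for pid, (template_id, per_template) in policy.polymer_species.items():
            if pid not in polymer_info:
                continue
            extra_coefficients[template_id] = -polymer_info[pid]["units"] / per_template
            pdef = defs_by_id[pid]
            drop_ids.add(pdef.proxy.monomer_id)
            drop_ids.update(
                f"{pid}:{c.monomer_id}" for c in pdef.constituents
                if c.source == "implicit"
            )
        comp = type(comp)(
            classes=comp.classes,
            monomers=[m for m in comp.monomers if m.monomer_id not in drop_ids],
        )
    lipid_mass = None
    if template is not None and policy is not None and policy.lipid_species:
        try:
            lipid_mass = comp.monomer("lipid").mass_fraction
            comp = type(comp)(
                classes=comp.classes,
                monomers=[m for m in comp.monomers if m.monomer_id != "lipid"],
            )
        except KeyError:
            pass
    coefficients = bofmod.mass_to_coefficients(comp, specs)
    coefficients.update(extra_coefficients)
    report["coefficients"] = dict(coefficients)
    if template is None:
        result = bofmod.BOF(dict(coefficients))
    else:
        result = bofmod.merge_with_template(
            coefficients, template, policy, specs=specs, lipid_mass=lipid_mass
        )
    if normalize:
        mass = bofmod.bof_mass(result, specs)
        report["bof_mass_before_normalization"] = mass
        result = bofmod.normalize_bof(result, specs)
    return result, report


def build_ecoli_ebof(model, comp: BiomassComposition | None = None):
    """Build the experimentally determined BOF against an E. coli template.

    Uses the shipped K-12 exponential-growth composition by default, splits
    deamidation pools by the template's own amino acid ratios, expands the
    K-12 envelope-polymer presets and merges into the template's namespace.
    Returns (eBOF, normalized template BOF, specs, build report).
    """
    from .bof import (
        ecoli_merge_policy,
        normalize_bof,
        residue_specs,
        specs_from_model,
        template_bof_from_model,
    )
    from .constants import data_path
    from .polymers import k12_presets

    if comp is None:
        with data_path("ecoli_k12_mg1655_exponential.tsv") as path:
            comp = load_composition(path)
    template = template_bof_from_model(model)
    specs = {**residue_specs(), **specs_from_model(model)}
    comp = infer_composition(comp, prevalence=template_pool_prevalence(template))
    ebof, report = build_bof(
        comp,
        specs=specs,
        polymer_defs=k12_presets(),
        template=template,
        policy=ecoli_merge_policy(),
    )
    return ebof, normalize_bof(template, specs), specs, report


def run_synthetic_pipeline(scenario, normalize: bool = True):
    """Full pipeline on one synthetic scenario; returns (BOF, report).

    The report's ``recovered`` entry maps monomer id to the mass fraction
    implied by the (unnormalized) coefficients, directly comparable to the
    scenario's true composition.
    """
    from .bof import residue_specs
    from .synthetic import generate_measurements, generate_sequences

    seqs = generate_sequences(scenario)
    table = generate_measurements(scenario)
    comp = load_composition(table)
    comp = infer_composition(comp, seqs)
    specs = residue_specs()
    built, report = build_bof(comp, specs=specs, normalize=normalize)
    scale = report.get("bof_mass_before_normalization", 1.0) if normalize else 1.0
    report["recovered"] = {
        m: -c * scale * specs[m].molar_mass
        for m, c in built.coefficients.items()
    }
    return built, report
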