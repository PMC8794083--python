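"""Polymer-proxy accounting: infer full polymer mass from marker monomers.

Hydrolysis-based assays see cell-envelope polymers only through the monomers
they release: peptidoglycan through N-acetylglucosamine (recovered as
glucosamine after de-N-acetylation) and K-12 core LPS through its single
protruding galactose. Given a polymer's repeat-unit stoichiometry, the measured
proxy monomer pins down the molar amount of polymer, and every constituent the
assay could not see (MurNAc, KDO, heptose, lipid A components, peptide stem) is
added back as a ``proxy_derived`` record.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

from .composition import BiomassComposition, MonomerRecord, total_coverage
from .constants import MONOMER_CLASS, data_path, residue_masses


class PolymerError(ValueError):
    """Invalid polymer definition or proxy accounting input."""


@dataclass(frozen=True)
class Constituent:
    monomer_id: str
    count: float
    source: str  # proxy | implicit | measured_pool

    def __post_init__(self):
        if self.count <= 0:
            raise PolymerError(f"{self.monomer_id}: count must be positive")
        if self.source not in ("proxy", "implicit", "measured_pool"):
            raise PolymerError(f"{self.monomer_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class PolymerDef:
    """Repeat-unit stoichiometry of a polymer and its measured proxy monomer."""

    polymer_id: str
    constituents: tuple[Constituent, ...]
    description: str = ""

    def __post_init__(self):
        proxies = [c for c in self.constituents if c.source == "proxy"]
        if len(proxies) != 1:
            raise PolymerError(
                f"{self.polymer_id}: exactly one proxy constituent required"
            )

    @property
    def proxy(self) -> Constituent:
        return next(c for c in self.constituents if c.source == "proxy")

    def unit_mass(self, masses: Mapping[str, float]) -> float:
        """Mass of one polymerized repeat unit [g/mmol]."""
        return sum(c.count * masses[c.monomer_id] for c in self.constituents)


def load_polymer_defs(path=None) -> dict[str, PolymerDef]:
    """Read polymer definitions from YAML (the shipped K-12 presets by default)."""
    if path is None:
        with data_path("polymer_presets.yaml") as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = {}
    for pid, entry in raw.items():
        constituents = tuple(
            Constituent(c["monomer"], float(c["count"]), c["source"])
            for c in entry["constituents"]
        )
        defs[pid] = PolymerDef(pid, constituents, entry.get("description", ""))
    return defs


def k12_presets() -> dict[str, PolymerDef]:
    """The shipped E. coli K-12 peptidoglycan and core-LPS definitions."""
    return load_polymer_defs()


DEFAULT_REASSIGNMENTS: Mapping[str, str] = {"glucosamine": "N-acetylglucosamine"}


def apply_polymer_proxies(
    comp: BiomassComposition,
    defs: Sequence[PolymerDef] | Mapping[str, PolymerDef],
    reassignments: Mapping[str, str] = DEFAULT_REASSIGNMENTS,
    residue_mass_overrides: Mapping[str, float] | None = None,
) -> tuple[BiomassComposition, dict[str, float]]:
    """Expand proxy monomers into full polymer composition.

    ``reassignments`` first renames chemically converted monomers (e.g.
    glucosamine -> N-acetylglucosamine, rescaling mass by the residue-mass
    ratio). Each polymer's molar amount is then fixed by its proxy monomer, and
    implicit constituents are added as ``proxy_derived`` records named
    ``polymer_id:monomer_id``; class totals grow by the implicit mass. The
    proxy monomer's own mass is conserved exactly. Returns the adjusted
    composition and, per polymer, its molar amount [mmol/gCDW] and total mass
    [g/gCDW] as ``{polymer_id: {"units": ..., "mass": ...}}``.
    """
    if isinstance(defs, Mapping):
        defs = list(defs.values())
    masses = residue_masses(residue_mass_overrides)
    comp = copy.deepcopy(comp)

    for source_id, target_id in reassignments.items():
        try:
            rec = comp.monomer(source_id)
        except KeyError:
            continue
        scale = masses[target_id] / masses[source_id]
        # drop any placeholder record for the target (e.g. not-detected GlcNAc)
        comp.monomers = [m for m in comp.monomers if m.monomer_id != target_id]
        comp.replace_monomer(
            source_id,
            monomer_id=target_id,
            macro_class=MONOMER_CLASS[target_id],
            mass_fraction=rec.mass_fraction * scale,
            status="proxy_derived",
            note=f"reassigned from {source_id}",
        )
        delta = rec.mass_fraction * (scale - 1.0)
        _grow_class(comp, MONOMER_CLASS[target_id], delta)

    polymer_mass: dict[str, dict[str, float]] = {}
    for pdef in defs:
        proxy = pdef.proxy
        try:
            rec = comp.monomer(proxy.monomer_id)
        except KeyError:
            raise PolymerError(
                f"{pdef.polymer_id}: proxy monomer {proxy.monomer_id} absent"
            )
        units = rec.mass_fraction / (proxy.count * masses[proxy.monomer_id])
        if units < 0:
            raise PolymerError(f"{pdef.polymer_id}: negative implied polymer mass")
        polymer_mass[pdef.polymer_id] = {
            "units": units,
            "mass": units * pdef.unit_mass(masses),
        }
        comp.replace_monomer(
            proxy.monomer_id,
            status="proxy_derived" if rec.status != "measured" else rec.status,
            note=(rec.note + "; " if rec.note else "") + f"proxy for {pdef.polymer_id}",
        )
        if units == 0:
            continue
        for c in pdef.constituents:
            if c.source != "implicit":
                continue
            mass = units * c.count * masses[c.monomer_id]
            cls = MONOMER_CLASS[c.monomer_id]
            comp.monomers.append(
                MonomerRecord(
                    monomer_id=f"{pdef.polymer_id}:{c.monomer_id}",
                    macro_class=cls,
                    mass_fraction=mass,
                    status="proxy_derived",
                    note=f"implicit {pdef.polymer_id} constituent",
                )
            )
            _grow_class(comp, cls, mass)
    return comp, polymer_mass


def _grow_class(comp: BiomassComposition, macro_class: str, delta: float) -> None:
    mass, sd = comp.classes.get(macro_class, (0.0, None))
    comp.classes[macro_class] = (mass + delta, sd)


def polymer_adjusted_coverage(
    comp_adjusted: BiomassComposition,
) -> tuple[float, dict[str, float]]:
    """Total and per-class coverage [g/gCDW] of a proxy-adjusted composition."""
    per_class = {cls: mass for cls, (mass, _) in comp_adjusted.classes.items()}
    return total_coverage(comp_adjusted), per_class
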