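"""Controlled vocabulary and physical constants shared across the pipeline.

Monomer identifiers form a fixed controlled vocabulary (20 amino acids, 4 NMPs,
4 dNMPs, named sugars, a lumped lipid class) so that measurement tables,
sequence-derived prevalence vectors and model metabolite ids join stably.
Residue masses are polymer-incorporated masses (monomer minus the water or
equivalent leaving group lost on polymerization), shipped as a versioned data
file and overridable per call.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

MACRO_CLASSES = ("protein", "RNA", "DNA", "carbohydrate", "lipid")
STATUSES = ("measured", "estimated", "proxy_derived", "not_detected")

#: map single-letter amino acid code -> canonical monomer id
AA_CODES: Mapping[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

#: RNA base -> ribonucleotide monophosphate residue id
RNA_BASES: Mapping[str, str] = {"A": "AMP", "C": "CMP", "G": "GMP", "U": "UMP"}
#: DNA base -> deoxyribonucleotide monophosphate residue id
DNA_BASES: Mapping[str, str] = {"A": "dAMP", "C": "dCMP", "G": "dGMP", "T": "dTMP"}

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: growth-associated maintenance (GAM) hydrolysis set, BiGG namespace;
#: ATP + H2O -> ADP + Pi + H is mass-neutral and excluded from normalization
GAM_SPECIES: Mapping[str, float] = {
    "atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
}

def _load_residue_table() -> pd.DataFrame:
    ref = resources.files("boftools.data").joinpath("residue_masses.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")

_RESIDUES = _load_residue_table()

#: monomer id -> residue molar mass [g/mmol]
RESIDUE_MASS: Mapping[str, float] = dict(
    zip(_RESIDUES["monomer_id"], _RESIDUES["residue_mass"])
)
#: monomer id -> elemental formula of the polymerized residue
RESIDUE_FORMULA: Mapping[str, str] = dict(
    zip(_RESIDUES["monomer_id"], _RESIDUES["residue_formula"])
)
#: monomer id -> macromolecular class it belongs to
MONOMER_CLASS: Mapping[str, str] = dict(
    zip(_RESIDUES["monomer_id"], _RESIDUES["macro_class"])
)

KNOWN_MONOMERS = frozenset(RESIDUE_MASS)


def residue_masses(overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Return the shipped residue-mass table with optional per-entry overrides."""
    table = dict(RESIDUE_MASS)
    if overrides:
        table.update(overrides)
    return table


def data_path(name: str):
    """Context manager yielding a real filesystem path to a shipped data file."""
    return resources.as_file(resources.files("boftools.data").joinpath(name))


#: measured monomer id -> (template metabolite id, byproducts per unit incorporated)
#: in the BiGG namespace used by the E. coli templates (iJO1366 / iML1515).
#: Byproducts express the template's polymerization convention: amino acids are
#: consumed as free acids releasing one water per peptide bond; (d)NMPs enter as
#: (d)NTPs releasing pyrophosphate.
TEMPLATE_ALIASES_BIGG: Mapping[str, tuple[str, Mapping[str, float]]] = {
    **{aa: (f"{aa.lower()}__L_c", {"h2o_c": 1.0}) for aa in AA_CODES.values()
       if aa != "Gly"},
    "Gly": ("gly_c", {"h2o_c": 1.0}),
    "AMP": ("atp_c", {"ppi_c": 1.0}),
    "GMP": ("gtp_c", {"ppi_c": 1.0}),
    "CMP": ("ctp_c", {"ppi_c": 1.0}),
    "UMP": ("utp_c", {"ppi_c": 1.0}),
    "dAMP": ("datp_c", {"ppi_c": 1.0}),
    "dGMP": ("dgtp_c", {"ppi_c": 1.0}),
    "dCMP": ("dctp_c", {"ppi_c": 1.0}),
    "dTMP": ("dttp_c", {"ppi_c": 1.0}),
    "glucose": ("glycogen_c", {}),
}
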