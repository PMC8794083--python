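"""Estimate monomer quantities the assays cannot measure.

Three inference steps feed the composition before BOF construction:

* amino acids lost or degraded during acid hydrolysis (Cys, Met, Pro, Trp) are
  imputed from an ordinary least-squares fit of measured amino acid mass
  fractions against their prevalence in the organism's protein-coding genes;
* jointly measured deamidation pools (Glu+Gln, Asp+Asn) are split in proportion
  to the same prevalence;
* ribonucleotide and deoxyribonucleotide distributions are taken from the
  monomeric composition of rRNA-encoding genes and of the (double-stranded)
  genome, respectively.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    AA_CODES,
    DNA_BASES,
    DNA_COMPLEMENT,
    RNA_BASES,
    residue_masses,
)

ROLES = ("genome", "rRNA_gene", "protein_coding")
_NT_CHARS = frozenset("ACGTUN")
_AA_CHARS = frozenset(AA_CODES) | {"X"}


class InferenceError(ValueError):
    """Invalid input to a monomer-inference operation."""


@dataclass(frozen=True)
class SequenceEntry:
    """One sequence record with its biological role in the pipeline."""

    id: str
    sequence: str
    alphabet: str  # nucleotide | protein
    role: str  # genome | rRNA_gene | protein_coding

    def __post_init__(self):
        if not self.sequence:
            raise InferenceError(f"{self.id}: empty sequence")
        if self.role not in ROLES:
            raise InferenceError(f"{self.id}: unknown role {self.role!r}")
        allowed = _NT_CHARS if self.alphabet == "nucleotide" else _AA_CHARS
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise InferenceError(
                f"{self.id}: invalid {self.alphabet} characters {sorted(bad)}"
            )


@dataclass
class SequenceSet:
    """Genome, rRNA-gene and protein-coding records used for inference."""

    records: list[SequenceEntry] = field(default_factory=list)

    def by_role(self, role: str) -> list[SequenceEntry]:
        return [r for r in self.records if r.role == role]

    @classmethod
    def from_fasta(cls, path: str | Path, role: str, alphabet: str) -> "SequenceSet":
        from Bio import SeqIO

        records = [
            SequenceEntry(rec.id, str(rec.seq).upper(), alphabet, role)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise InferenceError(f"{path}: no FASTA records")
        return cls(records)

    @classmethod
    def from_genbank(cls, path: str | Path) -> "SequenceSet":
        """Extract genome, rRNA gene and CDS translation records from GenBank."""
        from Bio import SeqIO

        records: list[SequenceEntry] = []
        for rec in SeqIO.parse(str(path), "genbank"):
            records.append(
                SequenceEntry(rec.id, str(rec.seq).upper(), "nucleotide", "genome")
            )
            for feat in rec.features:
                if feat.type == "rRNA":
                    seq = str(feat.extract(rec.seq)).upper()
                    name = feat.qualifiers.get("locus_tag", [feat.type])[0]
                    records.append(SequenceEntry(name, seq, "nucleotide", "rRNA_gene"))
                elif feat.type == "CDS" and "translation" in feat.qualifiers:
                    name = feat.qualifiers.get("locus_tag", ["cds"])[0]
                    records.append(
                        SequenceEntry(
                            name,
                            feat.qualifiers["translation"][0].upper(),
                            "protein",
                            "protein_coding",
                        )
                    )
        if not records:
            raise InferenceError(f"{path}: no GenBank records")
        return cls(records)


@dataclass(frozen=True)
class PrevalenceVector:
    """Relative monomer abundances summing to one on a molar or mass basis."""

    entries: Mapping[str, float]
    basis: str  # molar | mass

    def __post_init__(self):
        if self.basis not in ("molar", "mass"):
            raise InferenceError(f"unknown basis {self.basis!r}")
        values = np.array(list(self.entries.values()), dtype=float)
        if (values < 0).any():
            raise InferenceError("prevalence entries must be non-negative")
        if abs(values.sum() - 1.0) > 1e-9:
            raise InferenceError(
                f"prevalence entries sum to {values.sum():.12f}, expected 1"
            )

    def __getitem__(self, monomer_id: str) -> float:
        return self.entries[monomer_id]


def _normalize(counts: Mapping[str, float]) -> dict[str, float]:
    total = sum(counts.values())
    if total <= 0:
        raise InferenceError("no countable residues")
    return {k: v / total for k, v in counts.items()}


def proteome_prevalence(
    seqs: SequenceSet, residue_mass_overrides: Mapping[str, float] | None = None
) -> tuple[PrevalenceVector, PrevalenceVector]:
    """Amino acid prevalence across protein-coding records.

    Returns (mass-basis, molar-basis) vectors; counts are weighted by the
    polymerized residue mass for the mass basis. Unknown residue ``X`` is
    skipped with a warning; any other character is an error.
    """
    records = seqs.by_role("protein_coding")
    if not records:
        raise InferenceError("no protein_coding records")
    masses = residue_masses(residue_mass_overrides)
    counts: Counter[str] = Counter()
    skipped = 0
    for rec in records:
        for ch in rec.sequence.upper():
            if ch == "X":
                skipped += 1
                continue
            if ch not in AA_CODES:
                raise InferenceError(f"{rec.id}: unknown residue {ch!r}")
            counts[AA_CODES[ch]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} unknown 'X' residues")
    molar = _normalize(counts)
    mass = _normalize({aa: n * masses[aa] for aa, n in counts.items()})
    return (
        PrevalenceVector(mass, "mass"),
        PrevalenceVector(molar, "molar"),
    )


def impute_missing_monomers(
    measured: Mapping[str, float],
    prevalence: PrevalenceVector,
    targets: Sequence[str],
    intercept: bool = True,
) -> dict[str, float]:
    """Predict unmeasured monomer mass fractions by OLS on prevalence.

    Fits ``mass_fraction = a + b * prevalence`` over the measured pairs (or
    through the origin when ``intercept`` is False) and evaluates the line at
    each target's prevalence, clipping negative predictions to zero with a
    warning. Measured values are never altered.
    """
    pairs = [(prevalence[m], y) for m, y in measured.items() if m in prevalence.entries]
    if len(pairs) < 3:
        raise InferenceError(
            f"need at least 3 measured monomers with prevalence, got {len(pairs)}"
        )
    missing = [t for t in targets if t not in prevalence.entries]
    if missing:
        raise InferenceError(f"targets absent from prevalence: {missing}")
    x = np.array([p for p, _ in pairs])
    y = np.array([v for _, v in pairs])
    if intercept:
        design = np.column_stack([np.ones_like(x), x])
    else:
        design = x[:, None]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    predict = (lambda xv: coef[0] + coef[1] * xv) if intercept else (lambda xv: coef[0] * xv)
    out: dict[str, float] = {}
    for target in targets:
        value = float(predict(prevalence[target]))
        if value < 0:
            warnings.warn(f"{target}: negative prediction {value:.4g} clipped to 0")
            value = 0.0
        out[target] = value
    return out


def split_combined_pool(
    pool_total: float,
    pair: tuple[str, str],
    prevalence: PrevalenceVector,
) -> tuple[float, float]:
    """Split a jointly measured pool over its two members by prevalence.

    The split is proportional to the members' prevalence entries and conserves
    the pool total exactly.
    """
    if pool_total < 0:
        raise InferenceError("pool total must be non-negative")
    a, b = pair
    pa, pb = prevalence[a], prevalence[b]
    if pa + pb <= 0:
        raise InferenceError(f"zero prevalence for both pool members {pair}")
    share = pa / (pa + pb)
    mass_a = pool_total * share
    return mass_a, pool_total - mass_a


def nucleotide_distribution(
    seqs: SequenceSet,
    molecule: str,
    residue_mass_overrides: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
    max_ambiguous: float = 0.01,
) -> tuple[PrevalenceVector, PrevalenceVector]:
    """Base composition of RNA (from rRNA genes) or dsDNA (from the genome).

    RNA uses the gene-strand sequence of ``rRNA_gene`` records with T read as
    U; dsDNA counts both the supplied genome strand and its reverse complement,
    which forces the dAMP=dTMP, dGMP=dCMP symmetry of double-stranded DNA.
    Per-record ``weights`` multiply counts (e.g. rRNA operon stoichiometry).
    Returns (mass-basis, molar-basis) prevalence vectors.
    """
    if molecule == "RNA":
        records, base_map = seqs.by_role("rRNA_gene"), RNA_BASES
    elif molecule == "dsDNA":
        records, base_map = seqs.by_role("genome"), DNA_BASES
    else:
        raise InferenceError(f"unknown molecule {molecule!r}")
    if not records:
        raise InferenceError(f"no records with the role required for {molecule}")
    masses = residue_masses(residue_mass_overrides)
    counts: Counter[str] = Counter({m: 0.0 for m in base_map.values()})
    n_ambiguous = n_total = 0
    for rec in records:
        w = 1.0 if weights is None else float(weights.get(rec.id, 1.0))
        seq = rec.sequence.upper()
        if molecule == "RNA":
            seq = seq.replace("T", "U")
        else:
            seq = seq + seq.translate(DNA_COMPLEMENT)
        for ch in seq:
            n_total += 1
            if ch == "N":
                n_ambiguous += 1
                continue
            if ch not in base_map:
                raise InferenceError(f"{rec.id}: unexpected base {ch!r}")
            counts[base_map[ch]] += w
    if n_ambiguous:
        if n_ambiguous > max_ambiguous * n_total:
            raise InferenceError(
                f"{n_ambiguous}/{n_total} ambiguous bases exceed the "
                f"{max_ambiguous:.0%} limit"
            )
        warnings.warn(f"skipped {n_ambiguous} ambiguous 'N' bases")
    molar = _normalize(counts)
    mass = _normalize({m: c * masses[m] for m, c in counts.items()})
    return PrevalenceVector(mass, "mass"), PrevalenceVector(molar, "molar")
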