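"""Data model, validation and coverage accounting for biomass composition.

A :class:`BiomassComposition` is the computational image of a macromolecular
composition table: per-class totals measured independently (g/gCDW), per-monomer
mass fractions with provenance flags, and combined pools for monomers that were
quantified jointly (e.g. Glu+Gln after acid-hydrolysis deamidation). Class
totals and monomer sums may legitimately disagree, so a mismatch beyond
tolerance is reported as a warning diagnostic, never silently corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import pandas as pd

from .constants import MACRO_CLASSES, STATUSES

#: class total vs monomer sum agreement tolerance [g/gCDW]
SUM_TOLERANCE = 0.005


class CompositionError(ValueError):
    """Malformed or invariant-violating composition input."""


@dataclass(frozen=True)
class MonomerRecord:
    """One monomer's mass fraction [g/gCDW] with measurement provenance."""

    monomer_id: str
    macro_class: str
    mass_fraction: float
    sd: float | None = None
    status: str = "measured"
    note: str = ""

    def __post_init__(self):
        if self.macro_class not in MACRO_CLASSES:
            raise CompositionError(
                f"{self.monomer_id}: unknown macro class {self.macro_class!r}"
            )
        if self.status not in STATUSES:
            raise CompositionError(
                f"{self.monomer_id}: unknown status {self.status!r}"
            )
        if not math.isfinite(self.mass_fraction) or self.mass_fraction < 0:
            raise CompositionError(
                f"{self.monomer_id}: mass fraction must be a finite non-negative "
                f"g/gCDW value, got {self.mass_fraction!r}"
            )
        if self.mass_fraction > 1:
            raise CompositionError(
                f"{self.monomer_id}: mass fraction {self.mass_fraction} > 1; "
                "fractions must be g/gCDW, not percent"
            )
        if self.status == "not_detected" and self.mass_fraction != 0:
            raise CompositionError(
                f"{self.monomer_id}: status not_detected requires mass 0"
            )

    @property
    def excluded(self) -> bool:
        """True when the record is flagged out of coverage accounting."""
        return self.note.startswith("excluded")

    @property
    def is_pool(self) -> bool:
        return "+" in self.monomer_id

    def pool_members(self) -> tuple[str, str]:
        a, _, b = self.monomer_id.partition("+")
        return a, b


@dataclass
class BiomassComposition:
    """Class totals, monomer records and combined pools of one measurement set."""

    classes: dict[str, tuple[float, float | None]] = field(default_factory=dict)
    monomers: list[MonomerRecord] = field(default_factory=list)

    @property
    def combined_pools(self) -> list[tuple[str, str]]:
        return [r.pool_members() for r in self.monomers if r.is_pool]

    def monomer(self, monomer_id: str) -> MonomerRecord:
        for rec in self.monomers:
            if rec.monomer_id == monomer_id:
                return rec
        raise KeyError(monomer_id)

    def class_records(self, macro_class: str) -> list[MonomerRecord]:
        return [r for r in self.monomers if r.macro_class == macro_class]

    def monomer_sum(self, macro_class: str) -> float:
        """Sum of non-excluded monomer mass fractions in one class."""
        return sum(
            r.mass_fraction
            for r in self.class_records(macro_class)
            if not r.excluded
        )

    def mass_fractions(self, include_excluded: bool = False) -> dict[str, float]:
        return {
            r.monomer_id: r.mass_fraction
            for r in self.monomers
            if include_excluded or not r.excluded
        }

    def replace_monomer(self, target: str, **changes) -> None:
        """Update fields of the record with id ``target`` (may rename it)."""
        for i, rec in enumerate(self.monomers):
            if rec.monomer_id == target:
                self.monomers[i] = replace(rec, **changes)
                return
        raise KeyError(target)


def load_composition(source: str | Path | pd.DataFrame) -> BiomassComposition:
    """Read a delimited measurement table into a validated composition.

    The table needs columns (class, monomer, mass_fraction, sd, status); a
    ``note`` column is optional. Class-total rows use monomer id ``TOTAL``;
    jointly measured pools use ``A+B`` monomer ids. Comma- and tab-separated
    dialects are auto-detected. Raises :class:`CompositionError` naming the
    offending row on malformed input and listing all violations when the
    resulting composition breaks an invariant.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", comment="#")
    required = {"class", "monomer", "mass_fraction", "sd", "status"}
    missing = required - set(df.columns)
    if missing:
        raise CompositionError(f"measurement table lacks columns: {sorted(missing)}")
    if "note" not in df.columns:
        df["note"] = ""
    df["note"] = df["note"].fillna("")

    comp = BiomassComposition()
    for idx, row in df.iterrows():
        where = f"row {idx + 1} ({row['class']}/{row['monomer']})"
        try:
            mass = float(row["mass_fraction"])
        except (TypeError, ValueError) as exc:
            raise CompositionError(f"{where}: unparseable mass_fraction") from exc
        if math.isnan(mass):
            if str(row["status"]) == "estimated":
                mass = 0.0  # withheld value, to be imputed downstream
            else:
                raise CompositionError(f"{where}: missing mass_fraction")
        sd = None if pd.isna(row["sd"]) else float(row["sd"])
        try:
            if str(row["monomer"]).upper() == "TOTAL":
                if not 0 <= mass <= 1:
                    raise CompositionError(f"class total outside [0, 1]: {mass}")
                comp.classes[str(row["class"])] = (mass, sd)
            else:
                comp.monomers.append(
                    MonomerRecord(
                        monomer_id=str(row["monomer"]),
                        macro_class=str(row["class"]),
                        mass_fraction=mass,
                        sd=sd,
                        status=str(row["status"]),
                        note=str(row["note"]),
                    )
                )
        except CompositionError as exc:
            raise CompositionError(f"{where}: {exc}") from exc

    problems = [d for d in validate_composition(comp) if not d.startswith("warning")]
    if not comp.classes:
        problems.insert(0, "no class totals in table")
    if problems:
        raise CompositionError("; ".join(problems))
    return comp


def write_composition(comp: BiomassComposition, path: str | Path, sep: str = "\t") -> None:
    """Write the table dialect read by :func:`load_composition` (round-trip safe)."""
    rows = []
    for cls, (mass, sd) in comp.classes.items():
        rows.append((cls, "TOTAL", mass, sd, "measured", ""))
    for r in comp.monomers:
        rows.append((r.macro_class, r.monomer_id, r.mass_fraction, r.sd, r.status, r.note))
    pd.DataFrame(
        rows, columns=["class", "monomer", "mass_fraction", "sd", "status", "note"]
    ).to_csv(path, sep=sep, index=False)


def total_coverage(comp: BiomassComposition) -> float:
    """Total quantified biomass, the sum over class totals [g/gCDW]."""
    return float(sum(mass for mass, _ in comp.classes.values()))


def validate_composition(
    comp: BiomassComposition, tolerance: float = SUM_TOLERANCE
) -> list[str]:
    """Return diagnostics for every invariant violation or warning; [] iff clean.

    Hard violations (fractions outside [0, 1], class-total overflow) are plain
    messages; class-total vs monomer-sum disagreements beyond ``tolerance`` are
    prefixed ``warning:`` because totals are measured independently.
    """
    diagnostics: list[str] = []
    for cls, (mass, _) in comp.classes.items():
        if not 0 <= mass <= 1:
            diagnostics.append(f"{cls}: class total {mass} outside [0, 1]")
    if total_coverage(comp) > 1 + tolerance:
        diagnostics.append(
            f"class totals sum to {total_coverage(comp):.4f} > 1"
        )
    for cls in comp.classes:
        records = [r for r in comp.class_records(cls) if not r.excluded]
        if not records:
            continue
        if any(r.status == "estimated" and r.mass_fraction == 0 for r in records):
            continue  # withheld values pending imputation; sums not comparable yet
        mismatch = abs(comp.classes[cls][0] - comp.monomer_sum(cls))
        if mismatch > tolerance:
            diagnostics.append(
                f"warning: {cls} class total {comp.classes[cls][0]:.4f} vs monomer "
                f"sum {comp.monomer_sum(cls):.4f} differ by {mismatch:.4f}"
            )
    seen: set[str] = set()
    for r in comp.monomers:
        if r.monomer_id in seen:
            diagnostics.append(f"duplicate monomer record {r.monomer_id}")
        seen.add(r.monomer_id)
    return diagnostics
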