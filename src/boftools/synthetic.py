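"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's data under one seed: toy stoichiometric
models whose exact flux ranges come from an exhaustive, LP-free vertex
enumeration of the flux polytope; sequence sets constructed by explicit residue
counts so realized monomer frequencies match their targets exactly; and noisy
composition measurement tables drawn around a known true composition that is
consistent with the pipeline's inference assumptions (amino acid mass fractions
exactly proportional to proteome prevalence, pools split by prevalence,
nucleotide distributions equal to the sequence composition).

The noise model is truncated multiplicative Gaussian per record — measurements
report per-record standard deviations, and relative errors are the natural
scale for concentration assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import AA_CODES, DNA_BASES, RNA_BASES
from .fva import FluxRange
from .inference import SequenceEntry, SequenceSet

_ORACLE_TOL = 1e-9


# ---------------------------------------------------------------------------
# exhaustive flux-polytope oracle (independent of any LP solver)
# ---------------------------------------------------------------------------

def enumerate_vertices(
    S: np.ndarray, b: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    """All vertices of {v : S v = b, lb <= v <= ub} by basis enumeration.

    Every vertex has at least n - rank(S) coordinates at a bound; all such
    fixings are enumerated and the remaining square system solved exactly.
    Intended for tiny networks (n <= ~10).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    b = np.asarray(b, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue  # degenerate face; its vertices appear under other fixings
        for pattern in product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            for j, side in zip(fixed, pattern):
                v[j] = ub[j] if side else lb[j]
            rhs = b - S[:, fixed] @ v[list(fixed)] if n_fixed else b
            if free:
                x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = x
            if S.size and np.max(np.abs(S @ v - b)) > 1e-7:
                continue
            if np.all(v >= lb - _ORACLE_TOL) and np.all(v <= ub + _ORACLE_TOL):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    unique = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-7) for u in unique):
            unique.append(v)
    return np.array(unique)


def oracle_flux_ranges(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    objective_index: int,
    fraction: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact (mu*, vmin, vmax) for every reaction, by vertex enumeration.

    The optimality constraint v_obj >= fraction * mu* is encoded through a
    bounded slack variable so the restricted region is again a polytope in
    standard form.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    base = enumerate_vertices(S, np.zeros(m), lb, ub)
    if base.size == 0:
        raise ValueError("infeasible toy model: no polytope vertices")
    mu_star = float(base[:, objective_index].max())
    # v_obj - s = fraction * mu*, 0 <= s <= mu* - fraction * mu*
    target = fraction * mu_star
    S_ext = np.zeros((m + 1, n + 1))
    S_ext[:m, :n] = S
    S_ext[m, objective_index] = 1.0
    S_ext[m, n] = -1.0
    b_ext = np.zeros(m + 1)
    b_ext[m] = target
    lb_ext = np.append(lb, 0.0)
    ub_ext = np.append(ub, max(mu_star - target, 0.0))
    verts = enumerate_vertices(S_ext, b_ext, lb_ext, ub_ext)
    if verts.size == 0:
        raise ValueError("optimality-restricted polytope has no vertices")
    return mu_star, verts[:, :n].min(axis=0), verts[:, :n].max(axis=0)


def stoichiometry_arrays(model) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(S, lb, ub, reaction ids) of a cobra model, in reaction order."""
    met_index = {met.id: i for i, met in enumerate(model.metabolites)}
    S = np.zeros((len(met_index), len(model.reactions)))
    lb, ub, ids = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        ids.append(rxn.id)
    return S, np.array(lb), np.array(ub), ids


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

#: default true class totals [g/gCDW], mirroring exponentially growing E. coli
DEFAULT_CLASS_TOTALS: Mapping[str, float] = {
    "protein": 0.54,
    "RNA": 0.19,
    "DNA": 0.013,
    "carbohydrate": 0.031,
    "lipid": 0.061,
}


@dataclass
class SyntheticScenario:
    """One reproducible synthetic study: seed, truth, noise and model size."""

    seed: int = 0
    noise_sd: float = 0.0  # relative sd of multiplicative measurement noise
    model_size: str = "tiny"  # tiny (<= 8 reactions) | small (<= 40)
    class_totals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TOTALS)
    )
    withheld: tuple[str, ...] = ("Cys", "Met")  # imputed, like hydrolysis losses
    pools: tuple[tuple[str, str], ...] = (("Glu", "Gln"), ("Asp", "Asn"))
    protein_length: int = 400
    rrna_length: int = 120
    genome_length: int = 200

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.model_size not in ("tiny", "small"):
            raise ValueError(f"unknown model_size {self.model_size!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child generator per stream, all driven by one seed."""
        import zlib

        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# sequences with exact monomer counts
# ---------------------------------------------------------------------------

def _sequence_from_counts(counts: Mapping[str, int], rng: np.random.Generator) -> str:
    letters = [ch for ch, n in counts.items() for _ in range(n)]
    order = rng.permutation(len(letters))
    return "".join(letters[i] for i in order)


def _integer_counts(
    targets: Mapping[str, float], length: int
) -> dict[str, int]:
    counts = {}
    for ch, freq in targets.items():
        exact = freq * length
        n = round(exact)
        if abs(exact - n) > 1e-6:
            raise ValueError(
                f"target frequency {freq} unattainable at length {length}"
            )
        counts[ch] = int(n)
    if sum(counts.values()) != length:
        raise ValueError("target frequencies do not tile the requested length")
    return counts


def generate_sequences(scenario: SyntheticScenario) -> SequenceSet:
    """Protein-coding, rRNA-gene and genome records with exact residue counts.

    Counts are drawn once per scenario (every residue present at least once)
    and the realized frequencies are exact by construction, so prevalence
    computed from these records reproduces the scenario targets identically.
    """
    rng = scenario.rng("sequences")
    records = []

    aa_letters = list(AA_CODES)
    weights = rng.integers(1, 8, size=len(aa_letters))
    n_units = scenario.protein_length // int(weights.sum())
    counts = {ch: int(w * n_units) for ch, w in zip(aa_letters, weights)}
    records.append(
        SequenceEntry("synthetic_cds", _sequence_from_counts(counts, rng),
                      "protein", "protein_coding")
    )

    rna_letters = ["A", "C", "G", "T"]  # gene strand, T read as U downstream
    rw = rng.integers(1, 6, size=4)
    n_units = scenario.rrna_length // int(rw.sum())
    counts = {ch: int(w * n_units) for ch, w in zip(rna_letters, rw)}
    records.append(
        SequenceEntry("synthetic_rrna", _sequence_from_counts(counts, rng),
                      "nucleotide", "rRNA_gene")
    )

    gw = rng.integers(1, 6, size=4)
    n_units = scenario.genome_length // int(gw.sum())
    counts = {ch: int(w * n_units) for ch, w in zip(rna_letters, gw)}
    records.append(
        SequenceEntry("synthetic_genome", _sequence_from_counts(counts, rng),
                      "nucleotide", "genome")
    )
    return SequenceSet(records)


# ---------------------------------------------------------------------------
# true composition and noisy measurement tables
# ---------------------------------------------------------------------------

def true_composition(scenario: SyntheticScenario) -> dict[str, float]:
    """True per-monomer mass fractions implied by the scenario's sequences.

    Protein, RNA and DNA monomers are each class total times the mass-basis
    prevalence of the corresponding synthetic sequences — exactly the relation
    the inference stage assumes, so a noise-free run must recover them to
    machine precision. Carbohydrate is split over glucose/glucosamine/
    galactose; lipid is one lumped record.
    """
    from .inference import nucleotide_distribution, proteome_prevalence

    seqs = generate_sequences(scenario)
    truth: dict[str, float] = {}
    prev_mass, _ = proteome_prevalence(seqs)
    for aa, p in prev_mass.entries.items():
        truth[aa] = scenario.class_totals["protein"] * p
    rna_mass, _ = nucleotide_distribution(seqs, "RNA")
    for nmp, p in rna_mass.entries.items():
        truth[nmp] = scenario.class_totals["RNA"] * p
    dna_mass, _ = nucleotide_distribution(seqs, "dsDNA")
    for dnmp, p in dna_mass.entries.items():
        truth[dnmp] = scenario.class_totals["DNA"] * p
    carb = scenario.class_totals["carbohydrate"]
    truth["glucose"] = 0.72 * carb
    truth["glucosamine"] = 0.17 * carb
    truth["galactose"] = 0.11 * carb
    truth["lipid"] = scenario.class_totals["lipid"]
    return truth


def generate_measurements(scenario: SyntheticScenario) -> pd.DataFrame:
    """Measurement table around the true composition, in the loader's dialect.

    Multiplicative Gaussian noise (sd = noise_sd * truth) truncated at zero is
    applied independently per record; withheld monomers appear as ``estimated``
    rows with empty mass (to be imputed); designated pairs are merged into
    combined pools; RNA/DNA monomers are withheld the same way, mirroring
    assays that only measure class totals.
    """
    rng = scenario.rng("measurements")
    truth = true_composition(scenario)

    def noisy(value: float) -> float:
        if scenario.noise_sd == 0:
            return value
        return max(0.0, value * (1.0 + scenario.noise_sd * rng.standard_normal()))

    pooled = {m for pair in scenario.pools for m in pair}
    classes = {
        "protein": [aa for aa in AA_CODES.values()],
        "RNA": list(RNA_BASES.values()),
        "DNA": list(DNA_BASES.values()),
        "carbohydrate": ["glucose", "glucosamine", "galactose"],
        "lipid": ["lipid"],
    }
    rows = []
    for cls, monomers in classes.items():
        class_truth = sum(truth[m] for m in monomers)
        rows.append((cls, "TOTAL", noisy(class_truth),
                     scenario.noise_sd * class_truth or None, "measured", ""))
        if cls in ("RNA", "DNA"):
            for m in monomers:  # distribution inferred from sequence downstream
                rows.append((cls, m, None, None, "estimated", "from sequence"))
            continue
        for a, b in scenario.pools:
            if a in monomers:
                rows.append((cls, f"{a}+{b}", noisy(truth[a] + truth[b]),
                             None, "measured", "deamidation pool"))
        for m in monomers:
            if m in pooled:
                continue
            if m in scenario.withheld:
                rows.append((cls, m, None, None, "estimated", "withheld"))
            else:
                rows.append((cls, m, noisy(truth[m]),
                             scenario.noise_sd * truth[m] or None, "measured", ""))
    return pd.DataFrame(
        rows, columns=["class", "monomer", "mass_fraction", "sd", "status", "note"]
    )


# ---------------------------------------------------------------------------
# toy metabolic models with certified flux ranges
# ---------------------------------------------------------------------------

def generate_toy_model(scenario: SyntheticScenario):
    """A feasible toy model plus exact oracle flux ranges at 100% optimality.

    The network is substrate uptake -> per-precursor synthesis -> biomass, with
    an optional parallel (diamond) route creating non-degenerate FVA ranges.
    All bounds are finite so the flux polytope is bounded and the vertex
    oracle exact. Returns (cobra model, {reaction id: FluxRange}).
    """
    from cobra import Metabolite, Model, Reaction

    rng = scenario.rng("toy_model")
    n_precursors = int(rng.integers(2, 4))
    with_diamond = bool(rng.integers(0, 2))
    uptake_cap = float(rng.integers(5, 15))
    demands = rng.integers(1, 4, size=n_precursors).astype(float)

    model = Model(f"toy_{scenario.seed}")
    sub = Metabolite("sub_c", name="substrate", compartment="c")
    precursors = [
        Metabolite(f"pre{i}_c", compartment="c") for i in range(n_precursors)
    ]

    def add(rxn_id, stoich, lb, ub):
        rxn = Reaction(rxn_id, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites(stoich)
        model.add_reactions([rxn])
        return rxn

    add("EX_sub", {sub: 1.0}, 0.0, uptake_cap)
    for i, pre in enumerate(precursors):
        if with_diamond and i == 0:
            add("SYN0a", {sub: -1.0, pre: 1.0}, 0.0, uptake_cap)
            add("SYN0b", {sub: -1.0, pre: 1.0}, 0.0, uptake_cap)
        else:
            add(f"SYN{i}", {sub: -1.0, pre: 1.0}, 0.0, uptake_cap)
    biomass = add(
        "BIOMASS",
        {pre: -float(d) for pre, d in zip(precursors, demands)},
        0.0,
        uptake_cap,
    )
    model.objective = biomass.id

    S, lb, ub, ids = stoichiometry_arrays(model)
    _, vmin, vmax = oracle_flux_ranges(S, lb, ub, ids.index("BIOMASS"), 1.0)
    truth = {
        rid: FluxRange(rid, round(float(lo), 9), round(float(hi), 9))
        for rid, lo, hi in zip(ids, vmin, vmax)
    }
    return model, truth
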