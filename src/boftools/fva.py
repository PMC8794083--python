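"""FBA/FVA engine, BOF installation, and flux-range comparison metrics.

Linear programming is delegated to cobrapy (GLPK via optlang); this module owns
the comparison layer: the fractional overlap xi of two flux intervals, the
center-point ratio CP_r, and the genome-scale summary of how a BOF change
redistributes attainable fluxes. All fluxes are mmol/gCDW/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bof import BOF, coefficient_ratio, mass_redistribution

#: LP feasibility slack on the optimality constraint ("100% optimality")
OPTIMALITY_SLACK = 1e-9
#: reported fluxes are rounded to this grid before metric computation
FLUX_DECIMALS = 6
#: interval width below which a range counts as a point
WIDTH_TOLERANCE = 1e-9


class FVAError(ValueError):
    """Model/BOF mismatch or an LP that cannot be set up."""


class InfeasibleModel(FVAError):
    """The model has no feasible flux distribution."""


@dataclass(frozen=True)
class FluxRange:
    """Attainable [vmin, vmax] interval of one reaction at fixed optimality."""

    reaction_id: str
    vmin: float
    vmax: float

    def __post_init__(self):
        if self.vmin > self.vmax + 1e-6:
            raise FVAError(
                f"{self.reaction_id}: vmin {self.vmin} > vmax {self.vmax}"
            )

    @property
    def width(self) -> float:
        return max(self.vmax - self.vmin, 0.0)

    @property
    def center(self) -> float:
        return 0.5 * (self.vmin + self.vmax)


def objective_reaction(model):
    """The single objective reaction of a model."""
    objectives = [
        r for r in model.reactions if r.objective_coefficient
    ]
    if len(objectives) != 1:
        raise FVAError(f"expected exactly one objective reaction, found {len(objectives)}")
    return objectives[0]


def apply_medium_overrides(model, overrides: Mapping[str, float] | None):
    """Set lower bounds of named exchange reactions (in place)."""
    for rxn_id, lb in (overrides or {}).items():
        model.reactions.get_by_id(rxn_id).lower_bound = lb
    return model


def solve_fba(model):
    """Maximize the objective; returns (mu*, optimal flux vector as a Series).

    Raises :class:`InfeasibleModel` on infeasibility and :class:`FVAError` on
    an unbounded objective.
    """
    solution = model.optimize()
    if solution.status == "infeasible":
        raise InfeasibleModel(f"{model.id or 'model'} is infeasible")
    if solution.status != "optimal":
        raise FVAError(f"LP finished with status {solution.status!r}")
    return float(solution.objective_value), solution.fluxes


def run_fva(
    model,
    fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> list[FluxRange]:
    """Per-reaction flux min/max at a fixed fraction of the FBA optimum.

    The optimality constraint is objective flux >= (fraction - slack) * mu*,
    with a tiny slack absorbing LP round-off at fraction 1.0. Reported bounds
    are rounded to :data:`FLUX_DECIMALS` decimals.
    """
    if not 0 < fraction <= 1:
        raise FVAError(f"optimality fraction must be in (0, 1], got {fraction}")
    mu_star, _ = solve_fba(model)
    targets = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    ranges = []
    with model as m:
        obj = objective_reaction(m)
        threshold = fraction * mu_star
        obj.lower_bound = max(obj.lower_bound, threshold - abs(threshold) * OPTIMALITY_SLACK - 1e-12)
        for rxn_id in targets:
            rxn = m.reactions.get_by_id(rxn_id)
            bounds = {}
            for sense in ("min", "max"):
                m.objective = rxn
                m.objective_direction = sense
                sol = m.optimize()
                if sol.status != "optimal":
                    raise InfeasibleModel(
                        f"FVA subproblem {sense} {rxn_id}: {sol.status}"
                    )
                bounds[sense] = round(float(sol.objective_value), FLUX_DECIMALS)
            vmin, vmax = bounds["min"], bounds["max"]
            if vmin > vmax:  # round-off on a degenerate range
                vmin = vmax = 0.5 * (vmin + vmax)
            ranges.append(FluxRange(rxn_id, vmin, vmax))
    return ranges


def fractional_overlap(a: FluxRange, b: FluxRange, tol: float = WIDTH_TOLERANCE) -> float:
    """Fractional overlap xi of two flux ranges.

    xi = max(0, min(vmax) - max(vmin)) / max(width_a, width_b), clipped to
    [0, 1]. When both ranges are points the ratio is undefined; the limit
    motivates xi = 1 for coinciding centers and 0 otherwise.
    """
    overlap = min(a.vmax, b.vmax) - max(a.vmin, b.vmin)
    denom = max(a.width, b.width)
    if denom <= tol:
        return 1.0 if abs(a.center - b.center) <= tol else 0.0
    return min(max(overlap, 0.0) / denom, 1.0)


def center_point_ratio(e: FluxRange, m: FluxRange, tol: float = WIDTH_TOLERANCE) -> float:
    """Ratio of interval midpoints CP_r = center(e) / center(m).

    Returns NaN (flagged undefined) when the reference midpoint is below
    tolerance in magnitude.
    """
    if abs(m.center) < tol:
        return math.nan
    return e.center / m.center


def install_bof(model, bof: BOF, auto_create: bool = False):
    """Return a copy of the model with the objective stoichiometry replaced.

    Every BOF metabolite must exist in the model unless ``auto_create`` is set;
    the input model is left unmodified.
    """
    new = model.copy()
    reaction = objective_reaction(new)
    stoich = bof.total_coefficients()
    missing = [m for m in stoich if m not in {met.id for met in new.metabolites}]
    if missing and not auto_create:
        raise FVAError(f"BOF names metabolites absent from the model: {sorted(missing)}")
    if missing:
        from cobra import Metabolite

        new.add_metabolites([Metabolite(m) for m in missing])
    reaction.subtract_metabolites(dict(reaction.metabolites))
    reaction.add_metabolites(
        {new.metabolites.get_by_id(m): c for m, c in stoich.items()}
    )
    return new


@dataclass
class ComparisonReport:
    """Genome-scale impact of swapping one BOF for another.

    ``per_reaction`` columns: a_min/a_max (first BOF), b_min/b_max (second),
    xi, cp_r, high_flux. ``per_component``: S_r and mass delta [mg/g] per
    biomass component. ``summary`` holds the headline fractions.
    """

    per_reaction: pd.DataFrame
    per_component: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def xi_histogram(self, bins: int = 20) -> pd.Series:
        """Counts of xi values over equal-width bins on [0, 1]."""
        import numpy as np

        edges = np.linspace(0.0, 1.0, bins + 1)
        counts, _ = np.histogram(self.per_reaction["xi"].dropna(), bins=edges)
        labels = [f"[{lo:.2f},{hi:.2f})" for lo, hi in zip(edges[:-1], edges[1:])]
        return pd.Series(counts, index=labels, name="xi_count")


def compare_objectives(
    model,
    bofA: BOF,
    bofB: BOF,
    fraction: float = 1.0,
    flux_threshold: float = 0.001,
    cp_threshold: float = 0.1,
    medium_overrides: Mapping[str, float] | None = None,
    specs: Mapping | None = None,
    reactions: Sequence[str] | None = None,
) -> ComparisonReport:
    """FVA under two BOFs plus per-reaction and per-component comparison.

    A reaction is *high-flux* when its interval midpoint exceeds
    ``flux_threshold`` in magnitude under either BOF. The summary reports the
    share of reactions with no range overlap (xi ~ 0) and the share of
    high-flux reactions whose center point moved by more than ``cp_threshold``
    relative. Component-level S_r and mass redistribution are included when
    metabolite ``specs`` are supplied and both BOFs are normalized.
    """
    results = {}
    for label, bof in (("a", bofA), ("b", bofB)):
        prepared = install_bof(model, bof)
        apply_medium_overrides(prepared, medium_overrides)
        try:
            results[label] = {fr.reaction_id: fr for fr in run_fva(prepared, fraction, reactions)}
        except InfeasibleModel as exc:
            raise InfeasibleModel(f"BOF {label!r}: {exc}") from exc

    rows = []
    for rxn_id, fa in results["a"].items():
        fb = results["b"][rxn_id]
        xi = fractional_overlap(fa, fb)
        cp = center_point_ratio(fa, fb)
        high = max(abs(fa.center), abs(fb.center)) > flux_threshold
        rows.append(
            (rxn_id, fa.vmin, fa.vmax, fb.vmin, fb.vmax, xi, cp, high)
        )
    per_reaction = pd.DataFrame(
        rows,
        columns=["reaction", "a_min", "a_max", "b_min", "b_max", "xi", "cp_r", "high_flux"],
    ).set_index("reaction")

    high = per_reaction[per_reaction["high_flux"]]
    cp_changed = high[
        (high["cp_r"] - 1.0).abs() > cp_threshold
    ]
    summary = {
        "n_reactions": int(len(per_reaction)),
        "fraction_nonoverlap": float((per_reaction["xi"] <= WIDTH_TOLERANCE).mean()),
        "n_high_flux": int(len(high)),
        "fraction_high_flux_cp_changed": float(len(cp_changed) / len(high))
        if len(high)
        else math.nan,
    }

    s_r = coefficient_ratio(bofA, bofB)
    component = pd.DataFrame(
        {"s_r": pd.Series(s_r)}
    )
    if specs is not None:
        try:
            deltas, total = mass_redistribution(bofA, bofB, specs)
            component["delta_mass_mg_per_g"] = pd.Series(deltas)
            summary["mass_reallocated_fraction"] = total
        except Exception:
            pass  # unnormalized BOFs: S_r still reported
    return ComparisonReport(per_reaction, component, summary)
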