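"""Readers/writers for models, BOF tables, reports and run configuration.

Model exchange is SBML Level 3 + FBC (via cobrapy/libsbml) plus cobrapy's JSON
dialect for toy models and fixtures. Flux units are mmol/gCDW/h and BOF
coefficients mmol/gCDW throughout; every written artifact states this in its
header. The E. coli template model bundled with cobrapy (iJO1366) is exposed
as the default merge template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .bof import BOF
from .fva import ComparisonReport


class IOError_(ValueError):
    """Unreadable or malformed exchange file."""


def read_model(path: str | Path, dialect: str | None = None):
    """Load a constraint-based model from SBML-FBC or JSON.

    The dialect is inferred from the suffix unless given. Ids, stoichiometries,
    bounds and the objective are preserved exactly; a model without an
    objective is rejected.
    """
    import cobra.io

    path = Path(path)
    if dialect is None:
        dialect = "JSON" if path.suffix == ".json" else "SBML-FBC"
    if not path.exists():
        raise IOError_(f"model file not found: {path}")
    try:
        if dialect == "JSON":
            model = cobra.io.load_json_model(str(path))
        elif dialect == "SBML-FBC":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise IOError_(f"unknown model dialect {dialect!r}")
    except IOError_:
        raise
    except Exception as exc:
        raise IOError_(f"{path}: cannot parse as {dialect}: {exc}") from exc
    for rxn in model.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise IOError_(f"{path}: reaction {rxn.id} lacks flux bounds")
    if not any(r.objective_coefficient for r in model.reactions):
        raise IOError_(f"{path}: model has no objective reaction")
    return model


def write_model(model, path: str | Path) -> None:
    """Write SBML-FBC (.xml) or cobrapy JSON (.json), by suffix."""
    import cobra.io

    path = Path(path)
    if path.suffix == ".json":
        cobra.io.save_json_model(model, str(path))
    else:
        cobra.io.write_sbml_model(model, str(path))


def template_model():
    """The bundled E. coli genome-scale template (iJO1366), freshly loaded."""
    import cobra.io

    ref = resources.files("cobra").joinpath("data/iJO1366.xml.gz")
    with resources.as_file(ref) as path:
        return cobra.io.read_sbml_model(str(path))


def write_bof_table(
    bof: BOF, path: str | Path, class_tags: Mapping[str, str] | None = None
) -> None:
    """Delimited BOF exchange table: metabolite_id, coefficient, class tag."""
    class_tags = class_tags or {}
    rows = [
        (m, c, class_tags.get(m, ""))
        for m, c in sorted(bof.coefficients.items())
    ]
    with open(path, "w") as fh:
        fh.write("# biomass objective function; coefficients in mmol/gCDW\n")
        fh.write(f"# gam\t{bof.gam}\n")
        pd.DataFrame(rows, columns=["metabolite_id", "coefficient", "class"]).to_csv(
            fh, sep="\t", index=False
        )


def read_bof_table(path: str | Path) -> BOF:
    gam = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# gam\t"):
                gam = float(line.split("\t")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"metabolite_id", "coefficient"} <= set(df.columns):
        raise IOError_(f"{path}: not a BOF table")
    return BOF(dict(zip(df["metabolite_id"], df["coefficient"])), gam=gam)


def write_report(
    report: ComparisonReport,
    json_path: str | Path | None = None,
    table_path: str | Path | None = None,
    histogram_bins: int = 20,
) -> dict:
    """Serialize a comparison report (full JSON + human summary table).

    The JSON carries per-reaction ranges/metrics, per-component ratios, the
    summary statistics and the xi histogram counts; the delimited summary holds
    the headline numbers. Returns the JSON-ready dictionary.
    """
    payload = {
        "units": {"flux": "mmol/gCDW/h", "coefficient": "mmol/gCDW"},
        "summary": report.summary,
        "xi_histogram": report.xi_histogram(histogram_bins).to_dict(),
        "per_reaction": report.per_reaction.reset_index().to_dict(orient="records"),
        "per_component": report.per_component.reset_index()
        .rename(columns={"index": "component"})
        .replace([float("inf")], "inf")
        .to_dict(orient="records"),
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str))
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("# flux units mmol/gCDW/h; coefficients mmol/gCDW\n")
            for key, value in report.summary.items():
                fh.write(f"{key}\t{value}\n")
    return payload


@dataclass
class RunConfig:
    """Structured run configuration shared by the CLI commands."""

    model: str | None = None
    measurements: str | None = None
    sequences: dict = field(default_factory=dict)  # role -> fasta path
    polymer_defs: str | None = None
    constants_overrides: dict = field(default_factory=dict)
    optimality_fraction: float = 1.0
    flux_threshold: float = 0.001
    cp_threshold: float = 0.1
    medium_overrides: dict = field(default_factory=dict)
    regression_intercept: bool = True
    seed: int = 0
    tolerance: float = 1e-9

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise IOError_(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if not 0 < cfg.optimality_fraction <= 1:
            raise IOError_("optimality_fraction must be in (0, 1]")
        for key in ("model", "measurements", "polymer_defs"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise IOError_(f"{path}: {key} path does not exist: {value}")
        return cfg
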