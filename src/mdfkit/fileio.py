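"""File formats and run configuration.

Pathway files are YAML documents with sections ``compounds``, ``reactions``
(formula strings plus ``dg0_prime`` and optional ``dg0_by_ph``),
``constraints`` (overrides of the shipped defaults) and ``atp_accounting``.
A TSV dialect (columns: id, formula, dg0_prime_kj_mol) is accepted for the
reaction table.  JSON is the canonical report format; TSV projections are
derived from it.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .analysis import enzyme_demand_report
from .errors import ConfigurationError, MdfError
from .lp import MDFResult
from .model import (
    Compound,
    ConcentrationConstraints,
    PathwayModel,
    RatioConstraint,
    Reaction,
    default_constraints,
)
from .thermo import ThermoConstants

__all__ = [
    "RunConfig",
    "load_pathway",
    "read_reaction_tsv",
    "load_config",
    "constraints_from_section",
    "result_to_dict",
    "write_report_json",
    "write_report_tsv",
]

logger = logging.getLogger("mdfkit")


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration; shipped defaults reproduce the standard
    physiological setup (298.15 K, 1 uM - 10 mM, cofactor table)."""

    temperature_k: float = 298.15
    gas_constant_r: float = 8.314e-3
    default_lower: float = 1e-6
    default_upper: float = 1e-2
    solver: str = "highs"
    tie_break: bool = False
    out_dir: str = "."
    verbosity: str = "INFO"
    cofactors: dict = dataclasses.field(default_factory=dict)
    source: str = "defaults"

    def constants(self) -> ThermoConstants:
        return ThermoConstants(self.gas_constant_r, self.temperature_k)

    def constraints(self) -> ConcentrationConstraints:
        cons = default_constraints()
        cons.default_lower = self.default_lower
        cons.default_upper = self.default_upper
        if self.cofactors:
            cons.fixed = {
                str(k): float(v)
                for k, v in (self.cofactors.get("fixed") or {}).items()
            }
            cons.ratios = [
                RatioConstraint(r["numerator"], r["denominator"], float(r["ratio"]))
                for r in (self.cofactors.get("ratios") or [])
            ]
        return cons

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)} in {path}")
    cfg = RunConfig(**raw)
    cfg.source = str(path)
    return cfg


def _parse_dg0_by_ph(raw: Any, rxn_id: str) -> list[tuple[float, float]]:
    if isinstance(raw, dict):
        return [(float(p), float(g)) for p, g in raw.items()]
    if isinstance(raw, (list, tuple)):
        return [(float(p), float(g)) for p, g in raw]
    raise ConfigurationError(
        f"reaction {rxn_id!r}: dg0_by_ph must be a mapping or pair list"
    )


def constraints_from_section(
    section: dict | None, base: ConcentrationConstraints | None = None
) -> ConcentrationConstraints:
    """Apply a pathway file's ``constraints`` section on top of ``base``."""
    cons = (base or default_constraints()).copy()
    if not section:
        return cons
    if "default_lower" in section:
        cons.default_lower = float(section["default_lower"])
    if "default_upper" in section:
        cons.default_upper = float(section["default_upper"])
    for cid, b in (section.get("bounds") or {}).items():
        cons.set_bound(
            str(cid),
            lower=None if b.get("lower") is None else float(b["lower"]),
            upper=None if b.get("upper") is None else float(b["upper"]),
        )
    for cid, v in (section.get("fixed") or {}).items():
        cons.fix(str(cid), float(v))
    if "ratios" in section:
        cons.ratios = [
            RatioConstraint(r["numerator"], r["denominator"], float(r["ratio"]))
            for r in section["ratios"] or []
        ]
    return cons


def load_pathway(
    path: str | Path,
) -> tuple[PathwayModel, ConcentrationConstraints]:
    """Read a YAML pathway file; returns the model and its effective
    constraints (shipped defaults overlaid with the file's overrides)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict) or "reactions" not in raw:
        raise ConfigurationError(f"{path}: missing 'reactions' section")
    pw = PathwayModel(
        name=str(raw.get("name", path.stem)),
        metadata=raw.get("metadata") or {},
        atp_accounting=raw.get("atp_accounting"),
    )
    for entry in raw.get("compounds") or []:
        pw.add_compound(
            Compound(
                id=str(entry["id"]),
                name=str(entry.get("name", "")),
                is_cofactor=bool(entry.get("is_cofactor", False)),
            )
        )
    reactions = raw["reactions"]
    if isinstance(reactions, str):  # inline TSV reaction table
        reactions = _reactions_from_tsv_text(reactions, str(path))
    for entry in reactions:
        if isinstance(entry, Reaction):
            pw.add_reaction(entry)
            continue
        try:
            rxn = Reaction.from_formula(
                id=str(entry["id"]),
                formula=str(entry["formula"]),
                dg0_prime=(
                    None if entry.get("dg0_prime") is None
                    else float(entry["dg0_prime"])
                ),
                name=str(entry.get("name", "")),
                dg0_by_ph=(
                    _parse_dg0_by_ph(entry["dg0_by_ph"], str(entry["id"]))
                    if entry.get("dg0_by_ph") is not None
                    else None
                ),
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"{path}: reaction entry missing key {exc}"
            ) from exc
        pw.add_reaction(rxn)
    cons = constraints_from_section(raw.get("constraints"))
    return pw, cons


def _reactions_from_tsv_text(text: str, origin: str) -> list[Reaction]:
    rows = list(csv.DictReader(text.strip().splitlines(), delimiter="\t"))
    if not rows or "formula" not in rows[0]:
        raise ConfigurationError(
            f"{origin}: reaction TSV needs columns id, formula, dg0_prime_kj_mol"
        )
    out = []
    for row in rows:
        out.append(
            Reaction.from_formula(
                id=row["id"],
                formula=row["formula"],
                dg0_prime=(
                    float(row["dg0_prime_kj_mol"])
                    if row.get("dg0_prime_kj_mol") not in (None, "")
                    else None
                ),
            )
        )
    return out


def read_reaction_tsv(path: str | Path) -> list[Reaction]:
    """Read the standalone TSV reaction-table dialect."""
    return _reactions_from_tsv_text(Path(path).read_text(), str(path))


def result_to_dict(
    result: MDFResult,
    pathway: PathwayModel,
    config: RunConfig | None = None,
) -> dict:
    """Canonical JSON-ready report; numbers at full double precision."""
    cfg = config or RunConfig()
    constants = cfg.constants()
    out: dict = {
        "pathway": pathway.name,
        "solver_status": result.solver_status,
        "mdf_kj_mol": _f(result.mdf),
        "feasible": bool(result.feasible),
        "dual_objective_kj_mol": _f(result.dual_objective),
        "degenerate": bool(result.degenerate),
        "config": {
            "temperature_k": cfg.temperature_k,
            "rt_kj_mol": constants.rt,
            "solver": cfg.solver,
            "source": cfg.source,
        },
        "reactions": [],
        "compounds": [],
    }
    if result.solver_status != "optimal":
        return out
    demand = enzyme_demand_report(result, constants)
    for j, rxn in enumerate(pathway.reactions):
        out["reactions"].append(
            {
                "id": rxn.id,
                "formula": rxn.formula,
                "dg0_prime_kj_mol": _f(rxn.dg0_prime),
                "dg_prime_opt_kj_mol": _f(result.drg_prime_opt[j]),
                "driving_force_kj_mol": _f(-result.drg_prime_opt[j]),
                "flux_force_efficacy": _f(result.efficacy_opt[j]),
                "shadow_price": _f(result.reaction_shadow_prices[j]),
                "enzyme_demand_factor": _f(demand[rxn.id]),
            }
        )
    for i, cid in enumerate(result.compound_ids):
        out["compounds"].append(
            {
                "id": cid,
                "concentration_m": _f(np.exp(result.x_opt[i])),
                "log_concentration": _f(result.x_opt[i]),
                "shadow_price": _f(result.metabolite_shadow_prices[i]),
                "shadow_price_upper": _f(result.u_max[i]),
                "shadow_price_lower": _f(result.u_min[i]),
            }
        )
    return out


def _f(v) -> float | None:
    if v is None:
        return None
    v = float(v)
    return v  # json handles inf via allow_nan default


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_report_tsv(report: dict, path: str | Path) -> None:
    """Flat per-reaction projection of the JSON report."""
    path = Path(path)
    cols = [
        "id",
        "formula",
        "dg0_prime_kj_mol",
        "dg_prime_opt_kj_mol",
        "driving_force_kj_mol",
        "flux_force_efficacy",
        "shadow_price",
        "enzyme_demand_factor",
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for row in report["reactions"]:
            writer.writerow([repr(row[c]) if isinstance(row[c], float) else row[c]
                             for c in cols])


def load_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


class InputError(MdfError):
    """User-input failure that should map to CLI exit code 2."""
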