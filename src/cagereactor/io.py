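"""File formats: YAML model/scenario definitions, CSV observations and
time courses, JSON run reports.

Interface conventions follow laboratory practice: concentrations are mM
and times may be given in hours in files, converted to SI (M, s) at the
boundary.  Internally everything is M and s.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .equilibrium import BindingModel, Component, ComplexSpecies
from .fitting import RatioObservation
from .kinetics import TimeCourse

__all__ = [
    "load_binding_model",
    "dump_binding_model",
    "read_time_course",
    "write_time_course",
    "read_ratio_observations",
    "write_ratio_observations",
    "write_speciation_profile",
    "write_json_report",
]


class ParseError(ValueError):
    """Malformed input file."""


def load_binding_model(path: str | Path) -> BindingModel:
    """Read a binding model from YAML (totals in mM, beta as log10)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        comps = tuple(
            Component(c["name"], float(c["total_mM"]) * 1e-3)
            for c in doc["components"]
        )
        species = tuple(
            ComplexSpecies(
                s["name"],
                {k: int(v) for k, v in s["stoichiometry"].items()},
                float(s["log10_beta"]),
            )
            for s in doc.get("species", [])
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed binding model file {path}: {exc}") from exc
    return BindingModel(comps, species)


def dump_binding_model(model: BindingModel, path: str | Path) -> None:
    doc = {
        "components": [
            {"name": c.name, "total_mM": c.total * 1e3} for c in model.components
        ],
        "species": [
            {
                "name": s.name,
                "stoichiometry": dict(s.stoichiometry),
                "log10_beta": s.log_beta,
            }
            for s in model.species
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_time_course(path: str | Path) -> TimeCourse:
    """Read a long-format time-course CSV: time_s, species, concentration_M
    and optionally sigma_rel (one row per observation)."""
    df = pd.read_csv(path)
    required = {"time_s", "species", "concentration_M"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    if df.empty:
        raise ParseError(f"{path}: no observations")
    wide = df.pivot_table(index="time_s", columns="species", values="concentration_M")
    if wide.isna().any().any():
        raise ParseError(f"{path}: species sampled on inconsistent time grids")
    sigma = float(df["sigma_rel"].iloc[0]) if "sigma_rel" in df.columns else None
    return TimeCourse(
        times=wide.index.to_numpy(float),
        values={str(c): wide[c].to_numpy(float) for c in wide.columns},
        sigma=sigma,
    )


def write_time_course(tc: TimeCourse, path: str | Path) -> None:
    rows = []
    for species, vals in tc.values.items():
        for t, v in zip(tc.times, vals):
            rows.append(
                {
                    "time_s": t,
                    "species": species,
                    "concentration_M": v,
                    "sigma_rel": tc.sigma if tc.sigma is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ratio_observations(path: str | Path) -> list[RatioObservation]:
    """Read ratio observations: columns numerator, denominator, ratio,
    sigma_rel plus one ``total_<component>_mM`` column per component."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty observation file") from exc
    needed = {"numerator", "denominator", "ratio"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    total_cols = [c for c in df.columns if c.startswith("total_") and c.endswith("_mM")]
    if not total_cols:
        raise ParseError(f"{path}: no total_<component>_mM columns")
    obs = []
    for i, row in df.iterrows():
        comp = {c[len("total_"):-len("_mM")]: float(row[c]) * 1e-3 for c in total_cols}
        try:
            obs.append(
                RatioObservation(
                    composition=comp,
                    numerator=str(row["numerator"]),
                    denominator=str(row["denominator"]),
                    observed_ratio=float(row["ratio"]),
                    sigma=float(row.get("sigma_rel", 0.05) or 0.05),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return obs


def write_ratio_observations(obs: list[RatioObservation], path: str | Path) -> None:
    rows = []
    for o in obs:
        row: dict[str, Any] = {
            f"total_{k}_mM": v * 1e3 for k, v in o.composition.items()
        }
        row.update(
            numerator=o.numerator,
            denominator=o.denominator,
            ratio=o.observed_ratio,
            sigma_rel=o.sigma,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_speciation_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a speciation profile as CSV in mM with 6 significant digits."""
    out = profile.copy() * 1e3  # M -> mM, every column is a concentration
    out.insert(0, "point", range(len(out)))
    out.to_csv(path, index=False, float_format="%.6g")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")
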