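"""Configuration files, bundled parameter sets, and output plumbing.

Drug, perpetrator and regimen descriptions live in YAML files; the bundled
parameter sets (tegoprazan, M1, clarithromycin, rifampicin) resolve by bare
name.  Loaders validate strictly and name the offending key on error.
Delimited-text outputs use '.' decimals, 'NA' for missing values, hours and
ng/mL at the interface; every artifact is stamped with the config hash,
seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .absorption import DoseEvent, MealEvent
from .drug import DissolutionSpec, DrugParameters, MetabolicReaction, PerpetratorSpec
from .engine import SimulationResult

_BUNDLED = {"tegoprazan", "m1", "clarithromycin", "rifampicin"}


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the key."""


def _read_yaml(path_or_name: str | Path) -> dict:
    path = Path(path_or_name)
    if path.suffix in (".yaml", ".yml") and path.exists():
        with open(path) as fh:
            return yaml.safe_load(fh)
    name = str(path_or_name).lower()
    if name in _BUNDLED:
        with resources.files("tegopbpk.data").joinpath(f"{name}.yaml").open() as fh:
            return yaml.safe_load(fh)
    raise ConfigError(f"config {path_or_name!r} is neither an existing file nor a bundled name {sorted(_BUNDLED)}")


def _require(raw: dict, key: str, context: str):
    if key not in raw:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return raw[key]


def load_drug_parameters(path_or_name: str | Path) -> DrugParameters:
    """Load and validate a compound parameter file (or bundled name)."""
    raw = _read_yaml(path_or_name)
    ctx = str(path_or_name)
    name = _require(raw, "name", ctx)
    reactions: list[MetabolicReaction] = []
    metabolism = raw.get("metabolism", {})
    for key, clint in metabolism.get("intrinsic_clearance_uL_min_pmol", {}).items():
        try:
            enzyme, product = key.split("_to_")
        except ValueError:
            raise ConfigError(f"{ctx}: malformed reaction key {key!r} (expected ENZYME_to_PRODUCT)") from None
        reactions.append(MetabolicReaction(enzyme=enzyme, product=product, clint=float(clint)))
    dissolution = {
        state: DissolutionSpec(t50=float(_require(spec, "t50_h", f"{ctx}:dissolution.{state}")),
                               shape=float(_require(spec, "shape", f"{ctx}:dissolution.{state}")),
                               state=state)
        for state, spec in raw.get("dissolution", {}).items()
    }
    return DrugParameters(
        name=name,
        molecular_weight=float(_require(raw, "molecular_weight_g_mol", ctx)),
        logp=float(_require(raw, "lipophilicity_logp", ctx)),
        fu_plasma=float(_require(raw, "fraction_unbound_plasma", ctx)),
        solubility=float(_require(raw, "solubility_mg_L", ctx)),
        pka_entries=tuple((float(p["value"]), str(p["type"])) for p in raw.get("pka", [])),
        specific_intestinal_permeability=float(raw.get("specific_intestinal_permeability_cm_s", 0.0)),
        specific_organ_permeability=float(raw.get("specific_organ_permeability_cm_s", 0.0)),
        renal_plasma_clearance=float(raw.get("renal_plasma_clearance_mL_min_kg", 0.0)),
        total_hepatic_plasma_clearance=float(raw.get("total_hepatic_plasma_clearance_mL_min_kg", 0.0)),
        reactions=tuple(reactions),
        dissolution=dissolution,
        blood_to_plasma_ratio=raw.get("blood_to_plasma_ratio"),
        kp_overrides=dict(raw.get("kp_overrides", {})),
    )


def save_drug_parameters(drug: DrugParameters, path: str | Path) -> None:
    """Write a compound back to the file schema (lossless round-trip)."""
    raw: dict = {
        "name": drug.name,
        "molecular_weight_g_mol": drug.molecular_weight,
        "lipophilicity_logp": drug.logp,
        "fraction_unbound_plasma": drug.fu_plasma,
        "solubility_mg_L": drug.solubility,
        "pka": [{"value": v, "type": t} for v, t in drug.pka_entries],
        "specific_intestinal_permeability_cm_s": drug.specific_intestinal_permeability,
        "specific_organ_permeability_cm_s": drug.specific_organ_permeability,
        "renal_plasma_clearance_mL_min_kg": drug.renal_plasma_clearance,
        "total_hepatic_plasma_clearance_mL_min_kg": drug.total_hepatic_plasma_clearance,
    }
    if drug.reactions:
        raw["metabolism"] = {
            "intrinsic_clearance_uL_min_pmol": {
                f"{r.enzyme}_to_{r.product}": r.clint for r in drug.reactions
            }
        }
    if drug.dissolution:
        raw["dissolution"] = {
            state: {"t50_h": s.t50, "shape": s.shape} for state, s in drug.dissolution.items()
        }
    if drug.blood_to_plasma_ratio is not None:
        raw["blood_to_plasma_ratio"] = drug.blood_to_plasma_ratio
    if drug.kp_overrides:
        raw["kp_overrides"] = dict(drug.kp_overrides)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_fm_targets(path_or_name: str | Path = "tegoprazan") -> dict[str, float]:
    """Pathway apportionment targets (percent of dose) from a compound file."""
    raw = _read_yaml(path_or_name)
    return {k: float(v) for k, v in _require(
        raw.get("metabolism", {}), "fm_targets_percent", str(path_or_name)
    ).items()}


def load_perpetrator(path_or_name: str | Path) -> PerpetratorSpec:
    """Load a perpetrator file: interaction mechanism + own kinetics."""
    raw = _read_yaml(path_or_name)
    ctx = str(path_or_name)
    mechanism = _require(raw, "mechanism", ctx)
    return PerpetratorSpec(
        name=_require(raw, "name", ctx),
        mechanism=mechanism,
        enzyme=raw.get("target_enzyme", "CYP3A4"),
        ki=float(raw["ki_umol_L"]) if "ki_umol_L" in raw else None,
        kinact=float(raw["kinact_per_h"]) if "kinact_per_h" in raw else None,
        emax=float(raw["emax"]) if "emax" in raw else None,
        ec50=float(raw["ec50_umol_L"]) if "ec50_umol_L" in raw else None,
        own_kinetics=raw.get("own_kinetics"),
    )


def load_regimen(path: str | Path) -> list[DoseEvent | MealEvent]:
    """Read a regimen file: lists of dose and meal events."""
    raw = _read_yaml(path)
    events: list[DoseEvent | MealEvent] = []
    for d in raw.get("doses", []):
        events.append(
            DoseEvent(
                time=float(_require(d, "time_h", "doses")),
                amount=float(_require(d, "amount_mg", "doses")),
                route=d.get("route", "oral"),
                formulation=d.get("formulation", "fasted"),
            )
        )
    for m in raw.get("meals", []):
        events.append(
            MealEvent(
                time=float(_require(m, "time_h", "meals")),
                gastric_ph_peak=float(m.get("gastric_pH_peak", 5.5)),
                ph_decay_halflife=float(m.get("pH_decay_halflife_h", 0.75)),
                emptying_multiplier=float(m.get("emptying_multiplier", 0.25)),
            )
        )
    if not events:
        raise ConfigError(f"{path}: regimen contains no doses or meals")
    return events


def build_regimen(
    dose_mg: float, n_doses: int = 1, interval_h: float = 24.0, fed: bool = False
) -> list[DoseEvent | MealEvent]:
    """A simple repeated-dose regimen; fed arms add a meal at each dose time."""
    events: list[DoseEvent | MealEvent] = []
    for k in range(n_doses):
        t = k * interval_h
        formulation = "fed" if fed else "fasted"
        events.append(DoseEvent(time=t, amount=dose_mg, formulation=formulation))
        if fed:
            events.append(MealEvent(time=t))
    return events


def config_hash(*objects) -> str:
    """Stable short hash of configuration objects, for provenance stamps."""
    blob = json.dumps([repr(o) for o in objects], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(seed: int | None, *config_objects) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config_hash(*config_objects),
        "seed": seed,
    }


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format concentration table: time_h, analyte, plasma_ng_per_mL."""
    frames = [
        pd.DataFrame(
            {"time_h": result.time, "analyte": name, "plasma_ng_per_mL": conc}
        )
        for name, conc in result.conc.items()
    ]
    return pd.concat(frames, ignore_index=True)


def write_profile(result: SimulationResult, path: str | Path, seed: int | None = None) -> None:
    """Write a simulated profile plus a pathway-amount table and provenance."""
    path = Path(path)
    frame = result_to_frame(result)
    frame.to_csv(path, index=False, na_rep="NA")
    pathway = pd.DataFrame({"time_h": result.time, **result.cumulative})
    pathway.to_csv(path.with_suffix(".pathways.csv"), index=False, na_rep="NA")
    meta = {**provenance(seed, result.diagnostics), "diagnostics": _json_safe(result.diagnostics)}
    path.with_suffix(".provenance.json").write_text(json.dumps(meta, indent=2, default=str))


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
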