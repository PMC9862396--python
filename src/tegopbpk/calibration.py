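"""Parameter identification, enzyme-abundance calibration, sensitivity.

Three jobs live here.  ``apportion_fm`` and ``calibrate_enzyme_abundance``
turn the reported enzyme-level pathway split (fraction metabolized by
CYP3A4 / CYP2C19 / excreted renally) into product-level fractions and into
enzyme reference concentrations, exploiting that in a first-order system
the within-enzyme product split equals the CLint ratio exactly and the
between-enzyme split is proportional to abundance x total CLint.  ``fit``
identifies model parameters against observed concentration-time data by
derivative-free minimisation of summed squared log10 residuals — the same
geometry as the MRD evaluation metric.  ``local_sensitivity`` ranks
parameters by the relative change in AUC_inf per relative parameter change
(central differences).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .absorption import DoseEvent
from .drug import DissolutionSpec, DrugParameters, MetabolicReaction
from .engine import PBPKModel, mass_balance
from .evaluation import ObservedDataset
from .interactions import perpetrator_concentration, rate_modifiers
from .io import build_regimen, load_perpetrator
from .physiology import Individual

#: Loose-but-adequate solver settings for the many simulations inside a fit.
FIT_SOLVER_OPTIONS = {"rtol": 1e-6, "atol": 1e-9}


class CalibrationError(ValueError):
    """Raised for infeasible calibration targets or malformed fit specs."""


# ---------------------------------------------------------------------------
# Pathway apportionment and abundance calibration
# ---------------------------------------------------------------------------

def apportion_fm(
    fm_by_enzyme: dict[str, float], reactions: tuple[MetabolicReaction, ...]
) -> dict[str, float]:
    """Split enzyme-level fm (percent of dose) into product fractions.

    First-order metabolism implies the product split within an enzyme is
    exactly the CLint ratio, independent of physiology.
    """
    out: dict[str, float] = {}
    for enzyme, fm in fm_by_enzyme.items():
        if enzyme == "renal":
            out["renal"] = fm
            continue
        rs = [r for r in reactions if r.enzyme == enzyme]
        total = sum(r.clint for r in rs)
        if total <= 0:
            if fm > 0:
                raise CalibrationError(f"{enzyme}: fm target > 0 but no CLint")
            continue
        for r in rs:
            out[f"{enzyme}_to_{r.product}"] = fm * r.clint / total
    return out


def abundance_ratio(fm1: float, fm2: float, clint1_total: float, clint2_total: float) -> float:
    """Enzyme-abundance ratio implied by fm targets and total CLints.

    ratio = (fm1/fm2) * (clint2_total/clint1_total): each enzyme's share of
    elimination is proportional to abundance x total CLint.
    """
    if min(fm1, fm2, clint1_total, clint2_total) <= 0:
        raise CalibrationError("fm targets and CLints must be > 0 for a ratio")
    return (fm1 / fm2) * (clint2_total / clint1_total)


def calibrate_enzyme_abundance(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    fm_targets: dict[str, float],
    dose_mg: float = 50.0,
    t_end: float = 168.0,
    tol_pp: float = 0.1,
    max_iter: int = 10,
) -> tuple[dict[tuple[str, str], float], dict]:
    """Find enzyme reference concentrations reproducing the fm targets.

    ``fm_targets`` gives percent-of-dose targets per enzyme plus "renal";
    they are interpreted as relative shares of the eliminated drug, so a
    fraction of dose lost unabsorbed rescales all pathways alike.  Each
    enzyme's abundance is scaled by a common factor across its expression
    sites (preserving the gut:liver expression ratio) and the simulated
    mass balance is iterated to a fixed point.  Returns the abundance map
    and diagnostics including the achieved mass balance.
    """
    targets = dict(fm_targets)
    renal_target = targets.pop("renal", None)
    if renal_target is None or renal_target <= 0:
        raise CalibrationError("fm_targets must include a positive 'renal' share")
    for enzyme, fm in targets.items():
        if fm < 0 or fm >= 100:
            raise CalibrationError(f"{enzyme}: fm target must be in [0, 100)")
        if fm > 0 and drug.clint_total(enzyme) <= 0:
            raise CalibrationError(f"{enzyme}: positive fm target but zero CLint")
    if drug.renal_plasma_clearance <= 0:
        raise CalibrationError("renal share target requires a positive renal clearance")

    scale = {enzyme: 1.0 for enzyme in targets}
    regimen = build_regimen(dose_mg)
    achieved: dict[str, float] = {}
    history = []
    for iteration in range(max_iter):
        enzymes = tuple(
            dataclasses.replace(
                e, reference_concentration=e.reference_concentration * scale.get(e.enzyme, 1.0)
            )
            for e in individual.enzymes
        )
        ind = individual.with_enzymes(enzymes)
        model = PBPKModel(drug, metabolite, ind, solver_options=FIT_SOLVER_OPTIONS)
        mb = mass_balance(model.simulate(regimen, t_end))
        achieved = mb.enzyme_totals
        history.append(dict(achieved))
        # compare enzyme:renal ratios — invariant to the absorbed fraction
        done = True
        for enzyme, fm in targets.items():
            if fm == 0:
                scale[enzyme] = 0.0
                continue
            target_ratio = fm / renal_target
            achieved_ratio = achieved[enzyme] / achieved["renal"]
            scale[enzyme] *= target_ratio / achieved_ratio
            total = sum(targets.values()) + renal_target
            norm_achieved = achieved[enzyme] / (sum(achieved.values())) * total
            if abs(norm_achieved - fm) > tol_pp:
                done = False
        if done:
            break
    abundances = {
        (e.enzyme, e.organ): e.reference_concentration * scale.get(e.enzyme, 1.0)
        for e in individual.enzymes
    }
    return abundances, {
        "iterations": iteration + 1,
        "achieved_percent_of_dose": achieved,
        "converged": done,
        "history": history,
    }


# ---------------------------------------------------------------------------
# Parameter identification
# ---------------------------------------------------------------------------

#: Parameter paths understood by the fitter and the sensitivity analysis.
#: "clint.<ENZYME>_to_<PRODUCT>", "dissolution.<state>.t50",
#: "dissolution.<state>.shape", plus scalar drug attributes and
#: "metabolite.<attribute>" for the metabolite.
def _get_param(drug: DrugParameters, metabolite: DrugParameters | None, path: str) -> float:
    target, attr = _resolve(drug, metabolite, path)
    if isinstance(target, MetabolicReaction):
        return target.clint
    if isinstance(target, DissolutionSpec):
        return getattr(target, attr)
    return getattr(target, attr)


def _resolve(drug, metabolite, path: str):
    obj = drug
    if path.startswith("metabolite."):
        if metabolite is None:
            raise CalibrationError(f"{path}: no metabolite in this model")
        obj, path = metabolite, path.split(".", 1)[1]
    if path.startswith("clint."):
        key = path.split(".", 1)[1]
        for r in obj.reactions:
            if f"{r.enzyme}_to_{r.product}" == key:
                return r, "clint"
        raise CalibrationError(f"unknown reaction {key!r}")
    if path.startswith("dissolution."):
        _, state, attr = path.split(".")
        if state not in obj.dissolution:
            raise CalibrationError(f"no dissolution profile {state!r}")
        if attr not in ("t50", "shape"):
            raise CalibrationError(f"unknown dissolution attribute {attr!r}")
        return obj.dissolution[state], attr
    if not hasattr(obj, path):
        raise CalibrationError(f"unknown parameter path {path!r}")
    return obj, path


def _apply_params(
    drug: DrugParameters, metabolite: DrugParameters | None, updates: dict[str, float]
) -> tuple[DrugParameters, DrugParameters | None]:
    for path, value in updates.items():
        if path.startswith("metabolite."):
            sub = path.split(".", 1)[1]
            metabolite = _apply_one(metabolite, sub, value)
        else:
            drug = _apply_one(drug, path, value)
    return drug, metabolite


def _apply_one(compound: DrugParameters, path: str, value: float) -> DrugParameters:
    if path.startswith("clint."):
        key = path.split(".", 1)[1]
        reactions = tuple(
            dataclasses.replace(r, clint=value) if f"{r.enzyme}_to_{r.product}" == key else r
            for r in compound.reactions
        )
        return dataclasses.replace(compound, reactions=reactions)
    if path.startswith("dissolution."):
        _, state, attr = path.split(".")
        spec = dataclasses.replace(compound.dissolution[state], **{attr: value})
        return dataclasses.replace(compound, dissolution={**compound.dissolution, state: spec})
    return dataclasses.replace(compound, **{path: value})


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how: parameter paths, bounds, scale, budget."""

    parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    scale: str = "log"  # optimise log10 of positive parameters
    max_iterations: int = 600
    seed: int = 20230104
    xatol: float = 1e-4
    fatol: float = 1e-10

    def __post_init__(self) -> None:
        for p, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise CalibrationError(f"{p}: bounds must be finite and ordered")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    objective: float
    converged: bool
    n_evaluations: int
    start_values: dict[str, float]


def simulate_regimen(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    regimen: dict,
    fed_state: str,
    times: np.ndarray,
    solver_options: dict | None = None,
) -> dict[str, np.ndarray]:
    """One simulation of a regimen dict; concentrations at ``times``.

    ``times`` are hours after the first victim dose.  A ``perpetrator``
    entry (bundled name) turns the run into a DDI arm: the perpetrator is
    dosed from t=0 and the victim starts after ``pretreatment_h``.
    Returns every analyte, so datasets sharing a regimen share one run.
    """
    times = np.asarray(times, dtype=float)
    events = build_regimen(
        dose_mg=float(regimen.get("dose_mg", 50.0)),
        n_doses=int(regimen.get("n_doses", 1)),
        interval_h=float(regimen.get("interval_h", 24.0)),
        fed=fed_state == "fed",
    )
    modifiers = None
    offset = 0.0
    if regimen.get("perpetrator"):
        perp = load_perpetrator(regimen["perpetrator"])
        offset = float(regimen.get("pretreatment_h", 48.0))
        tau = float(regimen.get("perpetrator_interval_h", 8.0))
        n_perp = int(math.ceil((offset + float(times.max()) + tau) / tau))
        perp_doses = [
            DoseEvent(time=k * tau, amount=float(regimen.get("perpetrator_dose_mg", 500.0)))
            for k in range(n_perp)
        ]
        modifiers = rate_modifiers(perp, perpetrator_concentration(perp, perp_doses))
        events = [dataclasses.replace(e, time=e.time + offset) for e in events]
    model = PBPKModel(
        drug,
        metabolite,
        individual,
        solver_options=solver_options or FIT_SOLVER_OPTIONS,
        perpetrator_rate_modifiers=modifiers,
    )
    t_end = offset + float(times.max()) + 1.0
    t_eval = np.unique(np.concatenate([[0.0], times + offset, [t_end]]))
    res = model.simulate(events, t_end, t_eval=t_eval)
    return {
        name: np.interp(times + offset, res.time, conc) for name, conc in res.conc.items()
    }


def _dataset_prediction(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    ds: ObservedDataset,
) -> np.ndarray:
    """Model prediction at a dataset's observation times (its regimen)."""
    pred = simulate_regimen(
        drug, metabolite, individual, ds.regimen, ds.fed_state, np.asarray(ds.times)
    )
    return pred[ds.analyte]


def fit(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    datasets: list[ObservedDataset],
    spec: FitSpec,
) -> FitResult:
    """Jointly fit the requested parameters to all datasets.

    Objective: sum over datasets and observations of squared log10
    (predicted/observed) — unweighted, MRD-consistent.  Derivative-free
    simplex search on log10-transformed parameters; deterministic for a
    given (datasets, spec).
    """
    if not spec.parameters:
        raise CalibrationError("fit requires at least one free parameter")
    start = {p: _get_param(drug, metabolite, p) for p in spec.parameters}
    for p, v in start.items():
        if v <= 0 and spec.scale == "log":
            raise CalibrationError(f"{p}: log-scale fitting requires a positive start value")

    def unpack(x: np.ndarray) -> dict[str, float]:
        values = 10.0**x if spec.scale == "log" else x
        out = {}
        for p, v in zip(spec.parameters, values):
            lo, hi = spec.bounds.get(p, (-np.inf, np.inf))
            out[p] = float(np.clip(v, lo, hi))
        return out

    # Group datasets by regimen so parent and metabolite series (and any
    # replicates) share a single simulation per objective evaluation.
    import json as _json

    groups: dict[str, list[ObservedDataset]] = {}
    for ds in datasets:
        key = _json.dumps(ds.regimen, sort_keys=True) + "|" + ds.fed_state
        groups.setdefault(key, []).append(ds)

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        updates = unpack(x)
        d, m = _apply_params(drug, metabolite, updates)
        total = 0.0
        for members in groups.values():
            times = np.unique(np.concatenate([np.asarray(ds.times) for ds in members]))
            try:
                pred_all = simulate_regimen(d, m, individual, members[0].regimen, members[0].fed_state, times)
            except Exception:
                return 1e6
            for ds in members:
                pred = np.interp(np.asarray(ds.times), times, pred_all[ds.analyte])
                obs = np.asarray(ds.concentrations)
                ok = (pred > 0) & (obs > 0)
                if not ok.any():
                    return 1e6
                total += float(np.sum((np.log10(pred[ok]) - np.log10(obs[ok])) ** 2))
        return total

    x0 = np.array([math.log10(v) if spec.scale == "log" else v for v in start.values()])
    sol = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": spec.max_iterations,
            "xatol": spec.xatol,
            "fatol": spec.fatol,
            "adaptive": True,
        },
    )
    return FitResult(
        estimates=unpack(sol.x),
        objective=float(sol.fun),
        converged=bool(sol.success),
        n_evaluations=n_eval,
        start_values=start,
    )


# ---------------------------------------------------------------------------
# Local sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    coefficient: float  # relative dAUC_inf / relative dparameter
    perturbation: float
    flagged: str | None = None


def _auc_inf_single_dose(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    dose_mg: float,
    analyte: str,
    t_end: float = 120.0,
) -> float:
    model = PBPKModel(drug, metabolite, individual, solver_options=FIT_SOLVER_OPTIONS)
    res = model.simulate(build_regimen(dose_mg), t_end)
    t, c = res.time, res.conc[analyte]
    auc = float(np.trapezoid(c, t))
    # exponential tail correction from the terminal decline
    if c[-1] > 0 and c[-1] < 0.5 * c.max() and c[-1] < c[-20]:
        lam = (math.log(c[-20]) - math.log(c[-1])) / (t[-1] - t[-20])
        if lam > 0:
            auc += c[-1] / lam
    return auc


def local_sensitivity(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    individual: Individual,
    parameters: list[str],
    perturbation: float = 0.1,
    dose_mg: float = 50.0,
    analyte: str = "tegoprazan",
    t_end: float = 120.0,
) -> list[SensitivityResult]:
    """Central-difference sensitivity of single-dose AUC_inf, ranked.

    coefficient = (dAUC/AUC) / (dp/p); computed at +-``perturbation``
    around each parameter's current value with the others fixed.
    """
    if not 0 < perturbation <= 0.5:
        raise CalibrationError("perturbation must be in (0, 0.5]")
    base = _auc_inf_single_dose(drug, metabolite, individual, dose_mg, analyte, t_end)
    results = []
    for p in parameters:
        v0 = _get_param(drug, metabolite, p)
        if v0 == 0:
            results.append(SensitivityResult(p, 0.0, perturbation, "parameter is zero"))
            continue
        try:
            up = _apply_params(drug, metabolite, {p: v0 * (1 + perturbation)})
            dn = _apply_params(drug, metabolite, {p: v0 * (1 - perturbation)})
            auc_up = _auc_inf_single_dose(*up, individual, dose_mg, analyte, t_end)
            auc_dn = _auc_inf_single_dose(*dn, individual, dose_mg, analyte, t_end)
        except Exception as err:  # flagged, not fatal
            results.append(SensitivityResult(p, float("nan"), perturbation, str(err)))
            continue
        coeff = ((auc_up - auc_dn) / base) / (2 * perturbation)
        results.append(SensitivityResult(p, float(coeff), perturbation))
    return sorted(results, key=lambda r: -abs(r.coefficient) if math.isfinite(r.coefficient) else 0.0)
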