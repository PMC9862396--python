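"""Enzyme-turnover DDI engine: mechanism-based inactivation and induction.

The enzyme pool at each expression site turns over as
dE/dt = Rsyn - kdeg*E.  A mechanism-based inactivator adds an irreversible
loss term kinact*I/(KI+I)*E; an inducer multiplies the synthesis rate by
1 + Emax*I/(EC50+I).  The perpetrator concentration I(t) (unbound plasma,
µmol/L) comes either from a simplified one-compartment oral model of the
perpetrator's own kinetics or from a user-supplied forcing table — the
victim-side turnover mechanism is the contribution here; whole-body
perpetrator models are deliberately out of scope.

A DDI simulation runs the victim alone and combined with the perpetrator
on identical individuals, pretreating the perpetrator to its own steady
state, and reports first-dose and steady-state PK parameters with fold
changes, population min-max included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .absorption import DoseEvent, MealEvent
from .drug import DrugParameters, PerpetratorSpec
from .engine import PBPKModel, SimulationResult
from .evaluation import compute_pk_parameters
from .physiology import Individual


class InteractionError(ValueError):
    """Raised for invalid DDI scenarios or perpetrator configuration."""


@dataclass(frozen=True)
class DDIScenario:
    """Victim + perpetrator regimens with a perpetrator run-in period."""

    victim_regimen: tuple  # events, times relative to victim start
    perpetrator: PerpetratorSpec | None
    perpetrator_regimen: tuple = ()  # DoseEvents for the perpetrator, from t=0
    pretreatment_h: float = 72.0

    def __post_init__(self) -> None:
        if not self.victim_regimen:
            raise InteractionError("victim regimen must not be empty")
        if self.perpetrator is not None and self.perpetrator.own_kinetics is None:
            raise InteractionError(
                f"perpetrator {self.perpetrator.name!r} has no kinetics (model or forcing table)"
            )


@dataclass(frozen=True)
class ArmPK:
    """Population summary of one arm: value with min-max range."""

    auc_first: tuple[float, float, float]  # (mean, min, max) ng*h/mL
    auc_ss: tuple[float, float, float]
    cmax_first: tuple[float, float, float]  # ng/mL
    cmax_ss: tuple[float, float, float]


@dataclass(frozen=True)
class DDIResult:
    alone: ArmPK
    combined: ArmPK
    fold_auc_first: float
    fold_auc_ss: float
    fold_cmax_first: float
    fold_cmax_ss: float
    direction: str  # "increase" | "decrease"
    n_individuals: int
    diagnostics: dict = field(default_factory=dict)


def turnover_rhs(
    e: float, rsyn: float, kdeg: float, perpetrator_conc: float, spec: PerpetratorSpec | None
) -> float:
    """dE/dt for one enzyme pool under an optional perpetrator.

    Induction: dE/dt = Rsyn*(1 + Emax*I/(EC50+I)) - kdeg*E.
    MBI:       dE/dt = Rsyn - (kdeg + kinact*I/(KI+I))*E.
    """
    if e < 0:
        raise InteractionError("enzyme level must be >= 0")
    if spec is None or perpetrator_conc == 0.0:
        return rsyn - kdeg * e
    i = perpetrator_conc
    if spec.mechanism == "induction":
        return rsyn * (1.0 + spec.emax * i / (spec.ec50 + i)) - kdeg * e
    if spec.mechanism == "mbi":
        return rsyn - (kdeg + spec.kinact * i / (spec.ki + i)) * e
    raise InteractionError(f"unknown mechanism {spec.mechanism!r}")


def perpetrator_concentration(
    spec: PerpetratorSpec, regimen: Sequence[DoseEvent]
) -> Callable[[float], float]:
    """Unbound plasma concentration I(t) in µmol/L for the perpetrator.

    One-compartment oral kinetics are evaluated in closed form (Bateman
    superposition over doses); a forcing table is linearly interpolated.
    """
    kin = spec.own_kinetics
    if kin is None:
        raise InteractionError(f"{spec.name!r}: no own kinetics configured")
    if "time_h" in kin:  # forcing table of unbound concentrations
        t_tab = np.asarray(kin["time_h"], dtype=float)
        c_tab = np.asarray(kin["conc_umol_L"], dtype=float)

        def forcing(t: float) -> float:
            return float(np.interp(t, t_tab, c_tab, left=0.0, right=c_tab[-1]))

        return forcing

    try:
        ka = float(kin["ka_per_h"])
        v = float(kin["volume_L"])
        cl = float(kin["clearance_L_per_h"])
        f_oral = float(kin.get("bioavailability", 1.0))
        fu = float(kin.get("fu", 1.0))
        mw = float(kin["molecular_weight_g_mol"])
    except KeyError as err:
        raise InteractionError(f"{spec.name!r}: own_kinetics missing key {err}") from None
    ke = cl / v
    doses = sorted((d for d in regimen if isinstance(d, DoseEvent)), key=lambda d: d.time)
    if not doses:
        raise InteractionError(f"{spec.name!r}: perpetrator regimen has no doses")
    amounts = np.array([d.amount * 1000.0 / mw for d in doses])  # µmol
    times = np.array([d.time for d in doses])

    def conc(t: float) -> float:
        dt = t - times
        active = dt > 0
        if not active.any():
            return 0.0
        dt = dt[active]
        d_umol = amounts[active]
        if abs(ka - ke) < 1e-9:
            shape = ka * dt * np.exp(-ka * dt)
        else:
            shape = ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
        return float(fu * f_oral * np.sum(d_umol * shape) / v)

    return conc


def rate_modifiers(
    spec: PerpetratorSpec | None, conc_fn: Callable[[float], float] | None
) -> Callable[[float], tuple[float, float]] | None:
    """Map I(t) to (synthesis multiplier, added inactivation rate 1/h)."""
    if spec is None or conc_fn is None:
        return None

    if spec.mechanism == "induction":

        def modifiers(t: float) -> tuple[float, float]:
            i = conc_fn(t)
            return 1.0 + spec.emax * i / (spec.ec50 + i), 0.0

    else:  # mbi

        def modifiers(t: float) -> tuple[float, float]:
            i = conc_fn(t)
            return 1.0, spec.kinact * i / (spec.ki + i)

    return modifiers


def _shift_events(events: Sequence, offset: float) -> list:
    shifted = []
    for e in events:
        if isinstance(e, DoseEvent):
            shifted.append(DoseEvent(e.time + offset, e.amount, e.route, e.formulation))
        elif isinstance(e, MealEvent):
            shifted.append(
                MealEvent(e.time + offset, e.gastric_ph_peak, e.ph_decay_halflife, e.emptying_multiplier)
            )
        else:
            raise InteractionError(f"unknown event {e!r}")
    return shifted


def _victim_windows(victim_doses: list[DoseEvent]) -> tuple[float, float, float]:
    times = sorted(d.time for d in victim_doses)
    if len(times) > 1:
        interval = times[1] - times[0]
    else:
        interval = 24.0
    return times[0], times[-1], interval


def _arm_pk(results: list[SimulationResult], analyte: str, t0: float, t_last: float, interval: float):
    """Per-individual first-dose and steady-state NCA on the victim clock."""
    rows = []
    for res in results:
        t = res.time
        c = res.conc[analyte]
        window = t >= t0
        n_doses = int(round((t_last - t0) / interval)) + 1
        pk = compute_pk_parameters(t[window] - t0, c[window], interval, n_doses)
        rows.append((pk.auc_first, pk.auc_ss, pk.cmax_first, pk.cmax_ss))
    arr = np.array(rows)

    def stat(col: int) -> tuple[float, float, float]:
        return float(arr[:, col].mean()), float(arr[:, col].min()), float(arr[:, col].max())

    return ArmPK(auc_first=stat(0), auc_ss=stat(1), cmax_first=stat(2), cmax_ss=stat(3))


def simulate_ddi(
    scenario: DDIScenario,
    victim: DrugParameters,
    metabolite: DrugParameters | None,
    population: Sequence[Individual],
    solver_options: dict | None = None,
    washout_h: float = 24.0,
) -> DDIResult:
    """Run alone and combined arms on identical individuals; report folds.

    The perpetrator is dosed from t=0; the victim regimen starts after the
    pretreatment period in both arms, so the alone arm is bit-identical to
    a standalone victim simulation on the same absolute clock.
    """
    victim_events = _shift_events(scenario.victim_regimen, scenario.pretreatment_h)
    victim_doses = [e for e in victim_events if isinstance(e, DoseEvent)]
    if not victim_doses:
        raise InteractionError("victim regimen has no doses")
    t0, t_last, interval = _victim_windows(victim_doses)
    t_end = t_last + interval + washout_h

    perp = scenario.perpetrator
    modifiers = None
    if perp is not None:
        perp_doses = [d for d in scenario.perpetrator_regimen if isinstance(d, DoseEvent)]
        if not perp_doses and "time_h" not in (perp.own_kinetics or {}):
            raise InteractionError("perpetrator regimen has no doses and no forcing table")
        conc_fn = perpetrator_concentration(perp, perp_doses)
        modifiers = rate_modifiers(perp, conc_fn)

    alone_results, combined_results = [], []
    for ind in population:
        base = PBPKModel(victim, metabolite, ind, solver_options=solver_options)
        alone_results.append(base.simulate(victim_events, t_end))
        ddi = PBPKModel(
            victim,
            metabolite,
            ind,
            solver_options=solver_options,
            perpetrator_rate_modifiers=modifiers,
            perpetrator_enzyme=perp.enzyme if perp is not None else "CYP3A4",
        )
        combined_results.append(ddi.simulate(victim_events, t_end))

    analyte = victim.name
    alone = _arm_pk(alone_results, analyte, t0, t_last, interval)
    combined = _arm_pk(combined_results, analyte, t0, t_last, interval)
    direction = "decrease" if perp is not None and perp.mechanism == "induction" else "increase"
    folds = {
        name: fold_change(a[0], c[0], direction)
        for name, a, c in (
            ("auc_first", alone.auc_first, combined.auc_first),
            ("auc_ss", alone.auc_ss, combined.auc_ss),
            ("cmax_first", alone.cmax_first, combined.cmax_first),
            ("cmax_ss", alone.cmax_ss, combined.cmax_ss),
        )
    }
    return DDIResult(
        alone=alone,
        combined=combined,
        fold_auc_first=folds["auc_first"],
        fold_auc_ss=folds["auc_ss"],
        fold_cmax_first=folds["cmax_first"],
        fold_cmax_ss=folds["cmax_ss"],
        direction=direction,
        n_individuals=len(population),
        diagnostics={
            "pretreatment_h": scenario.pretreatment_h,
            "perpetrator": perp.name if perp is not None else "none",
            "t_end": t_end,
        },
    )


def fold_change(alone: float, combined: float, direction: str = "increase") -> float:
    """combined/alone for an increase, alone/combined for a decrease."""
    if alone <= 0 or combined <= 0:
        raise InteractionError("fold change requires positive PK parameters")
    if direction == "increase":
        return combined / alone
    if direction == "decrease":
        return alone / combined
    raise InteractionError(f"unknown direction {direction!r}")


def steady_state_enzyme_fraction(spec: PerpetratorSpec, i_unbound: float, kdeg: float) -> float:
    """Analytic E_ss/E_0 under a constant perpetrator concentration.

    MBI: kdeg/(kdeg + kinact*I/(KI+I)); induction: 1 + Emax*I/(EC50+I).
    Useful as an oracle for the turnover integration.
    """
    if spec.mechanism == "mbi":
        return kdeg / (kdeg + spec.kinact * i_unbound / (spec.ki + i_unbound))
    return 1.0 + spec.emax * i_unbound / (spec.ec50 + i_unbound)
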