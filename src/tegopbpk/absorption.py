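"""Gastrointestinal absorption: Weibull dissolution, transit, meal events.

The oral dose is deposited undissolved in the stomach.  Dissolution follows
a Weibull schedule m(t) = 1 - exp(-ln2 * (t/t50)^shape), parameterized so
that m(t50) = 0.5 exactly — t50 is the time to 50% dissolved.  Undissolved
and dissolved material both transit down a small chain of segments
(stomach + 4 small-intestinal segments + colon) with first-order transit;
dissolved drug is absorbed by permeability-driven uptake through the
effective (villi-amplified) surface area of whichever segment it occupies.
A meal raises gastric pH to a peak and slows gastric emptying, both
relaxing exponentially back to the fasted baseline, and switches the
formulation to its fed-state dissolution profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .drug import DissolutionSpec, DrugModelError

#: Hazard cap (1/h) guarding the integrable singularity of the Weibull
#: dissolution hazard at t=0 when shape < 1.
HAZARD_CAP = 200.0

#: cm^3/s -> L/h
_CM3_S_TO_L_H = 3.6


class AbsorptionError(ValueError):
    """Raised for invalid gastrointestinal inputs."""


@dataclass(frozen=True)
class GISegment:
    name: str
    volume: float  # L luminal fluid
    ph: float
    transit_rate: float  # 1/h
    surface_area: float  # cm^2 geometric
    area_multiplier: float  # effective-area amplification

    def __post_init__(self) -> None:
        if self.transit_rate <= 0:
            raise AbsorptionError(f"{self.name}: transit rate must be > 0")
        if not 1.0 <= self.ph <= 8.5:
            raise AbsorptionError(f"{self.name}: pH outside [1, 8.5]")

    @property
    def effective_area(self) -> float:
        return self.surface_area * self.area_multiplier


@dataclass(frozen=True)
class GITract:
    """Ordered luminal segments; the stomach is always first."""

    segments: tuple[GISegment, ...]

    def __post_init__(self) -> None:
        if not self.segments or self.segments[0].name != "stomach":
            raise AbsorptionError("the first GI segment must be the stomach")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)


@dataclass(frozen=True)
class DoseEvent:
    """An administered dose; oral doses reference a dissolution state."""

    time: float  # h
    amount: float  # mg
    route: str = "oral"  # "oral" | "iv"
    formulation: str = "fasted"  # DissolutionSpec state for oral doses

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise AbsorptionError("dose amount must be >= 0")
        if self.route not in ("oral", "iv"):
            raise AbsorptionError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class MealEvent:
    """A meal: gastric pH peak with exponential decay, slowed emptying."""

    time: float  # h
    gastric_ph_peak: float = 5.5
    ph_decay_halflife: float = 0.75  # h
    emptying_multiplier: float = 0.25

    def __post_init__(self) -> None:
        if not 1.0 <= self.gastric_ph_peak <= 8.5:
            raise AbsorptionError("gastric pH peak outside [1, 8.5]")
        if self.emptying_multiplier <= 0:
            raise AbsorptionError("emptying multiplier must be > 0")


def default_gi_tract() -> GITract:
    """The bundled GI segment table."""
    with resources.files("tegopbpk.data").joinpath("gi_tract.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return GITract(
        segments=tuple(
            GISegment(
                name=s["name"],
                volume=s["volume_L"],
                ph=s["pH"],
                transit_rate=s["transit_per_h"],
                surface_area=s["area_cm2"],
                area_multiplier=s["area_multiplier"],
            )
            for s in raw["segments"]
        )
    )


def default_meal_parameters() -> dict:
    with resources.files("tegopbpk.data").joinpath("gi_tract.yaml").open() as fh:
        return yaml.safe_load(fh)["meal"]


def weibull_fraction(t: float, spec: DissolutionSpec) -> float:
    """Accumulated fraction dissolved at time ``t`` since dosing.

    m(t) = 1 - exp(-ln2 * (t/t50)^shape); m(0) = 0, m(t50) = 0.5 exactly,
    nondecreasing and -> 1 as t -> infinity.
    """
    if t < 0:
        raise AbsorptionError("time since dose must be >= 0")
    return 1.0 - math.exp(-math.log(2.0) * (t / spec.t50) ** spec.shape)


def dissolution_hazard(t: float, spec: DissolutionSpec) -> float:
    """Instantaneous dissolution rate constant m'(t)/(1-m(t)) in 1/h.

    For shape < 1 the hazard diverges (integrably) at t=0; it is capped at
    ``HAZARD_CAP`` so the ODE right-hand side stays finite.
    """
    tau = max(t, 1e-9)
    h = math.log(2.0) * spec.shape * tau ** (spec.shape - 1.0) / spec.t50**spec.shape
    return min(h, HAZARD_CAP)


def absorption_flux(lumen_concentration: float, segment: GISegment, peff: float) -> float:
    """Permeability-driven uptake from a segment, in µmol/h.

    flux = Peff [cm/s] x effective area [cm^2] x C_lumen [µmol/L], with the
    cm^3/s volume-flow converted to L/h.  Linear in both Peff and C.
    """
    if lumen_concentration < 0:
        raise AbsorptionError("lumen concentration must be >= 0")
    return peff * segment.effective_area * _CM3_S_TO_L_H * lumen_concentration


def gastric_state(tract: GITract, meals: list[MealEvent], t: float) -> tuple[float, float]:
    """Gastric (pH, emptying-rate multiplier) at time ``t`` given past meals.

    After a meal the pH jumps to the meal's peak and relaxes exponentially
    to the fasted baseline; the emptying-rate multiplier relaxes back to 1
    with the same half-life.  Without meals the fasted baseline applies.
    """
    stomach = tract.segments[0]
    ph, mult = stomach.ph, 1.0
    for meal in meals:
        if meal.time <= t:
            lam = math.log(2.0) / meal.ph_decay_halflife
            decay = math.exp(-lam * (t - meal.time))
            ph = stomach.ph + (meal.gastric_ph_peak - stomach.ph) * decay
            mult = 1.0 + (meal.emptying_multiplier - 1.0) * decay
    return ph, mult


def apply_meal(tract: GITract, meal: MealEvent, t: float) -> GITract:
    """Return the tract with gastric pH/emptying modified by a past meal."""
    if meal.time > t:
        raise AbsorptionError("meal is in the future")
    ph, mult = gastric_state(tract, [meal], t)
    stomach = tract.segments[0]
    return GITract(
        segments=(replace(stomach, ph=ph, transit_rate=stomach.transit_rate * mult),)
        + tract.segments[1:]
    )


def active_dissolution_spec(
    dissolution: dict[str, DissolutionSpec], formulation: str
) -> DissolutionSpec:
    try:
        return dissolution[formulation]
    except KeyError:
        raise DrugModelError(f"no dissolution profile for state {formulation!r}") from None
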