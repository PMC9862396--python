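"""Virtual-individual physiology: organ volumes, blood flows, enzyme expression.

The whole-body model consumes an :class:`Individual` — an organ table with
regional blood flows plus the CYP expression sites.  A single bundled
reference adult (73.5 kg male, cardiac output 390 L/h) is scaled to the
requested body weight: volumes linearly, blood flows allometrically with
weight^0.75.  Enzyme expression is restricted to the two sites the model
needs, hepatic CYP3A4/CYP2C19 and small-intestinal mucosal CYP3A4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

REFERENCE_WEIGHT_KG = 73.5
REFERENCE_CARDIAC_OUTPUT = 390.0  # L/h
BODY_DENSITY = 1.03  # kg/L

#: Enzyme degradation rate constants (1/h).  Literature-typical turnover
#: half-lives: ~36 h for hepatic CYP3A4/CYP2C19, ~23 h for enterocyte CYP3A4.
DEFAULT_KDEG = {"liver": 0.019, "gut": 0.030}

#: Default enzyme reference concentrations (µmol enzyme / L tissue).  The
#: hepatic values are calibrated so that the simulated mass balance of a
#: 50 mg oral dose reproduces the reported pathway split (71.6% CYP3A4,
#: 20.2% CYP2C19, 7.82% renal); see calibration.calibrate_enzyme_abundance.
#: The mucosal CYP3A4 level gives a modest (~5%) gut-wall first pass.
DEFAULT_ENZYME_ABUNDANCE = {
    ("CYP3A4", "liver"): 4.042,
    ("CYP2C19", "liver"): 1.052,
    ("CYP3A4", "gut"): 1.121,
}


class PhysiologyError(ValueError):
    """Raised when a physiological input is outside its valid domain."""


@dataclass(frozen=True)
class OrganSpec:
    """One organ: volume, perfusion and bulk tissue composition."""

    name: str
    volume: float  # L
    blood_flow: float  # L/h; hepatic artery only for the liver
    water_fraction: float
    neutral_lipid_fraction: float
    phospholipid_fraction: float
    protein_fraction: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise PhysiologyError(f"{self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise PhysiologyError(f"{self.name}: blood flow must be >= 0")
        for frac in (
            self.water_fraction,
            self.neutral_lipid_fraction,
            self.phospholipid_fraction,
            self.protein_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise PhysiologyError(f"{self.name}: composition fraction outside [0, 1]")


@dataclass(frozen=True)
class EnzymeExpression:
    """Expression of one CYP at one site, with first-order turnover.

    ``reference_concentration`` is the baseline enzyme level (µmol enzyme per
    L tissue); with degradation constant ``kdeg`` the implied de novo
    synthesis rate is ``reference_concentration * kdeg``, so turnover rests
    at the reference level in the absence of perpetrators.
    """

    enzyme: str  # "CYP3A4" | "CYP2C19"
    organ: str  # "liver" | "gut"
    reference_concentration: float  # µmol/L tissue
    kdeg: float  # 1/h

    def __post_init__(self) -> None:
        if self.reference_concentration < 0:
            raise PhysiologyError("enzyme reference concentration must be >= 0")
        if self.kdeg <= 0:
            raise PhysiologyError("kdeg must be > 0")


@dataclass(frozen=True)
class Individual:
    """A virtual subject: demographics, organ table, enzyme expression."""

    sex: str
    age: float  # years
    weight: float  # kg
    bmi: float  # kg/m^2
    organs: tuple[OrganSpec, ...]
    cardiac_output: float  # L/h
    enzymes: tuple[EnzymeExpression, ...] = field(default_factory=tuple)
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise PhysiologyError("weight must be > 0")
        flow = sum(o.blood_flow for o in self.organs if o.name not in ("lung", "venous_blood", "arterial_blood"))
        if not math.isclose(flow, self.cardiac_output, rel_tol=1e-6):
            raise PhysiologyError(
                f"organ blood flows ({flow:.6g} L/h) do not sum to cardiac output "
                f"({self.cardiac_output:.6g} L/h)"
            )

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def total_volume(self) -> float:
        return sum(o.volume for o in self.organs)

    def with_enzymes(self, enzymes: tuple[EnzymeExpression, ...]) -> "Individual":
        return replace(self, enzymes=enzymes)


@lru_cache(maxsize=1)
def _reference_table_cached() -> pd.DataFrame:
    with resources.files("tegopbpk.data").joinpath("reference_physiology.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_reference_table() -> pd.DataFrame:
    """Return the bundled reference-adult organ table."""
    return _reference_table_cached().copy()


def default_enzymes(
    abundance: dict[tuple[str, str], float] | None = None,
    kdeg: dict[str, float] | None = None,
) -> tuple[EnzymeExpression, ...]:
    """The model's default CYP expression sites (liver 3A4/2C19, gut 3A4)."""
    abundance = dict(DEFAULT_ENZYME_ABUNDANCE if abundance is None else abundance)
    kdeg = dict(DEFAULT_KDEG if kdeg is None else kdeg)
    return tuple(
        EnzymeExpression(enzyme=enz, organ=org, reference_concentration=conc, kdeg=kdeg[org])
        for (enz, org), conc in abundance.items()
    )


def build_reference_individual(
    weight: float = REFERENCE_WEIGHT_KG,
    sex: str = "male",
    age: float = 30.0,
    bmi: float = 23.0,
    enzymes: tuple[EnzymeExpression, ...] | None = None,
) -> Individual:
    """Scale the bundled reference adult to the requested body weight.

    Organ volumes scale linearly with weight; regional blood flows and
    cardiac output scale with weight^0.75.
    """
    if not 20.0 <= weight <= 200.0:
        raise PhysiologyError(f"weight {weight} kg outside supported range [20, 200]")
    table = load_reference_table()
    vscale = weight / REFERENCE_WEIGHT_KG
    qscale = vscale**0.75
    organs = tuple(
        OrganSpec(
            name=row.organ,
            volume=row.volume_L * vscale,
            blood_flow=row.flow_L_per_h * qscale,
            water_fraction=row.f_water,
            neutral_lipid_fraction=row.f_neutral_lipid,
            phospholipid_fraction=row.f_phospholipid,
            protein_fraction=row.f_protein,
        )
        for row in table.itertuples()
    )
    return Individual(
        sex=sex,
        age=age,
        weight=weight,
        bmi=bmi,
        organs=organs,
        cardiac_output=REFERENCE_CARDIAC_OUTPUT * qscale,
        enzymes=default_enzymes() if enzymes is None else enzymes,
    )


def enzyme_baseline(expr: EnzymeExpression) -> float:
    """De novo synthesis rate Rsyn (µmol/L/h) balancing degradation.

    Rsyn = reference_concentration * kdeg, so dE/dt = Rsyn - kdeg*E has its
    steady state exactly at the reference concentration.
    """
    if expr.kdeg <= 0:
        raise PhysiologyError("kdeg must be > 0")
    return expr.reference_concentration * expr.kdeg


#: Variability keys accepted by :func:`sample_population`.
_SAMPLEABLE = ("weight", "cardiac_output", "CYP3A4", "CYP2C19", "renal")


def sample_population(
    n: int,
    seed: int,
    variability: dict[str, float] | None = None,
    base_weight: float = 50.0,
    sex: str = "male",
    age_range: tuple[float, float] = (19.0, 45.0),
    bmi_range: tuple[float, float] = (19.0, 28.0),
) -> list[Individual]:
    """Draw a virtual population with independent log-normal variability.

    ``variability`` maps a parameter name to its coefficient of variation;
    recognised keys are body weight, cardiac output and the per-enzyme
    abundance multipliers.  With all CVs zero the population is ``n``
    identical copies of the base individual.  Output is a pure function of
    ``(n, seed, variability)``.
    """
    if n < 1:
        raise PhysiologyError("population size must be >= 1")
    variability = dict(variability or {})
    for key, cv in variability.items():
        if key not in _SAMPLEABLE:
            raise PhysiologyError(f"unknown variability key {key!r}")
        if cv < 0:
            raise PhysiologyError(f"negative CV for {key!r}")
    rng = np.random.default_rng(seed)

    def lognormal(cv: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        sigma = math.sqrt(math.log(1.0 + cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    w_mult = lognormal(variability.get("weight", 0.0), n)
    co_mult = lognormal(variability.get("cardiac_output", 0.0), n)
    e34_mult = lognormal(variability.get("CYP3A4", 0.0), n)
    e19_mult = lognormal(variability.get("CYP2C19", 0.0), n)
    ages = rng.uniform(*age_range, size=n)
    bmis = rng.uniform(*bmi_range, size=n)

    population: list[Individual] = []
    for i in range(n):
        ind = build_reference_individual(weight=base_weight * w_mult[i], sex=sex, age=float(ages[i]), bmi=float(bmis[i]))
        if co_mult[i] != 1.0:
            organs = tuple(
                o if o.name in ("venous_blood", "arterial_blood") else replace(o, blood_flow=o.blood_flow * co_mult[i])
                for o in ind.organs
            )
            ind = replace(ind, organs=organs, cardiac_output=ind.cardiac_output * co_mult[i])
        enzymes = tuple(
            replace(
                e,
                reference_concentration=e.reference_concentration
                * (e34_mult[i] if e.enzyme == "CYP3A4" else e19_mult[i]),
            )
            for e in ind.enzymes
        )
        population.append(ind.with_enzymes(enzymes))
    return population
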