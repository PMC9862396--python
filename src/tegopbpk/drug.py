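"""Compound-specific parameters and small pure physicochemical operations.

Holds the parent (tegoprazan) and metabolite (M1, desmethyl tegoprazan)
parameter sets, the in-vitro-to-in-vivo ISEF correction for recombinant-CYP
intrinsic clearances, Henderson-Hasselbalch ionization, tissue-to-plasma
partition coefficients from a tissue-composition method, and the
erythrocyte-partitioning blood-to-plasma ratio estimate.

Unit conventions: intrinsic clearances are µL/min/pmol enzyme; multiplying
by an enzyme concentration (µmol/L tissue) and a tissue volume (L) and by
60 min/h yields an organ intrinsic clearance in L/h (the µL/pmol pair is
numerically identical to L/µmol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .physiology import Individual

#: Plasma and red-blood-cell composition used by the partition methods.
PLASMA_COMPOSITION = {"f_water": 0.9606, "f_neutral_lipid": 0.00147, "f_phospholipid": 0.00083}
RBC_COMPOSITION = {"f_water": 0.63, "f_neutral_lipid": 0.0017, "f_phospholipid": 0.0029}

KP_METHODS = ("poulin_theil", "berezhkovskiy")


class DrugModelError(ValueError):
    """Raised when a compound parameter or argument is outside its domain."""


@dataclass(frozen=True)
class MetabolicReaction:
    """One CYP-mediated reaction of the parent: enzyme, product, CLint."""

    enzyme: str  # "CYP3A4" | "CYP2C19"
    product: str  # "M1" | "other"
    clint: float  # µL/min/pmol enzyme

    def __post_init__(self) -> None:
        if self.clint < 0:
            raise DrugModelError("CLint must be >= 0")


@dataclass(frozen=True)
class DissolutionSpec:
    """Weibull dissolution: t50 is the time to 50% dissolved, shape the slope."""

    t50: float  # h
    shape: float
    state: str  # "fasted" | "fed"

    def __post_init__(self) -> None:
        if self.t50 <= 0 or self.shape <= 0:
            raise DrugModelError("Weibull t50 and shape must be > 0")


@dataclass(frozen=True)
class DrugParameters:
    """All compound-specific constants consumed by the whole-body model."""

    name: str
    molecular_weight: float  # g/mol
    logp: float
    fu_plasma: float  # fraction unbound
    solubility: float  # mg/L
    pka_entries: tuple[tuple[float, str], ...] = ()
    specific_intestinal_permeability: float = 0.0  # cm/s
    specific_organ_permeability: float = 0.0  # cm/s; carried but inert (flow-limited model)
    renal_plasma_clearance: float = 0.0  # mL/min/kg
    total_hepatic_plasma_clearance: float = 0.0  # mL/min/kg; metabolite only
    reactions: tuple[MetabolicReaction, ...] = ()
    dissolution: dict[str, DissolutionSpec] = field(default_factory=dict)
    blood_to_plasma_ratio: float | None = None  # computed from composition if None
    kp_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise DrugModelError("fu_plasma must be in (0, 1]")
        if self.molecular_weight <= 0:
            raise DrugModelError("molecular weight must be > 0")
        for cl in (self.renal_plasma_clearance, self.total_hepatic_plasma_clearance):
            if cl < 0:
                raise DrugModelError("clearances must be >= 0")

    def clint_total(self, enzyme: str) -> float:
        """Summed CLint of an enzyme over its products (µL/min/pmol)."""
        return sum(r.clint for r in self.reactions if r.enzyme == enzyme)


@dataclass(frozen=True)
class PerpetratorSpec:
    """A CYP perpetrator: interaction mechanism plus its own kinetics.

    ``mechanism`` is ``"mbi"`` (mechanism-based inactivation; KI µmol/L,
    kinact 1/h) or ``"induction"`` (Emax model on enzyme synthesis; Emax
    unitless, EC50 µmol/L).  ``own_kinetics`` is either a dict of
    one-compartment oral parameters (ka_per_h, volume_L, clearance_L_per_h,
    bioavailability, fu, molecular_weight) or a forcing concentration-time
    table ``{"time_h": [...], "conc_umol_L": [...]}`` of unbound plasma
    concentrations.
    """

    name: str
    mechanism: str
    enzyme: str = "CYP3A4"
    ki: float | None = None  # µmol/L
    kinact: float | None = None  # 1/h
    emax: float | None = None
    ec50: float | None = None  # µmol/L
    own_kinetics: dict | None = None

    def __post_init__(self) -> None:
        if self.mechanism == "mbi":
            if self.ki is None or self.kinact is None or self.ki <= 0 or self.kinact < 0:
                raise DrugModelError("mbi perpetrator requires KI > 0 and kinact >= 0")
        elif self.mechanism == "induction":
            if self.emax is None or self.ec50 is None or self.ec50 <= 0 or self.emax < 0:
                raise DrugModelError("induction perpetrator requires Emax >= 0 and EC50 > 0")
        else:
            raise DrugModelError(f"unknown mechanism {self.mechanism!r}")


def isef_correct(clint_rcyp: float, isef: float) -> float:
    """Scale a recombinant-CYP CLint by the intersystem extrapolation factor."""
    if clint_rcyp < 0 or isef < 0:
        raise DrugModelError("CLint and ISEF must be >= 0")
    return clint_rcyp * isef


def ionization_fraction(ph: float, pka: float, kind: str) -> float:
    """Henderson-Hasselbalch fraction ionized at the given pH.

    Diagnostic only: pH-dependent solubility is not wired into dissolution.
    """
    if not 0.0 <= ph <= 14.0:
        raise DrugModelError("pH must be in [0, 14]")
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise DrugModelError(f"unknown ionization type {kind!r}")


def _fu_tissue(fu_plasma: float) -> float:
    # Poulin-Theil assumption: tissue interstitial binding at half the
    # plasma-protein concentration.
    return 1.0 / (1.0 + 0.5 * (1.0 - fu_plasma) / fu_plasma)


def _composition_ratio(pow_: float, f_nl: float, f_ph: float, f_w: float) -> float:
    return pow_ * (f_nl + 0.3 * f_ph) + (f_w + 0.7 * f_ph)


def partition_coefficients(
    drug: DrugParameters, individual: Individual, method: str = "poulin_theil"
) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients from tissue composition.

    ``poulin_theil`` applies the plasma/tissue unbound-fraction correction
    (dropped in adipose); ``berezhkovskiy`` is the variant without the
    tissue-binding correction.  Per-organ overrides in the drug parameters
    take precedence.  The map is strictly positive and deterministic.
    """
    if method not in KP_METHODS:
        raise DrugModelError(f"unknown partition method {method!r}; choose from {KP_METHODS}")
    pow_ = 10.0**drug.logp
    denom = _composition_ratio(
        pow_,
        PLASMA_COMPOSITION["f_neutral_lipid"],
        PLASMA_COMPOSITION["f_phospholipid"],
        PLASMA_COMPOSITION["f_water"],
    )
    kps: dict[str, float] = {}
    for organ in individual.organs:
        if organ.name in ("venous_blood", "arterial_blood"):
            continue
        if organ.name in drug.kp_overrides:
            kps[organ.name] = float(drug.kp_overrides[organ.name])
            continue
        num = _composition_ratio(
            pow_, organ.neutral_lipid_fraction, organ.phospholipid_fraction, organ.water_fraction
        )
        kp = num / denom
        if method == "poulin_theil" and organ.name != "adipose":
            kp *= drug.fu_plasma / _fu_tissue(drug.fu_plasma)
        elif method == "poulin_theil":
            kp *= drug.fu_plasma  # adipose: unbound drug only partitions into fat
        kps[organ.name] = max(kp, 1e-6)
    return kps


def blood_to_plasma_ratio(drug: DrugParameters, hematocrit: float = 0.45) -> float:
    """B:P ratio from erythrocyte partitioning of the unbound drug.

    BP = (1 - Hct) + Hct * fu_p * K_rbc,u with the red-cell partition
    coefficient from the same composition rule as the tissue Kp method.
    An explicit ``blood_to_plasma_ratio`` on the drug takes precedence.
    """
    if drug.blood_to_plasma_ratio is not None:
        return drug.blood_to_plasma_ratio
    pow_ = 10.0**drug.logp
    k_rbc = _composition_ratio(
        pow_, RBC_COMPOSITION["f_neutral_lipid"], RBC_COMPOSITION["f_phospholipid"], RBC_COMPOSITION["f_water"]
    ) / _composition_ratio(
        pow_,
        PLASMA_COMPOSITION["f_neutral_lipid"],
        PLASMA_COMPOSITION["f_phospholipid"],
        PLASMA_COMPOSITION["f_water"],
    )
    return (1.0 - hematocrit) + hematocrit * drug.fu_plasma * k_rbc
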