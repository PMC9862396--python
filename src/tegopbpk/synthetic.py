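"""Synthetic clinical-study generator with known ground truth.

Emulates the kind of digitized clinical PK corpus the model was built
against: oral tegoprazan 50-400 mg, single and repeated doses, fasted and
fed arms, dense 0-24 h (or multi-day) sampling of both analytes, with
multiplicative log-normal residual error and LLOQ censoring.  Every study
carries the generating parameter set, so parameter-recovery and
evaluation-metric behaviour can be tested end to end without any external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import simulate_regimen
from .drug import DrugParameters
from .evaluation import ObservedDataset
from .physiology import Individual, build_reference_individual, sample_population

#: Dense default sampling: early points resolve Cmax, 24 h covers the tail.
DEFAULT_SAMPLING_H = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


class SyntheticDataError(ValueError):
    """Raised for study designs outside the simulable range."""


@dataclass(frozen=True)
class StudyDesign:
    """One study arm: regimen, sampling schedule, error model."""

    study_id: str
    dose: float  # mg
    n_doses: int = 1
    interval: float = 24.0  # h
    fed_state: str = "fasted"
    n_subjects: int = 1
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_H  # h after last dose start
    residual_cv: float = 0.20
    lloq: float = 1.0  # ng/mL
    seed: int = 0
    perpetrator: str | None = None  # bundled perpetrator name for a DDI arm
    analytes: tuple[str, ...] = ("tegoprazan", "M1")
    train: bool = True

    def __post_init__(self) -> None:
        if not 1.0 <= self.dose <= 800.0:
            raise SyntheticDataError(f"{self.study_id}: dose outside the modeled range")
        if self.residual_cv < 0:
            raise SyntheticDataError(f"{self.study_id}: residual CV must be >= 0")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise SyntheticDataError(f"{self.study_id}: sampling times must be sorted")

    def regimen_dict(self) -> dict:
        reg = {"dose_mg": self.dose, "n_doses": self.n_doses, "interval_h": self.interval}
        if self.perpetrator:
            reg.update(
                perpetrator=self.perpetrator,
                pretreatment_h=48.0,
                perpetrator_dose_mg=500.0,
                perpetrator_interval_h=8.0,
            )
        return reg

    def absolute_times(self) -> tuple[float, ...]:
        offset = (self.n_doses - 1) * self.interval
        return tuple(offset + t for t in self.sampling_times)


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated datasets plus the ground truth that produced them."""

    design: StudyDesign
    datasets: tuple[ObservedDataset, ...]
    truth: dict = field(default_factory=dict)
    n_censored: int = 0


def generate_study(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    design: StudyDesign,
    population: list[Individual] | None = None,
) -> SyntheticStudy:
    """Simulate one study arm and add observation noise.

    Per subject, the model is run under the design's regimen, sampled at
    the design's times, and perturbed multiplicatively by a log-normal
    residual with the design CV; values below the LLOQ are censored
    (dropped) and counted.  Deterministic for a given design (the design
    seed drives both physiology sampling and noise).
    """
    rng = np.random.default_rng(design.seed)
    if population is None:
        if design.n_subjects == 1:
            population = [build_reference_individual()]
        else:
            population = sample_population(
                design.n_subjects, seed=design.seed, variability={"CYP3A4": 0.3, "CYP2C19": 0.3},
                base_weight=73.5,
            )
    sigma = math.sqrt(math.log(1.0 + design.residual_cv**2)) if design.residual_cv > 0 else 0.0
    # times relative to the last dose -> relative to the first victim dose
    rel_times = np.asarray(design.absolute_times()) - 0.0
    reg = design.regimen_dict()

    # one simulation per distinct subject serves every analyte
    clean_by_subject: dict[int, dict[str, np.ndarray]] = {}
    for subject in population:
        if id(subject) not in clean_by_subject:
            clean_by_subject[id(subject)] = simulate_regimen(
                drug, metabolite, subject, reg, design.fed_state, rel_times
            )

    datasets = []
    n_censored = 0
    for analyte in design.analytes:
        all_t: list[float] = []
        all_c: list[float] = []
        for subject in population:
            clean = clean_by_subject[id(subject)][analyte]
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.size) if sigma > 0 else 1.0
            noisy = clean * noise
            keep = noisy >= design.lloq
            n_censored += int((~keep).sum())
            all_t.extend(rel_times[keep])
            all_c.extend(np.atleast_1d(noisy)[keep])
        order = np.argsort(all_t, kind="stable")
        datasets.append(
            ObservedDataset(
                study_id=design.study_id,
                analyte=analyte,
                times=tuple(np.asarray(all_t)[order]),
                concentrations=tuple(np.asarray(all_c)[order]),
                regimen=reg,
                fed_state=design.fed_state,
            )
        )
    truth = {
        "drug": drug,
        "metabolite": metabolite,
        "clint": {f"{r.enzyme}_to_{r.product}": r.clint for r in drug.reactions},
        "dissolution": {s: (spec.t50, spec.shape) for s, spec in drug.dissolution.items()},
        "seed": design.seed,
    }
    return SyntheticStudy(design=design, datasets=tuple(datasets), truth=truth, n_censored=n_censored)


def training_suite_designs(seed: int) -> list[StudyDesign]:
    """The 19-arm synthetic corpus: 10 training and 9 test designs.

    Spans 50-400 mg, single and repeated dosing, fasted and fed arms, and
    one DDI-layout arm (tegoprazan + clarithromycin, tegoprazan series
    only) whose metabolite series is deliberately absent — repeated-dose
    interaction arms are the exclusion case the evaluation handles.
    """
    multi = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    specs = [
        # (study_id, dose, n_doses, interval, fed, sampling, perpetrator, train)
        ("S01", 50, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, True),
        ("S02", 100, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, True),
        ("S03", 200, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, True),
        ("S04", 400, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, True),
        ("S05", 50, 1, 24.0, "fed", DEFAULT_SAMPLING_H, None, True),
        ("S06", 100, 1, 24.0, "fed", DEFAULT_SAMPLING_H, None, True),
        ("S07", 50, 7, 24.0, "fasted", multi, None, True),
        ("S08", 100, 7, 24.0, "fasted", multi, None, True),
        ("S09", 50, 5, 12.0, "fasted", multi, "clarithromycin", True),  # DDI layout
        ("S10", 200, 1, 24.0, "fed", DEFAULT_SAMPLING_H, None, True),
        ("S11", 50, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, False),
        ("S12", 100, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, False),
        ("S13", 200, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, False),
        ("S14", 400, 1, 24.0, "fed", DEFAULT_SAMPLING_H, None, False),
        ("S15", 100, 1, 24.0, "fed", DEFAULT_SAMPLING_H, None, False),
        ("S16", 100, 7, 24.0, "fasted", multi, None, False),
        ("S17", 200, 7, 24.0, "fasted", multi, None, False),
        ("S18", 50, 14, 12.0, "fasted", multi, None, False),
        ("S19", 400, 1, 24.0, "fasted", DEFAULT_SAMPLING_H, None, False),
    ]
    designs = []
    for k, (sid, dose, nd, tau, fed, sampling, perp, train) in enumerate(specs):
        analytes = ("tegoprazan",) if perp else ("tegoprazan", "M1")
        designs.append(
            StudyDesign(
                study_id=sid,
                dose=dose,
                n_doses=nd,
                interval=tau,
                fed_state=fed,
                sampling_times=tuple(sampling),
                seed=(seed * 1009 + k) % 2**31,
                perpetrator=perp,
                analytes=analytes,
                train=train,
            )
        )
    return designs


def emulate_training_suite(
    drug: DrugParameters,
    metabolite: DrugParameters | None,
    seed: int,
    n_subjects: int = 1,
    residual_cv: float = 0.20,
    designs: list[StudyDesign] | None = None,
) -> list[SyntheticStudy]:
    """Generate the full 19-study corpus (10 train / 9 test)."""
    import dataclasses

    if designs is None:
        designs = training_suite_designs(seed)
    studies = []
    for d in designs:
        d = dataclasses.replace(d, n_subjects=n_subjects, residual_cv=residual_cv)
        studies.append(generate_study(drug, metabolite, d))
    return studies
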