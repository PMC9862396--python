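"""Pathway apportionment, abundance calibration, fitting, sensitivity."""

import dataclasses

import numpy as np
import pytest

from tegopbpk.calibration import (
    CalibrationError,
    FitSpec,
    SensitivityResult,
    abundance_ratio,
    apportion_fm,
    calibrate_enzyme_abundance,
    fit,
    local_sensitivity,
    _apply_params,
    _get_param,
)
from tegopbpk.drug import MetabolicReaction
from tegopbpk.engine import PBPKModel, mass_balance
from tegopbpk.io import build_regimen
from tegopbpk.physiology import build_reference_individual
from tegopbpk.synthetic import StudyDesign, generate_study


class TestApportionFm:
    def test_symmetric_enzymes_split_equally(self):
        reactions = (
            MetabolicReaction("CYP3A4", "M1", 0.1),
            MetabolicReaction("CYP3A4", "other", 0.1),
        )
        out = apportion_fm({"CYP3A4": 50.0}, reactions)
        assert out["CYP3A4_to_M1"] == out["CYP3A4_to_other"] == 25.0

    def test_infeasible_target_rejected(self):
        with pytest.raises(CalibrationError):
            apportion_fm({"CYP2C19": 20.0}, (MetabolicReaction("CYP3A4", "M1", 0.1),))


class TestAbundanceRatio:
    def test_tabulated_values(self):
        # fm 71.6/20.2 with total CLints 0.2453 and 0.3341
        ratio = abundance_ratio(71.6, 20.2, 0.2453, 0.3341)
        assert ratio == pytest.approx(4.83, abs=0.01)

    def test_symmetry(self):
        assert abundance_ratio(30.0, 30.0, 0.2, 0.2) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            abundance_ratio(0.0, 30.0, 0.2, 0.2)


class TestCalibrateEnzymeAbundance:
    def test_reproduces_its_own_targets(self, tegoprazan, m1):
        ind = build_reference_individual()
        targets = {"CYP3A4": 71.6, "CYP2C19": 20.2, "renal": 7.82}
        abundances, diag = calibrate_enzyme_abundance(tegoprazan, m1, ind, targets)
        assert diag["converged"]
        enzymes = tuple(
            dataclasses.replace(e, reference_concentration=abundances[(e.enzyme, e.organ)])
            for e in ind.enzymes
        )
        model = PBPKModel(tegoprazan, m1, ind.with_enzymes(enzymes),
                          solver_options={"rtol": 1e-6, "atol": 1e-9})
        mb = mass_balance(model.simulate(build_regimen(50), 168.0))
        achieved = mb.enzyme_totals
        total_target = sum(targets.values())
        total_achieved = sum(achieved.values())
        for key, target in targets.items():
            normalized = achieved[key] / total_achieved * total_target
            assert normalized == pytest.approx(target, abs=0.2)

    def test_zero_target_zeroes_abundance(self, tegoprazan, m1):
        ind = build_reference_individual()
        targets = {"CYP3A4": 88.0, "CYP2C19": 0.0, "renal": 7.82}
        abundances, _ = calibrate_enzyme_abundance(
            tegoprazan, m1, ind, targets, max_iter=3, tol_pp=0.5
        )
        assert abundances[("CYP2C19", "liver")] == 0.0
        assert abundances[("CYP3A4", "liver")] > 0.0

    def test_missing_renal_target_rejected(self, tegoprazan, m1):
        with pytest.raises(CalibrationError):
            calibrate_enzyme_abundance(
                tegoprazan, m1, build_reference_individual(), {"CYP3A4": 90.0}
            )

    def test_target_without_clint_rejected(self, m1, tegoprazan):
        bare = dataclasses.replace(tegoprazan, reactions=())
        with pytest.raises(CalibrationError):
            calibrate_enzyme_abundance(
                bare, m1, build_reference_individual(),
                {"CYP3A4": 71.6, "renal": 7.82},
            )


class TestParameterPlumbing:
    def test_get_and_apply_roundtrip(self, tegoprazan, m1):
        for path, value in (
            ("clint.CYP3A4_to_other", 0.5),
            ("dissolution.fasted.t50", 1.5),
            ("fu_plasma", 0.1),
            ("metabolite.total_hepatic_plasma_clearance", 0.2),
        ):
            d, m = _apply_params(tegoprazan, m1, {path: value})
            assert _get_param(d, m, path) == value
        assert _get_param(tegoprazan, m1, "clint.CYP3A4_to_other") == 0.236

    def test_unknown_path_rejected(self, tegoprazan, m1):
        with pytest.raises(CalibrationError):
            _get_param(tegoprazan, m1, "clint.CYP1A2_to_other")


class TestFit:
    def test_single_parameter_noise_free_recovery(self, tegoprazan, m1):
        """A noise-free dataset generated at the bundled values pins a
        perturbed CYP3A4 CLint back to truth within 1%."""
        ind = build_reference_individual()
        study = generate_study(
            tegoprazan, m1,
            StudyDesign(study_id="F1", dose=50, residual_cv=0.0, lloq=0.0, seed=5),
        )
        start, _ = _apply_params(tegoprazan, None, {"clint.CYP3A4_to_other": 0.236 * 1.4})
        spec = FitSpec(parameters=("clint.CYP3A4_to_other",), max_iterations=60, xatol=1e-3)
        result = fit(start, m1, ind, list(study.datasets), spec)
        assert result.estimates["clint.CYP3A4_to_other"] == pytest.approx(0.236, rel=0.01)
        assert result.objective < 1e-4

    def test_determinism(self, tegoprazan, m1):
        ind = build_reference_individual()
        study = generate_study(
            tegoprazan, m1,
            StudyDesign(study_id="F2", dose=50, residual_cv=0.2, lloq=0.5, seed=6),
        )
        start, _ = _apply_params(tegoprazan, None, {"clint.CYP3A4_to_other": 0.3})
        spec = FitSpec(parameters=("clint.CYP3A4_to_other",), max_iterations=40, xatol=1e-3)
        r1 = fit(start, m1, ind, list(study.datasets), spec)
        r2 = fit(start, m1, ind, list(study.datasets), spec)
        assert r1.estimates == r2.estimates
        assert r1.objective == r2.objective

    def test_empty_parameter_list_rejected(self, tegoprazan, m1):
        with pytest.raises(CalibrationError):
            fit(tegoprazan, m1, build_reference_individual(), [], FitSpec(parameters=()))


@pytest.fixture(scope="module")
def ranked_sensitivities(tegoprazan, m1):
    ind = build_reference_individual()
    params = [
        "fu_plasma", "logp", "solubility", "renal_plasma_clearance",
        "clint.CYP3A4_to_other", "clint.CYP2C19_to_other",
        "clint.CYP3A4_to_M1", "dissolution.fasted.t50",
        "metabolite.total_hepatic_plasma_clearance",
    ]
    return local_sensitivity(tegoprazan, m1, ind, params, perturbation=0.1)


class TestLocalSensitivity:
    def test_unconnected_parameter_has_zero_coefficient(self, ranked_sensitivities):
        # the metabolite's own clearance cannot move the parent's AUC
        by_name = {r.parameter: r for r in ranked_sensitivities}
        assert abs(by_name["metabolite.total_hepatic_plasma_clearance"].coefficient) < 0.02

    def test_clearance_parameters_dominate_parent_auc(self, ranked_sensitivities):
        """AUC_inf of the parent is clearance-driven: fraction unbound, the
        two dominant CLints and renal clearance rank ahead of dissolution
        and solubility.  Lipophilicity is structurally inert here: with
        flow-limited distribution and first-order hepatic elimination
        driven by the unbound venous concentration, Kp cancels out of the
        clearance term (see the methods note)."""
        order = [r.parameter for r in ranked_sensitivities]
        top = set(order[:4])
        assert top == {
            "fu_plasma",
            "clint.CYP3A4_to_other",
            "clint.CYP2C19_to_other",
            "renal_plasma_clearance",
        }
        by_name = {r.parameter: r for r in ranked_sensitivities}
        assert abs(by_name["logp"].coefficient) < 0.05
        assert abs(by_name["solubility"].coefficient) < 0.01

    def test_metabolite_auc_driven_by_its_hepatic_clearance(self, tegoprazan, m1):
        ind = build_reference_individual()
        # M1's own elimination is slow (terminal half-life ~3 days), so the
        # AUC_inf needs a long horizon before the tail correction is small
        out = local_sensitivity(
            tegoprazan, m1, ind,
            ["metabolite.total_hepatic_plasma_clearance", "clint.CYP3A4_to_M1"],
            perturbation=0.1, analyte="M1", t_end=500.0,
        )
        by_name = {r.parameter: r for r in out}
        assert by_name["metabolite.total_hepatic_plasma_clearance"].coefficient < -0.8
        assert by_name["clint.CYP3A4_to_M1"].coefficient > 0.1

    def test_one_compartment_clearance_coefficient_is_minus_one(self):
        """In the degenerate one-compartment limit AUC = Dose/CL, so the
        sensitivity of AUC to clearance is exactly -1."""
        from tests.test_engine import _one_compartment_probe

        probe = _one_compartment_probe(clr=3.0)  # t1/2 well inside the horizon
        probe = dataclasses.replace(
            probe,
            specific_intestinal_permeability=1e-4,
            dissolution={"fasted": tegoprazan_diss()},
        )
        ind = build_reference_individual()
        out = local_sensitivity(probe, None, ind, ["renal_plasma_clearance"],
                                perturbation=0.1, analyte="probe")
        assert out[0].coefficient == pytest.approx(-1.0, abs=0.02)

    def test_coefficients_converge_with_perturbation(self, tegoprazan, m1):
        ind = build_reference_individual()
        c10 = local_sensitivity(tegoprazan, m1, ind, ["clint.CYP3A4_to_other"], 0.10)[0]
        c05 = local_sensitivity(tegoprazan, m1, ind, ["clint.CYP3A4_to_other"], 0.05)[0]
        assert c05.coefficient == pytest.approx(c10.coefficient, rel=0.10)

    def test_invalid_perturbation_rejected(self, tegoprazan, m1):
        with pytest.raises(CalibrationError):
            local_sensitivity(tegoprazan, m1, build_reference_individual(), ["fu_plasma"], 0.9)


def tegoprazan_diss():
    from tegopbpk.drug import DissolutionSpec

    return DissolutionSpec(t50=0.942, shape=0.990, state="fasted")
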