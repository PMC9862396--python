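"""ODE engine: rate arithmetic, conservation, linearity, closed forms."""

import dataclasses
import math

import numpy as np
import pytest

from tegopbpk.drug import DrugParameters
from tegopbpk.engine import (
    PATHWAYS,
    EngineError,
    PBPKModel,
    m1_hepatic_elimination_rate,
    mass_balance,
    metabolic_clearance_rate,
    renal_elimination_rate,
    simulate,
)
from tegopbpk.io import build_regimen
from tegopbpk.absorption import DoseEvent


class TestRateArithmetic:
    def test_zero_concentration_zero_rate(self):
        assert metabolic_clearance_rate(100.0, 0.236, 0.0) == 0.0
        assert renal_elimination_rate(0.297, 73.5, 0.0) == 0.0
        assert m1_hepatic_elimination_rate(0.140, 50.0, 0.0) == 0.0

    def test_intrinsic_clearance_unit_conversion(self):
        # 100 pmol x 0.236 µL/min/pmol = 23.6 µL/min = 1.416e-3 L/h
        assert metabolic_clearance_rate(100.0, 0.236, 1.0) == pytest.approx(1.416e-3)

    def test_first_order_in_enzyme_level(self):
        r1 = metabolic_clearance_rate(100.0, 0.0921, 2.5)
        assert metabolic_clearance_rate(200.0, 0.0921, 2.5) == pytest.approx(2 * r1)

    def test_renal_clearance_reconciles_printed_value(self):
        # 0.297 mL/min/kg at 73.5 kg is the printed 1.31 L/h
        assert 0.297 * 73.5 * 0.06 == pytest.approx(1.31, abs=0.005)
        # at 50 kg the per-kg value would give 0.891 L/h
        assert 0.297 * 50.0 * 0.06 == pytest.approx(0.891)
        assert renal_elimination_rate(0.297, 73.5, 2.0) == pytest.approx(1.3097 * 2.0 * 1000, rel=1e-3)

    def test_m1_hepatic_clearance_value(self):
        assert 0.140 * 50.0 * 0.06 == pytest.approx(0.42)
        r = m1_hepatic_elimination_rate(0.140, 50.0, 10.0)
        assert m1_hepatic_elimination_rate(0.140, 50.0, 5.0) == pytest.approx(r / 2)

    def test_negative_inputs_rejected(self):
        with pytest.raises(EngineError):
            metabolic_clearance_rate(-1.0, 0.2, 1.0)


class TestSimulateBasics:
    def test_zero_dose_gives_zero_concentrations(self, tegoprazan, m1, reference_individual, fit_solver):
        res = simulate(tegoprazan, m1, reference_individual,
                       [DoseEvent(time=0.0, amount=0.0)], 24.0, solver_options=fit_solver)
        assert np.all(res.conc["tegoprazan"] == 0.0)
        assert np.all(res.conc["M1"] == 0.0)

    def test_t_end_before_last_dose_rejected(self, tegoprazan, m1, reference_individual):
        with pytest.raises(EngineError):
            simulate(tegoprazan, m1, reference_individual, build_regimen(50, 3, 24.0), 24.0)

    def test_metabolite_appears_after_parent(self, single_dose_result):
        teg = single_dose_result.conc["tegoprazan"]
        m1c = single_dose_result.conc["M1"]
        assert m1c.max() > 0
        t = single_dose_result.time
        assert t[m1c.argmax()] > t[teg.argmax()]


class TestConservationAndLinearity:
    def test_mass_conserved_at_all_times(self, single_dose_result):
        res = single_dose_result
        dose = res.diagnostics["dose_umol"]
        eliminated = sum(
            res.cumulative[p] for p in PATHWAYS if p not in ("m1_hepatic", "absorbed")
        )
        total = res.body_amount["tegoprazan"] + res.lumen_amount + eliminated
        assert np.max(np.abs(total - dose)) <= 1e-3 * dose

    def test_metabolite_mass_closes(self, single_dose_result):
        res = single_dose_result
        formed = (
            res.cumulative["liver_cyp3a4_m1"]
            + res.cumulative["liver_cyp2c19_m1"]
            + res.cumulative["gut_cyp3a4_m1"]
        )
        held = res.body_amount["M1"] + res.cumulative["m1_hepatic"]
        assert np.allclose(held, formed, atol=1e-3 * res.diagnostics["dose_umol"])

    def test_dose_linearity(self, tegoprazan, m1, reference_individual, fit_solver):
        aucs, cmaxes = [], []
        for dose in (50.0, 400.0):
            res = simulate(tegoprazan, m1, reference_individual, build_regimen(dose), 96.0,
                           solver_options=fit_solver)
            aucs.append(np.trapezoid(res.conc["tegoprazan"], res.time))
            cmaxes.append(res.conc["tegoprazan"].max())
        assert aucs[1] / aucs[0] == pytest.approx(8.0, rel=0.005)
        assert cmaxes[1] / cmaxes[0] == pytest.approx(8.0, rel=0.005)

    def test_superposition_of_shifted_single_doses(self, tegoprazan, m1, reference_individual, fit_solver):
        grid = np.arange(0.0, 96.0 + 0.25, 0.25)
        single = simulate(tegoprazan, m1, reference_individual, build_regimen(50), 96.0,
                          solver_options=fit_solver, t_eval=grid)
        multi = simulate(tegoprazan, m1, reference_individual, build_regimen(50, 3, 24.0), 96.0,
                         solver_options=fit_solver, t_eval=grid)
        c1 = single.conc["tegoprazan"]
        expected = np.zeros_like(grid)
        for shift in (0.0, 24.0, 48.0):
            shifted = np.interp(grid - shift, grid, c1, left=0.0)
            expected += shifted
        got = multi.conc["tegoprazan"]
        scale = expected.max()
        mask = grid > 1.0
        assert np.max(np.abs(got[mask] - expected[mask])) <= 0.005 * scale

    def test_steady_state_interval_auc_matches_single_dose_auc_inf(
        self, tegoprazan, m1, reference_individual, fit_solver, single_dose_result
    ):
        res = simulate(tegoprazan, m1, reference_individual, build_regimen(50, 6, 24.0), 144.0,
                       solver_options=fit_solver)
        t, c = res.time, res.conc["tegoprazan"]
        mask = (t >= 120.0) & (t <= 144.0)
        auc_ss = np.trapezoid(c[mask], t[mask])
        ts, cs = single_dose_result.time, single_dose_result.conc["tegoprazan"]
        auc_inf = np.trapezoid(cs, ts)
        assert auc_ss == pytest.approx(auc_inf, rel=0.01)


class TestMassBalance:
    def test_within_enzyme_split_equals_clint_ratio(self, single_dose_result):
        mb = mass_balance(single_dose_result)
        f = mb.fractions
        assert f["CYP3A4_to_M1"] / f["CYP3A4_to_other"] == pytest.approx(9.29e-3 / 0.236, rel=1e-6)
        assert f["CYP2C19_to_M1"] / f["CYP2C19_to_other"] == pytest.approx(0.0921 / 0.242, rel=1e-6)

    def test_printed_ratio_identity(self):
        # the tabulated CLint ratios reproduce the printed fraction ratios
        assert 9.29e-3 / 0.236 == pytest.approx(2.71 / 68.9, rel=0.005)
        assert 0.0921 / 0.242 == pytest.approx(5.57 / 14.6, rel=0.005)

    def test_fractions_close(self, single_dose_result):
        mb = mass_balance(single_dose_result)
        total = (
            sum(mb.fractions[k] for k in ("CYP3A4_to_M1", "CYP3A4_to_other",
                                          "CYP2C19_to_M1", "CYP2C19_to_other", "renal"))
            + mb.fecal_percent
            + mb.remaining_percent
        )
        assert total == pytest.approx(100.0, abs=0.1)
        assert not mb.incomplete


def _one_compartment_probe(clr: float) -> DrugParameters:
    organs = ("adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
              "muscle", "skin", "spleen", "rest", "lung")
    return DrugParameters(
        name="probe",
        molecular_weight=300.0,
        logp=0.0,
        fu_plasma=1.0,
        solubility=100.0,
        renal_plasma_clearance=clr,
        blood_to_plasma_ratio=1.0,
        kp_overrides={o: 1.0 for o in organs},
    )


def _high_perfusion(individual, factor: float = 50.0):
    """Scale all regional flows up so perfusion no longer rate-limits.

    In the true one-compartment limit flows are infinite relative to
    clearance; physiological flows leave an O(CL*V_i/(V*Q_i)) venous lag
    of ~1% during first-order decay."""
    organs = tuple(
        o if o.name in ("venous_blood", "arterial_blood")
        else dataclasses.replace(o, blood_flow=o.blood_flow * factor)
        for o in individual.organs
    )
    return dataclasses.replace(
        individual, organs=organs, cardiac_output=individual.cardiac_output * factor
    )


class TestClosedFormLimit:
    def test_iv_bolus_renal_only_matches_one_compartment(self, reference_individual):
        """With unit partitioning everywhere the body collapses to one
        well-mixed volume; an IV bolus with renal-only clearance must decay
        as (D/V) e^(-CL t / V)."""
        ind = _high_perfusion(reference_individual)
        probe = _one_compartment_probe(clr=0.297)
        res = simulate(probe, None, ind,
                       [DoseEvent(time=0.0, amount=50.0, route="iv")], 48.0)
        v_total = ind.total_volume
        cl = 0.297 * ind.weight * 0.06
        dose_ng = 50.0 * 1e6
        t = res.time
        expected = dose_ng / (v_total * 1000.0) * np.exp(-cl * t / v_total)
        mask = t >= 1.0  # after the circulatory mixing transient
        rel_err = np.abs(res.conc["probe"][mask] - expected[mask]) / expected[mask]
        assert np.max(rel_err) <= 1e-3
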