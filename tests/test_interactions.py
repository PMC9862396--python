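"""Enzyme-turnover DDI engine: turnover kinetics, folds, knockout identity."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tegopbpk.absorption import DoseEvent
from tegopbpk.drug import DrugModelError, PerpetratorSpec
from tegopbpk.engine import PBPKModel, mass_balance
from tegopbpk.interactions import (
    DDIScenario,
    InteractionError,
    fold_change,
    perpetrator_concentration,
    rate_modifiers,
    simulate_ddi,
    steady_state_enzyme_fraction,
    turnover_rhs,
)
from tegopbpk.io import build_regimen, load_perpetrator
from tegopbpk.physiology import EnzymeExpression, build_reference_individual

MBI = PerpetratorSpec(name="inhibitor", mechanism="mbi", ki=5.49, kinact=2.52)
INDUCER = PerpetratorSpec(name="inducer", mechanism="induction", emax=9.0, ec50=0.34)


def _forcing(conc: float) -> PerpetratorSpec:
    """A perpetrator held at a constant unbound concentration."""
    return dataclasses.replace(
        MBI, own_kinetics={"time_h": [0.0, 1e4], "conc_umol_L": [conc, conc]}
    )


class TestTurnoverRHS:
    def test_baseline_is_steady(self):
        assert turnover_rhs(4.0, 0.08, 0.02, 0.0, None) == pytest.approx(0.0)
        assert turnover_rhs(4.0, 0.08, 0.02, 0.0, MBI) == pytest.approx(0.0)

    def test_induction_half_maximal(self):
        # at I = EC50 the synthesis term is Rsyn * (1 + Emax/2)
        de = turnover_rhs(4.0, 0.08, 0.02, INDUCER.ec50, INDUCER)
        assert de == pytest.approx(0.08 * (1 + 9.0 / 2) - 0.02 * 4.0)

    def test_mbi_half_maximal(self):
        # at I = KI the added loss rate is kinact/2 * E
        de = turnover_rhs(4.0, 0.08, 0.02, MBI.ki, MBI)
        assert de == pytest.approx(0.08 - (0.02 + 2.52 / 2) * 4.0)

    def test_missing_mechanism_fields_rejected(self):
        with pytest.raises(DrugModelError):
            PerpetratorSpec(name="broken", mechanism="mbi", ki=None, kinact=1.0)

    def test_negative_enzyme_rejected(self):
        with pytest.raises(InteractionError):
            turnover_rhs(-1.0, 0.08, 0.02, 0.0, MBI)


class TestTurnoverIntegration:
    @pytest.mark.parametrize("spec,conc", [(MBI, 2.0), (INDUCER, 1.0)], ids=["mbi", "induction"])
    def test_integration_reaches_analytic_steady_state(self, spec, conc):
        kdeg, e0 = 0.019, 4.0
        rsyn = e0 * kdeg
        sol = solve_ivp(
            lambda t, e: turnover_rhs(e[0], rsyn, kdeg, conc, spec),
            (0.0, 20.0 / kdeg),
            [e0],
            rtol=1e-10,
        )
        expected = e0 * steady_state_enzyme_fraction(spec, conc, kdeg)
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-4)

    def test_enzyme_never_negative_and_induction_bounded(self):
        kdeg, e0 = 0.019, 4.0
        rsyn = e0 * kdeg
        for spec, conc in ((MBI, 100.0), (INDUCER, 1000.0)):
            sol = solve_ivp(
                lambda t, e: turnover_rhs(max(e[0], 0.0), rsyn, kdeg, conc, spec),
                (0.0, 1000.0),
                [e0],
                rtol=1e-8,
            )
            assert np.all(sol.y[0] >= -1e-9)
            assert np.all(sol.y[0] <= e0 * (1 + INDUCER.emax) * (1 + 1e-9))

    def test_washout_returns_to_baseline(self, tegoprazan, m1, fit_solver):
        """Enzyme pools inactivated during a 24 h exposure recover to
        baseline after a washout of >= 10/kdeg."""
        ind = build_reference_individual()
        spec = dataclasses.replace(
            MBI, own_kinetics={"time_h": [0.0, 24.0, 24.001, 1000.0],
                               "conc_umol_L": [3.0, 3.0, 0.0, 0.0]}
        )
        modifiers = rate_modifiers(spec, perpetrator_concentration(spec, []))
        model = PBPKModel(tegoprazan, m1, ind, solver_options=fit_solver,
                          perpetrator_rate_modifiers=modifiers)
        horizon = 24.0 + 10.0 / 0.019
        res = model.simulate([DoseEvent(time=horizon - 24.0, amount=50.0)], horizon)
        for (enzyme, organ), levels in res.enzyme_levels.items():
            e0 = next(e.reference_concentration for e in ind.enzymes
                      if (e.enzyme, e.organ) == (enzyme, organ))
            if enzyme == "CYP3A4":
                assert levels.min() < 0.5 * e0  # was substantially inactivated
            assert levels[-1] == pytest.approx(e0, rel=0.01)


class TestPerpetratorKinetics:
    def test_one_compartment_superposition(self):
        clar = load_perpetrator("clarithromycin")
        doses = [DoseEvent(time=8.0 * k, amount=500.0) for k in range(6)]
        conc = perpetrator_concentration(clar, doses)
        assert conc(0.0) == 0.0
        assert conc(10.0) > 0.0
        # superposition: two doses give the sum of two shifted single doses
        one = perpetrator_concentration(clar, [DoseEvent(time=0.0, amount=500.0)])
        assert conc(10.0) == pytest.approx(one(10.0) + one(2.0), rel=1e-9)

    def test_forcing_table_interpolation(self):
        spec = _forcing(2.0)
        conc = perpetrator_concentration(spec, [])
        assert conc(5.0) == 2.0


class TestFoldChange:
    def test_identical_arms(self):
        assert fold_change(100.0, 100.0, "increase") == 1.0

    def test_printed_clarithromycin_fold(self):
        assert fold_change(2994.4, 11312.0, "increase") == pytest.approx(3.78, abs=0.005)

    def test_printed_rifampicin_fold(self):
        assert fold_change(2994.4, 568.8, "decrease") == pytest.approx(5.26, abs=0.005)

    def test_zero_denominator_rejected(self):
        with pytest.raises(InteractionError):
            fold_change(0.0, 1.0)


class TestSimulateDDI:
    def test_null_perpetrator_folds_are_unity(self, tegoprazan, m1, fit_solver):
        ind = build_reference_individual()
        scenario = DDIScenario(
            victim_regimen=tuple(build_regimen(50, 3, 24.0)),
            perpetrator=None,
            pretreatment_h=24.0,
        )
        res = simulate_ddi(scenario, tegoprazan, m1, [ind], solver_options=fit_solver)
        for fold in (res.fold_auc_first, res.fold_auc_ss, res.fold_cmax_first, res.fold_cmax_ss):
            assert fold == pytest.approx(1.0, rel=0.005)

    def test_null_mechanism_parameters_fold_unity(self, tegoprazan, m1, fit_solver):
        # kinact = 0 leaves the enzymes untouched even at high exposure
        ind = build_reference_individual()
        null_mbi = PerpetratorSpec(
            name="inert", mechanism="mbi", ki=5.49, kinact=0.0,
            own_kinetics={"time_h": [0.0, 1e4], "conc_umol_L": [50.0, 50.0]},
        )
        scenario = DDIScenario(
            victim_regimen=tuple(build_regimen(50, 2, 24.0)),
            perpetrator=null_mbi,
            pretreatment_h=24.0,
        )
        res = simulate_ddi(scenario, tegoprazan, m1, [ind], solver_options=fit_solver)
        assert res.fold_auc_ss == pytest.approx(1.0, rel=0.005)

    def test_alone_arm_matches_standalone_run(self, tegoprazan, m1, fit_solver):
        ind = build_reference_individual()
        scenario = DDIScenario(
            victim_regimen=tuple(build_regimen(50, 2, 24.0)),
            perpetrator=_forcing(2.0),
            perpetrator_regimen=(DoseEvent(time=0.0, amount=500.0),),
            pretreatment_h=24.0,
        )
        res = simulate_ddi(scenario, tegoprazan, m1, [ind], solver_options=fit_solver)
        # standalone run on the same absolute clock
        model = PBPKModel(tegoprazan, m1, ind, solver_options=fit_solver)
        events = [DoseEvent(time=24.0, amount=50.0), DoseEvent(time=48.0, amount=50.0)]
        alone = model.simulate(events, 96.0)
        from tegopbpk.evaluation import compute_pk_parameters

        mask = alone.time >= 24.0
        pk = compute_pk_parameters(alone.time[mask] - 24.0, alone.conc["tegoprazan"][mask], 24.0, 2)
        assert res.alone.auc_first[0] == pytest.approx(pk.auc_first, rel=1e-9)
        assert res.alone.cmax_ss[0] == pytest.approx(pk.cmax_ss, rel=1e-9)

    def test_empty_victim_regimen_rejected(self):
        with pytest.raises(InteractionError):
            DDIScenario(victim_regimen=(), perpetrator=None)
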