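"""Recirculating leukapheresis simulator and the in-vivo efficiency
estimators."""

import numpy as np
import pytest

import cifsim as cs


def _simple_subject(conc=1.0e4, volume_ml=26.0, name="WBC", influx=None):
    pops = (cs.CellPopulation(name, conc, 8.0, 0.0),)
    base = cs.BloodSample(pops, volume=1000.0, species="rat")
    return cs.Subject(
        weight_kg=volume_ml / 70.0,
        baseline=base,
        etbv_ml=volume_ml,
        influx_per_min=influx or {},
    )


def _two_type_subject(volume_ml=26.0):
    pops = (
        cs.CellPopulation("RBC", 7.0e6, 5.0, 0.0),
        cs.CellPopulation("WBC", 1.0e4, 8.0, 0.0),
    )
    base = cs.BloodSample(pops, volume=1000.0, species="rat")
    return cs.Subject(weight_kg=volume_ml / 70.0, baseline=base, etbv_ml=volume_ml)


class TestDynamics:
    def test_zero_ce_no_events_is_constant(self):
        subj = _simple_subject()
        proto = cs.RecirculationProtocol(
            duration_min=60.0, circuit_flow_ml_min=0.4, retentate_fraction=0.0
        )
        run = cs.simulate_recirculation(subj, {"WBC": 0.0}, proto)
        conc = run.concentrations["conc_per_ul"].to_numpy()
        assert np.allclose(conc, conc[0], rtol=1e-9)

    def test_matches_exponential_closed_form(self):
        # V = 26 mL, Q = 0.45 mL/min, CE = 60%, 180 min, no volume change:
        # C(T)/C0 = exp(-0.6 · Q·T/V)
        subj = _simple_subject(volume_ml=26.0)
        proto = cs.RecirculationProtocol(
            duration_min=180.0, circuit_flow_ml_min=0.45, retentate_fraction=0.0
        )
        run = cs.simulate_recirculation(subj, {"WBC": 60.0}, proto)
        assert run.etbv_processed == pytest.approx(0.45 * 180 / 26.0)
        expected = np.exp(-0.6 * run.etbv_processed)
        got = run.c_post["WBC"] / run.c_pre["WBC"]
        assert abs(got - expected) / expected < 1e-6

    def test_influx_balancing_removal_gives_steady_state(self):
        q, ce_frac, c0 = 0.4, 0.5, 1.0e4
        influx = q * ce_frac * c0  # cells/min entering = removal rate at C0
        subj = _simple_subject(conc=c0, influx={"WBC": influx})
        proto = cs.RecirculationProtocol(
            duration_min=120.0, circuit_flow_ml_min=q, retentate_fraction=0.0
        )
        run = cs.simulate_recirculation(subj, {"WBC": 100.0 * ce_frac}, proto)
        assert run.c_post["WBC"] == pytest.approx(c0, rel=1e-8)

    def test_cell_ledger_balances(self):
        subj = _two_type_subject()
        proto = cs.RecirculationProtocol(
            duration_min=180.0,
            circuit_flow_ml_min=0.427,
            retentate_fraction=0.05,
            sample_times_min=tuple(range(15, 181, 15)),
            sample_volume_ml=0.3,
            circuit_ecv_ml=0.736,
            fluid_events=((90.0, 1.0),),
        )
        run = cs.simulate_recirculation(subj, {"RBC": 8.0, "WBC": 85.0}, proto)
        assert max(run.cell_balance_error().values()) < 1e-6

    def test_volume_ledger(self):
        subj = _two_type_subject()
        proto = cs.RecirculationProtocol(
            duration_min=60.0,
            circuit_flow_ml_min=0.4,
            retentate_fraction=0.05,
            sample_times_min=(30.0,),
            sample_volume_ml=0.3,
        )
        run = cs.simulate_recirculation(subj, {"RBC": 5.0, "WBC": 90.0}, proto)
        # removed: one 0.3 mL draw + continuous retentate; given: replacement
        assert run.fluid_removed_ml == pytest.approx(0.3 + 0.05 * 0.4 * 60.0)
        assert run.fluid_given_ml == pytest.approx(0.3)
        assert run.v_proc_ml == pytest.approx(0.4 * 1.05 * 60.0)

    def test_sampling_would_empty_pool_aborts(self):
        subj = _simple_subject(volume_ml=2.0)
        proto = cs.RecirculationProtocol(
            duration_min=60.0,
            circuit_flow_ml_min=0.1,
            retentate_fraction=0.0,
            sample_times_min=(10.0,),
            sample_volume_ml=5.0,
            replace_sample_volume=False,
        )
        with pytest.raises(cs.SimulationAbort):
            cs.simulate_recirculation(subj, {"WBC": 0.0}, proto)

    def test_withdrawal_exhausting_volume_aborts(self):
        subj = _simple_subject(volume_ml=3.0)
        proto = cs.RecirculationProtocol(
            duration_min=180.0, circuit_flow_ml_min=2.0, retentate_fraction=0.4
        )
        with pytest.raises(cs.SimulationAbort):
            cs.simulate_recirculation(subj, {"WBC": 50.0}, proto)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            cs.RecirculationProtocol(retentate_fraction=0.6)
        with pytest.raises(ValueError):
            cs.RecirculationProtocol(sample_times_min=(200.0,), duration_min=180.0)
        with pytest.raises(ValueError):
            cs.RecirculationProtocol(duration_min=-5.0)


class TestEstimators:
    def test_cr_timepoint_arithmetic(self):
        assert cs.cr_timepoint(40.0, 2.0) == 20.0
        assert cs.cr_timepoint(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            cs.cr_timepoint(10.0, 0.0)

    def test_cr_full_capture_approaches_one_plus_fr(self):
        # with CE = 100% every processed cell lands in the retentate, whose
        # concentration is (1 + FR) times the contemporaneous blood
        subj = _simple_subject(volume_ml=200.0)
        proto = cs.RecirculationProtocol(
            duration_min=60.0, circuit_flow_ml_min=0.42, retentate_fraction=0.05
        )
        run = cs.simulate_recirculation(subj, {"WBC": 100.0}, proto)
        cr = cs.cr_timepoint_mean(run, "WBC", denominator="circulating")
        assert cr == pytest.approx(21.0, rel=2e-2)

    def test_cr_filtrate_denominator(self):
        subj = _simple_subject(volume_ml=200.0)
        proto = cs.RecirculationProtocol(
            duration_min=60.0, circuit_flow_ml_min=0.42, retentate_fraction=0.05
        )
        run = cs.simulate_recirculation(subj, {"WBC": 50.0}, proto)
        # mass balance: C_ret/C_fil = (CE/(1-CE)) · FR at fixed concentrations
        cr = cs.cr_timepoint_mean(run, "WBC", denominator="filtrate")
        assert cr == pytest.approx(0.5 / 0.5 * 20.0, rel=2e-2)

    def test_ce_invivo_hand_arithmetic(self):
        import pandas as pd

        run = cs.RecirculationRun(
            types=("WBC",),
            times_min=np.array([0.0, 60.0]),
            concentrations=pd.DataFrame(
                {
                    "time_min": [0.0, 60.0],
                    "type": ["WBC", "WBC"],
                    "conc_per_ul": [10.0, 6.0],
                    "volume_ml": [50.0, 50.0],
                }
            ),
            volume_ml=np.array([50.0, 50.0]),
            retentate_aliquots=pd.DataFrame(
                {
                    "epoch_start_min": [0.0, 30.0],
                    "epoch_end_min": [30.0, 60.0],
                    "type": ["WBC", "WBC"],
                    "c_ret_per_ul": [40.0, 40.0],
                    "v_ret_ml": [0.5, 0.5],
                }
            ),
            filtrate_mean_conc={"WBC": 8.0},
            c_pre={"WBC": 10.0},
            c_post={"WBC": 6.0},
            v_proc_ml=50.0,
            etbv_ml=26.0,
            device_ce={"WBC": 10.0},
            fluid_removed_ml=1.0,
            fluid_given_ml=1.0,
            cells_removed_retentate={"WBC": 40.0},
            cells_removed_sampling={"WBC": 0.0},
            cells_influx={"WBC": 0.0},
            cells_start={"WBC": 500.0},
            cells_end={"WBC": 300.0},
        )
        # (40·0.5·2) / ((10+6)/2 · 50) = 0.10
        assert cs.ce_invivo(run, "WBC") == pytest.approx(0.10)

    def test_ce_invivo_recovers_injected_ce(self):
        # modest processed volume keeps the pre/post trapezoid close to the
        # flow-weighted mean concentration
        subj = _two_type_subject(volume_ml=26.0)
        proto = cs.RecirculationProtocol(
            duration_min=30.0,
            circuit_flow_ml_min=0.427,
            retentate_fraction=0.05,
            retentate_epoch_min=5.0,
        )
        injected = {"RBC": 8.0, "WBC": 85.0}
        run = cs.simulate_recirculation(subj, injected, proto)
        for k, ce_true in injected.items():
            est = 100.0 * cs.ce_invivo(run, k)
            assert abs(est - ce_true) / ce_true < 0.05

    def test_wbc_rbc_ratio_below_one_iff_wbc_ce_larger(self):
        subj = _two_type_subject()
        proto = cs.RecirculationProtocol(
            duration_min=180.0,
            circuit_flow_ml_min=0.427,
            retentate_fraction=0.05,
            sample_times_min=tuple(range(15, 181, 15)),
            sample_volume_ml=0.3,
        )
        selective = cs.simulate_recirculation(subj, {"RBC": 8.0, "WBC": 85.0}, proto)
        assert cs.final_percent_and_ratios(selective)["ratios"]["WBC:RBC"] < 1.0
        inverted = cs.simulate_recirculation(subj, {"RBC": 85.0, "WBC": 8.0}, proto)
        assert cs.final_percent_and_ratios(inverted)["ratios"]["WBC:RBC"] > 1.0
        equal = cs.simulate_recirculation(subj, {"RBC": 40.0, "WBC": 40.0}, proto)
        assert cs.final_percent_and_ratios(equal)["ratios"]["WBC:RBC"] == pytest.approx(
            1.0, rel=1e-9
        )

    def test_final_percent_no_removal(self):
        subj = _two_type_subject()
        proto = cs.RecirculationProtocol(
            duration_min=60.0, circuit_flow_ml_min=0.4, retentate_fraction=0.0
        )
        run = cs.simulate_recirculation(subj, {"RBC": 0.0, "WBC": 0.0}, proto)
        fin = cs.final_percent_and_ratios(run)
        assert all(v == pytest.approx(100.0) for v in fin["final_percent"].values())
        assert fin["ratios"]["WBC:RBC"] == pytest.approx(1.0)


class TestShamContrast:
    def test_sham_sampling_dilutes_all_types_equally(self):
        """CE = 0 with serial replaced draws: RBC declines monotonically and
        the WBC:RBC loss ratio stays at 1 (no selective removal)."""
        tpl = cs.make_protocol_templates()["rat_sham"]
        base = cs.rat_blood(seed=4)
        subj = cs.Subject(weight_kg=tpl.subject_weight_kg, baseline=base)
        ce = {k: 0.0 for k in base.names}
        run = cs.simulate_recirculation(subj, ce, tpl.protocol)
        rbc = run.concentrations.query("type == 'RBC'")["conc_per_ul"].to_numpy()
        assert np.all(np.diff(rbc) <= 1e-9 * rbc[0])
        assert rbc[-1] < rbc[0]
        ratios = cs.final_percent_and_ratios(run)["ratios"]
        assert ratios["WBC:RBC"] >= 1.0 - 1e-9

    def test_demargination_influx_raises_ratio_above_one(self):
        tpl = cs.make_protocol_templates()["rat_sham"]
        base = cs.rat_blood(seed=4)
        pmn0 = base["PMN"].concentration
        subj = cs.Subject(
            weight_kg=tpl.subject_weight_kg,
            baseline=base,
            influx_per_min={"PMN": 0.02 * pmn0 * 18.7},  # slow marginated-pool release
        )
        ce = {k: 0.0 for k in base.names}
        run = cs.simulate_recirculation(subj, ce, tpl.protocol)
        assert run.c_post["PMN"] > pmn0 * 0.9
        assert cs.final_percent_and_ratios(run)["ratios"]["WBC:RBC"] > 1.0
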