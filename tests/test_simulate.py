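"""Integration behaviour: closed forms, conservation, the four assay
conditions, dose sweeps and summary statistics."""

import dataclasses

import numpy as np
import pytest

from glygln.simulate import (
    CONDITIONS,
    Scenario,
    dose_sweep,
    plateau_onset,
    run_assay_conditions,
    scenario_for_condition,
    simulate,
    simulate_fixed_step,
    summarize,
)

from conftest import make_constants


class TestClosedForms:
    def test_pure_glucose_uptake_is_exponential_decay(self):
        # Only uptake active: Glc_ex' = -kf_Glc * Capacity_Glc * Glc_ex.
        scen = Scenario(glc_ex=7500.0, horizon=120.0, n_samples=121,
                        sample_interval=1.0)
        k = make_constants(kf_Glc=1e-4)
        traj = simulate(scen, k)
        expected = 7500.0 * np.exp(-0.02 * traj.time)
        assert traj.series("Glc_ex") == pytest.approx(expected, rel=1e-6)
        assert traj.final("Glc_ex") == pytest.approx(680.4276, rel=1e-4)

    def test_glutamine_cascade_matches_two_compartment_solution(self):
        # Gln_ex -> Gln -> TCA with rates 0.01 and 0.05 per minute.
        scen = Scenario(glc_ex=0.0, gln_ex=2000.0, horizon=120.0,
                        n_samples=121, sample_interval=1.0)
        k = make_constants(kf_Gln=1e-4, kf_7=0.05)
        traj = simulate(scen, k)
        lam, mu = 0.01, 0.05
        expected = lam * 2000.0 / (mu - lam) * (
            np.exp(-lam * traj.time) - np.exp(-mu * traj.time)
        )
        assert traj.series("Gln") == pytest.approx(expected, rel=1e-6, abs=1e-8)
        assert traj.series("Gln")[60] == pytest.approx(249.5, abs=0.05)

    def test_empty_medium_stays_identically_zero(self, ref_k):
        traj = simulate(Scenario(glc_ex=0.0, gln_ex=0.0), ref_k)
        assert np.all(traj.species == 0.0)


class TestConservationAndGrid:
    @pytest.mark.parametrize("condition", sorted(CONDITIONS))
    def test_total_pool_is_conserved(self, ref_trajectories, condition):
        traj = ref_trajectories[condition]
        pool = traj.total_pool()
        assert pool[-1] > 0
        rtol = traj.diagnostics["rtol"]
        assert np.abs(pool - pool[0]).max() <= 10 * rtol * pool[0]

    def test_first_sample_equals_initial_state(self, ref_trajectories):
        traj = ref_trajectories["glucose_glutamine"]
        initial = traj.scenario.initial_state().species_vector()
        assert traj.species[:, 0] == pytest.approx(initial, abs=1e-12)
        assert np.all(np.diff(traj.time) > 0)

    def test_default_grid_matches_plate_protocol(self):
        grid = Scenario().grid()
        assert grid.size == 350
        assert np.allclose(np.diff(grid), 0.34)
        assert grid[0] == 0.0

    def test_adaptive_solution_matches_fixed_step_oracle(self, ref_k):
        scen = scenario_for_condition("glucose_glutamine")
        adaptive = simulate(scen, ref_k)
        oracle = simulate_fixed_step(scen, ref_k, step=1e-3)
        scale = np.abs(oracle.species).max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        assert np.abs(adaptive.species - oracle.species).max() <= 1e-5 * scale.max()
        assert (np.abs(adaptive.species - oracle.species) / scale).max() <= 1e-5


class TestAssayConditions:
    def test_four_conditions_with_printed_nutrients_and_doses(self, ref_trajectories):
        assert set(ref_trajectories) == set(CONDITIONS)
        scen = ref_trajectories["plus_oligomycin"].scenario
        assert (scen.glc_ex, scen.gln_ex, scen.dose_oligomycin) == (7500.0, 2000.0, 8.7)
        scen = ref_trajectories["plus_2DG"].scenario
        assert scen.dose_2DG == 9.9

    def test_glucose_only_has_no_glutaminolysis_flux(self, ref_trajectories):
        traj = ref_trajectories["glucose_only"]
        assert np.all(traj.fluxes[7] == 0.0)  # v8
        assert np.all(traj.fluxes[8] == 0.0)  # v9

    def test_glucose_only_etc_and_cellcomponents_are_proportional(
        self, ref_trajectories, ref_k
    ):
        # With Gln = 0 and no oligomycin, v6/v7 = kf_5/kf_6 at all times, so
        # kf_6 * ETC(t) = kf_5 * CellComponents(t) along the trajectory.
        traj = ref_trajectories["glucose_only"]
        lhs = ref_k.kf_6 * traj.series("ETC")
        rhs = ref_k.kf_5 * traj.series("CellComponents")
        scale = rhs.max()
        assert np.abs(lhs - rhs).max() <= 1e-6 * scale

    def test_glutamine_roughly_halves_final_lactate(self, ref_trajectories):
        ratio = (ref_trajectories["glucose_glutamine"].final("Lac_ex")
                 / ref_trajectories["glucose_only"].final("Lac_ex"))
        assert 0.40 <= ratio <= 0.60

    def test_glutamine_shifts_output_to_oxidative_pathway(self, ref_trajectories):
        traj = ref_trajectories["glucose_glutamine"]
        assert traj.final("ETC") > traj.final("Lac_ex")

    def test_modulator_directions_on_final_lactate(self, ref_trajectories):
        base = ref_trajectories["glucose_glutamine"].final("Lac_ex")
        assert ref_trajectories["plus_oligomycin"].final("Lac_ex") > base
        assert ref_trajectories["plus_2DG"].final("Lac_ex") < base

    def test_2dg_lactate_drops_early_then_rises_late(self, ref_trajectories):
        traj = ref_trajectories["plus_2DG"]
        lac = traj.series("Lac_ex")
        no_dose_final = ref_trajectories["glucose_glutamine"].final("Lac_ex")
        at_60 = lac[traj.time <= 60.0][-1]
        assert at_60 < 0.2 * no_dose_final
        late = traj.time >= 60.0
        slope = np.polyfit(traj.time[late], lac[late], 1)[0]
        assert slope > 0

    def test_2dg_accumulates_intracellular_glucose(self, ref_trajectories):
        blocked = ref_trajectories["plus_2DG"].series("Glc").max()
        unblocked = ref_trajectories["glucose_glutamine"].series("Glc").max()
        assert blocked > unblocked


class TestSweeps:
    def test_final_lactate_increases_with_glucose(self, ref_k):
        table = dose_sweep(scenario_for_condition("glucose_only"), ref_k, "Glc_ex")
        assert np.all(np.diff(table["final_Lac_ex"]) > 0)
        assert table["Glc_ex"].iloc[0] == 2000.0
        assert table["Glc_ex"].iloc[-1] == 20000.0

    def test_final_lactate_insensitive_to_glutamine(self, ref_k):
        table = dose_sweep(
            scenario_for_condition("glucose_glutamine"), ref_k, "Gln_ex"
        )
        lac = table["final_Lac_ex"].to_numpy()
        assert (lac.max() - lac.min()) / lac.mean() < 0.10

    def test_oligomycin_trades_etc_for_cell_components(self, ref_k):
        table = dose_sweep(
            scenario_for_condition("glucose_glutamine"), ref_k, "dose_oligomycin"
        )
        assert len(table) == 10
        assert np.all(np.diff(table["final_ETC"]) < 0)
        assert np.all(np.diff(table["final_CellComponents"]) > 0)

    def test_empty_values_give_empty_table(self, ref_k):
        table = dose_sweep(Scenario(), ref_k, "Glc_ex", values=[])
        assert len(table) == 0
        assert "final_Lac_ex" in table.columns

    def test_unknown_quantity_rejected(self, ref_k):
        with pytest.raises(KeyError, match="kf_9"):
            dose_sweep(Scenario(), ref_k, "kf_9", values=[1.0])


class TestSummary:
    def test_linear_ramp_plateaus_at_97_percent(self):
        time = np.arange(0.0, 101.0)
        onset, degenerate = plateau_onset(time, time.copy())
        assert not degenerate
        assert onset == 97.0

    def test_constant_zero_signal_is_degenerate(self):
        onset, degenerate = plateau_onset(np.arange(10.0), np.zeros(10))
        assert degenerate and onset == 0.0

    def test_summary_fields(self, ref_trajectories):
        stats = summarize(ref_trajectories["glucose_glutamine"])
        assert stats.signal == "Lac_ex"
        assert 0.0 <= stats.plateau_onset_min <= 120.0
        assert all(v >= 0 for v in stats.auc.values())
        assert stats.etc_exceeds_lac_ex

    def test_unknown_signal_rejected(self, ref_trajectories):
        with pytest.raises(KeyError):
            summarize(ref_trajectories["glucose_only"], signal="NADH")


def test_tidy_export_has_350_rows_per_species(ref_trajectories):
    frame = ref_trajectories["glucose_only"].to_frame(condition="glucose_only")
    counts = frame.groupby("species").size()
    assert (counts == 350).all()
    assert set(frame.columns) == {"time_min", "species", "value", "condition"}
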