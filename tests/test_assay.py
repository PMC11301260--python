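"""Synthetic plate generation, control-based normalisation and CSV I/O."""

import numpy as np
import pytest

from glygln.assay import (
    CONTROL_CONDITION,
    PlateFormatError,
    generate_plate,
    normalize_plate,
    read_plate_csv,
    write_plate_csv,
)
from glygln.simulate import scenario_for_condition, simulate


class TestGeneration:
    def test_every_well_has_the_protocol_grid(self, clean_plate):
        assert clean_plate.time.size == 350
        assert np.allclose(np.diff(clean_plate.time), 0.34)
        for well in clean_plate.wells:
            assert well.values.size == 350

    def test_triplicates_plus_control_structure(self, clean_plate):
        for cond in clean_plate.conditions:
            assert len(clean_plate.wells_for(cond)) == 3
        assert len(clean_plate.wells_for(CONTROL_CONDITION)) == 3

    def test_zero_noise_replicates_are_identical(self, clean_plate):
        for cond in clean_plate.conditions:
            wells = clean_plate.wells_for(cond)
            for w in wells[1:]:
                assert (w.values == wells[0].values).all()

    def test_raw_values_positive_and_finite(self, noisy_plate_normalized, ref_k):
        raw = generate_plate(ref_k, noise_cv=0.03, seed=7,
                             conditions=("glucose_only",))
        for w in raw.wells:
            assert np.all(np.isfinite(w.values))
            assert np.all(w.values > 0)

    def test_same_seed_gives_bit_identical_plates(self, ref_k):
        a = generate_plate(ref_k, noise_cv=0.05, seed=13, conditions=("glucose_only",))
        b = generate_plate(ref_k, noise_cv=0.05, seed=13, conditions=("glucose_only",))
        for wa, wb in zip(a.wells, b.wells):
            assert (wa.values == wb.values).all()

    def test_triplicate_scatter_matches_the_noise_model(self, ref_k):
        plate = generate_plate(ref_k, noise_cv=0.03, seed=2,
                               conditions=("glucose_only",))
        wells = np.array([w.values for w in plate.wells_for("glucose_only")])
        cv = (wells.std(axis=0, ddof=1) / wells.mean(axis=0)).mean()
        # E[sample sd of 3 draws] = c4(3) * sigma ~ 0.886 * sigma
        assert 0.02 <= cv <= 0.04

    def test_noisier_settings_scatter_more(self, ref_k):
        def mean_std(cv):
            total = 0.0
            for seed in range(20):
                plate = generate_plate(ref_k, noise_cv=cv, seed=seed,
                                       conditions=("glucose_only",))
                wells = np.array([w.values for w in plate.wells_for("glucose_only")])
                total += wells.std(axis=0, ddof=1).mean()
            return total / 20

        scatter = [mean_std(cv) for cv in (0.01, 0.03, 0.05)]
        assert scatter[0] < scatter[1] < scatter[2]

    def test_invalid_generator_settings_rejected(self, ref_k):
        with pytest.raises(ValueError):
            generate_plate(ref_k, gain=0.0)
        with pytest.raises(ValueError):
            generate_plate(ref_k, noise_cv=-0.1)
        with pytest.raises(ValueError, match="condition"):
            generate_plate(ref_k, conditions=("starved",))


class TestNormalization:
    def test_zero_noise_normalisation_recovers_scaled_lactate(
        self, ref_k, clean_plate_normalized, clean_plate
    ):
        gain = clean_plate.metadata["gain"]
        lac = simulate(scenario_for_condition("glucose_only"), ref_k).series("Lac_ex")
        trace = clean_plate_normalized.condition_mean("glucose_only")
        assert trace == pytest.approx(gain * lac, abs=1e-8 * gain * lac.max() + 1e-9)

    def test_drift_removed_from_drift_only_plate(self, ref_k):
        plate = generate_plate(ref_k, noise_cv=0.0, drift_per_min=0.002, seed=0,
                               conditions=("glucose_only",))
        flat = normalize_plate(plate)
        # residual after subtracting the lactate component must not trend
        trace = flat.condition_mean("glucose_only")
        lac = simulate(scenario_for_condition("glucose_only"), ref_k).series("Lac_ex")
        residual = trace - plate.metadata["gain"] * lac
        slope = np.polyfit(plate.time, residual, 1)[0]
        assert abs(slope) < 1e-9

    def test_control_wells_normalise_to_zero_mean(self, clean_plate_normalized):
        controls = clean_plate_normalized.wells_for(CONTROL_CONDITION)
        mean = np.mean([w.values for w in controls], axis=0)
        assert np.abs(mean).max() < 1e-9

    def test_double_normalisation_rejected(self, clean_plate_normalized):
        with pytest.raises(ValueError, match="already"):
            normalize_plate(clean_plate_normalized)

    def test_plate_without_controls_rejected(self, ref_k):
        plate = generate_plate(ref_k, conditions=("glucose_only",))
        import dataclasses
        stripped = dataclasses.replace(
            plate,
            wells=tuple(w for w in plate.wells if w.condition != CONTROL_CONDITION),
        )
        with pytest.raises(ValueError, match="control"):
            normalize_plate(stripped)


class TestCsvRoundTrip:
    def test_write_read_is_lossless(self, tmp_path, noisy_plate_normalized):
        path = tmp_path / "plate.csv"
        write_plate_csv(noisy_plate_normalized, path)
        back = read_plate_csv(path)
        assert back.normalized == noisy_plate_normalized.normalized
        assert (back.time == noisy_plate_normalized.time).all()
        for wa, wb in zip(noisy_plate_normalized.wells, back.wells):
            assert wa.well == wb.well
            assert wa.condition == wb.condition
            assert wa.replicate == wb.replicate
            assert (wa.values == wb.values).all()
        assert back.metadata["seed"] == noisy_plate_normalized.metadata["seed"]

    def test_ragged_grid_rejected(self, tmp_path, clean_plate):
        path = tmp_path / "plate.csv"
        write_plate_csv(clean_plate, path, sidecar=False)
        import pandas as pd
        frame = pd.read_csv(path)
        frame = frame.drop(frame[frame["well"] == "W01"].index[-1])
        frame.to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="W0"):
            read_plate_csv(path)

    def test_duplicate_well_time_rejected(self, tmp_path, clean_plate):
        path = tmp_path / "plate.csv"
        write_plate_csv(clean_plate, path, sidecar=False)
        import pandas as pd
        frame = pd.read_csv(path)
        frame = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        frame.to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="duplicate"):
            read_plate_csv(path)

    def test_missing_column_rejected(self, tmp_path, clean_plate):
        path = tmp_path / "plate.csv"
        write_plate_csv(clean_plate, path, sidecar=False)
        import pandas as pd
        pd.read_csv(path).drop(columns=["rfu"]).to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="rfu"):
            read_plate_csv(path)

    def test_unknown_condition_label_warned_and_preserved(self, tmp_path, clean_plate):
        path = tmp_path / "plate.csv"
        write_plate_csv(clean_plate, path, sidecar=False)
        import pandas as pd
        frame = pd.read_csv(path)
        frame.loc[frame["well"] == "W01", "condition"] = "mystery_mix"
        frame.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="mystery_mix"):
            plate = read_plate_csv(path)
        assert "mystery_mix" in {w.condition for w in plate.wells}
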