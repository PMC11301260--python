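"""Synthetic pH-sensitive plate-reader datasets.

Emulates the statistical structure of a kinetic extracellular-acidification
assay run: four treatment conditions measured in triplicate wells plus a
cell-free control, 350 samples per well at 0.34-min spacing, a shared
additive instrument drift, and multiplicative well noise.  The signal in a
treated well is an affine image (gain, offset) of the model-simulated
extracellular lactate, which is the quantity the pH-sensitive reagent
reports; cell-free wells carry offset, drift and noise only, so pointwise
subtraction of their mean removes both the offset and the drift from every
other well — the normalisation the real protocol performs.

The CO2 contribution to acidification is not modelled separately; it is
subsumed in the offset and noise terms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import RateConstants
from .simulate import CONDITIONS, Scenario, scenario_for_condition, simulate

__all__ = [
    "CONTROL_CONDITION",
    "WellTrace",
    "PlateDataset",
    "PlateFormatError",
    "generate_plate",
    "normalize_plate",
    "read_plate_csv",
    "write_plate_csv",
]

CONTROL_CONDITION = "cell_free_control"

#: Default affine map from model lactate (model units) to raw instrument
#: signal (RFU) and default disturbance magnitudes.  All invented: the real
#: instrument's absolute RFU scale is not constrained by anything the model
#: predicts, only the shape of the traces is.
DEFAULT_GAIN = 5.0
DEFAULT_OFFSET = 25000.0
DEFAULT_NOISE_CV = 0.03
DEFAULT_DRIFT_PER_MIN = 5e-4


class PlateFormatError(ValueError):
    """A plate CSV violates the documented long format."""


@dataclass(frozen=True)
class WellTrace:
    well: str
    condition: str
    replicate: int
    values: np.ndarray  # (n_samples,) RFU


@dataclass(frozen=True)
class PlateDataset:
    """Per-well kinetic traces on one shared time grid, plus provenance."""

    time: np.ndarray  # (n_samples,) minutes
    wells: tuple[WellTrace, ...]
    metadata: dict = field(default_factory=dict)
    normalized: bool = False

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.condition != CONTROL_CONDITION:
                seen.setdefault(w.condition, None)
        return tuple(seen)

    def wells_for(self, condition: str) -> tuple[WellTrace, ...]:
        return tuple(w for w in self.wells if w.condition == condition)

    def condition_mean(self, condition: str) -> np.ndarray:
        """Pointwise mean trace over the replicate wells of one condition."""
        traces = [w.values for w in self.wells_for(condition)]
        if not traces:
            raise KeyError(f"no wells with condition {condition!r}")
        return np.mean(traces, axis=0)

    def condition_std(self, condition: str) -> np.ndarray:
        traces = [w.values for w in self.wells_for(condition)]
        if not traces:
            raise KeyError(f"no wells with condition {condition!r}")
        return np.std(traces, axis=0, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                pd.DataFrame(
                    {
                        "well": w.well,
                        "condition": w.condition,
                        "replicate": w.replicate,
                        "time_min": self.time,
                        "rfu": w.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def generate_plate(
    k: RateConstants,
    gain: float = DEFAULT_GAIN,
    offset: float = DEFAULT_OFFSET,
    noise_cv: float = DEFAULT_NOISE_CV,
    drift_per_min: float = DEFAULT_DRIFT_PER_MIN,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
    base_scenario: Scenario | None = None,
    n_replicates: int = 3,
    n_control_wells: int = 3,
) -> PlateDataset:
    """Generate a synthetic plate under rate constants ``k``.

    For each condition the extracellular-lactate trajectory is simulated and
    mapped to RFU via ``gain * Lac_ex + offset``.  Every well then receives
    independent multiplicative Gaussian noise (sd = ``noise_cv`` x value,
    one substream per well derived from ``seed``) plus a drift term
    ``offset * drift_per_min * t`` shared by all wells.  Cell-free control
    wells carry offset, drift and noise only.
    """
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    if noise_cv < 0 or drift_per_min < 0:
        raise ValueError("noise_cv and drift_per_min must be non-negative")
    if n_replicates < 1 or n_control_wells < 1:
        raise ValueError("need at least one replicate and one control well")
    if conditions is None:
        conditions = tuple(CONDITIONS)
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown condition labels: {unknown}")

    base = base_scenario or Scenario()
    time = base.grid()
    drift = offset * drift_per_min * time

    clean: dict[str, np.ndarray] = {}
    for cond in conditions:
        traj = simulate(scenario_for_condition(cond, base), k)
        clean[cond] = gain * traj.series("Lac_ex") + offset
    clean[CONTROL_CONDITION] = np.full_like(time, offset)

    wells: list[WellTrace] = []
    well_index = 0
    for cond in list(conditions) + [CONTROL_CONDITION]:
        n_wells = n_control_wells if cond == CONTROL_CONDITION else n_replicates
        for rep in range(1, n_wells + 1):
            rng = np.random.default_rng([seed, well_index])
            signal = clean[cond] + drift
            noisy = signal * (1.0 + noise_cv * rng.standard_normal(time.size))
            wells.append(
                WellTrace(
                    well=f"W{well_index + 1:02d}",
                    condition=cond,
                    replicate=rep,
                    values=noisy,
                )
            )
            well_index += 1

    metadata = {
        "seed": int(seed),
        "gain": float(gain),
        "offset": float(offset),
        "noise_cv": float(noise_cv),
        "drift_per_min": float(drift_per_min),
        "rate_constants": k.to_mapping(),
        "n_samples": int(time.size),
        "sample_interval_min": float(base.sample_interval),
    }
    return PlateDataset(time=time, wells=tuple(wells), metadata=metadata)


def normalize_plate(plate: PlateDataset) -> PlateDataset:
    """Subtract the pointwise mean of the cell-free control wells from every
    well, removing the shared offset and measurement drift."""
    if plate.normalized:
        raise ValueError("plate is already normalized")
    controls = plate.wells_for(CONTROL_CONDITION)
    if not controls:
        raise ValueError("cannot normalize: plate has no cell-free control wells")
    control_mean = np.mean([w.values for w in controls], axis=0)
    wells = tuple(
        replace(w, values=w.values - control_mean) for w in plate.wells
    )
    return PlateDataset(
        time=plate.time,
        wells=wells,
        metadata=dict(plate.metadata),
        normalized=True,
    )


_REQUIRED_COLUMNS = ("well", "condition", "replicate", "time_min", "rfu")


def write_plate_csv(
    plate: PlateDataset, path: str | Path, sidecar: bool = True
) -> None:
    """Write the plate in the documented long format (columns: well,
    condition, replicate, time_min, rfu) plus a JSON metadata sidecar."""
    path = Path(path)
    # %.17g guarantees the written decimal text parses back to the same double
    plate.to_frame().to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = dict(plate.metadata)
        meta["normalized"] = plate.normalized
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )


def read_plate_csv(path: str | Path) -> PlateDataset:
    """Read a long-format plate CSV; lossless inverse of
    :func:`write_plate_csv`.

    Raises :class:`PlateFormatError` for missing columns, wells whose time
    grid disagrees with the plate's, or duplicate (well, time) pairs; an
    unrecognised condition label is only warned about and kept verbatim.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required columns {missing}")

    dup = frame.duplicated(subset=["well", "time_min"])
    if dup.any():
        rows = frame.index[dup].tolist()[:10]
        raise PlateFormatError(f"{path}: duplicate (well, time) pairs at rows {rows}")

    known = set(CONDITIONS) | {CONTROL_CONDITION}
    for label in frame["condition"].unique():
        if label not in known:
            warnings.warn(
                f"{path}: unknown condition label {label!r} (kept verbatim)",
                stacklevel=2,
            )

    wells: list[WellTrace] = []
    time: np.ndarray | None = None
    for well_id, group in frame.groupby("well", sort=False):
        group = group.sort_values("time_min")
        t = group["time_min"].to_numpy(dtype=float)
        if time is None:
            time = t
        elif t.size != time.size or not np.allclose(t, time, rtol=0, atol=1e-9):
            raise PlateFormatError(
                f"{path}: well {well_id!r} has a time grid of {t.size} samples "
                f"that disagrees with the plate grid of {time.size}"
            )
        wells.append(
            WellTrace(
                well=str(well_id),
                condition=str(group["condition"].iloc[0]),
                replicate=int(group["replicate"].iloc[0]),
                values=group["rfu"].to_numpy(dtype=float),
            )
        )
    if time is None:
        raise PlateFormatError(f"{path}: no wells found")

    metadata: dict = {}
    normalized = False
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        normalized = bool(metadata.pop("normalized", False))
    return PlateDataset(
        time=time, wells=tuple(wells), metadata=metadata, normalized=normalized
    )
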