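"""Core rate laws and derivatives of the glycolysis–glutaminolysis network.

The model lumps central carbon metabolism into ten dynamic species spread
over three unit-volume compartments:

* medium: extracellular glucose (``Glc_ex``), glutamine (``Gln_ex``) and
  exported lactate (``Lac_ex``);
* cytosol: internalised glucose (``Glc``), pyruvate (``Pyr``), lactate
  (``Lac``) and glutamine (``Gln``);
* mitochondria: the TCA-cycle pool (``TCA``), the electron-transport-chain
  output (``ETC``) and lumped biosynthetic by-products (``CellComponents``).

Nine reactions connect the species.  Every rate law is first order in its
substrate (``rate = k * [metabolite]``); uptake reactions are additionally
scaled by a constant, dimensionless *capacity* (transporter / organelle
capacity), and two reactions carry dose-dependent modulator factors for
oligomycin (an ATP-synthase inhibitor that indirectly stimulates glycolysis
and inhibits TCA→ETC flux) and 2-deoxyglucose (a hexokinase-competitive
glycolysis inhibitor).  Reversible reactions are expressed as forward minus
reverse terms, so their net rates may be negative.

Time is measured in minutes, rate constants in min^-1, and concentrations in
model units nominally equal to uM (``Glc_ex = 7500`` represents 7.5 mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "COMPARTMENT_OF",
    "RATE_CONSTANT_NAMES",
    "MetabolicState",
    "RateConstants",
    "FluxVector",
    "compute_fluxes",
    "compute_derivatives",
    "total_pool",
    "STOICHIOMETRY",
]

#: Dynamic species, in canonical order.  This order defines the rows of the
#: species matrix in a trajectory and the layout of packed state vectors.
SPECIES: tuple[str, ...] = (
    "Glc_ex",
    "Glc",
    "Pyr",
    "Lac",
    "Lac_ex",
    "Gln_ex",
    "Gln",
    "TCA",
    "ETC",
    "CellComponents",
)

COMPARTMENT_OF: dict[str, str] = {
    "Glc_ex": "medium",
    "Gln_ex": "medium",
    "Lac_ex": "medium",
    "Glc": "cell",
    "Pyr": "cell",
    "Lac": "cell",
    "Gln": "cell",
    "TCA": "mitochondria",
    "ETC": "mitochondria",
    "CellComponents": "mitochondria",
}

RATE_CONSTANT_NAMES: tuple[str, ...] = (
    "kf_Glc",
    "kf_Gln",
    "kf_1",
    "kf_2",
    "kf_3",
    "kf_4",
    "kf_5",
    "kf_6",
    "kf_7",
    "kr_1",
    "kr_2",
    "kr_3",
    "kr_4",
    "i1",
    "i2",
)

#: Net stoichiometry of the nine reactions over the ten dynamic species
#: (species x reaction).  Every reaction converts one unit of substrate into
#: one unit of product, so each column sums to zero and the total pool is
#: conserved along any trajectory.
STOICHIOMETRY: np.ndarray = np.zeros((10, 9))
for _j, (_subs, _prod) in enumerate(
    [
        ("Glc_ex", "Glc"),  # 1: glucose uptake
        ("Glc", "Pyr"),  # 2: lumped glycolysis / gluconeogenesis
        ("Pyr", "Lac"),  # 3: lactate fermentation
        ("Lac", "Lac_ex"),  # 4: lactate export
        ("Pyr", "TCA"),  # 5: mitochondrial pyruvate entry
        ("TCA", "ETC"),  # 6: oxidative phosphorylation output
        ("TCA", "CellComponents"),  # 7: biosynthetic by-products
        ("Gln", "TCA"),  # 8: mitochondrial glutamine entry (glutaminolysis)
        ("Gln_ex", "Gln"),  # 9: glutamine uptake
    ]
):
    STOICHIOMETRY[SPECIES.index(_subs), _j] = -1.0
    STOICHIOMETRY[SPECIES.index(_prod), _j] = 1.0
STOICHIOMETRY.setflags(write=False)


class InvalidStateError(ValueError):
    """A metabolic state contains non-finite or negative quantities."""


class InvalidParameterError(ValueError):
    """A rate-constant set violates its validity constraints."""


@dataclass(frozen=True)
class MetabolicState:
    """Concentrations of the ten dynamic species plus constant boundary factors.

    The three capacities and the two modulator doses are *boundary*
    quantities: they appear inside rate laws but have zero time derivative,
    and a simulation never changes them.
    """

    Glc_ex: float = 0.0
    Glc: float = 0.0
    Pyr: float = 0.0
    Lac: float = 0.0
    Lac_ex: float = 0.0
    Gln_ex: float = 0.0
    Gln: float = 0.0
    TCA: float = 0.0
    ETC: float = 0.0
    CellComponents: float = 0.0
    Capacity_Glc: float = 200.0
    Capacity_Gln: float = 100.0
    Capacity_M: float = 50.0
    dose_oligomycin: float = 0.0
    dose_2DG: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise InvalidStateError(f"{f.name} is not finite: {v!r}")
            if v < 0:
                raise InvalidStateError(f"{f.name} is negative: {v!r}")

    def species_vector(self) -> np.ndarray:
        """The ten dynamic species as a float array in :data:`SPECIES` order."""
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    def with_species(self, y: np.ndarray) -> "MetabolicState":
        """A copy with the dynamic species replaced by ``y`` (boundary
        quantities untouched)."""
        return replace(self, **dict(zip(SPECIES, map(float, y))))


@dataclass(frozen=True)
class RateConstants:
    """The thirteen kinetic constants (min^-1) plus the two dimensionless
    modulator sensitivities ``i1`` (2-deoxyglucose) and ``i2`` (oligomycin).

    ``kr_3``, the rate of lactate re-uptake from the medium, defaults to
    0.01; the modulator sensitivities default to 0.1 each so that doses on
    the 1–10 scale map onto fractional inhibition/stimulation below unity.
    """

    kf_Glc: float
    kf_Gln: float
    kf_1: float
    kf_2: float
    kf_3: float
    kf_4: float
    kf_5: float
    kf_6: float
    kf_7: float
    kr_1: float
    kr_2: float
    kr_3: float = 0.01
    kr_4: float = 0.0
    i1: float = 0.1
    i2: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{f.name} is not finite: {v!r}")
            if v < 0:
                raise InvalidParameterError(f"{f.name} is negative: {v!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RateConstants":
        unknown = set(mapping) - set(RATE_CONSTANT_NAMES)
        if unknown:
            raise InvalidParameterError(
                f"unknown rate-constant keys: {sorted(unknown)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_mapping(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class FluxVector:
    """Signed net rates of the nine reactions (concentration min^-1).

    Reactions 2–5 are reversible: a positive entry means the forward
    direction dominates, a negative one the reverse.  Reactions 1, 6, 7, 8
    and 9 are structurally unidirectional.
    """

    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    v6: float
    v7: float
    v8: float
    v9: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v1, self.v2, self.v3, self.v4, self.v5, self.v6, self.v7, self.v8, self.v9]
        )

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


def _flux_array(
    y: np.ndarray,
    caps: tuple[float, float, float],
    doses: tuple[float, float],
    k: RateConstants,
    clamp_modulator_factors: bool,
) -> np.ndarray:
    """Vectorised kernel: fluxes for a species vector (or a 10 x n matrix)."""
    glc_ex, glc, pyr, lac, lac_ex, gln_ex, gln, tca = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7],
    )
    cap_glc, cap_gln, cap_m = caps
    oligo, dg = doses

    glycolysis_factor = 1.0 + oligo * k.i2 - dg * k.i1
    etc_factor = 1.0 - oligo * k.i2
    if clamp_modulator_factors:
        glycolysis_factor = np.maximum(glycolysis_factor, 0.0)
        etc_factor = np.maximum(etc_factor, 0.0)

    return np.array(
        [
            k.kf_Glc * glc_ex * cap_glc,
            k.kf_1 * glc * glycolysis_factor - k.kr_1 * pyr,
            k.kf_2 * pyr - k.kr_2 * lac,
            k.kf_3 * lac - k.kr_3 * lac_ex,
            k.kf_4 * pyr * (cap_m - tca) - k.kr_4 * tca,
            k.kf_5 * tca * (1.0 + gln / 10.0) * etc_factor,
            k.kf_6 * tca,
            k.kf_7 * gln,
            k.kf_Gln * gln_ex * cap_gln,
        ]
    )


def compute_fluxes(
    state: MetabolicState,
    k: RateConstants,
    clamp_modulator_factors: bool = False,
) -> FluxVector:
    """Evaluate the nine reaction rate laws at ``state``.

    With ``clamp_modulator_factors`` the bracketed modulator factors
    ``(1 + oligo*i2 - 2DG*i1)`` and ``(1 - oligo*i2)`` are floored at zero
    before use, so extreme dose-times-sensitivity products cannot drive the
    stimulated/inhibited reactions backwards.  By default the factors are
    evaluated literally.
    """
    v = _flux_array(
        state.species_vector(),
        (state.Capacity_Glc, state.Capacity_Gln, state.Capacity_M),
        (state.dose_oligomycin, state.dose_2DG),
        k,
        clamp_modulator_factors,
    )
    return FluxVector(*map(float, v))


def compute_derivatives(
    state: MetabolicState,
    k: RateConstants,
    clamp_modulator_factors: bool = False,
) -> np.ndarray:
    """Time derivatives of the ten dynamic species, in :data:`SPECIES` order.

    Boundary quantities (capacities, doses) are constant by construction and
    have no entry here; their derivative is identically zero.
    """
    v = _flux_array(
        state.species_vector(),
        (state.Capacity_Glc, state.Capacity_Gln, state.Capacity_M),
        (state.dose_oligomycin, state.dose_2DG),
        k,
        clamp_modulator_factors,
    )
    return STOICHIOMETRY @ v


def total_pool(state: MetabolicState) -> float:
    """Sum of the ten dynamic species.

    Because every reaction converts one unit of substrate into one unit of
    product, this total is conserved along any trajectory and serves as an
    integration diagnostic.
    """
    return float(state.species_vector().sum())
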