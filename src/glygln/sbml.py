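"""SBML Level 3 export/import of the model.

The document mirrors the model structure exactly: three unit-size
compartments (medium, cell, mitochondria), ten dynamic species, the
capacities, doses and modulator sensitivities as constant parameters, and
nine reactions whose kinetic laws are the model's literal rate expressions
(reactions 2-5 are flagged reversible).  The clamped variant of the
modulator factors is not representable in a plain kinetic law, so scenarios
requesting clamping are refused at export.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .model import COMPARTMENT_OF, RATE_CONSTANT_NAMES, SPECIES, RateConstants
from .simulate import Scenario

__all__ = ["SBMLExportError", "export_sbml", "load_sbml"]

_COMPARTMENTS = ("medium", "cell", "mitochondria")

#: reaction id, reactant, product, reversible, modifiers, kinetic-law formula
_REACTIONS: tuple[tuple[str, str, str, bool, tuple[str, ...], str], ...] = (
    ("R1_glucose_uptake", "Glc_ex", "Glc", False, (),
     "kf_Glc * Glc_ex * Capacity_Glc"),
    ("R2_glycolysis", "Glc", "Pyr", True, (),
     "kf_1 * Glc * (1 + dose_oligomycin * i2 - dose_2DG * i1) - kr_1 * Pyr"),
    ("R3_lactate_fermentation", "Pyr", "Lac", True, (),
     "kf_2 * Pyr - kr_2 * Lac"),
    ("R4_lactate_export", "Lac", "Lac_ex", True, (),
     "kf_3 * Lac - kr_3 * Lac_ex"),
    ("R5_mitochondrial_pyruvate_entry", "Pyr", "TCA", True, (),
     "kf_4 * Pyr * (Capacity_M - TCA) - kr_4 * TCA"),
    # intracellular glutamine amplifies oxidative output without being
    # consumed here, so it enters as a modifier
    ("R6_oxidative_phosphorylation", "TCA", "ETC", False, ("Gln",),
     "kf_5 * TCA * (1 + Gln / 10) * (1 - dose_oligomycin * i2)"),
    ("R7_biosynthesis", "TCA", "CellComponents", False, (),
     "kf_6 * TCA"),
    ("R8_glutaminolysis", "Gln", "TCA", False, (),
     "kf_7 * Gln"),
    ("R9_glutamine_uptake", "Gln_ex", "Gln", False, (),
     "kf_Gln * Gln_ex * Capacity_Gln"),
)


class SBMLExportError(RuntimeError):
    """The model could not be serialised to (or read from) valid SBML."""


def _initial_concentrations(scenario: Scenario) -> dict[str, float]:
    out = dict.fromkeys(SPECIES, 0.0)
    out["Glc_ex"] = scenario.glc_ex
    out["Gln_ex"] = scenario.gln_ex
    return out


def _constant_parameters(k: RateConstants, scenario: Scenario) -> dict[str, float]:
    params = k.to_mapping()
    params.update(
        Capacity_Glc=scenario.capacity_glc,
        Capacity_Gln=scenario.capacity_gln,
        Capacity_M=scenario.capacity_m,
        dose_oligomycin=scenario.dose_oligomycin,
        dose_2DG=scenario.dose_2DG,
    )
    return params


def export_sbml(k: RateConstants, scenario: Scenario, path: str | Path) -> None:
    """Write the model under ``k`` and ``scenario`` as an SBML L3V2 document.

    The document is validated for internal consistency before writing;
    export is refused (with the validator's diagnostics) if any error is
    found, or if the scenario requests clamped modulator factors.
    """
    if scenario.clamp_modulator_factors:
        raise SBMLExportError(
            "clamped modulator factors have no kinetic-law representation; "
            "export the literal (unclamped) model instead"
        )
    document = libsbml.SBMLDocument(3, 2)
    model = document.createModel("glycolysis_glutaminolysis")
    model.setTimeUnits("dimensionless")

    for cid in _COMPARTMENTS:
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setSize(1.0)
        comp.setConstant(True)
        comp.setSpatialDimensions(3)

    inits = _initial_concentrations(scenario)
    for sid in SPECIES:
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setCompartment(COMPARTMENT_OF[sid])
        sp.setInitialConcentration(inits[sid])
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    for pid, value in _constant_parameters(k, scenario).items():
        par = model.createParameter()
        par.setId(pid)
        par.setValue(float(value))
        par.setConstant(True)

    for rid, reactant, product, reversible, modifiers, formula in _REACTIONS:
        rxn = model.createReaction()
        rxn.setId(rid)
        rxn.setReversible(reversible)
        sr = rxn.createReactant()
        sr.setSpecies(reactant)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        sp = rxn.createProduct()
        sp.setSpecies(product)
        sp.setStoichiometry(1.0)
        sp.setConstant(True)
        for modifier in modifiers:
            mod = rxn.createModifier()
            mod.setSpecies(modifier)
        law = rxn.createKineticLaw()
        ast = libsbml.parseL3Formula(formula)
        if ast is None:
            raise SBMLExportError(f"could not parse kinetic law for {rid}")
        law.setMath(ast)

    document.checkConsistency()
    errors = [
        document.getError(i).getMessage()
        for i in range(document.getNumErrors())
        if document.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        raise SBMLExportError(
            "refusing to export inconsistent SBML: " + " | ".join(errors[:5])
        )
    if libsbml.writeSBMLToFile(document, str(path)) != 1:
        raise SBMLExportError(f"could not write SBML to {path}")


def load_sbml(path: str | Path) -> tuple[RateConstants, Scenario]:
    """Read back a document written by :func:`export_sbml`.

    Returns the rate constants and a scenario carrying the document's
    initial nutrient levels, capacities and doses; the sampling protocol is
    not part of SBML and comes back as the default grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML file not found: {path}")
    document = libsbml.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            document.getError(i).getMessage()
            for i in range(document.getNumErrors())
            if document.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLExportError(f"invalid SBML in {path}: " + " | ".join(msgs[:5]))
    model = document.getModel()
    if model is None:
        raise SBMLExportError(f"{path} contains no model")

    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    missing = [n for n in RATE_CONSTANT_NAMES if n not in params]
    if missing:
        raise SBMLExportError(f"{path}: missing rate-constant parameters {missing}")
    k = RateConstants.from_mapping({n: params[n] for n in RATE_CONSTANT_NAMES})

    def species_init(sid: str) -> float:
        sp = model.getSpecies(sid)
        if sp is None:
            raise SBMLExportError(f"{path}: missing species {sid!r}")
        return float(sp.getInitialConcentration())

    scenario = Scenario(
        glc_ex=species_init("Glc_ex"),
        gln_ex=species_init("Gln_ex"),
        dose_oligomycin=params.get("dose_oligomycin", 0.0),
        dose_2DG=params.get("dose_2DG", 0.0),
        capacity_glc=params.get("Capacity_Glc", 200.0),
        capacity_gln=params.get("Capacity_Gln", 100.0),
        capacity_m=params.get("Capacity_M", 50.0),
    )
    return k, scenario
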