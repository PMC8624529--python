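"""Compound physicochemistry and subject-level pharmacokinetic parameters.

Metformin is the packaged default compound: a small (MW 129.17 g/mol),
very hydrophilic (log D at pH 4 of -3.37) biguanide whose single basic
center (pKa 11.5) keeps it essentially fully protonated at every
gastrointestinal pH.  It is freely soluble, so an immediate-release dose
behaves as a solution, and it is cleared renally without metabolism — the
disposition model here is one compartment with first-order renal
elimination.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field


class DosageForm(str, Enum):
    immediate_release = "immediate_release"


class CompoundProfile(BaseModel):
    """Physicochemical and dosing parameters of the simulated compound.

    ``papp`` is the cell-monolayer apparent permeability (cm/s), kept for
    provenance; absorption in the simulator is driven by segmental effective
    permeability supplied separately.  ``intrinsic_solubility_ref`` (mg/mL)
    is the reference solubility at ``solubility_pH``; it only gates the
    dose-number check supporting the instantaneous-dissolution assumption.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    molecular_weight: float = Field(gt=0.0)
    pKa: float
    logD_pH4: float
    intrinsic_solubility_ref: float = Field(gt=0.0)
    solubility_pH: float
    papp: float = Field(ge=0.0)
    dose: float = Field(gt=0.0)
    dosage_form: DosageForm = DosageForm.immediate_release
    water_coadministered: float = Field(gt=0.0)


class PKParameters(BaseModel):
    """Subject-level disposition parameters for one-compartment kinetics.

    Renal clearance is in L/h/kg and volume of distribution in L/kg, so the
    elimination rate constant CL/Vd (1/h) is weight-independent while
    absolute clearance CL x BW (L/h) and distribution volume Vd x BW (L)
    scale with body weight.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    body_weight: float = Field(gt=0.0)
    renal_clearance: float = Field(gt=0.0)
    volume_of_distribution: float = Field(gt=0.0)

    @property
    def elimination_rate(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.renal_clearance / self.volume_of_distribution

    @property
    def clearance_total(self) -> float:
        """Absolute clearance, L/h."""
        return self.renal_clearance * self.body_weight

    @property
    def vd_total(self) -> float:
        """Absolute volume of distribution, L."""
        return self.volume_of_distribution * self.body_weight


def cationic_fraction(pKa: float, pH: float) -> float:
    """Henderson-Hasselbalch ionized fraction for a monoprotic base.

    Returns 1/(1 + 10**(pH - pKa)), the fraction carrying the positive
    charge; 0.5 at pH == pKa, approaching 1 in acid and 0 in strong base.
    """
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def dose_number(dose: float, solubility: float, volume: float) -> float:
    """Dose number D0 = dose / (solubility x administered fluid volume).

    Values at or below 1 mean the whole dose dissolves in the
    co-administered fluid, licensing a solution-like (instantaneous
    dissolution) simulation.  ``dose`` mg, ``solubility`` mg/mL,
    ``volume`` mL.
    """
    if volume <= 0.0:
        raise ValueError(f"administered fluid volume must be positive, got {volume}")
    if solubility <= 0.0:
        raise ValueError(f"solubility must be positive, got {solubility}")
    return dose / (solubility * volume)


def metformin_profile(dose: float = 1000.0, water_coadministered: float = 250.0) -> CompoundProfile:
    """Packaged metformin profile with the study's physicochemical inputs."""
    return CompoundProfile(
        name="metformin",
        molecular_weight=129.17,
        pKa=11.5,
        logD_pH4=-3.37,
        intrinsic_solubility_ref=100.05,
        solubility_pH=12.24,
        papp=0.05e-5,
        dose=dose,
        water_coadministered=water_coadministered,
    )
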