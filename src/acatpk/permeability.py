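"""Permeability conversions: species scaling, paracellular sieving, segment maps.

Three conversions connect measured permeability to the simulator's
per-compartment inputs:

* rat -> human scaling of jejunal effective permeability by the empirical
  affine correlation ``Peff,man = 3.6 * Peff,rat + 0.03e-4`` (cm/s);
* a single-pore paracellular model in which a hydrophilic solute of
  molecular radius r permeates water-filled tight-junction pores of radius
  rp, hindered by the Renkin sieving factor — used to place a target
  fraction (for metformin, 90%) of total permeability on the paracellular
  route by adjusting the molecular radius;
* assignment of segmentally measured values (jejunum, mid small intestine,
  ileum) onto the eight absorbing gut compartments, with colonic
  permeability a configurable fraction of the ileal value.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field

from .physiology import GUT_COMPARTMENTS, COLON, CompartmentName, GutPhysiology
from .spip import Segment

#: Slope and intercept (cm/s) of the rat->human jejunal Peff correlation.
RAT_TO_HUMAN_SLOPE = 3.6
RAT_TO_HUMAN_INTERCEPT = 0.03e-4


class PermeabilityError(ValueError):
    """Invalid permeability conversion or assignment."""


class Provenance(str, Enum):
    single_value = "single_value"
    segmental_measured = "segmental_measured"
    calibrated = "calibrated"


class SegmentalPermeability(BaseModel):
    """Human effective permeability (cm/s) for each post-stomach compartment."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    values: dict[CompartmentName, float]
    provenance: Provenance

    @property
    def complete(self) -> bool:
        return set(self.values) == set(GUT_COMPARTMENTS)

    def __init__(self, **data) -> None:
        super().__init__(**data)
        if set(self.values) != set(GUT_COMPARTMENTS):
            raise PermeabilityError(
                "permeability map must cover exactly the eight post-stomach compartments"
            )
        for name, v in self.values.items():
            if v < 0.0:
                raise PermeabilityError(f"negative permeability for {name.value}: {v}")

    def scaled(self, multiplier: float, provenance: Provenance | None = None) -> "SegmentalPermeability":
        """All compartment values multiplied by ``multiplier`` (ratios preserved)."""
        if multiplier < 0.0:
            raise PermeabilityError(f"multiplier must be non-negative, got {multiplier}")
        return SegmentalPermeability(
            values={k: v * multiplier for k, v in self.values.items()},
            provenance=provenance or self.provenance,
        )


def rat_to_human(peff_rat: float) -> float:
    """Human jejunal Peff (cm/s) from rat jejunal Peff via the affine correlation."""
    if peff_rat < 0.0:
        raise PermeabilityError(f"rat permeability must be non-negative, got {peff_rat}")
    return RAT_TO_HUMAN_SLOPE * peff_rat + RAT_TO_HUMAN_INTERCEPT


def renkin_factor(lam: float) -> float:
    """Renkin hindered-diffusion sieving factor for lambda = r_molecule / r_pore.

    ``(1-lam)^2 * (1 - 2.104*lam + 2.09*lam^3 - 0.95*lam^5)`` for lambda < 1,
    zero at or beyond size exclusion (lambda >= 1).
    """
    if lam < 0.0:
        raise PermeabilityError(f"lambda must be non-negative, got {lam}")
    if lam >= 1.0:
        return 0.0
    return (1.0 - lam) ** 2 * (1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)


class ParacellularModel(BaseModel):
    """Single-pore paracellular permeability model.

    ``pore_capacity`` aggregates porosity, aqueous diffusivity and path
    length into the unhindered (point-solute) permeability, cm/s; the pore
    radius default of 6 Angstrom is a typical jejunal literature scale and a
    configuration value, not a measured claim.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    pore_radius: float = Field(default=6.0, gt=0.0)  # Angstrom
    pore_capacity: float = Field(ge=0.0)  # cm/s
    molecular_radius: float = Field(ge=0.0)  # Angstrom


def paracellular_peff(model: ParacellularModel) -> float:
    """Paracellular permeability: capacity times the Renkin sieving factor."""
    return model.pore_capacity * renkin_factor(model.molecular_radius / model.pore_radius)


def fit_molecular_radius(
    target_para_fraction: float,
    trans_peff: float,
    pore_radius: float = 6.0,
    pore_capacity: float = 0.0,
    tol: float = 1e-6,
) -> float:
    """Molecular radius (Angstrom) placing a target fraction on the paracellular route.

    Solves ``para(r) / (para(r) + trans_peff) = target`` for r by bisection;
    the fraction decreases monotonically in r from its maximum at r = 0, so
    the root is unique when reachable.

    Raises
    ------
    PermeabilityError
        If the target exceeds the maximum fraction ``capacity / (capacity +
        trans_peff)`` attained by a point solute.
    """
    if not 0.0 < target_para_fraction < 1.0:
        raise PermeabilityError(f"target fraction must be in (0, 1), got {target_para_fraction}")
    if trans_peff <= 0.0:
        raise PermeabilityError(f"transcellular permeability must be positive, got {trans_peff}")
    if pore_capacity < 0.0 or pore_radius <= 0.0:
        raise PermeabilityError("pore capacity must be >= 0 and pore radius > 0")

    def fraction(r: float) -> float:
        para = pore_capacity * renkin_factor(r / pore_radius)
        return para / (para + trans_peff)

    if fraction(0.0) < target_para_fraction:
        raise PermeabilityError(
            f"target paracellular fraction {target_para_fraction} unreachable: maximum "
            f"{fraction(0.0):.6f} at zero molecular radius"
        )
    lo, hi = 0.0, pore_radius  # fraction(lo) >= target, fraction(hi) = 0 < target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if abs(fraction(mid) - target_para_fraction) <= tol:
            return mid
        if fraction(mid) > target_para_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: Default segment -> compartment fan-out (configuration, not anatomy dogma).
DEFAULT_SEGMENT_MAP: dict[Segment, tuple[CompartmentName, ...]] = {
    Segment.jejunum: (CompartmentName.jejunum1, CompartmentName.jejunum2),
    Segment.mid_SI: (CompartmentName.ileum1,),
    Segment.ileum: (CompartmentName.ileum2, CompartmentName.ileum3),
}


def assign_segments(
    measured: dict[Segment, float],
    duodenal_peff: float,
    physiology: GutPhysiology,
    colon_factor: float = 0.1,
    segment_map: dict[Segment, tuple[CompartmentName, ...]] | None = None,
) -> SegmentalPermeability:
    """Map segmentally measured human Peff onto the eight gut compartments.

    The duodenal value is supplied separately (it is not perfusable in the
    three-segment protocol); caecum and ascending colon get ``colon_factor``
    times the ileal value, reflecting poor colonic absorption of hydrophilic
    paracellular compounds.  Bypassed compartments still receive values —
    the simulator ignores them.
    """
    if segment_map is None:
        segment_map = DEFAULT_SEGMENT_MAP
    missing = [s.value for s in Segment if s not in measured]
    if missing:
        raise PermeabilityError(f"missing measured segments: {missing}")
    if duodenal_peff < 0.0:
        raise PermeabilityError(f"duodenal permeability must be non-negative, got {duodenal_peff}")
    if not 0.0 <= colon_factor <= 1.0:
        raise PermeabilityError(f"colon_factor must be in [0, 1], got {colon_factor}")

    values: dict[CompartmentName, float] = {CompartmentName.duodenum: duodenal_peff}
    for segment, compartments in segment_map.items():
        for name in compartments:
            values[name] = measured[segment]
    for name in COLON:
        values[name] = colon_factor * measured[Segment.ileum]
    return SegmentalPermeability(values=values, provenance=Provenance.segmental_measured)


def uniform_permeability(
    peff: float, colon_factor: float = 0.1, provenance: Provenance = Provenance.single_value
) -> SegmentalPermeability:
    """A single jejunal-anchored value applied to every small-intestinal
    compartment (duodenum included), with colonic values down-weighted by
    ``colon_factor`` — the naive way a single compound-level permeability is
    spread over the gut."""
    if peff < 0.0:
        raise PermeabilityError(f"permeability must be non-negative, got {peff}")
    if not 0.0 <= colon_factor <= 1.0:
        raise PermeabilityError(f"colon_factor must be in [0, 1], got {colon_factor}")
    values = {name: peff for name in GUT_COMPARTMENTS}
    for name in COLON:
        values[name] = colon_factor * peff
    return SegmentalPermeability(values=values, provenance=provenance)
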