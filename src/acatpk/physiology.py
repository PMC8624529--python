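"""Nine-compartment gut physiology: stomach through ascending colon.

The absorption model divides the gastrointestinal tract into a stomach
followed by eight serial intestinal compartments (duodenum, two jejunal,
three ileal, caecum, ascending colon).  Each compartment carries the fasted
pH, mean transit time, resting luminal fluid volume and anatomical length
that drive transit and absorption kinetics.  A Roux-en-Y gastric bypass
(RYGB) transform shrinks the stomach to the surgical pouch and removes the
duodenum and proximal jejunum from the flow path by zeroing their transit
time, volume and length.

Bypassed compartments stay in the list with a flag so that compartment
indexing and per-segment reporting are stable across pre- and post-surgery
scenarios.
"""

from __future__ import annotations

import math
from enum import Enum

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class CompartmentName(str, Enum):
    """Anatomical labels, proximal to distal."""

    stomach = "stomach"
    duodenum = "duodenum"
    jejunum1 = "jejunum1"
    jejunum2 = "jejunum2"
    ileum1 = "ileum1"
    ileum2 = "ileum2"
    ileum3 = "ileum3"
    caecum = "caecum"
    asc_colon = "asc_colon"


#: Fixed anatomical order, stomach first.
COMPARTMENT_ORDER: tuple[CompartmentName, ...] = tuple(CompartmentName)

#: The eight post-stomach compartments that can absorb drug.
GUT_COMPARTMENTS: tuple[CompartmentName, ...] = COMPARTMENT_ORDER[1:]

#: Small-intestinal compartments (duodenum through ileum 3).
SMALL_INTESTINE: tuple[CompartmentName, ...] = COMPARTMENT_ORDER[1:7]

#: Colonic compartments.
COLON: tuple[CompartmentName, ...] = (CompartmentName.caecum, CompartmentName.asc_colon)


class PhysiologyError(ValueError):
    """Invalid physiology construction or transform."""


class Compartment(BaseModel):
    """One gut compartment.

    Units: ``transit_time`` hours, ``volume`` mL, ``length`` cm.  ``asf`` is
    the dimensionless absorption scale factor multiplying the basal
    absorption rate constant.  ``bypassed`` marks a compartment surgically
    removed from the flow path; it is equivalent to transit time, volume and
    length all being zero.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: CompartmentName
    pH: float = Field(ge=1.0, le=9.0)
    transit_time: float = Field(ge=0.0)
    volume: float = Field(ge=0.0)
    length: float = Field(ge=0.0)
    asf: float = Field(default=1.0, ge=0.0)
    bypassed: bool = False

    @model_validator(mode="after")
    def _bypass_consistency(self) -> "Compartment":
        zeroed = self.transit_time == 0.0 and self.volume == 0.0 and self.length == 0.0
        if self.bypassed != zeroed:
            raise ValueError(
                f"{self.name.value}: bypassed={self.bypassed} inconsistent with "
                f"transit_time={self.transit_time}, volume={self.volume}, "
                f"length={self.length} (bypassed iff all three are zero)"
            )
        return self

    @property
    def radius(self) -> float:
        """Cylinder radius (cm) consistent with the compartment volume and length."""
        return compartment_radius(self.volume, self.length)


def compartment_radius(volume: float, length: float) -> float:
    """Radius (cm) of a cylinder with the given ``volume`` (mL) and ``length`` (cm).

    Geometry is the single place compartment volume and length combine, so
    the radius is derived, never stored.  Bypassed compartments (zero volume
    and length) have no radius.

    Raises
    ------
    PhysiologyError
        If ``volume`` or ``length`` is not strictly positive.
    """
    if volume <= 0.0 or length <= 0.0:
        raise PhysiologyError(
            f"compartment radius undefined for volume={volume} mL, length={length} cm"
        )
    return math.sqrt(volume / (math.pi * length))


class GutPhysiology(BaseModel):
    """Ordered set of the nine gut compartments, stomach first."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    compartments: tuple[Compartment, ...]

    @field_validator("compartments")
    @classmethod
    def _check_order(cls, v: tuple[Compartment, ...]) -> tuple[Compartment, ...]:
        if len(v) != len(COMPARTMENT_ORDER):
            raise ValueError(f"expected {len(COMPARTMENT_ORDER)} compartments, got {len(v)}")
        names = tuple(c.name for c in v)
        if names != COMPARTMENT_ORDER:
            raise ValueError(f"compartments out of order: {[n.value for n in names]}")
        return v

    @model_validator(mode="after")
    def _check_flow_path(self) -> "GutPhysiology":
        if not any(not c.bypassed for c in self.compartments[1:]):
            raise ValueError("no non-bypassed intestinal compartment downstream of stomach")
        return self

    def __getitem__(self, name: CompartmentName | str) -> Compartment:
        name = CompartmentName(name)
        for c in self.compartments:
            if c.name is name:
                return c
        raise KeyError(name)  # unreachable: order validator guarantees all nine

    @property
    def stomach(self) -> Compartment:
        return self.compartments[0]

    @property
    def gut(self) -> tuple[Compartment, ...]:
        """The eight post-stomach compartments (bypassed ones included)."""
        return self.compartments[1:]

    @property
    def has_bypassed(self) -> bool:
        return any(c.bypassed for c in self.compartments)

    def small_intestinal_length(self) -> float:
        """Total length (cm) of non-bypassed small-intestinal compartments."""
        return sum(c.length for c in self.compartments if c.name in SMALL_INTESTINE and not c.bypassed)

    def to_frame(self) -> pd.DataFrame:
        """Physiology table, one row per compartment (for reports/CSV export)."""
        return pd.DataFrame(
            [
                {
                    "compartment": c.name.value,
                    "pH": c.pH,
                    "transit_time_h": c.transit_time,
                    "volume_mL": c.volume,
                    "length_cm": c.length,
                    "asf": c.asf,
                    "bypassed": c.bypassed,
                }
                for c in self.compartments
            ]
        )


# Fasted-state defaults: (pH, transit time h, volume mL, length cm) per compartment.
_FASTED_TABLE: dict[CompartmentName, tuple[float, float, float, float]] = {
    CompartmentName.stomach: (1.3, 0.25, 50.00, 30.0),
    CompartmentName.duodenum: (6.00, 0.26, 48.25, 15.00),
    CompartmentName.jejunum1: (6.20, 0.95, 175.3, 62.00),
    CompartmentName.jejunum2: (6.40, 0.73, 139.90, 62.00),
    CompartmentName.ileum1: (6.60, 0.59, 108.5, 62.00),
    CompartmentName.ileum2: (6.90, 0.43, 79.48, 62.00),
    CompartmentName.ileum3: (7.40, 0.31, 56.29, 62.00),
    CompartmentName.caecum: (6.40, 4.50, 52.92, 13.75),
    CompartmentName.asc_colon: (6.80, 13.50, 56.98, 29.02),
}

# Post-RYGB stomach pouch: (pH, transit time h, volume mL, length cm).
_RYGB_STOMACH = (6.4, 0.12, 30.0, 18.0)

#: Compartments removed from the flow path by Roux-en-Y gastric bypass.
BYPASSED_BY_RYGB: tuple[CompartmentName, ...] = (
    CompartmentName.duodenum,
    CompartmentName.jejunum1,
)


def default_fasted_physiology() -> GutPhysiology:
    """Human fasted-state physiology with no bypassed compartments."""
    return GutPhysiology(
        compartments=tuple(
            Compartment(
                name=name,
                pH=pH,
                transit_time=tt,
                volume=vol,
                length=length,
            )
            for name, (pH, tt, vol, length) in _FASTED_TABLE.items()
        )
    )


def apply_rygb(physiology: GutPhysiology) -> GutPhysiology:
    """Transform a pre-surgical physiology into the post-RYGB state.

    The stomach becomes the small surgical pouch (higher pH from reduced acid
    secretion, faster emptying, smaller volume and length); the duodenum and
    proximal jejunum are marked bypassed with transit time, volume and length
    set to zero.  All other compartments are unchanged; neither transit time
    nor fluid is redistributed to the remaining segments.

    Raises
    ------
    PhysiologyError
        If the input already contains bypassed compartments.
    """
    if physiology.has_bypassed:
        raise PhysiologyError("physiology already contains bypassed compartments")
    pH, tt, vol, length = _RYGB_STOMACH
    new = []
    for c in physiology.compartments:
        if c.name is CompartmentName.stomach:
            new.append(
                Compartment(
                    name=c.name, pH=pH, transit_time=tt, volume=vol, length=length, asf=c.asf
                )
            )
        elif c.name in BYPASSED_BY_RYGB:
            new.append(
                Compartment(
                    name=c.name,
                    pH=c.pH,
                    transit_time=0.0,
                    volume=0.0,
                    length=0.0,
                    asf=c.asf,
                    bypassed=True,
                )
            )
        else:
            new.append(c)
    return GutPhysiology(compartments=tuple(new))
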