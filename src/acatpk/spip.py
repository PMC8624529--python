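"""Single-pass intestinal perfusion (SPIP) permeability estimation.

In the SPIP protocol an isolated rat intestinal segment is perfused at a
constant flow rate; after an equilibration hour, outlet samples are
collected every 10 minutes for a second hour.  The effective permeability
follows from the steady-state disappearance of drug along a cylindrical
segment:

    Peff = -Q * ln(C'out / C'in) / (2 * pi * R * L)

where Q is the volumetric flow (converted to cm^3/s), C'out/C'in the
outlet/inlet concentration ratio corrected for net water transport by the
gravimetric method, R the segment radius (cm) and L its length (cm).

Net water absorption concentrates the outlet stream, so the raw
concentration ratio is multiplied by the collected outlet/inlet fluid mass
ratio (perfusate density taken as 1 g/mL) before entering the log.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

#: mL/min -> cm^3/s
_ML_PER_MIN_TO_CM3_PER_S = 1.0 / 60.0

#: End of the equilibration phase (min); only later samples are steady state.
STEADY_STATE_START_MIN = 60.0


class Segment(str, Enum):
    """Perfused intestinal segments, proximal to distal."""

    jejunum = "jejunum"
    mid_SI = "mid_SI"
    ileum = "ileum"


class SpipError(ValueError):
    """Invalid perfusion data or estimation request."""


class PerfusionRecord(BaseModel):
    """One SPIP sampling interval.

    ``flow_rate`` mL/min, concentrations in µM, collected fluid masses in
    grams per interval, ``interval`` and ``time`` in minutes from perfusion
    start (``time`` marks the end of the collection interval).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    flow_rate: float = Field(gt=0.0)
    inlet_conc: float = Field(gt=0.0)
    outlet_conc: float = Field(ge=0.0)
    inlet_mass: float = Field(gt=0.0)
    outlet_mass: float = Field(gt=0.0)
    interval: float = Field(gt=0.0)
    segment: Segment
    pH: float
    time: float


@dataclass(frozen=True)
class PeffEstimate:
    """Mean effective permeability over a steady-state window."""

    peff: float  # cm/s
    segment: Segment
    n_samples: int
    cv: float  # coefficient of variation across per-sample values
    n_flagged: int = 0  # samples with corrected ratio > 1 (negative Peff)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SpipError("estimate requires at least one sample")
        if self.cv < 0.0:
            raise SpipError("cv must be non-negative")


def water_flux_correct(record: PerfusionRecord) -> float:
    """Gravimetrically corrected outlet/inlet concentration ratio.

    Returns ``(Cout/Cin) * (outlet_mass/inlet_mass)``: net water absorption
    (outlet mass below inlet mass) deflates an outlet concentration inflated
    by solvent loss; equal masses leave the raw ratio unchanged.
    """
    if record.inlet_mass <= 0.0:  # unreachable through the validated model
        raise SpipError("inlet mass must be positive")
    return (record.outlet_conc / record.inlet_conc) * (record.outlet_mass / record.inlet_mass)


def steady_state_window(records: list[PerfusionRecord]) -> list[PerfusionRecord]:
    """Keep only samples collected after the equilibration hour (time > 60 min).

    A protocol-conforming two-hour run at 10-min sampling retains six
    samples.
    """
    window = [r for r in records if r.time > STEADY_STATE_START_MIN]
    if not window:
        raise SpipError(
            f"no steady-state samples: all {len(records)} records at time <= "
            f"{STEADY_STATE_START_MIN} min"
        )
    return window


def estimate_peff(window: list[PerfusionRecord], radius: float, length: float) -> PeffEstimate:
    """Per-sample effective permeability, averaged over a steady-state window.

    Each record yields ``-Q * ln(corrected ratio) / (2*pi*R*L)`` in cm/s;
    the estimate is the arithmetic mean with the between-sample coefficient
    of variation.  A corrected ratio above 1 (net secretion artifact) gives
    a negative per-sample value that is retained and flagged with a warning
    rather than clamped — visible data problems beat silent clipping.

    Raises
    ------
    SpipError
        On an empty window, mixed segments, non-positive geometry, or a
        corrected ratio <= 0 (the log is undefined).
    """
    if not window:
        raise SpipError("empty steady-state window")
    if radius <= 0.0 or length <= 0.0:
        raise SpipError(f"segment geometry must be positive (R={radius}, L={length})")
    segments = {r.segment for r in window}
    if len(segments) > 1:
        raise SpipError(f"mixed segments in window: {sorted(s.value for s in segments)}")

    area = 2.0 * math.pi * radius * length  # cm^2
    values = []
    n_flagged = 0
    for r in window:
        ratio = water_flux_correct(r)
        if ratio <= 0.0:
            raise SpipError(f"corrected outlet/inlet ratio {ratio} <= 0 at time {r.time} min")
        q = r.flow_rate * _ML_PER_MIN_TO_CM3_PER_S
        peff = -q * math.log(ratio) / area
        if ratio > 1.0:
            n_flagged += 1
            warnings.warn(
                f"corrected ratio {ratio:.4f} > 1 at time {r.time} min yields negative "
                "permeability; sample retained",
                stacklevel=2,
            )
        values.append(peff)

    arr = np.asarray(values)
    mean = float(arr.mean())
    if len(arr) > 1 and mean != 0.0:
        cv = float(arr.std(ddof=1) / abs(mean))
    else:
        cv = 0.0
    return PeffEstimate(
        peff=mean, segment=window[0].segment, n_samples=len(arr), cv=cv, n_flagged=n_flagged
    )


def classify_permeability(peff_drug: float, peff_boundary: float) -> str:
    """BCS-style class call against a supplied boundary marker.

    The jejunal permeability of metoprolol serves as the low/high boundary;
    a drug at or above it is "high", below it "low".  The boundary is always
    an input, never hard-coded.
    """
    if peff_drug < 0.0 or peff_boundary < 0.0:
        raise SpipError("permeabilities must be non-negative for classification")
    return "high" if peff_drug >= peff_boundary else "low"


_CSV_COLUMNS = [
    "flow_rate",
    "inlet_conc",
    "outlet_conc",
    "inlet_mass",
    "outlet_mass",
    "interval",
    "segment",
    "pH",
    "time",
]


def read_perfusion_csv(path) -> list[PerfusionRecord]:
    """Load perfusion records from a CSV with one row per sampling interval."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SpipError(f"perfusion CSV missing columns: {missing}")
    return [PerfusionRecord(**{c: row[c] for c in _CSV_COLUMNS}) for _, row in df.iterrows()]


def write_perfusion_csv(records: list[PerfusionRecord], path) -> None:
    """Write perfusion records to CSV in the schema ``read_perfusion_csv`` reads."""
    df = pd.DataFrame([{**r.model_dump(), "segment": r.segment.value} for r in records])
    df[_CSV_COLUMNS].to_csv(path, index=False)
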