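"""Synthetic perfusion series and noisy plasma profiles for end-to-end testing.

The published perfusion measurements and observed plasma curves exist only
as figures, so these generators produce data with the statistical structure
the estimators assume:

* ``synth_spip`` inverts the steady-state disappearance relation — outlet
  concentration ``Cin * exp(-2*pi*R*L*Peff/Q)``, concentrated by net water
  absorption and perturbed by multiplicative lognormal assay noise — at the
  protocol's sampling grid (every 10 min through the post-equilibration
  hour).
* ``synth_plasma`` runs a named scenario and samples its plasma profile at
  requested times under the same multiplicative noise model.

Noise is multiplicative lognormal because concentrations are positive and
assay variability is relative; the lognormal is mean-one so the noisy
samples are unbiased.  Net water flux is constant within a run (steady
state).  The generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .scenarios import ScenarioName, build_scenario
from .spip import PerfusionRecord, Segment

#: Default segment pH used for generated jejunal perfusions.
_SEGMENT_PH = {Segment.jejunum: 6.5, Segment.mid_SI: 7.0, Segment.ileum: 7.5}


class SpipSimSpec(BaseModel):
    """Parameters of a synthetic single-pass perfusion experiment.

    Defaults follow the perfusion protocol: 0.2 mL/min flow, 50 µM inlet,
    0.2 cm radius, 10 cm segment, six 10-min steady-state samples.
    ``net_water_flux`` is the fraction of inlet fluid mass absorbed per
    interval (positive = net water absorption); ``noise_cv`` is the relative
    assay noise per sample (default 10%, a realistic combined assay and
    biological variability).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    true_peff: float = Field(ge=0.0)  # cm/s
    Q: float = Field(default=0.2, gt=0.0)  # mL/min
    Cin: float = Field(default=50.0, gt=0.0)  # µM
    R: float = Field(default=0.2, gt=0.0)  # cm
    L: float = Field(default=10.0, gt=0.0)  # cm
    n_samples: int = Field(default=6, ge=1)
    noise_cv: float = Field(default=0.10, ge=0.0)
    net_water_flux: float = Field(default=0.02, gt=-1.0, lt=1.0)
    segment: Segment = Segment.jejunum
    seed: int = 0


class PlasmaSimSpec(BaseModel):
    """Parameters of a synthetic observed-style plasma profile."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    scenario: ScenarioName = ScenarioName.control_obese
    multiplier: float = Field(default=1.0, gt=0.0)
    noise_cv: float = Field(default=0.10, ge=0.0)
    sampling_times: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    seed: int = 0

    @model_validator(mode="after")
    def _times_ok(self) -> "PlasmaSimSpec":
        if any(t < 0.0 for t in self.sampling_times):
            raise ValueError("sampling times must be non-negative")
        return self


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def synth_spip(spec: SpipSimSpec) -> list[PerfusionRecord]:
    """Generate steady-state perfusion records with a known true permeability.

    Samples sit at 10-min spacing starting t = 70 min (the first collection
    after the equilibration hour).  The noiseless corrected outlet/inlet
    ratio is exactly ``exp(-2*pi*R*L*Peff/Q)``: water absorption raises the
    outlet concentration by 1/(1 - flux) while the collected outlet mass
    drops by (1 - flux), so the gravimetric correction recovers the clean
    ratio.
    """
    rng = np.random.default_rng(spec.seed)
    q_cm3_s = spec.Q / 60.0
    ratio_true = math.exp(-2.0 * math.pi * spec.R * spec.L * spec.true_peff / q_cm3_s)
    interval = 10.0  # min
    inlet_mass = spec.Q * interval  # g at density 1 g/mL
    outlet_mass = inlet_mass * (1.0 - spec.net_water_flux)
    cout_clean = spec.Cin * ratio_true / (1.0 - spec.net_water_flux)
    noise = _lognormal_noise(rng, spec.noise_cv, spec.n_samples)
    return [
        PerfusionRecord(
            flow_rate=spec.Q,
            inlet_conc=spec.Cin,
            outlet_conc=cout_clean * noise[i],
            inlet_mass=inlet_mass,
            outlet_mass=outlet_mass,
            interval=interval,
            segment=spec.segment,
            pH=_SEGMENT_PH[spec.segment],
            time=70.0 + interval * i,
        )
        for i in range(spec.n_samples)
    ]


def synth_plasma(spec: PlasmaSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample a scenario's plasma profile at given times under assay noise.

    Returns ``(times, concentrations)`` arrays; with ``noise_cv = 0`` the
    concentrations equal the simulator output interpolated at the sampling
    times.
    """
    rng = np.random.default_rng(spec.seed)
    scenario = build_scenario(spec.scenario, multiplier=spec.multiplier)
    result, _ = scenario.run()
    times = np.asarray(spec.sampling_times, dtype=float)
    if times.size and times.max() > result.time[-1]:
        raise ValueError(
            f"sampling time {times.max()} h beyond simulation horizon {result.time[-1]} h"
        )
    clean = np.interp(times, result.time, result.plasma_conc)
    return times, clean * _lognormal_noise(rng, spec.noise_cv, times.size)
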