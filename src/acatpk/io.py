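"""Configuration loading/validation, tabular writers and run manifests.

A scenario lives in a YAML file with one block each for subject dosing,
disposition, permeability and simulation settings, and a physiology that is
either one of the packaged states (``default`` fasted, ``rygb``) or a full
inline compartment table.  Validation is strict: unknown keys are rejected
and every violation is reported with its field path.  Units are fixed
package-wide (hours, mL, cm, cm/s, ng/mL) and suffixed in column names.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .compound import PKParameters, metformin_profile
from .physiology import (
    Compartment,
    GutPhysiology,
    apply_rygb,
    default_fasted_physiology,
)
from .pk_metrics import PKMetrics
from .scenarios import PermeabilitySpec, Scenario, ScenarioName
from .simulator import SimulationResult, SimulationSettings, regional_absorption


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


class PKBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    body_weight_kg: float = Field(gt=0.0)
    renal_clearance_L_per_h_per_kg: float = Field(gt=0.0)
    volume_of_distribution_L_per_kg: float = Field(gt=0.0)


class PermeabilityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    base_peff_cm_per_s: float = Field(default=1.0e-4, ge=0.0)
    multiplier: float = Field(default=1.0, ge=0.0)
    uniform: bool = True
    colon_factor: float = Field(default=0.1, ge=0.0, le=1.0)
    segment_ratios: dict[str, float] | None = None


class SettingsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    t_end_h: float = Field(default=96.0, gt=0.0)
    output_step_h: float = Field(default=0.05, gt=0.0)
    rtol: float = Field(default=1e-9, gt=0.0)
    atol: float = Field(default=1e-9, gt=0.0)
    colonic_asf: float = Field(default=0.1, ge=0.0)


class ScenarioConfig(BaseModel):
    """Validated top-level scenario configuration."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: ScenarioName
    dose_mg: float = Field(gt=0.0)
    water_mL: float = Field(default=250.0, gt=0.0)
    pk: PKBlock
    permeability: PermeabilityBlock = PermeabilityBlock()
    physiology: str | list[dict] = "default"
    settings: SettingsBlock = SettingsBlock()

    def build_physiology(self) -> GutPhysiology:
        if isinstance(self.physiology, str):
            if self.physiology == "default":
                return default_fasted_physiology()
            if self.physiology == "rygb":
                return apply_rygb(default_fasted_physiology())
            raise ConfigError(
                f"physiology must be 'default', 'rygb' or an inline table, got "
                f"{self.physiology!r}"
            )
        try:
            return GutPhysiology(compartments=tuple(Compartment(**b) for b in self.physiology))
        except ValidationError as exc:
            raise ConfigError(_format_validation_error(exc)) from exc

    def to_scenario(self) -> Scenario:
        kwargs = {
            "base_peff": self.permeability.base_peff_cm_per_s,
            "multiplier": self.permeability.multiplier,
            "uniform": self.permeability.uniform,
            "colon_factor": self.permeability.colon_factor,
        }
        if self.permeability.segment_ratios is not None:
            kwargs["segment_ratios"] = self.permeability.segment_ratios
        return Scenario(
            name=self.name,
            physiology=self.build_physiology(),
            perm_spec=PermeabilitySpec(**kwargs),
            compound=metformin_profile(dose=self.dose_mg, water_coadministered=self.water_mL),
            pk=PKParameters(
                body_weight=self.pk.body_weight_kg,
                renal_clearance=self.pk.renal_clearance_L_per_h_per_kg,
                volume_of_distribution=self.pk.volume_of_distribution_L_per_kg,
            ),
            settings=SimulationSettings(
                t_end=self.settings.t_end_h,
                output_step=self.settings.output_step_h,
                rtol=self.settings.rtol,
                atol=self.settings.atol,
                colonic_asf=self.settings.colonic_asf,
            ),
        )


def _format_validation_error(exc: ValidationError) -> str:
    lines = [f"{len(exc.errors())} configuration error(s):"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file.

    Raises ``FileNotFoundError`` for a missing file and ``ConfigError``
    (listing every offending field) for schema violations or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError(f"configuration file is empty: {path}")
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    try:
        return ScenarioConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    data = config.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def packaged_config(name: ScenarioName | str) -> ScenarioConfig:
    """One of the four scenario configurations shipped with the package."""
    name = ScenarioName(name)
    text = resources.files("acatpk.configs").joinpath(f"{name.value}.yaml").read_text()
    return ScenarioConfig(**yaml.safe_load(text))


def save_physiology_yaml(physiology: GutPhysiology, path: str | Path) -> None:
    blocks = [
        {**c.model_dump(mode="json"), "name": c.name.value} for c in physiology.compartments
    ]
    Path(path).write_text(yaml.safe_dump({"compartments": blocks}, sort_keys=False))


def load_physiology_yaml(path: str | Path) -> GutPhysiology:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "compartments" not in raw:
        raise ConfigError(f"physiology file must contain a 'compartments' list: {path}")
    try:
        return GutPhysiology(compartments=tuple(Compartment(**b) for b in raw["compartments"]))
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_outputs(
    result: SimulationResult,
    metrics: PKMetrics,
    outdir: str | Path,
    config_digest: str = "",
    scenario_name: str = "",
) -> dict[str, Path]:
    """Write the standard output file set for one run.

    Produces ``plasma_profile.csv`` (time_h, conc_ng_per_mL),
    ``regional_absorption.csv``, ``metrics.json`` and ``manifest.json`` (the
    input hash, package version and the run's mass-balance residual) under
    ``outdir``.  Deterministic: identical inputs give identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "profile": outdir / "plasma_profile.csv",
        "regional": outdir / "regional_absorption.csv",
        "metrics": outdir / "metrics.json",
        "manifest": outdir / "manifest.json",
    }
    result.profile_frame().to_csv(files["profile"], index=False, float_format="%.8g")
    regional_absorption(result).rename_axis("compartment").reset_index().to_csv(
        files["regional"], index=False, float_format="%.8g"
    )
    files["metrics"].write_text(
        json.dumps({"scenario": scenario_name, **metrics.as_dict()}, indent=2) + "\n"
    )
    files["manifest"].write_text(
        json.dumps(
            {
                "package": "acatpk",
                "version": __version__,
                "scenario": scenario_name,
                "config_sha256": config_digest,
                "dose_mg": result.dose,
                "mass_balance_residual": result.mass_balance_residual,
                "n_time_points": int(len(result.time)),
            },
            indent=2,
        )
        + "\n"
    )
    return files
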