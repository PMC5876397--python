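"""Domain types, unit conventions and validation for Transwell translocation assays.

All mass-balance computations in this package use a single internal unit
system: lengths in cm, volumes in cm³ (≡ ml), masses in mg, times in
seconds.  Permeabilities are therefore natively cm s⁻¹.  The interface
accepts the units an experimentalist records — hours for sampling times,
ml/µl for volumes, mg ml⁻¹ for concentrations — and converts exactly once,
at construction or I/O time.
"""

from __future__ import annotations

import enum
import json
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "DomainError",
    "ConfigError",
    "ParseError",
    "Condition",
    "Regime",
    "InsertGeometry",
    "SamplingSchedule",
    "DoseSpec",
    "TranslocationSeries",
    "TEERRecord",
    "ParticleSpec",
    "ExperimentConfig",
    "validate_series",
    "seeding_density",
    "blank_subtract",
    "hours_to_seconds",
    "seconds_to_hours",
    "microliters_to_ml",
    "ml_to_microliters",
    "load_config",
    "save_config",
]

SECONDS_PER_HOUR = 3600.0


class DomainError(ValueError):
    """A physically meaningless argument (negative volume, zero dose, ...)."""


class ConfigError(ValueError):
    """A malformed or inconsistent experiment configuration."""


class ParseError(ValueError):
    """A malformed readings file; the message names the offending cell/line."""


def hours_to_seconds(t_h: float) -> float:
    return t_h * SECONDS_PER_HOUR


def seconds_to_hours(t_s: float) -> float:
    return t_s / SECONDS_PER_HOUR


def microliters_to_ml(v_ul: float) -> float:
    return v_ul * 1e-3


def ml_to_microliters(v_ml: float) -> float:
    return v_ml * 1e3


class Condition(str, enum.Enum):
    """Barrier condition on the insert membrane."""

    CONTROL = "control"  # blank (cell-free) membrane
    BEWO = "bewo"  # trophoblast monolayer, apical side
    HPEC = "hpec"  # placental endothelial monolayer, basolateral side
    COCULTURE = "coculture"  # BeWo apical + HPEC basolateral


class Regime(str, enum.Enum):
    """Exposure regime during the translocation run."""

    STATIC = "static"
    SHAKEN = "shaken"


@dataclass(frozen=True)
class InsertGeometry:
    """Physical frame of a Transwell insert.

    Defaults are the 12-well polycarbonate insert used throughout:
    growth area 1.12 cm², apical volume 0.5 ml, basolateral volume 1.5 ml,
    3.0 µm pores.  The pore size is informational only; it enters no
    mass-balance equation.
    """

    membrane_area_cm2: float = 1.12
    apical_volume_ml: float = 0.5
    basolateral_volume_ml: float = 1.5
    pore_size_um: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "membrane_area_cm2",
            "apical_volume_ml",
            "basolateral_volume_ml",
            "pore_size_um",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"InsertGeometry.{name} must be > 0")

    @classmethod
    def transwell_12mm(cls) -> "InsertGeometry":
        """The default 12 mm insert profile."""
        return cls()


@dataclass(frozen=True)
class SamplingSchedule:
    """Scheduled basolateral draws: timepoints (h) and draw volume (ml).

    Each draw is withdrawn from the basolateral chamber and replaced with
    an equal volume of fresh (analyte-free) medium, so chamber volumes stay
    constant while mass leaves the system.  ``sample_volume_ml == 0`` is
    permitted for event-free simulation; :func:`validate_series` flags it
    for experimental series.
    """

    times_h: tuple[float, ...]
    sample_volume_ml: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", tuple(float(t) for t in self.times_h))
        if len(self.times_h) == 0:
            raise DomainError("SamplingSchedule.times_h must be non-empty")
        if self.times_h[0] < 0:
            raise DomainError("SamplingSchedule times must start at t >= 0")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise DomainError("SamplingSchedule times must be strictly increasing")
        if self.sample_volume_ml < 0:
            raise DomainError("SamplingSchedule.sample_volume_ml must be >= 0")

    @property
    def times_s(self) -> tuple[float, ...]:
        return tuple(hours_to_seconds(t) for t in self.times_h)

    def index_of(self, time_h: float, *, atol: float = 1e-9) -> int:
        for i, t in enumerate(self.times_h):
            if math.isclose(t, time_h, rel_tol=0.0, abs_tol=atol):
                return i
        raise KeyError(f"timepoint {time_h} h not in schedule {self.times_h}")

    @classmethod
    def fluorescence_24h(cls) -> "SamplingSchedule":
        """0/0.25/2/4/6/8/24 h, 50 µl draws (plate-reader compounds)."""
        return cls((0.0, 0.25, 2.0, 4.0, 6.0, 8.0, 24.0), 0.05)

    @classmethod
    def hplc_6h(cls) -> "SamplingSchedule":
        """0/0.25/1/2/6 h, 200 µl draws (HPLC compounds)."""
        return cls((0.0, 0.25, 1.0, 2.0, 6.0), 0.2)


@dataclass(frozen=True)
class DoseSpec:
    """Apical dose: C₀ (mg cm⁻³) and the initial dose ID = C₀ · V_apical (mg)."""

    initial_concentration_mg_ml: float
    initial_dose_mg: float
    compound: str = ""

    def __post_init__(self) -> None:
        if not self.initial_concentration_mg_ml > 0:
            raise DomainError("DoseSpec.initial_concentration_mg_ml must be > 0")
        if not self.initial_dose_mg > 0:
            raise DomainError("DoseSpec.initial_dose_mg must be > 0")

    @classmethod
    def from_concentration(
        cls,
        concentration_mg_ml: float,
        geometry: InsertGeometry,
        compound: str = "",
    ) -> "DoseSpec":
        return cls(
            initial_concentration_mg_ml=concentration_mg_ml,
            initial_dose_mg=concentration_mg_ml * geometry.apical_volume_ml,
            compound=compound,
        )


@dataclass(frozen=True)
class TranslocationSeries:
    """One insert's basolateral concentration time course plus metadata.

    ``concentrations_mg_ml`` are aligned to ``schedule.times_h``.  Readings
    below the limit of detection are stored as 0 with the matching
    ``below_lod`` flag set, so downstream math never sees censored values.
    """

    geometry: InsertGeometry
    schedule: SamplingSchedule
    dose: DoseSpec
    concentrations_mg_ml: tuple[float, ...]
    condition: Condition
    regime: Regime
    replicate_id: str
    below_lod: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "concentrations_mg_ml",
            tuple(float(c) for c in self.concentrations_mg_ml),
        )
        if not self.below_lod:
            object.__setattr__(
                self, "below_lod", tuple(False for _ in self.concentrations_mg_ml)
            )
        else:
            object.__setattr__(self, "below_lod", tuple(bool(b) for b in self.below_lod))
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))
        if not isinstance(self.regime, Regime):
            object.__setattr__(self, "regime", Regime(self.regime))

    @property
    def final_time_h(self) -> float:
        return self.schedule.times_h[-1]


@dataclass(frozen=True)
class TEERRecord:
    """Paired total/blank electrical resistance reading for one insert (Ω)."""

    total_resistance_ohm: float
    blank_resistance_ohm: float
    membrane_area_cm2: float = 1.12

    def __post_init__(self) -> None:
        for name in ("total_resistance_ohm", "blank_resistance_ohm", "membrane_area_cm2"):
            if not getattr(self, name) > 0:
                raise DomainError(f"TEERRecord.{name} must be > 0")


@dataclass(frozen=True)
class ParticleSpec:
    """Monodisperse spherical particle: nominal diameter, density, mass dose."""

    diameter_nm: float
    density_g_cm3: float
    mass_concentration_mg_ml: float

    def __post_init__(self) -> None:
        for name in ("diameter_nm", "density_g_cm3", "mass_concentration_mg_ml"):
            if not getattr(self, name) > 0:
                raise DomainError(f"ParticleSpec.{name} must be > 0")


def validate_series(series: TranslocationSeries) -> list[str]:
    """Check a series against the assay's structural rules.

    Returns a list of human-readable findings; an empty list means the
    series is well-formed.  Nothing is raised: callers decide whether a
    finding is fatal.
    """
    findings: list[str] = []
    sched = series.schedule
    geom = series.geometry

    if len(series.concentrations_mg_ml) != len(sched.times_h):
        findings.append(
            "concentrations: length "
            f"{len(series.concentrations_mg_ml)} does not match schedule "
            f"({len(sched.times_h)} timepoints)"
        )
    if len(series.below_lod) != len(series.concentrations_mg_ml):
        findings.append("below_lod: length does not match concentrations")
    if any(b <= a for a, b in zip(sched.times_h, sched.times_h[1:])):
        findings.append("schedule.times_h: times not strictly increasing")
    if sched.times_h and sched.times_h[0] < 0:
        findings.append("schedule.times_h: first time is negative")
    if sched.sample_volume_ml <= 0:
        findings.append("schedule.sample_volume_ml: sample volume must be positive")
    if sched.sample_volume_ml >= geom.basolateral_volume_ml:
        findings.append("schedule.sample_volume_ml: sample volume exceeds chamber")
    for i, (c, flag) in enumerate(zip(series.concentrations_mg_ml, series.below_lod)):
        if c < 0 and not flag:
            findings.append(
                f"concentrations[{i}]: negative reading not flagged below_lod"
            )
    expected_id = series.dose.initial_concentration_mg_ml * geom.apical_volume_ml
    if not math.isclose(series.dose.initial_dose_mg, expected_id, rel_tol=1e-9):
        findings.append(
            "dose.initial_dose_mg: inconsistent with C0 × apical volume "
            f"({series.dose.initial_dose_mg} vs {expected_id})"
        )
    return findings


def seeding_density(cell_count: float, area_cm2: float) -> float:
    """Cells per cm² for a given seeding number and membrane growth area."""
    if not cell_count > 0 or not area_cm2 > 0:
        raise DomainError("cell_count and area_cm2 must be > 0")
    return cell_count / area_cm2


def blank_subtract(series: TranslocationSeries) -> TranslocationSeries:
    """Subtract the pre-dose (t = 0) basolateral reading from every timepoint.

    The t = 0 draw is taken before any analyte can have crossed, so a
    nonzero reading there measures medium background (autofluorescence,
    carry-over).  Differences are floored at zero.  A series whose schedule
    does not start at t = 0 is returned unchanged.
    """
    if not math.isclose(series.schedule.times_h[0], 0.0, abs_tol=1e-12):
        return series
    c0 = series.concentrations_mg_ml[0]
    if c0 == 0.0:
        return series
    corrected = tuple(max(0.0, c - c0) for c in series.concentrations_mg_ml)
    return replace(series, concentrations_mg_ml=corrected)


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

_OPTION_DEFAULTS: dict[str, Any] = {
    "blank_subtract": True,
    "pe_reference_time_h": 2.0,
    "pm_mode": "pooled",  # or "per_replicate"
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Single source of truth for geometry, schedules, doses, LODs and options.

    ``schedules`` / ``doses`` are keyed by compound label; ``lod_mg_ml``
    gives the per-compound limit of detection (readings at or below it are
    zeroed and flagged); ``calibration`` maps an instrument unit to mg ml⁻¹
    via a linear coefficient (reading × coefficient = concentration).
    """

    geometry: InsertGeometry
    schedules: Mapping[str, SamplingSchedule]
    doses: Mapping[str, DoseSpec]
    lod_mg_ml: Mapping[str, float] = field(default_factory=dict)
    calibration_mg_ml_per_unit: Mapping[str, float] = field(default_factory=dict)
    blank_subtract: bool = True
    pe_reference_time_h: float = 2.0
    pm_mode: str = "pooled"

    def __post_init__(self) -> None:
        if self.pm_mode not in ("pooled", "per_replicate"):
            raise ConfigError(f"unknown pm_mode {self.pm_mode!r}")
        missing = set(self.doses) - set(self.schedules)
        if missing:
            raise ConfigError(f"doses without a schedule: {sorted(missing)}")
        for compound, lod in self.lod_mg_ml.items():
            if lod < 0:
                raise ConfigError(f"lod[{compound}] must be >= 0")

    def compounds(self) -> list[str]:
        return sorted(self.doses)


def _reject_unknown(table: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{where}]: {sorted(unknown)}")


def _config_from_mapping(data: Mapping[str, Any]) -> ExperimentConfig:
    _reject_unknown(
        data,
        {"geometry", "schedule", "dose", "lod", "calibration", "options"},
        "<root>",
    )
    geom_tbl = dict(data.get("geometry", {}))
    _reject_unknown(
        geom_tbl,
        {"membrane_area_cm2", "apical_volume_ml", "basolateral_volume_ml", "pore_size_um"},
        "geometry",
    )
    geometry = InsertGeometry(**geom_tbl)

    schedules: dict[str, SamplingSchedule] = {}
    for compound, tbl in dict(data.get("schedule", {})).items():
        _reject_unknown(dict(tbl), {"times_h", "sample_volume_ml"}, f"schedule.{compound}")
        schedules[compound] = SamplingSchedule(
            tuple(tbl["times_h"]), float(tbl["sample_volume_ml"])
        )

    doses: dict[str, DoseSpec] = {}
    for compound, tbl in dict(data.get("dose", {})).items():
        _reject_unknown(dict(tbl), {"concentration_mg_ml"}, f"dose.{compound}")
        doses[compound] = DoseSpec.from_concentration(
            float(tbl["concentration_mg_ml"]), geometry, compound
        )

    lod = {k: float(v) for k, v in dict(data.get("lod", {})).items()}
    calibration = {k: float(v) for k, v in dict(data.get("calibration", {})).items()}

    options = dict(data.get("options", {}))
    _reject_unknown(options, set(_OPTION_DEFAULTS), "options")
    opts = {**_OPTION_DEFAULTS, **options}

    return ExperimentConfig(
        geometry=geometry,
        schedules=schedules,
        doses=doses,
        lod_mg_ml=lod,
        calibration_mg_ml_per_unit=calibration,
        blank_subtract=bool(opts["blank_subtract"]),
        pe_reference_time_h=float(opts["pe_reference_time_h"]),
        pm_mode=str(opts["pm_mode"]),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from TOML or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    try:
        return _config_from_mapping(data)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc


def config_to_mapping(config: ExperimentConfig) -> dict[str, Any]:
    g = config.geometry
    return {
        "geometry": {
            "membrane_area_cm2": g.membrane_area_cm2,
            "apical_volume_ml": g.apical_volume_ml,
            "basolateral_volume_ml": g.basolateral_volume_ml,
            "pore_size_um": g.pore_size_um,
        },
        "schedule": {
            c: {"times_h": list(s.times_h), "sample_volume_ml": s.sample_volume_ml}
            for c, s in sorted(config.schedules.items())
        },
        "dose": {
            c: {"concentration_mg_ml": d.initial_concentration_mg_ml}
            for c, d in sorted(config.doses.items())
        },
        "lod": dict(sorted(config.lod_mg_ml.items())),
        "calibration": dict(sorted(config.calibration_mg_ml_per_unit.items())),
        "options": {
            "blank_subtract": config.blank_subtract,
            "pe_reference_time_h": config.pe_reference_time_h,
            "pm_mode": config.pm_mode,
        },
    }


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write an experiment config as JSON (readable back by :func:`load_config`)."""
    path = Path(path)
    if path.suffix.lower() != ".json":
        raise ConfigError("configs are written as .json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config_to_mapping(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
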