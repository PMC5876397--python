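"""Translocation kinetics: cumulative transport, permeability, TEER, additivity.

The central quantity is the sampling-corrected cumulative transported mass

    ΔQₙ = Cₙ · V_w + Σ_{j<n} V_s · C_j                                  (mass)

where Cₙ is the basolateral concentration read at the n-th scheduled draw,
V_w the basolateral (well) volume and V_s the draw volume.  Because every
draw removes V_s·C_j of analyte and replaces it with fresh medium, the sum
restores the mass withdrawn at earlier draws; under sample-and-replace this
correction is exact, not approximate.

From ΔQ the permeability across membrane-plus-cells follows as the secant
slope from dosing,

    P = (ΔQ(t)/Δt) / (A · C₀)                                        (cm s⁻¹)

with Δt the elapsed seconds since dosing, A the membrane area and C₀ the
applied apical concentration (held constant in this formula; apical
depletion makes the secant an underestimate at high P, which the simulator
quantifies).  The cell-layer-only apparent permeability removes the blank
membrane in series:

    Pₑ = 1 / (1/P_c − 1/P_m),    P_c < P_m.

When noise pushes P_c to or above P_m the pole makes Pₑ meaningless; such
entries carry a not-computable marker (``None``) and the ``pe_undefined``
flag rather than an unphysical negative number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .core import (
    Condition,
    DomainError,
    DoseSpec,
    InsertGeometry,
    TEERRecord,
    TranslocationSeries,
    hours_to_seconds,
)

__all__ = [
    "PermeabilityResult",
    "TEERResult",
    "cumulative_mass",
    "percent_of_initial_dose",
    "equilibrium_fraction",
    "permeability",
    "apparent_permeability",
    "teer_normalized",
    "naf_exclusion_endpoint",
    "series_composition",
    "additivity_deviation",
    "analyze_series",
]

BELOW_LOD = "below_lod"
PE_UNDEFINED = "pe_undefined"
OVER_EQUILIBRIUM = "over_equilibrium"


@dataclass(frozen=True)
class PermeabilityResult:
    """Per-insert kinetic summary: ΔQ series, %ID, P(t) and optional Pₑ(t).

    ``pe_at_cm_s`` values are ``None`` where the series-resistance pole
    makes Pₑ not computable (P_c ≥ P_m).
    """

    series: TranslocationSeries
    cumulative_mass_mg: tuple[float, ...]
    percent_id: tuple[float, ...]
    p_at_cm_s: dict[float, float]
    pe_at_cm_s: dict[float, float | None] = field(default_factory=dict)
    flags: frozenset[str] = frozenset()


class TEERResult(NamedTuple):
    """Blank-subtracted, area-corrected resistance with a sign warning."""

    resistance_ohm_cm2: float
    negative: bool


def cumulative_mass(series: TranslocationSeries) -> np.ndarray:
    """ΔQₙ (mg) at every scheduled timepoint, corrected for earlier draws."""
    c = np.asarray(series.concentrations_mg_ml, dtype=float)
    if c.shape[0] != len(series.schedule.times_h):
        raise DomainError(
            f"series has {c.shape[0]} readings for "
            f"{len(series.schedule.times_h)} scheduled timepoints"
        )
    v_w = series.geometry.basolateral_volume_ml
    v_s = series.schedule.sample_volume_ml
    withdrawn_before = np.concatenate(([0.0], np.cumsum(c)[:-1])) * v_s
    return c * v_w + withdrawn_before


def percent_of_initial_dose(
    cumulative_mass_mg: Sequence[float], dose: DoseSpec
) -> np.ndarray:
    """Cumulative transport as % of the applied initial dose (ID = C₀·V_apical)."""
    if not dose.initial_dose_mg > 0:
        raise DomainError("initial dose must be > 0")
    return 100.0 * np.asarray(cumulative_mass_mg, dtype=float) / dose.initial_dose_mg


def equilibrium_fraction(geometry: InsertGeometry) -> float:
    """Fraction of the ID in the basolateral chamber at diffusive equilibrium.

    A passively equilibrating system splits mass in proportion to chamber
    volumes: V_b/(V_a+V_b).  For the default insert (0.5/1.5 ml) this is
    0.75 — without sampling losses, at most 75% of the dose can ever appear
    basolaterally.
    """
    v_a = geometry.apical_volume_ml
    v_b = geometry.basolateral_volume_ml
    return v_b / (v_a + v_b)


def permeability(
    cumulative_mass_mg: Sequence[float],
    dose: DoseSpec,
    geometry: InsertGeometry,
    schedule_times_h: Sequence[float],
    at_time_h: float,
) -> float:
    """Secant permeability P (cm s⁻¹) at a scheduled timepoint.

    P = (ΔQ/Δt)/(A·C₀) with Δt the elapsed seconds since dosing.  The
    timepoint must be in the schedule and strictly positive.
    """
    times = tuple(float(t) for t in schedule_times_h)
    idx = None
    for i, t in enumerate(times):
        if math.isclose(t, at_time_h, rel_tol=0.0, abs_tol=1e-9):
            idx = i
            break
    if idx is None:
        raise KeyError(f"timepoint {at_time_h} h not in schedule {times}")
    if at_time_h <= 0:
        raise DomainError("permeability is undefined at t = 0 (Δt = 0)")
    dq = float(cumulative_mass_mg[idx])
    dt_s = hours_to_seconds(at_time_h)
    return (dq / dt_s) / (geometry.membrane_area_cm2 * dose.initial_concentration_mg_ml)


def apparent_permeability(p_c: float, p_m: float) -> float | None:
    """Membrane-corrected apparent permeability Pₑ = 1/(1/P_c − 1/P_m).

    Returns ``None`` (not computable) when P_c ≥ P_m: at the pole the
    measured barrier is no tighter than the blank membrane and the cell
    layer's resistance cannot be resolved.  P_c = 0 maps to Pₑ = 0.
    """
    if p_c < 0:
        raise DomainError("P_c must be >= 0")
    if not p_m > 0:
        raise DomainError("P_m must be > 0")
    if p_c == 0.0:
        return 0.0
    if p_c >= p_m:
        return None
    return 1.0 / (1.0 / p_c - 1.0 / p_m)


def teer_normalized(record: TEERRecord) -> TEERResult:
    """Blank-subtracted, area-corrected TEER: (R_total − R_blank) × A (Ω·cm²).

    A negative value (cells reading below the blank insert) is physically
    suspect but is returned as-is with ``negative=True``, never clamped.
    """
    value = (record.total_resistance_ohm - record.blank_resistance_ohm) * record.membrane_area_cm2
    return TEERResult(value, value < 0)


def naf_exclusion_endpoint(series: TranslocationSeries, at_time_h: float = 3.0) -> float:
    """Barrier-integrity endpoint: %ID found basolaterally at the 3 h draw.

    The exclusion assay takes a single draw, so the correction sum in ΔQ is
    empty and the endpoint reduces to 100·C(3h)·V_w/ID; the general
    formula is used so multi-draw schedules containing 3 h also work.
    """
    idx = series.schedule.index_of(at_time_h)  # KeyError if absent
    dq = cumulative_mass(series)
    return float(percent_of_initial_dose(dq, series.dose)[idx])


def series_composition(layer_permeabilities: Sequence[float]) -> float:
    """Combined permeability of layers in series: 1/P = Σ 1/Pᵢ."""
    ps = [float(p) for p in layer_permeabilities]
    if not ps:
        raise DomainError("at least one layer required")
    if any(p <= 0 for p in ps):
        raise DomainError("all layer permeabilities must be > 0")
    return 1.0 / sum(1.0 / p for p in ps)


def additivity_deviation(
    pe_combined: float, pe_layers: Sequence[float]
) -> float:
    """Observed/predicted series resistance for a multilayer barrier.

    Ratio = (1/Pₑ_combined) / Σ(1/Pₑᵢ).  1.0 means the layers act as
    perfectly additive resistances; < 1 means the combined barrier is
    leakier than their series prediction (e.g. a co-culture no tighter than
    its tightest single layer); > 1 means tighter than additive.
    """
    if not pe_combined > 0:
        raise DomainError("combined permeability must be > 0")
    predicted = series_composition(pe_layers)
    return predicted / pe_combined


def analyze_series(
    series: TranslocationSeries,
    p_membrane_cm_s: float | None = None,
    lod_mg_ml: float | None = None,
) -> PermeabilityResult:
    """Full per-insert kinetic work-up.

    Computes ΔQ and %ID at every timepoint and the secant P at every
    positive timepoint; if ``p_membrane_cm_s`` is given, the
    membrane-corrected Pₑ is computed alongside each P.  ``lod_mg_ml``
    marks the result ``below_lod`` when the final reading is censored.
    """
    dq = cumulative_mass(series)
    pct = percent_of_initial_dose(dq, series.dose)

    p_at: dict[float, float] = {}
    pe_at: dict[float, float | None] = {}
    flags: set[str] = set()
    for t in series.schedule.times_h:
        if t <= 0:
            continue
        p = permeability(dq, series.dose, series.geometry, series.schedule.times_h, t)
        p_at[t] = p
        if p_membrane_cm_s is not None:
            pe = apparent_permeability(max(p, 0.0), p_membrane_cm_s)
            pe_at[t] = pe
            if pe is None:
                flags.add(PE_UNDEFINED)

    final_below = (
        series.below_lod[-1]
        if series.below_lod
        else False
    )
    if lod_mg_ml is not None and (
        final_below or series.concentrations_mg_ml[-1] <= lod_mg_ml
    ):
        flags.add(BELOW_LOD)
    eq_pct = 100.0 * equilibrium_fraction(series.geometry)
    # Sampling losses legitimately push cumulative %ID past the no-sampling
    # equilibrium ceiling; flag only, never clip.
    if np.any(pct > eq_pct * (1.0 + 1e-9)):
        flags.add(OVER_EQUILIBRIUM)

    return PermeabilityResult(
        series=series,
        cumulative_mass_mg=tuple(float(x) for x in dq),
        percent_id=tuple(float(x) for x in pct),
        p_at_cm_s=p_at,
        pe_at_cm_s=pe_at,
        flags=frozenset(flags),
    )
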