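"""Two-compartment Transwell simulator with sample-and-replace events.

Ground-truth generator for every estimator in the package.  Between draws,
well-mixed two-compartment diffusion across a barrier of permeability P and
area A has the closed form

    M_b(t) = M_eq + (M_b(0) − M_eq) · exp(−P·A·(1/V_a + 1/V_b)·t),
    M_eq   = (M_a(0) + M_b(0)) · V_b / (V_a + V_b),

which the simulator advances exactly from event to event.  At each
scheduled draw the basolateral concentration is read, V_s·C of analyte is
withdrawn, and the volume is replaced with fresh (analyte-free) medium, so
volumes stay constant while mass leaves the system — precisely the
accounting that the ΔQ correction sum undoes.  Multi-layer barriers
(membrane, trophoblast, endothelium) combine as resistances in series.

Measurement noise is multiplicative Gaussian (CV × true value), truncated
at zero, applied to the *recorded* concentrations only; the returned truth
arrays stay noiseless so tests can hold estimators to exact tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    Condition,
    DomainError,
    DoseSpec,
    InsertGeometry,
    Regime,
    SamplingSchedule,
    TranslocationSeries,
    hours_to_seconds,
)
from .kinetics import series_composition

__all__ = [
    "BarrierModel",
    "SimConfig",
    "SimTruth",
    "StudyDesign",
    "CompoundDesign",
    "closed_form_basolateral_mass",
    "simulate_insert",
    "generate_study",
    "default_study_design",
    "CONDITION_LAYERS",
]

# Which physical layers each barrier condition stacks, in series.
CONDITION_LAYERS: dict[Condition, tuple[str, ...]] = {
    Condition.CONTROL: ("membrane",),
    Condition.BEWO: ("membrane", "bewo"),
    Condition.HPEC: ("membrane", "hpec"),
    Condition.COCULTURE: ("membrane", "bewo", "hpec"),
}


@dataclass(frozen=True)
class BarrierModel:
    """Stacked barrier layers, each a (label, permeability cm s⁻¹) pair."""

    layers: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise DomainError("BarrierModel needs at least one layer")
        if any(p <= 0 for _, p in self.layers):
            raise DomainError("all layer permeabilities must be > 0")

    @property
    def effective_permeability_cm_s(self) -> float:
        """Harmonic (series-resistance) composition of the layers."""
        return series_composition([p for _, p in self.layers])


@dataclass(frozen=True)
class SimConfig:
    """One simulated insert: physical frame, barrier, noise and identity."""

    geometry: InsertGeometry
    schedule: SamplingSchedule
    dose: DoseSpec
    barrier: BarrierModel
    noise_cv: float = 0.0
    n_replicates: int = 1
    rng_seed: int = 0
    condition: Condition = Condition.CONTROL
    regime: Regime = Regime.STATIC

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Noiseless per-event ground truth for one insert.

    ``net_transported_mass_mg[n]`` is the mass that has crossed the barrier
    by event n: basolateral content just before the draw plus everything
    withdrawn at earlier draws — the quantity ΔQₙ estimates.
    """

    times_h: tuple[float, ...]
    apical_mass_mg: tuple[float, ...]
    basolateral_mass_pre_sample_mg: tuple[float, ...]
    withdrawn_mass_mg: tuple[float, ...]
    net_transported_mass_mg: tuple[float, ...]


def closed_form_basolateral_mass(
    t_s: float,
    p_cm_s: float,
    geometry: InsertGeometry,
    m_apical0_mg: float,
    m_baso0_mg: float,
) -> float:
    """Exact basolateral mass after t seconds of event-free diffusion."""
    if t_s < 0:
        raise DomainError("t_s must be >= 0")
    if p_cm_s < 0:
        raise DomainError("p_cm_s must be >= 0")
    if p_cm_s == 0.0 or t_s == 0.0:
        return m_baso0_mg
    v_a = geometry.apical_volume_ml
    v_b = geometry.basolateral_volume_ml
    m_eq = (m_apical0_mg + m_baso0_mg) * v_b / (v_a + v_b)
    k = p_cm_s * geometry.membrane_area_cm2 * (1.0 / v_a + 1.0 / v_b)
    return m_eq + (m_baso0_mg - m_eq) * math.exp(-k * t_s)


def simulate_insert(
    config: SimConfig, replicate: int = 0, replicate_id: str | None = None
) -> tuple[TranslocationSeries, SimTruth]:
    """Simulate one insert through its sampling schedule.

    Event order at each scheduled timepoint: read the concentration
    (C = M_b/V_b, pre-replacement), withdraw V_s·C of analyte, refill with
    fresh medium.  Noise perturbs only the recorded reading.  Deterministic
    for a given (rng_seed, replicate) pair.
    """
    rng = np.random.default_rng([config.rng_seed, replicate])
    geom = config.geometry
    p_eff = config.barrier.effective_permeability_cm_s
    v_b = geom.basolateral_volume_ml
    v_s = config.schedule.sample_volume_ml

    m_a = config.dose.initial_dose_mg
    m_b = 0.0
    t_prev_s = 0.0

    times_h = config.schedule.times_h
    apical: list[float] = []
    baso_pre: list[float] = []
    withdrawn: list[float] = []
    net: list[float] = []
    recorded: list[float] = []

    cum_withdrawn = 0.0
    for t_h in times_h:
        t_s = hours_to_seconds(t_h)
        m_b_new = closed_form_basolateral_mass(t_s - t_prev_s, p_eff, geom, m_a, m_b)
        m_a -= m_b_new - m_b
        m_b = m_b_new
        t_prev_s = t_s

        c_true = m_b / v_b
        c_obs = c_true
        if config.noise_cv > 0:
            c_obs = max(0.0, c_true * (1.0 + config.noise_cv * rng.standard_normal()))
        drawn = v_s * c_true
        apical.append(m_a)
        baso_pre.append(m_b)
        net.append(m_b + cum_withdrawn)
        withdrawn.append(drawn)
        recorded.append(c_obs)

        m_b -= drawn  # refill volume is analyte-free; V_b unchanged
        cum_withdrawn += drawn

    series = TranslocationSeries(
        geometry=geom,
        schedule=config.schedule,
        dose=config.dose,
        concentrations_mg_ml=tuple(recorded),
        condition=config.condition,
        regime=config.regime,
        replicate_id=replicate_id or f"r{replicate + 1}",
    )
    truth = SimTruth(
        times_h=times_h,
        apical_mass_mg=tuple(apical),
        basolateral_mass_pre_sample_mg=tuple(baso_pre),
        withdrawn_mass_mg=tuple(withdrawn),
        net_transported_mass_mg=tuple(net),
    )
    return series, truth


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundDesign:
    """Per-compound study arm: dose, schedule, per-layer permeabilities, LOD."""

    concentration_mg_ml: float
    schedule: SamplingSchedule
    layer_p_cm_s: dict[str, float]  # keys: membrane, bewo, hpec
    lod_mg_ml: float = 0.0

    def barrier_for(self, condition: Condition, shaken_multiplier: float = 1.0) -> BarrierModel:
        layers = tuple(
            (name, self.layer_p_cm_s[name] * shaken_multiplier)
            for name in CONDITION_LAYERS[condition]
        )
        return BarrierModel(layers)


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial design: compounds × conditions × regimes × replicates."""

    geometry: InsertGeometry
    compounds: dict[str, CompoundDesign]
    conditions: tuple[Condition, ...] = tuple(Condition)
    regimes: tuple[Regime, ...] = (Regime.STATIC, Regime.SHAKEN)
    n_replicates: int = 4
    noise_cv: float = 0.1
    # Kinetic equivalence of static and shaken arms is the default (the
    # empirical null); set != 1 to impose a boundary-layer effect on the
    # shaken arm and break it.
    shaken_p_multiplier: float = 1.0

    def size(self) -> int:
        return (
            len(self.compounds)
            * len(self.conditions)
            * len(self.regimes)
            * self.n_replicates
        )


def default_study_design(
    noise_cv: float = 0.1, n_replicates: int = 4
) -> StudyDesign:
    """The emulated study design: 6 compounds × 4 barriers × 2 regimes.

    Doses are the applied concentrations (5 µM Na-F ≈ 1.88 µg/ml for
    MW 376, 5 µM 40 kDa FITC-dextran = 0.2 mg/ml, 100 µM antipyrine
    ≈ 18.8 µg/ml, 100 µM indomethacin ≈ 35.8 µg/ml, 0.5 mg/ml 49 nm PS NP,
    50 µg/ml 70 nm PS NP).  Layer permeabilities are design choices that
    reproduce the observed transport ordering — fast transcellular
    (antipyrine > indomethacin), size-dependent paracellular
    (Na-F ≫ FITC-dextran) and size-dependent particulate (49 nm ≫ 70 nm,
    the latter below detection across every cell layer); see the package
    methods note for the reasoning behind each value.
    """
    geometry = InsertGeometry.transwell_12mm()
    fluor = SamplingSchedule.fluorescence_24h()
    hplc = SamplingSchedule.hplc_6h()
    compounds = {
        "antipyrine": CompoundDesign(
            concentration_mg_ml=0.0188,
            schedule=hplc,
            layer_p_cm_s={"membrane": 1.5e-4, "bewo": 1.1e-4, "hpec": 8.5e-5},
            lod_mg_ml=1e-5,
        ),
        "indomethacin": CompoundDesign(
            concentration_mg_ml=0.0358,
            schedule=hplc,
            layer_p_cm_s={"membrane": 8.0e-5, "bewo": 4.0e-5, "hpec": 2.0e-5},
            lod_mg_ml=1e-5,
        ),
        "na_f": CompoundDesign(
            concentration_mg_ml=1.88e-3,
            schedule=fluor,
            layer_p_cm_s={"membrane": 6.0e-5, "bewo": 1.5e-6, "hpec": 9.0e-6},
            lod_mg_ml=1e-7,
        ),
        "fitc_dextran": CompoundDesign(
            concentration_mg_ml=0.2,
            schedule=fluor,
            layer_p_cm_s={"membrane": 3.0e-5, "bewo": 1.0e-9, "hpec": 3.5e-7},
            lod_mg_ml=1e-4,
        ),
        "ps_np_49nm": CompoundDesign(
            concentration_mg_ml=0.5,
            schedule=fluor,
            layer_p_cm_s={"membrane": 3.8e-6, "bewo": 5.0e-8, "hpec": 1.0e-7},
            lod_mg_ml=1e-5,
        ),
        "ps_np_70nm": CompoundDesign(
            concentration_mg_ml=0.05,
            schedule=fluor,
            layer_p_cm_s={"membrane": 1.2e-6, "bewo": 1.0e-9, "hpec": 1.5e-9},
            lod_mg_ml=1e-5,
        ),
    }
    return StudyDesign(
        geometry=geometry,
        compounds=compounds,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
    )


@dataclass(frozen=True)
class SimulatedInsert:
    """One generated insert with its compound label and ground truth."""

    compound: str
    series: TranslocationSeries
    truth: SimTruth


def generate_study(design: StudyDesign, seed: int = 0) -> list[SimulatedInsert]:
    """Generate the full synthetic study, deterministically for a given seed.

    Every (compound, condition, regime, replicate) cell gets its own
    deterministic RNG stream derived from the study seed and the cell's
    indices, so inserting or removing arms never reshuffles the noise of
    the others.
    """
    out: list[SimulatedInsert] = []
    for ci, (compound, cd) in enumerate(sorted(design.compounds.items())):
        dose = DoseSpec.from_concentration(cd.concentration_mg_ml, design.geometry, compound)
        for gi, condition in enumerate(design.conditions):
            for ri, regime in enumerate(design.regimes):
                mult = (
                    design.shaken_p_multiplier if regime is Regime.SHAKEN else 1.0
                )
                barrier = cd.barrier_for(condition, mult)
                for rep in range(design.n_replicates):
                    stream_seed = int(
                        np.random.SeedSequence([seed, ci, gi, ri, rep]).generate_state(1)[0]
                        % (2**31)
                    )
                    cfg = SimConfig(
                        geometry=design.geometry,
                        schedule=cd.schedule,
                        dose=dose,
                        barrier=barrier,
                        noise_cv=design.noise_cv,
                        rng_seed=stream_seed,
                        condition=condition,
                        regime=regime,
                    )
                    series, truth = simulate_insert(cfg, replicate=rep)
                    out.append(SimulatedInsert(compound=compound, series=series, truth=truth))
    return out
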