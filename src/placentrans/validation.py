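"""Self-validation experiments: parameter recovery, calibration, additivity.

These routines exercise the estimators against the simulator's ground
truth under the study's design (default insert geometry, scheduled draws,
multiplicative reading noise) and return the measured errors/rates.  They
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .core import DoseSpec, InsertGeometry, SamplingSchedule
from .kinetics import (
    apparent_permeability,
    cumulative_mass,
    permeability,
    series_composition,
)
from .stats import mann_whitney_exact
from .synthetic import BarrierModel, SimConfig, simulate_insert

__all__ = [
    "secant_recovery_errors",
    "noisy_pe_recovery",
    "type_i_error_rate",
    "additivity_ratio_noiseless",
]


def _estimate_p(
    barrier: BarrierModel,
    schedule: SamplingSchedule,
    dose: DoseSpec,
    geometry: InsertGeometry,
    at_time_h: float,
    noise_cv: float = 0.0,
    rng_seed: int = 0,
    replicate: int = 0,
) -> float:
    cfg = SimConfig(
        geometry=geometry,
        schedule=schedule,
        dose=dose,
        barrier=barrier,
        noise_cv=noise_cv,
        rng_seed=rng_seed,
    )
    series, _ = simulate_insert(cfg, replicate=replicate)
    return permeability(
        cumulative_mass(series), dose, geometry, schedule.times_h, at_time_h
    )


def secant_recovery_errors(
    p_values: tuple[float, ...] = (1e-7, 1e-6, 1e-5),
    at_time_h: float = 0.25,
) -> dict[float, float]:
    """Relative error of the noiseless earliest-secant P estimate per true P."""
    geometry = InsertGeometry.transwell_12mm()
    schedule = SamplingSchedule.fluorescence_24h()
    dose = DoseSpec.from_concentration(0.01, geometry, "probe")
    errors = {}
    for p_true in p_values:
        p_est = _estimate_p(
            BarrierModel((("layer", p_true),)), schedule, dose, geometry, at_time_h
        )
        errors[p_true] = abs(p_est - p_true) / p_true
    return errors


def noisy_pe_recovery(
    p_cell: float = 1e-5,
    p_membrane: float = 1e-4,
    n_studies: int = 500,
    n_replicates: int = 4,
    noise_cv: float = 0.1,
    at_time_h: float = 0.25,
    seed: int = 0,
) -> tuple[float, float]:
    """Median membrane-corrected Pₑ across simulated noisy studies.

    Each study simulates ``n_replicates`` cell-bearing and blank-membrane
    inserts with CV-``noise_cv`` reading noise, estimates per-replicate P_c
    against the pooled-median P_m, and takes the study median Pₑ.  Returns
    (median over studies, relative error vs the true cell permeability).
    """
    geometry = InsertGeometry.transwell_12mm()
    schedule = SamplingSchedule.fluorescence_24h()
    dose = DoseSpec.from_concentration(0.01, geometry, "probe")
    cell_barrier = BarrierModel((("membrane", p_membrane), ("cell", p_cell)))
    blank_barrier = BarrierModel((("membrane", p_membrane),))

    study_medians = []
    for study in range(n_studies):
        p_m = np.median(
            [
                _estimate_p(
                    blank_barrier, schedule, dose, geometry, at_time_h,
                    noise_cv=noise_cv, rng_seed=seed + 2 * study, replicate=rep,
                )
                for rep in range(n_replicates)
            ]
        )
        pes = []
        for rep in range(n_replicates):
            p_c = _estimate_p(
                cell_barrier, schedule, dose, geometry, at_time_h,
                noise_cv=noise_cv, rng_seed=seed + 2 * study + 1, replicate=rep,
            )
            pe = apparent_permeability(max(p_c, 0.0), float(p_m))
            if pe is not None:
                pes.append(pe)
        if pes:
            study_medians.append(float(np.median(pes)))
    median_pe = float(np.median(study_medians))
    return median_pe, abs(median_pe - p_cell) / p_cell


def type_i_error_rate(
    n_studies: int = 2000,
    n_replicates: int = 4,
    noise_cv: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Exact-test rejection rate for two arms drawn from identical kinetics."""
    geometry = InsertGeometry.transwell_12mm()
    schedule = SamplingSchedule.fluorescence_24h()
    dose = DoseSpec.from_concentration(0.01, geometry, "probe")
    barrier = BarrierModel((("membrane", 1e-5),))
    rejections = 0
    for study in range(n_studies):
        arms = []
        for arm in range(2):
            finals = []
            for rep in range(n_replicates):
                cfg = SimConfig(
                    geometry=geometry,
                    schedule=schedule,
                    dose=dose,
                    barrier=barrier,
                    noise_cv=noise_cv,
                    rng_seed=seed + 2 * study + arm,
                )
                series, _ = simulate_insert(cfg, replicate=rep)
                finals.append(cumulative_mass(series)[-1])
            arms.append(finals)
        if mann_whitney_exact(arms[0], arms[1]).p_two_sided < alpha - 1e-12:
            rejections += 1
    return rejections / n_studies


def additivity_ratio_noiseless(
    p_membrane: float = 1e-4,
    p_bewo: float = 3e-5,
    p_hpec: float = 5e-5,
    at_time_h: float = 0.25,
) -> float:
    """Observed/predicted series resistance for a truly additive co-culture.

    Simulates the blank membrane, the two monolayers and the co-culture
    noiselessly, pushes each through the estimator chain, and compares the
    recovered co-culture Pₑ against the series composition of the layer
    Pₑ's.  1.0 means the additivity diagnostic reads a built-to-be-additive
    barrier as additive.
    """
    from .kinetics import additivity_deviation

    geometry = InsertGeometry.transwell_12mm()
    schedule = SamplingSchedule.fluorescence_24h()
    dose = DoseSpec.from_concentration(0.01, geometry, "probe")

    def est(layers) -> float:
        return _estimate_p(BarrierModel(layers), schedule, dose, geometry, at_time_h)

    p_m = est((("membrane", p_membrane),))
    pe_bewo = apparent_permeability(est((("membrane", p_membrane), ("bewo", p_bewo))), p_m)
    pe_hpec = apparent_permeability(est((("membrane", p_membrane), ("hpec", p_hpec))), p_m)
    pe_co = apparent_permeability(
        est((("membrane", p_membrane), ("bewo", p_bewo), ("hpec", p_hpec))), p_m
    )
    return additivity_deviation(pe_co, [pe_bewo, pe_hpec])
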