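"""Nanoparticle dose metrics: mass → number concentration and applied dose.

A monodisperse spherical particle of nominal diameter d and bulk density ρ
has mass ρ·(π/6)·d³, so a suspension of mass concentration C contains

    N = C / (ρ · (π/6) · d³)        particles per ml.

Nominal (manufacturer) diameters are used for dosimetry rather than
hydrodynamic diameters: the hydrodynamic size includes solvent shell and
agglomerates and would misstate the particle count for a given mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DomainError, InsertGeometry, ParticleSpec

__all__ = [
    "ParticleDose",
    "sphere_mass_mg",
    "number_concentration",
    "particle_dose",
    "percent_id_to_particle_flux",
    "format_sigfig",
]

_CM_PER_NM = 1e-7
_MG_PER_G = 1e3


def sphere_mass_mg(diameter_nm: float, density_g_cm3: float) -> float:
    """Mass (mg) of one solid sphere of the given nominal diameter and density."""
    if not diameter_nm > 0 or not density_g_cm3 > 0:
        raise DomainError("diameter and density must be > 0")
    d_cm = diameter_nm * _CM_PER_NM
    return density_g_cm3 * (math.pi / 6.0) * d_cm**3 * _MG_PER_G


def number_concentration(spec: ParticleSpec) -> float:
    """Particles per ml for a monodisperse spherical suspension."""
    return spec.mass_concentration_mg_ml / sphere_mass_mg(
        spec.diameter_nm, spec.density_g_cm3
    )


@dataclass(frozen=True)
class ParticleDose:
    """Applied particle dose for one insert: number concentration and count."""

    spec: ParticleSpec
    number_concentration_per_ml: float
    total_particles_applied: float

    def __post_init__(self) -> None:
        if not self.number_concentration_per_ml > 0:
            raise DomainError("number_concentration_per_ml must be > 0")
        if not self.total_particles_applied > 0:
            raise DomainError("total_particles_applied must be > 0")


def particle_dose(spec: ParticleSpec, geometry: InsertGeometry) -> ParticleDose:
    """Dose bookkeeping: N per ml and total particles in the apical volume."""
    n = number_concentration(spec)
    return ParticleDose(
        spec=spec,
        number_concentration_per_ml=n,
        total_particles_applied=n * geometry.apical_volume_ml,
    )


def percent_id_to_particle_flux(percent_id: float, dose: ParticleDose) -> float:
    """Translate a %ID transport figure into an absolute particle count."""
    if percent_id < 0:
        raise DomainError("percent_id must be >= 0")
    return percent_id / 100.0 * dose.total_particles_applied


def format_sigfig(value: float, sig: int = 3) -> str:
    """Scientific notation at the reporting precision (default 3 sig figs)."""
    return f"{value:.{sig - 1}E}"
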