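"""Closed-form QCM-D acoustics for trace interpretation and simulation.

The module collects the small set of analytic relations the rest of the
package relies on:

* the shear-wave penetration depth ``δ_n = sqrt(η / (π n f0 ρ))``, which
  shrinks with overtone number so that low overtones probe deeper into a
  bacterial film than high ones (about 140 nm vs 70 nm for n = 3 and 11 on
  a 5 MHz sensor in water);
* the Sauerbrey relation ``Δm = −C Δf_n / n`` for rigidly coupled mass;
* a phenomenological dissipation kernel mapping an effective film state
  (thickness, softness, coverage) to per-overtone ΔD via the sensed-depth
  saturation ``δ_n (1 − exp(−h/δ_n))``.  This is a deliberately simple
  surrogate for full continuum viscoelastic (Voigt-type) modelling: it
  reproduces the qualitative overtone ordering and the growth of the
  overtone spread with film thickness in closed form;
* a frequency kernel combining a Sauerbrey term for rigid load (adsorbed
  phage) with a signed, coverage-proportional coupled-resonance term for
  adhering bacteria, which can push Δf positive on some sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "LiquidProperties",
    "FilmState",
    "WATER_25C",
    "WATER_37C",
    "QUARTZ_DENSITY",
    "QUARTZ_SHEAR_MODULUS",
    "penetration_depth",
    "sauerbrey_constant",
    "sauerbrey_mass",
    "dissipation_kernel",
    "frequency_kernel",
]

ArrayLike = Union[float, np.ndarray]

#: AT-cut quartz density, kg/m^3.
QUARTZ_DENSITY = 2648.0
#: AT-cut quartz shear modulus, Pa.
QUARTZ_SHEAR_MODULUS = 2.947e10


@dataclass(frozen=True)
class LiquidProperties:
    """Newtonian bulk liquid above the sensor.

    viscosity in Pa·s, density in kg/m³.
    """

    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("liquid viscosity and density must be positive")


#: Water at 25 °C — the reference liquid for quoted penetration depths.
WATER_25C = LiquidProperties(viscosity=8.9e-4, density=997.0)
#: Water at 37 °C (assay temperature); shallower penetration than at 25 °C.
WATER_37C = LiquidProperties(viscosity=6.9e-4, density=993.0)


@dataclass
class FilmState:
    """Effective state of the adsorbate film at one instant.

    Fields may be scalars or equally shaped arrays (one value per time
    point), which the kernels broadcast over.

    thickness : nm
        Effective bacterial-film thickness ``h``.
    softness : dimensionless in [0, 1]
        ``1`` for live, viscoelastic cells; small for collapsed debris.
    rigid_mass : ng/cm²
        Rigidly coupled areal load (e.g. adsorbed phage particles).
    coverage : dimensionless in [0, 1]
        Fractional surface coverage ``θ``.
    resonance_sign : {+1, -1}
        Sensor-specific sign of the coupled-resonance frequency response.
    """

    thickness: ArrayLike
    softness: ArrayLike
    rigid_mass: ArrayLike = 0.0
    coverage: ArrayLike = 1.0
    resonance_sign: int = +1

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.thickness) < 0):
            raise ValueError("film thickness must be >= 0")
        s = np.asarray(self.softness)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("film softness must lie in [0, 1]")
        if np.any(np.asarray(self.rigid_mass) < 0):
            raise ValueError("rigid mass must be >= 0")
        th = np.asarray(self.coverage)
        if np.any(th < 0) or np.any(th > 1):
            raise ValueError("coverage must lie in [0, 1]")
        if self.resonance_sign not in (+1, -1):
            raise ValueError("resonance_sign must be +1 or -1")


def penetration_depth(n: int, f0: float, liquid: LiquidProperties) -> float:
    """Shear-wave penetration depth ``δ_n`` into the liquid, in nm.

    ``δ_n = sqrt(η / (π n f0 ρ))``; strictly decreasing in the overtone
    number ``n`` (``δ_a/δ_b = sqrt(b/a)``).
    """
    if n < 1:
        raise ValueError("overtone number must be >= 1")
    if f0 <= 0:
        raise ValueError("fundamental frequency must be positive")
    delta_m = np.sqrt(liquid.viscosity / (np.pi * n * f0 * liquid.density))
    return float(delta_m * 1e9)


def sauerbrey_constant(f0: float) -> float:
    """Sauerbrey mass-sensitivity constant ``C`` in ng·cm⁻²·Hz⁻¹.

    ``C = sqrt(ρ_q μ_q) / (2 f0²)`` (≈ 17.7 ng·cm⁻²·Hz⁻¹ at 5 MHz).
    """
    if f0 <= 0:
        raise ValueError("fundamental frequency must be positive")
    c_si = np.sqrt(QUARTZ_DENSITY * QUARTZ_SHEAR_MODULUS) / (2.0 * f0**2)
    return float(c_si * 1e8)  # kg/m² -> ng/cm²


def sauerbrey_mass(delta_f: ArrayLike, n: int, f0: float) -> ArrayLike:
    """Areal mass change (ng/cm²) of a thin rigid film from ``Δf_n``.

    ``Δm = −C Δf_n / n``: mass uptake (positive Δm) lowers the frequency.
    """
    if n < 1:
        raise ValueError("overtone number must be >= 1")
    return -sauerbrey_constant(f0) * np.asarray(delta_f, dtype=float) / n


def dissipation_kernel(
    film: FilmState,
    n: int,
    f0: float,
    liquid: LiquidProperties,
    amplitude: ArrayLike,
) -> ArrayLike:
    """Per-overtone dissipation shift ``ΔD_n`` (1e-6 units) of a soft film.

    ``ΔD_n = A_D · s · θ · δ_n (1 − exp(−h/δ_n)) / δ_3``

    The bracket is the film thickness actually sensed by overtone ``n``:
    it saturates at the penetration depth ``δ_n``, so higher overtones
    (smaller ``δ_n``) sense less of a thick, soft film.  Normalizing by
    ``δ_3`` makes ``A_D`` the saturation value of ΔD₃ for a full-coverage,
    fully soft, infinitely thick film.  ΔD is non-negative, non-increasing
    in ``n`` and strictly increasing in ``h`` (for s, θ > 0).
    """
    if np.any(np.asarray(amplitude) < 0):
        raise ValueError("dissipation amplitude must be >= 0")
    d_n = penetration_depth(n, f0, liquid)
    d_3 = penetration_depth(3, f0, liquid)
    h = np.asarray(film.thickness, dtype=float)
    sensed = d_n * (1.0 - np.exp(-h / d_n))
    return amplitude * film.softness * film.coverage * sensed / d_3


def frequency_kernel(
    film: FilmState,
    n: int,
    f0: float,
    amplitude: ArrayLike,
) -> ArrayLike:
    """Per-overtone frequency shift ``Δf_n`` (Hz).

    ``Δf_n = −(n/C) m + χ · A_f · θ · n/3``

    The first term is the Sauerbrey response to rigidly coupled mass ``m``
    (adsorbed phage); the second is a coupled-resonance term for discrete
    adhering bacteria, linear in coverage ``θ`` with a per-sensor sign
    ``χ``: bacteria behaving as coupled resonators can shift Δf in either
    direction, and positive shifts during bacterial adhesion are common.
    With ``θ = 0`` the kernel reduces to pure Sauerbrey loading.
    """
    c = sauerbrey_constant(f0)
    m = np.asarray(film.rigid_mass, dtype=float)
    return -(n / c) * m + film.resonance_sign * amplitude * film.coverage * (n / 3.0)
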