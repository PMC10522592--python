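"""Optogenetic light-penetration estimate for fiber-coupled stimulation.

Estimates how deep below the fiber tip the delivered blue light stays above
the irradiance needed to activate ChR2.  The on-axis irradiance at depth
``z`` (mm) combines two attenuation factors:

* conical geometric spread of the beam leaving the fiber, with in-tissue
  half-angle ``theta = arcsin(NA / n)``.  Writing
  ``rho = r * sqrt((n/NA)**2 - 1)`` for the distance from the virtual cone
  apex to the fiber face, the geometric factor is ``rho**2 / (z + rho)**2``;
* diffusive scattering losses in gray matter, modelled with the
  Kubelka-Munk zero-absorption transmission ``1 / (S*z + 1)`` where ``S`` is
  the scatter coefficient per mm (11.2 /mm for mouse cortex/hippocampus at
  blue wavelengths; 10.3 /mm is the classical rat value).

This is the model used by the widely circulated fiber-irradiance
"brain light transmission" calculators.  It ignores absorption, refractive
losses at the fiber-tissue interface, and any beam profile structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Kubelka-Munk scatter coefficient for mouse gray matter, blue light (1/mm).
MOUSE_SCATTER_PER_MM = 11.2
#: Classical rat gray-matter value (1/mm).
RAT_SCATTER_PER_MM = 10.3


@dataclass(frozen=True)
class FiberSpec:
    """Optical parameters of the implanted fiber and the activation threshold.

    Parameters
    ----------
    power_at_tip_mw:
        Light power measured at the fiber tip, mW.
    numerical_aperture:
        Fiber NA (dimensionless).  Must be below the tissue refractive
        index for a real propagation cone to exist.
    fiber_radius_mm:
        Fiber core radius in mm.  If the quoted figure is a core *diameter*
        pass ``radius_is_diameter=True`` to :func:`activation_depth`.
    tissue_refractive_index:
        Refractive index of brain tissue (~1.35).
    threshold_irradiance_mw_mm2:
        Irradiance required to activate the opsin, mW/mm^2 (~1 for ChR2).
    """

    power_at_tip_mw: float
    numerical_aperture: float
    fiber_radius_mm: float
    tissue_refractive_index: float = 1.35
    threshold_irradiance_mw_mm2: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "power_at_tip_mw",
            "numerical_aperture",
            "fiber_radius_mm",
            "tissue_refractive_index",
            "threshold_irradiance_mw_mm2",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.numerical_aperture >= self.tissue_refractive_index:
            raise ValueError(
                "numerical_aperture must be below the tissue refractive index "
                "(no real propagation cone otherwise)"
            )

    @property
    def half_angle_deg(self) -> float:
        """In-tissue half-angle of the emission cone, degrees."""
        return float(
            np.degrees(
                np.arcsin(self.numerical_aperture / self.tissue_refractive_index)
            )
        )


def irradiance_profile(
    fiber: FiberSpec,
    z_mm: np.ndarray | float,
    *,
    scatter_per_mm: float = MOUSE_SCATTER_PER_MM,
    radius_is_diameter: bool = False,
    include_geometric: bool = True,
    include_scattering: bool = True,
) -> np.ndarray | float:
    """On-axis irradiance (mW/mm^2) at depth ``z_mm`` below the fiber tip."""
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    r = fiber.fiber_radius_mm / 2.0 if radius_is_diameter else fiber.fiber_radius_mm
    n = fiber.tissue_refractive_index
    na = fiber.numerical_aperture
    rho = r * np.sqrt((n / na) ** 2 - 1.0)
    surface = fiber.power_at_tip_mw / (np.pi * r**2)
    factor = np.ones_like(z)
    if include_geometric:
        factor = factor * rho**2 / (z + rho) ** 2
    if include_scattering:
        if scatter_per_mm < 0:
            raise ValueError("scatter_per_mm must be non-negative")
        factor = factor / (scatter_per_mm * z + 1.0)
    out = surface * factor
    return float(out) if np.isscalar(z_mm) else out


def activation_depth(
    fiber: FiberSpec,
    *,
    scatter_per_mm: float = MOUSE_SCATTER_PER_MM,
    radius_is_diameter: bool = False,
    include_geometric: bool = True,
    include_scattering: bool = True,
    z_max_mm: float = 50.0,
) -> float:
    """Depth (mm) at which irradiance falls to the activation threshold.

    Returns 0.0 when even the surface irradiance is at or below threshold.
    With both attenuation factors disabled the irradiance never decays and
    a ``ValueError`` is raised.
    """
    if not (include_geometric or include_scattering):
        raise ValueError("at least one attenuation mechanism must be enabled")

    def excess(z: float) -> float:
        return (
            irradiance_profile(
                fiber,
                z,
                scatter_per_mm=scatter_per_mm,
                radius_is_diameter=radius_is_diameter,
                include_geometric=include_geometric,
                include_scattering=include_scattering,
            )
            - fiber.threshold_irradiance_mw_mm2
        )

    if excess(0.0) <= 0:
        return 0.0
    hi = z_max_mm
    while excess(hi) > 0:  # expand bracket for very high powers
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("irradiance does not decay to threshold")
    return float(brentq(excess, 0.0, hi, xtol=1e-9))
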