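"""Spring and contact mechanics of the clip force sensor.

The clip senses finger force mechanically: a linear compression spring
(stiffness ``k_constant``, preloaded at rest) sits under a circular pressing
platform. Compressing the spring by ``x`` millimetres applies a force
``preload_force + k_constant * x`` to the fingertip, and that force acts over
the circular contact protrusion, producing a contact pressure on the digital
artery. All unit conversions are fixed internally: lengths in mm, forces in N,
pressures in Pa internally and mmHg at the API surface (1 mmHg = 133.322 Pa).

With the default constants (k = 0.49 N/mm, preload 0.1 N, 6.7 mm of travel,
10 mm contact diameter) the applied pressure spans roughly 9.5 to 315 mmHg,
i.e. from well below diastolic to above any plausible systolic pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PA_PER_MMHG = 133.322
"""Conversion constant: pascal per millimetre of mercury."""


@dataclass(frozen=True)
class SpringModel:
    """Linear compression spring with a preload.

    Parameters
    ----------
    k_constant : float
        Spring stiffness in N/mm. Must be positive.
    preload_force : float
        Force in N applied at zero compression (the spring is assembled
        slightly compressed). Must be non-negative.
    max_travel : float
        Maximum additional compression in mm. Must be positive.
    """

    k_constant: float = 0.49
    preload_force: float = 0.1
    max_travel: float = 6.7

    def __post_init__(self) -> None:
        if not self.k_constant > 0:
            raise ValueError(f"k_constant must be > 0, got {self.k_constant}")
        if self.preload_force < 0:
            raise ValueError(
                f"preload_force must be >= 0, got {self.preload_force}"
            )
        if not self.max_travel > 0:
            raise ValueError(f"max_travel must be > 0, got {self.max_travel}")

    @property
    def max_force(self) -> float:
        """Force in N at full compression."""
        return self.preload_force + self.k_constant * self.max_travel


@dataclass(frozen=True)
class ContactGeometry:
    """Circular finger-contact protrusion.

    Parameters
    ----------
    contact_diameter : float
        Diameter in mm of the circular platform the finger presses on.
    """

    contact_diameter: float = 10.0

    def __post_init__(self) -> None:
        if not self.contact_diameter > 0:
            raise ValueError(
                f"contact_diameter must be > 0, got {self.contact_diameter}"
            )

    @property
    def contact_area_m2(self) -> float:
        """Contact area in square metres."""
        return math.pi * (self.contact_diameter * 1e-3 / 2.0) ** 2


DEFAULT_SPRING = SpringModel()
DEFAULT_GEOMETRY = ContactGeometry()


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    return arr


def _maybe_scalar(arr, like):
    if np.isscalar(like) or np.ndim(like) == 0:
        return float(arr)
    return arr


def force_from_compression(x, spring: SpringModel = DEFAULT_SPRING):
    """Force in N applied at spring compression ``x`` (mm).

    Strictly increasing in ``x``. Raises ``ValueError`` outside
    ``[0, max_travel]``.
    """
    arr = _as_float(x)
    if np.any(arr < 0) or np.any(arr > spring.max_travel):
        raise ValueError(
            f"compression must lie in [0, {spring.max_travel}] mm, got {x}"
        )
    return _maybe_scalar(spring.preload_force + spring.k_constant * arr, x)


def compression_from_force(f, spring: SpringModel = DEFAULT_SPRING):
    """Inverse of :func:`force_from_compression`; returns compression in mm."""
    arr = _as_float(f)
    lo, hi = spring.preload_force, spring.max_force
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"force must lie in [{lo}, {hi}] N, got {f}")
    return _maybe_scalar((arr - spring.preload_force) / spring.k_constant, f)


def pressure_from_force(f, geometry: ContactGeometry = DEFAULT_GEOMETRY):
    """Contact pressure in mmHg produced by force ``f`` (N).

    The force is spread uniformly over the circular contact area; the
    resulting pressure in Pa is converted at 133.322 Pa/mmHg.
    """
    arr = _as_float(f)
    if np.any(arr < 0):
        raise ValueError(f"force must be >= 0, got {f}")
    return _maybe_scalar(arr / geometry.contact_area_m2 / PA_PER_MMHG, f)


def pressure_from_compression(
    x,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
):
    """Contact pressure in mmHg at spring compression ``x`` (mm)."""
    return pressure_from_force(force_from_compression(x, spring), geometry)


def compression_from_scale(scale_pct, spring: SpringModel = DEFAULT_SPRING):
    """Spring compression in mm at a force-scale position (0-100 %).

    The app's force scale is proportional to displacement, so scale s %
    corresponds to ``s/100 * max_travel`` of compression.
    """
    arr = _as_float(scale_pct)
    return _maybe_scalar(arr / 100.0 * spring.max_travel, scale_pct)


def pressure_at_scale(
    scale_pct,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
):
    """Contact pressure in mmHg at a force-scale position (0-100 %)."""
    return pressure_from_compression(
        compression_from_scale(scale_pct, spring), spring, geometry
    )
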