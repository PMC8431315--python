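"""Steady-state radial chemoattractant field around the egg.

The chemoattractant released from the egg coat is assumed to have reached a
time-independent profile, governed by the radial Laplace equation

    d2C/dr2 + (1/r) dC/dr = 0

on the annulus between the egg surface (radius ``a``, where the
concentration is pinned to the surface value ``C_s``) and the edge of the
simulated field (radius ``R``, where the concentration is zero).  The unique
solution is logarithmic,

    C(r) = C_s * ln(R / r) / ln(R / a),

which this module evaluates analytically.  Concentrations are stored in nM
internally (the half-saturation constant of the receptor is quoted in nM);
the conventional surface value of 100 pM is therefore 0.1 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialField", "solve_field"]

#: 1 pM expressed in the internal nM unit.
PM = 1e-3
#: 1 fM expressed in the internal nM unit.
FM = 1e-6


@dataclass(frozen=True)
class RadialField:
    """Analytic solution of the radial Laplace problem.

    Parameters
    ----------
    egg_radius
        Egg radius including the egg coat, μm.  Arrival detection and the
        inner boundary condition both use this radius.
    field_radius
        Radius of the simulated arena, μm; the concentration vanishes here.
    surface_concentration
        Chemoattractant concentration at the egg surface, nM.
    """

    egg_radius: float
    field_radius: float
    surface_concentration: float
    _log_ratio: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.egg_radius > 0:
            raise ValueError(f"egg_radius must be positive, got {self.egg_radius}")
        if not self.field_radius > self.egg_radius:
            raise ValueError(
                "field_radius must exceed egg_radius "
                f"({self.field_radius} <= {self.egg_radius})"
            )
        if self.surface_concentration < 0:
            raise ValueError("surface_concentration must be non-negative")
        object.__setattr__(
            self, "_log_ratio", float(np.log(self.field_radius / self.egg_radius))
        )

    def concentration(self, r):
        """Concentration (nM) at radial distance ``r`` (μm) from the egg center.

        Distances inside the egg clamp to the surface value; distances beyond
        the field edge give zero.  Accepts scalars or arrays.
        """
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore"):
            c = (
                self.surface_concentration
                * np.log(self.field_radius / np.maximum(r, self.egg_radius))
                / self._log_ratio
            )
        c = np.where(r >= self.field_radius, 0.0, c)
        c = np.where(r <= self.egg_radius, self.surface_concentration, c)
        return c if c.ndim else float(c)

    def concentration_at(self, position, egg_center=(0.0, 0.0)):
        """Concentration (nM) at a Cartesian ``position`` (μm).

        ``position`` may be a single ``(x, y)`` pair or an ``(n, 2)`` array;
        ``egg_center`` is the instantaneous egg center (it oscillates in the
        positional-disturbance experiments).
        """
        pos = np.asarray(position, dtype=float)
        delta = pos - np.asarray(egg_center, dtype=float)
        r = np.hypot(*np.moveaxis(delta, -1, 0))
        return self.concentration(r)

    def profile(self, n: int = 500) -> np.ndarray:
        """``(n, 2)`` array of (r, C(r)) pairs spanning the annulus (for export)."""
        r = np.linspace(self.egg_radius, self.field_radius, n)
        return np.column_stack([r, self.concentration(r)])


def solve_field(
    egg_radius: float, field_radius: float, surface_concentration: float
) -> RadialField:
    """Solve the time-independent radial diffusion problem.

    All arguments in μm / nM.  Returns the closed-form :class:`RadialField`
    with ``C(egg_radius) == surface_concentration`` and
    ``C(field_radius) == 0`` exactly.
    """
    return RadialField(egg_radius, field_radius, surface_concentration)
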