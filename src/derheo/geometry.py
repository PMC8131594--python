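"""Solid-shell-liquid-core (SSLC) geometry of the sandwiched cell.

The rounded cell is idealised as a thin elastic cortical shell (thickness
h_cort, Young's modulus E, Poisson ratio nu) wrapped around an incompressible
liquid interior.  Squeezed symmetrically between two parallel plates by a
distance Delta, the free surface bulges into a spherical zone of radius
R' > R fixed by volume conservation of the truncated-sphere shape:

    pi * (R'^2 H - H^3 / 12) = 4/3 pi R^3,        H = 2R - Delta,

which is linear in R'^2, and the contact radius is a = sqrt(R'^2 - H^2/4).
A uniform-tension membrane with internal pressure takes exactly this
constant-mean-curvature shape, so the truncated sphere is the equilibrium
configuration, not an approximation to it.

The cortex resists the areal stretch of the deformation with a 2-D stretching
modulus K_A = E * h_cort / (1 - nu) (equibiaxial membrane stretching) plus an
optional resting tension T0 (cortical prestress, zero by default):

    T(Delta)  = T0 + K_A * (A(Delta) - A0) / A0
    P(Delta)  = 2 T / R'                      (Laplace, free surface)
    F(Delta)  = T * dA/dDelta                 (virtual work at fixed volume)
    k_cell    = dF/dDelta                     (incremental stiffness).

Because K_A is linear in both E and h_cort, the stiffness per unit modulus

    G = k_cell(Delta; E = 1 Pa, h_cort)       [units: m]

is a frequency-independent geometry factor, and by the elastic-viscoelastic
correspondence principle the cortical dynamic modulus follows from the
de-embedded transfer function as E*(f) = g_c(f) / G.  The quasi-static use of
G across the band assumes shape inertia is negligible, which holds far below
the ~400 kHz regime where fluid inertia enters.

Two evaluation routes are provided: ``membrane_shell`` discretises the
deformed meridian (~200 nodes) and integrates area and volume by quadrature;
``plate_contact_surrogate`` evaluates the same mechanics in closed form.
They agree to numerical precision and cross-check each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .deembed import ComplexResponse
from .io import CellRecord, ValidationError
from .rheology import DynamicModulus

__all__ = [
    "CompressedShape",
    "GeometryFactor",
    "compressed_shape",
    "surface_area",
    "cell_spring_constant",
    "geometry_factor",
    "gc_to_modulus",
    "modulus_to_gc",
    "hertz_geometry_factor",
    "GeometryError",
]

POISSON_DEFAULT = 0.5
N_MERIDIAN_NODES = 201
VOLUME_RTOL = 1e-9


class GeometryError(RuntimeError):
    """The geometry solve failed or did not meet its tolerance."""


@dataclass
class CompressedShape:
    """Truncated-sphere shape of a volume-conserving compressed cell."""

    R: float  # free radius, m
    delta: float  # compression Delta, m
    H: float  # plate separation 2R - Delta, m
    R_bulge: float  # bulged free-surface radius R', m
    a: float  # contact radius, m
    volume: float  # conserved volume, m^3

    @property
    def area(self) -> float:
        """Total cortex area: spherical zone plus both contact discs."""
        return 2.0 * math.pi * self.R_bulge * self.H \
            + 2.0 * math.pi * self.a**2


def compressed_shape(R: float, delta: float) -> CompressedShape:
    """Solve the volume-conserving truncated-sphere shape at compression Delta."""
    if R <= 0:
        raise ValidationError("R must be positive")
    if not 0.0 <= delta < 2.0 * R:
        raise GeometryError(f"compression {delta:g} outside [0, 2R)")
    H = 2.0 * R - delta
    R_bulge_sq = 4.0 * R**3 / (3.0 * H) + H**2 / 12.0
    R_bulge = math.sqrt(R_bulge_sq)
    a_sq = R_bulge_sq - H**2 / 4.0
    a = math.sqrt(max(a_sq, 0.0))
    volume = math.pi * (R_bulge_sq * H - H**3 / 12.0)
    target = 4.0 / 3.0 * math.pi * R**3
    if abs(volume - target) > VOLUME_RTOL * target:
        raise GeometryError(
            f"volume constraint violated: {volume:g} vs {target:g}"
        )
    return CompressedShape(R, delta, H, R_bulge, a, volume)


def _area_volume_quadrature(shape: CompressedShape,
                            n_nodes: int = N_MERIDIAN_NODES):
    """Zone area and volume by meridional quadrature over the deformed shape.

    The meridian of the free surface is the circular arc of radius R' between
    the two contact circles; z runs over [-H/2, H/2] with r(z) =
    sqrt(R'^2 - z^2).  Used by the ``membrane_shell`` route and as the
    independent check on the closed forms.
    """
    z = np.linspace(-shape.H / 2.0, shape.H / 2.0, n_nodes)
    r = np.sqrt(shape.R_bulge**2 - z**2)
    drdz = -z / r
    # lateral (zone) area: 2 pi int r sqrt(1 + r'^2) dz; Simpson is exact for
    # the quadratic volume integrand and O(n^-4) for the area
    integrand = 2.0 * math.pi * r * np.sqrt(1.0 + drdz**2)
    zone = float(simpson(integrand, x=z))
    volume = float(simpson(math.pi * r**2, x=z))
    area = zone + 2.0 * math.pi * shape.a**2
    return area, volume


def surface_area(shape: CompressedShape, model_tag: str = "membrane_shell",
                 n_nodes: int = N_MERIDIAN_NODES) -> float:
    if model_tag == "plate_contact_surrogate":
        return shape.area
    area, volume = _area_volume_quadrature(shape, n_nodes)
    if abs(volume - shape.volume) > 1e-6 * shape.volume:
        raise GeometryError("meridional quadrature volume drifted")
    return area


def _tension_force(R: float, delta: float, E: float, h_cort: float,
                   nu: float, prestress: float, model_tag: str):
    """(T, P, F) of the compressed shell at one Delta."""
    shape = compressed_shape(R, delta)
    A0 = 4.0 * math.pi * R**2
    area = surface_area(shape, model_tag)
    K_A = E * h_cort / (1.0 - nu)
    T = prestress + K_A * (area - A0) / A0
    P = 2.0 * T / shape.R_bulge
    # dA/dDelta by central difference on the shape family (the area of the
    # constrained shape is smooth in Delta)
    d = max(delta, 1e-3 * R) * 1e-4
    lo = max(delta - d, 0.0)
    hi = delta + d
    a_hi = surface_area(compressed_shape(R, hi), model_tag)
    a_lo = surface_area(compressed_shape(R, lo), model_tag)
    dA = (a_hi - a_lo) / (hi - lo)
    F = T * dA
    return shape, T, P, F


def cell_spring_constant(
    shape_or_cell,
    E: float,
    h_cort: float | None = None,
    *,
    nu: float = POISSON_DEFAULT,
    prestress: float = 0.0,
    model_tag: str = "membrane_shell",
    richardson_check: bool = False,
) -> float:
    """Incremental plate stiffness k_cell = dF/dDelta of the compressed cell.

    ``shape_or_cell`` is a :class:`CompressedShape` or a :class:`CellRecord`
    (whose compression and cortex thickness are then used).  The derivative
    uses a central difference with step Delta/100; with
    ``richardson_check=True`` the step Delta/200 must agree within 1%.
    """
    if isinstance(shape_or_cell, CellRecord):
        R = shape_or_cell.radius
        delta = shape_or_cell.compression
        if h_cort is None:
            h_cort = shape_or_cell.h_cort
    else:
        R = shape_or_cell.R
        delta = shape_or_cell.delta
    if h_cort is None:
        raise ValidationError("h_cort required")
    if delta <= 0:
        raise GeometryError("incremental stiffness needs Delta > 0")
    if h_cort > R / 5.0:
        raise GeometryError("thin-shell model needs h_cort << R")

    def force(d):
        return _tension_force(R, d, E, h_cort, nu, prestress, model_tag)[3]

    def stiffness(step):
        return (force(delta + step) - force(delta - step)) / (2.0 * step)

    d_step = delta / 100.0
    k = stiffness(d_step)
    if richardson_check:
        k2 = stiffness(delta / 200.0)
        if abs(k2 - k) > 0.01 * abs(k2):
            raise GeometryError(
                f"stiffness derivative not converged: {k:g} vs {k2:g}"
            )
    if not math.isfinite(k):
        raise GeometryError("non-finite spring constant")
    return float(k)


@dataclass
class GeometryFactor:
    """Frequency-independent conversion between g_c (N/m) and E* (Pa)."""

    G: float  # m: stiffness per unit modulus
    h_cort: float
    model_tag: str
    shape: CompressedShape
    nu: float = POISSON_DEFAULT


def geometry_factor(cell: CellRecord, *, nu: float = POISSON_DEFAULT,
                    prestress: float = 0.0,
                    model_tag: str = "membrane_shell") -> GeometryFactor:
    """G = k_cell at unit modulus, for the cell's compression and thickness.

    With a nonzero prestress the force acquires a modulus-independent part
    and the linear g_c -> E* map no longer holds; the conversion therefore
    requires ``prestress = 0``.
    """
    if prestress != 0.0:
        raise ValidationError(
            "geometry factor is defined for zero prestress; the prestressed "
            "stiffness is not linear in the modulus"
        )
    shape = compressed_shape(cell.radius, cell.compression)
    G = cell_spring_constant(shape, 1.0, cell.h_cort, nu=nu,
                             model_tag=model_tag)
    if not (math.isfinite(G) and G > 0):
        raise GeometryError(f"geometry factor must be positive, got {G:g}")
    return GeometryFactor(G, cell.h_cort, model_tag, shape, nu)


def gc_to_modulus(gc: ComplexResponse, cell: CellRecord,
                  factor: GeometryFactor | None = None,
                  **kwargs) -> DynamicModulus:
    """Convert the de-embedded transfer function to cortical moduli.

    E*(f) = g_c(f) / G, elementwise; E' = Re, E'' = Im.  The map is linear
    and frequency-wise, so superpositions of g_c convert additively.
    """
    if factor is None:
        factor = geometry_factor(cell, **kwargs)
    values = gc.values / factor.G
    return DynamicModulus.from_complex(gc.frequencies, values, cell.cell_id)


def modulus_to_gc(modulus: DynamicModulus, cell: CellRecord,
                  factor: GeometryFactor | None = None,
                  **kwargs) -> ComplexResponse:
    """Inverse of :func:`gc_to_modulus`: g_c(f) = G * E*(f)."""
    if factor is None:
        factor = geometry_factor(cell, **kwargs)
    return ComplexResponse(modulus.frequencies,
                           factor.G * modulus.complex, label="g_c")


def hertz_geometry_factor(cell: CellRecord,
                          nu: float = POISSON_DEFAULT) -> float:
    """Hertzian sphere-plate alternative, for comparison only.

    Two Hertz contacts in series (one per plate, each indenting Delta/2)
    give k = E sqrt(R Delta / 2) / (1 - nu^2).  The contact volume storing
    elastic energy is much larger than the thin cortex, so for the same g_c
    the Hertz route yields much smaller moduli than the SSLC route
    (G_hertz >> G_sslc).
    """
    return math.sqrt(cell.radius * cell.compression / 2.0) / (1.0 - nu**2)
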