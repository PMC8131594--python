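"""Euler-Bernoulli clamped-free beam surrogate for laser-position effects.

The actuating (blue) and readout (red) laser spots do not sit at the same
point of the cantilever, while the lumped-element de-embedding assumes force,
readout and cell contact colocated.  A modal superposition over the
clamped-free beam modes gives the receptance (complex displacement per unit
point force)

    R(z_f, z_r, f) = sum_n  phi_n(z_f) phi_n(z_r)
                     / (m_b * 4 pi^2 * (f_n^2 - f^2 + i f_n f / Q_n)),

with mode shapes phi_n normalised to unit mean square over the length and
modal frequencies f_n = f_1 (lambda_n / lambda_1)^2.  The multiplicative
correction C(f) = R(z_red, z_red, f) / R(z_blue, z_red, f) "shifts" the
actuation point onto the readout point; applied to a sweep measured with
off-point actuation it reproduces the on-point sweep of the same beam.

The beam mass scale is fixed so that the static receptance at a reference
point matches a given spring constant, which pins the truncation error of the
modal sum to zero at f = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import CantileverParams, ValidationError
from .deembed import ComplexResponse

__all__ = [
    "BeamModel",
    "beam_response",
    "laser_position_correction",
    "clamped_free_eigenvalues",
    "mode_shape",
    "static_deflection",
    "TruncationWarning",
]


class TruncationWarning(UserWarning):
    """The requested frequency is too close to the truncated modes."""


def clamped_free_eigenvalues(n: int) -> np.ndarray:
    """First ``n`` roots of cosh(x) cos(x) = -1 (clamped-free beam)."""
    roots = []
    for k in range(1, n + 1):
        # roots approach (2k-1) pi/2; bracket around the asymptote
        guess = (2 * k - 1) * math.pi / 2.0
        lo, hi = guess - 0.7, guess + 0.7
        if k == 1:
            lo = 1.2
        func = lambda x: math.cos(x) + 1.0 / math.cosh(x)
        roots.append(brentq(func, lo, hi, xtol=1e-14))
    return np.asarray(roots)


def _sigma(lam: float) -> float:
    return (math.cosh(lam) + math.cos(lam)) / (math.sinh(lam) + math.sin(lam))


def mode_shape(lam: float, z) -> np.ndarray:
    """Clamped-free mode shape, unit mean square over z in [0, 1].

    Evaluated in the cancellation-free form
    phi = exp(-lam z) - cos(lam z) + sigma sin(lam z) + (1 - sigma) sinh(lam z)
    with 1 - sigma = (sin lam - cos lam - exp(-lam)) / (sinh lam + sin lam),
    which stays accurate for high modes where cosh and sinh overflow the
    direct expression's significand.
    """
    z = np.asarray(z, dtype=float)
    s = _sigma(lam)
    one_minus_s = (math.sin(lam) - math.cos(lam) - math.exp(-lam)) \
        / (math.sinh(lam) + math.sin(lam))
    return (np.exp(-lam * z) - np.cos(lam * z) + s * np.sin(lam * z)
            + one_minus_s * np.sinh(lam * z))


def static_deflection(z_force: float, z_read: float) -> float:
    """Static deflection at z_read per unit force at z_force (EI = L = 1).

    Classic cantilever statics: delta(x; a) = a^2 (3x - a) / 6 for x >= a and
    x^2 (3a - x) / 6 for x <= a.
    """
    a, x = z_force, z_read
    if x >= a:
        return a * a * (3.0 * x - a) / 6.0
    return x * x * (3.0 * a - x) / 6.0


@dataclass
class BeamModel:
    """Modal model of one cantilever.

    Parameters
    ----------
    f_1 : float
        First-mode resonance frequency (Hz), matched to the measured f_cant.
    Q : float or sequence
        Modal quality factor(s); a scalar is applied to every mode.
    n_modes : int
        Number of retained modes (>= 3).
    spring_constant : float
        Static stiffness (N/m) at ``z_ref``; fixes the beam mass scale.
    z_ref : float
        Reference point of the spring constant (fraction of L); default the
        free end.
    custom_modes : (frequency_ratios, shapes) or None
        Substitute mode set for non-rectangular geometries: ``shapes`` is a
        list of callables on z/L in [0, 1] (mean-square-normalised) and
        ``frequency_ratios`` the modal frequencies relative to the first
        mode.  The default is the analytic rectangular clamped-free set.
    """

    f_1: float
    Q: float | np.ndarray = 3.0
    n_modes: int = 6
    spring_constant: float = 0.35
    z_ref: float = 1.0
    length: float = 100e-6
    custom_modes: tuple | None = None
    eigenvalues: np.ndarray = field(init=False)
    f_n: np.ndarray = field(init=False)
    mass_scale: float = field(init=False)

    def __post_init__(self):
        if self.n_modes < 1:
            raise ValidationError("n_modes must be >= 1")
        if self.f_1 <= 0 or self.spring_constant <= 0:
            raise ValidationError("f_1 and spring_constant must be positive")
        if self.custom_modes is not None:
            ratios, shapes = self.custom_modes
            if len(ratios) != len(shapes):
                raise ValidationError("custom mode table lengths differ")
            self.n_modes = len(shapes)
            self._shapes = list(shapes)
            self.eigenvalues = np.sqrt(np.asarray(ratios, dtype=float)) \
                * 1.8751040687119611
            self.f_n = self.f_1 * np.asarray(ratios, dtype=float)
        else:
            self._shapes = None
            self.eigenvalues = clamped_free_eigenvalues(self.n_modes)
            self.f_n = self.f_1 * (self.eigenvalues
                                   / self.eigenvalues[0]) ** 2
        self.Q_n = np.broadcast_to(
            np.asarray(self.Q, dtype=float), (self.n_modes,)
        ).copy()
        if np.any(self.Q_n <= 0):
            raise ValidationError("modal Q must be positive")
        # mass scale from the static receptance at the reference point:
        # R(z_ref, z_ref, 0) = sum phi_n(z_ref)^2 / (m_b (2 pi f_n)^2) = 1/k
        phi_ref = np.asarray(self.phi(self.z_ref), dtype=float).ravel()
        s = np.sum(phi_ref**2 / (2.0 * math.pi * self.f_n) ** 2)
        self.mass_scale = self.spring_constant * s

    @classmethod
    def from_cantilever(cls, cant: CantileverParams,
                        n_modes: int = 6) -> "BeamModel":
        """Build the surrogate matched to a measured cantilever.

        The cantilever's spring constant is interpreted at the readout point
        ``z_red`` so that calibration amplitudes and the beam statics agree.
        """
        return cls(
            f_1=cant.f_cant, Q=cant.Q, n_modes=n_modes,
            spring_constant=cant.spring_constant, z_ref=cant.z_red,
            length=cant.length,
        )

    def phi(self, z) -> np.ndarray:
        """Mode-shape matrix, shape (n_modes,) + shape(z)."""
        if self._shapes is not None:
            return np.array([np.asarray(s(z), dtype=float)
                             for s in self._shapes])
        return np.array([mode_shape(l, z) for l in self.eigenvalues])


def beam_response(beam: BeamModel, z_force: float, z_read: float,
                  f) -> np.ndarray:
    """Complex receptance (m/N) of the beam; reciprocal in (z_force, z_read).

    Warns when ``f`` comes within 10% of the highest retained mode, where the
    truncated modal sum is no longer trustworthy.
    """
    if not (0.0 < z_force <= 1.0) or not (0.0 < z_read <= 1.0):
        raise ValidationError("z_force and z_read must lie in (0, 1]")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValidationError("frequencies must be non-negative")
    if np.any(f > 0.9 * beam.f_n[-1]):
        warnings.warn(
            f"frequencies above 0.9 x mode-{beam.n_modes} resonance "
            f"({beam.f_n[-1]:.3g} Hz): modal truncation unreliable",
            TruncationWarning,
        )
    phi_f = beam.phi(z_force)
    phi_r = beam.phi(z_read)
    fn = beam.f_n[:, None]
    Qn = beam.Q_n[:, None]
    denom = fn**2 - np.atleast_1d(f)[None, :] ** 2 \
        + 1j * fn * np.atleast_1d(f)[None, :] / Qn
    resp = np.sum(
        (phi_f * phi_r)[:, None]
        / (beam.mass_scale * 4.0 * math.pi**2 * denom),
        axis=0,
    )
    return resp if f.ndim else resp[0]


def laser_position_correction(beam: BeamModel, z_blue: float, z_red: float,
                              f_grid) -> ComplexResponse:
    """Multiplicative correction C(f) = R(z_red, z_red, f) / R(z_blue, z_red, f).

    Multiplying a sweep actuated at ``z_blue`` (and read at ``z_red``) by
    C(f) yields the sweep the same beam would show when actuated at the
    readout point.  ``z_blue = 0`` (clamped end) has zero response and is
    rejected.
    """
    if z_blue <= 0.0:
        raise ValidationError(
            "z_blue at the clamped end gives a singular correction"
        )
    f_grid = np.asarray(f_grid, dtype=float)
    on = beam_response(beam, z_red, z_red, f_grid)
    off = beam_response(beam, z_blue, z_red, f_grid)
    if np.any(np.abs(off) == 0):
        raise ValidationError("off-point response vanishes on the grid")
    C = on / off
    if beam.custom_modes is not None:
        # tabulated mode sets cannot be extended; no convergence guard
        return ComplexResponse(f_grid, C,
                               label=f"C({z_blue:g}->{z_red:g})")
    # convergence guard: the correction must be stable under adding 2 modes
    richer = BeamModel(
        f_1=beam.f_1, Q=float(beam.Q_n[0]), n_modes=beam.n_modes + 2,
        spring_constant=beam.spring_constant, z_ref=beam.z_ref,
        length=beam.length,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        C2 = (beam_response(richer, z_red, z_red, f_grid)
              / beam_response(richer, z_blue, z_red, f_grid))
    drift = np.max(np.abs(C2 - C) / np.abs(C2))
    if drift > 1e-3:
        warnings.warn(
            f"laser-position correction changes by {drift:.2%} when adding "
            "two modes; increase n_modes", TruncationWarning,
        )
    return ComplexResponse(f_grid, C, label=f"C({z_blue:g}->{z_red:g})")
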