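"""Single-cantilever calibration: oscillator fits, phase background, forces.

The phase response of a driven, damped harmonic oscillator with an additive
linear background (electronics time delay) is

    phi(f) = atan2(f * f_cant / Q, f_cant**2 - f**2) + b1 * f + b2,

where the atan branch is chosen so the resonance term rises monotonically from
~0 to ~pi through resonance.  The amplitude response in the centre region of
the resonance is

    A(f) = (F0 / m*) / (4 pi^2) / sqrt((f_cant^2 - f^2)^2 + (f_cant f / Q)^2).

Fitting these to a cell-free sweep yields the background coefficients
(b1, b2), the oscillator parameters (f_cant, Q) and the effective actuation
force F0; the background is subtracted from all cell sweeps before
de-embedding.

When the laser-position correction is done with the multi-mode beam surrogate
the same surrogate can serve as the resonance model of the phase fit
(``model="beam"``), so that higher-mode phase content is not aliased into the
linear background; ``model="sho"`` is the classic single-oscillator form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .io import FrequencySweep, ValidationError

__all__ = [
    "OscillatorFit",
    "EffectiveForce",
    "FitError",
    "fit_phase_background",
    "subtract_phase_background",
    "fit_amplitude_resonance",
    "effective_force",
    "sho_phase",
    "sho_amplitude",
]

MAX_ITER = 500
STEP_TOL = 1e-10


class FitError(RuntimeError):
    """A calibration fit could not be carried out."""

    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass
class OscillatorFit:
    """Result of a damped-driven-oscillator calibration fit.

    ``F0_over_mstar`` is only populated by the amplitude fit; ``b1``/``b2``
    only by the phase fit.  ``covariance`` is ordered like ``param_names``.
    """

    f_cant: float  # Hz
    Q: float
    b1: float = 0.0  # rad/Hz
    b2: float = 0.0  # rad
    F0_over_mstar: float = 0.0  # N/kg
    covariance: np.ndarray | None = None
    param_names: tuple = ()
    fit_window: tuple = (0.0, math.inf)
    residual_rms: float = math.nan
    converged: bool = True

    def __post_init__(self):
        if self.Q <= 0:
            raise ValidationError("Q must be positive")
        if not (self.fit_window[0] <= self.f_cant <= self.fit_window[1]):
            raise ValidationError(
                f"f_cant {self.f_cant:.4g} outside fit window {self.fit_window}"
            )


@dataclass
class EffectiveForce:
    """Effective actuation force on the sweep grid (complex allowed)."""

    frequencies: np.ndarray
    F: np.ndarray  # N, complex
    model_tag: str = "constant"

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.F = np.asarray(self.F, dtype=complex)
        if self.F.shape != self.frequencies.shape:
            raise ValidationError("force grid mismatch")
        if np.any(np.abs(self.F) <= 0):
            raise ValidationError("|F| must be positive on the band")


def sho_phase(f, f_cant, Q):
    """Resonance phase on the (0, pi) branch (no background)."""
    f = np.asarray(f, dtype=float)
    return np.arctan2(f * f_cant / Q, f_cant**2 - f**2)


def sho_amplitude(f, F0_over_mstar, f_cant, Q):
    """Driven damped oscillator amplitude response."""
    f = np.asarray(f, dtype=float)
    denom = np.sqrt((f_cant**2 - f**2) ** 2 + (f_cant * f / Q) ** 2)
    return F0_over_mstar / (4.0 * math.pi**2) / denom


def _initial_guesses(sweep: FrequencySweep):
    f = sweep.frequencies
    a = sweep.amplitudes
    i_pk = int(np.argmax(a))
    f_cant = f[i_pk]
    # Q from the half-power width; fall back to 3 when the flanks are cut off
    half = a[i_pk] / math.sqrt(2.0)
    above = a >= half
    if above[0] or above[-1] or not above.any():
        Q = 3.0
    else:
        lo = f[np.argmax(above)]
        hi = f[len(f) - 1 - np.argmax(above[::-1])]
        width = hi - lo
        Q = f_cant / width if width > 0 else 3.0
    # b1 from the end slope of the (unwrapped) phase, b2 from the start value
    tail = slice(max(0, len(f) - max(5, len(f) // 10)), len(f))
    b1 = float(np.polyfit(f[tail], sweep.phases[tail], 1)[0])
    b2 = float(sweep.phases[0] - sho_phase(f[0], f_cant, Q) - b1 * f[0])
    return f_cant, max(Q, 0.2), b1, b2


def _check_resonance(sweep: FrequencySweep):
    a = sweep.amplitudes
    i_pk = int(np.argmax(a))
    if i_pk == 0 or i_pk == len(a) - 1:
        raise FitError(
            "no interior amplitude maximum: sweep does not bracket a resonance"
        )


def fit_phase_background(
    sweep: FrequencySweep,
    init: OscillatorFit | None = None,
    model: str | Callable = "sho",
) -> OscillatorFit:
    """Fit phi(f) = resonance_phase(f) + b1*f + b2 by least squares.

    ``model`` selects the resonance phase: ``"sho"`` (single oscillator,
    parameters f_cant and Q are fitted) or a callable ``phase(f)`` returning
    the structural resonance phase on the grid (e.g. from the beam surrogate),
    in which case only (b1, b2) are fitted.
    """
    f = sweep.frequencies
    phi = sweep.phases
    _check_resonance(sweep)

    if callable(model):
        base = np.asarray(model(f), dtype=float)
        # linear least squares for b1, b2
        X = np.column_stack([f, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(X, phi - base, rcond=None)
        b1, b2 = (float(c) for c in coef)
        resid = phi - base - b1 * f - b2
        # report the structural model's resonance location
        f_cant = f[int(np.argmax(sweep.amplitudes))]
        return OscillatorFit(
            f_cant=f_cant, Q=init.Q if init else 3.0, b1=b1, b2=b2,
            param_names=("b1", "b2"),
            fit_window=(f[0], f[-1]),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )

    if model != "sho":
        raise ValueError(f"unknown phase model {model!r}")

    if init is not None:
        x0 = np.array([init.f_cant, init.Q, init.b1, init.b2])
    else:
        x0 = np.array(_initial_guesses(sweep))

    def residuals(p):
        f_c, Q, b1, b2 = p
        return sho_phase(f, f_c, abs(Q)) + b1 * f + b2 - phi

    sol = least_squares(
        residuals, x0, method="lm", xtol=STEP_TOL, ftol=STEP_TOL,
        gtol=STEP_TOL, max_nfev=MAX_ITER * 5,
    )
    if not sol.success:
        raise FitError("phase background fit did not converge",
                       last_iterate=sol.x)
    f_c, Q, b1, b2 = sol.x
    cov = _covariance(sol)
    return OscillatorFit(
        f_cant=float(f_c), Q=float(abs(Q)), b1=float(b1), b2=float(b2),
        covariance=cov, param_names=("f_cant", "Q", "b1", "b2"),
        fit_window=(f[0], f[-1]),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def subtract_phase_background(sweep: FrequencySweep,
                              fit: OscillatorFit) -> FrequencySweep:
    """Remove the fitted linear phase background; amplitudes untouched."""
    return sweep.with_phases(
        sweep.phases - fit.b1 * sweep.frequencies - fit.b2
    )


def fit_amplitude_resonance(
    sweep: FrequencySweep,
    window: tuple | None = None,
    model: str | Callable = "sho",
) -> OscillatorFit:
    """Fit the amplitude resonance and extract F0/m*.

    ``window`` restricts the fit to the centre region of the resonance;
    default is (f_peak/2, 2*f_peak) clipped to the sweep band.  With a
    callable ``model(f) -> |response per unit force|`` only the force scale is
    fitted (linear problem) and reported through ``F0_over_mstar`` using the
    single-oscillator identity at the peak.
    """
    _check_resonance(sweep)
    f_all, a_all = sweep.frequencies, sweep.amplitudes
    f_pk = f_all[int(np.argmax(a_all))]
    if window is None:
        window = (f_pk / 2.0, 2.0 * f_pk)
    lo, hi = window
    mask = (f_all >= lo) & (f_all <= hi)
    if mask.sum() < 4 or a_all[mask].max() < a_all.max():
        raise FitError("amplitude fit window excludes the resonance peak")
    f, a = f_all[mask], a_all[mask]

    if callable(model):
        shape = np.asarray(model(f), dtype=float)
        scale = float(np.dot(shape, a) / np.dot(shape, shape))  # F0 in N
        resid = a - scale * shape
        return OscillatorFit(
            f_cant=f_pk, Q=3.0, F0_over_mstar=scale,
            param_names=("F0",), fit_window=(lo, hi),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )

    f_c0, Q0, _, _ = _initial_guesses(sweep)
    amp0 = a.max() * (4.0 * math.pi**2) * f_c0**2 / Q0
    x0 = np.array([amp0, f_c0, Q0])

    def residuals(p):
        return sho_amplitude(f, *np.abs(p)) - a

    sol = least_squares(
        residuals, x0, method="lm", xtol=STEP_TOL, ftol=STEP_TOL,
        gtol=STEP_TOL, max_nfev=MAX_ITER * 5,
    )
    if not sol.success:
        raise FitError("amplitude resonance fit did not converge",
                       last_iterate=sol.x)
    F0m, f_c, Q = np.abs(sol.x)
    return OscillatorFit(
        f_cant=float(f_c), Q=float(Q), F0_over_mstar=float(F0m),
        covariance=_covariance(sol),
        param_names=("F0_over_mstar", "f_cant", "Q"),
        fit_window=(lo, hi),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def _covariance(sol) -> np.ndarray | None:
    m, n = sol.jac.shape
    if m <= n:
        return None
    try:
        jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return None
    s2 = 2.0 * sol.cost / (m - n)
    return jtj_inv * s2


def effective_force(
    fit: OscillatorFit,
    frequencies: np.ndarray,
    model_tag: str = "constant",
    *,
    m_star: float | None = None,
    spring_constant: float | None = None,
    f_th: float | None = None,
    table: tuple | None = None,
) -> EffectiveForce:
    """Build the effective actuation force F(f) on a frequency grid.

    Models
    ------
    constant
        F(f) = F0, with F0 = (F0/m*) * m*.  ``m_star`` may be given directly
        or through ``spring_constant`` via m* = k / (2 pi f_cant)^2.
    thermal_lowpass
        First-order low-pass F0 / (1 + i f / f_th); reduces to ``constant``
        as f_th -> infinity.
    tabulated
        ``table = (f_tab, F_tab)`` interpolated (real and imaginary parts
        separately) onto the grid; extrapolation is refused.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if fit.param_names == ("F0",):
        F0 = fit.F0_over_mstar  # already in N (beam-model amplitude fit)
    else:
        if m_star is None:
            if spring_constant is None:
                raise ValidationError(
                    "need m_star or spring_constant to convert F0/m* to N"
                )
            m_star = spring_constant / (2.0 * math.pi * fit.f_cant) ** 2
        F0 = fit.F0_over_mstar * m_star

    if model_tag == "constant":
        F = np.full_like(frequencies, F0, dtype=complex)
    elif model_tag == "thermal_lowpass":
        if f_th is None or f_th <= 0:
            raise ValidationError("thermal_lowpass needs a positive f_th")
        F = F0 / (1.0 + 1j * frequencies / f_th)
    elif model_tag == "tabulated":
        if table is None:
            raise ValidationError("tabulated model needs a (f, F) table")
        f_tab = np.asarray(table[0], dtype=float)
        F_tab = np.asarray(table[1], dtype=complex)
        if frequencies[0] < f_tab[0] or frequencies[-1] > f_tab[-1]:
            raise ValidationError(
                "tabulated force does not cover the sweep band"
            )
        F = (np.interp(frequencies, f_tab, F_tab.real)
             + 1j * np.interp(frequencies, f_tab, F_tab.imag))
    else:
        raise ValidationError(f"unknown force model {model_tag!r}")
    return EffectiveForce(frequencies, F, model_tag)
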