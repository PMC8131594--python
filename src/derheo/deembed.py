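"""Mechanical de-embedding: from three coupled sweeps to the cell's g_c(f).

The cell mechanically couples the master and slave cantilevers.  Writing the
measured responses as chi_j(f) = A_j(f) * exp(-i phi_j(f)) for the three
laser configurations j in {MM, MS, SS}, the cellular transfer function is

    g_c(f) = chi_MS / (chi_MM * chi_SS - (F_m / F_s) * chi_MS**2) * F_m,

with F_m, F_s the effective actuation forces of master and slave.  g_c has
units N/m (a complex, frequency-dependent stiffness) and is independent of
the cantilever dynamics — the cantilevers are "de-embedded".

For unequal actuation forces the literal formula and the two-oscillator
forward model only agree under a force-normalisation convention on the
channels: the ``normalized`` convention (default) rescales the slave-driven
channel to the master force, chi_SS -> chi_SS * F_s / F_m, which restores the
exact algebraic inversion of the coupled-oscillator model; ``verbatim``
applies the formula as printed.  Both conventions coincide when F_m = F_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import EffectiveForce
from .io import FrequencySweep, ValidationError

__all__ = [
    "ComplexResponse",
    "to_complex",
    "from_complex",
    "extract_gc",
    "gc_pipeline",
    "ExtractionError",
    "GridError",
    "StageError",
]

DENOMINATOR_FLOOR_FACTOR = 1e-6  # x median |chi_MM * chi_SS|
MAX_GRID_MISMATCH = 0.01


class ExtractionError(RuntimeError):
    """The de-embedding is ill-conditioned on too much of the band."""


class GridError(ValueError):
    """Frequency grids cannot be reconciled."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class ComplexResponse:
    """A complex-valued response on a frequency grid.

    ``values`` units are context dependent: metres for chi, N/m for g_c,
    dimensionless for corrections.  ``flags`` marks ill-conditioned samples.
    """

    frequencies: np.ndarray
    values: np.ndarray
    label: str = ""
    flags: np.ndarray | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.frequencies.shape:
            raise ValidationError("values and frequencies differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite response values")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return self.frequencies.size

    def interp_to(self, frequencies: np.ndarray) -> "ComplexResponse":
        """Linear interpolation, real and imaginary parts separately."""
        frequencies = np.asarray(frequencies, dtype=float)
        f0 = self.frequencies
        if frequencies[0] < f0[0] or frequencies[-1] > f0[-1]:
            span = f0[-1] - f0[0]
            if (max(f0[0] - frequencies[0], 0)
                    + max(frequencies[-1] - f0[-1], 0)) > MAX_GRID_MISMATCH * span:
                raise GridError(
                    f"grid [{frequencies[0]:g}, {frequencies[-1]:g}] extends "
                    f"beyond [{f0[0]:g}, {f0[-1]:g}] by more than "
                    f"{MAX_GRID_MISMATCH:.0%} of the band"
                )
        re = np.interp(frequencies, f0, self.values.real)
        im = np.interp(frequencies, f0, self.values.imag)
        return ComplexResponse(frequencies, re + 1j * im, self.label)

    def __mul__(self, other):
        if isinstance(other, ComplexResponse):
            if not np.array_equal(other.frequencies, self.frequencies):
                other = other.interp_to(self.frequencies)
            return ComplexResponse(self.frequencies,
                                   self.values * other.values, self.label)
        return ComplexResponse(self.frequencies, self.values * other,
                               self.label)

    __rmul__ = __mul__


def to_complex(sweep: FrequencySweep) -> ComplexResponse:
    """chi(f) = A(f) * exp(-i phi(f)) on the sweep's grid."""
    values = sweep.amplitudes * np.exp(-1j * sweep.phases)
    return ComplexResponse(sweep.frequencies, values,
                           label=f"chi_{sweep.config_label}")


def from_complex(resp: ComplexResponse, config_label: str,
                 cell_id: str = "", metadata: dict | None = None,
                 unwrap: bool = True) -> FrequencySweep:
    """Inverse of :func:`to_complex`: (|chi|, -arg chi) as a sweep."""
    phases = -np.angle(resp.values)
    if unwrap:
        phases = np.unwrap(phases)
    return FrequencySweep(resp.frequencies, np.abs(resp.values), phases,
                          config_label, cell_id, metadata or {})


def _common_grid(*responses: ComplexResponse):
    f0 = responses[0].frequencies
    out = [responses[0]]
    for r in responses[1:]:
        if np.array_equal(r.frequencies, f0):
            out.append(r)
        else:
            out.append(r.interp_to(f0))
    return out


def extract_gc(
    chi_MM: ComplexResponse,
    chi_MS: ComplexResponse,
    chi_SS: ComplexResponse,
    F_m: EffectiveForce,
    F_s: EffectiveForce,
    convention: str = "normalized",
    floor_factor: float = DENOMINATOR_FLOOR_FACTOR,
    max_flagged_fraction: float = 0.2,
) -> ComplexResponse:
    """De-embed the cellular transfer function from the three chi channels.

    Returns g_c(f) in N/m with per-sample flags where the denominator modulus
    falls below ``floor_factor`` times the median of |chi_MM * chi_SS|
    (ill-conditioned extraction).  Raises :class:`ExtractionError` when more
    than ``max_flagged_fraction`` of the band is flagged.
    """
    chi_MM, chi_MS, chi_SS = _common_grid(chi_MM, chi_MS, chi_SS)
    f = chi_MM.frequencies
    Fm = F_m.F if np.array_equal(F_m.frequencies, f) else np.interp(
        f, F_m.frequencies, F_m.F.real) + 1j * np.interp(
        f, F_m.frequencies, F_m.F.imag)
    Fs = F_s.F if np.array_equal(F_s.frequencies, f) else np.interp(
        f, F_s.frequencies, F_s.F.real) + 1j * np.interp(
        f, F_s.frequencies, F_s.F.imag)
    if np.any(np.abs(Fm) == 0) or np.any(np.abs(Fs) == 0):
        raise ValidationError("actuation forces must be nonzero on the band")

    mm, ms, ss = chi_MM.values, chi_MS.values, chi_SS.values
    if convention == "normalized":
        # rescale the slave-driven channel onto the master force (chi_SS is
        # proportional to F_s; re-expressed per unit force and re-driven with
        # F_m), then the symmetric-force formula applies exactly
        denom = mm * (ss * Fm / Fs) - ms**2
        gc = ms / denom * Fm
    elif convention == "verbatim":
        denom = mm * ss - (Fm / Fs) * ms**2
        gc = ms / denom * Fm
    else:
        raise ValidationError(f"unknown convention {convention!r}")

    floor = floor_factor * np.median(np.abs(mm * ss))
    flags = np.abs(denom) < floor
    if flags.mean() > max_flagged_fraction:
        raise ExtractionError(
            f"denominator below floor on {flags.mean():.0%} of the band"
        )
    return ComplexResponse(f, gc, label="g_c", flags=flags)


def gc_pipeline(
    bundle,
    *,
    convention: str = "normalized",
    beam_correct: bool = True,
    n_modes: int = 6,
    calibration_model: str = "sho",
    force_model: str = "constant",
    keep_intermediates: bool = False,
):
    """Full extraction: calibrate -> subtract background -> shift actuation
    point -> de-embed.

    Parameters
    ----------
    bundle : ExperimentBundle
        Cantilever parameters, cell record and sweep paths (MM/MS/SS plus
        ``calibration_paths`` with cell-free master/slave sweeps).
    calibration_model : {"sho", "beam"}
        Resonance model used for the phase-background and amplitude fits.
        "sho" is the single-oscillator form; "beam" uses the same multi-mode
        surrogate that provides the laser-position correction, so that
        higher-mode response is not aliased into the background estimate.
    keep_intermediates : bool
        Also return a dict with the corrected sweeps, fits and forces.

    Returns
    -------
    ComplexResponse (g_c), or (ComplexResponse, dict) with intermediates.
    """
    from .beam import BeamModel, beam_response, laser_position_correction
    from .calibration import (effective_force, fit_amplitude_resonance,
                              fit_phase_background, subtract_phase_background)
    from .io import read_sweep

    sweeps = {}
    for label in ("MM", "MS", "SS"):
        path = bundle.sweep_paths.get(label)
        if path is None or not getattr(path, "exists", lambda: True)():
            raise StageError("load", f"missing {label} sweep")
        sweeps[label] = read_sweep(path) if not isinstance(
            path, FrequencySweep) else path
    cal_sweeps = {}
    for side in ("master", "slave"):
        path = bundle.calibration_paths.get(side)
        if path is None:
            raise StageError("load", f"missing {side} calibration sweep")
        cal_sweeps[side] = read_sweep(path) if not isinstance(
            path, FrequencySweep) else path

    cants = {"master": bundle.master, "slave": bundle.slave}
    beams = {s: BeamModel.from_cantilever(c, n_modes=n_modes)
             for s, c in cants.items()}
    inter = {"sweeps_raw": dict(sweeps)}

    # --- calibration on the cell-free sweeps -------------------------------
    fits, forces = {}, {}
    # The measured calibration phase is (structural phase at off-point
    # actuation) + b1 f + b2.  The background is therefore fitted on the raw
    # sweep — with the off-point structural phase as the resonance model when
    # calibration_model="beam" — subtracted, and only then is the actuation
    # point shifted and the amplitude fitted on the corrected response.
    for side in cal_sweeps:
        cant = cants[side]
        try:
            if calibration_model == "beam":
                def phase_model(f, _b=beams[side], _c=cant):
                    r = beam_response(_b, _c.z_blue, _c.z_red, f)
                    return np.unwrap(-np.angle(r))
                pfit = fit_phase_background(cal_sweeps[side],
                                            model=phase_model)
            else:
                pfit = fit_phase_background(cal_sweeps[side])
        except Exception as exc:
            raise StageError(f"calibrate:{side}", str(exc)) from exc
        fits[side] = pfit
        cal_flat = subtract_phase_background(cal_sweeps[side], pfit)
        if beam_correct and cant.z_blue != cant.z_red:
            C = laser_position_correction(
                beams[side], cant.z_blue, cant.z_red, cal_flat.frequencies)
            cal_corr = from_complex(to_complex(cal_flat) * C,
                                    cal_flat.config_label)
        else:
            cal_corr = cal_flat
        try:
            if calibration_model == "beam":
                def amp_model(f, _b=beams[side], _c=cant):
                    return np.abs(beam_response(_b, _c.z_red, _c.z_red, f))
                afit = fit_amplitude_resonance(cal_corr, model=amp_model)
            else:
                afit = fit_amplitude_resonance(cal_corr)
        except Exception as exc:
            raise StageError(f"calibrate:{side}", str(exc)) from exc
        forces[side] = effective_force(
            afit, sweeps["MM"].frequencies, force_model,
            spring_constant=cant.spring_constant,
        )
        inter[f"calibration_fit_{side}"] = (pfit, afit)

    # --- background subtraction + actuation-point shift on the cell sweeps -
    # readout chains: MM reads the master photodiode, MS and SS the slave's;
    # actuation: MM and MS drive the master, SS drives the slave.
    chain = {"MM": "master", "MS": "slave", "SS": "slave"}
    drive = {"MM": "master", "MS": "master", "SS": "slave"}
    chis = {}
    for label, sweep in sweeps.items():
        flat = subtract_phase_background(sweep, fits[chain[label]])
        chi = to_complex(flat)
        cant = cants[drive[label]]
        if beam_correct and cant.z_blue != cant.z_red:
            try:
                C = laser_position_correction(
                    beams[drive[label]], cant.z_blue, cant.z_red,
                    chi.frequencies)
            except Exception as exc:
                raise StageError(f"beam:{label}", str(exc)) from exc
            chi = chi * C
        chis[label] = chi
        inter[f"chi_{label}"] = chi

    try:
        gc = extract_gc(chis["MM"], chis["MS"], chis["SS"],
                        forces["master"], forces["slave"],
                        convention=convention)
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc
    if keep_intermediates:
        inter["forces"] = forces
        return gc, inter
    return gc
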