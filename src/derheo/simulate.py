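"""Forward simulation of the coupled cantilever-cell-cantilever system.

The lumped-element model treats each cantilever as a driven damped oscillator
(spring k_j, dashpot c_j, effective mass m_j) and the cell as a complex,
frequency-dependent spring k_c*(f) coupling the two.  In the harmonic regime
the equations of motion

    k_m x_m + c_m x'_m + m_m x''_m - k_c (x_s - x_m) = F_m e^{i w t}
    k_s x_s + c_s x'_s + m_s x''_s - k_c (x_m - x_s) = 0

reduce per frequency to a 2x2 complex linear system.  With the cantilever-
alone receptances g_j(f) = 1 / (k_j + 2 pi i f c_j - (2 pi f)^2 m_j) the
master-driven steady state is

    (x_m - x_s) = g_m F_m / (1 + k_c (g_m + g_s))
    x_m = g_m F_m (1 + k_c g_s) / (1 + k_c (g_m + g_s))
    x_s = k_c g_s g_m F_m / (1 + k_c (g_m + g_s)),

and the slave-driven case follows by exchanging labels.  The same algebra
holds verbatim for the multi-mode beam surrogate with the scalars g_j
replaced by the point receptances at the cell contact, plus transfer
receptances from the drive point and to the readout point: this is the
"beam variant" used to emulate distributed cantilevers with off-point
actuation.

The generator emits the three measured configurations (MM, MS, SS) as
amplitude/phase sweeps, optionally with an injected linear phase background
(the electronics time delay), multiplicative log-normal amplitude noise and
additive Gaussian phase noise.  It is the package's ground-truth testbed:
extraction-pipeline outputs can be compared against the k_c*(f) that
generated them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .beam import BeamModel, beam_response
from .calibration import EffectiveForce
from .deembed import ComplexResponse, from_complex
from .geometry import geometry_factor
from .io import CantileverParams, CellRecord, FrequencySweep, ValidationError
from .rheology import F0_DEFAULT, eval_model

__all__ = [
    "LumpedSystem",
    "steady_state_response",
    "simulate_sweeps",
    "simulate_calibration_sweep",
    "stiffening_series",
    "make_cell_system",
    "default_system",
    "K_CELL_DEFAULT",
]

K_CELL_DEFAULT = 3e-3  # N/m, baseline cell spring constant
SPRING_DEFAULT = 0.35  # N/m
F_CANT_DEFAULT = 10e3  # Hz, soft cantilever resonance in liquid
Q_DEFAULT = 3.0


def _oscillator_constants(k: float, f_cant: float, Q: float):
    omega0 = 2.0 * math.pi * f_cant
    m = k / omega0**2
    c = m * omega0 / Q
    return m, c


@dataclass
class LumpedSystem:
    """Two driven oscillators coupled by a complex cell stiffness.

    ``k_c_star`` may be a real/complex constant, an array on the working
    grid, or a callable ``k_c_star(f) -> complex array``.
    """

    k_m: float
    k_s: float
    c_m: float
    c_s: float
    m_m: float
    m_s: float
    k_c_star: complex | np.ndarray | Callable = K_CELL_DEFAULT
    F_m: float = 1e-9
    F_s: float = 1e-9

    def __post_init__(self):
        for name in ("k_m", "k_s", "c_m", "c_s", "m_m", "m_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.F_m <= 0 or self.F_s <= 0:
            raise ValidationError("drive forces must be positive")

    @classmethod
    def from_cantilevers(cls, master: CantileverParams,
                         slave: CantileverParams,
                         k_c_star=K_CELL_DEFAULT,
                         F_m: float = 1e-9, F_s: float = 1e-9):
        m_m, c_m = _oscillator_constants(master.spring_constant,
                                         master.f_cant, master.Q)
        m_s, c_s = _oscillator_constants(slave.spring_constant,
                                         slave.f_cant, slave.Q)
        return cls(master.spring_constant, slave.spring_constant,
                   c_m, c_s, m_m, m_s, k_c_star, F_m, F_s)

    def kc(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if callable(self.k_c_star):
            return np.asarray(self.k_c_star(f), dtype=complex)
        kc = np.asarray(self.k_c_star, dtype=complex)
        if kc.ndim == 0:
            return np.full(f.shape, complex(kc))
        if kc.shape != f.shape:
            raise ValidationError("tabulated k_c_star grid mismatch")
        return kc

    def g_m(self, f) -> np.ndarray:
        """Master cantilever-alone receptance (m/N)."""
        w = 2.0 * math.pi * np.asarray(f, dtype=float)
        return 1.0 / (self.k_m + 1j * w * self.c_m - w**2 * self.m_m)

    def g_s(self, f) -> np.ndarray:
        w = 2.0 * math.pi * np.asarray(f, dtype=float)
        return 1.0 / (self.k_s + 1j * w * self.c_s - w**2 * self.m_s)


def default_system(k_c_star=K_CELL_DEFAULT, **kwargs) -> LumpedSystem:
    """Symmetric system with the experiment-scale defaults
    (k = 0.35 N/m, f_cant = 10 kHz, Q = 3, k_c = 3 mN/m)."""
    m, c = _oscillator_constants(SPRING_DEFAULT, F_CANT_DEFAULT, Q_DEFAULT)
    return LumpedSystem(SPRING_DEFAULT, SPRING_DEFAULT, c, c, m, m,
                        k_c_star, **kwargs)


def _coupled(drive_recept, read_drive_side, read_other_side,
             contact_drive, contact_other, kc, F):
    """Coupled steady state for one drive side.

    Parameters are receptances on the working grid: ``drive_recept`` maps the
    drive point to the cell contact; ``contact_*`` are point receptances at
    the contact; ``read_*`` map drive point / contact to the readout points.
    Returns (x at driven-side readout, x at other-side readout).
    """
    denom = 1.0 + kc * (contact_drive + contact_other)
    if np.any(np.abs(denom) == 0) or np.any(~np.isfinite(denom)):
        f_bad = np.nonzero(~np.isfinite(denom) | (np.abs(denom) == 0))[0]
        raise ValidationError(
            f"singular coupled system at grid index {f_bad[:3]}"
        )
    stretch = drive_recept["to_contact"] * F / denom  # x_drive - x_other
    x_driven = drive_recept["to_read"] * F \
        - kc * stretch * read_drive_side
    x_other = kc * stretch * read_other_side
    return x_driven, x_other


def steady_state_response(sys: LumpedSystem, drive: str, f_grid,
                          beam=None, z_blue: float = 0.1,
                          z_red: float = 0.9, z_cell: float | None = None):
    """Harmonic response (X_m, X_s) of the coupled system.

    ``drive`` is ``"master"`` or ``"slave"``.  Without a beam, the lumped
    receptances are used and the laser positions are irrelevant.  With
    ``beam`` (a :class:`BeamModel` or a (master, slave) pair) the force is
    applied at ``z_blue``, the displacement read at ``z_red`` and the cell
    couples the two beams at ``z_cell`` (defaults to ``z_red``).
    """
    f = np.asarray(f_grid, dtype=float)
    kc = sys.kc(f)
    if drive not in ("master", "slave"):
        raise ValidationError(f"drive must be master or slave, got {drive!r}")

    if beam is None:
        g = {"master": sys.g_m(f), "slave": sys.g_s(f)}
        F = {"master": sys.F_m, "slave": sys.F_s}[drive]
        other = "slave" if drive == "master" else "master"
        x_d, x_o = _coupled(
            {"to_contact": g[drive], "to_read": g[drive]},
            g[drive], g[other], g[drive], g[other], kc, F)
    else:
        if isinstance(beam, BeamModel):
            beams = {"master": beam, "slave": beam}
        else:
            beams = {"master": beam[0], "slave": beam[1]}
        if z_cell is None:
            z_cell = z_red
        R = {}
        for side, b in beams.items():
            R[side] = {
                "bc": beam_response(b, z_blue, z_cell, f),
                "br": beam_response(b, z_blue, z_red, f),
                "cc": beam_response(b, z_cell, z_cell, f),
                "cr": beam_response(b, z_cell, z_red, f),
            }
        F = {"master": sys.F_m, "slave": sys.F_s}[drive]
        other = "slave" if drive == "master" else "master"
        x_d, x_o = _coupled(
            {"to_contact": R[drive]["bc"], "to_read": R[drive]["br"]},
            R[drive]["cr"], R[other]["cr"],
            R[drive]["cc"], R[other]["cc"], kc, F)

    if drive == "master":
        X_m, X_s = x_d, x_o
    else:
        X_m, X_s = x_o, x_d
    return (ComplexResponse(f, X_m, label=f"X_m|{drive}"),
            ComplexResponse(f, X_s, label=f"X_s|{drive}"))


def _emit_sweep(resp: ComplexResponse, label: str, chain: str,
                background, noise, rng, cell_id="") -> FrequencySweep:
    sweep = from_complex(resp, label, cell_id)
    amps = sweep.amplitudes.copy()
    phases = sweep.phases.copy()
    if background:
        b1, b2 = background[chain] if isinstance(background, dict) \
            else background
        phases = phases + b1 * sweep.frequencies + b2
    if noise:
        a_sig = noise.get("amplitude_sigma", 0.0)
        p_sig = noise.get("phase_sigma", 0.0)
        if a_sig:
            amps = amps * rng.lognormal(0.0, a_sig, amps.size)
        if p_sig:
            phases = phases + rng.normal(0.0, p_sig, phases.size)
    return FrequencySweep(sweep.frequencies, amps, phases, label, cell_id,
                          dict(sweep.metadata))


def simulate_sweeps(sys: LumpedSystem, f_grid, noise: dict | None = None,
                    background=None, beam=None, seed=None,
                    z_blue: float = 0.1, z_red: float = 0.9,
                    z_cell: float | None = None, cell_id: str = ""):
    """Emit the three configuration sweeps (MM, MS, SS).

    MM is the driven master read at the master, MS the slave read under
    master drive, SS the driven slave read at the slave.  ``background`` is
    an injected linear phase background, either one ``(b1, b2)`` pair or a
    dict keyed ``"master"``/``"slave"`` per readout chain (MM reads the
    master chain; MS and SS read the slave chain).  ``noise`` holds
    ``amplitude_sigma`` (multiplicative log-normal) and ``phase_sigma``
    (additive Gaussian, rad); both default to off.  Fixed ``seed`` gives
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    X_m, X_s = steady_state_response(sys, "master", f_grid, beam,
                                     z_blue, z_red, z_cell)
    _, X_ss = steady_state_response(sys, "slave", f_grid, beam,
                                    z_blue, z_red, z_cell)
    mm = _emit_sweep(X_m, "MM", "master", background, noise, rng, cell_id)
    ms = _emit_sweep(X_s, "MS", "slave", background, noise, rng, cell_id)
    ss = _emit_sweep(X_ss, "SS", "slave", background, noise, rng, cell_id)
    return mm, ms, ss


def simulate_calibration_sweep(sys: LumpedSystem, side: str, f_grid,
                               background=None, noise: dict | None = None,
                               beam=None, seed=None, z_blue: float = 0.1,
                               z_red: float = 0.9) -> FrequencySweep:
    """Cell-free single-cantilever sweep of one side (for calibration fits)."""
    f = np.asarray(f_grid, dtype=float)
    rng = np.random.default_rng(seed)
    F = {"master": sys.F_m, "slave": sys.F_s}[side]
    if beam is None:
        g = sys.g_m(f) if side == "master" else sys.g_s(f)
        resp = ComplexResponse(f, g * F)
    else:
        b = beam if isinstance(beam, BeamModel) else (
            beam[0] if side == "master" else beam[1])
        resp = ComplexResponse(f, beam_response(b, z_blue, z_red, f) * F)
    label = "MM" if side == "master" else "SS"
    return _emit_sweep(resp, label, side, background, noise, rng)


def stiffening_series(sys: LumpedSystem, k_c_multipliers: Sequence[float],
                      f_grid, **kwargs):
    """One (MM, MS, SS) triple per stiffness multiplier.

    Mimics chemically induced stiffening: the baseline cell stiffness is
    scaled by each multiplier (>= 1, increasing).  Multiplier 1 reproduces
    the baseline sweeps.
    """
    mult = np.asarray(k_c_multipliers, dtype=float)
    if np.any(mult < 1) or np.any(np.diff(mult) <= 0):
        raise ValidationError("multipliers must be >= 1 and increasing")
    base = sys.k_c_star
    triples = []
    for m in mult:
        if callable(base):
            scaled = (lambda f, _m=m: _m * np.asarray(base(f), dtype=complex))
        else:
            scaled = base * m
        scaled_sys = LumpedSystem(sys.k_m, sys.k_s, sys.c_m, sys.c_s,
                                  sys.m_m, sys.m_s, scaled, sys.F_m, sys.F_s)
        triples.append(simulate_sweeps(scaled_sys, f_grid, **kwargs))
    return triples


def make_cell_system(master: CantileverParams, slave: CantileverParams,
                     cell: CellRecord, rheology: tuple,
                     f0: float = F0_DEFAULT,
                     F_m: float = 1e-9, F_s: float = 1e-9) -> LumpedSystem:
    """Bind a rheological model and the SSLC geometry into a forward system.

    ``rheology`` is ``(model_id, params)``; the cell stiffness is
    k_c*(f) = G * E*(f) with G the geometry factor of the compressed cell.
    """
    model_id, params = rheology
    G = geometry_factor(cell).G

    def k_c_star(f):
        m = eval_model(model_id, params, f, f0)
        return G * m.complex

    return LumpedSystem.from_cantilevers(master, slave, k_c_star, F_m, F_s)
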