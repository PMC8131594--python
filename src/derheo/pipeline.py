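"""End-to-end validation harness: forward-simulate, extract, compare.

The de-embedding framework is validated the way the method itself was:
forward-generate the three configuration sweeps from a known complex cell
stiffness using the multi-mode beam surrogate with off-point actuation and an
injected electronics phase background, push them through the full extraction
pipeline (phase-background fit and subtraction, laser-position correction,
force calibration, the g_c formula), and measure the worst-case relative
deviation of the extracted g_c(f) from the generating ground truth over the
band.  Five qualitatively different cortical rheologies (double power-law,
structural damping, Maxwell, polynomial, oscillating polynomial) probe the
extraction independently of any particular material model.

A second harness holds g_c fixed and perturbs the assumed cortical thickness
in the shell-geometry conversion, quantifying how thickness uncertainty
propagates into the reported moduli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamModel
from .deembed import ComplexResponse, gc_pipeline
from .geometry import geometry_factor
from .io import CantileverParams, CellRecord, ExperimentBundle
from .rheology import F0_DEFAULT, PowerLawParams, eval_model
from .simulate import (K_CELL_DEFAULT, LumpedSystem, simulate_calibration_sweep,
                       simulate_sweeps)

__all__ = [
    "band_grid",
    "default_cantilever",
    "default_cell",
    "reference_rheologies",
    "ValidationResult",
    "run_validation",
    "run_lumped_validation",
    "thickness_sensitivity",
    "synthetic_population",
    "DEFAULT_BACKGROUNDS",
]

# per-readout-chain electronics backgrounds injected by the harness
DEFAULT_BACKGROUNDS = {"master": (5e-5, 0.3), "slave": (3e-5, -0.2)}
BAND = (1e3, 38e3)
GRID_STEP = 200.0


def band_grid(f_lo: float = BAND[0], f_hi: float = BAND[1],
              step: float = GRID_STEP) -> np.ndarray:
    """The measurement grid: 1-38 kHz at 200 Hz spacing by default."""
    n = int(round((f_hi - f_lo) / step)) + 1
    return f_lo + step * np.arange(n)


def default_cantilever(name: str = "master") -> CantileverParams:
    """Soft-cantilever defaults: k = 0.35 N/m, f_cant = 10 kHz, Q = 3."""
    return CantileverParams(
        spring_constant=0.35, f_cant=10e3, Q=3.0, length=100e-6,
        z_blue=0.1, z_red=0.9, name=name,
    )


def default_cell(h_cort: float = 200e-9) -> CellRecord:
    """A 10 um radius cell compressed by 1 um (density 1040 kg/m^3)."""
    R = 10e-6
    density = 1040.0
    mass = 4.0 / 3.0 * math.pi * R**3 * density
    return CellRecord(mass=mass, density=density, compression=1e-6,
                      h_cort=h_cort, cell_id="sim")


def reference_rheologies(cell: CellRecord | None = None) -> dict:
    """Five ground-truth cortical rheologies for pipeline validation.

    The modulus scale is anchored so that the resulting cell stiffness
    |k_c*| = G |E*| is of order the experimental 3 mN/m at the normalisation
    frequency, whatever the geometry factor G of the simulated cell.
    """
    cell = cell or default_cell()
    G = geometry_factor(cell).G
    s = K_CELL_DEFAULT / G  # Pa
    return {
        "double_pl": ("double_pl",
                      {"A": s, "B": 0.05 * s, "alpha": 0.1, "beta": 0.9}),
        "structural_damping": ("structural_damping",
                               {"A": s, "alpha": 0.15, "mu": 0.02 * s}),
        "maxwell": ("maxwell", {"E": 2.0 * s, "f_r": 10e3}),
        "polynomial": ("polynomial",
                       {"real_coeffs": (0.8 * s, 0.15 * s, 0.002 * s),
                        "imag_coeffs": (0.0, 0.05 * s, 0.001 * s)}),
        "oscillating_polynomial": (
            "oscillating_polynomial",
            {"real_coeffs": (0.8 * s, 0.15 * s, 0.002 * s),
             "imag_coeffs": (0.0, 0.05 * s, 0.001 * s),
             "ripple": 0.1, "f_osc": 10e3}),
    }


@dataclass
class ValidationResult:
    """Extracted vs ground-truth transfer function for one rheology."""

    model_id: str
    gc_extracted: ComplexResponse
    gc_truth: ComplexResponse

    @property
    def relative_deviation(self) -> np.ndarray:
        return (np.abs(self.gc_extracted.values - self.gc_truth.values)
                / np.abs(self.gc_truth.values))

    @property
    def max_relative_deviation(self) -> float:
        return float(np.max(self.relative_deviation))

    @property
    def max_part_deviation(self) -> float:
        """Worst deviation of real and imaginary parts, relative to |g_c|."""
        d = self.gc_extracted.values - self.gc_truth.values
        mag = np.abs(self.gc_truth.values)
        return float(max(np.max(np.abs(d.real) / mag),
                         np.max(np.abs(d.imag) / mag)))


def run_validation(
    rheology: tuple,
    *,
    f_grid: np.ndarray | None = None,
    n_modes: int = 6,
    n_modes_sim: int = 12,
    backgrounds: dict = DEFAULT_BACKGROUNDS,
    noise: dict | None = None,
    seed: int | None = None,
    calibration_model: str = "beam",
    convention: str = "normalized",
    cell: CellRecord | None = None,
    f0: float = F0_DEFAULT,
) -> ValidationResult:
    """Forward-generate, run the full pipeline, compare with ground truth.

    ``rheology`` is ``(model_id, params)`` for the cortical modulus; the
    ground-truth cell stiffness is k_c*(f) = G E*(f).  The sweeps are
    generated with the multi-mode beam surrogate (actuation at z_blue = 0.1 L,
    readout at z_red = 0.9 L, cell contact at the readout spot) and injected
    per-chain linear phase backgrounds; the pipeline re-estimates everything
    from the generated calibration sweeps.

    The simulated "reality" retains ``n_modes_sim`` modes (default 12, at
    which the response is converged on the band), while the pipeline corrects
    with its own ``n_modes`` (default 6) — the same kind of structural
    mismatch the extraction faces against a full distributed model, so the
    measured deviation reflects genuine model error, not round-off.
    """
    f = band_grid() if f_grid is None else np.asarray(f_grid, dtype=float)
    cell = cell or default_cell()
    master = default_cantilever("master")
    slave = default_cantilever("slave")
    beams = (BeamModel.from_cantilever(master, n_modes=n_modes_sim),
             BeamModel.from_cantilever(slave, n_modes=n_modes_sim))

    model_id, params = rheology
    G = geometry_factor(cell).G

    def k_c_star(fgrid):
        return G * eval_model(model_id, params, fgrid, f0).complex

    sys = LumpedSystem.from_cantilevers(master, slave, k_c_star,
                                        F_m=1e-9, F_s=1e-9)
    rng = np.random.default_rng(seed)

    def sub_seed():
        return int(rng.integers(0, 2**31 - 1)) if noise else None

    mm, ms, ss = simulate_sweeps(
        sys, f, noise=noise, background=backgrounds, beam=beams,
        seed=sub_seed(), z_blue=master.z_blue, z_red=master.z_red,
        cell_id=cell.cell_id,
    )
    cal_m = simulate_calibration_sweep(
        sys, "master", f, background=backgrounds["master"], noise=noise,
        beam=beams[0], seed=sub_seed(), z_blue=master.z_blue,
        z_red=master.z_red)
    cal_s = simulate_calibration_sweep(
        sys, "slave", f, background=backgrounds["slave"], noise=noise,
        beam=beams[1], seed=sub_seed(), z_blue=slave.z_blue,
        z_red=slave.z_red)

    bundle = ExperimentBundle(
        master, slave, cell,
        sweep_paths={"MM": mm, "MS": ms, "SS": ss},
        calibration_paths={"master": cal_m, "slave": cal_s},
    )
    gc = gc_pipeline(bundle, convention=convention, beam_correct=True,
                     n_modes=n_modes, calibration_model=calibration_model)
    truth = ComplexResponse(f, k_c_star(f), label="k_c*")
    return ValidationResult(model_id, gc, truth)


def run_lumped_validation(
    rheology: tuple,
    *,
    f_grid: np.ndarray | None = None,
    backgrounds: dict = DEFAULT_BACKGROUNDS,
    noise: dict | None = None,
    seed: int | None = None,
    cell: CellRecord | None = None,
) -> ValidationResult:
    """Full loop on the lumped generator: build the cell system from a
    rheology and the shell geometry, simulate the three sweeps with injected
    phase backgrounds (colocated lasers, so no beam correction is involved),
    run the extraction pipeline and compare with the generating k_c*(f).

    This isolates the calibration and de-embedding algebra from beam-model
    mismatch; :func:`run_validation` is the beam-variant counterpart.
    """
    from .simulate import (LumpedSystem, simulate_calibration_sweep,
                           simulate_sweeps)

    f = band_grid() if f_grid is None else np.asarray(f_grid, dtype=float)
    cell = cell or default_cell()
    cant_m = default_cantilever("master")
    cant_s = default_cantilever("slave")
    cant_m.z_blue = cant_m.z_red
    cant_s.z_blue = cant_s.z_red

    model_id, params = rheology
    G = geometry_factor(cell).G

    def k_c_star(fgrid):
        return G * eval_model(model_id, params, fgrid).complex

    sys = LumpedSystem.from_cantilevers(cant_m, cant_s, k_c_star,
                                        F_m=1e-9, F_s=1e-9)
    rng = np.random.default_rng(seed)

    def sub_seed():
        return int(rng.integers(0, 2**31 - 1)) if noise else None

    mm, ms, ss = simulate_sweeps(sys, f, noise=noise, background=backgrounds,
                                 seed=sub_seed(), cell_id=cell.cell_id)
    cal_m = simulate_calibration_sweep(sys, "master", f,
                                       background=backgrounds["master"],
                                       noise=noise, seed=sub_seed())
    cal_s = simulate_calibration_sweep(sys, "slave", f,
                                       background=backgrounds["slave"],
                                       noise=noise, seed=sub_seed())
    bundle = ExperimentBundle(cant_m, cant_s, cell,
                              {"MM": mm, "MS": ms, "SS": ss},
                              {"master": cal_m, "slave": cal_s})
    gc = gc_pipeline(bundle, calibration_model="sho")
    truth = ComplexResponse(f, k_c_star(f), label="k_c*")
    return ValidationResult(model_id, gc, truth)


def thickness_sensitivity(
    gc: ComplexResponse | None = None,
    *,
    h_nominal: float = 200e-9,
    spread: float = 0.36,
    n_steps: int = 9,
    cell: CellRecord | None = None,
) -> dict:
    """Propagate cortical-thickness uncertainty into the extracted moduli.

    Holding the de-embedded g_c(f) fixed, the moduli are recomputed with the
    shell thickness swept over ``h_nominal * (1 +/- spread)``.  The reported
    ``relative_variation`` is the half-range of the induced moduli spread
    relative to the nominal moduli, i.e. the +/- variation a thickness
    uncertainty of ``spread`` induces.  Because the geometry factor is linear
    in the thickness, the number is frequency independent.
    """
    base_cell = cell or default_cell(h_cort=h_nominal)
    if gc is None:
        rheo = reference_rheologies(base_cell)["double_pl"]
        modulus = eval_model(rheo[0], rheo[1], band_grid())
        G0 = geometry_factor(base_cell).G
        gc = ComplexResponse(modulus.frequencies, G0 * modulus.complex)

    h_values = h_nominal * np.linspace(1.0 - spread, 1.0 + spread, n_steps)
    moduli = {}
    for h in h_values:
        cell_h = CellRecord(mass=base_cell.mass, density=base_cell.density,
                            compression=base_cell.compression, h_cort=float(h),
                            cell_id=base_cell.cell_id)
        E = gc.values / geometry_factor(cell_h).G
        moduli[float(h)] = E
    stack = np.stack([np.abs(m) for m in moduli.values()])
    nominal = np.abs(gc.values / geometry_factor(base_cell).G)
    half_range = (stack.max(axis=0) - stack.min(axis=0)) / 2.0
    rel = half_range / nominal
    return {
        "h_values": h_values,
        "relative_variation": float(np.max(rel)),
        "relative_variation_mean": float(np.mean(rel)),
        "moduli": moduli,
    }


def synthetic_population(n_cells: int = 10, seed: int | None = None,
                         scenario: str = "uncorrelated",
                         scale_sigma: float = 0.2) -> dict:
    """Draw a per-cell population of radii and double power-law parameters.

    Cells mirror rounded HeLa scale: radius ~7-11 um (from a mass draw at
    density 1040 kg/m^3), cortical thickness 194 +/- 27 nm, and double
    power-law parameters around (A = 1 kPa, B = 50 Pa, alpha = 0.1,
    beta = 0.9) with ``scale_sigma`` log-normal scale spread (default 20%,
    the biological scatter regime) and 0.02 exponent spread.  ``scenario``
    selects how the modulus scale relates to the radius: "uncorrelated"
    (the null), "constant_pressure" (A proportional to 1/R) or
    "constant_tension" (A proportional to 1/R^2).
    """
    rng = np.random.default_rng(seed)
    R0 = 9e-6
    R = rng.uniform(7e-6, 11e-6, n_cells)
    h = rng.normal(194e-9, 27e-9, n_cells).clip(100e-9, 300e-9)
    A = rng.lognormal(math.log(1000.0), scale_sigma, n_cells)
    B = rng.lognormal(math.log(50.0), scale_sigma, n_cells)
    alpha = rng.normal(0.10, 0.02, n_cells).clip(0.01, 0.5)
    beta = rng.normal(0.90, 0.02, n_cells).clip(0.5, 0.99)
    if scenario == "constant_pressure":
        factor = R0 / R
    elif scenario == "constant_tension":
        factor = (R0 / R) ** 2
    elif scenario == "uncorrelated":
        factor = np.ones(n_cells)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    A = A * factor
    B = B * factor
    params = [PowerLawParams(a, b, al, be)
              for a, b, al, be in zip(A, B, alpha, beta)]
    return {"R": R, "h_cort": h, "params": params,
            "generator_means": {"A": 1000.0 * float(np.mean(factor)),
                                "B": 50.0 * float(np.mean(factor)),
                                "alpha": 0.10, "beta": 0.90}}
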