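"""Sweep files, experiment configuration and the core record types.

A frequency sweep is one amplitude/phase record of the cantilever readout for
one laser configuration (MM, MS or SS).  Sweeps travel as plain UTF-8 CSV with
``#``-prefixed metadata header lines and the fixed column order
``frequency_hz, amplitude_m, phase_rad``; everything downstream works on the
validated in-memory :class:`FrequencySweep`.

Conventions used throughout the package:

* phases are stored in radians, as the measured lag (positive); degree input
  is converted at the boundary only,
* the complex response associated with a sweep is ``A * exp(-1j * phi)``,
* frequency grids are strictly increasing and positive.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FrequencySweep",
    "CantileverParams",
    "CellRecord",
    "ExperimentBundle",
    "read_sweep",
    "write_sweep",
    "load_experiment",
    "FormatError",
    "ValidationError",
]

FORMAT_VERSION = "derheo-sweep-1"
CONFIG_LABELS = ("MM", "MS", "SS")


class FormatError(ValueError):
    """A sweep file does not follow the expected dialect."""


class ValidationError(ValueError):
    """A record violates one of its invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class FrequencySweep:
    """One configuration's (f, A, phi) record.

    Parameters
    ----------
    frequencies : array of float
        Hz, strictly increasing, positive.
    amplitudes : array of float
        Metres, non-negative.
    phases : array of float
        Radians; the measured lag on a continuous (unwrapped) branch.
    config_label : {"MM", "MS", "SS"}
    cell_id : str
    metadata : dict
        Free key/value pairs (temperature, compression, laser positions, ...).
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    config_label: str
    cell_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = _as_float_array(self.frequencies, "frequencies")
        self.amplitudes = _as_float_array(self.amplitudes, "amplitudes")
        self.phases = _as_float_array(self.phases, "phases")
        n = self.frequencies.size
        if n < 2:
            raise ValidationError("a sweep needs at least 2 samples")
        if self.amplitudes.size != n or self.phases.size != n:
            raise ValidationError(
                f"array length mismatch: f={n}, A={self.amplitudes.size}, "
                f"phi={self.phases.size}"
            )
        df = np.diff(self.frequencies)
        if np.any(df <= 0):
            idx = int(np.argmax(df <= 0))
            raise ValidationError(
                f"frequencies not strictly increasing at index {idx + 1}"
            )
        if self.frequencies[0] <= 0:
            raise ValidationError("frequencies must be positive")
        if np.any(self.amplitudes < 0):
            raise ValidationError("amplitudes must be non-negative")
        if self.config_label not in CONFIG_LABELS:
            raise ValidationError(
                f"config_label must be one of {CONFIG_LABELS}, "
                f"got {self.config_label!r}"
            )

    def __len__(self) -> int:
        return self.frequencies.size

    def with_phases(self, phases: np.ndarray) -> "FrequencySweep":
        return replace(self, phases=np.asarray(phases, dtype=float))

    def with_amplitudes(self, amplitudes: np.ndarray) -> "FrequencySweep":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=float))


@dataclass
class CantileverParams:
    """Calibration metadata of one microcantilever.

    ``spring_constant`` is the static stiffness at the readout point,
    ``f_cant`` the (first) resonance frequency in liquid, ``Q`` the quality
    factor, ``length`` the cantilever length and ``z_blue``/``z_red`` the
    actuation and readout laser spot centres as fractions of the length.
    The effective mass obeys the single-oscillator identity
    ``m_star = spring_constant / (2 pi f_cant)**2``.
    """

    spring_constant: float  # N/m
    f_cant: float  # Hz
    Q: float
    length: float  # m
    z_blue: float = 0.1  # fraction of L
    z_red: float = 0.9  # fraction of L
    m_star: float | None = None  # kg
    geometry_tag: str = "rectangular"
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("spring_constant", "f_cant", "Q", "length"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        for attr in ("z_blue", "z_red"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{attr} must lie in [0, 1], got {v}")
        if self.geometry_tag not in ("rectangular", "triangular"):
            raise ValidationError(f"unknown geometry_tag {self.geometry_tag!r}")
        m_implied = self.spring_constant / (2.0 * math.pi * self.f_cant) ** 2
        if self.m_star is None:
            self.m_star = m_implied
        elif abs(self.m_star - m_implied) > 0.01 * m_implied:
            raise ValidationError(
                "m_star inconsistent with spring_constant and f_cant "
                f"(got {self.m_star:.4g}, expected {m_implied:.4g} within 1%)"
            )


@dataclass
class CellRecord:
    """Per-cell geometry inputs; radius and volume derive from the mass."""

    mass: float  # kg
    density: float = 1040.0  # kg/m^3
    compression: float = 1e-6  # m, plate approach distance Delta
    h_cort: float = 200e-9  # m, assumed cortical thickness
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.density <= 0:
            raise ValidationError("mass and density must be positive")
        if self.h_cort <= 0:
            raise ValidationError("h_cort must be positive")
        if self.compression < 0:
            raise ValidationError("compression must be non-negative")
        if self.compression >= 2.0 * self.radius:
            raise ValidationError(
                f"compression {self.compression:.3g} m >= cell diameter "
                f"{2 * self.radius:.3g} m"
            )
        if self.h_cort >= self.radius:
            raise ValidationError("h_cort must be smaller than the cell radius")

    @property
    def radius(self) -> float:
        """Free (spherical) cell radius, R = (3 m / (4 pi rho))^(1/3)."""
        return (3.0 * self.mass / (4.0 * math.pi * self.density)) ** (1.0 / 3.0)

    @property
    def volume(self) -> float:
        return self.mass / self.density


@dataclass
class ExperimentBundle:
    """Cross-validated inputs for one cell: cantilevers, cell, sweep paths."""

    master: CantileverParams
    slave: CantileverParams
    cell: CellRecord
    sweep_paths: dict  # config label -> Path
    calibration_paths: dict = field(default_factory=dict)  # "master"/"slave"


# ---------------------------------------------------------------------------
# sweep file I/O


def _unwrap(phases: np.ndarray) -> np.ndarray:
    return np.unwrap(phases)


def read_sweep(path, dialect: Mapping | None = None) -> FrequencySweep:
    """Read a sweep CSV and return a validated :class:`FrequencySweep`.

    The dialect mapping may declare ``phase_unit`` ("rad", default, or "deg")
    and ``deflection_sensitivity`` (m/V) for amplitude columns recorded in
    volts; header metadata keys of the same names take precedence.  Phases are
    unwrapped to a continuous branch on read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such sweep file: {path}")
    meta: dict = {}
    lines = path.read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith(FORMAT_VERSION):
                for token in body.split()[1:]:
                    key, _, value = token.partition("=")
                    meta[key] = value
            elif "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            data_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[data_start:])),
                     float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]

    cols = {c.lower(): c for c in df.columns}
    dialect = dict(dialect or {})

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    fcol = pick("frequency_hz", "frequency", "f_hz", "f")
    acol = pick("amplitude_m", "amplitude", "amplitude_v", "a")
    pcol = pick("phase_rad", "phase", "phase_deg", "phi")
    missing = [n for n, c in
               [("frequency", fcol), ("amplitude", acol), ("phase", pcol)]
               if c is None]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")

    freq = df[fcol].to_numpy(dtype=float)
    amp = df[acol].to_numpy(dtype=float)
    phase = df[pcol].to_numpy(dtype=float)

    phase_unit = meta.get("phase_unit", dialect.get("phase_unit"))
    if phase_unit is None:
        phase_unit = "deg" if "deg" in pcol.lower() else "rad"
    if phase_unit == "deg":
        phase = phase * math.pi / 180.0
    elif phase_unit != "rad":
        raise FormatError(f"unknown phase unit {phase_unit!r}")

    sens = meta.get("deflection_sensitivity_m_per_v",
                    dialect.get("deflection_sensitivity"))
    if acol.lower().endswith("_v"):
        if sens is None:
            raise FormatError(
                "amplitude column in volts but no deflection sensitivity given"
            )
        amp = amp * float(sens)

    label = meta.pop("config_label", dialect.get("config_label", "MM"))
    cell_id = meta.pop("cell_id", dialect.get("cell_id", ""))
    meta.pop("format", None)
    # numeric metadata round-trips as float where possible
    for k, v in list(meta.items()):
        try:
            meta[k] = float(v)
        except (TypeError, ValueError):
            pass
    return FrequencySweep(freq, amp, _unwrap(phase), label, cell_id, meta)


def write_sweep(sweep: FrequencySweep, path) -> Path:
    """Write a sweep as CSV; deterministic column order, full float precision.

    The first comment line carries the format version together with the
    configuration label and cell id; each metadata entry adds one further
    comment line.  A sweep with empty metadata therefore yields exactly one
    comment line.  Floats are written with ``repr`` (shortest round-trippable
    form, >= 15 significant digits), so write/read round-trips bit-equal.
    """
    path = Path(path)
    head = f"# {FORMAT_VERSION} config_label={sweep.config_label}"
    if sweep.cell_id:
        head += f" cell_id={sweep.cell_id}"
    lines = [head]
    for key in sorted(sweep.metadata):
        lines.append(f"# {key} = {sweep.metadata[key]}")
    lines.append("frequency_hz,amplitude_m,phase_rad")
    for f, a, p in zip(sweep.frequencies, sweep.amplitudes, sweep.phases):
        lines.append(f"{float(f)!r},{float(a)!r},{float(p)!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot write sweep to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# experiment configuration


def load_experiment(config_path) -> ExperimentBundle:
    """Load a YAML experiment config declaring cantilevers, cell and sweeps.

    Expected top-level keys: ``master``, ``slave`` (cantilever parameter
    mappings), ``cell`` (mass/density/compression/h_cort) and ``sweeps``
    (mapping MM/MS/SS to file paths, relative to the config file).  Optional
    ``calibration`` maps ``master``/``slave`` to single-cantilever sweeps.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    for key in ("master", "slave", "cell", "sweeps"):
        if key not in cfg:
            raise ValidationError(f"experiment config missing section {key!r}")

    def cantilever(section, name):
        d = dict(cfg[section])
        d.setdefault("name", name)
        return CantileverParams(**d)

    master = cantilever("master", "master")
    slave = cantilever("slave", "slave")
    cell = CellRecord(**cfg["cell"])

    base = config_path.parent
    paths = {}
    for label in CONFIG_LABELS:
        if label not in cfg["sweeps"]:
            raise ValidationError(f"sweeps section missing {label} path")
        paths[label] = base / cfg["sweeps"][label]
    cal = {k: base / v for k, v in cfg.get("calibration", {}).items()}

    ids = set()
    for label, p in paths.items():
        if p.exists():
            ids.add(read_sweep(p).cell_id)
    if len(ids - {""}) > 1:
        raise ValidationError(f"inconsistent cell_id across sweeps: {ids}")

    return ExperimentBundle(master, slave, cell, paths, cal)
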