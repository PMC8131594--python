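"""Cortex thickness from STED line profiles and population-level statistics.

A line profile across the actin cortex (fluorescence intensity I vs position
s) is fitted with an area-normalised Gaussian whose width parameter is the
full width at half maximum directly:

    I(s) = I0 + I1 * exp(-4 ln2 (s - s0)^2 / w^2) / (w sqrt(pi / (4 ln2))),

so the peak height above offset is I1 * sqrt(4 ln2 / pi) / w.  The per-cell
cortical thickness is the mean fitted w over that cell's profiles; cell
diameters come from the distance between the two cortex peaks of a line
through the cell centre, averaged over two orthogonal lines.

The Laplace law T = P R / 2 links cortical tension, excess pressure and
radius: a population that maintained one universal pressure would show
stiffness proportional to 1/R, one universal tension proportional to 1/R^2.
Whether either holds is tested by the Pearson correlation c between radius
and (log-)moduli with the t statistic t = c sqrt((n-2) / (1-c^2)) against
H0: c = 0 (two-sided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .io import ValidationError

__all__ = [
    "LineProfile",
    "GaussianPeakFit",
    "PopulationTable",
    "fit_gaussian_profile",
    "cortex_thickness",
    "radius_from_profiles",
    "correlation_test",
    "laplace_scenarios",
    "gaussian_profile",
    "ProfileFitError",
]

FWHM_NORM = math.sqrt(math.pi / (4.0 * math.log(2.0)))


class ProfileFitError(RuntimeError):
    """No usable peak in a line profile."""


@dataclass
class LineProfile:
    """Intensity-vs-position trace across the cortex."""

    positions: np.ndarray  # m, strictly increasing
    intensities: np.ndarray  # a.u., >= 0
    cell_id: str = ""
    location_tag: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size != self.intensities.size:
            raise ValidationError("profile arrays differ in length")
        if self.positions.size < 7:
            raise ValidationError("a profile needs at least 7 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")


@dataclass
class GaussianPeakFit:
    """Fitted parameters of the FWHM-parameterised Gaussian."""

    I0: float
    I1: float
    s0: float
    w: float  # FWHM, m
    residual_rms: float

    def __post_init__(self):
        if self.w <= 0:
            raise ValidationError("FWHM must be positive")

    @property
    def peak_height(self) -> float:
        """I(s0) - I0 = I1 sqrt(4 ln2 / pi) / w."""
        return self.I1 / (self.w * FWHM_NORM)


def gaussian_profile(s, I0, I1, s0, w):
    s = np.asarray(s, dtype=float)
    return I0 + I1 * np.exp(
        -4.0 * math.log(2.0) * (s - s0) ** 2 / w**2) / (w * FWHM_NORM)


def fit_gaussian_profile(profile: LineProfile,
                         noise_floor: float | None = None) -> GaussianPeakFit:
    """Least-squares fit of the area-normalised Gaussian to one profile.

    The offset I0 absorbs any constant background.  Profiles whose dynamic
    range is below three times the noise floor (estimated from first
    differences when not given) are rejected as peakless.
    """
    s, I = profile.positions, profile.intensities
    if noise_floor is None:
        noise_floor = float(np.std(np.diff(I)) / math.sqrt(2.0))
    if I.max() - I.min() < 3.0 * noise_floor:
        raise ProfileFitError("no peak: dynamic range below 3x noise floor")

    I0_0 = float(I.min())
    i_pk = int(np.argmax(I))
    s0_0 = float(s[i_pk])
    half = I0_0 + (I[i_pk] - I0_0) / 2.0
    above = I >= half
    w0 = float(max(s[above][-1] - s[above][0], (s[1] - s[0]) * 2.0))
    I1_0 = float((I[i_pk] - I0_0) * w0 * FWHM_NORM)

    def residuals(p):
        I0, I1, s0, w = p
        return gaussian_profile(s, I0, I1, s0, abs(w)) - I

    sol = least_squares(residuals, [I0_0, I1_0, s0_0, w0], method="lm",
                        xtol=1e-12, ftol=1e-12, max_nfev=5000)
    I0, I1, s0, w = sol.x
    if not (s[0] <= s0 <= s[-1]):
        raise ProfileFitError(f"fitted centre {s0:g} outside the span")
    return GaussianPeakFit(float(I0), float(I1), float(s0), float(abs(w)),
                           float(np.sqrt(np.mean(sol.fun**2))))


def cortex_thickness(profiles, grouping: str = "cell_id"):
    """Per-cell mean FWHM and the population mean +/- SD over cells.

    ``profiles`` is an iterable of :class:`LineProfile`.  Returns a dict
    ``{"per_cell": {cell_id: mean w}, "mean": ..., "sd": ..., "n_cells": ...}``;
    the SD is ``None`` for a single cell (degenerate population).
    """
    groups: dict[str, list] = {}
    for p in profiles:
        groups.setdefault(getattr(p, grouping), []).append(p)
    if not groups:
        raise ValidationError("no profiles given")
    per_cell = {}
    for cid, plist in groups.items():
        widths = [fit_gaussian_profile(p).w for p in plist]
        per_cell[cid] = float(np.mean(widths))
    vals = np.array(list(per_cell.values()))
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return {"per_cell": per_cell, "mean": float(vals.mean()), "sd": sd,
            "n_cells": int(vals.size)}


def _two_peak_centres(profile: LineProfile):
    """Fit the two cortex peaks of a diameter line independently."""
    s, I = profile.positions, profile.intensities
    mid = s[0] + (s[-1] - s[0]) / 2.0
    left = LineProfile(s[s <= mid], I[s <= mid], profile.cell_id)
    right = LineProfile(s[s > mid], I[s > mid], profile.cell_id)
    return fit_gaussian_profile(left).s0, fit_gaussian_profile(right).s0


def radius_from_profiles(diameter_profiles) -> float:
    """R from two orthogonal centre lines, each crossing the cortex twice.

    Each line yields one diameter (distance between the two fitted peak
    centres); the radius is the mean of the two diameters halved.
    """
    profiles = list(diameter_profiles)
    if len(profiles) != 2:
        raise ValidationError("need exactly two orthogonal diameter profiles")
    diameters = []
    for p in profiles:
        try:
            s_left, s_right = _two_peak_centres(p)
        except (ProfileFitError, ValidationError) as exc:
            raise ProfileFitError(
                f"cannot resolve two cortex peaks: {exc}") from exc
        diameters.append(abs(s_right - s_left))
    return float(np.mean(diameters) / 2.0)


@dataclass
class PopulationTable:
    """Per-cell radii, thicknesses, power-law parameters and moduli."""

    table: pd.DataFrame  # one row per cell

    def __post_init__(self):
        if "R" not in self.table.columns:
            raise ValidationError("population table needs an 'R' column")
        if len(self.table) < 3:
            raise ValidationError("population statistics need n >= 3 cells")


def correlation_test(table, predictor: str = "R", response: str = "E_prime",
                     log_response: bool = True):
    """Pearson correlation of a per-cell quantity with the predictor.

    Returns ``(c, t, p)``: the correlation coefficient, the t statistic
    t = c sqrt((n-2)/(1-c^2)) and the two-sided p-value on n-2 degrees of
    freedom.  ``response`` may be a scalar column or, for moduli sampled on a
    frequency grid (column holding arrays), the test is run on the
    frequency-averaged log-moduli by default, with the per-frequency table
    available through :func:`correlation_by_frequency`.
    """
    df = table.table if isinstance(table, PopulationTable) else table
    if len(df) < 3:
        raise ValidationError("correlation test needs n >= 3")
    x = np.asarray(df[predictor], dtype=float)
    col = df[response]
    if col.map(np.ndim).max() > 0:
        resp = np.stack([np.asarray(v, dtype=float) for v in col])
        if log_response:
            resp = np.log(resp)
        y = resp.mean(axis=1)
    else:
        y = np.asarray(col, dtype=float)
        if log_response and np.all(y > 0):
            y = np.log(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    n = x.size
    c = float(np.corrcoef(x, y)[0, 1])
    c = max(min(c, 1.0), -1.0)
    if abs(c) == 1.0:
        return c, math.inf if c > 0 else -math.inf, 0.0
    t = c * math.sqrt((n - 2) / (1.0 - c**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return c, float(t), float(p)


def correlation_by_frequency(table, frequencies, predictor: str = "R",
                             response: str = "E_prime",
                             bh_correction: bool = False) -> pd.DataFrame:
    """Per-frequency Pearson tests; optional Benjamini-Hochberg adjustment."""
    df = table.table if isinstance(table, PopulationTable) else table
    resp = np.stack([np.asarray(v, dtype=float) for v in df[response]])
    x = np.asarray(df[predictor], dtype=float)
    rows = []
    for j, f in enumerate(np.asarray(frequencies, dtype=float)):
        r, p = stats.pearsonr(x, resp[:, j])
        rows.append({"frequency_hz": f, "c": r, "p": p})
    out = pd.DataFrame(rows)
    if bh_correction:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            running = min(running, out["p"].iloc[idx] * m / rank)
            adj[idx] = running
        out["p_bh"] = adj
    return out


def laplace_scenarios(R_grid, anchor: tuple):
    """Reference curves for universal-pressure and universal-tension scaling.

    With T = P R / 2, a population holding the pressure P fixed shows
    stiffness E_P(R) = E0 R0 / R (tension grows with R), while holding the
    tension T fixed gives E_T(R) = E0 (R0 / R)^2.  Both are anchored at
    (R0, E0), which must lie inside the grid span.
    """
    R = np.asarray(R_grid, dtype=float)
    R0, E0 = anchor
    if not (R.min() <= R0 <= R.max()):
        raise ValidationError("anchor radius outside the grid span")
    return {"constant_pressure": E0 * R0 / R,
            "constant_tension": E0 * (R0 / R) ** 2}
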