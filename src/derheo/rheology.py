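"""Rheological models of the cell cortex and per-cell model fitting.

The workhorse is the double power-law dynamic modulus

    E*(f) = E'(f) + i E''(f) = A (i f / f0)^alpha + B (i f / f0)^beta,

with the principal branch i^x = exp(i pi x / 2), so that

    E'  = A cos(pi alpha / 2) (f/f0)^alpha + B cos(pi beta / 2) (f/f0)^beta
    E'' = A sin(pi alpha / 2) (f/f0)^alpha + B sin(pi beta / 2) (f/f0)^beta.

``f0`` is a normalisation constant, 1 kHz by default.  Competing models are a
single power-law, a structural-damping form (single power-law plus Newtonian
viscous term) and a single-relaxation-time Maxwell form; two phenomenological
forms (polynomial, oscillating polynomial) are provided for forward
simulations only.

Fitting follows the "global complex fit" recipe: real and imaginary parts are
stacked into one residual vector and minimised simultaneously (unweighted
least squares, Levenberg-Marquardt/TRF).  Fit quality is reported through the
distance measures

    l1* = sum |Re(y - yhat)| + |Im(y - yhat)|
    l2* = ( sum Re(y - yhat)^2 + Im(y - yhat)^2 )^0.5 .

`RheologyModel` / `RheologyResults` wrap this in a statsmodels-like
model/results pair; :func:`fit_modulus` is the functional entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .io import ValidationError

__all__ = [
    "DynamicModulus",
    "PowerLawParams",
    "ModelFitResult",
    "RheologyModel",
    "RheologyResults",
    "MODELS",
    "FIT_MODELS",
    "eval_model",
    "fit_modulus",
    "distance_measures",
    "crossing_frequency",
    "population_summary",
    "select_model",
    "F0_DEFAULT",
]

F0_DEFAULT = 1000.0  # Hz, power-law normalisation constant
CROSSING_BRACKET = (100.0, 400e3)  # Hz
PARSIMONY_TOL = 0.01  # relative l2* tie tolerance for model selection


@dataclass
class DynamicModulus:
    """Storage and loss moduli on a frequency grid."""

    frequencies: np.ndarray
    E_prime: np.ndarray  # Pa
    E_dprime: np.ndarray  # Pa
    cell_id: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.E_prime = np.asarray(self.E_prime, dtype=float)
        self.E_dprime = np.asarray(self.E_dprime, dtype=float)
        n = self.frequencies.size
        if self.E_prime.size != n or self.E_dprime.size != n:
            raise ValidationError("modulus grids not aligned")
        if not (np.all(np.isfinite(self.E_prime))
                and np.all(np.isfinite(self.E_dprime))):
            raise ValidationError("non-finite modulus values")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def complex(self) -> np.ndarray:
        return self.E_prime + 1j * self.E_dprime

    @property
    def negative_storage_flags(self) -> np.ndarray:
        """De-embedded points with E' < 0 are flagged, not rejected."""
        return self.E_prime < 0

    @classmethod
    def from_complex(cls, frequencies, values, cell_id="") -> "DynamicModulus":
        values = np.asarray(values, dtype=complex)
        return cls(frequencies, values.real, values.imag, cell_id)


@dataclass
class PowerLawParams:
    """Double power-law parameters (A, B in Pa; exponents in [0, 1])."""

    A: float
    B: float
    alpha: float
    beta: float
    f0: float = F0_DEFAULT

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise ValidationError("A and B must be non-negative")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.f0 <= 0:
            raise ValidationError("f0 must be positive")


# ---------------------------------------------------------------------------
# model registry


def _power_term(f, f0, scale, exponent):
    x = np.asarray(f, dtype=float) / f0
    return scale * np.exp(1j * math.pi * exponent / 2.0) * x**exponent


def _eval_single_pl(f, params, f0):
    A, alpha = params["A"], params["alpha"]
    return _power_term(f, f0, A, alpha)


def _eval_double_pl(f, params, f0):
    return (_power_term(f, f0, params["A"], params["alpha"])
            + _power_term(f, f0, params["B"], params["beta"]))


def _eval_structural_damping(f, params, f0):
    A, alpha, mu = params["A"], params["alpha"], params["mu"]
    x = np.asarray(f, dtype=float) / f0
    return (A * x**alpha * (1.0 + 1j * math.tan(math.pi * alpha / 2.0))
            + 1j * mu * x)


def _eval_maxwell(f, params, f0):
    E, f_r = params["E"], params["f_r"]
    s = 1j * np.asarray(f, dtype=float) / f_r
    return E * s / (1.0 + s)


def _eval_polynomial(f, params, f0):
    x = np.asarray(f, dtype=float) / f0
    re = np.polynomial.polynomial.polyval(x, params["real_coeffs"])
    im = np.polynomial.polynomial.polyval(x, params["imag_coeffs"])
    return re + 1j * im


def _eval_oscillating_polynomial(f, params, f0):
    base = _eval_polynomial(f, params, f0)
    ripple = 1.0 + params["ripple"] * np.sin(
        2.0 * math.pi * np.asarray(f, dtype=float) / params["f_osc"])
    return base * ripple


@dataclass(frozen=True)
class _ModelSpec:
    eval: callable
    param_names: tuple
    bounds: dict
    fittable: bool = True


MODELS = {
    "single_pl": _ModelSpec(_eval_single_pl, ("A", "alpha"),
                            {"A": (0, np.inf), "alpha": (0, 1)}),
    "double_pl": _ModelSpec(_eval_double_pl, ("A", "B", "alpha", "beta"),
                            {"A": (0, np.inf), "B": (0, np.inf),
                             "alpha": (0, 1), "beta": (0, 1)}),
    "structural_damping": _ModelSpec(
        _eval_structural_damping, ("A", "alpha", "mu"),
        {"A": (0, np.inf), "alpha": (0, 0.999), "mu": (0, np.inf)}),
    "maxwell": _ModelSpec(_eval_maxwell, ("E", "f_r"),
                          {"E": (0, np.inf), "f_r": (1e-3, np.inf)}),
    "polynomial": _ModelSpec(_eval_polynomial, ("real_coeffs", "imag_coeffs"),
                             {}, fittable=False),
    "oscillating_polynomial": _ModelSpec(
        _eval_oscillating_polynomial,
        ("real_coeffs", "imag_coeffs", "ripple", "f_osc"), {},
        fittable=False),
}

FIT_MODELS = tuple(k for k, v in MODELS.items() if v.fittable)


def eval_model(model_id: str, params: dict | PowerLawParams, f_grid,
               f0: float = F0_DEFAULT, cell_id: str = "") -> DynamicModulus:
    """Evaluate a registered model's complex modulus on a frequency grid."""
    if isinstance(params, PowerLawParams):
        f0 = params.f0
        params = {"A": params.A, "B": params.B,
                  "alpha": params.alpha, "beta": params.beta}
    if model_id not in MODELS:
        raise ValidationError(f"unknown model_id {model_id!r}")
    values = MODELS[model_id].eval(np.asarray(f_grid, dtype=float), params, f0)
    return DynamicModulus.from_complex(f_grid, values, cell_id)


# ---------------------------------------------------------------------------
# distance measures and crossing frequency


def distance_measures(data: DynamicModulus, fit: DynamicModulus):
    """(l1*, l2*) of a fit against data on the same grid."""
    if not np.array_equal(data.frequencies, fit.frequencies):
        raise ValidationError("distance measures need matching grids")
    d = data.complex - fit.complex
    l1 = float(np.sum(np.abs(d.real)) + np.sum(np.abs(d.imag)))
    l2 = float(math.sqrt(np.sum(d.real**2) + np.sum(d.imag**2)))
    return l1, l2


def crossing_frequency(params: PowerLawParams | dict,
                       bracket: tuple = CROSSING_BRACKET,
                       model_id: str = "double_pl",
                       tol: float = 1.0):
    """Frequency where E'' = E', by bisection; ``None`` without a sign change.

    The default bracket extends well beyond the measured band; a crossing
    above the band is an extrapolation of the fitted model and should be
    labelled as such by the caller.  For a single power-law with alpha = 0.5
    the moduli coincide at every frequency (tan(pi alpha / 2) = 1); this
    degenerate case is reported as the string ``"degenerate"``.  When several
    crossings fall inside the bracket the lowest is returned together with a
    ``"multiple"`` flag.
    """
    if isinstance(params, PowerLawParams):
        p = {"A": params.A, "B": params.B, "alpha": params.alpha,
             "beta": params.beta}
        f0 = params.f0
    else:
        p, f0 = dict(params), params.get("f0", F0_DEFAULT)
        p.pop("f0", None)

    def gap(f):
        m = MODELS[model_id].eval(np.asarray([f]), p, f0)
        return float(m.imag[0] - m.real[0])

    lo, hi = bracket
    # coarse sign scan to find the lowest crossing and flag multiplicity
    grid = np.geomspace(lo, hi, 200)
    m = MODELS[model_id].eval(grid, p, f0)
    gaps = m.imag - m.real
    scale = float(np.max(np.abs(m)))
    if scale == 0.0 or np.max(np.abs(gaps)) < 1e-9 * scale:
        return "degenerate"
    sign_changes = np.nonzero(np.diff(np.sign(gaps)) != 0)[0]
    if sign_changes.size == 0:
        return None
    multiple = sign_changes.size > 1
    a, b = grid[sign_changes[0]], grid[sign_changes[0] + 1]
    while b - a > tol:
        mid = 0.5 * (a + b)
        if gap(a) * gap(mid) <= 0:
            b = mid
        else:
            a = mid
    root = 0.5 * (a + b)
    return (root, "multiple") if multiple else root


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFitResult:
    """Converged parameters plus fit-quality measures for one cell."""

    model_id: str
    params: dict
    l1star: float
    l2star: float
    converged: bool
    crossing_f: float | None = None
    covariance: np.ndarray | None = None
    f0: float = F0_DEFAULT
    cell_id: str = ""
    n_points: int = 0

    def eval(self, f_grid) -> DynamicModulus:
        return eval_model(self.model_id, self.params, f_grid, self.f0)


def _default_init(model_id: str, data: DynamicModulus, f0: float) -> dict:
    """Moment-style starting values from the data itself."""
    f = data.frequencies
    Emag = np.hypot(data.E_prime, data.E_dprime)
    i0 = int(np.argmin(np.abs(f - f0)))
    scale = max(float(Emag[i0]), 1e-30)
    if model_id == "single_pl":
        return {"A": scale, "alpha": 0.2}
    if model_id == "double_pl":
        return {"A": 0.9 * scale, "B": 0.05 * scale,
                "alpha": 0.15, "beta": 0.85}
    if model_id == "structural_damping":
        return {"A": scale, "alpha": 0.2, "mu": 0.02 * scale}
    if model_id == "maxwell":
        return {"E": 2.0 * scale, "f_r": float(np.median(f))}
    raise ValidationError(f"model {model_id!r} is not fittable")


def fit_modulus(data: DynamicModulus, model_id: str,
                init: dict | None = None,
                f0: float = F0_DEFAULT) -> ModelFitResult:
    """Simultaneous real/imaginary least-squares fit of one cell's modulus.

    Parameters are bounded (scale factors non-negative, exponents in [0, 1]);
    for the double power-law the label-exchange symmetry is resolved by
    swapping so that alpha <= beta after the fit.  Requires at least four
    data points per parameter.
    """
    spec = MODELS.get(model_id)
    if spec is None or not spec.fittable:
        raise ValidationError(f"model {model_id!r} is not fittable")
    names = spec.param_names
    n_par = len(names)
    if len(data.frequencies) < 4 * n_par:
        raise ValidationError(
            f"need >= {4 * n_par} points to fit {model_id}, "
            f"got {len(data.frequencies)}"
        )
    p0 = dict(_default_init(model_id, data, f0))
    if init:
        p0.update(init)
    x0 = np.array([p0[n] for n in names], dtype=float)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0))

    y = data.complex
    f = data.frequencies

    def residuals(x):
        m = spec.eval(f, dict(zip(names, x)), f0)
        return np.concatenate([(m.real - y.real), (m.imag - y.imag)])

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
    params = dict(zip(names, (float(v) for v in sol.x)))
    converged = bool(sol.success)

    if model_id == "double_pl" and params["alpha"] > params["beta"]:
        params = {"A": params["B"], "B": params["A"],
                  "alpha": params["beta"], "beta": params["alpha"]}

    fit_curve = eval_model(model_id, params, f, f0)
    l1, l2 = distance_measures(data, fit_curve)

    crossing = None
    if model_id == "double_pl":
        crossing = crossing_frequency(
            PowerLawParams(params["A"], params["B"], params["alpha"],
                           params["beta"], f0))

    m, n = sol.jac.shape
    cov = None
    if m > n and converged:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (
                2.0 * sol.cost / (m - n))
        except np.linalg.LinAlgError:
            cov = None
    return ModelFitResult(model_id, params, l1, l2, converged,
                          crossing_f=crossing, covariance=cov, f0=f0,
                          cell_id=data.cell_id, n_points=len(f))


def select_model(data: DynamicModulus, model_ids=FIT_MODELS,
                 f0: float = F0_DEFAULT,
                 parsimony_tol: float = PARSIMONY_TOL):
    """Fit every candidate model and select by l2* with a parsimony rule.

    The single power-law is nested in both the double power-law and the
    structural-damping form, so the raw minimum of l2* cannot identify a
    nested generating model.  Among all candidates whose l2* lies within
    ``parsimony_tol`` (relative) of the smallest, the model with the fewest
    parameters wins; the tolerance matches the expected noise-fitting gain of
    a couple of extra parameters among ~2N residuals.

    Returns (best ModelFitResult, {model_id: ModelFitResult}).
    """
    fits = {m: fit_modulus(data, m, f0=f0) for m in model_ids}
    l2min = min(fit.l2star for fit in fits.values())
    candidates = [m for m, fit in fits.items()
                  if fit.l2star <= (1.0 + parsimony_tol) * l2min]
    best = min(candidates,
               key=lambda m: (len(MODELS[m].param_names), fits[m].l2star))
    return fits[best], fits


def population_summary(fits: list) -> dict:
    """Arithmetic mean and sample SD of each parameter over cells."""
    if len(fits) < 2:
        raise ValidationError("population summary needs >= 2 cells")
    model_ids = {f.model_id for f in fits}
    if len(model_ids) != 1:
        raise ValidationError(f"mixed models in population: {model_ids}")
    names = MODELS[fits[0].model_id].param_names
    out = {"model_id": fits[0].model_id, "n": len(fits)}
    for name in names:
        vals = np.array([f.params[name] for f in fits], dtype=float)
        out[name] = {"mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1))}
    return out


# ---------------------------------------------------------------------------
# statsmodels-style wrapper


class RheologyModel:
    """Rheological model bound to one cell's measured dynamic modulus.

    Examples
    --------
    >>> model = RheologyModel(modulus, "double_pl")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: DynamicModulus, model_id: str = "double_pl",
                 f0: float = F0_DEFAULT):
        if model_id not in MODELS or not MODELS[model_id].fittable:
            raise ValidationError(f"model {model_id!r} is not fittable")
        self.data = data
        self.model_id = model_id
        self.f0 = f0

    @classmethod
    def from_dataframe(cls, df, model_id: str = "double_pl",
                       f0: float = F0_DEFAULT,
                       columns=("frequency_hz", "e_prime_pa", "e_dprime_pa"),
                       cell_id: str = "") -> "RheologyModel":
        data = DynamicModulus(df[columns[0]].to_numpy(),
                              df[columns[1]].to_numpy(),
                              df[columns[2]].to_numpy(), cell_id)
        return cls(data, model_id, f0)

    def fit(self, init: dict | None = None) -> "RheologyResults":
        res = fit_modulus(self.data, self.model_id, init=init, f0=self.f0)
        return RheologyResults(self, res)


class RheologyResults:
    """Fit results: parameters, uncertainties, diagnostics, summary table."""

    def __init__(self, model: RheologyModel, fit: ModelFitResult):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> dict:
        return self.fit.params

    @property
    def bse(self) -> dict:
        """Approximate standard errors from the Gauss-Newton covariance."""
        names = MODELS[self.fit.model_id].param_names
        if self.fit.covariance is None:
            return {n: math.nan for n in names}
        se = np.sqrt(np.clip(np.diag(self.fit.covariance), 0, None))
        return dict(zip(names, (float(v) for v in se)))

    @property
    def l1star(self) -> float:
        return self.fit.l1star

    @property
    def l2star(self) -> float:
        return self.fit.l2star

    @property
    def crossing_frequency(self):
        return self.fit.crossing_f

    def predict(self, f_grid=None) -> DynamicModulus:
        f = self.model.data.frequencies if f_grid is None else f_grid
        return self.fit.eval(f)

    def summary(self) -> str:
        lines = [
            f"Rheology fit: {self.fit.model_id}",
            f"cell_id: {self.fit.cell_id or '-'}   "
            f"n = {self.fit.n_points}   converged: {self.fit.converged}",
            f"f0 = {self.fit.f0:g} Hz",
            "-" * 46,
            f"{'param':>10s} {'value':>14s} {'std err':>14s}",
        ]
        bse = self.bse
        for name, value in self.fit.params.items():
            lines.append(f"{name:>10s} {value:14.6g} {bse[name]:14.3g}")
        lines.append("-" * 46)
        lines.append(f"l1* = {self.fit.l1star:.6g} Pa   "
                     f"l2* = {self.fit.l2star:.6g} Pa")
        if self.fit.crossing_f is not None:
            c = self.fit.crossing_f
            if isinstance(c, tuple):
                lines.append(f"E''=E' crossing: {c[0]:.4g} Hz (multiple)")
            elif c == "degenerate":
                lines.append("E''=E' crossing: degenerate (equal everywhere)")
            else:
                lines.append(f"E''=E' crossing: {c:.4g} Hz")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curves on log-log axes (E' and E'')."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        m = self.predict()
        ax.loglog(d.frequencies, d.E_prime, "o", ms=3, color="tab:red",
                  label="E' data")
        ax.loglog(d.frequencies, d.E_dprime, "o", ms=3, color="k",
                  label="E'' data")
        ax.loglog(m.frequencies, m.E_prime, "-", color="tab:red",
                  label="E' fit")
        ax.loglog(m.frequencies, m.E_dprime, "-", color="k", label="E'' fit")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("modulus (Pa)")
        ax.legend()
        return ax
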