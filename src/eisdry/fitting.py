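"""Complex nonlinear least-squares fitting of circuit models to spectra.

The objective stacks real- and imaginary-part residuals per frequency and
minimises their sum of squares with the Nelder-Mead simplex.  Two weightings
are available:

* ``unit``     r = Z_model - Z_measured (ohm-scale residuals);
* ``modulus``  r = (Z_model - Z_measured) / |Z_measured| per point, the
  default: scale-free across spectra spanning orders of magnitude.

R, C and P parameters are optimised as log10 values (positivity and the wide
physical bounds come for free); the CPE exponent n is optimised untransformed
in (0, 1].  The simplex is local, so the fit restarts from log-uniformly
jittered copies of the initial point and keeps the best minimum; a final
polish run re-starts the simplex at that minimum.

Goodness of fit is reported as mean absolute percentage error and root mean
squared percentage error of the real and imaginary parts separately,
relative to the measured component at each frequency:

    mae_pct  = (100/N) sum |c_fit - c_meas| / |c_meas|
    rmse_pct = 100 sqrt((1/N) sum ((c_fit - c_meas)/c_meas)^2)

for c in {Re Z, Im Z}.  Both are undefined where a measured component is
exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from .circuits import CircuitModel, builtin_model, evaluate_circuit
from .errors import (
    AlignmentError,
    InitializationError,
    MetricError,
    ValidationError,
    WeightingError,
)
from .spectra import ImpedanceSpectrum

__all__ = [
    "FitOptions",
    "FitMetrics",
    "FitResult",
    "residual_vector",
    "initial_guess",
    "fit_model",
    "goodness_of_fit",
    "compare_models",
]

_LOG_KINDS = {"resistor", "capacitor", "cpe_p"}


@dataclass(frozen=True)
class FitOptions:
    """Knobs for :func:`fit_model`.

    ``xtol_rel``/``ftol_rel`` are the simplex stopping tolerances (applied to
    the log-scale parameter vector and the objective); ``n_restarts`` extra
    starts are drawn around the initial point with multiplicative jitter in
    [0.2, 5], seeded for reproducibility.
    """

    weighting: str = "modulus"
    max_iterations: int = 10_000
    xtol_rel: float = 1e-10
    ftol_rel: float = 1e-10
    n_restarts: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.weighting not in ("unit", "modulus"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if self.xtol_rel <= 0 or self.ftol_rel <= 0:
            raise ValidationError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.n_restarts < 0:
            raise ValidationError("n_restarts must be >= 0")


@dataclass(frozen=True)
class FitMetrics:
    mae_real_pct: float
    mae_imag_pct: float
    rmse_real_pct: float
    rmse_imag_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mae_real_pct": self.mae_real_pct,
            "mae_imag_pct": self.mae_imag_pct,
            "rmse_real_pct": self.rmse_real_pct,
            "rmse_imag_pct": self.rmse_imag_pct,
        }


@dataclass
class FitResult:
    model_name: str
    parameters: dict[str, float]
    objective: float
    metrics: FitMetrics | None
    converged: bool
    n_iterations: int
    weighting: str = "modulus"

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "parameters": dict(self.parameters),
            "objective": self.objective,
            "metrics": self.metrics.as_dict() if self.metrics else None,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "weighting": self.weighting,
        }


def residual_vector(circuit: CircuitModel, params: Mapping[str, float],
                    spectrum: ImpedanceSpectrum, weighting: str = "modulus"
                    ) -> np.ndarray:
    """Stacked (Re, Im) residuals per frequency, length 2N.

    Ordering is per point: (re_0, im_0, re_1, im_1, ...).
    """
    model = circuit.impedance(params, 2.0 * np.pi * spectrum.frequency_hz)
    diff = np.asarray(model) - spectrum.z
    if weighting == "modulus":
        mod = spectrum.modulus
        if np.any(mod == 0):
            raise WeightingError(
                "modulus weighting undefined: measured |Z| = 0 at rows "
                f"{np.flatnonzero(mod == 0).tolist()}"
            )
        diff = diff / mod
    elif weighting != "unit":
        raise ValidationError(f"unknown weighting {weighting!r}")
    return np.column_stack([diff.real, diff.imag]).ravel()


def goodness_of_fit(fitted: ImpedanceSpectrum, measured: ImpedanceSpectrum
                    ) -> FitMetrics:
    """Percentage-error metrics between a fitted and a measured spectrum on
    an identical frequency grid."""
    if len(fitted) != len(measured) or not np.allclose(
        fitted.frequency_hz, measured.frequency_hz, rtol=1e-9, atol=0.0
    ):
        raise AlignmentError("spectra are not on the same frequency grid")
    metrics = {}
    for comp, (f_c, m_c) in {
        "real": (fitted.re, measured.re),
        "imag": (fitted.im, measured.im),
    }.items():
        if np.any(m_c == 0):
            raise MetricError(
                f"measured {comp} part is zero at rows "
                f"{np.flatnonzero(m_c == 0).tolist()}; relative error undefined"
            )
        rel = (f_c - m_c) / m_c
        metrics[f"mae_{comp}_pct"] = 100.0 * float(np.mean(np.abs(rel)))
        metrics[f"rmse_{comp}_pct"] = 100.0 * float(np.sqrt(np.mean(rel**2)))
    return FitMetrics(**metrics)


def initial_guess(circuit: CircuitModel, spectrum: ImpedanceSpectrum
                  ) -> dict[str, float]:
    """Rough starting parameters from spectrum geometry.

    Resistances are seeded from the low- and high-frequency real-part levels;
    capacitances and CPE magnitudes from the frequency of the -Im(Z) extremum
    via omega_peak ~ 1/(R C); n starts mid-range at 0.8.  Deliberately crude:
    the restart jitter explores around it.
    """
    z_lo = float(abs(spectrum.re[0]))
    z_hi = float(abs(spectrum.re[-1]))
    z_lo = max(z_lo, 1e-3)
    z_hi = max(z_hi, 1e-3)
    i_pk = int(np.argmax(-spectrum.im)) if np.any(spectrum.im < 0) else len(spectrum) // 2
    omega_pk = 2.0 * np.pi * float(spectrum.frequency_hz[i_pk])
    c_scale = 1.0 / (z_lo * omega_pk)
    guess: dict[str, float] = {}
    first_resistor = True
    for pname, kind in circuit.param_kinds.items():
        if kind == "resistor":
            guess[pname] = z_lo if first_resistor else max(z_hi, 0.25 * z_lo)
            first_resistor = False
        elif kind in ("capacitor", "cpe_p"):
            guess[pname] = c_scale
        else:  # cpe_n
            guess[pname] = 0.8
    # clip into bounds
    for pname, (lo, hi) in circuit.bounds.items():
        guess[pname] = float(min(max(guess[pname], lo), hi))
    return guess


def _transform(circuit: CircuitModel, params: Mapping[str, float]) -> np.ndarray:
    kinds = circuit.param_kinds
    return np.array([
        math.log10(params[p]) if kinds[p] in _LOG_KINDS else params[p]
        for p in circuit.param_names
    ])


def _untransform(circuit: CircuitModel, x: np.ndarray) -> dict[str, float]:
    kinds = circuit.param_kinds
    return {
        p: (10.0 ** xi if kinds[p] in _LOG_KINDS else float(xi))
        for p, xi in zip(circuit.param_names, x)
    }


def fit_model(circuit: CircuitModel, spectrum: ImpedanceSpectrum,
              options: FitOptions | None = None,
              initial: Mapping[str, float] | None = None) -> FitResult:
    """Fit a circuit to a spectrum by Nelder-Mead simplex.

    ``initial`` overrides the geometry-based starting point (any missing
    parameter falls back to the circuit's defaults).  Deterministic for a
    given ``options.seed``.  If the iteration cap is reached the best point
    found is still returned, with ``converged=False``.
    """
    options = options or FitOptions()
    n_par = circuit.n_params
    if 2 * len(spectrum) < n_par:
        raise ValidationError(
            f"{len(spectrum)} points give {2 * len(spectrum)} residuals, "
            f"fewer than {n_par} free parameters"
        )

    start = initial_guess(circuit, spectrum)
    if initial is not None:
        start.update(initial)
    kinds = circuit.param_kinds
    lo = np.array([
        math.log10(circuit.bounds[p][0]) if kinds[p] in _LOG_KINDS
        else circuit.bounds[p][0]
        for p in circuit.param_names
    ])
    hi = np.array([
        math.log10(circuit.bounds[p][1]) if kinds[p] in _LOG_KINDS
        else circuit.bounds[p][1]
        for p in circuit.param_names
    ])
    x0 = np.clip(_transform(circuit, start), lo, hi)

    def objective(x: np.ndarray) -> float:
        try:
            r = residual_vector(circuit, _untransform(circuit, x), spectrum,
                                options.weighting)
        except (ValueError, FloatingPointError):
            return np.inf
        val = float(r @ r)
        return val if np.isfinite(val) else np.inf

    if not np.isfinite(objective(x0)):
        raise InitializationError("objective is non-finite at the initial point")

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_restarts):
        jitter = rng.uniform(math.log10(0.2), math.log10(5.0), size=n_par)
        xj = x0.copy()
        for i, p in enumerate(circuit.param_names):
            if kinds[p] in _LOG_KINDS:
                xj[i] += jitter[i]
            else:
                xj[i] += rng.uniform(-0.15, 0.15)
        starts.append(np.clip(xj, lo, hi))

    nm_opts = {
        "maxiter": options.max_iterations,
        "maxfev": 4 * options.max_iterations,
        "xatol": options.xtol_rel,
        "fatol": options.ftol_rel,
        "adaptive": n_par > 4,
    }
    sbounds = Bounds(lo, hi)
    best = None
    total_iter = 0
    for xs in starts:
        res = minimize(objective, xs, method="Nelder-Mead", bounds=sbounds,
                       options=nm_opts)
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    # polish: re-seed the simplex at the best vertex (fresh simplex escapes
    # a collapsed one)
    for _ in range(2):
        res = minimize(objective, best.x, method="Nelder-Mead", bounds=sbounds,
                       options=nm_opts)
        total_iter += res.nit
        if res.fun < best.fun:
            best = res
        else:
            break

    params = _untransform(circuit, best.x)
    fitted = evaluate_circuit(circuit, params, spectrum.frequency_hz)
    try:
        metrics = goodness_of_fit(fitted, spectrum)
    except MetricError:
        metrics = None
    return FitResult(
        model_name=circuit.name or circuit.expression,
        parameters=params,
        objective=float(best.fun),
        metrics=metrics,
        converged=bool(best.success),
        n_iterations=int(total_iter),
        weighting=options.weighting,
    )


def compare_models(spectrum: ImpedanceSpectrum,
                   model_names: Sequence[str],
                   options: FitOptions | None = None,
                   initials: Mapping[str, Mapping[str, float]] | None = None
                   ) -> pd.DataFrame:
    """Fit several built-in circuits to one spectrum and tabulate their
    goodness-of-fit, sorted by mae_real_pct ascending.

    A model whose fit raises is kept as a row with NaN metrics and the error
    message in the ``error`` column; the comparison itself never fails on a
    single bad model.
    """
    rows = []
    for name in model_names:
        circuit = builtin_model(name)  # raises LookupError on bad name
        row: dict = {"model": name, "mae_real_pct": np.nan,
                     "mae_imag_pct": np.nan, "rmse_real_pct": np.nan,
                     "rmse_imag_pct": np.nan, "objective": np.nan,
                     "converged": False, "error": ""}
        try:
            initial = initials.get(name) if initials else None
            result = fit_model(circuit, spectrum, options, initial=initial)
            row["objective"] = result.objective
            row["converged"] = result.converged
            if result.metrics is not None:
                row.update(result.metrics.as_dict())
        except Exception as exc:  # recorded per row, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("mae_real_pct", na_position="last").reset_index(drop=True)
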