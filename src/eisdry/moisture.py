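"""Moisture content from drying weights and its calibration against impedance.

Moisture is expressed relative to the solid content (dry-basis-like, in
grams of water per gram of solids):

    M = (m_t - s * m_o) / (s * m_o)

with m_o the initial sample weight, m_t the weight on day t and s the solid
fraction of the initial weight (default 0.13 for onion bulbs).  Calibrations
are ordinary least-squares polynomials (degree 1 or 2) mapping an impedance
predictor — |Z| at a spot frequency, or |Z| per unit sample weight in
ohm/kg — to M, reported with SSE, R-squared and RMSE = sqrt(SSE/N).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, DomainError, FrequencyLookupError
from .spectra import ImpedanceSpectrum

__all__ = [
    "DryingRecord",
    "MoistureCalibration",
    "moisture_from_weight",
    "impedance_per_unit_weight",
    "fit_calibration",
    "predict_moisture",
    "calibration_sweep",
    "per_unit_weight_calibration",
    "modulus_at_frequency",
    "DEFAULT_SOLID_FRACTION",
]

#: Solid fraction of initial onion weight assumed when none is given.
DEFAULT_SOLID_FRACTION = 0.13


@dataclass
class DryingRecord:
    """One daily observation of one sample: weight and (optionally) its
    measured impedance spectrum."""

    day: int
    sample_id: str
    weight_g: float
    spectrum: ImpedanceSpectrum | None = None

    def __post_init__(self):
        if self.day < 0:
            raise DomainError(f"day must be >= 0, got {self.day}")
        if not self.weight_g > 0:
            raise DomainError(f"weight must be positive, got {self.weight_g}")


def moisture_from_weight(m_t: float, m_o: float,
                         s: float = DEFAULT_SOLID_FRACTION) -> float:
    """Moisture content relative to solid content, M = (m_t - s m_o)/(s m_o).

    Returns a negative M with a warning when m_t falls below the estimated
    bone-dry weight s*m_o (physically impossible; indicates measurement noise
    or a wrong solid fraction).
    """
    if not m_o > 0:
        raise DomainError(f"initial weight must be positive, got {m_o}")
    if not 0 < s < 1:
        raise DomainError(f"solid fraction must lie in (0, 1), got {s}")
    if not m_t > 0:
        raise DomainError(f"weight must be positive, got {m_t}")
    solid = s * m_o
    m = (m_t - solid) / solid
    if m < 0:
        warnings.warn(
            f"weight {m_t} g below estimated solid mass {solid:.4g} g; "
            "moisture is negative",
            stacklevel=2,
        )
    return m


def impedance_per_unit_weight(z_mod: float, weight_g: float) -> float:
    """Impedance magnitude normalised by sample mass, in ohm/kg."""
    if not weight_g > 0:
        raise DomainError(f"weight must be positive, got {weight_g}")
    return z_mod / (weight_g / 1000.0)


@dataclass
class MoistureCalibration:
    """A polynomial map from an impedance predictor to moisture content.

    ``coefficients`` are ordered high-to-low degree (numpy.polyval
    convention).  ``predictor_range`` records the span of predictor values
    the fit saw; predictions outside it are extrapolations and are flagged
    with a warning.
    """

    predictor: str  # "impedance_at_frequency" | "impedance_per_unit_weight"
    degree: int
    coefficients: tuple[float, ...]
    sse: float
    r_squared: float
    rmse: float
    frequency_hz: float | None = None
    predictor_range: tuple[float, float] | None = None

    def __post_init__(self):
        if len(self.coefficients) != self.degree + 1:
            raise CalibrationError(
                f"degree {self.degree} needs {self.degree + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "frequency_hz": self.frequency_hz,
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "sse": self.sse,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "predictor_range": list(self.predictor_range)
            if self.predictor_range else None,
        }

    def to_json(self, path, metadata: dict | None = None) -> None:
        payload = self.as_dict()
        if metadata:
            payload["_meta"] = metadata
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MoistureCalibration":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload.pop("_meta", None)
        payload["coefficients"] = tuple(payload["coefficients"])
        if payload.get("predictor_range") is not None:
            payload["predictor_range"] = tuple(payload["predictor_range"])
        return cls(**payload)


def fit_calibration(m_values: Sequence[float], predictor_values: Sequence[float],
                    degree: int, predictor: str = "impedance_at_frequency",
                    frequency_hz: float | None = None) -> MoistureCalibration:
    """Ordinary least-squares polynomial fit of moisture against a predictor.

    Requires at least degree + 2 points and more distinct predictor values
    than polynomial coefficients; a constant predictor raises
    :class:`~eisdry.errors.CalibrationError`.
    """
    y = np.asarray(m_values, dtype=float)
    x = np.asarray(predictor_values, dtype=float)
    if degree not in (1, 2):
        raise CalibrationError(f"degree must be 1 or 2, got {degree}")
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("predictor and moisture must be equal-length 1-D")
    if x.size < degree + 2:
        raise CalibrationError(
            f"need at least {degree + 2} points for degree {degree}, got {x.size}"
        )
    if np.unique(x).size < degree + 1:
        raise CalibrationError("predictor values are degenerate (rank-deficient)")
    coeffs = np.polyfit(x, y, degree)
    yhat = np.polyval(coeffs, x)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 1.0 if sse == 0 else float("nan")
    rmse = float(np.sqrt(sse / x.size))
    return MoistureCalibration(
        predictor=predictor,
        frequency_hz=frequency_hz,
        degree=degree,
        coefficients=tuple(float(c) for c in coeffs),
        sse=sse,
        r_squared=r2,
        rmse=rmse,
        predictor_range=(float(x.min()), float(x.max())),
    )


def predict_moisture(calibration: MoistureCalibration, predictor_value: float
                     ) -> float:
    """Evaluate a calibration polynomial.  Extrapolation beyond the stored
    predictor range is permitted but warned about."""
    rng = calibration.predictor_range
    if rng is not None and not rng[0] <= predictor_value <= rng[1]:
        warnings.warn(
            f"predictor value {predictor_value} outside calibration range "
            f"[{rng[0]:.6g}, {rng[1]:.6g}]; extrapolating",
            stacklevel=2,
        )
    return float(np.polyval(calibration.coefficients, predictor_value))


def modulus_at_frequency(spectrum: ImpedanceSpectrum, frequency_hz: float,
                         rtol: float = 0.01) -> float:
    """|Z| at the grid point nearest ``frequency_hz``, required to lie within
    ``rtol`` relative of the request (grids differ run to run)."""
    idx = int(np.argmin(np.abs(spectrum.frequency_hz - frequency_hz)))
    found = spectrum.frequency_hz[idx]
    if abs(found - frequency_hz) > rtol * frequency_hz:
        raise FrequencyLookupError(
            f"no grid frequency within {100 * rtol:.3g}% of {frequency_hz} Hz "
            f"(nearest: {found} Hz)"
        )
    return float(spectrum.modulus[idx])


def _records_with_moisture(records: Iterable[DryingRecord],
                           solid_fraction: float):
    """Pair each record with its moisture, using each sample's earliest-day
    weight as m_o.  Warns when a sample's weight increases between days."""
    recs = sorted(records, key=lambda r: (r.sample_id, r.day))
    by_sample: dict[str, list[DryingRecord]] = {}
    for rec in recs:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    out = []
    for sample_id, series in by_sample.items():
        m_o = series[0].weight_g
        prev = None
        for rec in series:
            if prev is not None and rec.weight_g > prev:
                warnings.warn(
                    f"sample {sample_id}: weight rose from {prev} to "
                    f"{rec.weight_g} g on day {rec.day} (measurement noise?)",
                    stacklevel=3,
                )
            prev = rec.weight_g
            out.append((rec, moisture_from_weight(rec.weight_g, m_o,
                                                  solid_fraction)))
    return out


def calibration_sweep(records: Iterable[DryingRecord],
                      frequencies: Sequence[float], degree: int = 1,
                      solid_fraction: float = DEFAULT_SOLID_FRACTION
                      ) -> list[MoistureCalibration]:
    """Fit one moisture-vs-|Z(f)| calibration per requested frequency.

    Every record must carry a spectrum containing each frequency (nearest
    grid point within 1%).  The returned list is sorted by R-squared
    descending, so the best-correlated frequency comes first.
    """
    pairs = [(rec, m) for rec, m in
             _records_with_moisture(records, solid_fraction)
             if rec.spectrum is not None]
    if not pairs:
        raise CalibrationError("no records carry spectra")
    cals = []
    for f in frequencies:
        z = [modulus_at_frequency(rec.spectrum, f) for rec, _ in pairs]
        m = [moist for _, moist in pairs]
        cals.append(fit_calibration(m, z, degree,
                                    predictor="impedance_at_frequency",
                                    frequency_hz=float(f)))
    return sorted(cals, key=lambda c: c.r_squared, reverse=True)


def per_unit_weight_calibration(records: Iterable[DryingRecord],
                                frequency_hz: float = 10_000.0,
                                degree: int = 2,
                                solid_fraction: float = DEFAULT_SOLID_FRACTION
                                ) -> MoistureCalibration:
    """Calibrate moisture against |Z| per unit current-day weight (ohm/kg) at
    one frequency; degree-2 by default to capture the curvature this
    normalisation introduces."""
    pairs = [(rec, m) for rec, m in
             _records_with_moisture(records, solid_fraction)
             if rec.spectrum is not None]
    if not pairs:
        raise CalibrationError("no records carry spectra")
    zpu = [impedance_per_unit_weight(
        modulus_at_frequency(rec.spectrum, frequency_hz), rec.weight_g)
        for rec, _ in pairs]
    m = [moist for _, moist in pairs]
    return fit_calibration(m, zpu, degree,
                           predictor="impedance_per_unit_weight",
                           frequency_hz=float(frequency_hz))
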