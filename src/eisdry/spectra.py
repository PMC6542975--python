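"""Impedance spectra: container types, polar/cartesian conversion, CSV I/O.

A spectrum is an ordered sweep of complex impedance Z(f) over strictly
increasing frequencies.  The imaginary part is stored *signed*: capacitive
(tissue-like) points have Im(Z) < 0.  The reactance magnitude X_b commonly
quoted for bioimpedance, Z = R - jX, equals -Im(Z) for such points.  Phase is
expressed in degrees at the API surface and in files; internally complex
arithmetic is used throughout.

File dialect: comma-separated, mandatory header, '.' decimal separator, UTF-8.
The writer emits both polar and cartesian columns
(``frequency_hz, re_ohm, im_ohm, z_mod_ohm, phase_deg``); the reader accepts
either pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterator, Union

import numpy as np
import pandas as pd

from .errors import DomainError, SpectrumFormatError, ValidationError

__all__ = [
    "SpectrumPoint",
    "ImpedanceSpectrum",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "read_spectrum",
    "write_spectrum",
]

#: Columns written by :func:`write_spectrum`, in order.
CSV_COLUMNS = ("frequency_hz", "re_ohm", "im_ohm", "z_mod_ohm", "phase_deg")

_CARTESIAN = {"frequency_hz", "re_ohm", "im_ohm"}
_POLAR = {"frequency_hz", "z_mod_ohm", "phase_deg"}


def polar_to_cartesian(z_mod, theta_deg):
    """Convert |Z| and phase (degrees) to (R, X_signed) = (Re Z, Im Z).

    ``X_signed`` is the signed imaginary part; a capacitive point with
    theta = -90 deg maps to (0, -|Z|).
    """
    z_mod = np.asarray(z_mod, dtype=float)
    if np.any(z_mod < 0):
        raise DomainError("impedance modulus must be non-negative")
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r = z_mod * np.cos(theta)
    x = z_mod * np.sin(theta)
    if r.ndim == 0:
        return float(r), float(x)
    return r, x


def cartesian_to_polar(re_ohm, im_ohm):
    """Convert (Re Z, Im Z) to (|Z|, phase in degrees); inverse of
    :func:`polar_to_cartesian` up to floating-point round-off."""
    re_ohm = np.asarray(re_ohm, dtype=float)
    im_ohm = np.asarray(im_ohm, dtype=float)
    z_mod = np.hypot(re_ohm, im_ohm)
    theta = np.rad2deg(np.arctan2(im_ohm, re_ohm))
    if z_mod.ndim == 0:
        return float(z_mod), float(theta)
    return z_mod, theta


@dataclass(frozen=True)
class SpectrumPoint:
    """One frequency point of a sweep: f > 0 and a complex impedance."""

    frequency_hz: float
    z_complex: complex

    def __post_init__(self):
        if not self.frequency_hz > 0:
            raise ValidationError(
                f"frequency must be positive, got {self.frequency_hz}"
            )

    @property
    def modulus(self) -> float:
        return abs(self.z_complex)

    @property
    def phase_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.z_complex.imag, self.z_complex.real)))


@dataclass(eq=False)
class ImpedanceSpectrum:
    """An ordered frequency sweep of complex impedance.

    Frequencies are sorted ascending on construction; duplicates are an
    error.  The minimum-point requirement for fitting (2N >= number of free
    parameters) is enforced at fit time, not here.
    """

    frequency_hz: np.ndarray
    z: np.ndarray
    label: str = ""

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.frequency_hz, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=complex))
        if f.shape != z.shape:
            raise ValidationError(
                f"frequency and impedance arrays differ in length: "
                f"{f.shape} vs {z.shape}"
            )
        if f.size == 0:
            raise ValidationError("a spectrum needs at least one point")
        bad = f <= 0
        if np.any(bad):
            raise ValidationError(
                "non-positive frequencies at rows "
                f"{np.flatnonzero(bad).tolist()}: {f[bad].tolist()}"
            )
        order = np.argsort(f, kind="stable")
        f, z = f[order], z[order]
        dup = np.flatnonzero(np.diff(f) == 0)
        if dup.size:
            raise ValidationError(
                f"duplicate frequencies: {np.unique(f[dup]).tolist()} Hz"
            )
        self.frequency_hz = f
        self.z = z

    def __len__(self) -> int:
        return self.frequency_hz.size

    def __iter__(self) -> Iterator[SpectrumPoint]:
        return iter(self.points)

    @property
    def points(self) -> list[SpectrumPoint]:
        return [
            SpectrumPoint(float(f), complex(z))
            for f, z in zip(self.frequency_hz, self.z)
        ]

    @property
    def re(self) -> np.ndarray:
        return self.z.real

    @property
    def im(self) -> np.ndarray:
        return self.z.imag

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.rad2deg(np.arctan2(self.z.imag, self.z.real))

    def allclose(self, other: "ImpedanceSpectrum", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.frequency_hz, other.frequency_hz, rtol=rtol)
            and np.allclose(self.z, other.z, rtol=rtol, atol=0.0)
        )


Source = Union[str, "IO[str]"]


def read_spectrum(source: Source, label: str | None = None) -> ImpedanceSpectrum:
    """Read a spectrum from a delimited text table.

    The header must name either the cartesian pair (``frequency_hz, re_ohm,
    im_ohm``) or the polar pair (``frequency_hz, z_mod_ohm, phase_deg``);
    tables carrying both are read from the cartesian columns.  Rows are
    sorted by frequency; duplicate or non-positive frequencies raise
    :class:`~eisdry.errors.ValidationError` naming the offending values.
    Lines starting with ``#`` (run-metadata headers) are ignored.
    """
    frame = pd.read_csv(source, comment="#")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    cols = set(frame.columns)
    if _CARTESIAN <= cols:
        re_ohm = frame["re_ohm"].to_numpy(dtype=float)
        im_ohm = frame["im_ohm"].to_numpy(dtype=float)
    elif _POLAR <= cols:
        re_ohm, im_ohm = polar_to_cartesian(
            frame["z_mod_ohm"].to_numpy(dtype=float),
            frame["phase_deg"].to_numpy(dtype=float),
        )
        re_ohm = np.atleast_1d(re_ohm)
        im_ohm = np.atleast_1d(im_ohm)
    else:
        raise SpectrumFormatError(
            "unrecognised columns "
            f"{sorted(cols)}; expected {sorted(_CARTESIAN)} or {sorted(_POLAR)}"
        )
    return ImpedanceSpectrum(
        frame["frequency_hz"].to_numpy(dtype=float),
        re_ohm + 1j * im_ohm,
        label=label if label is not None else "",
    )


def write_spectrum(spectrum: ImpedanceSpectrum, sink: Source, *,
                   metadata: dict | None = None) -> None:
    """Write a spectrum as CSV with both polar and cartesian columns at full
    precision (17 significant digits).  Optional ``metadata`` key/value pairs
    are emitted as leading ``#`` comment lines."""
    frame = pd.DataFrame(
        {
            "frequency_hz": spectrum.frequency_hz,
            "re_ohm": spectrum.re,
            "im_ohm": spectrum.im,
            "z_mod_ohm": spectrum.modulus,
            "phase_deg": spectrum.phase_deg,
        }
    )
    body = frame.to_csv(index=False, float_format="%.17g", lineterminator="\n")
    header = ""
    if metadata:
        header = "".join(f"# {k} = {v}\n" for k, v in metadata.items())
    text = header + body
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
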