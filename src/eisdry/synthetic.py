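"""Synthetic drying-study generator.

Emulates the measurement design the analysis pipeline assumes: a cohort of
whole vegetable samples (default 10, initial weights 75-96 g) air-dried for
21 daily observations, each day yielding a weight and an impedance sweep at
27 spot frequencies between 0.5 and 10 kHz.  The generator provides ground
truth for every derived quantity, so parameter recovery and calibration can
be tested end to end without any measured data.

The physics stand-ins, both configurable and deliberately simple:

* Drying law — geometric daily water loss: the water mass decays by a
  constant relative rate per day while the solid mass stays fixed, so weight
  falls and moisture M (water/solids) decays as (1 - rate)^t.
* Moisture-to-circuit map — each circuit parameter follows a power law
  param = a * M^b anchored at the circuit defaults for day-0 moisture.
  Defaults: resistive parameters scale as M^-1 (less electrolyte, more
  resistance), capacitive and CPE magnitudes as M^-0.5 (membrane disruption
  raises membrane capacitance as tissue dries), CPE exponents constant.
  Under this map |Z| rises monotonically at every frequency as M falls.
* Noise — i.i.d. multiplicative Gaussian on Re and Im of each point,
  default sd 0.05%, the accuracy class of a bench LCR meter.

Identical config + seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .circuits import CircuitModel, builtin_model, evaluate_circuit, parse_circuit
from .errors import ConfigError
from .moisture import DryingRecord
from .spectra import ImpedanceSpectrum, write_spectrum

__all__ = [
    "DryingSimConfig",
    "DryingDataset",
    "default_param_map",
    "moisture_trajectory",
    "spectrum_for_moisture",
    "simulate_drying",
    "default_frequency_grid",
]

#: Exponent b of param = a * M^b by parameter kind.
DEFAULT_MAP_EXPONENTS = {
    "resistor": -1.0,
    "capacitor": -0.5,
    "cpe_p": -0.5,
    "cpe_n": 0.0,
}


#: Spot frequencies the calibration stage analyses; the default grid is
#: guaranteed to contain them exactly.
ANALYSIS_FREQUENCIES_HZ = (500.0, 1100.0, 5000.0, 10_000.0)


def default_frequency_grid(n: int = 27, low_hz: float = 500.0,
                           high_hz: float = 10_000.0,
                           include=ANALYSIS_FREQUENCIES_HZ) -> np.ndarray:
    """n log-spaced spot frequencies spanning [low, high] Hz.

    The grid points nearest each entry of ``include`` are snapped onto it,
    so the frequencies the moisture calibration analyses are measured
    exactly rather than within grid tolerance.
    """
    f = np.geomspace(low_hz, high_hz, n)
    for target in include or ():
        if low_hz <= target <= high_hz:
            f[int(np.argmin(np.abs(f - target)))] = target
    return np.sort(f)


@dataclass
class DryingSimConfig:
    """Study design and physics stand-ins for :func:`simulate_drying`."""

    n_samples: int = 10
    n_days: int = 21
    initial_weight_range_g: tuple[float, float] = (75.0, 96.0)
    solid_fraction: float = 0.13
    drying_rate_per_day: float = 0.01
    truth_circuit: str = "cpe_modified"
    moisture_to_param_map: dict[str, tuple[float, float]] | None = None
    frequencies: np.ndarray | None = None
    noise_sd_rel: float = 0.0005
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.drying_rate_per_day < 1:
            raise ConfigError("drying_rate_per_day must lie in [0, 1)")
        if self.noise_sd_rel < 0:
            raise ConfigError("noise_sd_rel must be >= 0")
        if not 0 < self.solid_fraction < 1:
            raise ConfigError("solid_fraction must lie in (0, 1)")
        if self.n_samples < 1 or self.n_days < 1:
            raise ConfigError("n_samples and n_days must be >= 1")
        if self.frequencies is None:
            self.frequencies = default_frequency_grid()
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ConfigError("frequency grid must be strictly increasing")

    def circuit(self) -> CircuitModel:
        try:
            return builtin_model(self.truth_circuit)
        except LookupError:
            return parse_circuit(self.truth_circuit)

    @property
    def initial_moisture(self) -> float:
        """Day-0 moisture, (1 - s)/s — identical for every sample because the
        solid fraction is relative to initial weight."""
        s = self.solid_fraction
        return (1.0 - s) / s

    def as_dict(self) -> dict:
        d = asdict(self)
        d["frequencies"] = self.frequencies.tolist()
        return d


def default_param_map(circuit: CircuitModel, m_ref: float,
                      exponents: Mapping[str, float] = DEFAULT_MAP_EXPONENTS
                      ) -> dict[str, tuple[float, float]]:
    """Power-law map param = a * M^b anchored so that at moisture ``m_ref``
    each parameter equals the circuit's default value."""
    mapping = {}
    for pname, kind in circuit.param_kinds.items():
        b = float(exponents[kind])
        a = circuit.defaults[pname] / m_ref**b
        mapping[pname] = (a, b)
    return mapping


def moisture_trajectory(config: DryingSimConfig, initial_weight_g: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (weight_g, M) arrays for one sample over config.n_days days.

    Water mass w(t) = w(0) (1 - rate)^t; solids s*m_o stay fixed; M =
    water/solids, strictly decreasing for rate > 0 and never negative.
    """
    s = config.solid_fraction
    solid = s * initial_weight_g
    water0 = (1.0 - s) * initial_weight_g
    t = np.arange(config.n_days, dtype=float)
    water = water0 * (1.0 - config.drying_rate_per_day) ** t
    weight = solid + water
    m = water / solid
    return weight, m


def spectrum_for_moisture(config: DryingSimConfig, m: float,
                          rng: np.random.Generator | int | None = None,
                          label: str = "") -> tuple[ImpedanceSpectrum,
                                                    dict[str, float]]:
    """Simulate one spectrum at moisture ``m``; returns (spectrum, true
    circuit parameters).

    Parameters come from the power-law map, the circuit is evaluated on the
    config grid, and multiplicative Gaussian noise of sd ``noise_sd_rel`` is
    applied independently to Re and Im of each point.
    """
    if not m > 0:
        raise ConfigError(f"moisture must be positive, got {m}")
    circuit = config.circuit()
    mapping = config.moisture_to_param_map or default_param_map(
        circuit, config.initial_moisture)
    params = {}
    for pname in circuit.param_names:
        try:
            a, b = mapping[pname]
        except KeyError:
            raise ConfigError(f"moisture_to_param_map misses {pname!r}") from None
        value = a * m**b
        lo, hi = circuit.bounds[pname]
        if not lo <= value <= hi:
            raise ConfigError(
                f"map gives {pname} = {value:.4g} outside bounds [{lo}, {hi}] "
                f"at M = {m:.4g}"
            )
        params[pname] = value
    spectrum = evaluate_circuit(circuit, params, config.frequencies, label=label)
    if config.noise_sd_rel > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        eps = rng.normal(0.0, config.noise_sd_rel, size=(len(spectrum), 2))
        z = (spectrum.re * (1.0 + eps[:, 0])
             + 1j * spectrum.im * (1.0 + eps[:, 1]))
        spectrum = ImpedanceSpectrum(spectrum.frequency_hz, z, label=label)
    return spectrum, params


@dataclass
class DryingDataset:
    """All records of a simulated (or loaded) drying study.

    ``truth`` is present only for synthetic data: per sample and day, the
    true moisture and circuit parameters used to generate the spectrum.
    """

    records: list[DryingRecord]
    truth: dict[str, dict[int, dict]] | None = None
    config: DryingSimConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})

    def record(self, sample_id: str, day: int) -> DryingRecord:
        for r in self.records:
            if r.sample_id == sample_id and r.day == day:
                return r
        raise KeyError(f"no record for sample {sample_id!r} day {day}")

    def to_dir(self, out_dir, metadata: dict | None = None) -> None:
        """Write a drying-log CSV, one spectrum CSV per record, and (for
        synthetic data) truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in self.records:
            fname = f"spectrum_{rec.sample_id}_day{rec.day:02d}.csv"
            if rec.spectrum is not None:
                write_spectrum(rec.spectrum, str(out / fname), metadata=metadata)
            rows.append({"day": rec.day, "sample_id": rec.sample_id,
                         "weight_g": rec.weight_g,
                         "spectrum_file": fname if rec.spectrum else ""})
        log = pd.DataFrame(rows)
        with open(out / "drying_log.csv", "w", encoding="utf-8") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k} = {v}\n")
            fh.write(log.to_csv(index=False, float_format="%.17g",
                                lineterminator="\n"))
        if self.truth is not None:
            payload = {"truth": self.truth}
            if self.config is not None:
                payload["config"] = self.config.as_dict()
            if metadata:
                payload["_meta"] = metadata
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2)

    @classmethod
    def from_dir(cls, in_dir) -> "DryingDataset":
        from .spectra import read_spectrum

        src = Path(in_dir)
        log = pd.read_csv(src / "drying_log.csv", comment="#")
        records = []
        for row in log.itertuples(index=False):
            spec = None
            if isinstance(row.spectrum_file, str) and row.spectrum_file:
                spec = read_spectrum(str(src / row.spectrum_file),
                                     label=f"{row.sample_id} day {row.day}")
            records.append(DryingRecord(int(row.day), str(row.sample_id),
                                        float(row.weight_g), spec))
        truth = None
        truth_path = src / "truth.json"
        if truth_path.exists():
            with open(truth_path, encoding="utf-8") as fh:
                truth = json.load(fh)["truth"]
            truth = {s: {int(d): v for d, v in days.items()}
                     for s, days in truth.items()}
        return cls(records=records, truth=truth)


def simulate_drying(config: DryingSimConfig | None = None) -> DryingDataset:
    """Simulate the full drying study: one record per (sample, day).

    Randomness (initial weights, measurement noise) derives entirely from
    ``config.seed`` via a spawned seed tree, so identical configs give
    byte-identical datasets after serialization.
    """
    config = config or DryingSimConfig()
    root_ss = np.random.SeedSequence(config.seed)
    weight_ss, noise_ss = root_ss.spawn(2)
    weight_rng = np.random.default_rng(weight_ss)
    lo, hi = config.initial_weight_range_g
    initial_weights = weight_rng.uniform(lo, hi, size=config.n_samples)
    sample_streams = noise_ss.spawn(config.n_samples)

    records: list[DryingRecord] = []
    truth: dict[str, dict[int, dict]] = {}
    for i in range(config.n_samples):
        sample_id = f"onion{i + 1:02d}"
        weights, m_series = moisture_trajectory(config, initial_weights[i])
        day_streams = sample_streams[i].spawn(config.n_days)
        truth[sample_id] = {}
        for day in range(config.n_days):
            rng = np.random.default_rng(day_streams[day])
            spectrum, params = spectrum_for_moisture(
                config, float(m_series[day]), rng,
                label=f"{sample_id} day {day}")
            records.append(DryingRecord(day, sample_id, float(weights[day]),
                                        spectrum))
            truth[sample_id][day] = {
                "moisture": float(m_series[day]),
                "weight_g": float(weights[day]),
                "params": {k: float(v) for k, v in params.items()},
            }
    return DryingDataset(records=records, truth=truth, config=config)
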