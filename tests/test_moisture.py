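import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eisdry.circuits import builtin_model, evaluate_circuit
from eisdry.errors import CalibrationError, DomainError, FrequencyLookupError
from eisdry.moisture import (
    DryingRecord,
    calibration_sweep,
    fit_calibration,
    impedance_per_unit_weight,
    modulus_at_frequency,
    moisture_from_weight,
    per_unit_weight_calibration,
    predict_moisture,
)
from eisdry.spectra import ImpedanceSpectrum
from eisdry.synthetic import DryingSimConfig, simulate_drying

# printed degree-2 per-unit-weight calibration used as a generator in tests
QUADRATIC = (-0.0002442, 0.03636, 5.346)


class TestMoistureFromWeight:
    def test_initial_weight_gives_water_to_solid_ratio(self):
        assert moisture_from_weight(80.0, 80.0, 0.13) == pytest.approx(
            6.6923, abs=1e-4
        )

    def test_bone_dry_weight_gives_zero(self):
        assert moisture_from_weight(0.13 * 96.0, 96.0, 0.13) == 0.0

    def test_partially_dried_sample(self):
        assert moisture_from_weight(90.0, 96.0, 0.13) == pytest.approx(
            6.2115, abs=1e-4
        )

    def test_below_solid_mass_warns_and_goes_negative(self):
        with pytest.warns(UserWarning, match="negative"):
            assert moisture_from_weight(10.0, 96.0, 0.13) < 0

    @pytest.mark.parametrize("kwargs", [
        {"m_t": 80.0, "m_o": 0.0}, {"m_t": 80.0, "m_o": 80.0, "s": 1.5},
        {"m_t": -1.0, "m_o": 80.0},
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            moisture_from_weight(**kwargs)

    @given(
        m_o=st.floats(min_value=10, max_value=200),
        s=st.floats(min_value=0.05, max_value=0.5),
        delta=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_monotone_in_weight_and_solid_fraction(self, m_o, s, delta):
        base = moisture_from_weight(m_o, m_o, s)
        assert moisture_from_weight(m_o + delta, m_o, s) > base
        assert moisture_from_weight(m_o, m_o, min(s + 0.1, 0.95)) < base


@pytest.mark.parametrize(
    "z, w, expected", [(100.0, 1000.0, 100.0), (100.0, 100.0, 1000.0),
                       (2500.0, 80.0, 31_250.0)]
)
def test_impedance_per_unit_weight(z, w, expected):
    assert impedance_per_unit_weight(z, w) == pytest.approx(expected)


def test_impedance_per_unit_weight_rejects_non_positive_weight():
    with pytest.raises(DomainError):
        impedance_per_unit_weight(100.0, 0.0)


class TestFitCalibration:
    def test_noiseless_linear_recovered_exactly(self):
        z = np.array([1000.0, 2000.0, 5000.0, 8000.0, 12_000.0])
        m = -0.0002 * z + 7.3
        cal = fit_calibration(m, z, degree=1)
        assert cal.coefficients[0] == pytest.approx(-0.0002, rel=1e-9)
        assert cal.coefficients[1] == pytest.approx(7.3, rel=1e-9)
        assert cal.sse == pytest.approx(0.0, abs=1e-18)
        assert cal.r_squared == pytest.approx(1.0)

    def test_printed_quadratic_recovered(self):
        zpu = np.array([10.0, 30.0, 60.0, 100.0, 140.0])
        m = np.polyval(QUADRATIC, zpu)
        cal = fit_calibration(m, zpu, degree=2,
                              predictor="impedance_per_unit_weight")
        for got, want in zip(cal.coefficients, QUADRATIC):
            assert got == pytest.approx(want, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], 1)

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0, 2.0], [1.0, 2.0], 1)

    def test_rmse_brackets_injected_noise_level(self):
        """Adding N(0, sigma) noise to a perfect line must give an RMSE
        within [0.5 sigma, 1.5 sigma] at N = 100."""
        rng = np.random.default_rng(13)
        sigma = 0.05
        z = np.linspace(1000, 10_000, 100)
        m = -0.0003 * z + 7.1 + rng.normal(0, sigma, z.size)
        cal = fit_calibration(m, z, degree=1)
        assert 0.5 * sigma <= cal.rmse <= 1.5 * sigma

    def test_predictions_reproduce_fitted_values(self):
        rng = np.random.default_rng(3)
        z = np.linspace(500, 9000, 30)
        m = -0.0002 * z + 7.0 + rng.normal(0, 0.02, z.size)
        cal = fit_calibration(m, z, degree=1)
        yhat = np.array([predict_moisture(cal, zi) for zi in z])
        assert np.sum((m - yhat) ** 2) == pytest.approx(cal.sse, rel=1e-9)


class TestPredictMoisture:
    def test_printed_quadratic_intercept(self):
        cal = fit_calibration(
            np.polyval(QUADRATIC, np.array([10.0, 30.0, 60.0, 100.0, 140.0])),
            [10.0, 30.0, 60.0, 100.0, 140.0], degree=2)
        with pytest.warns(UserWarning, match="extrapolating"):
            assert predict_moisture(cal, 0.0) == pytest.approx(5.346, rel=1e-6)

    def test_printed_10khz_linear_intercept(self):
        p1, p2 = -0.0003032, 7.119
        z = np.array([0.0, 2000.0, 5000.0, 9000.0])
        cal = fit_calibration(p1 * z + p2, z, degree=1)
        assert predict_moisture(cal, 0.0) == pytest.approx(7.119, rel=1e-9)

    def test_degree_one_evaluation(self):
        z = np.array([0.0, 1.0, 2.0, 10.0])
        cal = fit_calibration(-1.0 * z, z, degree=1)
        assert predict_moisture(cal, 5.0) == pytest.approx(-5.0)


def _toy_records():
    """Three-day toy drying series whose 10 kHz modulus is exactly linear in
    moisture while the 500 Hz modulus is a noisy, curved function of it."""
    records = []
    weights = [80.0, 75.0, 70.0]
    rng = np.random.default_rng(0)
    for day, w in enumerate(weights):
        m = moisture_from_weight(w, weights[0])
        z_hi = 12_000.0 - 1000.0 * m
        z_lo = 20_000.0 / (m + 0.5) + rng.normal(0, 50)
        f = np.array([500.0, 1000.0, 10_000.0])
        z = np.array([z_lo, 0.5 * (z_lo + z_hi), z_hi]) * np.exp(-0.2j)
        records.append(DryingRecord(day, "s1", w,
                                    ImpedanceSpectrum(f, z)))
    return records


class TestCalibrationSweep:
    def test_exactly_linear_frequency_ranks_first(self):
        cals = calibration_sweep(_toy_records(), [500.0, 10_000.0])
        assert cals[0].frequency_hz == 10_000.0
        assert cals[0].r_squared == pytest.approx(1.0)

    def test_one_calibration_per_requested_frequency(self):
        cals = calibration_sweep(_toy_records(), [500.0, 1000.0, 10_000.0])
        assert len(cals) == 3

    def test_missing_frequency_named_in_error(self):
        with pytest.raises(FrequencyLookupError, match="4000"):
            calibration_sweep(_toy_records(), [4000.0])

    def test_simulated_drying_gives_negative_slopes_everywhere(self):
        cfg = DryingSimConfig(n_samples=3, n_days=8, seed=21)
        ds = simulate_drying(cfg)
        cals = calibration_sweep(ds.records, [500.0, 1100.0, 5000.0, 10_000.0])
        assert len(cals) == 4
        assert all(c.coefficients[0] < 0 for c in cals)


def test_per_unit_weight_calibration_on_simulated_data():
    """The per-unit-weight quadratic fits and is falling over the observed
    predictor range.  Its correlation is deliberately NOT asserted to be
    tight: the simulator's impedance depends only on moisture, not sample
    size, so dividing by weight adds cross-sample scatter there (see the
    methods note)."""
    cfg = DryingSimConfig(n_samples=3, n_days=8, seed=22)
    ds = simulate_drying(cfg)
    cal = per_unit_weight_calibration(ds.records, 10_000.0, degree=2)
    assert cal.predictor == "impedance_per_unit_weight"
    assert cal.degree == 2 and len(cal.coefficients) == 3
    assert cal.r_squared <= 1.0
    lo, hi = cal.predictor_range
    assert predict_moisture(cal, hi) < predict_moisture(cal, lo)

    # single-sample data removes the size confound: correlation is tight
    one = [r for r in ds.records if r.sample_id == "onion01"]
    cal1 = per_unit_weight_calibration(one, 10_000.0, degree=2)
    assert cal1.r_squared > 0.99


def test_modulus_at_frequency_tolerance():
    s = ImpedanceSpectrum([995.0, 2000.0], [100 - 1j, 90 - 1j])
    assert modulus_at_frequency(s, 1000.0) == pytest.approx(abs(100 - 1j))
    with pytest.raises(FrequencyLookupError):
        modulus_at_frequency(s, 1500.0)
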