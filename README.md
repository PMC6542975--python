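# eisdry

Equivalent-circuit analysis of electrical impedance spectroscopy (EIS) data
from dehydrating plant tissue, and impedance-based estimation of moisture
content. Written for plant/food physiologists and instrumentation engineers
who track vegetables (the motivating case is whole onion bulbs) through
storage drying with a bench LCR meter and want a nondestructive moisture
proxy.

The package covers the full chain:

1. **Spectra** — read/write frequency sweeps of complex impedance
   Z(ω) = Re Z − j·X (capacitive points have Im Z < 0), with polar ↔
   cartesian conversion R = |Z| cos θ, X = |Z| sin θ.
2. **Circuits** — an expression language for series/parallel networks of
   resistors, capacitors and constant phase elements
   (Z_CPE = 1/(P·(jω)ⁿ)), with the classical plant-tissue circuits built
   in: Hayden `Re|((Rm|Cm)-Ri)`, simplified Hayden `Re|(Ri-Cm)`,
   CPE-modified `Re|(Ri-CPE)`, double-shell `R1|(C1-(R2|(C2-R3)))`, and a
   two-relaxation dehydration model `R1-(R2|CPE1)-(R3|C1)`.
3. **Fitting** — complex nonlinear least squares by Nelder–Mead simplex
   over log-transformed parameters, with modulus or unit weighting,
   seeded multi-start, and goodness-of-fit reported as mean absolute and
   root-mean-square *percentage* errors of the real and imaginary parts.
4. **Moisture** — moisture content relative to solid content,
   M = (m_t − s·m_o)/(s·m_o) (g water / g solids, solid fraction s = 0.13
   by default), polynomial calibrations of M against |Z| at spot
   frequencies or against impedance per unit weight (Ω/kg), with SSE, R²
   and RMSE.
5. **Synthetic data** — a seeded generator for a complete drying study
   (10 samples × 21 days × 27 frequencies from 0.5 to 10 kHz by default)
   with ground-truth circuit parameters and moisture, so every stage can
   be validated end to end.

## Worked example

```python
import numpy as np
from eisdry import (builtin_model, evaluate_circuit, fit_model, FitOptions,
                    DryingSimConfig, simulate_drying, calibration_sweep)

# Fit the CPE-modified circuit to one of its own spectra
model = builtin_model("cpe_modified")
truth = {"Re": 10_000.0, "Ri": 2_000.0, "P": 1e-6, "n": 0.8}
spectrum = evaluate_circuit(model, truth, np.geomspace(500, 10_000, 27))
result = fit_model(model, spectrum, FitOptions(seed=1),
                   initial={"Re": 15_000, "Ri": 1_400, "P": 2e-6, "n": 0.9})
print({k: float(f"{v:.6g}") for k, v in result.parameters.items()})
# {'Re': 10000.0, 'Ri': 2000.0, 'P': 1e-06, 'n': 0.8}
print(f"{result.objective:.3e}")   # 1.747e-23

# Simulate a drying study and calibrate moisture against |Z|
dataset = simulate_drying(DryingSimConfig(seed=1))
for cal in calibration_sweep(dataset.records, [500, 1100, 5000, 10000]):
    print(f"{cal.frequency_hz:>7.0f} Hz  slope={cal.coefficients[0]:.3e}  "
          f"R^2={cal.r_squared:.4f}")
#    5000 Hz  slope=-3.360e-03  R^2=0.9969
#   10000 Hz  slope=-3.318e-03  R^2=0.9968
#    1100 Hz  slope=-3.765e-03  R^2=0.9960
#     500 Hz  slope=-4.692e-03  R^2=0.9939
```

The fitted parameters match the generating truth to ~1e-10 relative; the
calibration sweep shows what drying tissue produces physically: impedance
rises as moisture falls (negative slopes at every frequency), and the
correlation is tighter in the upper part of the sweep — where current
penetrates the cells instead of detouring around them — than at 0.5 kHz.

A command-line interface wraps the same stages:

```sh
eisdry simulate --out-dir data --seed 1
eisdry fit --spectrum data/spectrum_onion01_day18.csv --model cpe_modified \
           --seed 1 --out fit.json
eisdry compare --spectrum data/spectrum_onion01_day18.csv --seed 1 --out cmp.csv
eisdry calibrate --data-dir data --frequencies 500,1100,5000,10000 --out-dir cals
eisdry predict --calibration cals/calibration_10000Hz.json --value 2500
```

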