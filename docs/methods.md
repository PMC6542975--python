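# Methods

## Problem and model

During unrefrigerated storage, plant tissue loses water; its electrical
impedance rises and its spectrum shape changes because cell-membrane
capacitance governs how much current can reach the intracellular fluid
(the β dispersion: at low frequency current is confined to the resistive
extracellular path, at high frequency membranes short out and the lower
intracellular resistance takes over). `eisdry` models a measured sweep
Z(ω) with lumped equivalent circuits, extracts the circuit parameters by
complex nonlinear least squares, and calibrates a nondestructive moisture
proxy against the impedance.

### Spectra

Impedance is stored as a complex number per frequency with the signed
convention Im Z < 0 for capacitive behaviour. The literature's
Z = R − jX with X a positive reactance magnitude corresponds to
X = −Im Z; storing the signed value removes any ambiguity in Nyquist
plotting (−Im Z vs Re Z) and in residuals. Files carry degrees and both
polar and cartesian columns at 17 significant digits; frequencies are
sorted ascending on read because all downstream mathematics is
order-insensitive.

### Circuits

Elements: resistor Z = R; capacitor Z = 1/(jωC); constant phase element
Z = 1/(P·(jω)ⁿ) on the principal branch, i.e. constant phase −n·90°. The
CPE is the standard lumped description of a distributed (depressed-arc)
membrane capacitance; n = 1 recovers an ideal capacitor with C = P and
n → 0 tends to a resistor 1/P. Circuit topologies are series/parallel
binary trees; series nodes sum impedances, parallel nodes sum
admittances. In the expression grammar `|` (parallel) binds tighter than
`-` (series) so the common `Re|(...)` forms are writable without extra
nesting.

Built-in circuits (defaults chosen to put the relaxations inside the
0.5–10 kHz band at vegetable-tissue scales, Re ~ 10 kΩ, Ri ~ 2 kΩ,
Cm ~ 50 nF):

| name | topology | parameters |
|---|---|---|
| hayden | `Re\|((Rm\|Cm)-Ri)` | 4 |
| simplified_hayden | `Re\|(Ri-Cm)` | 3 |
| cpe_modified | `Re\|(Ri-CPE)` | 4 |
| double_shell | `R1\|(C1-(R2\|(C2-R3)))` | 5 |
| proposed | `R1-(R2\|CPE1)-(R3\|C1)` | 6 |

The `proposed` entry is this package's default dehydration topology: a
series access resistance plus two relaxation blocks, one dispersive
(ZARC) and one ideal RC. Two properties motivated it: it is the minimal
structure with two time constants, and the R + ZARC sub-network is
*exactly* equivalent to the CPE-modified circuit (partial-fraction
identity: `Re|(Ri-CPE)` equals `R1-(R2|CPE')` with R1 = ReRi/(Re+Ri),
R1+R2 = Re and a rescaled P), so it strictly nests the single-arc model.
It is configurable — any expression string can replace it — and is not a
claim about a unique tissue circuit.

Fitting bounds default to R ∈ [1e-3, 1e9] Ω, C ∈ [1e-15, 1] F,
P ∈ [1e-15, 1], n ∈ (0, 1]: generous brackets that exclude nothing
physically plausible for tissue.

**Identifiability caveat.** Any series/parallel network containing a
single capacitor has an impedance bilinear in s = jω,
Z = (A + Bs)/(C + Ds), hence only three identifiable invariants. The
4-parameter Hayden circuit is therefore structurally over-parameterised:
a one-parameter family of (Re, Rm, Ri, Cm) reproduces any one spectrum
exactly, and only its DC resistance Re(Ri+Rm)/(Re+Ri+Rm), high-frequency
resistance ReRi/(Re+Ri) and pole time constant are recoverable from a
single sweep. Tests assert recovery of those invariants; per-parameter
recovery is asserted only for the four identifiable built-ins.

### Fitting

The objective is the sum of squared stacked real/imaginary residuals,
optionally divided per point by |Z_measured| (modulus weighting, the
default: a spectrum spanning decades of ohms then contributes evenly
across the band; unit weighting is selectable for instrument-limited
work). Minimisation is Nelder–Mead simplex — derivative-free, robust to
the CPE's non-smooth parameter dependence — over log10(R), log10(C),
log10(P) and untransformed n clipped to (0, 1]; the log transform
enforces positivity without penalties and makes the simplex steps
scale-free. Defaults: xtol = ftol = 1e-10, 10 000 iterations, 4 restarts
with multiplicative jitter drawn log-uniformly from [0.2, 5] around the
start (seeded), plus a final re-polish of the best vertex with a fresh
simplex; the restarts guard against the multi-modal surfaces typical of
multi-relaxation circuits. Initial values, when not supplied, come from
spectrum geometry: the low- and high-frequency real-part levels set the
resistance scales and the −Im Z peak frequency sets capacitance scales
via ω_peak ≈ 1/(RC); this guess is deliberately rough and relies on the
restarts. Hitting the iteration cap returns the best point with
`converged=False` rather than raising.

Goodness of fit follows the percentage-error convention for EIS model
comparison, per component c ∈ {Re Z, Im Z}:

    MAE%  = (100/N) Σ |c_fit − c_meas| / |c_meas|
    RMSE% = 100 √((1/N) Σ ((c_fit − c_meas)/c_meas)²)

Both are undefined where a measured component is exactly zero (relative
error has no meaning there); the comparison table records such models
with empty metrics rather than failing.

### Moisture and calibration

Moisture is kept on the solids-relative basis
M = (m_t − s·m_o)/(s·m_o) in g water per g solids; the default solid
fraction s = 0.13 of the initial weight is the conventional value for
onion bulbs. No wet-basis conversion is performed anywhere. A weight
below the bone-dry estimate s·m_o yields a negative M with a warning
(measurement noise or a wrong s), not an error.

Calibrations are ordinary least-squares polynomials (degree 1 or 2) of M
against either |Z| at a spot frequency or |Z| normalised by the
*current-day* sample weight in Ω/kg. The per-unit-weight denominator is
the measurement-day weight because the normalisation compensates for
sample size at measurement time; this is a documented convention, and
per-record weights are what the API takes, so callers can normalise by
initial weight instead if their protocol requires it. Reported
statistics: SSE = Σ(M − M̂)², R² = 1 − SSE/SST, RMSE = √(SSE/N).
Requested spot frequencies are matched to the nearest grid point within
1% (grids differ between instruments and runs); beyond that tolerance
the lookup fails loudly. Prediction outside the fitted predictor range
is allowed but warned about as extrapolation.

## Synthetic drying studies

The generator emulates the study design the analysis assumes: a cohort
(default 10 samples, initial weights uniform in 75–96 g) observed daily
(default 21 days) with a 27-point log-spaced sweep over 0.5–10 kHz.
Its three stand-in laws, all configurable:

* **Drying** — geometric daily water loss: water mass w(t) =
  w(0)·(1 − r)^t with r = 0.01/day, solids fixed, so M decays
  geometrically and weight is bounded below by the solid mass. Chosen for
  monotonicity and two-parameter simplicity.
* **Moisture → circuit parameters** — a power law per parameter,
  value = a·M^b, anchored so the circuit defaults hold at day-0 moisture
  (1 − s)/s ≈ 6.69. Default exponents: resistances b = −1 (less
  electrolyte → more resistance), capacitances and CPE magnitudes
  b = −0.5 (membrane disruption during drying raises membrane
  capacitance), CPE exponents constant. Under any such monotone map |Z|
  rises at every frequency as M falls, which is the qualitative behaviour
  the pipeline is designed to detect. There is no quantitative tissue
  model behind the exponents; they are the simulator's explicit
  assumption.
* **Noise** — i.i.d. multiplicative Gaussian on Re and Im per point,
  default sd 0.05%, a bench LCR meter's accuracy class. No
  frequency-dependent or correlated noise.

The default grid is 27 log-spaced spot frequencies over 0.5–10 kHz with
the points nearest 500, 1100, 5000 and 10 000 Hz snapped exactly onto
those values, mirroring an instrument whose spot list includes the
frequencies later analysed (a plain geometric grid leaves 1.1 kHz 1.8%
from its nearest neighbour, outside the calibration stage's 1% matching
tolerance).

Randomness derives from one seed through a spawned `SeedSequence` tree
(weights, then per-sample per-day noise streams), so identical configs
serialize byte-identically and distinct seeds differ.

What passing tests on synthetic data do and do not show: they validate
the *algebra and inference machinery* — circuit evaluation, fit
convergence and recovery, calibration statistics, monotone relationships
— under the generator's idealised laws. They do not validate the
power-law exponents against real tissue, electrode-contact artifacts,
temperature/humidity covariates, sample-to-sample biological variation
beyond initial weight, or sprouting/rotting; conclusions about real
produce require measured spectra. One known sensitivity: *which* spot
frequency calibrates best depends on where the dispersion sits relative
to the band in the moisture→parameter map, so the simulator's frequency
ranking is reported by the tests, not asserted as a property of real
onions. A second structural gap: the generator's impedance depends only
on moisture, never on sample size, whereas real impedance scales with
specimen geometry. Per-unit-weight normalisation — whose purpose with
real samples is to remove size variation — therefore *adds*
cross-sample scatter on pooled synthetic data; its calibration quality
is only meaningful per sample there.

## Numerical choices and problem sizes

* Circuit-evaluator validation: 500 random series/parallel trees of ≤ 8
  elements, 27 frequencies, agreement ≤ 1e-12 relative against an
  independent recursive oracle that uses complex exponentiation directly.
* Recovery tests start the fit at truth × (1.5, 0.7, 2.0, …) — a
  standard perturbed-truth protocol — and require ≤ 1e-3 relative
  parameter error with objective < 1e-10 for the identifiable circuits;
  noise robustness uses 0.5% multiplicative noise, 20 seeded replicates,
  median error ≤ 5% (simplified Hayden).
* The end-to-end study runs the full default design (210 records); model
  comparison fits all five built-ins on a late-drying spectrum with 2
  restarts and a 6 000-iteration cap, which keeps the whole validation
  run at desk scale (a few minutes on one core).
* Degenerate inputs fail loudly and early: non-positive frequencies or
  weights, duplicate frequencies, constant calibration predictors,
  out-of-bounds simulator parameters, zero measured components under
  relative metrics.

## Limitations

* No Warburg, inductive or transmission-line elements; no automatic
  topology search; no Kramers–Kronig consistency checking or weighting.
* No confidence intervals on circuit parameters (the simplex provides
  none; a future refinement could bootstrap the residuals).
* Calibrations are plain OLS — no robust or weighted variants — and are
  variety- and protocol-specific by nature; transferring one across
  cultivars or electrode geometries is not supported.
* The Hayden circuit's structural non-identifiability (above) is a
  property of the model class, not of the optimizer; reporting its
  fitted parameters individually is meaningful only with external
  constraints.
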