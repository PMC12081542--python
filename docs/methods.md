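# Methods

This note documents the models behind `tblmkit`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Measurement model

A tethered bilayer on a gold electrode, driven by a stepped voltage ramp,
is treated as a capacitance `C_m` in parallel with a voltage-dependent
conductance. On the rising limb the total current at step voltage `V` is

    i(V) = C_m · dV/dt + I_cond(V),

with the capacitive term constant because the ramp rate is constant
(default 100 V/s: 5 mV steps every 0.05 ms, each sample being the
instrument's average over the post-increment window). The electrode itself
is treated as ideal: for pulses this short the blocking gold electrode's
own impedance is small compared to the membrane's, so no series element is
included by default (an optional `series_resistance` scenario parameter
exists but is off in every preset).

`I_cond` is modelled as three regions: ohmic at low voltage (slope
`G_low`, through the origin), ohmic at high voltage (slope `G_high`), and
a smooth transition between breakpoints `v1 ≤ v2`. The transition's true
shape is not known; it is represented by the minimal smooth interpolant —
a C¹ cubic Hermite bridge whose endpoint value at `v2` is fixed by the
mean slope `(G_low + G_high)/2`. That choice makes the bridge monotone for
any non-negative slope pair (Fritsch–Carlson: α + β = 2) and leaves the
flanking lines, which carry all the physics reported downstream, exactly
linear.

## Capacitance estimation

`estimate_capacitance` divides the mean of the first `n_onset_steps`
samples (default 1 — each sample is already window-averaged by the
instrument) by the ramp rate, after subtracting a conductive correction
`g·V` when a conductance estimate is available. At onset voltages of a few
mV the conductive term is ~10⁻⁴ of the capacitive term, so the correction
matters only for exactness, not accuracy. A non-positive onset current is
an error, never `C = 0`: it means there is no capacitive signal to read.
A specific capacitance above 50 mF/m² (configurable) triggers a warning in
the pipeline — bare gold electrodes read hundreds of nF, so a very high
value suggests no bilayer formed.

## Segmentation

For every ordered breakpoint pair on the sampled voltage grid (breakpoints
are restricted to sampled voltages — 5 mV resolution matches the data, and
it keeps the search exhaustively enumerable), with at least 3 samples in
each flanking region, the full continuous three-region model is fitted to
**all** samples by OLS. Given the pair, the model is linear in three
coefficients (an intercept absorbing any residual capacitive offset, and
the two conductances), so each candidate costs one 3×3 solve; the
minimal-SSE pair wins.

Why fit all samples rather than only the two flanking segments? A
flanking-only residual has a degenerate minimum — shrinking both segments
always shrinks the SSE, so under noise the argmin collapses onto two
minimal 3-point segments with wildly variable slopes. And any rule that
assigns transition samples to the flanking lines whenever their curvature
is below the noise floor biases the breakpoints outward and the slopes
toward each other. Fitting the complete model is the maximum-likelihood
estimator of all five parameters; measured over 200 seeded traces at 1 %
full-scale noise, every parameter (C, G_low, G_high, v1, v2) is unbiased
within Monte-Carlo error, and on noise-free traces recovery is exact.

Numerical details: SSE is computed from normal equations, so two
objectives are declared tied when they differ by less than `1e-10` times
the trace's total centered sum of squares (the cancellation noise of the
computation, far below the misfit of a one-step breakpoint error); ties
are broken by the widest linear coverage, then the smallest `v1`. An
all-flat conductive trace returns zero slopes with both breakpoints at the
median voltage. Fewer than 10 rising-limb samples is an error. Fitted
slopes are reported as-is; a (physically impossible) negative slope on a
noise-dominated trace warns rather than raises, because hard-failing on an
unbiased estimator's tail draw would make analyses fail stochastically.

## Arrhenius analysis

`arrhenius_fit` is unweighted OLS of ln G on 1/T (kelvin); weighting is
deliberately not applied since the generator's noise is log-uniform across
the sweep. `E_a = −slope · R` with R = 8.314 J/(mol·K). The slope is also
reported per 10³/T, the conventional Arrhenius plot axis (slope −10 there
is E_a ≈ 83.1 kJ/mol). A constant series fits slope 0 with r² defined as 1
(zero residual). Temperatures are Celsius in every file and CLI boundary
and kelvin internally (T/K = T/°C + 273.15).

**Desorption detection.** Xenon leaves the bilayer irreversibly when a
warming sweep passes ≈ 24 °C, producing a sudden conductance jump; after
it the pre-event V–I behaviour is not recoverable. The detector walks the
sweep in order: at each index it fits the preceding points and computes
the standardized one-step-ahead ln-residual, flagging the first
|z| > threshold (default 5). The standardization scale is
`max(fit residual SD, robust SD, 1e-12)` multiplied by the OLS
prediction-leverage factor `sqrt(1 + 1/n + (x−x̄)²/Sxx)`. The robust SD
comes from the median absolute deviation of successive ln G differences
(differencing removes the near-constant Arrhenius increment; a single jump
cannot corrupt a median). Both guards matter: with 2–3 seed points the raw
fit SD is so noisy that an unguarded z-statistic has Cauchy-like tails and
flags clean data a few percent of the time, while on noise-free data the
fit SD collapses to rounding error and every residual would look infinite.
With them, injected 24 °C events in 2 %-noise sweeps are located at
exactly the right index in ≥ 99 % of seeded runs with no false alarms.
Detection starts at index 2 (an exact two-point line as the first seed) so
that an event early in a sweep is still flagged, and `fit_with_truncation`
can then refuse to fit a sub-3-point prefix. Events are only searched on
warming sweeps — desorption does not occur on cooling — unless forced.
Because a sweep through an event mixes two membrane states (the xenon
content itself is temperature-dependent), `fit_with_truncation` restricts
the fit to the longest event-free prefix and reports the event alongside.

## Pore energetics

The chain from activation energy to pore properties:

1. **Born energy** `W_B = E_a − E_aq`, with `E_aq = 18 kJ/mol` the
   activation energy of electrodiffusion in the aqueous phase. The default
   is the unique value consistent with both reference decompositions
   handled by this package (84 → 66 and 73 → 55 kJ/mol); it is exposed in
   config. `E_a < E_aq` is a domain error (a negative membrane barrier).
2. **Partition coefficient** `γ = exp(−W_B/RT)` at the measurement
   temperature (default 295.15 K, room temperature). Strictly decreasing
   in `W_B`, increasing in T, always in (0, 1].
3. **Per-pore conductance** `g = γ σ π r²/d`: the ohmic conductance of an
   electrolyte cylinder spanning the bilayer, scaled by the partitioning
   of carriers into it. σ defaults to 1.6 S/m (isotonic PBS at room
   temperature); d to 5 nm. The area-normalized `G_p = g/A` (A = 2.1×10⁻⁶
   m², the chip's electrode) is reported alongside, because pore
   conductivities in this field are conventionally quoted per electrode
   area.
4. **Pore density** `N = G_m(specific)/g`. The identity
   `N·g ≡ G_m(specific)` holds to 10⁻¹² relative by construction and is
   enforced by the `PoreProperties` container.

An E_a uncertainty of ±ΔE maps onto γ (and hence g and N) as the factor
`exp(ΔE/RT)` — ±4 kJ/mol is a factor ≈ 5; `ea_uncertainty_factor` computes
it.

**Pore radius.** The radius enters only through `g ∝ r²`. It can be given
directly (the usual mode — reported radii are inputs here) or inverted
from `W_B` through a barrier model `W(r)`. The default registered model is
an image-charge approximation for an ion of charge q centred in a
water-filled cylindrical pore of radius r through a low-dielectric slab of
thickness d:

    W(r) = N_A · q²/(4π ε₀ ε_w r) · (1 − ε_m/ε_w) · (d/r) / (d/r + ε_w/ε_m)

with ε_w = 80, ε_m = 2.2 (both configurable). The second factor is a
dimensionless screening term: it vanishes as the dielectric contrast
disappears or the pore becomes short and wide, and saturates for a long
narrow pore, so W is strictly decreasing in r and diverges as r → 0. This
form is a documented stand-in in the Parsegian dielectric-continuum
spirit, not a solution of the full electrostatics; published (W_B, r)
pairs for these membranes are not jointly consistent with any single
one-parameter 1/r law, which is why radius-as-input is the primary mode
and the model's absolute values are treated as regression values only.
Alternative models can be registered by name; each must expose its formula
string and citation and satisfy the monotonicity contract. Inversion is a
bracketed Brent root-find on [10⁻¹², 10⁻⁸] m (tolerance 10⁻¹⁵ m absolute /
10⁻⁹ relative, unique by monotonicity); targets outside the attainable
range raise an error reporting `W(r_min)` and `W(r_max)`.

**Lipid equilibrium.** `interfacial_free_energy` evaluates
`γ_m = (μ₁,₀ − μ_m,₀ + k_B T ln X₁)/a` for lipids in equilibrium between
bilayer and monomer states. Its role here is the qualitative packing
argument: a solute that tightens lipid packing lowers the area per
molecule `a` and therefore raises `γ_m`, changing pore formation. Negative
results are returned with a warning rather than rejected.

## Synthetic data

The generator emulates: the capacitive onset step; the three-region
conductive current; additive Gaussian current noise (per-sample,
zero-mean); Arrhenius G(T) with multiplicative lognormal noise of given
CV, parameterized with unit median so ln-residuals are zero-mean and the
log-space fit is unbiased; and the irreversible desorption jump, which is
path-dependent — it fires only when a warming sweep crosses the desorption
temperature and never reverts. Noise-free output is exactly reproducible;
seeded noisy output is bit-identical across runs. Only the rising limb is
emitted by default (the analysis uses only it); a flag appends the
symmetric falling limb, on which the capacitive term changes sign.

It does **not** emulate: electrode double-layer effects, drift, hysteresis
between limbs, temperature-dependent xenon content below the desorption
point, solubility thermodynamics of the gas-dosing protocol, or
channel-forming peptide kinetics. Passing tests therefore demonstrate that
the estimators recover the parameters of this idealized instrument — not
that real traces are free of systematics the model omits.

Preset values: capacitances (24 nF lipid-only, 20 nF with xenon over the
2.1 mm² electrode), the low-voltage conductance scale (0.9 µS) and the
activation energies (73 kJ/mol lipid-only, 84 kJ/mol with 10 % xenon) are
the reference values this package is validated against. High-voltage
conductances and the tether-density (T1/T10/T100) variants are
illustrative: they are chosen once to preserve the observed orderings —
xenon lowers capacitance and high-voltage conductance, and its effect
shrinks as tether density grows — with noise defaulting to 1 % of each
scenario's full-scale current (CV 2 % for thermal sweeps, matching
run-to-run scatter of repeated bench measurements). Breakpoints default to
0.15/0.30 V; no measured breakpoint voltages exist to calibrate against,
so recovered breakpoints are reported but only checked against the
generator.

## Pipeline and formats

Trace CSV: `time_s,voltage_V,current_A`; series CSV:
`temperature_C,conductance_S`; UTF-8, '.' decimal, headers mandatory,
17-significant-digit floats so write→read round-trips are bit-exact
(reading uses round-trip float parsing). Malformed rows are reported with
1-based line numbers. Config is INI (`[membrane] [protocol] [analysis]
[simulate] [output]`); unknown keys or sections are rejected, keys are
case-sensitive. JSON reports are sorted-key and therefore byte-identical
for a fixed seed. `pipeline.log` echoes every numeric constant exactly
once as the provenance record. CLI exit codes: 0 success, 2 config/usage
error, 3 data/analysis error.

## Problem sizes used in validation

The validation suite runs at desk scale by design: 100-step ramps (the
instrument's native resolution), 12–17-point temperature sweeps (one point
per °C over the 10–26 °C window), 200 seeds for the unbiasedness and
detector-reliability checks, brute-force segmentation oracles up to 101
points, and a 10⁶-point grid oracle for radius inversion. These sizes make
every statistical assertion reproducible in seconds while keeping
Monte-Carlo error small enough (SE ≈ SD/√200) that estimator bias at the
percent level would be detected.

## Known limitations

- The three-region model assumes exactly two breakpoints; membranes with
  richer V–I structure will be force-fitted.
- Segmentation assumes strictly increasing voltages on the rising limb
  (the generator's grid); duplicated voltage samples must be pre-averaged.
- The activation energy in the high-voltage region is deliberately not
  extracted: high-voltage V–I segments at different temperatures are
  parallel (temperature-independent slope), so there is no slope gradient
  to fit — the package only verifies the parallelism.
- The default barrier model is a stand-in (above); inverted radii are
  model-dependent and should be read comparatively, not absolutely.
- Xenon content varies with temperature even below the desorption point,
  so fitted activation energies for xenon-loaded membranes are effective
  values for a slowly changing system.
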