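# Methods

This note records the models implemented in `starburst`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Bipolar receptive-field model

Each bipolar cell (BC) is a point neuron at arena position `x` with two
Gaussian spatial components, center and surround, described by their full
widths at half maximum.  Stimuli are one-dimensional space–time indicator
functions on a 1-mm arena sampled at Δt = 1 ms: moving bright bars
(leading edge enters at t = 0; bar length = speed × dwell, dwell 2 s, so
every point is lit for exactly 2 s) and full-field flashes.  At every
step, `area_t` is the fraction of a component's unit-normalized Gaussian
mass covered by the *instantaneous* stimulus footprint, evaluated in
closed form with the error function.  This term is the model's key
spatial ingredient: for an approaching bar, a wide center accumulates
mass long before the bar reaches the cell, which is what produces
negative motion-onset lags.

The temporal recursion, per 1-ms step:

    RF_center[t]  = ((area_c[t] − RF_center[t−1]) / rise_c
                     + RF_center[t−1]) · adaptation[t−1]
    adaptation[t] = max(0, adaptation[t−1] − RF_center[t] / decay_c)
    RF_surround[t]= RF_surround[t−1]
                     + (area_s[t] · strength_s − RF_surround[t−1]) / rise_s
    RF_full[t]    = A · (RF_center[t] + RF_surround[t] · reversal_s)
                     / (RF_center[t] + RF_surround[t] + R_in)

with `R_in = 0.1 ×` the center's total mass inside the arena, adaptation
initialized to 1 (no within-trial recovery; state reset between trials),
and `RF_full ∈ [0, 1]`.  Rise/decay constants are dimensionless per-step
divisors (values below 1 are clipped to 1 to keep the update a stable
low-pass).  The surround recursion is a plain low-pass toward the
strength-scaled surround drive, paralleling the center; the surround
enters the denominator fully but the numerator only via
`reversal_s ∈ [0, 1]`, so `reversal_s = 0` is pure shunting.  A ninth
parameter, `delay`, shifts the response in time (linear-interpolated
fractional shift) after the geometry-driven timing.

Fluorescence reported by the glutamate sensor is the release waveform
convolved with `k(τ) = exp(−τ/50 ms) − exp(−τ/10 ms)`, peak-normalized
(analytic peak at ≈20.1 ms).  Peak normalization means filtered and raw
traces share peak scale for impulses; all downstream fitting compares
peak-normalized waveforms, so the kernel's overall gain is irrelevant.

Degenerate inputs: a zero-contrast stimulus yields identically zero
output; all-zero fit targets are answered by a zero-amplitude RF rather
than a spurious optimization.

## Compartmental SAC model

Morphologies are SWC point trees; reconstructions get the standard SAC
correction (dendrites beyond 30 µm from the soma set to 0.2 µm
diameter).  The bundled synthetic SAC is a radially symmetric tree —
8 primary dendrites, 4 branch orders, 64 terminal tips near a 120 µm
radius, ≈4.3 mm total dendritic length — sized to match real mouse SAC
reconstructions in tip count, radius and total length.  It is
deterministic per seed.

Compartments are cylinders (one per SWC edge, subdivided by the d-lambda
rule at 100 Hz; the soma is an equivalent sphere), coupled by series
half-axial resistances; compartment voltages live at segment electrical
centers.  Membrane: g_pas = 4e-4 S/cm², Cm = 1 µF/cm², leak reversal
−60 mV, Ra = 150 Ω·cm (all tunable).  Integration is backward Euler
(default dt = 0.1 ms; drive waveforms on the 1-ms grid are linearly
interpolated onto solver steps), solving the tree-structured linear
system exactly each step by Hines elimination — O(n) per step and
unconditionally stable.  Training runs use dt = 0.25 ms; the refinement
test shows halving dt and the spatial step changes peak voltage by <1%.

Synaptic drive is conductance-based, `g(t) = g_max · RF_full(t)` toward
0 mV.  200 synapses are placed uniformly over dendritic *length* within
110 µm path distance of the soma, each presynaptic RF centered at its
synapse's position.  Calcium is recorded at terminal dendrites within
30 µm of the horizontal axis; a site's outward direction is the sign of
its x position relative to the soma.

### Calcium channel and pool

The paper-cited N-type model is not restated in our sources, so the
channel here is an explicit stand-in: m² kinetics with sigmoidal steady
state (base half-activation −25 mV plus a tunable offset of ±30 mV,
slope 6 mV, τ_m = 1 ms) and an ohmic driving force toward +60 mV.  Two
calibration choices matter and were made once, on first principles:

* **Density bound 3e-5 S/cm².**  The channel must read out voltage, not
  rewrite it: with densities approaching the leak density the m²
  nonlinearity becomes regenerative and fires all-or-none calcium spikes
  whose recruitment asymmetry produces ~20% DSI *independently of
  presynaptic kinetics* — the unstable threshold strategy that the
  directional metric is supposed to discourage.  Keeping the maximal
  conductance far below leak makes calcium a steep graded function of
  local voltage instead.
* **Influx scale 25000 nM/(mA/cm²·ms).**  With the small conductance,
  the pool amplitude is set by this scale; it was chosen so that evolved
  models produce outward calcium peaks near the 500 nM optimum of the
  training metric.  The pool obeys
  `dCa/dt = −(Ca − 100 nM)/50 ms + k·J` and has the closed-form steady
  state `Ca_rest + k·J·τ` used in the tests.

Perisomatic manipulations scale Ra and/or membrane resistance only within
a 15-µm annulus around the soma, to decouple ("high-Ra") or
hyperconnect ("low-Ra") the dendritic tree without touching distal
membrane.

## Evolutionary optimization

Genome = presynaptic RF parameters (9 per population; one shared set in
the identical scenario; a per-annulus cluster id in the annulus scenario)
plus five postsynaptic parameters: g_pas ∈ [1e-5, 1e-3] S/cm²,
Ra ∈ [50, 300] Ω·cm, channel voltage offset ±30 mV, channel density
∈ [1e-6, 3e-5] S/cm² (package bound, see above), synaptic conductance
∈ [0.01, 1] nS.  Selection keeps the two best verbatim; every other slot
copies one of them (fair coin) and mutates every parameter by a Gaussian
factor (mean 1, SD 5%) plus a uniform ±1.5% of the bound range, clipped.
The additive term acts on the normalized range — in raw units it would be
invisible for large-scale parameters like Ra.  In the annulus scenario
each 10-µm input annulus additionally swaps its assigned waveform cluster
with probability 5% per generation.

Initialization is random within bounds, log-uniform for positive
parameters whose bounds span a decade or more (conductances other than
g_pas, widths, rise/decay constants) and raw-uniform otherwise.  Raw
uniform draws across two decades start essentially every circuit
saturated or silent; g_pas stays raw-uniform because its raw median
(5e-4 S/cm²) matches the default leak and keeps typical random drive
below saturation.  Fitness is deterministic per genome, evaluated once
and cached for elites, so the best-fitness history is exactly
non-decreasing.

Reduced-scale runs (smaller population, fewer generations, a velocity
subset, dt = 0.25 ms) use the same code path as full runs; the test and
acceptance experiments use population 8, 10 generations and
{0.5, 1} mm/s, which completes in minutes on one CPU.

### What the reduced-scale comparison shows

At these sizes the full scenario reliably *can* find space-time solutions
(hand-constructed sustained/delayed-proximal + transient-distal circuits
score DSI ≈ 10–15% at 0.5 mm/s vs ≈ 6% for the best identical-RF
circuits), and evolved full runs reach up to ~15% within 10 generations.
But ten generations of 5% mutations refine kinetics only partially, while
the identical scenario's morphology-intrinsic DS (centrifugal summation
amplified by the calcium readout) is found almost immediately — so the
full/identical gap at generation 10 (factor ≈1.3 over 3 seeds) is smaller
than at convergence.  The ordering invariant (identical ≤ full) holds;
the factor grows with training budget.

## RF estimation from motion waveforms

`fit_rf_to_motion` runs the same EA over the nine RF parameters with the
total MSE between peak-normalized, sensor-filtered model waveforms and
the targets across five velocities.  Targets and model outputs are
peak-normalized, so absolute amplitude is structurally unidentifiable and
the fit reports it as such; a post-fit sensitivity screen (±25%
perturbation of each fitted parameter) flags any parameter whose value
does not constrain the targets (e.g. surround kinetics when the fitted
surround strength is ≈0).  Flash responses are never fit; they validate
the fitted model on a held-out stimulus class.  On noiseless synthetic
targets, ten independent fits recover the center FWHM well within 15%
and the center rise time within 20%.

## Imaging pipeline

Pixels with peak dF/F > 20% are segmented into ROIs by Ward-linkage
agglomerative clustering of pixel waveforms constrained to the pixel
adjacency graph, increasing the cluster count until no ROI spans more
than 10 µm; ROIs whose pixel peak amplitudes vary with CV > 1 are
discarded.  Traces are low-passed (first-order Butterworth, normalized
critical frequency 0.1, zero-phase), smoothed with a 5-sample rolling
average (window length is not dictated by anything physical; it is
configurable), baseline-subtracted and peak-normalized.  The two motion
directions at the 0.5 mm/s reference speed are aligned by shifting each
trace so its half-maximum rise lands on the mean of the two rise times,
then averaged; this removes the RF-position dependence exactly (the
aligned waveform of one RF is position-invariant up to interpolation
error), which is what makes waveforms from different fields of view
comparable.

Functional clustering is hierarchical (Ward linkage on Euclidean
distances for ON data, on maximum/Chebyshev distances for OFF data,
matching the two datasets' conventions), optionally after discarding
time points with across-ROI variance below a floor.  The cluster count
comes from the within-cluster-variance curve (exactly non-increasing in
k for nested partitions): the elbow is the k farthest below the chord
joining the curve's endpoints, computed on the log curve because the
variance typically spans orders of magnitude between k = 1 and the true
count — on a linear scale the first split dominates and the rule
systematically undershoots.  Clusters are renumbered by descending
transiency (TI = 1 − mean/peak within the response window; a plateau
scores ~0, an impulse ~1), C1 most transient.

Spatial RF maps are reconstructed from oriented-bar responses (five
orientations 36° apart × 32 positions over ~300 µm — a 5-angle sinogram)
by filtered back-projection with the Ram–Lak filter.  Five angles are
severely undersampled and leave streak artifacts; the tests quantify that
the dominant peak position is still recovered within 10 µm and a 100-µm
Gaussian's FWHM within 10%.  The 2-D Gaussian fit reports σ along the
motion axis; FWHM = 2√(2 ln 2)·σₓ.

Onset ("initiation") of any response is the first upward crossing of 5%
of peak after baseline subtraction, linearly interpolated; the threshold
is a package convention (nothing in our sources pins it down) and is
configurable everywhere.

## Synthetic data

The cluster libraries emulate the qualitative structure of recorded
bipolar release around SAC dendrites: a transient→sustained kinetic
gradient (center decay constants ~100 → ~5000 steps, with a rising
surround-reversal ladder adding sustained plateaus), mostly narrow
centers (45–100 µm) plus wide-center entries (≈200 and 380 µm for the ON
library) that produce negative motion lags.  Center widths are pairwise
distinct so that the lag-vs-half-width relation is strictly monotone, and
the templates were spaced until every pair of aligned reference-speed
waveforms differs by ≥0.1 normalized RMS — below that, clustering
recovery becomes ill-posed rather than merely noisy.  ROI datasets sample
clusters by prevalence, place RFs uniformly in the central arena,
downsample to the 50 Hz imaging frame rate, jitter per-ROI gain (SD 10%)
and add white noise (default SD 0.1 of unit peak, i.e. SNR 10).  Movies
paint ROI discs into a 164-µm field of view with a Gaussian PSF and
pixel noise; oriented-bar tables are exact Radon projections of the
center Gaussian plus optional noise.  All generators are deterministic
per seed (PCG64) and record their settings in emitted metadata.

What passing tests show — and do not.  Recovery results (ARI ≥ 0.9 at
SNR 10, elbow at 7 ± 1, FWHM/rise recovery) demonstrate that the
pipeline is correct and well-conditioned on data matching its
assumptions: linear release generation, additive white noise, no motion
artifacts, no overlapping sources, cluster-pure ROIs.  Real recordings
violate several of these (scan noise is not white, adaptation drifts,
gap-junction coupling blurs cluster boundaries), so performance there is
expected to be lower; the synthetic results bound what the *method* can
do, not what any particular dataset will yield.

## Known limitations

* The calcium channel is a stand-in; absolute DSI levels depend on its
  calibration (the voltage-offset search absorbs moderate differences,
  but steeper channels shift the balance between graded and
  threshold-like directional strategies).
* The stimulus model is one-dimensional; bar height and any
  vertical RF structure are ignored.
* SAC–SAC inhibition, cholinergic feedback, potassium channels and
  mGluR effects are out of scope, as are scanner artifacts in the
  synthetic movies.
* Reduced-scale evolution runs under-converge by design; quantitative
  DSI levels from such runs are lower bounds on what longer training
  reaches.
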