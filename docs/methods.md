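# Methods

This note documents the models, algorithms and design choices behind
`fretflux`: what is simulated, how movies become flux readouts, which
parameters matter, and what the synthetic-data tests do and do not show
about real recordings.

## The measurement principle

Genetically encoded FRET biosensors report an intracellular analyte
concentration as a fluorescence ratio. Two sensor families are
modelled: a lactate sensor (mTFP/Venus pair whose FRET efficiency falls
as lactate binds) and a glucose sensor (eCFP/Citrine, FRET rises with
glucose). Both are represented by a one-site Hill curve

    R(c) = r_min + (r_max − r_min) · c^h / (Kd^h + c^h)

oriented so the reported ratio *increases* with analyte for both
sensors (donor/acceptor for the lactate sensor, acceptor/donor for the
glucose sensor). One orientation means one sign convention everywhere
downstream. Defaults: lactate Kd = 1.0 mM, r_min = 1.0, r_max = 1.3;
glucose Kd = 0.6 mM, r_min = 1.0, r_max = 1.8; h = 1. These are
working defaults for the simulator, not calibrated constants; all are
configurable.

Flux readouts come from transport-stop and trans-acceleration logic:

* **Trans-acceleration (20 mM oxamate).** Oxamate in the bath occupies
  the monocarboxylate carrier in trans and accelerates lactate export,
  emptying the intracellular pool. The depleted tail defines a
  nominal-zero anchor; the pre-drug level above that anchor is the
  *basal lactate* readout.
* **Transport block (5 µM AR-C155858).** With MCT1/2 export blocked the
  lactate pool integrates net production: the initial post-block slope
  is the *production rate* and the late plateau the *accumulation
  amplitude*. MCT4 is insensitive to this blocker, so any MCT4-like
  transport fraction lets lactate escape and biases the slope downward
  (modelled explicitly, see below).
* **Glucose-transport block (20 µM cytochalasin B).** With import
  blocked, intracellular glucose decays at the hexokinase rate: the
  initial downward slope is the *consumption rate*. A terminal
  zero-glucose (aglycemia) segment anchors the trace so the pre-drug
  level is the *basal glucose* readout.

## Kinetic forward model

The simulator integrates two pools per cell, glucose G and lactate L
(mM):

    dG/dt = V_glut·[S/(K_glut+S) − G/(K_glut+G)]·(1 − cytB) − J_hk
    J_hk  = V_hk·G/(K_hk+G)
    dL/dt = f_lac·J_hk − J_mct
    J_mct = V_mct_eff·[L/(K_mct+L) − L_out/(K_mct·(1+ox/K_ox)+L_out)]
    V_mct_eff = V_mct·(1 + g_ta·ox/(K_ox+ox)),  ×mct4_frac under AR-C155858

This is the minimal facilitative-carrier scheme that reproduces all
four protocol behaviours. It deliberately omits phototransduction,
Ca²⁺, pH effects on transport, and the pentose-phosphate branch.
Assumptions worth stating:

* **Bath switches are instantaneous** step functions at the event
  onsets (the perfusion exchange time is not modelled; a dead time
  before the slope fit absorbs it on the analysis side).
* **Saturating inhibitors are complete blocks**: AR-C155858 at 5 µM
  suppresses the blocker-sensitive transport fraction entirely, and
  cytochalasin B at 20 µM zeroes carrier-mediated glucose flux.
* **Initial conditions are the baseline steady state**, found by
  bracketed root finding; a parameter set whose lactate production
  exceeds its export capacity has no steady state and is rejected.

Default parameters (all configurable):

| parameter | default | meaning |
|---|---|---|
| `j_hk_vmax` | 0.01 mM/s | maximal hexokinase flux |
| `k_hk_km` | 0.1 mM | hexokinase Km |
| `glut_vmax` | 0.03 mM/s | glucose carrier capacity |
| `glut_km` | 5 mM | glucose carrier Km |
| `lac_prod_frac` | 1.0 | lactate produced per glucose consumed (0–2) |
| `mct_vmax` | 0.05 mM/s | lactate carrier capacity |
| `mct_km` | 1.5 mM | lactate carrier Km |
| `trans_accel_gain` | 40 | trans-substrate efflux amplification |
| `oxamate_k` | 5 mM | half-saturation of oxamate effects |
| `mct4_frac` | 0 | transport fraction insensitive to AR-C155858 |
| `glc_out_baseline` | 6 mM | bath glucose |
| `lac_out_baseline` | 0 mM | bath lactate |

With these values the control cell sits at ≈0.35 mM lactate and
≈1.5 mM glucose, produces lactate at ≈0.55 mM/min, and — the property
the trans-acceleration experiment depends on — a long oxamate exposure
depletes lactate to within a few percent of the aglycemia floor. The
large `trans_accel_gain` is phenomenological: it encodes the observed
fact that trans-stimulated export overwhelms ongoing production, which
is exactly what makes oxamate usable as a zero-lactate anchor. The
bath-lactate default of zero matches a lactate-free perfusion medium;
the cell is then a net lactate exporter at baseline.

Numerics: single traces use adaptive RK45 (`scipy.integrate.solve_ivp`,
atol 1e-9 mM, rtol 1e-8) segment by segment so the state carries across
bath switches exactly. Cohorts share one protocol, so the generator
integrates all parameter sets at once with a fixed-step classical RK4
(step ≤ 0.25 s, far inside the stability region of these kinetics —
the fastest relaxation is ≈1 /s); the two integrators agree to ≤2e-5 mM
on the standard protocols and the test suite asserts it. Pools are
clamped at zero stock (an empty pool cannot be drained).

## Synthetic movies and cohorts

A movie is rendered from a concentration series as elliptical cells on
a dark background. The denominator channel carries each cell's
brightness; the numerator is ratio × denominator pixelwise inside each
cell, so a masked ratio-of-means reproduces the sensor curve exactly in
the noise-free limit (asserted to 1e-6 in the tests). Artifacts are
applied after signal synthesis, in this order: per-channel exponential
bleaching, integer-pixel random-walk drift (whole-frame circular
shift, truth offsets recorded in the metadata), Poisson shot noise on
scaled expected counts, additive Gaussian read noise. Every stochastic
step is driven by one seed; identical seeds give bit-identical stacks.

Cohorts reproduce the groups → mice → slices → cells hierarchy. A
lognormal "metabolic capacity" effect at the mouse and at the slice
level (CVs 0.15 and 0.10 by default, truncated at ±2.5 σ to exclude
non-physiological tail phenotypes) scales the three flux capacities
*jointly*: slice-to-slice differences in expression, tissue health and
imaging depth affect all fluxes together, which keeps flux ratios — and
with them the baseline steady state and the sensor operating point —
stable while rates vary. Mosaicism is Bernoulli per cell: each cell in
a knockout-group slice carries the knockout parameters with probability
`mosaic_fraction`, and wild-type cells follow the control kinetics, so
the whole-frame trace is a brightness-weighted mixture — the dilution
that incomplete Cre recombination causes in tissue.

For cohort-scale Monte-Carlo work the generator can skip image
rendering (`render=False`, the default) and synthesise the whole-frame
ratio trace directly: the knockout-weighted mixture of the two genotype
sensor curves plus Gaussian trace noise (sd 0.003 ratio units) and the
standard smoothing. The render-and-extract route and the direct route
target the same quantity; the image pipeline is exercised separately at
full fidelity, and the equivalence in the noise-free limit is tested.

The canned study designs (in `fretflux.experiments`) fix the simulated
counterparts of the imaging experiments: a knockout genotype with 1.5×
lactate yield *and* 1.5× lactate export capacity (the latter reflects
upregulated MCT4-class transport in this genotype and keeps basal
lactate unchanged while production rises — the configuration in which
basal levels do not separate but slopes do); identical-parameter null
cohorts of 8 mice × 1 slice per group (one slice per mouse keeps
observations independent, n = 8 keeps the rank test on its exact path);
and a three-population glucose design where photoreceptor-like cells
have 3× the hexokinase and 3× the glucose-carrier capacity of
inner-retina-like cells.

## Image pipeline

1. **Registration.** Per-frame integer (dy, dx) offsets maximise the
   frequency-domain cross-correlation of the zero-mean channel-sum
   image against a reference frame (first frame by default). The score
   is the normalised peak correlation; ties break toward the smallest
   Euclidean offset, then row-major. Offsets are estimated once on the
   channel sum and applied to both channels, so the ratio is immune to
   the common shift. Vacated pixels are filled with the frame's median
   and flagged invalid, excluding them from all masked statistics.
   Subpixel registration is deliberately not attempted: the whole-frame
   ratio is insensitive to sub-pixel common shifts, and integer
   recovery is exactly testable against the renderer's truth offsets.
2. **Masking.** Li's minimum cross-entropy threshold, computed once on
   the time-averaged channel-sum image, gives a single static tissue
   mask (a per-frame mask would modulate the trace through mask
   composition changes). The implementation iterates the fixed point
   t ← (μ_b − μ_f)/(ln μ_b − ln μ_f) from the image mean, stopping at
   0.5 intensity units; non-positive images are lifted by 1 − min and
   the threshold lowered back, since the update needs positive means.
   Tests verify the iterate against an exhaustive scan of the
   cross-entropy objective and against `skimage.filters.threshold_li`.
3. **Extraction.** Per frame, the trace value is the ratio of masked
   channel means (not the mean of pixel ratios, which amplifies noise
   at dim pixels); zero-denominator and registration-fill pixels are
   excluded from both means.
4. **Smoothing.** A centred moving average — 11 frames for the lactate
   sensor, 5 for the glucose sensor by default — applied to the ratio
   trace (smoothing before or after ratio formation is equivalent for
   the linear operations involved here up to masking effects; this
   implementation smooths the trace). Edge windows shrink
   symmetrically; no padding values are invented.

## Flux readouts

Traces are anchored subtractively: Δratio = R − mean(R over the anchor
window). Subtractive anchoring (rather than ΔR/R₀) preserves the
linear map to concentration in the sensor's quasi-linear range and
matches the nominal-zero logic of the anchoring experiments; a
divisive variant would couple the readout to the anchor level.

Window defaults (all in `AnalysisConfig`, none dictated by the assay):
baseline window 60 s ending at the first onset; anchor window 30 s at
the trace end; slope fit from 10 s after onset (perfusion dead time)
for 60 s; plateau window 60 s at the trace end. Readouts:

* **basal** — mean Δratio over the baseline window of an end-anchored
  trace; flagged `unstable_baseline` when the baseline drifts faster
  than 0.01 ratio/min.
* **amplitude** — mean Δratio over the terminal plateau of a
  baseline-anchored trace; flagged `saturation` when the raw plateau
  ratio exceeds 95% of the sensor range.
* **slope** — ordinary least-squares line over the fit window, reported
  in Δratio/min, positive = accumulation; consumption protocols give a
  negative slope whose magnitude is the consumption rate. r² below 0.5
  flags `low_r2`.

The terminal anchor and plateau use window means rather than pointwise
extrema; a pointwise minimum is noise-biased. Ratio units are the
primary output; conversion to mM (levels through the exact sensor
inverse, slopes through the local sensor gain at the fit-window
midpoint) is available when a sensor model is supplied, and inherits
that model's calibration uncertainty.

QC-flagged traces are excluded from group statistics by default but
always written to the per-trace table with flags visible.

## Group statistics

Slice-level values are the observational unit, matching how such
cohorts are reported; because slices within a mouse are not
independent, a mouse-aggregated mode (median per mouse) is provided.
Two groups: Mann-Whitney U (exact enumeration when both n ≤ 8 without
ties, else normal approximation with tie and continuity corrections;
U = min(U_a, U_b) is reported). Three or more: Kruskal-Wallis with tie
correction, then many-to-one post hoc comparisons against a reference
group. The default post hoc is Dunn-style pooled-rank z tests with
Bonferroni adjustment over the k−1 comparisons — the internally
consistent nonparametric companion to Kruskal-Wallis. The parametric
Dunnett procedure is available behind `--posthoc dunnett` for users who
want the classical many-to-one test; the two answer slightly different
questions and neither is asserted as canonical. All tests are
two-sided at α = 0.05; stars follow the 0.05/0.01/0.001/0.0001
convention.

## What the synthetic tests show — and what they don't

The generator emulates: saturating sensor response, the four
pharmacological protocols, multi-level biological variability, cell
mosaicism, shot/read noise, bleaching, and xy drift. Passing tests
therefore demonstrate that the pipeline recovers known inputs under
those artifact models, that the statistics are calibrated under the
generator's null, and that the documented bias mechanisms
(blocker-insensitive transport, mosaic dilution) behave monotonically.

They do not demonstrate performance against: z-drift and focal plane
loss, perfusion transients, sensor expression gradients, pH- or
crowding-dependent sensor behaviour, autofluorescence, or real optics
(no PSF is modelled). Slope and amplitude readouts in ratio units are
also only proportional to fluxes within the sensor's quasi-linear
range; the saturation guard flags, but cannot correct, operation
outside it.

## Problem sizes

Unit tests run on small scenes (64×64, 1–2 cells, tens of frames).
The cohort-level checks use 100 replicates of 2 × 20-slice cohorts for
directional effects, 200 null replicates of 2 × 8 slices for type-I
calibration, 100 replicates of 3 × 15 slices for the many-to-one
detection check, and paired 15-replicate curves for the mosaic-dilution
grid; trace-level generation at 5.94 Hz makes each replicate a
fraction of a second, and the full suite completes in a few minutes on
one CPU. The reproduction script (`scripts/acceptance.py`) re-runs the
same designs from scratch at the same sizes.
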