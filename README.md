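# fretflux

Analysis of two-photon FRET-biosensor time-lapse recordings of cellular
energy metabolism — and a kinetic forward simulator that makes every
stage of that analysis testable without access to raw microscope data.

## The problem

Genetically encoded FRET sensors report intracellular lactate or
glucose as a fluorescence ratio. Combined with transporter
pharmacology in perfused tissue (retinal slices and flatmounts are the
motivating preparation), they turn a ratio movie into metabolic fluxes:

* bath **oxamate** trans-accelerates the monocarboxylate carrier and
  empties the lactate pool, so the depleted tail is a nominal-zero
  anchor and the pre-drug level above it is **basal lactate**;
* **AR-C155858** blocks MCT1/2 lactate export, so the pool integrates
  net production — the post-block slope is the **lactate production
  rate** and the late plateau the **accumulation amplitude**;
* **cytochalasin B** blocks glucose import, so intracellular glucose
  decays at the hexokinase rate — the **glucose consumption rate** —
  and a terminal **aglycemia** (zero-glucose) segment anchors basal
  glucose.

`fretflux` implements the full chain: drift registration by
frequency-domain cross-correlation, automatic tissue masking with Li's
minimum cross-entropy threshold, whole-frame ratio-of-means extraction
with temporal smoothing, window-statistic flux readouts with QC flags,
and nonparametric group comparisons (Mann-Whitney; Kruskal-Wallis with
Dunn or Dunnett many-to-one post hocs). Because studies of this kind
rarely deposit raw stacks, the package ships a carrier-kinetics
simulator (hexokinase-limited glycolysis, facilitative glucose and
lactate carriers with trans-acceleration, an AR-C155858-insensitive
transport fraction) that renders noisy, drifting two-channel movies and
hierarchical cohorts with known ground truth. See `docs/methods.md`
for the model and all defaults.

## Worked example

Simulate a control cell under the lactate-transport-block protocol,
render a noisy drifting movie, and run the pipeline:

```python
import numpy as np
from fretflux import (
    KineticParams, get_protocol, simulate_concentrations,
    ScenePhantom, NoiseModel, render_movie, process_movie,
    FluxModel, LACONIC,
)

params = KineticParams()                      # control photoreceptor kinetics
protocol = get_protocol("mct_block")          # 5 uM AR-C155858 at t = 120 s
series = simulate_concentrations(params, protocol, dt=0.5)

scene = ScenePhantom.random(12, shape=(128, 128), rng=np.random.default_rng(0))
noise = NoiseModel(read_noise_sd=0.5, drift_sd=0.3, photons_per_unit=5.0, seed=0)
movie = render_movie(series, LACONIC, scene, noise, frame_rate=5.94)

trace, drift, mask = process_movie(movie, window=11)   # register, mask, extract
result = FluxModel(trace, protocol, sensor=LACONIC).fit()
print(result.summary())
print(f"max drift: {drift.max_abs_offset} px   mask fraction: {mask.fraction:.3f}")
```

which prints:

```
Flux readout summary
====================
protocol:     mct_block
frames:       2495 @ 5.94 Hz
smoothing:    11 frames
amplitude    0.14540 dratio  (window 360-420 s, n=357)
slope        0.05800 dratio/min  (window 130-190 s, n=356, r2=0.9913)
max drift: 20 px   mask fraction: 0.078
```

The slope, 0.058 Δratio/min fitted over the first minute after the
block (r² = 0.99), is the sensor-space lactate production rate: through
the sensor gain at the fit-window midpoint (`result.in_mM()`) it
converts to 0.563 mM/min, within 0.1% of the generating model's true
net production flux of 0.563 mM/min. The amplitude is the plateau Δratio accumulated by the end of
the recording, and the random-walk drift (up to 20 px here) has been
registered out before masking.

Cohort-level work goes through the drivers or the CLI. A YAML config
describing sensor, protocol, and a group/mouse/slice design runs end to
end:

```bash
fretflux run-all --config run.yaml --seed 7 --outdir out/
```

writing per-slice OME-TIFF stacks (or trace CSVs), a manifest, the
ground-truth parameter table, the per-trace results table, group
summaries, comparison tables with significance stars, and a JSON
report. `fretflux simulate`, `process`, `analyze` and `compare` run
the stages separately; `examples/run.yaml` is a starting point.

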