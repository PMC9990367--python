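# End-to-end run: simulate a two-genotype lactate-accumulation cohort,
# process every slice, and compare the groups.
#
#   fretflux run-all --config examples/run.yaml --seed 7 --outdir out/

sensor: laconic              # smoothing window defaults to 11 frames
protocol: mct_block          # 5 uM AR-C155858 at t = 120 s
frame_rate: 5.94             # Hz
seed: 7

cohort:
  between_mouse_cv: 0.15
  between_slice_cv: 0.10
  groups:
    - name: ctrl
      n_mice: 10
      slices_per_mouse: 2
    - name: knockout
      n_mice: 10
      slices_per_mouse: 2
      mosaic_fraction: 0.8   # incomplete recombination: 80% of cells converted
      param_overrides:
        lac_prod_frac: 1.5   # more pyruvate diverted to lactate
        mct_vmax: 0.075      # matching upregulated export capacity

# analysis windows (seconds); these are the defaults, shown for visibility
analysis:
  baseline_window: 60.0
  anchor_window: 30.0
  slope_delay: 10.0
  slope_duration: 60.0
  plateau_window: 60.0
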