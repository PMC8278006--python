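# Two-condition imaging cohort with a medium-strength treatment effect
# (dendritic intensity x1.3, AIS shortened by 4 um) plus a small
# electrophysiology cohort; 100-repeat 70/30 SVM experiment.
seed: 42
out_dir: runs/demo
cohort:
  n_per_condition: 40
effect:
  length_delta_um: -4.0
  dendrite_scale: 1.3
classify:
  n_repeats: 100
ephys:
  n_cells: 4
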