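#!/bin/sh
# End-to-end pipeline through the command-line interface on a small design.
# Writes datasets, checkpoints, the RMSE report and envelope plots to runs/demo.
set -e

cat > /tmp/naloxsim_demo.yaml <<'YAML'
seed: 0
population:
  size: 20
scenario_grid:
  opioid_doses: [0.013, 0.085, 0.157]
  naloxone_counts: [0, 1]
  thresholds: [0.40, 0.10]
  delays: [3.0]
sim:
  horizon: 3600.0
  output_step: 120.0
  rtol: 1.0e-6
  atol: 1.0e-9
train:
  epochs: 5
  batch_size: 16
  learning_rate: 5.0e-3
emulator:
  recurrent_width: 8
  dense_width: 16
plsr:
  max_components: 6
  folds: 5
YAML

naloxsim simulate --config /tmp/naloxsim_demo.yaml --outdir runs/demo
naloxsim train    --config /tmp/naloxsim_demo.yaml --outdir runs/demo --architecture blackbox
naloxsim train    --config /tmp/naloxsim_demo.yaml --outdir runs/demo --architecture semimechanistic
naloxsim evaluate --config /tmp/naloxsim_demo.yaml --outdir runs/demo
naloxsim report   --outdir runs/demo
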