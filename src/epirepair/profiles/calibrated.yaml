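# Default calibrated parameter profile.
#
# Calibration anchors (see docs/methods.md): the initial edge speed of a
# long-ablation run is ~7.4 µm/h (0.30 µm/step at 0.04 h/step); the
# division threshold and activation depth are set so a ~20 µm ablation
# induces no division while 55-100 µm ablations produce two division
# bands whose median spacing falls in the 230-300 µm stretch-zone range.
name: calibrated
model:
  cell_spacing: 6.7       # µm, initial lattice pitch
  motility_sigma: 0.12    # µm per step, per-axis random-walk scale
  d_rep: 6.03             # µm  (0.90 x spacing), repulsion onset
  d_att: 7.035            # µm  (1.05 x spacing), attraction onset
  d_max: 8.375            # µm  (1.25 x spacing), junctional force cutoff
  d_sense: 11.39          # µm  (1.70 x spacing), stretch/polarity sensing
  k_rep: 0.4              # displacement gain per step
  k_att: 0.4
  d_div: 9.045            # µm  (1.35 x spacing), division threshold
  p_div: 0.3              # division probability per step once competent
  delay_steps: 100        # consecutive over-threshold steps before competence
  step_hours: 0.04        # h of real time per iteration
  n_steps: 1200           # 48 h simulated
  edge_speed: 0.3         # µm per step active crawling
  polarity_threshold: 0.3 # tapered-resultant magnitude: any polarisation
  front_threshold: 0.55   # tapered-resultant magnitude: wound-edge leader
  activation_depth: 120.0 # µm, migratory activation behind the edge
  k_sub: 0.0015           # substrate-adhesion stiffness (per step)
  tau_adh: 400.0          # steps, adhesion remodelling time
  div_margin: 33.5        # µm, no divisions within this of the anchors
  baseline_p_div: 0.0     # stretch-independent division (off)
geometry:
  rows: 10
  cols: 80
  gap_um: 90.0            # default long-segment ablation
  anchor_margin_um: 13.4  # 2 x spacing anchored at each axial end
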