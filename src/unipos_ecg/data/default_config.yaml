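# Default run configuration.  The dynamics blocks spell out every published
# model parameter literally; geometry/calibration values are package defaults.
seed: 1
output_dir: results

phantom:
  grid_shape: [150, 150]
  spacing: 0.75
  include_electrode_layer: true

dynamics:
  alpha: 1.0
  beta: 0.5
  gamma: 1.0
  delta: 0.0
  theta: 0.15
  cubic_gain: 2.1
  epsilon:
    sinoatrial_node: 0.003
    atria: 0.015
    atrioventricular_node: 0.015
    his_bundle: 0.01
    bundle_branches: 0.01
    purkinje_fibers: 0.005
    ventricles: 0.005
  diffusion:
    torso: 0.2
    lung: 0.2
    sinoatrial_node: 0.1
    atria: 0.15
    atrioventricular_node: 0.1
    his_bundle: 0.1
    bundle_branches: 0.1
    purkinje_fibers: 0.3
    ventricles: 0.1
    blood_chamber: 0.7
    electrode_layer: 0.2
    fibrous_barrier: 0.0
  theta_overrides:
    sinoatrial_node: 0.45
    atria: 0.05
    atrioventricular_node: 0.05
    his_bundle: 0.05
    bundle_branches: 0.05
    purkinje_fibers: 0.05
    ventricles: 0.05

protocol:
  period: 1200.0        # simulation time units; maps to one cardiac cycle
  amplitude: 0.5
  pulse_width: 12.0
  start: 20.0
  cycle_seconds: 0.8    # one cycle = 0.8 s  (75 bpm sinus rate)

simulate:
  duration_beats: 8.0

synth:
  mode: static
  fs: 500.0
  mean_bpm: 70.0
  sdnn_s: 0.03
  duration_s: 300.0
  experimental_preset: sitting
  control_preset: sitting
  dynamic_schedule: [sitting, office, turning, stepping]
  segment_s: 120.0

filters:
  static_arm:
    highpass_cutoff_hz: 0.5
    lowpass_cutoff_hz: 100.0
    notch_freqs_hz: [50.0, 100.0]
    highpass_order: 4
    lowpass_order: 4
    notch_q: 30.0
  modified_arm:
    highpass_cutoff_hz: 0.25
    lowpass_cutoff_hz: 100.0
    notch_freqs_hz: [50.0, 100.0]
    highpass_order: 4
    lowpass_order: 4
    notch_q: 30.0
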