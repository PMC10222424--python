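# Methods

This note records the models, the parameter choices and their rationale, the
numerical scheme, and what the synthetic experiments can and cannot show.

## Tissue model

The heart–torso phantom is a 2-D coronal-slice cartoon on a labelled
rectangular grid.  Seven cardiac regions (sinoatrial node, atria, AV node,
His bundle, bundle branches, Purkinje fibers, ventricles) carry
FitzHugh–Nagumo kinetics; the torso, lungs, blood chambers and the optional
electrode layer are passive volume conductor (zero reaction source), and a
fibrous barrier (zero diffusion) separates atria from ventricles except at
the AV node.  All quantities are dimensionless; time is mapped to seconds
only at the recording stage.

Dynamics per active cell:

    du1/dt = div(D grad u1) + g*u1*(u1 - theta)*(alpha - u1) - u2
    du2/dt = eps * (beta*u1 - gamma*u2 - delta)

with alpha = 1, beta = 0.5, gamma = 1, delta = 0 and per-region
excitability eps (SA 0.003; atria, AV 0.015; His, branches 0.01; Purkinje,
ventricles 0.005) and diffusion D (torso/lung 0.2, SA 0.1, atrium 0.15,
AV/His/branches 0.1, Purkinje 0.3, ventricle 0.1, blood 0.7; electrode layer
0.2 by assignment, since it is not tabulated).

### Cubic gain and thresholds

The cubic has roots {0, theta, alpha}; its overall scale g is a free
parameter that the root placement does not fix.  g is bounded above by a
repolarisation condition: the excited branch must not intersect the
u2-nullcline u2 = (beta/gamma) u1 away from the origin, i.e.

    g * ((alpha - theta)/2)^2 < beta/gamma .

Above this bound the tissue latches into a stable depolarised state and
never repolarises.  With beta/gamma = 0.5 and theta = 0.15 the bound is
g < 2.77.  Front speed scales as sqrt(g * D) * (alpha - 2 theta), so the
calibration pushes theta down and g near the bound: the shipped defaults are
g = 2.1 with theta = 0.05 for all active regions except the SA node.

The SA node uses theta = 0.45.  Its tiny excitability (eps = 0.003) would
otherwise give it the longest action-potential plateau of any region, and a
node still depolarised after the surrounding atria have recovered re-excites
them — an artificial flutter.  The higher threshold shortens the SA plateau
below the atrial refractory period.  The node is driven by a periodic
suprathreshold stimulus (amplitude 0.5, pulse width 12 time units, period
1200 units); the tabulated kinetics are not self-oscillatory, so pacing is
imposed rather than emergent.

### Geometry

Geometry is specified in grid-shape fractions so one layout serves any
resolution (builder minimum 100x100; default 150x150, spacing h = 0.75).
Two figures drive the layout:

* the excitation wavelength c * APD / h must span each region so that the
  region-mean of u1 crosses the 0.5 activation level (the activation-time
  definition); this motivated h < 1 and the low theta, and sizes the atria;
* per-beat diffusion length in the passive torso, sqrt(D * T_beat) ~ 15
  length units, must reach the surface probes, which keeps the heart large
  within the torso (margins of roughly 10-15 cells).

The His bundle is painted as a thin serpentine channel inside an insulating
fibrous block, with the AV node box bridging the atria-ventricle barrier
into it.  The serpentine's path length creates the PR-interval analogue:
without it, the atrial and ventricular surface deflections merge and the
conventional lead shows no separate P-like wave.  The insulation mirrors the
real bundle's fibrous sheath and prevents premature lateral breakthrough
into the ventricles.

Default probes: the conventional pair sits at the top-centre and
bottom-centre of the torso boundary, directly above/below the heart, where
the P-, QRS- and T-like deflections are all separable; the corners of the
rectangular slab are disproportionately far from the heart and smear the
atrial deflection below visibility.  The single-position probe sits on the
upper-left part of the electrode/torso contact, where diffusion smoothing
produces the characteristic wave-like trace.

### Discretisation

Explicit Euler with a 5-point flux-form Laplacian; per-face diffusion is the
harmonic mean of the two cell values, so a zero-D face (fibrous tissue,
outer boundary) carries no flux, and the scheme conserves total u1 exactly
when sources are off.  Time step obeys dt <= h^2/(4 Dmax); the driver picks
dt so that an integer number of steps equals 2 ms of mapped time, giving
exactly 500 Hz recordings.  One stimulus period maps to one cardiac cycle
(0.8 s, 75 bpm).  The mapping is a presentation choice: the source model
publishes no time units, and amplitude/time are explicitly only qualitative.

## Synthetic recordings

The generator emulates the paired device experiment: one RR-interval
sequence drives both channels.

* RR model: i.i.d. truncated normal (bounds 0.2-3 s), mean 60/bpm, SD =
  SDNN.  Defaults: 70 bpm, SDNN 0.03 s, 5 min at 500 Hz.  No HRV
  autocorrelation, respiratory sinus arrhythmia, or ectopy is modelled.
* Morphology: sums of Gaussian bumps — five components (P, Q, R, S, T) for
  the control channel, two broad lobes of smaller amplitude for the
  experimental channel, with the dominant lobe centred on the beat time so
  both channels mark the same instants.
* Noise: baseline drift (four random-phase sinusoids; band 0.05-0.20 Hz for
  seated presets, 0.05-0.45 Hz for motion presets — seated wander is slow
  electrode/skin drift, motion pushes drift energy toward the band edge),
  a 50 Hz powerline sinusoid, and white noise rescaled so the realised
  clean-signal-to-white-noise ratio equals the preset target exactly.
  "SNR" of a preset always means this white-noise ratio; drift and
  powerline are structured interference accounted separately, which makes
  the ground truth exact by construction.
* Presets: sitting 20 dB; office/turning/stepping 12 dB with increasing
  drift; `modified_sitting` (the two-contact modified electrode) 24 dB with
  minimal drift, reflecting that its local reference contact cancels most
  common-mode interference before amplification.

Because beats are template-identical up to placement, a passing pipeline
demonstrates rhythm recovery under the stated noise — not robustness to real
morphology variability, electrode motion transients, or arrhythmia.

## Signal processing

Butterworth high-pass (order 4; 0.5 Hz plain arm, 0.25 Hz modified arm) →
50 Hz and 100 Hz second-order notches (Q = 30) → Butterworth low-pass
(order 4, 100 Hz), applied forward-backward (zero phase) so peak timing is
unbiased.  Filter family, order and zero-phase application are conventional
ECG choices and are config-overridable.  Band energies use a Welch
periodogram (nperseg 4096), half-open bands, DC excluded, Nyquist bin kept
by the top band so a partition sums to one.

## Heart-rate analysis

* Detector: 18 Hz zero-phase low-pass (so broadband noise does not swamp
  the differentiator and broad wave-like beats are handled by the same
  code path) → derivative → square → 150 ms moving integration → adaptive
  threshold (running 5 s median + 5 MAD; the multiplier balances missing
  no beats at 12 dB against triggering on noise extremes) → 200 ms
  refractory → refinement to the local maximum of the band-limited trace.
  Scale- and offset-invariant by construction.
* Heart-rate graph: FHR = 60/(n*T) bpm per adjacent-peak interval,
  timestamped at the closing peak; values outside (20, 300) bpm are
  discarded as detection artifacts.
* Comparison: both curves linearly interpolated onto a shared uniform 1 s
  grid over their overlap; Pearson correlation and absolute differences of
  the curve maxima/minima.  Overlaps under 60 s warn; zero-variance curves
  raise.
* SNR estimator: beats windowed [-0.35, +0.55] of the median interval
  around each peak (capped at [-0.3, +0.5] s), aligned to the ensemble
  template by +/-6-sample cross-correlation (detector jitter is not noise),
  template = aligned mean; residuals get a per-window linear baseline
  removal (high-pass filtering leaves each beat on a slightly different
  local baseline, which is alignment error, not noise).  Signal power =
  template energy spread over one median interval; noise power = mean
  residual power.  On white-noise-only corruption at 20 dB truth the
  estimator is biased about -0.4 dB.
* Recognizability: 10 s windows fail on any of — implied rate outside
  (20, 300) bpm; interval coefficient of variation >= 0.5; RMS above 10x
  the median window RMS; median beat-to-template correlation < 0.6.  The
  fourth rule exists because a handful of noise extremes can be spaced
  deceptively regularly (the refractory period quantises them) yet never
  share a waveform.

## Problem sizes

Desk-scale defaults throughout: the phantom is 150x150 (about 480k explicit
steps for the 60 s sinus-rate run, a few minutes on one core; property tests
use 100x100 and two beats), synthetic recordings are 5 min at 500 Hz, and
estimator-bias sweeps use 50 seeds of 60 s records.

## Limitations

2-D slab, not a torso mesh; monodomain u1 diffusion stands in for the
electrostatic forward problem, so surface amplitudes are qualitative only;
no arrhythmias, no amplitude calibration in millivolts, no real-device data
ingestion; sinus rhythm only, paced SA node; i.i.d. RR intervals; noise
model limited to drift + powerline + white noise.
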