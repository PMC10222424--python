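"""Forward-model tests: reaction kinetics, the explicit diffusion step,
phantom validation, and whole-simulation conduction properties."""

import dataclasses

import numpy as np
import pytest

from unipos_ecg.cardiac_model import (ACTIVE_REGIONS, CONDUCTION_ORDER,
                                      DynamicParams, FieldState,
                                      PhantomConfig, PhantomValidationError,
                                      ProbeSpec, RegionLabel, StimulusProtocol,
                                      TissuePhantom, build_phantom,
                                      default_probes,
                                      extract_conventional_lead,
                                      extract_single_position, reaction_term,
                                      run_simulation, stability_limit,
                                      step_field)
from unipos_ecg.cardiac_model import _CODE


# ----------------------------------------------------------------- kinetics

def test_reaction_term_resting_equilibrium():
    params = DynamicParams()
    for region in ACTIVE_REGIONS:
        assert reaction_term(0.0, 0.0, region, params) == (0.0, 0.0)


def test_reaction_term_at_upper_root():
    # u1 = 1 is a root of the cubic; gate source is eps*beta*u1 = 0.0075
    params = DynamicParams()
    du1, du2 = reaction_term(1.0, 0.0, RegionLabel.ATRIA, params)
    assert du1 == pytest.approx(0.0, abs=1e-15)
    assert du2 == pytest.approx(0.015 * 0.5, rel=1e-12)


def test_reaction_term_passive_regions_source_free():
    params = DynamicParams()
    for region in (RegionLabel.TORSO, RegionLabel.LUNG,
                   RegionLabel.BLOOD_CHAMBER, RegionLabel.ELECTRODE_LAYER,
                   RegionLabel.FIBROUS_BARRIER):
        assert reaction_term(0.5, 0.1, region, params) == (0.0, 0.0)


def test_reaction_term_regenerative_between_roots():
    params = DynamicParams()
    theta = params.theta_of(RegionLabel.VENTRICLES)
    u_mid = 0.5 * (theta + 1.0)
    du1, _ = reaction_term(u_mid, 0.0, RegionLabel.VENTRICLES, params)
    assert du1 > 0.0


# ---------------------------------------------------------------- phantom

def test_default_phantom_has_all_regions(small_phantom):
    assert small_phantom.regions_present() == set(RegionLabel)


def test_atria_only_contact_ventricles_through_av_node(small_phantom):
    labels = small_phantom.labels
    a = labels == _CODE[RegionLabel.ATRIA]
    v = labels == _CODE[RegionLabel.VENTRICLES]
    for da, dv in (((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                   ((slice(1, None), slice(None)), (slice(None, -1), slice(None))),
                   ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                   ((slice(None), slice(1, None)), (slice(None), slice(None, -1)))):
        assert not (a[da] & v[dv]).any()


def test_phantom_without_electrode_layer():
    phantom = build_phantom(PhantomConfig(grid_shape=(100, 100),
                                          include_electrode_layer=False))
    assert RegionLabel.ELECTRODE_LAYER not in phantom.regions_present()
    assert phantom.region_at((0, 0)) is RegionLabel.TORSO


def test_degenerate_geometry_rejected():
    with pytest.raises(PhantomValidationError, match="missing or empty"):
        # zero-size ventricles: barrier band below the whole heart
        build_phantom(PhantomConfig(grid_shape=(100, 100), barrier_row=0.95))


def test_too_small_grid_rejected():
    with pytest.raises(PhantomValidationError, match="100x100"):
        build_phantom(PhantomConfig(grid_shape=(80, 80)))


def test_negative_diffusion_rejected():
    with pytest.raises(ValueError, match=">= 0"):
        diff = dict(DynamicParams().diffusion_by_region)
        diff[RegionLabel.TORSO] = -0.1
        DynamicParams(diffusion_by_region=diff)


# ------------------------------------------------------------- field step

def test_resting_state_is_fixed_point(small_phantom):
    state = FieldState.resting(small_phantom)
    dt = 0.9 * stability_limit(small_phantom)
    out = step_field(state, small_phantom, dt)
    assert np.all(out.u1 == 0.0)
    assert np.all(out.u2 == 0.0)


def test_step_rejects_unstable_dt(small_phantom):
    bound = stability_limit(small_phantom)
    state = FieldState.resting(small_phantom)
    with pytest.raises(ValueError, match="stability bound"):
        step_field(state, small_phantom, 10.0 * bound)


def _scalar_oracle(u1, u2, params, region, dt, n_steps):
    """Independent explicit-Euler integration of the space-clamped kinetics."""
    g, th = params.cubic_gain, params.theta_of(region)
    eps = params.epsilon(region)
    for _ in range(n_steps):
        du1 = g * u1 * (u1 - th) * (params.alpha - u1) - u2
        du2 = eps * (params.beta * u1 - params.gamma * u2 - params.delta)
        u1, u2 = u1 + dt * du1, u2 + dt * du2
    return u1, u2


def test_isolated_cell_matches_scalar_ode_oracle():
    """With D = 0 everywhere, the grid step must reproduce the scalar
    two-variable kinetics integrated by the same scheme."""
    params = DynamicParams(diffusion_by_region={r: 0.0 for r in RegionLabel})
    labels = np.full((3, 3), _CODE[RegionLabel.VENTRICLES], dtype=np.int8)
    phantom = TissuePhantom(labels=labels, spacing=1.0, params=params)
    state = FieldState(u1=np.full((3, 3), 0.6), u2=np.zeros((3, 3)))
    dt, n_steps = 0.05, 400
    for _ in range(n_steps):
        state = step_field(state, phantom, dt)
    u1_ref, u2_ref = _scalar_oracle(0.6, 0.0, params, RegionLabel.VENTRICLES,
                                    dt, n_steps)
    assert np.allclose(state.u1, u1_ref, rtol=1e-12)
    assert np.allclose(state.u2, u2_ref, rtol=1e-12)


def test_diffusion_only_conserves_total_and_relaxes_to_mean():
    """Zero-flux Laplacian: the grid total is conserved and the field
    relaxes toward its spatial mean when all sources are off."""
    labels = np.full((20, 20), _CODE[RegionLabel.TORSO], dtype=np.int8)
    phantom = TissuePhantom(labels=labels, spacing=1.0,
                            params=DynamicParams())
    rng = np.random.default_rng(7)
    u1 = rng.uniform(0, 1, size=(20, 20))
    state = FieldState(u1=u1.copy(), u2=np.zeros((20, 20)))
    total0 = state.u1.sum()
    spread0 = np.ptp(state.u1)
    dt = 0.9 * stability_limit(phantom)
    for _ in range(2000):
        state = step_field(state, phantom, dt)
    assert state.u1.sum() == pytest.approx(total0, rel=1e-9)
    assert np.ptp(state.u1) < 0.01 * spread0
    assert np.allclose(state.u1, u1.mean(), atol=0.01)


# --------------------------------------------------------------- simulation

def test_activation_strictly_ordered_along_conduction_path(short_recording):
    acts = [short_recording.activation_times[r] for r in CONDUCTION_ORDER]
    assert all(b > a for a, b in zip(acts, acts[1:]))
    assert not short_recording.warnings


def test_ventricular_activations_match_stimulus_count(short_recording):
    vent = short_recording.region_mean_u1[RegionLabel.VENTRICLES]
    assert short_recording.threshold_crossings(vent).size == 2


def test_zero_amplitude_stimulus_leaves_traces_flat(small_phantom):
    protocol = StimulusProtocol(amplitude=0.0)
    with pytest.warns(RuntimeWarning, match="propagation failure"):
        rec = run_simulation(small_phantom, protocol,
                             default_probes(small_phantom),
                             duration=2 * protocol.period, record_every=40)
    for trace in rec.probe_traces.values():
        assert np.all(trace == 0.0)
    assert "propagation_failure" in rec.warnings


def test_passive_regions_never_exceed_cardiac_amplitude(small_phantom,
                                                        default_protocol):
    """Passive tissue has no source, so over a run its |u1| can never exceed
    the largest |u1| the cardiac tissue produced (maximum principle for the
    source-free diffusion that feeds it)."""
    cardiac = np.zeros(small_phantom.grid_shape, dtype=bool)
    for r in ACTIVE_REGIONS:
        cardiac |= small_phantom.mask(r)
    passive = ~cardiac & ~small_phantom.mask(RegionLabel.FIBROUS_BARRIER)
    stim = np.where(small_phantom.mask(RegionLabel.SINOATRIAL_NODE),
                    default_protocol.amplitude, 0.0)
    state = FieldState.resting(small_phantom)
    dt = 0.9 * stability_limit(small_phantom)
    n_steps = int(default_protocol.period / dt)
    max_passive = max_cardiac = 0.0
    for k in range(n_steps):
        s = stim if default_protocol.active_at(state.t) else None
        state = step_field(state, small_phantom, dt, stimulus=s)
        if k % 25 == 0:
            max_passive = max(max_passive, float(np.max(np.abs(state.u1[passive]))))
            max_cardiac = max(max_cardiac, float(np.max(np.abs(state.u1[cardiac]))))
            assert max_passive <= max_cardiac + 1e-12
    assert max_cardiac > 0.5  # the run actually produced a beat


def test_av_block_stops_ventricular_activation(default_protocol):
    """Relabelling the AV node as fibrous tissue leaves an atria-only rhythm:
    the barrier is then the only atria-ventricle interface."""
    phantom = build_phantom(PhantomConfig(grid_shape=(100, 100)))
    labels = phantom.labels.copy()
    labels[labels == _CODE[RegionLabel.ATRIOVENTRICULAR_NODE]] = \
        _CODE[RegionLabel.FIBROUS_BARRIER]
    blocked = TissuePhantom(labels=labels, spacing=phantom.spacing,
                            params=phantom.params)
    with pytest.warns(RuntimeWarning, match="propagation failure"):
        rec = run_simulation(blocked, default_protocol, default_probes(blocked),
                             duration=2 * default_protocol.period,
                             record_every=40)
    assert "propagation_failure" in rec.warnings
    assert RegionLabel.VENTRICLES not in rec.activation_times
    assert RegionLabel.ATRIA in rec.activation_times


def _strip_phantom(D: float) -> TissuePhantom:
    labels = np.full((5, 200), _CODE[RegionLabel.VENTRICLES], dtype=np.int8)
    diff = dict(DynamicParams().diffusion_by_region)
    diff[RegionLabel.VENTRICLES] = D
    return TissuePhantom(labels=labels, spacing=1.0,
                         params=DynamicParams(diffusion_by_region=diff))


def _front_speed(D: float) -> float:
    phantom = _strip_phantom(D)
    state = FieldState.resting(phantom)
    state.u1[:, :5] = 1.0
    dt = 0.9 * stability_limit(_strip_phantom(0.3))  # same dt for both
    probes, times = (60, 160), {}
    while state.t < 3000 and len(times) < 2:
        state = step_field(state, phantom, dt)
        for p in probes:
            if p not in times and state.u1[2, p] > 0.5:
                times[p] = state.t
    assert len(times) == 2, f"front never arrived for D={D}"
    return (probes[1] - probes[0]) / (times[probes[1]] - times[probes[0]])


def test_plane_wave_speed_increases_with_diffusion():
    """Purkinje-grade tissue (D=0.3) conducts faster than ventricular
    tissue (D=0.1)."""
    v_slow = _front_speed(0.1)
    v_fast = _front_speed(0.3)
    assert v_fast > v_slow
    # continuum prediction is sqrt(D) scaling; allow generous tolerance
    assert v_fast / v_slow == pytest.approx(np.sqrt(3.0), rel=0.25)


def test_simulation_is_deterministic(small_phantom, default_protocol,
                                     short_recording):
    rec2 = run_simulation(small_phantom, default_protocol,
                          default_probes(small_phantom),
                          duration=2 * default_protocol.period)
    for name, trace in short_recording.probe_traces.items():
        assert np.array_equal(trace, rec2.probe_traces[name])


# ---------------------------------------------------------------- extraction

def test_conventional_lead_is_probe_difference(short_recording):
    lead = extract_conventional_lead(short_recording)
    det = short_recording.probe_traces["conventional:a"]
    ref = short_recording.probe_traces["conventional:b"]
    expect = (det - ref) - (det - ref).mean()
    assert np.allclose(lead.samples, expect)
    assert lead.samples.mean() == pytest.approx(0.0, abs=1e-12)


def test_extract_unknown_probe_raises(short_recording):
    with pytest.raises(KeyError, match="no conventional probe"):
        extract_conventional_lead(short_recording, "nope")
    with pytest.raises(KeyError, match="no single-position probe"):
        extract_single_position(short_recording, "nope")


def test_single_position_requires_electrode_layer(default_protocol):
    phantom = build_phantom(PhantomConfig(grid_shape=(100, 100),
                                          include_electrode_layer=False))
    probes = [ProbeSpec("single", "single_position", (0, 10))]
    with pytest.raises(ValueError, match="electrode layer"):
        run_simulation(phantom, default_protocol, probes,
                       duration=2 * default_protocol.period)
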