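import numpy as np
import pandas as pd
import pytest

from popmodes import (
    GeneratorConfig,
    ModeProjection,
    apply_perturbation,
    compare_mode_changes,
    connection_fraction,
    epsp_features,
    generate_session,
    membrane_time_constant,
    mode_change_under_perturbation,
    nested_bootstrap_performance,
    photoinhibition_rate_change,
    tag_units,
)


# ---------------------------------------------------------------------------
# nested bootstrap
# ---------------------------------------------------------------------------

def _behavior_table(p_ctrl, p_stim, n_mice=3, n_sessions=2, n_trials=100, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        for s in range(n_sessions):
            for stim, p in ((False, p_ctrl), (True, p_stim)):
                for _ in range(n_trials):
                    r = rng.random()
                    outcome = "correct" if r < p else ("early_lick" if r > 0.97 else "error")
                    rows.append(
                        {"mouse_id": f"m{m}", "session_id": f"m{m}s{s}",
                         "photostim": stim, "outcome": outcome}
                    )
    return pd.DataFrame(rows)


def test_identical_tables_give_zero_delta():
    df = _behavior_table(0.8, 0.8, seed=1)
    # force photostim outcomes identical to control outcomes
    ctrl = df[~df.photostim].reset_index(drop=True)
    stim = ctrl.copy()
    stim["photostim"] = True
    out = nested_bootstrap_performance(pd.concat([ctrl, stim]), n_boot=200, seed=0)
    assert out["observed_delta"] == pytest.approx(0.0)


def test_large_performance_drop_detected():
    df = _behavior_table(0.9, 0.5, seed=2)
    out = nested_bootstrap_performance(df, n_boot=1000, seed=0)
    assert out["observed_delta"] < -0.3
    assert out["p_value"] < 0.01


def test_nested_bootstrap_requires_columns_and_mice():
    with pytest.raises(ValueError, match="missing columns"):
        nested_bootstrap_performance(pd.DataFrame({"mouse_id": []}), n_boot=10)
    df = _behavior_table(0.8, 0.7, n_mice=1, seed=3)
    with pytest.raises(ValueError, match="2 mice"):
        nested_bootstrap_performance(df, n_boot=10)


# ---------------------------------------------------------------------------
# spike-rate change
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def silenced_session():
    cfg = GeneratorConfig(
        n_units=12, baseline_rate_hz=(18.0, 22.0), mode_amplitude_hz=0.0,
        gain_sd=0.0, n_prototypes=1,
        n_trials_per_condition={"CR": 60, "CL": 60, "ER": 6, "EL": 6},
        seed=31,
    )
    session, truth = generate_session(cfg)
    stimmed = apply_perturbation(session, truth, cfg, "thal", "delay", 0.0, trial_fraction=0.4)
    return stimmed


def test_full_silencing_flagged(silenced_session):
    out = photoinhibition_rate_change(
        silenced_session, "u0000", silenced_session.epochs.delay
    )
    assert out["label"] == "silenced"
    assert out["p_value"] < 1e-6
    assert out["ratio"] < 0.05


def test_null_factor_mostly_unchanged():
    cfg = GeneratorConfig(
        n_units=15, baseline_rate_hz=(8.0, 12.0), mode_amplitude_hz=0.0,
        gain_sd=0.0, n_prototypes=1,
        n_trials_per_condition={"CR": 50, "CL": 50, "ER": 5, "EL": 5},
        seed=33,
    )
    session, truth = generate_session(cfg)
    stimmed = apply_perturbation(session, truth, cfg, "thal", "delay", 1.0)
    labels = [
        photoinhibition_rate_change(stimmed, u, stimmed.epochs.delay)["label"]
        for u in stimmed.unit_ids
    ]
    assert labels.count("unchanged") >= 14  # ~ alpha = 0.01


def test_low_rate_unit_flagged(silenced_session):
    session = silenced_session
    # a nearly silent unit: strip almost all its spikes
    uid = "u0001"
    session.spikes = {
        k: v[:1] if k[0] == uid else v for k, v in session.spikes.items()
    }
    session.validate()
    out = photoinhibition_rate_change(session, uid, session.epochs.delay)
    assert out["low_rate"]
    assert out["label"] == "unchanged"


# ---------------------------------------------------------------------------
# mode changes
# ---------------------------------------------------------------------------

def _projection(values_by_mode, groups=("R", "L"), t=None):
    t = np.linspace(-3, 1.3, 50) if t is None else t
    values = {m: {g: v.copy() for g in groups} for m, v in values_by_mode.items()}
    se = {m: {g: np.zeros_like(t) for g in groups} for m in values_by_mode}
    return ModeProjection(time_s=t, values=values, se=se,
                          mode_names=tuple(values_by_mode), groups=groups)


def test_identical_projections_zero_change():
    t = np.linspace(-3, 1.3, 50)
    ctrl = _projection({"choice": np.sin(t), "ramping": t * 0.1}, t=t)
    stim = _projection({"choice": np.sin(t), "ramping": t * 0.1}, t=t)
    out = mode_change_under_perturbation(ctrl, stim, (-1.3, 0.0))
    assert all(v == pytest.approx(0.0) for v in out.values())


def test_mode_change_invariant_to_projection_offset():
    t = np.linspace(-3, 1.3, 50)
    rng = np.random.default_rng(0)
    a, b = np.sin(t), np.sin(t) * 0.3 + 0.1 * rng.standard_normal(50)
    ctrl = _projection({"choice": a}, t=t)
    stim = _projection({"choice": b}, t=t)
    base = mode_change_under_perturbation(ctrl, stim, (-1.3, 0.0))
    ctrl2 = _projection({"choice": a + 5.0}, t=t)
    stim2 = _projection({"choice": b + 5.0}, t=t)
    shifted = mode_change_under_perturbation(ctrl2, stim2, (-1.3, 0.0))
    assert shifted["choice"] == pytest.approx(base["choice"])


def test_zero_sd_control_mode_skipped():
    t = np.linspace(-3, 1.3, 50)
    ctrl = _projection({"go": np.ones_like(t)}, t=t)
    stim = _projection({"go": np.zeros_like(t)}, t=t)
    assert mode_change_under_perturbation(ctrl, stim, (-1.3, 0.0)) == {}


def test_equal_planted_effects_give_intermediate_p():
    rng = np.random.default_rng(1)
    ps = [
        compare_mode_changes(
            rng.normal(1.0, 0.5, 200), rng.normal(1.0, 0.5, 200), n_boot=500, seed=s
        )
        for s in range(10)
    ]
    assert 0.1 < np.median(ps) < 0.9


# ---------------------------------------------------------------------------
# photo-tagging
# ---------------------------------------------------------------------------

def _poisson_train(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.random(n) * duration)


def test_tagging_connected_and_controls():
    rng = np.random.default_rng(2)
    pulses = np.arange(100) * 0.2 + 1.0
    duration = pulses[-1] + 1.0
    base = _poisson_train(5.0, duration, rng)
    # connected: extra spike at ~2 ms latency on 60% of pulses
    connected = np.sort(np.concatenate([base, pulses[rng.random(100) < 0.6] + 0.002]))
    # suppressed: silence 20 ms after each pulse
    sup = base.copy()
    for t0 in pulses:
        sup = sup[(sup < t0) | (sup > t0 + 0.02)]
    # weakly evoked: 0.15 spikes/pulse
    weak = np.sort(np.concatenate([base, pulses[rng.random(100) < 0.15] + 0.002]))
    results = {
        r.unit_id: r
        for r in tag_units(
            {"conn": connected, "sup": sup, "weak": weak}, pulses
        )
    }
    assert results["conn"].tagged
    assert results["conn"].latency_ms < 4.0
    assert results["conn"].evoked_spikes_per_pulse > 0.4
    assert not results["sup"].tagged  # excitation test is one-directional
    assert not results["weak"].tagged  # fails the 0.2 spikes/pulse criterion


def test_tagging_needs_pulses():
    with pytest.raises(ValueError, match="pulses"):
        tag_units({"u": np.array([0.1])}, np.arange(10) * 0.2)


# ---------------------------------------------------------------------------
# EPSP features
# ---------------------------------------------------------------------------

def _epsp_trace(onset_ms=3.0, peak_mv=5.0, fs=20000, spike_at_ms=None):
    t = np.arange(0, 0.2, 1 / fs)
    stim = 0.1
    v = np.full_like(t, -65.0)
    rel = (t - stim - onset_ms / 1000.0) * 1000.0
    rise = peak_mv * (1 - np.exp(-np.clip(rel, 0, None) / 2.0)) * np.exp(-np.clip(rel, 0, None) / 30.0)
    v += np.where(rel > 0, rise, 0.0)
    if spike_at_ms is not None:
        sp = stim + spike_at_ms / 1000.0
        mask = (t >= sp) & (t < sp + 0.001)
        v[mask] = 20.0
    return t, v, stim


def test_epsp_latency_and_connection():
    t, v, stim = _epsp_trace()
    f = epsp_features(t, v, stim)
    assert f.connected
    assert 3.0 <= f.latency_ms <= 4.5  # onset + 10%-rise offset
    assert f.mean_epsp_mv > 1.0


def test_flat_trace_unconnected():
    t = np.arange(0, 0.2, 5e-5)
    v = -65.0 + 0.01 * np.sin(t * 100)
    f = epsp_features(t, v, 0.1)
    assert not f.connected and f.latency_ms is None


def test_spike_clipping_preserves_features():
    t, v, stim = _epsp_trace()
    _, v_spike, _ = _epsp_trace(spike_at_ms=2.0)
    clean = epsp_features(t, v, stim)
    clipped = epsp_features(t, v_spike, stim)
    assert clipped.connected
    assert clipped.mean_epsp_mv == pytest.approx(clean.mean_epsp_mv, rel=0.1)
    assert clipped.peak_mv == pytest.approx(clean.peak_mv, rel=0.1)


# ---------------------------------------------------------------------------
# connection fractions
# ---------------------------------------------------------------------------

def test_connection_fraction_trivial_and_se_shrinks():
    rng = np.random.default_rng(3)
    out_small = connection_fraction(
        np.repeat([0, 1], 20), np.ones(40, bool), np.ones(40, bool), n_boot=300, seed=0
    )
    out_big = connection_fraction(
        np.repeat([0, 1], 500), np.ones(1000, bool), np.ones(1000, bool), n_boot=300, seed=0
    )
    assert out_small["fraction"][0] == 1.0
    assert all(se == 0 for se in out_small["se"].values())  # all connected: no variance
    labels = np.repeat([0, 1], 200)
    tested = rng.random(400) < 0.5
    connected = tested & (rng.random(400) < 0.4)
    out = connection_fraction(labels, tested, connected, n_boot=300, seed=0)
    assert 0 <= out["chi2_p"] <= 1
    assert all(0 < se < 0.2 for se in out["se"].values())


def test_connected_must_be_tested():
    with pytest.raises(ValueError, match="tested"):
        connection_fraction(np.zeros(4), np.array([1, 0, 1, 0], bool), np.array([0, 1, 0, 0], bool))


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------

def test_single_exponential_recovered():
    t = np.arange(0, 100, 0.05)
    y = 8.0 * np.exp(-t / 15.0)
    assert membrane_time_constant(t, y) == pytest.approx(15.0, abs=1.0)


def test_double_exponential_slow_component():
    t = np.arange(0, 120, 0.05)
    y = 5.0 * np.exp(-t / 2.0) + 3.0 * np.exp(-t / 20.0)
    assert membrane_time_constant(t, y) == pytest.approx(20.0, abs=2.0)


def test_noise_only_trace_errors():
    rng = np.random.default_rng(4)
    t = np.arange(0, 50, 0.05)
    with pytest.raises(RuntimeError):
        membrane_time_constant(t, rng.standard_normal(t.size))
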