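"""Perturbation, photo-tagging and whole-cell connectivity statistics.

Covers the optogenetic side of the pipeline: hierarchical (mouse, session,
trial) bootstrap for behavioral effects of photoinhibition, per-unit spike-
rate change tests, standardized activity-mode changes under perturbation,
short-latency photo-tagging of putatively connected units, EPSP feature
extraction from whole-cell membrane-potential traces, and connection-fraction
comparisons across functional populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import chi2_contingency, ttest_ind, ttest_rel

from .binning import window_counts
from .modes import ModeProjection
from .session import Trial, TrialAlignedSession

__all__ = [
    "nested_bootstrap_performance",
    "photoinhibition_rate_change",
    "mode_change_under_perturbation",
    "compare_mode_changes",
    "TagResult",
    "tag_units",
    "EPSPFeatures",
    "epsp_features",
    "connection_fraction",
    "membrane_time_constant",
]


# ---------------------------------------------------------------------------
# nested bootstrap for behavioral effects
# ---------------------------------------------------------------------------

def _performance(counts: np.ndarray) -> np.ndarray:
    """Fraction correct excluding early-lick and ignore trials.

    ``counts[..., :]`` = (correct, error, early, ignore).
    """
    denom = counts[..., 0] + counts[..., 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts[..., 0] / denom, np.nan)


def nested_bootstrap_performance(
    behavior: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Hierarchical bootstrap test for a photoinhibition performance change.

    ``behavior`` has one row per trial with columns ``mouse_id``,
    ``session_id``, ``photostim`` (bool) and ``outcome`` in
    {correct, error, early_lick, ignore}.  Performance is the fraction of
    correct choices excluding early-lick and ignore trials.  Each bootstrap
    replicate resamples with replacement (1) mice, (2) sessions within each
    resampled mouse, (3) trials within each resampled session, and recomputes
    the photostim-minus-control performance change.  The one-sided p-value is
    the fraction of replicates whose change has the sign opposite to the
    observed change.
    """
    req = {"mouse_id", "session_id", "photostim", "outcome"}
    missing = req - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    cats = ["correct", "error", "early_lick", "ignore"]
    # per (mouse, session): trial-category counts for control and photostim
    mice: list[str] = []
    sess_counts: list[np.ndarray] = []  # per mouse: (n_sessions, 2, 4)
    for mouse, mdf in behavior.groupby("mouse_id"):
        rows = []
        for _, sdf in mdf.groupby("session_id"):
            c = np.zeros((2, 4))
            for stim in (0, 1):
                sub = sdf[sdf["photostim"].astype(bool) == bool(stim)]
                for j, cat in enumerate(cats):
                    c[stim, j] = int((sub["outcome"] == cat).sum())
            rows.append(c)
        arr = np.stack(rows)
        if arr[:, 1].sum() == 0:  # mouse never photostimulated
            continue
        mice.append(mouse)
        sess_counts.append(arr)
    if len(mice) < 2:
        raise ValueError("nested bootstrap needs >= 2 mice with photostim sessions")

    def dataset_delta(per_mouse: list[np.ndarray]) -> float:
        tot = np.sum([a.sum(axis=0) for a in per_mouse], axis=0)
        perf = _performance(tot)
        return float(perf[1] - perf[0])

    observed = dataset_delta(sess_counts)
    rng = np.random.default_rng(seed)
    M = len(mice)
    deltas = np.empty(n_boot)
    # vectorized over bootstrap replicates: resample mice, then sessions
    # within each drawn mouse, then trials (multinomially) within each session
    mouse_draws = rng.integers(0, M, size=(n_boot, M))
    tot = np.zeros((n_boot, 2, 4))
    for m in range(M):
        arr = sess_counts[m]  # (S, 2, 4)
        S = arr.shape[0]
        occur = (mouse_draws == m).sum(axis=1)  # times mouse m drawn, per replicate
        reps = np.nonzero(occur)[0]
        if reps.size == 0:
            continue
        # for each occurrence draw S sessions with replacement
        n_occ = occur[reps]
        for r, k in zip(reps, n_occ):
            sess_idx = rng.integers(0, S, size=k * S)
            picked = arr[sess_idx]  # (k*S, 2, 4)
            n_trials = picked.reshape(len(sess_idx), -1).sum(axis=1).astype(int)
            flat = picked.reshape(len(sess_idx), 8)
            with np.errstate(invalid="ignore"):
                pvals = flat / n_trials[:, None]
            resampled = rng.multinomial(n_trials, pvals)
            tot[r] += resampled.sum(axis=0).reshape(2, 4)
    perf = _performance(tot)
    deltas = perf[:, 1] - perf[:, 0]
    sign = np.sign(observed) if observed != 0 else 1.0
    p = float(np.mean(sign * deltas < 0))
    return {
        "observed_delta": observed,
        "p_value": p,
        "bootstrap_deltas": deltas,
        "n_mice": M,
    }


# ---------------------------------------------------------------------------
# spike-rate change under photoinhibition
# ---------------------------------------------------------------------------

def photoinhibition_rate_change(
    session: TrialAlignedSession,
    unit_id: str,
    stim_window: tuple[float, float],
    alpha: float = 0.01,
    min_trials: int = 5,
    min_rate_hz: float = 0.5,
) -> dict:
    """Spike-rate change of one unit in the stimulation window.

    Photostim trials are compared with control trials in the same window
    (trial types pooled) by a two-tailed t-test; the unit is labeled excited /
    silenced / unchanged at the 0.01 level.  Units whose control rate is below
    ``min_rate_hz`` are flagged low-rate and excluded from the label.
    """
    stim = [t for t in session.trials if t.photostim is not None]
    ctrl = [t for t in session.trials if t.photostim is None]
    if len(stim) < min_trials or len(ctrl) < min_trials:
        raise ValueError(f"need >= {min_trials} photostim and control trials")
    dur = stim_window[1] - stim_window[0]
    cs = window_counts(session, [unit_id], stim, stim_window)[0]
    cc = window_counts(session, [unit_id], ctrl, stim_window)[0]
    rate_stim = cs.mean() / dur
    rate_ctrl = cc.mean() / dur
    if cs.sum() == 0 and cc.sum() == 0:
        return {
            "unit_id": unit_id, "rate_stim_hz": 0.0, "rate_ctrl_hz": 0.0,
            "ratio": np.nan, "p_value": 1.0, "label": "unchanged", "low_rate": True,
        }
    p = float(ttest_ind(cs, cc, equal_var=False).pvalue)
    low_rate = rate_ctrl < min_rate_hz
    if low_rate or p >= alpha:
        label = "unchanged"
    else:
        label = "excited" if rate_stim > rate_ctrl else "silenced"
    return {
        "unit_id": unit_id,
        "rate_stim_hz": float(rate_stim),
        "rate_ctrl_hz": float(rate_ctrl),
        "ratio": float(rate_stim / rate_ctrl) if rate_ctrl > 0 else np.inf,
        "p_value": p,
        "label": label,
        "low_rate": bool(low_rate),
    }


# ---------------------------------------------------------------------------
# mode changes under perturbation
# ---------------------------------------------------------------------------

def mode_change_under_perturbation(
    control: ModeProjection,
    stim: ModeProjection,
    stim_window: tuple[float, float],
) -> dict[str, float]:
    """Standardized |change| of each activity-mode projection.

    For every mode, projections are averaged over the trial groups (lick
    directions pooled), the absolute control-minus-photostim difference is
    averaged inside the stimulation window, and the result is divided by the
    s.d. of the control projection across time.  Modes whose control
    projection has zero temporal s.d. are skipped.
    """
    t = control.time_s
    win = (t >= stim_window[0]) & (t < stim_window[1])
    out: dict[str, float] = {}
    for m in control.mode_names:
        c = np.mean([control.values[m][g] for g in control.groups], axis=0)
        groups = [g for g in stim.groups]
        s = np.mean([stim.values[m][g] for g in groups], axis=0)
        sd = float(np.std(c))
        if sd == 0:
            continue
        out[m] = float(np.mean(np.abs(c[win] - s[win])) / sd)
    return out


def compare_mode_changes(
    per_neuron_a: np.ndarray,
    per_neuron_b: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> float:
    """One-sided neuron-bootstrap p for manipulation A vs B mode changes.

    Inputs are per-neuron contributions to the standardized change under two
    manipulations (same neuron set).  p is the fraction of neuron resamples
    in which the sign of the mean difference is inconsistent with the
    observed one.
    """
    a = np.asarray(per_neuron_a, float)
    b = np.asarray(per_neuron_b, float)
    obs = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    na, nb = len(a), len(b)
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    diff = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    sign = np.sign(obs) if obs != 0 else 1.0
    return float(np.mean(sign * diff < 0))


# ---------------------------------------------------------------------------
# photo-tagging
# ---------------------------------------------------------------------------

@dataclass
class TagResult:
    unit_id: str
    evoked_spikes_per_pulse: float
    latency_ms: float | None
    p_value: float
    tagged: bool
    note: str = ""


def tag_units(
    spike_times_s: dict[str, np.ndarray],
    pulse_times_s: np.ndarray,
    window_ms: float = 20.0,
    latency_bin_ms: float = 0.5,
    alpha: float = 0.01,
    latency_max_ms: float = 5.0,
    min_evoked: float = 0.2,
) -> list[TagResult]:
    """Identify putatively connected units from pulse-locked responses.

    For each unit, spike counts in ``window_ms`` windows before and after
    every light pulse are compared (paired two-tailed t-test across pulses).
    Among significantly *excited* units, the evoked response is the mean
    baseline-subtracted spikes per pulse and the latency is the first
    ``latency_bin_ms`` bin in which the baseline-subtracted rate reaches 50%
    of its peak.  Tagged requires p < 0.01, latency < 5 ms (strict) and
    evoked > 0.2 spikes per pulse.
    """
    pulses = np.asarray(pulse_times_s, float)
    if pulses.size < 20:
        raise ValueError(f"need >= 20 pulses, got {pulses.size}")
    w = window_ms / 1000.0
    nb = int(round(window_ms / latency_bin_ms))
    results = []
    for uid, st in spike_times_s.items():
        st = np.asarray(st, float)
        pre = np.searchsorted(st, pulses) - np.searchsorted(st, pulses - w)
        post = np.searchsorted(st, pulses + w) - np.searchsorted(st, pulses)
        if pre.sum() == 0 and post.sum() == 0:
            results.append(TagResult(uid, 0.0, None, 1.0, False, "no spikes"))
            continue
        if np.all(post - pre == (post - pre)[0]):
            p = 1.0 if (post - pre)[0] == 0 else 0.0
        else:
            p = float(ttest_rel(post, pre).pvalue)
        evoked = float(np.mean(post - pre))
        excited = evoked > 0 and p < alpha
        latency = None
        if excited:
            rel = np.concatenate([st[np.searchsorted(st, t0):np.searchsorted(st, t0 + w)] - t0 for t0 in pulses])
            hist, _ = np.histogram(rel, bins=nb, range=(0, w))
            base_rate = pre.sum() / nb  # expected per-bin count from baseline
            bs = hist - base_rate
            peak = bs.max()
            if peak > 0:
                first = int(np.argmax(bs >= 0.5 * peak))
                latency = (first + 0.5) * latency_bin_ms
        tagged = bool(
            excited and latency is not None and latency < latency_max_ms and evoked > min_evoked
        )
        results.append(TagResult(uid, evoked, latency, p, tagged))
    return results


# ---------------------------------------------------------------------------
# whole-cell EPSP features
# ---------------------------------------------------------------------------

@dataclass
class EPSPFeatures:
    baseline_mv: float
    mean_epsp_mv: float
    peak_mv: float
    latency_ms: float | None
    connected: bool


def epsp_features(
    time_s: np.ndarray,
    vm_mv: np.ndarray,
    stim_onset_s: float,
    power_mW: float = 20.0,
    spike_threshold_mv: float = -20.0,
    latency_max_ms: float = 5.0,
) -> EPSPFeatures:
    """EPSP features from a membrane-potential trace.

    Spikes (V_m above threshold) are clipped by linear interpolation from 1 ms
    before to 4 ms after each event.  Baseline is the 10-ms pre-stimulus mean;
    the mean EPSP is taken in a 20-ms post-onset window; latency is where the
    baseline-subtracted V_m first reaches 10% of its peak (peak searched in
    0-20 ms; a peak below 3x the baseline s.d. leaves the latency undefined
    and the cell unconnected).  Connected requires latency <= 5 ms at the
    calibration power (20 mW).
    """
    t = np.asarray(time_s, float)
    v = np.asarray(vm_mv, float).copy()
    dt = t[1] - t[0]
    if dt > 1e-4 + 1e-12:
        raise ValueError("V_m must be sampled at >= 10 kHz")
    above = v > spike_threshold_mv
    if above.any():
        edges = np.flatnonzero(np.diff(above.astype(int)) == 1)
        for e in edges:
            i0 = max(0, e - int(round(1e-3 / dt)))
            i1 = min(len(v) - 1, e + int(round(4e-3 / dt)))
            v[i0 : i1 + 1] = np.interp(t[i0 : i1 + 1], [t[i0], t[i1]], [v[i0], v[i1]])

    pre = (t >= stim_onset_s - 0.010) & (t < stim_onset_s)
    post = (t >= stim_onset_s) & (t < stim_onset_s + 0.020)
    baseline = float(v[pre].mean())
    noise_sd = float(v[pre].std())
    epsp = v - baseline
    mean_epsp = float(epsp[post].mean())
    peak = float(epsp[post].max())
    latency = None
    if peak > 3 * noise_sd and peak > 0:
        idx = np.flatnonzero(post & (epsp >= 0.1 * peak))
        if idx.size:
            latency = float((t[idx[0]] - stim_onset_s) * 1000.0)
    connected = bool(latency is not None and latency <= latency_max_ms and power_mW >= 20.0)
    return EPSPFeatures(
        baseline_mv=baseline, mean_epsp_mv=mean_epsp, peak_mv=peak,
        latency_ms=latency, connected=connected,
    )


# ---------------------------------------------------------------------------
# connection fractions
# ---------------------------------------------------------------------------

def connection_fraction(
    population_labels: np.ndarray,
    tested: np.ndarray,
    connected: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fraction of connected neurons per population with bootstrap s.e.

    The fraction is connected/tested within each population; the standard
    error bootstraps the *entire* dataset (tested or not), and a chi-squared
    test (no continuity correction) compares connection counts across
    populations.
    """
    labels = np.asarray(population_labels)
    tested = np.asarray(tested, bool)
    connected = np.asarray(connected, bool)
    if np.any(connected & ~tested):
        raise ValueError("connected units must be tested")
    pops = [p for p in np.unique(labels) if np.sum(tested & (labels == p)) > 0]
    frac = {}
    for p in pops:
        m = tested & (labels == p)
        frac[p] = float(connected[m].sum() / m.sum())
    rng = np.random.default_rng(seed)
    n = len(labels)
    boots = {p: [] for p in pops}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb, tb, cb = labels[idx], tested[idx], connected[idx]
        for p in pops:
            m = tb & (lb == p)
            if m.sum():
                boots[p].append(cb[m].sum() / m.sum())
    se = {p: float(np.std(boots[p])) for p in pops}
    table = np.array(
        [
            [int(connected[tested & (labels == p)].sum()),
             int((~connected[tested & (labels == p)]).sum())]
            for p in pops
        ]
    )
    if table.shape[0] >= 2 and table.sum(axis=0).min() > 0:
        chi2_p = float(chi2_contingency(table, correction=False).pvalue)
    else:
        chi2_p = float("nan")
    return {"fraction": frac, "se": se, "chi2_p": chi2_p, "populations": pops}


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------

def membrane_time_constant(
    time_ms: np.ndarray, vm_decay_mv: np.ndarray
) -> float:
    """Slow time constant of a double-exponential fit to an averaged V_m decay.

    Raises with fit diagnostics when the optimizer fails to converge or the
    fit does not beat a flat model.
    """
    t = np.asarray(time_ms, float)
    y = np.asarray(vm_decay_mv, float)

    def model(t, a1, tau1, a2, tau2):
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    span = max(t[-1] - t[0], 1.0)
    amp = y[0] if abs(y[0]) > 1e-12 else 1.0
    try:
        popt, _ = curve_fit(
            model, t, y,
            p0=[amp * 0.5, span / 20, amp * 0.5, span / 2],
            bounds=([-np.inf, 1e-3, -np.inf, 1e-3], [np.inf, 10 * span, np.inf, 10 * span]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"double-exponential fit failed to converge: {exc}") from exc
    resid = y - model(t, *popt)
    flat_resid = y - y.mean()
    if np.sum(resid**2) > 0.9 * np.sum(flat_resid**2):
        raise RuntimeError(
            "double-exponential fit no better than a constant "
            f"(residual ratio {np.sum(resid**2) / np.sum(flat_resid**2):.2f})"
        )
    (a1, t1, a2, t2) = popt
    amps = np.abs([a1, a2])
    # an effectively single-exponential decay makes the second component
    # unidentifiable; return the dominant time constant in that case
    if amps.min() < 0.05 * amps.sum():
        return float(t1 if amps[0] >= amps[1] else t2)
    return float(max(t1, t2))
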