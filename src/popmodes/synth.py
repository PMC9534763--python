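"""Synthetic trial-aligned sessions with planted ground truth.

The generator emulates the statistical structure of frontal-cortex recordings
during a delayed two-alternative licking task: each unit's firing rate is a
baseline plus a weighted sum of seven temporal "activity-mode" templates whose
signs depend on the trial condition, plus a per-trial gain shared within a
subnetwork, rectified at zero and turned into spikes by an inhomogeneous
Poisson process:

    lambda_i(t | trial k) = max(0, b_i + sum_m w_im f_m(t, cond_k) + g_k b_i)

Two mixing regimes are provided.  In the ``clustered`` regime units inherit
their mode weights from a small set of prototypes (each loading on a limited
number of modes), producing discrete response-profile clusters and segregated
coding vectors.  In the ``random_mixed`` regime weights are i.i.d. zero-mean
normal across modes, producing a continuum of profiles with randomly mixed
selectivity.  The planted weights, prototype labels, subnetwork labels and
noiseless condition rates are returned as :class:`GroundTruth` so every
pipeline stage has a recovery oracle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .session import (
    Correctness,
    EpochWindows,
    InstructedType,
    PhotostimCondition,
    Response,
    Trial,
    TrialAlignedSession,
    Unit,
)

__all__ = [
    "MODE_NAMES",
    "GeneratorConfig",
    "GroundTruth",
    "generate_session",
    "apply_perturbation",
    "condition_rates",
]

MODE_NAMES = ("stimulus", "choice", "action", "outcome", "ramping", "go", "response")

_DEFAULT_TRIALS = {"CR": 40, "CL": 40, "ER": 12, "EL": 12, "ignore": 4, "early_lick": 4}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-session generator.

    ``mode_amplitude_hz`` scales the mode templates (peak rate modulation of a
    unit with unit weight); ``gain_sd`` is the s.d. of the per-trial shared
    gain, expressed as a fraction of baseline rate; ``n_inconsistent_units``
    plants units with a flat, condition-independent rate that must fail the
    split-half consistency filter downstream.
    """

    n_units: int = 120
    n_trials_per_condition: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TRIALS)
    )
    delay_duration_s: float = 1.3
    n_prototypes: int = 5
    mixing_regime: str = "clustered"  # "clustered" | "random_mixed"
    modes_per_prototype: int = 1
    baseline_rate_hz: tuple[float, float] = (4.0, 12.0)
    mode_amplitude_hz: float = 6.0
    weight_jitter: float = 0.15
    n_subnetworks: int | None = None  # default: one per prototype
    gain_sd: float = 0.1
    n_inconsistent_units: int = 0
    bin_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixing_regime not in ("clustered", "random_mixed"):
            raise ValueError(f"unknown mixing_regime {self.mixing_regime!r}")
        if self.gain_sd < 0:
            raise ValueError("gain_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated session."""

    prototype_id: np.ndarray  # (n_units,), -1 for inconsistent units
    true_mode_weights: np.ndarray  # (n_units, 7)
    mixing_regime: str
    subnetwork_id: np.ndarray  # (n_units,)
    gain_sd: float
    seed: int
    mode_names: tuple[str, ...] = MODE_NAMES
    baseline_hz: np.ndarray | None = None
    bin_centers_s: np.ndarray | None = None
    condition_rates: dict[str, np.ndarray] | None = None  # cond -> (n_units, n_bins)
    mode_templates: dict[str, np.ndarray] | None = None  # cond -> (7, n_bins)


# ---------------------------------------------------------------------------
# temporal templates
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _template_shapes(t: np.ndarray, epochs: EpochWindows) -> np.ndarray:
    """Unit-amplitude temporal shapes of the seven modes, shape (7, n_bins)."""
    s0, d0 = epochs.sample_start, epochs.delay_start
    delay = epochs.delay_duration_s
    # shapes are chosen to be separable in the windows that define the seven
    # modes (sample epoch, delay, 0.1-0.3 s, response, delay-end vs presample,
    # +-100 ms around the go cue, whole-trial energy), so planted weights are
    # identifiable from the recovery formulas
    stim = _sigmoid((t - (s0 + 0.15)) / 0.05) * np.where(
        t < d0, 1.0, np.where(t < 0, 0.7, 0.0)
    )
    choice = np.clip((t - (d0 - 0.4)) / (delay + 0.4), 0.0, 1.0) * (t < 0)
    action = np.exp(-0.5 * ((t - 0.30) / 0.10) ** 2) * (t > 0.05)
    outcome = _sigmoid((t - 0.45) / 0.08) * (t > 0.15)
    # ramp holds through the go cue so it cancels in the go-mode contrast
    ramping = np.clip((t - s0) / (0.0 - s0), 0.0, 1.0) * np.where(
        t < 0.15, 1.0, np.maximum(0.4, 1.0 - 2.0 * (t - 0.15))
    )
    go = 1.5 * np.exp(-0.5 * ((t - 0.06) / 0.03) ** 2) * (t > 0)
    # largest-energy component by construction: the response mode is defined
    # as the top singular vector, so its template must dominate total energy;
    # the rise starts after the go-mode window and decays before the late
    # outcome plateau, keeping the three response-epoch shapes separable
    response = (
        3.0
        * _sigmoid((t - 0.18) / 0.04)
        * np.exp(-np.clip(t - 0.18, 0, None) / 0.45)
        * (t > 0.08)
    )
    return np.vstack([stim, choice, action, outcome, ramping, go, response])


#: Per-condition multipliers of (stimulus, choice, action, outcome, ramping,
#: go, response).  Stimulus sign follows the instructed pole position, choice/
#: action follow the actual lick direction, outcome is +1 on rewarded trials.
#: Ignore trials keep stimulus coding but have attenuated choice/ramping and no
#: action/go; early-lick trials develop choice/ramping faster.
_COEFFS = {
    "CR": (1, 1, 1, 1, 1.0, 1.0, 1.0),
    "CL": (-1, -1, -1, 1, 1.0, 1.0, 1.0),
    "ER": (1, -1, -1, -1, 1.0, 1.0, 1.0),
    "EL": (-1, 1, 1, -1, 1.0, 1.0, 1.0),
    "ignore": (1, 0.3, 0.0, -1, 0.5, 0.0, 0.3),
    "early_lick": (1, 1.3, 1.0, 1, 1.3, 1.0, 1.0),
}


def _condition_coeffs(cond: str, instructed_sign: int = 1) -> np.ndarray:
    c = np.array(_COEFFS[cond], dtype=float)
    if cond in ("ignore", "early_lick"):
        c = c.copy()
        c[[0, 1, 2]] *= instructed_sign
    return c


def condition_rates(
    config: GeneratorConfig,
    baseline: np.ndarray,
    weights: np.ndarray,
    t: np.ndarray,
    epochs: EpochWindows,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Noiseless rate (n_units, n_bins) and mode templates per condition."""
    shapes = _template_shapes(t, epochs)
    rates: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    for cond in _COEFFS:
        if cond in ("ignore", "early_lick"):
            # report the lick-right-instructed variant; the generator flips
            # signs per trial via _condition_coeffs
            coeff = _condition_coeffs(cond, 1)
        else:
            coeff = _condition_coeffs(cond)
        f = config.mode_amplitude_hz * coeff[:, None] * shapes
        templates[cond] = f
        rates[cond] = np.maximum(0.0, baseline[:, None] + weights @ f)
    return rates, templates


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

#: Per-mode prototype weight amplitudes.  The response and go modes occupy
#: short windows (or compete in the SVD step), so their planted weights are
#: larger to give every mode comparable recoverability.
_MODE_WEIGHT_AMP = np.array([1.0, 1.0, 1.2, 1.0, 1.0, 1.3, 1.6])


def _plant_weights(config: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_units - config.n_inconsistent_units
    n_modes = len(MODE_NAMES)
    # balanced prototype membership, randomly permuted across units
    proto = rng.permutation(np.arange(n) % config.n_prototypes)
    if config.mixing_regime == "clustered":
        proto_w = np.zeros((config.n_prototypes, n_modes))
        for p in range(config.n_prototypes):
            for j in range(config.modes_per_prototype):
                m = (p * config.modes_per_prototype + j) % n_modes
                sign = 1.0 if (p // n_modes) % 2 == 0 else -1.0
                proto_w[p, m] = sign * _MODE_WEIGHT_AMP[m]
        w = proto_w[proto] * (
            1.0 + config.weight_jitter * rng.standard_normal((n, n_modes))
        )
        # zero stays zero: jitter only scales the planted entries
        w[proto_w[proto] == 0.0] = 0.0
    else:
        w = rng.standard_normal((n, n_modes)) / np.sqrt(n_modes)
    if config.n_inconsistent_units:
        proto = np.concatenate([proto, np.full(config.n_inconsistent_units, -1)])
        w = np.vstack([w, np.zeros((config.n_inconsistent_units, n_modes))])
    return proto, w


def _spikes_from_rates(
    lam: np.ndarray, t0: float, dt: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains per unit from a rate matrix (Hz)."""
    counts = rng.poisson(lam * dt)
    out = []
    for i in range(lam.shape[0]):
        c = counts[i]
        nz = np.nonzero(c)[0]
        if nz.size == 0:
            out.append(np.array([], dtype=float))
            continue
        reps = c[nz]
        starts = np.repeat(t0 + nz * dt, reps)
        times = starts + rng.random(starts.size) * dt
        out.append(np.sort(times))
    return out


def generate_session(config: GeneratorConfig) -> tuple[TrialAlignedSession, GroundTruth]:
    """Generate a session and its ground truth, deterministic given the seed.

    Per-trial randomness is drawn from counter-based substreams keyed by
    (seed, trial_id), so the same trial is reproducible independently of how
    many trials are generated.
    """
    epochs = EpochWindows(config.delay_duration_s)
    dt = config.bin_ms / 1000.0
    t_lo, t_hi = epochs.trial_window
    n_bins = int(round((t_hi - t_lo) / dt))
    t = t_lo + (np.arange(n_bins) + 0.5) * dt

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    proto, weights = _plant_weights(config, rng)
    lo, hi = config.baseline_rate_hz
    baseline = rng.uniform(lo, hi, size=config.n_units)
    n_sub = config.n_subnetworks or config.n_prototypes
    subnet = np.where(proto >= 0, proto % n_sub, rng.integers(0, n_sub, config.n_units))

    rates, templates = condition_rates(config, baseline, weights, t, epochs)
    shapes = _template_shapes(t, epochs)

    units = [
        Unit(
            unit_id=f"u{i:04d}",
            mouse_id="m00",
            session_id="s00",
            depth_um=float(rng.uniform(50, 1000)),
            spike_width_ms=float(rng.uniform(0.5, 0.9)),
        )
        for i in range(config.n_units)
    ]

    # build the trial list: interleave conditions deterministically
    trial_specs: list[tuple[str, int]] = []
    for cond, n_tr in config.n_trials_per_condition.items():
        if cond not in _COEFFS:
            raise ValueError(f"unknown condition {cond!r}")
        for j in range(n_tr):
            sign = 1 if (cond not in ("ignore", "early_lick") or j % 2 == 0) else -1
            trial_specs.append((cond, sign))

    trials: list[Trial] = []
    spikes: dict[tuple[str, int], np.ndarray] = {}
    amp = config.mode_amplitude_hz
    for trial_id, (cond, sign) in enumerate(trial_specs):
        trng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, trial_id]))
        gains = trng.normal(0.0, config.gain_sd, size=n_sub) if config.gain_sd else None
        if cond in ("ignore", "early_lick"):
            coeff = _condition_coeffs(cond, sign)
            lam = baseline[:, None] + weights @ (amp * coeff[:, None] * shapes)
        else:
            lam = rates[cond].copy()
        if gains is not None:
            lam = lam + (gains[subnet] * baseline)[:, None]
        lam = np.maximum(0.0, lam)
        trains = _spikes_from_rates(lam, t_lo, dt, trng)
        inst, resp, corr = _trial_meta(cond, sign)
        rt = None
        if corr in (Correctness.CORRECT, Correctness.ERROR):
            rt = float(np.exp(trng.normal(np.log(150.0), 0.35)))
        trials.append(
            Trial(
                trial_id=trial_id,
                instructed_type=inst,
                response=resp,
                correctness=corr,
                sample_start_s=epochs.sample_start,
                delay_start_s=epochs.delay_start,
                reaction_time_ms=rt,
            )
        )
        for i, u in enumerate(units):
            if trains[i].size:
                spikes[(u.unit_id, trial_id)] = trains[i]

    session = TrialAlignedSession(
        units=units,
        trials=trials,
        spikes=spikes,
        delay_duration_s=config.delay_duration_s,
        name=f"synthetic-seed{config.seed}",
    )
    truth = GroundTruth(
        prototype_id=proto,
        true_mode_weights=weights,
        mixing_regime=config.mixing_regime,
        subnetwork_id=subnet,
        gain_sd=config.gain_sd,
        seed=config.seed,
        baseline_hz=baseline,
        bin_centers_s=t,
        condition_rates=rates,
        mode_templates=templates,
    )
    return session, truth


def _trial_meta(cond: str, sign: int) -> tuple[InstructedType, Response, Correctness]:
    if cond == "CR":
        return InstructedType.LICK_RIGHT, Response.RIGHT, Correctness.CORRECT
    if cond == "CL":
        return InstructedType.LICK_LEFT, Response.LEFT, Correctness.CORRECT
    if cond == "ER":
        return InstructedType.LICK_RIGHT, Response.LEFT, Correctness.ERROR
    if cond == "EL":
        return InstructedType.LICK_LEFT, Response.RIGHT, Correctness.ERROR
    inst = InstructedType.LICK_RIGHT if sign > 0 else InstructedType.LICK_LEFT
    if cond == "ignore":
        return inst, Response.NONE, Correctness.IGNORE
    return inst, Response.NONE, Correctness.EARLY_LICK


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

def apply_perturbation(
    session: TrialAlignedSession,
    truth: GroundTruth,
    config: GeneratorConfig,
    target: str,
    epoch: str,
    factors: float | dict[int, float],
    trial_fraction: float = 0.25,
    power_mW: float = 3.0,
) -> TrialAlignedSession:
    """Return a session with photostimulation trials added.

    A ``trial_fraction`` subset of trials (deterministic given the generator
    seed) is marked as photostimulated and its spikes *inside the stimulation
    window only* are regenerated from rates scaled multiplicatively — per
    subnetwork if ``factors`` is a mapping, uniformly if it is a scalar.
    Control trials are untouched.
    """
    fac = factors if isinstance(factors, dict) else {s: float(factors) for s in set(truth.subnetwork_id.tolist())}
    for f in fac.values():
        if f < 0:
            raise ValueError("perturbation factor must be >= 0")
    epochs = session.epochs
    win = epochs.window(epoch)
    dt = config.bin_ms / 1000.0
    t = truth.bin_centers_s
    in_win = (t >= win[0]) & (t < win[1])
    sel_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_stim = int(round(trial_fraction * len(session.trials)))
    stim_ids = set(
        sel_rng.choice([tr.trial_id for tr in session.trials], size=n_stim, replace=False).tolist()
    )

    factor_per_unit = np.array([fac.get(int(s), 1.0) for s in truth.subnetwork_id])
    amp = config.mode_amplitude_hz
    shapes = _template_shapes(t, epochs)
    baseline = truth.baseline_hz
    weights = truth.true_mode_weights
    n_sub = int(truth.subnetwork_id.max()) + 1

    new_trials: list[Trial] = []
    new_spikes = dict(session.spikes)
    sign_cache = _instructed_signs(session)
    for tr in session.trials:
        if tr.trial_id not in stim_ids:
            new_trials.append(tr)
            continue
        new_trials.append(
            replace(tr, photostim=PhotostimCondition(target=target, epoch=epoch, power_mW=power_mW))
        )
        trng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, tr.trial_id])
        )
        gains = (
            np.random.default_rng(np.random.SeedSequence([config.seed, 1, tr.trial_id]))
            .normal(0.0, config.gain_sd, size=n_sub)
            if config.gain_sd
            else None
        )
        coeff = _condition_coeffs(tr.condition, sign_cache[tr.trial_id])
        lam = baseline[:, None] + weights @ (amp * coeff[:, None] * shapes)
        if gains is not None:
            lam = lam + (gains[truth.subnetwork_id] * baseline)[:, None]
        lam = np.maximum(0.0, lam) * factor_per_unit[:, None]
        lam_win = lam[:, in_win]
        t0 = t[in_win][0] - 0.5 * dt
        trains = _spikes_from_rates(lam_win, t0, dt, trng)
        for i, u in enumerate(session.units):
            st = session.spike_times(u.unit_id, tr.trial_id)
            outside = st[(st < win[0]) | (st >= win[1])]
            merged = np.sort(np.concatenate([outside, trains[i]]))
            if merged.size:
                new_spikes[(u.unit_id, tr.trial_id)] = merged
            else:
                new_spikes.pop((u.unit_id, tr.trial_id), None)

    out = copy.copy(session)
    out.trials = new_trials
    out.spikes = new_spikes
    out.validate()
    return out


def _instructed_signs(session: TrialAlignedSession) -> dict[int, int]:
    return {
        tr.trial_id: 1 if tr.instructed_type is InstructedType.LICK_RIGHT else -1
        for tr in session.trials
    }
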