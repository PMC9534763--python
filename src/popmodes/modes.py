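"""Selectivity vectors, the seven activity modes, and projection machinery.

Activity modes are fixed directions in n-neuron activity space onto which
population activity is projected.  With trial-averaged condition vectors
CRbar, CLbar, ERbar, ELbar (correct/error x instructed lick-right/lick-left;
the letter encodes the *instructed* direction, so ER is a lick-right-instructed
trial in which the animal licked left):

    stimulus selectivity = ((CR - EL) + (ER - CL)) / 2     (pole position)
    choice   selectivity = ((CR - ER) + (EL - CL)) / 2     (lick direction)
    outcome  selectivity = ((CR - ER) + (CL - EL)) / 2     (reward)

The seven modes are: stimulus (sample-epoch stimulus selectivity), choice
(delay-epoch choice selectivity), action (CR - CL in 0.1-0.3 s after the go
cue), outcome (response-epoch outcome selectivity), ramping (last 500 ms of
delay minus presample, correct trials combined), go (100 ms after minus 100 ms
before the go cue) and response (the top singular vector of the
baseline-subtracted concatenated PSTH matrix).  Modes are made exactly
orthogonal by Gram-Schmidt; projections use trials disjoint from the
mode-definition trials, with neuron-bootstrap standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .binning import window_counts
from .psth import PSTHMatrix, _grid, _raw_rate_matrix
from .session import EpochWindows, Trial, TrialAlignedSession

__all__ = [
    "MODE_ORDER",
    "ConditionAverages",
    "SelectivityVectors",
    "ModeSet",
    "ModeProjection",
    "condition_averages",
    "selectivity_vectors",
    "selectivity_correlation_map",
    "split_trials",
    "define_modes",
    "orthogonalize",
    "project",
    "session_offset_project",
    "variance_captured",
    "synthesize_mixture_population",
    "MixturePopulation",
]

MODE_ORDER = ("stimulus", "choice", "action", "outcome", "ramping", "go", "response")


# ---------------------------------------------------------------------------
# condition averages & selectivity
# ---------------------------------------------------------------------------

@dataclass
class ConditionAverages:
    """Windowed trial-averaged rates per condition, (n_units, n_times) each."""

    rates: dict[str, np.ndarray]
    time_s: np.ndarray
    unit_ids: list[str]
    window_s: float
    trial_ids: dict[str, list[int]]

    def __getitem__(self, cond: str) -> np.ndarray:
        return self.rates[cond]


def condition_averages(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials_by_cond: dict[str, list[Trial]] | None = None,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
) -> ConditionAverages:
    """Sliding-window trial-averaged population rates per condition.

    Rates are averaged in centered windows of ``window_ms`` advanced in
    ``step_ms`` steps over the full trial.  Conditions lacking trials are
    skipped with a warning.
    """
    if trials_by_cond is None:
        trials_by_cond = {
            c: session.trials_of(c) for c in ("CR", "CL", "ER", "EL")
        }
    dt = step_ms / 1000.0
    edges = _grid(session.epochs, dt)
    centers = edges[:-1] + dt / 2
    width = max(1, int(round(window_ms / step_ms)))
    rates: dict[str, np.ndarray] = {}
    used: dict[str, list[int]] = {}
    for cond, trials in trials_by_cond.items():
        if not trials:
            warnings.warn(f"no trials for condition {cond!r}; skipped", stacklevel=2)
            continue
        raw = _raw_rate_matrix(session, unit_ids, trials, edges)
        rates[cond] = uniform_filter1d(raw, width, axis=1, mode="nearest")
        used[cond] = [t.trial_id for t in trials]
    return ConditionAverages(
        rates=rates, time_s=centers, unit_ids=list(unit_ids),
        window_s=window_ms / 1000.0, trial_ids=used,
    )


@dataclass
class SelectivityVectors:
    stimulus: np.ndarray
    choice: np.ndarray
    outcome: np.ndarray
    time_s: np.ndarray | None = None


def selectivity_vectors(avgs: ConditionAverages | dict[str, np.ndarray]) -> SelectivityVectors:
    """Stimulus / choice / outcome selectivity from the four condition averages."""
    r = avgs.rates if isinstance(avgs, ConditionAverages) else avgs
    missing = [c for c in ("CR", "CL", "ER", "EL") if c not in r]
    if missing:
        raise ValueError(f"missing condition averages: {missing}")
    CR, CL, ER, EL = r["CR"], r["CL"], r["ER"], r["EL"]
    return SelectivityVectors(
        stimulus=((CR - EL) + (ER - CL)) / 2.0,
        choice=((CR - ER) + (EL - CL)) / 2.0,
        outcome=((CR - ER) + (CL - EL)) / 2.0,
        time_s=avgs.time_s if isinstance(avgs, ConditionAverages) else None,
    )


def selectivity_correlation_map(
    sel: np.ndarray, sel_split: tuple[np.ndarray, np.ndarray] | None = None
) -> np.ndarray:
    """Time x time Pearson correlation of a selectivity-vector time series.

    ``sel`` is (n_units, n_times).  If split-half selectivity series are given,
    the diagonal is replaced by the correlation between the two halves at each
    time.  Zero-variance columns produce NaN cells.
    """
    n, T = sel.shape
    if T < 2:
        raise ValueError("need at least 2 time points")

    def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        sa = np.linalg.norm(Ac, axis=0)
        sb = np.linalg.norm(Bc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (Ac.T @ Bc) / np.outer(sa, sb)
        return C

    C = _corr_cols(sel, sel)
    if sel_split is not None:
        a, b = sel_split
        Ac = a - a.mean(axis=0)
        Bc = b - b.mean(axis=0)
        num = (Ac * Bc).sum(axis=0)
        den = np.linalg.norm(Ac, axis=0) * np.linalg.norm(Bc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            np.fill_diagonal(C, num / den)
    return C


# ---------------------------------------------------------------------------
# mode definition
# ---------------------------------------------------------------------------

@dataclass
class ModeSet:
    """The seven activity-mode directions, columns of an (n_units x 7) matrix."""

    weights: np.ndarray  # (n_units, 7), canonical MODE_ORDER columns
    unit_ids: list[str]
    orthogonalized: bool
    definition_trial_ids: dict[str, list[int]]
    degenerate: dict[str, bool] = field(default_factory=dict)
    names: tuple[str, ...] = MODE_ORDER

    def mode(self, name: str) -> np.ndarray:
        return self.weights[:, self.names.index(name)]

    @property
    def gram(self) -> np.ndarray:
        return self.weights.T @ self.weights


def split_trials(
    session: TrialAlignedSession,
    fraction: float = 0.5,
    seed: int = 0,
    conditions: tuple[str, ...] = ("CR", "CL", "ER", "EL"),
) -> tuple[dict[str, list[Trial]], dict[str, list[Trial]]]:
    """Random per-condition split into mode-definition and projection trials."""
    rng = np.random.default_rng(seed)
    definition: dict[str, list[Trial]] = {}
    projection: dict[str, list[Trial]] = {}
    for cond in conditions:
        trials = session.trials_of(cond)
        idx = rng.permutation(len(trials))
        n_def = int(round(fraction * len(trials)))
        definition[cond] = [trials[i] for i in sorted(idx[:n_def])]
        projection[cond] = [trials[i] for i in sorted(idx[n_def:])]
    return definition, projection


def _epoch_mean_rate(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials: list[Trial],
    window: tuple[float, float],
) -> np.ndarray:
    if not trials:
        raise ValueError("no trials for epoch-mean rate")
    counts = window_counts(session, unit_ids, trials, window)
    return counts.mean(axis=1) / (window[1] - window[0])


def define_modes(
    session: TrialAlignedSession,
    unit_ids: list[str],
    definition_trials: dict[str, list[Trial]],
    min_error_trials: int = 1,
) -> ModeSet:
    """Compute the seven raw (un-orthogonalized) activity modes.

    Trial-type-selective modes need error trials; if a definition set has
    fewer than ``min_error_trials`` of either error type, an error lists the
    modes that would be undefined.  A raw mode with (near-)zero norm is
    flagged degenerate rather than rejected; orthogonalization will refuse it.
    """
    ep = session.epochs
    for cond in ("CR", "CL"):
        if not definition_trials.get(cond):
            raise ValueError(f"no correct {cond} definition trials")
    short = [
        c for c in ("ER", "EL") if len(definition_trials.get(c, [])) < min_error_trials
    ]
    if short:
        raise ValueError(
            f"insufficient error trials ({short}): stimulus, choice and outcome "
            f"modes undefined"
        )

    def mean_rates(window: tuple[float, float], conds: tuple[str, ...]) -> dict[str, np.ndarray]:
        return {
            c: _epoch_mean_rate(session, unit_ids, definition_trials[c], window)
            for c in conds
        }

    all4 = ("CR", "CL", "ER", "EL")
    r_sample = mean_rates(ep.sample, all4)
    r_delay = mean_rates(ep.delay, all4)
    r_resp = mean_rates(ep.response, all4)
    stim = selectivity_vectors(r_sample).stimulus
    choice = selectivity_vectors(r_delay).choice
    outcome = selectivity_vectors(r_resp).outcome

    r_action = mean_rates((0.1, 0.3), ("CR", "CL"))
    action = r_action["CR"] - r_action["CL"]

    correct = definition_trials["CR"] + definition_trials["CL"]
    r_pre = _epoch_mean_rate(session, unit_ids, correct, ep.presample)
    r_late_delay = _epoch_mean_rate(session, unit_ids, correct, (-0.5, 0.0))
    ramping = r_late_delay - r_pre
    r_before_go = _epoch_mean_rate(session, unit_ids, correct, (-0.1, 0.0))
    r_after_go = _epoch_mean_rate(session, unit_ids, correct, (0.0, 0.1))
    go = r_after_go - r_before_go

    response = _response_mode(session, unit_ids, definition_trials, ep)

    raw = {
        "stimulus": stim,
        "choice": choice,
        "action": action,
        "outcome": outcome,
        "ramping": ramping,
        "go": go,
        "response": response,
    }
    degenerate = {}
    W = np.zeros((len(unit_ids), len(MODE_ORDER)))
    for j, name in enumerate(MODE_ORDER):
        v = raw[name]
        nv = np.linalg.norm(v)
        degenerate[name] = bool(nv < 1e-10)
        W[:, j] = v if degenerate[name] else v / nv
        if degenerate[name]:
            warnings.warn(f"mode {name!r} is degenerate (zero norm)", stacklevel=2)
    return ModeSet(
        weights=W,
        unit_ids=list(unit_ids),
        orthogonalized=False,
        definition_trial_ids={c: [t.trial_id for t in ts] for c, ts in definition_trials.items()},
        degenerate=degenerate,
    )


def _response_mode(
    session: TrialAlignedSession,
    unit_ids: list[str],
    definition_trials: dict[str, list[Trial]],
    ep: EpochWindows,
    dt_ms: float = 10.0,
) -> np.ndarray:
    """Top singular vector of the baseline-subtracted concatenated PSTHs."""
    edges = _grid(ep, dt_ms / 1000.0)
    centers = edges[:-1] + dt_ms / 2000.0
    pre = (centers >= ep.presample[0]) & (centers < ep.presample[1])
    segs = []
    for cond in ("CR", "CL"):
        raw = _raw_rate_matrix(session, unit_ids, definition_trials[cond], edges)
        raw = uniform_filter1d(raw, 10, axis=1, mode="nearest")
        segs.append(raw - raw[:, pre].mean(axis=1, keepdims=True))
    R = np.concatenate(segs, axis=1)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    mode = U[:, 0]
    # orient so mean response-epoch activity projects positively
    resp = np.concatenate([(centers >= 0.0) & (centers < ep.response[1])] * 2)
    if (mode @ R[:, resp]).mean() < 0:
        mode = -mode
    return mode


def orthogonalize(modeset: ModeSet, order: tuple[str, ...] = MODE_ORDER) -> ModeSet:
    """Gram-Schmidt orthogonalization in the declared order.

    Output columns stay in canonical order; each mode is unit norm and the
    Gram matrix is the identity to 1e-9.  A mode whose residual after
    projection is near zero is collinear with earlier modes and raises.
    """
    W = modeset.weights.copy().astype(float)
    basis: list[np.ndarray] = []
    out = np.zeros_like(W)
    for name in order:
        j = modeset.names.index(name)
        v = W[:, j].copy()
        for b in basis:
            v -= (b @ W[:, j]) * b
        nv = np.linalg.norm(v)
        if nv < 1e-8:
            raise ValueError(f"mode {name!r} is collinear with preceding modes")
        v /= nv
        basis.append(v)
        out[:, j] = v
    return ModeSet(
        weights=out,
        unit_ids=modeset.unit_ids,
        orthogonalized=True,
        definition_trial_ids=modeset.definition_trial_ids,
        degenerate=modeset.degenerate,
        names=modeset.names,
    )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

@dataclass
class ModeProjection:
    """Mode^T rbar(t) per trial group, with neuron-bootstrap standard errors."""

    time_s: np.ndarray
    values: dict[str, dict[str, np.ndarray]]  # mode -> group -> (n_times,)
    se: dict[str, dict[str, np.ndarray]]
    mode_names: tuple[str, ...]
    groups: tuple[str, ...]


def project(
    modeset: ModeSet,
    session: TrialAlignedSession,
    trial_groups: dict[str, list[Trial]],
    window_ms: float = 100.0,
    step_ms: float = 10.0,
    bootstrap_n: int = 1000,
    seed: int = 0,
    align: str = "go",
) -> ModeProjection:
    """Project trial-group-averaged activity onto each mode over time.

    ``align='first_lick'`` re-references each trial's spikes to its first-lick
    time (go-cue time plus reaction time) before averaging.  Standard errors
    are the s.d. of projections over ``bootstrap_n`` resamples of neurons.
    Empty groups are omitted with a warning.
    """
    unit_ids = modeset.unit_ids
    dt = step_ms / 1000.0
    edges = _grid(session.epochs, dt)
    centers = edges[:-1] + dt / 2
    width = max(1, int(round(window_ms / step_ms)))
    rng = np.random.default_rng(seed)
    n = len(unit_ids)
    boot_counts = rng.multinomial(n, np.full(n, 1.0 / n), size=bootstrap_n) if bootstrap_n else None

    values: dict[str, dict[str, np.ndarray]] = {m: {} for m in modeset.names}
    se: dict[str, dict[str, np.ndarray]] = {m: {} for m in modeset.names}
    kept_groups = []
    for gname, trials in trial_groups.items():
        if not trials:
            warnings.warn(f"trial group {gname!r} is empty; omitted", stacklevel=2)
            continue
        kept_groups.append(gname)
        if align == "first_lick":
            A = _aligned_rate_matrix(session, unit_ids, trials, edges)
        else:
            A = _raw_rate_matrix(session, unit_ids, trials, edges)
        A = uniform_filter1d(A, width, axis=1, mode="nearest")
        for j, m in enumerate(modeset.names):
            w = modeset.weights[:, j]
            P = w[:, None] * A
            values[m][gname] = P.sum(axis=0)
            if boot_counts is not None:
                se[m][gname] = (boot_counts @ P).std(axis=0)
            else:
                se[m][gname] = np.zeros(A.shape[1])
    return ModeProjection(
        time_s=centers, values=values, se=se,
        mode_names=modeset.names, groups=tuple(kept_groups),
    )


def _aligned_rate_matrix(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials: list[Trial],
    edges: np.ndarray,
) -> np.ndarray:
    """Trial-averaged rates with each trial re-aligned to its first lick."""
    n_bins = edges.size - 1
    dt = edges[1] - edges[0]
    acc = np.zeros((len(unit_ids), n_bins))
    for tr in trials:
        shift = (tr.reaction_time_ms or 0.0) / 1000.0
        for i, uid in enumerate(unit_ids):
            st = session.spike_times(uid, tr.trial_id) - shift
            st = st[(st >= edges[0]) & (st < edges[-1])]
            if st.size:
                bins = np.minimum(((st - edges[0]) / dt).astype(int), n_bins - 1)
                np.add.at(acc[i], bins, 1.0)
    return acc / (len(trials) * dt)


def session_offset_project(
    per_session: list[tuple[TrialAlignedSession, ModeSet, dict[str, list[Trial]], dict[str, list[Trial]]]],
    min_units: int = 10,
    min_trials: int = 10,
    **project_kwargs,
) -> ModeProjection:
    """Pool projections across simultaneously recorded sessions.

    Each entry is (session, modeset, definition_groups, projection_groups).
    Sessions with fewer than ``min_units`` units or ``min_trials`` trials per
    group are skipped.  Each session's projections are offset by the global
    mean of its *definition-trial* projections across trials, groups and time
    (removing session-to-session rate offsets without touching the projection
    trials), then averaged across sessions.
    """
    pooled: list[ModeProjection] = []
    for sess, modeset, def_groups, proj_groups in per_session:
        if len(modeset.unit_ids) < min_units:
            continue
        if any(len(ts) < min_trials for ts in proj_groups.values()):
            continue
        ref = project(modeset, sess, def_groups, bootstrap_n=0, **project_kwargs)
        prj = project(modeset, sess, proj_groups, **project_kwargs)
        for m in prj.mode_names:
            offset = float(np.mean([ref.values[m][g] for g in ref.groups]))
            for g in prj.values[m]:
                prj.values[m][g] = prj.values[m][g] - offset
        pooled.append(prj)
    if not pooled:
        raise ValueError("no session qualifies for pooled projection")
    out = pooled[0]
    groups = out.groups
    values = {
        m: {g: np.mean([p.values[m][g] for p in pooled], axis=0) for g in groups}
        for m in out.mode_names
    }
    se = {
        m: {
            g: np.sqrt(np.mean([p.se[m][g] ** 2 for p in pooled], axis=0) / len(pooled))
            for g in groups
        }
        for m in out.mode_names
    }
    return ModeProjection(
        time_s=out.time_s, values=values, se=se, mode_names=out.mode_names, groups=groups
    )


# ---------------------------------------------------------------------------
# variance / selectivity captured
# ---------------------------------------------------------------------------

def variance_captured(
    modeset: ModeSet,
    activity: np.ndarray,
    selectivity: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Fraction of activity (and selectivity) energy in the 7-mode subspace.

    ``activity`` is the (n_units, n_times) baseline-subtracted population
    activity restricted to the epochs of interest; ``selectivity`` optionally
    maps names to (n_units, n_times) selectivity-vector series.  Fractions are
    ratios of sums of squares; the modes must be orthogonalized.
    """
    if not modeset.orthogonalized:
        raise ValueError("variance_captured requires orthogonalized modes")
    W = modeset.weights
    out = {}
    tot = float(np.sum(activity**2))
    cap = float(np.sum((W.T @ activity) ** 2))
    out["activity"] = cap / tot if tot > 0 else np.nan
    if selectivity:
        for name, S in selectivity.items():
            tot = float(np.sum(S**2))
            out[name] = float(np.sum((W.T @ S) ** 2)) / tot if tot > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# random-mixture synthetic population
# ---------------------------------------------------------------------------

@dataclass
class MixturePopulation:
    """Synthetic rows built from random combinations of modes + eigenvectors."""

    rows: np.ndarray  # (n_units, n_times)
    mode_weights: np.ndarray  # (n_units, 7) random weights on the mode components
    all_weights: np.ndarray  # (n_units, n_components)
    component_timecourses: np.ndarray  # (n_components, n_times)
    component_energy: np.ndarray  # original per-component energy


def synthesize_mixture_population(
    modeset: ModeSet,
    matrix: PSTHMatrix,
    seed: int = 0,
    n_components: int | None = None,
) -> MixturePopulation:
    """Build a population coding random mixtures of the activity modes.

    The component basis is the seven orthogonalized modes followed by the SVD
    eigenvectors of the response matrix Gram-Schmidt-orthogonalized against
    them.  Each synthetic neuron is a random zero-mean-normal combination of
    the component time courses, with per-component variance scaled so every
    component carries the same energy as in the original population; the
    population-level modes are preserved while per-neuron weights are
    scrambled.  ``mode_weights`` are the i.i.d. weights on the seven mode
    components (identical to what least-squares recovery from the rows gives,
    since the time courses span the rows by construction).
    """
    if modeset.unit_ids != matrix.unit_ids:
        raise ValueError("modeset and matrix must cover the same units, same order")
    if not modeset.orthogonalized:
        raise ValueError("requires orthogonalized modes")
    R = matrix.matrix
    n, T = R.shape
    W = modeset.weights  # (n, 7) orthonormal columns
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    rank = int((S > 1e-12 * S[0]).sum())
    basis = [W[:, j] for j in range(W.shape[1])]
    for j in range(rank):
        v = U[:, j].copy()
        for b in basis:
            v -= (b @ U[:, j]) * b
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            basis.append(v / nv)
    B = np.stack(basis, axis=1)  # (n, C) orthonormal
    C = B.shape[1]
    if n_components is not None and n_components < C:
        B = B[:, :n_components]
        C = n_components
    elif n_components is not None and n_components > C:
        warnings.warn(
            f"requested {n_components} components but rank allows {C}; truncated",
            stacklevel=2,
        )
    A = B.T @ R  # component time courses; energy of comp c = ||A[c]||^2
    rng = np.random.default_rng(seed)
    weights = rng.standard_normal((n, C)) / np.sqrt(n)
    rows = weights @ A
    return MixturePopulation(
        rows=rows,
        mode_weights=weights[:, : W.shape[1]],
        all_weights=weights,
        component_timecourses=A,
        component_energy=np.sum(A**2, axis=1),
    )
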