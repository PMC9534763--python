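"""PSTH computation, consistency filtering and the population response matrix.

The response matrix is the substrate of the landscape analyses: one row per
unit, the correct-trial lick-right and lick-left PSTHs concatenated, each
segment baseline-subtracted (mean over the 500-ms presample window) and the
concatenated row divided by its Euclidean norm.  Rows with zero norm are
excluded and logged, as are units failing the split-half consistency filter
(Pearson r of split-half PSTHs below 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import resample_poly

from .session import CellClass, EpochWindows, Trial, TrialAlignedSession

__all__ = [
    "PSTH",
    "PSTHMatrix",
    "compute_psth",
    "split_half_consistency",
    "build_response_matrix",
    "resample_delay",
]

DEFAULT_DT_MS = 1.0
DEFAULT_KERNEL_MS = 100.0
CONSISTENCY_THRESHOLD = 0.5


@dataclass
class PSTH:
    unit_id: str
    condition: str
    time_s: np.ndarray
    rate: np.ndarray  # spikes/s
    n_trials: int


@dataclass
class PSTHMatrix:
    """n_units x (2 * n_bins) matrix of concatenated CR/CL response profiles."""

    matrix: np.ndarray
    unit_ids: list[str]
    time_s: np.ndarray  # per-segment time grid
    conditions: tuple[str, ...]
    delay_duration_s: float
    dt_s: float
    provenance: dict = field(default_factory=dict)
    filter_log: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.time_s.size

    def segment(self, i: int) -> np.ndarray:
        """View of condition segment i, shape (n_units, n_bins)."""
        return self.matrix[:, i * self.n_bins : (i + 1) * self.n_bins]

    @property
    def epochs(self) -> EpochWindows:
        return EpochWindows(self.delay_duration_s)


# ---------------------------------------------------------------------------
# PSTH computation
# ---------------------------------------------------------------------------

def _causal_boxcar(raw: np.ndarray, width_bins: int) -> np.ndarray:
    """Causal moving average along the last axis, edge-normalized."""
    k = np.ones(width_bins)
    num = np.apply_along_axis(lambda r: np.convolve(r, k, mode="full")[: r.size], -1, raw)
    den = np.convolve(np.ones(raw.shape[-1]), k, mode="full")[: raw.shape[-1]]
    return num / den


def _gaussian(raw: np.ndarray, sigma_bins: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(raw, sigma_bins, axis=-1, mode="nearest")


def _smooth(raw: np.ndarray, kernel: str, width_bins: int) -> np.ndarray:
    if kernel == "boxcar":
        return _causal_boxcar(raw, width_bins)
    if kernel == "gaussian":
        return _gaussian(raw, width_bins / 4.0)
    raise ValueError(f"unknown kernel {kernel!r}")


def _raw_rate_matrix(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials: list[Trial],
    edges: np.ndarray,
) -> np.ndarray:
    """Trial-averaged un-smoothed rate (Hz), shape (n_units, n_bins)."""
    n_bins = edges.size - 1
    dt = edges[1] - edges[0]
    uidx = {uid: i for i, uid in enumerate(unit_ids)}
    acc = np.zeros(len(unit_ids) * n_bins)
    t0, t1 = edges[0], edges[-1]
    for tr in trials:
        for uid in unit_ids:
            st = session.spike_times(uid, tr.trial_id)
            if st.size == 0:
                continue
            st = st[(st >= t0) & (st < t1)]
            if st.size == 0:
                continue
            bins = np.minimum(((st - t0) / dt).astype(int), n_bins - 1)
            np.add.at(acc, uidx[uid] * n_bins + bins, 1.0)
    rate = acc.reshape(len(unit_ids), n_bins) / (len(trials) * dt)
    return rate


def _grid(epochs: EpochWindows, dt_s: float) -> np.ndarray:
    t_lo, t_hi = epochs.trial_window
    n = int(round((t_hi - t_lo) / dt_s))
    return t_lo + np.arange(n + 1) * dt_s


def compute_psth(
    session: TrialAlignedSession,
    unit_id: str,
    condition: str | tuple[str, ...],
    kernel: str = "boxcar",
    kernel_width_ms: float = DEFAULT_KERNEL_MS,
    dt_ms: float = DEFAULT_DT_MS,
    trials: list[Trial] | None = None,
) -> PSTH:
    """Trial-averaged smoothed spike rate of one unit on the common grid.

    The default kernel is a 100-ms causal boxcar: the rate at time t averages
    spikes in [t - 100 ms, t], matching the 100-ms analysis windows used by the
    windowed analyses.
    """
    conditions = (condition,) if isinstance(condition, str) else tuple(condition)
    if trials is None:
        trials = session.trials_of(*conditions)
    if not trials:
        raise ValueError(f"no trials of condition {conditions!r}")
    epochs = session.epochs
    dt = dt_ms / 1000.0
    edges = _grid(epochs, dt)
    raw = _raw_rate_matrix(session, [unit_id], trials, edges)[0]
    width_bins = max(1, int(round(kernel_width_ms / dt_ms)))
    rate = _smooth(raw[None, :], kernel, width_bins)[0]
    centers = edges[:-1] + dt / 2
    return PSTH(unit_id=unit_id, condition="+".join(conditions), time_s=centers, rate=rate, n_trials=len(trials))


# ---------------------------------------------------------------------------
# consistency filter
# ---------------------------------------------------------------------------

def split_half_consistency(
    session: TrialAlignedSession,
    unit_id: str,
    conditions: tuple[str, ...] = ("CR", "CL"),
    threshold: float = CONSISTENCY_THRESHOLD,
    dt_ms: float = 10.0,
    kernel_width_ms: float = DEFAULT_KERNEL_MS,
) -> tuple[float, bool, str]:
    """Split-half PSTH reliability of one unit.

    Trials of each condition are split into interleaved (odd/even) halves, the
    concatenated condition PSTHs are computed for each half, and the Pearson
    correlation between halves is returned together with an inclusive pass
    flag at the 0.5 threshold.  A constant (zero-variance) half makes the
    correlation undefined and fails the unit with a reason.
    """
    epochs = session.epochs
    dt = dt_ms / 1000.0
    edges = _grid(epochs, dt)
    width_bins = max(1, int(round(kernel_width_ms / dt_ms)))
    halves: list[list[np.ndarray]] = [[], []]
    for cond in conditions:
        trials = session.trials_of(cond)
        if len(trials) < 2:
            return np.nan, False, f"fewer than 2 trials of {cond}"
        a, b = trials[0::2], trials[1::2]
        for h, sub in enumerate((a, b)):
            raw = _raw_rate_matrix(session, [unit_id], sub, edges)[0]
            halves[h].append(_smooth(raw[None, :], "boxcar", width_bins)[0])
    x = np.concatenate(halves[0])
    y = np.concatenate(halves[1])
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, False, "zero-variance PSTH"
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r >= threshold, "" if r >= threshold else f"consistency {r:.3f} < {threshold}"


# ---------------------------------------------------------------------------
# response matrix
# ---------------------------------------------------------------------------

def build_response_matrix(
    session: TrialAlignedSession,
    unit_ids: list[str] | None = None,
    conditions: tuple[str, str] = ("CR", "CL"),
    cell_classes: tuple[CellClass, ...] = (CellClass.PYRAMIDAL,),
    consistency_threshold: float | None = CONSISTENCY_THRESHOLD,
    kernel: str = "boxcar",
    kernel_width_ms: float = DEFAULT_KERNEL_MS,
    dt_ms: float = DEFAULT_DT_MS,
) -> PSTHMatrix:
    """Assemble the baseline-subtracted, norm-normalized response matrix.

    Rows are concatenated correct-trial PSTHs (lick-right then lick-left); each
    condition segment has its presample mean subtracted and the concatenated
    row is divided by its norm.  Every exclusion (cell class, consistency,
    zero norm) is recorded in ``filter_log`` with a reason.
    """
    if unit_ids is None:
        unit_ids = session.unit_ids
    epochs = session.epochs
    dt = dt_ms / 1000.0
    edges = _grid(epochs, dt)
    centers = edges[:-1] + dt / 2
    width_bins = max(1, int(round(kernel_width_ms / dt_ms)))
    log: list[tuple[str, str]] = []

    kept: list[str] = []
    for uid in unit_ids:
        u = session.unit(uid)
        if cell_classes and u.cell_class not in cell_classes:
            log.append((uid, f"cell class {u.cell_class.value}"))
            continue
        if consistency_threshold is not None:
            r, ok, reason = split_half_consistency(
                session, uid, conditions, threshold=consistency_threshold
            )
            if not ok:
                log.append((uid, reason))
                continue
        kept.append(uid)

    segments = []
    pres_lo, pres_hi = epochs.presample
    pres_mask = (centers >= pres_lo) & (centers < pres_hi)
    for cond in conditions:
        trials = session.trials_of(cond)
        raw = _raw_rate_matrix(session, kept, trials, edges)
        sm = _smooth(raw, kernel, width_bins)
        sm = sm - sm[:, pres_mask].mean(axis=1, keepdims=True)
        segments.append(sm)
    mat = np.concatenate(segments, axis=1)

    norms = np.linalg.norm(mat, axis=1)
    zero = norms < 1e-12
    for uid in np.array(kept)[zero]:
        log.append((str(uid), "zero norm"))
    keep = ~zero
    mat = mat[keep] / norms[keep, None]
    kept = [uid for uid, k in zip(kept, keep) if k]
    if len(kept) < 2:
        raise ValueError("fewer than 2 units survive the response-matrix filters")
    return PSTHMatrix(
        matrix=mat,
        unit_ids=kept,
        time_s=centers,
        conditions=conditions,
        delay_duration_s=session.delay_duration_s,
        dt_s=dt,
        provenance={
            "kernel": kernel,
            "kernel_width_ms": kernel_width_ms,
            "dt_ms": dt_ms,
            "consistency_threshold": consistency_threshold,
            "source": session.name,
        },
        filter_log=log,
    )


def resample_delay(
    matrix: PSTHMatrix, from_delay: float = 1.7, to_delay: float = 1.3
) -> PSTHMatrix:
    """Resample the delay-epoch segment of a long-delay matrix to a shorter
    delay grid (polyphase, linear-extension padding); other epochs are kept
    and rows are re-normalized."""
    if abs(matrix.delay_duration_s - from_delay) > 1e-9:
        raise ValueError(
            f"matrix delay is {matrix.delay_duration_s}, expected {from_delay}"
        )
    src = matrix.epochs
    dst = EpochWindows(to_delay)
    t = matrix.time_s
    dt = matrix.dt_s
    pre = t < src.delay_start
    dly = (t >= src.delay_start) & (t < 0)
    post = t >= 0
    n_to = int(round(to_delay / dt))
    up, down = n_to, int(dly.sum())
    g = np.gcd(up, down)
    segs_out = []
    for i in range(len(matrix.conditions)):
        seg = matrix.segment(i)
        d = resample_poly(seg[:, dly], up // g, down // g, axis=1, padtype="line")
        segs_out.append(np.concatenate([seg[:, pre], d, seg[:, post]], axis=1))
    mat = np.concatenate(segs_out, axis=1)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    mat = mat / norms
    t_new = dst.trial_window[0] + (np.arange(mat.shape[1] // len(matrix.conditions)) + 0.5) * dt
    return replace(
        matrix,
        matrix=mat,
        time_s=t_new,
        delay_duration_s=to_delay,
        provenance={**matrix.provenance, "resampled_from_delay": from_delay},
    )
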