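"""Spike binning helpers shared across the analysis modules."""

from __future__ import annotations

import numpy as np

from .session import Trial, TrialAlignedSession

__all__ = ["bin_counts", "window_counts", "trial_tensor"]


def bin_counts(spike_times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Spike counts per bin for one spike train (edges define len(edges)-1 bins)."""
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts


def trial_tensor(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials: list[Trial],
    edges: np.ndarray,
) -> np.ndarray:
    """Spike-count tensor (n_units, n_trials, n_bins) on shared bin edges."""
    out = np.zeros((len(unit_ids), len(trials), len(edges) - 1), dtype=np.int32)
    for i, uid in enumerate(unit_ids):
        for j, tr in enumerate(trials):
            st = session.spike_times(uid, tr.trial_id)
            if st.size:
                out[i, j] = np.histogram(st, bins=edges)[0]
    return out


def window_counts(
    session: TrialAlignedSession,
    unit_ids: list[str],
    trials: list[Trial],
    window: tuple[float, float],
) -> np.ndarray:
    """Spike counts in a single time window, shape (n_units, n_trials)."""
    lo, hi = window
    out = np.zeros((len(unit_ids), len(trials)))
    for i, uid in enumerate(unit_ids):
        for j, tr in enumerate(trials):
            st = session.spike_times(uid, tr.trial_id)
            if st.size:
                out[i, j] = np.searchsorted(st, hi) - np.searchsorted(st, lo)
    return out
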